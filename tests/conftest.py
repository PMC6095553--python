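import numpy as np
import pytest

from mitocomp.synthetic import GenomeBlueprint, RepeatSpec, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def repeat_only_sim():
    """60 kb genome with six planted repeats and nothing else."""
    specs = (
        RepeatSpec(2160, "DR"),
        RepeatSpec(446, "IR"),
        RepeatSpec(315, "DR"),
        RepeatSpec(232, "IR"),
        RepeatSpec(160, "DR"),
        RepeatSpec(127, "IR"),
    )
    return generate(
        GenomeBlueprint(
            seed=5, length=60_000, n_genes=0, n_trna=0, n_rrna=0,
            pseudogenes=(), repeats=specs,
        )
    )


@pytest.fixture(scope="session")
def full_sim():
    """80 kb genome with genes, one large repeat and the 25-fragment
    pseudogene complement."""
    return generate(GenomeBlueprint(seed=7, length=80_000, repeats=(RepeatSpec(2160, "DR"),)))
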