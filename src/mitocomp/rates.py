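"""Synonymous/nonsynonymous divergence (NG86) and absolute rates.

dS and dN are estimated by Nei–Gojobori (1986) counting: synonymous and
nonsynonymous *sites* are apportioned per codon from the fraction of
single-nucleotide neighbours that preserve the amino acid (neighbours
creating stop codons are excluded from the denominator, so every sense
codon contributes exactly three sites), *differences* between codon
pairs are averaged over all substitution orderings that avoid stop
codons, and the resulting proportions are corrected for multiple hits
with the Jukes–Cantor transform ``d = -3/4 ln(1 - 4/3 p)``.

Absolute rates per site per billion years follow by dividing a
divergence estimate by the age of the corresponding branch or split:
``R = d / (T_myr / 1000)``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def _neighbors(codon: str, pos: int) -> list[str]:
    return [codon[:pos] + b + codon[pos + 1 :] for b in _BASES if b != codon[pos]]


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Position ``i`` contributes ``syn_i / viable_i`` synonymous sites,
    where ``viable_i`` counts the non-stop single-nucleotide neighbours
    at that position. S + N = 3 for every sense codon.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    if codon not in _AA:
        raise ValueError(f"not a valid codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        viable = [n for n in _neighbors(codon, pos) if n not in STOP_CODONS]
        if not viable:
            continue
        syn = sum(_AA[n] == _AA[codon] for n in viable)
        s += syn / len(viable)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts for one codon pair.

    Averages over all substitution orderings between ``c1`` and ``c2``
    that never pass through a stop codon (equal weights). If every
    ordering hits a stop, all orderings are used as a fallback.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for perm in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        ok = True
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((ok, steps))
    valid = [steps for ok, steps in pathways if ok]
    if not valid:
        valid = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in valid:
        for cur, nxt in steps:
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                nd += 1  # fallback pathways only
            elif _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
    k = len(valid)
    return sd / k, nd / k


def _jc_correct(p: float) -> float:
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class RateEstimate:
    """Divergence and absolute-rate estimates for one sequence pair/branch."""

    pair_id: str
    dS: float
    dN: float
    S: float = math.nan
    N: float = math.nan
    Sd: float = math.nan
    Nd: float = math.nan
    n_codons: int = 0
    T_myr: float | None = None
    saturated: bool = False

    @property
    def omega(self) -> float:
        return self.dN / self.dS if self.dS else math.nan

    @property
    def R_S(self) -> float:
        """Absolute synonymous rate per site per billion years."""
        if self.T_myr is None:
            return math.nan
        return absolute_rate(self.dS, self.T_myr)

    @property
    def R_N(self) -> float:
        if self.T_myr is None:
            return math.nan
        return absolute_rate(self.dN, self.T_myr)


def _clean_codons(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    if len(a) % 3:
        raise ValueError("aligned length must be divisible by 3")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3].upper(), b[i : i + 3].upper()
        if any(ch not in _BASES for ch in ca + cb):
            continue  # gap- or N-containing codon: masked
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        pairs.append((ca, cb))
    return pairs


def ng86_pairwise(a: str, b: str, pair_id: str = "pair") -> RateEstimate:
    """NG86 dS/dN between two aligned, in-frame coding sequences.

    Gapped, ambiguous and stop codons are masked pairwise. Site counts
    are averaged between the two sequences; proportions are corrected
    with the Jukes–Cantor transform. Saturated proportions (p >= 3/4)
    yield NaN and set the ``saturated`` flag.
    """
    pairs = _clean_codons(a, b)
    if len(pairs) < 30:
        warnings.warn(f"only {len(pairs)} unmasked codons; NG86 estimates will be noisy")
    if not pairs:
        raise ValueError("no unmasked codon pairs to compare")
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        s1, n1 = ng86_site_counts(ca)
        s2, n2 = ng86_site_counts(cb)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    dS, dN = _jc_correct(pS), _jc_correct(pN)
    return RateEstimate(
        pair_id=pair_id,
        dS=dS,
        dN=dN,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        n_codons=len(pairs),
        saturated=math.isnan(dS) or math.isnan(dN),
    )


def absolute_rate(d: float, t_myr: float) -> float:
    """Substitutions per site per **billion** years from a branch age in Myr."""
    if t_myr <= 0:
        raise ValueError("branch age must be positive")
    return d / (t_myr / 1000.0)


def rates_table(
    alignment: Mapping[str, str],
    ages_myr: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """All-pairs NG86 estimates for a codon alignment, with optional ages.

    ``ages_myr`` maps unordered taxon pairs to divergence times in Myr;
    pairs with an age get absolute R_S/R_N columns filled in.
    """
    taxa = sorted(alignment)
    rows = []
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            est = ng86_pairwise(alignment[ta], alignment[tb], pair_id=f"{ta}|{tb}")
            t = None
            if ages_myr is not None:
                t = ages_myr.get((ta, tb), ages_myr.get((tb, ta)))
            if t is not None:
                est = RateEstimate(**{**est.__dict__, "T_myr": float(t)})
            rows.append(
                {
                    "taxon_a": ta,
                    "taxon_b": tb,
                    "n_codons": est.n_codons,
                    "dS": est.dS,
                    "dN": est.dN,
                    "omega": est.omega,
                    "T_myr": est.T_myr,
                    "R_S": est.R_S,
                    "R_N": est.R_N,
                    "saturated": est.saturated,
                }
            )
    return pd.DataFrame(rows)


def read_ages_tsv(path) -> dict[tuple[str, str], float]:
    """Ages TSV with columns taxon_a, taxon_b, age_myr."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r["taxon_a"]), str(r["taxon_b"])): float(r["age_myr"]) for _, r in df.iterrows()
    }
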