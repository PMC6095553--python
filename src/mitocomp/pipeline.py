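"""Stage orchestration: run the analyses and emit the report bundle.

Each stage writes one or two TSV reports whose header comments record
the tool version and the parameters used, so a bundle is reproducible
from its own files. Stages are individually optional: with an explicit
stage list, a missing input fails fast before any computation; without
one, every stage whose inputs are present runs and the rest are
skipped with a logged reason.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import pandas as pd

import mitocomp
from mitocomp import composition, gene_order, homology_scan, intron_scan, rates, recomb, repeat_finder
from mitocomp.seqio import read_fasta, read_gff3, read_reads, revcomp, write_fasta, write_gff3
from mitocomp import synthetic

log = logging.getLogger("mitocomp")

ALL_STAGES = ("repeats", "compose", "pseudo", "share", "order", "introns", "rates", "recomb")


class InputError(ValueError):
    """A requested stage is missing an input."""


def write_tsv(df: pd.DataFrame, path: Path, params: dict[str, Any]) -> None:
    """TSV with '#'-prefixed header lines recording version and parameters."""
    with open(path, "w") as fh:
        fh.write(f"# mitocomp {mitocomp.__version__}\n")
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: dict, outdir: Path) -> dict[str, Any]:
    inputs: dict[str, Any] = {}
    if "synthetic" in config:
        syn_cfg = dict(config["synthetic"])
        syn_seed = syn_cfg.pop("seed", None)
        seed = int(config.get("seed", 0 if syn_seed is None else syn_seed))
        blueprint = synthetic.GenomeBlueprint(seed=seed, **syn_cfg)
        sim = synthetic.generate(blueprint)
        inputs["genome"] = sim.genome
        inputs["annotation"] = sim.annotation
        inputs["gene_seqs"] = sim.gene_sequences()
        inputs["truth"] = sim.truth
        write_fasta([sim.genome], outdir / "genome.fasta")
        write_gff3(sim.annotation, outdir / "annotation.gff3")
        sim.truth.to_json(outdir / "truth.json")
        # derived companions so every stage has an input
        derived, dtruth = synthetic.derive_pair(
            sim.genome,
            synthetic.DivergenceSpec(insertion_lengths=(10_000,)),
            seed=seed + 1,
        )
        inputs["genome_b"] = derived
        largest = max(sim.truth.repeat_pairs(), key=lambda r: r.size, default=None)
        if largest is not None:
            reads, rtruth = synthetic.simulate_reads(
                sim.genome,
                synthetic.ReadSpec(
                    mean_len=8_000, sd_len=1_000, coverage=12.0, recombined_fraction=1 / 3
                ),
                repeat=largest,
                seed=seed + 2,
            )
            inputs["reads"] = reads
            inputs["recomb_repeat"] = largest
        aln, _ = synthetic.make_intron_alignment(seed=seed + 3)
        inputs["alignments"] = {"ccmFci829_like": aln}
        a, b = synthetic.simulate_codon_pair(2_000, 0.3, 0.03, seed=seed + 4)
        inputs["coding_alignment"] = {"taxon_a": a, "taxon_b": b}
        inputs["ages"] = {("taxon_a", "taxon_b"): 50.0}
        anc = synthetic.random_gene_order(30, seed=seed + 5, genome_id="anc")
        der1, _ = synthetic.evolve_by_inversions(anc, 3, seed=seed + 6, derived_id="der3")
        der2, _ = synthetic.evolve_by_inversions(anc, 4, seed=seed + 7, derived_id="der4")
        inputs["orders"] = [anc, der1, der2]
    if "genome" in config:
        inputs["genome"] = read_fasta(config["genome"], circular=True)[0]
    if "genome_b" in config:
        inputs["genome_b"] = read_fasta(config["genome_b"], circular=True)[0]
    if "annotation" in config:
        length = len(inputs["genome"]) if "genome" in inputs else None
        inputs["annotation"] = read_gff3(config["annotation"], length=length)
    if "reads" in config:
        inputs["reads"] = read_reads(config["reads"])
    if "alignments" in config:
        inputs["alignments"] = {
            Path(p).stem: intron_scan.read_alignment_fasta(p) for p in config["alignments"]
        }
    if "coding_alignment" in config:
        inputs["coding_alignment"] = intron_scan.read_alignment_fasta(config["coding_alignment"])
    if "ages" in config:
        inputs["ages"] = rates.read_ages_tsv(config["ages"])
    if "orders" in config:
        inputs["orders"] = gene_order.read_gene_orders(config["orders"])
    if "gene_seqs" not in inputs and "annotation" in inputs and "genome" in inputs:
        genome, ann = inputs["genome"], inputs["annotation"]
        inputs["gene_seqs"] = {
            f.gene: (
                genome.seq[f.start : f.end]
                if f.strand == "+"
                else revcomp(genome.seq[f.start : f.end])
            )
            for f in ann.genes()
        }
    return inputs


_REQUIRES = {
    "repeats": ("genome",),
    "compose": ("genome", "annotation"),
    "pseudo": ("genome", "annotation", "gene_seqs"),
    "share": ("genome", "genome_b"),
    "order": ("orders",),
    "introns": ("alignments",),
    "rates": ("coding_alignment",),
    "recomb": ("genome", "reads"),
}


def run_pipeline(config: dict, outdir: str | Path) -> dict[str, Any]:
    """Run the requested stages; return per-stage result objects.

    ``config`` maps input names to paths (or a ``synthetic`` profile)
    plus an optional ``stages`` list; see the package README.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config, outdir)
    explicit = config.get("stages")
    stages = tuple(explicit) if explicit else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise InputError(f"unknown stages: {sorted(unknown)}")
    if explicit:
        for st in stages:
            missing = [r for r in _REQUIRES[st] if r not in inputs]
            if missing:
                raise InputError(f"stage {st!r} requires missing inputs: {missing}")

    results: dict[str, Any] = {}
    for st in stages:
        missing = [r for r in _REQUIRES[st] if r not in inputs]
        if missing:
            log.info("skipping stage %s: missing inputs %s", st, missing)
            continue
        log.info("running stage %s", st)
        results[st] = _STAGE_FUNCS[st](inputs, outdir, config)
    return results


def _stage_repeats(inputs, outdir, config):
    genome = inputs["genome"]
    user = config.get("repeats", {})
    params = {
        "min_len": int(user.get("min_len", 20)),
        "min_identity": float(user.get("min_identity", 0.80)),
        "k": int(user.get("k", 12)),
    }
    reps = repeat_finder.find_repeats(genome, **params)
    summary = repeat_finder.summarize_repeats(reps, len(genome))
    write_tsv(repeat_finder.repeats_to_table(reps, len(genome)), outdir / "repeats.tsv", params)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "genome": genome.id,
                    "pairs": summary.total_pairs,
                    "small": summary.n_small,
                    "medium": summary.n_medium,
                    "large": summary.n_large,
                    "repeat_bp": summary.total_bp,
                    "fraction": round(summary.fraction, 4),
                }
            ]
        ),
        outdir / "repeats_summary.tsv",
        params,
    )
    write_tsv(
        repeat_finder.circos_links(reps, genome.id, len(genome)), outdir / "repeat_links.tsv", {}
    )
    log.info("repeats: %d pairs, %d bp", summary.total_pairs, summary.total_bp)
    return reps, summary


def _stage_compose(inputs, outdir, config):
    genome, ann = inputs["genome"], inputs["annotation"]
    report = composition.partition_genome(len(genome), ann, sequence=genome)
    write_tsv(composition.composition_table([report]), outdir / "composition.tsv", {})
    log.info(
        "composition: coding %.1f%%, intron %.1f%%, intergenic %.1f%%",
        report.coding_percent,
        report.intron_percent,
        report.intergenic_percent,
    )
    return report


def _stage_pseudo(inputs, outdir, config):
    params = config.get("pseudo", {})
    hits = homology_scan.scan_pseudogenes(
        inputs["genome"],
        inputs["annotation"],
        inputs["gene_seqs"],
        min_len=int(params.get("min_len", 28)),
        min_identity=float(params.get("min_identity", 0.92)),
    )
    truth = inputs.get("truth")
    if truth is not None and truth.repeats:
        hits = homology_scan.flag_repeat_association(
            hits, truth.repeat_pairs(), len(inputs["genome"])
        )
    write_tsv(homology_scan.pseudogenes_table(hits), outdir / "pseudogenes.tsv", params)
    log.info("pseudogene fragments: %d", len(hits))
    return hits


def _stage_share(inputs, outdir, config):
    params = config.get("share", {})
    rep = homology_scan.shared_content(
        inputs["genome"],
        inputs["genome_b"],
        min_len=int(params.get("min_len", 100)),
        min_identity=float(params.get("min_identity", 0.70)),
    )
    df = pd.DataFrame(
        [
            {
                "genome_a": rep.id_a,
                "genome_b": rep.id_b,
                "shared_bp_a": rep.shared_bp_a,
                "shared_bp_b": rep.shared_bp_b,
                "fraction_a": round(rep.fraction_a, 4),
                "fraction_b": round(rep.fraction_b, 4),
            }
        ]
    )
    write_tsv(df, outdir / "sharing.tsv", {"min_len": rep.min_len, "min_identity": rep.min_identity})
    log.info("sharing: %d bp on %s (%.1f%%)", rep.shared_bp_a, rep.id_a, 100 * rep.fraction_a)
    return rep


def _stage_order(inputs, outdir, config):
    mat = gene_order.pairwise_matrix(inputs["orders"])
    mat.to_csv(outdir / "rearrangements.tsv", sep="\t")
    write_tsv(gene_order.matrix_long_format(mat), outdir / "rearrangements_long.tsv", {})
    log.info("gene order: %d genomes, max distance %d", len(mat), int(mat.values.max()))
    return mat


def _stage_introns(inputs, outdir, config):
    params = config.get("introns", {})
    alignments = inputs["alignments"]
    table = intron_scan.intron_length_table(alignments)
    table.to_csv(outdir / "intron_lengths.tsv", sep="\t")
    all_blocks = []
    all_edges = []
    for aln_id, aln in alignments.items():
        blocks = intron_scan.find_deletion_blocks(
            aln,
            min_del=int(params.get("min_del", 50)),
            merge_gap=int(params.get("merge_gap", 10)),
            alignment_id=aln_id,
        )
        all_blocks.extend(blocks)
        for b in blocks:
            retainer = next(
                (t for t in aln if t not in b.affected_taxa), None
            )
            if retainer is None:
                continue
            hits = intron_scan.edge_repeat_search(
                aln[retainer],
                b,
                min_rep=int(params.get("min_rep", 10)),
                window=int(params.get("window", 5)),
            )
            edf = intron_scan.edge_repeats_table(hits)
            edf.insert(0, "alignment", aln_id)
            edf.insert(1, "taxon", b.taxon)
            all_edges.append(edf)
    write_tsv(intron_scan.deletion_blocks_table(all_blocks), outdir / "deletion_blocks.tsv", params)
    edges = pd.concat(all_edges, ignore_index=True) if all_edges else pd.DataFrame()
    write_tsv(edges, outdir / "edge_repeats.tsv", params)
    log.info("introns: %d deletion blocks, %d edge-repeat hits", len(all_blocks), len(edges))
    return all_blocks, edges


def _stage_rates(inputs, outdir, config):
    table = rates.rates_table(inputs["coding_alignment"], inputs.get("ages"))
    write_tsv(table, outdir / "rates.tsv", {})
    log.info("rates: %d pairs", len(table))
    return table


def _stage_recomb(inputs, outdir, config):
    params = config.get("recomb", {})
    repeat = inputs.get("recomb_repeat")
    if repeat is None:
        reps = repeat_finder.find_repeats(inputs["genome"])
        if not reps:
            log.info("recomb: no repeats found; nothing to survey")
            return None
        repeat = max(reps, key=lambda r: r.size)
    summary, calls = recomb.survey_repeat(
        inputs["reads"],
        inputs["genome"],
        repeat,
        min_flank=int(params.get("min_flank", 500)),
    )
    write_tsv(recomb.spanning_reads_table(calls), outdir / "spanning_reads.tsv", params)
    lo, hi = summary.wilson95
    df = pd.DataFrame(
        [
            {
                "repeat_size": repeat.size,
                "spanning": summary.n_spanning,
                "parental": summary.n_parental,
                "recombined": summary.n_recombined,
                "uninformative": summary.n_uninformative,
                "fraction": round(summary.fraction, 4) if summary.n_spanning else "",
                "wilson95_lo": round(lo, 4),
                "wilson95_hi": round(hi, 4),
            }
        ]
    )
    write_tsv(df, outdir / "recombination.tsv", params)
    log.info(
        "recomb: %d/%d spanning reads recombined", summary.n_recombined, summary.n_spanning
    )
    return summary, calls


_STAGE_FUNCS = {
    "repeats": _stage_repeats,
    "compose": _stage_compose,
    "pseudo": _stage_pseudo,
    "share": _stage_share,
    "order": _stage_order,
    "introns": _stage_introns,
    "rates": _stage_rates,
    "recomb": _stage_recomb,
}
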