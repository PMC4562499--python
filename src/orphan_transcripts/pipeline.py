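"""End-to-end orchestration: simulate -> screen -> assemble -> join ->
annotate -> associate -> neighbors -> histone -> saturate.

Every stage reads and writes plain-text files under the run directory and
records its parameters and record counts in a JSON manifest, together with
sha256 digests of every output, so a rerun with the same configuration is
byte-for-byte reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import (
    assembly_join,
    expression_quant,
    histone_marks,
    neighborhood,
    read_screening,
    saturation,
    synthetic_data,
    transcript_annotation,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "screen", "assemble", "join", "annotate",
    "associate", "neighbors", "histone", "saturate",
)


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    n_genes: int = 20
    n_novel: int = 8
    hidden_fraction: float = 0.1
    depth: float = 30.0
    n_junction_pairs: int = 10
    n_background_pairs: int = 200
    fragment_len: int = 300
    read_len: int = 100
    error_rate: float = 0.0
    k: int = 28
    phred_threshold: float = 17.0
    window_frac: float = 0.15
    min_overlap: int = 31
    min_len: int = 200
    min_support: int = 5
    gap: int = 50
    gc_cutoff: float = 0.65
    alpha: float = 1e-4
    freq_cutoff: float = 0.10
    samples_per_cell: int = 60
    chip_fold: float = 20.0
    chip_base_depth: float = 30.0
    saturation_reps: int = 10
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order; return (and write) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": asdict(config), "stages": {}}
    state: dict[str, Any] = {}

    def record(stage: str, counts: dict[str, Any], files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "counts": counts,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
        }

    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise ValueError(f"unknown stage {stage}")
        try:
            runner = globals()[f"_stage_{stage}"]
            runner(config, out, state, record)
        except Exception as exc:
            manifest["error"] = {"stage": stage, "message": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _stage_simulate(config, out, state, record):
    world = synthetic_data.make_world(
        config.seed, n_genes=config.n_genes, n_novel=config.n_novel,
        hidden_fraction=config.hidden_fraction,
    )
    state["world"] = world
    paths = synthetic_data.write_world(world, out / "world")
    pairs = []
    for tid, planted in sorted(world.planted.items()):
        for fs, fe in planted.fragments:
            # short fragments take a tighter insert so starts still vary
            insert = min(config.fragment_len, max(2 * config.read_len, fe - fs - 60))
            frag_pairs = synthetic_data._pairs_from_seq(
                planted.seq[fs:fe], f"{tid}:{fs}",
                int(round(config.depth * (fe - fs) / (2 * config.read_len))),
                insert, config.read_len, config.error_rate,
                synthetic_data._rng(config.seed, "frag", tid, fs),
            )
            pairs.extend(frag_pairs)
        pairs.extend(
            synthetic_data.simulate_junction_pairs(
                world, tid, n_per_junction=config.n_junction_pairs,
                fragment_len=config.fragment_len, read_len=config.read_len,
                seed=config.seed,
            )
        )
    pairs.extend(
        synthetic_data.simulate_reference_pairs(
            world, config.n_background_pairs, fragment_len=config.fragment_len,
            read_len=config.read_len, seed=config.seed,
        )
    )
    state["raw_pairs"] = pairs
    r1, r2 = out / "reads_1.fastq", out / "reads_2.fastq"
    read_screening.write_fastq_pairs(pairs, r1, r2)
    record("simulate", {"planted": len(world.planted), "pairs": len(pairs)},
           list(paths.values()) + [r1, r2])


def _stage_screen(config, out, state, record):
    if "raw_pairs" not in state:
        state["raw_pairs"] = read_screening.read_fastq_pairs(out / "reads_1.fastq", out / "reads_2.fastq")
    if "world" not in state:
        raise RuntimeError("screen stage requires the simulate stage (world fixtures missing)")
    index = read_screening.KmerIndex(k=config.k)
    index.add_tier("genome", state["world"].public_reference.values())
    retained, stats = read_screening.screen_library(
        state["raw_pairs"], index,
        window_frac=config.window_frac, phred_threshold=config.phred_threshold,
    )
    state["retained"] = retained
    r1, r2 = out / "retained_1.fastq", out / "retained_2.fastq"
    read_screening.write_fastq_pairs(retained, r1, r2)
    stats_path = out / "screen_stats.tsv"
    stats.to_tsv(stats_path)
    record("screen", {"input": stats.input, "retained": stats.retained,
                      "mapped": stats.mapped}, [r1, r2, stats_path])


def _stage_assemble(config, out, state, record):
    contigs = assembly_join.greedy_assemble(
        state["retained"], min_overlap=config.min_overlap, min_len=config.min_len,
    )
    state["contigs"] = contigs
    path = out / "contigs.fa"
    assembly_join.write_transcripts_fasta(contigs, path)
    record("assemble", {"contigs": len(contigs)}, [path])


def _stage_join(config, out, state, record):
    links = assembly_join.map_pairs_to_transcripts(state["retained"], state["contigs"], k=config.k)
    graph = assembly_join.build_join_graph(links, min_support=config.min_support)
    joined = assembly_join.join_transcripts(graph, state["contigs"], gap=config.gap)
    fraction = assembly_join.validate_joins(joined, state["world"].truth_sequences)
    state["transcripts"] = joined
    links_path, fasta_path = out / "links.tsv", out / "transcripts.fa"
    assembly_join.write_links_tsv(links, links_path)
    assembly_join.write_transcripts_fasta(joined, fasta_path)
    n_multi = sum(1 for t in joined if len(t.members) > 1)
    state["join_fraction"] = fraction
    record("join", {"links": len(links), "edges": len(graph.edges),
                    "joined": n_multi, "join_correct_fraction": fraction},
           [links_path, fasta_path])


def _stage_annotate(config, out, state, record):
    world = state["world"]
    seqs = {t.id: t.seq for t in state["transcripts"]}
    seqs.update(world.decoys)  # off-target transcripts enter the GC/taxonomy census
    alignments = []
    for tid, seq in sorted(seqs.items()):
        alignments.extend(
            transcript_annotation.seed_align(tid, seq, world.proxy_genome, k=config.k)
        )
    psl_path = out / "alignments.psl"
    transcript_annotation.write_psl(alignments, psl_path)
    state["alignments"] = alignments

    taxonomy = {tid: "primate" for tid in seqs} | world.decoy_taxa
    table = transcript_annotation.build_taxonomy_table(seqs, taxonomy, cutoff=config.gc_cutoff)
    chi2, p, dof = transcript_annotation.taxonomy_chisq(table.values.tolist())
    table_path = out / "taxonomy_table.tsv"
    table.to_csv(table_path, sep="\t")
    state["taxonomy_chi2"] = (chi2, p, dof)
    low, high = transcript_annotation.split_by_gc(seqs, cutoff=config.gc_cutoff)
    record("annotate", {"alignments": len(alignments), "gc_low": len(low),
                        "gc_high": len(high), "chi2": round(chi2, 4), "chi2_p": p},
           [psl_path, table_path])


def _stage_associate(config, out, state, record):
    world = state["world"]
    design = {
        (tissue, cond): config.samples_per_cell
        for tissue in world.tissues for cond in ("cancer", "normal")
    }
    sim = synthetic_data.simulate_expression(world, design, seed=config.seed)
    state["expression"] = sim
    freq = expression_quant.expression_frequency(sim.transcripts)
    frequent = expression_quant.classify_frequent(freq, freq_cutoff=config.freq_cutoff)
    results = expression_quant.classify_association(
        frequent, sim.transcripts, alpha=config.alpha, freq_cutoff=config.freq_cutoff,
    )
    state["frequent"] = frequent
    state["freq_records"] = freq
    state["association"] = results
    mat_path, meta_path = out / "expression.tsv", out / "samples.tsv"
    sim.transcripts.write(mat_path, meta_path)
    genes_path = out / "gene_expression.tsv"
    sim.genes.values.to_csv(genes_path, sep="\t", index_label="gene")
    assoc_path = out / "association.tsv"
    expression_quant.association_table(results).to_csv(assoc_path, sep="\t", index=False)
    counts = pd.Series([r.category for r in results]).value_counts().to_dict()
    record("associate", {"frequent": len(frequent), **{str(k): int(v) for k, v in counts.items()}},
           [mat_path, meta_path, genes_path, assoc_path])


def _stage_neighbors(config, out, state, record):
    world = state["world"]
    # expression truth is planted-level, so neighborhoods are resolved for the
    # planted sequences (the assembled contigs are their reconstructions)
    planted_alignments = []
    for tid, seq in sorted(world.truth_sequences.items()):
        planted_alignments.extend(
            transcript_annotation.seed_align(tid, seq, world.proxy_genome, k=config.k)
        )
    assignment = neighborhood.assign_adjacent_gene(
        planted_alignments, {"proxy": world.annotations["proxy"]},
        {"proxy": world.homologs},
    )
    conservation = neighborhood.neighborhood_conservation(
        world.annotations["human"], world.annotations["proxy"],
        neighborhood.HomologMap(pairs={v: k for k, v in world.homologs.pairs.items()}),
    )
    sim = state["expression"]
    # association is defined on the planted (truth-level) transcripts
    tx_assign = {
        tid: assignment.get(tid) for tid in sim.transcripts.values.index
        if assignment.get(tid)
    }
    categories = neighborhood.adjacent_gene_association(
        sim.genes, sim.transcripts, tx_assign, alpha=config.alpha,
    )
    state["adjacent_categories"] = categories
    state["conservation"] = conservation
    path = out / "adjacent_genes.tsv"
    with open(path, "w") as fh:
        fh.write("transcript\tadjacent_gene\tcategory\n")
        for tid in sorted(tx_assign):
            fh.write(f"{tid}\t{tx_assign[tid]}\t{categories.get(tid, 'none')}\n")
    counts = pd.Series(list(categories.values())).value_counts().to_dict()
    record("neighbors", {"assigned": len(tx_assign),
                         "conservation": round(conservation, 4),
                         **{str(k): int(v) for k, v in counts.items()}}, [path])


def _stage_histone(config, out, state, record):
    world = state["world"]
    enriched = synthetic_data.default_enriched(world)
    signals = synthetic_data.simulate_chip(
        world, enriched, fold=config.chip_fold, base_depth=config.chip_base_depth,
        seed=config.seed,
    )
    calls = histone_marks.call_marks(signals, cutoff=config.alpha)
    freq_tissues = expression_quant.frequent_tissues(
        state["freq_records"], freq_cutoff=config.freq_cutoff
    )
    table, fisher_p = histone_marks.tissue_match_enrichment(
        calls, freq_tissues, world.cell_lines
    )
    path = out / "mark_calls.tsv"
    with open(path, "w") as fh:
        fh.write("transcript\tcell_line\tpattern\n")
        for c in calls:
            fh.write(f"{c.transcript}\t{c.cell_line}\t{c.pattern}\n")
    n_marked = len({c.transcript for c in calls if c.pattern != "none"})
    state["histone"] = {"n_marked": n_marked, "fisher_p": fisher_p, "table": table}
    record("histone", {"signals": len(signals), "marked_transcripts": n_marked,
                       "tissue_match_p": fisher_p}, [path])


def _stage_saturate(config, out, state, record):
    sim = state["expression"]
    detections = sim.transcripts.values > 0
    n_lib = detections.shape[1]
    sizes = sorted({max(1, n_lib // 8), n_lib // 4, n_lib // 2, 3 * n_lib // 4, n_lib})
    table = saturation.subsample_discovery(
        detections, sizes, n_rep=config.saturation_reps, seed=config.seed
    )
    means = table.groupby("size")["discovered"].mean()
    fit = saturation.fit_one_site(list(means.index), list(means.values))
    curve_path = out / "saturation.tsv"
    table.to_csv(curve_path, sep="\t", index=False)
    fit_path = out / "saturation_fit.json"
    fit_path.write_text(json.dumps(asdict(fit), indent=2, sort_keys=True))
    state["saturation"] = fit
    record("saturate", {"sizes": sizes, "bmax": round(fit.bmax, 3),
                        "kd": round(fit.kd, 3)}, [curve_path, fit_path])
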