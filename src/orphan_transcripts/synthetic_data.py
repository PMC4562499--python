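"""Seeded synthetic worlds with planted ground truth.

A world emulates the setting the pipeline assumes: a public reference genome
that is *missing* some regions, a better-assembled proxy-species genome that
contains them, paired-end reads drawn from the hidden regions (hence
unmappable to the public reference), a tissue x condition expression design
with planted frequency effects and adjacent-gene shifts, and ChIP-style
treatment/control counts with planted fold enrichment.

Hidden regions are rejection-sampled against the public reference's k-mer set,
so the screening invariant (no shared k-mer, either strand) holds by
construction rather than by probability.  All randomness flows from a single
integer seed, split per concern through numpy SeedSequence spawn keys.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import kmer_set, revcomp
from .expression_quant import ExpressionMatrix
from .histone_marks import MARKS, HistoneSignal
from .neighborhood import Feature, FeatureSet, HomologMap
from .read_screening import ReadPair

SCREEN_K = 28
BASES = np.array(list("ACGT"))

# planted per-class expression frequencies (fraction of samples expressing)
CLASS_FREQS = {
    "cancer_up": {"cancer": 0.5, "normal": 0.05},
    "normal_up": {"cancer": 0.05, "normal": 0.5},
    "similar": {"cancer": 0.30, "normal": 0.30},
    "infrequent": {"cancer": 0.02, "normal": 0.02},
}
BACKGROUND_FREQ = 0.02  # in tissues other than the transcript's home tissue
ADJACENT_SHIFT = 1.5    # log-scale shift of the neighbor gene in expressing samples
CHIP_FOLD = 20.0

GENE_LEN = 1000
INTERGENIC_LEN = 500


@dataclass
class PlantedTranscript:
    tid: str
    seq: str
    fragments: list[tuple[int, int]]
    home_tissue: str
    klass: str
    adjacent_gene_proxy: str
    adjacent_gene_human: str
    effect_cancer: float
    effect_normal: float
    taxon: str = "primate"


@dataclass
class SyntheticWorld:
    seed: int
    public_reference: dict[str, str]
    hidden_regions: dict[str, str]
    proxy_genome: dict[str, str]
    annotations: dict[str, FeatureSet]      # species -> features
    homologs: HomologMap                    # proxy gene id -> human gene id
    planted: dict[str, PlantedTranscript]
    decoys: dict[str, str]                  # high-GC off-target transcripts
    decoy_taxa: dict[str, str]
    tissues: tuple[str, ...]
    cell_lines: dict[str, str]              # cell line -> tissue

    @property
    def truth_sequences(self) -> dict[str, str]:
        return {tid: p.seq for tid, p in self.planted.items()}

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for p in self.planted.values():
            rows.append(
                {
                    "transcript": p.tid,
                    "length": len(p.seq),
                    "n_fragments": len(p.fragments),
                    "fragments": ";".join(f"{s}-{e}" for s, e in p.fragments),
                    "home_tissue": p.home_tissue,
                    "class": p.klass,
                    "adjacent_gene_proxy": p.adjacent_gene_proxy,
                    "adjacent_gene_human": p.adjacent_gene_human,
                    "effect_cancer": p.effect_cancer,
                    "effect_normal": p.effect_normal,
                    "taxon": p.taxon,
                }
            )
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _rng(seed: int, *key: int | str) -> np.random.Generator:
    ints = [seed] + [k if isinstance(k, int) else zlib.crc32(k.encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(ints))


def _chain_plan(n_novel: int) -> list[int]:
    """Fragment counts per planted transcript: 3-member chains first, then
    2-member chains, then singletons (mirrors the joined-transcript mix)."""
    plan = []
    for i in range(n_novel):
        if i < 3:
            plan.append(3)
        elif i < 8:
            plan.append(2)
        else:
            plan.append(1)
    return plan


def make_world(
    seed: int,
    n_genes: int = 20,
    n_novel: int = 8,
    hidden_fraction: float = 0.1,
    tissues: Sequence[str] = ("adrenal", "prostate", "lung"),
) -> SyntheticWorld:
    """Build a deterministic world with ``n_novel`` planted transcripts."""
    if not 0 < hidden_fraction < 1:
        raise ValueError("hidden_fraction must be in (0, 1)")
    if n_novel < 1 or n_genes < 2:
        raise ValueError("need n_novel >= 1 and n_genes >= 2")

    rng_genes = _rng(seed, "genes")
    genes = [_random_seq(rng_genes, GENE_LEN) for _ in range(n_genes)]

    # --- human (public) chromosome: genes separated by intergenic spacers ---
    rng_ig = _rng(seed, "intergenic")
    human_parts, human_feats, pos = [], [], 0
    for i, g in enumerate(genes):
        spacer = _random_seq(rng_ig, INTERGENIC_LEN)
        human_parts.append(spacer)
        pos += len(spacer)
        human_feats.append(Feature("human_chr1", pos, pos + len(g), f"hgene_{i}", "+"))
        human_parts.append(g)
        pos += len(g)
    human_parts.append(_random_seq(rng_ig, INTERGENIC_LEN))
    human_chr = "".join(human_parts)
    public_reference = {"human_chr1": human_chr}
    public_kmers = kmer_set([human_chr], SCREEN_K, both_strands=True)

    # --- hidden regions: rejection-sampled to share no k-mer with the public ref
    plan = _chain_plan(n_novel)
    total_frags = sum(plan)
    frag_len = int(np.clip(hidden_fraction * len(human_chr) / total_frags, 260, 600))
    rng_hidden = _rng(seed, "hidden")
    hidden_regions: dict[str, str] = {}
    planted_raw: list[tuple[str, str, list[tuple[int, int]]]] = []
    for i, n_frag in enumerate(plan):
        length = n_frag * frag_len + int(rng_hidden.integers(0, 40))
        for _ in range(200):
            cand = _random_seq(rng_hidden, length)
            if not (kmer_set([cand], SCREEN_K) & public_kmers):
                break
        else:  # pragma: no cover - astronomically unlikely at these sizes
            raise RuntimeError("could not sample a hidden region disjoint from the reference")
        name = f"hidden_{i}"
        hidden_regions[name] = cand
        bounds = np.linspace(0, length, n_frag + 1).astype(int)
        frags = [(int(bounds[j]), int(bounds[j + 1])) for j in range(n_frag)]
        planted_raw.append((f"planted_{i:03d}", name, frags))

    # --- proxy genome: same gene order, hidden regions inserted intergenic ---
    rng_proxy = _rng(seed, "proxy")
    gap_choices = rng_proxy.choice(n_genes - 1, size=min(n_novel, n_genes - 1), replace=False)
    gap_of_region = {f"hidden_{i}": int(gap_choices[i % len(gap_choices)]) for i in range(n_novel)}
    proxy_parts, proxy_feats, pos = [], [], 0
    hidden_pos: dict[str, tuple[int, int]] = {}
    for i, g in enumerate(genes):
        spacer = _random_seq(rng_proxy, INTERGENIC_LEN)
        proxy_parts.append(spacer)
        pos += len(spacer)
        proxy_feats.append(Feature("proxy_chr1", pos, pos + len(g), f"pgene_{i}", "+"))
        proxy_parts.append(g)
        pos += len(g)
        for name, gap in sorted(gap_of_region.items()):
            if gap == i:
                half = _random_seq(rng_proxy, INTERGENIC_LEN // 2)
                proxy_parts.append(half)
                pos += len(half)
                hidden_pos[name] = (pos, pos + len(hidden_regions[name]))
                proxy_parts.append(hidden_regions[name])
                pos += len(hidden_regions[name])
    proxy_parts.append(_random_seq(rng_proxy, INTERGENIC_LEN))
    proxy_genome = {"proxy_chr1": "".join(proxy_parts)}

    annotations = {
        "human": FeatureSet(species="human", features=human_feats),
        "proxy": FeatureSet(species="proxy", features=proxy_feats),
    }
    homologs = HomologMap(pairs={f"pgene_{i}": f"hgene_{i}" for i in range(n_genes)})

    # --- planted truth: class, home tissue, adjacent gene, effects ---
    classes = ("cancer_up", "normal_up", "similar", "infrequent")
    planted: dict[str, PlantedTranscript] = {}
    proxy_fs = annotations["proxy"]
    from .neighborhood import nearest_feature  # local import avoids cycle at module load

    for idx, (tid, region, frags) in enumerate(planted_raw):
        klass = classes[idx % len(classes)]
        tissue = tissues[idx % len(tissues)]
        start, end = hidden_pos[region]
        gene_proxy, _ = nearest_feature(proxy_fs, "proxy_chr1", start, end)
        gene_human = homologs.get(gene_proxy) or ""
        effect_cancer = ADJACENT_SHIFT if klass in ("cancer_up", "similar") else 0.0
        effect_normal = ADJACENT_SHIFT if klass in ("normal_up", "similar") else 0.0
        planted[tid] = PlantedTranscript(
            tid=tid,
            seq=hidden_regions[region],
            fragments=frags,
            home_tissue=tissue,
            klass=klass,
            adjacent_gene_proxy=gene_proxy or "",
            adjacent_gene_human=gene_human,
            effect_cancer=effect_cancer,
            effect_normal=effect_normal,
        )

    # --- high-GC decoys (off-target taxa for the GC x taxonomy contingency) ---
    rng_decoy = _rng(seed, "decoys")
    decoy_taxa_cycle = ("bacteria", "bacteria", "other_eukaryote", "other")
    decoys, decoy_taxa = {}, {}
    for i in range(max(4, n_novel // 2)):
        name = f"decoy_{i:03d}"
        decoys[name] = _random_seq(rng_decoy, 300 + int(rng_decoy.integers(0, 200)), gc=0.78)
        decoy_taxa[name] = decoy_taxa_cycle[i % len(decoy_taxa_cycle)]

    cell_lines = {f"{t}_cl": t for t in tissues}
    return SyntheticWorld(
        seed=seed,
        public_reference=public_reference,
        hidden_regions=hidden_regions,
        proxy_genome=proxy_genome,
        annotations=annotations,
        homologs=homologs,
        planted=planted,
        decoys=decoys,
        decoy_taxa=decoy_taxa,
        tissues=tuple(tissues),
        cell_lines=cell_lines,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _pairs_from_seq(
    seq: str,
    name: str,
    n_pairs: int,
    fragment_len: int,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
    starts: np.ndarray | None = None,
) -> list[ReadPair]:
    if len(seq) < fragment_len:
        raise ValueError(f"sequence {name} (len {len(seq)}) shorter than fragment_len {fragment_len}")
    if starts is None:
        starts = rng.integers(0, len(seq) - fragment_len + 1, size=n_pairs)
    pairs = []
    for i, s in enumerate(starts):
        frag = seq[s : s + fragment_len]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])

        def mutate(read: str) -> tuple[str, tuple[int, ...]]:
            if error_rate == 0:
                return read, (40,) * len(read)
            errs = rng.random(len(read)) < error_rate
            if not errs.any():
                return read, (40,) * len(read)
            chars = list(read)
            quals = [40] * len(read)
            for j in np.flatnonzero(errs):
                alt = [b for b in "ACGT" if b != chars[j]]
                chars[j] = alt[int(rng.integers(0, 3))]
                quals[j] = 10
            return "".join(chars), tuple(quals)

        s1, q1 = mutate(r1)
        s2, q2 = mutate(r2)
        pairs.append(ReadPair(pair_id=f"{name}:{i}", seq1=s1, seq2=s2, qual1=q1, qual2=q2))
    return pairs


def simulate_read_pairs(
    world: SyntheticWorld,
    transcript_id: str,
    depth: float,
    fragment_len: int = 300,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPair]:
    """FR mate pairs from fragment ends of one planted transcript.

    Expected pair count is depth * L / (2 * read_len); per-base qualities are
    40, or 10 where a sequencing error was injected.
    """
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    if fragment_len < read_len:
        raise ValueError("fragment_len must be >= read_len")
    if transcript_id not in world.planted:
        raise KeyError(f"unknown planted transcript {transcript_id}")
    seq = world.planted[transcript_id].seq
    n_pairs = int(round(depth * len(seq) / (2 * read_len)))
    if n_pairs == 0:
        return []
    rng = _rng(seed, "reads", transcript_id)
    return _pairs_from_seq(seq, transcript_id, n_pairs, fragment_len, read_len, error_rate, rng)


def simulate_junction_pairs(
    world: SyntheticWorld,
    transcript_id: str,
    n_per_junction: int = 8,
    fragment_len: int = 300,
    read_len: int = 100,
    seed: int = 0,
) -> list[ReadPair]:
    """Bridging pairs straddling each planted fragment junction.

    Fragment placement keeps each mate wholly inside one fragment (the
    junction falls in the unsequenced middle of the insert), so these pairs
    supply joining evidence without letting the assembler cross the junction.
    """
    planted = world.planted[transcript_id]
    rng = _rng(seed, "junction", transcript_id)
    pairs: list[ReadPair] = []
    for j, (fs, fe) in enumerate(planted.fragments[:-1]):
        junction = fe
        lo = junction - fragment_len + read_len
        hi = junction - read_len
        if lo > hi:
            raise ValueError("fragment_len too small to straddle a junction cleanly")
        starts = rng.integers(lo, hi + 1, size=n_per_junction)
        pairs.extend(
            _pairs_from_seq(
                planted.seq, f"{transcript_id}:junc{j}", n_per_junction,
                fragment_len, read_len, 0.0, rng, starts=np.asarray(starts),
            )
        )
    return pairs


def simulate_reference_pairs(
    world: SyntheticWorld,
    n_pairs: int,
    fragment_len: int = 300,
    read_len: int = 100,
    seed: int = 0,
) -> list[ReadPair]:
    """Background pairs drawn from the public reference (screening must remove them)."""
    rng = _rng(seed, "background")
    name, seq = next(iter(world.public_reference.items()))
    return _pairs_from_seq(seq, f"ref:{name}", n_pairs, fragment_len, read_len, 0.0, rng)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExpression:
    transcripts: ExpressionMatrix
    genes: ExpressionMatrix
    truth: pd.DataFrame  # transcript, class, home_tissue


def planted_rate(world: SyntheticWorld, tid: str, tissue: str, condition: str) -> float:
    p = world.planted[tid]
    if tissue == p.home_tissue:
        return CLASS_FREQS[p.klass][condition]
    if p.klass == "mixed":  # reserved for externally supplied rate tables
        return BACKGROUND_FREQ
    return BACKGROUND_FREQ


def simulate_expression(
    world: SyntheticWorld,
    design: Mapping[tuple[str, str], int],
    positive_rate: Mapping[tuple[str, str, str], float] | None = None,
    seed: int = 0,
) -> SimulatedExpression:
    """Planted-frequency expression matrix plus adjacent-gene matrix.

    ``design`` maps (tissue, condition) to a sample count and must include
    both conditions for at least one tissue.  ``positive_rate`` optionally
    overrides the world's per-class planted rates with explicit
    (transcript, tissue, condition) probabilities.
    """
    conditions = {cond for _, cond in design}
    if not {"cancer", "normal"} <= conditions:
        raise ValueError("design must include both cancer and normal samples")
    rng = _rng(seed, "expression")

    samples, tissues_of, conds_of = [], [], []
    for (tissue, cond), n in sorted(design.items()):
        for i in range(n):
            samples.append(f"{tissue}_{cond}_{i:04d}")
            tissues_of.append(tissue)
            conds_of.append(cond)
    meta = pd.DataFrame({"tissue": tissues_of, "condition": conds_of}, index=samples)

    tids = sorted(world.planted)
    rates = np.zeros((len(tids), len(samples)))
    for i, tid in enumerate(tids):
        for j, s in enumerate(samples):
            if positive_rate is not None:
                r = positive_rate[(tid, tissues_of[j], conds_of[j])]
            else:
                r = planted_rate(world, tid, tissues_of[j], conds_of[j])
            if not 0 <= r <= 1:
                raise ValueError(f"positive rate {r} outside [0, 1]")
            rates[i, j] = r
    expressed = rng.random(rates.shape) < rates
    levels = np.exp(rng.normal(np.log(5.0), 1.0, size=rates.shape))
    values = pd.DataFrame(np.where(expressed, levels, 0.0), index=tids, columns=samples)

    lengths = pd.Series({tid: len(world.planted[tid].seq) for tid in tids})
    lib_sizes = pd.Series(20_000_000, index=samples)
    tx_matrix = ExpressionMatrix(values=values, meta=meta, lengths=lengths, lib_sizes=lib_sizes)

    # adjacent-gene expression: lognormal base, shifted in expressing samples
    gene_ids = sorted({f.name for f in world.annotations["human"].features})
    gene_vals = np.exp(rng.normal(np.log(50.0), 0.7, size=(len(gene_ids), len(samples))))
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    for i, tid in enumerate(tids):
        p = world.planted[tid]
        if p.adjacent_gene_human not in gene_row:
            continue
        gi = gene_row[p.adjacent_gene_human]
        for j in range(len(samples)):
            if not expressed[i, j]:
                continue
            shift = p.effect_cancer if conds_of[j] == "cancer" else p.effect_normal
            if shift:
                gene_vals[gi, j] *= np.exp(shift)
    gene_matrix = ExpressionMatrix(
        values=pd.DataFrame(gene_vals, index=gene_ids, columns=samples),
        meta=meta,
        lengths=pd.Series(GENE_LEN, index=gene_ids),
        lib_sizes=lib_sizes,
    )
    truth = pd.DataFrame(
        {
            "transcript": tids,
            "class": [world.planted[t].klass for t in tids],
            "home_tissue": [world.planted[t].home_tissue for t in tids],
        }
    )
    return SimulatedExpression(transcripts=tx_matrix, genes=gene_matrix, truth=truth)


# ---------------------------------------------------------------------------
# ChIP simulation
# ---------------------------------------------------------------------------

def simulate_chip(
    world: SyntheticWorld,
    enriched: set[tuple[str, str, str]],
    fold: float = CHIP_FOLD,
    base_depth: float = 30.0,
    seed: int = 0,
    cell_lines: Sequence[str] | None = None,
    marks: Sequence[str] = MARKS,
    read_len: int = 100,
    control_ratio: int = 50,
) -> list[HistoneSignal]:
    """Treatment/control count records for every transcript x cell line x mark.

    Control counts are Poisson(base_depth * L / read_len) scaled to a
    control library sequenced ``control_ratio`` times deeper (a deep input
    makes the background rate estimate nearly noise-free, as the Poisson
    caller assumes).  Treatment counts for entries in ``enriched`` (keyed
    (transcript, mark, cell_line)) use ``fold`` times the base rate.
    Library sizes are set so that one mapped read is about one RPKM unit.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = _rng(seed, "chip")
    if cell_lines is None:
        cell_lines = sorted(world.cell_lines)
    signals = []
    for tid in sorted(world.planted):
        length = len(world.planted[tid].seq)
        mu = base_depth * length / read_len
        n_t = max(1, round(1e9 / length))
        for cl in cell_lines:
            for mark in marks:
                rate = fold * mu if (tid, mark, cl) in enriched else mu
                c_t = int(rng.poisson(rate)) if rate > 0 else 0
                c_c = int(rng.poisson(control_ratio * mu)) if mu > 0 else 0
                signals.append(
                    HistoneSignal(
                        transcript=tid,
                        cell_line=cl,
                        mark=mark,
                        treatment_count=c_t,
                        control_count=c_c,
                        n_treatment=n_t,
                        n_control=control_ratio * n_t,
                        effective_length=length if (c_t or c_c) else 0,
                    )
                )
    return signals


def default_enriched(world: SyntheticWorld) -> set[tuple[str, str, str]]:
    """The world's planted mark pattern: H3K27ac in the home-tissue cell line
    for every frequently expressed (non-infrequent) transcript."""
    out = set()
    for tid, p in world.planted.items():
        if p.klass == "infrequent":
            continue
        cl = f"{p.home_tissue}_cl"
        out.add((tid, "H3K27ac", cl))
    return out


# ---------------------------------------------------------------------------
# Fixture writing (plain-text formats only)
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_fasta(name: str, seqs: Mapping[str, str]) -> None:
        path = out / f"{name}.fa"
        SeqIO.write(
            [SeqRecord(Seq(s), id=k, description="") for k, s in sorted(seqs.items())],
            str(path), "fasta",
        )
        paths[name] = path

    write_fasta("public_reference", world.public_reference)
    write_fasta("hidden_regions", world.hidden_regions)
    write_fasta("proxy_genome", world.proxy_genome)
    write_fasta("planted_transcripts", world.truth_sequences)
    write_fasta("decoys", world.decoys)
    for sp, fs in world.annotations.items():
        path = out / f"genes_{sp}.bed"
        fs.to_bed(path)
        paths[f"genes_{sp}"] = path
    paths["homologs"] = out / "homologs.tsv"
    world.homologs.to_tsv(paths["homologs"])
    paths["truth"] = out / "truth.tsv"
    world.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    paths["taxonomy"] = out / "taxonomy.tsv"
    taxa = {tid: p.taxon for tid, p in world.planted.items()} | world.decoy_taxa
    with open(paths["taxonomy"], "w") as fh:
        fh.write("transcript\ttaxon\n")
        for tid, taxon in sorted(taxa.items()):
            fh.write(f"{tid}\t{taxon}\n")
    return paths


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
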