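"""Self-contained synthetic study generator with planted ground truth.

Generates a toy genome, TSS annotation, CGI track, multi-sample H3K4me3/
H3K27me3 peak calls with controllable per-mark detection probabilities,
factor peak sets, bulk/single-cell expression and DE gene lists, and a
second "species" linked by one-to-one orthologs — everything the pipeline
consumes, reproducible byte-for-byte from a master seed.

Seed derivation: the master seed feeds a ``numpy.random.SeedSequence``;
each sub-generator (sequence, chip, factors, expression, orthologs) draws
from its own spawned child, so adding samples to one stage never perturbs
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross_species import OrthologPair
from .genomic_io import (
    Genome,
    GenomicInterval,
    PeakSet,
    PromoterRegion,
    TssRecord,
    promoter_window,
    write_bed,
    write_fasta,
)

TRUE_CLASSES = ["BIVALENT", "ACTIVE", "REPRESSED", "LATENT"]

#: Map a planted true class to the consensus class recovering it.
TRUE_TO_HC = {
    "BIVALENT": "HC_BIVALENT",
    "ACTIVE": "HC_ACTIVE",
    "REPRESSED": "HC_REPRESSED",
    "LATENT": "HC_LATENT",
}

DEFAULT_CLASS_PROPORTIONS = {
    "BIVALENT": 0.30,
    "ACTIVE": 0.30,
    "REPRESSED": 0.05,
    "LATENT": 0.35,
}

#: Motif planted per class: (motif, planting rate, fixed transcript offset).
DEFAULT_MOTIF_RULES = {
    "BIVALENT": ("TCCCC", 0.5, 150),
    "ACTIVE": ("CGGAA", 0.4, 150),
}

DEFAULT_EXPRESSION_MEANS = {
    "ACTIVE": 40.0,
    "BIVALENT": 4.0,
    "REPRESSED": 2.0,
    "LATENT": 0.0,
}

DEFAULT_DROPOUT = {
    "ACTIVE": 0.2,
    "BIVALENT": 0.6,
    "REPRESSED": 0.7,
    "LATENT": 0.95,
}

DEFAULT_FACTOR_ODDS = {
    "ACTIVE": 5.0,
    "BIVALENT": 3.0,
    "REPRESSED": 1.0,
    "LATENT": 0.5,
}

DEFAULT_CONSERVATION = {
    "BIVALENT": 0.66,
    "ACTIVE": 0.84,
    "REPRESSED": 0.5,
    "LATENT": 0.7,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class GroundTruth:
    """Planted per-promoter truth: the oracle for every recovery test."""

    promoters: pd.DataFrame  # promoter_id, gene_id, chrom, tss_pos, strand, ...
    chrom: str
    chrom_length: int
    spacing: int
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_promoters(self) -> int:
        return len(self.promoters)

    def tss_records(self) -> list[TssRecord]:
        return [
            TssRecord(
                transcript_id=row.promoter_id,
                gene_id=row.gene_id,
                chrom=row.chrom,
                position=int(row.tss_pos),
                strand=row.strand,
            )
            for row in self.promoters.itertuples()
        ]

    def promoter_regions(
        self, upstream: int = 1000, downstream: int = 2000
    ) -> list[PromoterRegion]:
        return [promoter_window(t, upstream, downstream) for t in self.tss_records()]

    def classes(self, level: str = "promoter") -> dict[str, str]:
        """True classes keyed by promoter_id or gene_id."""
        key = "promoter_id" if level == "promoter" else "gene_id"
        return dict(zip(self.promoters[key], self.promoters["true_class"]))

    def hc_classes(self, level: str = "promoter") -> dict[str, str]:
        """True classes translated to the HC label space."""
        return {k: TRUE_TO_HC[v] for k, v in self.classes(level).items()}


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_truth(
    n_promoters: int = 2000,
    class_proportions: Mapping[str, float] | None = None,
    motif_rules: Mapping[str, tuple[str, float, int]] | None = None,
    expression_means: Mapping[str, float] | None = None,
    spacing: int = 12000,
    chrom: str = "chrS",
    seed: int = 0,
) -> GroundTruth:
    """Draw the per-promoter ground-truth table (no sequence yet).

    Promoters sit ``spacing`` bp apart on one synthetic chromosome, far
    enough that +-5 kb profile windows never overlap.
    """
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if set(props) - set(TRUE_CLASSES):
        raise ValueError(f"unknown classes in proportions: {set(props) - set(TRUE_CLASSES)}")
    if spacing < 11000:
        raise ValueError("spacing too small: promoter windows would collide")
    motif_rules = dict(DEFAULT_MOTIF_RULES if motif_rules is None else motif_rules)
    expr_means = dict(expression_means or DEFAULT_EXPRESSION_MEANS)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    labels = [c for c in TRUE_CLASSES if props.get(c, 0) > 0]
    p = np.array([props[c] for c in labels])
    classes = rng.choice(labels, size=n_promoters, p=p / p.sum())
    strands = rng.choice(["+", "-"], size=n_promoters)

    margin = 10000
    tss_pos = margin + spacing // 2 + spacing * np.arange(n_promoters)
    chrom_length = 2 * margin + spacing * n_promoters

    motifs = []
    offsets = []
    for cls in classes:
        rule = motif_rules.get(cls)
        if rule is not None and rng.random() < rule[1]:
            motifs.append(rule[0])
            offsets.append(rule[2])
        else:
            motifs.append("")
            offsets.append(0)

    expr = []
    for cls in classes:
        mean = expr_means.get(cls, 0.0)
        if mean <= 0:
            # latent promoters: mostly silent, rare leaky low expression
            expr.append(0.0 if rng.random() < 0.9 else float(rng.lognormal(-1.0, 0.5)))
        else:
            expr.append(float(mean * rng.lognormal(0.0, 0.5)))

    width = max(4, len(str(n_promoters)))
    table = pd.DataFrame(
        {
            "promoter_id": [f"t{i:0{width}d}" for i in range(n_promoters)],
            "gene_id": [f"g{i:0{width}d}" for i in range(n_promoters)],
            "chrom": chrom,
            "tss_pos": tss_pos,
            "strand": strands,
            "true_class": classes,
            "cpg_rich": np.isin(classes, ["BIVALENT", "ACTIVE"]),
            "motif": motifs,
            "motif_offset": offsets,
            "expression_mean": expr,
        }
    )
    return GroundTruth(
        promoters=table,
        chrom=chrom,
        chrom_length=int(chrom_length),
        spacing=spacing,
        seed=seed,
        params={
            "class_proportions": props,
            "motif_rules": motif_rules,
            "expression_means": expr_means,
        },
    )


@dataclass
class Reference:
    """Synthetic genome sequence plus annotation and CGI track."""

    genome: Genome
    tss: list[TssRecord]
    cgi: PeakSet
    truth: GroundTruth
    sequence: str  # raw chromosome string, for byte-exact FASTA output


# scrub targets: both planted motifs and their reverse complements
_SCRUB_PATTERNS = ("TCCCC", "GGGGA", "CGGAA", "TTCCG")


def _scrub_motifs(seq: np.ndarray, start: int, end: int) -> None:
    """Destroy chance occurrences of the planted motifs in seq[start:end].

    Mutates the centre base of each occurrence and repeats until clean, so
    motif-fraction statistics reflect planting alone.
    """
    for _ in range(12):
        region = seq[start:end].tobytes().decode()
        hits = []
        for pat in _SCRUB_PATTERNS:
            i = region.find(pat)
            while i != -1:
                hits.append((i, pat))
                i = region.find(pat, i + 1)
        if not hits:
            return
        for i, pat in hits:
            replacement = "A" if pat[2] != "A" else "T"
            seq[start + i + 2] = replacement.encode()
    raise RuntimeError("motif scrubbing did not converge")


def simulate_reference(
    n_promoters: int = 300,
    class_proportions: Mapping[str, float] | None = None,
    cpg_rules: Mapping[str, float] | None = None,
    seed: int = 0,
    spacing: int = 12000,
    truth: GroundTruth | None = None,
) -> Reference:
    """Build the genome: CpG-depleted background, CGI cores, planted motifs.

    BIVALENT/ACTIVE promoters receive a GC-rich core (obs/exp CpG around 1,
    GC > 50%) recorded in the CGI track; REPRESSED and LATENT promoters sit
    in CpG-depleted background.  Chance occurrences of the planted motifs
    are scrubbed within +-5.1 kb of every TSS so planted rates are
    identifiable.
    """
    rules = {
        "background_gc": 0.42,
        "cpg_depletion": 0.9,
        "core_halfwidth": 200,
        "core_gc": 0.6,
        **(cpg_rules or {}),
    }
    if truth is None:
        truth = simulate_truth(
            n_promoters=n_promoters,
            class_proportions=class_proportions,
            spacing=spacing,
            seed=seed,
        )
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(2)[1])

    gc = rules["background_gc"]
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=truth.chrom_length, p=p_bg).astype(np.uint8)

    # CpG depletion of the background (methylation-style C->T at CpG sites)
    cpg_pos = np.nonzero((codes[:-1] == _CODE["C"]) & (codes[1:] == _CODE["G"]))[0]
    deplete = cpg_pos[rng.random(len(cpg_pos)) < rules["cpg_depletion"]]
    codes[deplete] = _CODE["T"]

    half = int(rules["core_halfwidth"])
    core_gc = rules["core_gc"]
    p_core = np.array([(1 - core_gc) / 2, core_gc / 2, core_gc / 2, (1 - core_gc) / 2])
    cgi_intervals = []
    for row in truth.promoters.itertuples():
        if row.cpg_rich:
            lo, hi = int(row.tss_pos) - half, int(row.tss_pos) + half
            codes[lo:hi] = rng.choice(4, size=hi - lo, p=p_core).astype(np.uint8)
            cgi_intervals.append(GenomicInterval(truth.chrom, lo, hi))

    seq = _BASES[codes].copy()
    for row in truth.promoters.itertuples():
        pos = int(row.tss_pos)
        _scrub_motifs(seq, max(0, pos - 5100), min(truth.chrom_length, pos + 5100))

    # plant motifs at the configured transcript-relative offset
    for row in truth.promoters.itertuples():
        if not row.motif:
            continue
        pos, off = int(row.tss_pos), int(row.motif_offset)
        motif = row.motif
        if row.strand == "+":
            for j, base in enumerate(motif):
                seq[pos + off + j] = base.encode()
        else:
            rc = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            g0 = pos - off - len(motif) + 1
            for j, base in enumerate(rc):
                seq[g0 + j] = base.encode()

    sequence = seq.tobytes().decode()
    genome = Genome.from_dict({truth.chrom: sequence})
    cgi = PeakSet("reference", "CGI", cgi_intervals)
    return Reference(
        genome=genome, tss=truth.tss_records(), cgi=cgi, truth=truth, sequence=sequence
    )


@dataclass
class ChipSample:
    """One paired H3K4me3/H3K27me3 sample with optional fragment tracks."""

    sample_id: str
    k4_peaks: PeakSet
    k27_peaks: PeakSet
    k4_fragments: PeakSet | None
    k27_fragments: PeakSet | None
    depth: int
    k4_p: float
    k27_p: float


@dataclass
class ChipStudy:
    samples: list[ChipSample]
    truth: GroundTruth

    def sample_pairs(self) -> list[tuple[str, PeakSet, PeakSet]]:
        return [(s.sample_id, s.k4_peaks, s.k27_peaks) for s in self.samples]

    def depths(self) -> list[int]:
        return [s.depth for s in self.samples]


def _uniform_or_fixed(rng: np.random.Generator, value) -> float:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return float(rng.uniform(lo, hi))
    return float(value)


def simulate_chip_samples(
    truth: GroundTruth,
    n_samples: int = 10,
    k4_detect_p=(0.93, 0.99),
    k27_detect_p=(0.4, 0.95),
    false_positive_rate: float = 0.002,
    depth_range: tuple[int, int] = (20000, 60000),
    seed: int = 0,
    sample_prefix: str = "s",
    with_fragments: bool = False,
) -> ChipStudy:
    """Emit per-sample peak calls (and optionally fragment tracks).

    Each truly marked promoter emits a peak with the mark's detection
    probability; probabilities given as (lo, hi) intervals are drawn
    per sample, which is how the high cross-sample variability of
    H3K27me3 detection is planted.  Unmarked promoters emit spurious
    peaks at ``false_positive_rate``.  Peak scores follow a fixed
    per-promoter strength times per-sample noise, and bivalent promoters
    carry stronger H3K27me3 signal than repressed ones.
    """
    children = np.random.SeedSequence(seed ^ truth.seed).spawn(3)
    rng = np.random.default_rng(children[0])
    # fragments draw from their own stream so peak calls are invariant to
    # with_fragments
    frag_rng = np.random.default_rng(children[1])
    n = truth.n_promoters
    cls = truth.promoters["true_class"].to_numpy()
    pos = truth.promoters["tss_pos"].to_numpy()
    has_k4 = np.isin(cls, ["BIVALENT", "ACTIVE"])
    has_k27 = np.isin(cls, ["BIVALENT", "REPRESSED"])

    # per-promoter mark strengths, fixed across samples
    k27_strength = np.where(
        cls == "BIVALENT",
        rng.lognormal(np.log(12.0), 0.5, size=n),
        rng.lognormal(np.log(5.0), 0.5, size=n),
    )
    k4_strength = np.where(
        cls == "ACTIVE",
        rng.lognormal(np.log(14.0), 0.4, size=n),
        rng.lognormal(np.log(8.0), 0.5, size=n),
    )

    samples = []
    for s in range(n_samples):
        sid = f"{sample_prefix}{s:02d}"
        p4 = _uniform_or_fixed(rng, k4_detect_p)
        p27 = _uniform_or_fixed(rng, k27_detect_p)
        emitted = {}
        for mark, present, p_det, strength, half_lo, half_hi in (
            ("H3K4me3", has_k4, p4, k4_strength, 400, 600),
            ("H3K27me3", has_k27, p27, k27_strength, 800, 1200),
        ):
            detected = present & (rng.random(n) < p_det)
            spurious = ~present & (rng.random(n) < false_positive_rate)
            idx = np.nonzero(detected | spurious)[0]
            jitter = rng.integers(-100, 101, size=len(idx))
            noise = rng.lognormal(0.0, 0.3, size=len(idx))
            intervals = []
            for j, i in enumerate(idx):
                base = strength[i] if present[i] else 1.5
                intervals.append(
                    GenomicInterval(
                        truth.chrom,
                        int(pos[i]) - half_lo + int(jitter[j]),
                        int(pos[i]) + half_hi + int(jitter[j]),
                        score=float(base * noise[j]),
                    )
                )
            emitted[mark] = (PeakSet(sid, mark, intervals), idx)

        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        k4_frag = k27_frag = None
        if with_fragments:
            k4_frag = _fragments_for(
                frag_rng, sid, "H3K4me3", emitted["H3K4me3"][0], depth, truth.chrom_length
            )
            k27_frag = _fragments_for(
                frag_rng, sid, "H3K27me3", emitted["H3K27me3"][0], depth, truth.chrom_length
            )
        samples.append(
            ChipSample(
                sample_id=sid,
                k4_peaks=emitted["H3K4me3"][0],
                k27_peaks=emitted["H3K27me3"][0],
                k4_fragments=k4_frag,
                k27_fragments=k27_frag,
                depth=depth,
                k4_p=p4,
                k27_p=p27,
            )
        )
    return ChipStudy(samples=samples, truth=truth)


def _fragments_for(
    rng: np.random.Generator,
    sample_id: str,
    mark: str,
    peaks: PeakSet,
    depth: int,
    chrom_length: int,
    frag_len: int = 200,
    signal_share: float = 0.8,
) -> PeakSet:
    """Uniform fragments within peak bodies plus Poisson background."""
    weights = np.array([iv.score or 1.0 for iv in peaks.intervals])
    intervals = []
    if len(weights) and weights.sum() > 0:
        lam = weights / weights.sum() * depth * signal_share
        counts = rng.poisson(lam)
        for iv, c in zip(peaks.intervals, counts):
            if c == 0:
                continue
            starts = rng.integers(iv.start, iv.end, size=c)
            for st in starts:
                intervals.append(
                    GenomicInterval(iv.chrom, int(st), int(st) + frag_len)
                )
    n_bg = rng.poisson(depth * (1 - signal_share))
    chrom = peaks.intervals[0].chrom if len(peaks) else "chrS"
    for st in rng.integers(0, max(1, chrom_length - frag_len), size=n_bg):
        intervals.append(GenomicInterval(chrom, int(st), int(st) + frag_len))
    return PeakSet(sample_id, f"{mark}_fragments", intervals)


def simulate_factors(
    truth: GroundTruth,
    n_factors: int = 20,
    class_odds: Mapping[str, float] | Sequence[Mapping[str, float]] | None = None,
    base_rate: float = 0.08,
    seed: int = 0,
    name_prefix: str = "factor",
) -> dict[str, PeakSet]:
    """Factor binding peak sets with class-dependent binding odds.

    Binding probability at a promoter is ``base_rate * odds[true_class]``
    (capped at 0.95).  ``class_odds`` may be one mapping for all factors or
    a per-factor sequence of mappings.
    """
    if n_factors == 0:
        return {}
    if class_odds is None:
        per_factor = [DEFAULT_FACTOR_ODDS] * n_factors
    elif isinstance(class_odds, Mapping):
        per_factor = [class_odds] * n_factors
    else:
        per_factor = list(class_odds)
        if len(per_factor) != n_factors:
            raise ValueError("need one odds mapping per factor")
    for odds in per_factor:
        if any(v <= 0 for v in odds.values()):
            raise ValueError("odds must be > 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed ^ truth.seed).spawn(4)[1])
    cls = truth.promoters["true_class"].to_numpy()
    pos = truth.promoters["tss_pos"].to_numpy()
    factors = {}
    for f, odds in enumerate(per_factor):
        prob = np.clip(
            base_rate * np.array([odds.get(c, 1.0) for c in cls]), 0.0, 0.95
        )
        bound = rng.random(truth.n_promoters) < prob
        intervals = [
            GenomicInterval(truth.chrom, int(p) - 200, int(p) + 200)
            for p in pos[bound]
        ]
        name = f"{name_prefix}{f:02d}"
        factors[name] = PeakSet(name, name, intervals)
    return factors


@dataclass
class ExpressionStudy:
    bulk: pd.Series                 # gene -> FPKM
    single_cell: pd.DataFrame       # genes x cells FPKM
    de_lists: dict[str, set[str]]   # perturbation label -> gene set


def simulate_expression(
    truth: GroundTruth,
    dropout_rates: Mapping[str, float] | None = None,
    n_cells: int = 63,
    n_de_lists: int = 30,
    de_odds: float = 12.0,
    de_list_size: tuple[int, int] = (100, 200),
    seed: int = 0,
) -> ExpressionStudy:
    """Class-dependent bulk FPKM, zero-inflated single cells, DE lists.

    Bulk values are log-normal around each gene's planted mean; latent
    genes are mostly exactly 0.  Single-cell values are zero-inflated with
    per-class dropout.  DE lists sample genes with ``de_odds``-fold weight
    on truly bivalent genes.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    dropout = dict(dropout_rates or DEFAULT_DROPOUT)
    if any(not (0 <= d <= 1) for d in dropout.values()):
        raise ValueError("dropout rates must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed ^ truth.seed).spawn(5)[2])

    genes = truth.promoters["gene_id"].to_numpy()
    cls = truth.promoters["true_class"].to_numpy()
    means = truth.promoters["expression_mean"].to_numpy()

    bulk_vals = np.where(
        means > 0, rng.lognormal(np.log(np.where(means > 0, means, 1.0)), 0.4), 0.0
    )
    bulk = pd.Series(bulk_vals, index=genes, name="fpkm")

    sc = np.zeros((len(genes), n_cells))
    for i, (m, c) in enumerate(zip(means, cls)):
        d = dropout.get(c, 0.5)
        expressed = rng.random(n_cells) >= d
        if m > 0:
            sc[i, expressed] = rng.lognormal(np.log(m), 0.6, size=expressed.sum())
        else:
            sc[i, :] = 0.0
    single_cell = pd.DataFrame(
        sc, index=genes, columns=[f"cell{j:02d}" for j in range(n_cells)]
    )

    weights = np.where(cls == "BIVALENT", de_odds, 1.0)
    weights = weights / weights.sum()
    de_lists = {}
    for l in range(n_de_lists):
        size = int(rng.integers(de_list_size[0], de_list_size[1] + 1))
        chosen = rng.choice(genes, size=min(size, len(genes)), replace=False, p=weights)
        de_lists[f"perturbation{l:02d}"] = set(chosen)
    return ExpressionStudy(bulk=bulk, single_cell=single_cell, de_lists=de_lists)


def simulate_orthologs(
    truth_a: GroundTruth,
    conservation_rates: Mapping[str, float] | None = None,
    seed: int = 0,
    suffix: str = "_B",
) -> tuple[GroundTruth, list[OrthologPair]]:
    """Derive a species-B ground truth linked to A by one-to-one orthologs.

    Each gene keeps its class with the per-class conservation rate,
    otherwise the class is resampled uniformly from the other three.
    Species B reuses A's promoter coordinates (only classes differ), so it
    can feed a second ChIP simulation directly.
    """
    rates = dict(conservation_rates or DEFAULT_CONSERVATION)
    if any(not (0 <= r <= 1) for r in rates.values()):
        raise ValueError("conservation rates must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed ^ truth_a.seed).spawn(6)[3])

    table = truth_a.promoters.copy()
    new_classes = []
    for c in table["true_class"]:
        if rng.random() < rates.get(c, 1.0):
            new_classes.append(c)
        else:
            others = [x for x in TRUE_CLASSES if x != c]
            new_classes.append(others[int(rng.integers(len(others)))])
    table["true_class"] = new_classes
    table["cpg_rich"] = table["true_class"].isin(["BIVALENT", "ACTIVE"])
    table["gene_id"] = table["gene_id"] + suffix
    table["promoter_id"] = table["promoter_id"] + suffix

    truth_b = GroundTruth(
        promoters=table,
        chrom=truth_a.chrom,
        chrom_length=truth_a.chrom_length,
        spacing=truth_a.spacing,
        seed=seed ^ truth_a.seed,
        params={"conservation_rates": rates, "parent_seed": truth_a.seed},
    )
    pairs = [
        OrthologPair(g, g + suffix) for g in truth_a.promoters["gene_id"]
    ]
    return truth_b, pairs


# ---------------------------------------------------------------------------
# file writers


def write_truth(truth: GroundTruth, path) -> None:
    truth.promoters.to_csv(path, sep="\t", index=False)


def write_tss_gtf(truth: GroundTruth, path) -> None:
    """Write one transcript feature per promoter in GENCODE-style GTF."""
    lines = []
    for row in truth.promoters.itertuples():
        pos = int(row.tss_pos)
        if row.strand == "+":
            start_1b, end_1b = pos + 1, pos + 100
        else:
            start_1b, end_1b = max(1, pos + 1 - 99), pos + 1
        attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.promoter_id}";'
        lines.append(
            "\t".join(
                [
                    row.chrom,
                    "bivalscan_sim",
                    "transcript",
                    str(start_1b),
                    str(end_1b),
                    ".",
                    row.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_reference(ref: Reference, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gtf": out / "annotation.gtf",
        "cgi": out / "cgi.bed",
        "truth": out / "ground_truth.tsv",
    }
    write_fasta({ref.truth.chrom: ref.sequence}, paths["fasta"])
    write_tss_gtf(ref.truth, paths["gtf"])
    write_bed(ref.cgi, paths["cgi"])
    write_truth(ref.truth, paths["truth"])
    return paths


def write_chip_study(study: ChipStudy, out_dir, prefix: str = "") -> Path:
    """Write per-sample peak BEDs (and fragment BEDs) plus pairs.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in study.samples:
        k4_path = out / f"{prefix}{s.sample_id}_H3K4me3.bed"
        k27_path = out / f"{prefix}{s.sample_id}_H3K27me3.bed"
        write_bed(s.k4_peaks, k4_path)
        write_bed(s.k27_peaks, k27_path)
        row = {"sample_id": s.sample_id, "k4_bed": k4_path.name, "k27_bed": k27_path.name}
        if s.k4_fragments is not None:
            frag4 = out / f"{prefix}{s.sample_id}_H3K4me3_fragments.bed"
            frag27 = out / f"{prefix}{s.sample_id}_H3K27me3_fragments.bed"
            write_bed(s.k4_fragments, frag4)
            write_bed(s.k27_fragments, frag27)
            row["k4_fragments"] = frag4.name
            row["k27_fragments"] = frag27.name
        row["depth"] = s.depth
        rows.append(row)
    pairs_path = out / f"{prefix}pairs.tsv"
    pd.DataFrame(rows).to_csv(pairs_path, sep="\t", index=False)
    return pairs_path


def write_expression(expr: ExpressionStudy, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bulk": out / "bulk_fpkm.tsv",
        "sc": out / "sc_fpkm.tsv",
        "de_dir": out / "de_lists",
    }
    expr.bulk.rename_axis("gene_id").to_csv(paths["bulk"], sep="\t")
    expr.single_cell.rename_axis("gene_id").to_csv(paths["sc"], sep="\t")
    paths["de_dir"].mkdir(exist_ok=True)
    for name, genes in expr.de_lists.items():
        (paths["de_dir"] / f"{name}.tsv").write_text(
            "\n".join(sorted(genes)) + "\n"
        )
    return paths


def write_factors(factors: Mapping[str, PeakSet], out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, peaks in factors.items():
        path = out / f"{name}.bed"
        write_bed(peaks, path)
        rows.append({"factor": name, "bed": path.name})
    manifest = out / "factors.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def write_orthologs(pairs: Sequence[OrthologPair], path) -> None:
    pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class SyntheticStudy:
    """Everything one full synthetic run produces, in memory."""

    reference: Reference
    chip_a: ChipStudy
    chip_b: ChipStudy
    truth_b: GroundTruth
    ortholog_pairs: list[OrthologPair]
    factors: dict[str, PeakSet]
    expression: ExpressionStudy


def simulate_study(
    seed: int = 0,
    n_promoters: int = 2000,
    n_samples_a: int = 10,
    n_samples_b: int = 8,
    n_factors: int = 20,
    n_de_lists: int = 30,
    n_cells: int = 63,
    with_fragments: bool = False,
    out_dir=None,
) -> SyntheticStudy:
    """Run every sub-generator under one master seed; optionally write files."""
    ref = simulate_reference(n_promoters=n_promoters, seed=seed)
    truth = ref.truth
    chip_a = simulate_chip_samples(
        truth,
        n_samples=n_samples_a,
        seed=seed + 1,
        sample_prefix="a",
        with_fragments=with_fragments,
    )
    truth_b, pairs = simulate_orthologs(truth, seed=seed + 2)
    chip_b = simulate_chip_samples(
        truth_b,
        n_samples=n_samples_b,
        seed=seed + 3,
        sample_prefix="b",
        with_fragments=False,
    )
    factors = simulate_factors(truth, n_factors=n_factors, seed=seed + 4)
    expression = simulate_expression(
        truth, n_cells=n_cells, n_de_lists=n_de_lists, seed=seed + 5
    )
    study = SyntheticStudy(
        reference=ref,
        chip_a=chip_a,
        chip_b=chip_b,
        truth_b=truth_b,
        ortholog_pairs=pairs,
        factors=factors,
        expression=expression,
    )
    if out_dir is not None:
        out = Path(out_dir)
        write_reference(ref, out)
        write_chip_study(chip_a, out / "chip_a")
        write_chip_study(chip_b, out / "chip_b")
        write_truth(truth_b, out / "ground_truth_b.tsv")
        write_orthologs(pairs, out / "orthologs.tsv")
        write_factors(factors, out / "factors")
        write_expression(expression, out / "expression")
    return study
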