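"""Per-sample promoter chromatin states and high-confidence consensus classes.

A promoter's state in one sample is determined by overlap of its window with
that sample's H3K4me3 and H3K27me3 peak calls.  Across samples, a state seen
in strictly more than ``fraction`` of samples (default 70%) promotes the
promoter to the corresponding high-confidence (HC) class; the residual is
UNCLASSIFIED.  The strict inequality with fraction >= 0.5 guarantees at most
one HC class per promoter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import PeakSet, PromoterRegion


class SampleState(IntEnum):
    """Chromatin state of one promoter in one sample."""

    LATENT = 0      # neither mark
    ACTIVE = 1      # H3K4me3 only
    REPRESSED = 2   # H3K27me3 only
    BIVALENT = 3    # both marks


class ConsensusClass(str, Enum):
    """High-confidence consensus class of a promoter across samples."""

    HC_BIVALENT = "HC_BIVALENT"
    HC_ACTIVE = "HC_ACTIVE"
    HC_REPRESSED = "HC_REPRESSED"
    HC_LATENT = "HC_LATENT"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # plain value in TSV output
        return self.value


STATE_TO_HC: dict[SampleState, ConsensusClass] = {
    SampleState.BIVALENT: ConsensusClass.HC_BIVALENT,
    SampleState.ACTIVE: ConsensusClass.HC_ACTIVE,
    SampleState.REPRESSED: ConsensusClass.HC_REPRESSED,
    SampleState.LATENT: ConsensusClass.HC_LATENT,
}

# Precedence when collapsing per-transcript classes to one gene-level class.
_GENE_PRIORITY = [
    ConsensusClass.HC_BIVALENT,
    ConsensusClass.HC_ACTIVE,
    ConsensusClass.HC_REPRESSED,
    ConsensusClass.HC_LATENT,
    ConsensusClass.UNCLASSIFIED,
]


def call_sample_state(k4_overlap: bool, k27_overlap: bool) -> SampleState:
    """Map the (H3K4me3, H3K27me3) overlap flags of one sample to a state."""
    if k4_overlap and k27_overlap:
        return SampleState.BIVALENT
    if k4_overlap:
        return SampleState.ACTIVE
    if k27_overlap:
        return SampleState.REPRESSED
    return SampleState.LATENT


@dataclass
class StateMatrix:
    """Promoters x samples grid of per-sample chromatin states."""

    promoter_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray  # int8, shape (n_promoters, n_samples)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.promoter_ids), len(self.sample_ids)):
            raise ValueError("states shape does not match id lists")
        if len(self.sample_ids) < 1:
            raise ValueError("need at least one sample")

    @property
    def n_promoters(self) -> int:
        return len(self.promoter_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def state_counts(self, state: SampleState) -> np.ndarray:
        """Per-promoter count of samples exhibiting ``state``."""
        return (self.states == int(state)).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[SampleState(v).name for v in row] for row in self.states],
            index=self.promoter_ids,
            columns=self.sample_ids,
        )


def build_state_matrix(
    promoters: Sequence[PromoterRegion],
    sample_pairs: Sequence[tuple[str, PeakSet, PeakSet]],
) -> StateMatrix:
    """Call per-sample states for every promoter.

    ``sample_pairs`` is a sequence of (sample_id, H3K4me3 peaks, H3K27me3
    peaks) triples — one per paired ChIP-seq sample.
    """
    if not sample_pairs:
        raise ValueError("need at least one sample pair")
    states = np.zeros((len(promoters), len(sample_pairs)), dtype=np.int8)
    for j, (_, k4, k27) in enumerate(sample_pairs):
        for i, prom in enumerate(promoters):
            states[i, j] = int(
                call_sample_state(
                    k4.overlaps_any(prom.interval), k27.overlaps_any(prom.interval)
                )
            )
    return StateMatrix(
        promoter_ids=[p.promoter_id for p in promoters],
        sample_ids=[sid for sid, _, _ in sample_pairs],
        states=states,
    )


def consensus_threshold(n_samples: int, fraction: float = 0.7) -> int:
    """Smallest k with k/n strictly greater than ``fraction``.

    E.g. 8 of 11 samples and 6 of 8 samples for the default 70% rule.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    # epsilon guards float representation of e.g. 0.7 * 10
    return int(math.floor(n_samples * fraction + 1e-9)) + 1


def consensus_classify(
    matrix: StateMatrix, fraction: float = 0.7
) -> dict[str, ConsensusClass]:
    """Assign each promoter its HC consensus class, or UNCLASSIFIED.

    A promoter is HC_X iff state X occurs in at least
    ``consensus_threshold(n_samples, fraction)`` samples.  With
    fraction >= 0.5 the threshold exceeds half the samples, so at most one
    state can reach it.
    """
    k = consensus_threshold(matrix.n_samples, fraction)
    result: dict[str, ConsensusClass] = {}
    counts = {s: matrix.state_counts(s) for s in SampleState}
    for i, pid in enumerate(matrix.promoter_ids):
        assigned = ConsensusClass.UNCLASSIFIED
        for state, hc in STATE_TO_HC.items():
            if counts[state][i] >= k:
                assigned = hc
                break
        result[pid] = assigned
    return result


def collapse_to_gene(
    classes: Mapping[str, ConsensusClass], promoter_to_gene: Mapping[str, str]
) -> dict[str, ConsensusClass]:
    """Collapse per-transcript consensus classes to one class per gene.

    A gene takes the highest-precedence HC class among its transcripts
    (bivalent > active > repressed > latent > unclassified), i.e. gene-level
    calls are the union of the gene's TSS calls.
    """
    rank = {c: i for i, c in enumerate(_GENE_PRIORITY)}
    gene_class: dict[str, ConsensusClass] = {}
    for pid, cls in classes.items():
        gene = promoter_to_gene[pid]
        best = gene_class.get(gene)
        if best is None or rank[cls] < rank[best]:
            gene_class[gene] = cls
    return gene_class


def detection_curve(matrix: StateMatrix, state: SampleState) -> np.ndarray:
    """Counts of promoters showing ``state`` in at least n samples, n=1..S.

    The returned vector is non-increasing by construction.
    """
    counts = matrix.state_counts(state)
    return np.array(
        [int((counts >= n).sum()) for n in range(1, matrix.n_samples + 1)],
        dtype=np.int64,
    )


def promoter_signal_scores(
    promoters: Sequence[PromoterRegion], peaks: PeakSet
) -> dict[str, float]:
    """Per-promoter signal score from one sample's peaks.

    Score = sum of scores of peaks overlapping the promoter window; when the
    peak set carries no scores, the total overlapped bp is used instead.
    """
    use_scores = len(peaks) > 0 and all(iv.score is not None for iv in peaks)
    scores: dict[str, float] = {}
    for prom in promoters:
        hits = peaks.overlapping(prom.interval)
        if use_scores:
            scores[prom.promoter_id] = float(sum(iv.score for iv in hits))
        else:
            scores[prom.promoter_id] = float(
                sum(iv.overlap_length(prom.interval) for iv in hits)
            )
    return scores


def top_signal_overlap(
    per_sample_scores: Mapping[str, float], hc_set: Iterable[str]
) -> float:
    """Fraction of the HC set recovered by the top-|HC| scored promoters.

    Ties are broken by promoter id (ascending) for determinism.
    """
    hc = set(hc_set)
    if not hc:
        raise ValueError("hc_set must be non-empty")
    if len(hc) > len(per_sample_scores):
        raise ValueError("hc_set larger than the number of scored promoters")
    ranked = sorted(per_sample_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = {pid for pid, _ in ranked[: len(hc)]}
    return len(top & hc) / len(hc)


def mark_colocation_fraction(
    k4_peaks: PeakSet,
    k27_peaks: PeakSet,
    promoters: Sequence[PromoterRegion],
) -> float:
    """Fraction of promoters whose in-window K4 and K27 peaks co-locate.

    A promoter counts as co-located when some H3K4me3 peak overlapping its
    window shares >= 1 bp with some H3K27me3 peak overlapping the window.
    Callers should pass promoters carrying both marks in this sample.
    """
    if not promoters:
        raise ValueError("promoters must be non-empty")
    n_coloc = 0
    for prom in promoters:
        k4_hits = k4_peaks.overlapping(prom.interval)
        k27_hits = k27_peaks.overlapping(prom.interval)
        if any(a.overlaps(b) for a in k4_hits for b in k27_hits):
            n_coloc += 1
    return n_coloc / len(promoters)


@dataclass
class SampleQcSummary:
    """Cross-sample consistency summary of per-sample state counts."""

    state_counts: pd.DataFrame       # samples x states
    summary: pd.DataFrame            # per state: mean, sd, relative_sd_pct
    depth_correlation: pd.Series | None = None  # per state Pearson r vs depth


def sample_qc(
    matrix: StateMatrix, read_depths: Sequence[float] | None = None
) -> SampleQcSummary:
    """Per-sample state counts with cross-sample mean, SD and relative SD.

    Relative SD is 100 * sample SD / mean (ddof=1); it is NaN when the mean
    is 0.  When per-sample read depths are supplied, the Pearson correlation
    between counts and depth is reported per state.
    """
    if matrix.n_samples < 2:
        raise ValueError("sample_qc needs at least 2 samples")
    if read_depths is not None and len(read_depths) != matrix.n_samples:
        raise ValueError("read_depths must align with sample_ids")

    state_names = [s.name for s in SampleState]
    counts = pd.DataFrame(
        {s.name: (matrix.states == int(s)).sum(axis=0) for s in SampleState},
        index=matrix.sample_ids,
    )[state_names]

    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    rel = 100.0 * sd / mean.where(mean != 0, np.nan)
    summary = pd.DataFrame(
        {"mean": mean, "sd": sd, "relative_sd_pct": rel}
    )

    depth_corr = None
    if read_depths is not None:
        depths = np.asarray(read_depths, dtype=float)
        corr = {}
        for name in state_names:
            col = counts[name].to_numpy(dtype=float)
            if np.std(col) == 0 or np.std(depths) == 0:
                corr[name] = np.nan
            else:
                corr[name] = float(stats.pearsonr(col, depths)[0])
        depth_corr = pd.Series(corr)

    return SampleQcSummary(
        state_counts=counts, summary=summary, depth_correlation=depth_corr
    )
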