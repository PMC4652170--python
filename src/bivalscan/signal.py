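"""TSS-centred read-density matrices, k-means clustering and group tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genomic_io import STRAND_PLUS, BedGraph, PeakSet, PromoterRegion


@dataclass
class DensityMatrix:
    """Promoters x bins normalized read coverage around TSSs for one factor.

    Values are reads-per-million (fragment mode) or mean coverage (bedGraph
    mode).  Rows are oriented 5'->3' in transcript coordinates; bin 0 starts
    at -span.
    """

    factor: str
    promoter_ids: list[str]
    bin_size: int
    span: int
    values: np.ndarray
    library_size: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_bins = 2 * self.span // self.bin_size
        if self.values.shape != (len(self.promoter_ids), n_bins):
            raise ValueError("values shape inconsistent with ids/span/bin_size")
        if (self.values < 0).any():
            raise ValueError("densities must be >= 0")


def _window_bounds(prom: PromoterRegion, span: int) -> tuple[int, int, bool]:
    """Genomic bounds of the oriented +-span window and a reverse flag."""
    pos = prom.tss.position
    if prom.tss.strand == STRAND_PLUS:
        return pos - span, pos + span, False
    return pos - span + 1, pos + span + 1, True


def binned_density(
    fragments: PeakSet,
    promoters: Sequence[PromoterRegion],
    span: int = 5000,
    bin_size: int = 100,
    library_size: int | None = None,
    factor: str | None = None,
) -> DensityMatrix:
    """Fragment-overlap density matrix, reads-per-million normalized.

    A fragment contributes one count to every bin it overlaps (overlap
    counting, not midpoint).  ``library_size`` defaults to the total number
    of fragments in the set.
    """
    if library_size is None:
        library_size = len(fragments)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if span % bin_size != 0:
        raise ValueError("span must be a multiple of bin_size")
    n_bins = 2 * span // bin_size
    scale = 1e6 / library_size
    values = np.zeros((len(promoters), n_bins))
    for i, prom in enumerate(promoters):
        w_start, w_end, reverse = _window_bounds(prom, span)
        query_start = max(0, w_start)
        if query_start >= w_end:
            continue
        from .genomic_io import GenomicInterval

        window = GenomicInterval(prom.tss.chrom, query_start, w_end)
        for frag in fragments.overlapping(window):
            lo = max(frag.start, w_start) - w_start
            hi = min(frag.end, w_end) - w_start - 1
            values[i, lo // bin_size : hi // bin_size + 1] += 1
        if reverse:
            values[i] = values[i, ::-1]
    values *= scale
    return DensityMatrix(
        factor=factor or fragments.mark,
        promoter_ids=[p.promoter_id for p in promoters],
        bin_size=bin_size,
        span=span,
        values=values,
        library_size=library_size,
    )


def binned_density_from_coverage(
    coverage: BedGraph,
    promoters: Sequence[PromoterRegion],
    factor: str,
    span: int = 5000,
    bin_size: int = 100,
) -> DensityMatrix:
    """Density matrix from bedGraph coverage: per-bin mean value."""
    if span % bin_size != 0:
        raise ValueError("span must be a multiple of bin_size")
    n_bins = 2 * span // bin_size
    values = np.zeros((len(promoters), n_bins))
    for i, prom in enumerate(promoters):
        w_start, _, reverse = _window_bounds(prom, span)
        for b in range(n_bins):
            b_start = w_start + b * bin_size
            b_end = b_start + bin_size
            if b_end <= 0:
                continue
            values[i, b] = coverage.mean(prom.tss.chrom, max(0, b_start), b_end)
        if reverse:
            values[i] = values[i, ::-1]
    return DensityMatrix(
        factor=factor,
        promoter_ids=[p.promoter_id for p in promoters],
        bin_size=bin_size,
        span=span,
        values=values,
    )


@dataclass
class ClusterAssignment:
    """Deterministic k-means labels for promoters, numbered 1..k.

    Labels are renumbered by descending cluster mean of the first factor, so
    equally good solutions from different seeds get the same numbering.
    """

    promoter_ids: list[str]
    labels: np.ndarray
    k: int
    seed: int
    inertia: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.promoter_ids, name="cluster")


def cluster_promoters(
    matrices: Sequence[DensityMatrix],
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """k-means over concatenated per-factor density profiles.

    Each factor's matrix is scaled to unit maximum before concatenation so
    deep-coverage factors do not dominate the distance metric.  Runs
    ``n_init`` restarts and keeps the minimum-inertia solution.
    """
    if not matrices:
        raise ValueError("need at least one density matrix")
    ids = matrices[0].promoter_ids
    for m in matrices[1:]:
        if m.promoter_ids != ids:
            raise ValueError("matrices must cover the same promoters in order")
    if k > len(ids):
        raise ValueError("k exceeds the number of promoters")
    scaled = []
    for m in matrices:
        peak = m.values.max()
        scaled.append(m.values / peak if peak > 0 else m.values)
    features = np.concatenate(scaled, axis=1)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(features)
    # renumber by descending mean signal of the first factor
    first = scaled[0]
    means = [
        first[raw == c].mean() if (raw == c).any() else -np.inf for c in range(k)
    ]
    order = sorted(range(k), key=lambda c: (-means[c], c))
    relabel = {c: rank + 1 for rank, c in enumerate(order)}
    labels = np.array([relabel[c] for c in raw], dtype=np.int64)
    return ClusterAssignment(
        promoter_ids=list(ids),
        labels=labels,
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


@dataclass
class ClusterProfiles:
    """Per-cluster mean density profile; empty clusters get a zero vector."""

    factor: str
    profiles: dict[int, np.ndarray]
    empty_clusters: set[int] = field(default_factory=set)


def cluster_mean_profiles(
    assignment: ClusterAssignment, matrix: DensityMatrix
) -> ClusterProfiles:
    """Mean row per cluster for one factor's density matrix."""
    if matrix.promoter_ids != assignment.promoter_ids:
        raise ValueError("assignment does not cover this matrix's promoters")
    profiles: dict[int, np.ndarray] = {}
    empty: set[int] = set()
    for c in range(1, assignment.k + 1):
        members = matrix.values[assignment.labels == c]
        if len(members) == 0:
            profiles[c] = np.zeros(matrix.values.shape[1])
            empty.add(c)
        else:
            profiles[c] = members.mean(axis=0)
    return ClusterProfiles(factor=matrix.factor, profiles=profiles, empty_clusters=empty)


def promoter_mark_density(
    fragments: PeakSet,
    promoters: Sequence[PromoterRegion],
    library_size: int | None = None,
) -> pd.Series:
    """Per-promoter scalar density: fragments overlapping the promoter
    window, reads-per-million normalized."""
    if library_size is None:
        library_size = len(fragments)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    scale = 1e6 / library_size
    return pd.Series(
        {
            p.promoter_id: len(fragments.overlapping(p.interval)) * scale
            for p in promoters
        }
    )


def log_density(values) -> np.ndarray:
    """log10(x + 1), the display transform for density comparisons."""
    return np.log10(np.asarray(values, dtype=float) + 1.0)


def group_compare(
    values: Sequence[float],
    labels: Sequence[object],
    test: str = "t",
) -> tuple[float, float]:
    """Compare per-promoter values between groups.

    ``test='t'`` runs a two-sided two-sample t-test (exactly 2 groups);
    ``test='kruskal'`` runs a Kruskal-Wallis test across >= 2 groups.
    Every group needs >= 2 values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if test == "t":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        stat, p = stats.ttest_ind(groups[0], groups[1])
    elif test == "kruskal":
        stat, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)
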