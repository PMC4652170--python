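"""Hypergeometric overlap statistics, TF density and expression analyses."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import PeakSet, PromoterRegion


@dataclass(frozen=True)
class EnrichmentResult:
    """One upper-tail hypergeometric overlap test.

    Universe of size N contains a class of size K; a set of size n drawn
    from the universe overlaps the class in x elements.
    """

    set_label: str
    class_label: str
    universe_size: int
    class_size: int
    set_size: int
    overlap: int
    p_value: float


def hypergeom_upper_tail(x: int, K: int, n: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n).

    Delegates to the survival function of the standard hypergeometric
    distribution, which is evaluated in log space internally.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes: K={K}, n={n}, N={N}")
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"overlap x={x} outside [0, min(K={K}, n={n})]")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def factor_enrichment(
    factor_peaks: Mapping[str, PeakSet],
    class_promoters: Iterable[str],
    universe: Sequence[PromoterRegion],
    class_label: str = "class",
) -> list[EnrichmentResult]:
    """Enrichment of each factor's bound promoters in a promoter class.

    A promoter counts as bound by a factor when >= 1 of its peaks overlaps
    the promoter window.  The universe defines N; the class (a subset of
    universe ids) defines K; bound promoters define n; their intersection
    defines x.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    universe_ids = [p.promoter_id for p in universe]
    universe_set = set(universe_ids)
    class_set = set(class_promoters)
    if not class_set <= universe_set:
        raise ValueError("class promoters must be a subset of the universe")
    results = []
    for name, peaks in factor_peaks.items():
        bound = {
            p.promoter_id for p in universe if peaks.overlaps_any(p.interval)
        }
        x = len(bound & class_set)
        results.append(
            EnrichmentResult(
                set_label=name,
                class_label=class_label,
                universe_size=len(universe_set),
                class_size=len(class_set),
                set_size=len(bound),
                overlap=x,
                p_value=hypergeom_upper_tail(
                    x, len(class_set), len(bound), len(universe_set)
                ),
            )
        )
    return results


def tf_density(
    promoters: Sequence[PromoterRegion],
    factor_peaks: Mapping[str, PeakSet],
) -> pd.Series:
    """Number of distinct factors bound at each promoter window.

    Multiple peaks of one factor count once.
    """
    if not factor_peaks:
        raise ValueError("need at least one factor")
    counts = {
        p.promoter_id: sum(
            1 for peaks in factor_peaks.values() if peaks.overlaps_any(p.interval)
        )
        for p in promoters
    }
    return pd.Series(counts, dtype=np.int64)


def tf_density_by_class(
    density: pd.Series, classes: Mapping[str, object]
) -> tuple[pd.DataFrame, float, float]:
    """Per-class TF-density summary plus a Kruskal-Wallis rank test."""
    labels = pd.Series({pid: str(classes[pid]) for pid in density.index})
    summary = (
        pd.DataFrame({"density": density, "label": labels})
        .groupby("label")["density"]
        .agg(n="size", mean="mean", median="median")
    )
    groups = [density[labels == g].to_numpy() for g in summary.index]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 classes with >= 2 promoters each")
    stat, p = stats.kruskal(*groups)
    return summary, float(stat), float(p)


def perturbation_overlap(
    de_gene_lists: Mapping[str, Iterable[str]],
    class_genes: Iterable[str],
    universe: Iterable[str],
    alpha: float = 1e-3,
) -> tuple[float, pd.DataFrame]:
    """Share of differentially-expressed gene lists enriched in a gene class.

    Each list is tested for overlap with ``class_genes`` by the upper-tail
    hypergeometric over the given gene universe; lists restricted to the
    universe first.  Empty lists are skipped with a warning.  Returns the
    fraction of lists with p < alpha plus the per-list results.
    """
    universe_set = set(universe)
    class_set = set(class_genes) & universe_set
    rows = []
    for label, genes in de_gene_lists.items():
        gene_set = set(genes) & universe_set
        if not gene_set:
            warnings.warn(f"DE list {label!r} empty after universe restriction")
            continue
        x = len(gene_set & class_set)
        p = hypergeom_upper_tail(
            x, len(class_set), len(gene_set), len(universe_set)
        )
        rows.append(
            {
                "list": label,
                "n": len(gene_set),
                "overlap": x,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    if not rows:
        raise ValueError("no non-empty DE lists")
    table = pd.DataFrame(rows).set_index("list")
    return float(table["significant"].mean()), table


def expression_by_class(
    expression: Mapping[str, float] | pd.Series,
    classes: Mapping[str, object],
) -> tuple[pd.DataFrame, float, float]:
    """Per-class expression summaries plus a Kruskal-Wallis omnibus test.

    Classes absent from the expression table appear with n=0.  The test
    runs across all classes with >= 2 measured genes; fewer than two such
    classes is an error.
    """
    expr = pd.Series(expression, dtype=float)
    rows = {}
    groups = []
    for label in sorted({str(c) for c in classes.values()}):
        genes = [g for g, c in classes.items() if str(c) == label]
        values = expr.reindex(genes).dropna()
        rows[label] = {
            "n": len(values),
            "median": values.median() if len(values) else np.nan,
            "q25": values.quantile(0.25) if len(values) else np.nan,
            "q75": values.quantile(0.75) if len(values) else np.nan,
            "mean": values.mean() if len(values) else np.nan,
        }
        if len(values) >= 2:
            groups.append(values.to_numpy())
    if len(groups) < 2:
        raise ValueError("need >= 2 classes with >= 2 measured genes")
    stat, p = stats.kruskal(*groups)
    return pd.DataFrame.from_dict(rows, orient="index"), float(stat), float(p)


def nonexpressing_fraction(
    sc_matrix: pd.DataFrame,
    genes: Iterable[str],
    bulk_expression: Mapping[str, float] | pd.Series | None = None,
    bulk_low_threshold: float = 4.0,
) -> pd.Series:
    """Per-gene fraction of single cells with zero expression.

    ``sc_matrix`` is genes x cells.  When bulk expression is supplied, genes
    are first restricted to those lowly expressed in bulk (FPKM below the
    threshold).  Genes absent from the matrix are skipped with a warning.
    """
    genes = list(genes)
    if bulk_expression is not None:
        bulk = pd.Series(bulk_expression, dtype=float)
        genes = [
            g for g in genes if g in bulk.index and bulk[g] < bulk_low_threshold
        ]
    fractions = {}
    for gene in genes:
        if gene not in sc_matrix.index:
            warnings.warn(f"gene {gene!r} absent from single-cell matrix; skipped")
            continue
        row = sc_matrix.loc[gene]
        fractions[gene] = float((row == 0).sum() / len(row))
    return pd.Series(fractions, dtype=float)
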