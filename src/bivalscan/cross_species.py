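"""Cross-species comparison of consensus chromatin classes over orthologs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .chromatin_state import ConsensusClass

CLASS_ORDER = [c.value for c in ConsensusClass]


class OrthologPair(NamedTuple):
    """A one-to-one ortholog gene pair between species A and B."""

    gene_a: str
    gene_b: str


def validate_pairs(pairs: Iterable[OrthologPair]) -> list[OrthologPair]:
    pairs = [OrthologPair(*p) for p in pairs]
    genes_a = [p.gene_a for p in pairs]
    genes_b = [p.gene_b for p in pairs]
    if len(set(genes_a)) != len(genes_a) or len(set(genes_b)) != len(genes_b):
        raise ValueError("ortholog pairs must be one-to-one in both directions")
    return pairs


@dataclass
class StateOverlapMatrix:
    """5x5 class-by-class counts of ortholog pairs, one direction.

    Rows are source-species classes; each row sums to that class's count
    among classified pairs.  ``row_percent`` normalizes rows to 100.
    """

    counts: pd.DataFrame
    direction: str

    @property
    def row_percent(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return 100.0 * self.counts.div(totals.where(totals > 0), axis=0)


def state_overlap(
    classes_a: Mapping[str, object],
    classes_b: Mapping[str, object],
    pairs: Iterable[OrthologPair],
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[StateOverlapMatrix, StateOverlapMatrix]:
    """Count (class_A, class_B) combinations over ortholog pairs.

    Classes are gene-level consensus labels.  Pairs where either gene lacks
    a class are dropped, so the grand total equals the number of pairs with
    both genes classified.  Returns both directions; the B->A counts are the
    transpose of A->B.
    """
    pairs = validate_pairs(pairs)
    counts = pd.DataFrame(0, index=CLASS_ORDER, columns=CLASS_ORDER, dtype=int)
    for pair in pairs:
        if pair.gene_a not in classes_a or pair.gene_b not in classes_b:
            continue
        ca = str(classes_a[pair.gene_a])
        cb = str(classes_b[pair.gene_b])
        if ca not in CLASS_ORDER or cb not in CLASS_ORDER:
            raise ValueError(f"unknown class label {ca!r} or {cb!r}")
        counts.loc[ca, cb] += 1
    forward = StateOverlapMatrix(counts=counts, direction=f"{label_a}->{label_b}")
    backward = StateOverlapMatrix(
        counts=counts.T.copy(), direction=f"{label_b}->{label_a}"
    )
    return forward, backward


#: Default conserved/divergent groups: I-III conserved bivalent/active/latent,
#: IV bivalent-in-A-active-in-B, V the mirror case.
DEFAULT_GROUP_SPEC: dict[tuple[str, str], str] = {
    (ConsensusClass.HC_BIVALENT.value, ConsensusClass.HC_BIVALENT.value): "I",
    (ConsensusClass.HC_ACTIVE.value, ConsensusClass.HC_ACTIVE.value): "II",
    (ConsensusClass.HC_LATENT.value, ConsensusClass.HC_LATENT.value): "III",
    (ConsensusClass.HC_BIVALENT.value, ConsensusClass.HC_ACTIVE.value): "IV",
    (ConsensusClass.HC_ACTIVE.value, ConsensusClass.HC_BIVALENT.value): "V",
}


def divergence_groups(
    classes_a: Mapping[str, object],
    classes_b: Mapping[str, object],
    pairs: Iterable[OrthologPair],
    group_spec: Mapping[tuple[str, str], str]
    | Iterable[tuple[tuple[str, str], str]]
    | None = None,
) -> pd.Series:
    """Assign each ortholog pair a conservation/divergence group label.

    Pairs matching no pattern in ``group_spec`` get ``"other"``.  The spec
    may be given as a mapping or as (pattern, label) pairs; duplicate
    patterns are a configuration error.
    """
    if group_spec is None:
        spec = dict(DEFAULT_GROUP_SPEC)
    elif isinstance(group_spec, Mapping):
        spec = dict(group_spec)
    else:
        spec = {}
        for pattern, label in group_spec:
            if tuple(pattern) in spec:
                raise ValueError(f"overlapping pattern {pattern!r} in group spec")
            spec[tuple(pattern)] = label
    pairs = validate_pairs(pairs)
    labels = {}
    for pair in pairs:
        if pair.gene_a not in classes_a or pair.gene_b not in classes_b:
            continue
        key = (str(classes_a[pair.gene_a]), str(classes_b[pair.gene_b]))
        labels[pair.gene_a] = spec.get(key, "other")
    return pd.Series(labels, name="group")
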