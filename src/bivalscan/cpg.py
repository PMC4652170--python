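"""CpG density: observed/expected ratio, TSS-centred profiles, CGI overlap."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    STRAND_PLUS,
    Genome,
    PeakSet,
    PromoterRegion,
    TssRecord,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cpg_obs_exp_ratio(sequence: str) -> float:
    """Observed/expected CpG ratio: (N_CpG * L) / (N_C * N_G).

    Case-insensitive; ``N`` bases never match.  Returns 0 when the sequence
    contains no C or no G (zero-division convention of the standard CGI
    definition).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cpg = seq.count("CG")
    return n_cpg * len(seq) / (n_c * n_g)


@dataclass
class CpGProfile:
    """Per-bin obs/exp CpG ratios around a TSS, oriented 5'->3'.

    ``mask`` flags bins whose genomic window extends beyond the chromosome;
    their value is forced to 0.
    """

    bin_size: int
    span: int
    values: np.ndarray
    mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return 2 * self.span // self.bin_size


def _oriented_window(genome: Genome, tss: TssRecord, span: int) -> tuple[str, int, int]:
    """Extract the +-span window around a TSS in transcript orientation.

    Index 0 of the returned sequence is transcript coordinate -span.  Also
    returns the genomic start/end of the window for edge masking.
    """
    if tss.strand == STRAND_PLUS:
        start, end = tss.position - span, tss.position + span
        seq = genome.fetch(tss.chrom, start, end)
    else:
        start, end = tss.position - span + 1, tss.position + span + 1
        seq = reverse_complement(genome.fetch(tss.chrom, start, end))
    return seq, start, end


def cpg_profile(
    genome: Genome, tss: TssRecord, span: int = 5000, bin_size: int = 100
) -> CpGProfile:
    """Binned obs/exp CpG ratio from -span to +span around the TSS.

    Minus-strand profiles are computed on the reverse complement so that
    bin 0 is always the 5'-most bin of the transcript.
    """
    if span % bin_size != 0:
        raise ValueError("span must be a multiple of bin_size")
    seq, g_start, g_end = _oriented_window(genome, tss, span)
    length = genome.chrom_length(tss.chrom)
    n_bins = 2 * span // bin_size
    values = np.zeros(n_bins)
    mask = np.zeros(n_bins, dtype=bool)
    # genomic extent of each oriented bin, for off-chromosome masking
    for i in range(n_bins):
        sub = seq[i * bin_size : (i + 1) * bin_size]
        if tss.strand == STRAND_PLUS:
            b_start = g_start + i * bin_size
        else:
            b_start = g_end - (i + 1) * bin_size
        b_end = b_start + bin_size
        if b_start < 0 or b_end > length:
            mask[i] = True
            values[i] = 0.0
        else:
            values[i] = cpg_obs_exp_ratio(sub)
    return CpGProfile(bin_size=bin_size, span=span, values=values, mask=mask)


def cgi_overlap_flags(
    promoters: Sequence[PromoterRegion], cgi: PeakSet
) -> pd.Series:
    """Per-promoter flag: does the window overlap >= 1 CGI interval."""
    return pd.Series(
        {p.promoter_id: cgi.overlaps_any(p.interval) for p in promoters},
        dtype=bool,
    )


def cgi_overlap_by_class(
    promoters: Sequence[PromoterRegion],
    classes: Mapping[str, object],
    cgi: PeakSet,
) -> pd.DataFrame:
    """Percentage of promoters per consensus class overlapping >= 1 CGI.

    Every promoter must have a class in ``classes``.  Classes present in the
    mapping but with no promoters get NaN percentage.
    """
    flags = cgi_overlap_flags(promoters, cgi)
    rows = {}
    labels = sorted({str(classes[p.promoter_id]) for p in promoters})
    for label in labels:
        ids = [
            p.promoter_id for p in promoters if str(classes[p.promoter_id]) == label
        ]
        n = len(ids)
        n_overlap = int(flags.loc[ids].sum()) if n else 0
        rows[label] = {
            "n": n,
            "n_overlapping": n_overlap,
            "percent": 100.0 * n_overlap / n if n else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
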