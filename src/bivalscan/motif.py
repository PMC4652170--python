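"""Fixed k-mer occurrence statistics around TSSs.

Verifies and profiles given motifs (e.g. TCCCC, CGGAA) on promoter
sequences: the fraction of promoters containing a motif and the positional
occurrence density in transcript-relative coordinates.  Scanning is
double-stranded by default and overlapping occurrences count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cpg import _oriented_window, reverse_complement
from .genomic_io import Genome, TssRecord

_VALID = set("ACGT")


def _check_motif(motif: str) -> str:
    motif = motif.upper()
    if len(motif) < 3 or not set(motif) <= _VALID:
        raise ValueError(
            f"motif must be >= 3 bases over A/C/G/T, got {motif!r}"
        )
    return motif


def occurrence_positions(
    sequence: str, motif: str, both_strands: bool = True
) -> list[int]:
    """0-based positions of the 5'-most base of each occurrence.

    With ``both_strands`` the reverse complement of the motif is also
    scanned on the given sequence.  Overlapping occurrences are all
    reported.
    """
    motif = _check_motif(motif)
    seq = sequence.upper()
    patterns = {motif}
    if both_strands:
        patterns.add(reverse_complement(motif))
    positions = []
    for pat in patterns:
        i = seq.find(pat)
        while i != -1:
            positions.append(i)
            i = seq.find(pat, i + 1)
    return sorted(positions)


def motif_fraction(
    promoter_sequences: Sequence[str], motif: str, both_strands: bool = True
) -> float:
    """Fraction of sequences containing >= 1 occurrence of the motif."""
    motif = _check_motif(motif)
    if not promoter_sequences:
        raise ValueError("promoter_sequences must be non-empty")
    n_hit = sum(
        1
        for seq in promoter_sequences
        if occurrence_positions(seq, motif, both_strands)
    )
    return n_hit / len(promoter_sequences)


@dataclass
class MotifProfile:
    """Positional motif density around TSSs.

    ``density[b]`` is the mean number of occurrences per promoter whose
    5'-most base falls in bin ``b`` of the transcript-oriented window;
    bin 0 starts at -span.
    """

    motif: str
    bin_size: int
    span: int
    density: np.ndarray
    containing_fraction: float
    n_promoters: int


def motif_profile_from_sequences(
    oriented_sequences: Sequence[str],
    motif: str,
    span: int,
    bin_size: int = 50,
    both_strands: bool = True,
) -> MotifProfile:
    """Profile from pre-extracted, transcript-oriented windows of length 2*span."""
    motif = _check_motif(motif)
    if not oriented_sequences:
        raise ValueError("need at least one sequence")
    if span % bin_size != 0:
        raise ValueError("span must be a multiple of bin_size")
    n_bins = 2 * span // bin_size
    density = np.zeros(n_bins)
    n_hit = 0
    for seq in oriented_sequences:
        if len(seq) != 2 * span:
            raise ValueError("each sequence must have length 2*span")
        positions = occurrence_positions(seq, motif, both_strands)
        if positions:
            n_hit += 1
        for pos in positions:
            density[pos // bin_size] += 1
    density /= len(oriented_sequences)
    return MotifProfile(
        motif=motif,
        bin_size=bin_size,
        span=span,
        density=density,
        containing_fraction=n_hit / len(oriented_sequences),
        n_promoters=len(oriented_sequences),
    )


def motif_density_profile(
    genome: Genome,
    tss_list: Sequence[TssRecord],
    motif: str,
    span: int = 2000,
    bin_size: int = 50,
    both_strands: bool = True,
) -> MotifProfile:
    """Occurrence density of a motif from -span to +span around TSSs.

    Occurrences are binned by the transcript-relative coordinate of their
    5'-most base; minus-strand windows are reverse-complemented first so
    profiles are comparable across strands.
    """
    seqs = [_oriented_window(genome, tss, span)[0] for tss in tss_list]
    return motif_profile_from_sequences(seqs, motif, span, bin_size, both_strands)
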