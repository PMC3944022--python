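"""Somatic copy-number alteration (SCNA) categorisation and burden summaries.

Each segment is assigned exactly one of five alteration categories from its
integer total copy number and LOH flag, under the standard diploid reading:

====================  =========================================
category              condition
====================  =========================================
homozygous_loss       copy number 0
one_copy_loss         copy number 1
one_copy_gain         copy number 3
high_copy_gain        copy number >= 4
loh                   copy number 2 with the LOH flag set
neutral               copy number 2 without LOH
====================  =========================================

The copy-number class takes precedence over the LOH flag, so "loh" here means
copy-neutral LOH.  The per-sample "total SCNA number" is the sum of the four
copy-number categories; copy-neutral LOH is tallied separately and never
enters the total (the convention of the reference cohort's summary table).

SCNA burden counts segments (events), not bases.  For clustering, segment
lists are rasterised onto fixed genomic bins: a bin's value is the per-base
mean deviation of the copy number from the diploid 2 (uncovered bases count
as diploid), and a parallel LOH layer holds the fraction of the bin's bases
covered by LOH segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import CohortManifest, SegmentRecord

CATEGORIES = (
    "one_copy_gain",
    "one_copy_loss",
    "high_copy_gain",
    "homozygous_loss",
    "loh",
)

#: Categories that count toward the total SCNA number (LOH excluded).
TOTAL_CATEGORIES = CATEGORIES[:4]


def categorize_segment(copy_number: int, loh: bool) -> str:
    """Assign the SCNA category for one segment.

    Total function on ``copy_number >= 0``; see the module docstring for the
    category table.
    """
    if copy_number < 0:
        raise ValueError(f"copy_number must be >= 0, got {copy_number}")
    if copy_number == 0:
        return "homozygous_loss"
    if copy_number == 1:
        return "one_copy_loss"
    if copy_number == 3:
        return "one_copy_gain"
    if copy_number >= 4:
        return "high_copy_gain"
    return "loh" if loh else "neutral"


@dataclass(frozen=True)
class ScnaSummary:
    """Per-sample SCNA burden: the five category counts plus the total."""

    sample_id: str
    n_one_copy_gain: int
    n_one_copy_loss: int
    n_high_copy_gain: int
    n_homozygous_loss: int
    n_loh: int

    @property
    def total_scna(self) -> int:
        """Sum of the four copy-number categories; copy-neutral LOH excluded."""
        return (
            self.n_one_copy_gain
            + self.n_one_copy_loss
            + self.n_high_copy_gain
            + self.n_homozygous_loss
        )

    def as_dict(self) -> dict[str, int | str]:
        return {
            "sample": self.sample_id,
            "one_copy_gain": self.n_one_copy_gain,
            "one_copy_loss": self.n_one_copy_loss,
            "high_copy_gain": self.n_high_copy_gain,
            "homozygous_loss": self.n_homozygous_loss,
            "loh": self.n_loh,
            "total_scna": self.total_scna,
        }


def summarize_scna(segments: Iterable[SegmentRecord], sample_id: str) -> ScnaSummary:
    """Count segments per SCNA category for one sample.

    All segments must belong to ``sample_id``; a foreign segment raises.
    Neutral segments are ignored.
    """
    counts = dict.fromkeys(CATEGORIES, 0)
    for seg in segments:
        if seg.sample_id != sample_id:
            raise ValueError(
                f"segment for sample {seg.sample_id!r} passed to summary of "
                f"{sample_id!r}"
            )
        cat = categorize_segment(seg.copy_number, seg.loh)
        if cat != "neutral":
            counts[cat] += 1
    return ScnaSummary(
        sample_id=sample_id,
        n_one_copy_gain=counts["one_copy_gain"],
        n_one_copy_loss=counts["one_copy_loss"],
        n_high_copy_gain=counts["high_copy_gain"],
        n_homozygous_loss=counts["homozygous_loss"],
        n_loh=counts["loh"],
    )


def summarize_cohort_scna(
    segments: Iterable[SegmentRecord], sample_ids: Sequence[str]
) -> list[ScnaSummary]:
    """Per-sample summaries for a cohort; samples with no segments get zeros."""
    by_sample: dict[str, list[SegmentRecord]] = {sid: [] for sid in sample_ids}
    for seg in segments:
        if seg.sample_id in by_sample:
            by_sample[seg.sample_id].append(seg)
    return [summarize_scna(by_sample[sid], sid) for sid in sample_ids]


@dataclass
class CnvMatrix:
    """Binned copy-number profiles for a set of samples.

    ``values[i, j]`` is sample *i*'s mean copy-number deviation from diploid
    over bin *j*; ``loh_values[i, j]`` is the fraction of bin *j* covered by
    LOH segments.  Bins tile each chromosome without overlap, in the order of
    ``bin_coordinates``.
    """

    sample_ids: list[str]
    bin_coordinates: list[tuple[str, int, int]]
    values: np.ndarray
    loh_values: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.sample_ids), len(self.bin_coordinates)
        if self.values.shape != (n, m) or self.loh_values.shape != (n, m):
            raise ValueError("matrix shapes do not match ids/bins")

    def features(self, loh_weight: float = 1.0) -> np.ndarray:
        """Copy-number bins with the LOH layer appended at the given weight."""
        return np.hstack([self.values, loh_weight * self.loh_values])


DEFAULT_BIN_SIZE = 1_000_000  # 1 Mb, conventional for array CNV clustering


def make_bins(
    chrom_lengths: Mapping[str, int], bin_size: int
) -> list[tuple[str, int, int]]:
    """Tile each chromosome with fixed-size bins (last bin may be shorter)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        start = 1
        while start <= length:
            end = min(start + bin_size - 1, length)
            bins.append((chrom, start, end))
            start = end + 1
    return bins


def build_cnv_matrix(
    segments: Iterable[SegmentRecord],
    manifest: CohortManifest,
    chrom_lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> CnvMatrix:
    """Rasterise segment lists into a sample-by-bin copy-number matrix.

    A segment contributes to each bin it overlaps in proportion to the
    overlap length; bases not covered by any segment count as diploid
    (deviation 0).  Coordinates are 1-based closed at the interface and
    converted to half-open arithmetic internally.
    """
    sample_ids = manifest.tumor_ids
    sample_index = {sid: i for i, sid in enumerate(sample_ids)}
    bins = make_bins(chrom_lengths, bin_size)

    # Per-chromosome bin offsets for O(1) bin lookup (uniform tiling).
    chrom_offset: dict[str, int] = {}
    offset = 0
    for chrom, length in chrom_lengths.items():
        chrom_offset[chrom] = offset
        offset += -(-length // bin_size)  # ceil division

    bin_len = np.array([end - start + 1 for _, start, end in bins], dtype=float)
    n, m = len(sample_ids), len(bins)
    values = np.zeros((n, m))
    loh_values = np.zeros((n, m))

    for seg in segments:
        if seg.sample_id not in sample_index:
            continue
        if seg.chromosome not in chrom_offset:
            raise ValueError(f"unknown chromosome {seg.chromosome!r}")
        length = chrom_lengths[seg.chromosome]
        if seg.end > length:
            raise ValueError(
                f"segment {seg.chromosome}:{seg.start}-{seg.end} exceeds "
                f"chromosome length {length}"
            )
        i = sample_index[seg.sample_id]
        first_bin = (seg.start - 1) // bin_size
        last_bin = (seg.end - 1) // bin_size
        for b in range(first_bin, last_bin + 1):
            j = chrom_offset[seg.chromosome] + b
            bin_start = b * bin_size + 1
            bin_end = min(bin_start + bin_size - 1, length)
            overlap = min(seg.end, bin_end) - max(seg.start, bin_start) + 1
            values[i, j] += overlap * (seg.copy_number - 2)
            if seg.loh:
                loh_values[i, j] += overlap
    values /= bin_len
    loh_values /= bin_len
    return CnvMatrix(
        sample_ids=sample_ids,
        bin_coordinates=bins,
        values=values,
        loh_values=loh_values,
    )
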