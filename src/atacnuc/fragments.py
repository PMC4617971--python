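"""Paired-end fragment I/O and Tn5 coordinate conventions.

Tn5 inserts as a dimer leaving a 9-bp stagger, so sequenced fragment ends are
offset from the centers of the two Tn5 binding sites.  Insertion centers are
recovered as ``start + 4`` (plus strand end) and ``end - 1 - 4`` (minus strand
end), and the adjusted fragment size — the inclusive span between the two
insertion centers — is the sequenced length minus 8 bp.  All coordinates are
0-based half-open; BED input/output is bit-compatible with that convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np

from .occupancy import SizeDistribution

OFFSET = 4  # bp from a sequenced fragment end to the Tn5 binding-site center
SIZE_ADJUST = 2 * OFFSET  # sequenced length minus adjusted (center-to-center) size
MIN_SEQUENCED = SIZE_ADJUST + 1  # shortest fragment with a positive adjusted size


class Region(NamedTuple):
    chrom: str
    start: int
    end: int


class FragmentError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class FragmentRecord:
    """One sequenced fragment with derived Tn5 insertion-center coordinates."""

    chrom: str
    start: int  # 0-based inclusive leftmost sequenced base
    end: int  # 0-based exclusive right bound

    def __post_init__(self) -> None:
        if self.end - self.start < MIN_SEQUENCED:
            raise FragmentError(
                f"fragment {self.chrom}:{self.start}-{self.end} shorter than "
                f"{MIN_SEQUENCED} bp has no valid insertion centers"
            )

    @property
    def left_center(self) -> int:
        return self.start + OFFSET

    @property
    def right_center(self) -> int:
        return self.end - 1 - OFFSET

    @property
    def adj_size(self) -> int:
        return self.end - self.start - SIZE_ADJUST

    def midpoint_weights(self) -> tuple:
        """Integer midpoint(s) of the insertion-center span with weights.

        Odd adjusted sizes have an integer midpoint (weight 1); even sizes
        have a half-integer midpoint whose weight is split 0.5/0.5 across the
        two flanking bases.
        """
        tot = self.left_center + self.right_center
        if tot % 2 == 0:
            return ((tot // 2, 1.0),)
        return ((tot // 2, 0.5), (tot // 2 + 1, 0.5))


@dataclass
class Track:
    """Per-base values over [start, start + len(values)) on one chromosome."""

    chrom: str
    start: int
    values: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def slice(self, start: int, end: int) -> np.ndarray:
        if start < self.start or end > self.end:
            raise IndexError("requested interval outside track bounds")
        return self.values[start - self.start : end - self.start]


@dataclass
class ReadStats:
    n_kept: int = 0
    n_too_short: int = 0
    n_duplicate: int = 0
    n_low_mapq: int = 0
    n_improper: int = 0
    n_outside: int = 0


def _midpoint_in_regions(frag: FragmentRecord, regions) -> bool:
    if regions is None:
        return True
    mid = (frag.left_center + frag.right_center) / 2.0
    return any(
        frag.chrom == r[0] and r[1] <= mid < r[2] for r in regions
    )


def _iter_bed(path: str) -> Iterator[tuple]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            yield parts[0], int(parts[1]), int(parts[2])


def _iter_bam(path: str, regions, min_mapq: int) -> Iterator[tuple]:
    import pysam

    with pysam.AlignmentFile(path, "rb") as bam:
        if not bam.has_index():
            raise FragmentError(f"{path} has no index; run samtools index first")
        seen_paired = False
        if regions is None:
            iters = [bam.fetch(c) for c in bam.references]
        else:
            # pad so fragments whose midpoint is in-region are always fetched
            iters = [
                bam.fetch(r[0], max(0, r[1] - 2000), r[2] + 2000) for r in regions
            ]
        for it in iters:
            for read in it:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if not read.is_paired:
                    continue
                seen_paired = True
                if not read.is_proper_pair or read.is_read2:
                    continue
                if read.mapping_quality < min_mapq:
                    yield None, -1, -1  # tallied as low mapq by caller
                    continue
                tlen = read.template_length
                if tlen <= 0:
                    continue
                yield read.reference_name, read.reference_start, read.reference_start + tlen
        if not seen_paired:
            raise FragmentError(
                f"{path} contains no paired reads; paired-end alignments are required"
            )


def read_fragments(
    path: str,
    regions: Optional[Sequence] = None,
    min_mapq: int = 30,
    dedup: bool = True,
    stats: Optional[ReadStats] = None,
) -> list[FragmentRecord]:
    """Read fragments from a BAM or 3-column BED file.

    One record per properly paired fragment whose midpoint lies in one of
    ``regions`` (all fragments if None); fragments shorter than 9 bp are
    rejected and tallied, exact (chrom, start, end) duplicates collapsed when
    ``dedup`` is set.  Output order is deterministic: (chrom, start, end).
    """
    if stats is None:
        stats = ReadStats()
    is_bam = path.endswith((".bam", ".cram"))
    raw = _iter_bam(path, regions, min_mapq) if is_bam else _iter_bed(path)

    out: list[FragmentRecord] = []
    seen: set = set()
    for chrom, start, end in raw:
        if chrom is None:
            stats.n_low_mapq += 1
            continue
        if end - start < MIN_SEQUENCED:
            stats.n_too_short += 1
            continue
        frag = FragmentRecord(chrom, start, end)
        if not _midpoint_in_regions(frag, regions):
            stats.n_outside += 1
            continue
        key = (chrom, start, end)
        if dedup:
            if key in seen:
                stats.n_duplicate += 1
                continue
            seen.add(key)
        out.append(frag)
    out.sort()
    stats.n_kept = len(out)
    return out


def write_fragments_bed(frags: Iterable[FragmentRecord], path: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
    os.replace(tmp, path)


def insertion_track(frags: Iterable[FragmentRecord], region) -> Track:
    """Count Tn5 insertion centers per base over ``region``.

    Both centers of every fragment are placed; a center outside the region is
    ignored while the other still contributes.  Empty input yields zeros.
    """
    chrom, start, end = region
    counts = np.zeros(end - start, dtype=int)
    for f in frags:
        if f.chrom != chrom:
            continue
        for c in (f.left_center, f.right_center):
            if start <= c < end:
                counts[c - start] += 1
    return Track(chrom, start, counts)


def size_distribution(
    frags: Iterable[FragmentRecord], size_range: tuple = (1, 500)
) -> SizeDistribution:
    """Empirical distribution of adjusted fragment sizes within a range."""
    lo, hi = size_range
    if lo < 1:
        raise ValueError("minimum size must be >= 1")
    sizes = np.array([f.adj_size for f in frags], dtype=int)
    return SizeDistribution.from_sizes(sizes, lo, hi)


def fragment_weight_matrix(
    frags: Iterable[FragmentRecord],
    region,
    size_lo: int = 105,
    size_hi: int = 250,
) -> np.ndarray:
    """Midpoint-weight matrix W[size - size_lo, pos - start] over a region.

    Rows are adjusted sizes ``size_lo..size_hi``; columns genomic positions in
    the half-open region.  Even-size fragments split 0.5/0.5 across the two
    bases flanking their half-integer midpoint.
    """
    chrom, start, end = region
    W = np.zeros((size_hi - size_lo + 1, end - start))
    for f in frags:
        if f.chrom != chrom or not (size_lo <= f.adj_size <= size_hi):
            continue
        row = f.adj_size - size_lo
        for pos, w in f.midpoint_weights():
            if start <= pos < end:
                W[row, pos - start] += w
    return W


def write_bedgraph(track: Track, path: str, precision: int = 6) -> None:
    """Write a track as bedGraph, merging runs of equal values."""
    tmp = path + ".tmp"
    vals = np.round(np.asarray(track.values, dtype=float), precision)
    with open(tmp, "w") as fh:
        i = 0
        n = len(vals)
        while i < n:
            j = i
            while j + 1 < n and vals[j + 1] == vals[i]:
                j += 1
            if vals[i] != 0:
                fh.write(
                    f"{track.chrom}\t{track.start + i}\t{track.start + j + 1}\t"
                    f"{vals[i]:g}\n"
                )
            i = j + 1
    os.replace(tmp, path)


def read_regions_bed(path: str) -> list[Region]:
    return [Region(c, s, e) for c, s, e in _iter_bed(path)]
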