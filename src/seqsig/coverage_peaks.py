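"""ChIP-seq coverage handling and local peak-height normalization.

Mapped reads are extended to the sequenced fragment length (150 bp) from
their 5' ends, piled up per base, thresholded at a minimum read depth to
define enriched regions, and normalized to heights in (0, 1] against the
local maximum within the adjacent 2-kbp neighbourhood.  The per-base
height at a 6-bp locus is then the probability that the locus sits in a
peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d

from .region_io import SEGMENT_LENGTH, TssWindow

DEFAULT_READ_EXTENSION = 150
DEFAULT_MIN_READS = 5
DEFAULT_NEIGHBORHOOD = 2000


@dataclass
class CoverageTrack:
    """Per-base coverage over [start, start+len(values)) on one chromosome."""

    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be 1-D")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Values over genomic [start, end); out-of-track bases are 0."""
        out = np.zeros(end - start, dtype=float)
        lo = max(start, self.start)
        hi = min(end, self.end)
        if hi > lo:
            out[lo - start : hi - start] = self.values[lo - self.start : hi - self.start]
        return out


@dataclass
class PeakHeightProfile:
    """Per-base normalized peak heights h in [0, 1] with the enriched mask.

    h is values/local-max inside enriched regions and exactly 0 elsewhere.
    """

    chrom: str
    start: int
    h: np.ndarray
    enriched: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.enriched = np.asarray(self.enriched, dtype=bool)
        if self.h.shape != self.enriched.shape:
            raise ValueError("h and enriched mask must have identical shape")
        if ((self.h < 0) | (self.h > 1)).any():
            raise ValueError("peak heights must lie in [0, 1]")

    @property
    def end(self) -> int:
        return self.start + len(self.h)

    def slice(self, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=float)
        lo = max(start, self.start)
        hi = min(end, self.end)
        if hi > lo:
            out[lo - start : hi - start] = self.h[lo - self.start : hi - self.start]
        return out


def extend_reads(
    reads: Iterable[tuple[str, int, int, str]],
    length: int = DEFAULT_READ_EXTENSION,
    chrom_sizes: dict[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Extend each mapped read to ``length`` bp from its 5' end.

    Plus-strand reads keep their start; minus-strand reads keep their end.
    Intervals are clipped to [0, chromosome length) when sizes are given.
    """
    if length <= 0:
        raise ValueError(f"extension length must be positive, got {length}")
    out: list[tuple[str, int, int]] = []
    for chrom, start, end, strand in reads:
        if strand == "+":
            s, e = start, start + length
        elif strand == "-":
            s, e = end - length, end
        else:
            raise ValueError(f"read strand must be '+' or '-', got {strand!r}")
        s = max(s, 0)
        if chrom_sizes is not None:
            e = min(e, chrom_sizes[chrom])
        if e > s:
            out.append((chrom, s, e))
    return out


def pileup(
    intervals: Iterable[tuple[str, int, int]],
    region: tuple[str, int, int],
) -> CoverageTrack:
    """Count, per base of ``region`` = (chrom, start, end), covering intervals."""
    chrom, start, end = region
    n = end - start
    if n <= 0:
        raise ValueError(f"empty region [{start}, {end})")
    delta = np.zeros(n + 1, dtype=float)
    for c, s, e in intervals:
        if c != chrom:
            continue
        s = max(s, start)
        e = min(e, end)
        if e > s:
            delta[s - start] += 1
            delta[e - start] -= 1
    return CoverageTrack(chrom=chrom, start=start, values=np.cumsum(delta[:-1]))


def enriched_mask(track: CoverageTrack, min_reads: int = DEFAULT_MIN_READS) -> np.ndarray:
    """Boolean mask of bases with at least ``min_reads`` reads mapped."""
    return track.values >= min_reads


def local_max(values: np.ndarray, neighborhood: int = DEFAULT_NEIGHBORHOOD) -> np.ndarray:
    """Sliding maximum over the window of ``neighborhood+1`` bases centred on
    each base (``neighborhood/2`` on each side), restricted to in-bounds bases.
    """
    if neighborhood <= 0 or neighborhood % 2:
        raise ValueError("neighborhood must be even and positive")
    # constant 0 padding equals in-bounds restriction for non-negative values
    return maximum_filter1d(
        np.asarray(values, dtype=float), size=neighborhood + 1,
        mode="constant", cval=0.0,
    )


def peak_height(
    track: CoverageTrack,
    mask: np.ndarray | None = None,
    neighborhood: int = DEFAULT_NEIGHBORHOOD,
    min_reads: int = DEFAULT_MIN_READS,
) -> PeakHeightProfile:
    """Normalize coverage to local peak heights in (0, 1].

    For each enriched base i, h_i = values[i] / max(values over the 2-kbp
    neighbourhood centred on i); non-enriched bases get 0.  Local maxima of
    enriched regions therefore score exactly 1.
    """
    if mask is None:
        mask = enriched_mask(track, min_reads=min_reads)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != track.values.shape:
        raise ValueError("mask and track shapes differ")
    lm = local_max(track.values, neighborhood=neighborhood)
    h = np.zeros_like(track.values, dtype=float)
    if mask.any():
        assert (lm[mask] > 0).all(), "enriched base with zero local maximum"
        h[mask] = track.values[mask] / lm[mask]
    return PeakHeightProfile(chrom=track.chrom, start=track.start, h=h, enriched=mask)


def segment_heights(
    profile: PeakHeightProfile,
    window: TssWindow,
    reduce: str = "mean",
) -> np.ndarray:
    """Per-segment peak height for a TSS window (334 values in [0, 1]).

    Each oriented 6-bp segment is reduced over its genomic bases with the
    mean (default) or max of the per-base normalized heights.
    """
    if reduce not in ("mean", "max"):
        raise ValueError(f"reduce must be 'mean' or 'max', got {reduce!r}")
    if profile.chrom != window.chrom:
        raise ValueError("profile and window are on different chromosomes")
    base_h = profile.slice(window.start, window.end)
    per_segment = base_h.reshape(-1, SEGMENT_LENGTH)
    if window.strand == "-":
        # oriented segment i maps to genomic bases counted from the window end
        per_segment = per_segment[::-1]
    if reduce == "mean":
        return per_segment.mean(axis=1)
    return per_segment.max(axis=1)


def segment_enriched(profile: PeakHeightProfile, window: TssWindow) -> np.ndarray:
    """Per-segment flag: does any base of the segment lie in an enriched region."""
    mask = np.zeros(window.end - window.start, dtype=bool)
    lo = max(window.start, profile.start)
    hi = min(window.end, profile.end)
    if hi > lo:
        mask[lo - window.start : hi - window.start] = profile.enriched[
            lo - profile.start : hi - profile.start
        ]
    per_segment = mask.reshape(-1, SEGMENT_LENGTH)
    if window.strand == "-":
        per_segment = per_segment[::-1]
    return per_segment.any(axis=1)


def read_bedgraph(path, region: tuple[str, int, int]) -> CoverageTrack:
    """Read per-base coverage for ``region`` from a bedGraph file."""
    chrom, start, end = region
    values = np.zeros(end - start, dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
            c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if c != chrom:
                continue
            s = max(s, start)
            e = min(e, end)
            if e > s:
                values[s - start : e - start] = v
    return CoverageTrack(chrom=chrom, start=start, values=values)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track as run-length-merged bedGraph."""
    v = track.values
    with open(path, "w") as fh:
        if len(v) == 0:
            return
        breaks = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [len(v)]))
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(
                    f"{track.chrom}\t{track.start + s}\t{track.start + e}\t{_fmt(v[s])}\n"
                )


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def brute_force_peak_height(
    values: Sequence[float],
    mask: Sequence[bool],
    neighborhood: int = DEFAULT_NEIGHBORHOOD,
) -> np.ndarray:
    """O(n·w) reference for :func:`peak_height`; the independent test oracle."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    half = neighborhood // 2
    h = np.zeros_like(values)
    for i in np.flatnonzero(mask):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        h[i] = values[i] / values[lo:hi].max()
    return h
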