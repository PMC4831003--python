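"""Probability-weighted 6-mer emission spectra for peak and dip states.

Each 6-bp segment of a TSS window contributes its peak height h as
fractional evidence that its 6-mer sits in an H3K27ac peak, and (1-h) as
evidence for the depleted state.  Normalizing peak frequencies by dip
frequencies cancels the GC-rich base composition of promoter regions, so
the ratio measures sequence preference rather than composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .region_io import SEGMENT_LENGTH, TssWindow

KMER_LENGTH = SEGMENT_LENGTH
ALL_KMERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=KMER_LENGTH)
)
N_KMERS = len(ALL_KMERS)  # 4096

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_index(kmer: str) -> int:
    """Index of an ACGT 6-mer in ALL_KMERS; -1 for N-containing segments."""
    idx = 0
    for b in kmer:
        code = _BASE_CODE.get(b)
        if code is None:
            return -1
        idx = idx * 4 + code
    return idx


def encode_segments(segments: Sequence[str]) -> np.ndarray:
    """Vector of k-mer indices for a window's segments (-1 where ambiguous)."""
    return np.fromiter((kmer_index(s) for s in segments), dtype=np.int64,
                       count=len(segments))


@dataclass
class KmerSpectrum:
    """Normalized peak- and dip-state emission probabilities over all 6-mers."""

    p_peak: np.ndarray
    p_dip: np.ndarray
    pseudocount: float
    n_peak: float
    n_dip: float

    def __post_init__(self) -> None:
        self.p_peak = np.asarray(self.p_peak, dtype=float)
        self.p_dip = np.asarray(self.p_dip, dtype=float)
        for name, p in (("p_peak", self.p_peak), ("p_dip", self.p_dip)):
            if p.shape != (N_KMERS,):
                raise ValueError(f"{name} must have length {N_KMERS}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1 (got {p.sum():.12f})")
            if (p < 0).any():
                raise ValueError(f"{name} has negative entries")

    def peak_prob(self, kmer: str) -> float:
        return float(self.p_peak[kmer_index(kmer)])

    def dip_prob(self, kmer: str) -> float:
        return float(self.p_dip[kmer_index(kmer)])

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.p_peak) - np.log(self.p_dip)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kmer": ALL_KMERS,
                "p_peak": self.p_peak,
                "p_dip": self.p_dip,
                "ratio": self.p_peak / self.p_dip,
            }
        ).set_index("kmer")

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t")


def spectrum_from_tsv(path) -> KmerSpectrum:
    df = pd.read_csv(path, sep="\t").set_index("kmer")
    df = df.loc[list(ALL_KMERS)]
    return KmerSpectrum(
        p_peak=df["p_peak"].to_numpy(), p_dip=df["p_dip"].to_numpy(),
        pseudocount=float("nan"), n_peak=float("nan"), n_dip=float("nan"),
    )


def count_weighted_kmers(
    windows: Iterable[TssWindow] | Iterable[Sequence[str]],
    heights: Sequence[np.ndarray],
    dip_source: str = "non_enriched_only",
    enriched: Sequence[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate height-weighted 6-mer counts for the peak and dip states.

    Each segment with 6-mer s and height h adds h to peak_counts[s].  Dip
    weight depends on ``dip_source``:

    - ``non_enriched_only`` (default): (1-h) is counted only for segments
      outside enriched regions (taken as those with h == 0, or with an
      explicit per-window ``enriched`` flag vector when provided);
    - ``residual_everywhere``: every segment also adds its residual (1-h).

    Segments containing N contribute to neither state.
    """
    if dip_source not in ("non_enriched_only", "residual_everywhere"):
        raise ValueError(f"unknown dip_source {dip_source!r}")
    windows = list(windows)
    heights = list(heights)
    if len(windows) != len(heights):
        raise ValueError(
            f"{len(windows)} windows but {len(heights)} height vectors"
        )
    if enriched is not None:
        enriched = list(enriched)
        if len(enriched) != len(windows):
            raise ValueError("enriched flags misaligned with windows")
    peak_counts = np.zeros(N_KMERS, dtype=float)
    dip_counts = np.zeros(N_KMERS, dtype=float)
    for w_i, (win, h) in enumerate(zip(windows, heights)):
        segments = win.segments if isinstance(win, TssWindow) else win
        h = np.asarray(h, dtype=float)
        if len(segments) != len(h):
            raise ValueError(
                f"window {w_i}: {len(segments)} segments vs {len(h)} heights"
            )
        if ((h < 0) | (h > 1)).any():
            raise ValueError(f"window {w_i}: heights outside [0, 1]")
        idx = encode_segments(segments)
        valid = idx >= 0
        np.add.at(peak_counts, idx[valid], h[valid])
        if dip_source == "residual_everywhere":
            dip_eligible = valid
        elif enriched is not None:
            dip_eligible = valid & ~np.asarray(enriched[w_i], dtype=bool)
        else:
            dip_eligible = valid & (h == 0.0)
        np.add.at(dip_counts, idx[dip_eligible], 1.0 - h[dip_eligible])
    return peak_counts, dip_counts


def estimate_spectrum(
    peak_counts: np.ndarray,
    dip_counts: np.ndarray,
    pseudocount: float = 1.0,
) -> KmerSpectrum:
    """Laplace-smoothed emission probabilities from weighted counts."""
    peak_counts = np.asarray(peak_counts, dtype=float)
    dip_counts = np.asarray(dip_counts, dtype=float)
    if (peak_counts < 0).any() or (dip_counts < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    p_peak = peak_counts + pseudocount
    p_dip = dip_counts + pseudocount
    if p_peak.sum() == 0 or p_dip.sum() == 0:
        raise ValueError("all-zero counts with zero pseudocount")
    return KmerSpectrum(
        p_peak=p_peak / p_peak.sum(),
        p_dip=p_dip / p_dip.sum(),
        pseudocount=pseudocount,
        n_peak=float(peak_counts.sum()),
        n_dip=float(dip_counts.sum()),
    )


def enrichment_report(spectrum: KmerSpectrum, top_n: int = 20) -> pd.DataFrame:
    """Rank 6-mers by peak/dip enrichment ratio (ties broken lexicographically)."""
    top_n = min(int(top_n), N_KMERS)
    df = spectrum.as_frame().reset_index()
    df = df.sort_values(["ratio", "kmer"], ascending=[False, True], kind="mergesort")
    return df.head(top_n).reset_index(drop=True)
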