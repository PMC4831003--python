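"""Factor-by-position association screens around the TSS.

Per-gene factor enrichment is summarized in 200-bp sliding windows with
100-bp overlap across the TSS region, then related to mRNA levels with
both the maximal information coefficient (MIC, capturing non-linear
dependence) and Pearson correlation.  MIC is computed with an
equipartition grid-search approximation of the MINE statistic: over all
grids with nx*ny <= n^alpha cells (equal-frequency and equal-width
binning on each axis), the normalized mutual information
I(X;Y)/log2(min(nx, ny)) is maximized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage_peaks import CoverageTrack
from .region_io import TssWindow

DEFAULT_GRID_SPAN = 2200
DEFAULT_GRID_WIDTH = 200
DEFAULT_GRID_STEP = 100


def position_grid(
    span: int = DEFAULT_GRID_SPAN,
    width: int = DEFAULT_GRID_WIDTH,
    step: int = DEFAULT_GRID_STEP,
) -> list[tuple[int, int]]:
    """Sliding-window offsets relative to the region centre (the TSS).

    The default 2,200-bp span with 200-bp windows overlapping by 100 bp
    yields 21 positions, labelled by their centre offset from the TSS.
    """
    if width > span:
        raise ValueError("grid width exceeds the spanned region")
    n_pos = (span - width) // step + 1
    half = span // 2
    return [(-half + i * step, -half + i * step + width) for i in range(n_pos)]


def window_enrichment(
    track: CoverageTrack,
    window: TssWindow | tuple[str, int],
    grid: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Per-position coverage sums for one gene's TSS region.

    ``window`` is a TssWindow (its TSS anchors the grid) or a bare
    (chrom, tss) pair.  Offsets are genomic for plus-strand genes and
    mirrored for minus-strand genes so positions stay gene-oriented.
    """
    if grid is None:
        grid = position_grid()
    if isinstance(window, TssWindow):
        tss, strand = window.tss, window.strand
        if window.chrom != track.chrom:
            raise ValueError("track and window chromosomes differ")
    else:
        tss, strand = window[1], "+"
    out = np.empty(len(grid))
    for i, (lo, hi) in enumerate(grid):
        if strand == "+":
            s, e = tss + lo, tss + hi
        else:
            s, e = tss - hi + 1, tss - lo + 1
        out[i] = track.slice(s, e).sum()
    return out


# ---------------------------------------------------------------------------
# MIC
# ---------------------------------------------------------------------------

def _bin_indices(v: np.ndarray, nb: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency and equal-width bin assignments for one vector."""
    n = len(v)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    eqfreq = ranks * nb // n
    lo, hi = v.min(), v.max()
    if hi > lo:
        eqwidth = np.minimum(((v - lo) / (hi - lo) * nb).astype(np.int64), nb - 1)
    else:
        eqwidth = np.zeros(n, dtype=np.int64)
    return eqfreq, eqwidth


def _grid_pairs(max_cells: float) -> list[tuple[int, int]]:
    pairs = []
    nx = 2
    while nx * 2 <= max_cells:
        ny = 2
        while nx * ny <= max_cells:
            pairs.append((nx, ny))
            ny += 1
        nx += 1
    return pairs


def _mutual_information(xi: np.ndarray, yi: np.ndarray, nx: int, ny: int) -> float:
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).astype(float)
    n = len(xi)
    joint /= n
    px = joint.reshape(nx, ny).sum(axis=1)
    py = joint.reshape(nx, ny).sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py).ravel()
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mic(x: np.ndarray, y: np.ndarray, alpha: float = 0.6, c: float = 15) -> float:
    """Approximate maximal information coefficient in [0, 1].

    Searches equipartition grids (equal-frequency and equal-width on each
    axis) with at most B(n) = n**alpha cells and returns the maximal
    I(X;Y)/log2(min(nx, ny)).  ``c`` is accepted for interface parity with
    MINE's clump factor but has no role in the equipartition search.
    Constant inputs give 0 by convention (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    n = len(x)
    if n < 20:
        raise ValueError(f"need at least 20 paired values, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MIC is 0 by convention")
        return 0.0
    max_cells = n ** alpha
    pairs = _grid_pairs(max_cells)
    if not pairs:
        return 0.0
    max_bins = max(max(nx, ny) for nx, ny in pairs)
    xbins = {nb: _bin_indices(x, nb) for nb in range(2, max_bins + 1)}
    ybins = {nb: _bin_indices(y, nb) for nb in range(2, max_bins + 1)}
    best = 0.0
    for nx, ny in pairs:
        norm = np.log2(min(nx, ny))
        for xi in xbins[nx]:
            for yi in ybins[ny]:
                mi = _mutual_information(xi, yi, nx, ny) / norm
                if mi > best:
                    best = mi
    return min(best, 1.0)


def mic_permutation_threshold(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    quantile: float = 0.95,
    seed: int = 0,
    alpha: float = 0.6,
) -> float:
    """The ``quantile`` of MIC(x, permuted y) over ``n_perm`` permutations."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    null = np.array([mic(x, rng.permutation(y), alpha=alpha) for _ in range(n_perm)])
    return float(np.quantile(null, quantile))


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    """MIC and Pearson statistics for every (factor, position) cell."""

    mic: pd.DataFrame
    pcc: pd.DataFrame
    pcc_p: pd.DataFrame

    def ranked(self, by: str = "mic") -> pd.DataFrame:
        stat = getattr(self, by)
        long = stat.stack().rename(by).reset_index()
        long.columns = ["factor", "position", by]
        key = long[by].abs() if by != "mic" else long[by]
        return long.loc[key.sort_values(ascending=False).index].reset_index(drop=True)


def association_screen(
    factor_matrices: dict[str, np.ndarray],
    expression: np.ndarray,
    position_labels: list | None = None,
) -> AssociationMatrix:
    """Screen each factor x position enrichment column against expression.

    ``factor_matrices`` maps factor name → (genes x positions) enrichment;
    rows must align with the expression vector (genes with missing values
    are dropped with a logged count).
    """
    from scipy import stats as sps

    if len(factor_matrices) < 2:
        raise ValueError("need at least two factors to screen")
    expression = np.asarray(expression, dtype=float)
    shapes = {m.shape for m in map(np.asarray, factor_matrices.values())}
    if len(shapes) != 1:
        raise ValueError("factor matrices have inconsistent shapes")
    (n_genes, n_pos), = shapes
    if len(expression) != n_genes:
        raise ValueError("expression misaligned with factor matrices")
    if position_labels is None:
        position_labels = list(range(n_pos))
    keep = np.isfinite(expression)
    for m in factor_matrices.values():
        keep &= np.isfinite(np.asarray(m, dtype=float)).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        import logging
        logging.getLogger("seqsig").info("dropped %d genes with missing values", n_dropped)
    expr = expression[keep]
    mic_rows, pcc_rows, p_rows = [], [], []
    for name, m in factor_matrices.items():
        m = np.asarray(m, dtype=float)[keep]
        mic_rows.append([mic(m[:, j], expr) for j in range(n_pos)])
        pr = [sps.pearsonr(m[:, j], expr) if np.ptp(m[:, j]) > 0 else (0.0, 1.0)
              for j in range(n_pos)]
        pcc_rows.append([r for r, _ in pr])
        p_rows.append([p for _, p in pr])
    factors = list(factor_matrices)
    return AssociationMatrix(
        mic=pd.DataFrame(mic_rows, index=factors, columns=position_labels),
        pcc=pd.DataFrame(pcc_rows, index=factors, columns=position_labels),
        pcc_p=pd.DataFrame(p_rows, index=factors, columns=position_labels),
    )


def permutation_false_hit_rate(
    factor_matrices: dict[str, np.ndarray],
    expression_replicates: np.ndarray,
    stat: str = "mic",
    n_perm: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Fraction of screen cells exceeding their permutation-null bound.

    ``expression_replicates`` is (replicates x genes): each row is screened
    against every (factor, position) cell and compared with that cell's
    ``quantile`` over ``n_perm`` permutations of the first replicate.  With
    expression truly independent of the factors the rate estimates
    1 - quantile; used to check the screens' calibration.
    """
    if stat not in ("mic", "pcc"):
        raise ValueError(f"stat must be 'mic' or 'pcc', got {stat!r}")
    reps = np.atleast_2d(np.asarray(expression_replicates, dtype=float))
    cols = [
        np.asarray(m, dtype=float)[:, j]
        for m in factor_matrices.values()
        for j in range(np.asarray(m).shape[1])
    ]
    rng = np.random.default_rng(seed)

    def stat_fn(x, y):
        if stat == "mic":
            return mic(x, y)
        return abs(np.corrcoef(x, y)[0, 1])

    null = np.empty((len(cols), n_perm))
    base = reps[0]
    for b in range(n_perm):
        y = rng.permutation(base)
        for i, x in enumerate(cols):
            null[i, b] = stat_fn(x, y)
    # k-th largest null value: exceedance probability k/(n_perm+1) exactly,
    # the standard permutation-test construction
    k = max(1, int(np.floor((1.0 - quantile) * (n_perm + 1))))
    thresholds = np.sort(null, axis=1)[:, n_perm - k]
    hits = total = 0
    for y in reps:
        for i, x in enumerate(cols):
            hits += stat_fn(x, y) > thresholds[i]
            total += 1
    return hits / total


def position_correlation_map(track_windows: np.ndarray) -> pd.DataFrame:
    """Pairwise Pearson correlations between positions over genes.

    Input is a (genes x positions) enrichment matrix; the result is a
    symmetric matrix with unit diagonal.  Zero-variance positions yield
    NaN cells and a warning.
    """
    M = np.asarray(track_windows, dtype=float)
    if M.ndim != 2 or M.shape[0] < 3:
        raise ValueError("need a (genes x positions) matrix with >= 3 genes")
    sd = M.std(axis=0)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance positions: correlations undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(M, rowvar=False)
    np.fill_diagonal(C, np.where(sd > 0, 1.0, np.nan))
    C = (C + C.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(C)
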