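"""Cell-type comparison of H3K27ac peaks, signatures, and expression.

Loci are classified as common when the peak probability (or normalized
peak height) exceeds ``hi`` in both cell types, as cell-type-specific
when it exceeds ``hi`` in one type but stays below ``lo`` in the other,
and as unclassified otherwise (intermediate loci are kept visible rather
than silently dropped).  Class-wise signature levels are compared with
Wilcoxon rank-sum tests and expression with log2 fold changes on the
FPKM+1 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_models import wilcoxon_rank_sum

DEFAULT_HI = 0.5
DEFAULT_LO = 0.1

COMMON = "common"
TYPE_A = "typeA_specific"
TYPE_B = "typeB_specific"
UNCLASSIFIED = "unclassified"
CLASSES = (COMMON, TYPE_A, TYPE_B, UNCLASSIFIED)


@dataclass(frozen=True)
class CellTypeCall:
    locus_id: str
    cls: str
    level_a: float
    level_b: float


def classify_signature(
    gamma_a: float, gamma_b: float, hi: float = DEFAULT_HI, lo: float = DEFAULT_LO
) -> str:
    """Three-way call from the two cell types' posterior peak probabilities."""
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    a, b = float(gamma_a), float(gamma_b)
    for v in (a, b):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability {v} outside [0, 1]")
    if a > hi and b > hi:
        return COMMON
    if a > hi and b < lo:
        return TYPE_A
    if b > hi and a < lo:
        return TYPE_B
    return UNCLASSIFIED


def classify_profiles(
    levels_a: np.ndarray,
    levels_b: np.ndarray,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
    ids: list[str] | None = None,
) -> pd.Series:
    """Vectorized classify_signature over aligned locus arrays."""
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("misaligned loci between cell types")
    cls = np.full(a.shape, UNCLASSIFIED, dtype=object)
    cls[(a > hi) & (b > hi)] = COMMON
    cls[(a > hi) & (b < lo)] = TYPE_A
    cls[(b > hi) & (a < lo)] = TYPE_B
    return pd.Series(cls, index=ids)


def classify_peaks(
    heights_a: np.ndarray,
    heights_b: np.ndarray,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
    ids: list[str] | None = None,
) -> pd.Series:
    """Three-way call from normalized ChIP peak heights (same thresholds
    as the signature classification by default)."""
    if len(np.asarray(heights_a)) != len(np.asarray(heights_b)):
        raise ValueError("misaligned loci between cell types")
    return classify_profiles(heights_a, heights_b, hi=hi, lo=lo, ids=ids)


def specificity_test(levels_by_class: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of signature levels between classes.

    Classes with fewer than two loci are skipped with a warning.  Returns
    rows (class_a, class_b, W, p) where W is the rank sum of class_a.
    """
    usable = {}
    for name, values in levels_by_class.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            warnings.warn(f"class {name!r} has fewer than 2 loci; skipped")
            continue
        usable[name] = v
    rows = []
    names = list(usable)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            W, p = wilcoxon_rank_sum(usable[na], usable[nb])
            rows.append({"class_a": na, "class_b": nb,
                         "n_a": len(usable[na]), "n_b": len(usable[nb]),
                         "W": W, "p": p})
    return pd.DataFrame(rows, columns=["class_a", "class_b", "n_a", "n_b", "W", "p"])


def foldchange_summary(
    expression_a: pd.Series | np.ndarray,
    expression_b: pd.Series | np.ndarray,
    gene_classes: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Per-class distribution of log2((FPKM_A + 1) / (FPKM_B + 1)).

    The +1 offsets keep fold changes consistent with the log2(FPKM+1)
    expression scale.  Returns per-class n, median and quartiles.
    """
    fa = np.asarray(expression_a, dtype=float)
    fb = np.asarray(expression_b, dtype=float)
    cls = np.asarray(gene_classes, dtype=object)
    if not (len(fa) == len(fb) == len(cls)):
        raise ValueError("expression vectors and classes misaligned")
    lfc = np.log2(fa + 1.0) - np.log2(fb + 1.0)
    rows = []
    for name in CLASSES:
        sel = cls == name
        if not sel.any():
            continue
        v = lfc[sel]
        rows.append({
            "class": name, "n": int(sel.sum()),
            "q25": float(np.quantile(v, 0.25)),
            "median": float(np.median(v)),
            "q75": float(np.quantile(v, 0.75)),
        })
    return pd.DataFrame(rows, columns=["class", "n", "q25", "median", "q75"])


def fold_changes(
    expression_a: np.ndarray, expression_b: np.ndarray
) -> np.ndarray:
    """Per-gene log2((FPKM_A + 1) / (FPKM_B + 1))."""
    fa = np.asarray(expression_a, dtype=float)
    fb = np.asarray(expression_b, dtype=float)
    return np.log2(fa + 1.0) - np.log2(fb + 1.0)
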