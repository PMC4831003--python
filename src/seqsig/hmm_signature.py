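"""Two-state HMM decoding of H3K27ac sequence signatures.

The hidden chain runs over the 334 six-bp segments of a TSS window with
states M (H3K27ac peak) and d (dip).  Emissions are the peak/dip 6-mer
spectra; transitions encode the cooperative persistence of acetylation
peaks, estimated directly from ChIP-derived peak labels rather than by
EM.  The per-segment posterior gamma_i(M) from the forward-backward
recursion is the "sequence signature": the probability, read from DNA
alone, that segment i lies in a peak.

All recursions are scaled per step so T=334 windows decode without
underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .kmer_spectrum import N_KMERS, KmerSpectrum, encode_segments

STATE_M = 0  # peak
STATE_D = 1  # dip

BAND_THRESHOLDS = (0.1, 0.5, 0.9)
BAND_NAMES = ("low", "medium", "high", "very_high")

_NORM_TOL = 1e-9


@dataclass
class HmmModel:
    """Initial distribution, transition matrix and emission spectra.

    State order is [M, d].  ``pi`` defaults to the empirical marginal at
    estimation time; ``stationary()`` gives the chain's stationary
    alternative.
    """

    pi: np.ndarray
    A: np.ndarray
    spectrum: KmerSpectrum

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.pi.shape != (2,) or self.A.shape != (2, 2):
            raise ValueError("pi must be length 2 and A must be 2x2")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if np.abs(self.A.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("rows of A must sum to 1")
        if (self.pi < 0).any() or (self.A < 0).any():
            raise ValueError("probabilities must be non-negative")
        if (self.spectrum.p_peak <= 0).any() or (self.spectrum.p_dip <= 0).any():
            raise ValueError("emission probabilities must be strictly positive")

    def stationary(self) -> np.ndarray:
        """Stationary distribution of A."""
        a_md, a_dm = self.A[STATE_M, STATE_D], self.A[STATE_D, STATE_M]
        if a_md + a_dm == 0:
            return np.array([0.5, 0.5])
        return np.array([a_dm, a_md]) / (a_md + a_dm)

    def emissions(self, segments: Sequence[str]) -> np.ndarray:
        """T x 2 emission likelihoods; N-containing segments emit uniformly
        (1/4096) from both states, carrying only transition information."""
        idx = encode_segments(segments)
        e = np.empty((len(idx), 2), dtype=float)
        valid = idx >= 0
        e[valid, STATE_M] = self.spectrum.p_peak[idx[valid]]
        e[valid, STATE_D] = self.spectrum.p_dip[idx[valid]]
        e[~valid] = 1.0 / N_KMERS
        return e


@dataclass
class SignatureProfile:
    """Posterior peak probabilities (gamma) and their bands for one gene."""

    gene_id: str
    gamma: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if ((self.gamma < -_NORM_TOL) | (self.gamma > 1 + _NORM_TOL)).any():
            raise ValueError("posteriors outside [0, 1]")

    @property
    def bands(self) -> list[str]:
        return [band(g) for g in self.gamma]


def estimate_transitions(
    state_calls: Iterable[Sequence[bool]],
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate A and pi from per-window boolean peak labels.

    A[M→M] is the fraction of peak segments whose next segment (within the
    same window) is also a peak — the proportion of peaks physically
    adjacent to other peaks; A[d→d] analogously.  pi is the empirical
    marginal state frequency.
    """
    n_m = n_d = 0
    mm = dd = 0
    from_m = from_d = 0
    for labels in state_calls:
        lab = np.asarray(labels, dtype=bool)
        n_m += int(lab.sum())
        n_d += int((~lab).sum())
        if len(lab) < 2:
            continue
        cur, nxt = lab[:-1], lab[1:]
        mm += int((cur & nxt).sum())
        dd += int((~cur & ~nxt).sum())
        from_m += int(cur.sum())
        from_d += int((~cur).sum())
    if n_m == 0:
        raise ValueError(
            "no peak-labelled segments; lower the peak-call threshold"
        )
    if n_d == 0:
        raise ValueError(
            "no dip-labelled segments; raise the peak-call threshold"
        )
    if from_m == 0 or from_d == 0:
        # a state occurs but never with a successor (e.g. only at window
        # ends): its outgoing row is unidentified, fall back to uniform
        warnings.warn("a state has no observed outgoing transitions; "
                      "its transition row defaults to uniform")
    a_mm = mm / from_m if from_m else 0.5
    a_dd = dd / from_d if from_d else 0.5
    A = np.array([[a_mm, 1.0 - a_mm], [1.0 - a_dd, a_dd]])
    pi = np.array([n_m, n_d], dtype=float) / (n_m + n_d)
    return A, pi


def forward(model: HmmModel, segments: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward recursion.

    Returns (alpha_hat, c) where alpha_hat[i, s] = P(state_i=s | obs_1..i)
    and c[i] are the per-step scaling factors, so that
    alpha_i(s) = alpha_hat[i, s] * prod(c[:i+1]).
    """
    e = model.emissions(segments)
    T = len(e)
    if T < 1:
        raise ValueError("need at least one segment")
    alpha = np.empty((T, 2), dtype=float)
    c = np.empty(T, dtype=float)
    a = model.pi * e[0]
    c[0] = a.sum()
    assert c[0] > 0, "zero forward mass (impossible with positive emissions)"
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ model.A) * e[t]
        c[t] = a.sum()
        assert c[t] > 0
        alpha[t] = a / c[t]
    return alpha, c


def backward(
    model: HmmModel, segments: Sequence[str], c: np.ndarray | None = None
) -> np.ndarray:
    """Backward recursion scaled by the forward factors.

    beta_hat[i, s] = beta_i(s) / prod(c[i+1:]); with the boundary
    beta_T(s) = 1 for both states.
    """
    e = model.emissions(segments)
    T = len(e)
    if c is None:
        _, c = forward(model, segments)
    beta = np.empty((T, 2), dtype=float)
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (model.A @ (e[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


def posterior(
    model: HmmModel, segments: Sequence[str], gene_id: str = ""
) -> SignatureProfile:
    """Forward-backward posterior gamma_i(M) = alpha_i(M)beta_i(M) / sum_s.

    The normalizing denominator sum_s alpha_i(s)beta_i(s) equals the total
    observation probability and is therefore invariant across positions i;
    this is asserted numerically.
    """
    alpha, c = forward(model, segments)
    beta = backward(model, segments, c)
    joint = alpha * beta
    denom = joint.sum(axis=1)
    # in scaled form each row's denominator is exactly P(obs)/P(obs) = 1
    assert np.abs(denom - 1.0).max() < 1e-6, "posterior denominator varies across i"
    gamma = joint[:, STATE_M] / denom
    return SignatureProfile(
        gene_id=gene_id, gamma=gamma, log_likelihood=float(np.log(c).sum())
    )


def posterior_batch(
    model: HmmModel, segment_lists: Sequence[Sequence[str]],
    gene_ids: Sequence[str] | None = None,
) -> list[SignatureProfile]:
    """Vectorized forward-backward over many equal-length windows."""
    if not segment_lists:
        return []
    T = len(segment_lists[0])
    if any(len(s) != T for s in segment_lists):
        raise ValueError("all windows must have equal segment counts")
    n = len(segment_lists)
    e = np.stack([model.emissions(s) for s in segment_lists])  # n x T x 2
    alpha = np.empty((n, T, 2))
    c = np.empty((n, T))
    a = model.pi[None, :] * e[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ model.A) * e[:, t, :]
        c[:, t] = a.sum(axis=1)
        alpha[:, t, :] = a / c[:, t, None]
    beta = np.empty((n, T, 2))
    beta[:, T - 1, :] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t, :] = ((e[:, t + 1, :] * beta[:, t + 1, :]) @ model.A.T) / c[
            :, t + 1, None
        ]
    joint = alpha * beta
    gamma = joint[..., STATE_M] / joint.sum(axis=2)
    ll = np.log(c).sum(axis=1)
    if gene_ids is None:
        gene_ids = [""] * n
    return [
        SignatureProfile(gene_id=g, gamma=gamma[i], log_likelihood=float(ll[i]))
        for i, g in enumerate(gene_ids)
    ]


def band(gamma_value: float) -> str:
    """Band a posterior: >0.9 very_high; (0.5,0.9] high; (0.1,0.5] medium;
    <=0.1 low.  Intervals are closed on their upper ends below 0.9."""
    g = float(gamma_value)
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"posterior {g} outside [0, 1]")
    if g > 0.9:
        return "very_high"
    if g > 0.5:
        return "high"
    if g > 0.1:
        return "medium"
    return "low"


def band_counts(gammas: np.ndarray) -> dict[str, int]:
    """Number of segments per band over a flat array of posteriors."""
    out = {name: 0 for name in BAND_NAMES}
    for g in np.asarray(gammas, dtype=float).ravel():
        out[band(g)] += 1
    return out


def enumerate_posterior(model: HmmModel, segments: Sequence[str]) -> np.ndarray:
    """Posterior P(state_i = M | obs) by exhaustive path enumeration.

    Brute-force O(2^T) reference used to validate the scaled recursions;
    practical only for T <= ~16.
    """
    e = model.emissions(segments)
    T = len(e)
    if T > 20:
        raise ValueError("enumeration oracle limited to T <= 20")
    mass = np.zeros(T)
    total = 0.0
    for bits in range(2 ** T):
        path = [(bits >> t) & 1 for t in range(T)]
        p = model.pi[path[0]] * e[0, path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]] * e[t, path[t]]
        total += p
        for t in range(T):
            if path[t] == STATE_M:
                mass[t] += p
    return mass / total
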