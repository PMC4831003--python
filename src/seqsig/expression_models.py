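"""Expression prediction from H3K27ac profiles and sequence signatures.

Two predictors:

* a fractional-response logistic model mapping measured peak heights in
  200-bp windows around the TSS to the probability that a gene is
  expressed (targets are log-levels rescaled into [0, 1], fit by
  Bernoulli cross-entropy, which reduces to ordinary logistic regression
  for 0/1 targets);
* a small neural network mapping the 334 per-segment sequence signatures
  to log expression, whose 334→2 encoder is initialized from an
  autoencoder bottleneck trained to reconstruct the signature profiles.

The autoencoder/network stack is a deliberately minimal numpy MLP
(sigmoid hidden layer, linear output, Adam) with principal-component
encoder initialization and an exact least-squares solve of the linear
output layer, which makes runs fully deterministic per seed.

Evaluation metrics follow rank conventions: AUC via the Mann-Whitney
statistic with tie correction, the Wilcoxon rank-sum W as the rank sum
of the first sample with a normal-approximation p-value, and a df=1
chi-squared without continuity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import roc_auc_score

from .region_io import ExpressionTable

logger = logging.getLogger("seqsig")

DEFAULT_L2 = 1e-4
DEFAULT_TRAIN_SIZE = 10_000
DEFAULT_VALIDATION_SIZE = 3_000


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

def expression_target(table: ExpressionTable) -> pd.Series:
    """Per-gene probability-scale target: log2(FPKM+1) / max log level."""
    log_level = table.log_level
    max_level = log_level.max()
    if max_level <= 0:
        raise ValueError("all genes have zero expression; targets undefined")
    return log_level / max_level


# ---------------------------------------------------------------------------
# fractional logistic model
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LogisticModel:
    """Fractional-response logistic regression over K window features."""

    intercept: float
    coef: np.ndarray
    n_iter: int = 0
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return _sigmoid(self.intercept + X @ self.coef)


class ConvergenceError(RuntimeError):
    pass


def fit_logistic(
    X: np.ndarray,
    p: np.ndarray,
    l2: float = DEFAULT_L2,
    max_iter: int = 2000,
    grad_tol: float = 1e-6,
) -> LogisticModel:
    """Fit logistic coefficients to fractional targets p in [0, 1].

    Minimizes mean Bernoulli cross-entropy (a quasi-likelihood valid for
    continuous targets) plus an L2 penalty on the slopes, via L-BFGS with
    analytic gradients.  Raises ConvergenceError when the gradient norm
    stays above ``grad_tol``.
    """
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (genes x features)")
    n, k = X.shape
    if len(p) != n:
        raise ValueError("X and targets misaligned")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("targets must lie in [0, 1]")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than features ({k})")

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        b0, beta = w[0], w[1:]
        z = b0 + X @ beta
        # cross-entropy via logaddexp for stability
        ce = np.mean(np.logaddexp(0.0, z) - p * z)
        mu = _sigmoid(z)
        r = (mu - p) / n
        grad = np.empty_like(w)
        grad[0] = r.sum()
        grad[1:] = X.T @ r + 2.0 * l2 * beta
        return ce + l2 * float(beta @ beta), grad

    res = optimize.minimize(
        objective, np.zeros(k + 1), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 1e-10, "ftol": 1e-14},
    )
    gnorm = float(np.linalg.norm(objective(res.x)[1]))
    if gnorm > grad_tol:
        raise ConvergenceError(
            f"logistic fit did not converge after {res.nit} iterations "
            f"(gradient norm {gnorm:.2e})"
        )
    return LogisticModel(
        intercept=float(res.x[0]), coef=res.x[1:], n_iter=int(res.nit),
        converged=True,
    )


def tss_window_features(
    segment_heights: np.ndarray, span: int = 2000, width: int = 200
) -> np.ndarray:
    """Collapse per-segment heights into K non-overlapping ``width``-bp
    window features centred on the TSS (K = span/width; default 10)."""
    H = np.atleast_2d(np.asarray(segment_heights, dtype=float))
    n_seg = H.shape[1]
    seg_per_win = width // 6
    k = span // width
    centre = n_seg // 2
    lo = centre - (k // 2) * seg_per_win
    feats = [
        H[:, lo + j * seg_per_win : lo + (j + 1) * seg_per_win].mean(axis=1)
        for j in range(k)
    ]
    return np.column_stack(feats)


# ---------------------------------------------------------------------------
# autoencoder + expression network (numpy MLP)
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class AutoencoderModel:
    """Bottleneck autoencoder: x → sigmoid(xW_e + b_e) → hW_d + b_d."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    mean: np.ndarray
    explained_variance: float
    seed: int
    epochs: int
    learning_rate: float

    @property
    def latent_dim(self) -> int:
        return self.W_enc.shape[1]

    def encode(self, S: np.ndarray) -> np.ndarray:
        S = np.atleast_2d(np.asarray(S, dtype=float))
        return _sigmoid((S - self.mean) @ self.W_enc + self.b_enc)

    def decode(self, H: np.ndarray) -> np.ndarray:
        return np.atleast_2d(H) @ self.W_dec + self.b_dec

    def reconstruct(self, S: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(S))


def _explained_variance(S: np.ndarray, recon: np.ndarray) -> float:
    ss_total = float(((S - S.mean(axis=0)) ** 2).sum())
    if ss_total == 0:
        raise ValueError("constant input: explained variance undefined")
    return 1.0 - float(((S - recon) ** 2).sum()) / ss_total


def _solve_linear_output(H: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact least-squares weights/bias for a linear layer H → Y."""
    Hc = np.column_stack([H, np.ones(len(H))])
    sol, *_ = np.linalg.lstsq(Hc, Y, rcond=None)
    return sol[:-1], sol[-1]


def fit_autoencoder(
    S: np.ndarray,
    latent: int = 2,
    seed: int = 0,
    epochs: int = 500,
    learning_rate: float = 1e-3,
) -> AutoencoderModel:
    """Train the 334→latent→334 autoencoder on signature profiles in [0, 1].

    The encoder is initialized on the top principal components (scaled so
    the sigmoid operates in its near-linear range, plus a small seeded
    jitter) and the linear decoder is solved exactly by least squares both
    at initialization and after Adam refinement.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ValueError("S must be 2-D (genes x positions)")
    if ((S < 0) | (S > 1)).any():
        raise ValueError("signature values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mean = S.mean(axis=0)
    Sc = S - mean
    if float((Sc ** 2).sum()) <= 1e-12 * S.size:
        raise ValueError("constant input: explained variance undefined")
    latent = min(latent, min(S.shape))
    # PCA initialization of the encoder
    _, sing, Vt = np.linalg.svd(Sc, full_matrices=False)
    V = Vt[:latent].T                          # p x latent
    z_sd = sing[:latent] / np.sqrt(max(len(S) - 1, 1))
    z_sd[z_sd == 0] = 1.0
    W_enc = V * (0.5 / z_sd)                   # keep pre-activations ~N(0, 0.5)
    W_enc += rng.normal(scale=1e-3, size=W_enc.shape)
    b_enc = np.zeros(latent)
    H = _sigmoid(Sc @ W_enc + b_enc)
    W_dec, b_dec = _solve_linear_output(H, S)

    params = [W_enc, b_enc, W_dec, b_dec]
    opt = _Adam(params, lr=learning_rate)
    n = len(S)
    for _ in range(epochs):
        U = Sc @ W_enc + b_enc
        H = _sigmoid(U)
        R = H @ W_dec + b_dec
        err = (R - S) / n                      # d(mean SSE/2)/dR up to factor
        gW_dec = H.T @ err
        gb_dec = err.sum(axis=0)
        dH = err @ W_dec.T
        dU = dH * H * (1.0 - H)
        gW_enc = Sc.T @ dU
        gb_enc = dU.sum(axis=0)
        opt.step(params, [gW_enc, gb_enc, gW_dec, gb_dec])
    H = _sigmoid(Sc @ W_enc + b_enc)
    W_dec, b_dec = _solve_linear_output(H, S)
    ev = _explained_variance(S, H @ W_dec + b_dec)
    return AutoencoderModel(
        W_enc=W_enc, b_enc=b_enc, W_dec=W_dec, b_dec=b_dec, mean=mean,
        explained_variance=ev, seed=seed, epochs=epochs,
        learning_rate=learning_rate,
    )


@dataclass
class ExpressionPredictor:
    """Signature → log-expression network, encoder warm-started from the
    autoencoder bottleneck."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    w_out: np.ndarray
    b_out: float
    mean: np.ndarray
    seed: int
    metrics: dict = field(default_factory=dict)

    def predict(self, S: np.ndarray) -> np.ndarray:
        S = np.atleast_2d(np.asarray(S, dtype=float))
        H = _sigmoid((S - self.mean) @ self.W_enc + self.b_enc)
        return H @ self.w_out + self.b_out


def split_train_validation(
    n: int,
    train_size: int = DEFAULT_TRAIN_SIZE,
    validation_size: int = DEFAULT_VALIDATION_SIZE,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/validation index split, scaled down proportionally when
    fewer than train+validation genes are available."""
    if n < 4:
        raise ValueError("need at least 4 genes to split")
    total = train_size + validation_size
    if n < total:
        scaled_train = max(int(round(n * train_size / total)), 2)
        scaled_val = n - scaled_train
        logger.warning(
            "only %d genes available; scaling split %d/%d -> %d/%d",
            n, train_size, validation_size, scaled_train, scaled_val,
        )
        train_size, validation_size = scaled_train, scaled_val
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return perm[:train_size], perm[train_size : train_size + validation_size]


def fit_expression_net(
    ae: AutoencoderModel,
    S: np.ndarray,
    y: np.ndarray,
    detected: np.ndarray | None = None,
    split: tuple[int, int] = (DEFAULT_TRAIN_SIZE, DEFAULT_VALIDATION_SIZE),
    seed: int = 0,
    epochs: int = 500,
    learning_rate: float = 1e-2,
) -> ExpressionPredictor:
    """Train the expression network on log levels y and report validation
    Spearman/Pearson and the ROC AUC against the detected flag.

    ``detected`` defaults to log2(FPKM+1) > 1, i.e. FPKM > 1.
    """
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(S) != len(y):
        raise ValueError("S and y misaligned")
    if detected is None:
        detected = y > 1.0
    detected = np.asarray(detected, dtype=bool)
    train_idx, val_idx = split_train_validation(
        len(S), split[0], split[1], seed=seed
    )
    Xtr, ytr = S[train_idx], y[train_idx]

    W_enc = ae.W_enc.copy()
    b_enc = ae.b_enc.copy()
    mean = ae.mean
    Xc = Xtr - mean
    H = _sigmoid(Xc @ W_enc + b_enc)
    w_out, b_out = _solve_linear_output(H, ytr)
    w_out = np.atleast_1d(w_out).astype(float)
    b_out = float(np.atleast_1d(b_out)[0])

    params = [W_enc, b_enc, w_out]
    opt = _Adam(params, lr=learning_rate)
    n = len(Xtr)
    for _ in range(epochs):
        U = Xc @ W_enc + b_enc
        H = _sigmoid(U)
        pred = H @ w_out + b_out
        err = (pred - ytr) / n
        gw = H.T @ err
        gb = float(err.sum())
        dU = np.outer(err, w_out) * H * (1.0 - H)
        gW_enc = Xc.T @ dU
        gb_enc = dU.sum(axis=0)
        opt.step(params, [gW_enc, gb_enc, gw])
        b_out -= opt.lr * gb  # plain step for the scalar bias
    H = _sigmoid(Xc @ W_enc + b_enc)
    w_out, b_out = _solve_linear_output(H, ytr)
    w_out = np.atleast_1d(w_out).astype(float)
    b_out = float(np.atleast_1d(b_out)[0])

    predictor = ExpressionPredictor(
        W_enc=W_enc, b_enc=b_enc, w_out=w_out, b_out=b_out, mean=mean,
        seed=seed,
    )
    val_pred = predictor.predict(S[val_idx])
    val_y = y[val_idx]
    val_det = detected[val_idx]
    m: dict[str, float] = {
        "pearson": float(stats.pearsonr(val_pred, val_y)[0]),
        "spearman": float(stats.spearmanr(val_pred, val_y)[0]),
        "n_train": int(len(train_idx)),
        "n_validation": int(len(val_idx)),
    }
    if val_det.any() and not val_det.all():
        m["auc"] = float(roc_auc_score(val_det, val_pred))
    else:
        m["auc"] = float("nan")
        warnings.warn("single-class detected flag in validation; AUC undefined")
    predictor.metrics = m
    return predictor


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rank-sum W of sample x (midranks for ties) and two-sided normal p.

    W is the sum of the combined-sample ranks of x; the normal
    approximation includes the tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    W = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return W, 1.0
    z = (W - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return W, float(p)


def chisq_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) for a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(chi2), float(p)


def auc_score(flags: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) statistic with tie correction."""
    flags = np.asarray(flags, dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError("AUC undefined for single-class truth")
    return float(roc_auc_score(flags, np.asarray(scores, dtype=float)))


def metrics(
    pred: np.ndarray,
    truth: np.ndarray,
    detected: np.ndarray | None = None,
) -> dict:
    """Evaluation bundle: Pearson, Spearman, AUC vs the detected flag,
    rank-sum W/p between detected and undetected genes, and a df=1
    chi-squared on detected x (prediction above its matching quantile)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth misaligned")
    if detected is None:
        detected = truth > 1.0
    detected = np.asarray(detected, dtype=bool)
    out = {
        "pearson": float(stats.pearsonr(pred, truth)[0]),
        "spearman": float(stats.spearmanr(pred, truth)[0]),
        "auc": auc_score(detected, pred),
    }
    W, p = wilcoxon_rank_sum(pred[detected], pred[~detected])
    out["wilcoxon_W"] = W
    out["wilcoxon_p"] = p
    cutoff = np.quantile(pred, 1.0 - detected.mean())
    pred_high = pred >= cutoff
    table = np.array(
        [
            [(pred_high & detected).sum(), (pred_high & ~detected).sum()],
            [(~pred_high & detected).sum(), (~pred_high & ~detected).sum()],
        ]
    )
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, chi_p = chisq_2x2(table)
        out["chisq"] = chi2
        out["chisq_p"] = chi_p
    return out
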