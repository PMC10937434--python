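"""Per-OAR one-class outlier models on single-contour features.

Three model families score how far a contour's feature vector sits from the
training distribution of acceptable contours:

* **z-score** — the maximum absolute per-feature standardised deviation;
* **Mahalanobis distance** — the quadratic form
  ``D(x) = (x - mu)^T Sigma^{-1} (x - mu)`` (squared form, no square root;
  thresholding is monotone-invariant so classification is unaffected);
* **autoencoder** — mean squared reconstruction error (MSRE) of a single
  hidden-layer network (20 -> 18 -> 20, sigmoid hidden units, linear
  output) trained on feature z-scores with an L2 weight penalty.

Training corpora are first cleaned with a robust median/MAD filter: any
contour whose features stray more than ``k`` (default 12) unscaled median
absolute deviations from the per-feature median is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit


@dataclass
class FeatureStats:
    """Per-feature location/spread statistics of a training table."""

    names: list[str]
    mean: np.ndarray
    std: np.ndarray
    median: np.ndarray
    mad: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.median = np.asarray(self.median, dtype=float)
        self.mad = np.asarray(self.mad, dtype=float)
        if np.any(self.std < 0) or np.any(self.mad < 0):
            raise ValueError("negative spread statistic")


@dataclass
class MdModel:
    """Mean and (shrinkage-regularised) covariance of training features."""

    mean: np.ndarray
    cov: np.ndarray
    cov_inv: np.ndarray


@dataclass
class AeModel:
    """Weights of the single hidden-layer autoencoder plus training config."""

    w1: np.ndarray  # (d, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden, d)
    b2: np.ndarray  # (d,)
    hidden: int = 18
    l2: float = 0.005
    max_epochs: int = 7000
    seed: int = 0
    final_loss: float = np.nan
    n_epochs: int = 0
    loss_history: list = field(default_factory=list, repr=False)


def fit_feature_stats(table: pd.DataFrame, feature_names: list[str]) -> FeatureStats:
    """Mean, sample std, median and unscaled MAD per feature column."""
    x = table[feature_names].to_numpy(dtype=float)
    median = np.median(x, axis=0)
    mad = np.median(np.abs(x - median), axis=0)
    return FeatureStats(
        names=list(feature_names),
        mean=x.mean(axis=0),
        std=x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1]),
        median=median,
        mad=mad,
    )


def mad_filter(table: pd.DataFrame, feature_names: list[str], k: float = 12.0
               ) -> tuple[pd.DataFrame, pd.Index]:
    """Drop rows whose features stray beyond ``k`` MAD from the median.

    A row is removed iff any feature satisfies |x - median| > k * MAD; the
    MAD is unscaled (no 1.4826 normal-consistency factor) and features with
    MAD = 0 are skipped.  Returns the filtered table and the removed index.
    Raises if every row would be removed (``k`` too small for the data).
    """
    x = table[feature_names].to_numpy(dtype=float)
    median = np.median(x, axis=0)
    mad = np.median(np.abs(x - median), axis=0)
    informative = mad > 0
    dev = np.abs(x - median)
    bad = (dev[:, informative] > k * mad[informative]).any(axis=1)
    if bad.all():
        raise ValueError("MAD filter removed every training row; k is too small")
    return table.loc[~bad], table.index[bad]


def zscore_metric(x: np.ndarray, stats: FeatureStats) -> float:
    """Maximum absolute z-score |x - mu| / sigma over all features.

    Features with sigma = 0 contribute 0 when x equals the mean and +inf
    otherwise (a zero-variance feature that moved is always suspicious).
    NaN entries (missing CT features) are imputed with the training mean,
    contributing 0.
    """
    x = _impute(np.asarray(x, dtype=float), stats.mean)
    dev = np.abs(x - stats.mean)
    z = np.where(stats.std > 0, dev / np.where(stats.std > 0, stats.std, 1.0),
                 np.where(dev > 0, np.inf, 0.0))
    return float(z.max())


def fit_md(table: pd.DataFrame, feature_names: list[str],
           shrinkage: float = 1e-6) -> MdModel:
    """Mean vector and shrinkage-regularised covariance of the features.

    Sigma = sample covariance + delta * (tr Sigma / d) * I keeps the inverse
    finite even for rank-deficient training tables.
    """
    x = table[feature_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features in MD training table")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    ridge = shrinkage * (np.trace(cov) / d if np.trace(cov) > 0 else 1.0)
    cov_reg = cov + ridge * np.eye(d)
    cov_inv = np.linalg.inv(cov_reg)
    cov_inv = 0.5 * (cov_inv + cov_inv.T)  # enforce symmetry
    return MdModel(mean=mean, cov=cov_reg, cov_inv=cov_inv)


def md_metric(x: np.ndarray, model: MdModel) -> float:
    """Squared Mahalanobis distance (x - mu)^T Sigma^{-1} (x - mu)."""
    x = _impute(np.asarray(x, dtype=float), model.mean)
    if x.shape[0] != model.mean.shape[0]:
        raise ValueError("feature dimension mismatch")
    delta = x - model.mean
    return float(delta @ model.cov_inv @ delta)


def zscore_transform(x: np.ndarray, stats: FeatureStats) -> np.ndarray:
    """Signed per-feature z-scores; sigma = 0 features map to 0."""
    x = _impute(np.asarray(x, dtype=float), stats.mean)
    safe = np.where(stats.std > 0, stats.std, 1.0)
    z = (x - stats.mean) / safe
    return np.where(stats.std > 0, z, 0.0)


def _impute(x: np.ndarray, fill: np.ndarray) -> np.ndarray:
    if np.isnan(x).any():
        x = np.where(np.isnan(x), fill, x)
    return x


def fit_autoencoder(z_table: np.ndarray, hidden: int = 18, l2: float = 0.005,
                    max_epochs: int = 7000, seed: int = 0,
                    lr0: float = 0.05, rel_tol: float = 1e-9) -> AeModel:
    """Train the autoencoder on an (n, d) array of feature z-scores.

    Full-batch gradient descent with a backtracking adaptive step: a step
    that would increase the loss is halved and retried, an accepted step
    grows the learning rate slightly.  The loss is the mean squared
    reconstruction error plus ``l2 * sum(W**2)`` over both weight matrices
    (biases unpenalised).  Training stops at ``max_epochs``, when the
    relative loss change drops below ``rel_tol``, or when the step size
    underflows.  Deterministic given ``seed``.
    """
    z = np.asarray(z_table, dtype=float)
    if z.ndim != 2:
        raise ValueError("z_table must be 2D")
    n, d = z.shape
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / (d + hidden))
    w1 = rng.uniform(-lim1, lim1, size=(d, hidden))
    b1 = np.zeros(hidden)
    w2 = rng.uniform(-lim1, lim1, size=(hidden, d))
    b2 = np.zeros(d)

    def loss_and_grads(w1, b1, w2, b2):
        a = expit(z @ w1 + b1)
        xhat = a @ w2 + b2
        resid = xhat - z
        mse = float((resid ** 2).mean())
        loss = mse + l2 * (float((w1 ** 2).sum()) + float((w2 ** 2).sum()))
        scale = 2.0 / (n * d)
        g_xhat = scale * resid
        g_w2 = a.T @ g_xhat + 2.0 * l2 * w2
        g_b2 = g_xhat.sum(axis=0)
        g_a = g_xhat @ w2.T
        g_pre = g_a * a * (1.0 - a)
        g_w1 = z.T @ g_pre + 2.0 * l2 * w1
        g_b1 = g_pre.sum(axis=0)
        return loss, (g_w1, g_b1, g_w2, g_b2)

    loss, grads = loss_and_grads(w1, b1, w2, b2)
    lr = lr0
    history = [loss]
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        accepted = False
        for _ in range(40):
            trial = (w1 - lr * grads[0], b1 - lr * grads[1],
                     w2 - lr * grads[2], b2 - lr * grads[3])
            new_loss, new_grads = loss_and_grads(*trial)
            if np.isfinite(new_loss) and new_loss <= loss:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            break
        w1, b1, w2, b2 = trial
        rel_change = (loss - new_loss) / max(loss, 1e-300)
        loss, grads = new_loss, new_grads
        history.append(loss)
        lr *= 1.05
        if rel_change < rel_tol:
            break
    if not np.isfinite(loss):
        raise RuntimeError("autoencoder training diverged; lower the learning rate")
    return AeModel(w1=w1, b1=b1, w2=w2, b2=b2, hidden=hidden, l2=l2,
                   max_epochs=max_epochs, seed=seed, final_loss=loss,
                   n_epochs=epoch, loss_history=history)


def ae_reconstruct(z: np.ndarray, model: AeModel) -> np.ndarray:
    """Forward pass (sigmoid hidden, linear output) on z-scored features."""
    z = np.asarray(z, dtype=float)
    a = expit(z @ model.w1 + model.b1)
    return a @ model.w2 + model.b2


def ae_metric(x: np.ndarray, model: AeModel, stats: FeatureStats) -> float:
    """Mean squared reconstruction error of the z-scored feature vector."""
    z = zscore_transform(x, stats)
    xhat = ae_reconstruct(z, model)
    return float(((xhat - z) ** 2).mean())
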