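"""PLS1 time regression: spectra vs days of storage.

NIPALS decomposition of mean-centred spectra against the centred response
(days in storage).  For a single response the NIPALS component extraction is
closed-form per component:

    w_a = X'y / ||X'y||     (weights)
    t_a = X w_a             (scores)
    p_a = X't_a / t_a't_a   (loadings)
    q_a = y't_a / t_a't_a   (response loading)

with X and y deflated after each component.  The regression vector for the
first ``a`` components is ``b_a = W_a (P_a' W_a)^{-1} q_a``.

Metrics follow chemometrics convention: SEC = sqrt(RSS/n) on the calibration
set, SECV = sqrt(PRESS/n) from segment-wise cross-validation with contiguous
blocks left out in acquisition order (default block size 6 — one fruit-day),
R2c = 1 - RSS/TSS and R2cv = 1 - PRESS/TSS.  The number of latent variables is
capped at 15; the chosen rank minimises SECV.

A roughness statistic (normalised sum of squared second differences of the
regression vector) automates the visual "jaggedness" screen against
overfitting: models > 10x rougher than their own 2-LV baseline are flagged,
not rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .exceptions import (
    DegenerateResponseError,
    IncompatibleGridError,
    InsufficientDataError,
    LimitExceededError,
)

MAX_LATENT_VARIABLES = 15


def _nipals_pls1(X0: np.ndarray, y0: np.ndarray, n_lv: int):
    """Return (W, P, Q, T) of the NIPALS PLS1 decomposition of centred data."""
    n, p = X0.shape
    X = X0.copy()
    y = y0.astype(float).copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= np.finfo(float).tiny:
            # X carries no further covariance with y; pad with zeros
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= np.finfo(float).tiny:
            break
        p_a = X.T @ t / tt
        q_a = y @ t / tt
        X = X - np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t
    return W, P, Q, T


def _coefficients(W, P, Q, a: int) -> np.ndarray:
    """Regression vector using the first ``a`` components."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:a]
    M = Pa.T @ Wa
    return Wa @ np.linalg.solve(M, Qa)


def roughness(b: np.ndarray) -> float:
    """Normalised jaggedness of a regression vector: sum of squared second
    differences over the sum of squared coefficients."""
    b = np.asarray(b, dtype=float).ravel()
    if b.size < 3 or not np.any(b):
        return 0.0
    return float((np.diff(b, n=2) ** 2).sum() / (b**2).sum())


class PLSTimeRegression:
    """PLS1 model of spectra against a numeric response (days of storage).

    Parameters
    ----------
    dataset
        Training spectra (raw; the model mean-centres internally).
    y
        Response per spectrum; defaults to the ``day`` metadata column.
    n_components
        Latent variables to extract (1..15).
    """

    def __init__(
        self,
        dataset: SpectralDataset,
        y=None,
        n_components: int = 10,
    ):
        self.dataset = dataset
        if y is None:
            y = dataset.meta["day"].to_numpy(dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.y.size != dataset.n_spectra:
            raise InsufficientDataError("response length must match spectra count")
        if n_components < 1:
            raise LimitExceededError("need at least 1 latent variable")
        if n_components > MAX_LATENT_VARIABLES:
            raise LimitExceededError(
                f"latent variables limited to {MAX_LATENT_VARIABLES}"
            )
        if dataset.n_spectra <= n_components:
            raise InsufficientDataError("need n_spectra > n_components")
        if np.ptp(self.y) == 0:
            raise DegenerateResponseError("response is constant")
        self.n_components = n_components

    def fit(self) -> "PLSResults":
        X = self.dataset.absorbance
        x_mean = X.mean(axis=0)
        y_mean = self.y.mean()
        W, P, Q, T = _nipals_pls1(X - x_mean, self.y - y_mean, self.n_components)
        return PLSResults(self, x_mean, y_mean, W, P, Q, T)


class PLSResults:
    """Fitted PLS1 model: decomposition, regression vector and fit metrics."""

    def __init__(self, model, x_mean, y_mean, W, P, Q, T):
        self.model = model
        self.wavelengths = model.dataset.wavelengths.copy()
        self.x_mean = x_mean
        self.y_mean = y_mean
        self.weights = W
        self.loadings = P
        self.y_loadings = Q
        self.scores = T
        self.n_lv = model.n_components
        self.coef = _coefficients(W, P, Q, self.n_lv)
        self.intercept = float(y_mean - x_mean @ self.coef)
        y = model.y
        resid = y - self.fitted_values
        tss = float(((y - y.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        self.sec = float(np.sqrt(rss / y.size))
        self.r2_calibration = 1.0 - rss / tss
        b2 = _coefficients(W, P, Q, min(2, self.n_lv))
        base = roughness(b2)
        self.roughness = roughness(self.coef)
        self.jagged_flag = bool(base > 0 and self.roughness > 10.0 * base)

    @property
    def fitted_values(self) -> np.ndarray:
        return self.intercept + self.model.dataset.absorbance @ self.coef

    def coef_for(self, a: int) -> np.ndarray:
        """Regression vector truncated to the first ``a`` latent variables."""
        if not 1 <= a <= self.n_lv:
            raise LimitExceededError(f"a must be in 1..{self.n_lv}")
        return _coefficients(self.weights, self.loadings, self.y_loadings, a)

    def predict(self, data) -> np.ndarray:
        """Predicted days for new spectra on the training grid."""
        if isinstance(data, SpectralDataset):
            wl = data.wavelengths
            X = data.absorbance
        else:
            X = np.atleast_2d(np.asarray(data, dtype=float))
            wl = self.wavelengths if X.shape[1] == self.wavelengths.size else None
        if (
            wl is None
            or wl.size != self.wavelengths.size
            or not np.allclose(wl, self.wavelengths)
        ):
            raise IncompatibleGridError("prediction grid differs from training grid")
        return self.intercept + X @ self.coef

    def summary(self) -> str:
        lines = ["PLS1 time-regression model", "=" * 40]
        lines.append(f"n = {self.model.dataset.n_spectra}, "
                     f"channels = {self.wavelengths.size}, LV = {self.n_lv}")
        lines.append(f"R2c  = {self.r2_calibration:.4f}")
        lines.append(f"SEC  = {self.sec:.4f} days")
        lines.append(f"roughness = {self.roughness:.3g}"
                     + ("  [flagged jagged]" if self.jagged_flag else ""))
        b = self.coef
        top = np.argsort(np.abs(b))[::-1][:5]
        tops = ", ".join(
            f"{self.wavelengths[i]:.0f} nm ({b[i]:+.2g})" for i in sorted(top)
        )
        lines.append(f"largest coefficients: {tops}")
        return "\n".join(lines)


@dataclass
class CVResults:
    """Per-rank calibration/validation metrics from segment cross-validation."""

    metrics: pd.DataFrame          # columns n_lv, sec, r2c, secv, r2cv
    n_lv: int                      # argmin-SECV choice
    cv_predictions: np.ndarray = field(repr=False)  # at the chosen rank
    segment: int = 6
    method: str = "block"

    @property
    def secv(self) -> float:
        row = self.metrics[self.metrics["n_lv"] == self.n_lv].iloc[0]
        return float(row["secv"])

    @property
    def r2_cv(self) -> float:
        row = self.metrics[self.metrics["n_lv"] == self.n_lv].iloc[0]
        return float(row["r2cv"])

    def to_csv(self, path) -> None:
        self.metrics.to_csv(path, index=False)


def _folds(n: int, segment: int, method: str):
    idx = np.arange(n)
    if method == "venetian":
        n_folds = int(np.ceil(n / segment))
        return [idx[f::n_folds] for f in range(n_folds)]
    return [idx[i : i + segment] for i in range(0, n, segment)]


def cross_validate(
    ds: SpectralDataset,
    y=None,
    n_lv_max: int = MAX_LATENT_VARIABLES,
    segment: int = 6,
    method: str = "block",
) -> CVResults:
    """Stepwise-exclusion cross-validation of the PLS1 time regression.

    Contiguous blocks of ``segment`` spectra (in dataset order) are left out in
    turn; each left-out spectrum is predicted once per candidate rank.  The
    venetian-blind alternative interleaves folds instead (``method``).

    Returns per-rank SEC/R2c (full-data fit) and SECV/R2cv, plus the rank with
    the lowest SECV.
    """
    if segment <= 0:
        raise LimitExceededError("segment size must be positive")
    if y is None:
        y = ds.meta["day"].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = ds.n_spectra
    if n < 2 * segment:
        raise InsufficientDataError("need at least two cross-validation segments")
    if n_lv_max > MAX_LATENT_VARIABLES:
        raise LimitExceededError(f"latent variables limited to {MAX_LATENT_VARIABLES}")
    n_lv_max = min(n_lv_max, n - segment - 1, ds.n_channels)

    X = ds.absorbance
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise DegenerateResponseError("response is constant")

    press = np.zeros(n_lv_max)
    cv_pred = np.zeros((n, n_lv_max))
    for fold in _folds(n, segment, method):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, ytr = X[mask], y[mask]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, Q, _T = _nipals_pls1(Xtr - x_mean, ytr - y_mean, n_lv_max)
        X0 = X[fold] - x_mean
        for a in range(1, n_lv_max + 1):
            b = _coefficients(W, P, Q, a)
            cv_pred[fold, a - 1] = y_mean + X0 @ b
    for a in range(n_lv_max):
        press[a] = float(((y - cv_pred[:, a]) ** 2).sum())

    # full-data fit for calibration metrics at every rank
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    W, P, Q, _T = _nipals_pls1(X - x_mean, y - y_mean, n_lv_max)
    rows = []
    for a in range(1, n_lv_max + 1):
        b = _coefficients(W, P, Q, a)
        fit = y_mean + (X - x_mean) @ b
        rss = float(((y - fit) ** 2).sum())
        rows.append(
            {
                "n_lv": a,
                "sec": np.sqrt(rss / n),
                "r2c": 1.0 - rss / tss,
                "secv": np.sqrt(press[a - 1] / n),
                "r2cv": 1.0 - press[a - 1] / tss,
            }
        )
    metrics = pd.DataFrame(rows)
    best = int(metrics.loc[metrics["secv"].idxmin(), "n_lv"])
    return CVResults(
        metrics=metrics,
        n_lv=best,
        cv_predictions=cv_pred[:, best - 1],
        segment=segment,
        method=method,
    )


def fit_plsr(ds: SpectralDataset, y=None, n_lv: int = 10) -> PLSResults:
    """Functional wrapper: fit a PLS1 time regression with ``n_lv`` components."""
    return PLSTimeRegression(ds, y=y, n_components=n_lv).fit()
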