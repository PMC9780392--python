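"""Soft independent modelling of class analogies (SIMCA).

One principal-component submodel is fitted per class (here: storage day).  A
sample is judged by its squared reconstruction residual under each class model;
classification assigns the class with the smallest standardised residual
distance.  Class separation and variable importance are both expressed through
cross-fitted residual variances:

* ``s_ij^2`` — mean squared residual of class-*i* samples reconstructed by the
  class-*j* model (pooled over channels, or kept per channel).
* interclass distance ``d_ij = sqrt((s_ij^2 + s_ji^2) / (s_ii^2 + s_jj^2)) - 1``
  so two identical classes score ~0.
* discriminating power per channel
  ``DP(l) = sqrt( sum_{i<j} (s_ij^2(l) + s_ji^2(l)) / sum_i s_ii^2(l) )``,
  flat ~1 for two indistinguishable classes and peaked at channels that drive
  separation.

SIMCA consumes raw (not SNV-treated) spectra; each submodel centres its own
class data.  The retained rank per class is the smallest number of components
explaining a target fraction of class variance (default 95%), capped at
``min(5, n_class - 2)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectralDataset
from .exceptions import (
    DegenerateModelError,
    IncompatibleGridError,
    NeedTwoClassesError,
    UndersizedClassError,
)


@dataclass
class _ClassModel:
    label: object
    mean: np.ndarray        # (p,)
    loadings: np.ndarray    # (p, k), orthonormal columns
    k: int
    n: int
    explained: float        # fraction of class variance captured


class SIMCA:
    """SIMCA classifier of spectra by a metadata class key.

    Parameters
    ----------
    dataset
        Training spectra (raw absorbance; submodels centre per class).
    class_key
        Metadata column defining the classes, default ``"day"``.
    variance_explained
        Per-class PCA rank rule: smallest k whose cumulative explained
        variance reaches this fraction.
    max_components
        Hard cap on the retained rank (further capped at ``n_class - 2``).
    """

    def __init__(
        self,
        dataset: SpectralDataset,
        class_key: str = "day",
        variance_explained: float = 0.95,
        max_components: int = 5,
    ):
        self.dataset = dataset
        self.class_key = class_key
        self.variance_explained = variance_explained
        self.max_components = max_components

    def fit(self) -> "SIMCAResults":
        ds = self.dataset
        labels = ds.meta[self.class_key].to_numpy()
        classes = sorted(pd.unique(labels).tolist())
        if len(classes) < 2:
            raise NeedTwoClassesError("SIMCA needs at least two classes")
        models = []
        groups = {}
        for c in classes:
            Xc = ds.absorbance[labels == c]
            if Xc.shape[0] < 3:
                raise UndersizedClassError(
                    f"class {c!r} has {Xc.shape[0]} spectra (< 3)"
                )
            mu = Xc.mean(axis=0)
            Xc0 = Xc - mu
            # economy SVD; principal directions in rows of Vt
            _U, s, Vt = np.linalg.svd(Xc0, full_matrices=False)
            var = s**2
            total = var.sum()
            if total <= 0:
                ratio = np.ones_like(var)
            else:
                ratio = np.cumsum(var) / total
            cap = max(1, min(self.max_components, Xc.shape[0] - 2))
            k = int(np.searchsorted(ratio, self.variance_explained) + 1)
            k = min(k, cap)
            models.append(
                _ClassModel(
                    label=c,
                    mean=mu,
                    loadings=Vt[:k].T.copy(),
                    k=k,
                    n=Xc.shape[0],
                    explained=float(ratio[k - 1]),
                )
            )
            groups[c] = Xc
        return SIMCAResults(self, models, groups)


class SIMCAResults:
    """Fitted SIMCA model: submodels, cross residual variances, distances,
    discriminating power, and classification."""

    def __init__(self, model: SIMCA, class_models, groups):
        self.model = model
        self.wavelengths = model.dataset.wavelengths.copy()
        self.class_models = class_models
        self.classes = [m.label for m in class_models]
        C = len(class_models)
        p = self.wavelengths.size
        # Cross residual variances with the classical SIMCA degree-of-freedom
        # corrections: fitting a k-component model to its own n samples leaves
        # (n-k-1)(p-k) residual degrees of freedom, while foreign samples keep
        # (p-k) each.  Without the correction the in-sample optimism of the
        # class PCA inflates every cross/self variance ratio.
        self.s2_channel = np.zeros((C, C, p))
        self.s2_pooled = np.zeros((C, C))
        for i, mi in enumerate(class_models):
            Xi = groups[mi.label]
            for j, mj in enumerate(class_models):
                R = self._residual(Xi, mj)
                if i == j:
                    dof = max((mi.n - mi.k - 1) * (p - mi.k), 1)
                else:
                    dof = max(mi.n * (p - mj.k), 1)
                ss_channel = (R**2).sum(axis=0)
                self.s2_pooled[i, j] = ss_channel.sum() / dof
                # per-channel variances scaled so their mean equals the pooled
                self.s2_channel[i, j] = ss_channel * p / dof
        self._dp = None
        self._D = None

    # -- internals -----------------------------------------------------------
    @staticmethod
    def _residual(X: np.ndarray, m: _ClassModel) -> np.ndarray:
        X0 = X - m.mean
        return X0 - (X0 @ m.loadings) @ m.loadings.T

    def _index(self, label) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"class {label!r} not fitted")

    # -- statistics ----------------------------------------------------------
    @property
    def interclass_distances(self) -> pd.DataFrame:
        """Symmetric distance matrix; ~0 for indistinguishable classes."""
        if self._D is None:
            C = len(self.classes)
            D = np.zeros((C, C))
            for i in range(C):
                for j in range(i + 1, C):
                    denom = self.s2_pooled[i, i] + self.s2_pooled[j, j]
                    if denom <= 0:
                        raise DegenerateModelError(
                            "zero self-residual variance in both classes"
                        )
                    num = self.s2_pooled[i, j] + self.s2_pooled[j, i]
                    D[i, j] = D[j, i] = float(np.sqrt(num / denom) - 1.0)
            self._D = D
        return pd.DataFrame(self._D, index=self.classes, columns=self.classes)

    def interclass_distance(self, i, j) -> float:
        """Distance between classes labelled ``i`` and ``j`` (0 for i == j)."""
        a, b = self._index(i), self._index(j)
        return float(self.interclass_distances.to_numpy()[a, b])

    @property
    def discriminating_power(self) -> np.ndarray:
        """Per-channel variable importance (>= 0, unitless ratio)."""
        if self._dp is None:
            C = len(self.classes)
            num = np.zeros(self.wavelengths.size)
            for i in range(C):
                for j in range(i + 1, C):
                    num += self.s2_channel[i, j] + self.s2_channel[j, i]
            den = self.s2_channel[np.arange(C), np.arange(C)].sum(axis=0)
            floor = np.finfo(float).eps
            if np.any(den <= floor):
                warnings.warn(
                    "zero within-class residual variance at some channels; "
                    "flooring denominator at machine epsilon"
                )
                den = np.maximum(den, floor)
            self._dp = np.sqrt(num / den)
        return self._dp

    # -- classification ------------------------------------------------------
    def _check_grid(self, wavelengths) -> None:
        wl = np.asarray(wavelengths, dtype=float).ravel()
        if wl.size != self.wavelengths.size or not np.allclose(wl, self.wavelengths):
            raise IncompatibleGridError("sample wavelength grid differs from model")

    def distances(self, X: np.ndarray) -> np.ndarray:
        """Standardised residual distance of each sample to each class:
        RMS residual under the class model divided by the class's own pooled
        residual SD."""
        X = np.atleast_2d(X)
        p = self.wavelengths.size
        out = np.zeros((X.shape[0], len(self.classes)))
        for j, m in enumerate(self.class_models):
            s2_x = (self._residual(X, m) ** 2).sum(axis=1) / max(p - m.k, 1)
            s_jj = np.sqrt(self.s2_pooled[j, j])
            if s_jj <= 0:
                s_jj = np.sqrt(np.finfo(float).eps)
            out[:, j] = np.sqrt(s2_x) / s_jj
        return out

    def classify(self, data, alpha: float = 0.05) -> pd.DataFrame:
        """Assign each spectrum the class with the smallest distance.

        ``no_match`` flags samples whose best residual variance exceeds the
        class critical limit (F test at ``alpha``); assignment itself stays
        argmin, with no reject class.
        """
        if isinstance(data, SpectralDataset):
            self._check_grid(data.wavelengths)
            X = data.absorbance
        else:
            X = np.atleast_2d(np.asarray(data, dtype=float))
            self._check_grid_width(X)
        d = self.distances(X)
        best = d.argmin(axis=1)
        crit = np.array([self._critical_ratio(m, alpha) for m in self.class_models])
        no_match = d[np.arange(len(best)), best] ** 2 > crit[best]
        frame = pd.DataFrame(d, columns=[f"d_{c}" for c in self.classes])
        frame.insert(0, "label", [self.classes[b] for b in best])
        frame["no_match"] = no_match
        return frame

    def _check_grid_width(self, X) -> None:
        if X.shape[1] != self.wavelengths.size:
            raise IncompatibleGridError(
                f"{X.shape[1]} channels, model expects {self.wavelengths.size}"
            )

    def _critical_ratio(self, m: _ClassModel, alpha: float) -> float:
        # F limit on (sample residual variance / class residual variance)
        p = self.wavelengths.size
        df1 = max(p - m.k, 1)
        df2 = max((m.n - m.k - 1) * (p - m.k), 1)
        return float(stats.f.ppf(1 - alpha, df1, df2))

    def predict(self, data) -> np.ndarray:
        return self.classify(data)["label"].to_numpy()

    def accuracy(self, data=None, class_key: str | None = None) -> float:
        """Fraction of spectra assigned their true class (argmin, no reject)."""
        ds = data if data is not None else self.model.dataset
        key = class_key or self.model.class_key
        truth = ds.meta[key].to_numpy()
        return float((self.predict(ds) == truth).mean())

    # -- presentation & persistence -------------------------------------------
    def summary(self) -> str:
        lines = ["SIMCA classification model", "=" * 40]
        lines.append(f"classes ({self.model.class_key}): {self.classes}")
        lines.append(f"{'class':>8} {'n':>5} {'k':>3} {'explained':>10}")
        for m in self.class_models:
            lines.append(f"{m.label!s:>8} {m.n:>5} {m.k:>3} {m.explained:>10.3f}")
        D = self.interclass_distances.to_numpy()
        iu = np.triu_indices(len(self.classes), 1)
        lines.append(
            f"interclass distance: min={D[iu].min():.3f} "
            f"median={np.median(D[iu]):.3f} max={D[iu].max():.3f}"
        )
        dp = self.discriminating_power
        top = np.argsort(dp)[::-1][:5]
        tops = ", ".join(f"{self.wavelengths[i]:.0f} nm ({dp[i]:.1f})" for i in sorted(top))
        lines.append(f"top discriminating-power channels: {tops}")
        return "\n".join(lines)

    def to_json(self, path=None):
        """Serialise means, loadings and variances for later classification."""
        payload = {
            "class_key": self.model.class_key,
            "wavelengths": self.wavelengths.tolist(),
            "classes": [
                {
                    "label": m.label,
                    "n": m.n,
                    "k": m.k,
                    "explained": m.explained,
                    "mean": m.mean.tolist(),
                    "loadings": m.loadings.tolist(),
                }
                for m in self.class_models
            ],
            "s2_channel": self.s2_channel.tolist(),
            "s2_pooled": self.s2_pooled.tolist(),
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, source) -> "SIMCAResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        obj = cls.__new__(cls)
        obj.model = None
        obj.wavelengths = np.asarray(payload["wavelengths"], dtype=float)
        obj.class_models = [
            _ClassModel(
                label=c["label"],
                mean=np.asarray(c["mean"], dtype=float),
                loadings=np.asarray(c["loadings"], dtype=float),
                k=int(c["k"]),
                n=int(c["n"]),
                explained=float(c["explained"]),
            )
            for c in payload["classes"]
        ]
        obj.classes = [m.label for m in obj.class_models]
        obj.s2_channel = np.asarray(payload["s2_channel"], dtype=float)
        obj.s2_pooled = np.asarray(payload["s2_pooled"], dtype=float)
        obj._dp = None
        obj._D = None
        return obj


def fit_simca(
    ds: SpectralDataset,
    class_key: str = "day",
    variance_explained: float = 0.95,
    max_components: int = 5,
) -> SIMCAResults:
    """Functional wrapper: fit a SIMCA model on ``ds``."""
    return SIMCA(ds, class_key, variance_explained, max_components).fit()
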