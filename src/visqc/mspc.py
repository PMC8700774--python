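"""Multivariate statistical process control on PCA scores.

A PCA model is calibrated on feature vectors of in-control ("fresh")
samples.  A new sample x is autoscaled to z, projected onto the A retained
loadings P to give scores t = P'z, and judged by two statistics:

* Hotelling's T^2 = sum_a t_a^2 / lambda_a, the Mahalanobis distance of the
  scores from the calibration mean (lambda_a are the calibration score
  variances);
* Q (squared prediction error) = ||z - P t||^2, the part of the sample the
  model cannot explain.

A sample conforms to the in-control population at level alpha when both
statistics fall strictly below their 95% (by default) limits:

    T2_lim = A (O - 1) / (O - A) * F_{A, O-A; alpha}
    Q_lim  = (nu / 2 mu) * chi2_{2 mu^2 / nu; alpha}

with O the calibration size, mu and nu the mean and variance of the
calibration Q residuals (the Box approximation, matching a g*chi2_h fit by
moments).  A reading of nu as the standard deviation is selectable via
``nu_convention="sd"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import (DegreesOfFreedomError, FeatureMapError, MomentError,
                         RankError)


def t2_limit(A: int, O: int, alpha: float = 0.05,
             new_observation: bool = False) -> float:
    """F-distribution confidence limit for Hotelling's T^2.

    The calibration form ``A(O-1)/(O-A) * F`` is the default; the
    new-observation form ``A(O^2-1)/(O(O-A)) * F`` is available via
    ``new_observation`` (the difference is negligible for large O).
    """
    if O <= A:
        raise DegreesOfFreedomError(f"need O > A (got O={O}, A={A})")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    fq = stats.f.ppf(1.0 - alpha, A, O - A)
    if new_observation:
        return A * (O ** 2 - 1) / (O * (O - A)) * fq
    return A * (O - 1) / (O - A) * fq


def q_limit(mu: float, nu: float, alpha: float = 0.05,
            nu_convention: str = "variance") -> float:
    """Box chi-square confidence limit for the Q (SPE) statistic.

    Matches a scaled chi-square g*chi2_h to the calibration residuals by
    moments: g = nu/(2 mu), h = 2 mu^2/nu, with ``mu`` the mean and ``nu``
    the variance of the calibration Q values (``nu_convention="sd"`` squares
    nu first).
    """
    if mu <= 0 or nu <= 0:
        raise MomentError("mu and nu must be positive")
    if nu_convention == "sd":
        nu = nu ** 2
    elif nu_convention != "variance":
        raise ValueError("nu_convention must be 'variance' or 'sd'")
    g = nu / (2.0 * mu)
    h = 2.0 * mu ** 2 / nu
    return g * stats.chi2.ppf(1.0 - alpha, h)


@dataclass(frozen=True)
class ChartPoint:
    """One sample's position on the T^2/Q control chart."""

    sample_id: str
    t2: float
    q: float
    conform: bool
    metadata: dict | None = None


class PCAConformanceMonitor(BaseEstimator, OutlierMixin):
    """PCA-based T^2/Q conformance monitor (multivariate control chart).

    Parameters
    ----------
    n_components : int, default 7
        Number of retained principal components (A).
    alpha : float, default 0.05
        Significance level of both control limits.
    scale : bool, default True
        Autoscale features (unit variance) in addition to mean centering.
        Zero-variance columns are dropped and recorded.
    nu_convention : {"variance", "sd"}, default "variance"
        Reading of the second Q-residual moment in the Q-limit formula.
    t2_new_observation : bool, default False
        Use the new-observation form of the T^2 limit.

    Attributes
    ----------
    mean_, scale_ : (M,) arrays — centering and scaling of the kept columns.
    components_ : (A, M_kept) array — orthonormal loadings (rows).
    score_variances_ : (A,) array — calibration score variances lambda_a.
    kept_columns_, dropped_columns_ : column index maps.
    q_mean_, q_var_ : calibration Q residual moments (mu, nu).
    t2_limit_, q_limit_ : control limits.
    n_samples_, n_features_in_ : calibration shape.
    """

    def __init__(self, n_components: int = 7, alpha: float = 0.05,
                 scale: bool = True, nu_convention: str = "variance",
                 t2_new_observation: bool = False):
        self.n_components = n_components
        self.alpha = alpha
        self.scale = scale
        self.nu_convention = nu_convention
        self.t2_new_observation = t2_new_observation

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        O, M = X.shape
        A = self.n_components
        if O < A + 2:
            raise DegreesOfFreedomError(
                f"need at least A+2={A + 2} calibration samples, got {O}")
        self.n_features_in_ = M
        self.n_samples_ = O

        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if self.scale:
            kept = np.flatnonzero(sd > 0)
        else:
            kept = np.arange(M)
        self.kept_columns_ = kept
        self.dropped_columns_ = np.setdiff1d(np.arange(M), kept)
        self.mean_ = mean[kept]
        self.scale_ = sd[kept] if self.scale else np.ones(kept.size)

        Z = (X[:, kept] - self.mean_) / self.scale_
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        tol = s.max() * max(Z.shape) * np.finfo(float).eps
        rank = int(np.sum(s > tol))
        if A > rank:
            raise RankError(
                f"A={A} exceeds the rank {rank} of the calibration data")
        self.components_ = Vt[:A]
        self.score_variances_ = (s[:A] ** 2) / (O - 1)

        self.t2_limit_ = t2_limit(A, O, self.alpha,
                                  new_observation=self.t2_new_observation)
        _, q = self._t2_q(Z)
        self.q_mean_ = float(q.mean())
        self.q_var_ = float(q.var(ddof=1))
        if self.q_mean_ <= 0.0 or self.q_var_ <= 0.0:
            # perfect reconstruction (data lies in the component span):
            # any nonzero residual is out of control
            self.q_limit_ = 0.0
        else:
            self.q_limit_ = q_limit(self.q_mean_, self.q_var_, self.alpha,
                                    nu_convention=self.nu_convention)
        return self

    # ------------------------------------------------------------------
    def _scale_rows(self, X) -> np.ndarray:
        X = check_array(X, dtype=np.float64, ensure_2d=True)
        if X.shape[1] != self.n_features_in_:
            raise FeatureMapError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return (X[:, self.kept_columns_] - self.mean_) / self.scale_

    def _t2_q(self, Z) -> tuple[np.ndarray, np.ndarray]:
        T = Z @ self.components_.T
        t2 = np.sum(T ** 2 / self.score_variances_, axis=1)
        resid = Z - T @ self.components_
        q = np.sum(resid ** 2, axis=1)
        return t2, q

    def transform(self, X) -> np.ndarray:
        """Scores of the samples in the retained component space (N x A)."""
        check_is_fitted(self)
        return self._scale_rows(X) @ self.components_.T

    def t2_q(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Hotelling's T^2 and Q (SPE) for each row of X."""
        check_is_fitted(self)
        return self._t2_q(self._scale_rows(X))

    def predict(self, X) -> np.ndarray:
        """+1 for conforming (in-control) samples, -1 otherwise."""
        t2, q = self.t2_q(X)
        conform = (t2 < self.t2_limit_) & (q < self.q_limit_)
        return np.where(conform, 1, -1)

    def conformance(self, X, metadata: pd.DataFrame | None = None,
                    sample_ids=None) -> pd.DataFrame:
        """Chart-ready table with T^2, Q, limits and the conform verdict."""
        t2, q = self.t2_q(X)
        conform = (t2 < self.t2_limit_) & (q < self.q_limit_)
        if sample_ids is None:
            sample_ids = np.arange(len(t2))
        df = pd.DataFrame({"sample_id": sample_ids, "t2": t2, "q": q,
                           "t2_limit": self.t2_limit_,
                           "q_limit": self.q_limit_, "conform": conform})
        if metadata is not None:
            df = pd.concat([df.reset_index(drop=True),
                            metadata.reset_index(drop=True)], axis=1)
        return df

    # ------------------------------------------------------------------
    def to_json(self, path=None, feature_names=None) -> str:
        """Serialize the fitted model (optionally to ``path``)."""
        check_is_fitted(self)
        payload = {
            "n_components": self.n_components, "alpha": self.alpha,
            "scale": self.scale, "nu_convention": self.nu_convention,
            "t2_new_observation": self.t2_new_observation,
            "n_samples": self.n_samples_,
            "n_features_in": self.n_features_in_,
            "kept_columns": self.kept_columns_.tolist(),
            "mean": self.mean_.tolist(), "scale_vector": self.scale_.tolist(),
            "components": self.components_.tolist(),
            "score_variances": self.score_variances_.tolist(),
            "q_mean": self.q_mean_, "q_var": self.q_var_,
            "t2_limit": self.t2_limit_, "q_limit": self.q_limit_,
            "feature_names": (list(feature_names)
                              if feature_names is not None else None),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PCAConformanceMonitor":
        """Rebuild a fitted monitor from ``to_json`` output (str or path)."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        model = cls(n_components=payload["n_components"],
                    alpha=payload["alpha"], scale=payload["scale"],
                    nu_convention=payload["nu_convention"],
                    t2_new_observation=payload["t2_new_observation"])
        model.n_samples_ = payload["n_samples"]
        model.n_features_in_ = payload["n_features_in"]
        model.kept_columns_ = np.asarray(payload["kept_columns"], dtype=int)
        model.dropped_columns_ = np.setdiff1d(
            np.arange(model.n_features_in_), model.kept_columns_)
        model.mean_ = np.asarray(payload["mean"])
        model.scale_ = np.asarray(payload["scale_vector"])
        model.components_ = np.asarray(payload["components"])
        model.score_variances_ = np.asarray(payload["score_variances"])
        model.q_mean_ = payload["q_mean"]
        model.q_var_ = payload["q_var"]
        model.t2_limit_ = payload["t2_limit"]
        model.q_limit_ = payload["q_limit"]
        model.feature_names_ = payload.get("feature_names")
        return model


# ---------------------------------------------------------------------------
# Monte-Carlo validation helper
# ---------------------------------------------------------------------------

def simulate_low_rank_gaussian(n: int, rng: np.random.Generator,
                               n_features: int = 20, rank: int = 7,
                               score_variances=None,
                               noise_sd: float = 0.5,
                               loadings: np.ndarray | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Draw in-control samples with low-rank-plus-noise covariance.

    Samples are ``T P' + E`` with orthonormal loadings P (n_features x rank),
    independent Gaussian scores of the given variances (default linearly
    spaced 10..4) and isotropic Gaussian noise.  Returns ``(X, P)`` so a
    second call can reuse the same subspace for held-out draws.
    """
    if loadings is None:
        loadings, _ = np.linalg.qr(rng.standard_normal((n_features, rank)))
    if score_variances is None:
        score_variances = np.linspace(10.0, 4.0, rank)
    T = rng.standard_normal((n, rank)) * np.sqrt(score_variances)
    X = T @ loadings.T + noise_sd * rng.standard_normal((n, n_features))
    return X, loadings


def control_limit_coverage(seed: int, O: int = 336, A: int = 7,
                           alpha: float = 0.05, n_test: int = 10_000
                           ) -> tuple[float, float]:
    """Held-out coverage (%) of the T^2 and Q limits at the study conditions.

    Calibrates on O draws from a 20-variable low-rank-plus-noise Gaussian,
    then measures the percentage of ``n_test`` independent in-control draws
    falling below each limit.
    """
    rng = np.random.default_rng(seed)
    X_cal, P = simulate_low_rank_gaussian(O, rng)
    monitor = PCAConformanceMonitor(n_components=A, alpha=alpha).fit(X_cal)
    X_test, _ = simulate_low_rank_gaussian(n_test, rng, loadings=P)
    t2, q = monitor.t2_q(X_test)
    return (100.0 * float(np.mean(t2 < monitor.t2_limit_)),
            100.0 * float(np.mean(q < monitor.q_limit_)))


# ---------------------------------------------------------------------------
# thin functional surface
# ---------------------------------------------------------------------------

def fit_pca(X, A: int = 7, alpha: float = 0.05,
            **kwargs) -> PCAConformanceMonitor:
    """Calibrate a conformance monitor on in-control feature rows."""
    return PCAConformanceMonitor(n_components=A, alpha=alpha, **kwargs).fit(X)


def project(model: PCAConformanceMonitor, x, sample_id: str = "0",
            metadata: dict | None = None) -> ChartPoint:
    """Project one feature vector and return its chart point."""
    t2, q = model.t2_q(np.atleast_2d(x))
    conform = bool(t2[0] < model.t2_limit_ and q[0] < model.q_limit_)
    return ChartPoint(sample_id=sample_id, t2=float(t2[0]), q=float(q[0]),
                      conform=conform, metadata=metadata)


def conformance_test(points: pd.DataFrame,
                     group_cols=("condition", "storage_day")) -> pd.DataFrame:
    """Per-group rejection summary of a conformance table.

    ``points`` must carry a boolean ``conform`` column plus the grouping
    columns; the summary reports group size, rejected count and the
    rejection percentage.
    """
    group_cols = [c for c in group_cols if c in points.columns]
    if points.empty:
        raise ValueError("empty conformance table")
    if not group_cols:
        grouped = [((), points)]
    else:
        grouped = points.groupby(group_cols, dropna=False)
    rows = []
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        rej = int((~grp["conform"]).sum())
        rows.append(dict(zip(group_cols, key))
                    | {"n": n, "n_rejected": rej,
                       "rejection_pct": 100.0 * rej / n})
    return pd.DataFrame(rows)
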