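"""Conjugate Bayesian analysis of phase II data and bootstrap hypothesis weights.

The regression parameters and residual variance get a normal-inverse-gamma
prior, NIG(theta0, V0, a, b).  With response vector ``y`` and design matrix
``X0`` (n_II rows) the posterior is NIG(theta_m*, V*, a*, b*) with

    V*      = (V0^-1 + X0'X0)^-1
    theta_m* = V* (V0^-1 theta0 + X0'y)
    a*      = a + n_II / 2
    b*      = b + (theta0' V0^-1 theta0 + y'y - theta_m*' (V*)^-1 theta_m*) / 2,

and the marginal of theta is multivariate Student-t with 2a* degrees of
freedom, location theta_m* and scale Sigma* = (b*/a*) V*.

For each candidate hypothesis r the screen computes
``P_r = P(c_r' theta < tau_r)`` under this marginal.  Because a single small
phase II sample is a noisy basis for selection, the data are bootstrapped
(patients resampled with replacement, responses kept paired with their
covariates) and P_r is averaged over replications to give E(P_r).  The
importance weight is ``w_r = E(P_r)`` when ``E(P_r) >= kappa`` and 0
otherwise; hypotheses with ``w_r > 0`` are carried into the confirmatory
design.  The weights need not sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .model import Contrast, RegressionSpec, contrast_catalogue

__all__ = [
    "NIGPrior",
    "NIGPosterior",
    "WeightResult",
    "nig_update",
    "bootstrap_weights",
    "threshold_weights",
    "BayesianPhaseII",
]


@dataclass
class NIGPrior:
    """Normal-inverse-gamma prior NIG(theta0, V0, a, b) for (theta, sigma^2)."""

    theta0: np.ndarray
    V0: np.ndarray
    a: float
    b: float

    def __post_init__(self) -> None:
        self.theta0 = np.asarray(self.theta0, dtype=float)
        V0 = np.asarray(self.V0, dtype=float)
        if V0.ndim == 1:
            V0 = np.diag(V0)
        self.V0 = V0
        if self.a <= 0 or self.b <= 0:
            raise ValueError("shape a and rate b must be positive")
        if V0.shape != (self.theta0.size, self.theta0.size):
            raise ValueError("V0 dimension does not match theta0")
        try:
            linalg.cholesky(V0, lower=True)
        except linalg.LinAlgError:
            raise ValueError("V0 must be symmetric positive definite") from None

    @classmethod
    def vague(cls, p: int, scale: float = 1.0, a: float = 1e-4, b: float = 1e-4):
        """A weakly informative prior: zero mean, ``scale * I`` covariance."""
        return cls(theta0=np.zeros(p), V0=scale * np.eye(p), a=a, b=b)


@dataclass
class NIGPosterior:
    """Posterior NIG(theta_m, V, a, b); theta's marginal is multivariate t."""

    theta_m: np.ndarray
    V: np.ndarray
    a: float
    b: float

    @property
    def Sigma(self) -> np.ndarray:
        """Scale matrix (b/a) V of the marginal multivariate t."""
        return (self.b / self.a) * self.V

    @property
    def df(self) -> float:
        return 2.0 * self.a

    def contrast_prob(self, c: np.ndarray, tau: float = 0.0,
                      method: str = "exact", draws: int = 10_000,
                      rng: np.random.Generator | None = None) -> float:
        """P(c'theta < tau) under the marginal posterior of theta.

        ``method="exact"`` uses the univariate Student-t CDF (c'theta is t
        with the posterior's degrees of freedom); ``"mc"`` draws from the
        multivariate t and returns the empirical fraction; ``"normal"`` uses
        the large-df normal approximation.
        """
        c = np.asarray(c, dtype=float)
        mean = float(c @ self.theta_m)
        var = float(c @ self.Sigma @ c)
        if var <= 0:
            raise ValueError("contrast has non-positive posterior variance")
        z = (tau - mean) / np.sqrt(var)
        if method == "exact":
            return float(stats.t.cdf(z, df=self.df))
        if method == "normal":
            return float(stats.norm.cdf(z))
        if method == "mc":
            rng = np.random.default_rng() if rng is None else rng
            sd = np.sqrt(var)
            g = rng.chisquare(self.df, size=draws) / self.df
            samples = mean + sd * rng.standard_normal(draws) / np.sqrt(g)
            return float(np.mean(samples < tau))
        raise ValueError(f"unknown method {method!r}")


def nig_update(prior: NIGPrior, X0: np.ndarray, y: np.ndarray) -> NIGPosterior:
    """Conjugate NIG update for the normal linear model.

    With no data the prior is returned unchanged.
    """
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n == 0:
        return NIGPosterior(prior.theta0.copy(), prior.V0.copy(), prior.a, prior.b)
    if X0.shape != (n, prior.theta0.size):
        raise ValueError(
            f"X0 shape {X0.shape} incompatible with n={n}, p={prior.theta0.size}"
        )
    V0inv = linalg.inv(prior.V0)
    precision = V0inv + X0.T @ X0
    cho = linalg.cho_factor((precision + precision.T) / 2.0)
    theta_m = linalg.cho_solve(cho, V0inv @ prior.theta0 + X0.T @ y)
    V = linalg.cho_solve(cho, np.eye(prior.theta0.size))
    V = (V + V.T) / 2.0
    a_star = prior.a + n / 2.0
    b_star = prior.b + 0.5 * (
        prior.theta0 @ V0inv @ prior.theta0 + y @ y - theta_m @ precision @ theta_m
    )
    return NIGPosterior(theta_m=theta_m, V=V, a=a_star, b=float(b_star))


@dataclass
class WeightResult:
    """Per-replication posterior probabilities and thresholded weights."""

    prob: np.ndarray           # (B, R) matrix of P_r per bootstrap replication
    expected_prob: np.ndarray  # E(P_r), mean over replications
    weights: np.ndarray        # w_r = E(P_r) * 1{E(P_r) >= kappa_r}
    kappa: np.ndarray
    tau: np.ndarray
    theta_mean: np.ndarray     # posterior mean averaged over replications

    @property
    def selected(self) -> np.ndarray:
        """0-based indices of hypotheses with positive weight."""
        return np.flatnonzero(self.weights > 0)


def threshold_weights(expected_prob, kappa) -> np.ndarray:
    """w_r = E(P_r) when E(P_r) >= kappa_r, else 0.

    With kappa = 0 selection is a no-op and every hypothesis keeps its
    weight; the weights deliberately do not sum to one.
    """
    expected_prob = np.asarray(expected_prob, dtype=float)
    kappa = _broadcast(kappa, expected_prob.size, "kappa")
    return np.where(expected_prob >= kappa, expected_prob, 0.0)


def _broadcast(value, R: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(R, float(arr))
    if arr.shape != (R,):
        raise ValueError(f"{name} must be a scalar or length-{R} vector")
    return arr


def bootstrap_weights(X0: np.ndarray, y: np.ndarray, prior: NIGPrior,
                      contrasts: np.ndarray, *, n_boot: int = 10_000,
                      kappa=0.5, tau=0.0, method: str = "exact",
                      draws: int = 10_000, resample: bool = True,
                      rng: np.random.Generator | None = None) -> WeightResult:
    """Bootstrap the phase II sample and average the hypothesis probabilities.

    ``contrasts`` is an (R, p) matrix of contrast vectors in the coordinates
    of the prior.  Rows of ``(X0, y)`` are resampled jointly with replacement
    ``n_boot`` times; per-hypothesis thresholds ``kappa``/``tau`` may be
    scalars or length-R vectors.  ``resample=False`` analyses the observed
    data identically in every replication (useful for checks).
    """
    X0 = np.asarray(X0, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("phase II data must be nonempty")
    C = np.atleast_2d(np.asarray(contrasts, dtype=float))
    R = C.shape[0]
    kappa = _broadcast(kappa, R, "kappa")
    tau = _broadcast(tau, R, "tau")
    rng = np.random.default_rng() if rng is None else rng

    n = y.size
    prob = np.empty((n_boot, R))
    theta_sum = np.zeros(prior.theta0.size)
    for b in range(n_boot):
        if resample:
            idx = rng.integers(0, n, size=n)
            Xb, yb = X0[idx], y[idx]
        else:
            Xb, yb = X0, y
        post = nig_update(prior, Xb, yb)
        theta_sum += post.theta_m
        for r in range(R):
            prob[b, r] = post.contrast_prob(C[r], tau=tau[r], method=method,
                                            draws=draws, rng=rng)
    expected = prob.mean(axis=0)
    weights = threshold_weights(expected, kappa)
    return WeightResult(prob=prob, expected_prob=expected, weights=weights,
                        kappa=kappa, tau=tau, theta_mean=theta_sum / n_boot)


class BayesianPhaseII:
    """Bayesian screen of a phase II biomarker trial.

    Built from a patient-level table with columns ``x1..xL`` (binary
    biomarker indicators), ``arm`` (0 = control, 1..K experimental) and ``y``
    (continuous response).  :meth:`fit` runs the conjugate analysis with
    bootstrap averaging and returns a results object carrying E(P_r), the
    thresholded weights w_r and the selected hypotheses.

    Parameters
    ----------
    data : pandas.DataFrame
        Phase II patient table.
    spec : RegressionSpec, optional
        Analysis model; defaults to the full model inferred from the columns.
    prior : NIGPrior, optional
        Defaults to a vague unit-variance NIG prior.
    contrasts : list of Contrast, optional
        Candidate hypotheses; defaults to the full treatment-versus-control
        catalogue.
    """

    def __init__(self, data: pd.DataFrame, spec: RegressionSpec | None = None,
                 prior: NIGPrior | None = None,
                 contrasts: list[Contrast] | None = None):
        if spec is None:
            L = sum(1 for c in data.columns if str(c).startswith("x"))
            K = int(data["arm"].max())
            spec = RegressionSpec.full(K, L)
        self.spec = spec
        self.data = data.reset_index(drop=True)
        self.exog = spec.design_matrix(self.data)
        self.endog = self.data["y"].to_numpy(dtype=float)
        self.prior = prior if prior is not None else NIGPrior.vague(spec.n_params)
        self.contrasts = (contrasts if contrasts is not None
                          else contrast_catalogue(spec.K, spec.L))

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BayesianPhaseII":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, *, n_boot: int = 10_000, kappa=0.5, tau=0.0,
            method: str = "exact", draws: int = 10_000,
            seed=None) -> "BayesianPhaseIIResults":
        rng = np.random.default_rng(seed)
        C = np.vstack([c.vector(self.spec) for c in self.contrasts])
        res = bootstrap_weights(self.exog, self.endog, self.prior, C,
                                n_boot=n_boot, kappa=kappa, tau=tau,
                                method=method, draws=draws, rng=rng)
        posterior = nig_update(self.prior, self.exog, self.endog)
        return BayesianPhaseIIResults(self, res, posterior)


class BayesianPhaseIIResults:
    """Results of the bootstrap-averaged Bayesian phase II screen."""

    def __init__(self, model: BayesianPhaseII, weight_result: WeightResult,
                 posterior: NIGPosterior):
        self.model = model
        self.weight_result = weight_result
        self.posterior = posterior

    @property
    def expected_prob(self) -> np.ndarray:
        return self.weight_result.expected_prob

    @property
    def weights(self) -> np.ndarray:
        return self.weight_result.weights

    @property
    def theta_mean(self) -> np.ndarray:
        """Posterior mean of theta averaged over bootstrap replications."""
        return self.weight_result.theta_mean

    @property
    def selected(self) -> list[Contrast]:
        return [self.model.contrasts[i] for i in self.weight_result.selected]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, con in enumerate(self.model.contrasts):
            rows.append({
                "r": con.r,
                "contrast": "+".join(con.terms),
                "E_P": self.expected_prob[i],
                "w": self.weights[i],
                "selected": self.weights[i] > 0,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame().copy()
        df["E_P"] = df["E_P"].round(3)
        df["w"] = df["w"].round(3)
        lines = [
            "Bayesian phase II hypothesis screen",
            f"  n = {self.model.endog.size}, "
            f"p = {self.model.spec.n_params}, "
            f"hypotheses = {len(self.model.contrasts)}",
            df.to_string(index=False),
            f"selected: {[c.r for c in self.selected]}",
        ]
        return "\n".join(lines)
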