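"""Monte Carlo evaluation of confirmatory-trial designs.

Patients are simulated from the biomarker-stratified linear model: biomarker
profiles as independent Bernoulli draws with given prevalences, treatment
arms from a randomization scheme's per-subgroup probabilities, and normal
responses.  Each simulated trial is analysed by ordinary least squares and
every candidate hypothesis is tested with the one-sided Wald statistic.
Rejection rates are aggregated over a nested replication plan (biomarker
profiles replicated ``n_bio`` times, treatment allocation ``n_alloc`` times
per profile set) and classified as power (true contrast value negative,
i.e. the treatment genuinely benefits that subgroup) or Type I error (true
value nonnegative).  The expected number of correct rejections (ENCR) is the
sum of powers over the false null hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import RandomizationScheme
from .model import Contrast, RegressionSpec, contrast_catalogue, enumerate_support

__all__ = [
    "simulate_biomarkers",
    "assign_and_respond",
    "simulate_phase2",
    "fit_least_squares",
    "analytic_power",
    "ConfirmatoryTrial",
    "SimulationResult",
    "RankDeficientError",
]


class RankDeficientError(np.linalg.LinAlgError):
    """The realized design matrix does not identify the analysis model."""


def simulate_biomarkers(n: int, prevalence, rng: np.random.Generator) -> np.ndarray:
    """n x L matrix of independent Bernoulli(prevalence_l) biomarker indicators."""
    prevalence = np.asarray(prevalence, dtype=float)
    return (rng.random((n, prevalence.size)) < prevalence).astype(int)


def assign_and_respond(profiles: np.ndarray, scheme: RandomizationScheme,
                       theta_full: np.ndarray, sigma2: float,
                       rng: np.random.Generator,
                       full_spec: RegressionSpec | None = None) -> pd.DataFrame:
    """Randomize patients per subgroup and draw responses from the model.

    Patients whose profile the scheme does not enroll are dropped from the
    returned table.  Responses are ``f(x, T) theta + N(0, sigma2)`` with the
    feature map of the full model.
    """
    profiles = np.asarray(profiles)
    K, L = scheme.K, scheme.L
    if full_spec is None:
        full_spec = RegressionSpec.full(K, L)
    rows = []
    for i, x in enumerate(profiles):
        x = tuple(int(v) for v in x)
        if not scheme.enrolled(x):
            continue
        arm = int(rng.choice(K + 1, p=scheme.probabilities(x)))
        mean = float(full_spec.feature_row(x, arm) @ theta_full)
        y = mean + (np.sqrt(sigma2) * rng.standard_normal() if sigma2 > 0 else 0.0)
        row = {"id": i}
        row.update({f"x{l + 1}": x[l] for l in range(L)})
        row.update(arm=arm, y=y)
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", *[f"x{l+1}" for l in range(L)],
                                       "arm", "y"])


def simulate_phase2(n: int, prevalence, theta_full: np.ndarray, sigma2: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """A phase II trial: equal randomization over all arms, all subgroups.

    The number of treatments K is inferred from the full-model dimension
    p = 1 + K + L + K*L.
    """
    prevalence = np.asarray(prevalence, dtype=float)
    L = prevalence.size
    p = len(np.asarray(theta_full))
    K = (p - 1 - L) // (1 + L)
    if 1 + K + L + K * L != p:
        raise ValueError("theta length inconsistent with a full model")
    scheme = RandomizationScheme.rct(K, L)
    profiles = simulate_biomarkers(n, prevalence, rng)
    return assign_and_respond(profiles, scheme, theta_full, sigma2, rng)


def fit_least_squares(table: pd.DataFrame, spec: RegressionSpec
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS fit of the analysis model: (theta_hat, cov(theta_hat), sigma2_hat).

    The covariance plugs the residual variance estimate RSS/(n - p) into
    (X'X)^-1.  Raises :class:`RankDeficientError` when the realized design
    matrix is rank deficient.
    """
    X = spec.design_matrix(table)
    y = table["y"].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise RankDeficientError(f"n={n} too small for p={p} parameters")
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < p:
        raise RankDeficientError("design matrix is rank deficient")
    theta_hat = np.linalg.solve(XtX, X.T @ y)
    rss = float(y @ y - theta_hat @ (X.T @ y))
    sigma2_hat = max(rss, 0.0) / (n - p)
    cov = sigma2_hat * np.linalg.inv(XtX)
    return theta_hat, cov, sigma2_hat


def _expected_information(scheme: RandomizationScheme, prevalence,
                          spec: RegressionSpec) -> np.ndarray:
    """Expected per-patient information E[f'f] under prevalence and scheme.

    Conditional on enrollment: profile probabilities are renormalized over
    the enrolled subgroups.
    """
    prevalence = np.asarray(prevalence, dtype=float)
    points = enumerate_support(scheme.K, scheme.L)
    M = np.zeros((spec.n_params, spec.n_params))
    total = 0.0
    for pt in points:
        if pt.arm != 0 or not scheme.enrolled(pt.x):
            continue
        total += float(np.prod(np.where(pt.x, prevalence, 1 - prevalence)))
    for pt in points:
        if not scheme.enrolled(pt.x):
            continue
        pg = float(np.prod(np.where(pt.x, prevalence, 1 - prevalence))) / total
        w = pg * scheme.probabilities(pt.x)[pt.arm]
        if w == 0:
            continue
        f = spec.feature_row(pt.x, pt.arm)
        M += w * np.outer(f, f)
    return M


def analytic_power(scheme: RandomizationScheme, n: int, prevalence,
                   theta_full: np.ndarray, sigma2: float, contrast: Contrast,
                   spec: RegressionSpec, alpha: float = 0.05,
                   full_spec: RegressionSpec | None = None) -> float:
    """Normal-approximation rejection probability of one contrast.

    Uses the expected per-patient information matrix under the prevalence
    and randomization scheme: the standard error of c'theta_hat is
    sqrt(sigma2 c' M^-1 c / n) and the rejection probability is
    Phi(-z_alpha - c'theta / se).  Serves as an independent cross-check of
    the simulation engine.
    """
    if full_spec is None:
        full_spec = RegressionSpec.full(scheme.K, scheme.L)
    M = _expected_information(scheme, prevalence, spec)
    c = contrast.vector(spec)
    try:
        Minv_c = np.linalg.solve(M, c)
    except np.linalg.LinAlgError:
        raise RankDeficientError(
            f"contrast r={contrast.r} not estimable under this scheme") from None
    var = sigma2 * float(c @ Minv_c) / n
    if var <= 0:
        raise RankDeficientError(f"contrast r={contrast.r} has zero variance")
    effect = contrast.true_value(theta_full, full_spec, spec)
    z = stats.norm.ppf(1 - alpha)
    return float(stats.norm.cdf(-z - effect / np.sqrt(var)))


@dataclass
class SimulationResult:
    """Aggregated operating characteristics of a design."""

    contrasts: list[Contrast]
    true_values: np.ndarray
    rejection_rate: np.ndarray
    alpha: float
    n_fitted: int
    n_dropped: int
    seed: object = None

    @property
    def is_false_null(self) -> np.ndarray:
        return self.true_values < 0

    @property
    def power(self) -> dict[int, float]:
        """Rejection rate of each false null hypothesis (true value < 0)."""
        return {c.r: float(rate) for c, rate, f in
                zip(self.contrasts, self.rejection_rate, self.is_false_null) if f}

    @property
    def type1(self) -> dict[int, float]:
        """Rejection rate of each true null hypothesis (true value >= 0)."""
        return {c.r: float(rate) for c, rate, f in
                zip(self.contrasts, self.rejection_rate, self.is_false_null) if not f}

    @property
    def encr(self) -> float:
        """Expected number of correct rejections: sum of the powers."""
        return float(self.rejection_rate[self.is_false_null].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r": [c.r for c in self.contrasts],
            "true_value": self.true_values,
            "rejection_rate": self.rejection_rate,
            "class": np.where(self.is_false_null, "power", "type1"),
        })

    def summary(self) -> str:
        df = self.to_frame().copy()
        df["true_value"] = df["true_value"].round(3)
        df["rejection_rate"] = df["rejection_rate"].round(2)
        lines = [
            "Confirmatory trial operating characteristics",
            f"  replications: {self.n_fitted} fitted, {self.n_dropped} dropped",
            df.to_string(index=False),
            f"ENCR = {self.encr:.3f}",
        ]
        if self.n_dropped > 0.01 * (self.n_fitted + self.n_dropped):
            lines.append("WARNING: more than 1% of replicates were dropped "
                         "for rank deficiency")
        return "\n".join(lines)


class ConfirmatoryTrial:
    """Nested Monte Carlo evaluation of a randomization scheme.

    Parameters
    ----------
    scheme : RandomizationScheme
        Per-subgroup arm probabilities under evaluation.
    theta_full : array-like
        True parameters of the data-generating full model.
    sigma2 : float
        Residual variance of the response.
    n : int
        Total enrolled sample size per simulated trial.
    prevalence : array-like
        Marginal positivity probability of each biomarker.
    analysis_spec : RegressionSpec, optional
        Model fitted in the analysis (full model by default; pass a reduced
        spec together with matching ``contrasts`` for a parsimonious design).
    contrasts : list of Contrast, optional
        Hypotheses tested each replicate, in ``analysis_spec`` coordinates;
        defaults to the full catalogue.
    alpha : float
        One-sided test level (default 0.05).

    Notes
    -----
    Each replicate draws subgroup sizes from a multinomial over the enrolled
    profiles, arm counts from each subgroup's randomization probabilities,
    and patient-level normal responses; the least-squares fit and Wald
    statistics are computed from the per-cell sufficient statistics, which
    is algebraically identical to assembling the patient-level design matrix.
    """

    def __init__(self, scheme: RandomizationScheme, theta_full, sigma2: float,
                 n: int, prevalence, analysis_spec: RegressionSpec | None = None,
                 contrasts: list[Contrast] | None = None, alpha: float = 0.05):
        self.scheme = scheme
        self.full_spec = RegressionSpec.full(scheme.K, scheme.L)
        self.theta_full = np.asarray(theta_full, dtype=float)
        if self.theta_full.size != self.full_spec.n_params:
            raise ValueError("theta_full must be in full-model coordinates")
        self.sigma2 = float(sigma2)
        self.n = int(n)
        self.prevalence = np.asarray(prevalence, dtype=float)
        self.spec = analysis_spec if analysis_spec is not None else self.full_spec
        if contrasts is None:
            contrasts = contrast_catalogue(scheme.K, scheme.L)
        self.contrasts = list(contrasts)
        self.alpha = float(alpha)
        self._z = float(stats.norm.ppf(1 - self.alpha))
        if self.n <= self.spec.n_params:
            raise ValueError("n must exceed the number of analysis parameters")

        # enrolled profiles, their conditional probabilities, per-profile cells
        self._profiles = [pt.x for pt in enumerate_support(scheme.K, scheme.L)
                          if pt.arm == 0 and scheme.enrolled(pt.x)]
        if not self._profiles:
            raise ValueError("scheme enrolls no subgroup")
        pg = np.array([np.prod(np.where(np.array(x, dtype=bool),
                                        self.prevalence, 1 - self.prevalence))
                       for x in self._profiles])
        self._profile_prob = pg / pg.sum()
        self._arm_probs = [scheme.probabilities(x) for x in self._profiles]
        # analysis feature matrix and true cell means on the enrolled cells
        self._cells = [(x, arm) for x in self._profiles
                       for arm in range(scheme.K + 1)]
        self._Fa = np.vstack([self.spec.feature_row(x, arm)
                              for x, arm in self._cells])
        self._mu = np.array([self.full_spec.feature_row(x, arm) @ self.theta_full
                             for x, arm in self._cells])
        self._true = np.array([c.true_value(self.theta_full, self.full_spec,
                                            self.spec) for c in self.contrasts])
        self._C = np.vstack([c.vector(self.spec) for c in self.contrasts])

    def true_values(self) -> np.ndarray:
        """c'theta in full-model coordinates for every tested contrast."""
        return self._true.copy()

    def _replicate(self, subgroup_counts: np.ndarray, rng: np.random.Generator):
        """One allocation replicate: returns a boolean rejection vector."""
        counts = np.concatenate([
            rng.multinomial(ng, arm_p)
            for ng, arm_p in zip(subgroup_counts, self._arm_probs)
        ])
        n_tot = counts.sum()
        mu_rep = np.repeat(self._mu, counts)
        y = mu_rep + np.sqrt(self.sigma2) * rng.standard_normal(n_tot)
        cell_ids = np.repeat(np.arange(len(self._cells)), counts)
        s1 = np.bincount(cell_ids, weights=y, minlength=len(self._cells))
        XtX = (self._Fa * counts[:, None]).T @ self._Fa
        Xty = self._Fa.T @ s1
        try:
            theta_hat = np.linalg.solve(XtX, Xty)
        except np.linalg.LinAlgError:
            raise RankDeficientError from None
        dof = n_tot - self.spec.n_params
        rss = max(float(y @ y - theta_hat @ Xty), 0.0)
        sigma2_hat = rss / dof
        CM = np.linalg.solve(XtX, self._C.T)
        var = sigma2_hat * np.einsum("rp,pr->r", self._C, CM)
        if np.any(var <= 0):
            raise RankDeficientError
        stat = (self._C @ theta_hat) / np.sqrt(var)
        return stat < -self._z

    def simulate(self, n_bio: int = 100, n_alloc: int = 100,
                 seed=None) -> SimulationResult:
        """Nested replication: ``n_bio`` profile draws x ``n_alloc`` allocations."""
        if n_bio < 1 or n_alloc < 1:
            raise ValueError("replication counts must be >= 1")
        rng = np.random.default_rng(seed)
        R = len(self.contrasts)
        rejections = np.zeros(R)
        fitted = dropped = 0
        for _ in range(n_bio):
            subgroup_counts = rng.multinomial(self.n, self._profile_prob)
            for _ in range(n_alloc):
                try:
                    rejections += self._replicate(subgroup_counts, rng)
                    fitted += 1
                except RankDeficientError:
                    dropped += 1
        if fitted == 0:
            raise RankDeficientError("every replicate was rank deficient")
        return SimulationResult(
            contrasts=self.contrasts, true_values=self._true.copy(),
            rejection_rate=rejections / fitted, alpha=self.alpha,
            n_fitted=fitted, n_dropped=dropped, seed=seed,
        )
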