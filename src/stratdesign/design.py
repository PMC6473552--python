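"""Weighted L-optimal randomization design on the biomarker-treatment simplex.

A continuous design is a probability measure over the biomarker-treatment
combinations: support points (x, T) with proportions p_i >= 0 summing to 1.
The weighted L-optimality criterion is

    Phi(p) = sum_r w_r c_r' M(p)^-1 c_r,     M(p) = n sum_i p_i f_i' f_i,

the weighted sum of variances of the selected treatment-versus-control
contrasts; it reduces to c-optimality for a single contrast and to classical
L-optimality for unit weights.  Phi is convex on the simplex, so any local
minimum of the constrained search is global.  Because exact per-subgroup
enrollment proportions cannot be imposed on recruitment, the optimal measure
is converted into per-subgroup randomization probabilities (proportions
renormalized within each biomarker profile); no rounding to an exact design
is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .model import Contrast, DesignPoint, RegressionSpec, enumerate_support

__all__ = [
    "DesignMeasure",
    "RandomizationScheme",
    "DesignProblem",
    "DesignResults",
    "fixed_scheme",
]

_SINGULAR_PENALTY = 1e15


class RandomizationScheme:
    """Per-subgroup randomization probabilities over control and K arms.

    ``probs`` maps each biomarker profile (tuple of 0/1) to a length-(K+1)
    probability vector; profiles absent from the map are not enrolled.
    """

    def __init__(self, K: int, L: int, probs: dict[tuple, np.ndarray]):
        self.K = K
        self.L = L
        self.probs = {}
        for profile, vec in probs.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (K + 1,):
                raise ValueError(f"profile {profile}: need {K + 1} arm probabilities")
            if np.any(vec < 0) or not np.isclose(vec.sum(), 1.0):
                raise ValueError(f"profile {profile}: probabilities must sum to 1")
            self.probs[tuple(int(v) for v in profile)] = vec / vec.sum()

    def enrolled(self, profile) -> bool:
        return tuple(int(v) for v in profile) in self.probs

    def probabilities(self, profile) -> np.ndarray:
        return self.probs[tuple(int(v) for v in profile)]

    @property
    def profiles(self) -> list[tuple]:
        return sorted(self.probs)

    @classmethod
    def rct(cls, K: int, L: int) -> "RandomizationScheme":
        """Randomized controlled trial: every subgroup, equal 1/(K+1) arms."""
        equal = np.full(K + 1, 1.0 / (K + 1))
        return cls(K, L, {pt.x: equal for pt in enumerate_support(K, L)
                          if pt.arm == 0})

    @classmethod
    def linked(cls, K: int, L: int,
               linkage: dict[int, int] | None = None) -> "RandomizationScheme":
        """Biomarker-treatment linked trial.

        Each subgroup is offered control plus every treatment whose linked
        biomarker it is positive for, with equal probabilities; a subgroup
        positive for no biomarker is offered all arms equally.  ``linkage``
        maps treatment k to its biomarker l (default: treatment k to
        biomarker k).
        """
        if linkage is None:
            if K != L:
                raise ValueError("default linkage needs K == L")
            linkage = {k: k for k in range(1, K + 1)}
        if sorted(linkage) != list(range(1, K + 1)) or any(
                not 1 <= l <= L for l in linkage.values()):
            raise ValueError("linkage must map each treatment 1..K to a biomarker")
        probs = {}
        for pt in enumerate_support(K, L):
            if pt.arm != 0:
                continue
            offered = [0] + [k for k in range(1, K + 1) if pt.x[linkage[k] - 1] == 1]
            if len(offered) == 1:          # all-negative profile: open trial
                offered = list(range(K + 1))
            vec = np.zeros(K + 1)
            vec[offered] = 1.0 / len(offered)
            probs[pt.x] = vec
        return cls(K, L, probs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for profile in self.profiles:
            vec = self.probs[profile]
            for arm in range(self.K + 1):
                row = {f"x{l + 1}": profile[l] for l in range(self.L)}
                row.update(arm=arm, probability=vec[arm], enrolled=True)
                rows.append(row)
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"{p}:{np.round(v, 2).tolist()}" for p, v in sorted(self.probs.items())]
        return f"RandomizationScheme({', '.join(parts)})"


def fixed_scheme(kind: str, K: int, L: int,
                 linkage: dict[int, int] | None = None) -> RandomizationScheme:
    """The standard comparator schemes: ``"rct"`` or ``"linked"``."""
    if kind == "rct":
        return RandomizationScheme.rct(K, L)
    if kind == "linked":
        return RandomizationScheme.linked(K, L, linkage)
    raise ValueError(f"unknown scheme kind {kind!r}")


@dataclass
class DesignMeasure:
    """Support points with proportions p_i on the simplex."""

    points: list[DesignPoint]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.points),):
            raise ValueError("one proportion per support point required")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")

    def to_frame(self) -> pd.DataFrame:
        L = len(self.points[0].x)
        rows = []
        for pt, pi in zip(self.points, self.p):
            row = {"i_prime": pt.index}
            row.update({f"x{l + 1}": pt.x[l] for l in range(L)})
            row.update(arm=pt.arm, p=pi)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_randomization_scheme(self, mass_threshold: float = 1e-6
                                ) -> RandomizationScheme:
        """Per-subgroup renormalization of the proportions.

        Within each biomarker profile the arm probabilities are the design
        proportions divided by the profile's total mass; profiles with total
        mass below ``mass_threshold`` are not enrolled.
        """
        K = max(pt.arm for pt in self.points)
        L = len(self.points[0].x)
        mass: dict[tuple, np.ndarray] = {}
        for pt, pi in zip(self.points, self.p):
            vec = mass.setdefault(pt.x, np.zeros(K + 1))
            vec[pt.arm] += pi
        probs = {x: vec / vec.sum() for x, vec in mass.items()
                 if vec.sum() >= mass_threshold}
        if not probs:
            raise ValueError("design measure carries no mass")
        return RandomizationScheme(K, L, probs)


class DesignProblem:
    """Minimize the weighted sum of contrast variances over the simplex.

    Parameters
    ----------
    spec : RegressionSpec
        Analysis model (possibly reduced) for the future trial.
    contrasts : list of Contrast
        Selected hypotheses, expressed in ``spec`` coordinates.
    weights : array-like
        Positive relative importances w_r, one per contrast.
    points : list of DesignPoint, optional
        Candidate support; defaults to the full enumeration for (K, L).
    exclusions : iterable of int, optional
        1-based indices of points forced to zero proportion (subgroup-arm
        combinations not enrolled by the selected hypotheses).
    n : float
        Nominal sample size; a pure scale factor that does not move the
        optimum (default 1).
    """

    def __init__(self, spec: RegressionSpec, contrasts: list[Contrast],
                 weights, points: list[DesignPoint] | None = None,
                 exclusions=(), n: float = 1.0):
        self.spec = spec
        self.contrasts = list(contrasts)
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.shape != (len(self.contrasts),):
            raise ValueError("one weight per contrast required")
        if np.any(self.weights <= 0):
            raise ValueError("weights of included contrasts must be positive")
        self.points = (points if points is not None
                       else enumerate_support(spec.K, spec.L))
        self.exclusions = frozenset(exclusions)
        unknown = self.exclusions - {pt.index for pt in self.points}
        if unknown:
            raise ValueError(f"excluded indices not in support: {sorted(unknown)}")
        self.n = float(n)
        self._F = spec.design_matrix(self.points)
        self._C = np.vstack([c.vector(spec) for c in self.contrasts])
        self._free = np.array([pt.index not in self.exclusions
                               for pt in self.points])

    # -- criterion ---------------------------------------------------------

    def information(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        M = self.n * self._F.T @ (self._F * p[:, None])
        return (M + M.T) / 2.0

    def objective(self, p) -> float:
        """sum_r w_r c_r' M(p)^-1 c_r, or a large penalty when singular."""
        M = self.information(p)
        try:
            cho = linalg.cho_factor(M)
        except linalg.LinAlgError:
            return _SINGULAR_PENALTY
        MC = linalg.cho_solve(cho, self._C.T)          # p x R
        variances = np.einsum("rp,pr->r", self._C, MC)
        if np.any(variances <= 0) or not np.all(np.isfinite(variances)):
            return _SINGULAR_PENALTY
        return float(self.weights @ variances)

    def gradient(self, p) -> np.ndarray:
        """d Phi / d p_i = -n * sum_r w_r (c_r' M^-1 f_i)^2."""
        M = self.information(p)
        try:
            cho = linalg.cho_factor(M)
        except linalg.LinAlgError:
            return np.zeros(len(self.points))
        MC = linalg.cho_solve(cho, self._C.T)          # p x R
        proj = self._F @ MC                            # m x R
        return -self.n * (proj ** 2) @ self.weights

    # -- solver ------------------------------------------------------------

    def solve(self, tol: float = 1e-10, starts: int = 5, seed=None,
              zero_clip: float = 1e-6) -> "DesignResults":
        """Multi-start constrained minimization on the simplex.

        Starts from equal allocation over the non-excluded points plus
        ``starts - 1`` Dirichlet(1) draws; the criterion is convex so the
        starts should agree, and their objective spread is reported.
        Proportions below ``zero_clip`` are clipped to zero and the measure
        renormalized.
        """
        rng = np.random.default_rng(seed)
        free = np.flatnonzero(self._free)
        if free.size == 0:
            raise ValueError("all support points are excluded")
        m = free.size

        # The search minimizes log(Phi): same minimizer, but the criterion's
        # huge dynamic range near the simplex boundary no longer stalls the
        # SQP line search.
        def fun(q):
            p = np.zeros(len(self.points))
            p[free] = q
            return np.log(self.objective(p))

        def jac(q):
            p = np.zeros(len(self.points))
            p[free] = q
            return self.gradient(p)[free] / self.objective(p)

        x0s = [np.full(m, 1.0 / m)]
        for _ in range(max(0, starts - 1)):
            x0s.append(rng.dirichlet(np.ones(m)))

        constraints = [{"type": "eq", "fun": lambda q: q.sum() - 1.0,
                        "jac": lambda q: np.ones(m)}]
        solutions = []
        for x0 in x0s:
            # SLSQP occasionally declares convergence prematurely from a
            # steep random start; restarting from its own solution (which
            # resets the Hessian approximation) until the objective
            # stabilizes makes every start reach the global optimum of this
            # convex criterion.
            res, previous = None, np.inf
            x = x0
            for _ in range(5):
                res = optimize.minimize(
                    fun, x, jac=jac, method="SLSQP",
                    bounds=[(0.0, 1.0)] * m, constraints=constraints,
                    options={"ftol": min(tol, 1e-12), "maxiter": 1000},
                )
                x = np.clip(res.x, 0.0, 1.0)
                if previous - res.fun <= 1e-12:
                    break
                previous = res.fun
            if res.success and res.fun < np.log(_SINGULAR_PENALTY) - 1:
                solutions.append(res)
        if not solutions:
            raise RuntimeError("design optimization failed from every start")

        best = min(solutions, key=lambda r: r.fun)
        values = np.exp([r.fun for r in solutions])
        q = np.clip(best.x, 0.0, None)
        q[q < zero_clip] = 0.0
        q /= q.sum()
        p = np.zeros(len(self.points))
        p[free] = q
        measure = DesignMeasure(points=self.points, p=p)
        return DesignResults(problem=self, measure=measure,
                             objective_value=self.objective(p),
                             start_values=values)


@dataclass
class DesignResults:
    """Solved design: optimal measure, criterion value, multistart diagnostics."""

    problem: DesignProblem
    measure: DesignMeasure
    objective_value: float
    start_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def multistart_gap(self) -> float:
        """Objective spread across converged starts (uniqueness diagnostic)."""
        if self.start_values.size < 2:
            return 0.0
        return float(self.start_values.max() - self.start_values.min())

    @property
    def scheme(self) -> RandomizationScheme:
        return self.measure.to_randomization_scheme()

    def summary(self) -> str:
        df = self.measure.to_frame().copy()
        df["p"] = df["p"].round(2)
        lines = [
            "Weighted L-optimal design",
            f"  criterion value: {self.objective_value:.6g}",
            f"  multistart objective gap: {self.multistart_gap:.3g}",
            df.to_string(index=False),
            "Per-subgroup randomization probabilities:",
        ]
        scheme = self.scheme
        for profile in scheme.profiles:
            lines.append(f"  {profile}: "
                         f"{np.round(scheme.probabilities(profile), 2).tolist()}")
        return "\n".join(lines)
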