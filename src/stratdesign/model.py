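"""Linear response model for biomarker-stratified multi-arm trials.

The response of a patient with binary biomarker profile ``x = (x_1, ..., x_L)``
receiving experimental treatment ``k`` (or control, ``k = 0``) is modelled as

    y = alpha + sum_k beta_k T_k + sum_l gamma_l x_l
        + sum_{k,l} delta_kl x_l T_k + eps,      eps ~ N(0, sigma^2),

where ``T_k`` is the indicator of treatment ``k``.  ``alpha`` is the control
mean in the all-negative subgroup, ``beta_k`` the main effect of treatment
``k``, ``gamma_l`` the prognostic effect of biomarker ``l`` and ``delta_kl``
the treatment-by-biomarker interaction.  Negative effects are beneficial and
all hypothesis tests are one-sided lower by default.

This module provides the regression specification (full and reduced /
parsimonious forms), the catalogue of treatment-versus-control contrasts, the
information matrix of a design measure, and the one-sided Wald test.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DesignPoint",
    "RegressionSpec",
    "Contrast",
    "enumerate_support",
    "contrast_catalogue",
    "support_for_selection",
    "information_matrix",
    "wald_test",
    "reduce_model",
    "NonEstimableError",
]


class NonEstimableError(ValueError):
    """A contrast cannot be estimated on the given design support."""


_LABEL_RE = re.compile(r"^(alpha|beta(\d)|gamma(\d)|delta(\d)(\d))'?$")


def _base_indicator(label: str, x: tuple[int, ...], arm: int) -> int:
    """Value of the design-matrix column for a single base parameter."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unknown parameter label {label!r}")
    if label.startswith("alpha"):
        return 1
    if label.startswith("beta"):
        return int(arm == int(m.group(2)))
    if label.startswith("gamma"):
        return x[int(m.group(3)) - 1]
    k, l = int(m.group(4)), int(m.group(5))
    return x[l - 1] * int(arm == k)


@dataclass(frozen=True)
class DesignPoint:
    """A biomarker-profile / treatment-arm combination.

    ``index`` is 1-based and follows the canonical enumeration: profiles in
    lexicographic order, arms (control first) nested within profile.
    """

    index: int
    x: tuple[int, ...]
    arm: int


def enumerate_support(K: int, L: int) -> list[DesignPoint]:
    """All (K+1)*2**L biomarker-treatment combinations in canonical order."""
    if K < 1 or L < 0:
        raise ValueError("need K >= 1 and L >= 0")
    points = []
    i = 1
    for x in itertools.product((0, 1), repeat=L):
        for arm in range(K + 1):
            points.append(DesignPoint(i, x, arm))
            i += 1
    return points


@dataclass
class RegressionSpec:
    """Which regression terms are present and how they map to features.

    ``terms`` is the ordered tuple of parameter labels.  For a reduced
    (parsimonious) model, ``substitutions`` records for each merged label the
    tuple of full-model labels whose sum it estimates, e.g.
    ``{"beta2'": ("beta2", "delta22")}``; the merged column equals the column
    of its first (primary) component on the supported design points.
    """

    K: int
    L: int
    terms: tuple[str, ...]
    substitutions: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K > 9 or self.L > 9:
            raise ValueError("labels are single-digit indexed; K, L <= 9")
        if "alpha" not in self.terms:
            raise ValueError("the intercept alpha is always included")

    @classmethod
    def full(cls, K: int, L: int) -> "RegressionSpec":
        """The saturated first-order-interaction model.

        Canonical parameter order: alpha, beta_1..K, gamma_1..L, then the
        interactions delta_kl with k outermost (delta11, delta12, ...,
        delta21, ...).
        """
        terms = (
            ["alpha"]
            + [f"beta{k}" for k in range(1, K + 1)]
            + [f"gamma{l}" for l in range(1, L + 1)]
            + [f"delta{k}{l}" for k in range(1, K + 1) for l in range(1, L + 1)]
        )
        return cls(K=K, L=L, terms=tuple(terms))

    @property
    def n_params(self) -> int:
        return len(self.terms)

    def index_of(self, label: str) -> int:
        return self.terms.index(label)

    def feature_row(self, x, arm: int) -> np.ndarray:
        """The row f(x, T) of the design matrix for one patient."""
        x = tuple(int(v) for v in x)
        if len(x) != self.L:
            raise ValueError(f"profile has length {len(x)}, expected {self.L}")
        if any(v not in (0, 1) for v in x):
            raise ValueError("biomarker indicators must be 0 or 1")
        if not 0 <= arm <= self.K:
            raise ValueError(f"arm {arm} outside 0..{self.K}")
        row = np.empty(self.n_params)
        for j, term in enumerate(self.terms):
            primary = self.substitutions.get(term, (term,))[0]
            row[j] = _base_indicator(primary, x, arm)
        return row

    def design_matrix(self, points) -> np.ndarray:
        """Stack feature rows for a sequence of DesignPoints (or a table).

        Accepts a list of DesignPoints or a pandas DataFrame with columns
        ``x1..xL`` and ``arm``.
        """
        if hasattr(points, "columns"):
            xs = points[[f"x{l}" for l in range(1, self.L + 1)]].to_numpy()
            arms = points["arm"].to_numpy()
            return np.vstack([self.feature_row(x, a) for x, a in zip(xs, arms)])
        return np.vstack([self.feature_row(pt.x, pt.arm) for pt in points])

    def expand_terms(self, coef: dict[str, float]) -> dict[str, float]:
        """Rewrite a coefficient map over this spec's terms in full-model labels."""
        out: dict[str, float] = {}
        for label, c in coef.items():
            for base in self.substitutions.get(label, (label,)):
                out[base] = out.get(base, 0.0) + c
        return out

    def theta_from_labels(self, values: dict[str, float]) -> np.ndarray:
        """Parameter vector aligned with ``terms`` from a label->value map."""
        missing = set(values) - set(self.terms)
        if missing:
            raise ValueError(f"labels not in model: {sorted(missing)}")
        return np.array([values.get(t, 0.0) for t in self.terms])


@dataclass
class Contrast:
    """A treatment-versus-control effect c'theta with one-sided threshold tau.

    ``terms`` maps parameter labels (in the coordinates of some spec) to
    coefficients; ``tau`` is the minimum uninteresting difference used by the
    posterior-probability screen, and ``r`` the hypothesis index.
    """

    r: int
    terms: dict[str, float]
    tau: float = 0.0

    def vector(self, spec: RegressionSpec) -> np.ndarray:
        c = np.zeros(spec.n_params)
        for label, coef in self.terms.items():
            try:
                c[spec.index_of(label)] = coef
            except ValueError:
                raise NonEstimableError(
                    f"contrast r={self.r} involves {label!r}, absent from the model"
                ) from None
        return c

    def value(self, theta: np.ndarray, spec: RegressionSpec) -> float:
        """Inner product c'theta in the coordinates of ``spec``."""
        return float(self.vector(spec) @ np.asarray(theta))

    def full_terms(self, spec: RegressionSpec) -> dict[str, float]:
        """This contrast's coefficients expanded to full-model labels."""
        return spec.expand_terms(self.terms)

    def true_value(self, theta_full: np.ndarray, full_spec: RegressionSpec,
                   spec: RegressionSpec | None = None) -> float:
        """c'theta evaluated against the full (data-generating) parameters.

        ``spec`` is the analysis spec whose substitution records are used to
        map merged parameters back to full-model coordinates.
        """
        terms = self.terms if spec is None else self.full_terms(spec)
        c = np.zeros(full_spec.n_params)
        for label, coef in terms.items():
            c[full_spec.index_of(label)] = coef
        return float(c @ np.asarray(theta_full))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = " + ".join(
            (f"{v:g}*{k}" if v != 1 else k) for k, v in self.terms.items()
        )
        return f"Contrast(r={self.r}, {body}, tau={self.tau:g})"


def contrast_catalogue(K: int, L: int, tau: float = 0.0) -> list[Contrast]:
    """All 2**L * K treatment-versus-control contrasts.

    For each treatment k and each biomarker subset S, the contrast selects
    ``beta_k + sum_{l in S} delta_kl`` — the benefit of treatment k over
    control in the subgroup positive exactly for the biomarkers in S.
    Ordered with treatment outermost and subsets in binary order, so for
    K = L = 2 the eight contrasts are beta1; beta1+delta11; beta1+delta12;
    beta1+delta11+delta12; then the same pattern for treatment 2.
    """
    out = []
    r = 1
    for k in range(1, K + 1):
        for mask in range(2 ** L):
            terms = {f"beta{k}": 1.0}
            for l in range(1, L + 1):
                if mask >> (l - 1) & 1:
                    terms[f"delta{k}{l}"] = 1.0
            out.append(Contrast(r=r, terms=terms, tau=tau))
            r += 1
    return out


def _contrast_profile_arm(contrast: Contrast) -> tuple[tuple[int, ...], int]:
    """The subgroup profile and treatment arm a catalogue contrast refers to."""
    arm = None
    positives = set()
    for label in contrast.terms:
        m = _LABEL_RE.match(label)
        if label.startswith("beta"):
            arm = int(m.group(2))
        elif label.startswith("delta"):
            positives.add(int(m.group(5)))
    if arm is None:
        raise ValueError(f"contrast r={contrast.r} has no treatment main effect")
    return positives, arm


def support_for_selection(selected: list[Contrast], K: int, L: int) -> list[DesignPoint]:
    """Design points enrolled by a set of selected hypotheses.

    Each hypothesis enrolls its subgroup's control point and the point of the
    treatment it tests; the subgroup is positive exactly for the biomarkers
    appearing in the contrast's interaction terms.
    """
    all_points = enumerate_support(K, L)
    by_key = {(pt.x, pt.arm): pt for pt in all_points}
    chosen: set[int] = set()
    for con in selected:
        positives, arm = _contrast_profile_arm(con)
        x = tuple(int(l + 1 in positives) for l in range(L))
        chosen.add(by_key[(x, 0)].index)
        chosen.add(by_key[(x, arm)].index)
    return [pt for pt in all_points if pt.index in chosen]


def information_matrix(p, points, spec: RegressionSpec, n: float = 1.0) -> np.ndarray:
    """Information matrix n * sum_i p_i f_i' f_i of a design measure."""
    p = np.asarray(p, dtype=float)
    if p.shape[0] != len(points):
        raise ValueError("one proportion per design point required")
    F = spec.design_matrix(points)
    M = n * F.T @ (F * p[:, None])
    return (M + M.T) / 2.0


def wald_test(theta_hat, cov, contrast: Contrast, spec: RegressionSpec,
              alpha: float = 0.05) -> tuple[float, bool]:
    """One-sided Wald test of c'theta = 0 against c'theta < 0.

    Returns the standardized statistic and whether it falls below the
    standard-normal critical value ``-z_{alpha}``.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    c = contrast.vector(spec)
    var = float(c @ np.asarray(cov) @ c)
    if var <= 0:
        raise NonEstimableError(f"contrast r={contrast.r} has non-positive variance")
    stat = float(c @ np.asarray(theta_hat)) / np.sqrt(var)
    z = stats.norm.ppf(1 - alpha)
    return stat, stat < -z


def express_in(contrast: Contrast, reduced: RegressionSpec) -> Contrast:
    """Rewrite a full-model contrast in the coordinates of a reduced spec.

    Valid only when the contrast is estimable under the reduction: its
    coefficients must be zero on dropped terms and constant within each merge
    group, in which case the group's common coefficient transfers to the
    merged parameter.
    """
    group_of: dict[str, str] = {}
    for merged, members in reduced.substitutions.items():
        for m in members:
            group_of[m] = merged
    for term in reduced.terms:
        if term not in reduced.substitutions:
            group_of.setdefault(term, term)

    new_terms: dict[str, float] = {}
    for label, coef in contrast.terms.items():
        if coef == 0:
            continue
        if label not in group_of:
            raise NonEstimableError(
                f"contrast r={contrast.r}: {label} is not estimable on this support"
            )
        g = group_of[label]
        if g in new_terms and new_terms[g] != coef:
            raise NonEstimableError(
                f"contrast r={contrast.r}: unequal coefficients within merged "
                f"parameter {g}"
            )
        new_terms[g] = coef
    # every member of a touched merge group must carry the same coefficient
    for g, coef in new_terms.items():
        for member in reduced.substitutions.get(g, (g,)):
            if contrast.terms.get(member, 0.0) != coef:
                raise NonEstimableError(
                    f"contrast r={contrast.r}: only the combination "
                    f"{'+'.join(reduced.substitutions[g])} is estimable"
                )
    return Contrast(r=contrast.r, terms=new_terms, tau=contrast.tau)


def reduce_model(selected: list[Contrast], support: list[DesignPoint],
                 full: RegressionSpec) -> RegressionSpec:
    """Parsimonious reformulation of the model on a restricted support.

    Terms whose design-matrix column is identically zero on the support are
    dropped; terms whose columns coincide on the support (a treatment main
    effect that only ever occurs together with an interaction) are merged
    into a single combined parameter carrying a substitution record, e.g.
    ``beta2' = beta2 + delta22`` when treatment 2 is only given to
    biomarker-2-positive patients.  Raises :class:`NonEstimableError` if a
    selected contrast is not estimable on the support, and ``ValueError`` if
    the reduced information matrix is still singular.
    """
    F = full.design_matrix(support)
    kept = [j for j in range(full.n_params) if np.any(F[:, j] != 0)]

    groups: dict[tuple, list[str]] = {}
    for j in kept:
        groups.setdefault(tuple(F[:, j]), []).append(full.terms[j])

    new_terms: list[str] = []
    substitutions: dict[str, tuple[str, ...]] = {}
    for members in groups.values():
        members = sorted(members, key=full.terms.index)
        if len(members) == 1:
            new_terms.append(members[0])
        else:
            name = members[0] + "'"
            new_terms.append(name)
            substitutions[name] = tuple(members)
    new_terms.sort(key=lambda t: full.terms.index(t.rstrip("'")))

    reduced = RegressionSpec(K=full.K, L=full.L, terms=tuple(new_terms),
                             substitutions=substitutions)
    for con in selected:
        express_in(con, reduced)  # raises NonEstimableError when infeasible
    Fr = reduced.design_matrix(support)
    if np.linalg.matrix_rank(Fr) < reduced.n_params:
        raise ValueError("reduced model is still rank-deficient on this support")
    return reduced
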