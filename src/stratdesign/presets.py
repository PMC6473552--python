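"""Parameter presets for the worked two-biomarker, two-treatment example.

A phase II trial tests two targeted treatments against control in a
population carrying two binary biomarkers (each with prevalence 0.3), with a
continuous endpoint where negative responses indicate benefit; treatment k
is believed, but not known, to work best in biomarker-k-positive patients.
These presets bundle the data-generating parameters, the prior, and the
screening output used throughout the documentation and tests, so that every
stage of the pipeline can be exercised without external data.
"""

from __future__ import annotations

import numpy as np

from .bayes import NIGPrior
from .model import RegressionSpec, contrast_catalogue

K = 2
L = 2
PREVALENCE = (0.3, 0.3)
SIGMA2 = 1.15
ALPHA = 0.05
N_PHASE2 = 400
N_CONFIRMATORY = 1000

#: Data-generating parameters of the simulated phase II study.
THETA_PHASE2 = {
    "alpha": -0.356, "beta1": -0.213, "beta2": 0.240,
    "gamma1": 1.0, "gamma2": 1.0,
    "delta11": -0.182, "delta12": 0.527, "delta21": 0.240, "delta22": -0.586,
}

#: True parameters of the confirmatory-trial simulation (the bootstrap
#: expectation of the posterior mean from the phase II analysis).
THETA_CONFIRMATORY = {
    "alpha": -0.326, "beta1": -0.155, "beta2": 0.324,
    "gamma1": 0.794, "gamma2": 1.061,
    "delta11": -0.014, "delta12": 0.290, "delta21": 0.426, "delta22": -0.784,
}

#: Prior mean and diagonal scale: skeptical about every effect except the
#: linked interactions delta11 and delta22, which are given a mildly negative
#: mean and extra variance.
PRIOR_THETA0 = (0.0, 0.0, 0.0, 0.0, 0.0, -0.1, 0.0, 0.0, -0.1)
PRIOR_V0_DIAG = (1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 1.0, 1.0, 2.0)
PRIOR_A = 1e-4
PRIOR_B = 1e-4

#: Bootstrap-averaged posterior probabilities E(P_r) obtained for one phase II
#: realization; with kappa = 0.5 these select hypotheses 1, 2, 7 and 8.
EXPECTED_PROB = (0.761, 0.683, 0.326, 0.367, 0.097, 0.032, 0.883, 0.501)
KAPPA = 0.5
SELECTED = (1, 2, 7, 8)
SELECTED_WEIGHTS = (0.761, 0.683, 0.883, 0.501)


def full_spec() -> RegressionSpec:
    return RegressionSpec.full(K, L)


def prior() -> NIGPrior:
    return NIGPrior(theta0=np.array(PRIOR_THETA0),
                    V0=np.array(PRIOR_V0_DIAG), a=PRIOR_A, b=PRIOR_B)


def theta_phase2() -> np.ndarray:
    return full_spec().theta_from_labels(THETA_PHASE2)


def theta_confirmatory() -> np.ndarray:
    return full_spec().theta_from_labels(THETA_CONFIRMATORY)


def selected_contrasts():
    """The four selected hypotheses, in full-model coordinates."""
    catalogue = contrast_catalogue(K, L)
    return [catalogue[r - 1] for r in SELECTED]


def theta_flat_effects(effect: float = -0.2) -> np.ndarray:
    """Parameters giving every selected-subgroup contrast the same effect.

    Sets beta1 = beta2 + delta22 = ``effect`` with delta11 = delta21 = 0, so
    hypotheses 1, 2, 7 and 8 all have true value ``effect``, while beta2 and
    delta12 are chosen to keep the remaining contrasts (3, 4, 5, 6) positive.
    Used by the summary-statistics illustration.
    """
    return full_spec().theta_from_labels({
        "alpha": 0.0, "beta1": effect, "beta2": -2 * effect,
        "gamma1": 1.0, "gamma2": 1.0,
        "delta11": 0.0, "delta12": -2 * effect,
        "delta21": 0.0, "delta22": 3 * effect,
    })
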