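"""Named study conditions for recovery and calibration experiments.

Each builder returns a :class:`ScenarioConfig` for one simulation arm of the
package's validation experiments.  Default effect sizes are fixed design
choices made once, picked so the corresponding recovery analyses are
well-powered at the split-plot design's sample sizes; they are not fitted
to any field dataset.
"""

from __future__ import annotations

from .synthetic_data import FUNCTIONS, FunctionParams, ScenarioConfig


def default_scenario(seed: int) -> ScenarioConfig:
    """The standard suppression experiment (paper-like effect structure)."""
    return ScenarioConfig(seed=seed)


def mediation_scenario(seed: int) -> ScenarioConfig:
    """Identity-link chain with a known mediator slope and zero direct effect.

    The identity link makes the planted per-species rate slope
    (``beta_richness``) the exact estimand of the mediator path in a linear
    path model, so confidence-interval coverage can be measured against
    known truth.  ``scavenging`` carries the reference chain:
    direct effect 0, mediator slope 0.025 per species.
    """
    fns = {
        "scavenging": FunctionParams(0.15, 0.025, 0.0),
        "myrmecochory": FunctionParams(0.2, 0.02, 0.0),
        "granivory": FunctionParams(0.5, -0.015, 0.08),
        "plant_protection": FunctionParams(0.5, 0.02, -0.1),
    }
    return ScenarioConfig(seed=seed, link="identity", noise_sd=0.05,
                          functions=fns)


MEDIATION_TRUE_SLOPE = 0.025       # planted scavenging mediator slope
MEDIATION_TRUE_DIRECT = 0.0


def mde_power_scenario(seed: int) -> ScenarioConfig:
    """Uniform positive direct suppression effect on all four functions."""
    fns = {f: FunctionParams(-0.2, 0.08, 0.5) for f in FUNCTIONS}
    return ScenarioConfig(seed=seed, functions=fns)


def null_scenario(seed: int) -> ScenarioConfig:
    """No treatment effects anywhere (size / false-positive calibration)."""
    fns = {f: FunctionParams(0.0, 0.0, 0.0) for f in FUNCTIONS}
    return ScenarioConfig(seed=seed, nontarget_release=1.0, functions=fns)


def negative_covariance_scenario(seed: int) -> ScenarioConfig:
    """Strong planted negative granivory-protection plot noise correlation."""
    import numpy as np
    corr = np.array([[1.0, 0.0, 0.0, 0.0],
                     [0.0, 1.0, 0.0, 0.0],
                     [0.0, 0.0, 1.0, -0.8],
                     [0.0, 0.0, -0.8, 1.0]])
    return ScenarioConfig(seed=seed, function_corr=corr, noise_sd=0.5)
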