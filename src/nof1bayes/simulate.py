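"""Synthetic N-of-1 diary data under the assumed data-generating process.

The generator mirrors the model the trial's power study assumes: each
patient *i* has a random intercept ``a_i ~ N(0, sigma_intercept^2)`` and a
random treatment-effect deviation ``b_i ~ N(0, sigma_slope^2)`` around the
population mean effect ``beta0``; observations add within-person residual
noise.  The sign convention throughout the package is that a positive
treatment effect *lowers* the severity score on the active arm:

    placebo:  y ~ Normal(mu + a_i, resid_sd_i)
    active:   y ~ Normal(mu + a_i - (beta0 + beta_subgroup * x_i + b_i), resid_sd_i)

where ``x_i`` is the centered subgroup contrast (chloride -1/2, sodium +1/2).

Outcomes are continuous by default, matching the normal working model; IVR
ordinal clipping to the 1-9 scale is an opt-in stress test
(:func:`clip_to_ivr`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import DesignSpec, PeriodOrder, randomize_orders

#: Long-format column schema shared across the package.
SERIES_COLUMNS = [
    "patient_id",
    "subgroup",
    "set",
    "period",
    "order",
    "arm",
    "day",
    "outcome",
]

#: Centered subgroup contrast keeping beta0 the overall mean effect.
SUBGROUP_CONTRAST = {"chloride": -0.5, "sodium": +0.5}


@dataclass(frozen=True)
class CohortParams:
    """Population parameters of the data-generating process.

    ``mu`` is the mean severity on placebo (the published RCT placebo mean
    was 4.21 on the 1-9 IVR scale).  ``sigma_resid`` defaults to the
    reported within-subject SD of 1.5; the between-patient SDs are the
    package's documented defaults since no published values exist.
    ``per_patient_resid_heterogeneity`` is the log-scale SD of a lognormal
    multiplier on each patient's residual SD (0 = common residual SD).
    """

    mu: float = 4.21
    beta0: float = 1.75
    beta_subgroup: float = 0.0
    sigma_intercept: float = 1.0
    sigma_slope: float = 0.5
    sigma_resid: float = 1.5
    per_patient_resid_heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        sds = (
            self.sigma_intercept,
            self.sigma_slope,
            self.sigma_resid,
            self.per_patient_resid_heterogeneity,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all SD parameters must be non-negative")


def simulate_trial(
    params: CohortParams,
    patient_effects: tuple[float, float, float],
    n_pairs: int,
    obs_per_period: int,
    orders: PeriodOrder,
    seed: int | np.random.Generator = 0,
    patient_id: str = "P01",
    subgroup: str = "chloride",
) -> pd.DataFrame:
    """Simulate one patient's diary series over ``n_pairs`` treatment sets.

    ``patient_effects`` is the realized triple ``(a_i, b_i, resid_sd_i)``.
    Returns ``2 * obs_per_period * n_pairs`` rows in the long format.
    """
    if int(n_pairs) != n_pairs or n_pairs < 1:
        raise ValueError("n_pairs must be a positive integer")
    if int(obs_per_period) != obs_per_period or obs_per_period < 1:
        raise ValueError("obs_per_period must be a positive integer")
    if len(orders.labels) < n_pairs:
        raise ValueError("orders must provide a label for every treatment set")
    a_i, b_i, resid_sd_i = patient_effects
    if resid_sd_i < 0:
        raise ValueError("residual SD must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    x_i = SUBGROUP_CONTRAST.get(subgroup, 0.0)
    effect_i = params.beta0 + params.beta_subgroup * x_i + b_i
    rows = []
    for s in range(1, n_pairs + 1):
        for period in (1, 2):
            arm = orders.arm_of(s, period)
            level = params.mu + a_i - (effect_i if arm == "active" else 0.0)
            y = rng.normal(level, resid_sd_i, size=obs_per_period)
            for day, val in enumerate(y, start=1):
                rows.append(
                    (patient_id, subgroup, s, period, orders.labels[s - 1], arm, day, val)
                )
    return pd.DataFrame(rows, columns=SERIES_COLUMNS)


def simulate_cohort(
    design: DesignSpec,
    params: CohortParams,
    n_pairs: int = 2,
    seed: int = 0,
    obs_per_period: int | None = None,
) -> pd.DataFrame:
    """Simulate a full cohort of independent N-of-1 trials.

    Per-patient effects are drawn ``a_i ~ N(0, sigma_intercept^2)``,
    ``b_i ~ N(0, sigma_slope^2)``; period orders are block-randomized per
    patient and set.  ``obs_per_period`` defaults to the design's
    ``obs_per_arm_per_pair``.
    """
    if obs_per_period is None:
        obs_per_period = design.obs_per_arm_per_pair
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    labels = design.subgroup_labels()
    n = design.n_patients
    a = rng.normal(0.0, params.sigma_intercept, size=n)
    b = rng.normal(0.0, params.sigma_slope, size=n)
    h = params.per_patient_resid_heterogeneity
    if h > 0:
        # lognormal multiplier with median 1, so sigma_resid is the median SD
        resid = params.sigma_resid * np.exp(rng.normal(0.0, h, size=n))
    else:
        resid = np.full(n, params.sigma_resid)

    width = len(str(n))
    frames = []
    child_seeds = ss.spawn(n)
    for i in range(n):
        child = np.random.default_rng(child_seeds[i])
        orders = PeriodOrder(
            labels=tuple(
                "active_first" if f else "placebo_first"
                for f in child.integers(0, 2, size=n_pairs)
            ),
            seed=seed,
        )
        frames.append(
            simulate_trial(
                params,
                (a[i], b[i], resid[i]),
                n_pairs,
                obs_per_period,
                orders,
                seed=child,
                patient_id=f"P{i + 1:0{width}d}",
                subgroup=labels[i],
            )
        )
    return pd.concat(frames, ignore_index=True)


def clip_to_ivr(values, enabled: bool = True):
    """Round to the nearest integer and clamp to the 1-9 IVR scale.

    Identity when ``enabled`` is False.  Idempotent.
    """
    if not enabled:
        return values
    arr = np.clip(np.rint(np.asarray(values, dtype=float)), 1.0, 9.0)
    return arr


def simulate_cost_effect(
    n_patients: int,
    mean_costs: dict[str, float],
    mean_effects: dict[str, float],
    cost_sd: float = 0.0,
    effect_sd: float = 0.0,
    correlation: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired per-patient cost/effect records for the CEA layer.

    ``mean_costs`` and ``mean_effects`` map arm name -> mean; each patient
    gets one bivariate normal (cost, effect) draw per arm with the stated
    SDs and within-pair correlation.
    """
    if cost_sd < 0 or effect_sd < 0:
        raise ValueError("SDs must be non-negative")
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if set(mean_costs) != set(mean_effects):
        raise ValueError("mean_costs and mean_effects must cover the same arms")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [cost_sd**2, correlation * cost_sd * effect_sd],
            [correlation * cost_sd * effect_sd, effect_sd**2],
        ]
    )
    width = len(str(n_patients))
    rows = []
    for arm in sorted(mean_costs):
        mean = np.array([mean_costs[arm], mean_effects[arm]])
        draws = rng.multivariate_normal(mean, cov, size=n_patients)
        for i in range(n_patients):
            rows.append((f"P{i + 1:0{width}d}", arm, draws[i, 0], draws[i, 1]))
    return pd.DataFrame(rows, columns=["patient_id", "arm", "cost", "effect"])
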