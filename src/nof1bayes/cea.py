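"""Trial-level cost-effectiveness: costs, ICER, bootstrap intervals.

Costs per patient are resource volumes times unit costs (Dutch national
guideline rates, price year 2014, Euros, by convention of the protocol);
effects are quality-of-life scores supplied as scalars per patient-arm.
The incremental cost-effectiveness ratio (ICER) is reported only when the
active arm is more effective and more expensive — or less effective and
less expensive — than placebo; otherwise one arm dominates and a flag is
returned instead of a ratio.  Uncertainty is quantified with a percentile
nonparametric bootstrap, resampling patients with replacement within arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

ICER_STATUS = "icer"
DOMINANT = "dominant"  # active cheaper and more effective
DOMINATED = "dominated"  # active costlier and less effective
UNDEFINED = "undefined"  # zero effect difference


class MissingUnitCostError(KeyError):
    """A resource category has no unit cost."""


def compute_costs(volumes: Mapping[str, float], unit_costs: Mapping[str, float]) -> float:
    """Total cost: sum over categories of volume x unit cost."""
    missing = [k for k in volumes if k not in unit_costs]
    if missing:
        raise MissingUnitCostError(
            f"no unit cost for categories: {sorted(missing)}"
        )
    if any(c < 0 for c in unit_costs.values()):
        raise ValueError("unit costs must be non-negative")
    return float(sum(v * unit_costs[k] for k, v in volumes.items()))


@dataclass(frozen=True)
class ICERResult:
    """ICER value, or a dominance/undefined flag when the ratio is not meaningful."""

    status: str
    value: float | None = None

    def __bool__(self) -> bool:
        return self.status == ICER_STATUS


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Incremental cost-effectiveness ratio for active-minus-placebo deltas."""
    if delta_effect == 0:
        return ICERResult(status=UNDEFINED)
    if delta_cost * delta_effect > 0:
        return ICERResult(status=ICER_STATUS, value=float(delta_cost / delta_effect))
    if delta_effect > 0:  # more effective, not more expensive
        return ICERResult(status=DOMINANT)
    return ICERResult(status=DOMINATED)


@dataclass(frozen=True)
class CEBootstrapResult:
    """Point estimates and percentile bootstrap CIs for the CE contrast."""

    delta_cost: float
    delta_effect: float
    icer: ICERResult
    ci_delta_cost: tuple[float, float]
    ci_delta_effect: tuple[float, float]
    ci_icer: tuple[float, float] | None
    icer_ci_suppressed_reason: str | None
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": {"status": self.icer.status, "value": self.icer.value},
            "ci_delta_cost": list(self.ci_delta_cost),
            "ci_delta_effect": list(self.ci_delta_effect),
            "ci_icer": list(self.ci_icer) if self.ci_icer else None,
            "icer_ci_suppressed_reason": self.icer_ci_suppressed_reason,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def bootstrap_ce(
    records: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
    active: str = "active",
    placebo: str = "placebo",
) -> CEBootstrapResult:
    """Percentile bootstrap CIs for mean cost/effect differences and the ICER.

    ``records`` needs columns ``patient_id``, ``arm``, ``cost``, ``effect``.
    Patients are resampled with replacement within each arm.  The ICER CI is
    produced only when every resample yields sign-matching deltas; otherwise
    it is suppressed with an explanatory flag while the cost/effect CIs are
    still returned.
    """
    required = {"patient_id", "arm", "cost", "effect"}
    if not required <= set(records.columns):
        raise ValueError(f"records missing columns: {sorted(required - set(records.columns))}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    arms = {}
    for arm in (active, placebo):
        grp = records[records["arm"] == arm]
        if grp["patient_id"].nunique() < 2:
            raise ValueError(f"need at least two patients in arm {arm!r}")
        arms[arm] = grp[["cost", "effect"]].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    d_cost = float(arms[active][:, 0].mean() - arms[placebo][:, 0].mean())
    d_eff = float(arms[active][:, 1].mean() - arms[placebo][:, 1].mean())

    na, npl = len(arms[active]), len(arms[placebo])
    ia = rng.integers(0, na, size=(n_boot, na))
    ip = rng.integers(0, npl, size=(n_boot, npl))
    boot_cost = arms[active][ia, 0].mean(axis=1) - arms[placebo][ip, 0].mean(axis=1)
    boot_eff = arms[active][ia, 1].mean(axis=1) - arms[placebo][ip, 1].mean(axis=1)

    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    ci_cost = (float(np.quantile(boot_cost, lo)), float(np.quantile(boot_cost, hi)))
    ci_eff = (float(np.quantile(boot_eff, lo)), float(np.quantile(boot_eff, hi)))

    point = icer(d_cost, d_eff)
    ci_icer = None
    reason = None
    signs_ok = np.all(boot_cost * boot_eff > 0) and point.status == ICER_STATUS
    if signs_ok:
        ratios = boot_cost / boot_eff
        ci_icer = (float(np.quantile(ratios, lo)), float(np.quantile(ratios, hi)))
    else:
        reason = (
            "bootstrap resamples mix cost/effect signs (or the point ICER is "
            "not a ratio); the ICER interval is not meaningful"
        )
    return CEBootstrapResult(
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=point,
        ci_delta_cost=ci_cost,
        ci_delta_effect=ci_eff,
        ci_icer=ci_icer,
        icer_ci_suppressed_reason=reason,
        n_boot=n_boot,
        seed=seed,
    )
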