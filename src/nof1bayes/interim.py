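"""Per-patient sequential interim decisions after treatment sets 1-3.

After each completed treatment set (up to the third) the patient's
cumulative data are analyzed with the single-patient model under a
non-informative prior, and the posterior probability that the individual
treatment effect exceeds the MCID (0.75 IVR points) is compared against
stopping bounds: at least 80% -> stop, treatment effective (start regular
treatment); at most 20% -> stop, ineffective; otherwise continue.  The
fourth set is never followed by an interim decision — its data flow only
into the combined analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .hierarchical import McmcSettings, ModelSpec, fit_hierarchical, posterior_prob_at_least
from .priors import PriorSpec

STOP_EFFECTIVE = "stop_effective"
STOP_INEFFECTIVE = "stop_ineffective"
CONTINUE = "continue"

#: Last treatment set after which an interim decision is taken.
LAST_INTERIM_SET = 3


@dataclass(frozen=True)
class StoppingRule:
    """Interim stopping thresholds on P(individual effect >= delta)."""

    delta: float = 0.75
    upper: float = 0.80
    lower: float = 0.20
    max_sets: int = 4
    interim_prior: PriorSpec = field(default_factory=PriorSpec.flat)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower < self.upper <= 1.0:
            raise ValueError("need 0 <= lower < upper <= 1")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.max_sets < 1:
            raise ValueError("max_sets must be at least 1")


@dataclass(frozen=True)
class InterimDecision:
    decision: str
    probability: float
    set_index: int

    def to_dict(self) -> dict:
        return {
            "set": self.set_index,
            "posterior_probability": self.probability,
            "decision": self.decision,
        }


def interim_decision(prob: float, rule: StoppingRule, set_index: int = 0) -> InterimDecision:
    """Map a posterior probability onto a stopping decision.

    Boundaries are inclusive: exactly 80% stops for effectiveness, exactly
    20% stops for ineffectiveness.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {prob!r}")
    if prob >= rule.upper:
        decision = STOP_EFFECTIVE
    elif prob <= rule.lower:
        decision = STOP_INEFFECTIVE
    else:
        decision = CONTINUE
    return InterimDecision(decision=decision, probability=float(prob), set_index=set_index)


def run_sequential(
    series: pd.DataFrame,
    rule: StoppingRule | None = None,
    mcmc: McmcSettings | None = None,
) -> list[InterimDecision]:
    """Sequential interim decisions for one patient's cumulative data.

    Fits the single-patient model with the rule's interim prior (flat by
    default; the informative cohort prior is deliberately never used here)
    on the data accumulated through each completed set, emitting decisions
    after sets 1..3 and stopping at the first stop decision.  Sets missing
    one of the two arms are excluded with a warning.
    """
    rule = rule or StoppingRule()
    mcmc = mcmc or McmcSettings(chains=2, warmup=300, draws=1000)
    if series["patient_id"].nunique() != 1:
        raise ValueError("run_sequential expects data for exactly one patient")

    complete = []
    for s, grp in series.groupby("set"):
        if {"active", "placebo"} <= set(grp["arm"].unique()):
            complete.append(int(s))
        else:
            warnings.warn(
                f"treatment set {s} is incomplete (one period missing); excluded",
                UserWarning,
                stacklevel=2,
            )
    complete.sort()

    model = ModelSpec(prior_beta0=rule.interim_prior, subgroup_fixed_effect=False)
    decisions: list[InterimDecision] = []
    for k, s in enumerate(complete, start=1):
        if k > min(LAST_INTERIM_SET, rule.max_sets - 1):
            break
        cumulative = series[series["set"].isin(complete[:k])]
        draws = fit_hierarchical(cumulative, model, mcmc)
        prob = posterior_prob_at_least(draws, rule.delta)
        decision = interim_decision(prob, rule, set_index=s)
        decisions.append(decision)
        if decision.decision != CONTINUE:
            break
    return decisions
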