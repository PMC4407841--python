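"""Hierarchical Bayesian combination of N-of-1 trials.

Model
-----
For observation *j* of patient *i* (severity score ``y_ij``, treatment
indicator ``T_ij`` = 1 on mexiletine):

    y_ij = mu + a_i - (beta0 + beta_g * x_i + b_i + interactions) * T_ij + eps_ij

    a_i ~ Normal(0, sigma_a^2)         random intercept
    b_i ~ Normal(0, sigma_b^2)         random treatment-effect deviation
    eps_ij ~ Normal(0, sigma_i^2)      within-person residual

``x_i`` is the centered subgroup contrast (chloride -1/2, sodium +1/2), so
``beta0`` stays interpretable as the population mean effect, with positive
values meaning symptom improvement on active treatment.  The residual
variance is either common to all patients or patient-specific with the
``sigma_i^2`` drawn from a shared heavy-tailed (scaled inverse-chi-square)
distribution whose scale gets its own conjugate update.

Inference is a blocked Gibbs sampler: the fixed-effect vector is drawn
jointly from its multivariate-normal full conditional, random effects and
variance components from their conjugate conditionals.  Normal and flat
priors on ``beta0`` enter the joint fixed-effect update; a histogram
(elicited) prior is handled exactly by a piecewise-truncated-normal scalar
conditional.  Convergence is monitored with split-R-hat and effective
sample size (arviz); runs with R-hat(beta0) > 1.05 are flagged, never
silently accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .priors import PriorSpec, MEXILETINE_RCT_PRIOR, FLAT_PRIOR_SCALE
from .simulate import SUBGROUP_CONTRAST

__all__ = [
    "ModelSpec",
    "McmcSettings",
    "PosteriorDraws",
    "FrequentistResult",
    "NotEstimableError",
    "ConvergenceWarning",
    "fit_hierarchical",
    "posterior_prob_at_least",
    "individual_effects",
    "estimate_interactions",
    "fit_crossover_frequentist",
]

RHAT_LIMIT = 1.05
ESS_MIN = 400.0

# weakly-informative hyperpriors (inverse-gamma shape/scale) on the
# between-patient variances; diffuse on the residual variance
_A_RE, _B_RE = 1.0, 0.5
_A_EPS, _B_EPS = 0.001, 0.001
_A_TAU, _B_TAU = 1.0, 0.5


class NotEstimableError(ValueError):
    """Requested term is structurally unidentifiable in the data."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics failed the acceptance gate."""


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the hierarchical model.

    ``interactions`` may include ``"set"`` (treatment x treatment-set) and
    ``"order"`` (treatment x period-order).  ``residual_variance_mode`` is
    ``"per_patient"`` (patient-specific variances from a shared scaled
    inverse-chi-square with ``nu_resid`` df) or ``"common"``.  The
    ``fixed_sigma_*`` fields pin a variance component to a known value
    (0 removes the corresponding random effect) — used for conjugate
    verification and for speed-sensitive paths.
    """

    prior_beta0: PriorSpec = MEXILETINE_RCT_PRIOR
    subgroup_fixed_effect: bool = True
    interactions: tuple[str, ...] = ()
    residual_variance_mode: str = "per_patient"
    nu_resid: float = 4.0
    fixed_sigma_intercept: float | None = None
    fixed_sigma_slope: float | None = None
    fixed_sigma_resid: float | None = None

    def __post_init__(self) -> None:
        if not self.prior_beta0.is_analysis_prior:
            raise ValueError("prior_beta0 must be a normal, flat or histogram prior")
        bad = set(self.interactions) - {"set", "order"}
        if bad:
            raise ValueError(f"unknown interaction terms: {sorted(bad)}")
        if self.residual_variance_mode not in ("common", "per_patient"):
            raise ValueError("residual_variance_mode must be 'common' or 'per_patient'")
        for s in (self.fixed_sigma_intercept, self.fixed_sigma_slope, self.fixed_sigma_resid):
            if s is not None and s < 0:
                raise ValueError("fixed variance components must be non-negative")


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 4
    warmup: int = 500
    draws: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.draws < 1:
            raise ValueError("invalid MCMC settings")


@dataclass
class PosteriorDraws:
    """Posterior draws and diagnostics from :func:`fit_hierarchical`.

    Arrays are shaped ``(chains, draws)`` (plus a trailing patient axis for
    random effects).  ``diagnostics`` maps parameter name to
    ``{"rhat": ..., "ess": ...}`` (NaN with a single chain).
    """

    fixed_names: list[str]
    fixed: np.ndarray  # (chains, draws, p)
    a: np.ndarray  # (chains, draws, m) random intercepts
    b: np.ndarray  # (chains, draws, m) random slope deviations
    variances: dict[str, np.ndarray]  # name -> (chains, draws), on SD scale
    patient_ids: list[str]
    patient_contrast: np.ndarray  # x_i per patient (0 when no subgroup term)
    diagnostics: dict[str, dict[str, float]]
    seed: int
    model: ModelSpec
    warnings_: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def beta0(self) -> np.ndarray:
        """Flattened draws of the population mean treatment effect."""
        j = self.fixed_names.index("treatment")
        return self.fixed[:, :, j].reshape(-1)

    def fixed_effect(self, name: str) -> np.ndarray:
        j = self.fixed_names.index(name)
        return self.fixed[:, :, j].reshape(-1)

    def patient_effects(self) -> np.ndarray:
        """Draws of theta_i = beta0 + beta_g * x_i + b_i, shape (n_draws, m)."""
        j = self.fixed_names.index("treatment")
        beta0 = self.fixed[:, :, j].reshape(-1, 1)
        b = self.b.reshape(-1, len(self.patient_ids))
        if "treatment:subgroup" in self.fixed_names:
            jg = self.fixed_names.index("treatment:subgroup")
            bg = self.fixed[:, :, jg].reshape(-1, 1)
            return beta0 + bg * self.patient_contrast[None, :] + b
        return beta0 + b

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.fixed_names:
            d = self.fixed_effect(name)
            rows.append(self._row(name, d))
        for name, arr in self.variances.items():
            rows.append(self._row(name, arr.reshape(-1)))
        return pd.DataFrame(rows).set_index("parameter")

    def _row(self, name: str, d: np.ndarray) -> dict:
        diag = self.diagnostics.get(name, {})
        return {
            "parameter": name,
            "mean": float(np.mean(d)),
            "sd": float(np.std(d, ddof=1)),
            "hdi_2.5%": float(np.quantile(d, 0.025)),
            "hdi_97.5%": float(np.quantile(d, 0.975)),
            "rhat": diag.get("rhat", np.nan),
            "ess": diag.get("ess", np.nan),
        }


@dataclass(frozen=True)
class FrequentistResult:
    """Paired crossover analysis of patient-level period-mean differences."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    per_patient_differences: pd.Series

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must contain the point estimate")


# ---------------------------------------------------------------------------
# data preparation


def _subgroup_contrasts(labels: pd.Series) -> tuple[np.ndarray, bool]:
    """Per-patient centered contrast; returns (values, usable)."""
    uniq = sorted(labels.unique())
    if len(uniq) == 1:
        return np.zeros(len(labels)), False
    if len(uniq) > 2:
        raise NotEstimableError(
            f"subgroup fixed effect needs a binary subgroup, got {uniq}"
        )
    if set(uniq) <= set(SUBGROUP_CONTRAST):
        mapping = SUBGROUP_CONTRAST
    else:
        mapping = {uniq[0]: -0.5, uniq[1]: +0.5}
    return labels.map(mapping).to_numpy(dtype=float), True


def _prepare(data: pd.DataFrame, model: ModelSpec):
    if data is None or len(data) == 0:
        raise ValueError("empty data: at least one observation is required")
    required = {"patient_id", "arm", "outcome"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns: {sorted(missing)}")
    bad_arm = set(data["arm"].unique()) - {"active", "placebo"}
    if bad_arm:
        raise ValueError(f"unknown arm labels: {sorted(bad_arm)}")

    y = data["outcome"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    patient_ids, pat = np.unique(data["patient_id"].to_numpy(), return_inverse=True)
    m = len(patient_ids)
    ct = np.where(data["arm"].to_numpy() == "active", -1.0, 0.0)

    warns: list[str] = []
    both = pd.crosstab(data["patient_id"], data["arm"])
    for col in ("active", "placebo"):
        if col not in both.columns:
            both[col] = 0
    one_armed = both.index[(both["active"] == 0) | (both["placebo"] == 0)].tolist()
    if len(one_armed) == m:
        raise ValueError("no patient has observations in both arms")
    for pid in one_armed:
        msg = (
            f"patient {pid} has observations in only one arm; "
            "its individual effect is prior-dominated"
        )
        warns.append(msg)
        warnings.warn(msg, UserWarning, stacklevel=3)

    cols = [np.ones_like(y), ct]
    names = ["intercept", "treatment"]
    x_pat = np.zeros(m)
    if model.subgroup_fixed_effect and "subgroup" in data.columns:
        sub_by_pat = data.groupby("patient_id")["subgroup"].first().reindex(patient_ids)
        x_pat, usable = _subgroup_contrasts(sub_by_pat)
        if usable:
            cols.append(ct * x_pat[pat])
            names.append("treatment:subgroup")

    if "set" in model.interactions:
        if "set" not in data.columns or data["set"].nunique() < 2:
            raise NotEstimableError(
                "treatment x set interaction needs at least two treatment sets"
            )
        z = data["set"].to_numpy(dtype=float)
        cols.append(ct * (z - z.mean()))
        names.append("treatment:set")
    if "order" in model.interactions:
        if "order" not in data.columns or data["order"].nunique() < 2:
            raise NotEstimableError(
                "treatment x order interaction needs both period orders present"
            )
        z = np.where(data["order"].to_numpy() == "active_first", 0.5, -0.5)
        cols.append(ct * (z - z.mean()))
        names.append("treatment:order")

    X = np.column_stack(cols)
    return y, pat, ct, X, names, list(map(str, patient_ids)), x_pat, warns


# ---------------------------------------------------------------------------
# histogram-prior scalar conditional


def _log_normal_mass(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) computed stably for standardized bounds a < b."""
    out = np.empty_like(a)
    neg = b <= 0
    pos = a >= 0
    mid = ~(neg | pos)
    # both bounds in one tail: factor out the larger log-CDF
    la, lb = special.log_ndtr(a[neg]), special.log_ndtr(b[neg])
    out[neg] = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-12)))
    la, lb = special.log_ndtr(-b[pos]), special.log_ndtr(-a[pos])
    out[pos] = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-12)))
    out[mid] = np.log(special.ndtr(b[mid]) - special.ndtr(a[mid]))
    return out


def _sample_histogram_conditional(
    mhat: float, prec: float, edges: np.ndarray, probs: np.ndarray, rng
) -> float:
    """Exact draw from N(mhat, 1/prec) x piecewise-constant prior."""
    s = 1.0 / np.sqrt(prec)
    z = (edges - mhat) / s
    widths = np.diff(edges)
    with np.errstate(divide="ignore"):
        logw = np.where(probs > 0, np.log(probs / widths), -np.inf)
    logw = logw + _log_normal_mass(z[:-1], z[1:])
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    k = rng.choice(len(w), p=w)
    lo, hi = special.ndtr(z[k]), special.ndtr(z[k + 1])
    u = rng.uniform(lo, hi)
    u = min(max(u, 1e-15), 1 - 1e-15)
    x = mhat + s * special.ndtri(u)
    # guard against round-off pushing the draw outside its bin
    return float(min(max(x, edges[k]), edges[k + 1]))


# ---------------------------------------------------------------------------
# Gibbs sampler


def _invgamma_draw(shape: float, scale: float, rng) -> float:
    return scale / rng.gamma(shape)


def _run_chain(
    y,
    pat,
    ct,
    X,
    names,
    model: ModelSpec,
    n_warm: int,
    n_keep: int,
    rng: np.random.Generator,
    use_re: bool,
):
    n, p = X.shape
    m = int(pat.max()) + 1
    j_t = names.index("treatment")
    counts = np.bincount(pat, minlength=m).astype(float)
    ct2_by_pat = np.bincount(pat, weights=ct * ct, minlength=m)

    hist_prior = model.prior_beta0.kind == "histogram"
    prior_mean = np.zeros(p)
    prior_prec = np.full(p, 1.0 / FLAT_PRIOR_SCALE**2)
    if not hist_prior:
        loc, scale = model.prior_beta0.gaussian_moments()
        prior_mean[j_t] = loc
        prior_prec[j_t] = 1.0 / scale**2
    else:
        edges = np.asarray(model.prior_beta0.edges)
        probs = np.asarray(model.prior_beta0.probs)
        jmask = np.arange(p) != j_t
        Xm = X[:, jmask]
        pm_mean, pm_prec = prior_mean[jmask], prior_prec[jmask]

    re_a = use_re and model.fixed_sigma_intercept != 0
    re_b = use_re and model.fixed_sigma_slope != 0
    fix_a = model.fixed_sigma_intercept
    fix_b = model.fixed_sigma_slope
    fix_e = model.fixed_sigma_resid
    per_patient = model.residual_variance_mode == "per_patient" and fix_e is None
    nu = model.nu_resid

    # init
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    theta = theta + rng.normal(0.0, 0.1, size=p)
    a = np.zeros(m)
    b = np.zeros(m)
    resid0 = y - X @ theta
    s2_init = max(float(np.var(resid0)), 1e-6)
    sig2 = np.full(m, s2_init) if per_patient else s2_init
    if fix_e is not None:
        sig2 = fix_e**2
    tau2 = s2_init
    sig2_a = fix_a**2 if fix_a is not None else 1.0
    sig2_b = fix_b**2 if fix_b is not None else 0.25

    XtX = X.T @ X  # reused on the common-variance path
    if hist_prior:
        XmtXm = Xm.T @ Xm

    out_fixed = np.empty((n_keep, p))
    out_a = np.empty((n_keep, m))
    out_b = np.empty((n_keep, m))
    out_var = {
        "sigma_intercept": np.empty(n_keep),
        "sigma_slope": np.empty(n_keep),
        "sigma_resid": np.empty(n_keep),
    }

    for it in range(n_warm + n_keep):
        scalar_w = not per_patient
        w = (1.0 / sig2) if scalar_w else (1.0 / sig2)[pat]

        # --- fixed effects -------------------------------------------------
        r = y - a[pat] - b[pat] * ct
        if not hist_prior:
            if scalar_w:
                A = XtX * w + np.diag(prior_prec)
                rhs = (X.T @ r) * w + prior_prec * prior_mean
            else:
                Xw = X * w[:, None]
                A = X.T @ Xw + np.diag(prior_prec)
                rhs = Xw.T @ r + prior_prec * prior_mean
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, rhs)
            z = rng.standard_normal(p)
            theta = mean + np.linalg.solve(L.T, z)
        else:
            # other fixed effects jointly, given current beta0
            r2 = r - X[:, j_t] * theta[j_t]
            if scalar_w:
                A = XmtXm * w + np.diag(pm_prec)
                rhs = (Xm.T @ r2) * w + pm_prec * pm_mean
            else:
                Xmw = Xm * w[:, None]
                A = Xm.T @ Xmw + np.diag(pm_prec)
                rhs = Xmw.T @ r2 + pm_prec * pm_mean
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, rhs)
            th_m = mean + np.linalg.solve(L.T, rng.standard_normal(p - 1))
            theta[jmask] = th_m
            # beta0 | rest: Gaussian likelihood x piecewise-constant prior
            r3 = r - Xm @ th_m
            if scalar_w:
                lam = float((ct * ct).sum() * w)
                num = float((ct * r3).sum() * w)
            else:
                lam = float((ct * ct * w).sum())
                num = float((ct * r3 * w).sum())
            mhat = num / lam
            theta[j_t] = _sample_histogram_conditional(mhat, lam, edges, probs, rng)

        # --- random intercepts --------------------------------------------
        if re_a:
            r = y - X @ theta - b[pat] * ct
            if scalar_w:
                sw = counts * w
                swr = np.bincount(pat, weights=r, minlength=m) * w
            else:
                sw = np.bincount(pat, weights=w, minlength=m)
                swr = np.bincount(pat, weights=w * r, minlength=m)
            prec = sw + 1.0 / sig2_a
            a = swr / prec + rng.standard_normal(m) / np.sqrt(prec)
            if fix_a is None:
                sig2_a = _invgamma_draw(_A_RE + m / 2.0, _B_RE + 0.5 * float(a @ a), rng)

        # --- random slopes -------------------------------------------------
        if re_b:
            r = y - X @ theta - a[pat]
            if scalar_w:
                sw = ct2_by_pat * w
                swr = np.bincount(pat, weights=ct * r, minlength=m) * w
            else:
                sw = np.bincount(pat, weights=w * ct * ct, minlength=m)
                swr = np.bincount(pat, weights=w * ct * r, minlength=m)
            prec = sw + 1.0 / sig2_b
            b = swr / prec + rng.standard_normal(m) / np.sqrt(prec)
            if fix_b is None:
                sig2_b = _invgamma_draw(_A_RE + m / 2.0, _B_RE + 0.5 * float(b @ b), rng)

        # --- translation (recentering) moves -------------------------------
        # The likelihood is invariant under (mu + d, a_i - d) and
        # (beta0 + d, b_i - d); sampling d from its exact conditional under
        # the priors removes the random-walk degeneracy between the
        # population means and the random-effect averages.
        if re_a:
            prec_d = prior_prec[0] + m / sig2_a
            mean_d = (prior_prec[0] * (prior_mean[0] - theta[0]) + a.sum() / sig2_a) / prec_d
            d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
            theta[0] += d
            a -= d
        if re_b:
            if not hist_prior:
                prec_d = prior_prec[j_t] + m / sig2_b
                mean_d = (
                    prior_prec[j_t] * (prior_mean[j_t] - theta[j_t]) + b.sum() / sig2_b
                ) / prec_d
                d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
                theta[j_t] += d
                b -= d
            else:
                new_b0 = _sample_histogram_conditional(
                    float(theta[j_t] + b.mean()), m / sig2_b, edges, probs, rng
                )
                b -= new_b0 - theta[j_t]
                theta[j_t] = new_b0

        # --- residual variance ----------------------------------------------
        e = y - X @ theta - a[pat] - b[pat] * ct
        if fix_e is None:
            if per_patient:
                sse = np.bincount(pat, weights=e * e, minlength=m)
                shape = 0.5 * (nu + counts)
                scale = 0.5 * (nu * tau2 + sse)
                sig2 = scale / rng.gamma(shape)
                tau2 = rng.gamma(_A_TAU + 0.5 * m * nu) / (
                    _B_TAU + 0.5 * nu * float(np.sum(1.0 / sig2))
                )
            else:
                sig2 = _invgamma_draw(
                    _A_EPS + n / 2.0, _B_EPS + 0.5 * float(e @ e), rng
                )

        if it >= n_warm:
            k = it - n_warm
            out_fixed[k] = theta
            out_a[k] = a
            out_b[k] = b
            out_var["sigma_intercept"][k] = np.sqrt(sig2_a)
            out_var["sigma_slope"][k] = np.sqrt(sig2_b)
            out_var["sigma_resid"][k] = np.sqrt(tau2 if per_patient else sig2)

    return out_fixed, out_a, out_b, out_var


def _diagnostics(draws_by_name: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Split-R-hat and bulk ESS per parameter via arviz; NaN for 1 chain."""
    import arviz as az

    out: dict[str, dict[str, float]] = {}
    n_chains = next(iter(draws_by_name.values())).shape[0]
    if n_chains < 2:
        return {k: {"rhat": float("nan"), "ess": float("nan")} for k in draws_by_name}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=draws_by_name)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    for k in draws_by_name:
        out[k] = {"rhat": float(rhat[k].values), "ess": float(ess[k].values)}
    return out


def fit_hierarchical(
    data: pd.DataFrame,
    model: ModelSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> PosteriorDraws:
    """Fit the hierarchical model to long-format N-of-1 data.

    With a single patient the random effects are dropped (absorbed into the
    intercept and the treatment effect), giving the single-patient model
    used at interim analyses.
    """
    model = model or ModelSpec()
    mcmc = mcmc or McmcSettings()
    y, pat, ct, X, names, patient_ids, x_pat, warns = _prepare(data, model)
    use_re = len(patient_ids) > 1

    ss = np.random.SeedSequence(mcmc.seed)
    chain_seeds = ss.spawn(mcmc.chains)
    fixed, aa, bb = [], [], []
    var: dict[str, list] = {"sigma_intercept": [], "sigma_slope": [], "sigma_resid": []}
    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        f, a_, b_, v = _run_chain(
            y, pat, ct, X, names, model, mcmc.warmup, mcmc.draws, rng, use_re
        )
        fixed.append(f)
        aa.append(a_)
        bb.append(b_)
        for k in var:
            var[k].append(v[k])
    fixed = np.stack(fixed)  # (chains, draws, p)
    aa = np.stack(aa)
    bb = np.stack(bb)
    variances = {k: np.stack(v) for k, v in var.items()}

    diag_input = {name: fixed[:, :, j] for j, name in enumerate(names)}
    diag_input.update(variances)
    diagnostics = _diagnostics(diag_input)

    converged = True
    rhat_b0 = diagnostics["treatment"]["rhat"]
    ess_b0 = diagnostics["treatment"]["ess"]
    if np.isfinite(rhat_b0) and (rhat_b0 > RHAT_LIMIT or ess_b0 < ESS_MIN):
        converged = False
        msg = (
            f"convergence gate failed for beta0: rhat={rhat_b0:.3f}, ess={ess_b0:.0f}"
        )
        warns.append(msg)
        warnings.warn(msg, ConvergenceWarning, stacklevel=2)

    return PosteriorDraws(
        fixed_names=names,
        fixed=fixed,
        a=aa,
        b=bb,
        variances=variances,
        patient_ids=patient_ids,
        patient_contrast=x_pat,
        diagnostics=diagnostics,
        seed=mcmc.seed,
        model=model,
        warnings_=warns,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# posterior functionals


def posterior_prob_at_least(draws: PosteriorDraws | np.ndarray, delta: float) -> float:
    """Posterior probability that the mean treatment effect is >= delta."""
    beta0 = draws.beta0 if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if beta0.size == 0:
        raise ValueError("no posterior draws")
    return float(np.mean(beta0 >= delta))


def individual_effects(draws: PosteriorDraws, delta: float = 0.75) -> pd.DataFrame:
    """Per-patient posterior summaries of theta_i = beta0 + beta_g x_i + b_i.

    Individual estimates borrow strength from the cohort: they are shrunk
    from each patient's raw contrast toward the population mean in
    proportion to within- vs between-patient variability.
    """
    th = draws.patient_effects()
    return pd.DataFrame(
        {
            "patient_id": draws.patient_ids,
            "mean": th.mean(axis=0),
            "sd": th.std(axis=0, ddof=1),
            "ci_2.5%": np.quantile(th, 0.025, axis=0),
            "ci_97.5%": np.quantile(th, 0.975, axis=0),
            f"P(effect>={delta})": (th >= delta).mean(axis=0),
        }
    ).set_index("patient_id")


def estimate_interactions(
    data: pd.DataFrame,
    model: ModelSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> pd.DataFrame:
    """Posterior summaries for treatment x set / treatment x order terms.

    Raises :class:`NotEstimableError` when the requested interaction is
    structurally unidentifiable (single set, or one period order only).
    """
    model = model or ModelSpec(interactions=("set", "order"))
    if not model.interactions:
        raise ValueError("model.interactions must request at least one term")
    draws = fit_hierarchical(data, model, mcmc)
    rows = []
    for name in draws.fixed_names:
        if name.startswith("treatment:") and name != "treatment:subgroup":
            d = draws.fixed_effect(name)
            rows.append(
                {
                    "term": name,
                    "mean": float(d.mean()),
                    "sd": float(d.std(ddof=1)),
                    "ci_2.5%": float(np.quantile(d, 0.025)),
                    "ci_97.5%": float(np.quantile(d, 0.975)),
                }
            )
    return pd.DataFrame(rows).set_index("term")


def fit_crossover_frequentist(data: pd.DataFrame, alpha: float = 0.05) -> FrequentistResult:
    """Frequentist paired analysis mirroring the earlier crossover RCT.

    Each patient contributes one period-mean difference
    ``mean(placebo) - mean(active)``; the differences enter a paired
    (one-sample) t analysis.
    """
    required = {"patient_id", "arm", "outcome"}
    if not required <= set(data.columns):
        raise ValueError(f"data is missing columns: {sorted(required - set(data.columns))}")
    means = data.groupby(["patient_id", "arm"])["outcome"].mean().unstack("arm")
    if "active" not in means.columns or "placebo" not in means.columns:
        raise ValueError("every included patient needs both arms")
    means = means.dropna()
    if len(means) < 2:
        raise ValueError("paired analysis needs at least two patients with both arms")
    diffs = means["placebo"] - means["active"]
    n = len(diffs)
    est = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        return FrequentistResult(est, est, est, 1.0 if est == 0 else 0.0, diffs)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    tstat, pval = stats.ttest_1samp(diffs, 0.0)
    return FrequentistResult(
        estimate=est,
        ci_low=est - tcrit * se,
        ci_high=est + tcrit * se,
        p_value=float(pval),
        per_patient_differences=diffs,
    )
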