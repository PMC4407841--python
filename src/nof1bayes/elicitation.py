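"""Histogram-based expert prior elicitation and pooling.

Each expert distributes weight (e.g. chips) over bins of a common grid on
the treatment-effect scale; the normalized weights form an individual
clinical prior.  Individual priors are aggregated by a linear opinion pool
(weighted average of bin probabilities, equal weights by default) into one
group clinical prior.  A moment-matched normal approximation bridges
elicited histograms to the normal-prior path of the sampler; the sampler
also accepts histogram priors directly.
"""

from __future__ import annotations

import numpy as np

from .priors import PriorSpec


def make_histogram_prior(edges, weights) -> PriorSpec:
    """Build a histogram prior from raw (non-negative) bin weights."""
    weights = np.asarray(weights, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if weights.ndim != 1 or weights.size < 1:
        raise ValueError("need at least one bin weight")
    if edges.size != weights.size + 1:
        raise ValueError("need exactly one more edge than weights")
    if np.any(weights < 0):
        raise ValueError("bin weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("at least one bin weight must be positive")
    return PriorSpec.histogram(edges, weights / total)


def pool_priors(priors: list[PriorSpec], expert_weights=None) -> PriorSpec:
    """Linear opinion pool of histogram priors on a common grid."""
    if not priors:
        raise ValueError("need at least one prior to pool")
    if any(p.kind != "histogram" for p in priors):
        raise ValueError("all pooled priors must be histogram priors")
    edges = np.asarray(priors[0].edges)
    for p in priors[1:]:
        if len(p.edges) != len(edges) or not np.allclose(p.edges, edges):
            raise ValueError("all experts must use the same bin grid")
    if expert_weights is None:
        w = np.full(len(priors), 1.0 / len(priors))
    else:
        w = np.asarray(expert_weights, dtype=float)
        if w.size != len(priors):
            raise ValueError("one weight per expert required")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("expert weights must be non-negative and sum to 1")
    probs = np.zeros(len(edges) - 1)
    for wi, p in zip(w, priors):
        probs += wi * np.asarray(p.probs)
    probs /= probs.sum()  # exact renormalization against round-off
    return PriorSpec.histogram(edges, probs)


def fit_normal_to_histogram(prior: PriorSpec) -> PriorSpec:
    """Moment-matched normal (mean and SD via bin midpoints).

    Raises when all mass sits in a single bin (the midpoint SD is zero);
    use the histogram prior directly in that case.
    """
    if prior.kind != "histogram":
        raise ValueError("expected a histogram prior")
    probs = np.asarray(prior.probs)
    if np.count_nonzero(probs) < 2:
        raise ValueError(
            "all mass in one bin: SD is degenerate; use the histogram prior directly"
        )
    edges = np.asarray(prior.edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    mean = float(mids @ probs)
    sd = float(np.sqrt(probs @ (mids - mean) ** 2))
    if sd <= 0:
        raise ValueError("histogram has zero spread; use the histogram prior directly")
    return PriorSpec.normal(mean, sd)
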