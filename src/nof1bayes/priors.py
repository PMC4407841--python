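"""Prior specifications for the population mean treatment effect.

Three usable prior families are supported for the mean effect ``beta0``:

* ``normal(location, scale)`` — e.g. the informative prior N(1.75, 0.89)
  derived from the earlier mexiletine crossover RCT;
* ``flat`` — a non-informative prior, implemented as a proper normal with a
  very large scale (:data:`FLAT_PRIOR_SCALE`) so every posterior stays proper;
* ``histogram`` — a piecewise-constant density on an ordered bin grid, as
  produced by expert elicitation (see :mod:`nof1bayes.elicitation`).

A fourth kind, ``point``, is a degenerate sampling-only distribution used to
fix the *true* effect in assurance simulations; it cannot serve as an
analysis prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Scale of the proper normal standing in for a flat prior.  The outcome is a
#: 1-9 severity score, so a prior SD of 1000 contributes negligible precision.
FLAT_PRIOR_SCALE = 1.0e3

_HIST_TOL = 1e-9


@dataclass(frozen=True)
class PriorSpec:
    """Prior on a scalar effect parameter.

    Use the classmethod constructors (:meth:`normal`, :meth:`flat`,
    :meth:`histogram`, :meth:`point`) rather than the raw constructor.
    """

    kind: str
    location: float = 0.0
    scale: float = 1.0
    edges: tuple[float, ...] | None = None
    probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "flat", "histogram", "point"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "normal" and not self.scale > 0:
            raise ValueError("normal prior requires scale > 0")
        if self.kind == "histogram":
            edges = np.asarray(self.edges, dtype=float)
            probs = np.asarray(self.probs, dtype=float)
            if edges.ndim != 1 or edges.size < 2:
                raise ValueError("histogram prior needs at least one bin")
            if probs.size != edges.size - 1:
                raise ValueError("need one probability per bin")
            if np.any(np.diff(edges) <= 0):
                raise ValueError("histogram edges must be strictly increasing")
            if np.any(probs < 0):
                raise ValueError("histogram probabilities must be non-negative")
            if abs(probs.sum() - 1.0) > _HIST_TOL:
                raise ValueError("histogram probabilities must sum to 1")

    # -- constructors -------------------------------------------------------

    @classmethod
    def normal(cls, location: float, scale: float) -> "PriorSpec":
        return cls(kind="normal", location=float(location), scale=float(scale))

    @classmethod
    def flat(cls) -> "PriorSpec":
        return cls(kind="flat", location=0.0, scale=FLAT_PRIOR_SCALE)

    @classmethod
    def histogram(cls, edges, probs) -> "PriorSpec":
        return cls(
            kind="histogram",
            edges=tuple(float(e) for e in edges),
            probs=tuple(float(p) for p in probs),
        )

    @classmethod
    def point(cls, location: float) -> "PriorSpec":
        """Degenerate distribution; valid only for drawing 'true' effects."""
        return cls(kind="point", location=float(location), scale=0.0)

    # -- behaviour ----------------------------------------------------------

    @property
    def is_analysis_prior(self) -> bool:
        return self.kind in ("normal", "flat", "histogram")

    def gaussian_moments(self) -> tuple[float, float]:
        """(location, scale) of the normal used in conjugate updates.

        Flat priors map onto a wide proper normal; histogram priors are
        handled by their own conditional sampler and raise here.
        """
        if self.kind == "normal":
            return self.location, self.scale
        if self.kind == "flat":
            return 0.0, FLAT_PRIOR_SCALE
        raise ValueError(f"{self.kind} prior has no single Gaussian form")

    def mean(self) -> float:
        if self.kind in ("normal", "point"):
            return self.location
        if self.kind == "flat":
            return 0.0
        edges = np.asarray(self.edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        return float(mids @ np.asarray(self.probs))

    def sd(self) -> float:
        if self.kind == "normal":
            return self.scale
        if self.kind == "point":
            return 0.0
        if self.kind == "flat":
            return FLAT_PRIOR_SCALE
        edges = np.asarray(self.edges)
        probs = np.asarray(self.probs)
        mids = 0.5 * (edges[:-1] + edges[1:])
        m = mids @ probs
        # within-bin variance of the uniform adds widths^2 / 12
        widths = np.diff(edges)
        var = probs @ ((mids - m) ** 2 + widths**2 / 12.0)
        return float(np.sqrt(var))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw from the prior (used for assurance truth draws)."""
        if self.kind == "point":
            return np.full(size, self.location)
        if self.kind in ("normal", "flat"):
            loc, scale = self.gaussian_moments()
            return rng.normal(loc, scale, size=size)
        edges = np.asarray(self.edges)
        probs = np.asarray(self.probs)
        k = rng.choice(probs.size, size=size, p=probs)
        return rng.uniform(edges[k], edges[k + 1])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind in ("normal", "point"):
            d["location"] = self.location
        if self.kind == "normal":
            d["scale"] = self.scale
        if self.kind == "histogram":
            d["edges"] = list(self.edges)
            d["probs"] = list(self.probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        kind = d["kind"]
        if kind == "normal":
            return cls.normal(d["location"], d["scale"])
        if kind == "flat":
            return cls.flat()
        if kind == "point":
            return cls.point(d["location"])
        if kind == "histogram":
            return cls.histogram(d["edges"], d["probs"])
        raise ValueError(f"unknown prior kind {kind!r}")


#: Informative prior on the mean IVR-stiffness treatment effect, carried over
#: from the earlier mexiletine crossover RCT evidence.
MEXILETINE_RCT_PRIOR = PriorSpec.normal(1.75, 0.89)
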