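"""Parameterization of bursty gene-expression cascades.

A cascade is an ordered list of genes that activate each other sequentially.
Each gene product is a continuous-valued concentration produced in random
bursts (a compound Poisson process with rate ``k``) and diluted
exponentially at the shared rate ``gamma`` set by cell growth.  The derived
per-gene quantities exposed here are the steady-state level
``x_bar = k <b> / gamma``, the relative activation threshold
``alpha = X / x_bar`` and the stationary intrinsic noise
``CV^2 = <b^2> / (2 <b> x_bar)``.

Units are minutes and min^-1 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BurstModel",
    "GeneSpec",
    "CascadeSpec",
    "InvalidParameterError",
    "FeasibilityWarning",
    "steady_state_level",
    "relative_threshold",
    "absolute_threshold",
    "intrinsic_noise",
]


class InvalidParameterError(ValueError):
    """A model parameter is outside its physical domain."""


class FeasibilityWarning(UserWarning):
    """A relative threshold lies outside (0, 1).

    Not fatal: the optimizer legitimately emits ``alpha = 0`` boundary
    cases, and thresholds above steady state are simulable (though the
    crossing may take a very long time).
    """


#: burst-size families with closed-form first two moments
_FAMILIES = ("geometric", "geometric_shifted", "fixed", "exponential")


@dataclass(frozen=True)
class BurstModel:
    """Burst-size law of one gene: first two moments plus a sampler.

    Parameters
    ----------
    family
        One of ``geometric`` (support {0, 1, 2, ...}; the default
        convention, since it admits means below one), ``geometric_shifted``
        (support {1, 2, ...}, requires ``mean >= 1``), ``fixed``
        (deterministic size) or ``exponential`` (continuous).
    mean
        Mean burst size ``<b>`` in concentration units, > 0.

    Notes
    -----
    The second moment is determined by the family:

    ============  =====================  ==================
    family        variance               second moment
    ============  =====================  ==================
    geometric     m(m + 1)               m(2m + 1)
    geo_shifted   m(m - 1)               m(2m - 1)
    fixed         0                      m^2
    exponential   m^2                    2 m^2
    ============  =====================  ==================
    """

    family: str
    mean: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidParameterError(
                f"unknown burst family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not self.mean > 0:
            raise InvalidParameterError(f"burst mean must be > 0, got {self.mean}")
        if self.family == "geometric_shifted" and self.mean < 1:
            raise InvalidParameterError(
                "geometric burst on support {1,2,...} requires mean >= 1; "
                "use family='geometric' (support {0,1,...}) for smaller means"
            )

    @property
    def second_moment(self) -> float:
        """``<b^2>`` implied by the family and the mean."""
        m = self.mean
        if self.family == "geometric":
            return m * (2 * m + 1)
        if self.family == "geometric_shifted":
            return m * (2 * m - 1)
        if self.family == "fixed":
            return m * m
        return 2 * m * m  # exponential

    @property
    def variance(self) -> float:
        return self.second_moment - self.mean**2

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw burst sizes.  Zero-size bursts are legal no-op events."""
        m = self.mean
        if self.family == "geometric":
            # support {0,1,...}: shift numpy's {1,2,...} convention
            return rng.geometric(1.0 / (m + 1.0), size) - 1.0
        if self.family == "geometric_shifted":
            return rng.geometric(1.0 / m, size).astype(float)
        if self.family == "fixed":
            return m if size is None else np.full(size, m)
        return rng.exponential(m, size)


@dataclass(frozen=True)
class GeneSpec:
    """Rates and activation threshold of one gene in the cascade.

    Exactly one of ``threshold`` (absolute concentration ``X``) or
    ``relative_threshold`` (``alpha = X / x_bar``, dimensionless) is given;
    the other is derived once the shared dilution rate is known.
    """

    burst_rate: float  # bursts per minute, k > 0
    burst: BurstModel
    threshold: float | None = None
    relative_threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.burst_rate > 0:
            raise InvalidParameterError(
                f"burst_rate must be > 0, got {self.burst_rate}"
            )
        given = (self.threshold is not None) + (self.relative_threshold is not None)
        if given != 1:
            raise InvalidParameterError(
                "exactly one of threshold / relative_threshold must be given"
            )
        if self.threshold is not None and not self.threshold > 0:
            raise InvalidParameterError(f"threshold must be > 0, got {self.threshold}")
        if self.relative_threshold is not None:
            a = self.relative_threshold
            if not a > 0:
                raise InvalidParameterError(
                    f"relative_threshold must be > 0, got {a}"
                )
            if a >= 1:
                warnings.warn(
                    f"relative_threshold {a} >= 1: threshold above steady state; "
                    "crossings will be rare and the small-noise theory invalid",
                    FeasibilityWarning,
                    stacklevel=2,
                )

    @classmethod
    def from_steady_state(
        cls,
        steady_state: float,
        burst: BurstModel,
        gamma: float,
        threshold: float | None = None,
        relative_threshold: float | None = None,
    ) -> "GeneSpec":
        """Declare a gene by its steady state ``x_bar`` instead of ``k``.

        The burst rate is back-derived as ``k = gamma * x_bar / <b>``,
        matching the common way published parameter sets are reported.
        """
        if not gamma > 0:
            raise InvalidParameterError(f"gamma must be > 0, got {gamma}")
        if not steady_state > 0:
            raise InvalidParameterError(
                f"steady_state must be > 0, got {steady_state}"
            )
        k = gamma * steady_state / burst.mean
        return cls(
            burst_rate=k,
            burst=burst,
            threshold=threshold,
            relative_threshold=relative_threshold,
        )


@dataclass(frozen=True)
class CascadeSpec:
    """An ordered activation cascade of N >= 1 genes sharing one dilution rate."""

    genes: tuple[GeneSpec, ...] = field(default_factory=tuple)
    dilution_rate: float = 0.05  # per minute

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) < 1:
            raise InvalidParameterError("cascade needs at least one gene")
        if not self.dilution_rate > 0:
            raise InvalidParameterError(
                f"dilution_rate must be > 0, got {self.dilution_rate}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def alphas(self) -> np.ndarray:
        """Relative thresholds of all genes."""
        return np.array(
            [relative_threshold(g, self.dilution_rate) for g in self.genes]
        )

    def intrinsic_noises(self) -> np.ndarray:
        """Stationary protein-level noise CV_i^2 of all genes."""
        return np.array([intrinsic_noise(g, self.dilution_rate) for g in self.genes])


def steady_state_level(gene: GeneSpec, gamma: float) -> float:
    """Stationary mean concentration ``x_bar = k <b> / gamma``.

    This is the level the always-active gene relaxes to; the relative
    threshold and the intrinsic noise are both expressed against it.
    """
    if not gamma > 0:
        raise InvalidParameterError(f"gamma must be > 0, got {gamma}")
    return gene.burst_rate * gene.burst.mean / gamma


def absolute_threshold(gene: GeneSpec, gamma: float) -> float:
    """Activation threshold ``X`` in concentration units."""
    if gene.threshold is not None:
        return gene.threshold
    return gene.relative_threshold * steady_state_level(gene, gamma)


def relative_threshold(gene: GeneSpec, gamma: float) -> float:
    """Threshold as a fraction of steady state, ``alpha = X / x_bar``.

    Emits :class:`FeasibilityWarning` when alpha falls outside (0, 1):
    the small-noise approximations require 0 < alpha < 1.
    """
    if gene.relative_threshold is not None:
        return gene.relative_threshold
    alpha = gene.threshold / steady_state_level(gene, gamma)
    if not 0 < alpha < 1:
        warnings.warn(
            f"relative threshold {alpha:.4g} outside (0, 1)",
            FeasibilityWarning,
            stacklevel=2,
        )
    return alpha


def intrinsic_noise(gene: GeneSpec, gamma: float) -> float:
    """Stationary squared coefficient of variation of the protein level.

    ``CV^2 = <b^2> / (2 <b> x_bar)`` — for fixed steady state this depends
    only on the burst-size statistics, not separately on ``k`` or ``gamma``.
    """
    xbar = steady_state_level(gene, gamma)
    return gene.burst.second_moment / (2.0 * gene.burst.mean * xbar)
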