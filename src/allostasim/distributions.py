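"""Validated sampling-distribution specifications.

These are thin, frozen wrappers around :class:`numpy.random.Generator`
draws.  They exist so that configuration files and function signatures can
talk about *which* distribution governs a trait (e.g. the gamma law for a
person's average nightly impulse count) without passing bare tuples around,
and so that invariants (positive shape/scale, ordered bounds, non-negative
spread) are checked once, at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GammaSpec", "UniformSpec", "NormalSpec"]


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution with shape ``k`` and scale ``theta``.

    The mean is ``k * theta``; support is the positive reals, which makes it
    the natural choice for strictly positive rate parameters such as average
    daily impulse counts.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError(f"gamma shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise ValueError(f"gamma scale must be > 0, got {self.scale}")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.gamma(self.shape, self.scale, size)


@dataclass(frozen=True)
class UniformSpec:
    """Continuous uniform distribution on ``[lower, upper]``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"uniform bounds must satisfy lower <= upper, got "
                f"[{self.lower}, {self.upper}]"
            )

    @property
    def mean(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def variance(self) -> float:
        return (self.upper - self.lower) ** 2 / 12.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.uniform(self.lower, self.upper, size)


@dataclass(frozen=True)
class NormalSpec:
    """Normal distribution with mean ``mean`` and standard deviation ``sd``."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"normal sd must be >= 0, got {self.sd}")

    @property
    def variance(self) -> float:
        return self.sd**2

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.normal(self.mean, self.sd, size)
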