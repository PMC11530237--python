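"""Core model rules: trait space, hazards, mutation kernel and the Lansing rule.

The model describes an asexual, haploid, age-structured population in which
every individual carries a heritable life-history trait ``(x_b, x_d)``:

* ``x_b`` — the age at which the fertility span ``[0, x_b)`` ends; while
  fertile, an individual gives birth at constant intensity ``i_b``.
* ``x_d`` — the age at which the intrinsic mortality hazard switches on;
  past ``x_d`` the individual dies at constant intensity ``i_d``.

Selection acts only through a logistic competition term ``c`` added to every
individual's death rate in proportion to the number of other living
individuals, which imposes a carrying capacity without giving any trait an
explicit adaptive value.  At each birth, each gene independently mutates with
probability ``p`` by a Gaussian increment of standard deviation ``sigma``.
Optionally, a lineage carries the Lansing effect: a parent that reproduces
past its own ``x_d`` (possible only when ``x_d < x_b``) transmits a reduced
``x_d`` to that offspring — at full magnitude the offspring's ``x_d`` is
exactly 0.

Everything in this module is a pure function; the stochastic engine, the
fitness solvers and the experiment drivers all consume these rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "Trait",
    "Intensities",
    "MutationKernel",
    "LansingRule",
    "ModelParams",
    "birth_rate",
    "death_rate",
    "mutate",
    "apply_lansing",
]


class Trait(NamedTuple):
    """Heritable life-history trait: end of fertility and onset of mortality.

    Both components are plain (finite) reals; negative values are legal —
    a non-positive ``x_b`` means the individual is sterile, a negative
    ``x_d`` means the intrinsic hazard is active from birth.
    """

    x_b: float
    x_d: float


@dataclass(frozen=True)
class Intensities:
    """Event intensities: birth rate while fertile, death hazard past ``x_d``."""

    i_b: float
    i_d: float

    def __post_init__(self) -> None:
        if not (self.i_b >= 0 and self.i_d >= 0):
            raise ValueError("intensities must be nonnegative")
        if not (math.isfinite(self.i_b) and math.isfinite(self.i_d)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class MutationKernel:
    """Per-gene mutation probability ``p`` and Gaussian step width ``sigma``."""

    p: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"mutation probability p={self.p} outside [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class LansingRule:
    """Transgenerational effect: late reproduction shrinks offspring ``x_d``.

    ``magnitude`` interpolates linearly between no effect (0) and the full
    effect (1, offspring ``x_d`` set exactly to 0).
    """

    enabled: bool = False
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("Lansing magnitude must lie in [0, 1]")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the population process."""

    intensities: Intensities
    c: float = 0.0
    kernel: MutationKernel = field(default_factory=lambda: MutationKernel(0.0, 0.0))
    lansing: LansingRule = field(default_factory=LansingRule)

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("competition coefficient c must be nonnegative")


def birth_rate(a: float, trait: Trait, i_b: float) -> float:
    """Birth intensity of an individual of age ``a``.

    The fertility window is the half-open interval ``[0, x_b)``; a
    non-positive ``x_b`` is sterile.
    """
    if a < 0:
        raise ValueError("age must be nonnegative")
    return i_b if a < trait.x_b else 0.0


def death_rate(a: float, trait: Trait, i_d: float, c: float, n_alive: int) -> float:
    """Total death intensity: intrinsic step hazard plus logistic competition.

    The intrinsic hazard is ``i_d`` once age reaches ``max(x_d, 0)`` (a
    negative onset means the hazard runs from birth).  Competition adds
    ``c * (n_alive - 1)``, counting every other living individual across
    all lineages — the whole population shares one carrying capacity.
    """
    if a < 0:
        raise ValueError("age must be nonnegative")
    if n_alive < 1:
        raise ValueError("the focal individual must be alive (n_alive >= 1)")
    intrinsic = i_d if a >= max(trait.x_d, 0.0) else 0.0
    return intrinsic + c * (n_alive - 1)


def mutate(parent_trait: Trait, kernel: MutationKernel, rng) -> Trait:
    """Offspring trait before any transgenerational adjustment.

    Each gene independently receives, with probability ``kernel.p``, an
    additive Gaussian increment of mean 0 and s.d. ``kernel.sigma``; the
    trait space is unbounded so no clamping is applied.  ``rng`` is a
    :class:`random.Random` (or any object with ``random`` and ``gauss``).
    """
    x_b, x_d = parent_trait
    p, sigma = kernel.p, kernel.sigma
    if rng.random() < p:
        x_b += rng.gauss(0.0, sigma)
    if rng.random() < p:
        x_d += rng.gauss(0.0, sigma)
    return Trait(x_b, x_d)


def apply_lansing(
    child_trait: Trait, parent_trait: Trait, parent_age: float, rule: LansingRule
) -> Trait:
    """Apply the Lansing rule to a freshly mutated offspring trait.

    The rule fires only when the parent is physiologically old at the birth
    event: its own ``x_d`` lies strictly below its ``x_b`` (otherwise it can
    never reproduce past ``x_d``) and its age exceeds ``x_d``.  The
    offspring's post-mutation ``x_d`` is then scaled by ``1 - magnitude``,
    which at full magnitude pins it to exactly 0.
    """
    if parent_age < 0:
        raise ValueError("parent age must be nonnegative")
    if (
        rule.enabled
        and parent_trait.x_d < parent_trait.x_b
        and parent_age > parent_trait.x_d
    ):
        return Trait(child_trait.x_b, (1.0 - rule.magnitude) * child_trait.x_d)
    return child_trait
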