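"""Malthusian fitness: Euler-Lotka renewal equation, gradients, landscapes.

For a fixed trait ``(x_b, x_d)`` the population of one genotype grows
exponentially at the Malthusian parameter ``lambda``, the unique real root of
the Euler-Lotka renewal equation

    i_b * \\int_0^{x_b} S(a) e^{-lambda a} da = 1,

where the survivorship ``S`` is 1 before the (clamped) mortality onset
``max(x_d, 0)`` and decays at rate ``i_d`` afterwards.  The integral has a
closed piecewise-exponential form, so the residual and its lambda-derivative
are evaluated analytically and the root is found by a safeguarded Newton
iteration (bracketed; bisection fallback).

A lineage carrying the Lansing effect with ``x_d < x_b`` is a two-type
system: "normal" individuals beget normal offspring only while younger than
``x_d`` (later births are pinned to ``x_d = 0``), and ``x_d = 0`` individuals
beget only ``x_d = 0`` offspring.  The ``x_d = 0`` subtree is autonomous, so
the lineage's long-run growth rate is the larger of the two branch roots:
the normal->normal renewal root (fertile window truncated at ``x_d``, no
intrinsic hazard inside it) and the ordinary root of the trait
``(x_b, 0)``.  Above the diagonal (``x_d >= x_b``) the rule never fires and
both lineages have identical fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import Intensities, Trait

__all__ = [
    "FitnessResult",
    "LandscapeGrid",
    "renewal_residual",
    "malthusian",
    "fitness_gradient",
    "landscape",
    "viability_threshold",
]

#: absolute residual tolerance of the renewal-equation solver
SOLVER_TOL = 1e-12
MAX_ITER = 100


@dataclass(frozen=True)
class FitnessResult:
    """Root of the renewal equation plus solver diagnostics.

    ``branch`` records which growth branch the returned root belongs to:
    ``"normal"`` (ordinary single-type renewal root, including the truncated
    normal->normal Lansing branch), ``"lansing_subtree"`` (the autonomous
    ``x_d = 0`` subtree dominates) or ``"overlapping"`` (``x_d >= x_b``, the
    Lansing rule is inert and the root coincides with the non-Lansing one).
    """

    lambda_: float
    residual: float
    branch: str
    iterations: int


@dataclass(frozen=True)
class LandscapeGrid:
    """Fitness over a trait grid for both lineages.

    ``lambda_non_lansing[i, j]`` and ``lambda_lansing[i, j]`` hold the
    Malthusian parameter at ``x_d = x_d_axis[i]``, ``x_b = x_b_axis[j]``.
    """

    x_b_axis: np.ndarray
    x_d_axis: np.ndarray
    lambda_non_lansing: np.ndarray
    lambda_lansing: np.ndarray


def _phi(z: float) -> float:
    """(1 - exp(-z)) / z, the finite-window Laplace kernel; phi(0) = 1."""
    if abs(z) < 1e-5:
        return 1.0 - z / 2.0 + z * z / 6.0 - z * z * z / 24.0
    return -math.expm1(-z) / z


def _dphi(z: float) -> float:
    """Derivative of :func:`_phi`; the z -> 0 limit is -1/2."""
    if abs(z) < 1e-4:
        return -0.5 + z / 3.0 - z * z / 8.0 + z * z * z / 30.0
    return (math.exp(-z) * (z + 1.0) - 1.0) / (z * z)


def _residual_parts(lam: float, w: float, m: float, i_b: float, i_d: float):
    """Residual F(lam) and dF/dlam for a window [0, w) with hazard onset m.

    The survivorship is 1 on [0, m) and exp(-i_d (a - m)) on [m, w); the
    closed-form integral is
        m phi(lam m) + exp(-lam m) g phi((lam + i_d) g),   g = w - m.
    """
    g = w - m
    em = math.exp(-lam * m)
    z1 = lam * m
    z2 = (lam + i_d) * g
    integral = m * _phi(z1) + em * g * _phi(z2)
    d_integral = (
        m * m * _dphi(z1)
        - m * em * g * _phi(z2)
        + em * g * g * _dphi(z2)
    )
    return i_b * integral - 1.0, i_b * d_integral


def _window(trait: Trait) -> tuple[float, float]:
    """Fertility window end and clamped hazard onset for the one-type case."""
    w = trait.x_b
    m = min(max(trait.x_d, 0.0), w)
    return w, m


def renewal_residual(lam: float, trait: Trait, ints: Intensities) -> float:
    """Euler-Lotka residual ``i_b * integral - 1`` at growth rate ``lam``.

    At ``lam = 0`` this is the net reproduction number minus one.  A
    non-positive ``x_b`` (no reproduction) returns -1 identically.
    """
    if ints.i_d <= 0:
        raise ValueError("renewal equation requires i_d > 0")
    if trait.x_b <= 0:
        return -1.0
    w, m = _window(trait)
    value, _ = _residual_parts(lam, w, m, ints.i_b, ints.i_d)
    return value


def _solve_renewal(w: float, m: float, i_b: float, i_d: float) -> tuple[float, float, int]:
    """Root of the renewal equation on window [0, w), hazard onset m.

    F is strictly decreasing in lambda with F(-inf) = +inf and
    F(+inf) = -1, so the real root is unique.  Newton from
    lambda0 = max(0, i_b (1 - 1/R0)) with a maintained bracket; any step
    leaving the bracket falls back to bisection.
    """
    if w <= 0 or i_b <= 0:
        return -math.inf, math.nan, 0

    r0 = _residual_parts(0.0, w, m, i_b, i_d)[0] + 1.0  # net reproduction number
    lam = max(0.0, i_b * (1.0 - 1.0 / max(r0, 1.0 + 1e-12)))

    # bracket: F(i_b) < 0 always (integral < 1/i_b); walk lo down until F > 0
    hi = i_b if i_b > 0 else 1.0
    lo = min(lam, 0.0)
    flo = _residual_parts(lo, w, m, i_b, i_d)[0]
    step = 1.0
    while flo < 0.0:
        hi = lo
        lo -= step
        step *= 2.0
        flo = _residual_parts(lo, w, m, i_b, i_d)[0]
        if not math.isfinite(flo):  # pragma: no cover - defensive
            raise ArithmeticError("renewal residual overflowed while bracketing")

    lam = min(max(lam, lo), hi)
    f, fp = _residual_parts(lam, w, m, i_b, i_d)
    for it in range(1, MAX_ITER + 1):
        if abs(f) < SOLVER_TOL:
            return lam, f, it
        if f > 0:
            lo = lam
        else:
            hi = lam
        if fp < 0:
            nxt = lam - f / fp
        else:  # non-monotone numerical corner: bisect
            nxt = 0.5 * (lo + hi)
        if not (lo < nxt < hi):
            nxt = 0.5 * (lo + hi)
        lam = nxt
        f, fp = _residual_parts(lam, w, m, i_b, i_d)
    raise ArithmeticError(
        f"renewal solver did not converge in {MAX_ITER} iterations; last residual {f:.3e}"
    )


def malthusian(trait: Trait, ints: Intensities, lineage: str = "non_lansing") -> FitnessResult:
    """Malthusian parameter of a genotype, for either lineage type.

    Non-viable traits return a negative root; a sterile trait
    (``x_b <= 0``, or a Lansing lineage with no reproducing branch) returns
    ``lambda = -inf``.
    """
    if ints.i_d <= 0:
        raise ValueError("malthusian requires i_d > 0")
    if lineage not in ("lansing", "non_lansing"):
        raise ValueError(f"unknown lineage {lineage!r}")

    if lineage == "non_lansing" or trait.x_d >= trait.x_b:
        branch = "normal" if lineage == "non_lansing" else "overlapping"
        if trait.x_b <= 0:
            return FitnessResult(-math.inf, math.nan, branch, 0)
        w, m = _window(trait)
        lam, res, it = _solve_renewal(w, m, ints.i_b, ints.i_d)
        return FitnessResult(lam, res, branch, it)

    # Lansing lineage below the diagonal: two-type system.
    if trait.x_b <= 0:
        return FitnessResult(-math.inf, math.nan, "normal", 0)
    # normal -> normal: births only before x_d, no intrinsic hazard inside.
    w_n = min(trait.x_d, trait.x_b)
    lam_n, res_n, it_n = (
        _solve_renewal(w_n, w_n, ints.i_b, ints.i_d) if w_n > 0 else (-math.inf, math.nan, 0)
    )
    # x_d = 0 subtree: ordinary root of the trait (x_b, 0).
    lam_l, res_l, it_l = _solve_renewal(trait.x_b, 0.0, ints.i_b, ints.i_d)
    if lam_n >= lam_l:
        return FitnessResult(lam_n, res_n, "normal", it_n)
    return FitnessResult(lam_l, res_l, "lansing_subtree", it_l)


def fitness_gradient(
    trait: Trait, ints: Intensities, lineage: str = "non_lansing"
) -> tuple[float, float]:
    """Selection gradient ``(d lambda / d x_b, d lambda / d x_d)``.

    Obtained by implicit differentiation of the renewal equation on the
    active branch; both components are nonnegative (enlarging the fertility
    span or delaying the mortality onset never decreases fitness).  Raises
    for traits whose growth rate is not solvable (``x_b <= 0``).
    """
    res = malthusian(trait, ints, lineage)
    lam = res.lambda_
    if not math.isfinite(lam):
        raise ValueError("fitness gradient undefined for a sterile trait")
    i_b, i_d = ints.i_b, ints.i_d

    if res.branch in ("normal", "overlapping") and not (
        lineage == "lansing" and trait.x_d < trait.x_b
    ):
        w, m = _window(trait)
        _, dflam = _residual_parts(lam, w, m, i_b, i_d)
        g = w - m
        df_dxb = i_b * math.exp(-i_d * g) * math.exp(-lam * w)
        if 0.0 < trait.x_d < trait.x_b:
            # d/dx_d of the integral = i_d * (post-onset part of the integral)
            df_dxd = i_b * i_d * math.exp(-lam * m) * g * _phi((lam + i_d) * g)
        else:
            df_dxd = 0.0
        return (-df_dxb / dflam, -df_dxd / dflam)

    if res.branch == "normal":  # truncated normal->normal branch, x_d < x_b
        w = min(trait.x_d, trait.x_b)
        _, dflam = _residual_parts(lam, w, w, i_b, i_d)
        df_dxd = i_b * math.exp(-lam * w)  # window end is x_d itself
        return (0.0, -df_dxd / dflam)

    # lansing_subtree: root of (x_b, 0); independent of the parent's x_d.
    _, dflam = _residual_parts(lam, trait.x_b, 0.0, i_b, i_d)
    df_dxb = i_b * math.exp(-(lam + i_d) * trait.x_b)
    return (-df_dxb / dflam, 0.0)


def landscape(
    x_b_axis, x_d_axis, ints: Intensities
) -> LandscapeGrid:
    """Malthusian parameter of both lineages over a rectangular trait grid."""
    xb = np.asarray(x_b_axis, dtype=float)
    xd = np.asarray(x_d_axis, dtype=float)
    if xb.size == 0 or xd.size == 0:
        raise ValueError("landscape axes must be nonempty")
    lam_n = np.empty((xd.size, xb.size))
    lam_l = np.empty_like(lam_n)
    for i, d in enumerate(xd):
        for j, b in enumerate(xb):
            t = Trait(float(b), float(d))
            lam_n[i, j] = malthusian(t, ints, "non_lansing").lambda_
            lam_l[i, j] = malthusian(t, ints, "lansing").lambda_
    return LandscapeGrid(xb, xd, lam_n, lam_l)


def viability_threshold(ints: Intensities) -> float:
    """Minimal fertility span compatible with positive growth: ``1 / i_b``.

    The net reproduction number is bounded by ``i_b * x_b``, so any trait
    with ``x_b <= 1 / i_b`` has ``lambda <= 0`` regardless of ``x_d``.
    """
    if ints.i_b <= 0:
        raise ValueError("no viable trait exists when i_b = 0")
    return 1.0 / ints.i_b
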