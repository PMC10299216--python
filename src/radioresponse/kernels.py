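"""Closed-form radiobiological factors.

Pure, stateless functions evaluating the per-step multiplicative factors
of the voxel model: oxygen enhancement ratio, linear-quadratic survival
for tumour and normal cells, the Gompertz proliferation factor,
angiogenesis, dead-cell resorption and tumour repopulation. All accept
NumPy arrays where a scalar argument is documented.
"""

from __future__ import annotations

import math

import numpy as np

from .params import RadiobiologyParams

__all__ = [
    "oer",
    "survival_fraction_tumour",
    "survival_fraction_normal",
    "proliferation_factor",
    "angiogenesis_factor",
    "resorption_fraction",
    "repopulation_factor",
]

LN2 = math.log(2.0)


def _check_nonnegative(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be >= 0")


def oer(pO2, m: float = 3.0, k: float = 3.0):
    """Oxygen enhancement ratio (m*pO2 + k) / (pO2 + k).

    Rises from 1 under anoxia to the plateau ``m`` at high pO2; ``k`` is
    the pO2 at which half of the rise is reached, i.e. OER(k) = (m+1)/2.
    """
    _check_nonnegative("pO2", pO2)
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    pO2 = np.asarray(pO2, dtype=float)
    out = (m * pO2 + k) / (pO2 + k)
    return out if out.ndim else float(out)


def _effective_dose(d, pO2, params: RadiobiologyParams):
    ratio = oer(pO2, params.m, params.k)
    if params.oer_convention == "printed":
        return params.m * np.asarray(d, dtype=float) * ratio
    return np.asarray(d, dtype=float) * ratio / params.m


def survival_fraction_tumour(
    d, pO2, params: RadiobiologyParams, phase_weight: float = 1.0
):
    """Tumour-cell surviving fraction after a dose ``d`` at oxygenation ``pO2``.

    The LQ exponent is evaluated at an oxygen-scaled effective dose; more
    oxygen means a larger effective dose (oxygen sensitizes), so hypoxic
    cells always survive at least as well as oxic ones. ``phase_weight``
    multiplies the linear coefficient (and, if ``params.weight_beta``,
    the quadratic one by its square) to express cell-cycle-phase
    dependent sensitivity.
    """
    _check_nonnegative("d", d)
    _check_nonnegative("pO2", pO2)
    deff = _effective_dose(d, pO2, params)
    alpha = params.alpha_t * phase_weight
    beta = params.beta_t * (phase_weight**2 if params.weight_beta else 1.0)
    out = np.exp(-(alpha * deff + beta * deff**2))
    return out if out.ndim else float(out)


def survival_fraction_normal(d, params: RadiobiologyParams):
    """Normal-tissue surviving fraction exp(-alpha_n d (1 + d beta_n/alpha_n)).

    Algebraically identical to the plain LQ exp(-alpha_n d - beta_n d^2);
    evaluated in the expanded form, which stays defined for alpha_n -> 0.
    No oxygen dependence.
    """
    _check_nonnegative("d", d)
    d = np.asarray(d, dtype=float)
    out = np.exp(-(params.alpha_n * d + params.beta_n * d**2))
    return out if out.ndim else float(out)


def proliferation_factor(pO2, params: RadiobiologyParams):
    """Oxygen-gated division probability, Gompertz in pO2.

    PF = C exp(-exp(-B (pO2 - M))): sigmoid rising to the asymptote ``C``
    with inflection at pO2 = M, where PF(M) = C/e.
    """
    _check_nonnegative("pO2", pO2)
    pO2 = np.asarray(pO2, dtype=float)
    out = params.C * np.exp(-np.exp(-params.B * (pO2 - params.M)))
    return out if out.ndim else float(out)


def angiogenesis_factor(ta: float, dt: float) -> float:
    """Capillary growth multiplier exp(ln2 dt / ta) over a step of ``dt`` h."""
    if ta <= 0:
        raise ValueError(f"ta must be > 0, got {ta}")
    _check_nonnegative("dt", dt)
    return math.exp(LN2 * dt / ta)


def resorption_fraction(tr: float, dt: float) -> float:
    """Fraction of dead cells resorbed during ``dt`` h: 1 - exp(-ln2 dt/tr)."""
    if tr <= 0:
        raise ValueError(f"tr must be > 0, got {tr}")
    _check_nonnegative("dt", dt)
    return 1.0 - math.exp(-LN2 * dt / tr)


def repopulation_factor(
    t_since_treatment_start: float, dt: float, params: RadiobiologyParams
) -> float:
    """Tumour repopulation multiplier over one step.

    The doubling time switches from ``Tp_early`` to the accelerated
    ``Tp_late`` once ``t_since_treatment_start`` reaches
    ``Tp_switch_time`` (two weeks by default). Times before treatment
    start (negative) use the early doubling time.
    """
    _check_nonnegative("dt", dt)
    tp = (
        params.Tp_early
        if t_since_treatment_start < params.Tp_switch_time
        else params.Tp_late
    )
    if math.isinf(tp):
        return 1.0
    return math.exp(LN2 * dt / tp)
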