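"""Hourly compartmental cell-cycle engine.

The 24-h cycle is divided into 1-h compartments: 14 for G1, 6 for S, 3
for G2 and 1 for M, plus a quiescent G0 pool. Two checkpoints gate
progression: G1->S (oxygen-gated through the proliferation factor;
failures enter G0 and re-attempt hourly) and G2->M (a constant pass
probability outside the post-irradiation arrest window; failures remain
arrested in the last G2 compartment and retry, which is what produces
the post-irradiation G2 accumulation). Cells completing M divide into
two cells entering the first G1 compartment.

Two execution modes are supported throughout: ``expectation`` propagates
means (fully deterministic, the default for regression work) and
``stochastic`` draws integer counts through :func:`checkpoint_draw`.

The low-level ``_advance_arrays``/``_survival_arrays`` routines operate
on ``(V, 24)`` slot matrices so the voxel-grid engine can step every
voxel at once; :class:`PhaseState` is the single-population view used by
the public per-voxel operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

from . import kernels
from .params import RadiobiologyParams

__all__ = [
    "N_G1",
    "N_S",
    "N_G2",
    "N_M",
    "N_SLOTS",
    "PhaseState",
    "CheckpointPolicy",
    "checkpoint_draw",
    "advance_one_hour",
    "irradiate_phases",
    "apply_phase_survival",
    "phase_percentages",
    "phase_survival_fractions",
]

N_G1, N_S, N_G2, N_M = 14, 6, 3, 1
N_SLOTS = N_G1 + N_S + N_G2 + N_M  # 24 = cycle time in hours

_G1 = slice(0, N_G1)
_S = slice(N_G1, N_G1 + N_S)
_G2 = slice(N_G1 + N_S, N_G1 + N_S + N_G2)
_M_IDX = N_SLOTS - 1

#: cycling phase label per slot index
SLOT_PHASE = np.array(["G1"] * N_G1 + ["S"] * N_S + ["G2"] * N_G2 + ["M"] * N_M)

#: index into a (G0, G1, S, G2, M) vector for each slot
SLOT_PHASE_INDEX = np.array(
    [1] * N_G1 + [2] * N_S + [3] * N_G2 + [4] * N_M, dtype=np.intp
)

_NORMAL_APPROX_THRESHOLD = 30


def checkpoint_draw(n, p, rng: np.random.Generator):
    """Number of cells passing a Bernoulli(p) checkpoint out of ``n``.

    Exact binomial for small populations; for n >= 30 the binomial is
    approximated by a rounded, clipped Normal(np, np(1-p)). Vectorised
    over arrays; reproducible for a fixed generator state.
    """
    n_arr = np.asarray(n)
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p must lie in [0, 1]")
    if np.any(n_arr < 0):
        raise ValueError("n must be >= 0")
    n_int = np.asarray(n_arr, dtype=np.int64)
    p_b = np.broadcast_to(p_arr, n_int.shape)
    small = n_int < _NORMAL_APPROX_THRESHOLD
    exact = rng.binomial(np.where(small, n_int, 0), p_b)
    mean = n_int * p_b
    sd = np.sqrt(np.maximum(mean * (1.0 - p_b), 0.0))
    approx = np.rint(rng.normal(mean, sd)).astype(np.int64)
    approx = np.clip(approx, 0, n_int)
    out = np.where(small, exact, approx)
    return out if out.ndim else int(out)


@dataclass
class CheckpointPolicy:
    """Checkpoint pass rules.

    ``g1s_probability`` may be a constant, a callable of pO2, or None, in
    which case the oxygen-gated proliferation factor is used (division is
    gated by the current oxygenation). ``g2m_probability`` is the hourly
    pass probability at G2->M outside arrest; during the post-irradiation
    arrest window it is forced to zero.
    """

    g1s_probability: float | Callable[[float], float] | None = None
    g2m_probability: float | None = None
    arrest_duration: float | None = None

    def g1s(self, pO2: float, params: RadiobiologyParams) -> float:
        rule = self.g1s_probability
        if rule is None:
            return float(kernels.proliferation_factor(pO2, params))
        if callable(rule):
            return float(rule(pO2))
        return float(rule)

    def g2m(self, params: RadiobiologyParams) -> float:
        if self.g2m_probability is None:
            return params.g2m_pass_probability
        return float(self.g2m_probability)

    def arrest(self, params: RadiobiologyParams) -> float:
        if self.arrest_duration is None:
            return params.arrest_duration
        return float(self.arrest_duration)

    @classmethod
    def for_histogram(cls, hist, params: RadiobiologyParams) -> "CheckpointPolicy":
        """Policy whose G1->S rule is the histogram-expected proliferation
        factor — the per-voxel route, where a population experiences a
        distribution of oxygen tensions rather than a single pO2."""
        p1 = hist.expect(lambda p: kernels.proliferation_factor(p, params))
        return cls(g1s_probability=float(p1))


@dataclass
class PhaseState:
    """Cell counts in the 24 hourly cycle compartments plus quiescent G0."""

    slots: np.ndarray = field(default_factory=lambda: np.zeros(N_SLOTS))
    g0: float = 0.0
    arrest_remaining: float = 0.0

    def __post_init__(self):
        self.slots = np.asarray(self.slots, dtype=float).copy()
        if self.slots.shape != (N_SLOTS,):
            raise ValueError(f"slots must have shape ({N_SLOTS},)")
        if np.any(self.slots < 0) or self.g0 < 0:
            raise ValueError("cell counts must be nonnegative")

    # -- constructors -------------------------------------------------
    @classmethod
    def cycling_uniform(cls, total: float) -> "PhaseState":
        """All cells cycling, spread uniformly over the 24 compartments."""
        return cls(np.full(N_SLOTS, total / N_SLOTS))

    @classmethod
    def from_phase_percentages(
        cls, percentages: Mapping[str, float], total: float = 1.0e6
    ) -> "PhaseState":
        """Build a state from G1/S/G2/M (and optional G0) percentages.

        Each phase's share is spread uniformly over its compartments.
        """
        pct = dict(percentages)
        g0_pct = pct.pop("G0", 0.0)
        slots = np.zeros(N_SLOTS)
        spans = {"G1": _G1, "S": _S, "G2": _G2}
        for phase, span in spans.items():
            share = pct.pop(phase, 0.0) / 100.0 * total
            n = span.stop - span.start
            slots[span] = share / n
        slots[_M_IDX] = pct.pop("M", 0.0) / 100.0 * total
        if pct:
            raise ValueError(f"unknown phase(s): {sorted(pct)}")
        return cls(slots, g0=g0_pct / 100.0 * total)

    # -- views ---------------------------------------------------------
    @property
    def total(self) -> float:
        return float(self.slots.sum() + self.g0)

    def phase_counts(self) -> dict[str, float]:
        return {
            "G0": float(self.g0),
            "G1": float(self.slots[_G1].sum()),
            "S": float(self.slots[_S].sum()),
            "G2": float(self.slots[_G2].sum()),
            "M": float(self.slots[_M_IDX]),
        }

    def copy(self) -> "PhaseState":
        return PhaseState(self.slots.copy(), self.g0, self.arrest_remaining)


# ---------------------------------------------------------------------
# vectorised core shared with the voxel grid
# ---------------------------------------------------------------------

def _draw(n, p, rng: Optional[np.random.Generator]):
    """Expected or sampled number of successes, depending on mode."""
    if rng is None:
        return np.asarray(n, dtype=float) * p
    return checkpoint_draw(n, p, rng)


def _advance_arrays(P, g0, p1, p2, rng=None):
    """Advance every row of ``P`` (V, 24) by one hour.

    Returns (newP, new_g0, born) where ``born`` counts the extra cells
    created by mitosis (one per divider); the caller may cancel part of
    the births (capacity limits) by subtracting from slot 0.
    """
    P = np.asarray(P)
    out_m = P[:, _M_IDX]
    g1_out = P[:, N_G1 - 1]
    s_out = P[:, N_G1 + N_S - 1]
    g2_out = P[:, N_SLOTS - 2]  # last G2 compartment (arrest queue)

    g1_pass = _draw(g1_out, p1, rng)
    g0_pass = _draw(g0, p1, rng)
    m_in = _draw(g2_out, p2, rng)

    new = np.empty_like(P)
    new[:, 0] = 2 * out_m
    new[:, 1:N_G1] = P[:, 0 : N_G1 - 1]
    new[:, N_G1] = g1_pass + g0_pass
    new[:, N_G1 + 1 : N_G1 + N_S] = P[:, N_G1 : N_G1 + N_S - 1]
    new[:, N_G1 + N_S] = s_out
    new[:, N_G1 + N_S + 1] = P[:, N_G1 + N_S]
    # failed G2->M cells stay arrested in the last G2 compartment
    new[:, N_SLOTS - 2] = P[:, N_SLOTS - 3] + (g2_out - m_in)
    new[:, _M_IDX] = m_in
    new_g0 = g0 - g0_pass + (g1_out - g1_pass)
    return new, new_g0, out_m.copy()


def phase_survival_fractions(
    d: float,
    params: RadiobiologyParams,
    pO2: float | None = None,
    hist=None,
) -> np.ndarray:
    """Surviving fraction per phase (G0, G1, S, G2, M) for a dose ``d``.

    Evaluated either at a single pO2 or integrated over an oxygen
    histogram (the per-voxel route).
    """
    out = np.empty(5)
    for i, phase in enumerate(("G0", "G1", "S", "G2", "M")):
        w = params.phase_weights[phase]
        if hist is not None:
            out[i] = hist.expect(
                lambda p, w=w: kernels.survival_fraction_tumour(d, p, params, w)
            )
        else:
            out[i] = kernels.survival_fraction_tumour(d, pO2, params, w)
    return out


def _survival_arrays(P, g0, sf_by_phase, rng=None):
    """Apply per-phase survival to (V, 24) slots and g0.

    ``sf_by_phase`` has shape (V, 5) ordered (G0, G1, S, G2, M).
    Returns (newP, new_g0, killed_per_row).
    """
    sf_slots = sf_by_phase[:, SLOT_PHASE_INDEX]
    newP = _draw(P, sf_slots, rng)
    new_g0 = _draw(g0, sf_by_phase[:, 0], rng)
    killed = (np.asarray(P) - newP).sum(axis=1) + (np.asarray(g0) - new_g0)
    return newP, new_g0, killed


# ---------------------------------------------------------------------
# public per-population operations
# ---------------------------------------------------------------------

def advance_one_hour(
    state: PhaseState,
    pO2: float,
    policy: CheckpointPolicy | None = None,
    rng: np.random.Generator | None = None,
    params: RadiobiologyParams | None = None,
) -> PhaseState:
    """One hour of cycle progression for a single population.

    In stochastic mode (``rng`` given) counts must be integers; in
    expectation mode means are propagated. Total count changes only
    through mitosis.
    """
    params = params or RadiobiologyParams()
    policy = policy or CheckpointPolicy()
    p1 = policy.g1s(pO2, params)
    p2 = 0.0 if state.arrest_remaining > 0 else policy.g2m(params)
    P = state.slots[None, :]
    g0 = np.asarray([state.g0])
    if rng is not None:
        P = np.rint(P).astype(np.int64)
        g0 = np.rint(g0).astype(np.int64)
    new, new_g0, _ = _advance_arrays(P, g0, p1, p2, rng)
    out = PhaseState(
        np.asarray(new[0], dtype=float),
        float(new_g0[0]),
        max(0.0, state.arrest_remaining - params.dt),
    )
    return out


def irradiate_phases(
    state: PhaseState,
    d: float,
    pO2: float,
    params: RadiobiologyParams | None = None,
    rng: np.random.Generator | None = None,
    policy: CheckpointPolicy | None = None,
) -> tuple[PhaseState, float]:
    """Phase-resolved irradiation of a population at a single pO2.

    Each phase survives with the LQ fraction evaluated with its weighted
    linear coefficient; the G2->M checkpoint is then blocked for the
    arrest duration, so survivors accumulate in G2 afterwards.
    """
    params = params or RadiobiologyParams()
    if d < 0:
        raise ValueError("dose must be >= 0")
    if d == 0:
        return state.copy(), 0.0
    sf = phase_survival_fractions(d, params, pO2=pO2)
    return apply_phase_survival(state, sf, params, rng, policy)


def apply_phase_survival(
    state: PhaseState,
    sf_by_phase: np.ndarray,
    params: RadiobiologyParams | None = None,
    rng: np.random.Generator | None = None,
    policy: CheckpointPolicy | None = None,
) -> tuple[PhaseState, float]:
    """Apply precomputed per-phase survival fractions (G0, G1, S, G2, M)."""
    params = params or RadiobiologyParams()
    arrest = (policy or CheckpointPolicy()).arrest(params)
    P = state.slots[None, :]
    g0 = np.asarray([state.g0])
    if rng is not None:
        P = np.rint(P).astype(np.int64)
        g0 = np.rint(g0).astype(np.int64)
    newP, new_g0, killed = _survival_arrays(
        P, g0, np.asarray(sf_by_phase, dtype=float)[None, :], rng
    )
    out = PhaseState(np.asarray(newP[0], dtype=float), float(new_g0[0]), arrest)
    return out, float(killed[0])


def phase_percentages(state: PhaseState) -> dict[str, float]:
    """Percentage of cells per phase, relative to cycling + quiescent total."""
    total = state.total
    if total <= 0:
        raise ValueError("cannot compute percentages of an empty population")
    return {k: 100.0 * v / total for k, v in state.phase_counts().items()}
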