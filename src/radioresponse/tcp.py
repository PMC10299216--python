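"""Tumour control probability curves and TCD50 estimation.

A tumour is controlled when no tumour cell survives. In Poisson mode the
control probability is exp(-E[N]) with E[N] the expected number of
surviving tumour cells at the end of treatment (expectation-mode
simulation); in empirical mode it is the fraction of stochastic
replicates ending with zero tumour cells. The dose axis is swept by
rescaling every per-fraction dose while keeping the protocol's timing
fixed — TCD50 values depend on this convention, stated here explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .schedules import Protocol, build_protocol
from .simulate import run_grid
from .voxel import GridState

__all__ = ["tcp_poisson", "TCPCurve", "simulate_tcp_curve", "estimate_tcd50"]


def tcp_poisson(expected_survivors: float) -> float:
    """Poisson control probability exp(-E[N])."""
    if expected_survivors < 0:
        raise ValueError("expected_survivors must be >= 0")
    return math.exp(-expected_survivors)


@dataclass
class TCPCurve:
    """Control probability against total dose for one protocol."""

    total_doses: np.ndarray
    tcp: np.ndarray
    protocol: str
    replicates: int = 1
    se: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.total_doses = np.asarray(self.total_doses, dtype=float)
        self.tcp = np.asarray(self.tcp, dtype=float)
        if np.any(np.diff(self.total_doses) <= 0):
            raise ValueError("total_doses must be strictly ascending")
        if np.any((self.tcp < 0) | (self.tcp > 1)):
            raise ValueError("tcp values must lie in [0, 1]")

    def isotonic(self) -> "TCPCurve":
        """Monotone (non-decreasing) cleanup via a running maximum."""
        return TCPCurve(
            self.total_doses,
            np.maximum.accumulate(self.tcp),
            self.protocol,
            self.replicates,
            self.se,
            list(self.notes),
        )


def _end_of_treatment_survivors(
    grid_template: GridState, protocol: Protocol, seed: int
) -> float:
    grid = grid_template.copy()
    if grid.mode == "stochastic":
        grid.rng = np.random.default_rng(seed)
    res = run_grid(grid, protocol, record=False)
    return res.grid.totals()["tumour"]


def _tcp_at_dose(grid_template, base_protocol, total_dose, mode, replicates, seed):
    if total_dose <= 0:
        scaled = Protocol(base_protocol.name, (), base_protocol.lead_in)
        # untreated run over the same horizon as the treated ones
        horizon = base_protocol.last_fraction_time + 24.0
        grid = grid_template.copy()
        res = run_grid(grid, scaled, horizon=horizon, record=False)
        n = res.grid.totals()["tumour"]
        if mode == "poisson":
            return tcp_poisson(n), 0.0
        return float(n == 0), 0.0
    scaled = base_protocol.scaled(total_dose / base_protocol.total_dose)
    if mode == "poisson":
        n = _end_of_treatment_survivors(grid_template, scaled, seed)
        return tcp_poisson(n), 0.0
    controlled = 0
    for r in range(replicates):
        n = _end_of_treatment_survivors(grid_template, scaled, seed + 1000003 * r)
        controlled += n == 0
    p = controlled / replicates
    return p, math.sqrt(max(p * (1 - p) / replicates, 0.0))


def simulate_tcp_curve(
    grid_template: GridState,
    protocol_name: str | Protocol,
    dose_grid: Sequence[float],
    mode: str = "poisson",
    replicates: int = 1,
    seed: int = 0,
    lead_in: float = 72.0,
    refine_step: float | None = 0.5,
) -> TCPCurve:
    """TCP against total dose for one protocol.

    Per-fraction doses are rescaled so the schedule delivers each total
    dose on the grid with unchanged timing; each point is a full
    simulation to the end of treatment. With ``refine_step`` set, extra
    doses are inserted around the TCP=0.5 crossing after the coarse
    pass. ``mode`` is "poisson" (expectation template) or "empirical"
    (stochastic template, ``replicates`` runs per dose).
    """
    doses = np.asarray(sorted(set(float(d) for d in dose_grid)))
    if len(doses) < 2:
        raise ValueError("dose_grid needs at least two doses")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if mode not in ("poisson", "empirical"):
        raise ValueError("mode must be 'poisson' or 'empirical'")
    base = (
        protocol_name
        if isinstance(protocol_name, Protocol)
        else build_protocol(protocol_name, lead_in)
    )

    def evaluate(ds):
        pts = [
            _tcp_at_dose(grid_template, base, d, mode, replicates, seed) for d in ds
        ]
        return np.array([p for p, _ in pts]), np.array([s for _, s in pts])

    tcp, se = evaluate(doses)

    if refine_step:
        iso = np.maximum.accumulate(tcp)
        cross = np.nonzero((iso[:-1] < 0.5) & (iso[1:] >= 0.5))[0]
        if len(cross):
            i = cross[0]
            extra = np.arange(doses[i], doses[i + 1], refine_step)[1:]
            if len(extra):
                tcp_x, se_x = evaluate(extra)
                doses = np.concatenate([doses, extra])
                order = np.argsort(doses)
                doses = doses[order]
                tcp = np.concatenate([tcp, tcp_x])[order]
                se = np.concatenate([se, se_x])[order]

    notes = []
    iso = np.maximum.accumulate(tcp)
    if iso[0] >= 0.5 or iso[-1] < 0.5:
        notes.append("dose grid does not bracket TCP=0.5")
    return TCPCurve(doses, tcp, base.name, replicates, se, notes)


def estimate_tcd50(curve: TCPCurve) -> float:
    """Dose at which the (isotonic) TCP curve crosses 0.5.

    Linear interpolation in logit(TCP) between the bracketing grid
    points; exact 0.5 hits are returned directly.
    """
    iso = curve.isotonic()
    doses, tcp = iso.total_doses, iso.tcp
    exact = np.nonzero(tcp == 0.5)[0]
    if len(exact):
        return float(doses[exact[0]])
    above = np.nonzero(tcp > 0.5)[0]
    below = np.nonzero(tcp < 0.5)[0]
    if not len(above) or not len(below) or below[0] > above[0]:
        raise ValueError(
            "TCP curve does not cross 0.5 within the dose grid "
            f"(range {tcp.min():.3g}..{tcp.max():.3g}); extend the grid"
        )
    hi = above[0]
    lo = hi - 1
    eps = 1e-12
    logit = lambda p: math.log(max(p, eps) / max(1 - p, eps))
    y0, y1 = logit(tcp[lo]), logit(tcp[hi])
    if y1 == y0:
        return float(0.5 * (doses[lo] + doses[hi]))
    frac = (0.0 - y0) / (y1 - y0)
    return float(doses[lo] + frac * (doses[hi] - doses[lo]))
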