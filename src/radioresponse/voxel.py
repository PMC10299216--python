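"""Per-voxel population bookkeeping at fixed cell density.

Every voxel holds four populations — phase-resolved tumour cells, normal
cells, capillary cells and dead cells — whose total equals the voxel
capacity (cell density x voxel volume) after every step. One hour of
dynamics comprises: cell-cycle progression under the voxel's
histogram-expected oxygenation (division displaces normal cells),
repopulation, angiogenesis in hypoxic voxels, resorption of dead cells
and their replacement by normal/capillary cells in fixed proportions.
Irradiation kills tumour cells phase by phase with oxygen-histogram-
integrated LQ survival, and normal/capillary cells with the normal-
tissue LQ; killed cells move to the dead compartment, so capacity is
conserved exactly.

Voxels never interact, which the :class:`GridState` engine exploits by
stepping all voxels as ``(V, ...)`` arrays and by collapsing voxels with
identical initial composition into weighted equivalence classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd

from . import kernels
from .cellcycle import (
    PhaseState,
    _advance_arrays,
    _survival_arrays,
    _G1,
    _S,
    _G2,
    _M_IDX,
    phase_survival_fractions,
)
from .oxygen import VfBinTable, default_vf_table
from .params import RadiobiologyParams

__all__ = ["VoxelState", "GridState", "replace_dead", "split_replacement"]


def split_replacement(freed, normal_share: float = 0.964, capillary_share: float = 0.036):
    """Split freed capacity between normal and capillary cells.

    Integer inputs use largest-remainder rounding so the parts always sum
    to ``freed`` exactly; float inputs split exactly. Vectorised.
    """
    if abs(normal_share + capillary_share - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    freed_arr = np.asarray(freed)
    if np.any(freed_arr < 0):
        raise ValueError("freed must be >= 0")
    if not np.issubdtype(freed_arr.dtype, np.integer):
        n = freed_arr * normal_share
        c = freed_arr * capillary_share
        return (n, c) if freed_arr.ndim else (float(n), float(c))
    n_exact = freed_arr * normal_share
    c_exact = freed_arr * capillary_share
    n = np.floor(n_exact).astype(np.int64)
    c = np.floor(c_exact).astype(np.int64)
    leftover = freed_arr - n - c
    n_frac = n_exact - n
    c_frac = c_exact - c
    to_normal = n_frac >= c_frac  # ties go to the filler population
    n = n + np.where(to_normal, leftover, 0)
    c = c + np.where(to_normal, 0, leftover)
    if freed_arr.ndim:
        return n, c
    return int(n), int(c)


def replace_dead(freed, normal_share: float = 0.964, capillary_share: float = 0.036):
    """(normal_added, capillary_added) for ``freed`` resorbed cells."""
    n, c = split_replacement(freed, normal_share, capillary_share)
    return n, c


@dataclass
class VoxelState:
    """Single-voxel view: four populations at fixed capacity."""

    tumour: PhaseState
    normal: float
    capillary: float
    dead: float
    capacity: float

    def __post_init__(self):
        if min(self.normal, self.capillary, self.dead) < 0:
            raise ValueError("cell counts must be nonnegative")
        total = self.tumour.total + self.normal + self.capillary + self.dead
        if abs(total - self.capacity) > 1e-6 * max(self.capacity, 1.0):
            raise ValueError(
                f"populations sum to {total}, capacity is {self.capacity}"
            )

    @property
    def vf(self) -> float:
        """Vascular fraction: capillary cells / capacity."""
        return self.capillary / self.capacity

    @property
    def total(self) -> float:
        return self.tumour.total + self.normal + self.capillary + self.dead


@dataclass
class GridState:
    """Vectorised state of all voxels, grouped into equivalence classes.

    ``phases``/``g0``/``normal``/``capillary``/``dead`` hold one row per
    voxel *class*; ``multiplicity`` counts the identical voxels each row
    represents and ``class_of_voxel`` maps flattened grid positions to
    rows. Arrays are float64 in expectation mode and int64 in stochastic
    mode.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    phases: np.ndarray
    g0: np.ndarray
    normal: np.ndarray
    capillary: np.ndarray
    dead: np.ndarray
    capacity: np.ndarray
    multiplicity: np.ndarray
    class_of_voxel: np.ndarray
    params: RadiobiologyParams = field(default_factory=RadiobiologyParams)
    vf_table: VfBinTable = field(default_factory=default_vf_table)
    mode: str = "expectation"
    rng: Optional[np.random.Generator] = None
    clock: float = 0.0
    treatment_start: float = 0.0
    arrest: np.ndarray = None  # type: ignore[assignment]
    repopulation: bool = True

    def __post_init__(self):
        if self.mode not in ("expectation", "stochastic"):
            raise ValueError("mode must be 'expectation' or 'stochastic'")
        if self.arrest is None:
            self.arrest = np.zeros(len(self.normal))
        if self.mode == "stochastic" and self.rng is None:
            self.rng = np.random.default_rng(0)

    # -- derived quantities -------------------------------------------
    @property
    def n_classes(self) -> int:
        return len(self.normal)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def tumour_by_class(self) -> np.ndarray:
        return self.phases.sum(axis=1) + self.g0

    def vf(self) -> np.ndarray:
        return self.capillary / self.capacity

    def bin_indices(self) -> np.ndarray:
        thresholds = np.asarray(self.vf_table.thresholds)
        return np.searchsorted(thresholds, self.vf(), side="right")

    def _bin_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin expected proliferation factor and mean pO2 (cached)."""
        cache = getattr(self, "_bin_cache", None)
        key = id(self.vf_table)
        if cache is not None and cache[0] == key:
            return cache[1], cache[2]
        epf = np.array(
            [
                h.expect(lambda p: kernels.proliferation_factor(p, self.params))
                for h in self.vf_table.histograms
            ]
        )
        means = self.vf_table.means()
        self._bin_cache = (key, epf, means)
        return epf, means

    def totals(self) -> dict[str, float]:
        """Grid-wide cell totals (multiplicity-weighted)."""
        mult = self.multiplicity
        return {
            "tumour": float(self.tumour_by_class() @ mult),
            "normal": float(self.normal @ mult),
            "capillary": float(self.capillary @ mult),
            "dead": float(self.dead @ mult),
            "capacity": float(self.capacity @ mult),
        }

    def phase_totals(self) -> dict[str, float]:
        mult = self.multiplicity
        return {
            "G0": float(self.g0 @ mult),
            "G1": float(self.phases[:, _G1].sum(axis=1) @ mult),
            "S": float(self.phases[:, _S].sum(axis=1) @ mult),
            "G2": float(self.phases[:, _G2].sum(axis=1) @ mult),
            "M": float(self.phases[:, _M_IDX] @ mult),
        }

    # -- dynamics ------------------------------------------------------
    def _rng_or_none(self):
        return self.rng if self.mode == "stochastic" else None

    def step(self) -> None:
        """Advance the whole grid by one hour (params.dt)."""
        params = self.params
        dt = params.dt
        rng = self._rng_or_none()
        epf_by_bin, mean_by_bin = self._bin_tables()
        bins = self.bin_indices()

        p1 = epf_by_bin[bins]
        p2 = np.where(self.arrest > 0, 0.0, params.g2m_pass_probability)

        new, new_g0, born = _advance_arrays(self.phases, self.g0, p1, p2, rng)

        # mitosis: the extra copies displace normal cells, never below zero
        normal = self.normal.copy()
        allowed = np.minimum(born, normal)
        new[:, 0] -= born - allowed
        normal = normal - allowed

        # repopulation: extra divisions proportional to the whole tumour pool
        if self.repopulation:
            f = kernels.repopulation_factor(
                self.clock - self.treatment_start, dt, params
            )
            if f > 1.0:
                total_t = new.sum(axis=1) + new_g0
                if rng is None:
                    grow = total_t * (f - 1.0)
                else:
                    grow = rng.binomial(total_t, min(f - 1.0, 1.0))
                grow = np.minimum(grow, normal)
                new[:, 0] += grow
                normal = normal - grow

        # angiogenesis in hypoxic voxels displaces normal cells
        fac = kernels.angiogenesis_factor(params.ta, dt)
        capillary = self.capillary.copy()
        if fac > 1.0:
            hypoxic = mean_by_bin[bins] < params.hypoxia_threshold
            if rng is None:
                cg = capillary * (fac - 1.0)
            else:
                cg = rng.binomial(capillary, min(fac - 1.0, 1.0))
            cg = np.where(hypoxic, np.minimum(cg, normal), 0)
            capillary = capillary + cg
            normal = normal - cg

        # resorption of dead cells; freed capacity is refilled
        rf = kernels.resorption_fraction(params.tr, dt)
        dead = self.dead.copy()
        if rng is None:
            removed = dead * rf
        else:
            removed = rng.binomial(dead, rf)
        dead = dead - removed
        n_add, c_add = split_replacement(
            removed, params.normal_share, params.capillary_share
        )
        normal = normal + n_add
        capillary = capillary + c_add

        self._commit(new, new_g0, normal, capillary, dead)
        self.arrest = np.maximum(self.arrest - dt, 0.0)
        self.clock += dt

    def irradiate(self, d: float) -> dict[str, float]:
        """Deliver a fraction of ``d`` Gy to every voxel.

        Tumour survival is integrated over each voxel's oxygen histogram
        phase by phase; normal and capillary cells respond with the
        normal-tissue LQ. Killed cells join the dead compartment and the
        G2/M checkpoint is blocked for the arrest duration. Returns
        multiplicity-weighted kill counts by cell type.
        """
        if d < 0:
            raise ValueError("dose must be >= 0")
        if d == 0:
            return {"tumour": 0.0, "normal": 0.0, "capillary": 0.0}
        params = self.params
        rng = self._rng_or_none()
        bins = self.bin_indices()
        sf_bin_phase = np.stack(
            [
                phase_survival_fractions(d, params, hist=h)
                for h in self.vf_table.histograms
            ]
        )  # (6, 5)
        sf_by_phase = sf_bin_phase[bins]

        newP, new_g0, killed_t = _survival_arrays(
            self.phases, self.g0, sf_by_phase, rng
        )

        sfn = kernels.survival_fraction_normal(d, params)
        if rng is None:
            normal_s = self.normal * sfn
            cap_s = self.capillary * sfn
        else:
            normal_s = rng.binomial(self.normal, sfn)
            cap_s = rng.binomial(self.capillary, sfn)
        killed_n = self.normal - normal_s
        killed_c = self.capillary - cap_s
        dead = self.dead + killed_t + killed_n + killed_c

        self._commit(newP, new_g0, normal_s, cap_s, dead)
        self.arrest = np.full(self.n_classes, params.arrest_duration)
        mult = self.multiplicity
        return {
            "tumour": float(killed_t @ mult),
            "normal": float(killed_n @ mult),
            "capillary": float(killed_c @ mult),
        }

    def _commit(self, phases, g0, normal, capillary, dead) -> None:
        """Restore the capacity invariant exactly and store the new state.

        The normal population absorbs the (float) reconciliation
        residual; in stochastic mode all transfers are integer so the
        invariant must already hold to the cell.
        """
        total = phases.sum(axis=1) + g0 + normal + capillary + dead
        resid = self.capacity - total
        if np.any(np.abs(resid) > 1e-6 * np.maximum(self.capacity, 1.0)):
            raise RuntimeError(
                "capacity invariant violated before reconciliation "
                f"(max residual {np.max(np.abs(resid))})"
            )
        if self.mode == "stochastic":
            if np.any(resid != 0):
                raise RuntimeError("integer bookkeeping lost cells")
            self.normal = np.asarray(normal, dtype=np.int64)
            self.capillary = np.asarray(capillary, dtype=np.int64)
            self.dead = np.asarray(dead, dtype=np.int64)
            self.phases = np.asarray(phases, dtype=np.int64)
            self.g0 = np.asarray(g0, dtype=np.int64)
        else:
            self.phases = np.asarray(phases, dtype=float)
            self.g0 = np.asarray(g0, dtype=float)
            self.normal = np.asarray(normal + resid, dtype=float)
            self.capillary = np.asarray(capillary, dtype=float)
            self.dead = np.asarray(dead, dtype=float)

    # -- conversions ---------------------------------------------------
    def voxel(self, index: int) -> VoxelState:
        """Materialise the :class:`VoxelState` of one grid position."""
        c = int(self.class_of_voxel[index])
        state = PhaseState(
            np.asarray(self.phases[c], dtype=float),
            float(self.g0[c]),
            float(self.arrest[c]),
        )
        return VoxelState(
            tumour=state,
            normal=float(self.normal[c]),
            capillary=float(self.capillary[c]),
            dead=float(self.dead[c]),
            capacity=float(self.capacity[c]),
        )

    def copy(self) -> "GridState":
        g = dc_replace(
            self,
            phases=self.phases.copy(),
            g0=self.g0.copy(),
            normal=self.normal.copy(),
            capillary=self.capillary.copy(),
            dead=self.dead.copy(),
            capacity=self.capacity.copy(),
            multiplicity=self.multiplicity.copy(),
            class_of_voxel=self.class_of_voxel.copy(),
            arrest=self.arrest.copy(),
        )
        return g

    def snapshot(self) -> pd.DataFrame:
        """Per-voxel table: index, populations, vf and mean pO2."""
        _, mean_by_bin = self._bin_tables()
        bins = self.bin_indices()
        cls = self.class_of_voxel
        tumour = self.tumour_by_class()
        return pd.DataFrame(
            {
                "index": np.arange(len(cls)),
                "tumour": tumour[cls],
                "normal": self.normal[cls],
                "capillary": self.capillary[cls],
                "dead": self.dead[cls],
                "vf": self.vf()[cls],
                "mean_pO2": mean_by_bin[bins][cls],
            }
        )


# ---------------------------------------------------------------------
# single-voxel convenience wrappers
# ---------------------------------------------------------------------

def _grid_from_voxel(
    voxel: VoxelState,
    params: RadiobiologyParams,
    vf_table: VfBinTable,
    rng: Optional[np.random.Generator],
    t: float = 0.0,
) -> GridState:
    mode = "stochastic" if rng is not None else "expectation"
    if rng is not None:
        to = lambda x: np.asarray([round(x)], dtype=np.int64)
        phases = np.rint(voxel.tumour.slots).astype(np.int64)[None, :]
        g0 = to(voxel.tumour.g0)
        capillary = to(voxel.capillary)
        dead = to(voxel.dead)
        capacity = to(voxel.capacity)
        # the filler population absorbs the quantization residual
        normal = capacity - phases.sum(axis=1) - g0 - capillary - dead
        if normal[0] < 0:
            raise ValueError("rounded populations exceed capacity")
    else:
        to = lambda x: np.asarray([x], dtype=float)
        phases = np.asarray(voxel.tumour.slots, dtype=float)[None, :]
        g0 = to(voxel.tumour.g0)
        capillary = to(voxel.capillary)
        dead = to(voxel.dead)
        capacity = to(voxel.capacity)
        normal = to(voxel.normal)
    return GridState(
        dims=(1, 1, 1),
        voxel_size=(1.0, 1.0, 1.0),
        phases=phases.copy(),
        g0=g0,
        normal=normal,
        capillary=capillary,
        dead=dead,
        capacity=capacity,
        multiplicity=np.ones(1),
        class_of_voxel=np.zeros(1, dtype=np.intp),
        params=params,
        vf_table=vf_table,
        mode=mode,
        rng=rng,
        clock=t,
        arrest=np.asarray([voxel.tumour.arrest_remaining], dtype=float),
    )


def step_voxel(
    voxel: VoxelState,
    t: float,
    params: RadiobiologyParams | None = None,
    rng: np.random.Generator | None = None,
    vf_table: VfBinTable | None = None,
) -> VoxelState:
    """One hour of dynamics for a single voxel at simulation time ``t``."""
    params = params or RadiobiologyParams()
    vf_table = vf_table or default_vf_table()
    grid = _grid_from_voxel(voxel, params, vf_table, rng, t)
    grid.step()
    return grid.voxel(0)


def irradiate_voxel(
    voxel: VoxelState,
    d: float,
    params: RadiobiologyParams | None = None,
    rng: np.random.Generator | None = None,
    vf_table: VfBinTable | None = None,
) -> VoxelState:
    """Deliver a dose of ``d`` Gy to a single voxel."""
    params = params or RadiobiologyParams()
    vf_table = vf_table or default_vf_table()
    grid = _grid_from_voxel(voxel, params, vf_table, rng)
    grid.irradiate(d)
    return grid.voxel(0)
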