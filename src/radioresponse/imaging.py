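"""PET-like image input/output and grid initialization.

Voxel intensities are taken as proportional to tumour-cell number (a
stated modelling assumption about tracer uptake, not a validated
biological claim). A voxel at the image maximum is seeded with 80% of
its capacity as tumour cells; the non-tumour remainder splits 96.4% /
3.6% between normal and capillary cells. The inverse map renders a
simulated image from the evolving tumour counts.

A synthetic spherical "virtual tumour" (~3 cm diameter) generator stands
in for real hypoxia-tracer PET volumes in tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .cellcycle import N_SLOTS, PhaseState
from .oxygen import VfBinTable, default_vf_table
from .params import RadiobiologyParams
from .voxel import GridState, split_replacement

__all__ = [
    "ImageVolume",
    "make_virtual_tumour",
    "init_grid_from_image",
    "render_image",
    "read_image",
    "write_image",
]


@dataclass
class ImageVolume:
    """A 3-D intensity volume with isotropic-or-not voxel size in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("image data must be 3-D")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")
        if len(self.voxel_size) != 3 or min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be three positive lengths (mm)")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


def read_image(path: str | Path, voxel_size=None) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or NumPy (.npy) volume.

    Voxel size comes from the NIfTI header unless overridden.
    """
    path = Path(path)
    if path.suffix == ".npy":
        data = np.load(path)
        if voxel_size is None:
            raise ValueError("voxel_size is required for raw .npy volumes")
        return ImageVolume(data, tuple(voxel_size))
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if voxel_size is not None:
        zooms = tuple(voxel_size)
    return ImageVolume(np.asarray(img.get_fdata(), dtype=float), tuple(float(z) for z in zooms))


def write_image(image: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NumPy (.npy)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, image.data)
        return
    import nibabel as nib

    affine = np.diag(list(image.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), str(path))


def make_virtual_tumour(
    diameter: float = 30.0,
    voxel_size: float | tuple[float, float, float] = 2.0,
    profile: str = "uniform",
    padding: int = 2,
) -> ImageVolume:
    """Synthetic spherical lesion on a zero background.

    ``profile`` is "uniform" (intensity 1 inside the sphere) or
    "gaussian" (radial Gaussian with sigma = diameter/4, zero outside
    the sphere). The lesion is centred in a volume padded by ``padding``
    voxels on every side. Deterministic.
    """
    if np.isscalar(voxel_size):
        vs = (float(voxel_size),) * 3
    else:
        vs = tuple(float(v) for v in voxel_size)
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if diameter < min(vs):
        raise ValueError("diameter smaller than one voxel")
    if profile not in ("uniform", "gaussian"):
        raise ValueError("profile must be 'uniform' or 'gaussian'")
    radius = diameter / 2.0
    dims = tuple(int(np.ceil(diameter / v)) + 2 * padding for v in vs)
    centre = [(n - 1) / 2.0 * v for n, v in zip(dims, vs)]
    axes = [np.arange(n) * v - c for n, v, c in zip(dims, vs, centre)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r2 = xx**2 + yy**2 + zz**2
    inside = r2 <= radius**2
    if profile == "uniform":
        data = inside.astype(float)
    else:
        sigma = diameter / 4.0
        data = np.where(inside, np.exp(-r2 / (2.0 * sigma**2)), 0.0)
    return ImageVolume(data, vs)


def _distribute_slots(
    ntum: np.ndarray, distribution: Optional[Mapping[str, float]], integer: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Spread per-class tumour counts over cycle compartments (+ G0)."""
    if distribution is None:
        weights = np.full(N_SLOTS + 1, 1.0 / N_SLOTS)
        weights[-1] = 0.0  # no quiescent cells initially
    else:
        proto = PhaseState.from_phase_percentages(distribution, total=1.0)
        weights = np.concatenate([proto.slots, [proto.g0]])
    raw = ntum[:, None] * weights[None, :]
    if not integer:
        return raw[:, :N_SLOTS], raw[:, -1]
    base = np.floor(raw).astype(np.int64)
    leftover = ntum.astype(np.int64) - base.sum(axis=1)
    frac = raw - base
    order = np.argsort(-frac, axis=1, kind="stable")
    take = np.arange(N_SLOTS + 1)[None, :] < leftover[:, None]
    bump = np.zeros_like(base)
    np.put_along_axis(bump, order, take.astype(np.int64), axis=1)
    base += bump
    return base[:, :N_SLOTS], base[:, -1]


def init_grid_from_image(
    image: ImageVolume,
    params: RadiobiologyParams | None = None,
    vf_table: VfBinTable | None = None,
    mode: str = "expectation",
    seed: int | None = None,
    initial_phases: Optional[Mapping[str, float]] = None,
    deduplicate: bool = True,
) -> GridState:
    """Seed a voxel grid from image intensities.

    The tumour count of a voxel is (i_vox / i_max) x V_vox x mu_t x mu
    rounded to an integer; the remaining capacity splits between normal
    and capillary cells in the fixed proportions. In expectation mode,
    voxels with identical tumour counts evolve identically and are
    grouped into weighted classes when ``deduplicate`` is on; stochastic
    grids always keep one row per voxel so draws stay independent.
    """
    params = params or RadiobiologyParams()
    vf_table = vf_table or default_vf_table()
    if mode == "stochastic":
        deduplicate = False
    imax = float(image.data.max())
    if imax <= 0:
        raise ValueError("image has no positive intensity; cannot initialize")
    vvox = image.voxel_volume
    capacity = round(params.cell_density * vvox)
    ntum_full = np.rint(
        image.data.ravel() / imax * vvox * params.tumour_fraction * params.cell_density
    ).astype(np.int64)
    if np.any(ntum_full > capacity):
        raise ValueError("tumour count exceeds voxel capacity")

    if deduplicate:
        uniq, class_of_voxel, counts = np.unique(
            ntum_full, return_inverse=True, return_counts=True
        )
        multiplicity = counts.astype(float)
    else:
        uniq = ntum_full
        class_of_voxel = np.arange(len(ntum_full), dtype=np.intp)
        multiplicity = np.ones(len(ntum_full))

    remainder = capacity - uniq
    normal, capillary = split_replacement(
        remainder, params.normal_share, params.capillary_share
    )

    stochastic = mode == "stochastic"
    phases, g0 = _distribute_slots(uniq, initial_phases, integer=stochastic)
    dtype = np.int64 if stochastic else float
    rng = np.random.default_rng(seed) if stochastic else None

    return GridState(
        dims=image.dims,
        voxel_size=image.voxel_size,
        phases=np.asarray(phases, dtype=dtype),
        g0=np.asarray(g0, dtype=dtype),
        normal=np.asarray(normal, dtype=dtype),
        capillary=np.asarray(capillary, dtype=dtype),
        dead=np.zeros(len(uniq), dtype=dtype),
        capacity=np.asarray(np.full(len(uniq), capacity), dtype=dtype),
        multiplicity=multiplicity,
        class_of_voxel=np.asarray(class_of_voxel, dtype=np.intp),
        params=params,
        vf_table=vf_table,
        mode=mode,
        rng=rng,
    )


def render_image(grid: GridState, reference: ImageVolume) -> ImageVolume:
    """Simulated image from current tumour counts (inverse of seeding).

    intensity = N_tum / (mu_t x capacity) x i_max; immediately after
    initialization this reproduces the input image up to the integer
    rounding of cell counts.
    """
    imax = float(reference.data.max())
    tumour = grid.tumour_by_class()[grid.class_of_voxel]
    cap = grid.capacity[grid.class_of_voxel].astype(float)
    intensities = tumour / (grid.params.tumour_fraction * cap) * imax
    return ImageVolume(
        intensities.reshape(reference.dims), reference.voxel_size
    )
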