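"""Voxel oxygenation: pO2 histograms keyed by vascular fraction.

Each voxel carries a binned pO2 probability distribution chosen by its
vascular fraction (vf = capillary cells / voxel capacity). Six vf classes
are used (<1%, <3%, <4%, <5%, <8%, >=8%); better-vascularized classes are
better oxygenated. The shipped histograms are truncated lognormal
distributions over [0, 100] mmHg in 1-mmHg bins; their medians are
calibration inputs, not measured ground truth (see docs/methods.md), and
user-supplied histograms in the same TSV format may replace them.

Radiobiological kernels are integrated over a voxel's histogram with
:func:`expect_kernel` rather than sampling a pO2 per cell, which keeps
the expectation-mode engine fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OxygenHistogram",
    "VfBinTable",
    "truncated_lognormal_histogram",
    "default_vf_table",
    "assign_histogram",
    "bin_index",
    "expect_kernel",
    "load_vf_table_tsv",
    "save_vf_table_tsv",
    "DEFAULT_BIN_MEDIANS",
    "DEFAULT_SIGMA",
    "VF_THRESHOLDS",
]

#: Upper vascular-fraction bounds of the six oxygenation classes.
VF_THRESHOLDS: tuple[float, ...] = (0.01, 0.03, 0.04, 0.05, 0.08, math.inf)

#: Median pO2 (mmHg) of the shipped histogram for each vf class.
#: Calibration inputs (see docs/methods.md).
DEFAULT_BIN_MEDIANS: tuple[float, ...] = (0.25, 0.6, 1.2, 2.5, 8.0, 45.0)

#: Log-scale spread of the shipped lognormal histograms.
DEFAULT_SIGMA: float = 0.6

_PO2_MAX = 100.0
_BIN_WIDTH = 1.0


@dataclass(frozen=True)
class OxygenHistogram:
    """Binned pO2 probability distribution.

    ``bin_edges`` are ascending pO2 values (mmHg, length n+1) within
    [0, 100]; ``probabilities`` (length n) are nonnegative and sum to 1.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if edges.ndim != 1 or probs.ndim != 1 or len(edges) != len(probs) + 1:
            raise ValueError("bin_edges must have one more entry than probabilities")
        if len(probs) == 0:
            raise ValueError("histogram must have at least one bin")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if edges[0] < 0 or edges[-1] > _PO2_MAX + 1e-9:
            raise ValueError(f"histogram support must lie within [0, {_PO2_MAX}] mmHg")
        if np.any(probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean(self) -> float:
        """Mean pO2 (mmHg)."""
        return float(self.probabilities @ self.midpoints)

    def expect(self, kernel: Callable[[np.ndarray], np.ndarray]) -> float:
        """Expectation of ``kernel(pO2)`` over the histogram (bin midpoints)."""
        return float(self.probabilities @ np.asarray(kernel(self.midpoints), dtype=float))


def expect_kernel(kernel: Callable, hist: OxygenHistogram) -> float:
    """Histogram expectation of a pO2-dependent kernel; linear in the kernel."""
    return hist.expect(kernel)


def truncated_lognormal_histogram(
    median: float,
    sigma: float = DEFAULT_SIGMA,
    p_max: float = _PO2_MAX,
    bin_width: float = _BIN_WIDTH,
) -> OxygenHistogram:
    """Lognormal pO2 distribution truncated to [0, p_max], binned.

    ``median`` is the (untruncated) lognormal median in mmHg and ``sigma``
    the log-scale standard deviation.
    """
    if median <= 0 or sigma <= 0:
        raise ValueError("median and sigma must be > 0")
    edges = np.arange(0.0, p_max + bin_width / 2, bin_width)
    dist = stats.lognorm(s=sigma, scale=median)
    cdf = dist.cdf(edges)
    probs = np.diff(cdf)
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate histogram: no mass within the support")
    return OxygenHistogram(edges, probs / total)


@dataclass(frozen=True)
class VfBinTable:
    """Mapping of vascular-fraction classes to oxygen histograms."""

    thresholds: tuple[float, ...]
    histograms: tuple[OxygenHistogram, ...]

    def __post_init__(self):
        if len(self.thresholds) != 6 or len(self.histograms) != 6:
            raise ValueError("exactly six vf bins are required")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly ascending")

    def force_bin(self, index: int) -> "VfBinTable":
        """Table in which every vf maps to the given bin's histogram.

        Used for imposed oxygenation conditions: bin 0 emulates breathing
        a low-oxygen mixture (hypoxic), bin 5 carbogen (well-oxygenated).
        """
        return VfBinTable(self.thresholds, (self.histograms[index],) * 6)

    def means(self) -> np.ndarray:
        return np.array([h.mean for h in self.histograms])


def default_vf_table(
    medians: Sequence[float] = DEFAULT_BIN_MEDIANS,
    sigma: float = DEFAULT_SIGMA,
) -> VfBinTable:
    """The shipped six-class histogram table (truncated lognormals)."""
    if len(medians) != 6:
        raise ValueError("six medians are required")
    hists = tuple(truncated_lognormal_histogram(m, sigma) for m in medians)
    return VfBinTable(VF_THRESHOLDS, hists)


def bin_index(vf, table: VfBinTable):
    """Index of the first bin whose upper bound exceeds vf (vectorised)."""
    vf_arr = np.asarray(vf, dtype=float)
    if np.any(vf_arr < 0) or np.any(vf_arr > 1):
        raise ValueError("vf must lie in [0, 1]")
    idx = np.searchsorted(np.asarray(table.thresholds), vf_arr, side="right")
    return idx if idx.ndim else int(idx)


def assign_histogram(vf: float, table: VfBinTable) -> OxygenHistogram:
    """Histogram of the vf class containing ``vf``; deterministic."""
    return table.histograms[bin_index(vf, table)]


def save_vf_table_tsv(table: VfBinTable, path: str | Path) -> None:
    """Write a table as TSV with columns bin_id, pO2_mmHg, probability."""
    rows = []
    for b, hist in enumerate(table.histograms):
        for p, prob in zip(hist.midpoints, hist.probabilities):
            rows.append((b, p, prob))
    pd.DataFrame(rows, columns=["bin_id", "pO2_mmHg", "probability"]).to_csv(
        path, sep="\t", index=False
    )


def load_vf_table_tsv(path: str | Path) -> VfBinTable:
    """Read a histogram table from the TSV format of :func:`save_vf_table_tsv`.

    ``pO2_mmHg`` values are bin midpoints; bins must be evenly spaced
    within each histogram.
    """
    df = pd.read_csv(path, sep="\t")
    hists = []
    for b in sorted(df["bin_id"].unique()):
        sub = df[df["bin_id"] == b].sort_values("pO2_mmHg")
        mids = sub["pO2_mmHg"].to_numpy(dtype=float)
        probs = sub["probability"].to_numpy(dtype=float)
        if len(mids) == 1:
            width = 1.0
        else:
            widths = np.diff(mids)
            if np.any(np.abs(widths - widths[0]) > 1e-9):
                raise ValueError("histogram bins must be evenly spaced")
            width = float(widths[0])
        edges = np.concatenate([mids - width / 2, [mids[-1] + width / 2]])
        edges = np.clip(edges, 0.0, _PO2_MAX)
        hists.append(OxygenHistogram(edges, probs / probs.sum()))
    if len(hists) != 6:
        raise ValueError(f"expected six histograms, found {len(hists)}")
    return VfBinTable(VF_THRESHOLDS, tuple(hists))
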