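"""Model parameters for the tumour-response simulator.

All times are hours, doses Gy, oxygen partial pressures mmHg, lengths mm.
Defaults are the rhabdomyosarcoma parameter set used throughout the
package; every value can be overridden programmatically or from a
YAML/TOML file (see :meth:`RadiobiologyParams.from_file`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

PHASES = ("G0", "G1", "S", "G2", "M")

#: Default cell-cycle phase sensitivity multipliers applied to the linear
#: LQ coefficient: S is radioresistant, G2/M are the most sensitive,
#: quiescent (G0) cells mildly resistant.
DEFAULT_PHASE_WEIGHTS: dict[str, float] = {
    "G0": 0.85,
    "G1": 1.0,
    "S": 0.7,
    "G2": 1.2,
    "M": 1.3,
}


@dataclass
class RadiobiologyParams:
    """Radiobiological constants of the voxel model.

    Attributes
    ----------
    alpha_t, beta_t:
        Tumour-cell linear-quadratic coefficients (Gy^-1, Gy^-2).
    alpha_n, beta_n:
        Normal-tissue LQ coefficients; the default alpha/beta = 3 Gy is the
        classic late-responding-tissue value. Capillary cells share these.
    m, k:
        Maximum oxygen enhancement ratio and the pO2 (mmHg) at which the
        OER reaches (m + 1)/2.
    C, B, M:
        Gompertz proliferation-factor parameters: upper asymptote,
        growth rate (mmHg^-1) and inflection pO2 (mmHg).
    ta:
        Capillary-cell doubling time (h).
    tr:
        Half-life of dead-cell resorption (h).
    Tp_early, Tp_late, Tp_switch_time:
        Tumour repopulation doubling time before/after the accelerated-
        repopulation switch, and the switch time (h after the first
        fraction; 336 h = two weeks).
    phase_weights:
        Phase -> multiplier applied to ``alpha_t`` at irradiation.
    weight_beta:
        If True (default) the quadratic coefficient is scaled by the
        squared phase weight as well, i.e. the whole LQ exponent is
        evaluated at a weighted alpha; set False to weight alpha only.
    dt:
        Simulation step (h).
    cell_density:
        Fixed voxel cell density (cells/mm^3).
    tumour_fraction, normal_share, capillary_share:
        Initial tumour occupancy of an image-maximum voxel and the
        normal/capillary split of the non-tumour remainder (also the
        replacement proportions for resorbed dead cells).
    arrest_duration:
        Post-irradiation G2/M checkpoint block (h).
    g2m_pass_probability:
        Default hourly pass probability at the G2->M checkpoint outside
        the post-irradiation arrest window (calibrated against untreated
        24-h phase kinetics; see docs/methods.md).
    hypoxia_threshold:
        Histogram-mean pO2 (mmHg) below which angiogenesis is active.
    oer_convention:
        "printed" uses the survival expression with effective dose
        m*d*OER(pO2); "effective_dose" uses the textbook construction
        d*OER(pO2)/m. See docs/methods.md for the rationale.
    """

    alpha_t: float = 0.273
    beta_t: float = 0.045
    alpha_n: float = 0.15
    beta_n: float = 0.05
    m: float = 3.0
    k: float = 3.0
    C: float = 1.0
    B: float = 0.075
    M: float = 26.3
    ta: float = 612.0
    tr: float = 168.0
    Tp_early: float = 1200.0
    Tp_late: float = 120.0
    Tp_switch_time: float = 336.0
    phase_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_WEIGHTS)
    )
    weight_beta: bool = True
    dt: float = 1.0
    cell_density: float = 1.0e6
    tumour_fraction: float = 0.8
    normal_share: float = 0.964
    capillary_share: float = 0.036
    arrest_duration: float = 8.0
    g2m_pass_probability: float = 0.26
    hypoxia_threshold: float = 10.0
    oer_convention: str = "printed"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "alpha_t": self.alpha_t,
            "beta_t": self.beta_t,
            "alpha_n": self.alpha_n,
            "beta_n": self.beta_n,
            "k": self.k,
            "B": self.B,
            "ta": self.ta,
            "tr": self.tr,
            "Tp_early": self.Tp_early,
            "Tp_late": self.Tp_late,
            "cell_density": self.cell_density,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not 0 < self.C <= 1:
            raise ValueError(f"C must be in (0, 1], got {self.C}")
        if self.dt < 0:
            raise ValueError(f"dt must be >= 0, got {self.dt}")
        for phase in PHASES:
            if phase not in self.phase_weights:
                raise ValueError(f"phase_weights missing phase {phase!r}")
            if not self.phase_weights[phase] > 0:
                raise ValueError(f"phase weight for {phase} must be > 0")
        if not 0 <= self.g2m_pass_probability <= 1:
            raise ValueError("g2m_pass_probability must be in [0, 1]")
        if abs(self.normal_share + self.capillary_share - 1.0) > 1e-9:
            raise ValueError("normal_share + capillary_share must equal 1")
        if not 0 < self.tumour_fraction <= 1:
            raise ValueError("tumour_fraction must be in (0, 1]")
        if self.oer_convention not in ("printed", "effective_dose"):
            raise ValueError(
                "oer_convention must be 'printed' or 'effective_dose'"
            )

    def replace(self, **changes) -> "RadiobiologyParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def without_repopulation(self) -> "RadiobiologyParams":
        """Copy with the repopulation term switched off (infinite Tp)."""
        return self.replace(Tp_early=math.inf, Tp_late=math.inf)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RadiobiologyParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "RadiobiologyParams":
        """Load parameters from a YAML (.yaml/.yml) or TOML (.toml) file."""
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        elif path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            raise ValueError(f"unsupported parameter file type: {path.suffix}")
        return cls.from_mapping(data)
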