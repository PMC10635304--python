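"""Domain parameter containers for CEST signal modeling.

Conventions used throughout the package:

* frequency offsets are expressed in ppm at module interfaces, positive
  downfield of water (amide +3.5 ppm, NOE −3.5 ppm), and converted to
  rad/s internally via ``hz_per_ppm * 2π``;
* saturation amplitude ``omega1`` is given in μT and converted with the
  proton gyromagnetic ratio γ/2π = 42.5775 Hz/μT;
* all relaxation and exchange rates are s⁻¹, pool fractions are relative
  to water (water ≡ 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GAMMA_HZ_PER_UT",
    "DEFAULT_HZ_PER_PPM",
    "PoolParams",
    "TissueState",
    "AcquisitionParams",
    "ZSpectrum",
    "ComponentSpectra",
    "default_offset_grid",
    "default_acquisition",
    "ut_to_radps",
    "ppm_to_radps",
]

#: proton gyromagnetic ratio over 2π, Hz per μT
GAMMA_HZ_PER_UT = 42.5775

#: default ppm→Hz conversion matching the acquisition grid listing
#: (100 kHz control offset printed as 250 ppm → 400 Hz/ppm)
DEFAULT_HZ_PER_PPM = 400.0


def ut_to_radps(omega1_ut: float) -> float:
    """Convert a saturation amplitude from μT to rad/s (1 μT → 267.52 rad/s)."""
    return float(omega1_ut) * GAMMA_HZ_PER_UT * 2.0 * np.pi


def ppm_to_radps(ppm, hz_per_ppm: float = DEFAULT_HZ_PER_PPM):
    """Convert offsets in ppm to angular frequency in rad/s."""
    return np.asarray(ppm, dtype=float) * hz_per_ppm * 2.0 * np.pi


@dataclass(frozen=True)
class PoolParams:
    """One exchanging/coupling proton pool.

    Parameters
    ----------
    name : str
        Pool label (``"amide"``, ``"noe35"``, ``"mt"``, ...).
    fs : float
        Pool-size fraction relative to water, dimensionless, ≥ 0.
    ksw : float
        Solute→water exchange rate (s⁻¹), ≥ 0.
    delta : float
        Resonance offset from water (ppm), positive downfield.
    R1s, R2s : float
        Longitudinal / transverse relaxation rates of the pool (s⁻¹), > 0.
    """

    name: str
    fs: float
    ksw: float
    delta: float
    R1s: float = 1.0
    R2s: float = 30.0

    def __post_init__(self):
        if self.fs < 0:
            raise ValueError(f"pool {self.name!r}: fs must be >= 0, got {self.fs}")
        if self.ksw < 0:
            raise ValueError(f"pool {self.name!r}: ksw must be >= 0, got {self.ksw}")
        if self.R1s <= 0 or self.R2s <= 0:
            raise ValueError(
                f"pool {self.name!r}: relaxation rates must be > 0 "
                f"(R1s={self.R1s}, R2s={self.R2s})"
            )

    def with_(self, **kwargs) -> "PoolParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TissueState:
    """Bulk water / semisolid state entering the inverse-summation composer.

    ``R1obs`` is the observed water longitudinal rate; ``r_amines`` and
    ``r_MT`` are the amplitude scaling factors applied to the measured
    amine-CEST and semisolid-MT components.
    """

    R1obs: float
    R1w: float
    R2w: float
    R1M: float = 1.0
    fm: float = 0.0
    r_amines: float = 1.0
    r_MT: float = 1.0

    def __post_init__(self):
        for attr in ("R1obs", "R1w", "R2w", "R1M"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0, got {getattr(self, attr)}")
        if not (0.0 <= self.fm <= 0.3):
            raise ValueError(f"fm must lie in [0, 0.3], got {self.fm}")
        if self.r_amines < 0 or self.r_MT < 0:
            raise ValueError("scaling factors must be >= 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """Continuous-wave CEST acquisition description.

    The default grid reproduces a 9.4 T protocol: offsets at ±4000, ±3500,
    ±3000 Hz and −2000…2000 Hz in 50 Hz steps (±10, ±8.75, ±7.5 and
    −5…5 ppm in 0.125 ppm steps at 400 Hz/ppm; 87 points), 1 μT / 5 s
    rectangular saturation, control image at 250 ppm.
    """

    B0: float = 9.4
    hz_per_ppm: float = DEFAULT_HZ_PER_PPM
    omega1_ut: float = 1.0
    t_sat: float = 5.0
    TR: float = 7.0
    offsets: tuple = field(default_factory=lambda: tuple(default_offset_grid()))
    control_offset: float = 250.0

    def __post_init__(self):
        if self.omega1_ut < 0:
            raise ValueError("omega1_ut must be >= 0")
        if self.t_sat <= 0:
            raise ValueError("t_sat must be > 0")
        off = np.asarray(self.offsets, dtype=float)
        if off.ndim != 1 or off.size < 2 or not np.all(np.diff(off) > 0):
            raise ValueError("offsets must be a strictly increasing 1-D grid")
        if abs(self.control_offset) < 100.0:
            raise ValueError("control_offset must sit far off-resonance (|x| >= 100 ppm)")

    @property
    def omega1_radps(self) -> float:
        """Saturation amplitude in rad/s."""
        return ut_to_radps(self.omega1_ut)

    @property
    def offsets_ppm(self) -> np.ndarray:
        return np.asarray(self.offsets, dtype=float)


def default_offset_grid() -> np.ndarray:
    """The 87-point acquisition offset grid in ppm, ascending."""
    inner = np.round(np.arange(-40, 41) * 0.125, 3)
    outer = np.array([-10.0, -8.75, -7.5])
    return np.concatenate([outer, inner, -outer[::-1]])


def default_acquisition(**kwargs) -> AcquisitionParams:
    """The default 9.4 T continuous-wave acquisition (overridable per field)."""
    return AcquisitionParams(**kwargs)


@dataclass
class ZSpectrum:
    """A normalized Z-spectrum: S/S0 sampled on an offset grid (ppm)."""

    offsets: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets.shape != self.values.shape:
            raise ValueError("offsets and values must have matching shapes")
        if self.values.size and (
            np.nanmin(self.values) < -0.05 or np.nanmax(self.values) > 1.05
        ):
            raise ValueError("Z-spectrum values must lie in [0, 1.05] up to noise")

    def __len__(self) -> int:
        return self.offsets.size

    def at(self, offset_ppm: float) -> float:
        """Value at the grid point closest to ``offset_ppm``."""
        return float(self.values[np.argmin(np.abs(self.offsets - offset_ppm))])


@dataclass
class ComponentSpectra:
    """Rotating-frame component spectra entering the inverse-summation model.

    Each component is a rate spectrum (s⁻¹) on a shared ppm grid;
    ``provenance`` records per component whether it was simulated or
    fitted from a measured spectrum.
    """

    offsets: np.ndarray
    Reff: np.ndarray
    Rex_apt: np.ndarray
    Rex_noe: np.ndarray
    Rex_amines: np.ndarray
    Rex_mt: np.ndarray
    provenance: dict = field(default_factory=dict)

    _FIELDS = ("Reff", "Rex_apt", "Rex_noe", "Rex_amines", "Rex_mt")

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        for name in self._FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.offsets.shape:
                raise ValueError(f"component {name} does not match the offset grid")
            setattr(self, name, arr)
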