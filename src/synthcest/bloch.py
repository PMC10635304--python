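"""Multi-pool Bloch-McConnell simulation of continuous-wave CEST.

Water exchanges with up to six solute/semisolid pools in a star topology
(each pool exchanges with water only).  Under a constant-amplitude
rectangular saturation pulse the coupled magnetization system is linear
with constant coefficients,

    dM/dt = A·M + b,

so the steady state is the solution of A·M = −b and the transient state
is obtained by matrix exponentiation of the homogenized system.  The
semisolid (MT) pool is propagated with full (x, y, z) components, i.e.
with the Lorentzian absorption lineshape implied by its R2s — consistent
with fitting MT as a Lorentzian downstream; a super-Lorentzian lineshape
is deliberately not used.

The simulator provides tissue-mimicking Z-spectra with known ground
truth: the true CESTR APT spectrum of a pool set is the difference of
two simulated Z-spectra with and without the amide pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .params import AcquisitionParams, PoolParams, ZSpectrum, ppm_to_radps

__all__ = [
    "PoolSet",
    "GroundTruthAPT",
    "default_brain_pools",
    "TISSUE_MIMICKING_RANGES",
    "simulate_zspectrum",
    "ground_truth_apt",
    "sample_tissue_mimicking",
    "peak_amplitude_width",
]


@dataclass(frozen=True)
class PoolSet:
    """One water pool plus an ordered list of solute/semisolid pools."""

    water: PoolParams
    solutes: tuple = ()

    def __post_init__(self):
        names = [p.name for p in self.solutes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate solute pool names: {names}")
        object.__setattr__(self, "solutes", tuple(self.solutes))

    def without(self, name: str) -> "PoolSet":
        """A copy with the named solute pool removed."""
        kept = tuple(p for p in self.solutes if p.name != name)
        if len(kept) == len(self.solutes):
            raise ValueError(f"pool set has no solute named {name!r}")
        return replace(self, solutes=kept)

    def get(self, name: str) -> PoolParams:
        for p in self.solutes:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self):
        return tuple(p.name for p in self.solutes)


@dataclass
class GroundTruthAPT:
    """True CESTR APT spectrum of a pool set, with peak amplitude and width."""

    offsets: np.ndarray
    spectrum: np.ndarray
    A_true: float
    W_true: float


def _system_matrices(pools: PoolSet, offsets_ppm, acq: AcquisitionParams):
    """Stacked Bloch-McConnell matrices A (n_off, 3N, 3N) and source b (3N,)."""
    offsets_ppm = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    n_off = offsets_ppm.size
    sol = pools.solutes
    n_pool = 1 + len(sol)
    dim = 3 * n_pool
    w1 = acq.omega1_radps

    fs = np.array([p.fs for p in sol])
    ksw = np.array([p.ksw for p in sol])
    k_water_out = float(np.sum(fs * ksw))

    A = np.zeros((n_off, dim, dim))
    b = np.zeros(dim)

    # precession frequency of pool p in the frame rotating at the RF offset
    dw_sat = ppm_to_radps(offsets_ppm, acq.hz_per_ppm)

    def fill(idx, R1, R2, kout, delta_ppm, M0):
        x, y, z = 3 * idx, 3 * idx + 1, 3 * idx + 2
        omega = ppm_to_radps(delta_ppm, acq.hz_per_ppm) - dw_sat
        A[:, x, x] = -(R2 + kout)
        A[:, x, y] = -omega
        A[:, y, x] = omega
        A[:, y, y] = -(R2 + kout)
        A[:, y, z] = w1
        A[:, z, y] = -w1
        A[:, z, z] = -(R1 + kout)
        b[z] = R1 * M0

    fill(0, pools.water.R1s, pools.water.R2s, k_water_out, 0.0, 1.0)
    for i, p in enumerate(sol, start=1):
        fill(i, p.R1s, p.R2s, p.ksw, p.delta, p.fs)
        for comp in range(3):
            A[:, 3 * i + comp, comp] = p.fs * p.ksw  # water -> solute
            A[:, comp, 3 * i + comp] = p.ksw         # solute -> water
    return A, b


def _equilibrium(pools: PoolSet) -> np.ndarray:
    m0 = np.zeros(3 * (1 + len(pools.solutes)))
    m0[2] = 1.0
    for i, p in enumerate(pools.solutes, start=1):
        m0[3 * i + 2] = p.fs
    return m0


def _water_mz(pools: PoolSet, offsets_ppm, acq: AcquisitionParams, mode: str):
    A, b = _system_matrices(pools, offsets_ppm, acq)
    if mode == "steady":
        try:
            rhs = np.broadcast_to(-b[:, None], (A.shape[0], b.size, 1))
            M = np.linalg.solve(A, rhs)[..., 0]
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise ValueError(f"singular Bloch-McConnell system: {err}") from err
        return M[:, 2]
    if mode == "transient":
        m0 = _equilibrium(pools)
        out = np.empty(A.shape[0])
        for j in range(A.shape[0]):
            mss = np.linalg.solve(A[j], -b)
            out[j] = (expm(A[j] * acq.t_sat) @ (m0 - mss))[2] + mss[2]
        return out
    raise ValueError(f"mode must be 'steady' or 'transient', got {mode!r}")


def simulate_zspectrum(
    pools: PoolSet, acq: AcquisitionParams, mode: str = "steady"
) -> ZSpectrum:
    """Simulate a normalized Z-spectrum S(Δω)/S0.

    ``mode='steady'`` solves the stationary Bloch-McConnell state per
    offset; ``mode='transient'`` propagates from thermal equilibrium for
    ``acq.t_sat`` seconds.  S0 is the same simulation at the control
    offset (default 250 ppm).
    """
    offsets = acq.offsets_ppm
    s = _water_mz(pools, offsets, acq, mode)
    s0 = _water_mz(pools, [acq.control_offset], acq, mode)[0]
    values = np.clip(s / s0, 0.0, 1.05)
    return ZSpectrum(
        offsets,
        values,
        meta={"provenance": "bloch-simulated", "mode": mode,
              "pools": pools.names, "omega1_ut": acq.omega1_ut},
    )


def peak_amplitude_width(offsets, spectrum, center: float, window: float = 1.5):
    """Peak amplitude and FWHM (ppm) of a spectral peak near ``center``.

    The amplitude is read at the grid point closest to ``center``; the
    width comes from linear interpolation of the half-maximum crossings
    adjacent to the peak maximum (asymmetric shoulders are resolved by
    taking the nearest crossing on each side).  Returns (A, W); W is 0
    when the peak amplitude is not positive.
    """
    offsets = np.asarray(offsets, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    a = float(spectrum[np.argmin(np.abs(offsets - center))])
    in_win = np.abs(offsets - center) <= window
    ipk = np.flatnonzero(in_win)[np.argmax(spectrum[in_win])]
    peak = spectrum[ipk]
    if peak <= 0 or a <= 0:
        return max(a, 0.0), 0.0
    half = 0.5 * peak

    def cross(direction):
        i = ipk
        while 0 <= i + direction < spectrum.size and spectrum[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= spectrum.size:
            return offsets[i]  # never drops below half inside the grid
        # linear interpolation between the bracketing samples
        f = (spectrum[i] - half) / (spectrum[i] - spectrum[j])
        return offsets[i] + f * (offsets[j] - offsets[i])

    w = abs(cross(+1) - cross(-1))
    return a, float(w)


def ground_truth_apt(pools: PoolSet, acq: AcquisitionParams,
                     mode: str = "steady") -> GroundTruthAPT:
    """Ground-truth CESTR APT spectrum by paired simulation with/without amide.

    CESTR(Δω) = Z_without-amide(Δω) − Z_with-amide(Δω); the amplitude is
    read at the amide offset and the width is the FWHM of the peak.
    """
    if "amide" not in pools.names:
        raise ValueError("pool set has no amide pool")
    z_lab = simulate_zspectrum(pools, acq, mode)
    z_ref = simulate_zspectrum(pools.without("amide"), acq, mode)
    spec = z_ref.values - z_lab.values
    amide_delta = pools.get("amide").delta
    a, w = peak_amplitude_width(z_lab.offsets, spec, amide_delta)
    return GroundTruthAPT(z_lab.offsets, spec, a, w)


# ---------------------------------------------------------------------------
# tissue-mimicking sampling

def default_brain_pools() -> PoolSet:
    """A representative seven-pool 9.4 T brain model (midpoint parameters)."""
    return PoolSet(
        water=PoolParams("water", 1.0, 0.0, 0.0, R1s=1.0 / 1.8, R2s=1.0 / 0.05),
        solutes=(
            PoolParams("amide", 1.5e-3, 50.0, 3.5, R1s=1.0, R2s=1.0 / 0.015),
            PoolParams("amine", 2.5e-3, 3000.0, 3.0, R1s=1.0, R2s=1.0 / 0.008),
            PoolParams("guanidinium", 1.0e-3, 500.0, 2.0, R1s=1.0, R2s=1.0 / 0.010),
            PoolParams("noe16", 1.0e-3, 30.0, -1.6, R1s=1.0, R2s=1.0 / 0.003),
            PoolParams("noe35", 8.0e-3, 30.0, -3.5, R1s=1.0, R2s=1.0 / 0.001),
            PoolParams("mt", 0.09, 40.0, -2.3, R1s=1.0, R2s=1.0 / 10e-6),
        ),
    )


#: physiological 9.4 T parameter ranges for the tissue-mimicking generator.
#: T1/T2 in seconds; each entry is (min, max) and is sampled uniformly.
TISSUE_MIMICKING_RANGES: dict = {
    "water": {"T1": (1.5, 2.2), "T2": (0.030, 0.070)},
    "amide": {"fs": (0.2e-3, 3.0e-3), "ksw": (10.0, 100.0), "T2": (0.005, 0.030)},
    "amine": {"fs": (0.5e-3, 5.0e-3), "ksw": (1000.0, 6000.0), "T2": (0.004, 0.012)},
    "guanidinium": {"fs": (0.2e-3, 2.0e-3), "ksw": (100.0, 1000.0), "T2": (0.005, 0.015)},
    "noe16": {"fs": (0.2e-3, 2.0e-3), "ksw": (10.0, 50.0), "T2": (0.001, 0.005)},
    "noe35": {"fs": (2.0e-3, 20.0e-3), "ksw": (10.0, 50.0), "T2": (0.0003, 0.002)},
    "mt": {"fs": (0.03, 0.15), "ksw": (20.0, 60.0), "T2": (5e-6, 15e-6)},
}


def _draw_pools(rng: np.random.Generator, ranges: dict, base: PoolSet):
    """One uniform draw of a PoolSet (and its parameter dict) from ranges."""

    def u(lo_hi):
        lo, hi = lo_hi
        if lo > hi:
            raise ValueError(f"invalid range ({lo}, {hi})")
        return float(rng.uniform(lo, hi))

    params = {}
    wr = ranges.get("water", {})
    t1w = u(wr["T1"]) if "T1" in wr else 1.0 / base.water.R1s
    t2w = u(wr["T2"]) if "T2" in wr else 1.0 / base.water.R2s
    params["water"] = {"T1": t1w, "T2": t2w}
    water = base.water.with_(R1s=1.0 / t1w, R2s=1.0 / t2w)

    solutes = []
    for p in base.solutes:
        r = ranges.get(p.name, {})
        fs = u(r["fs"]) if "fs" in r else p.fs
        ksw = u(r["ksw"]) if "ksw" in r else p.ksw
        t2 = u(r["T2"]) if "T2" in r else 1.0 / p.R2s
        params[p.name] = {"fs": fs, "ksw": ksw, "T2": t2}
        solutes.append(p.with_(fs=fs, ksw=ksw, R2s=1.0 / t2))
    return PoolSet(water=water, solutes=tuple(solutes)), params


def sample_tissue_mimicking(
    ranges: dict | None = None,
    n: int = 1,
    seed: int | np.random.Generator = 0,
    acq: AcquisitionParams | None = None,
    mode: str = "steady",
):
    """Draw ``n`` tissue-mimicking spectra with paired ground truth.

    Parameters are sampled independently and uniformly within ``ranges``
    (default: :data:`TISSUE_MIMICKING_RANGES`).  Returns a list of
    ``(ZSpectrum, GroundTruthAPT, params_dict)`` records; each record's
    ``params_dict`` carries the full generating parameter draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = TISSUE_MIMICKING_RANGES if ranges is None else ranges
    if not ranges:
        raise ValueError("empty parameter ranges")
    acq = acq or AcquisitionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = default_brain_pools()
    out = []
    for _ in range(n):
        pools, params = _draw_pools(rng, ranges, base)
        gt = ground_truth_apt(pools, acq, mode)
        z = simulate_zspectrum(pools, acq, mode)
        out.append((z, gt, params))
    return out
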