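"""Closed-form rotating-frame building blocks of the CEST signal.

At steady state under continuous-wave saturation the normalized water
signal is well described by an inverse summation of rotating-frame rates:
an effective water relaxation ``R_eff`` (direct saturation) plus one
exchange-induced relaxation term ``R_ex`` per solute pool.  This module
implements those blocks, the composer that assembles partially synthetic
Z-spectra from any mix of simulated and measured components, the CESTR
and AREX quantification metrics, and the transient (non-steady-state)
extension.
"""

from __future__ import annotations

import numpy as np

from .params import (
    AcquisitionParams,
    ComponentSpectra,
    PoolParams,
    TissueState,
    ZSpectrum,
    DEFAULT_HZ_PER_PPM,
    ppm_to_radps,
)

__all__ = [
    "lorentzian_line",
    "rex_slow",
    "cos2theta",
    "reff",
    "r1obs_from_components",
    "compose_zspectrum",
    "cestr",
    "arex",
    "transient_signal",
]


def lorentzian_line(A: float, W: float, center: float, offsets) -> np.ndarray:
    """Lorentzian line ``A / (1 + (Δω − center)² / (W/2)²)``.

    ``A`` is the peak amplitude (attained exactly at ``center``), ``W`` the
    full width at half maximum in ppm, ``offsets`` the ppm grid.
    """
    if W <= 0:
        raise ValueError(f"FWHM W must be > 0, got {W}")
    offsets = np.asarray(offsets, dtype=float)
    return A / (1.0 + ((offsets - center) / (0.5 * W)) ** 2)


def rex_slow(
    pool: PoolParams,
    omega1_radps: float,
    offsets,
    hz_per_ppm: float = DEFAULT_HZ_PER_PPM,
) -> np.ndarray:
    """Exchange-induced rotating-frame relaxation of a slow pool (s⁻¹).

    For slowly exchanging/coupling pools (amide, NOE),

        R_ex(Δω) = fs·ksw·ω1² / [ω1² + (R2s+ksw)·ksw + (Δω−Δ)²·ksw/(R2s+ksw)]

    with Δω and Δ in rad/s.  The spectrum is a Lorentzian in Δω centred at
    the pool offset Δ with on-resonance value
    fs·ksw·ω1²/(ω1² + (R2s+ksw)·ksw).
    """
    if omega1_radps < 0:
        raise ValueError("omega1 must be >= 0")
    if pool.ksw <= 0 or pool.R2s <= 0:
        raise ValueError("rex_slow requires ksw > 0 and R2s > 0")
    dw = ppm_to_radps(offsets, hz_per_ppm)
    delta = ppm_to_radps(pool.delta, hz_per_ppm)
    k = pool.ksw
    denom = omega1_radps**2 + (pool.R2s + k) * k + (dw - delta) ** 2 * k / (pool.R2s + k)
    return pool.fs * k * omega1_radps**2 / denom


def cos2theta(
    offsets, omega1_radps: float, hz_per_ppm: float = DEFAULT_HZ_PER_PPM
) -> np.ndarray:
    """cos²θ = Δω²/(ω1²+Δω²) of the effective saturation field tilt."""
    dw = ppm_to_radps(offsets, hz_per_ppm)
    denom = omega1_radps**2 + dw**2
    with np.errstate(invalid="ignore"):
        c2 = np.where(denom > 0, dw**2 / denom, 1.0)
    return c2


def reff(
    tissue: TissueState,
    omega1_radps: float,
    offsets,
    hz_per_ppm: float = DEFAULT_HZ_PER_PPM,
) -> np.ndarray:
    """Effective water rotating-frame relaxation (direct saturation), s⁻¹.

    R_eff(Δω) = R1obs·cos²θ + R2w·sin²θ.
    """
    c2 = cos2theta(offsets, omega1_radps, hz_per_ppm)
    return tissue.R1obs * c2 + tissue.R2w * (1.0 - c2)


def r1obs_from_components(R1w: float, R1M: float, fm: float, r_MT: float) -> float:
    """Observed water longitudinal rate from water and semisolid pools.

    R1obs = (R1w + r_MT·fm·R1M) / (1 + r_MT·fm) — the pool-size-weighted
    mean of the free-water and semisolid longitudinal rates.
    """
    if R1w <= 0 or R1M <= 0:
        raise ValueError("relaxation rates must be > 0")
    if fm < 0 or r_MT < 0:
        raise ValueError("fm and r_MT must be >= 0")
    return (R1w + r_MT * fm * R1M) / (1.0 + r_MT * fm)


def compose_zspectrum(
    components: ComponentSpectra,
    tissue: TissueState,
    omega1_radps: float,
    offsets=None,
    hz_per_ppm: float = DEFAULT_HZ_PER_PPM,
    return_r1rho: bool = False,
):
    """Assemble a Z-spectrum by inverse summation of rotating-frame components.

    S/S0 = R1obs·cos²θ / [ R_eff + (R_ex^APT + R_ex^NOE + r_amines·R_ex^amines)
                           / (1 + r_MT·fm) + r_MT·R_ex^MT ]

    The denominator is the rotating-frame relaxation rate R_1ρ, optionally
    returned for the transient extension.  Components may each come from a
    simulation or from a measured (Lorentzian-fitted) spectrum; that is the
    partially synthetic construction.
    """
    if offsets is None:
        offsets = components.offsets
    offsets = np.asarray(offsets, dtype=float)
    if not np.array_equal(offsets, components.offsets):
        raise ValueError("component grid does not match the requested offsets")
    c2 = cos2theta(offsets, omega1_radps, hz_per_ppm)
    scale = 1.0 + tissue.r_MT * tissue.fm
    r1rho = (
        components.Reff
        + (
            components.Rex_apt
            + components.Rex_noe
            + tissue.r_amines * components.Rex_amines
        )
        / scale
        + tissue.r_MT * components.Rex_mt
    )
    if np.any(r1rho <= 0):
        raise ValueError(
            "non-positive rotating-frame rate in composition: "
            "component set is unphysical"
        )
    values = tissue.R1obs * c2 / r1rho
    z = ZSpectrum(offsets, values, meta={"provenance": "composed"})
    if return_r1rho:
        return z, r1rho
    return z


def _common_grid(S_ref, S_lab):
    ref_off = np.asarray(S_ref.offsets if isinstance(S_ref, ZSpectrum) else S_ref[0])
    lab_off = np.asarray(S_lab.offsets if isinstance(S_lab, ZSpectrum) else S_lab[0])
    if not np.array_equal(ref_off, lab_off):
        raise ValueError("S_ref and S_lab must share the same offset grid")


def cestr(S_ref, S_lab) -> np.ndarray:
    """CEST ratio metric: CESTR(Δω) = S_ref/S0 − S_lab/S0.

    Both inputs are normalized spectra on a common grid (``ZSpectrum`` or
    plain arrays).
    """
    if isinstance(S_ref, ZSpectrum) and isinstance(S_lab, ZSpectrum):
        _common_grid(S_ref, S_lab)
        return S_ref.values - S_lab.values
    ref = np.asarray(S_ref, dtype=float)
    lab = np.asarray(S_lab, dtype=float)
    if ref.shape != lab.shape:
        raise ValueError("S_ref and S_lab must share the same grid")
    return ref - lab


def arex(S_ref, S_lab, R1obs: float, fm: float = 0.0) -> np.ndarray:
    """Apparent exchange-dependent relaxation (s⁻¹).

    AREX(Δω) = (S0/S_lab − S0/S_ref)·R1obs·(1 + fm); the inverse difference
    removes the spillover/MT shine-through of CESTR and approximates R_ex.
    Raises if a normalized signal is ≤ 0 anywhere (the inverse of a near-zero
    value blows up on-resonance).
    """
    if isinstance(S_ref, ZSpectrum) and isinstance(S_lab, ZSpectrum):
        _common_grid(S_ref, S_lab)
        ref, lab = S_ref.values, S_lab.values
    else:
        ref = np.asarray(S_ref, dtype=float)
        lab = np.asarray(S_lab, dtype=float)
        if ref.shape != lab.shape:
            raise ValueError("S_ref and S_lab must share the same grid")
    if np.any(ref <= 0) or np.any(lab <= 0):
        raise ValueError("AREX undefined where a normalized signal is <= 0")
    return (1.0 / lab - 1.0 / ref) * R1obs * (1.0 + fm)


def transient_signal(S_ss, R1rho, t_p: float):
    """Non-steady-state signal after a finite saturation time.

    S^nss/S0 = (1 − S/S0)·exp(−R_1ρ·t_p) + S/S0, where R_1ρ is the full
    rotating-frame rate (the denominator of the inverse-summation model).
    Recovers S^nss/S0 = 1 at t_p = 0 and the steady state as t_p → ∞.
    """
    if t_p < 0:
        raise ValueError("t_p must be >= 0")
    r1rho = np.asarray(R1rho, dtype=float)
    if np.any(r1rho <= 0):
        raise ValueError("R1rho must be > 0")
    if isinstance(S_ss, ZSpectrum):
        vals = (1.0 - S_ss.values) * np.exp(-r1rho * t_p) + S_ss.values
        meta = dict(S_ss.meta)
        meta["t_p"] = t_p
        return ZSpectrum(S_ss.offsets, vals, meta=meta)
    s = np.asarray(S_ss, dtype=float)
    return (1.0 - s) * np.exp(-r1rho * t_p) + s
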