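"""Builders for the training corpora.

Three kinds of datasets feed the machine-learning stage:

* **partially synthetic** — Z-spectra composed by inverse summation from
  *simulated* APT/NOE/direct-saturation components and *measured*
  (Lorentzian-fitted) amine and semisolid-MT components, with scaling
  factors r_amines and r_MT standing in for their amplitude variation;
* **fully synthetic** — Bloch-McConnell simulations of the complete
  seven-pool model;
* **tissue-mimicking** — Bloch-McConnell simulations used as a test bed
  with known ground truth (see :mod:`synthcest.bloch`).

Every record carries the CESTR-quantified APT truth spectrum obtained by
pairing each Z-spectrum with its amide-free counterpart, together with
the peak amplitude A and width W that are the regression targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import bloch
from .lorentzian import MeasuredComponents
from .params import AcquisitionParams, ComponentSpectra, PoolParams, TissueState, ZSpectrum
from .signal_model import compose_zspectrum, r1obs_from_components, reff, rex_slow

__all__ = [
    "TrainingRecord",
    "RangeConfig",
    "DEFAULT_TRAINING_RANGES",
    "build_partial_synthetic",
    "build_fully_synthetic",
    "add_noise",
    "augment_pair_average",
    "iter_pair_averages",
    "pair_average_count",
    "records_from_tissue_mimicking",
]

#: loss / truth-spectrum retention window around the amide peak (ppm)
TRUTH_WINDOW = (2.0, 5.0)


@dataclass
class TrainingRecord:
    """One (Z-spectrum, APT target) training pair."""

    offsets: np.ndarray
    features: np.ndarray
    target_A: float
    target_W: float
    truth_offsets: np.ndarray
    truth_spectrum: np.ndarray
    gen_params: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass
class RangeConfig:
    """Uniform sampling ranges for the synthetic-data generators.

    Each pool entry maps parameter name → (min, max); T1/T2 in seconds.
    ``r_amines``/``r_MT`` scale the measured amine and MT component
    amplitudes; they are drawn log-uniformly (the natural measure for a
    multiplicative factor) over ranges wide enough that the training
    set covers the tissue amplitude variation regardless of which
    source spectrum the components were fitted from — e.g. a semisolid
    pool-size ratio span of 0.03–0.15 requires r_MT up to 5 when the
    source sits at the low end.  The widths of the measured components
    are deliberately not varied.
    """

    amide: dict = field(default_factory=lambda: {
        "fs": (0.1e-3, 3.3e-3), "ksw": (10.0, 110.0), "T2": (0.005, 0.030)})
    noe35: dict = field(default_factory=lambda: {
        "fs": (1.0e-3, 22.0e-3), "ksw": (10.0, 50.0), "T2": (0.0003, 0.002)})
    noe16: dict = field(default_factory=lambda: {
        "fs": (0.2e-3, 2.0e-3), "ksw": (10.0, 50.0), "T2": (0.001, 0.005)})
    water: dict = field(default_factory=lambda: {
        "T1": (1.4, 2.3), "T2": (0.028, 0.075)})
    r_amines: tuple = (0.1, 10.0)
    r_MT: tuple = (0.2, 5.0)
    noise_sd: float = 0.01
    R1M: float = 1.0

    def validate(self):
        for name in ("amide", "noe35", "noe16", "water"):
            entry = getattr(self, name)
            if not entry:
                raise ValueError(f"empty range entry for {name!r}")
            for key, (lo, hi) in entry.items():
                if lo > hi or (lo < 0 and key != "delta"):
                    raise ValueError(f"invalid range {name}.{key} = ({lo}, {hi})")
        for key in ("r_amines", "r_MT"):
            lo, hi = getattr(self, key)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range {key} = ({lo}, {hi})")
        return self


DEFAULT_TRAINING_RANGES = RangeConfig()

_POOL_DELTAS = {"amide": 3.5, "noe35": -3.5, "noe16": -1.6}


def _truth_window_mask(offsets):
    lo, hi = TRUTH_WINDOW
    return (offsets >= lo) & (offsets <= hi)


def _draw(rng, lo_hi):
    return float(rng.uniform(*lo_hi))


def _draw_scale(rng, lo_hi):
    """Log-uniform draw for a multiplicative scaling factor."""
    lo, hi = lo_hi
    if lo <= 0:
        raise ValueError("scaling-factor range must be positive")
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _record_from_pair(offsets, lab, ref, amide_delta, gen_params, seed):
    truth = ref - lab
    a, w = bloch.peak_amplitude_width(offsets, truth, amide_delta)
    mask = _truth_window_mask(offsets)
    return TrainingRecord(
        offsets=offsets,
        features=lab,
        target_A=a,
        target_W=w,
        truth_offsets=offsets[mask],
        truth_spectrum=truth[mask],
        gen_params=gen_params,
        seed=seed,
    )


def build_partial_synthetic(
    measured: MeasuredComponents,
    ranges: RangeConfig | None = None,
    acq: AcquisitionParams | None = None,
    n: int = 1,
    seed: int = 0,
) -> list[TrainingRecord]:
    """Compose ``n`` partially synthetic training records.

    Per record: draw amide/NOE exchange parameters, water relaxation and
    the scaling factors; evaluate the simulated R_ex^APT and R_ex^NOE
    lines and R_eff; combine them with the measured amine and MT
    components through the inverse-summation model.  The truth spectrum
    is the CESTR difference of the composed pair with and without the
    amide component.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = (ranges or DEFAULT_TRAINING_RANGES).validate()
    acq = acq or AcquisitionParams()
    offsets = acq.offsets_ppm
    if not np.array_equal(np.asarray(measured.offsets, float), offsets):
        raise ValueError("measured component grid does not match the acquisition grid")
    rng = np.random.default_rng(seed)
    w1 = acq.omega1_radps
    hpp = acq.hz_per_ppm

    out = []
    for i in range(n):
        params = {}
        pools = {}
        for name in ("amide", "noe35", "noe16"):
            r = getattr(ranges, name)
            p = {k: _draw(rng, v) for k, v in r.items()}
            params[name] = p
            pools[name] = PoolParams(
                name, p["fs"], p["ksw"], _POOL_DELTAS[name], R1s=1.0, R2s=1.0 / p["T2"]
            )
        t1w, t2w = _draw(rng, ranges.water["T1"]), _draw(rng, ranges.water["T2"])
        r_am = _draw_scale(rng, ranges.r_amines)
        r_mt = _draw_scale(rng, ranges.r_MT)
        params.update({
            "water": {"T1": t1w, "T2": t2w},
            "r_amines": r_am, "r_MT": r_mt, "fm": measured.fm,
        })

        r1w = 1.0 / t1w
        r1obs = r1obs_from_components(r1w, ranges.R1M, measured.fm, r_mt)
        tissue = TissueState(
            R1obs=r1obs, R1w=r1w, R2w=1.0 / t2w, R1M=ranges.R1M,
            fm=measured.fm, r_amines=r_am, r_MT=r_mt,
        )
        rex_apt = rex_slow(pools["amide"], w1, offsets, hpp)
        rex_noe = rex_slow(pools["noe35"], w1, offsets, hpp) + rex_slow(
            pools["noe16"], w1, offsets, hpp
        )
        comp = ComponentSpectra(
            offsets=offsets,
            Reff=reff(tissue, w1, offsets, hpp),
            Rex_apt=rex_apt,
            Rex_noe=rex_noe,
            Rex_amines=np.asarray(measured.Rex_amines, float),
            Rex_mt=np.asarray(measured.Rex_mt, float),
            provenance={"Rex_apt": "simulated", "Rex_noe": "simulated",
                        "Reff": "simulated", "Rex_amines": "fitted",
                        "Rex_mt": "fitted"},
        )
        lab = compose_zspectrum(comp, tissue, w1, offsets, hpp).values
        comp_ref = ComponentSpectra(
            offsets=offsets, Reff=comp.Reff, Rex_apt=np.zeros_like(offsets),
            Rex_noe=comp.Rex_noe, Rex_amines=comp.Rex_amines, Rex_mt=comp.Rex_mt,
        )
        ref = compose_zspectrum(comp_ref, tissue, w1, offsets, hpp).values
        out.append(_record_from_pair(offsets, lab, ref, 3.5, params, seed))
    return out


def build_fully_synthetic(
    ranges: RangeConfig | None = None,
    acq: AcquisitionParams | None = None,
    n: int = 1,
    seed: int = 0,
    variant: str = "type1",
) -> list[TrainingRecord]:
    """Bloch-McConnell training records over the full seven-pool model.

    ``variant='type1'`` draws the same parameters as the partially
    synthetic builder and maps the scaling factors onto pool sizes as
    amine f_s = 0.003·r_amine and MT f_m = 0.1·r_MT, keeping the
    guanidinium pool at its nominal size (n records).  ``'type2'``
    additionally varies the guanidinium pool size, producing three
    records per draw (3n records).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if variant not in ("type1", "type2"):
        raise ValueError("variant must be 'type1' or 'type2'")
    ranges = (ranges or DEFAULT_TRAINING_RANGES).validate()
    acq = acq or AcquisitionParams()
    offsets = acq.offsets_ppm
    rng = np.random.default_rng(seed)
    base = bloch.default_brain_pools()
    guan_range = bloch.TISSUE_MIMICKING_RANGES["guanidinium"]["fs"]

    out = []
    for i in range(n):
        params = {}
        drawn = {}
        for name in ("amide", "noe35", "noe16"):
            r = getattr(ranges, name)
            p = {k: _draw(rng, v) for k, v in r.items()}
            params[name] = p
            drawn[name] = base.get(name).with_(
                fs=p["fs"], ksw=p["ksw"], R2s=1.0 / p["T2"]
            )
        t1w, t2w = _draw(rng, ranges.water["T1"]), _draw(rng, ranges.water["T2"])
        r_am = _draw_scale(rng, ranges.r_amines)
        r_mt = _draw_scale(rng, ranges.r_MT)
        params.update({"water": {"T1": t1w, "T2": t2w},
                       "r_amines": r_am, "r_MT": r_mt})
        water = base.water.with_(R1s=1.0 / t1w, R2s=1.0 / t2w)
        amine = base.get("amine").with_(fs=0.003 * r_am)
        mt = base.get("mt").with_(fs=0.1 * r_mt)
        params["amine"] = {"fs": amine.fs}
        params["mt"] = {"fs": mt.fs}

        if variant == "type1":
            guan_fs = [base.get("guanidinium").fs]
        else:
            guan_fs = [guan_range[0],
                       0.5 * (guan_range[0] + guan_range[1]),
                       guan_range[1]]
        for gfs in guan_fs:
            guan = base.get("guanidinium").with_(fs=gfs)
            pools = bloch.PoolSet(water=water, solutes=(
                drawn["amide"], amine, guan, drawn["noe16"], drawn["noe35"], mt))
            z_lab = bloch.simulate_zspectrum(pools, acq)
            z_ref = bloch.simulate_zspectrum(pools.without("amide"), acq)
            rec_params = dict(params)
            rec_params["guanidinium"] = {"fs": gfs}
            out.append(_record_from_pair(
                offsets, z_lab.values, z_ref.values, 3.5, rec_params, seed))
    return out


def records_from_tissue_mimicking(samples) -> list[TrainingRecord]:
    """Convert ``sample_tissue_mimicking`` output into training records."""
    out = []
    for z, gt, params in samples:
        mask = _truth_window_mask(z.offsets)
        out.append(TrainingRecord(
            offsets=z.offsets, features=z.values,
            target_A=gt.A_true, target_W=gt.W_true,
            truth_offsets=z.offsets[mask], truth_spectrum=gt.spectrum[mask],
            gen_params=params,
        ))
    return out


def add_noise(records, sd: float, seed: int = 0) -> list[TrainingRecord]:
    """Add i.i.d. Gaussian noise to the feature spectra (targets untouched)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return list(records)
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        noisy = rec.features + rng.normal(0.0, sd, rec.features.shape)
        out.append(TrainingRecord(
            offsets=rec.offsets, features=noisy,
            target_A=rec.target_A, target_W=rec.target_W,
            truth_offsets=rec.truth_offsets, truth_spectrum=rec.truth_spectrum,
            gen_params=rec.gen_params, seed=rec.seed,
        ))
    return out


def pair_average_count(k: int, include_originals: bool = False) -> int:
    """Number of unordered pair averages of ``k`` spectra: k(k−1)/2."""
    if k < 2:
        raise ValueError("need at least 2 spectra to form pairs")
    n = math.comb(k, 2)
    return n + k if include_originals else n


def _as_value_matrix(spectra):
    mats, grid = [], None
    for s in spectra:
        off = s.offsets if isinstance(s, ZSpectrum) else np.asarray(s[0], float)
        val = s.values if isinstance(s, ZSpectrum) else np.asarray(s[1], float)
        if grid is None:
            grid = np.asarray(off, float)
        elif not np.array_equal(grid, off):
            raise ValueError("pair averaging requires a common offset grid")
        mats.append(np.asarray(val, float))
    return grid, np.asarray(mats)


def iter_pair_averages(spectra):
    """Lazily yield the mean of each unordered pair of spectra.

    For k inputs this yields k(k−1)/2 spectra without materializing them,
    which matters at in-vivo scale (k ≈ 2000 voxels → millions of pairs).
    """
    grid, vals = _as_value_matrix(spectra)
    k = vals.shape[0]
    for i in range(k - 1):
        for j in range(i + 1, k):
            yield ZSpectrum(grid, 0.5 * (vals[i] + vals[j]),
                            meta={"provenance": "pair-average", "pair": (i, j)})


def augment_pair_average(spectra, include_originals: bool = True):
    """Materialize the pair-average augmentation of a spectrum list.

    Returns the originals (optionally) followed by one averaged spectrum
    per unordered pair; use :func:`iter_pair_averages` /
    :func:`pair_average_count` for large inputs.
    """
    grid, vals = _as_value_matrix(spectra)
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 spectra to form pairs")
    out = [ZSpectrum(grid, v) for v in vals] if include_originals else []
    out.extend(iter_pair_averages(spectra))
    return out
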