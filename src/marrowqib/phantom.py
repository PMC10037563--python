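"""Synthetic multi-contrast tibia bone-marrow phantom generator.

Stands in for raw study data (available only on request): builds a
tubular marrow VOI with known proximal→distal gradients in ADC, PDFF and
MTR, synthesizes the three acquisitions from their forward signal models
(DWI mono-exponential decay, multi-peak chemical-shift MGE, MT-off/on
FLASH), and draws test–retest pairs and longitudinal cohorts whose
section-level truth values carry a specified within-subject SD — so the
repeatability module's recovery target is exact by construction, with
voxel noise (Rician for magnitude, complex Gaussian for MGE) on top.

Cohort defaults are the study's measured conditions: wild-type section
means, diseased longitudinal trajectories with between-animal SDs, and
the per-(QIB, section) within-subject SDs and repeatability
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .adc import DwiSet
from .fatwater import FatSpectrum, MultiEchoSeries, fat_modulation, mge_te_schedule
from .io_formats import ImageVolume
from .mtr import MtPair
from .sections import DEFAULT_SPANS_MM, SECTION_NAMES, SectionSet, parse_sections

QIB_NAMES = ("ADC", "PDFF", "MTR")

# --- Measured study conditions used as generator defaults -----------------

#: Within-subject SD per (QIB, section): ADC µm²/ms, PDFF %, MTR unitless.
WSD_BY_STRATUM: dict[tuple[str, str], float] = {
    ("ADC", "S1"): 0.013, ("ADC", "S2"): 0.031, ("ADC", "S3"): 0.011,
    ("PDFF", "S1"): 0.56, ("PDFF", "S2"): 5.58, ("PDFF", "S3"): 9.2,
    ("MTR", "S1"): 0.06, ("MTR", "S2"): 0.04, ("MTR", "S3"): 0.03,
}

#: Repeatability coefficient (2.77·wSD, as printed) per (QIB, section).
RC_BY_STRATUM: dict[tuple[str, str], float] = {
    ("ADC", "S1"): 0.037, ("ADC", "S2"): 0.087, ("ADC", "S3"): 0.030,
    ("PDFF", "S1"): 1.6, ("PDFF", "S2"): 15.5, ("PDFF", "S3"): 25.5,
    ("MTR", "S1"): 0.16, ("MTR", "S2"): 0.11, ("MTR", "S3"): 0.09,
}

#: Usable test–retest pair counts per (QIB, section).
N_PAIRS_BY_STRATUM: dict[tuple[str, str], int] = {
    ("ADC", "S1"): 33, ("ADC", "S2"): 29, ("ADC", "S3"): 20,
    ("PDFF", "S1"): 37, ("PDFF", "S2"): 27, ("PDFF", "S3"): 22,
    ("MTR", "S1"): 37, ("MTR", "S2"): 28, ("MTR", "S3"): 22,
}

#: Wild-type section means (and between-animal SDs) per QIB, (S1, S2, S3).
WT_SECTION_MEANS: dict[str, tuple[float, float, float]] = {
    "ADC": (0.15, 0.18, 0.11),
    "PDFF": (4.8, 9.6, 17.7),
    "MTR": (0.56, 0.55, 0.38),
}
WT_SECTION_SDS: dict[str, tuple[float, float, float]] = {
    "ADC": (0.03, 0.06, 0.05),
    "PDFF": (0.2, 0.7, 3.9),
    "MTR": (0.03, 0.04, 0.09),
}

#: Diseased cohort trajectories: (QIB, section) → {weeks: (mean, between-animal SD)}.
#: Timepoints are window midpoints of the biweekly schedule; ADC has no
#: b=3000 acquisition at weeks 3–4, hence no entry there.
DISEASED_TRAJECTORIES: dict[tuple[str, str], dict[float, tuple[float, float]]] = {
    ("ADC", "S1"): {5.5: (0.28, 0.02), 7.5: (0.31, 0.02), 9.5: (0.33, 0.01),
                    11.5: (0.32, 0.02), 13.5: (0.33, 0.01)},
    ("ADC", "S2"): {5.5: (0.11, 0.03), 7.5: (0.13, 0.04), 9.5: (0.20, 0.03),
                    11.5: (0.21, 0.06), 13.5: (0.27, 0.04)},
    ("ADC", "S3"): {5.5: (0.08, 0.05), 7.5: (0.06, 0.02), 9.5: (0.06, 0.01),
                    11.5: (0.07, 0.02), 13.5: (0.09, 0.01)},
    ("PDFF", "S1"): {3.5: (4.4, 0.8), 5.5: (3.5, 0.6), 7.5: (3.3, 0.6),
                     9.5: (3.0, 0.5), 11.5: (3.7, 0.9), 13.5: (4.2, 3.9)},
    ("PDFF", "S2"): {3.5: (34.2, 12.3), 5.5: (26.0, 7.0), 7.5: (18.5, 9.4),
                     9.5: (18.3, 8.5), 11.5: (13.3, 5.1), 13.5: (9.7, 6.2)},
    ("PDFF", "S3"): {3.5: (53.8, 14.0), 5.5: (48.1, 7.1), 7.5: (45.4, 16.9),
                     9.5: (47.4, 16.3), 11.5: (46.3, 16.5), 13.5: (46.0, 23.3)},
    ("MTR", "S1"): {3.5: (0.57, 0.14), 5.5: (0.56, 0.08), 7.5: (0.59, 0.03),
                    9.5: (0.60, 0.04), 11.5: (0.60, 0.03), 13.5: (0.61, 0.01)},
    ("MTR", "S2"): {3.5: (0.22, 0.07), 5.5: (0.31, 0.12), 7.5: (0.33, 0.13),
                    9.5: (0.37, 0.12), 11.5: (0.44, 0.08), 13.5: (0.50, 0.10)},
    ("MTR", "S3"): {3.5: (0.12, 0.02), 5.5: (0.21, 0.13), 7.5: (0.17, 0.06),
                    9.5: (0.19, 0.07), 11.5: (0.21, 0.07), 13.5: (0.26, 0.08)},
}

_QIB_RANGES = {"ADC": (0.0, np.inf), "PDFF": (0.0, 100.0), "MTR": (0.0, 1.0)}


# --- Geometry and truth ----------------------------------------------------


@dataclass
class PhantomGeometry:
    """Tubular marrow VOI in a 3D grid (z = tibia long axis).

    Defaults: 64³ voxels at 0.1×0.1×0.3 mm (z covers 18.9 mm, enough for
    the 13.5 mm section span), a 0.8 mm diameter marrow tube (<1 mm, as
    in the mouse tibia), and a wider bulge near the proximal end that
    fixes the section origin slice.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.3)
    tube_radius_mm: float = 0.4
    bulge_slice: int = 10
    bulge_radius_mm: float = 0.7


def make_voi_mask(geom: PhantomGeometry | None = None) -> np.ndarray:
    geom = geom or PhantomGeometry()
    nx, ny, nz = geom.shape
    dx, dy, _ = geom.spacing
    cx, cy = (nx - 1) / 2 * dx, (ny - 1) / 2 * dy
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    mask = np.zeros(geom.shape, dtype=bool)
    mask[...] = (r2 <= geom.tube_radius_mm**2)[:, :, None]
    mask[:, :, geom.bulge_slice] = r2 <= geom.bulge_radius_mm**2
    return mask


@dataclass
class PhantomTruth:
    """Ground-truth biomarker fields plus the VOI/section decomposition."""

    adc_true: ImageVolume
    pdff_true: ImageVolume
    mtr_true: ImageVolume
    fieldmap_true: ImageVolume
    w_true: ImageVolume
    f_true: ImageVolume
    voi_mask: np.ndarray
    section_set: SectionSet
    section_values: dict[str, tuple[float, float, float]]
    geometry: PhantomGeometry


def _z_profile(section_values, spans_mm, origin_slice, nz, dz) -> np.ndarray:
    """Per-slice value: constant inside each section span, linear between."""
    z = (np.arange(nz) - origin_slice) * dz
    knots_z, knots_v = [], []
    for name, v in zip(SECTION_NAMES, section_values):
        lo, hi = spans_mm[name]
        knots_z += [lo, hi]
        knots_v += [v, v]
    return np.interp(z, knots_z, knots_v)


def make_phantom_truth(
    section_values: Mapping[str, tuple[float, float, float]],
    geometry: PhantomGeometry | None = None,
    field_amplitude_hz: float = 20.0,
    s0_mge: float = 100.0,
) -> PhantomTruth:
    """Truth fields whose section means equal the requested values.

    ``section_values`` maps QIB name → (S1, S2, S3) values.  Fields vary
    only along z: constant within each section span (so section-mask
    means match the request exactly) and linearly interpolated across
    the guard bands.  The B0 field map is a low-order 3D polynomial
    scaled to ``field_amplitude_hz`` peak amplitude.
    """
    geometry = geometry or PhantomGeometry()
    for qib, vals in section_values.items():
        lo, hi = _QIB_RANGES[qib]
        if any(not (lo <= v < hi if qib == "MTR" else lo <= v <= hi) for v in vals):
            raise ValueError(f"{qib} section values {vals} outside physical range")

    voi = make_voi_mask(geometry)
    section_set = parse_sections(voi, geometry.spacing)
    nz, dz = geometry.shape[2], geometry.spacing[2]
    origin = section_set.origin_slice_index

    def field_for(qib):
        prof = _z_profile(section_values[qib], section_set.spans_mm, origin, nz, dz)
        return np.broadcast_to(prof[None, None, :], geometry.shape).copy()

    adc = field_for("ADC")
    pdff = field_for("PDFF")
    mtr = field_for("MTR")

    nx, ny, _ = geometry.shape
    xn = np.linspace(-1, 1, nx)[:, None, None]
    yn = np.linspace(-1, 1, ny)[None, :, None]
    zn = np.linspace(-1, 1, nz)[None, None, :]
    poly = 0.35 + 0.40 * zn + 0.15 * xn * yn + 0.10 * (zn**2 - 0.5) + 0.0 * xn
    poly = np.broadcast_to(poly, geometry.shape).copy()
    peak = np.abs(poly).max()
    fieldmap = field_amplitude_hz * poly / peak if field_amplitude_hz > 0 else np.zeros_like(poly)

    f_true = s0_mge * pdff / 100.0
    w_true = s0_mge * (1.0 - pdff / 100.0)
    spacing = geometry.spacing
    vol = lambda a: ImageVolume(a, spacing)
    return PhantomTruth(
        adc_true=vol(adc), pdff_true=vol(pdff), mtr_true=vol(mtr),
        fieldmap_true=vol(fieldmap), w_true=vol(w_true), f_true=vol(f_true),
        voi_mask=voi, section_set=section_set,
        section_values={q: tuple(v) for q, v in section_values.items()},
        geometry=geometry,
    )


# --- Forward signal models -------------------------------------------------


def _rician(signal: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    if noise_sd == 0:
        return signal.copy()
    re = signal + noise_sd * rng.standard_normal(signal.shape)
    im = noise_sd * rng.standard_normal(signal.shape)
    return np.hypot(re, im)


def synthesize_dwi(
    truth: PhantomTruth,
    b_values: tuple[float, float, float] = (3000.0, 3000.0, 3000.0),
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DwiSet:
    """DWI set from S(b) = S0·exp(−b·ADC·10⁻³), Rician noise per volume.

    b in s/mm², ADC truth in µm²/ms (hence the 10⁻³ unit bridge); the
    signal is supported on the VOI.
    """
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    if any(b < 0 for b in b_values):
        raise ValueError("b-values must be >= 0")
    rng = rng or np.random.default_rng()
    adc = truth.adc_true.data
    support = truth.voi_mask.astype(float)
    vols = []
    for b in (0.0, *b_values):
        clean = s0 * np.exp(-b * adc * 1e-3) * support
        vols.append(truth.adc_true.with_data(_rician(clean, noise_sd, rng)))
    s_b0, s_bx, s_by, s_bz = vols
    return DwiSet(s_b0, s_bx, s_by, s_bz, *b_values)


def synthesize_mge(
    truth: PhantomTruth,
    te_schedule_ms: list[list[float]] | None = None,
    r2star_per_ms: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    spectrum: FatSpectrum | None = None,
    center_frequency_mhz: float = 300.0,
) -> list[MultiEchoSeries]:
    """Staggered 3-echo series from the multi-peak water–fat signal model.

    s(TE) = (W + F·Σ α_p e^{i2πf_p TE})·e^{i2πψTE}·e^{−R2*·TE}, complex
    Gaussian noise per echo.  Returns one ``MultiEchoSeries`` per
    acquisition series (merge with :func:`~marrowqib.fatwater.combine_series`).
    """
    rng = rng or np.random.default_rng()
    spectrum = spectrum or FatSpectrum()
    te_schedule_ms = te_schedule_ms or mge_te_schedule()
    w = truth.w_true.data * truth.voi_mask
    f = truth.f_true.data * truth.voi_mask
    psi = truth.fieldmap_true.data
    series = []
    for te_list in te_schedule_ms:
        echoes = []
        for te in te_list:
            c = fat_modulation(np.array([te]), spectrum, center_frequency_mhz)[0]
            s = (w + f * c) * np.exp(2j * np.pi * psi * te * 1e-3) * np.exp(-r2star_per_ms * te)
            if noise_sd > 0:
                s = s + noise_sd * (
                    rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
                )
            echoes.append(truth.w_true.with_data(s))
        series.append(MultiEchoSeries(echoes, list(te_list), center_frequency_mhz))
    return series


def synthesize_mt_pair(
    truth: PhantomTruth,
    s_off: float = 100.0,
    noise_sd: float = 0.0,
    coil_falloff: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MtPair:
    """MT-off/on pair: MTon = MToff·(1 − MTR_true), Rician noise.

    ``coil_falloff`` in [0, 1) linearly attenuates MToff toward the
    distal (high-z) end, emulating the receive-coil sensitivity drop
    that degrades distal-section SNR.
    """
    if s_off <= 0:
        raise ValueError("s_off must be > 0")
    if not (0 <= coil_falloff < 1):
        raise ValueError("coil_falloff must be in [0, 1)")
    rng = rng or np.random.default_rng()
    nz = truth.geometry.shape[2]
    profile = 1.0 - coil_falloff * np.arange(nz) / max(nz - 1, 1)
    off_clean = s_off * profile[None, None, :] * truth.voi_mask
    on_clean = off_clean * (1.0 - truth.mtr_true.data)
    mt_off = truth.mtr_true.with_data(_rician(off_clean, noise_sd, rng))
    mt_on = truth.mtr_true.with_data(_rician(on_clean, noise_sd, rng))
    return MtPair(mt_off, mt_on, noise_sd=noise_sd if noise_sd > 0 else None)


@dataclass
class SimulatedStudy:
    """One synthetic imaging session: all contrasts plus the truth."""

    dwi: DwiSet
    mge_series: list[MultiEchoSeries]
    mt: MtPair
    voi_mask: np.ndarray
    truth: PhantomTruth
    animal_id: str = "A00"
    session_role: str = "test"
    weeks_post_ablation: float = 0.0
    cohort: str = "diseased"


def simulate_study(
    section_values: Mapping[str, tuple[float, float, float]],
    geometry: PhantomGeometry | None = None,
    field_amplitude_hz: float = 20.0,
    noise_sd_dwi: float = 0.0,
    noise_sd_mge: float = 0.0,
    noise_sd_mt: float = 0.0,
    coil_falloff: float = 0.0,
    rng: np.random.Generator | None = None,
    **meta,
) -> SimulatedStudy:
    """Full multi-contrast synthetic session for given section truths."""
    rng = rng or np.random.default_rng()
    truth = make_phantom_truth(section_values, geometry, field_amplitude_hz)
    return SimulatedStudy(
        dwi=synthesize_dwi(truth, noise_sd=noise_sd_dwi, rng=rng),
        mge_series=synthesize_mge(truth, noise_sd=noise_sd_mge, rng=rng),
        mt=synthesize_mt_pair(truth, noise_sd=noise_sd_mt, coil_falloff=coil_falloff, rng=rng),
        voi_mask=truth.voi_mask,
        truth=truth,
        **meta,
    )


# --- Test–retest and longitudinal cohorts (section-value level) ------------


def _clip_to_range(qib: str, value: float) -> float:
    lo, hi = _QIB_RANGES[qib]
    eps = 1e-9
    return float(np.clip(value, lo, hi - eps if np.isfinite(hi) else np.inf))


def draw_session_values(
    animal_values: Mapping[tuple[str, str], float],
    wsd: Mapping[tuple[str, str], float],
    rng: np.random.Generator,
) -> dict[tuple[str, str], float]:
    """One session's section truths: animal value + N(0, wSD²) per stratum.

    Independent draws per session give SD(retest − test) = √2·wSD, the
    within-subject model the repeatability statistics assume.
    """
    out = {}
    for key, v in animal_values.items():
        sd = float(wsd.get(key, 0.0))
        if sd < 0:
            raise ValueError("wSD target must be >= 0")
        out[key] = _clip_to_range(key[0], v + sd * rng.standard_normal())
    return out


def make_test_retest_pair(
    animal_values: Mapping[tuple[str, str], float],
    wsd_target: Mapping[tuple[str, str], float],
    rng: np.random.Generator,
) -> tuple[dict, dict]:
    """Paired consecutive-day sessions (test, retest) of one animal."""
    test = draw_session_values(animal_values, wsd_target, rng)
    retest = draw_session_values(animal_values, wsd_target, rng)
    return test, retest


@dataclass
class CohortConfig:
    """Longitudinal cohort description (defaults: the diseased cohort).

    ``trajectories`` maps (QIB, section) → {weeks: (mean, between-animal
    SD)}; ``wsd`` is the visit-level within-subject SD per stratum.
    """

    n_animals: int = 13
    cohort: str = "diseased"
    trajectories: dict = field(default_factory=lambda: dict(DISEASED_TRAJECTORIES))
    wsd: dict = field(default_factory=lambda: dict(WSD_BY_STRATUM))
    timepoints_weeks: tuple | None = None  # None: each stratum's own schedule
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.wsd.values()):
            raise ValueError("wSD values must be >= 0")
        for key, traj in self.trajectories.items():
            if any(sd < 0 for _, sd in traj.values()):
                raise ValueError(f"between-animal SDs must be >= 0 ({key})")
            if self.timepoints_weeks is not None:
                missing = set(self.timepoints_weeks) - set(traj)
                if missing:
                    raise ValueError(f"timepoints {sorted(missing)} not in trajectory {key}")


def wildtype_cohort_config(
    n_animals: int = 6, timepoints_weeks=(7.5, 9.5, 11.5, 13.5), seed: int = 0
) -> CohortConfig:
    """Non-ablated wild-type cohort: time-constant section trajectories."""
    traj = {}
    for qib in QIB_NAMES:
        for s_idx, section in enumerate(SECTION_NAMES):
            traj[(qib, section)] = {
                w: (WT_SECTION_MEANS[qib][s_idx], WT_SECTION_SDS[qib][s_idx])
                for w in timepoints_weeks
            }
    return CohortConfig(n_animals=n_animals, cohort="wildtype", trajectories=traj, seed=seed)


def make_longitudinal_cohort(config: CohortConfig) -> pd.DataFrame:
    """Per-scan section values for a cohort: trajectory + animal offset + visit noise.

    Animal-level offsets are drawn once per (animal, QIB, section) with
    the trajectory's first-timepoint between-animal SD; visit noise has
    SD wSD.  Deterministic under a fixed config seed (per-animal
    substreams).  Columns: animal_id, cohort, weeks, qib, section,
    truth_value, value.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_animals)
    rows = []
    for a in range(config.n_animals):
        rng = np.random.default_rng(streams[a])
        for (qib, section), traj in sorted(config.trajectories.items()):
            weeks_sorted = (
                sorted(traj) if config.timepoints_weeks is None
                else sorted(config.timepoints_weeks)
            )
            offset_sd = traj[weeks_sorted[0]][1]
            offset = offset_sd * rng.standard_normal()
            visit_sd = float(config.wsd.get((qib, section), 0.0))
            for w in weeks_sorted:
                mean, _ = traj[w]
                truth_v = _clip_to_range(qib, mean + offset)
                meas = _clip_to_range(qib, truth_v + visit_sd * rng.standard_normal())
                rows.append(
                    dict(
                        animal_id=f"{config.cohort[:2].upper()}{a:02d}",
                        cohort=config.cohort,
                        weeks=w,
                        qib=qib,
                        section=section,
                        truth_value=truth_v,
                        value=meas,
                    )
                )
    return pd.DataFrame(rows)
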