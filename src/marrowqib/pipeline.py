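"""End-to-end orchestration: manifests ↔ disk, maps, section statistics.

Glue between the synthetic generator / on-disk studies and the map,
section and statistics modules; the CLI is a thin wrapper over these
functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .adc import DwiSet, compute_adc_map
from .fatwater import (
    FatSpectrum,
    FatWaterResult,
    MultiEchoSeries,
    combine_series,
    decompose_water_fat,
    estimate_fieldmap,
    pdff_quality_flags,
)
from .io_formats import (
    ImageVolume,
    QibMap,
    StudyManifest,
    read_complex_volume,
    read_volume,
    write_complex_volume,
    write_volume,
)
from .mtr import MtPair, compute_mtr_map, estimate_noise_sd
from .phantom import SimulatedStudy
from .sections import SectionSet, SectionStat, apply_section_qc, parse_sections, section_mean


@dataclass
class MapConfig:
    """Pipeline parameters for one study's map generation."""

    foreground_dilation_voxels: int = 2  # DWI reference-mean region = dilated VOI
    fieldmap_range_hz: float = 600.0
    fieldmap_step_hz: float = 10.0
    fieldmap_smoothness: float = 0.05
    fieldmap_refine: bool = True
    mtr_snr_threshold: float = 20.0
    mtr_noise_sd: float | None = None  # None: estimate from background


def dilated_foreground(voi: np.ndarray, voxels: int) -> np.ndarray:
    if voxels <= 0:
        return np.asarray(voi, dtype=bool)
    return ndimage.binary_dilation(voi, iterations=voxels)


def compute_maps(
    dwi: DwiSet,
    mge_series: list[MultiEchoSeries],
    mt: MtPair,
    voi: np.ndarray,
    config: MapConfig | None = None,
    spectrum: FatSpectrum | None = None,
):
    """ADC, PDFF, MTR maps (plus trace DWI and water/fat diagnostics)."""
    config = config or MapConfig()
    foreground = dilated_foreground(voi, config.foreground_dilation_voxels)

    adc_map, trace = compute_adc_map(dwi, foreground)

    merged = combine_series(mge_series)
    fieldmap = estimate_fieldmap(
        merged,
        voi,
        spectrum=spectrum,
        psi_range_hz=config.fieldmap_range_hz,
        psi_step_hz=config.fieldmap_step_hz,
        smoothness_weight=config.fieldmap_smoothness,
        refine=config.fieldmap_refine,
    )
    fw = decompose_water_fat(merged, fieldmap, voi, spectrum=spectrum)

    pair = mt
    if config.mtr_noise_sd is not None:
        pair = MtPair(mt.mt_off, mt.mt_on, noise_sd=config.mtr_noise_sd)
    elif pair.noise_sd is None:
        background = ~dilated_foreground(voi, config.foreground_dilation_voxels + 2)
        sd = estimate_noise_sd(mt.mt_off, background)
        if sd == 0 and mt.mt_off.data.any():
            # noise-free input: nominal sigma so every signal pixel passes the gate
            sd = 1e-12 * float(mt.mt_off.data.max())
        pair = MtPair(mt.mt_off, mt.mt_on, noise_sd=sd)
    mtr_map = compute_mtr_map(pair, snr_threshold=config.mtr_snr_threshold)

    return {"ADC": adc_map, "PDFF": fw.pdff, "MTR": mtr_map, "trace_dwi": trace, "fatwater": fw}


def session_section_stats(
    maps: dict,
    voi: np.ndarray,
    spacing: tuple[float, float, float],
    manual_exclusions: set[tuple[str, str]] | None = None,
    section_set: SectionSet | None = None,
) -> tuple[list[SectionStat], SectionSet]:
    """Section means for the three QIB maps, with section-level QC applied."""
    section_set = section_set or parse_sections(voi, spacing)
    stats: list[SectionStat] = []
    for qib in ("ADC", "PDFF", "MTR"):
        for name, mask in section_set.masks.items():
            stats.append(section_mean(maps[qib], mask, section=name))
    fw: FatWaterResult = maps["fatwater"]
    flags = pdff_quality_flags(fw, section_set.masks)
    stats = apply_section_qc(stats, pdff_flags=flags, manual_exclusions=manual_exclusions)
    return stats, section_set


def process_study(study: SimulatedStudy, config: MapConfig | None = None):
    """Maps + QC'd section stats for one (simulated or loaded) study."""
    maps = compute_maps(study.dwi, study.mge_series, study.mt, study.voi_mask, config)
    spacing = study.dwi.s_b0.spacing
    stats, section_set = session_section_stats(maps, study.voi_mask, spacing)
    return maps, stats, section_set


# ---------------------------------------------------------------------------
# Disk round-trip


def save_study(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Write a study's volumes as MHD plus a JSON manifest; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dwi_paths = {}
    for key, vol in (
        ("b0", study.dwi.s_b0), ("bx", study.dwi.s_bx),
        ("by", study.dwi.s_by), ("bz", study.dwi.s_bz),
    ):
        dwi_paths[key] = str(write_volume(vol, out / f"dwi_{key}.mhd"))
    mge_paths, mge_tes = [], []
    for i, series in enumerate(study.mge_series):
        for j, (echo, te) in enumerate(zip(series.echoes, series.te_ms)):
            write_complex_volume(echo, out / f"mge_s{i}_e{j}.mhd")
        mge_paths.append(str(out / f"mge_s{i}"))
        mge_tes.append(list(series.te_ms))
    mt_paths = {
        "off": str(write_volume(study.mt.mt_off, out / "mt_off.mhd")),
        "on": str(write_volume(study.mt.mt_on, out / "mt_on.mhd")),
    }
    voi_path = str(write_volume(
        ImageVolume(study.voi_mask.astype(np.uint8), study.dwi.s_b0.spacing),
        out / "voi.mhd",
    ))
    manifest = StudyManifest(
        animal_id=study.animal_id,
        session_role=study.session_role,
        weeks_post_ablation=study.weeks_post_ablation,
        cohort=study.cohort,
        dwi_paths=dwi_paths,
        b_values={"bx": study.dwi.b_x, "by": study.dwi.b_y, "bz": study.dwi.b_z},
        mge_paths=mge_paths,
        mge_te_ms=mge_tes,
        mt_paths=mt_paths,
        voi_path=voi_path,
    )
    return manifest.to_json(out / "manifest.json")


def load_study(manifest_path: str | Path) -> SimulatedStudy:
    """Load a saved study back into memory (truth is not persisted)."""
    m = StudyManifest.from_json(manifest_path)
    dwi = DwiSet(
        read_volume(m.dwi_paths["b0"]),
        read_volume(m.dwi_paths["bx"]),
        read_volume(m.dwi_paths["by"]),
        read_volume(m.dwi_paths["bz"]),
        m.b_values["bx"], m.b_values["by"], m.b_values["bz"],
    )
    mge_series = []
    for base, tes in zip(m.mge_paths, m.mge_te_ms):
        echoes = [read_complex_volume(f"{base}_e{j}.mhd") for j in range(len(tes))]
        mge_series.append(MultiEchoSeries(echoes, list(tes)))
    mt = MtPair(read_volume(m.mt_paths["off"]), read_volume(m.mt_paths["on"]))
    voi = read_volume(m.voi_path).data > 0
    return SimulatedStudy(
        dwi=dwi, mge_series=mge_series, mt=mt, voi_mask=voi, truth=None,
        animal_id=m.animal_id, session_role=m.session_role,
        weeks_post_ablation=m.weeks_post_ablation, cohort=m.cohort,
    )


def save_maps(maps: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    named: list[tuple[str, ImageVolume]] = [
        ("ADC.mhd", maps["ADC"].values),
        ("ADC_valid.mhd", maps["ADC"].values.with_data(maps["ADC"].valid_mask.astype(np.uint8))),
        ("DWI_trace.mhd", maps["trace_dwi"]),
        ("PDFF.mhd", maps["PDFF"].values),
        ("MTR.mhd", maps["MTR"].values),
        ("MTR_valid.mhd", maps["MTR"].values.with_data(maps["MTR"].valid_mask.astype(np.uint8))),
    ]
    fw: FatWaterResult = maps["fatwater"]
    named += [
        ("W.mhd", fw.w_map), ("F.mhd", fw.f_map),
        ("B0.mhd", fw.fieldmap), ("meanMGE.mhd", fw.mean_mge),
    ]
    for name, vol in named:
        write_volume(vol, out / name)
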