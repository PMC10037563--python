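"""Chemical-shift water–fat decomposition (PDFF) from merged multi-echo data.

Four 3-echo complex gradient-echo series, acquired with staggered first
echo times and identical gains, are merged and sorted by TE into one
12-echo train.  At each voxel the signal is modeled as

    s(TE) = (W + F · Σ_p α_p · e^{i·2π·f_p·TE}) · e^{i·2π·ψ·TE}

with complex water W and fat F amplitudes, a multi-peak fat spectrum
(relative amplitudes α_p summing to 1, resonance offsets f_p in Hz at
the scanner's proton frequency), and an off-resonance field map ψ (Hz).

Field-map estimation is the classic discretize-and-smooth approach: the
variable-projection residual of the linear W/F fit is evaluated on a
candidate ψ grid, then a globally optimal smooth labeling minimizing
``Σ residual(ψ_v) + λ·Σ |ψ_v − ψ_u|`` is found by a single min-cut
(exact for this convex pairwise term; see ``_mrf``), optionally followed
by continuous per-voxel refinement.  PDFF = 100·|F|/(|W|+|F|).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._mrf import mrf_energy, solve_ishikawa
from .io_formats import GridMismatchError, ImageVolume, QibMap

WATER_PPM = 4.70
DEFAULT_CENTER_FREQ_MHZ = 300.0  # 7 T proton frequency

#: First-echo TEs (ms) of the four staggered gradient-echo series and the
#: constant intra-series echo spacing (ms).
DEFAULT_FIRST_TES_MS = (1.476, 1.793, 2.110, 2.427)
DEFAULT_INTRA_SPACING_MS = 2.174
DEFAULT_ECHOES_PER_SERIES = 3


@dataclass
class FatSpectrum:
    """Multi-peak triglyceride ¹H spectrum, relative amplitudes summing to 1."""

    shifts_ppm: tuple[float, ...] = (0.90, 1.30, 1.60, 2.02, 2.24, 2.75, 4.20)
    amplitudes: tuple[float, ...] = (0.088, 0.642, 0.058, 0.062, 0.058, 0.006, 0.086)

    def __post_init__(self) -> None:
        if len(self.shifts_ppm) != len(self.amplitudes):
            raise ValueError("shifts and amplitudes differ in length")
        total = sum(self.amplitudes)
        if not np.isclose(total, 1.0, atol=1e-6):
            self.amplitudes = tuple(a / total for a in self.amplitudes)

    def offsets_hz(self, center_frequency_mhz: float = DEFAULT_CENTER_FREQ_MHZ) -> np.ndarray:
        """Resonance offsets relative to water, in Hz (fat peaks negative)."""
        return (np.asarray(self.shifts_ppm) - WATER_PPM) * center_frequency_mhz

    @classmethod
    def from_json(cls, path: str | Path) -> "FatSpectrum":
        peaks = json.loads(Path(path).read_text())
        return cls(
            shifts_ppm=tuple(p["shift_ppm"] for p in peaks),
            amplitudes=tuple(p["amplitude"] for p in peaks),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                [
                    {"shift_ppm": s, "amplitude": a}
                    for s, a in zip(self.shifts_ppm, self.amplitudes)
                ],
                indent=2,
            )
        )
        return path


def fat_modulation(
    te_ms: np.ndarray,
    spectrum: FatSpectrum,
    center_frequency_mhz: float = DEFAULT_CENTER_FREQ_MHZ,
) -> np.ndarray:
    """Complex fat dephasing factor c(TE) = Σ_p α_p exp(i2π f_p TE)."""
    te_s = np.asarray(te_ms, dtype=float) * 1e-3
    f_hz = spectrum.offsets_hz(center_frequency_mhz)
    amps = np.asarray(spectrum.amplitudes)
    return (amps[None, :] * np.exp(2j * np.pi * f_hz[None, :] * te_s[:, None])).sum(axis=1)


def mge_te_schedule(
    first_tes_ms=DEFAULT_FIRST_TES_MS,
    intra_spacing_ms: float = DEFAULT_INTRA_SPACING_MS,
    echoes_per_series: int = DEFAULT_ECHOES_PER_SERIES,
) -> list[list[float]]:
    """TE list (ms) per series for the staggered acquisition scheme."""
    return [
        [te0 + n * intra_spacing_ms for n in range(echoes_per_series)] for te0 in first_tes_ms
    ]


@dataclass
class MultiEchoSeries:
    """Complex echo volumes with a strictly increasing TE list (ms)."""

    echoes: list[ImageVolume]
    te_ms: list[float]
    center_frequency_mhz: float = DEFAULT_CENTER_FREQ_MHZ

    def __post_init__(self) -> None:
        if len(self.echoes) != len(self.te_ms):
            raise ValueError("echo count and TE count differ")
        if np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("TE list must be strictly increasing")
        grid = self.echoes[0]
        for e in self.echoes[1:]:
            if not grid.same_grid(e):
                raise GridMismatchError("echo volumes on different grids")

    @property
    def n_echoes(self) -> int:
        return len(self.echoes)

    def signals(self, mask: np.ndarray) -> np.ndarray:
        """Stack masked voxel signals into an (n_echoes, n_voxels) matrix."""
        return np.stack([e.data[mask] for e in self.echoes]).astype(complex)


def combine_series(series_list: list[MultiEchoSeries]) -> MultiEchoSeries:
    """Merge staggered series into one TE-sorted train (no rescaling).

    The receiver/transmit gains are held constant across series, so the
    echoes are pooled as-is and only sorted by TE.  Duplicate TEs or
    inconsistent grids are rejected.
    """
    if not series_list:
        raise ValueError("no series given")
    f0 = series_list[0].center_frequency_mhz
    grid = series_list[0].echoes[0]
    echoes, tes = [], []
    for s in series_list:
        if s.center_frequency_mhz != f0:
            raise ValueError("series differ in center frequency")
        for e, te in zip(s.echoes, s.te_ms):
            if not grid.same_grid(e):
                raise GridMismatchError("series on different grids")
            echoes.append(e)
            tes.append(float(te))
    order = np.argsort(tes)
    tes_sorted = [tes[i] for i in order]
    if np.any(np.diff(tes_sorted) < 1e-6):
        raise ValueError("duplicate echo times across series")
    return MultiEchoSeries([echoes[i] for i in order], tes_sorted, f0)


# ---------------------------------------------------------------------------
# Field-map estimation


def _projection_complement(te_ms, spectrum, f0) -> np.ndarray:
    """N×N matrix B = I − A·pinv(A) for the linear W/F design A = [1, c]."""
    c = fat_modulation(np.asarray(te_ms), spectrum, f0)
    A = np.stack([np.ones_like(c), c], axis=1)  # (N, 2)
    return np.eye(len(c)) - A @ np.linalg.pinv(A)


def residual_landscape(
    signals: np.ndarray,
    te_ms,
    spectrum: FatSpectrum,
    psi_grid_hz: np.ndarray,
    center_frequency_mhz: float = DEFAULT_CENTER_FREQ_MHZ,
) -> np.ndarray:
    """Variable-projection residual ‖(I−P)·D(ψ)·s‖² per voxel and candidate ψ.

    Returns an (n_voxels, n_candidates) array; the per-voxel argmin is the
    brute-force (smoothness-free) field-map estimate.
    """
    te_s = np.asarray(te_ms, dtype=float) * 1e-3
    B = _projection_complement(te_ms, spectrum, center_frequency_mhz)
    out = np.empty((signals.shape[1], len(psi_grid_hz)))
    for l, psi in enumerate(np.asarray(psi_grid_hz, dtype=float)):
        demod = np.exp(-2j * np.pi * psi * te_s)[:, None] * signals
        out[:, l] = np.abs(B @ demod).__pow__(2).sum(axis=0)
    return out


def _mask_edges(mask: np.ndarray) -> np.ndarray:
    """6-neighborhood edge list (pairs of flat in-mask voxel ids)."""
    idx = -np.ones(mask.shape, dtype=np.intp)
    idx[mask] = np.arange(int(mask.sum()))
    pairs = []
    for axis in range(3):
        a = np.take(idx, np.arange(mask.shape[axis] - 1), axis=axis)
        b = np.take(idx, np.arange(1, mask.shape[axis]), axis=axis)
        ok = (a >= 0) & (b >= 0)
        pairs.append(np.stack([a[ok], b[ok]], axis=1))
    return np.concatenate(pairs) if pairs else np.empty((0, 2), dtype=np.intp)


def _refine_continuous(signals, te_ms, spectrum, f0, psi_hz, half_window_hz, iters=60):
    """Vectorized golden-section refinement of per-voxel ψ within ±window."""
    te_s = np.asarray(te_ms, dtype=float) * 1e-3
    B = _projection_complement(te_ms, spectrum, f0)

    def res_at(psi_v):
        demod = np.exp(-2j * np.pi * psi_v[None, :] * te_s[:, None]) * signals
        return np.abs(B @ demod).__pow__(2).sum(axis=0)

    inv_phi = (np.sqrt(5.0) - 1.0) / 2.0
    lo = psi_hz - half_window_hz
    hi = psi_hz + half_window_hz
    for _ in range(iters):
        x1 = hi - inv_phi * (hi - lo)
        x2 = lo + inv_phi * (hi - lo)
        left = res_at(x1) < res_at(x2)
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
    return (lo + hi) / 2.0


def estimate_fieldmap(
    series: MultiEchoSeries,
    mask: np.ndarray,
    spectrum: FatSpectrum | None = None,
    psi_range_hz: float = 600.0,
    psi_step_hz: float = 2.0,
    smoothness_weight: float = 0.05,
    refine: bool = False,
    return_energy: bool = False,
):
    """Smooth off-resonance map ψ (Hz) over the mask.

    The candidate grid spans ±``psi_range_hz`` in ``psi_step_hz`` steps.
    The pairwise cost per grid step of ψ difference between 6-neighbors
    is ``smoothness_weight`` times the median per-voxel residual range,
    so the default follows the data scale.  With ``refine`` the discrete
    labels are polished by bounded golden-section search (±1 step),
    removing the grid quantization on smooth fields.

    Returns the field map as an :class:`ImageVolume` (zero outside the
    mask); with ``return_energy`` also the labeling energy and the
    per-voxel unary matrix (for oracle comparisons).
    """
    if series.n_echoes < 3:
        raise ValueError("need at least 3 echoes to separate W, F and psi")
    mask = np.asarray(mask, dtype=bool)
    grid_vol = series.echoes[0]
    if mask.shape != grid_vol.shape:
        raise GridMismatchError("mask not on the series grid")
    spectrum = spectrum or FatSpectrum()
    psi_grid = np.arange(-psi_range_hz, psi_range_hz + psi_step_hz / 2, psi_step_hz)

    signals = series.signals(mask)
    unary = residual_landscape(
        signals, series.te_ms, spectrum, psi_grid, series.center_frequency_mhz
    )
    ranges = unary.max(axis=1) - unary.min(axis=1)
    lam = smoothness_weight * float(np.median(ranges))
    edges = _mask_edges(mask)
    if lam > 0 and len(edges):
        labels = solve_ishikawa(unary, edges, lam)
    else:
        labels = np.argmin(unary, axis=1)
    psi = psi_grid[labels]

    if refine:
        psi = _refine_continuous(
            signals, series.te_ms, spectrum, series.center_frequency_mhz, psi, psi_step_hz
        )

    out = np.zeros(mask.shape)
    out[mask] = psi
    fieldmap = grid_vol.with_data(out)
    if return_energy:
        return fieldmap, mrf_energy(labels, unary, edges, lam), unary, lam, edges
    return fieldmap


# ---------------------------------------------------------------------------
# Decomposition


@dataclass
class FatWaterResult:
    """Water/fat magnitudes, PDFF map, field map, and diagnostics."""

    w_map: ImageVolume
    f_map: ImageVolume
    fieldmap: ImageVolume
    pdff: QibMap
    mean_mge: ImageVolume
    rel_residual: ImageVolume = None  # fit residual / signal energy, per voxel
    mask: np.ndarray = field(default=None)


def decompose_water_fat(
    series: MultiEchoSeries,
    fieldmap: ImageVolume,
    mask: np.ndarray,
    spectrum: FatSpectrum | None = None,
) -> FatWaterResult:
    """Per-voxel linear least-squares W/F solve given the field map.

    Demodulates the field-map phase, solves ``s·e^{−i2πψTE} = W + F·c(TE)``
    for complex W, F, and reports magnitude maps and
    PDFF = 100·|F|/(|W|+|F|) (zero, invalid, where |W|+|F| = 0).
    """
    mask = np.asarray(mask, dtype=bool)
    grid_vol = series.echoes[0]
    if not grid_vol.same_grid(fieldmap):
        raise GridMismatchError("fieldmap not on the series grid")
    spectrum = spectrum or FatSpectrum()
    te_s = np.asarray(series.te_ms) * 1e-3
    c = fat_modulation(np.asarray(series.te_ms), spectrum, series.center_frequency_mhz)
    A = np.stack([np.ones_like(c), c], axis=1)
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("rank-deficient W/F design: degenerate TE set")
    pinvA = np.linalg.pinv(A)

    signals = series.signals(mask)
    demod = np.exp(-2j * np.pi * fieldmap.data[mask][None, :] * te_s[:, None]) * signals
    wf = pinvA @ demod  # (2, V) complex
    w_abs, f_abs = np.abs(wf[0]), np.abs(wf[1])
    fit = A @ wf
    energy = np.abs(demod).__pow__(2).sum(axis=0)
    resid = np.abs(demod - fit).__pow__(2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(energy > 0, resid / energy, 0.0)

    def vol(flat):
        out = np.zeros(mask.shape)
        out[mask] = flat
        return grid_vol.with_data(out)

    total = w_abs + f_abs
    pdff_flat = np.where(total > 0, 100.0 * f_abs / np.where(total > 0, total, 1.0), 0.0)
    valid = np.zeros(mask.shape, dtype=bool)
    valid[mask] = total > 0
    pdff = QibMap(vol(pdff_flat), kind="PDFF", units="%", valid_mask=valid)
    mean_mge = grid_vol.with_data(
        np.mean([np.abs(e.data) for e in series.echoes], axis=0)
    )
    return FatWaterResult(
        w_map=vol(w_abs),
        f_map=vol(f_abs),
        fieldmap=fieldmap,
        pdff=pdff,
        mean_mge=mean_mge,
        rel_residual=vol(rel),
        mask=mask,
    )


def pdff_quality_flags(
    result: FatWaterResult,
    section_masks: dict[str, np.ndarray],
    roughness_threshold_hz: float = 20.0,
    residual_fraction_threshold: float = 0.2,
    residual_rel_cut: float = 0.25,
) -> dict[str, bool]:
    """Automated proxy for visual screening of water–fat decomposition errors.

    A section is flagged when the median absolute field-map difference
    between 6-neighbors inside the section exceeds
    ``roughness_threshold_hz`` (checkerboard/swap signature), or when the
    fraction of section voxels with relative fit residual above
    ``residual_rel_cut`` exceeds ``residual_fraction_threshold``.
    Thresholds of ``inf`` disable flagging.
    """
    flags = {}
    psi = result.fieldmap.data
    rel = result.rel_residual.data
    for name, smask in section_masks.items():
        smask = np.asarray(smask, dtype=bool)
        if not smask.any():
            flags[name] = False
            continue
        edges = _mask_edges(smask)
        psi_flat = psi[smask]
        roughness = (
            float(np.median(np.abs(psi_flat[edges[:, 0]] - psi_flat[edges[:, 1]])))
            if len(edges)
            else 0.0
        )
        bad_frac = float((rel[smask] > residual_rel_cut).mean())
        flags[name] = bool(
            roughness > roughness_threshold_hz or bad_frac > residual_fraction_threshold
        )
    return flags
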