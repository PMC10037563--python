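"""Apparent diffusion coefficient maps from a directional DWI set.

The acquisition provides a b=0 volume plus one diffusion-weighted volume
per gradient axis (nominal b = 3000 s/mm²; the actual per-axis b-values
are manifest inputs).  Per direction j,

    ADC_j = (1/b_j) · ln(S_b0 / S_bj)            [mm²/s → ×10³ µm²/ms]

and the isotropic ADC is the arithmetic mean over the three directions.
The trace DWI is the voxelwise geometric mean of the three directional
diffusion-weighted volumes.

Pixel exclusions: a pixel is kept only if, in every direction, its
diffusion-weighted signal is at least 20% of the mean diffusion-weighted
signal over the foreground region AND its b=0 signal is not lower than
the diffusion-weighted signal (which would imply a negative ADC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GridMismatchError, ImageVolume, QibMap

MM2_PER_S_TO_UM2_PER_MS = 1e3


@dataclass
class DwiSet:
    """b=0 plus three directional DWI volumes with per-axis b-values (s/mm²)."""

    s_b0: ImageVolume
    s_bx: ImageVolume
    s_by: ImageVolume
    s_bz: ImageVolume
    b_x: float = 3000.0
    b_y: float = 3000.0
    b_z: float = 3000.0

    def __post_init__(self) -> None:
        for name in ("s_bx", "s_by", "s_bz"):
            if not self.s_b0.same_grid(getattr(self, name)):
                raise GridMismatchError(f"{name} not on the b0 grid")
        if min(self.b_x, self.b_y, self.b_z) <= 0:
            raise ValueError("directional b-values must be > 0")

    @property
    def directional(self):
        return ((self.s_bx, self.b_x), (self.s_by, self.b_y), (self.s_bz, self.b_z))


def dwi_exclusion_mask(dwi: DwiSet, foreground: np.ndarray) -> np.ndarray:
    """Combined validity mask for ADC computation.

    Kept iff for every direction j: ``s_bj >= 0.2 * mean(s_bj | foreground)``
    and ``s_b0 >= s_bj``; intersected with the foreground mask.  The 20%
    reference mean is recomputed per direction over the foreground.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.shape != dwi.s_b0.shape:
        raise GridMismatchError("foreground mask not on the DWI grid")
    if not foreground.any():
        raise ValueError("empty foreground mask")
    keep = foreground.copy()
    for s_bj, _b in dwi.directional:
        ref = float(s_bj.data[foreground].mean())
        keep &= s_bj.data >= 0.2 * ref
        keep &= dwi.s_b0.data >= s_bj.data
    return keep


def directional_adc(
    s_b0: ImageVolume, s_bj: ImageVolume, b_j: float, valid: np.ndarray
) -> QibMap:
    """Directional ADC map in µm²/ms, computed on valid pixels only."""
    if b_j <= 0:
        raise ValueError("b_j must be > 0")
    if not s_b0.same_grid(s_bj):
        raise GridMismatchError("b0 and bj volumes on different grids")
    valid = np.asarray(valid, dtype=bool)
    num, den = s_b0.data[valid], s_bj.data[valid]
    if np.any(den <= 0) or np.any(num <= 0):
        raise ValueError("nonpositive signal on a valid pixel; exclusion mask must prevent this")
    out = np.zeros(s_b0.shape, dtype=float)
    out[valid] = (1.0 / b_j) * np.log(num / den) * MM2_PER_S_TO_UM2_PER_MS
    return QibMap(s_b0.with_data(out), kind="ADC", units="um^2/ms", valid_mask=valid)


def isotropic_adc(adc_x: QibMap, adc_y: QibMap, adc_z: QibMap) -> QibMap:
    """Arithmetic mean of the three directional ADC maps (shared mask)."""
    if not (
        np.array_equal(adc_x.valid_mask, adc_y.valid_mask)
        and np.array_equal(adc_x.valid_mask, adc_z.valid_mask)
    ):
        raise GridMismatchError("directional ADC maps carry different valid masks")
    mean = (adc_x.values.data + adc_y.values.data + adc_z.values.data) / 3.0
    mean[~adc_x.valid_mask] = 0.0
    return QibMap(adc_x.values.with_data(mean), "ADC", "um^2/ms", adc_x.valid_mask)


def trace_dwi(s_bx: ImageVolume, s_by: ImageVolume, s_bz: ImageVolume) -> ImageVolume:
    """Voxelwise geometric mean of the directional DWI volumes."""
    if not (s_bx.same_grid(s_by) and s_bx.same_grid(s_bz)):
        raise GridMismatchError("directional DWI volumes on different grids")
    stack = np.stack([s_bx.data, s_by.data, s_bz.data])
    if np.any(stack < 0):
        raise ValueError("negative DWI intensities")
    return s_bx.with_data(np.cbrt(stack[0] * stack[1] * stack[2]))


def compute_adc_map(dwi: DwiSet, foreground: np.ndarray) -> tuple[QibMap, ImageVolume]:
    """Full ADC pipeline: exclusions → directional maps → isotropic mean.

    Returns the isotropic ADC map and the trace DWI.
    """
    valid = dwi_exclusion_mask(dwi, foreground)
    maps = [directional_adc(dwi.s_b0, s_bj, b_j, valid) for s_bj, b_j in dwi.directional]
    return isotropic_adc(*maps), trace_dwi(dwi.s_bx, dwi.s_by, dwi.s_bz)
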