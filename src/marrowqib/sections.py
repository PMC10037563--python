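"""Tibia bone-marrow section parsing and section-level statistics/QC.

The VOI mask is split into three sections by z-distance from an origin
slice: the axial slice holding the largest in-VOI pixel count is assigned
z = 0 mm (ties break to the smallest index), and a voxel belongs to a
section when its slice-center z-distance, measured distally from the
origin, falls inclusively within the section span:

    S1: 1.8–9.0 mm   S2: 9.8–11.7 mm   S3: 12.6–13.5 mm

The 9.0–9.8 and 11.7–12.6 mm gaps are guard bands; voxels there belong
to no section.  Section-level QC automatically eliminates ADC section
means below 0.05 µm²/ms and MTR section means below 0.1 (strict
inequalities); PDFF sections are eliminated by decomposition-artifact
flags or a manual exclusion list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import GridMismatchError, QibMap

#: Section z-spans in mm measured distally from the origin slice (inclusive).
DEFAULT_SPANS_MM: dict[str, tuple[float, float]] = {
    "S1": (1.8, 9.0),
    "S2": (9.8, 11.7),
    "S3": (12.6, 13.5),
}

ADC_MIN_SECTION_MEAN = 0.05  # um^2/ms
MTR_MIN_SECTION_MEAN = 0.1

SECTION_NAMES = ("S1", "S2", "S3")


@dataclass
class SectionSet:
    """Disjoint section masks plus the origin slice they are measured from."""

    origin_slice_index: int
    masks: dict[str, np.ndarray]
    spans_mm: dict[str, tuple[float, float]]

    def labels_volume(self) -> np.ndarray:
        """Label image: 1/2/3 for S1/S2/S3, 0 elsewhere."""
        out = np.zeros(next(iter(self.masks.values())).shape, dtype=np.uint8)
        for i, name in enumerate(SECTION_NAMES, start=1):
            out[self.masks[name]] = i
        return out


@dataclass
class SectionStat:
    """Mean QIB value over one section's valid pixels, with QC status."""

    qib_kind: str
    section: str
    mean: float  # NaN when no valid pixels
    n_valid_pixels: int
    qc_pass: bool = True
    exclusion_reason: str = "none"


def parse_sections(
    voi: np.ndarray,
    spacing: tuple[float, float, float],
    spans_mm: dict[str, tuple[float, float]] | None = None,
    z_direction: int = +1,
) -> SectionSet:
    """Split a VOI mask into S1/S2/S3 by slice-center z-distance.

    ``z_direction`` is the sign of increasing distal position along the
    array's last axis (+1: distal = increasing slice index).
    """
    voi = np.asarray(voi, dtype=bool)
    if voi.ndim != 3:
        raise ValueError("VOI mask must be 3D")
    if not voi.any():
        raise ValueError("empty VOI mask")
    if z_direction not in (+1, -1):
        raise ValueError("z_direction must be +1 or -1")
    spans = dict(spans_mm) if spans_mm is not None else dict(DEFAULT_SPANS_MM)
    dz = float(spacing[2])

    counts = voi.sum(axis=(0, 1))
    origin = int(np.argmax(counts))  # np.argmax: first (smallest) index on ties
    z_mm = (np.arange(voi.shape[2]) - origin) * dz * z_direction

    masks = {}
    tol = 1e-6  # mm; keeps inclusive bounds robust to float slice arithmetic
    for name, (lo, hi) in spans.items():
        in_span = (z_mm >= lo - tol) & (z_mm <= hi + tol)
        masks[name] = voi & in_span[None, None, :]
    if all(not m.any() for m in masks.values()):
        warnings.warn("VOI does not extend into any section span", stacklevel=2)
    return SectionSet(origin_slice_index=origin, masks=masks, spans_mm=spans)


def section_mean(qib_map: QibMap, section_mask: np.ndarray, section: str = "") -> SectionStat:
    """Mean over voxels in the section that survive the map's validity mask."""
    section_mask = np.asarray(section_mask, dtype=bool)
    if section_mask.shape != qib_map.values.shape:
        raise GridMismatchError("section mask not on the map grid")
    use = section_mask & qib_map.valid_mask
    n = int(use.sum())
    mean = float(qib_map.values.data[use].mean()) if n else float("nan")
    return SectionStat(qib_kind=qib_map.kind, section=section, mean=mean, n_valid_pixels=n)


def apply_section_qc(
    stats: list[SectionStat],
    pdff_flags: dict[str, bool] | None = None,
    manual_exclusions: set[tuple[str, str]] | None = None,
    adc_min: float = ADC_MIN_SECTION_MEAN,
    mtr_min: float = MTR_MIN_SECTION_MEAN,
) -> list[SectionStat]:
    """Apply automatic and manual section-level exclusions.

    ``pdff_flags`` maps section name → artifact flag (from the water–fat
    QC proxy); ``manual_exclusions`` holds (qib_kind, section) pairs.
    Idempotent: re-applying changes nothing.
    """
    pdff_flags = pdff_flags or {}
    manual_exclusions = manual_exclusions or set()
    out = []
    for st in stats:
        reason = "none"
        if st.n_valid_pixels == 0 or not np.isfinite(st.mean):
            reason = "no_data"
        elif (st.qib_kind, st.section) in manual_exclusions:
            reason = "manual"
        elif st.qib_kind == "ADC" and np.isfinite(st.mean) and st.mean < adc_min:
            reason = "low_adc"
        elif st.qib_kind == "MTR" and np.isfinite(st.mean) and st.mean < mtr_min:
            reason = "low_mtr"
        elif st.qib_kind == "PDFF" and pdff_flags.get(st.section, False):
            reason = "pdff_artifact"
        elif st.exclusion_reason != "none":
            reason = st.exclusion_reason  # keep previous verdict (idempotence)
        out.append(replace(st, qc_pass=reason == "none", exclusion_reason=reason))
    return out
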