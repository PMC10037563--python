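"""Image volumes, MetaImage (MHD) I/O, study manifests, and result tables.

Axis convention used throughout the package: array index ``(i, j, k)``
corresponds to spatial ``(x, y, z)`` with ``z`` (the last axis) the tibia
long axis, i.e. the axial-slice stacking direction.  MetaImage files store
their raw payload x-fastest, so arrays are transposed on read/write.

Complex volumes (multi-echo gradient-echo data) are stored as paired real
``*_real.mhd`` / imaginary ``*_imag.mhd`` files, since MetaImage has no
complex element type.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk


class FormatError(ValueError):
    """Malformed or unsupported image header."""


class GridMismatchError(ValueError):
    """Volumes expected on a common grid disagree in dims or spacing."""


@dataclass
class ImageVolume:
    """A 3D scalar (real or complex) grid with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities, arbitrary units.  Complex dtype only for
        multi-echo series.
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel size in mm; strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise FormatError("every axis must have extent >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=0, atol=tol
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """New volume sharing this grid geometry."""
        return ImageVolume(data, self.spacing, self.origin)


@dataclass
class QibMap:
    """A quantitative-imaging-biomarker volume plus its validity mask.

    ``values`` is zero wherever ``valid_mask`` is 0.  Units: ADC in
    µm²/ms, PDFF in percent, MTR dimensionless.
    """

    values: ImageVolume
    kind: str  # "ADC" | "PDFF" | "MTR"
    units: str
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise GridMismatchError("valid_mask shape differs from values")
        v = self.values.data
        if not np.all(np.isfinite(v[self.valid_mask])):
            raise ValueError("non-finite values on valid pixels")


# ---------------------------------------------------------------------------
# MetaImage read/write


def _check_mhd_header(path: Path) -> None:
    """Light pre-validation of the MHD text header (NDims, element type)."""
    try:
        text = path.read_text(errors="replace")
    except OSError as exc:
        raise OSError(f"cannot read header {path}: {exc}") from exc
    fields = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    if "NDims" not in fields:
        raise FormatError(f"{path}: missing NDims in MHD header")
    if fields["NDims"] != "3":
        raise FormatError(f"{path}: NDims={fields['NDims']}, expected 3")


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D MetaImage (or any ITK-readable) volume.

    Raises ``FormatError`` for malformed headers and ``OSError`` for
    truncated / unreadable payloads.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    if path.suffix.lower() == ".mhd":
        _check_mhd_header(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        msg = str(exc)
        if "Premature end" in msg or "File is too small" in msg or "read" in msg.lower():
            raise OSError(f"truncated or unreadable payload for {path}: {msg}") from exc
        raise FormatError(f"cannot parse {path}: {msg}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected 3 dimensions, got {img.GetDimension()}")
    # sitk arrays are indexed [z, y, x]; our convention is [x, y, z]
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a real-valued volume as MHD (header + raw pair).

    Complex volumes must go through :func:`write_complex_volume`.
    """
    if vol.is_complex:
        raise ValueError("complex volume: use write_complex_volume")
    path = Path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    try:
        sitk.WriteImage(img, str(path), useCompression=False)
    except RuntimeError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


def _complex_pair_paths(path: Path) -> tuple[Path, Path]:
    stem = path.name[: -len(path.suffix)] if path.suffix else path.name
    return (path.with_name(stem + "_real.mhd"), path.with_name(stem + "_imag.mhd"))


def write_complex_volume(vol: ImageVolume, path: str | Path) -> tuple[Path, Path]:
    """Store a complex volume as a ``*_real.mhd`` / ``*_imag.mhd`` pair."""
    re_path, im_path = _complex_pair_paths(Path(path))
    write_volume(vol.with_data(np.real(vol.data).astype(np.float64)), re_path)
    write_volume(vol.with_data(np.imag(vol.data).astype(np.float64)), im_path)
    return re_path, im_path


def read_complex_volume(path: str | Path) -> ImageVolume:
    re_path, im_path = _complex_pair_paths(Path(path))
    re_vol = read_volume(re_path)
    im_vol = read_volume(im_path)
    if not re_vol.same_grid(im_vol):
        raise GridMismatchError(f"real/imag grids differ for {path}")
    return re_vol.with_data(re_vol.data + 1j * im_vol.data)


# ---------------------------------------------------------------------------
# Study manifests


@dataclass
class StudyManifest:
    """Paths + metadata for one imaging session of one animal.

    All referenced volumes must live on a single grid (the acquisitions
    are spatially linked), which :meth:`validate` checks.
    """

    animal_id: str
    session_role: str  # "test" | "retest"
    weeks_post_ablation: float
    cohort: str  # "diseased" | "wildtype"
    dwi_paths: dict[str, str] = field(default_factory=dict)  # b0, bx, by, bz
    b_values: dict[str, float] = field(default_factory=dict)  # bx, by, bz in s/mm^2
    mge_paths: list[str] = field(default_factory=list)  # complex base paths, 4 series
    mge_te_ms: list[list[float]] = field(default_factory=list)  # TE list per series
    mt_paths: dict[str, str] = field(default_factory=dict)  # off, on
    voi_path: str = ""

    def __post_init__(self) -> None:
        if self.session_role not in ("test", "retest"):
            raise ValueError(f"session_role must be test|retest, got {self.session_role!r}")
        if self.cohort not in ("diseased", "wildtype"):
            raise ValueError(f"cohort must be diseased|wildtype, got {self.cohort!r}")
        if self.weeks_post_ablation < 0:
            raise ValueError("weeks_post_ablation must be >= 0")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyManifest":
        return cls(**json.loads(Path(path).read_text()))

    def iter_volume_paths(self):
        for p in self.dwi_paths.values():
            yield p, False
        for p in self.mge_paths:
            yield p, True
        for p in self.mt_paths.values():
            yield p, False
        if self.voi_path:
            yield self.voi_path, False

    def validate(self) -> None:
        """Check that every referenced volume shares one grid."""
        ref: ImageVolume | None = None
        for p, is_complex in self.iter_volume_paths():
            vol = read_complex_volume(p) if is_complex else read_volume(p)
            if ref is None:
                ref = vol
            elif not ref.same_grid(vol):
                raise GridMismatchError(
                    f"{p}: grid {vol.shape}/{vol.spacing} differs from "
                    f"{ref.shape}/{ref.spacing}"
                )


# ---------------------------------------------------------------------------
# Result tables


def write_results_table(records: Sequence, path: str | Path) -> Path:
    """Write homogeneous result records (dataclasses or dicts) to CSV.

    Values round-trip at full float precision (pandas writes full repr).
    An empty record list yields a header-only file when the schema can be
    inferred, otherwise an empty file with no rows.
    """
    rows = []
    schema: tuple | None = None
    for rec in records:
        row = dataclasses.asdict(rec) if dataclasses.is_dataclass(rec) else dict(rec)
        keys = tuple(row.keys())
        if schema is None:
            schema = keys
        elif keys != schema:
            raise ValueError(f"mixed record schemas: {keys} vs {schema}")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(schema) if schema else None)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
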