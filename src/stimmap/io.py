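"""Spatial data model and readers/writers for the standard formats the pipeline touches.

All internal coordinates are template-space millimetres.  Voxel indices are
0-based and the volume affine is the single source of truth for the
voxel-to-world mapping.  Streamline files (TRK/TCK) are read and written
through :mod:`nibabel.streamlines`; a plain JSON point-list dialect is also
supported so that small fixtures stay text-only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, GridMismatchError, SchemaError

DEFAULT_FRAME = "MNI-like synthetic"

# Cohort CSV schema.  Mandatory columns must be present; optional columns are
# added as all-NaN when absent so downstream code never sees silent zeros.
COHORT_MANDATORY = ("patient_id", "updrs3_pre", "updrs3_post")
COHORT_OPTIONAL = ("ledd_pre", "ledd_post", "followup_years", "cohort_label", "arm")


@dataclass
class Volume:
    """A 3-D scalar grid with an affine into template-space mm.

    ``data`` units are context dependent: V/mm for E-fields, dimensionless
    for correlation maps and {0,1} masks.
    """

    data: np.ndarray
    affine: np.ndarray
    frame: str = DEFAULT_FRAME

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(
                f"volume data must be 3-D with positive dimensions, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible (header field: affine/srow)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) 0-based voxel indices to mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) mm coordinates to continuous 0-based voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """World mm coordinates of every voxel centre, shape (*shape, 3)."""
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        ijk = np.stack([ii, jj, kk], axis=-1)
        return self.voxel_to_world(ijk)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def require_same_grid(self, other: "Volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: shape {self.shape} vs {other.shape} or affines disagree"
            )
        if self.frame != other.frame:
            warnings.warn(
                f"template frame mismatch: {self.frame!r} vs {other.frame!r}", stacklevel=3
            )

    def is_mask(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume on this grid holding ``data``."""
        return Volume(np.asarray(data), self.affine.copy(), self.frame)


def _validate_streamline(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 2:
        raise FormatError(f"streamline must be an (n>=2, 3) point list, got shape {points.shape}")
    if np.any(np.all(np.diff(points, axis=0) == 0, axis=1)):
        raise FormatError("streamline has repeated consecutive points")
    return points


@dataclass
class Tractogram:
    """Streamlines in template-space mm with optional per-streamline Fiber-R-Scores."""

    streamlines: list[np.ndarray]
    fiber_r: np.ndarray | None = None
    unscored: np.ndarray | None = None
    frame: str = DEFAULT_FRAME

    def __post_init__(self) -> None:
        self.streamlines = [_validate_streamline(s) for s in self.streamlines]
        if self.fiber_r is not None:
            self.fiber_r = np.asarray(self.fiber_r, dtype=float)
            if len(self.fiber_r) != len(self.streamlines):
                raise FormatError("fiber_r length must equal number of streamlines")
            if np.any(np.abs(self.fiber_r) > 1 + 1e-12):
                raise FormatError("fiber_r values must lie in [-1, 1]")
        if self.unscored is not None:
            self.unscored = np.asarray(self.unscored, dtype=bool)
            if len(self.unscored) != len(self.streamlines):
                raise FormatError("unscored length must equal number of streamlines")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class ElectrodeStim:
    """Active-contact position and stimulation parameters for one hemisphere of one patient."""

    patient_id: str
    contact_mm: np.ndarray
    amplitude: float
    amplitude_unit: str = "V"  # "V" or "mA"
    pulse_width_us: float = 60.0
    frequency_hz: float = 130.0
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.contact_mm = np.asarray(self.contact_mm, dtype=float).reshape(3)
        if self.amplitude <= 0 or self.pulse_width_us <= 0 or self.frequency_hz <= 0:
            raise FormatError("amplitude, pulse width and frequency must all be > 0")
        if self.hemisphere not in ("left", "right"):
            raise FormatError(f"hemisphere must be left|right, got {self.hemisphere!r}")


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path: str | Path, frame: str = DEFAULT_FRAME) -> Volume:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume(data, np.asarray(img.affine), frame)


def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    data = vol.data
    # keep integer masks bit-identical through the round trip
    dtype = data.dtype if np.issubdtype(data.dtype, np.integer) else np.float32
    if np.issubdtype(data.dtype, np.floating) and data.dtype.itemsize >= 8:
        dtype = np.float64
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), vol.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Tractograms (TRK / TCK / JSON dialect)


def read_tractogram(path: str | Path, frame: str = DEFAULT_FRAME) -> Tractogram:
    path = Path(path)
    suffix = path.name.lower()
    if suffix.endswith(".json"):
        return _read_tractogram_json(path, frame)
    if suffix.endswith((".trk", ".tck")):
        try:
            tf = nib.streamlines.load(str(path))
        except Exception as exc:
            raise FormatError(f"cannot read streamline file {path}: {exc}") from exc
        streamlines = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
        fiber_r = None
        dps = tf.tractogram.data_per_streamline
        if "fiber_r" in dps:
            fiber_r = np.asarray(dps["fiber_r"], dtype=float).reshape(-1)
        elif _sidecar(path).exists():  # TCK cannot embed per-streamline scalars
            fiber_r = np.asarray(json.loads(_sidecar(path).read_text()), dtype=float)
        return Tractogram(streamlines, fiber_r=fiber_r, frame=frame)
    raise FormatError(f"unknown streamline file extension: {path.name}")


def write_tractogram(tract: Tractogram, path: str | Path) -> Path:
    path = Path(path)
    suffix = path.name.lower()
    if suffix.endswith(".json"):
        payload: dict = {"streamlines": [s.tolist() for s in tract.streamlines]}
        if tract.fiber_r is not None:
            payload["fiber_r"] = tract.fiber_r.tolist()
        if tract.unscored is not None:
            payload["unscored"] = tract.unscored.astype(int).tolist()
        path.write_text(json.dumps(payload))
        return path
    if suffix.endswith((".trk", ".tck")):
        dps = {}
        if tract.fiber_r is not None and suffix.endswith(".trk"):
            dps["fiber_r"] = tract.fiber_r.reshape(-1, 1)
        nt = nib.streamlines.Tractogram(
            tract.streamlines, data_per_streamline=dps, affine_to_rasmm=np.eye(4)
        )
        nib.streamlines.save(nt, str(path))
        if tract.fiber_r is not None and suffix.endswith(".tck"):
            _sidecar(path).write_text(json.dumps(tract.fiber_r.tolist()))
        return path
    raise FormatError(f"unknown streamline file extension: {path.name}")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".fiber_r.json")


def _read_tractogram_json(path: Path, frame: str) -> Tractogram:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON streamline file {path}: {exc}") from exc
    if isinstance(payload, list):  # bare list-of-lists dialect
        payload = {"streamlines": payload}
    if "streamlines" not in payload:
        raise FormatError(f"{path}: JSON tractogram needs a 'streamlines' key")
    fiber_r = payload.get("fiber_r")
    unscored = payload.get("unscored")
    return Tractogram(
        [np.asarray(s, dtype=float) for s in payload["streamlines"]],
        fiber_r=None if fiber_r is None else np.asarray(fiber_r, dtype=float),
        unscored=None if unscored is None else np.asarray(unscored, dtype=bool),
        frame=frame,
    )


# ---------------------------------------------------------------------------
# Cohort tables and electrode descriptions


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV into a typed DataFrame.

    Mandatory columns: patient_id, updrs3_pre, updrs3_post.  Optional columns
    are added as NaN when absent.  Non-numeric placeholders ("N/A", "", ...)
    become NaN while their record is retained.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, na_values=["N/A", "NA", "n/a", ""])
    missing = [c for c in COHORT_MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table {path} missing mandatory columns: {missing}")
    for col in COHORT_OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
    numeric = ["updrs3_pre", "updrs3_post", "ledd_pre", "ledd_post", "followup_years"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_stims(path: str | Path) -> list[ElectrodeStim]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid stim JSON {path}: {exc}") from exc
    stims = []
    for rec in payload:
        try:
            stims.append(
                ElectrodeStim(
                    patient_id=str(rec["patient_id"]),
                    contact_mm=rec["contact_mm"],
                    amplitude=float(rec["amplitude"]),
                    amplitude_unit=rec.get("amplitude_unit", "V"),
                    pulse_width_us=float(rec.get("pulse_width_us", 60.0)),
                    frequency_hz=float(rec.get("frequency_hz", 130.0)),
                    hemisphere=rec.get("hemisphere", "left"),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"stim record missing field {exc}") from exc
    return stims


def write_stims(stims: Sequence[ElectrodeStim], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "patient_id": s.patient_id,
            "contact_mm": s.contact_mm.tolist(),
            "amplitude": s.amplitude,
            "amplitude_unit": s.amplitude_unit,
            "pulse_width_us": s.pulse_width_us,
            "frequency_hz": s.frequency_hz,
            "hemisphere": s.hemisphere,
        }
        for s in stims
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path
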