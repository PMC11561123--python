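"""Sweet-spot model: voxel-wise outcome correlation map and spatial rank-correlation scoring.

The model is built from a training cohort's E-fields and improvement scores:
a support mask keeps voxels reached by enough fields, and at each supported
voxel the across-patient correlation between local field magnitude and
clinical improvement is stored (the "R-map").  New patients are scored by
rank-correlating their field magnitudes with the R-map over the voxels their
field reaches — a Sweet Spot Score in [-1, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ConfigError, InputError
from .io import Volume, read_volume, write_volume

#: a patient score needs at least this many support voxels to be declared
MIN_SUPPORT_VOXELS = 10


@dataclass
class SweetSpotModel:
    rmap: Volume
    mask: Volume
    efield_threshold: float = 0.2
    min_n: int = 3
    statistic: str = "spearman"

    def __post_init__(self) -> None:
        self.rmap.require_same_grid(self.mask)
        if not self.mask.is_mask():
            raise ConfigError("support mask must be {0,1}-valued")
        if np.any(self.rmap.data[self.mask.data == 0] != 0):
            raise ConfigError("rmap must be zero outside the support mask")
        if np.any(np.abs(self.rmap.data) > 1 + 1e-9):
            raise ConfigError("rmap values must lie in [-1, 1]")
        if self.efield_threshold <= 0 or self.min_n < 1:
            raise ConfigError("efield_threshold must be > 0 and min_n >= 1")

    def peak_mm(self) -> np.ndarray:
        """World coordinate of the R-map argmax (the model's hot spot)."""
        idx = np.unravel_index(int(np.argmax(self.rmap.data)), self.rmap.shape)
        return self.rmap.voxel_to_world(np.asarray(idx))

    def save(self, out_dir: str | Path, prefix: str = "sweetspot") -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(self.rmap, out_dir / f"{prefix}_rmap.nii.gz")
        write_volume(self.mask, out_dir / f"{prefix}_mask.nii.gz")
        sidecar = {
            "efield_threshold": self.efield_threshold,
            "min_n": self.min_n,
            "statistic": self.statistic,
            "frame": self.rmap.frame,
        }
        (out_dir / f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))
        return out_dir

    @classmethod
    def load(cls, out_dir: str | Path, prefix: str = "sweetspot") -> "SweetSpotModel":
        out_dir = Path(out_dir)
        sidecar = json.loads((out_dir / f"{prefix}.json").read_text())
        frame = sidecar.pop("frame", None)
        rmap = read_volume(out_dir / f"{prefix}_rmap.nii.gz", frame=frame or "unknown")
        mask = read_volume(out_dir / f"{prefix}_mask.nii.gz", frame=frame or "unknown")
        mask = mask.like(np.rint(mask.data).astype(np.uint8))
        return cls(rmap=rmap, mask=mask, **sidecar)


@dataclass
class SweetSpotScore:
    patient_id: str
    rho: float  # NaN marks an undefined score (support too small)
    n_voxels: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def _check_cohort(efields: list[Volume]) -> None:
    if not efields:
        raise InputError("empty E-field cohort")
    for ef in efields[1:]:
        efields[0].require_same_grid(ef)


def build_support_mask(
    efields: list[Volume], threshold: float = 0.2, min_n: int = 3
) -> Volume:
    """Voxels reached (strictly above ``threshold`` V/mm) by at least ``min_n`` fields."""
    _check_cohort(efields)
    counts = np.zeros(efields[0].shape, dtype=np.int64)
    for ef in efields:
        counts += ef.data > threshold
    return efields[0].like((counts >= min_n).astype(np.uint8))


def _columnwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of x (n, m) against y (n,); zero-variance columns -> 0."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    num = xc.T @ yc
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def map_sweet_spot(
    efields: list[Volume],
    improvements: np.ndarray,
    mask: Volume | None = None,
    efield_threshold: float = 0.2,
    min_n: int = 3,
    statistic: str = "spearman",
) -> SweetSpotModel:
    """Fit the voxel-wise outcome-correlation map on the training cohort.

    ``improvements`` must be in improvement polarity (higher = clinically
    better), one value per E-field; positive R-map values then mark voxels
    where stronger stimulation associates with better outcome.  Voxels with
    zero across-patient variance in magnitude get r = 0.
    """
    _check_cohort(efields)
    improvements = np.asarray(improvements, dtype=float)
    if len(improvements) != len(efields):
        raise InputError("one improvement value per E-field required")
    if len(efields) < min_n:
        raise InputError(f"need at least min_n={min_n} patients, got {len(efields)}")
    if statistic not in ("spearman", "pearson"):
        raise ConfigError(f"unknown statistic {statistic!r}")
    if mask is None:
        mask = build_support_mask(efields, threshold=efield_threshold, min_n=min_n)
    else:
        efields[0].require_same_grid(mask)

    sel = mask.data > 0
    mags = np.stack([ef.data[sel] for ef in efields])  # (n_patients, n_voxels)
    if statistic == "spearman":
        mags = stats.rankdata(mags, axis=0)
        y = stats.rankdata(improvements)
    else:
        y = improvements
    r = _columnwise_pearson(mags, y)
    # zero-variance magnitude columns already 0; zero-variance outcome -> all 0
    rmap_data = np.zeros(mask.shape, dtype=float)
    rmap_data[sel] = r
    return SweetSpotModel(
        rmap=mask.like(rmap_data),
        mask=mask,
        efield_threshold=efield_threshold,
        min_n=min_n,
        statistic=statistic,
    )


def sweet_spot_score(
    efield: Volume,
    model: SweetSpotModel,
    support: str = "patient_threshold",
    patient_id: str = "",
) -> SweetSpotScore:
    """Spatial rank correlation between a patient's E-field and the R-map.

    Supports: ``patient_threshold`` (default; mask voxels where this patient's
    magnitude exceeds the model threshold), ``mask`` (all mask voxels), or
    ``union`` (mask voxels where the patient's field is nonzero).  Fewer than
    MIN_SUPPORT_VOXELS voxels yields an undefined score (NaN), never a 0.
    """
    efield.require_same_grid(model.rmap)
    in_mask = model.mask.data > 0
    if support == "patient_threshold":
        sel = in_mask & (efield.data > model.efield_threshold)
    elif support == "mask":
        sel = in_mask
    elif support == "union":
        sel = in_mask & (efield.data > 0)
    else:
        raise ConfigError(f"unknown support rule {support!r}")
    n = int(sel.sum())
    if n < MIN_SUPPORT_VOXELS:
        return SweetSpotScore(patient_id=patient_id, rho=float("nan"), n_voxels=n)
    rho = stats.spearmanr(efield.data[sel], model.rmap.data[sel]).statistic
    if np.isnan(rho):  # zero variance on the support
        return SweetSpotScore(patient_id=patient_id, rho=float("nan"), n_voxels=n)
    return SweetSpotScore(patient_id=patient_id, rho=float(rho), n_voxels=n)


def score_cohort(
    efields: dict[str, Volume], model: SweetSpotModel, support: str = "patient_threshold"
) -> list[SweetSpotScore]:
    return [
        sweet_spot_score(ef, model, support=support, patient_id=pid)
        for pid, ef in efields.items()
    ]
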