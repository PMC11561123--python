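"""Fiber filtering: per-streamline outcome correlations and weighted patient scores.

Model fitting assigns each atlas streamline a Fiber-R-Score — the
across-patient correlation between the peak E-field magnitude sampled along
the streamline and clinical improvement.  Validation scoring superimposes a
new patient's field on the scored tractogram and averages the Fiber-R-Scores
of the streamlines the field reaches, weighted by the mean field magnitude
along each (the "Weighted Mean of Fiber R-scores").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates

from .errors import ConfigError, InputError, StateError
from .io import Tractogram, Volume


@dataclass
class FiberScoreParams:
    """efield_threshold (V/mm) defines "the field reaches this streamline";
    min_exposed is the minimum number of patients whose field must reach a
    streamline for its Fiber-R-Score to be estimated (fewer -> unscored, r=0)."""

    efield_threshold: float = 0.2
    min_exposed: int = 3
    interpolation_order: int = 1  # trilinear

    def __post_init__(self) -> None:
        if self.efield_threshold <= 0:
            raise ConfigError("efield_threshold must be > 0")
        if self.min_exposed < 2:
            raise ConfigError("min_exposed must be >= 2")


@dataclass
class FiberScore:
    """Per-patient fiber-model scores; all NaN when no streamline is intersected.

    Three readings of "average magnitudes multiplied with the correlation
    weight of each intersected streamline" are reported.  With m_s the mean
    field magnitude along intersected streamline s and r_s its Fiber-R-Score:

    stim_weighted_mean_r : sum(m_s * r_s) / n_intersected — the validation
        coefficient the pipeline uses; keeps the stimulation-strength
        information, so under-stimulating a beneficial tract lowers it.
    weighted_mean_r : sum(m_s * r_s) / sum(m_s) — a convex (magnitude-
        normalized) mean of the intersected r_s values.
    weighted_sum_r : sum(m_s * r_s) — unnormalized, for sensitivity checks.
    """

    patient_id: str
    stim_weighted_mean_r: float
    weighted_mean_r: float
    weighted_sum_r: float
    n_intersected: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.stim_weighted_mean_r)


def _sample_magnitudes(efield: Volume, points_mm: np.ndarray, order: int = 1) -> np.ndarray:
    """Interpolated field magnitudes at world-space points; out-of-grid reads 0."""
    vox = efield.world_to_voxel(points_mm)
    return map_coordinates(
        np.asarray(efield.data, dtype=float), vox.T, order=order, mode="constant", cval=0.0
    )


def _per_streamline_stats(
    efield: Volume, tract: Tractogram, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """(peak, mean) interpolated magnitude per streamline, one field, one pass."""
    points = np.concatenate(tract.streamlines, axis=0)
    values = _sample_magnitudes(efield, points, order=order)
    starts = np.cumsum([0] + [len(s) for s in tract.streamlines])[:-1]
    peaks = np.maximum.reduceat(values, starts)
    sums = np.add.reduceat(values, starts)
    counts = np.asarray([len(s) for s in tract.streamlines], dtype=float)
    return peaks, sums / counts


def peak_magnitude_along(
    streamline: np.ndarray, efield: Volume, order: int = 1
) -> float:
    """Maximum trilinearly interpolated magnitude over the streamline's points."""
    return float(_sample_magnitudes(efield, np.asarray(streamline, float), order=order).max())


def mean_magnitude_along(streamline: np.ndarray, efield: Volume, order: int = 1) -> float:
    return float(_sample_magnitudes(efield, np.asarray(streamline, float), order=order).mean())


def fit_fiber_r(
    efields: list[Volume],
    improvements: np.ndarray,
    tractogram: Tractogram,
    params: FiberScoreParams | None = None,
) -> Tractogram:
    """Assign Fiber-R-Scores by correlating peak magnitudes with improvement.

    ``improvements`` must be in improvement polarity.  Streamlines reached
    (peak > threshold) by fewer than ``min_exposed`` patients, or with zero
    across-patient variance in peak magnitude, are flagged unscored with r = 0.
    """
    params = params or FiberScoreParams()
    improvements = np.asarray(improvements, dtype=float)
    if len(efields) < 3:
        raise InputError("fiber filtering needs a cohort of at least 3 patients")
    if len(improvements) != len(efields):
        raise InputError("one improvement value per E-field required")
    for ef in efields[1:]:
        efields[0].require_same_grid(ef)

    peaks = np.stack(
        [_per_streamline_stats(ef, tractogram, params.interpolation_order)[0] for ef in efields]
    )  # (n_patients, n_streamlines)
    exposed = (peaks > params.efield_threshold).sum(axis=0)
    variance_ok = peaks.std(axis=0) > 0

    ranks = stats.rankdata(peaks, axis=0)
    y = stats.rankdata(improvements)
    yc = y - y.mean()
    xc = ranks - ranks.mean(axis=0)
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, (xc.T @ yc) / np.where(den > 0, den, 1.0), 0.0)
    scored = (exposed >= params.min_exposed) & variance_ok
    fiber_r = np.where(scored, np.clip(r, -1.0, 1.0), 0.0)
    return replace(tractogram, fiber_r=fiber_r, unscored=~scored)


def weighted_fiber_score(
    efield: Volume,
    scored_tractogram: Tractogram,
    params: FiberScoreParams | None = None,
    patient_id: str = "",
) -> FiberScore:
    """Weighted Mean of Fiber R-scores for one patient's E-field.

    A streamline is intersected when its peak interpolated magnitude exceeds
    the threshold; see :class:`FiberScore` for the three coefficients
    computed over the intersected set.  No intersected streamlines ->
    undefined score (NaN), never a silent 0.
    """
    params = params or FiberScoreParams()
    if scored_tractogram.fiber_r is None:
        raise StateError("tractogram has no fiber_r; run fit_fiber_r first")
    peaks, means = _per_streamline_stats(efield, scored_tractogram, params.interpolation_order)
    hit = peaks > params.efield_threshold
    n_hit = int(hit.sum())
    if n_hit == 0:
        nan = float("nan")
        return FiberScore(patient_id, nan, nan, nan, 0)
    w = means[hit]
    r = scored_tractogram.fiber_r[hit]
    wsum = float(np.dot(w, r))
    return FiberScore(patient_id, wsum / n_hit, wsum / float(w.sum()), wsum, n_hit)


def score_cohort(
    efields: dict[str, Volume],
    scored_tractogram: Tractogram,
    params: FiberScoreParams | None = None,
) -> list[FiberScore]:
    return [
        weighted_fiber_score(ef, scored_tractogram, params, patient_id=pid)
        for pid, ef in efields.items()
    ]
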