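"""Synthetic two-cohort datasets with a planted sweet spot and ground truth.

The generator emulates the study design the pipeline is built for: a small
training cohort of early-stage patients with two-year motor-progression
change scores, a larger independent validation cohort of advanced-stage
patients with long-term percent-change outcomes, electrode contacts
scattered around a small target nucleus, and streamline bundles that either
traverse the target region ("on-target", signal-carrying) or stay well away
from it ("off-target").

Planted outcome model: improvement = a - b * distance(contact, target) + noise,
so proximity of stimulation to the target causes better outcomes.  Every
random draw flows from one seed through independent substreams (train /
valid / tractogram), so changing one cohort's size never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import ConfigError
from .io import ElectrodeStim, Tractogram, Volume


@dataclass
class OutcomeModel:
    """improvement = intercept - slope_per_mm * distance + N(0, noise_sd)."""

    intercept: float
    slope_per_mm: float
    noise_sd: float


@dataclass
class BundleSpec:
    n_on_target: int = 2
    n_off_target: int = 2
    streamlines_per_bundle: int = 20
    n_control_points: int = 5
    n_points: int = 40
    length_mm: float = 40.0
    off_target_margin_mm: float = 2.0


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic experiment.

    Cohort sizes and stimulation-parameter distributions follow the emulated
    trial design: 14 training patients stimulated at 1.9 +/- 0.3 V, 60 us,
    130 Hz; 29 validation patients at 2.9 +/- 0.9 V (with a subset of
    current-controlled devices programmed at 3.0 +/- 0.6 mA).  The planted
    target sits at a dorsolateral-STN-like template coordinate; contacts
    scatter isotropically around it (or its right-hemisphere mirror).
    """

    seed: int = 0
    voxel_size_mm: float = 0.5
    grid_half_extent_mm: float = 10.0
    target_center: tuple[float, float, float] = (-12.0, -13.0, -6.0)
    target_sigma: float = 1.5
    n_train: int = 14
    n_valid: int = 29
    contact_scatter_sigma: float = 2.0
    train_amplitude: tuple[float, float] = (1.9, 0.3)  # volts (mean, sd)
    valid_amplitude_v: tuple[float, float] = (2.9, 0.9)
    valid_amplitude_ma: tuple[float, float] = (3.0, 0.6)
    valid_ma_fraction: float = 8.0 / 29.0
    train_outcome: OutcomeModel = field(
        default_factory=lambda: OutcomeModel(intercept=4.0, slope_per_mm=2.0, noise_sd=1.2)
    )
    valid_outcome: OutcomeModel = field(
        default_factory=lambda: OutcomeModel(intercept=45.0, slope_per_mm=7.0, noise_sd=10.0)
    )
    bundles: BundleSpec = field(default_factory=BundleSpec)

    def __post_init__(self) -> None:
        if self.target_sigma <= 0 or self.contact_scatter_sigma <= 0:
            raise ConfigError("all sigmas must be > 0")
        if self.n_train < 5 or self.n_valid < 5:
            raise ConfigError("cohort sizes must be >= 5")
        if self.voxel_size_mm <= 0 or self.grid_half_extent_mm <= self.voxel_size_mm:
            raise ConfigError("degenerate grid specification")

    # independent substreams: 0 = train, 1 = valid, 2 = tractogram
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[stream])

    def make_grid(self) -> Volume:
        """Empty volume centred on the planted target, isotropic voxels."""
        n = int(round(2 * self.grid_half_extent_mm / self.voxel_size_mm)) + 1
        affine = np.eye(4)
        affine[:3, :3] *= self.voxel_size_mm
        affine[:3, 3] = np.asarray(self.target_center) - self.grid_half_extent_mm
        return Volume(np.zeros((n, n, n)), affine)


def generate_cohort(
    config: GeneratorConfig, which: Literal["train", "valid"]
) -> tuple[list[ElectrodeStim], pd.DataFrame, dict]:
    """Electrode stims, clinical table, and ground-truth record for one cohort.

    Training outcomes are emitted as progression change scores (post - pre,
    positive = worsening); validation outcomes as pre/post pairs whose
    percent change carries the planted signal.  The truth record holds the
    target coordinate, per-patient contact distances and noiseless outcomes.
    """
    if which not in ("train", "valid"):
        raise ConfigError(f"unknown cohort {which!r}")
    rng = config._rng(0 if which == "train" else 1)
    n = config.n_train if which == "train" else config.n_valid
    model = config.train_outcome if which == "train" else config.valid_outcome
    target = np.asarray(config.target_center, dtype=float)
    prefix = "T" if which == "train" else "V"

    scatter = rng.normal(0.0, config.contact_scatter_sigma, size=(n, 3))
    distances = np.linalg.norm(scatter, axis=1)
    hemis = rng.random(n) < 0.5  # True -> right hemisphere (mirrored placement)
    noiseless = model.intercept - model.slope_per_mm * distances
    improvements = noiseless + rng.normal(0.0, model.noise_sd, size=n)

    if which == "train":
        amps = np.clip(rng.normal(*config.train_amplitude, size=n), 0.5, 5.0)
        units = ["V"] * n
        pre = np.clip(rng.normal(28.0, 6.0, size=n), 10.0, 60.0)
        post = np.clip(pre - improvements, 0.0, None)  # progression = post - pre
        ledd_pre = np.clip(rng.normal(450.0, 120.0, size=n), 100.0, None)
        ledd_post = np.clip(
            ledd_pre - 100.0 + 30.0 * distances + rng.normal(0.0, 60.0, size=n), 0.0, None
        )
        followup = np.full(n, 2.0)
        label = "early_synthetic"
    else:
        n_ma = int(round(config.valid_ma_fraction * n))
        units = ["V"] * (n - n_ma) + ["mA"] * n_ma
        amps = np.concatenate(
            [
                np.clip(rng.normal(*config.valid_amplitude_v, size=n - n_ma), 0.5, 6.0),
                np.clip(rng.normal(*config.valid_amplitude_ma, size=n_ma), 0.5, 6.0),
            ]
        )
        order = rng.permutation(n)
        amps, units = amps[order], [units[i] for i in order]
        pre = np.clip(rng.normal(35.0, 8.0, size=n), 10.0, 80.0)
        post = np.clip(pre * (1.0 - improvements / 100.0), 0.0, None)
        ledd_pre = np.clip(rng.normal(1000.0, 250.0, size=n), 200.0, None)
        ledd_post = np.clip(
            ledd_pre - 300.0 + 40.0 * distances + rng.normal(0.0, 150.0, size=n), 0.0, None
        )
        followup = np.clip(rng.normal(5.4, 2.0, size=n), 2.0, 10.0)
        label = "advanced_synthetic"

    stims, rows = [], []
    for i in range(n):
        pid = f"{prefix}{i + 1:03d}"
        contact = target + scatter[i]
        hemi = "left"
        if hemis[i]:
            contact = contact.copy()
            contact[0] = -contact[0]
            hemi = "right"
        stims.append(
            ElectrodeStim(
                patient_id=pid,
                contact_mm=contact,
                amplitude=float(amps[i]),
                amplitude_unit=units[i],
                pulse_width_us=60.0,
                frequency_hz=130.0,
                hemisphere=hemi,
            )
        )
        rows.append(
            {
                "patient_id": pid,
                "updrs3_pre": pre[i],
                "updrs3_post": post[i],
                "ledd_pre": ledd_pre[i],
                "ledd_post": ledd_post[i],
                "followup_years": followup[i],
                "cohort_label": label,
                "arm": "DBS",
            }
        )
    cohort = pd.DataFrame(rows)
    truth = {
        "target_center": target.tolist(),
        "distance_mm": distances.tolist(),
        "noiseless_improvement": noiseless.tolist(),
        "improvement": improvements.tolist(),
        "hemisphere": ["right" if h else "left" for h in hemis],
        "patient_id": [s.patient_id for s in stims],
    }
    return stims, cohort, truth


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= u * (v @ u)
    return v / np.linalg.norm(v)


def generate_tractogram(config: GeneratorConfig) -> tuple[Tractogram, pd.DataFrame]:
    """Smooth streamline bundles around the planted target, with truth labels.

    On-target bundles pass within ``target_sigma`` of the target centre;
    off-target bundles keep every point farther than 4 * target_sigma away.
    Returns the tractogram and a per-streamline frame (bundle id, on_target).
    """
    spec = config.bundles
    if spec.n_on_target < 1 or spec.n_off_target < 1:
        raise ConfigError("need at least one on-target and one off-target bundle")
    off_dist = 4.0 * config.target_sigma + spec.off_target_margin_mm
    if off_dist >= config.grid_half_extent_mm:
        raise ConfigError("off-target bundle offset exceeds the grid extent")
    rng = config._rng(2)
    target = np.asarray(config.target_center, dtype=float)
    sigma = config.target_sigma

    streamlines: list[np.ndarray] = []
    rows = []
    t_ctrl = np.linspace(-spec.length_mm / 2, spec.length_mm / 2, spec.n_control_points)
    t_fine = np.linspace(-spec.length_mm / 2, spec.length_mm / 2, spec.n_points)
    bundle_id = 0
    for on_target, count in ((True, spec.n_on_target), (False, spec.n_off_target)):
        for _ in range(count):
            axis = _unit_vector(rng)
            center = target.copy()
            if not on_target:
                center = target + _perpendicular(axis, rng) * off_dist
            for s in range(spec.streamlines_per_bundle):
                # radial offset and control-point jitter are clipped so the
                # on/off-target distance guarantees hold by construction
                radial = _perpendicular(axis, rng) * min(
                    abs(rng.normal(0.0, 0.4 * sigma)), 0.6 * sigma
                )
                jitter = rng.normal(0.0, 0.15 * sigma, size=(spec.n_control_points, 3))
                norms = np.linalg.norm(jitter, axis=1, keepdims=True)
                jitter *= np.minimum(1.0, 0.3 * sigma / np.maximum(norms, 1e-12))
                ctrl = center + radial + np.outer(t_ctrl, axis) + jitter
                spline = CubicSpline(t_ctrl, ctrl, axis=0)
                pts = spline(t_fine)
                streamlines.append(pts)
                rows.append({"bundle_id": bundle_id, "on_target": on_target})
            bundle_id += 1

    tract = Tractogram(streamlines)
    truth = pd.DataFrame(rows)
    # construction-time verification of the planted geometry
    dmin = np.asarray(
        [np.linalg.norm(s - target, axis=1).min() for s in tract.streamlines]
    )
    on = truth["on_target"].to_numpy()
    if not (np.all(dmin[on] < sigma) and np.all(dmin[~on] > 4.0 * sigma)):
        raise ConfigError("bundle geometry violates the planted distance guarantees")
    return tract, truth
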