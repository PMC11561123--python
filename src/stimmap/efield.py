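"""Simplified per-patient E-field model.

The stimulated tissue around an active contact is modelled as an isotropic
point source: magnitude(r) = amplitude * k_cal / max(r, r_min)**2, in V/mm.
This is a declared stand-in for a finite-element field solution; the
downstream sweet-spot and fiber-filtering statistics consume only magnitudes
and their ranks, so any smooth monotone radial falloff preserves the logic.
With k_cal = 1 mm a 2 V stimulation crosses the conventional 0.2 V/mm
activation threshold at sqrt(10) ~ 3.2 mm, a plausible stimulation extent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, UnitError
from .io import ElectrodeStim, Volume


@dataclass
class FieldModelParams:
    """Parameters of the point-source field model.

    k_cal : calibration constant (mm); scales the field amplitude.
    r_min : clamp radius (mm) below which the 1/r^2 singularity is frozen.
    ma_to_v : conversion applied to amplitudes tagged "mA" to place them on
        the model's volt scale (current-controlled devices; default 1 mA -> 1 V).
    """

    k_cal: float = 1.0
    r_min: float = 0.5
    ma_to_v: float = 1.0

    def __post_init__(self) -> None:
        if self.k_cal <= 0 or self.r_min <= 0:
            raise ConfigError("k_cal and r_min must be > 0")


def effective_amplitude_v(stim: ElectrodeStim, params: FieldModelParams) -> float:
    if stim.amplitude_unit == "V":
        return stim.amplitude
    if stim.amplitude_unit == "mA":
        return stim.amplitude * params.ma_to_v
    raise UnitError(f"unknown amplitude unit {stim.amplitude_unit!r} (expected V or mA)")


def compute_efield(
    stim: ElectrodeStim, grid: Volume, params: FieldModelParams | None = None
) -> Volume:
    """E-field magnitude volume (V/mm) for one stimulation on ``grid``'s geometry."""
    params = params or FieldModelParams()
    amp = effective_amplitude_v(stim, params)
    world = grid.world_grid()
    r = np.linalg.norm(world - stim.contact_mm, axis=-1)
    mag = amp * params.k_cal / np.maximum(r, params.r_min) ** 2
    return grid.like(mag.astype(float))


def mirror_stim(stim: ElectrodeStim, plane_x_mm: float = 0.0) -> ElectrodeStim:
    """Reflect the active contact about the midsagittal plane x = plane_x_mm."""
    mirrored = stim.contact_mm.copy()
    mirrored[0] = 2.0 * plane_x_mm - mirrored[0]
    flipped = "right" if stim.hemisphere == "left" else "left"
    return replace(stim, contact_mm=mirrored, hemisphere=flipped)


def pool_bilateral(efield_left: Volume, efield_right: Volume, mode: str = "max") -> Volume:
    """Combine two hemispheric fields on one grid into a per-patient field."""
    efield_left.require_same_grid(efield_right)
    if mode == "max":
        return efield_left.like(np.maximum(efield_left.data, efield_right.data))
    if mode == "mean":
        return efield_left.like((efield_left.data + efield_right.data) / 2.0)
    raise ConfigError(f"unknown pooling mode {mode!r} (expected max|mean)")
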