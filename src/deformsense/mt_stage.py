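"""MT stage: Gaussian spatial pooling and opponent direction tuning.

Energy maps are pooled over four adjacent filter positions (stride 1,
Gaussian weights, SD 1.2 position units), then passed through
direction-tuned units: a cosine weighting over the 24 energy channels
whose negative lobe implements motion opponency, followed by half-wave
rectification and the same divisive normalization as the V1 stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimulus import StimulusClip
from .v1_energy import (EnergyMap, FilterBankSpec, NormalizationConstants,
                        compute_energy_map)


class PoolingError(ValueError):
    """Fewer input positions than the pooling window."""


@dataclass(frozen=True)
class PoolingSpec:
    """Spatial pooling over adjacent filter positions.

    Weights are a Gaussian of SD ``gaussian_sd`` (in position units)
    centred on the pooling range, renormalized to sum to 1 over the window.
    """

    window: int = 4
    gaussian_sd: float = 1.2
    stride: int = 1

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.gaussian_sd <= 0:
            raise ValueError("gaussian_sd must be > 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def weights(self) -> np.ndarray:
        offsets = np.arange(self.window) - (self.window - 1) / 2.0
        w = np.exp(-offsets ** 2 / (2.0 * self.gaussian_sd ** 2))
        return w / w.sum()


@dataclass
class DirectionMap:
    """MT-like responses over pooled positions × 24 preferred directions."""

    values: np.ndarray              # (n_positions, n_directions), >= 0
    positions_deg: np.ndarray
    direction_labels_deg: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("direction responses must be >= 0")
        if self.values.shape != (len(self.positions_deg),
                                 len(self.direction_labels_deg)):
            raise ValueError("values shape inconsistent with labels")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def position_spacing_deg(self) -> float:
        if len(self.positions_deg) < 2:
            return float("nan")
        return float(np.mean(np.diff(self.positions_deg)))

    def to_frame(self) -> pd.DataFrame:
        p, d = np.meshgrid(np.arange(self.n_positions),
                           self.direction_labels_deg, indexing="ij")
        return pd.DataFrame({
            "position_index": p.ravel(),
            "position_deg": self.positions_deg[p.ravel()],
            "direction_deg": d.ravel(),
            "value": self.values.ravel(),
        })


def pool_responses(energy: EnergyMap,
                   spec: PoolingSpec | None = None) -> EnergyMap:
    """Gaussian-weighted pooling over ``window`` adjacent positions.

    With window 4 and stride 1 an N-position map yields N − 3 pooled
    positions (e.g. 32/64/128 → 29/61/125).
    """
    spec = spec or PoolingSpec()
    n = energy.n_positions
    if n < spec.window:
        raise PoolingError(f"{n} positions < pooling window {spec.window}")
    w = spec.weights()
    out_idx = np.arange(0, n - spec.window + 1, spec.stride)
    values = np.zeros((len(out_idx), energy.values.shape[1]))
    positions = np.zeros(len(out_idx))
    for j, i in enumerate(out_idx):
        values[j] = w @ energy.values[i:i + spec.window]
        positions[j] = w @ energy.positions_deg[i:i + spec.window]
    return EnergyMap(values=values, positions_deg=positions,
                     direction_labels_deg=energy.direction_labels_deg)


def opponent_drive(pooled: EnergyMap,
                   preferred_directions_deg: np.ndarray | None = None,
                   ) -> np.ndarray:
    """Pre-rectification drive of the direction-tuned units.

    L(p, α) = Σ_o cos(dir_o − α) · E(p, o): cosine weights whose negative
    lobe subtracts energy in opposite directions (opponency). Antisymmetric
    under α → α + 180°.
    """
    if preferred_directions_deg is None:
        preferred_directions_deg = pooled.direction_labels_deg
    delta = np.deg2rad(pooled.direction_labels_deg[:, None]
                       - np.asarray(preferred_directions_deg)[None, :])
    return pooled.values @ np.cos(delta)


def direction_tuning(pooled: EnergyMap,
                     constants: NormalizationConstants | None = None,
                     preferred_directions_deg: np.ndarray | None = None,
                     ) -> DirectionMap:
    """Opponent cosine weighting, rectification, and normalization.

    The normalization runs across the 24 preferred directions per pooled
    position with the same constants contract as the V1 stage.
    """
    constants = constants or NormalizationConstants()
    if preferred_directions_deg is None:
        preferred_directions_deg = pooled.direction_labels_deg
    drive = opponent_drive(pooled, preferred_directions_deg)
    rect = np.maximum(drive, 0.0)
    denom = rect.sum(axis=1) + constants.semi_saturation
    values = constants.max_response * rect / denom[:, None]
    return DirectionMap(values=values, positions_deg=pooled.positions_deg,
                        direction_labels_deg=np.asarray(
                            preferred_directions_deg, dtype=float))


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end parameters from clip to direction map.

    ``n_temporal_offsets=1`` analyses a single 6-frame window starting at
    ``start_frame``: the travelling deformation makes the alternating
    left/right response pattern drift vertically, so averaging raw
    responses over a long clip would cancel the spatial structure the
    higher-order kernel monitors. Set to None to average all valid
    windows.
    """

    strip_width_deg: float = 0.08
    strip_height_deg: float = 4.97
    target_positions: int | None = 64
    filter_spec: FilterBankSpec = field(default_factory=FilterBankSpec)
    constants: NormalizationConstants = field(
        default_factory=NormalizationConstants)
    pooling: PoolingSpec = field(default_factory=PoolingSpec)
    n_temporal_offsets: int | None = 1
    start_frame: int = 0

    # Strip width / filter size / position count per grating spatial
    # frequency in the moiré experiments (cpd → (deg, count)).
    MOIRE_STRIPS = {6.4: (0.16, 32), 12.9: (0.08, 64), 25.8: (0.04, 128)}

    @classmethod
    def for_deforming_bar(cls, **overrides) -> "PipelineConfig":
        return cls(**overrides)

    @classmethod
    def for_moire(cls, grating_sf: float, **overrides) -> "PipelineConfig":
        try:
            width, count = cls.MOIRE_STRIPS[grating_sf]
        except KeyError:
            raise ValueError(
                f"no strip preset for grating_sf={grating_sf}; "
                f"known: {sorted(cls.MOIRE_STRIPS)}") from None
        return cls(strip_width_deg=width, target_positions=count,
                   filter_spec=FilterBankSpec(filter_size_deg=width),
                   **overrides)


def compute_direction_map(clip: StimulusClip,
                          config: PipelineConfig | None = None,
                          return_energy: bool = False):
    """Full pipeline: strip → energy → pooling → direction tuning.

    Deterministic: identical inputs and config give bit-identical outputs.
    """
    from .stimulus import extract_analysis_strip

    config = config or PipelineConfig()
    strip = extract_analysis_strip(clip, config.strip_width_deg,
                                   strip_height_deg=config.strip_height_deg)
    energy = compute_energy_map(
        strip, config.filter_spec, config.constants,
        target_positions=config.target_positions,
        n_temporal_offsets=config.n_temporal_offsets,
        start_frame=config.start_frame)
    pooled = pool_responses(energy, config.pooling)
    dmap = direction_tuning(pooled, config.constants)
    if return_energy:
        return dmap, energy
    return dmap
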