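"""V1 stage: oriented spatiotemporal filtering, rectification, normalization.

The filter bank holds 24 direction-selective spatiotemporal Gabor kernels
(15° steps) at two carrier phases (0 and π). Direction labels follow the
package convention: 0° = leftward, 90° = downward (image rows increase
downward), 180° = rightward, 270° = upward. Each kernel is a drifting
plane-wave carrier under an isotropic spatial Gaussian envelope and a flat
temporal window, DC-subtracted so uniform inputs yield exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .stimulus import ClipGeometry, StimulusClip, ResolutionError


class TemporalExtentError(ValueError):
    """The clip is shorter than the filters' temporal support."""


N_DIRECTIONS = 24
DIRECTION_STEP_DEG = 360.0 / N_DIRECTIONS


def direction_unit_vector(direction_deg: float) -> tuple[float, float]:
    """Unit motion vector (dx, dy) in screen coordinates (y downward).

    0° = leftward, 90° = downward, 180° = rightward, 270° = upward.
    """
    d = np.deg2rad(direction_deg)
    return (-float(np.cos(d)), float(np.sin(d)))


@dataclass(frozen=True)
class FilterBankSpec:
    """Parameters of the spatiotemporal filter bank.

    ``filter_size_deg`` sets the square spatial support *and* the carrier
    spatial wavelength (they are equal by design); ``temporal_freq`` is the
    carrier temporal frequency, deliberately slow (0.4 Hz) so a 6-frame
    (~100 ms) window sees a one-way phase ramp.
    """

    filter_size_deg: float = 0.08
    n_orientations: int = N_DIRECTIONS
    phases: tuple[float, ...] = (0.0, np.pi)
    temporal_extent_frames: int = 6
    temporal_freq: float = 0.4

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("n_orientations must be >= 2")
        if self.filter_size_deg <= 0:
            raise ValueError("filter_size_deg must be > 0")
        if self.temporal_extent_frames < 2:
            raise ValueError("temporal_extent_frames must be >= 2")

    @classmethod
    def quadrature(cls, **kwargs) -> "FilterBankSpec":
        """Variant with a quadrature (0, π/2) phase pair."""
        return cls(phases=(0.0, np.pi / 2.0), **kwargs)


@dataclass(frozen=True)
class NormalizationConstants:
    """Divisive-normalization constants shared by the V1 and MT stages."""

    max_response: float = 1.0
    semi_saturation: float = 0.1

    def __post_init__(self) -> None:
        if self.max_response <= 0 or self.semi_saturation <= 0:
            raise ValueError("normalization constants must be > 0")


@dataclass
class FilterBank:
    """Realized kernels: (n_orientations, n_phases, T, size_px, size_px)."""

    kernels: np.ndarray
    direction_labels_deg: np.ndarray
    spec: FilterBankSpec
    size_px: int


@dataclass
class EnergyMap:
    """Normalized motion energy over filter positions × direction channels."""

    values: np.ndarray              # (n_positions, n_orientations), >= 0
    positions_deg: np.ndarray       # filter centres, deg from strip top
    direction_labels_deg: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("energy values must be >= 0")
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
        """Long-format table: position_index, position_deg, direction_deg, value."""
        p, d = np.meshgrid(np.arange(self.n_positions),
                           self.direction_labels_deg, indexing="ij")
        return pd.DataFrame({
            "position_index": p.ravel(),
            "position_deg": self.positions_deg[p.ravel()],
            "direction_deg": d.ravel(),
            "value": self.values.ravel(),
        })


# ---------------------------------------------------------------------------
# Filter construction
# ---------------------------------------------------------------------------

def build_filter_bank(spec: FilterBankSpec,
                      geom: ClipGeometry) -> FilterBank:
    """Realize the spatiotemporal Gabor bank at the clip's resolution.

    Kernel for direction d, phase φ:
        env(x, y) · cos(2π·fs·(r·v(d)) − 2π·ft·τ + φ) − temporal mean
    with fs = 1/filter_size_deg, ft = temporal_freq, v(d) the unit motion
    vector, env an isotropic Gaussian of SD filter_size/4, flat in τ.
    Subtracting the global DC leaves the kernels with zero coefficient
    sum (uniform fields elicit no response) but, deliberately, a nonzero
    response to static *structured* patterns: an edge drives the
    near-vertical channels tonically, the baseline that makes the V1
    energy maps noisier than the MT direction maps.
    """
    size_px = int(round(spec.filter_size_deg * geom.pixels_per_degree))
    if size_px < 4:
        raise ResolutionError(
            f"filter support {size_px} px < 4; increase pixels_per_degree")

    ppd = geom.pixels_per_degree
    coords = (np.arange(size_px) + 0.5 - size_px / 2.0) / ppd
    X, Y = np.meshgrid(coords, coords, indexing="xy")   # X: columns, Y: rows
    tau = np.arange(spec.temporal_extent_frames) / geom.frame_rate
    fs = 1.0 / spec.filter_size_deg
    sd = spec.filter_size_deg / 4.0
    env = np.exp(-(X ** 2 + Y ** 2) / (2.0 * sd ** 2))

    dirs = np.arange(spec.n_orientations) * (360.0 / spec.n_orientations)
    kernels = np.empty((spec.n_orientations, len(spec.phases),
                        spec.temporal_extent_frames, size_px, size_px))
    for oi, d in enumerate(dirs):
        vx, vy = direction_unit_vector(d)
        u = X * vx + Y * vy
        for pi, phi in enumerate(spec.phases):
            carrier = np.cos(2.0 * np.pi * fs * u[None, :, :]
                             - 2.0 * np.pi * spec.temporal_freq * tau[:, None, None]
                             + phi)
            k = env[None, :, :] * carrier
            kernels[oi, pi] = k - k.mean()
    return FilterBank(kernels=kernels, direction_labels_deg=dirs,
                      spec=spec, size_px=size_px)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_placements(strip_height_px: int, size_px: int,
                      target_positions: int | None = None) -> np.ndarray:
    """Row offsets of the filter placements along the strip.

    Default: non-overlapping tiling (stride = filter size). When
    ``target_positions`` exceeds the natural count, the stride shrinks
    (placements at round(linspace)) so that downstream pooled counts match
    a required total.
    """
    if strip_height_px < size_px:
        raise ValueError("strip shorter than the filter support")
    if target_positions is None:
        return np.arange(0, strip_height_px - size_px + 1, size_px)
    if target_positions < 1:
        raise ValueError("target_positions must be >= 1")
    if target_positions == 1:
        return np.array([(strip_height_px - size_px) // 2])
    return np.round(
        np.linspace(0, strip_height_px - size_px, target_positions)
    ).astype(int)


def apply_filters(strip: StimulusClip, bank: FilterBank,
                  target_positions: int | None = None,
                  n_temporal_offsets: int | None = None,
                  start_frame: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Correlate the bank with the strip at each tiled placement.

    Returns ``(raw, positions_deg)`` with ``raw`` of shape
    (n_positions, n_orientations, n_phases): the inner product of each
    kernel with the clip patch, averaged over the analysed temporal
    offsets. ``n_temporal_offsets`` limits the average to the first k valid
    offsets from ``start_frame`` (None = all valid offsets).
    """
    T_k = bank.spec.temporal_extent_frames
    if strip.n_frames - start_frame < T_k:
        raise TemporalExtentError(
            f"clip has {strip.n_frames - start_frame} usable frames; "
            f"filters need {T_k}")
    size = bank.size_px
    h_px = strip.geometry.height_px
    if abs(strip.geometry.width_px - size) > 0:
        raise ValueError(
            f"strip width {strip.geometry.width_px} px must equal the "
            f"filter support {size} px")

    starts = filter_placements(h_px, size, target_positions)
    frames = strip.frames[start_frame:].astype(np.float64)
    n_valid = frames.shape[0] - T_k + 1
    k = n_valid if n_temporal_offsets is None else min(n_temporal_offsets,
                                                       n_valid)
    frames = frames[:T_k + k - 1]

    n_ori, n_ph = bank.kernels.shape[:2]
    raw = np.empty((len(starts), n_ori, n_ph))
    for oi in range(n_ori):
        for pi in range(n_ph):
            corr = signal.correlate(frames, bank.kernels[oi, pi],
                                    mode="valid")[:, :, 0]
            raw[:, oi, pi] = corr[:k].mean(axis=0)[starts]
    ppd = strip.geometry.pixels_per_degree
    positions_deg = (starts + size / 2.0) / ppd
    return raw, positions_deg


def rectify_and_normalize(raw: np.ndarray,
                          constants: NormalizationConstants,
                          positions_deg: np.ndarray | None = None,
                          direction_labels_deg: np.ndarray | None = None,
                          ) -> EnergyMap:
    """Half-wave rectify, divisively normalize, and sum over carrier phases.

    Per position: A(o, φ) = max(raw, 0);
    E(o) = Σ_φ R_max·A(o, φ) / (Σ_{o', φ'} A(o', φ') + σ)
    with R_max the maximum attainable response and σ the semi-saturation
    constant. Zero input yields zero output (σ > 0 guards the quotient).
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw responses must be finite")
    if raw.ndim != 3:
        raise ValueError("raw must be (positions, orientations, phases)")
    rect = np.maximum(raw, 0.0)
    denom = rect.sum(axis=(1, 2)) + constants.semi_saturation
    energy = constants.max_response * rect.sum(axis=2) / denom[:, None]

    n_pos, n_ori = energy.shape
    if positions_deg is None:
        positions_deg = np.arange(n_pos, dtype=float)
    if direction_labels_deg is None:
        direction_labels_deg = np.arange(n_ori) * (360.0 / n_ori)
    return EnergyMap(values=energy, positions_deg=np.asarray(positions_deg),
                     direction_labels_deg=np.asarray(direction_labels_deg))


def compute_energy_map(strip: StimulusClip, spec: FilterBankSpec,
                       constants: NormalizationConstants,
                       target_positions: int | None = None,
                       n_temporal_offsets: int | None = None,
                       start_frame: int = 0) -> EnergyMap:
    """Filter bank construction + filtering + normalization in one call."""
    bank = build_filter_bank(spec, strip.geometry)
    raw, pos = apply_filters(strip, bank, target_positions=target_positions,
                             n_temporal_offsets=n_temporal_offsets,
                             start_frame=start_frame)
    return rectify_and_normalize(raw, constants, positions_deg=pos,
                                 direction_labels_deg=bank.direction_labels_deg)
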