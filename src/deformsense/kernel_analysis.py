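"""Higher-order kernel: a space × direction template scored by zero-mean NCC.

The proposed deformation detector monitors the spatial pattern of
direction responses with a separable template
``K(x, θ) = sin(2π·f·x + φ) · cos(θ − α)``: sinusoidal along position
(spatial frequency ``f`` cpd, phase ``φ``) and cosine-tuned in direction
around the preferred direction ``α`` (0° = leftward). The match between a
kernel and an energy or direction map is the zero-mean normalized
cross-correlation, maximized over a 32-step phase grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The canonical kernel frequencies swept in the analyses (cpd).
DEFAULT_KERNEL_FREQUENCIES = (0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4)

#: 32 phases at 0.0625π steps tile [0, 2π) exactly.
PHASE_GRID = np.arange(32) * 0.0625 * np.pi


@dataclass(frozen=True)
class KernelSpec:
    f: float                 # spatial frequency along position (cpd)
    phi: float = 0.0         # phase (radians), in [0, 2π)
    alpha: float = 0.0       # preferred direction (deg); 0 = leftward

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if not 0.0 <= self.phi < 2.0 * np.pi:
            raise ValueError("phi must lie in [0, 2π)")


@dataclass
class Kernel:
    values: np.ndarray           # (n_positions, n_directions)
    spec: KernelSpec
    positions_deg: np.ndarray
    direction_labels_deg: np.ndarray


def build_kernel(spec: KernelSpec, positions_deg: np.ndarray,
                 directions_deg: np.ndarray) -> Kernel:
    """Evaluate K(x, θ) = sin(2π·f·x + φ)·cos(θ − α) on the given grid.

    Positions are in degrees from the strip top (strictly increasing);
    directions must sample the circle uniformly for the kernel to be
    zero-mean along the direction axis.
    """
    positions_deg = np.asarray(positions_deg, dtype=float)
    directions_deg = np.asarray(directions_deg, dtype=float)
    if positions_deg.size == 0 or directions_deg.size == 0:
        raise ValueError("empty position or direction grid")
    if positions_deg.size > 1 and np.any(np.diff(positions_deg) <= 0):
        raise ValueError("positions must be strictly increasing")
    s = np.sin(2.0 * np.pi * spec.f * positions_deg + spec.phi)
    d = np.cos(np.deg2rad(directions_deg - spec.alpha))
    return Kernel(values=np.outer(s, d), spec=spec,
                  positions_deg=positions_deg,
                  direction_labels_deg=directions_deg)


def _map_values(map_like) -> np.ndarray:
    if hasattr(map_like, "values") and not isinstance(map_like, np.ndarray):
        return np.asarray(map_like.values, dtype=float)
    return np.asarray(map_like, dtype=float)


def zncc(kernel, map_like) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape fields.

    Σ(K−μ_K)(I−μ_I) / sqrt(Σ(K−μ_K)²·Σ(I−μ_I)²), bounded in [−1, 1];
    returns 0 when either field is constant (zero variance).
    """
    k = _map_values(kernel)
    i = _map_values(map_like)
    if k.shape != i.shape:
        raise ValueError(f"shape mismatch: kernel {k.shape} vs map {i.shape}")
    kc = k - k.mean()
    ic = i - i.mean()
    denom = np.sqrt((kc ** 2).sum() * (ic ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((kc * ic).sum() / denom, -1.0, 1.0))


def max_ncc_over_phase(f: float, map_like, alpha: float = 0.0,
                       ) -> tuple[float, float]:
    """Best ZNCC over the 32-step phase grid and the phase achieving it.

    The map must expose ``positions_deg`` and ``direction_labels_deg``
    (EnergyMap or DirectionMap).
    """
    best = -np.inf
    best_phi = 0.0
    for phi in PHASE_GRID:
        k = build_kernel(KernelSpec(f=f, phi=float(phi), alpha=alpha),
                         map_like.positions_deg,
                         map_like.direction_labels_deg)
        v = zncc(k.values, map_like.values)
        if v > best:
            best, best_phi = v, float(phi)
    return best, best_phi


@dataclass
class NCCProfile:
    """Best NCC per kernel spatial frequency for one target map."""

    frequencies: np.ndarray
    best_ncc: np.ndarray
    argmax_phase: np.ndarray
    target: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "target_map": self.target,
            "kernel_f_cpd": self.frequencies,
            "best_ncc": self.best_ncc,
            "argmax_phase_rad": self.argmax_phase,
        })

    @property
    def argmax_frequency(self) -> float:
        return float(self.frequencies[int(np.argmax(self.best_ncc))])


def ncc_profile(map_like, frequencies=DEFAULT_KERNEL_FREQUENCIES,
                alpha: float = 0.0, target: str = "") -> NCCProfile:
    """Sweep the kernel spatial frequency; deterministic per-f maxima."""
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size == 0:
        raise ValueError("frequency list must be non-empty")
    best = np.empty(frequencies.size)
    phases = np.empty(frequencies.size)
    for i, f in enumerate(frequencies):
        best[i], phases[i] = max_ncc_over_phase(f, map_like, alpha=alpha)
    return NCCProfile(frequencies=frequencies, best_ncc=best,
                      argmax_phase=phases, target=target)
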