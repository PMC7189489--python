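"""Experiment presets, reproducible end-to-end runs, and test fixtures.

A RunConfig fully determines an experiment-scale run: stimulus conditions,
pipeline parameters, kernel sweep, and the synthetic observer that stands
in for human deformation reports. All randomness flows from the single run
seed; rerunning a config yields byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .stimulus import (ClipGeometry, DeformingBarSpec, MoireSpec,
                       StimulusClip, render_deforming_bar,
                       render_moire_stimulus)
from .v1_energy import EnergyMap, FilterBankSpec, NormalizationConstants
from .mt_stage import DirectionMap, PipelineConfig, compute_direction_map
from .kernel_analysis import (DEFAULT_KERNEL_FREQUENCIES, KernelSpec,
                              build_kernel, ncc_profile)
from .psychometrics import (PsychoDataset, fit_exponential,
                            kernel_frequency_sweep, simulate_observer)

log = logging.getLogger("deformsense")

EXP1_DEFORM_SFS = (0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4)
EXP2_ORIENTATIONS = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0)
EXP2_GRATING_SFS = (6.4, 12.9, 25.8)
EXP3_ORIENTATIONS = (1.0, 16.0)
EXP3_BAR_LUMINANCES = (0.0, 17.5, 37.0, 58.0, 76.0, 95.0, 112.0, 132.0, 148.0)

#: Pooled trials per condition when the per-observer designs are pooled
#: across the reported observer counts (7 × 2 × 10; 12 × 4 × 5; 12 × 4 × 5).
POOLED_TRIALS = {"exp1": 140, "exp2": 240, "exp3": 240}

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Flat, losslessly serializable configuration of a preset run.

    The synthetic observer reports deformation with probability
    ``observer_a·exp(observer_b·NCC)`` where the NCC is scored against the
    direction maps with a kernel at ``observer_f_cpd``. Defaults place the
    report probabilities in roughly the 0.1–0.95 range the psychophysics
    spans.
    """

    experiment: str = "exp1"
    seed: int = 0
    pixels_per_degree: float = 200.0
    frame_rate: float = 60.0
    n_frames: int = 12
    field_width_deg: float = 1.2
    field_height_deg: float = 5.5
    kernel_frequencies: tuple = DEFAULT_KERNEL_FREQUENCIES
    observer_a: float = 0.1
    observer_b: float = 2.5
    observer_f_cpd: float = 0.1
    n_trials_per_condition: int | None = None
    exp1_bar_luminance: float = 38.0
    exp1_drift_sign: int = -1
    exp2_bar_luminance: float = 37.0
    exp2_grating_sfs: tuple = EXP2_GRATING_SFS
    max_response: float = 1.0
    semi_saturation: float = 0.1
    n_temporal_offsets: int | None = 1
    start_frame: int = 0
    make_figures: bool = False
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2", "exp3", "custom"):
            raise ValueError(f"unknown experiment {self.experiment!r}")

    # -- serialization ----------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        d["kernel_frequencies"] = list(self.kernel_frequencies)
        d["exp2_grating_sfs"] = list(self.exp2_grating_sfs)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if d.get("schema_version", 1) != CONFIG_SCHEMA_VERSION:
            raise ValueError("unsupported config schema version")
        d["kernel_frequencies"] = tuple(d["kernel_frequencies"])
        d["exp2_grating_sfs"] = tuple(d["exp2_grating_sfs"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def geometry(self) -> ClipGeometry:
        return ClipGeometry(pixels_per_degree=self.pixels_per_degree,
                            frame_rate=self.frame_rate,
                            width_deg=self.field_width_deg,
                            height_deg=self.field_height_deg,
                            n_frames=self.n_frames)

    def constants(self) -> NormalizationConstants:
        return NormalizationConstants(max_response=self.max_response,
                                      semi_saturation=self.semi_saturation)

    def n_trials(self) -> int:
        if self.n_trials_per_condition is not None:
            return self.n_trials_per_condition
        return POOLED_TRIALS.get(self.experiment, 100)


def _conditions(config: RunConfig):
    """(label, stimulus spec, pipeline config) per behavioral condition."""
    geom_kwargs = dict(constants=config.constants(),
                       n_temporal_offsets=config.n_temporal_offsets,
                       start_frame=config.start_frame)
    out = []
    if config.experiment == "exp1":
        for sf in EXP1_DEFORM_SFS:
            spec = DeformingBarSpec(deform_sf=sf,
                                    bar_luminance=config.exp1_bar_luminance,
                                    drift_sign=config.exp1_drift_sign)
            out.append((f"sf={sf:g}", spec,
                        PipelineConfig.for_deforming_bar(**geom_kwargs)))
    elif config.experiment == "exp2":
        for gsf in config.exp2_grating_sfs:
            for ori in EXP2_ORIENTATIONS:
                spec = MoireSpec(grating_sf=gsf, grating_orientation_deg=ori,
                                 bar_luminance=config.exp2_bar_luminance)
                out.append((f"sf={gsf:g},ori={ori:g}", spec,
                            PipelineConfig.for_moire(gsf, **geom_kwargs)))
    elif config.experiment == "exp3":
        for ori in EXP3_ORIENTATIONS:
            for lum in EXP3_BAR_LUMINANCES:
                spec = MoireSpec(grating_sf=12.9,
                                 grating_orientation_deg=ori,
                                 bar_luminance=lum)
                out.append((f"ori={ori:g},lum={lum:g}", spec,
                            PipelineConfig.for_moire(12.9, **geom_kwargs)))
    else:
        raise ValueError("custom runs: assemble the pipeline directly")
    return out


def render_condition(spec, geom: ClipGeometry) -> StimulusClip:
    if isinstance(spec, DeformingBarSpec):
        return render_deforming_bar(spec, geom)
    if isinstance(spec, MoireSpec):
        return render_moire_stimulus(spec, geom)
    raise TypeError(f"unknown stimulus spec {type(spec).__name__}")


@dataclass
class ExperimentBundle:
    """Everything a preset run produces, in memory."""

    config: RunConfig
    labels: list
    direction_maps: list
    energy_maps: list
    direction_nccs: np.ndarray       # NCC at observer_f_cpd per condition
    dataset: PsychoDataset
    sweeps: dict                     # {"direction": SweepResult, "energy": ...}
    fit: object                      # ExpFitResult at observer_f_cpd


def run_experiment_preset(config: RunConfig,
                          outdir: str | Path | None = None,
                          ) -> ExperimentBundle:
    """Render every condition, run the model, score, simulate, and fit.

    When ``outdir`` is given, maps, profiles, the sweep tables, the
    synthetic dataset, the fit report, and a manifest (config hash, seed,
    versions) are written as CSV/JSON.
    """
    geom = config.geometry()
    conditions = _conditions(config)
    labels, dmaps, emaps = [], [], []
    for label, spec, pipe in conditions:
        log.info("rendering + simulating condition %s", label)
        clip = render_condition(spec, geom)
        dmap, emap = compute_direction_map(clip, pipe, return_energy=True)
        labels.append(label)
        dmaps.append(dmap)
        emaps.append(emap)

    from .kernel_analysis import max_ncc_over_phase
    nccs = np.array([max_ncc_over_phase(config.observer_f_cpd, m)[0]
                     for m in dmaps])
    dataset = simulate_observer(config.observer_a, config.observer_b, nccs,
                                n_trials=config.n_trials(), seed=config.seed,
                                labels=labels)
    fit = fit_exponential(dataset)
    sweeps = {
        "direction": kernel_frequency_sweep(
            dmaps, dataset, frequencies=config.kernel_frequencies),
        "energy": kernel_frequency_sweep(
            emaps, dataset, frequencies=config.kernel_frequencies),
    }
    bundle = ExperimentBundle(config=config, labels=labels,
                              direction_maps=dmaps, energy_maps=emaps,
                              direction_nccs=nccs, dataset=dataset,
                              sweeps=sweeps, fit=fit)
    if outdir is not None:
        write_bundle(bundle, Path(outdir))
    return bundle


def write_bundle(bundle: ExperimentBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config

    frames = []
    for label, dmap, emap in zip(bundle.labels, bundle.direction_maps,
                                 bundle.energy_maps):
        for kind, m in (("direction", dmap), ("energy", emap)):
            df = m.to_frame()
            df.insert(0, "map", kind)
            df.insert(0, "condition", label)
            frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "maps.csv", index=False)

    bundle.dataset.to_frame().to_csv(outdir / "dataset.csv", index=False)
    for kind, sweep in bundle.sweeps.items():
        sweep.table.to_csv(outdir / f"sweep_{kind}.csv", index=False)
        sweep.nccs.to_csv(outdir / f"nccs_{kind}.csv", index=False)
    fit = bundle.fit
    (outdir / "fit.json").write_text(json.dumps(
        {"a": fit.a, "b": fit.b, "c": fit.c, "r2": fit.r2,
         "degenerate": fit.degenerate}, indent=2))
    (outdir / "config.yaml").write_text(cfg.to_yaml())

    versions = {"deformsense": __version__, "numpy": np.__version__,
                "pandas": pd.__version__}
    (outdir / "manifest.json").write_text(json.dumps(
        {"config_hash": cfg.config_hash(), "seed": cfg.seed,
         "experiment": cfg.experiment, "versions": versions}, indent=2))

    if cfg.make_figures:
        export_density_plots(bundle, outdir / "figures")


def export_density_plots(bundle: ExperimentBundle, figdir: Path) -> None:
    """Position × direction density plots (normalized 0–1 per panel)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = Path(figdir)
    figdir.mkdir(parents=True, exist_ok=True)
    for label, dmap in zip(bundle.labels, bundle.direction_maps):
        fig, ax = plt.subplots(figsize=(4, 5))
        v = dmap.values
        vmax = v.max() if v.max() > 0 else 1.0
        ax.imshow(v / vmax, aspect="auto", origin="upper",
                  extent=[dmap.direction_labels_deg[0],
                          dmap.direction_labels_deg[-1],
                          dmap.positions_deg[-1], dmap.positions_deg[0]])
        ax.set_xlabel("preferred direction (deg)")
        ax.set_ylabel("position (deg)")
        ax.set_title(label)
        safe = label.replace("=", "").replace(",", "_").replace(".", "p")
        fig.savefig(figdir / f"direction_{safe}.png", dpi=100)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixtures(seed: int = 0) -> dict:
    """Miniature, seeded test objects used across the test suite.

    Returns small clips (≤ 0.5° field, ≤ 12 frames), a one-hot energy map,
    and a direction map built from a 0.4-cpd kernel; contents are a pure
    function of the seed.
    """
    rng = np.random.default_rng(seed)
    geom = ClipGeometry(pixels_per_degree=50.0, width_deg=0.5,
                        height_deg=0.5, n_frames=12)
    static_bar = render_deforming_bar(
        DeformingBarSpec(bar_width_deg=0.2, bar_height_deg=0.4,
                         amplitude_deg=0.0, deform_sf=0.4), geom)
    wobble_bar = render_deforming_bar(
        DeformingBarSpec(bar_width_deg=0.2, bar_height_deg=0.4,
                         amplitude_deg=0.02, deform_sf=2.0), geom)

    n_dirs = 24
    dirs = np.arange(n_dirs) * 15.0
    one_hot = np.zeros((16, n_dirs))
    one_hot[:, 0] = 1.0
    one_hot_map = EnergyMap(values=one_hot,
                            positions_deg=np.arange(16) * 0.08,
                            direction_labels_deg=dirs)

    positions = np.arange(61) * (4.97 / 61) + 4.97 / 122
    k = build_kernel(KernelSpec(f=0.4, phi=float(rng.uniform(0, 2 * np.pi))),
                     positions, dirs)
    kernel_map = EnergyMap(values=k.values - k.values.min(),
                           positions_deg=positions, direction_labels_deg=dirs)
    return {"static_bar": static_bar, "wobble_bar": wobble_bar,
            "one_hot_map": one_hot_map, "kernel_map": kernel_map}


def fixture_checksums(seed: int = 0) -> dict:
    """Stable content hashes of the generated fixtures."""
    fx = generate_fixtures(seed)
    out = {}
    for name, obj in fx.items():
        arr = obj.frames if isinstance(obj, StimulusClip) else obj.values
        out[name] = hashlib.sha256(
            np.ascontiguousarray(arr, dtype=np.float64).tobytes()
        ).hexdigest()[:16]
    return out
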