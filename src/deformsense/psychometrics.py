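"""Linking model scores to deformation reports.

The per-condition proportion of "deforming" reports is modelled as an
exponential function of the kernel's NCC score, p = a·exp(b·NCC), fitted
by least squares; goodness of fit is summarized by r². Sweeping the
kernel spatial frequency and refitting gives the r²-vs-frequency curves
used to compare the energy-based and direction-based accounts. A
synthetic Bernoulli observer and factorial trial-schedule builders
emulate the psychophysical designs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kernel_analysis import DEFAULT_KERNEL_FREQUENCIES, max_ncc_over_phase


class FitError(RuntimeError):
    """The exponential fit could not be carried out."""


@dataclass
class PsychoDataset:
    """Per-condition NCC predictor, trial counts, and deformation reports."""

    labels: list
    ncc: np.ndarray
    n_trials: np.ndarray
    n_reports: np.ndarray

    def __post_init__(self) -> None:
        self.ncc = np.asarray(self.ncc, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_reports = np.asarray(self.n_reports, dtype=int)
        n = len(self.labels)
        if not (self.ncc.shape == self.n_trials.shape
                == self.n_reports.shape == (n,)):
            raise ValueError("all fields must share one length")
        if np.any(self.n_trials < 1):
            raise ValueError("n_trials must be >= 1")
        if np.any(self.n_reports < 0) or np.any(self.n_reports > self.n_trials):
            raise ValueError("0 <= n_reports <= n_trials is required")

    @property
    def proportions(self) -> np.ndarray:
        return self.n_reports / self.n_trials

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.labels, "ncc": self.ncc,
            "n_trials": self.n_trials, "n_reports": self.n_reports,
            "proportion": self.proportions,
        })


@dataclass
class ExpFitResult:
    a: float
    b: float
    c: float                    # offset; 0 for the two-parameter family
    r2: float
    residuals: np.ndarray
    fitted: np.ndarray
    degenerate: bool = False    # constant proportions: r² undefined (NaN)

    def predict(self, ncc) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(ncc, dtype=float)) + self.c


def fit_exponential(dataset: PsychoDataset, weighted: bool = False,
                    with_offset: bool = False) -> ExpFitResult:
    """Least-squares fit of p = a·exp(b·NCC) (+ c with ``with_offset``).

    Initialized by log-linear regression of log(p + 1e−3) on the NCC.
    ``weighted=True`` weights conditions by inverse binomial variance.
    Constant proportions leave r² undefined; the result is flagged
    degenerate with r² = NaN. Non-convergence raises FitError with the
    optimizer's diagnostics.
    """
    x = dataset.ncc
    p = dataset.proportions
    if len(x) < 3:
        raise FitError("need at least 3 conditions to fit")
    if np.allclose(x, x[0]):
        raise FitError("degenerate predictor: all NCC values equal")

    slope, intercept = np.polyfit(x, np.log(p + 1e-3), 1)
    a0 = float(np.exp(intercept))
    b0 = float(slope)

    sigma = None
    if weighted:
        var = np.maximum(p * (1 - p), 1e-4) / dataset.n_trials
        sigma = np.sqrt(var)
    try:
        if with_offset:
            popt, _ = curve_fit(lambda x, a, b, c: a * np.exp(b * x) + c,
                                x, p, p0=[a0, b0, 0.0], sigma=sigma,
                                maxfev=20000)
            a, b, c = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(lambda x, a, b: a * np.exp(b * x),
                                x, p, p0=[a0, b0], sigma=sigma, maxfev=20000)
            a, b = (float(v) for v in popt)
            c = 0.0
    except RuntimeError as err:       # pragma: no cover - optimizer detail
        raise FitError(f"exponential fit did not converge: {err}") from err

    fitted = a * np.exp(b * x) + c
    residuals = p - fitted
    ss_res = float((residuals ** 2).sum())
    ss_tot = float(((p - p.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return ExpFitResult(a=a, b=b, c=c, r2=float("nan"),
                            residuals=residuals, fitted=fitted,
                            degenerate=True)
    return ExpFitResult(a=a, b=b, c=c, r2=1.0 - ss_res / ss_tot,
                        residuals=residuals, fitted=fitted)


@dataclass
class SweepResult:
    """r² of the exponential link per kernel spatial frequency."""

    table: pd.DataFrame          # kernel_f_cpd, r2, a, b
    nccs: pd.DataFrame           # condition × kernel_f_cpd NCC matrix

    @property
    def best_frequency(self) -> float:
        return float(self.table.loc[self.table["r2"].idxmax(),
                                    "kernel_f_cpd"])

    @property
    def best_r2(self) -> float:
        return float(self.table["r2"].max())


def kernel_frequency_sweep(maps, dataset: PsychoDataset,
                           frequencies=DEFAULT_KERNEL_FREQUENCIES,
                           alpha: float = 0.0,
                           weighted: bool = False) -> SweepResult:
    """Refit the exponential link for kernels of each spatial frequency.

    ``maps`` holds one EnergyMap/DirectionMap per dataset condition, in
    condition order. For each kernel frequency the per-condition NCC is
    recomputed (max over the 32-step phase grid) and the exponential link
    refitted; the returned table mirrors the r²-vs-frequency curves.
    """
    maps = list(maps)
    if len(maps) != len(dataset.labels):
        raise ValueError("need exactly one map per behavioral condition")
    frequencies = np.asarray(frequencies, dtype=float)
    ncc_matrix = np.empty((len(maps), frequencies.size))
    for ci, m in enumerate(maps):
        for fi, f in enumerate(frequencies):
            ncc_matrix[ci, fi], _ = max_ncc_over_phase(f, m, alpha=alpha)

    rows = []
    for fi, f in enumerate(frequencies):
        ds = PsychoDataset(labels=dataset.labels, ncc=ncc_matrix[:, fi],
                           n_trials=dataset.n_trials,
                           n_reports=dataset.n_reports)
        fit = fit_exponential(ds, weighted=weighted)
        rows.append({"kernel_f_cpd": f, "r2": fit.r2, "a": fit.a, "b": fit.b})
    nccs = pd.DataFrame(ncc_matrix, columns=[f"f={f:g}" for f in frequencies])
    nccs.insert(0, "condition", dataset.labels)
    return SweepResult(table=pd.DataFrame(rows), nccs=nccs)


def simulate_observer(true_a: float, true_b: float, nccs, n_trials: int,
                      seed: int, labels=None) -> PsychoDataset:
    """Bernoulli observer whose report probability is exponential in NCC.

    Per condition, p = clip(a·exp(b·NCC), 0, 1) and reports are
    Binomial(n_trials, p), drawn from a seeded generator.
    """
    if true_a < 0:
        raise ValueError("true_a must be >= 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    nccs = np.asarray(nccs, dtype=float)
    p = np.clip(true_a * np.exp(true_b * nccs), 0.0, 1.0)
    rng = np.random.default_rng(seed)
    reports = rng.binomial(n_trials, p)
    if labels is None:
        labels = [f"cond{i}" for i in range(len(nccs))]
    return PsychoDataset(labels=list(labels), ncc=nccs,
                         n_trials=np.full(len(nccs), n_trials),
                         n_reports=reports)


# ---------------------------------------------------------------------------
# Trial scheduling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialDesign:
    """A factorial within-session design, repeated over sessions."""

    name: str
    n_sessions: int
    factors: dict = field(default_factory=dict)   # factor -> tuple of levels
    repetitions: int = 1

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.repetitions < 1:
            raise ValueError("counts must be positive")
        if not self.factors or any(len(v) == 0 for v in self.factors.values()):
            raise ValueError("every factor needs at least one level")

    @property
    def trials_per_session(self) -> int:
        n = self.repetitions
        for levels in self.factors.values():
            n *= len(levels)
        return n


@dataclass
class TrialSchedule:
    design: TrialDesign
    trials: pd.DataFrame          # session, trial, one column per factor

    @property
    def total_trials(self) -> int:
        return len(self.trials)


def build_trial_schedule(design: TrialDesign, seed: int = 0) -> TrialSchedule:
    """Expand the factorial design, pseudo-randomized within each session.

    Every session contains each factor combination exactly ``repetitions``
    times; the within-session order is shuffled from the given seed.
    """
    combos = list(itertools.product(*design.factors.values()))
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(design.n_sessions):
        session = combos * design.repetitions
        order = rng.permutation(len(session))
        for trial, idx in enumerate(order):
            row = {"session": s + 1, "trial": trial + 1}
            row.update(zip(design.factors.keys(), session[idx]))
            rows.append(row)
    return TrialSchedule(design=design, trials=pd.DataFrame(rows))


#: The three experimental designs: a deforming bar judged over seven
#: deformation frequencies; the moiré illusion over grating spatial
#: frequency × orientation; and the illusion over orientation × bar
#: luminance. Totals per observer: 140, 420, and 360 trials.
EXP1_DESIGN = TrialDesign(
    name="exp1", n_sessions=2,
    factors={"deform_sf_cpd": (0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4)},
    repetitions=10)
EXP2_DESIGN = TrialDesign(
    name="exp2", n_sessions=4,
    factors={"grating_sf_cpd": (6.4, 12.9, 25.8),
             "grating_orientation_deg": (0.5, 1, 2, 4, 8, 12, 16)},
    repetitions=5)
EXP3_DESIGN = TrialDesign(
    name="exp3", n_sessions=4,
    factors={"grating_orientation_deg": (1, 16),
             "bar_luminance_cdm2": (0.0, 17.5, 37, 58, 76, 95, 112, 132, 148)},
    repetitions=5)
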