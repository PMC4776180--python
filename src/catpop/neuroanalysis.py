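"""Population-dynamics analysis of multi-task recording tables.

The pipeline mirrors a standard IT-cortex population analysis: neurons are
grouped by preferred stimulus, rates are normalized to each neuron's
fixation-task maximum, the 11-point population activity profile per
(task, stimulus, time bin) is fitted with a Gaussian, and the peak-locus
difference between tasks is tracked over time bins, normalized by its
value at the first analyzed bin (100 ms).  A neuron-level bootstrap
provides per-point dispersion, and the sign change of the late-window
shifts locates the category boundary.

Recording tables are tidy :class:`pandas.DataFrame` objects with columns
``neuron_id, task, stimulus, time_bin_ms, rate`` (trial-averaged rates in
spikes/s).  A synthetic generator with known ground truth stands in for
the non-public recordings the pipeline is designed for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import FitFailedError, InvalidInputError, InvalidParameterError

REQUIRED_COLUMNS = ("neuron_id", "task", "stimulus", "time_bin_ms", "rate")
TASKS = ("fixation", "categorization", "discrimination")
DEFAULT_TIME_BINS = tuple(np.arange(100, 551, 50).tolist())  # bin centers, ms
N_STIMULI = 11
NORMALIZATION_BIN_MS = 100.0
NORMALIZATION_FLOOR = 1e-3  # index units; below this the curve stays raw
ANALYSIS_STIMULI = tuple(range(2, 11))  # extremes 1 and 11 excluded


def validate_recording_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and basic invariants of a tidy recording table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"recording table missing columns: {missing}")
    if (table["rate"] < 0).any():
        raise InvalidInputError("rates must be nonnegative")
    bad_tasks = set(table["task"].unique()) - set(TASKS)
    if bad_tasks:
        raise InvalidInputError(f"unknown tasks: {sorted(bad_tasks)}")
    return table


@dataclass(frozen=True)
class PopulationProfileFit:
    """Gaussian fit A*exp(-(x-mu)^2/(2*sigma^2)) of an 11-point profile."""

    peak_locus: float
    amplitude: float
    width: float
    rss: float
    reliable: bool


@dataclass(eq=False)
class PeakShiftCurve:
    """Task-difference peak loci per (stimulus 2..10, time bin).

    ``raw_shift`` holds peak_locus(task_a) - peak_locus(task_b) in
    stimulus-index units; ``shift`` is the same divided per stimulus by
    |raw shift| at the 100 ms bin, except where that value fell below the
    normalization floor (``normalized`` False: the row stays raw).
    Positive = toward stimulus 11 (green), negative = toward 1 (red).
    """

    stimuli: np.ndarray
    time_bins: np.ndarray
    raw_shift: np.ndarray           # (n_stimuli, n_bins)
    shift: np.ndarray               # normalized where possible
    norm_value: np.ndarray          # per-stimulus |shift| at 100 ms
    normalized: np.ndarray          # per-stimulus bool
    task_a: str = "categorization"
    task_b: str = "discrimination"


@dataclass(frozen=True, eq=False)
class BoundaryResult:
    """Late-window mean shift per stimulus and the sign-change locus."""

    stimuli: np.ndarray
    late_mean: np.ndarray
    crossing: Optional[float]


@dataclass(eq=False)
class SynthGroundTruth:
    """Parameters injected by the synthetic recording generator.

    The categorization task carries a peak displacement that grows over
    time bins and points away from the category boundary (reddish stimuli
    biased toward index 1, greenish toward 11), emulating a time-growing
    categorical bias; fixation and discrimination carry none.
    """

    task_gains: dict = field(default_factory=lambda: {
        "fixation": 1.0, "categorization": 1.2, "discrimination": 1.0})
    boundary: float = 5.5
    shift_start: float = 0.1   # index units at the 100 ms bin
    shift_end: float = 0.5     # index units at the last bin
    noise_sd: float = 0.5      # spikes/s, additive
    amplitude: float = 10.0    # spikes/s at the preferred stimulus
    tuning_width: float = 1.5  # index units
    time_bins: Tuple[float, ...] = DEFAULT_TIME_BINS

    def shift_at(self, time_bin_ms: float) -> float:
        """Injected displacement magnitude at a time-bin center."""
        t0, t1 = self.time_bins[0], self.time_bins[-1]
        frac = 0.0 if t1 == t0 else (time_bin_ms - t0) / (t1 - t0)
        return self.shift_start + frac * (self.shift_end - self.shift_start)

    def polarity(self, stimulus: int) -> float:
        """-1 toward red (index 1) below the boundary, +1 toward green above,
        0 for a stimulus sitting exactly on the boundary."""
        return float(np.sign(stimulus - self.boundary))

    @property
    def shift_at_normalization_bin(self) -> float:
        return self.shift_at(NORMALIZATION_BIN_MS)


def generate_synthetic_recording(truth: Optional[SynthGroundTruth] = None,
                                 n_neurons: int = 125,
                                 n_stimuli: int = N_STIMULI,
                                 tasks: Sequence[str] = TASKS,
                                 time_bins: Optional[Sequence[float]] = None,
                                 rng: Optional[np.random.Generator] = None
                                 ) -> Tuple[pd.DataFrame, SynthGroundTruth]:
    """Emulate a multi-task recording table with known ground truth.

    Each neuron gets a preferred stimulus (balanced across 1..n_stimuli),
    Gaussian tuning over the stimulus index, a task gain, and — in the
    categorization task — a peak displacement of magnitude Delta(t) directed
    away from the category boundary.  Additive Gaussian noise is clipped
    at zero.
    """
    if truth is None:
        truth = SynthGroundTruth()
    if time_bins is None:
        time_bins = truth.time_bins
    else:
        truth = SynthGroundTruth(task_gains=dict(truth.task_gains),
                                 boundary=truth.boundary,
                                 shift_start=truth.shift_start,
                                 shift_end=truth.shift_end,
                                 noise_sd=truth.noise_sd,
                                 amplitude=truth.amplitude,
                                 tuning_width=truth.tuning_width,
                                 time_bins=tuple(time_bins))
    if n_neurons < n_stimuli:
        raise InvalidParameterError("need at least one neuron per stimulus")
    unknown = set(tasks) - set(TASKS)
    if unknown:
        raise InvalidParameterError(f"unknown tasks: {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(0)

    prefs = np.arange(n_neurons) % n_stimuli + 1  # balanced 1..n_stimuli
    amps = truth.amplitude * (1.0 + 0.1 * rng.standard_normal(n_neurons))
    amps = np.maximum(amps, 0.1 * truth.amplitude)
    stimuli = np.arange(1, n_stimuli + 1)

    rows = []
    for task in tasks:
        gain = truth.task_gains.get(task, 1.0)
        for tb in time_bins:
            delta = truth.shift_at(tb) if task == "categorization" else 0.0
            for s in stimuli:
                s_eff = s + truth.polarity(int(s)) * delta
                mean = gain * amps * np.exp(
                    -0.5 * ((prefs - s_eff) / truth.tuning_width) ** 2)
                rate = mean
                if truth.noise_sd > 0:
                    rate = np.maximum(
                        mean + rng.normal(0.0, truth.noise_sd, size=n_neurons), 0.0)
                rows.append(pd.DataFrame({
                    "neuron_id": np.arange(n_neurons),
                    "task": task,
                    "stimulus": int(s),
                    "time_bin_ms": float(tb),
                    "rate": rate,
                }))
    table = pd.concat(rows, ignore_index=True)
    return validate_recording_table(table), truth


def classify_preferred_stimulus(table: pd.DataFrame,
                                task: str = "fixation") -> pd.Series:
    """Preferred stimulus per neuron: argmax of the stimulus-mean response.

    Responses are averaged over time bins within the reference task
    (fixation by default, the task-neutral condition); ties break to the
    lowest stimulus index.
    """
    validate_recording_table(table)
    sub = table[table["task"] == task]
    if sub.empty:
        raise InvalidInputError(f"task {task!r} absent from table")
    mean = (sub.groupby(["neuron_id", "stimulus"])["rate"].mean().unstack())
    expected = set(range(1, N_STIMULI + 1))
    gaps = {}
    for nid, row in mean.iterrows():
        missing = expected - set(row.dropna().index)
        if missing:
            gaps[nid] = sorted(missing)
    if gaps:
        raise InvalidInputError(f"neurons with missing stimuli: {gaps}")
    # idxmax returns the first (lowest) index on ties
    prefs = mean[sorted(mean.columns)].idxmax(axis=1)
    prefs.name = "preferred_stimulus"
    return prefs.astype(int)


def normalize_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every neuron's rates by its maximum fixation-task rate.

    Neurons whose fixation maximum is zero carry no usable signal and are
    dropped with a warning.
    """
    validate_recording_table(table)
    fix = table[table["task"] == "fixation"]
    if fix.empty:
        raise InvalidInputError("fixation task required for normalization")
    fix_max = fix.groupby("neuron_id")["rate"].max()
    missing = set(table["neuron_id"].unique()) - set(fix_max.index)
    if missing:
        raise InvalidInputError(f"neurons lacking fixation rows: {sorted(missing)[:5]}")
    dead = fix_max[fix_max == 0.0].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} neuron(s) with zero fixation max",
                      RuntimeWarning)
    out = table[~table["neuron_id"].isin(dead)].copy()
    out["rate"] = out["rate"] / out["neuron_id"].map(fix_max)
    return out


def population_profile(table: pd.DataFrame, preferences: pd.Series, task: str,
                       stimulus_index: int, time_bin: float) -> np.ndarray:
    """11-vector of group-mean rates; element k averages neurons preferring k.

    Empty preference groups yield NaN and are skipped by the Gaussian fit.
    """
    sub = table[(table["task"] == task)
                & (table["stimulus"] == stimulus_index)
                & (table["time_bin_ms"] == time_bin)]
    if sub.empty:
        raise InvalidInputError(
            f"no rows for task={task} stimulus={stimulus_index} bin={time_bin}")
    merged = sub.merge(preferences.rename("pref"), left_on="neuron_id",
                       right_index=True)
    means = merged.groupby("pref")["rate"].mean()
    profile = np.full(N_STIMULI, np.nan)
    for k, v in means.items():
        profile[int(k) - 1] = v
    return profile


def _gauss_residuals(p, x, y):
    a, mu, sigma = p
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) - y


def fit_gaussian_profile(profile: np.ndarray,
                         x0_hints: Optional[Sequence[float]] = None
                         ) -> PopulationProfileFit:
    """Unweighted least-squares Gaussian fit over stimulus indices 1..11.

    Multi-start over mu0 in {argmax, activity-weighted mean} (or caller
    hints); the best-RSS solution is returned.  Fits whose peak falls
    outside [1, 11] or whose width exceeds the stimulus range are flagged
    unreliable rather than reported as spurious peaks.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size != N_STIMULI:
        raise InvalidInputError("profile must have 11 elements")
    mask = np.isfinite(profile)
    if mask.sum() < 5:
        raise InvalidInputError("need at least 5 non-missing profile elements")
    x = np.arange(1, N_STIMULI + 1, dtype=float)[mask]
    y = profile[mask]

    amp0 = max(float(y.max()), 1e-6)
    if x0_hints is None:
        w = np.maximum(y, 0.0)
        weighted = float((x * w).sum() / w.sum()) if w.sum() > 0 else float(x.mean())
        x0_hints = (float(x[int(np.argmax(y))]), weighted)

    best = None
    diagnostics = {}
    for mu0 in x0_hints:
        for sigma0 in (2.0, 4.0):
            try:
                res = least_squares(_gauss_residuals, x0=[amp0, mu0, sigma0],
                                    args=(x, y), method="lm", max_nfev=2000)
            except Exception as exc:  # pragma: no cover - scipy internal failure
                diagnostics[(mu0, sigma0)] = repr(exc)
                continue
            if not res.success and not np.all(np.isfinite(res.x)):
                diagnostics[(mu0, sigma0)] = res.message
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[0]:
                best = (rss, res.x)
    if best is None:
        raise FitFailedError("Gaussian fit failed from all starts", diagnostics)
    rss, (a, mu, sigma) = best
    a, sigma = float(a), float(abs(sigma))
    reliable = (1.0 <= mu <= 11.0) and (0 < sigma <= N_STIMULI) and a > 0
    return PopulationProfileFit(peak_locus=float(mu), amplitude=a,
                                width=sigma, rss=rss, reliable=reliable)


def _shift_matrix(table: pd.DataFrame, preferences: pd.Series, task_a: str,
                  task_b: str, stimuli: Sequence[int], time_bins: Sequence[float],
                  hints: Optional[dict] = None) -> np.ndarray:
    raw = np.empty((len(stimuli), len(time_bins)))
    for i, s in enumerate(stimuli):
        for j, tb in enumerate(time_bins):
            fits = {}
            for task in (task_a, task_b):
                prof = population_profile(table, preferences, task, s, tb)
                hint = hints.get((task, s, tb)) if hints else None
                fits[task] = fit_gaussian_profile(
                    prof, x0_hints=(hint,) if hint is not None else None)
            raw[i, j] = fits[task_a].peak_locus - fits[task_b].peak_locus
    return raw


def peak_shift_dynamics(table: pd.DataFrame, task_a: str = "categorization",
                        task_b: str = "discrimination",
                        preferences: Optional[pd.Series] = None) -> PeakShiftCurve:
    """Peak-locus difference between two tasks over stimuli 2..10 and bins.

    The table is fixation-normalized internally (idempotent for
    already-normalized data only if the fixation max is 1).  Each
    stimulus's curve is divided by its |difference| at the 100 ms bin;
    when that value is below the floor the curve is reported raw and
    flagged.
    """
    validate_recording_table(table)
    for task in (task_a, task_b):
        if not (table["task"] == task).any():
            raise InvalidInputError(f"task {task!r} absent from table")
    if NORMALIZATION_BIN_MS not in set(table["time_bin_ms"].unique()):
        raise InvalidInputError("time bins must include the 100 ms bin")
    if preferences is None:
        preferences = classify_preferred_stimulus(table)
    norm_table = normalize_rates(table)
    time_bins = np.sort(table["time_bin_ms"].unique())
    stimuli = np.array(ANALYSIS_STIMULI)

    raw = _shift_matrix(norm_table, preferences, task_a, task_b,
                        stimuli, time_bins)
    norm_idx = int(np.where(time_bins == NORMALIZATION_BIN_MS)[0][0])
    norm_value = np.abs(raw[:, norm_idx])
    normalized = norm_value >= NORMALIZATION_FLOOR
    shift = raw.copy()
    shift[normalized] = raw[normalized] / norm_value[normalized, None]
    return PeakShiftCurve(stimuli=stimuli, time_bins=time_bins, raw_shift=raw,
                          shift=shift, norm_value=norm_value,
                          normalized=normalized, task_a=task_a, task_b=task_b)


def bootstrap_peak_sd(table: pd.DataFrame, task_a: str = "categorization",
                      task_b: str = "discrimination", n_resamples: int = 100,
                      rng: Optional[np.random.Generator] = None,
                      curve: Optional[PeakShiftCurve] = None) -> np.ndarray:
    """Neuron-level bootstrap SD of the reported shift, per (stimulus, bin).

    Neurons are resampled with replacement keeping their original preferred
    stimulus (resampling across neurons, not re-classifying), the pipeline
    is recomputed, and each resample's raw shifts are scaled by the
    original curve's normalization decision so the SDs are error bars for
    the reported curve.
    """
    if n_resamples < 2:
        raise InvalidParameterError("n_resamples must be >= 2")
    if rng is None:
        rng = np.random.default_rng(0)
    validate_recording_table(table)
    preferences = classify_preferred_stimulus(table)
    if curve is None:
        curve = peak_shift_dynamics(table, task_a, task_b, preferences)
    norm_table = normalize_rates(table)
    neuron_ids = np.asarray(sorted(norm_table["neuron_id"].unique()))
    n_neurons = neuron_ids.size

    # dense rate tensor (neuron, task, stimulus, bin) for fast resampling
    time_bins = curve.time_bins
    tasks = (task_a, task_b)
    id_pos = {nid: i for i, nid in enumerate(neuron_ids)}
    bin_pos = {tb: j for j, tb in enumerate(time_bins)}
    R = np.full((n_neurons, 2, N_STIMULI, time_bins.size), np.nan)
    for k, task in enumerate(tasks):
        sub = norm_table[norm_table["task"] == task]
        ni = sub["neuron_id"].map(id_pos).to_numpy()
        si = sub["stimulus"].to_numpy(dtype=int) - 1
        bi = sub["time_bin_ms"].map(bin_pos).to_numpy()
        R[ni, k, si, bi] = sub["rate"].to_numpy()
    pref_idx = preferences.loc[neuron_ids].to_numpy(dtype=int) - 1
    group_mask = np.zeros((N_STIMULI, n_neurons))
    group_mask[pref_idx, np.arange(n_neurons)] = 1.0

    # original fits seed the bootstrap fits (single-start for speed)
    hints = {}
    for s in curve.stimuli:
        for tb in time_bins:
            for task in (task_a, task_b):
                prof = population_profile(norm_table, preferences, task, int(s), tb)
                hints[(task, int(s), tb)] = fit_gaussian_profile(prof).peak_locus

    scale = np.where(curve.normalized, curve.norm_value, 1.0)
    flat = np.nan_to_num(R).reshape(n_neurons, -1)
    finite = np.isfinite(R).reshape(n_neurons, -1).astype(float)
    samples = np.empty((n_resamples, curve.stimuli.size, time_bins.size))
    for b in range(n_resamples):
        w = np.bincount(rng.integers(n_neurons, size=n_neurons),
                        minlength=n_neurons).astype(float)
        gw = group_mask * w  # (pref, neuron) weights for this resample
        num = (gw @ flat).reshape(N_STIMULI, 2, N_STIMULI, time_bins.size)
        den = (gw @ finite).reshape(N_STIMULI, 2, N_STIMULI, time_bins.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            profiles = num / den  # NaN where a preference group is empty
        for i, s in enumerate(curve.stimuli):
            for j, tb in enumerate(time_bins):
                loci = []
                for k, task in enumerate(tasks):
                    prof = profiles[:, k, int(s) - 1, j]
                    fit = fit_gaussian_profile(
                        prof, x0_hints=(hints[(task, int(s), tb)],))
                    loci.append(fit.peak_locus)
                samples[b, i, j] = loci[0] - loci[1]
        samples[b] /= scale[:, None]
    return samples.std(axis=0, ddof=1)


def boundary_consistency(curve: PeakShiftCurve,
                         late_window: Tuple[float, float] = (450.0, 550.0)
                         ) -> BoundaryResult:
    """Average late-window shifts and locate the sign-change stimulus.

    The crossing is interpolated linearly between the adjacent stimuli
    where the late-window mean changes from negative to positive; ``None``
    when no sign change occurs.
    """
    lo, hi = late_window
    in_win = (curve.time_bins >= lo) & (curve.time_bins <= hi)
    if not in_win.any():
        raise InvalidParameterError("late window contains no time bins")
    late_mean = curve.shift[:, in_win].mean(axis=1)

    crossing = None
    for i in range(late_mean.size - 1):
        a, b = late_mean[i], late_mean[i + 1]
        if a < 0 <= b and b > 0:
            s_a, s_b = curve.stimuli[i], curve.stimuli[i + 1]
            crossing = float(s_a + (0.0 - a) / (b - a) * (s_b - s_a))
            break
    return BoundaryResult(stimuli=curve.stimuli, late_mean=late_mean,
                          crossing=crossing)
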