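"""Whole-cell patch-clamp kinetics: peak detection, desensitization fits,
weighted time constants, equilibrium and resensitization measures.

Conventions: inward currents are negative (cells held at −60 mV); all
percentages are computed on magnitudes. The decay phase is fit from the
point where the current has decayed to 95% of the peak through the end of
the agonist pulse (minus a short guard), with one or two exponentials plus
a steady-state offset. When two exponentials are used the weighted
desensitization time constant is

    tau_w = tau_f * A_f / (A_f + A_s) + tau_s * A_s / (A_f + A_s)

with amplitudes referenced to the peak time. Steady state is
operationalized as the mean of the final 50 ms of the pulse.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .errors import FitError, NoResponseError, ParameterError, WindowError

__all__ = [
    "CurrentTrace",
    "PeakResult",
    "DesensFit",
    "TimecourseFit",
    "read_trace_csv",
    "write_trace_csv",
    "detect_peak",
    "fit_desensitization",
    "equilibrium_pct",
    "resensitization_pct",
    "fit_timecourse",
    "summarize",
]

_STEADY_WINDOW_S = 0.050   # averaging window for the steady-state current
_END_TRIM_S = 0.010        # guard before pulse end excluded from fits
_TROUGH_SMOOTH_MS = 2.0    # moving average for trough landmark detection


@dataclass
class CurrentTrace:
    """A uniformly sampled current recording with stimulus epochs."""

    times: np.ndarray      # s
    currents: np.ndarray   # pA
    epochs: list[tuple[float, float]]
    sample_rate: float     # Hz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.shape != self.currents.shape:
            raise ParameterError("times and currents differ in length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ParameterError("sampling is not uniform")
        if not self.epochs:
            raise ParameterError("at least one stimulus epoch is required")
        t_lo, t_hi = self.times[0], self.times[-1]
        for (a, b) in self.epochs:
            if not (t_lo <= a < b <= t_hi + 1.0 / self.sample_rate):
                raise ParameterError(f"epoch ({a}, {b}) outside record")

    def epoch_indices(self, epoch: tuple[float, float]) -> np.ndarray:
        a, b = epoch
        return np.flatnonzero((self.times >= a) & (self.times < b))


def read_trace_csv(path: str | Path, sample_rate: float | None = None,
                   metadata: dict | None = None) -> CurrentTrace:
    """Read a (time_s, current_pA[, stimulus_flag]) CSV; epochs are taken
    from rising/falling edges of the stimulus flag."""
    df = pd.read_csv(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    times = df.time_s.to_numpy(dtype=float)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(times)))
    epochs: list[tuple[float, float]] = []
    if "stimulus_flag" in df.columns:
        flag = df.stimulus_flag.to_numpy() > 0
        edges = np.flatnonzero(np.diff(flag.astype(int)))
        starts = [times[i + 1] for i in edges if not flag[i]]
        ends = [times[i + 1] for i in edges if flag[i]]
        if flag[0]:
            starts.insert(0, times[0])
        if flag[-1]:
            ends.append(times[-1])
        epochs = list(zip(starts, ends))
    if not epochs:
        epochs = [(times[0], times[-1])]
    return CurrentTrace(times=times, currents=df.current_pA.to_numpy(dtype=float),
                        epochs=epochs, sample_rate=sample_rate,
                        metadata=metadata or {})


def write_trace_csv(trace: CurrentTrace, path: str | Path) -> Path:
    flag = np.zeros(len(trace.times), dtype=int)
    for ep in trace.epochs:
        flag[trace.epoch_indices(ep)] = 1
    df = pd.DataFrame(dict(time_s=trace.times, current_pA=trace.currents,
                           stimulus_flag=flag))
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")
    return Path(path)


@dataclass
class PeakResult:
    amplitude: float   # pA, baseline-subtracted, signed
    time: float        # s
    index: int
    baseline: float    # pA


def _baseline(trace: CurrentTrace, epoch: tuple[float, float],
              window_s: float = 0.050) -> tuple[float, float]:
    """(mean, sd) of the pre-pulse baseline."""
    a = epoch[0]
    mask = (trace.times >= a - window_s) & (trace.times < a)
    if not mask.any():  # pulse starts at the very beginning of the record
        mask = np.zeros_like(mask)
        mask[:max(2, int(0.001 * trace.sample_rate))] = True
    seg = trace.currents[mask]
    return float(seg.mean()), float(seg.std())


def _smooth(y: np.ndarray, n: int) -> np.ndarray:
    """Moving average with edge padding (no zero-padding artefacts)."""
    if n <= 1:
        return y
    pad = n // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, np.ones(n) / n, mode="valid")[:len(y)]


def detect_peak(trace: CurrentTrace, epoch: tuple[float, float] | None = None,
                smooth_ms: float = 0.0) -> PeakResult:
    """Baseline-subtracted extremum of the current within an epoch.

    The raw extremum is exact on noise-free traces; for a noise-robust
    peak estimate use the fitted peak reported by
    :func:`fit_desensitization`.
    """
    epoch = epoch or trace.epochs[0]
    idx = trace.epoch_indices(epoch)
    if idx.size < 10:
        raise WindowError("epoch contains fewer than 10 samples")
    base, base_sd = _baseline(trace, epoch)
    y = trace.currents[idx] - base
    if smooth_ms > 0:
        y = _smooth(y, max(1, int(round(smooth_ms * 1e-3 * trace.sample_rate))))
    k = int(np.argmax(np.abs(y)))
    amp = float(y[k])
    if abs(amp) < max(6.0 * base_sd, 1e-9):
        raise NoResponseError(
            f"no response above noise floor (|peak|={abs(amp):.3g} pA, "
            f"baseline sd={base_sd:.3g} pA)")
    return PeakResult(amplitude=amp, time=float(trace.times[idx[k]]),
                      index=int(idx[k]), baseline=base)


@dataclass
class DesensFit:
    """Desensitization kinetics of one agonist pulse."""

    n_exp: int
    tau_f: float                 # ms
    tau_s: float | None          # ms; None for a mono-exponential fit
    A_f: float                   # pA, referenced to the peak time, signed
    A_s: float | None
    tau_w: float                 # ms, amplitude-weighted
    peak: float                  # pA, raw baseline-subtracted extremum
    peak_fit: float              # pA, fitted value extrapolated to peak time
    equilibrium_pct: float       # steady state as % of raw peak
    equilibrium_pct_fit: float   # fitted plateau as % of fitted peak
    resensitization_pct: float
    fit_window: tuple[float, float]  # s
    residual_sd: float           # pA
    baseline: float = 0.0
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tau_f <= 0 or (self.tau_s is not None and self.tau_s <= 0):
            raise FitError("non-positive time constant")
        if self.tau_s is not None and not self.tau_f < self.tau_s:
            raise FitError("tau_f must be < tau_s")
        lo = self.tau_f
        hi = self.tau_s if self.tau_s is not None else self.tau_f
        if not (lo - 1e-9 <= self.tau_w <= hi + 1e-9):
            raise FitError(f"tau_w={self.tau_w} outside [{lo}, {hi}]")


def _multi_exp(t: np.ndarray, c: float, amps: Sequence[float],
               taus: Sequence[float]) -> np.ndarray:
    y = np.full_like(t, c, dtype=float)
    for a, tau in zip(amps, taus):
        y = y + a * np.exp(-t / tau)
    return y


def _fit_n_exp(t: np.ndarray, y: np.ndarray, n_exp: int) -> dict:
    """Least-squares fit of y = c + sum a_i exp(-t/tau_i), a_i >= 0."""
    c0 = float(y[t >= t[-1] - _STEADY_WINDOW_S].mean())
    a_tot = max(float(y[0] - c0), 1e-9)
    # crude 1/e crossing for an initial tau
    target = c0 + a_tot / np.e
    below = np.flatnonzero(y <= target)
    tau0 = float(t[below[0]]) if below.size else float(t[-1] / 3)
    tau0 = min(max(tau0, 2.0 / len(t) * float(t[-1])), float(t[-1]))
    tau_min, tau_max = 1e-5, 50.0

    params = Parameters()
    params.add("c", value=c0)
    if n_exp == 1:
        params.add("a1", value=a_tot, min=0.0)
        params.add("tau1", value=tau0, min=tau_min, max=tau_max)
    else:
        params.add("a1", value=0.6 * a_tot, min=0.0)
        params.add("tau1", value=tau0 / 3.0, min=tau_min, max=tau_max)
        params.add("a2", value=0.4 * a_tot, min=0.0)
        params.add("tau2", value=min(tau0 * 3.0, tau_max), min=tau_min,
                   max=tau_max)

    def residual(p):
        amps = [p[f"a{i}"].value for i in range(1, n_exp + 1)]
        taus = [p[f"tau{i}"].value for i in range(1, n_exp + 1)]
        return _multi_exp(t, p["c"].value, amps, taus) - y

    result = minimize(residual, params, method="least_squares")
    if not result.success:
        raise FitError(f"desensitization fit failed: {result.message}")
    p = result.params
    amps = [float(p[f"a{i}"].value) for i in range(1, n_exp + 1)]
    taus = [float(p[f"tau{i}"].value) for i in range(1, n_exp + 1)]
    for tau in taus:
        if tau < tau_min * 1.01 or tau > tau_max * 0.99:
            warnings.warn(f"fitted tau={tau:.4g} s is at a parameter bound")
    order = np.argsort(taus)
    amps = [amps[i] for i in order]
    taus = [taus[i] for i in order]
    resid = residual(p)
    n, k = len(y), len(result.params)
    ssr = float(np.sum(resid ** 2))
    aicc = n * np.log(max(ssr, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aicc += 2 * k * (k + 1) / (n - k - 1)
    return dict(c=float(p["c"].value), amps=amps, taus=taus,
                residual_sd=float(np.std(resid)), aicc=aicc)


def fit_desensitization(trace: CurrentTrace,
                        epoch: tuple[float, float] | None = None,
                        n_exp: Literal[1, 2, "auto"] = "auto") -> DesensFit:
    """Fit the decay phase of one agonist pulse.

    The fit starts at the first post-peak sample where the current has
    decayed to 95% of the peak and ends 10 ms before the pulse end. With
    ``n_exp="auto"``, one vs two exponentials is chosen by the
    small-sample-corrected Akaike criterion.
    """
    epoch = epoch or trace.epochs[0]
    pk = detect_peak(trace, epoch)
    sign = 1.0 if pk.amplitude >= 0 else -1.0
    mag = abs(pk.amplitude)
    idx = trace.epoch_indices(epoch)
    y_all = sign * (trace.currents[idx] - pk.baseline)
    k_peak = int(np.searchsorted(idx, pk.index))

    after = np.flatnonzero(y_all[k_peak:] <= 0.95 * mag)
    if after.size == 0:
        raise FitError("current never decays to 95% of the peak")
    w0 = k_peak + int(after[0])
    t_end = trace.times[idx[-1]] - _END_TRIM_S
    w1 = int(np.searchsorted(trace.times[idx], t_end))
    if w1 - w0 < 20:
        raise FitError(f"decay window has {w1 - w0} samples (< 20)")
    t = trace.times[idx[w0:w1]] - trace.times[idx[w0]]
    y = y_all[w0:w1]

    if n_exp == "auto":
        f1 = _fit_n_exp(t, y, 1)
        f2 = _fit_n_exp(t, y, 2)
        fit, chosen = (f1, 1) if f1["aicc"] <= f2["aicc"] else (f2, 2)
    else:
        chosen = int(n_exp)
        if chosen not in (1, 2):
            raise ParameterError("n_exp must be 1, 2 or 'auto'")
        fit = _fit_n_exp(t, y, chosen)

    # amplitudes referenced back to the response onset (the mid-rise
    # crossing preceding the extremum), which locates the true peak time
    # to within a sample even on noisy traces
    below_half = np.flatnonzero(y_all[:k_peak + 1] <= 0.5 * mag)
    k_on = min(int(below_half[-1]) + 1, k_peak) if below_half.size else 0
    dt0 = trace.times[idx[w0]] - trace.times[idx[k_on]]
    amps_pk = [a * np.exp(dt0 / tau) for a, tau in zip(fit["amps"], fit["taus"])]
    taus_ms = [tau * 1e3 for tau in fit["taus"]]
    a_sum = sum(amps_pk)
    if a_sum <= 0:
        raise FitError("fitted decay has zero amplitude")
    tau_w = sum(tau * a for tau, a in zip(taus_ms, amps_pk)) / a_sum
    peak_fit = sign * (fit["c"] + a_sum)

    # steady state: mean of the last 50 ms of the pulse (raw), and plateau
    t_pulse_end = trace.times[idx[-1]]
    ss_mask = trace.times[idx] >= t_pulse_end - _STEADY_WINDOW_S
    i_ss = float(y_all[ss_mask].mean())
    eq_raw = 100.0 * i_ss / mag
    eq_fit = 100.0 * fit["c"] / abs(peak_fit) if peak_fit else float("nan")

    notes: list[str] = []
    try:
        resens = resensitization_pct(trace, epoch, _notes=notes)
    except WindowError as exc:
        resens = float("nan")
        notes.append(f"resensitization not measurable: {exc}")

    if chosen == 1:
        tau_f, tau_s = taus_ms[0], None
        A_f, A_s = sign * amps_pk[0], None
    else:
        tau_f, tau_s = taus_ms
        A_f, A_s = sign * amps_pk[0], sign * amps_pk[1]
    return DesensFit(
        n_exp=chosen, tau_f=tau_f, tau_s=tau_s, A_f=A_f, A_s=A_s,
        tau_w=tau_w, peak=pk.amplitude, peak_fit=peak_fit,
        equilibrium_pct=eq_raw, equilibrium_pct_fit=eq_fit,
        resensitization_pct=resens,
        fit_window=(float(trace.times[idx[w0]]), float(trace.times[idx[w1 - 1]])),
        residual_sd=fit["residual_sd"], baseline=pk.baseline, notes=notes)


def equilibrium_pct(obj: "DesensFit | CurrentTrace",
                    epoch: tuple[float, float] | None = None) -> float:
    """Steady-state current as a percentage of the peak current.

    The steady state is the mean of the final 50 ms of the pulse. Accepts
    a fitted :class:`DesensFit` (returns its raw-steady-state measure; the
    fitted-plateau variant is on the fit object) or a trace.
    """
    if isinstance(obj, DesensFit):
        return obj.equilibrium_pct
    trace = obj
    epoch = epoch or trace.epochs[0]
    pk = detect_peak(trace, epoch)
    idx = trace.epoch_indices(epoch)
    sign = 1.0 if pk.amplitude >= 0 else -1.0
    y = sign * (trace.currents[idx] - pk.baseline)
    ss_mask = trace.times[idx] >= trace.times[idx[-1]] - _STEADY_WINDOW_S
    return 100.0 * float(y[ss_mask].mean()) / abs(pk.amplitude)


def resensitization_pct(trace: CurrentTrace,
                        epoch: tuple[float, float] | None = None,
                        smooth_ms: float = _TROUGH_SMOOTH_MS,
                        _notes: list[str] | None = None) -> float:
    """Excess steady-state current after desensitization, % of peak.

    Measured as the difference between the end-of-pulse current (mean of
    the last 50 ms) and the post-peak trough of a lightly smoothed copy of
    the trace, clamped at zero. Smoothing is applied only to locate the
    trough, never to the averaged values.
    """
    epoch = epoch or trace.epochs[0]
    pk = detect_peak(trace, epoch)
    idx = trace.epoch_indices(epoch)
    sign = 1.0 if pk.amplitude >= 0 else -1.0
    y = sign * (trace.currents[idx] - pk.baseline)
    k_peak = int(np.searchsorted(idx, pk.index))
    if trace.times[idx[-1]] - pk.time < 0.5:
        raise WindowError("epoch extends less than 0.5 s past the peak")
    n_sm = max(1, int(round(smooth_ms * 1e-3 * trace.sample_rate)))
    y_sm = _smooth(y, n_sm)
    post = y_sm[k_peak + 1:]
    k_trough = k_peak + 1 + int(np.argmin(post))
    ss_mask = trace.times[idx] >= trace.times[idx[-1]] - _STEADY_WINDOW_S
    i_end = float(y[ss_mask].mean())
    i_trough = float(y_sm[k_trough])
    last_start = int(np.flatnonzero(ss_mask)[0])
    if k_trough >= last_start:
        if _notes is not None:
            _notes.append("trough at epoch end; decay still monotone, "
                          "resensitization reported as 0")
        return 0.0
    return max(0.0, 100.0 * (i_end - i_trough) / abs(pk.amplitude))


@dataclass
class TimecourseFit:
    """Single-exponential fit of a sweep-indexed τ series."""

    tau_mod_s: float
    start: float     # ms (fitted value at time 0)
    plateau: float   # ms
    direction: str   # "NAM" (plateau < start), "PAM" (>), or "none"
    degenerate: bool
    residual_sd: float


def fit_timecourse(sweep_taus: "pd.DataFrame | np.ndarray",
                   sweep_interval: float = 5.0) -> TimecourseFit:
    """Fit tau(t) = plateau + (start - plateau) exp(-t / tau_mod).

    ``sweep_taus`` is either a frame with ``time_s``/``tau_ms`` columns or
    a plain array of per-sweep τ values spaced ``sweep_interval`` s apart.
    The wash-in time constant is reported in seconds.
    """
    if isinstance(sweep_taus, pd.DataFrame):
        t = sweep_taus.time_s.to_numpy(dtype=float)
        y = sweep_taus.tau_ms.to_numpy(dtype=float)
    else:
        y = np.asarray(sweep_taus, dtype=float)
        t = np.arange(len(y)) * sweep_interval
    if len(y) < 5:
        raise ParameterError("need at least 5 sweeps")

    span = float(y[0] - y[-1])
    if np.ptp(y) < 1e-12:  # exactly flat series
        return TimecourseFit(tau_mod_s=float("nan"), start=float(y[0]),
                             plateau=float(y[0]), direction="none",
                             degenerate=True, residual_sd=0.0)
    params = Parameters()
    params.add("plateau", value=float(y[-1]))
    params.add("delta", value=span if span else float(np.ptp(y)))
    params.add("tau_mod", value=max(float(t[-1]) / 3.0, sweep_interval),
               min=1e-3, max=1e5)

    def residual(p):
        return (p["plateau"].value + p["delta"].value
                * np.exp(-t / p["tau_mod"].value) - y)

    result = minimize(residual, params, method="least_squares")
    if not result.success:
        raise FitError(f"time-course fit failed: {result.message}")
    p = result.params
    start = float(p["plateau"].value + p["delta"].value)
    plateau = float(p["plateau"].value)
    resid_sd = float(np.std(residual(p)))
    degenerate = abs(start - plateau) <= 2.0 * resid_sd
    if degenerate:
        direction = "none"
    else:
        direction = "NAM" if plateau < start else "PAM"
    return TimecourseFit(tau_mod_s=float(p["tau_mod"].value), start=start,
                         plateau=plateau, direction=direction,
                         degenerate=degenerate, residual_sd=resid_sd)


def summarize(fits: Sequence[DesensFit], labels: Sequence[str]) -> pd.DataFrame:
    """Per-group n, mean and SEM of τw, equilibrium %, resensitization %
    and peak amplitude. SEM is blank (NaN) for single-cell groups."""
    if len(fits) != len(labels):
        raise ParameterError("fits and labels differ in length")
    df = pd.DataFrame(dict(
        group=list(labels),
        tau_w=[f.tau_w for f in fits],
        equilibrium_pct=[f.equilibrium_pct for f in fits],
        resensitization_pct=[f.resensitization_pct for f in fits],
        peak=[f.peak for f in fits]))
    rows = []
    for group, sub in df.groupby("group", sort=True):
        row: dict = dict(group=group, n=len(sub))
        for col in ("tau_w", "equilibrium_pct", "resensitization_pct", "peak"):
            vals = sub[col].to_numpy()
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sem"] = (float(vals.std(ddof=1) / np.sqrt(len(vals)))
                                 if len(vals) > 1 else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
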