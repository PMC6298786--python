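"""F–V extraction and Boltzmann decomposition of voltage-clamp fluorometry.

Fluorescent probes on the voltage-sensor domain (TMRM at G214C or Q208C) or
in the catalytic region (Anap at position 555) report conformational changes
during depolarizing pulses.  The steady-state fluorescence–voltage (F–V)
relation is described by one Boltzmann component,

    F(V) = A / (1 + exp((V½ − V) / s)),

or by the sum of two such components with distinct half-activation voltages
V½ and slope factors s.  Slopes are constrained positive; the direction of
the fluorescence change is carried by the sign of the amplitude A.  (The
equivalent falling-sigmoid convention negates the slope; the midpoint
identity F(V½) = A/2 and all fitted |s| are unchanged.)  For two-component
fits the per-component amplitude ratio Aᵢ/(A₁+A₂) quantifies how much of the
total change each transition carries.

Kinetics of the fluorescence change are summarized by the time to
half-maximum (t½) and by single- or double-exponential fits with a
slow-component fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitError, NormalizationError, ProtocolError

__all__ = [
    "FluorescenceSweepSet",
    "FVDataset",
    "BoltzmannFit",
    "KineticsResult",
    "boltzmann",
    "boltzmann_sum",
    "extract_fv",
    "fit_boltzmann",
    "select_model",
    "compute_t_half",
    "fit_fluorescence_kinetics",
]


def boltzmann(v, amplitude, v_half, slope):
    """Rising Boltzmann sigmoid: amplitude / (1 + exp((v_half − v)/slope))."""
    x = np.clip((v_half - np.asarray(v, dtype=float)) / slope, -500.0, 500.0)
    return amplitude / (1.0 + np.exp(x))


def boltzmann_sum(v, components):
    """Sum of (amplitude, v_half, slope) Boltzmann components."""
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    for a, vh, s in components:
        out += boltzmann(v, a, vh, s)
    return out


@dataclass
class FluorescenceSweepSet:
    """Per-voltage ΔF/F time series on a common timebase.

    ``traces`` maps test voltage (mV) to a ΔF/F array sampled at
    ``time_ms``; the pulse spans ``pulse_window_ms`` and the baseline window
    precedes its onset.
    """

    time_ms: np.ndarray
    traces: Mapping[float, np.ndarray]
    probe: str = "TMRM_G214C"
    pulse_window_ms: tuple[float, float] = (10.0, 510.0)
    baseline_window_ms: tuple[float, float] = (0.0, 10.0)
    holding_mV: float = -60.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        n = len(self.time_ms)
        for v, tr in self.traces.items():
            if len(tr) != n:
                raise ProtocolError(f"trace at {v} mV has {len(tr)} samples, expected {n}")
        if self.baseline_window_ms[1] > self.pulse_window_ms[0]:
            raise ProtocolError("baseline window must precede pulse onset")

    def voltages(self) -> np.ndarray:
        return np.array(sorted(self.traces), dtype=float)


@dataclass
class FVDataset:
    """Fluorescence–voltage points with their extraction provenance."""

    voltage_mV: np.ndarray
    f: np.ndarray
    strategy: str
    normalized_at_mV: float | None = None

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if np.any(np.diff(self.voltage_mV) <= 0):
            raise ProtocolError("F–V voltages must be strictly increasing")


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann decomposition of an F–V curve.

    ``components`` are (amplitude, v_half_mV, slope_mV) triples sorted by
    v_half; ``ratios_pct`` are the amplitude fractions for two-component
    fits.  ``covariance`` is ordered (A₁, V½₁, s₁[, A₂, V½₂, s₂]).
    """

    n_components: int
    components: list[tuple[float, float, float]]
    ratios_pct: list[float]
    residual_norm: float
    covariance: np.ndarray | None
    n_points: int

    @property
    def rss(self) -> float:
        return self.residual_norm**2

    @property
    def n_params(self) -> int:
        return 3 * self.n_components

    def predict(self, v):
        return boltzmann_sum(v, self.components)

    def aicc(self) -> float:
        """Small-sample corrected Akaike criterion for least squares."""
        n, p = self.n_points, self.n_params
        if n - p - 2 <= 0:
            return float("inf")
        # +1 free parameter for the implicit noise variance
        k = p + 1
        return n * np.log(max(self.rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    def as_rows(self, construct: str = "") -> list[dict]:
        rows = []
        for i, (a, vh, s) in enumerate(self.components, start=1):
            rows.append(
                {
                    "construct": construct,
                    "component": i,
                    "ratio_pct": self.ratios_pct[i - 1] if self.ratios_pct else float("nan"),
                    "amplitude": a,
                    "v_half_mV": vh,
                    "slope_mV": s,
                }
            )
        return rows


@dataclass
class KineticsResult:
    """t½ plus exponential decomposition of one fluorescence trace."""

    t_half_ms: float
    components: list[tuple[float, float]]  # (amplitude, tau_ms), fast first
    slow_fraction_pct: float
    residual_norm: float


# ---------------------------------------------------------------------------
# extraction


def extract_fv(
    sweeps: FluorescenceSweepSet,
    strategy: str = "last_1ms_mean",
    reference_mV: float | None = None,
    normalize: bool = False,
) -> FVDataset:
    """One F value per test voltage, by one of three strategies.

    ``last_1ms_mean`` averages the final 1 ms of the pulse; ``endpoint``
    takes the last in-pulse sample; ``at_reference_peak_time`` samples every
    trace at the peak time of the reference-voltage trace (the convention
    for probes whose signal is transient, e.g. Q208C-TMRM read at the peak
    of the 200 mV trace).  ``normalize`` divides all points by the value at
    ``reference_mV``.
    """
    t = sweeps.time_ms
    onset, end = sweeps.pulse_window_ms
    if end > t[-1] + 1e-9 or onset < t[0] - 1e-9:
        raise ProtocolError("pulse window outside sweep")
    volts = sweeps.voltages()

    if strategy == "last_1ms_mean":
        mask = (t >= end - 1.0 - 1e-9) & (t <= end + 1e-9)
        values = np.array([float(np.mean(sweeps.traces[v][mask])) for v in volts])
    elif strategy == "endpoint":
        idx = int(np.searchsorted(t, end + 1e-9) - 1)
        values = np.array([float(sweeps.traces[v][idx]) for v in volts])
    elif strategy == "at_reference_peak_time":
        if reference_mV is None or reference_mV not in sweeps.traces:
            raise ProtocolError(f"reference trace {reference_mV!r} mV not present")
        ref = sweeps.traces[reference_mV]
        in_pulse = (t >= onset) & (t <= end)
        seg = ref[in_pulse]
        peak_idx = np.flatnonzero(in_pulse)[int(np.argmax(np.abs(seg)))]
        values = np.array([float(sweeps.traces[v][peak_idx]) for v in volts])
    else:
        raise ProtocolError(f"unknown extraction strategy {strategy!r}")

    normalized_at = None
    if normalize:
        if reference_mV is None or reference_mV not in sweeps.traces:
            raise NormalizationError(f"normalization reference {reference_mV!r} mV not present")
        ref_val = values[np.where(volts == reference_mV)[0][0]]
        if ref_val == 0:
            raise NormalizationError("reference F value is zero")
        values = values / ref_val
        normalized_at = float(reference_mV)
    return FVDataset(voltage_mV=volts, f=values, strategy=strategy, normalized_at_mV=normalized_at)


# ---------------------------------------------------------------------------
# Boltzmann fitting


def _initial_guesses(v: np.ndarray, f: np.ndarray, n_components: int) -> np.ndarray:
    """Heuristic start: midpoints seeded from fractional-amplitude crossings
    of the (lightly smoothed) cumulative change, amplitudes from the plateau
    level between the transitions."""
    total = f[-1] - f[0]
    if total == 0:
        total = np.ptp(f) if np.ptp(f) else 1.0
    span = v[-1] - v[0]
    slope0 = max(span / 15.0, 1.0)
    s = np.clip((f - f[0]) / total, 0.0, 1.0)
    s = np.maximum.accumulate(s)  # monotone envelope tames noise

    def crossing(level: float) -> float:
        idx = np.searchsorted(s, level)
        if idx == 0:
            return float(v[0])
        if idx >= len(v):
            return float(v[-1])
        return float(np.interp(level, s[idx - 1 : idx + 1], v[idx - 1 : idx + 1]))

    if n_components == 1:
        return np.array([total, crossing(0.5), slope0])
    vh1, vh2 = crossing(0.25), crossing(0.75)
    if vh2 - vh1 < 0.05 * span:
        vh1, vh2 = vh1 - 0.1 * span, vh2 + 0.1 * span
    a1 = float(np.clip(s[np.searchsorted(v, 0.5 * (vh1 + vh2))] if vh1 < vh2 else 0.4, 0.05, 0.95))
    return np.array([a1 * total, vh1, slope0, (1 - a1) * total, vh2, slope0])


def fit_boltzmann(
    fv: FVDataset,
    n_components: int = 1,
    n_starts: int = 16,
    seed: int = 0,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit with seeded multi-start initialization.

    Starts are Gaussian jitters of a heuristic initial guess; the best
    converged solution by residual sum of squares is kept.  Components are
    returned sorted by V½; slopes are bounded positive.
    """
    if n_components not in (1, 2):
        raise FitError("n_components must be 1 or 2")
    v, f = fv.voltage_mV, fv.f
    if len(v) < 4 * n_components:
        raise FitError(f"need >= {4 * n_components} points for a {n_components}-component fit")
    scale = np.ptp(f)
    if scale == 0:
        raise FitError("flat F–V data; Boltzmann fit is degenerate")

    span = v[-1] - v[0]
    p0 = _initial_guesses(v, f, n_components)
    lo = np.tile([-np.inf, v[0] - span, 0.5], n_components)
    hi = np.tile([np.inf, v[-1] + span, 2 * span], n_components)

    def resid(p):
        comps = [tuple(p[3 * i : 3 * i + 3]) for i in range(n_components)]
        return boltzmann_sum(v, comps) - f

    rng = np.random.default_rng(seed)
    best = None
    no_improve = 0
    for start in range(n_starts):
        p_init = p0.copy()
        if start > 0:
            jitter = rng.normal(size=p0.shape)
            p_init = p0 * (1 + 0.3 * jitter)
            p_init[1::3] = p0[1::3] + 0.25 * span * jitter[1::3]
        p_init = np.clip(p_init, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(resid, p_init, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(sol.cost * 2)
        if best is None or rss < best[0] * (1 - 5e-3):
            best = (rss, sol) if best is None or rss < best[0] else best
            no_improve = 0
        else:
            if rss < best[0]:
                best = (rss, sol)
            no_improve += 1
        # stop early once the optimum is stable across restarts or the fit
        # is already at numerical noise
        if best[0] < (1e-8 * scale) ** 2 * len(v) or (start >= 7 and no_improve >= 5):
            break
    if best is None:
        raise FitError("Boltzmann fit failed to converge from any start")
    rss, sol = best
    p = sol.x

    comps = sorted(
        [(float(p[3 * i]), float(p[3 * i + 1]), float(p[3 * i + 2])) for i in range(n_components)],
        key=lambda c: c[1],
    )
    ratios: list[float] = []
    if n_components == 2:
        a1, a2 = comps[0][0], comps[1][0]
        total = a1 + a2
        if total != 0:
            ratios = [100.0 * a1 / total, 100.0 * a2 / total]
        else:
            ratios = [float("nan"), float("nan")]

    # covariance from the Gauss-Newton approximation at the solution
    cov = None
    dof = len(v) - len(p)
    if dof > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
        except np.linalg.LinAlgError:
            cov = None
    return BoltzmannFit(
        n_components=n_components,
        components=comps,
        ratios_pct=ratios,
        residual_norm=float(np.sqrt(rss)),
        covariance=cov,
        n_points=len(v),
    )


def select_model(
    fv: FVDataset,
    criterion: str = "aicc",
    alpha: float = 0.05,
    n_starts: int = 16,
    seed: int = 0,
) -> tuple[int, dict]:
    """Choose between one and two Boltzmann components.

    Default criterion is small-sample corrected AIC; ``criterion="ftest"``
    uses the extra-sum-of-squares F-test at level ``alpha`` instead.  Returns
    the chosen component count and a report holding both fits and the
    criterion values.
    """
    fit1 = fit_boltzmann(fv, 1, n_starts=n_starts, seed=seed)
    fit2 = fit_boltzmann(fv, 2, n_starts=n_starts, seed=seed)
    report: dict = {"fit1": fit1, "fit2": fit2, "criterion": criterion}
    if criterion == "aicc":
        report["aicc1"], report["aicc2"] = fit1.aicc(), fit2.aicc()
        choice = 2 if report["aicc2"] < report["aicc1"] else 1
    elif criterion == "ftest":
        from scipy import stats as _stats

        df1 = fv.f.size - fit1.n_params
        df2 = fv.f.size - fit2.n_params
        if df2 <= 0:
            choice = 1
            report["f_pvalue"] = float("nan")
        else:
            num = (fit1.rss - fit2.rss) / (df1 - df2)
            den = fit2.rss / df2
            fstat = num / den if den > 0 else np.inf
            pval = float(_stats.f.sf(fstat, df1 - df2, df2))
            report["f_pvalue"] = pval
            choice = 2 if pval < alpha else 1
    else:
        raise FitError(f"unknown selection criterion {criterion!r}")
    report["choice"] = choice
    return choice, report


# ---------------------------------------------------------------------------
# kinetics


def compute_t_half(
    time_ms: np.ndarray,
    trace: np.ndarray,
    window_ms: tuple[float, float],
    baseline: float | None = None,
) -> float:
    """Time (ms, from window start) to half-maximum change within the window.

    The half level is baseline + 0.5 × (extremum − baseline), where the
    extremum is the largest absolute deviation from baseline inside the
    window; the first crossing is located by linear interpolation.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    trace = np.asarray(trace, dtype=float)
    lo, hi = window_ms
    mask = (time_ms >= lo - 1e-9) & (time_ms <= hi + 1e-9)
    t, y = time_ms[mask], trace[mask]
    if len(t) < 2:
        raise ProtocolError("t½ window contains fewer than 2 samples")
    if baseline is None:
        baseline = float(y[0])
    dev = y - baseline
    ext = dev[int(np.argmax(np.abs(dev)))]
    if ext == 0:
        raise FitError("trace never deviates from baseline within the window")
    half = 0.5 * ext
    s = dev / ext  # normalized: 0 at baseline, 1 at extremum
    crossed = np.where(s >= 0.5)[0]
    if len(crossed) == 0:
        raise FitError("trace never reaches half-maximum within the window")
    i = crossed[0]
    if i == 0:
        return float(t[0] - lo)
    # linear interpolation between the straddling samples
    frac = (0.5 - s[i - 1]) / (s[i] - s[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]) - lo)


def _exp_rise(t, amps, taus):
    out = np.zeros_like(t)
    for a, tau in zip(amps, taus):
        out += a * (1.0 - np.exp(-t / tau))
    return out


def fit_fluorescence_kinetics(
    time_ms: np.ndarray,
    trace: np.ndarray,
    n_components: int,
    onset_ms: float,
    seed: int = 0,
) -> KineticsResult:
    """Sum-of-exponentials fit of a fluorescence change after pulse onset.

    Fits F(t′) = Σ Aᵢ(1 − exp(−t′/τᵢ)) for t′ = t − onset.  For two
    components the slow fraction is |A_slow| / Σ|Aᵢ| × 100.
    """
    if n_components not in (1, 2):
        raise FitError("n_components must be 1 or 2")
    time_ms = np.asarray(time_ms, dtype=float)
    trace = np.asarray(trace, dtype=float)
    mask = time_ms >= onset_ms
    t = time_ms[mask] - onset_ms
    y = trace[mask] - trace[mask][0]
    if len(t) < 4 * n_components:
        raise FitError(f"need >= {4 * n_components} samples after onset")
    total = y[-1] if y[-1] != 0 else (np.ptp(y) or 1.0)
    t_span = t[-1] - t[0] or 1.0

    def resid(p):
        amps, taus = p[:n_components], p[n_components:]
        return _exp_rise(t, amps, taus) - y

    rng = np.random.default_rng(seed)
    if n_components == 1:
        p0 = np.array([total, t_span / 5])
    else:
        p0 = np.array([0.5 * total, 0.5 * total, t_span / 20, t_span / 3])
    lo = np.concatenate([np.full(n_components, -np.inf), np.full(n_components, 1e-6)])
    hi = np.concatenate([np.full(n_components, np.inf), np.full(n_components, 100 * t_span)])
    best = None
    for start in range(12):
        p_init = p0 if start == 0 else p0 * np.exp(rng.normal(scale=0.5, size=p0.shape))
        p_init = np.clip(p_init, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(resid, p_init, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("kinetics fit failed to converge")
    p = best.x
    comps = sorted(zip(p[:n_components], p[n_components:]), key=lambda c: c[1])
    comps = [(float(a), float(tau)) for a, tau in comps]
    abs_total = sum(abs(a) for a, _ in comps)
    slow_frac = 100.0 * abs(comps[-1][0]) / abs_total if (n_components == 2 and abs_total) else (
        100.0 if n_components == 1 else 0.0
    )
    t_half = compute_t_half(time_ms, trace, (onset_ms, time_ms[-1]))
    return KineticsResult(
        t_half_ms=t_half,
        components=comps,
        slow_fraction_pct=float(slow_frac),
        residual_norm=float(np.sqrt(2 * best.cost)),
    )
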