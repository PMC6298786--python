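"""Voltage-dependent phosphatase activity from episodic voltage-clamp data.

A VSP coexpressed with a PI(4,5)P2-dependent reporter channel (an inward
rectifier Kir, or KCNQ) depletes the channel's lipid cofactor each time the
membrane is depolarized.  Repeating a short protocol — ramp, test pulse at
−120 mV, depolarization at +50 mV — therefore yields test-pulse current
amplitudes that decay with *accumulated depolarization time*.  The decay rate
constant of the normalized amplitudes, obtained by single-exponential
fitting, is the standard proxy for voltage-dependent phosphatase activity.

Very active constructs exhaust the reporter within one depolarization; when
the second episode's normalized amplitude falls below 1% of the first, the
fit is bypassed and the time constant is rounded to 0.065 s (rate constant
15.4 s⁻¹), the conventional cap for this protocol.

The module also integrates off-sensing charge (a surface-expression measure)
from P/N leak-subtracted repolarization transients, normalizes in vitro
malachite-green phosphate-release assays, and correlates per-mutant
activities with side-chain properties such as Hessa-scale hydrophobicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, NormalizationError, ProtocolError

__all__ = [
    "CAP_RATE_CONSTANT_PER_S",
    "CAP_TAU_S",
    "CAP_THRESHOLD",
    "ProtocolMeta",
    "EpisodicRecording",
    "DecaySeries",
    "ActivityResult",
    "ChargeResult",
    "extract_test_amplitude",
    "build_decay_series",
    "fit_decay",
    "integrate_off_sensing_charge",
    "correlate_activity_property",
    "relative_invitro_activity",
    "compare_groups",
]

#: Cap applied when the second episode retains <1% of the first amplitude.
CAP_THRESHOLD = 0.01
CAP_TAU_S = 0.065
CAP_RATE_CONSTANT_PER_S = 1.0 / CAP_TAU_S  # 15.384..., reported rounded to 15.4


@dataclass(frozen=True)
class ProtocolMeta:
    """Segment layout of one episode, in ms from sweep start.

    The canonical Kir protocol is a 50 ms ramp, a 50 ms test pulse at
    −120 mV, and a 300 ms (or 50 ms for fast constructs) depolarization at
    +50 mV, from a holding potential of −60 mV.
    """

    ramp_window_ms: tuple[float, float] = (0.0, 50.0)
    test_window_ms: tuple[float, float] = (50.0, 100.0)
    depol_window_ms: tuple[float, float] = (100.0, 400.0)
    test_voltage_mV: float = -120.0
    depol_voltage_mV: float = 50.0
    holding_mV: float = -60.0

    @property
    def depol_duration_ms(self) -> float:
        lo, hi = self.depol_window_ms
        return hi - lo

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("ramp", self.ramp_window_ms),
            ("test", self.test_window_ms),
            ("depol", self.depol_window_ms),
        ):
            if hi <= lo:
                raise ProtocolError(f"{name} window {lo}–{hi} ms is empty or inverted")
        if self.test_window_ms[1] > self.depol_window_ms[0] and self.test_window_ms[0] < self.depol_window_ms[1]:
            raise ProtocolError("test and depolarization windows overlap")


@dataclass
class EpisodicRecording:
    """Ordered sweeps sharing one timebase.

    ``time_ms`` is the (uniform) sample clock of every sweep; ``episodes`` is
    a list of current traces in μA, one per protocol repetition.
    """

    time_ms: np.ndarray
    episodes: list[np.ndarray]
    protocol: ProtocolMeta

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if len(self.episodes) < 2:
            raise ProtocolError("an episodic recording needs at least 2 episodes")
        n = len(self.time_ms)
        for i, ep in enumerate(self.episodes):
            if len(ep) != n:
                raise ProtocolError(f"episode {i} has {len(ep)} samples, expected {n}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table with columns episode, time_ms, current_uA."""
        frames = [
            pd.DataFrame({"episode": i + 1, "time_ms": self.time_ms, "current_uA": ep})
            for i, ep in enumerate(self.episodes)
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class DecaySeries:
    """Normalized test-pulse amplitudes vs accumulated depolarization time (s)."""

    t_acc_s: np.ndarray
    i_norm: np.ndarray

    def __post_init__(self) -> None:
        self.t_acc_s = np.asarray(self.t_acc_s, dtype=float)
        self.i_norm = np.asarray(self.i_norm, dtype=float)
        if self.t_acc_s[0] != 0.0 or not np.isclose(self.i_norm[0], 1.0):
            raise NormalizationError("decay series must start at (t=0, I=1)")
        if np.any(np.diff(self.t_acc_s) <= 0):
            raise NormalizationError("accumulated times must be strictly increasing")


@dataclass
class ActivityResult:
    """Fitted decay parameters; ``k`` (s⁻¹) is the activity proxy."""

    k_per_s: float
    tau_s: float
    plateau: float
    capped: bool
    residual_norm: float
    model: str = "exp_with_plateau"

    def as_dict(self) -> dict:
        return {
            "k_per_s": self.k_per_s,
            "tau_s": self.tau_s,
            "plateau": self.plateau,
            "capped": self.capped,
            "residual_norm": self.residual_norm,
            "model": self.model,
        }


@dataclass
class ChargeResult:
    """Integrated off-sensing charge after P/N subtraction."""

    q_off_nC: float
    pn_order: int
    integration_window_ms: tuple[float, float]
    baseline_window_ms: tuple[float, float]


# ---------------------------------------------------------------------------


def extract_test_amplitude(
    time_ms: np.ndarray,
    current_uA: np.ndarray,
    protocol: ProtocolMeta,
    averaging_ms: float = 2.0,
) -> float:
    """Mean current over the final ``averaging_ms`` of the test pulse.

    Averaging a short tail rather than taking the literal last sample makes
    the amplitude robust to single-sample noise; the window never extends
    before the test-pulse onset.
    """
    lo, hi = protocol.test_window_ms
    time_ms = np.asarray(time_ms, dtype=float)
    if lo < time_ms[0] or hi > time_ms[-1] + 1e-9:
        raise ProtocolError(
            f"test window {lo}–{hi} ms outside sweep ({time_ms[0]}–{time_ms[-1]} ms)"
        )
    start = max(lo, hi - averaging_ms)
    mask = (time_ms >= start - 1e-9) & (time_ms <= hi + 1e-9)
    if not mask.any():
        raise ProtocolError("averaging window contains no samples")
    return float(np.mean(np.asarray(current_uA, dtype=float)[mask]))


def build_decay_series(recording: EpisodicRecording, averaging_ms: float = 2.0) -> DecaySeries:
    """Normalized amplitude vs accumulated depolarization time.

    Episode i (1-based) has accumulated time (i − 1) × depol duration: the
    first test pulse precedes any depolarization.  Amplitudes are normalized
    to the first episode; inward (negative) currents are handled by the sign
    of the reference.
    """
    amps = np.array(
        [extract_test_amplitude(recording.time_ms, ep, recording.protocol, averaging_ms)
         for ep in recording.episodes]
    )
    a0 = amps[0]
    if a0 == 0:
        raise NormalizationError("first test-pulse amplitude is zero; cannot normalize")
    i_norm = amps / a0
    if np.any(i_norm < -0.5):
        raise NormalizationError("normalized amplitudes changed sign; check electrode polarity")
    t_acc = np.arange(len(amps)) * recording.protocol.depol_duration_ms / 1000.0
    return DecaySeries(t_acc_s=t_acc, i_norm=i_norm)


def _exp_plateau(t, k, c):
    return (1.0 - c) * np.exp(-k * t) + c


def fit_decay(series: DecaySeries, model: str = "exp_with_plateau") -> ActivityResult:
    """Single-exponential fit of the normalized decay; k is the activity.

    ``model`` is ``"exp_with_plateau"`` — I(t) = (1 − C)·exp(−kt) + C with the
    plateau C free in [0, 1) — or ``"exp"`` with C fixed at 0.  The cap rule
    is applied before fitting: if the second episode retains <1% of the first
    amplitude the decay is too fast to resolve under this protocol and the
    result is capped at τ = 0.065 s (k = 15.4 s⁻¹).
    """
    t, y = series.t_acc_s, series.i_norm
    if y[1] < CAP_THRESHOLD:
        return ActivityResult(
            k_per_s=round(CAP_RATE_CONSTANT_PER_S, 1),
            tau_s=CAP_TAU_S,
            plateau=0.0,
            capped=True,
            residual_norm=float("nan"),
            model=model,
        )
    if len(t) < 4:
        raise FitError("need at least 4 points to fit the decay")
    if y[-1] > y[0]:
        warnings.warn("series increases overall; decay rate is poorly defined", stacklevel=2)

    c0 = float(np.clip(y[-1], 0.0, 0.95)) if model == "exp_with_plateau" else 0.0
    span = max(y[0] - c0, 1e-6)
    # crude log-linear initial slope over the early, above-plateau points
    above = y > c0 + 0.05 * span
    if above[1:].any():
        idx = np.where(above)[0]
        k0 = max(-np.polyfit(t[idx], np.log(np.maximum(y[idx] - c0, 1e-9) / span), 1)[0], 1e-3)
    else:
        k0 = 1.0 / max(t[1], 1e-3)

    try:
        if model == "exp_with_plateau":
            popt, _ = optimize.curve_fit(
                _exp_plateau, t, y, p0=[k0, c0],
                bounds=([1e-6, 0.0], [np.inf, 1.0 - 1e-9]), maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            k, c = float(popt[0]), float(popt[1])
        elif model == "exp":
            popt, _ = optimize.curve_fit(
                lambda tt, k: np.exp(-k * tt), t, y,
                p0=[k0], bounds=([1e-6], [np.inf]), maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            k, c = float(popt[0]), 0.0
        else:
            raise FitError(f"unknown decay model {model!r}")
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge: {exc}") from exc

    resid = y - _exp_plateau(t, k, c)
    return ActivityResult(
        k_per_s=k, tau_s=1.0 / k, plateau=c, capped=False,
        residual_norm=float(np.linalg.norm(resid)), model=model,
    )


# ---------------------------------------------------------------------------
# off-sensing charge


def integrate_off_sensing_charge(
    time_ms: np.ndarray,
    main_sweep_uA: np.ndarray,
    pn_sweeps_uA: Sequence[np.ndarray],
    step_onset_ms: float,
    pn_order: int,
    integration_window_ms: tuple[float, float] | None = None,
    baseline_ms: float = 5.0,
    decay_fraction: float = 0.01,
    drift_tolerance_uA: float = 0.05,
) -> ChargeResult:
    """Off-sensing charge (nC) of a repolarization transient.

    The P/N estimate of leak plus symmetric capacitative current — the mean
    of the 1/N-scaled subsweeps times N — is subtracted from the main sweep;
    the residual is baseline-corrected by its mean over the ``baseline_ms``
    preceding the step, then integrated from step onset until the transient
    has decayed below ``decay_fraction`` of its peak (or to the window end
    when ``integration_window_ms`` is given).  μA × ms integrates to nC.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    main = np.asarray(main_sweep_uA, dtype=float)
    if not 4 <= pn_order <= 8:
        raise ProtocolError(f"P/N order must be in 4–8, got {pn_order}")
    for i, sub in enumerate(pn_sweeps_uA):
        if len(sub) != len(main):
            raise ProtocolError(f"P/N subsweep {i} timebase differs from main sweep")
    leak = pn_order * np.mean(np.asarray(pn_sweeps_uA, dtype=float), axis=0)
    corrected = main - leak

    base_mask = (time_ms >= step_onset_ms - baseline_ms) & (time_ms < step_onset_ms)
    if not base_mask.any():
        raise ProtocolError("baseline window before the step contains no samples")
    baseline = corrected[base_mask]
    if np.ptp(baseline) > drift_tolerance_uA:
        warnings.warn(
            f"baseline drifts by {np.ptp(baseline):.3g} μA before the step", stacklevel=2
        )
    resid = corrected - float(np.mean(baseline))

    if integration_window_ms is None:
        after = time_ms >= step_onset_ms
        seg = resid[after]
        peak_i = int(np.argmax(np.abs(seg)))
        peak = abs(seg[peak_i])
        below = np.where(np.abs(seg[peak_i:]) < decay_fraction * peak)[0]
        end_i = peak_i + (int(below[0]) if len(below) else len(seg) - 1 - peak_i)
        t_after = time_ms[after]
        window = (float(step_onset_ms), float(t_after[end_i]))
    else:
        window = integration_window_ms
        if window[0] < time_ms[0] or window[1] > time_ms[-1]:
            raise ProtocolError("integration window outside sweep")
    mask = (time_ms >= window[0]) & (time_ms <= window[1])
    q = float(np.trapezoid(resid[mask], time_ms[mask]))
    return ChargeResult(
        q_off_nC=q,
        pn_order=pn_order,
        integration_window_ms=window,
        baseline_window_ms=(step_onset_ms - baseline_ms, step_onset_ms),
    )


# ---------------------------------------------------------------------------
# cross-construct analyses


def correlate_activity_property(
    activity: Mapping[str, float], table: Mapping[str, float]
) -> pd.DataFrame:
    """Pair per-residue activities with a side-chain property and report
    Pearson and Spearman coefficients.

    Returns a tidy frame of the paired series; the coefficients and p-values
    sit in ``frame.attrs["pearson"]`` / ``attrs["spearman"]`` as (r, p).
    Degenerate (constant) inputs yield NaN coefficients.
    """
    shared = sorted(set(activity) & set(table))
    if len(shared) < 3:
        raise ValueError(f"need >=3 overlapping residues, got {len(shared)}")
    x = np.array([table[r] for r in shared], dtype=float)
    y = np.array([activity[r] for r in shared], dtype=float)
    out = pd.DataFrame({"residue": shared, "property": x, "activity_k_per_s": y})
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        out.attrs["pearson"] = (float("nan"), float("nan"))
        out.attrs["spearman"] = (float("nan"), float("nan"))
    else:
        pr = stats.pearsonr(x, y)
        sp = stats.spearmanr(x, y)
        out.attrs["pearson"] = (float(pr.statistic), float(pr.pvalue))
        out.attrs["spearman"] = (float(sp.statistic), float(sp.pvalue))
    return out


def relative_invitro_activity(
    raw: Mapping[str, Sequence[float]], reference: str = "WT"
) -> pd.DataFrame:
    """Normalize phosphate-release replicates to the reference construct.

    Every replicate is divided by the reference construct's mean; returns
    per-construct mean ± SD (ddof=1) of the normalized values.
    """
    if reference not in raw:
        raise NormalizationError(f"reference construct {reference!r} missing from table")
    ref_mean = float(np.mean(raw[reference]))
    if ref_mean <= 0:
        raise NormalizationError("reference mean must be positive")
    rows = []
    for construct, reps in raw.items():
        vals = np.asarray(reps, dtype=float) / ref_mean
        rows.append(
            {
                "construct": construct,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(a: Sequence[float], b: Sequence[float], equal_var: bool = True) -> float:
    """Two-tailed two-sample Student's t-test p-value (Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
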