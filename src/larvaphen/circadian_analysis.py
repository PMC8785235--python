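"""Free-running periodicity and dusk/dawn ramp-response analysis.

Periodicity is assessed with a least-squares (Lomb-Scargle) periodogram
over a period band, significance by circular-shift permutations of the
linearly detrended series, and a cosinor refit (mesor, amplitude,
acrophase) at the dominant period.  A linear trend is removed first to
account for the slow activity decline larvae show over long dark spans.

Dusk/dawn ramps are stepwise: the shipped dusk profile drops 5% every
2 min to 5% and then 1% every 2 min to off; dawn mirrors it.  Dusk steps
fire at the *end* of each hold interval (the ramp starts at full intensity)
while dawn steps fire at the *start* (the light leaves zero immediately),
which makes dawn(t) = dusk(D - t) exact in the interval interior.  The
enumerated step profile sums to 48 min; where a schedule records a
different stated duration the profile is rescaled onto it and both numbers
are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from larvaphen.errors import ConfigError, DataError
from larvaphen.stats_core import ModelResult, fit_condition_time_lmm
from larvaphen.trace_model import (
    AssaySession,
    LocomotionTrace,
    StepRamp,
    slice_segment,
)

__all__ = [
    "PeriodogramResult",
    "RampFunction",
    "build_ramp",
    "estimate_period",
    "analyze_ramp_response",
]


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    power: np.ndarray
    best_period_h: float
    p_value: float
    n_permutations: int
    mesor: float
    amplitude: float
    acrophase_h: float

    def __repr__(self) -> str:  # compact: the arrays are long
        return (
            f"PeriodogramResult(best_period_h={self.best_period_h:.3f}, "
            f"p_value={self.p_value:.4g}, mesor={self.mesor:.3g}, "
            f"amplitude={self.amplitude:.3g}, acrophase_h={self.acrophase_h:.2f})"
        )


@dataclass(frozen=True)
class RampFunction:
    """Piecewise-constant light intensity enumerated from a step schedule."""

    direction: str
    levels: np.ndarray  # intensity held during each interval, %
    interval_s: np.ndarray  # hold duration of each interval, s
    terminal_pct: float  # intensity after the last step

    @property
    def total_duration_s(self) -> float:
        return float(self.interval_s.sum())

    @property
    def n_steps(self) -> int:
        return len(self.levels)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        edges = np.concatenate([[0.0], np.cumsum(self.interval_s)])
        idx = np.searchsorted(edges, t, side="right") - 1
        vals = np.where(
            idx >= len(self.levels),
            self.terminal_pct,
            self.levels[np.clip(idx, 0, len(self.levels) - 1)],
        )
        vals = np.where(idx < 0, self.levels[0], vals)
        return vals if vals.ndim else float(vals)


def build_ramp(profile: StepRamp) -> RampFunction:
    """Enumerate a stepwise ramp into a piecewise-constant intensity function.

    For a "down" ramp each level (starting at ``start_pct``) is held for its
    interval and then stepped; for an "up" ramp the step fires first and the
    new level is held.  The actual duration is the step-sum of the schedule,
    recorded even when it differs from a stated segment duration.
    """
    sign = -1.0 if profile.direction == "down" else 1.0
    current = profile.start_pct
    levels: list[float] = []
    intervals: list[float] = []
    for step_pct, interval_s, until_pct in profile.phases:
        if step_pct <= 0 or interval_s <= 0:
            raise ConfigError("ramp steps and intervals must be positive")
        if sign * (until_pct - current) < 0:
            raise ConfigError(
                f"ramp phase target {until_pct}% lies behind current {current}%"
            )
        n = (until_pct - current) / (sign * step_pct)
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"step size {step_pct}% does not reach {until_pct}% from {current}%"
            )
        for _ in range(int(round(n))):
            if profile.direction == "down":
                levels.append(current)
                intervals.append(interval_s)
                current += sign * step_pct
            else:
                current += sign * step_pct
                levels.append(current)
                intervals.append(interval_s)
    terminal = current if profile.direction == "down" else current
    if profile.direction == "down" and abs(terminal - profile.phases[-1][2]) > 1e-9:
        raise ConfigError("ramp schedule does not reach its terminal intensity")
    return RampFunction(
        direction=profile.direction,
        levels=np.array(levels),
        interval_s=np.array(intervals),
        terminal_pct=float(terminal),
    )


def ls_periodogram(
    t: np.ndarray, y: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Normalized least-squares (Lomb-Scargle) periodogram.

    Uses the classic tau-shifted formulation, which equals the least-squares
    fit of a single sinusoid at each frequency; power is normalized by the
    total variance of the (mean-centered) series, so a noiseless sinusoid
    peaks at 1.  ``freqs`` are ordinary frequencies (cycles per unit of
    ``t``).
    """
    y = y - y.mean()
    omega = 2.0 * np.pi * np.asarray(freqs, dtype=float)
    C, S, cc, ss = _ls_basis(t, omega)
    return _ls_power(y[None, :], C, S, cc, ss)[0] / (0.5 * len(y) * y.var())


def _ls_basis(t: np.ndarray, omega: np.ndarray):
    arg2 = 2.0 * np.outer(t, omega)  # n x F
    tau = np.arctan2(np.sin(arg2).sum(axis=0), np.cos(arg2).sum(axis=0)) / (2.0 * omega)
    phase = np.outer(t, omega) - omega * tau
    C, S = np.cos(phase), np.sin(phase)
    return C, S, (C * C).sum(axis=0), (S * S).sum(axis=0)


def _ls_power(Y: np.ndarray, C, S, cc, ss) -> np.ndarray:
    """Raw LS power for each row of ``Y`` (rows must be mean-centered)."""
    return 0.5 * ((Y @ C) ** 2 / cc + (Y @ S) ** 2 / ss)


def estimate_period(
    trace: LocomotionTrace,
    band_h: tuple[float, float] = (16.0, 32.0),
    *,
    n_permutations: int = 999,
    seed: int = 0,
    n_frequencies: int = 400,
) -> PeriodogramResult:
    """Dominant activity period of one trace within a period band.

    The trace should cover the free-running (constant-dark) span at coarse
    (e.g. 1-min) bins.  Missing bins are dropped; a linear trend is removed;
    the normalized least-squares periodogram is evaluated on an even
    frequency grid across the band; the permutation p-value compares the
    observed peak power against peaks of circularly shifted series.
    """
    lo, hi = band_h
    if not 0 < lo < hi:
        raise ValueError(f"invalid period band {band_h}")
    if trace.span < 2 * lo * 3600.0:
        raise ValueError(
            f"trace span {trace.span / 3600.0:.1f} h is shorter than twice the "
            f"band minimum ({lo} h)"
        )
    t_h = (trace.bin_starts() + trace.bin_width / 2.0) / 3600.0
    y = trace.distances
    ok = np.isfinite(y)
    t_h, y = t_h[ok], y[ok]
    if len(y) < 10:
        raise ValueError("too few non-missing bins for a periodogram")
    # linear detrend
    A = np.column_stack([np.ones_like(t_h), t_h])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef

    freqs = np.linspace(1.0 / hi, 1.0 / lo, n_frequencies)  # cycles/h
    omega = 2.0 * np.pi * freqs
    C, S, cc, ss = _ls_basis(t_h, omega)
    norm = 0.5 * len(resid) * resid.var() or 1.0
    yc = resid - resid.mean()
    power = _ls_power(yc[None, :], C, S, cc, ss)[0] / norm
    best = int(np.argmax(power))
    best_period = 1.0 / freqs[best]
    obs_peak = float(power[best])

    # circular shifts preserve values, hence the normalization constant
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, len(yc), size=n_permutations)
    idx = (np.arange(len(yc))[None, :] + shifts[:, None]) % len(yc)
    peaks = _ls_power(yc[idx], C, S, cc, ss).max(axis=1) / norm
    p_value = (1.0 + int(np.sum(peaks >= obs_peak))) / (n_permutations + 1.0)

    # cosinor refit at the dominant period
    w = 2.0 * np.pi / best_period
    Xc = np.column_stack([np.ones_like(t_h), np.cos(w * t_h), np.sin(w * t_h)])
    (mesor, a, b), *_ = np.linalg.lstsq(Xc, y, rcond=None)
    amplitude = float(np.hypot(a, b))
    acro = float(np.arctan2(b, a) % (2.0 * np.pi)) / (2.0 * np.pi) * best_period

    return PeriodogramResult(
        periods_h=1.0 / freqs,
        power=power,
        best_period_h=float(best_period),
        p_value=float(p_value),
        n_permutations=n_permutations,
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase_h=acro,
    )


def ramp_windows(session: AssaySession) -> list[tuple[str, float, float]]:
    """(label, start, end) of every stepwise ramp segment in the regime."""
    out = [
        (label, a, b)
        for seg, (label, a, b) in zip(
            session.regime.segments, session.regime.segment_bounds()
        )
        if seg.ramp is not None
    ]
    if not out:
        raise DataError("session regime contains no ramp segments")
    return out


def analyze_ramp_response(
    session: AssaySession, *, control: str = "control"
) -> tuple[pd.DataFrame, dict[str, ModelResult]]:
    """Per-subject ramp statistics and per-ramp condition/time models.

    For every ramp segment, each subject contributes its mean per-bin
    distance and an ordinary least-squares time slope within the window;
    condition contrasts come from a mixed model
    ``distance ~ condition * time + (1 | subject)`` fitted on the per-bin
    data of that window (time in seconds from the ramp start).
    """
    windows = ramp_windows(session)
    rows = []
    models: dict[str, ModelResult] = {}
    for label, a, b in windows:
        long_rows = []
        for tr in session.traces:
            if tr.t_end < b - 1e-9:
                raise DataError(
                    f"trace of subject {tr.subject_id!r} does not cover ramp "
                    f"segment {label!r}"
                )
            seg = slice_segment(tr, (a, b))
            t = seg.bin_starts() - a
            d = seg.distances
            ok = np.isfinite(d)
            slope = np.nan
            if ok.sum() >= 3:
                slope = float(np.polyfit(t[ok], d[ok], 1)[0])
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "condition": tr.condition,
                    "segment": label,
                    "mean_mm_per_bin": float(np.nanmean(d)) if ok.any() else np.nan,
                    "slope_mm_per_bin_per_s": slope,
                }
            )
            long_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": tr.subject_id,
                        "condition": tr.condition,
                        "t": t,
                        "distance_mm": d,
                    }
                )
            )
        long = pd.concat(long_rows, ignore_index=True)
        if long["condition"].nunique() >= 2:
            models[label] = fit_condition_time_lmm(long, control=control)
    return pd.DataFrame(rows), models
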