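"""Forced light-dark transition (FLD) analysis.

The assay alternates dark and light: a 10-min dark baseline, 10 min light,
10 min dark, a 1-min light event and a final 10 min dark.  Three statistics
are derived per subject:

* per-period total and mean distance (locomotion differences between
  conditions, mixed model with a random intercept per fish);
* the "recovery rate" -- the within-period time slope of distance moved,
  positive when movement increases as larvae recover from the
  light-transition freeze;
* the startle ratio -- movement in the 20 s after the light-to-dark
  transition relative to movement during the preceding 1-min light event.
  Both windows are summed totals and the ratio is compressed to
  q = d20 / (d20 + d60) so beta regression is well-defined (the raw
  20-s/60-s ratio, also reported, can exceed 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from larvaphen.errors import DataError
from larvaphen.stats_core import (
    ModelResult,
    build_condition_design,
    fit_betareg,
    fit_condition_lmm,
    fit_condition_time_lmm,
    fit_lmm,
    smithson_verkuilen,
    tukey_contrasts,
)
from larvaphen.trace_model import AssaySession, rebin, slice_segment

__all__ = [
    "FLD_PERIODS",
    "split_fld_periods",
    "period_long_table",
    "fit_period_locomotion",
    "fit_recovery_slope",
    "compute_startle_ratio",
    "test_startle_ratio",
]

FLD_PERIODS = ("baseline", "light10", "dark10", "light1", "dark5")


def _check_fld(session: AssaySession) -> None:
    if session.kind != "fld":
        raise DataError(f"expected an fld session, got {session.kind!r}")
    span = session.regime.total_duration_s
    for tr in session.traces:
        if tr.span + 1e-9 < span:
            raise DataError(
                f"trace of subject {tr.subject_id!r} ({tr.span:.0f} s) shorter "
                f"than the regime ({span:.0f} s)"
            )


def split_fld_periods(session: AssaySession) -> pd.DataFrame:
    """Per-subject period statistics for every segment of the FLD schedule.

    Returns one row per subject x period with the total (mm) and mean
    per-bin (mm/bin) distance; period totals sum to the whole-trace total.
    """
    _check_fld(session)
    rows = []
    for tr in session.traces:
        for label, a, b in session.regime.segment_bounds():
            seg = slice_segment(tr, (a, b))
            d = seg.distances
            ok = np.isfinite(d)
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "condition": tr.condition,
                    "period": label,
                    "total_mm": float(np.nansum(d)),
                    "mean_mm_per_bin": float(np.nanmean(d)) if ok.any() else np.nan,
                    "n_bins": int(ok.sum()),
                }
            )
    return pd.DataFrame(rows)


def period_long_table(
    session: AssaySession, period: str, *, rebin_to: float | None = 10.0
) -> pd.DataFrame:
    """Tidy per-bin table for one FLD period (optionally re-binned, default
    the coarse 10-s resolution), with time in seconds from the period start."""
    _check_fld(session)
    a, b = session.regime.interval(period)
    frames = []
    for tr in session.traces:
        seg = slice_segment(tr, (a, b))
        if rebin_to and rebin_to > seg.bin_width:
            seg = rebin(seg, rebin_to)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "condition": tr.condition,
                    "t": seg.bin_starts() - a,
                    "distance_mm": seg.distances,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fit_period_locomotion(
    session: AssaySession,
    period: str,
    *,
    control: str = "control",
    rebin_to: float | None = 10.0,
) -> ModelResult:
    """Condition effect on locomotion within one period.

    Mixed model ``distance_per_bin ~ condition + (1 | fish)`` on the
    period's per-bin data, with the omnibus condition chi-squared (LRT) test
    and Tukey-adjusted pairwise condition contrasts.
    """
    long = period_long_table(session, period, rebin_to=rebin_to)
    return fit_condition_lmm(long, control=control)


def fit_recovery_slope(
    session: AssaySession,
    period: str,
    *,
    control: str = "control",
    rebin_to: float | None = 10.0,
) -> ModelResult:
    """Within-period time slope of distance moved ("recovery rate").

    Fits ``distance ~ condition * time + (1 | fish)``; ``slopes`` maps each
    condition to its slope in mm per bin per second (bin width = the
    analysis bin), positive when movement increases over the period.  With a
    single condition the model reduces to ``distance ~ time + (1 | fish)``.
    """
    long = period_long_table(session, period, rebin_to=rebin_to)
    if long["t"].nunique() < 3:
        raise ValueError("need >= 3 time bins to estimate a recovery slope")
    if long["condition"].nunique() >= 2:
        return fit_condition_time_lmm(long, control=control)
    X = np.column_stack([np.ones(len(long)), long["t"].to_numpy(float)])
    out = fit_lmm(
        long, "distance_mm", X, ["Intercept", "t"], "subject_id",
        formula="distance_mm ~ t + (1|subject_id)",
    )
    cond = str(long["condition"].iloc[0])
    out.slopes = {cond: (float(out.params["t"]), float(out.bse["t"]))}
    return out


def compute_startle_ratio(
    session: AssaySession,
    *,
    light_period: str = "light1",
    window_s: float = 20.0,
) -> pd.DataFrame:
    """Startle ratio of every subject around the 1-min light event.

    ``d60`` is the total distance during the light event, ``d20`` the total
    in the ``window_s`` seconds after the light-to-dark transition; the
    compressed ratio ``q = d20 / (d20 + d60)`` lies in [0, 1] and the raw
    ratio ``d20 / d60`` is kept for transparency.  Subjects with
    ``d20 + d60 = 0`` are flagged, not dropped here.
    """
    _check_fld(session)
    a, b = session.regime.interval(light_period)
    rows = []
    for tr in session.traces:
        d60 = slice_segment(tr, (a, b)).total_distance()
        d20 = slice_segment(tr, (b, b + window_s)).total_distance()
        tot = d20 + d60
        rows.append(
            {
                "subject_id": tr.subject_id,
                "condition": tr.condition,
                "d20_mm": d20,
                "d60_mm": d60,
                "ratio_raw": d20 / d60 if d60 > 0 else np.inf if d20 > 0 else np.nan,
                "q": d20 / tot if tot > 0 else np.nan,
                "flagged": tot == 0,
            }
        )
    return pd.DataFrame(rows)


def test_startle_ratio(
    ratios: pd.DataFrame, *, control: str = "control"
) -> ModelResult:
    """Beta regression of the compressed startle ratio on condition.

    Boundary values (a subject that never moved in one window) are pulled
    inside (0, 1) by the Smithson-Verkuilen compression over the scored
    subjects before fitting; the omnibus condition LRT and Tukey-adjusted
    pairwise contrasts are attached.
    """
    ok = ratios[~ratios["flagged"] & np.isfinite(ratios["q"])].copy()
    counts = ok.groupby("condition").size()
    if len(counts) < 2:
        raise ValueError("need >= 2 conditions with scored subjects")
    if (counts < 3).any():
        bad = counts[counts < 3].index.tolist()
        raise DataError(f"conditions with < 3 scored subjects: {bad}")
    y = smithson_verkuilen(ok["q"].to_numpy(), len(ok))
    X, names, levels = build_condition_design(ok, control=control)
    dummies = [n for n in names if n.startswith("cond[")]
    out = fit_betareg(
        y, X, names, omnibus_cols=dummies, formula="q' ~ condition (betareg)"
    )
    vectors = {}
    for lev in levels:
        v = np.zeros(len(names))
        v[0] = 1.0
        if lev != control:
            v[names.index(f"cond[{lev}]")] = 1.0
        vectors[lev] = v
    out.contrasts = tukey_contrasts(vectors, out.params, out.cov_params)
    return out
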