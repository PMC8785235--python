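"""Acoustic-startle habituation analysis.

Two complementary views of habituation across a 25-tap train:

1. the *slope model* -- a mixed model of distance moved per 2-s tap event
   on the tap index, with condition-by-tap interactions (a negative slope
   is habituation);
2. the *responder model* -- each fish is called a responder on a tap if its
   mean per-second movement during the event exceeds the condition's
   threshold (pooled baseline mean per-second distance + 2 sample SD,
   strict inequality), and the per-tap responder proportions are analyzed
   with beta regression on tap x condition, with a likelihood-ratio test of
   the interaction against the no-interaction nested model.

Thresholds pool baseline bins across all subjects of a condition ("2 SD"
is read as two sample standard deviations of the pooled per-second
distances, not standard errors, so thresholds do not shrink with sample
size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from larvaphen.errors import DataError
from larvaphen.stats_core import (
    ModelResult,
    build_condition_design,
    fit_betareg,
    fit_condition_time_lmm,
    smithson_verkuilen,
    tukey_contrasts,
)
from larvaphen.trace_model import AssaySession, slice_segment

__all__ = [
    "ResponderMatrix",
    "extract_tap_events",
    "compute_thresholds",
    "classify_responders",
    "fit_habituation_slope",
    "fit_responder_curve",
]


@dataclass
class ResponderMatrix:
    """Boolean responder calls and the thresholds that produced them.

    ``calls`` has one row per subject x tap (``responded`` bool);
    ``proportions`` one row per condition x tap with the responder fraction
    ``p_hat`` over the ``n`` scored subjects; ``thresholds`` maps condition
    to its mm/s cutoff.
    """

    thresholds: dict[str, float]
    calls: pd.DataFrame
    proportions: pd.DataFrame
    window_s: float


def extract_tap_events(session: AssaySession) -> pd.DataFrame:
    """Distance moved in every tap-event window, one row per subject x tap.

    Window sums follow the half-open convention ``[start, start+window)``;
    a window containing a missing bin yields a missing distance.
    """
    if session.stimuli is None:
        raise DataError("session has no stimulus train")
    rows = []
    for tr in session.traces:
        for k, (a, b) in enumerate(session.stimuli.windows(), start=1):
            if b > tr.t_end + 1e-9:
                raise DataError(
                    f"tap window [{a}, {b}) extends past the trace of subject "
                    f"{tr.subject_id!r}"
                )
            d = slice_segment(tr, (a, b)).distances
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "condition": tr.condition,
                    "tap": k,
                    "distance_mm": float(d.sum()),  # NaN if any bin missing
                }
            )
    return pd.DataFrame(rows)


def compute_thresholds(
    session: AssaySession, baseline_interval: tuple[float, float] = (0.0, 60.0)
) -> dict[str, float]:
    """Per-condition responder thresholds, mm/s.

    Pooled over all subjects of a condition: mean per-second baseline
    distance plus two sample standard deviations.  The baseline interval
    must precede the first stimulus.
    """
    a, b = baseline_interval
    if session.stimuli is not None and b > session.stimuli.start_times[0] + 1e-9:
        raise ValueError("baseline interval must precede the first stimulus")
    pooled: dict[str, list[np.ndarray]] = {}
    for tr in session.traces:
        seg = slice_segment(tr, (a, b))
        rates = seg.distances / seg.bin_width
        pooled.setdefault(tr.condition, []).append(rates[np.isfinite(rates)])
    out = {}
    for cond, chunks in pooled.items():
        vals = np.concatenate(chunks)
        if len(vals) < 10:
            raise DataError(
                f"condition {cond!r} has only {len(vals)} non-missing baseline bins"
            )
        sd = float(np.std(vals, ddof=1))
        out[cond] = float(np.mean(vals)) + 2.0 * sd
    return out


def classify_responders(
    events: pd.DataFrame,
    thresholds: dict[str, float],
    *,
    window_s: float = 2.0,
) -> ResponderMatrix:
    """Call responders: event mean per-second rate strictly above the
    condition threshold.  Events with missing distance are excluded from
    the per-tap proportions."""
    missing = set(events["condition"].unique()) - set(thresholds)
    if missing:
        raise ValueError(f"conditions without thresholds: {sorted(missing)}")
    calls = events.copy()
    thr = calls["condition"].map(thresholds).to_numpy(dtype=float)
    rate = calls["distance_mm"].to_numpy(dtype=float) / window_s
    responded = pd.array(rate > thr, dtype="boolean")
    responded[~np.isfinite(rate)] = pd.NA
    calls["responded"] = responded
    scored = calls.dropna(subset=["responded"])
    props = (
        scored.groupby(["condition", "tap"], sort=True)["responded"]
        .agg(p_hat="mean", n="size")
        .reset_index()
    )
    props["p_hat"] = props["p_hat"].astype(float)
    return ResponderMatrix(
        thresholds=dict(thresholds),
        calls=calls,
        proportions=props,
        window_s=window_s,
    )


def fit_habituation_slope(
    events: pd.DataFrame, *, control: str = "control"
) -> ModelResult:
    """Slope model: ``event distance ~ condition * tap + (1 | fish)``.

    ``slopes`` maps condition to mm per tap; negative slopes mark
    habituation.  Interaction contrasts (Tukey-adjusted) compare slopes
    between conditions.
    """
    if events["tap"].nunique() < 3:
        raise ValueError("need >= 3 tap events to estimate a habituation slope")
    if events["condition"].nunique() < 2:
        raise ValueError("need >= 2 conditions")
    return fit_condition_time_lmm(
        events, response="distance_mm", time_col="tap", control=control
    )


def fit_responder_curve(
    matrix: ResponderMatrix, *, control: str = "control"
) -> ModelResult:
    """Responder model: beta regression of the per-tap responder proportion
    on tap x condition.

    Proportions are compressed off the boundary with the Smithson-Verkuilen
    transform using each condition's subject count; the attached LRT
    (``omnibus``) compares the interaction model against the nested
    no-interaction model, and pairwise condition contrasts are evaluated at
    the mean tap index with Tukey adjustment.
    """
    props = matrix.proportions.copy()
    if props["condition"].nunique() < 2:
        raise ValueError("need >= 2 conditions")
    if props["tap"].nunique() < 2:
        raise ValueError("need >= 2 tap events")
    boundary = ((props["p_hat"] <= 0) | (props["p_hat"] >= 1)).any()
    y = np.empty(len(props))
    for cond, grp in props.groupby("condition"):
        n = int(grp["n"].max())
        y[grp.index] = smithson_verkuilen(grp["p_hat"].to_numpy(), n)
    X, names, levels = build_condition_design(
        props, control=control, covariate="tap", interaction=True
    )
    inter_cols = [n for n in names if ":tap" in n]
    out = fit_betareg(
        y, X, names,
        omnibus_cols=inter_cols,
        formula="p_hat' ~ condition*tap (betareg)",
    )
    out.lrt_result = out.omnibus  # the omnibus here *is* the interaction LRT
    if boundary:
        out.warnings.append("boundary proportions compressed before fitting")
    tbar = float(props["tap"].mean())
    vectors = {}
    for lev in levels:
        v = np.zeros(len(names))
        v[0] = 1.0
        v[names.index("tap")] = tbar
        if lev != control:
            v[names.index(f"cond[{lev}]")] = 1.0
            v[names.index(f"cond[{lev}]:tap")] = tbar
        vectors[lev] = v
    out.contrasts = tukey_contrasts(vectors, out.params, out.cov_params)
    return out
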