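"""Sociability-arena analysis: Social Preference Index and boldness.

A test fish explores a two-sided choice arena; conspecific stimulus fish
sit behind a partition on one end-third during the experimental phase.
The Social Preference Index (SPI) contrasts occupancy of the two
end-thirds, normalized to [-1, 1]; middle-zone time is excluded from both
numerator and denominator.  The shipped orientation is *away-positive*
(SPI = +1 when all scored time is spent in the third far from the
stimuli), so the Correlation Index

    r = SPI(experimental) - SPI(acclimation)

is positive for fish that move away from the stimuli once they appear --
the exploratory/bold phenotype.  A fish is bold iff r > 0 (r = 0 is not
bold).  Orientation can be flipped for pipelines that prefer
approach-positive SPIs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from larvaphen.errors import DataError
from larvaphen.trace_model import AssaySession, ZoneTrace, slice_zone

__all__ = [
    "compute_spi",
    "compute_correlation_index",
    "score_session",
    "summarize_bold_fraction",
]


def compute_spi(
    zone_trace: ZoneTrace,
    interval: tuple[float, float],
    *,
    orientation: str = "away",
) -> float:
    """Social Preference Index over a phase interval.

    Aggregates non-missing occupancy time of the two end-thirds across the
    interval; returns NaN (undefined) when no end-third time was scored.
    ``orientation="away"`` (default) gives +1 for the far third;
    ``"toward"`` flips the sign.
    """
    if orientation not in ("away", "toward"):
        raise ValueError(f"orientation must be 'away' or 'toward', got {orientation!r}")
    seg = slice_zone(zone_trace, interval)
    social = seg.zones["social"]
    far = seg.zones["far"]
    ok = np.isfinite(social) & np.isfinite(far)
    t_social = float(social[ok].sum()) * seg.bin_width
    t_far = float(far[ok].sum()) * seg.bin_width
    denom = t_social + t_far
    if denom <= 0:
        return float("nan")
    spi = (t_far - t_social) / denom
    return spi if orientation == "away" else -spi


def compute_correlation_index(
    spi_acclim: float, spi_exp: float
) -> tuple[float, bool]:
    """Correlation Index r = SPI(experimental) - SPI(acclimation) and the
    bold flag (strictly positive r)."""
    if not (np.isfinite(spi_acclim) and np.isfinite(spi_exp)):
        raise ValueError("both SPIs must be defined to compute r")
    r = spi_exp - spi_acclim
    return float(r), bool(r > 0)


def score_session(
    session: AssaySession,
    *,
    acclim_label: str = "acclimation",
    exp_label: str = "experimental",
    orientation: str = "away",
) -> pd.DataFrame:
    """Per-subject SPI, Correlation Index and bold call for a social session.

    Subjects with an undefined SPI in either phase are kept with
    ``excluded=True`` and NaN index values.
    """
    if not session.zone_traces:
        raise DataError("social session carries no zone traces")
    acclim = session.regime.interval(acclim_label)
    exp = session.regime.interval(exp_label)
    rows = []
    for zt in session.zone_traces:
        spi_a = compute_spi(zt, acclim, orientation=orientation)
        spi_e = compute_spi(zt, exp, orientation=orientation)
        if np.isfinite(spi_a) and np.isfinite(spi_e):
            r, bold = compute_correlation_index(spi_a, spi_e)
            rows.append(
                {
                    "subject_id": zt.subject_id,
                    "condition": zt.condition,
                    "spi_acclim": spi_a,
                    "spi_exp": spi_e,
                    "r": r,
                    "bold": bold,
                    "excluded": False,
                }
            )
        else:
            rows.append(
                {
                    "subject_id": zt.subject_id,
                    "condition": zt.condition,
                    "spi_acclim": spi_a,
                    "spi_exp": spi_e,
                    "r": np.nan,
                    "bold": pd.NA,
                    "excluded": True,
                }
            )
    return pd.DataFrame(rows)


def summarize_bold_fraction(
    results: pd.DataFrame, *, conf_level: float = 0.95
) -> tuple[pd.DataFrame, dict]:
    """Percent bold per condition with exact (Clopper-Pearson) binomial CIs.

    Returns the per-condition summary and an across-condition homogeneity
    test: Fisher's exact test for a 2x2 layout, otherwise a chi-squared
    contingency test.
    """
    scored = results[~results["excluded"]]
    if scored.empty:
        raise DataError("no classified subjects")
    rows = []
    table = []
    for cond, grp in scored.groupby("condition", sort=True):
        n = len(grp)
        k = int(grp["bold"].sum())
        ci = stats.binomtest(k, n).proportion_ci(
            confidence_level=conf_level, method="exact"
        )
        rows.append(
            {
                "condition": cond,
                "n": n,
                "n_bold": k,
                "percent_bold": 100.0 * k / n,
                "ci_low_pct": 100.0 * ci.low,
                "ci_high_pct": 100.0 * ci.high,
            }
        )
        table.append([k, n - k])
    summary = pd.DataFrame(rows)
    test: dict = {"test": None, "statistic": np.nan, "p": np.nan}
    if len(table) >= 2:
        arr = np.asarray(table)
        if arr.shape == (2, 2):
            res = stats.fisher_exact(arr)
            test = {"test": "fisher", "statistic": float(res.statistic), "p": float(res.pvalue)}
        else:
            chi2, p, dof, _ = stats.chi2_contingency(arr)
            test = {"test": "chi2", "statistic": float(chi2), "p": float(p), "df": int(dof)}
    return summary, test
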