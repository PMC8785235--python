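"""Core data types for plate-based locomotion experiments.

A *trace* is one subject's time-binned distance record: ``distances[i]`` is
the distance moved (mm) during the half-open bin
``[t0 + i*bin_width, t0 + (i+1)*bin_width)``.  Missing bins (tracking
dropouts) are carried as NaN, excluded from summaries and never imputed.

The canonical on-disk representation is a tidy delimited table with one row
per subject x bin (columns ``subject_id, well_id, condition, t_bin_start_s,
distance_mm`` plus optional ``zone_<name>`` occupancy-fraction columns);
``read_tracking_table`` / ``write_tracking_table`` round-trip it losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from larvaphen.errors import ConfigError, DataError, SchemaError

__all__ = [
    "LocomotionTrace",
    "ZoneTrace",
    "StepRamp",
    "Segment",
    "LightRegime",
    "StimulusTrain",
    "AssaySession",
    "SchemaConfig",
    "read_tracking_table",
    "write_tracking_table",
    "rebin",
    "slice_segment",
]

ZONE_NAMES = ("social", "middle", "far")


@dataclass
class LocomotionTrace:
    """Per-bin distance moved by one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier (unique within a session).
    well_id : str
        Plate coordinate, e.g. ``"A1"``.
    condition : str
        Treatment label, e.g. ``"control"`` or ``"nicotine"``.
    bin_width : float
        Bin width in seconds (> 0, constant within the trace).
    t0 : float
        Start of the first bin, seconds from assay start.
    distances : ndarray
        Distance per bin in millimetres; NaN marks a missing bin.
    """

    subject_id: str
    well_id: str
    condition: str
    bin_width: float
    t0: float
    distances: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise DataError(f"bin_width must be > 0, got {self.bin_width}")
        self.distances = np.asarray(self.distances, dtype=float)
        finite = self.distances[np.isfinite(self.distances)]
        if (finite < 0).any():
            raise DataError(
                f"negative distance in trace for subject {self.subject_id!r}"
            )

    def __len__(self) -> int:
        return len(self.distances)

    @property
    def span(self) -> float:
        """Total duration covered, seconds."""
        return len(self.distances) * self.bin_width

    @property
    def t_end(self) -> float:
        return self.t0 + self.span

    def bin_starts(self) -> np.ndarray:
        return self.t0 + self.bin_width * np.arange(len(self.distances))

    def total_distance(self) -> float:
        """Sum of non-missing distances, mm."""
        return float(np.nansum(self.distances))


@dataclass
class ZoneTrace:
    """Per-bin occupancy fractions of named arena zones for one subject.

    ``zones`` maps zone name -> fraction-of-bin array; for each bin with no
    missing data the fractions sum to 1 within 1e-9.
    """

    subject_id: str
    condition: str
    bin_width: float
    t0: float
    zones: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.zones = {k: np.asarray(v, dtype=float) for k, v in self.zones.items()}
        lengths = {len(v) for v in self.zones.values()}
        if len(lengths) != 1:
            raise DataError("zone arrays must share a common length")
        stack = np.vstack(list(self.zones.values()))
        if np.nanmin(stack) < -1e-12 or np.nanmax(stack) > 1 + 1e-9:
            raise DataError("zone fractions must lie in [0, 1]")
        totals = stack.sum(axis=0)
        ok = np.isnan(totals) | (np.abs(totals - 1.0) <= 1e-9)
        if not ok.all():
            bad = int(np.argmin(ok))
            raise DataError(
                f"zone fractions of subject {self.subject_id!r} do not sum to 1 "
                f"at bin {bad} (sum={totals[bad]:.6g})"
            )

    def __len__(self) -> int:
        return len(next(iter(self.zones.values())))

    @property
    def span(self) -> float:
        return len(self) * self.bin_width


@dataclass(frozen=True)
class StepRamp:
    """Stepwise light ramp: intensity changes by ``step_pct`` every
    ``step_interval_s`` seconds, in one or more phases.

    ``phases`` is a sequence of ``(step_pct, step_interval_s, until_pct)``
    triples applied in order, starting from ``start_pct`` and stepping toward
    ``until_pct``.  ``direction`` is ``"down"`` (dusk) or ``"up"`` (dawn).
    """

    direction: str
    start_pct: float
    phases: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.direction not in ("down", "up"):
            raise ConfigError(f"ramp direction must be 'down' or 'up', got {self.direction!r}")


@dataclass(frozen=True)
class Segment:
    """One light-regime segment: constant intensity or a stepwise ramp."""

    label: str
    duration_s: float
    intensity_pct: float | None = None
    ramp: StepRamp | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError(f"segment {self.label!r}: duration must be > 0")
        if (self.intensity_pct is None) == (self.ramp is None):
            raise ConfigError(
                f"segment {self.label!r}: exactly one of intensity_pct / ramp required"
            )
        if self.intensity_pct is not None and not 0 <= self.intensity_pct <= 100:
            raise ConfigError(f"segment {self.label!r}: intensity outside [0, 100]")


@dataclass(frozen=True)
class LightRegime:
    """Ordered light segments making up one assay schedule."""

    segments: tuple[Segment, ...]
    name: str = ""

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def segment_bounds(self) -> list[tuple[str, float, float]]:
        """(label, start_s, end_s) for every segment, half-open intervals."""
        out, t = [], 0.0
        for s in self.segments:
            out.append((s.label, t, t + s.duration_s))
            t += s.duration_s
        return out

    def interval(self, label: str) -> tuple[float, float]:
        for lab, a, b in self.segment_bounds():
            if lab == label:
                return a, b
        raise KeyError(f"regime has no segment labelled {label!r}")


@dataclass(frozen=True)
class StimulusTrain:
    """Timed tap (sound/vibration) events of a fixed window length."""

    start_times: tuple[float, ...]
    window_s: float = 2.0

    def __post_init__(self) -> None:
        t = np.asarray(self.start_times, dtype=float)
        if len(t) and (np.diff(t) < self.window_s - 1e-12).any():
            raise ConfigError("stimulus events must be non-overlapping and increasing")

    @property
    def count(self) -> int:
        return len(self.start_times)

    def windows(self) -> list[tuple[float, float]]:
        return [(t, t + self.window_s) for t in self.start_times]


@dataclass
class AssaySession:
    """A complete recording session: traces plus its schedule."""

    kind: str  # fld | startle | social | circadian | dusk_dawn
    traces: list[LocomotionTrace]
    regime: LightRegime
    stimuli: StimulusTrain | None = None
    zone_traces: list[ZoneTrace] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        widths = {t.bin_width for t in self.traces}
        if len(widths) > 1:
            raise DataError(f"traces mix bin widths: {sorted(widths)}")
        if self.kind == "startle" and self.stimuli is None:
            raise DataError("startle sessions require a StimulusTrain")
        if self.kind != "startle" and self.stimuli is not None:
            raise DataError(f"{self.kind} sessions must not carry a StimulusTrain")

    @property
    def bin_width(self) -> float:
        return self.traces[0].bin_width

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.traces:
            seen.setdefault(t.condition, None)
        return list(seen)

    def to_long(self) -> pd.DataFrame:
        """Tidy long table: one row per subject x bin."""
        frames = []
        for tr in self.traces:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": tr.subject_id,
                        "well_id": tr.well_id,
                        "condition": tr.condition,
                        "t_bin_start_s": tr.bin_starts(),
                        "distance_mm": tr.distances,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        if self.zone_traces:
            zframes = []
            for zt in self.zone_traces:
                zcols = {f"zone_{k}": v for k, v in zt.zones.items()}
                zframes.append(
                    pd.DataFrame(
                        {
                            "subject_id": zt.subject_id,
                            "t_bin_start_s": zt.t0
                            + zt.bin_width * np.arange(len(zt)),
                            **zcols,
                        }
                    )
                )
            zdf = pd.concat(zframes, ignore_index=True)
            df = df.merge(zdf, on=["subject_id", "t_bin_start_s"], how="left")
        return df


@dataclass(frozen=True)
class SchemaConfig:
    """Column mapping adapting a vendor export to the canonical schema.

    ``unit_to_mm`` multiplies distances at ingest, so exports in cm or m can
    be read directly (e.g. ``unit_to_mm=10`` for cm).
    """

    subject_col: str = "subject_id"
    well_col: str = "well_id"
    condition_col: str = "condition"
    time_col: str = "t_bin_start_s"
    distance_col: str = "distance_mm"
    unit_to_mm: float = 1.0
    zone_prefix: str = "zone_"


def read_tracking_table(
    path,
    schema: SchemaConfig | None = None,
    *,
    kind: str = "fld",
    regime: "LightRegime | None" = None,
    stimuli: StimulusTrain | None = None,
    sep: str = ",",
) -> AssaySession:
    """Read a tidy time-binned tracking export into an :class:`AssaySession`.

    One :class:`LocomotionTrace` is built per subject; bins are sorted by
    time, interior gaps are filled with NaN missing-markers, and '.' or empty
    distance cells are treated as missing.
    """
    schema = schema or SchemaConfig()
    df = pd.read_csv(
        path, sep=sep, na_values=["."], dtype={0: str}, float_precision="round_trip"
    )
    for col in (schema.subject_col, schema.condition_col, schema.time_col, schema.distance_col):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    has_well = schema.well_col in df.columns
    zone_cols = [c for c in df.columns if c.startswith(schema.zone_prefix)]

    if regime is None:
        regime = LightRegime(segments=(Segment("all", duration_s=max(float(df[schema.time_col].max()) + 1.0, 1.0), intensity_pct=100.0),), name="unspecified")

    traces: list[LocomotionTrace] = []
    zone_traces: list[ZoneTrace] = []
    for sid, grp in df.groupby(schema.subject_col, sort=False):
        t = grp[schema.time_col].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        t = t[order]
        if (np.diff(t) <= 0).any():
            raise DataError(f"non-monotone time bins for subject {sid!r}")
        d = grp[schema.distance_col].to_numpy(dtype=float)[order] * schema.unit_to_mm
        if (d[np.isfinite(d)] < 0).any():
            raise DataError(f"negative distance for subject {sid!r}")
        dt = np.diff(t)
        bin_width = float(np.min(dt)) if len(dt) else 1.0
        # gap-fill: place observed bins on the regular grid, NaN elsewhere
        n = int(round((t[-1] - t[0]) / bin_width)) + 1
        idx = np.round((t - t[0]) / bin_width).astype(int)
        if len(np.unique(idx)) != len(idx):
            raise DataError(f"duplicate time bins for subject {sid!r}")
        filled = np.full(n, np.nan)
        filled[idx] = d
        well = str(grp[schema.well_col].iloc[0]) if has_well else ""
        cond = str(grp[schema.condition_col].iloc[0])
        traces.append(
            LocomotionTrace(
                subject_id=str(sid),
                well_id=well,
                condition=cond,
                bin_width=bin_width,
                t0=float(t[0]),
                distances=filled,
            )
        )
        if zone_cols:
            zones = {}
            for zc in zone_cols:
                zarr = np.full(n, np.nan)
                zarr[idx] = grp[zc].to_numpy(dtype=float)[order]
                zones[zc[len(schema.zone_prefix):]] = zarr
            if not all(np.isnan(v).all() for v in zones.values()):
                zone_traces.append(
                    ZoneTrace(
                        subject_id=str(sid),
                        condition=cond,
                        bin_width=bin_width,
                        t0=float(t[0]),
                        zones=zones,
                    )
                )
    return AssaySession(
        kind=kind, traces=traces, regime=regime, stimuli=stimuli, zone_traces=zone_traces
    )


def write_tracking_table(session: AssaySession, path, *, sep: str = ",") -> None:
    """Write a session to the canonical tidy table (missing -> empty cell)."""
    session.to_long().to_csv(path, sep=sep, index=False)


def rebin(trace: LocomotionTrace, new_bin_width: float) -> LocomotionTrace:
    """Aggregate a trace to a coarser bin width.

    ``new_bin_width`` must be an integer multiple of the current width.
    Distances are summed within each new bin; a new bin containing any
    missing value becomes missing, so total non-missing distance is conserved
    across the non-missing bins.
    """
    factor_f = new_bin_width / trace.bin_width
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"new_bin_width {new_bin_width} is not an integer multiple of "
            f"{trace.bin_width}"
        )
    if factor == 1:
        return replace(trace, distances=trace.distances.copy())
    n_full = len(trace.distances) // factor
    if n_full * factor != len(trace.distances):
        raise ValueError(
            f"trace length {len(trace.distances)} not divisible by factor {factor}"
        )
    blocks = trace.distances[: n_full * factor].reshape(n_full, factor)
    summed = blocks.sum(axis=1)  # NaN-propagating by design
    return replace(trace, bin_width=float(new_bin_width), distances=summed)


def slice_segment(
    trace: LocomotionTrace, interval: tuple[float, float]
) -> LocomotionTrace:
    """Extract the half-open time interval ``[start, end)`` from a trace."""
    start, end = float(interval[0]), float(interval[1])
    if start < trace.t0 - 1e-9 or end > trace.t_end + 1e-9 or end <= start:
        raise ValueError(
            f"interval [{start}, {end}) outside trace span "
            f"[{trace.t0}, {trace.t_end})"
        )
    i0 = int(round((start - trace.t0) / trace.bin_width))
    i1 = int(round((end - trace.t0) / trace.bin_width))
    return replace(trace, t0=trace.t0 + i0 * trace.bin_width, distances=trace.distances[i0:i1].copy())


def slice_zone(zt: ZoneTrace, interval: tuple[float, float]) -> ZoneTrace:
    """Half-open interval slice of a zone-occupancy trace."""
    start, end = float(interval[0]), float(interval[1])
    if start < zt.t0 - 1e-9 or end > zt.t0 + zt.span + 1e-9 or end <= start:
        raise ValueError(f"interval [{start}, {end}) outside zone-trace span")
    i0 = int(round((start - zt.t0) / zt.bin_width))
    i1 = int(round((end - zt.t0) / zt.bin_width))
    return ZoneTrace(
        subject_id=zt.subject_id,
        condition=zt.condition,
        bin_width=zt.bin_width,
        t0=zt.t0 + i0 * zt.bin_width,
        zones={k: v[i0:i1].copy() for k, v in zt.zones.items()},
    )
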