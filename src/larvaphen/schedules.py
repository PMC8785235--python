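"""Shipped assay schedules and the plain-text schedule format.

Five presets reproduce the study designs the pipeline targets:

``fld_default``
    10 min dark baseline; 10 min light; 10 min dark; 1 min light; 10 min
    dark (2460 s at 100%/0% intensity, infrared darkness treated as 0%).
``startle_default``
    1 min baseline then 25 tap stimuli at 2-s inter-stimulus intervals,
    each analyzed over a 2-s event window.
``social_default``
    30 min acclimation followed by a 15 min experimental phase with
    conspecific stimulus fish behind a partition.
``circadian_default``
    3 h light; 54 h dark (free-running); 2 h light — 59 h in total.
``duskdawn_default``
    3 h light; gradual dusk; 10 h dark; gradual dawn; 2 h light.  The ramp
    segments carry the schedule's stated 46-min duration; the stepwise
    profile itself (5%/2 min down to 5%, then 1%/2 min to off, mirrored at
    dawn) enumerates to 48 min — both numbers are recorded and the
    discrepancy is surfaced by :func:`larvaphen.circadian_analysis.build_ramp`.
"""

from __future__ import annotations

import configparser

from larvaphen.errors import ConfigError
from larvaphen.trace_model import LightRegime, Segment, StepRamp, StimulusTrain

__all__ = [
    "DUSK_RAMP",
    "DAWN_RAMP",
    "regime_preset",
    "stimulus_preset",
    "load_schedule",
    "REGIME_PRESETS",
]

DUSK_RAMP = StepRamp(
    direction="down",
    start_pct=100.0,
    phases=((5.0, 120.0, 5.0), (1.0, 120.0, 0.0)),
)

DAWN_RAMP = StepRamp(
    direction="up",
    start_pct=0.0,
    phases=((1.0, 120.0, 5.0), (5.0, 120.0, 100.0)),
)

_MIN = 60.0
_HOUR = 3600.0

REGIME_PRESETS: dict[str, LightRegime] = {
    "fld_default": LightRegime(
        name="fld_default",
        segments=(
            Segment("baseline", 10 * _MIN, intensity_pct=0.0),
            Segment("light10", 10 * _MIN, intensity_pct=100.0),
            Segment("dark10", 10 * _MIN, intensity_pct=0.0),
            Segment("light1", 1 * _MIN, intensity_pct=100.0),
            Segment("dark5", 10 * _MIN, intensity_pct=0.0),
        ),
    ),
    "startle_default": LightRegime(
        name="startle_default",
        segments=(
            Segment("baseline", 1 * _MIN, intensity_pct=100.0),
            Segment("taps", 50.0, intensity_pct=100.0),
        ),
    ),
    "social_default": LightRegime(
        name="social_default",
        segments=(
            Segment("acclimation", 30 * _MIN, intensity_pct=100.0),
            Segment("experimental", 15 * _MIN, intensity_pct=100.0),
        ),
    ),
    "circadian_default": LightRegime(
        name="circadian_default",
        segments=(
            Segment("light_pre", 3 * _HOUR, intensity_pct=100.0),
            Segment("free_running_dark", 54 * _HOUR, intensity_pct=0.0),
            Segment("light_post", 2 * _HOUR, intensity_pct=100.0),
        ),
    ),
    "duskdawn_default": LightRegime(
        name="duskdawn_default",
        segments=(
            Segment("light_pre", 3 * _HOUR, intensity_pct=100.0),
            Segment("dusk", 46 * _MIN, ramp=DUSK_RAMP),
            Segment("dark", 10 * _HOUR, intensity_pct=0.0),
            Segment("dawn", 46 * _MIN, ramp=DAWN_RAMP),
            Segment("light_post", 2 * _HOUR, intensity_pct=100.0),
        ),
    ),
}

_RAMP_PRESETS = {"dusk": DUSK_RAMP, "dawn": DAWN_RAMP}


def regime_preset(name: str) -> LightRegime:
    """Look up a shipped :class:`LightRegime` by preset name."""
    try:
        return REGIME_PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown regime preset {name!r}; available: {sorted(REGIME_PRESETS)}"
        ) from None


def stimulus_preset(name: str = "taps_25x2s") -> StimulusTrain:
    """Shipped stimulus trains (currently the 25-tap, 2-s-ISI train starting
    after the 1-min baseline)."""
    if name != "taps_25x2s":
        raise ConfigError(f"unknown stimulus preset {name!r}")
    return StimulusTrain(
        start_times=tuple(60.0 + 2.0 * i for i in range(25)), window_s=2.0
    )


def load_schedule(path) -> tuple[LightRegime, StimulusTrain | None]:
    """Parse a plain-text (INI) schedule file.

    Sections named ``[segment <label>]`` are read in order; each requires
    ``duration_s`` and either ``intensity_pct`` or ``ramp = dusk|dawn``.
    An optional ``[stimuli]`` section with ``start_s``, ``count``, ``isi_s``
    and ``window_s`` defines a tap train.
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise ConfigError(f"schedule file {path!r} not found or unreadable")
    segments: list[Segment] = []
    stimuli: StimulusTrain | None = None
    for section in cp.sections():
        if section.startswith("segment"):
            label = section.split(None, 1)[1] if " " in section else section
            sec = cp[section]
            duration = sec.getfloat("duration_s")
            if duration is None:
                raise ConfigError(f"{section}: duration_s required")
            if "ramp" in sec:
                ramp = _RAMP_PRESETS.get(sec["ramp"])
                if ramp is None:
                    raise ConfigError(f"{section}: unknown ramp {sec['ramp']!r}")
                segments.append(Segment(label, duration, ramp=ramp))
            else:
                segments.append(
                    Segment(label, duration, intensity_pct=sec.getfloat("intensity_pct"))
                )
        elif section == "stimuli":
            sec = cp[section]
            start = sec.getfloat("start_s", 60.0)
            count = sec.getint("count", 25)
            isi = sec.getfloat("isi_s", 2.0)
            window = sec.getfloat("window_s", 2.0)
            stimuli = StimulusTrain(
                start_times=tuple(start + isi * i for i in range(count)),
                window_s=window,
            )
    if not segments:
        raise ConfigError(f"schedule file {path!r} defines no segments")
    return LightRegime(segments=tuple(segments), name=str(path)), stimuli
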