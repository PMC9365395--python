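"""Event-file reading and writing.

The interchange format is a TSV dialect: leading comment lines of the form
``#key<TAB>value`` carry recording metadata (recording id, voltage in mV,
filter cutoff in Hz, dead time in seconds, ligand concentrations in uM),
followed by a header row and the columns ``index``, ``class`` (0 shut /
1 open), ``duration_s`` and an optional ``amplitude_pA`` (may be empty).
Durations are written with enough digits for a lossless round trip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .events import EventList

_META_KEYS = ("recording_id", "voltage_mV", "filter_fc_Hz", "dead_time_s")


def write_events(events: EventList, path: str | Path) -> None:
    path = Path(path)
    lines: list[str] = []
    meta = events.meta
    for key in _META_KEYS:
        if key in meta:
            lines.append(f"#{key}\t{meta[key]}")
    for ligand, conc in sorted(meta.get("concentrations", {}).items()):
        lines.append(f"#conc_uM:{ligand}\t{conc!r}")
    has_amp = events.amplitudes is not None
    header = "index\tclass\tduration_s" + ("\tamplitude_pA" if has_amp else "")
    lines.append(header)
    for i in range(len(events)):
        # repr = shortest digits that round-trip the float64 exactly
        row = f"{i}\t{int(events.classes[i])}\t{float(events.durations[i])!r}"
        if has_amp:
            a = events.amplitudes[i]
            row += "\t" if np.isnan(a) else f"\t{float(a)!r}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_events(path: str | Path) -> EventList:
    path = Path(path)
    meta: dict = {"concentrations": {}}
    classes: list[int] = []
    durations: list[float] = []
    amplitudes: list[float] = []
    saw_amp_column = False
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            if key.startswith("conc_uM:"):
                meta["concentrations"][key.split(":", 1)[1]] = float(value)
            elif key in ("voltage_mV", "filter_fc_Hz", "dead_time_s"):
                meta[key] = float(value)
            else:
                meta[key] = value
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields[0] != "index":
                raise ConfigurationError(
                    f"{path}:{lineno}: expected header row, got {line!r}"
                )
            saw_amp_column = "amplitude_pA" in fields
            header_seen = True
            continue
        try:
            cls = int(fields[1])
            dur = float(fields[2])
        except (IndexError, ValueError) as exc:
            raise ConfigurationError(
                f"{path}:{lineno}: malformed event line {line!r}"
            ) from exc
        if dur <= 0:
            raise ConfigurationError(
                f"{path}:{lineno}: non-positive duration {dur}"
            )
        classes.append(cls)
        durations.append(dur)
        if saw_amp_column:
            amp = fields[3] if len(fields) > 3 else ""
            amplitudes.append(float(amp) if amp.strip() else np.nan)
    if not header_seen or not classes:
        warnings.warn(f"{path}: no event rows found", stacklevel=2)
        return EventList(np.empty(0, dtype=int), np.empty(0) + 1.0, None, meta)
    return EventList(
        np.array(classes),
        np.array(durations),
        np.array(amplitudes) if saw_amp_column else None,
        meta,
    )
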