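"""Readers/writers and match-clock synchronisation.

Formats are deliberately plain: comma-separated text for accelerometer
traces, intensity series, annotations, periods and masks; YAML or JSON for
the match configuration; JSON for reports.  The match clock is 0-based in
whole seconds with second 0 at tip-off, and all intervals are half-open
``[start_s, end_s)`` so that ``duration = end - start`` exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .signal import AccelTrace, RelativeIntensitySeries


class FormatError(ValueError):
    """A file did not match the expected plain-text layout."""


@dataclass
class PlayerSpec:
    """Roster entry: identity, body mass and %V̇O2R calibration line."""

    player_id: str
    body_mass_kg: float
    cal_slope: float  # %V̇O2R per newton
    cal_intercept: float  # %V̇O2R at zero net force

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError(f"player {self.player_id}: body mass must be positive")
        if not (np.isfinite(self.cal_slope) and np.isfinite(self.cal_intercept)):
            raise ValueError(f"player {self.player_id}: non-finite calibration")


@dataclass
class MatchConfig:
    """Everything the pipeline needs to know about one match.

    ``exclusion_intervals`` are match-clock intervals forced inactive
    (half time, by convention annotated manually); they must be
    non-overlapping and inside ``[0, match_end_s)``.
    """

    players: list[PlayerSpec]
    match_end_s: int
    tipoff_offset_s: int = 0
    exclusion_intervals: list[tuple[int, int]] = field(default_factory=list)
    window_s: int = 9
    threshold_pct: float = 31.0
    min_gap_s: int = 10
    min_players_active: int = 3

    def __post_init__(self) -> None:
        if self.match_end_s <= 0:
            raise ValueError("match_end_s must be positive")
        if self.tipoff_offset_s < 0:
            raise ValueError("tipoff_offset_s must be non-negative")
        if self.window_s < 1:
            raise ValueError("window_s must be >= 1")
        if not 0 < self.threshold_pct < 100:
            raise ValueError("threshold_pct must lie in (0, 100)")
        if self.min_gap_s < 0:
            raise ValueError("min_gap_s must be >= 0")
        if self.min_players_active < 1:
            raise ValueError("min_players_active must be >= 1")
        ivals = sorted((int(a), int(b)) for a, b in self.exclusion_intervals)
        for start, end in ivals:
            if not 0 <= start < end <= self.match_end_s:
                raise ValueError(
                    f"exclusion interval [{start}, {end}) outside match clock "
                    f"[0, {self.match_end_s})"
                )
        for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError("exclusion intervals overlap")
        self.exclusion_intervals = ivals


@dataclass
class AnnotationSet:
    """Manual live-play annotation: the criterion measure.

    ``periods`` is the team-level timeline.  When the source file carries a
    ``player_id`` column, ``by_player`` holds per-player timelines as well
    (rows labelled ``team`` feed the team timeline).
    """

    periods: list[tuple[int, int]]
    observer_id: str = "observer"
    by_player: dict[str, list[tuple[int, int]]] | None = None

    def __post_init__(self) -> None:
        self.periods = _validate_periods(self.periods, "team")
        if self.by_player is not None:
            self.by_player = {
                pid: _validate_periods(p, pid) for pid, p in self.by_player.items()
            }


def _validate_periods(
    periods: Sequence[tuple[int, int]], label: str
) -> list[tuple[int, int]]:
    out = [(int(s), int(e)) for s, e in periods]
    bad = [(s, e) for s, e in out if e <= s]
    if bad:
        raise ValueError(f"{label}: inverted/empty periods {bad}")
    out.sort()
    overlaps = [
        (a, b) for a, b in zip(out, out[1:]) if b[0] < a[1]
    ]
    if overlaps:
        raise ValueError(f"{label}: overlapping periods {overlaps}")
    return out


# ---------------------------------------------------------------------------
# accelerometer traces


def read_accel_csv(path: str | Path, sample_rate_hz: float, player_id: str = "player") -> AccelTrace:
    """Read a ``time,x,y,z`` (or ``x,y,z``) CSV of accelerations in g.

    Vendor exports often prepend a free-text header block; any leading lines
    whose first comma-separated field is not numeric are skipped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    first_data = None
    for i, line in enumerate(lines):
        head = line.split(",")[0].strip()
        try:
            float(head)
        except ValueError:
            continue
        first_data = i
        break
    if first_data is None:
        raise FormatError(f"{path}: no numeric data rows found")
    try:
        frame = pd.read_csv(
            path, skiprows=first_data, header=None, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: {exc}") from exc
    if frame.shape[1] == 4:
        data = frame.iloc[:, 1:4]
    elif frame.shape[1] == 3:
        data = frame
    else:
        raise FormatError(
            f"{path}: expected 3 (x,y,z) or 4 (time,x,y,z) columns, "
            f"got {frame.shape[1]} at line {first_data + 1}"
        )
    values = data.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad_rows = np.nonzero(~np.isfinite(values).all(axis=1))[0]
    if bad_rows.size:
        raise FormatError(
            f"{path}: non-numeric value at line {first_data + 1 + int(bad_rows[0])}"
        )
    if values.shape[0] == 0:
        raise FormatError(f"{path}: zero data rows")
    return AccelTrace(data=values, sample_rate_hz=sample_rate_hz, player_id=player_id)


def write_accel_csv(trace: AccelTrace, path: str | Path, with_time: bool = True) -> None:
    """Write a trace as ``time,x,y,z`` rows (time in seconds)."""
    path = Path(path)
    if with_time:
        t = np.arange(trace.n_samples) / trace.sample_rate_hz
        out = np.column_stack([t, trace.data])
    else:
        out = trace.data
    # repr-precision floats so a write/read round-trip is bit-identical
    with path.open("w") as fh:
        for row in out:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def align_to_match_clock(
    obj: AccelTrace | RelativeIntensitySeries, tipoff_offset_s: int
):
    """Shift a trace or intensity series so tip-off becomes time zero.

    Samples/epochs before tip-off are discarded; inter-event intervals are
    preserved exactly.
    """
    if tipoff_offset_s < 0:
        raise ValueError("tip-off offset must be non-negative")
    if isinstance(obj, AccelTrace):
        n_skip = int(round(tipoff_offset_s * obj.sample_rate_hz))
        if n_skip >= obj.n_samples:
            raise ValueError(
                f"offset {tipoff_offset_s} s is beyond the trace duration "
                f"({obj.duration_s:.2f} s)"
            )
        return replace(obj, data=obj.data[n_skip:])
    if isinstance(obj, RelativeIntensitySeries):
        if tipoff_offset_s >= len(obj):
            raise ValueError(
                f"offset {tipoff_offset_s} s is beyond the series length ({len(obj)} s)"
            )
        avf = obj.avfnet[tipoff_offset_s:] if obj.avfnet is not None else None
        return replace(obj, values=obj.values[tipoff_offset_s:], avfnet=avf)
    raise TypeError(f"cannot align object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# annotations, periods, masks


def read_annotations(path: str | Path, observer_id: str = "observer") -> AnnotationSet:
    """Read ``start_s,end_s[,player_id]`` annotation CSV."""
    frame = pd.read_csv(path)
    cols = [c.strip().lower() for c in frame.columns]
    frame.columns = cols
    if "start_s" not in cols or "end_s" not in cols:
        raise FormatError(f"{path}: need start_s and end_s columns, got {cols}")
    if "player_id" in cols:
        by_player: dict[str, list[tuple[int, int]]] = {}
        for pid, grp in frame.groupby("player_id"):
            by_player[str(pid)] = list(zip(grp["start_s"], grp["end_s"]))
        team = by_player.pop("team", None)
        if team is None:
            # no explicit team rows: the team timeline is the merged union
            team = merge_periods(
                [p for periods in by_player.values() for p in periods]
            )
        return AnnotationSet(periods=team, observer_id=observer_id,
                             by_player=by_player or None)
    periods = list(zip(frame["start_s"], frame["end_s"]))
    return AnnotationSet(periods=periods, observer_id=observer_id)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    rows = [("team", s, e) for s, e in ann.periods]
    if ann.by_player:
        for pid, periods in ann.by_player.items():
            rows += [(pid, s, e) for s, e in periods]
    pd.DataFrame(rows, columns=["player_id", "start_s", "end_s"]).to_csv(
        path, index=False
    )


def merge_periods(periods: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted((int(s), int(e)) for s, e in periods):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def periods_to_mask(periods: Sequence[tuple[int, int]], length_s: int) -> np.ndarray:
    """Boolean per-second mask over ``[0, length_s)`` from half-open periods."""
    mask = np.zeros(int(length_s), dtype=bool)
    for s, e in periods:
        if not 0 <= s < e <= length_s:
            raise ValueError(f"period [{s}, {e}) outside [0, {length_s})")
        mask[s:e] = True
    return mask


def write_periods_csv(
    periods_by_player: Mapping[str, Sequence], path: str | Path
) -> None:
    """``player_id,start_s,end_s,duration_s`` rows; accepts LivePlayPeriod or tuples."""
    rows = []
    for pid, periods in periods_by_player.items():
        for p in periods:
            s, e = (p.start_s, p.end_s) if hasattr(p, "start_s") else (p[0], p[1])
            rows.append((pid, int(s), int(e), int(e) - int(s)))
    pd.DataFrame(rows, columns=["player_id", "start_s", "end_s", "duration_s"]).to_csv(
        path, index=False
    )


def read_periods_csv(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    frame = pd.read_csv(path)
    out: dict[str, list[tuple[int, int]]] = {}
    for pid, grp in frame.groupby("player_id", sort=False):
        out[str(pid)] = _validate_periods(
            list(zip(grp["start_s"], grp["end_s"])), str(pid)
        )
    return out


def write_masks_csv(masks: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Long-format ``player_id,second,active`` per-second mask export."""
    frames = [
        pd.DataFrame(
            {"player_id": pid, "second": np.arange(len(m)), "active": np.asarray(m, int)}
        )
        for pid, m in masks.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_masks_csv(path: str | Path) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path)
    out: dict[str, np.ndarray] = {}
    for pid, grp in frame.groupby("player_id", sort=False):
        grp = grp.sort_values("second")
        seconds = grp["second"].to_numpy()
        if not np.array_equal(seconds, np.arange(len(seconds))):
            raise FormatError(f"{path}: mask for {pid} has gaps or does not start at 0")
        out[str(pid)] = grp["active"].to_numpy() != 0
    return out


# ---------------------------------------------------------------------------
# intensity series


def write_intensity_csv(
    series: Mapping[str, RelativeIntensitySeries] | Sequence[RelativeIntensitySeries],
    path: str | Path,
) -> None:
    """Long-format ``player_id,second,vo2r_pct[,avfnet_n]`` export."""
    if isinstance(series, Mapping):
        series = list(series.values())
    frames = []
    with_force = all(s.avfnet is not None for s in series)
    for s in series:
        frame = pd.DataFrame(
            {
                "player_id": s.player_id,
                "second": np.arange(len(s)),
                "vo2r_pct": s.values,
            }
        )
        if with_force:
            frame["avfnet_n"] = s.avfnet
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_intensity_csv(path: str | Path) -> dict[str, RelativeIntensitySeries]:
    frame = pd.read_csv(path)
    needed = {"player_id", "second", "vo2r_pct"}
    if not needed.issubset(frame.columns):
        raise FormatError(f"{path}: need columns {sorted(needed)}, got {list(frame.columns)}")
    out: dict[str, RelativeIntensitySeries] = {}
    for pid, grp in frame.groupby("player_id", sort=False):
        grp = grp.sort_values("second")
        seconds = grp["second"].to_numpy()
        if not np.array_equal(seconds, np.arange(len(seconds))):
            raise FormatError(
                f"{path}: intensity for {pid} has gaps or does not start at second 0"
            )
        avf = grp["avfnet_n"].to_numpy() if "avfnet_n" in grp.columns else None
        out[str(pid)] = RelativeIntensitySeries(
            values=grp["vo2r_pct"].to_numpy(), player_id=str(pid), avfnet=avf
        )
    return out


# ---------------------------------------------------------------------------
# configuration and reports


def load_config(path: str | Path) -> MatchConfig:
    """Load a :class:`MatchConfig` from YAML or JSON."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    players = [PlayerSpec(**p) for p in raw.pop("players", [])]
    excl = [tuple(iv) for iv in raw.pop("exclusion_intervals", [])]
    known = {f.name for f in dataclasses.fields(MatchConfig)} - {"players", "exclusion_intervals"}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return MatchConfig(players=players, exclusion_intervals=excl, **raw)


def save_config(config: MatchConfig, path: str | Path) -> None:
    doc = dataclasses.asdict(config)
    doc["exclusion_intervals"] = [list(iv) for iv in config.exclusion_intervals]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_report(report: Mapping, path: str | Path) -> None:
    """Serialise a report mapping (dataclasses/ndarrays allowed) to JSON."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=2, allow_nan=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
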