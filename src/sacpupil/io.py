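"""Reading and writing raw samples, trial metadata, epochs and results.

Two sample dialects are supported.  ``csv`` is the package's native,
inspectable format: a UTF-8 table with header ``trial,t,x,y,p`` where gaze
is in degrees from screen center (y positive up) and missing fields are
empty.  ``asc_like`` is a documented subset of EyeLink ASC output: sample
lines ``t  x  y  p`` in screen pixels (y positive down) with ``.`` for
missing data, and ``MSG`` lines delimiting trials and carrying metadata::

    MSG 0 TRIALID 3
    MSG 0 VAR participant p01
    MSG 0 VAR direction left
    ...
    1000  512.0  384.0  1213.0
    MSG 4000 TRIAL_END

Pixel coordinates are converted to degrees on ingestion via a
:class:`~sacpupil.config.ScreenGeometry`.  After ingestion a missing sample
is a *masked* sample — never a pupil value of 0, which is only the
tracker's blink sentinel on disk.
"""

from __future__ import annotations

import io as _io
from contextlib import contextmanager
from dataclasses import dataclass
from typing import IO, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import ScreenGeometry
from .eye_signal import GazeTrace

Pathish = Union[str, IO[str]]

META_KEYS = ("participant", "direction", "condition", "cue_onset",
             "fixation_pos", "target_pos", "spatial_frequency")


@dataclass
class TrialMeta:
    """Per-trial metadata.

    ``fixation_pos`` and ``target_pos`` are (x, y) in degrees and are
    point-symmetric about the screen center (the target sits opposite the
    fixation dot).
    """

    participant: str
    trial_id: int
    direction: str                      # left | right | up | down
    condition: str                      # intrasaccadic_percept | no_percept | part1
    cue_onset: float                    # ms
    fixation_pos: Tuple[float, float]   # deg
    target_pos: Tuple[float, float]     # deg
    spatial_frequency: Optional[float] = None  # cycles/deg, when applicable


@dataclass
class Trial:
    """One trial: metadata plus its gaze/pupil trace."""

    meta: Optional[TrialMeta]
    trace: GazeTrace


@contextmanager
def _open(source: Pathish, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        yield source
    else:
        fh = open(source, mode, encoding="utf-8", newline="")
        try:
            yield fh
        finally:
            fh.close()


def _fmt(v: float) -> str:
    return "" if not np.isfinite(v) else repr(float(v))


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------

def read_samples(
    source: Pathish,
    dialect: str = "csv",
    geometry: Optional[ScreenGeometry] = None,
) -> List[Trial]:
    """Parse a sample stream into one :class:`Trial` per trial.

    Malformed lines raise ``ValueError`` naming the line number.  In the
    csv dialect a missing ``trial`` column means a single trial with id 0;
    metadata, if any, travels in a separate table (:func:`read_trial_meta`).
    """
    if dialect == "csv":
        return _read_samples_csv(source)
    if dialect == "asc_like":
        return _read_samples_asc(source, geometry or ScreenGeometry())
    raise ValueError(f"unknown dialect {dialect!r}")


def write_samples(
    trials: Sequence[Trial],
    sink: Pathish,
    dialect: str = "csv",
    geometry: Optional[ScreenGeometry] = None,
) -> None:
    if dialect == "csv":
        _write_samples_csv(trials, sink)
    elif dialect == "asc_like":
        _write_samples_asc(trials, sink, geometry or ScreenGeometry())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _finish_trial(trial_id, rows) -> Trial:
    t = np.array([r[0] for r in rows], dtype=np.int64)
    x = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    p = np.array([r[3] for r in rows])
    valid = np.isfinite(x) & np.isfinite(y) & np.isfinite(p) & (p != 0)
    p = np.where(valid, p, np.nan)
    x = np.where(np.isfinite(x), x, np.nan)
    y = np.where(np.isfinite(y), y, np.nan)
    trace = GazeTrace(t=t, x=x, y=y, pupil=p, valid=valid)
    return trial_id, trace


def _read_samples_csv(source: Pathish) -> List[Trial]:
    trials: List[Trial] = []
    current: Optional[int] = None
    rows: list = []
    with _open(source, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    header = [c.strip() for c in lines[0].split(",")]
    try:
        it_ix = header.index("t")
        ix, iy, ip = header.index("x"), header.index("y"), header.index("p")
    except ValueError as exc:
        raise ValueError(f"line 1: bad header {lines[0]!r}") from exc
    itrial = header.index("trial") if "trial" in header else None

    def flush():
        if rows:
            tid, trace = _finish_trial(current, rows)
            trials.append(Trial(meta=None, trace=trace))
            trials[-1].trial_id = tid  # type: ignore[attr-defined]

    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(",")
        try:
            tid = int(fields[itrial]) if itrial is not None else 0
            t = int(fields[it_ix])
            x = float(fields[ix]) if fields[ix].strip() else np.nan
            y = float(fields[iy]) if fields[iy].strip() else np.nan
            p = float(fields[ip]) if fields[ip].strip() else np.nan
        except (ValueError, IndexError) as exc:
            raise ValueError(f"line {lineno}: malformed sample {line!r}") from exc
        if current is None:
            current = tid
        if tid != current:
            flush()
            rows = []
            current = tid
        rows.append((t, x, y, p))
    flush()
    return trials


def _write_samples_csv(trials: Sequence[Trial], sink: Pathish) -> None:
    out = ["trial,t,x,y,p"]
    for i, trial in enumerate(trials):
        tid = trial.meta.trial_id if trial.meta is not None else i
        tr = trial.trace
        for j in range(len(tr)):
            p = tr.pupil[j] if tr.valid[j] else np.nan
            out.append(f"{tid},{tr.t[j]},{_fmt(tr.x[j])},{_fmt(tr.y[j])},{_fmt(p)}")
    with _open(sink, "w") as fh:
        fh.write("\n".join(out) + "\n")


def _parse_pos(text: str) -> Tuple[float, float]:
    a, b = text.split(",")
    return float(a), float(b)


def _read_samples_asc(source: Pathish, geometry: ScreenGeometry) -> List[Trial]:
    trials: List[Trial] = []
    meta_kv: dict = {}
    rows: list = []
    current: Optional[int] = None

    def flush():
        nonlocal rows, meta_kv
        if current is None:
            return
        _, trace = _finish_trial(current, rows)
        x, y = geometry.to_degrees(trace.x, trace.y)
        trace.x, trace.y = np.asarray(x, float), np.asarray(y, float)
        meta = None
        if meta_kv:
            meta = TrialMeta(
                participant=str(meta_kv.get("participant", "")),
                trial_id=current,
                direction=str(meta_kv.get("direction", "")),
                condition=str(meta_kv.get("condition", "")),
                cue_onset=float(meta_kv.get("cue_onset", 0.0)),
                fixation_pos=_parse_pos(meta_kv.get("fixation_pos", "0,0")),
                target_pos=_parse_pos(meta_kv.get("target_pos", "0,0")),
                spatial_frequency=(float(meta_kv["spatial_frequency"])
                                   if "spatial_frequency" in meta_kv else None),
            )
        trials.append(Trial(meta=meta, trace=trace))
        rows, meta_kv = [], {}

    with _open(source, "r") as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split()
        if parts[0] == "MSG":
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: malformed MSG {line!r}")
            kind = parts[2]
            if kind == "TRIALID":
                flush()
                current = int(parts[3])
            elif kind == "VAR":
                if len(parts) < 5:
                    raise ValueError(f"line {lineno}: malformed VAR {line!r}")
                meta_kv[parts[3]] = " ".join(parts[4:])
            elif kind == "TRIAL_END":
                flush()
                current = None
            else:
                raise ValueError(f"line {lineno}: unknown MSG kind {kind!r}")
            continue
        if current is None:
            raise ValueError(f"line {lineno}: sample outside any trial")
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: malformed sample {line!r}")
        try:
            t = int(parts[0])
            x = np.nan if parts[1] == "." else float(parts[1])
            y = np.nan if parts[2] == "." else float(parts[2])
            p = np.nan if parts[3] == "." else float(parts[3])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed sample {line!r}") from exc
        rows.append((t, x, y, p))
    flush()
    return trials


def _write_samples_asc(trials: Sequence[Trial], sink: Pathish,
                       geometry: ScreenGeometry) -> None:
    out: List[str] = []
    for i, trial in enumerate(trials):
        meta, tr = trial.meta, trial.trace
        tid = meta.trial_id if meta is not None else i
        t0 = tr.t[0]
        out.append(f"MSG {t0} TRIALID {tid}")
        if meta is not None:
            out.append(f"MSG {t0} VAR participant {meta.participant}")
            out.append(f"MSG {t0} VAR direction {meta.direction}")
            out.append(f"MSG {t0} VAR condition {meta.condition}")
            out.append(f"MSG {t0} VAR cue_onset {_fmt(meta.cue_onset)}")
            out.append(f"MSG {t0} VAR fixation_pos "
                       f"{_fmt(meta.fixation_pos[0])},{_fmt(meta.fixation_pos[1])}")
            out.append(f"MSG {t0} VAR target_pos "
                       f"{_fmt(meta.target_pos[0])},{_fmt(meta.target_pos[1])}")
            if meta.spatial_frequency is not None:
                out.append(f"MSG {t0} VAR spatial_frequency "
                           f"{_fmt(meta.spatial_frequency)}")
        for j in range(len(tr)):
            if tr.valid[j]:
                xp, yp = geometry.to_pixels(tr.x[j], tr.y[j])
                out.append(f"{tr.t[j]}\t{_fmt(xp)}\t{_fmt(yp)}\t{_fmt(tr.pupil[j])}")
            else:
                out.append(f"{tr.t[j]}\t.\t.\t.")
        out.append(f"MSG {tr.t[-1]} TRIAL_END")
    with _open(sink, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Trial metadata tables
# ---------------------------------------------------------------------------

def write_trial_meta(trials: Sequence[Trial], sink: Pathish) -> None:
    rows = ["trial,participant,direction,condition,cue_onset,"
            "fix_x,fix_y,targ_x,targ_y,spatial_frequency"]
    for trial in trials:
        m = trial.meta
        if m is None:
            continue
        sf = ("" if m.spatial_frequency is None
              else repr(float(m.spatial_frequency)))
        rows.append(
            f"{m.trial_id},{m.participant},{m.direction},{m.condition},"
            f"{_fmt(m.cue_onset)},{_fmt(m.fixation_pos[0])},"
            f"{_fmt(m.fixation_pos[1])},{_fmt(m.target_pos[0])},"
            f"{_fmt(m.target_pos[1])},{sf}")
    with _open(sink, "w") as fh:
        fh.write("\n".join(rows) + "\n")


def read_trial_meta(source: Pathish) -> List[TrialMeta]:
    with _open(source, "r") as fh:
        df = pd.read_csv(fh)
    metas = []
    for _, r in df.iterrows():
        sf = r.get("spatial_frequency")
        metas.append(TrialMeta(
            participant=str(r["participant"]), trial_id=int(r["trial"]),
            direction=str(r["direction"]), condition=str(r["condition"]),
            cue_onset=float(r["cue_onset"]),
            fixation_pos=(float(r["fix_x"]), float(r["fix_y"])),
            target_pos=(float(r["targ_x"]), float(r["targ_y"])),
            spatial_frequency=None if pd.isna(sf) else float(sf)))
    return metas


def attach_meta(trials: Sequence[Trial], metas: Sequence[TrialMeta]) -> List[Trial]:
    """Pair metadata rows with sample trials by position."""
    if len(trials) != len(metas):
        raise ValueError("trial/metadata count mismatch")
    return [Trial(meta=m, trace=t.trace) for t, m in zip(trials, metas)]


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

EPOCH_COLUMNS = ("participant", "trial", "condition", "direction",
                 "t_ms", "pupil")


def epochs_to_frame(epochs: Sequence) -> pd.DataFrame:
    """Long-format table of epoched pupil values (masked samples empty)."""
    if not epochs:
        return pd.DataFrame(columns=EPOCH_COLUMNS)
    grid = epochs[0].rel_t
    parts = []
    for ep in epochs:
        if len(ep.rel_t) != len(grid) or np.any(ep.rel_t != grid):
            raise ValueError("epochs do not share one time grid")
        m = ep.meta
        parts.append(pd.DataFrame({
            "participant": m.participant if m else "",
            "trial": m.trial_id if m else -1,
            "condition": m.condition if m else "",
            "direction": m.direction if m else "",
            "t_ms": ep.rel_t,
            "pupil": np.where(ep.valid, ep.values, np.nan),
        }))
    return pd.concat(parts, ignore_index=True)


def write_epochs(epochs, sink: Pathish) -> None:
    """Write epochs (list or long DataFrame) as canonical CSV.

    Formatting is deterministic (floats via ``repr``), so
    write -> read -> write is byte-identical.
    """
    df = epochs if isinstance(epochs, pd.DataFrame) else epochs_to_frame(epochs)
    lines = [",".join(EPOCH_COLUMNS)]
    for row in df.itertuples(index=False):
        lines.append(f"{row.participant},{row.trial},{row.condition},"
                     f"{row.direction},{row.t_ms},{_fmt(row.pupil)}")
    with _open(sink, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_epochs(source: Pathish) -> pd.DataFrame:
    with _open(source, "r") as fh:
        df = pd.read_csv(fh, dtype={"participant": str, "condition": str,
                                    "direction": str})
    return df


def frame_to_matrix(df: pd.DataFrame, decimate: int = 1):
    """Pivot a long epochs table to (values, times, factors) for the sweep.

    ``values`` is (n_epochs, n_times) with NaN for masked samples; ``times``
    the (possibly decimated) grid; ``factors`` one row per epoch with
    participant, condition, direction.
    """
    wide = df.pivot(index=["participant", "trial", "condition", "direction"],
                    columns="t_ms", values="pupil")
    times = wide.columns.to_numpy(dtype=float)
    values = wide.to_numpy(dtype=float)
    if decimate > 1:
        values = values[:, ::decimate]
        times = times[::decimate]
    factors = wide.index.to_frame(index=False)
    return values, times, factors
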