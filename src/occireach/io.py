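"""Reading and writing trial data in standard text formats.

Two dialects are supported for marker trajectories:

* **TRC** -- the tab-delimited Track Row Column format used by optical
  motion-capture pipelines (header with DataRate / NumFrames / NumMarkers /
  Units, then one row per frame).  One trial per file; participant id and
  side are encoded in the file name as ``<participant>_<side>_<k>.trc``.
* **long CSV** -- one row per (trial, frame, marker) with explicit
  ``trial_id, participant_id, side, limb, frame, marker, x, y, z`` columns;
  many trials per file.

Positions are normalized to millimetres on read; a marker-name aliasing
table maps common Plug-in-Gait naming variants onto the canonical subset.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RateMismatchError, TrialParseError
from .trial import NON_PARALYZED, PARALYZED, TrialRecording

#: common alternate marker names -> canonical names
DEFAULT_ALIASES = {
    "RSHOULDER": "RSHO", "LSHOULDER": "LSHO",
    "RELBOW": "RELB", "LELBOW": "LELB",
    "RWRIST_A": "RWRA", "RWRIST_B": "RWRB",
    "LWRIST_A": "LWRA", "LWRIST_B": "LWRB",
    "RFINGER": "RFIN", "LFINGER": "LFIN",
    "STRN": "CLAV",
}

_UNIT_SCALE = {"mm": 1.0, "cm": 10.0, "m": 1000.0}

_SIDE_RE = re.compile(r"(non_paralyzed|nonparalyzed|paralyzed)")


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(trial: TrialRecording, path) -> Path:
    """Write one trial as a TRC file (tab-delimited, mm)."""
    path = Path(path)
    names = list(trial.markers)
    n = trial.n_frames
    fs = trial.sampling_rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{fs:.2f}\t{fs:.2f}\t{n}\t{len(names)}\tmm\t{fs:.2f}\t1\t{n}\n")
        header = ["Frame#", "Time"]
        for name in names:
            header += [name, "", ""]
        fh.write("\t".join(header) + "\n")
        sub = ["", ""]
        for i in range(1, len(names) + 1):
            sub += [f"X{i}", f"Y{i}", f"Z{i}"]
        fh.write("\t".join(sub) + "\n\n")
        data = np.hstack([trial.markers[name] for name in names])
        for i in range(n):
            row = [str(i + 1), f"{i / fs:.5f}"]
            row += [f"{v:.6f}" for v in data[i]]
            fh.write("\t".join(row) + "\n")
    return path


def _parse_trc(path, aliases: dict[str, str]) -> tuple[dict, float]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise TrialParseError(path, None, "truncated TRC file")
    if not lines[0].startswith("PathFileType"):
        raise TrialParseError(path, 1, "missing PathFileType header")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    if len(vals) < len(keys):
        raise TrialParseError(path, 3, "malformed TRC header value row")
    header = dict(zip(keys, vals))
    try:
        fs = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
    except (KeyError, ValueError) as exc:
        raise TrialParseError(path, 3, f"bad TRC header field: {exc}")
    units = header.get("Units", "mm")
    if units not in _UNIT_SCALE:
        raise TrialParseError(path, 3, f"unknown units {units!r}")
    scale = _UNIT_SCALE[units]

    marker_row = lines[3].split("\t")
    names = [aliases.get(m.upper(), m) for m in marker_row[2:] if m.strip()]
    if len(names) != n_markers:
        raise TrialParseError(path, 4,
                              f"header declares {n_markers} markers, "
                              f"found {len(names)} names")
    data = []
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 + 3 * n_markers:
            raise TrialParseError(path, lineno,
                                  f"expected {2 + 3 * n_markers} columns, "
                                  f"got {len(parts)}")
        try:
            data.append([float(v) for v in parts[2:]])
        except ValueError as exc:
            raise TrialParseError(path, lineno, f"non-numeric value: {exc}")
    arr = np.asarray(data, dtype=float) * scale
    if arr.shape[0] != n_frames:
        raise TrialParseError(path, None,
                              f"header declares {n_frames} frames, "
                              f"file contains {arr.shape[0]}")
    markers = {name: arr[:, 3 * i:3 * i + 3] for i, name in enumerate(names)}
    return markers, fs


def _labels_from_name(path) -> tuple[str, str, str]:
    stem = Path(path).stem
    m = _SIDE_RE.search(stem)
    side = PARALYZED
    if m:
        side = NON_PARALYZED if m.group(1) != "paralyzed" else PARALYZED
    participant = stem.split("_")[0] if "_" in stem else stem
    return participant, side, stem


def read_trc(path, aliases: dict[str, str] | None = None,
             covariates: pd.DataFrame | None = None) -> TrialRecording:
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    markers, fs = _parse_trc(path, aliases)
    participant, side, trial_id = _labels_from_name(path)
    limb = "R" if "RFIN" in markers else "L"
    meta = _lookup_covariates(covariates, participant)
    return TrialRecording(participant_id=participant, side=side,
                          markers=markers, sampling_rate=fs, limb=limb,
                          trial_id=trial_id, metadata=meta)


# ---------------------------------------------------------------------------
# long CSV
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["trial_id", "participant_id", "side", "limb",
                "frame", "marker", "x", "y", "z"]


def write_long_csv(trials, path) -> Path:
    """Write trials in long format: one row per (trial, frame, marker)."""
    path = Path(path)
    chunks = []
    for trial in trials:
        for name, xyz in trial.markers.items():
            chunks.append(pd.DataFrame({
                "trial_id": trial.trial_id,
                "participant_id": trial.participant_id,
                "side": trial.side,
                "limb": trial.limb,
                "frame": np.arange(xyz.shape[0]),
                "marker": name,
                "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
            }))
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)
    return path


def read_long_csv(path, sampling_rate: float = 100.0,
                  aliases: dict[str, str] | None = None,
                  covariates: pd.DataFrame | None = None) -> list[TrialRecording]:
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TrialParseError(path, None, f"unreadable CSV: {exc}")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(path, 1, f"missing columns {missing}")
    df["marker"] = df["marker"].map(lambda m: aliases.get(str(m).upper(), m))

    trials = []
    for trial_id, g in df.groupby("trial_id", sort=True):
        markers = {}
        n_frames = None
        for marker, mg in g.groupby("marker", sort=True):
            mg = mg.sort_values("frame")
            xyz = mg[["x", "y", "z"]].to_numpy(dtype=float)
            if n_frames is None:
                n_frames = xyz.shape[0]
            elif xyz.shape[0] != n_frames:
                raise TrialParseError(
                    path, None,
                    f"trial {trial_id!r}: marker {marker!r} has "
                    f"{xyz.shape[0]} frames, expected {n_frames}")
            markers[marker] = xyz
        first = g.iloc[0]
        meta = _lookup_covariates(covariates, str(first["participant_id"]))
        trials.append(TrialRecording(
            participant_id=str(first["participant_id"]),
            side=str(first["side"]),
            markers=markers,
            sampling_rate=sampling_rate,
            limb=str(first["limb"]),
            trial_id=str(trial_id),
            metadata=meta))
    return trials


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def write_covariates_csv(trials, path) -> Path:
    """Per-participant covariate table distilled from trial metadata."""
    rows = {}
    for t in trials:
        rows.setdefault(t.participant_id, {"participant_id": t.participant_id,
                                           **t.metadata})
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["participant_id"]))
    df.to_csv(path, index=False)
    return Path(path)


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise TrialParseError(path, 1, "covariate table needs participant_id")
    return df


def _lookup_covariates(covariates: pd.DataFrame | None, participant: str) -> dict:
    if covariates is None:
        return {}
    hit = covariates[covariates["participant_id"].astype(str) == participant]
    if hit.empty:
        return {}
    row = hit.iloc[0].to_dict()
    row.pop("participant_id", None)
    return row


# ---------------------------------------------------------------------------
# batch ingest
# ---------------------------------------------------------------------------

def read_trial_files(paths, covariates: pd.DataFrame | None = None,
                     aliases: dict[str, str] | None = None,
                     sampling_rate: float = 100.0) -> list[TrialRecording]:
    """Read a batch of TRC / long-CSV files into validated recordings.

    All trials in one batch must share a sampling rate; marker checks are
    deferred to the extraction stage so that passthrough markers survive.
    """
    trials: list[TrialRecording] = []
    for p in map(Path, paths):
        if p.suffix.lower() == ".trc":
            trials.append(read_trc(p, aliases=aliases, covariates=covariates))
        elif p.suffix.lower() == ".csv":
            trials.extend(read_long_csv(p, sampling_rate=sampling_rate,
                                        aliases=aliases, covariates=covariates))
        else:
            raise TrialParseError(p, None, f"unsupported extension {p.suffix!r}")
    rates = {t.sampling_rate for t in trials}
    if len(rates) > 1:
        raise RateMismatchError(
            f"mixed sampling rates in one batch: {sorted(rates)}")
    return trials
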