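"""Reading and writing records, cycles, ground truth and annotations.

Plain-text formats only: records as two-column CSV (``time_s,amplitude``) or
a single amplitude column with an explicit sampling rate; detected cycles as
CSV plus a JSON mirror carrying provenance; expert annotations as CSV with
``onset_s,offset_s`` columns.  EDF and WFDB are recognized format names but
require readers (pyedflib / wfdb) that are not available in this
environment, so they raise an informative error.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .detect import CycleInterval
from .evaluate import AnnotationSet
from .preprocess import Record
from .synth import GroundTruth

__all__ = [
    "read_record",
    "write_record",
    "write_cycles",
    "read_cycles",
    "write_ground_truth",
    "read_annotations",
]


def read_record(path, format: str = "csv", fs: Optional[float] = None,
                label: str = "EMGdi", units: str = "uV") -> Record:
    """Load a single-channel record.

    CSV dialects: a header ``time_s,amplitude`` (sampling rate inferred from
    the median time step) or a single ``amplitude`` column with ``fs`` given
    explicitly.
    """
    if format in ("edf", "wfdb"):
        raise ValueError(
            f"{format.upper()} support requires the "
            f"{'pyedflib' if format == 'edf' else 'wfdb'} package, which is "
            "not installed in this environment; convert to CSV instead")
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    if "time_s" in cols and "amplitude" in cols:
        t = df["time_s"].to_numpy(dtype=float)
        x = df["amplitude"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("need at least two samples to infer the rate")
        dt = float(np.median(np.diff(t)))
        if dt <= 0:
            raise ValueError("time_s column must be increasing")
        return Record(x, 1.0 / dt, label, units)
    if "amplitude" in cols and len(cols) == 1:
        if fs is None:
            raise ValueError(
                "single-column CSV needs an explicit sampling rate (fs)")
        return Record(df["amplitude"].to_numpy(dtype=float), fs, label, units)
    raise ValueError(
        f"malformed header {list(df.columns)!r}: expected 'time_s,amplitude' "
        "or a single 'amplitude' column")


def write_record(record: Record, path) -> None:
    df = pd.DataFrame({"time_s": record.times(), "amplitude": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def _fmt(v) -> str:
    return "" if v is None else f"{v:.9g}"


def write_cycles(cycles: Sequence[CycleInterval], path,
                 provenance: Optional[dict] = None) -> None:
    """Write detected cycles to CSV with a JSON mirror (same stem, ``.json``).

    The JSON mirror repeats the rows and adds ``provenance`` (method tags,
    seed, package version, ...) so a result file is self-describing.
    """
    path = Path(path)
    rows = []
    for k, c in enumerate(cycles):
        rows.append({
            "cycle_index": k,
            "marker_s": _fmt(c.marker),
            "onset_s": _fmt(c.onset),
            "offset_s": _fmt(c.offset),
            "onset_corrected_s": _fmt(c.onset_corrected),
            "offset_corrected_s": _fmt(c.offset_corrected),
            "flags": ";".join(sorted(c.flags)),
        })
    cols = ["cycle_index", "marker_s", "onset_s", "offset_s",
            "onset_corrected_s", "offset_corrected_s", "flags"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    meta = dict(provenance or {})
    meta.setdefault("version", __version__)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"provenance": meta, "cycles": rows}, fh, indent=1,
                  sort_keys=True)
        fh.write("\n")


def _parse_time(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_cycles(path) -> list[CycleInterval]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        flags = row.get("flags")
        flags = set() if (not isinstance(flags, str) or not flags) else set(
            flags.split(";"))
        out.append(CycleInterval(
            marker=float(row["marker_s"]),
            onset=_parse_time(row.get("onset_s")),
            offset=_parse_time(row.get("offset_s")),
            onset_corrected=_parse_time(row.get("onset_corrected_s")),
            offset_corrected=_parse_time(row.get("offset_corrected_s")),
            flags=flags))
    return out


def write_ground_truth(truth: GroundTruth, csv_path,
                       json_path=None) -> None:
    df = pd.DataFrame({
        "cycle_index": np.arange(truth.n_cycles),
        "onset_s": truth.onsets,
        "offset_s": truth.offsets,
    })
    df.to_csv(csv_path, index=False, float_format="%.9g")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({
                "onsets_s": truth.onsets.tolist(),
                "offsets_s": truth.offsets.tolist(),
                "cycle_markers_s": truth.cycle_markers.tolist(),
            }, fh, indent=1)
            fh.write("\n")


def read_annotations(path, scorer_id: str) -> AnnotationSet:
    """Read one scorer's onset-offset intervals from CSV."""
    df = pd.read_csv(path)
    if not {"onset_s", "offset_s"} <= set(df.columns):
        raise ValueError(
            f"annotation file {path} needs 'onset_s' and 'offset_s' columns")
    ivs = sorted(zip(df["onset_s"].astype(float), df["offset_s"].astype(float)))
    return AnnotationSet(scorer_id=scorer_id, intervals=ivs)
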