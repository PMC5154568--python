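"""File I/O: cohort CSV round-trip, MBR series text files, ROI JSON, stacks.

Interchange formats are deliberately plain: the cohort table is a UTF-8 CSV
with a fixed header, an MBR series is two-column delimited text with the
frame rate in a header comment, an ROI is a small JSON object, and a flow-map
stack is a ``.npy`` array with a JSON sidecar for acquisition metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .onh import EllipseRoi
from .synthetic import COHORT_COLUMNS, FlowMapStack
from .waveform import MbrSeries

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_mbr_series",
    "write_mbr_series",
    "read_roi_json",
    "write_roi_json",
    "read_stack",
    "write_stack",
    "load_s1_table",
]


class SchemaError(ValueError):
    """A table does not match the cohort schema."""


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with the canonical column order."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")
    cohort[COHORT_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises :class:`SchemaError` on problems."""
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: no rows") from None
    if df.empty:
        raise SchemaError(f"{path}: no rows")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad = df[~df["condition"].isin(["undilated", "dilated"])]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"{path}: invalid condition at line(s) {lines}")
    df["scan_success"] = df["scan_success"].astype(bool)
    return df[COHORT_COLUMNS]


def write_mbr_series(series: MbrSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# frame_rate={series.frame_rate}\n")
        fh.write(f"# region_label={series.region_label}\n")
        fh.write("frame_index\tmbr_au\n")
        for i, v in enumerate(series.values):
            fh.write(f"{i}\t{v:.6f}\n")


def read_mbr_series(path: str | Path, scan_id: str = "") -> MbrSeries:
    """Read a two-column (frame_index, mbr_au) text file.

    The frame rate comes from a ``# frame_rate=...`` header comment and
    defaults to 30 frames/s when absent.
    """
    path = Path(path)
    frame_rate = 30.0
    region = "all"
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key.strip() == "frame_rate":
                    frame_rate = float(val)
                elif key.strip() == "region_label":
                    region = val.strip()
                continue
            parts = line.replace(",", "\t").split()
            if parts[0] == "frame_index":
                continue
            try:
                values.append(float(parts[-1]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from None
    if len(values) < 2:
        raise ValueError(f"{path}: no usable samples")
    return MbrSeries(values=np.asarray(values), frame_rate=frame_rate,
                     scan_id=scan_id or path.stem, region_label=region)


def write_roi_json(roi: EllipseRoi, path: str | Path) -> None:
    Path(path).write_text(json.dumps(roi.to_dict(), indent=2), encoding="utf-8")


def read_roi_json(path: str | Path) -> EllipseRoi:
    return EllipseRoi.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def write_stack(stack: FlowMapStack, path: str | Path) -> None:
    """Save frames as ``.npy`` plus a ``.json`` sidecar with acquisition metadata."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), stack.frames)
    sidecar = {"frame_rate": stack.frame_rate, "exposure": stack.exposure}
    path.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def read_stack(path: str | Path) -> FlowMapStack:
    path = Path(path)
    frames = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    return FlowMapStack(frames=frames, frame_rate=meta.get("frame_rate", 30.0),
                        exposure=meta.get("exposure", 1.0 / 500.0))


def load_s1_table(path: str | Path) -> pd.DataFrame:
    """Load a deposited raw-data workbook (or CSV) into the cohort schema.

    Expects one row per (subject, condition, repeat) with the cohort columns;
    column names are matched case-insensitively and common aliases
    (``gender`` → ``sex``, ``success`` → ``scan_success``) are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: deposited raw-data table not found; place the study's "
            "supplementary workbook there to run the external-data analyses")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    aliases = {"gender": "sex", "success": "scan_success", "heart_rate": "hr"}
    rename = {}
    lower_to_canon = {c.lower(): c for c in COHORT_COLUMNS}
    for col in df.columns:
        key = col.strip().lower()
        key = aliases.get(key, key)
        if key in lower_to_canon:
            rename[col] = lower_to_canon[key]
    df = df.rename(columns=rename)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df[COHORT_COLUMNS]
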