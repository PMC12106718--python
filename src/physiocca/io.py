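"""Plain-text readers and writers for every artifact the pipeline exchanges.

Conventions: tab-separated matrices with a ``# key=value`` comment header
where metadata is needed (TR for BOLD runs, sampling rate for physio
traces); behavior/family/atlas tables as TSV with a header row; ground
truth and reports as JSON.  All numeric output is written at full
precision so that write -> read round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .physio import PhysioTrace
from .topography import RunSeries


def _read_header_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = float(v)
    return meta


def write_run_tsv(path, run: RunSeries) -> None:
    """ROI rows x frame columns, ``# tr_s=`` header, roi id as first column."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tr_s={run.tr_s!r}\n")
        for rid, row in zip(run.roi_ids, run.bold):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_run_tsv(path) -> RunSeries:
    path = Path(path)
    meta = _read_header_meta(path)
    if "tr_s" not in meta:
        raise InvalidArgumentError(f"{path}: missing '# tr_s=' header")
    roi_ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if "," in line and "\t" not in line:
                raise InvalidArgumentError(
                    f"{path}: comma-delimited data in a .tsv file")
            parts = line.rstrip("\n").split("\t")
            roi_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    bold = np.asarray(rows)
    if not np.isfinite(bold).all():
        raise InvalidArgumentError(f"{path}: NaN/inf in BOLD matrix")
    return RunSeries(bold, tr_s=meta["tr_s"], roi_ids=roi_ids)


def write_physio_txt(path, trace: PhysioTrace) -> None:
    """One sample per line, with a ``# fs=`` and ``# kind=`` header."""
    with open(path, "w") as fh:
        fh.write(f"# fs={trace.fs!r}\n# kind={trace.kind}\n")
        fh.write("\n".join(repr(float(v)) for v in trace.samples) + "\n")


def read_physio_txt(path, kind: str | None = None) -> PhysioTrace:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            data_start = i + 1
        else:
            break
    if "fs" not in meta:
        raise InvalidArgumentError(f"{path}: missing '# fs=' header")
    samples = np.array([float(x) for x in lines[data_start:] if x.strip()])
    return PhysioTrace(samples, fs=float(meta["fs"]),
                       kind=kind or meta.get("kind", "respiratory"))


def write_matrix_tsv(path, df: pd.DataFrame) -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def read_matrix_tsv(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "," in first and "\t" not in first:
        raise InvalidArgumentError(f"{path}: comma-delimited data in a .tsv file")
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_table_tsv(path, df: pd.DataFrame) -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_table_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_truth_json(path, truth) -> None:
    def enc(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v
    from dataclasses import asdict
    Path(path).write_text(json.dumps(asdict(truth), default=enc, indent=1))


def load_dataset(run_paths: dict[str, list], behavior_path, family_path,
                 atlas_path) -> dict:
    """Load and cross-validate a cohort written to disk.

    ``run_paths`` maps participant id to a list of run TSV files.  Raises
    a named validation error for roster mismatches, NaN in BOLD, or
    malformed delimiters.
    """
    runs = {pid: [read_run_tsv(p) for p in paths] for pid, paths in run_paths.items()}
    behavior = read_matrix_tsv(behavior_path)
    family = read_table_tsv(family_path, required=("participant", "family_id"))
    atlas = read_table_tsv(atlas_path, required=("roi", "network"))
    roster = set(map(str, runs))
    extra = set(map(str, behavior.index)) - roster
    if extra:
        raise InvalidArgumentError(
            f"behavior table has unknown participants: {sorted(extra)[:5]}")
    missing_fam = roster - set(map(str, family["participant"]))
    if missing_fam:
        raise InvalidArgumentError(
            f"participants without family assignment: {sorted(missing_fam)[:5]}")
    n_roi = {r.n_roi for rr in runs.values() for r in rr}
    if len(n_roi) != 1:
        raise InvalidArgumentError(f"inconsistent ROI counts across runs: {n_roi}")
    if len(atlas) != n_roi.pop():
        raise InvalidArgumentError("atlas does not match the runs' ROI count")
    return {"runs": runs, "behavior": behavior, "family": family, "atlas": atlas}
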