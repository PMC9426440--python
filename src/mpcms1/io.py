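"""Reading feature tables and design files; writing pipeline outputs.

Two input dialects are supported for intensity tables:

``wide``
    Header row of sample ids; first column ``feature_id`` and optional
    ``rt`` / ``mz`` columns; one row per MS1 feature.

``openms_consensus``
    The consensus CSV written by OpenMS TextExporter after feature
    linking: ``#``-prefixed header lines declare the column layout
    (``#CONSENSUS`` block), ``MAP`` lines name the constituent maps, and
    ``CONSENSUS`` rows carry one rt/mz/intensity triple per map.  Both
    comma and tab separation occur across OpenMS versions and both are
    accepted.

Zero and empty intensity cells are both treated as absent on input: the
upstream linker emits 0 for maps where a feature was not matched.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .types import DesignTable, IntensityMatrix

logger = logging.getLogger(__name__)


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_feature_table(path: str | Path, dialect: str = "wide") -> IntensityMatrix:
    """Read an aligned feature-intensity table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"wide"`` or ``"openms_consensus"`` (see module docstring).

    Returns
    -------
    IntensityMatrix with absent measurements (empty or zero cells) as NaN,
    feature order preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide":
        return _read_wide(path)
    if dialect == "openms_consensus":
        return _read_openms_consensus(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _parse_cell(raw: str, row: int, col: str) -> float:
    raw = raw.strip()
    if raw == "" or raw.lower() in {"na", "nan"}:
        return np.nan
    try:
        value = float(raw)
    except ValueError as exc:
        raise ValueError(
            f"unparseable numeric cell at row {row}, column {col!r}: {raw!r}"
        ) from exc
    if value == 0.0:
        return np.nan
    if value < 0:
        raise ValueError(f"negative intensity at row {row}, column {col!r}: {raw!r}")
    return value


def _read_wide(path: Path) -> IntensityMatrix:
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"empty feature table: {path}")
        sep = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=sep))
        rows = list(csv.reader(fh, delimiter=sep))
    header = [h.strip() for h in header]
    if header[0] != "feature_id":
        raise ValueError("wide table must start with a 'feature_id' column")
    annot_cols = [c for c in header[1:] if c in ("rt", "mz")]
    sample_ids = header[1 + len(annot_cols):]
    if not sample_ids:
        raise ValueError("wide table has no sample columns")

    feature_ids: list[str] = []
    rt: list[float] = []
    mz: list[float] = []
    values: list[list[float]] = []
    for i, row in enumerate(rows):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise ValueError(f"row {i + 2} has {len(row)} cells, expected {len(header)}")
        feature_ids.append(row[0].strip())
        offset = 1
        for c in annot_cols:
            cell = row[offset].strip()
            (rt if c == "rt" else mz).append(float(cell) if cell else np.nan)
            offset += 1
        values.append(
            [_parse_cell(cell, i + 2, sample_ids[j]) for j, cell in enumerate(row[offset:])]
        )
    return IntensityMatrix(
        values=np.array(values, dtype=float) if values else np.empty((0, len(sample_ids))),
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        rt=np.array(rt) if "rt" in annot_cols else None,
        mz=np.array(mz) if "mz" in annot_cols else None,
    )


def _read_openms_consensus(path: Path) -> IntensityMatrix:
    consensus_header: list[str] | None = None
    map_names: dict[int, str] = {}
    data_rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            sep = _sniff_delimiter(line)
            cells = next(csv.reader([line], delimiter=sep))
            tag = cells[0].strip()
            if tag.startswith("#"):
                if tag.lstrip("#").strip().upper() == "CONSENSUS":
                    consensus_header = [c.strip() for c in cells]
                continue
            if tag.upper() == "MAP":
                # MAP <index> <filename> [...]
                idx = int(float(cells[1]))
                name = Path(cells[2]).stem if len(cells) > 2 and cells[2] else f"map_{idx}"
                map_names[idx] = name
                continue
            if tag.upper() == "CONSENSUS":
                data_rows.append(cells)
    if consensus_header is None:
        raise ValueError("no #CONSENSUS header block found; not a TextExporter consensus file")

    # per-map intensity columns are matched by their numeric suffix
    intensity_cols: list[tuple[int, int]] = []  # (column position, map index)
    rt_col = mz_col = None
    for pos, name in enumerate(consensus_header):
        low = name.lower().lstrip("#").strip()
        if low in ("rt_cf", "rt"):
            rt_col = pos
        elif low in ("mz_cf", "mz"):
            mz_col = pos
        elif low.startswith("intensity_") and low != "intensity_cf":
            suffix = low.split("_", 1)[1]
            if suffix.isdigit():
                intensity_cols.append((pos, int(suffix)))
    if not intensity_cols:
        raise ValueError("consensus header declares no per-map intensity columns")
    intensity_cols.sort(key=lambda t: t[1])
    sample_ids = [map_names.get(m, f"map_{m}") for _, m in intensity_cols]

    feature_ids, rt, mz, values = [], [], [], []
    for i, row in enumerate(data_rows):
        feature_ids.append(f"cons_{i:06d}")
        rt.append(float(row[rt_col]) if rt_col is not None and row[rt_col].strip() else np.nan)
        mz.append(float(row[mz_col]) if mz_col is not None and row[mz_col].strip() else np.nan)
        values.append([_parse_cell(row[pos], i + 1, consensus_header[pos]) for pos, _ in intensity_cols])
    return IntensityMatrix(
        values=np.array(values, dtype=float) if values else np.empty((0, len(sample_ids))),
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        rt=np.array(rt),
        mz=np.array(mz),
    )


def write_matrix(matrix: IntensityMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write an IntensityMatrix as a wide table (round-trips with ``read_feature_table``)."""
    path = Path(path)
    cols = ["feature_id"]
    data: dict[str, Any] = {"feature_id": matrix.feature_ids}
    if matrix.rt is not None:
        cols.append("rt")
        data["rt"] = matrix.rt
    if matrix.mz is not None:
        cols.append("mz")
        data["mz"] = matrix.mz
    df = pd.DataFrame(data, columns=cols)
    vals = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
    df = pd.concat([df, vals], axis=1)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_design(path: str | Path) -> DesignTable:
    """Read a delimited design file with ``sample_id`` and ``condition`` columns.

    Additional columns are kept as covariates.  Condition levels are ordered
    by first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty design file: {path}")
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"empty design file: {path}")
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ValueError(f"design file missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample ids in design: {dups}")
    if df["condition"].isna().any() or (df["condition"].str.strip() == "").any():
        bad = df.loc[
            df["condition"].isna() | (df["condition"].str.strip() == ""), "sample_id"
        ].tolist()
        raise ValueError(f"samples missing a condition: {bad}")
    covar_cols = [c for c in df.columns if c not in ("sample_id", "condition")]
    return DesignTable(
        sample_ids=df["sample_id"].tolist(),
        condition=df["condition"].str.strip().tolist(),
        covariates=df[covar_cols].reset_index(drop=True) if covar_cols else None,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(results: dict[str, Any], out_dir: str | Path) -> dict[str, str]:
    """Write every available pipeline output and return a {file: sha256} manifest.

    Recognized keys in ``results``: ``normalized`` (IntensityMatrix),
    ``modules`` / ``eigenfeatures`` / ``correlation`` / ``flat_labels``
    (DataFrames), ``tree`` (ConditionTree), ``report`` (JSON-serializable
    dict).  A partial write is cleaned up before the error propagates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, str] = {}
    try:
        if "normalized" in results:
            p = out_dir / "normalized_matrix.tsv"
            written.append(p)
            write_matrix(results["normalized"], p)
        for key, fname in (
            ("modules", "feature_modules.tsv"),
            ("eigenfeatures", "eigenfeatures.tsv"),
            ("correlation", "module_condition_correlation.tsv"),
            ("flat_labels", "condition_flat_labels.tsv"),
        ):
            if key in results:
                p = out_dir / fname
                written.append(p)
                results[key].to_csv(p, sep="\t", index=False, float_format="%.17g")
        if "tree" in results:
            p = out_dir / "condition_tree.nwk"
            written.append(p)
            p.write_text(results["tree"].to_newick() + "\n")
        for p in written:
            manifest[p.name] = _sha256(p)
        if "report" in results:
            report = dict(results["report"])
            report["manifest"] = manifest
            p = out_dir / "run_report.json"
            written.append(p)
            p.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return manifest
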