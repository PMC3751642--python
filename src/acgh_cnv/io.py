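"""Readers and writers for the package's tabular formats.

Conventions:

* all TSV catalogs use 1-based inclusive coordinates;
* BED exports use the standard 0-based half-open columns (start - 1, end);
* profile matrices are probe rows x sample columns, preceded by
  ``probe_id  chrom  start  end``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CnvCall, UniqueCnv
from .genome import GenomeSpec, ProbeMap
from .population import RegionClassification
from .profiles import ArrayProfile
from .regions import CatalogStats, CnvRegion
from .simulate import TruthCnv

__all__ = [
    "write_profiles",
    "read_profiles",
    "write_line_map",
    "read_line_map",
    "write_truth",
    "read_truth",
    "write_calls_bed",
    "write_cnv_table",
    "read_cnv_table",
    "write_cnvr_table",
    "write_cnvr_bed",
    "write_classifications",
    "write_stats",
    "read_external_intervals",
]

_FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# profiles


def write_profiles(path: str | Path, probe_map: ProbeMap, profiles: list[ArrayProfile]) -> None:
    """Tab-delimited probe/log2 matrix: probe coordinates then one column
    per sample.  Values are written to 6 decimals (lossless round-trip at
    that precision)."""
    df = pd.DataFrame(
        {
            "probe_id": probe_map.probe_ids,
            "chrom": probe_map.chroms,
            "start": probe_map.starts,
            "end": probe_map.ends,
        }
    )
    for p in profiles:
        if len(p) != probe_map.n_probes:
            raise ValueError(f"profile {p.sample_id!r} length mismatch with probe map")
        df[p.sample_id] = p.values
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_profiles(
    path: str | Path,
    line_map: dict[str, str] | None = None,
    genome: GenomeSpec | None = None,
    spacing_bp: int = 4000,
) -> tuple[ProbeMap, list[ArrayProfile]]:
    """Read a profile matrix; validates probe ordering, ids and numerics.

    Sample columns become profiles; line identity is looked up in
    ``line_map`` when given (otherwise left empty).
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={"chrom": str})
    required = ["probe_id", "chrom", "start", "end"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"profile file must start with columns {required}")
    if df["probe_id"].duplicated().any():
        row = int(df.index[df["probe_id"].duplicated()][0]) + 2
        raise ValueError(f"duplicated probe id at row {row}")
    for chrom, group in df.groupby("chrom", sort=False):
        starts = group["start"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            row = int(group.index[np.argmax(np.diff(starts) <= 0) + 1]) + 2
            raise ValueError(f"probes unsorted on chromosome {chrom} near row {row}")
    sample_cols = [c for c in df.columns[4:]]
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = numeric
    probe_map = ProbeMap(
        probe_ids=df["probe_id"].to_numpy(dtype=object),
        chroms=df["chrom"].to_numpy(dtype=object),
        starts=df["start"].to_numpy(dtype=np.int64),
        ends=df["end"].to_numpy(dtype=np.int64),
        spacing_bp=spacing_bp,
        genome=genome,
    )
    profiles = [
        ArrayProfile(
            sample_id=col,
            line_id=(line_map or {}).get(col, ""),
            values=df[col].to_numpy(dtype=float),
        )
        for col in sample_cols
    ]
    return probe_map, profiles


def write_line_map(path: str | Path, profiles: list[ArrayProfile]) -> None:
    rows = [(p.sample_id, p.line_id, p.sex) for p in profiles]
    pd.DataFrame(rows, columns=["sample_id", "line_id", "sex"]).to_csv(path, sep="\t", index=False)


def read_line_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if not {"sample_id", "line_id"} <= set(df.columns):
        raise ValueError("line map needs sample_id and line_id columns")
    return dict(zip(df["sample_id"], df["line_id"]))


# ---------------------------------------------------------------------------
# truth CNVs


def write_truth(path: str | Path, truth: list[TruthCnv]) -> None:
    """BED-like TSV with a copy_number column (1-based inclusive coords)."""
    pd.DataFrame(
        [(t.sample_id, t.chrom, t.start, t.end, t.copy_number) for t in truth],
        columns=["sample_id", "chrom", "start", "end", "copy_number"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthCnv]:
    df = pd.read_csv(Path(path), sep="\t", dtype={"chrom": str})
    return [
        TruthCnv(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            copy_number=int(r.copy_number),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# calls and unique CNVs


def write_calls_bed(path: str | Path, calls: list[CnvCall]) -> None:
    """Per-sample calls as BED: 0-based half-open, score = mean log2."""
    with open(path, "w") as fh:
        for c in calls:
            name = f"{c.sample_id}|{c.cnv_class}|{c.n_probes}p"
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{name}\t{c.mean_log2:.4f}\t.\n")


def write_cnv_table(path: str | Path, cnvs: list[UniqueCnv], line_ids: list[str]) -> None:
    """Unique-CNV catalog: id, region placeholder, coordinates, class,
    overall occurrence, then one occurrence column per line."""
    rows = []
    for c in cnvs:
        row = {
            "cnv_id": c.cnv_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "cnv_class": c.cnv_class,
            "occurrence": c.occurrence_total,
            "carrier_samples": ",".join(c.carrier_samples),
        }
        for line in line_ids:
            row[f"line:{line}"] = c.occurrence_per_line.get(line, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_AF1_SYNONYMS = {
    "cnv_id": ("cnv_id", "cnv", "cnv number", "cnv_number"),
    "cnvr_id": ("cnvr_id", "cnvr", "cnvr number", "cnvr_number"),
    "chrom": ("chrom", "chr", "chromosome"),
    "start": ("start", "start position", "start_position"),
    "end": ("end", "end position", "end_position"),
    "occurrence": ("occurrence", "occurrence_total", "overall occurrence", "frequency"),
}


def read_cnv_table(
    path: str | Path,
    dialect: str = "internal",
    line_ids: list[str] | None = None,
) -> list[UniqueCnv]:
    """Read a unique-CNV catalog.

    ``internal``: the exact format of :func:`write_cnv_table`.
    ``additional_file_1``: a published-catalog dialect — CNV number, CNVR
    number, coordinates, overall occurrence, then per-line occurrence
    columns; header matching is case-insensitive with synonyms and extra
    columns (e.g. literature-review annotations) are tolerated.  Class is
    taken from a ``cnv_class``/``class``/``type`` column when present,
    otherwise inferred as loss (the catalog majority) — callers needing
    classes should provide the column.
    """
    if dialect not in ("internal", "additional_file_1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(Path(path), sep="\t")
    cols = {str(c).strip().lower(): c for c in df.columns}

    def find(key: str, required: bool = True) -> str | None:
        for syn in _AF1_SYNONYMS.get(key, (key,)):
            if syn in cols:
                return cols[syn]
        if required:
            raise ValueError(f"catalog file lacks a {key!r} column")
        return None

    class_col = next((cols[k] for k in ("cnv_class", "class", "type") if k in cols), None)
    line_cols: dict[str, str] = {}
    if dialect == "internal":
        line_cols = {c[len("line:"):]: c for c in df.columns if str(c).startswith("line:")}
    else:
        known = {find("cnv_id"), find("cnvr_id", required=False), find("chrom"), find("start"),
                 find("end"), find("occurrence"), class_col}
        if line_ids is None:
            raise ValueError("additional_file_1 dialect requires the cohort's line ids")
        lowered = {l.lower(): l for l in line_ids}
        for c in df.columns:
            if c in known:
                continue
            if str(c).strip().lower() in lowered:
                line_cols[lowered[str(c).strip().lower()]] = c
        unknown = set(line_ids) - set(line_cols)
        if unknown:
            raise ValueError(f"line columns not found in catalog: {sorted(unknown)}")
    out: list[UniqueCnv] = []
    for i, r in df.iterrows():
        occurrence = int(r[find("occurrence")])
        if occurrence < 1:
            raise ValueError(f"row {int(i) + 2}: occurrence must be >= 1")
        per_line = {line: int(r[col]) for line, col in line_cols.items() if int(r[col]) > 0}
        if not per_line:
            per_line = {"unknown": occurrence}
        if sum(per_line.values()) != occurrence:
            raise ValueError(f"row {int(i) + 2}: per-line occurrences do not sum to total")
        carriers = []
        if "carrier_samples" in cols and isinstance(r[cols["carrier_samples"]], str):
            carriers = r[cols["carrier_samples"]].split(",")
        out.append(
            UniqueCnv(
                cnv_id=str(r[find("cnv_id")]),
                chrom=str(r[find("chrom")]),
                start=int(r[find("start")]),
                end=int(r[find("end")]),
                cnv_class=str(r[class_col]) if class_col else "loss",
                occurrence_total=occurrence,
                occurrence_per_line=per_line,
                carrier_samples=carriers,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CNVRs, classifications, stats


def write_cnvr_table(path: str | Path, regions: list[CnvRegion], line_ids: list[str]) -> None:
    rows = []
    for r in regions:
        row = {
            "cnvr_id": r.cnvr_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "type": r.region_type,
            "n_members": len(r.member_cnvs),
            "occurrence": r.occurrence_total,
            "members": ",".join(r.member_cnvs),
        }
        for line in line_ids:
            row[f"line:{line}"] = r.occurrence_per_line.get(line, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cnvr_bed(path: str | Path, regions: list[CnvRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.cnvr_id}|{r.region_type}\t"
                     f"{r.occurrence_total}\t.\n")


def write_classifications(path: str | Path, classifications: list[RegionClassification]) -> None:
    rows = [
        {
            "cnvr_id": c.cnvr_id,
            "is_fixed": int(c.is_fixed),
            "fixed_lines": ",".join(sorted(c.fixed_lines)),
            "is_line_specific": int(c.is_line_specific),
            "specific_line": c.specific_line or "",
        }
        for c in classifications
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_stats(path: str | Path, stats: CatalogStats) -> None:
    payload = asdict(stats)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# external CNV sets


def read_external_intervals(path: str | Path, fmt: str = "tsv") -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) intervals; ``bed`` converts from 0-based
    half-open to the package's 1-based inclusive convention."""
    if fmt not in ("tsv", "bed"):
        raise ValueError("fmt must be 'tsv' or 'bed'")
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if ln == 1 and fmt == "tsv" and not parts[1].isdigit():
                continue  # header row
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if fmt == "bed":
                start += 1
            out.append((chrom, start, end))
    return out
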