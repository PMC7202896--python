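"""Delimited-text I/O with schema validation for every pipeline dataset.

All interchange formats are plain TSV.  Readers validate column presence and
types and fail with the offending rows named (at most 20 shown); writers
round-trip losslessly through the readers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .chem import ChemicalRecord
from .worm import WELL_COLUMNS, validate_wells

__all__ = [
    "read_worm_wells",
    "write_worm_wells",
    "read_fingerprints",
    "write_fingerprints",
    "read_speeds",
    "write_speeds",
    "read_traces",
    "write_traces",
    "read_paired",
    "read_ct",
]


def _read_tsv(path: str | Path, required: list[str], dtype=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=dtype)
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_worm_wells(path: str | Path) -> pd.DataFrame:
    """Read a well table (condition_id, replicate, count_L1L3, count_L4,
    count_adult, is_control); duplicate (condition, replicate, is_control)
    keys are rejected."""
    df = _read_tsv(path, WELL_COLUMNS)
    dup = df.duplicated(subset=["condition_id", "replicate", "is_control"])
    if dup.any():
        bad = df.loc[dup, ["condition_id", "replicate"]].head(20)
        raise ValueError(f"duplicate (condition, replicate) keys:\n{bad}")
    return validate_wells(df)


def write_worm_wells(wells: pd.DataFrame, path: str | Path) -> None:
    validate_wells(wells)[WELL_COLUMNS].to_csv(path, sep="\t", index=False)


FP_COLUMNS = ["compound_id", "library_id", "is_hit", "classes", "fingerprint"]


def read_fingerprints(path: str | Path) -> list[ChemicalRecord]:
    """Read a fingerprint TSV (compound_id, library_id, is_hit, classes,
    fingerprint bitstring; optional smiles column passed through).  Every
    fingerprint must have the same width; offenders are named."""
    df = _read_tsv(path, FP_COLUMNS, dtype={"fingerprint": str})
    widths = df["fingerprint"].str.len()
    if widths.nunique() > 1:
        expected = widths.iloc[0]
        bad = df.loc[widths != expected, "compound_id"].head(20).tolist()
        raise ValueError(f"fingerprint width differs from {expected} for compounds {bad}")
    records = []
    has_smiles = "smiles" in df.columns
    for _, row in df.iterrows():
        bits = str(row["fingerprint"])
        if set(bits) - {"0", "1"}:
            raise ValueError(f"compound {row['compound_id']}: fingerprint is not a 0/1 bitstring")
        labels = str(row["classes"]) if not pd.isna(row["classes"]) else ""
        records.append(
            ChemicalRecord(
                compound_id=str(row["compound_id"]),
                fingerprint=np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"),
                library_id=str(row["library_id"]),
                class_labels=frozenset(x for x in labels.split(";") if x),
                is_hit=bool(row["is_hit"]),
                smiles=str(row["smiles"]) if has_smiles and not pd.isna(row["smiles"]) else None,
            )
        )
    return records


def write_fingerprints(records: list[ChemicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "library_id": r.library_id,
                "is_hit": r.is_hit,
                "classes": ";".join(sorted(r.class_labels)),
                "fingerprint": "".join(map(str, r.fingerprint)),
                **({"smiles": r.smiles} if r.smiles else {}),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


SPEED_FILE_COLUMNS = ["larva_id", "assay_id", "genotype", "treatment", "speed_mm_s"]


def read_speeds(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, SPEED_FILE_COLUMNS)
    bad = df.loc[~np.isfinite(pd.to_numeric(df["speed_mm_s"], errors="coerce"))]
    if len(bad):
        raise ValueError(f"non-numeric speeds for larvae {bad['larva_id'].head(20).tolist()}")
    df["speed_mm_s"] = df["speed_mm_s"].astype(float)
    return df


def write_speeds(records: pd.DataFrame, path: str | Path) -> None:
    cols = SPEED_FILE_COLUMNS + (["speed_norm"] if "speed_norm" in records.columns else [])
    records[cols].to_csv(path, sep="\t", index=False)


def read_traces(path: str | Path) -> list[CalciumTrace]:
    """Read calcium traces: cell_id, group_id, time_s, ratio_340_380,
    caffeine_time_s (constant per cell)."""
    df = _read_tsv(path, ["cell_id", "group_id", "time_s", "ratio_340_380", "caffeine_time_s"])
    traces = []
    for (cell, group), grp in df.groupby(["cell_id", "group_id"], sort=False):
        t0 = grp["caffeine_time_s"].unique()
        if len(t0) != 1:
            raise ValueError(f"cell {cell}: inconsistent caffeine_time_s")
        grp = grp.sort_values("time_s")
        traces.append(
            CalciumTrace(
                cell_id=str(cell),
                group_id=str(group),
                time=grp["time_s"].to_numpy(float),
                ratio=grp["ratio_340_380"].to_numpy(float),
                caffeine_time=float(t0[0]),
            )
        )
    return traces


def write_traces(traces: list[CalciumTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "group_id": tr.group_id,
                    "time_s": tr.time,
                    "ratio_340_380": tr.ratio,
                    "caffeine_time_s": tr.caffeine_time,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_paired(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["cell_id", "group_id", "ca_25", "ca_37"])
    df[["ca_25", "ca_37"]] = df[["ca_25", "ca_37"]].astype(float)
    return df


def read_ct(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample_id", "condition", "gene", "ct"])
    df["ct"] = df["ct"].astype(float)
    return df
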