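"""CSV readers and writers for the pipeline's standard layouts.

Canonical input layouts (long/tidy):

* phenotypes: ``genotype, replicate, trait, value`` — wide frames
  (``genotype, replicate`` + one column per trait) are accepted and melted;
* germination: ``genotype, replicate, day, count, seeds_sown`` with
  incremental daily counts;
* seedlings: ``genotype, replicate, SL_cm, SDM_mg``.

Validation errors carry the offending file and, where possible, the row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data import PhenotypeTable

__all__ = [
    "read_phenotypes",
    "read_germination",
    "read_seedlings",
    "write_distance_matrix",
    "read_distance_matrix",
]


class ValidationError(ValueError):
    """Input file failed validation."""


def _fail(path, msg: str):
    raise ValidationError(f"{path}: {msg}")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a tidy or wide phenotype CSV into a PhenotypeTable."""
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if not {"genotype", "replicate"} <= cols:
        _fail(path, "phenotype CSV needs 'genotype' and 'replicate' columns")
    if {"trait", "value"} <= cols:
        table = frame[["genotype", "replicate", "trait", "value"]].copy()
    else:  # wide layout
        table = frame.melt(
            id_vars=["genotype", "replicate"], var_name="trait", value_name="value"
        )
    non_numeric = pd.to_numeric(table["value"], errors="coerce").isna() & table[
        "value"
    ].notna()
    if non_numeric.any():
        row = int(non_numeric.idxmax()) + 2  # header + 1-based
        _fail(path, f"non-numeric trait value near line {row}")
    table["value"] = pd.to_numeric(table["value"], errors="coerce")
    try:
        return PhenotypeTable(table)
    except ValueError as exc:
        _fail(path, str(exc))


def read_germination(path: str | Path) -> pd.DataFrame:
    """Read and validate a germination time-course CSV."""
    frame = pd.read_csv(path)
    required = ["genotype", "replicate", "day", "count", "seeds_sown"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        _fail(path, f"germination CSV missing column(s) {missing}")
    for col in ("day", "count", "seeds_sown"):
        bad = pd.to_numeric(frame[col], errors="coerce").isna()
        if bad.any():
            _fail(path, f"non-numeric {col!r} near line {int(bad.idxmax()) + 2}")
        frame[col] = pd.to_numeric(frame[col]).astype(int)
    if (frame["day"] < 1).any():
        row = int((frame["day"] < 1).idxmax()) + 2
        _fail(path, f"day < 1 near line {row}")
    if (frame["count"] < 0).any():
        row = int((frame["count"] < 0).idxmax()) + 2
        _fail(path, f"negative count near line {row}")
    totals = frame.groupby(["genotype", "replicate"]).agg(
        germinated=("count", "sum"), sown=("seeds_sown", "first")
    )
    over = totals[totals["germinated"] > totals["sown"]]
    if len(over):
        _fail(path, f"germinated > seeds sown for {list(over.index)}")
    return frame


def read_seedlings(path: str | Path) -> pd.DataFrame:
    """Read and validate a seedling measurement CSV."""
    frame = pd.read_csv(path)
    required = ["genotype", "replicate", "SL_cm", "SDM_mg"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        _fail(path, f"seedling CSV missing column(s) {missing}")
    if (frame["SL_cm"] <= 0).any():
        row = int((frame["SL_cm"] <= 0).idxmax()) + 2
        _fail(path, f"non-positive seedling length near line {row}")
    if (frame["SDM_mg"] < 0).any():
        row = int((frame["SDM_mg"] < 0).idxmax()) + 2
        _fail(path, f"negative seedling dry mass near line {row}")
    return frame


def write_distance_matrix(dist, path: str | Path) -> None:
    """Square CSV: genotype labels in header and first column."""
    dist.to_frame().to_csv(path, index_label="genotype")


def read_distance_matrix(path: str | Path):
    from .distance import DistanceMatrix

    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return DistanceMatrix.from_frame(frame)
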