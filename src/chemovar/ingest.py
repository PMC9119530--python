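"""Reading, harmonizing and quality-filtering per-lab testing tables.

Each lab ships a delimited table of per-sample compound measurements in
its own unit (% weight, ppm, or mg/g) and its own compound dialect (some
report ocimene/nerolidol isomers separately).  Harmonization converts
everything to % weight, sums isomer families, and intersects compound
panels across labs so downstream analysis sees one consistent table.

Quality filters mirror conservative plausibility rules for dried flower:

* exact duplicate rows are dropped (first occurrence kept);
* any single cannabinoid over 40 %wt, summed total cannabinoids over
  50 %wt, or both total THC and total CBD null/zero -> row removed;
* terpene data (not the row) is invalidated when the 14-terpene row
  variance is below 0.001, any single terpene exceeds 5 %wt, or more
  than 10 of the 14 panel values are zero.

Rules apply sequentially in the order listed, so per-rule counts are
disjoint and sum to the total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import panels
from .chemotype import add_totals
from .errors import PanelError, SchemaError, UnitError

# unit name -> divisor taking raw values to % weight
_UNIT_DIVISORS = {"percent": 1.0, "ppm": 10_000.0, "mg_per_g": 10.0}
_UNIT_ALIASES = {
    "percent": "percent",
    "% weight": "percent",
    "percent_weight": "percent",
    "pct": "percent",
    "ppm": "ppm",
    "mg_per_g": "mg_per_g",
    "mg/g": "mg_per_g",
}

_REQUIRED_COLUMNS = ("sample_id", "producer_id", "strain_name", "category_label")


def normalize_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[str(unit).strip().lower()]
    except KeyError:
        raise UnitError(f"unknown measurement unit: {unit!r}") from None


@dataclass
class LabBatch:
    """One lab's sample table plus the metadata needed to harmonize it.

    ``panel`` maps each measurement column to its role: "cannabinoid_acid",
    "neutral_cannabinoid" or "terpene".
    """

    lab_id: str
    unit: str
    data: pd.DataFrame
    panel: dict[str, str]
    n_coerced: int = 0  # malformed numeric cells coerced to null on read

    def measurement_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in self.panel]

    def copy(self) -> "LabBatch":
        return LabBatch(self.lab_id, self.unit, self.data.copy(), dict(self.panel), self.n_coerced)


def infer_panel(columns) -> dict[str, str]:
    """Infer compound roles from column names.

    Known acid columns map to "cannabinoid_acid", known neutral
    cannabinoids to "neutral_cannabinoid"; any other non-metadata column
    is treated as a terpene (isomer columns included).
    """
    acid_cols = set(panels.ACID_OF.values()) | {"cbdva"}
    neutral_cols = set(panels.CANNABINOIDS) | {"cbdv"}
    panel: dict[str, str] = {}
    for col in columns:
        if col in panels.METADATA_COLUMNS:
            continue
        if col in acid_cols:
            panel[col] = "cannabinoid_acid"
        elif col in neutral_cols:
            panel[col] = "neutral_cannabinoid"
        else:
            panel[col] = "terpene"
    return panel


def read_lab_table(path, lab_meta: dict) -> LabBatch:
    """Read one lab's CSV into a :class:`LabBatch`.

    ``lab_meta`` must provide ``lab_id`` and ``unit``; ``panel`` is
    optional (inferred from column names when absent).  Malformed
    numeric cells become nulls and are tallied in ``n_coerced``.
    """
    path = Path(path)
    # keep_default_na=False so malformed cells ("N/A", "nan", ...) survive
    # to the numeric coercion step and can be counted
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "producer_id": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns: {missing}")
    panel = lab_meta.get("panel") or infer_panel(df.columns)
    n_coerced = 0
    for col in panel:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_coerced += int((coerced.isna() & df[col].notna()).sum())
        df[col] = coerced
        if (coerced.dropna() < 0).any():
            raise SchemaError(f"{path.name}: negative values in column {col!r}")
    if "test_date" not in df.columns:
        df["test_date"] = pd.NaT
    return LabBatch(
        lab_id=str(lab_meta["lab_id"]),
        unit=normalize_unit(lab_meta["unit"]),
        data=df,
        panel=dict(panel),
        n_coerced=n_coerced,
    )


def convert_units(batch: LabBatch) -> LabBatch:
    """Convert all measurements to % weight (ppm /10,000; mg/g /10)."""
    unit = normalize_unit(batch.unit)
    out = batch.copy()
    divisor = _UNIT_DIVISORS[unit]
    if divisor != 1.0:
        cols = out.measurement_columns()
        out.data[cols] = out.data[cols] / divisor
    out.unit = "percent"
    return out


def sum_isomer_groups(
    batch: LabBatch, groups: dict[str, tuple[str, ...]] = panels.ISOMER_GROUPS
) -> LabBatch:
    """Replace isomer member columns by their summed group column.

    Labs already reporting a single summed column pass through
    unchanged.  A group whose members are all null in a row yields null
    (a null is distinct from a measured zero).
    """
    out = batch.copy()
    for group, members in groups.items():
        present = [m for m in members if m in out.data.columns]
        if not present:
            continue
        summed = out.data[present].sum(axis=1, min_count=1)
        if group in out.data.columns:
            # defensive: a lab reporting both a sum and isomers keeps the sum
            out.data[group] = out.data[group].fillna(summed)
        else:
            out.data[group] = summed
        out.data = out.data.drop(columns=present)
        for m in present:
            out.panel.pop(m, None)
        out.panel[group] = "terpene"
    return out


def intersect_common_panel(batches: list[LabBatch]) -> pd.DataFrame:
    """Concatenate batches keeping only compounds measured by every lab.

    All batches must already be in % weight.  Returns the harmonized
    sample table with ``lab_id`` provenance; the retained panel is
    stored in ``result.attrs["panel"]``.
    """
    if not batches:
        raise PanelError("no batches to harmonize")
    for b in batches:
        if normalize_unit(b.unit) != "percent":
            raise UnitError(f"batch {b.lab_id} not converted to % weight")
    common = set(batches[0].panel)
    for b in batches[1:]:
        common &= set(b.panel)
    if not common:
        raise PanelError("empty compound-panel intersection across labs")
    panel = {c: batches[0].panel[c] for c in common}
    meta = [c for c in panels.METADATA_COLUMNS if c != "lab_id"]
    # canonical column order: metadata, cannabinoids, terpenes
    cann = [c for c in panels.CANNABINOID_COLUMNS if c in common]
    cann += sorted(c for c in common if panel[c] != "terpene" and c not in cann)
    terp = [t for t in panels.TERPENES if t in common]
    terp += sorted(c for c in common if panel[c] == "terpene" and c not in terp)
    frames = []
    for b in batches:
        df = b.data.copy()
        df["lab_id"] = b.lab_id
        keep = [c for c in meta if c in df.columns] + ["lab_id"] + cann + terp
        frames.append(df[keep])
    table = pd.concat(frames, ignore_index=True)
    table.attrs["panel"] = panel
    return table


@dataclass
class FilterReport:
    """Per-rule audit counts from one filter pass.

    Rules are applied sequentially, so counts are disjoint; ``overlap``
    is therefore structurally 0 and reported for completeness.
    """

    kind: str  # "removed" or "terpene_invalidated"
    n_input: int
    rule_counts: dict[str, int] = field(default_factory=dict)
    overlap: int = 0

    @property
    def total(self) -> int:
        return sum(self.rule_counts.values()) - self.overlap

    @property
    def fraction(self) -> float:
        return self.total / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_input": self.n_input,
            "rule_counts": dict(self.rule_counts),
            "overlap": self.overlap,
            "total": self.total,
            "fraction": self.fraction,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _duplicate_subset(table: pd.DataFrame) -> list[str]:
    """Columns defining row identity for duplicate detection.

    A duplicate is identical on every measurement column plus
    producer_id and strain_name (sample IDs are lab bookkeeping and may
    differ between true duplicates).
    """
    panel = table.attrs.get("panel")
    if panel:
        meas = [c for c in table.columns if c in panel]
    else:
        meas = [
            c
            for c in table.columns
            if c in panels.CANNABINOID_COLUMNS or c in panels.TERPENES
        ]
    return ["producer_id", "strain_name"] + meas


def apply_cannabinoid_filters(
    table: pd.DataFrame,
    single_cap: float = 40.0,
    sum_cap: float = 50.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove implausible rows; returns the surviving table and audit counts.

    Application order: exact duplicates; any single cannabinoid (acid or
    neutral) strictly over ``single_cap``; summed total cannabinoids
    strictly over ``sum_cap``; both total THC and total CBD null-or-zero.
    Thresholds are strict inequalities.  Totals columns are computed if
    absent and retained on the output.
    """
    df = table.copy()
    report = FilterReport(kind="removed", n_input=len(df))

    dup = df.duplicated(subset=_duplicate_subset(df), keep="first")
    report.rule_counts["duplicate"] = int(dup.sum())
    df = df[~dup]

    cann_cols = [c for c in panels.CANNABINOID_COLUMNS if c in df.columns]
    over_single = (df[cann_cols] > single_cap).any(axis=1)
    report.rule_counts["single_cannabinoid_over_cap"] = int(over_single.sum())
    df = df[~over_single]

    if not all(c in df.columns for c in panels.TOTAL_COLUMNS):
        df = add_totals(df)
    total_cols = [c for c in panels.TOTAL_COLUMNS if c in df.columns]
    over_sum = df[total_cols].sum(axis=1) > sum_cap
    report.rule_counts["summed_totals_over_cap"] = int(over_sum.sum())
    df = df[~over_sum]

    thc0 = df["total_thc"].isna() | (df["total_thc"] == 0)
    cbd0 = df["total_cbd"].isna() | (df["total_cbd"] == 0)
    both0 = thc0 & cbd0
    report.rule_counts["null_thc_and_cbd"] = int(both0.sum())
    df = df[~both0]

    df = df.reset_index(drop=True)
    df.attrs = dict(table.attrs)
    return df, report


def apply_terpene_filters(
    table: pd.DataFrame,
    variance_floor: float = 0.001,
    single_cap: float = 5.0,
    max_zeros: int = 10,
    terpene_cols=panels.TERPENES,
) -> tuple[pd.DataFrame, FilterReport]:
    """Invalidate (not remove) implausible terpene data.

    Rows failing a rule keep their cannabinoid data but get
    ``terpene_valid = False`` and nulled terpene values.  Rules, in
    order, evaluated with nulls counted as zeros: row variance below
    ``variance_floor``; any single terpene strictly over ``single_cap``;
    strictly more than ``max_zeros`` zero values among the panel.
    Already-invalid rows are skipped, making the pass idempotent.
    """
    df = table.copy()
    cols = [t for t in terpene_cols if t in df.columns]
    if "terpene_valid" not in df.columns:
        df["terpene_valid"] = True
    report = FilterReport(
        kind="terpene_invalidated", n_input=int(df["terpene_valid"].sum())
    )

    active = df["terpene_valid"].to_numpy(dtype=bool).copy()
    filled = df[cols].fillna(0.0).to_numpy(dtype=float)

    low_var = active & (filled.var(axis=1, ddof=0) < variance_floor)
    report.rule_counts["low_variance"] = int(low_var.sum())
    active &= ~low_var

    over_cap = active & (filled > single_cap).any(axis=1)
    report.rule_counts["single_terpene_over_cap"] = int(over_cap.sum())
    active &= ~over_cap

    many_zeros = active & ((filled == 0.0).sum(axis=1) > max_zeros)
    report.rule_counts["excess_zeros"] = int(many_zeros.sum())

    invalid = low_var | over_cap | many_zeros
    df.loc[invalid, cols] = np.nan
    df.loc[invalid, "terpene_valid"] = False
    df.attrs = dict(table.attrs)
    return df, report


def harmonize(batches: list[LabBatch]) -> pd.DataFrame:
    """Convenience wrapper: units -> isomer sums -> common-panel table."""
    prepared = [sum_isomer_groups(convert_units(b)) for b in batches]
    return intersect_common_panel(prepared)
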