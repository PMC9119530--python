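"""Total-cannabinoid computation, THC:CBD chemotyping and product aggregation.

Lab reports quantify a cannabinoid twice: as its acid form (e.g. THCA)
and its neutral form (THC).  Heating decarboxylates the acid, losing CO2,
so the "total" level assuming complete decarboxylation is

    total = factor * acid + neutral

with factor 0.877 (molecular-weight ratio) for THC, CBD, CBG, CBC and
CBN, and 0.8668 for the propyl analogues THCV/CBDV.

Samples are then classified into three chemotypes by the total THC:CBD
ratio: THC-dominant at 5:1 or higher, CBD-dominant at 1:5 or lower, and
Balanced in between.  Both bounds are inclusive of the dominant class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import panels
from .errors import ChemovarError

THC_DOMINANT_RATIO: float = 5.0
CBD_DOMINANT_RATIO: float = 1.0 / 5.0


def total_cannabinoid(acid, neutral, factor: float = panels.DECARB_FACTOR_DEFAULT):
    """Total cannabinoid level ``factor * acid + neutral`` in % weight.

    Accepts scalars or array-likes.  A null input is treated as 0 unless
    *both* acid and neutral are null, in which case the total is null.
    Negative inputs raise ``ValueError``.
    """
    acid_arr = np.asarray(acid, dtype=float)
    neut_arr = np.asarray(neutral, dtype=float)
    if np.any(np.nan_to_num(acid_arr) < 0) or np.any(np.nan_to_num(neut_arr) < 0):
        raise ValueError("cannabinoid measurements must be nonnegative")
    both_null = np.isnan(acid_arr) & np.isnan(neut_arr)
    total = factor * np.nan_to_num(acid_arr) + np.nan_to_num(neut_arr)
    total = np.where(both_null, np.nan, total)
    if np.ndim(acid) == 0 and np.ndim(neutral) == 0:
        return float(total)
    return total


def add_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``total_<cannabinoid>`` columns for the six-compound panel.

    Missing acid or neutral columns are treated as all-null, so a lab
    reporting only THCA still yields a total THC.
    """
    out = table.copy()
    n = len(out)
    for c in panels.CANNABINOIDS:
        acid_col = panels.ACID_OF[c]
        acid = out[acid_col] if acid_col in out else pd.Series(np.nan, index=out.index)
        neut = out[c] if c in out else pd.Series(np.nan, index=out.index)
        out[f"total_{c}"] = total_cannabinoid(
            acid.to_numpy(dtype=float) if n else np.empty(0),
            neut.to_numpy(dtype=float) if n else np.empty(0),
            factor=panels.DECARB_FACTORS[c],
        )
    return out


def thc_cbd_ratio(total_thc, total_cbd):
    """THC:CBD ratio; infinite when CBD is 0 and THC positive.

    Raises ``ChemovarError`` if any sample has both totals zero or null
    (such samples are removed by QC before chemotyping).
    """
    thc = np.nan_to_num(np.asarray(total_thc, dtype=float))
    cbd = np.nan_to_num(np.asarray(total_cbd, dtype=float))
    if np.any((thc == 0) & (cbd == 0)):
        raise ChemovarError(
            "both total THC and total CBD are zero/null; "
            "such samples should have been removed by QC"
        )
    with np.errstate(divide="ignore"):
        ratio = np.where(cbd > 0, thc / np.where(cbd > 0, cbd, 1.0), np.inf)
    if np.ndim(total_thc) == 0 and np.ndim(total_cbd) == 0:
        return float(ratio)
    return ratio


def classify_chemotypes(total_thc, total_cbd) -> np.ndarray:
    """Vectorized three-way THC:CBD chemotype classification.

    ratio >= 5 -> THC-dominant; ratio <= 1/5 -> CBD-dominant; Balanced
    in between.  CBD = 0 gives an infinite ratio (THC-dominant); THC = 0
    gives ratio 0 (CBD-dominant).
    """
    ratio = np.atleast_1d(thc_cbd_ratio(total_thc, total_cbd))
    out = np.full(ratio.shape, panels.CHEMOTYPE_BALANCED, dtype=object)
    out[ratio >= THC_DOMINANT_RATIO] = panels.CHEMOTYPE_THC
    out[ratio <= CBD_DOMINANT_RATIO] = panels.CHEMOTYPE_CBD
    return out


def classify_thc_cbd(total_thc: float, total_cbd: float) -> tuple[float, str]:
    """Classify a single sample; returns ``(ratio, chemotype)``."""
    ratio = thc_cbd_ratio(total_thc, total_cbd)
    return ratio, str(classify_chemotypes(total_thc, total_cbd)[0])


def add_chemotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``thc_cbd_ratio`` and ``chemotype`` columns (totals required)."""
    out = table.copy()
    out["thc_cbd_ratio"] = thc_cbd_ratio(
        out["total_thc"].to_numpy(), out["total_cbd"].to_numpy()
    )
    out["chemotype"] = classify_chemotypes(
        out["total_thc"].to_numpy(), out["total_cbd"].to_numpy()
    )
    return out


def dominant_terpene(profile, named_set=panels.DOMINANT_TERPENE_SET) -> str:
    """Most abundant terpene of a 14-terpene profile, or "other".

    ``profile`` is a mapping/Series of terpene name -> level.  The argmax
    terpene name is returned if it belongs to ``named_set``; otherwise
    "other".  Exact ties are broken by canonical panel order.  An
    all-null profile raises ``ChemovarError``.
    """
    s = pd.Series(profile, dtype=float)
    if s.isna().all():
        raise ChemovarError("cannot assign a dominant terpene to an all-null profile")
    s = s.fillna(0.0)
    # reindex to canonical order so idxmax ties resolve deterministically
    order = [t for t in panels.TERPENES if t in s.index]
    order += [t for t in s.index if t not in order]
    s = s.reindex(order)
    top = s.idxmax()
    return top if top in named_set else "other"


def add_dominant_terpenes(
    table: pd.DataFrame, terpene_cols=panels.TERPENES
) -> pd.DataFrame:
    """Vectorized dominant-terpene labels for table rows.

    Rows whose terpene data is entirely null (terpene-invalid samples)
    receive a null label rather than an error.
    """
    out = table.copy()
    cols = [t for t in terpene_cols if t in out.columns]
    mat = out[cols].to_numpy(dtype=float)
    all_null = np.all(np.isnan(mat), axis=1)
    filled = np.nan_to_num(mat)
    top_idx = np.argmax(filled, axis=1)  # first max = canonical order tie-break
    names = np.array(cols, dtype=object)[top_idx]
    labels = np.where(
        np.isin(names, list(panels.DOMINANT_TERPENE_SET)), names, "other"
    ).astype(object)
    labels[all_null] = None
    out["dominant_terpene"] = labels
    return out


def aggregate_products(
    table: pd.DataFrame,
    terpene_cols=panels.TERPENES,
    zero_fill_invalid_terpenes: bool = False,
) -> pd.DataFrame:
    """Average samples into products: one row per (producer, strain name).

    Rows without a strain name are excluded.  Cannabinoid totals are
    averaged over all samples of the product; terpene columns are
    averaged only over terpene-valid samples (set
    ``zero_fill_invalid_terpenes`` to instead zero-fill and average over
    all samples).  The product chemotype is assigned from the *mean*
    total THC and CBD.
    """
    df = table[table["strain_name"].notna()].copy()
    if "terpene_valid" not in df.columns:
        df["terpene_valid"] = True
    terpene_cols = [t for t in terpene_cols if t in df.columns]
    if zero_fill_invalid_terpenes:
        df[terpene_cols] = df[terpene_cols].fillna(0.0)
    else:
        df.loc[~df["terpene_valid"], terpene_cols] = np.nan

    value_cols = [c for c in panels.TOTAL_COLUMNS if c in df.columns] + terpene_cols
    grouped = df.groupby(["producer_id", "strain_name"], sort=True)
    products = grouped[value_cols].mean()
    products["n_samples"] = grouped.size()
    products["n_terpene_valid"] = grouped["terpene_valid"].sum().astype(int)
    # the category label is a property of the strain name; take the modal label
    products["category_label"] = grouped["category_label"].agg(
        lambda s: s.mode().iloc[0] if not s.mode().empty else panels.UNKNOWN_LABEL
    )
    products = products.reset_index()
    products["chemotype"] = classify_chemotypes(
        products["total_thc"].to_numpy(), products["total_cbd"].to_numpy()
    )
    return products
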