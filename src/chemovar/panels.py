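"""Canonical compound panels shared across the package.

Commercial testing labs quantify overlapping but non-identical sets of
cannabinoids and terpenes.  Cross-lab analyses run on the intersection:
six "total" cannabinoids (each computed from an acid + neutral pair) and
fourteen terpenes (after summing ocimene and nerolidol isomers).
"""

from __future__ import annotations

# --- cannabinoids -----------------------------------------------------------

#: The six cannabinoids measured by every lab, as neutral-form names.
CANNABINOIDS: tuple[str, ...] = ("thc", "cbd", "cbg", "cbc", "cbn", "thcv")

#: Acid-form column for each neutral cannabinoid (THCA for THC, etc.).
ACID_OF: dict[str, str] = {c: c + "a" for c in CANNABINOIDS}

#: Decarboxylation mass-loss factor: acid -> neutral-equivalent weight.
#: 0.877 applies to THC, CBD, CBG, CBC and CBN; the propyl-side-chain
#: (varin) cannabinoids THCV and CBDV use 0.8668.
DECARB_FACTOR_DEFAULT: float = 0.877
DECARB_FACTOR_VARIN: float = 0.8668

DECARB_FACTORS: dict[str, float] = {
    "thc": 0.877,
    "cbd": 0.877,
    "cbg": 0.877,
    "cbc": 0.877,
    "cbn": 0.877,
    "thcv": 0.8668,
    "cbdv": 0.8668,
}

#: All raw cannabinoid measurement columns (acid and neutral forms).
CANNABINOID_COLUMNS: tuple[str, ...] = tuple(
    col for c in CANNABINOIDS for col in (ACID_OF[c], c)
)

TOTAL_COLUMNS: tuple[str, ...] = tuple(f"total_{c}" for c in CANNABINOIDS)

# --- terpenes ---------------------------------------------------------------

#: The 14-terpene common panel, in canonical (alphabetical) order.  This
#: order is also the documented tie-break for dominant-terpene calls.
TERPENES: tuple[str, ...] = (
    "alpha_pinene",
    "alpha_terpinene",
    "beta_pinene",
    "bisabolol",
    "camphene",
    "caryophyllene",
    "gamma_terpinene",
    "humulene",
    "limonene",
    "linalool",
    "myrcene",
    "nerolidol",
    "ocimene",
    "terpinolene",
)

#: Isomer families some labs report separately; harmonization sums them.
ISOMER_GROUPS: dict[str, tuple[str, ...]] = {
    "nerolidol": ("cis_nerolidol", "trans_nerolidol"),
    "ocimene": ("alpha_ocimene", "beta_ocimene", "cis_ocimene", "trans_ocimene"),
}

#: Terpenes eligible as a named dominant-terpene label; anything else is
#: reported as "other".
DOMINANT_TERPENE_SET: frozenset[str] = frozenset(
    {"myrcene", "caryophyllene", "limonene", "terpinolene", "alpha_pinene", "ocimene"}
)

#: Eight-terpene summary used for polar profiles; alpha- and beta-pinene
#: are summed as "pinene" here (display only, never in the 14-panel).
POLAR_TERPENES: tuple[str, ...] = (
    "myrcene",
    "caryophyllene",
    "limonene",
    "terpinolene",
    "pinene",
    "ocimene",
    "linalool",
    "humulene",
)

# --- table schema -----------------------------------------------------------

#: Non-measurement columns carried through harmonization.
METADATA_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "lab_id",
    "producer_id",
    "strain_name",
    "category_label",
    "test_date",
)

CATEGORY_LABELS: tuple[str, ...] = ("Indica", "Hybrid", "Sativa")
UNKNOWN_LABEL: str = "Unknown"

CHEMOTYPE_THC: str = "THC-dominant"
CHEMOTYPE_BALANCED: str = "Balanced"
CHEMOTYPE_CBD: str = "CBD-dominant"
CHEMOTYPES: tuple[str, ...] = (CHEMOTYPE_THC, CHEMOTYPE_BALANCED, CHEMOTYPE_CBD)
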