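"""Synthetic multi-lab testing datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes,
so the whole pipeline runs and can be validated without any download:

* a three-class THC:CBD chemotype mixture dominated by THC-dominant
  samples (defaults follow the observed commercial shares, ~96.5%
  THC-dominant);
* within THC-dominant material, three latent terpene clusters with
  distinct dominant terpenes — caryophyllene+limonene, myrcene+pinene,
  terpinolene+myrcene — drawn as log-normal perturbations around
  cluster mean vectors (nonnegative and right-skewed, like real panels);
* positive latent correlation for the alpha/beta-pinene pair and the
  caryophyllene/humulene pair (co-produced by shared enzymes), and CBG
  coupled to terpinolene inside the terpinolene cluster;
* producer x strain nesting: samples aggregate into products, products
  of a strain usually draw from the strain's latent cluster
  (``strain_consistency``), and a strain's commercial category label
  usually matches its cluster's enriched label (``label_fidelity``);
* per-lab unit dialects (% weight / ppm / mg per g) and isomer dialects
  (ocimene and nerolidol reported summed or as separate isomers);
* optional contaminant rows spiked to exercise every QC filter, with
  the spiked IDs recorded for exact audit.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import panels
from .errors import ChemovarError, ConfigError
from .ingest import LabBatch, infer_panel

#: Cluster mean terpene vectors in % weight.  Dominant terpenes match the
#: three commercial chemotypes: I caryophyllene+limonene, II
#: myrcene+pinene, III terpinolene+myrcene.
CLUSTER_TERPENE_MEANS: tuple[dict[str, float], ...] = (
    {  # cluster 0: high caryophyllene-limonene
        "caryophyllene": 0.65, "limonene": 0.60, "myrcene": 0.28, "humulene": 0.20,
        "linalool": 0.16, "alpha_pinene": 0.08, "beta_pinene": 0.05, "bisabolol": 0.08,
        "camphene": 0.02, "alpha_terpinene": 0.01, "gamma_terpinene": 0.01,
        "nerolidol": 0.04, "ocimene": 0.05, "terpinolene": 0.015,
    },
    {  # cluster 1: high myrcene-pinene
        "myrcene": 0.85, "alpha_pinene": 0.30, "beta_pinene": 0.16, "limonene": 0.22,
        "caryophyllene": 0.22, "humulene": 0.07, "linalool": 0.10, "ocimene": 0.06,
        "terpinolene": 0.02, "bisabolol": 0.04, "camphene": 0.03, "nerolidol": 0.03,
        "alpha_terpinene": 0.01, "gamma_terpinene": 0.01,
    },
    {  # cluster 2: high terpinolene-myrcene
        "terpinolene": 0.75, "myrcene": 0.38, "ocimene": 0.15, "alpha_pinene": 0.12,
        "beta_pinene": 0.07, "caryophyllene": 0.16, "limonene": 0.14, "humulene": 0.05,
        "linalool": 0.06, "alpha_terpinene": 0.03, "gamma_terpinene": 0.03,
        "camphene": 0.02, "bisabolol": 0.03, "nerolidol": 0.02,
    },
)

#: Commercial category most associated with each latent cluster; the
#: terpinolene cluster is the Sativa-enriched one.
CLUSTER_ENRICHED_LABEL: tuple[str, ...] = ("Indica", "Hybrid", "Sativa")

#: QC contaminant rule names accepted by ``contaminant_counts``.
CONTAMINANT_RULES: tuple[str, ...] = (
    "duplicate",
    "single_cannabinoid_over_cap",
    "summed_totals_over_cap",
    "null_thc_and_cbd",
    "low_variance",
    "single_terpene_over_cap",
    "excess_zeros",
)

_UNIT_FACTORS = {"percent": 1.0, "ppm": 10_000.0, "mg_per_g": 10.0}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study population.

    ``chemotype_proportions`` is (THC-dominant, balanced, CBD-dominant);
    ``terpene_cluster_proportions`` applies within THC-dominant samples.
    Proportion vectors may be given at printed precision (summing to 1
    within 5e-3) and are renormalized internally.
    """

    n_labs: int = 3
    n_producers: int = 30
    n_strains: int = 24
    samples_per_producer_strain: tuple[int, int] = (2, 6)
    chemotype_proportions: tuple[float, float, float] = (0.965, 0.022, 0.014)
    terpene_cluster_proportions: tuple[float, float, float] = (0.45, 0.43, 0.12)
    label_fidelity: float = 0.7
    strain_consistency: float = 0.9
    noise_scale: float = 0.25
    product_effect_scale: float = 0.15
    isomer_correlation: float = 0.8
    unknown_label_rate: float = 0.1
    contaminant_counts: dict[str, int] = field(default_factory=dict)
    unit_dialects: tuple[str, ...] | None = None
    isomer_dialects: tuple[str, ...] | None = None  # "summed" | "separate"
    extra_compounds: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: {0: ("guaiol",)}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_labs", "n_producers", "n_strains"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        lo, hi = self.samples_per_producer_strain
        if lo < 1 or hi < lo:
            raise ConfigError("samples_per_producer_strain must be a valid count range")
        for name in ("chemotype_proportions", "terpene_cluster_proportions"):
            props = np.asarray(getattr(self, name), dtype=float)
            if props.shape != (3,) or np.any(props < 0):
                raise ConfigError(f"{name} must be 3 nonnegative values")
            if abs(props.sum() - 1.0) > 5e-3:
                raise ConfigError(f"{name} must sum to 1 (within printed precision)")
        for name in (
            "label_fidelity", "strain_consistency", "unknown_label_rate",
            "isomer_correlation",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_scale < 0 or self.product_effect_scale < 0:
            raise ConfigError("noise_scale and product_effect_scale must be >= 0")
        for rule, count in self.contaminant_counts.items():
            if rule not in CONTAMINANT_RULES:
                raise ConfigError(f"contaminant_counts: unknown rule {rule!r}")
            if count < 0:
                raise ConfigError(f"contaminant_counts[{rule!r}] must be >= 0")
        if self.unit_dialects is not None:
            for u in self.unit_dialects:
                if u not in _UNIT_FACTORS:
                    raise ConfigError(f"unit_dialects: unknown unit {u!r}")
        if self.isomer_dialects is not None:
            for d in self.isomer_dialects:
                if d not in ("summed", "separate"):
                    raise ConfigError(f"isomer_dialects: unknown dialect {d!r}")

    def lab_units(self) -> list[str]:
        if self.unit_dialects is not None:
            return [self.unit_dialects[i % len(self.unit_dialects)] for i in range(self.n_labs)]
        cycle = ("percent", "ppm", "mg_per_g")
        return [cycle[i % 3] for i in range(self.n_labs)]

    def lab_isomer_dialects(self) -> list[str]:
        if self.isomer_dialects is not None:
            return [self.isomer_dialects[i % len(self.isomer_dialects)] for i in range(self.n_labs)]
        return ["separate" if i % 2 else "summed" for i in range(self.n_labs)]


@dataclass
class GroundTruth:
    """Latent state behind a generated dataset."""

    samples: pd.DataFrame  # sample_id, chemotype, terpene_cluster, strain, producer
    strain_clusters: dict[str, int]
    contaminants: dict[str, list[str]] = field(default_factory=dict)

    def chemotype_shares(self) -> pd.Series:
        return self.samples["chemotype"].value_counts(normalize=True)


def _correlated_noise(rng, n: int, sigma: float, rho: float) -> np.ndarray:
    """(n, 14) log-scale noise with shared factors for isomer pairs."""
    eps = rng.normal(0.0, 1.0, size=(n, len(panels.TERPENES)))
    cols = {t: i for i, t in enumerate(panels.TERPENES)}
    for pair in (("alpha_pinene", "beta_pinene"), ("caryophyllene", "humulene")):
        shared = rng.normal(0.0, 1.0, size=n)
        for t in pair:
            j = cols[t]
            eps[:, j] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps[:, j]
    return sigma * eps


def _draw_cannabinoid_totals(rng, chemotypes: np.ndarray) -> dict[str, np.ndarray]:
    """Class-consistent total THC/CBD plus minor cannabinoid totals."""
    n = len(chemotypes)
    thc = np.empty(n)
    cbd = np.empty(n)
    is_thc = chemotypes == 0
    is_bal = chemotypes == 1
    is_cbd = chemotypes == 2

    k = int(is_thc.sum())
    thc[is_thc] = np.clip(rng.lognormal(np.log(18.0), 0.30, k), 3.0, 32.0)
    ratio = np.exp(rng.uniform(np.log(5.5), np.log(800.0), k))
    cbd_vals = thc[is_thc] / ratio
    cbd_vals[rng.random(k) < 0.3] = 0.0  # many labs report no CBD at all
    cbd[is_thc] = cbd_vals

    # symmetric level x ratio parameterization keeps balanced samples
    # inside plausibility caps at any ratio in (1/4.5, 4.5)
    k = int(is_bal.sum())
    level = np.clip(rng.lognormal(np.log(7.0), 0.35, k), 1.0, 15.0)
    ratio = np.exp(rng.uniform(np.log(1 / 4.5), np.log(4.5), k))
    thc[is_bal] = level * np.sqrt(ratio)
    cbd[is_bal] = level / np.sqrt(ratio)

    k = int(is_cbd.sum())
    cbd[is_cbd] = np.clip(rng.lognormal(np.log(11.0), 0.35, k), 2.0, 28.0)
    ratio = np.exp(rng.uniform(np.log(1 / 800.0), np.log(1 / 5.5), k))
    thc_vals = cbd[is_cbd] * ratio
    thc_vals[rng.random(k) < 0.1] = 0.0
    thc[is_cbd] = thc_vals

    totals = {"thc": thc, "cbd": cbd}
    totals["cbg"] = np.clip(rng.lognormal(np.log(0.6), 0.5, n), 0.0, 3.0)
    for minor, level in (("cbc", 0.08), ("cbn", 0.06), ("thcv", 0.04)):
        totals[minor] = np.clip(rng.lognormal(np.log(level), 0.6, n), 0.0, 1.0)
    return totals


def generate_dataset(config: GeneratorConfig) -> tuple[list[LabBatch], GroundTruth]:
    """Generate per-lab batches plus the latent ground truth.

    See the module docstring for the generative model.  Contaminants are
    *not* spiked here; call :func:`spike_contaminants` afterwards (the
    pipeline does this when ``contaminant_counts`` is nonempty).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chemo_p = np.asarray(config.chemotype_proportions, dtype=float)
    chemo_p = chemo_p / chemo_p.sum()
    clust_p = np.asarray(config.terpene_cluster_proportions, dtype=float)
    clust_p = clust_p / clust_p.sum()

    strains = [f"strain-{i:03d}" for i in range(config.n_strains)]
    strain_cluster = rng.choice(3, size=config.n_strains, p=clust_p)
    # commercial category per strain: enriched label with prob label_fidelity
    strain_label = []
    for c in strain_cluster:
        if rng.random() < config.unknown_label_rate:
            strain_label.append(panels.UNKNOWN_LABEL)
        elif rng.random() < config.label_fidelity:
            strain_label.append(CLUSTER_ENRICHED_LABEL[c])
        else:
            strain_label.append(panels.CATEGORY_LABELS[rng.integers(3)])

    producers = [f"producer-{i:03d}" for i in range(config.n_producers)]
    producer_lab = np.arange(config.n_producers) % config.n_labs

    mean_mat = np.array(
        [[CLUSTER_TERPENE_MEANS[c][t] for t in panels.TERPENES] for c in range(3)]
    )
    # balanced / CBD-dominant material: mostly myrcene-dominant profiles
    non_thc_mean = 0.8 * mean_mat[1]

    lo, hi = config.samples_per_producer_strain
    records = []
    truth_rows = []
    sid = 0
    for p_idx, producer in enumerate(producers):
        for s_idx, strain in enumerate(strains):
            if rng.random() < config.strain_consistency:
                product_cluster = int(strain_cluster[s_idx])
            else:
                product_cluster = int(rng.integers(3))
            z_product = _correlated_noise(
                rng, 1, config.product_effect_scale, config.isomer_correlation
            )[0]
            n_samples = int(rng.integers(lo, hi + 1))
            chemos = rng.choice(3, size=n_samples, p=chemo_p)
            totals = _draw_cannabinoid_totals(rng, chemos)
            z_sample = _correlated_noise(
                rng, n_samples, config.noise_scale, config.isomer_correlation
            )
            base = np.where(
                (chemos == 0)[:, None], mean_mat[product_cluster], non_thc_mean
            )
            terps = np.clip(base * np.exp(z_product + z_sample), 1e-4, 4.9)
            terp_idx = {t: j for j, t in enumerate(panels.TERPENES)}
            # CBG rides with terpinolene inside the terpinolene-dominant cluster
            if product_cluster == 2:
                tpl = terps[:, terp_idx["terpinolene"]]
                boost = (tpl / CLUSTER_TERPENE_MEANS[2]["terpinolene"]) ** 0.6
                totals["cbg"] = np.clip(totals["cbg"] * boost, 0.0, 4.0)
            acid_frac = rng.uniform(0.85, 0.95, size=n_samples)
            for i in range(n_samples):
                rec = {
                    "sample_id": f"S{sid:07d}",
                    "producer_id": producer,
                    "strain_name": strain,
                    "category_label": strain_label[s_idx],
                    "test_date": None,
                    "_lab": int(producer_lab[p_idx]),
                }
                for c in panels.CANNABINOIDS:
                    total = totals[c][i]
                    factor = panels.DECARB_FACTORS[c]
                    rec[panels.ACID_OF[c]] = total * acid_frac[i] / factor
                    rec[c] = total * (1.0 - acid_frac[i])
                for t, j in terp_idx.items():
                    rec[t] = terps[i, j]
                records.append(rec)
                truth_rows.append(
                    {
                        "sample_id": rec["sample_id"],
                        "chemotype": panels.CHEMOTYPES[chemos[i]],
                        "terpene_cluster": product_cluster if chemos[i] == 0 else -1,
                        "strain_name": strain,
                        "producer_id": producer,
                        "lab": int(producer_lab[p_idx]),
                    }
                )
                sid += 1

    full = pd.DataFrame(records)
    batches = _emit_lab_batches(full, config, rng)
    truth = GroundTruth(
        samples=pd.DataFrame(truth_rows),
        strain_clusters={s: int(c) for s, c in zip(strains, strain_cluster)},
    )
    return batches, truth


def _emit_lab_batches(
    full: pd.DataFrame, config: GeneratorConfig, rng
) -> list[LabBatch]:
    """Split the master table into per-lab tables in each lab's dialect."""
    units = config.lab_units()
    dialects = config.lab_isomer_dialects()
    batches = []
    for lab in range(config.n_labs):
        df = full[full["_lab"] == lab].drop(columns="_lab").reset_index(drop=True)
        if dialects[lab] == "separate":
            for group, members in panels.ISOMER_GROUPS.items():
                vals = df[group].to_numpy()
                parts = rng.dirichlet(np.full(len(members), 2.0), size=len(df))
                for m_idx, member in enumerate(members):
                    df[member] = vals * parts[:, m_idx]
                df = df.drop(columns=group)
        for extra in config.extra_compounds.get(lab, ()):
            df[extra] = rng.lognormal(np.log(0.05), 0.5, size=len(df))
        meas = [c for c in df.columns if c not in panels.METADATA_COLUMNS]
        factor = _UNIT_FACTORS[units[lab]]
        if factor != 1.0:
            df[meas] = df[meas] * factor
        batches.append(
            LabBatch(
                lab_id=f"lab-{lab:02d}",
                unit=units[lab],
                data=df,
                panel=infer_panel(df.columns),
            )
        )
    return batches


# --- contaminant spiking ----------------------------------------------------


def spike_contaminants(
    batches: list[LabBatch],
    config: GeneratorConfig,
    truth: GroundTruth | None = None,
) -> tuple[list[LabBatch], GroundTruth]:
    """Append contaminant rows that trip each QC rule exactly once each.

    ``config.contaminant_counts`` maps rule names (see
    :data:`CONTAMINANT_RULES`) to spike counts.  Spiked rows are cloned
    from distinct existing rows, modified in the batch's own unit, given
    fresh ``SPIKE-*`` sample IDs (except duplicates, which must be exact
    row copies up to sample ID), and recorded in the returned ground
    truth's ``contaminants``.
    """
    config.validate()
    counts = {r: int(config.contaminant_counts.get(r, 0)) for r in CONTAMINANT_RULES}
    out = [b.copy() for b in batches]
    contaminants: dict[str, list[str]] = {r: [] for r in CONTAMINANT_RULES}
    if sum(counts.values()) == 0:
        gt = truth or GroundTruth(samples=pd.DataFrame(), strain_clusters={})
        gt.contaminants = contaminants
        return out, gt

    rng = np.random.default_rng((config.seed + 1) % 2**31)
    n_total = sum(len(b.data) for b in out)
    if counts["duplicate"] > n_total:
        raise ChemovarError("requested more duplicates than available rows")

    # distinct template rows per batch, assigned round-robin over batches
    spike_jobs = []  # (batch index, rule)
    b_idx = 0
    for rule in CONTAMINANT_RULES:
        for _ in range(counts[rule]):
            spike_jobs.append((b_idx % len(out), rule))
            b_idx += 1

    used: dict[int, set[int]] = {i: set() for i in range(len(out))}
    new_rows: dict[int, list[pd.Series]] = {i: [] for i in range(len(out))}
    spike_n = 0
    for batch_i, rule in spike_jobs:
        batch = out[batch_i]
        df = batch.data
        avail = [i for i in range(len(df)) if i not in used[batch_i]]
        if not avail:
            raise ChemovarError(f"batch {batch.lab_id} has no rows left to clone")
        tmpl_i = int(rng.choice(avail))
        used[batch_i].add(tmpl_i)
        row = df.iloc[tmpl_i].copy()
        factor = _UNIT_FACTORS[batch.unit]
        sid = f"SPIKE-{rule}-{spike_n:04d}"
        spike_n += 1
        if rule == "duplicate":
            row["sample_id"] = sid
        else:
            row["sample_id"] = sid
            _apply_rule(row, rule, factor, batch, rng)
        contaminants[rule].append(sid)
        new_rows[batch_i].append(row)

    for i, rows in new_rows.items():
        if rows:
            out[i].data = pd.concat(
                [out[i].data, pd.DataFrame(rows)], ignore_index=True
            )
    gt = truth or GroundTruth(samples=pd.DataFrame(), strain_clusters={})
    gt.contaminants = contaminants
    return out, gt


def _terpene_cols(batch: LabBatch) -> list[str]:
    return [c for c, role in batch.panel.items() if role == "terpene"]


def _set_panel_terpenes(row: pd.Series, batch: LabBatch, values_pct: dict[str, float],
                        factor: float) -> None:
    """Write %wt terpene values into a row honoring the isomer dialect.

    ``values_pct`` is keyed by summed-panel terpene name; for labs that
    report isomers separately the value is placed on the first member
    and the remaining members set to 0, so the harmonized sum is exact.
    """
    known = set(panels.TERPENES)
    for members in panels.ISOMER_GROUPS.values():
        known.update(members)
    for col in _terpene_cols(batch):
        if col in known:
            row[col] = 0.0
    for name, val in values_pct.items():
        members = panels.ISOMER_GROUPS.get(name)
        if members and members[0] in row.index:
            row[members[0]] = val * factor
        elif name in row.index:
            row[name] = val * factor


def _apply_rule(row: pd.Series, rule: str, factor: float, batch: LabBatch, rng) -> None:
    if rule == "single_cannabinoid_over_cap":
        row["thca"] = 45.0 * factor
    elif rule == "summed_totals_over_cap":
        # total THC ~30 + total CBD ~25 = 55 > 50, no single value > 40
        row["thca"] = (30.0 * 0.9 / 0.877) * factor
        row["thc"] = (30.0 * 0.1) * factor
        row["cbda"] = (25.0 * 0.9 / 0.877) * factor
        row["cbd"] = (25.0 * 0.1) * factor
    elif rule == "null_thc_and_cbd":
        for col in ("thca", "thc", "cbda", "cbd"):
            if col in row.index:
                row[col] = 0.0
    elif rule == "low_variance":
        vals = {t: 0.01 for t in panels.TERPENES}
        _set_panel_terpenes(row, batch, vals, factor)
    elif rule == "single_terpene_over_cap":
        vals = {t: float(v) for t, v in zip(
            panels.TERPENES, rng.uniform(0.05, 0.5, len(panels.TERPENES)))}
        vals["limonene"] = 6.0
        _set_panel_terpenes(row, batch, vals, factor)
    elif rule == "excess_zeros":
        vals = {t: 0.0 for t in panels.TERPENES}
        for t, v in zip(("myrcene", "limonene", "caryophyllene"), (0.4, 0.3, 0.2)):
            vals[t] = v + float(rng.uniform(0, 0.05))
        _set_panel_terpenes(row, batch, vals, factor)
    else:  # pragma: no cover
        raise ChemovarError(f"unknown contaminant rule {rule!r}")


# --- persistence ------------------------------------------------------------


def write_dataset(batches: list[LabBatch], truth: GroundTruth, outdir) -> None:
    """Write one CSV per lab plus a JSON ground-truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for b in batches:
        path = outdir / f"{b.lab_id}.csv"
        b.data.to_csv(path, index=False)
        meta.append({"lab_id": b.lab_id, "unit": b.unit, "file": path.name})
    (outdir / "labs.json").write_text(json.dumps(meta, indent=2))
    gt = {
        "strain_clusters": truth.strain_clusters,
        "contaminants": truth.contaminants,
        "samples": truth.samples.to_dict(orient="list"),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=2))


def config_from_mapping(mapping: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a plain mapping (e.g. parsed YAML)."""
    kwargs = {}
    valid = {f for f in GeneratorConfig.__dataclass_fields__}
    for key, value in mapping.items():
        if key not in valid:
            raise ConfigError(f"unknown generator parameter {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    cfg = GeneratorConfig(**kwargs)
    cfg.validate()
    return cfg
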