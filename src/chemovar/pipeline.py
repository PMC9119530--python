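"""End-to-end orchestration: data -> QC -> chemotypes -> clusters -> labels.

The pipeline runs every analysis stage in order from a single config —
synthetic generation (or per-lab file ingest), harmonization, QC
filtering, chemotyping, terpene chemometrics, k-means clustering with
label-system comparison, product aggregation and strain-consistency
nulls — and collects everything into a JSON-serializable report bundle.
A fixed seed reproduces the bundle exactly, bootstraps included.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import chemometrics, chemotype, clustering, consistency, ingest, panels, synthetic
from .errors import ChemovarError, ConfigError, PipelineStageError

log = logging.getLogger("chemovar")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their conventional defaults."""

    mode: str = "synthetic"  # "synthetic" | "files"
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    lab_files: list[dict] = field(default_factory=list)  # for mode="files"
    single_cannabinoid_cap: float = 40.0
    summed_totals_cap: float = 50.0
    terpene_variance_floor: float = 0.001
    single_terpene_cap: float = 5.0
    max_terpene_zeros: int = 10
    k: int = 3
    null_reps: int = 200
    min_producers: int = 5
    min_samples: int = 5
    alpha: float = 0.05
    network_threshold: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError("mode must be 'synthetic' or 'files'")
        for name in (
            "single_cannabinoid_cap", "summed_totals_cap", "terpene_variance_floor",
            "single_terpene_cap", "network_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("k", "null_reps", "min_producers", "min_samples"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        self.generator.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        gen = synthetic.config_from_mapping(raw.pop("generator", {}))
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ConfigError(f"unknown pipeline parameters: {sorted(unknown)}")
        cfg = cls(generator=gen, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class ReportBundle:
    """Machine-readable results of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    filter_report: dict
    terpene_filter_report: dict
    chemotype_shares: dict
    n_samples: int
    n_terpene_valid: int
    chemometrics: dict
    clusters: dict
    silhouette: dict
    products: dict
    strain_consistency: dict
    enrichment: list

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _ctx:
        def __init__(self):
            self.t0 = None

        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs", name, dt)
                if not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, str(exc)) from exc
                return False
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _ctx()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order and return the report bundle."""
    config.validate()
    seed = config.seed

    with _stage("data"):
        if config.mode == "synthetic":
            gen = config.generator
            batches, truth = synthetic.generate_dataset(gen)
            if any(gen.contaminant_counts.values()):
                batches, truth = synthetic.spike_contaminants(batches, gen, truth)
        else:
            batches = [
                ingest.read_lab_table(meta["file"], meta) for meta in config.lab_files
            ]

    with _stage("harmonize"):
        table = ingest.harmonize(batches)

    with _stage("qc"):
        table, cann_report = ingest.apply_cannabinoid_filters(
            table, config.single_cannabinoid_cap, config.summed_totals_cap
        )
        table, terp_report = ingest.apply_terpene_filters(
            table,
            config.terpene_variance_floor,
            config.single_terpene_cap,
            config.max_terpene_zeros,
        )

    with _stage("chemotype"):
        table = chemotype.add_chemotypes(table)
        table = chemotype.add_dominant_terpenes(table)
        shares = table["chemotype"].value_counts(normalize=True).to_dict()

    terp_cols = [t for t in panels.TERPENES if t in table.columns]
    valid = table[table["terpene_valid"]].reset_index(drop=True)

    with _stage("chemometrics"):
        norm_all = chemometrics.normalize_profiles(valid[terp_cols])
        pca_res = chemometrics.pca(norm_all)
        corr = chemometrics.correlation_matrix(valid[terp_cols], alpha=config.alpha)
        leaf_order = chemometrics.hierarchical_order(corr)
        edges, nodes = chemometrics.threshold_network(corr, config.network_threshold)
        pair_r = {
            "pinene_isomers": chemometrics.spearman(
                valid["alpha_pinene"], valid["beta_pinene"]
            )[0],
            "caryophyllene_humulene": chemometrics.spearman(
                valid["caryophyllene"], valid["humulene"]
            )[0],
        }
        chemo_section = {
            "pca_variance_fractions": pca_res.explained_variance_ratio,
            "n_pairwise_comparisons": corr.m,
            "n_significant_pairs": int(corr.significant.to_numpy().sum() // 2),
            "leaf_order": leaf_order,
            "n_network_edges": int(len(edges)),
            "pair_correlations": pair_r,
        }

    with _stage("cluster"):
        thc_mask = (valid["chemotype"] == panels.CHEMOTYPE_THC).to_numpy()
        thc = valid[thc_mask].reset_index(drop=True)
        norm_thc = chemometrics.normalize_profiles(thc[terp_cols])
        model = clustering.kmeans_fit(norm_thc, config.k, seed=seed)
        names = clustering.cluster_names(model)
        summary = clustering.cluster_summary(model, norm_thc.data)
        systems = {
            "kmeans": np.array([names[a] for a in model.assignments], dtype=object),
            "dominant_terpene": thc["dominant_terpene"].to_numpy(dtype=object),
            "commercial": thc["category_label"].to_numpy(dtype=object),
        }
        sil = clustering.compare_label_systems(norm_thc, systems, alpha=config.alpha)
        cluster_section = {
            "k": config.k,
            "sizes": {s["cluster"]: s["size"] for s in summary},
            "summary": summary,
        }
        sil_section = {
            "means": sil.means,
            "ranking": sil.ranking(),
            "comparisons": sil.comparisons,
        }

    with _stage("products"):
        products = chemotype.aggregate_products(table)
        thc_products = products[
            (products["chemotype"] == panels.CHEMOTYPE_THC)
            & (products["n_terpene_valid"] > 0)
        ].reset_index(drop=True)
        prod_norm = chemometrics.normalize_profiles(thc_products[terp_cols])
        keep = ~prod_norm.all_zero.to_numpy()
        thc_products = thc_products[keep].reset_index(drop=True)
        k_prod = min(config.k, len(thc_products))
        prod_model = clustering.kmeans_fit(
            chemometrics.normalize_profiles(thc_products[terp_cols]), k_prod, seed=seed
        )
        prod_names = clustering.cluster_names(prod_model)
        thc_products["cluster"] = [prod_names[a] for a in prod_model.assignments]
        diversity = consistency.product_diversity(
            products[products["n_terpene_valid"] > 0], terp_cols, seed=seed
        )
        products_section = {
            "n_products": int(len(products)),
            "n_thc_dominant_products": int(len(thc_products)),
            "diversity_means": {
                c: float(v.mean()) for c, v in diversity.per_product.items()
            },
            "diversity_comparisons": diversity.comparisons,
        }

    with _stage("consistency"):
        strains = consistency.eligible_strains(
            thc_products, config.min_producers, config.min_samples
        )
        if strains:
            eligible = thc_products[
                thc_products["strain_name"].isin(strains)
            ].reset_index(drop=True)
            null = consistency.shuffled_name_null(
                eligible, reps=config.null_reps, seed=seed, profile_cols=terp_cols
            )
            strain_table = consistency.strain_consistency(
                eligible, strains, terp_cols, null=null, alpha=config.alpha
            )
            cluster_null = consistency.shuffled_cluster_null(
                eligible, strains, reps=config.null_reps, seed=seed
            )
            share_tests = consistency.cluster_share_vs_null(
                eligible, strains, cluster_null, alpha=config.alpha
            )
            strain_section = {
                "n_eligible_strains": len(strains),
                "null_mean_similarity": null.mean,
                "null_reps": null.reps,
                "strains": strain_table,
                "top_cluster_null_mean": cluster_null.mean,
                "top_cluster_shares": share_tests,
            }
        else:
            strain_section = {"n_eligible_strains": 0}
        enrichment = consistency.category_cluster_enrichment(
            thc_products, alpha=config.alpha
        )

    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return ReportBundle(
        config_hash=cfg_hash,
        seed=seed,
        version=__version__,
        filter_report=cann_report.to_dict(),
        terpene_filter_report=terp_report.to_dict(),
        chemotype_shares={k: float(v) for k, v in shares.items()},
        n_samples=int(len(table)),
        n_terpene_valid=int(table["terpene_valid"].sum()),
        chemometrics=chemo_section,
        clusters=cluster_section,
        silhouette=sil_section,
        products=products_section,
        strain_consistency=strain_section,
        enrichment=enrichment.to_dict(orient="records"),
    )


def summarize_report(bundle: ReportBundle) -> str:
    """Human-readable digest of a report bundle."""
    lines = [
        f"chemovar pipeline report (seed {bundle.seed}, config {bundle.config_hash})",
        f"samples after QC: {bundle.n_samples} "
        f"({bundle.n_terpene_valid} with valid terpene data)",
        "chemotype shares:",
    ]
    for name, share in sorted(
        bundle.chemotype_shares.items(), key=lambda kv: -kv[1]
    ):
        lines.append(f"  {name}: {100 * share:.1f}%")
    lines.append("terpene clusters:")
    for s in bundle.clusters["summary"]:
        lines.append(f"  Cluster {s['cluster']}: n={s['size']}, {s['character']}")
    lines.append("label-system mean silhouette:")
    for name in bundle.silhouette["ranking"]:
        lines.append(f"  {name}: {bundle.silhouette['means'][name]:.3f}")
    sc = bundle.strain_consistency
    if sc.get("n_eligible_strains", 0) == 0:
        lines.append("strain consistency: no eligible strains")
    else:
        lines.append(
            f"strain consistency: {sc['n_eligible_strains']} eligible strains, "
            f"shuffled-name null mean {sc['null_mean_similarity']:.3f}"
        )
        table = sc["strains"]
        if isinstance(table, pd.DataFrame) and not table.empty:
            top = table.nlargest(5, "mean_similarity")
            bottom = table.nsmallest(5, "mean_similarity")
            lines.append("  most consistent: " + ", ".join(
                f"{r.strain_name} ({r.mean_similarity:.3f})" for r in top.itertuples()
            ))
            lines.append("  least consistent: " + ", ".join(
                f"{r.strain_name} ({r.mean_similarity:.3f})"
                for r in bottom.itertuples()
            ))
    return "\n".join(lines)
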