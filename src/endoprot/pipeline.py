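"""End-to-end pipeline orchestration from a single YAML-style config.

Stage order: QC -> clustering (scree, fit, stability, reproducibility,
embedding) -> differential expression (both contrasts + trichotomy) ->
co-expression network (modules, eigenproteins, module-trait) -> hub
networks -> enrichment -> clinical model. All randomness flows from one
master seed through named substreams; the report bundle carries
provenance (package version, seeds, config hash) and every stage's
machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clinical_model as cm
from . import clustering as cl
from . import data_io_qc as io
from . import diffexp as de
from . import enrichment as en
from . import networks as nw
from . import synthetic_data as sim
from . import wgcna as wg

logger = logging.getLogger("endoprot")

_STAGE_SEEDS = {"cluster": 1, "reproducibility": 2, "embed": 3, "enrich": 4, "clinical": 5}


@dataclass
class PipelineConfig:
    """Run settings: either input file paths or a simulate block."""

    npx_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    simulate: sim.SimConfig | None = None
    layout: str = "wide"
    seed: int = 0
    out_dir: str = "out"
    # stage parameters
    cov_threshold: float = 20.0
    cov_scale: str = "linear"
    cov_mode: str = "keep-above"
    k_patients: int = 2
    k_all: int = 3
    restarts: int = 25
    iterations: int = 100
    split_fraction: float = 0.7
    lfc: float = 1.2
    alpha: float = 0.05
    min_module_size: int = 20
    merge_height: float = 0.25
    cut_quantile: float = 0.99
    kme_rescue: float = 0.3
    r2_target: float = 0.9
    top_k: int = 30
    nperm: int = 1000
    trait_samples: str = "ad"  # module-trait correlation on patients only
    run_stability: bool = True
    run_reproducibility: bool = True
    run_embedding: bool = True
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        simulate = raw.pop("simulate", None)
        cfg = cls(**raw)
        if simulate is not None:
            cfg.simulate = sim.SimConfig(**simulate)
        if (cfg.npx_path is None) == (cfg.simulate is None):
            raise ValueError("config needs exactly one of npx_path or a simulate block")
        return cfg

    def config_hash(self) -> str:
        payload = {k: repr(v) for k, v in sorted(vars(self).items())}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(_STAGE_SEEDS[stage],)).generate_state(1)[0] % (2 ** 31))


@dataclass
class ReportBundle:
    """All stage outputs of one pipeline run (None = stage skipped)."""

    provenance: dict
    qc: io.QCReport | None = None
    scree: pd.DataFrame | None = None
    cluster_patients: cl.ClusterModel | None = None
    cluster_all: cl.ClusterModel | None = None
    stability: cl.StabilityReport | None = None
    reproducibility: cl.ReproducibilityReport | None = None
    embedding: pd.DataFrame | None = None
    de_ad_vs_hc: de.DEResult | None = None
    de_c1_vs_c2: de.DEResult | None = None
    de_groups: de.DEGroups | None = None
    network: wg.NetworkModel | None = None
    modules: wg.ModuleAssignment | None = None
    eigen: wg.EigenproteinSet | None = None
    module_trait: wg.ModuleTraitCorr | None = None
    hub_networks: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    importance: cm.ImportanceTable | None = None
    oob_accuracy: float | None = None
    comparisons: cm.ComparisonTable | None = None

    def summary(self) -> dict:
        """JSON-serialisable run summary."""
        out: dict = {"provenance": self.provenance}
        if self.qc:
            out["qc"] = {"n_before": self.qc.n_before, "n_after": self.qc.n_after}
        if self.scree is not None:
            out["scree"] = self.scree.to_dict("records")
        if self.cluster_patients:
            out["cluster_sizes"] = self.cluster_patients.cluster_sizes().to_dict()
        if self.stability:
            out["stability"] = {
                "agreement": self.stability.agreement,
                "outliers": self.stability.outliers,
            }
        if self.reproducibility:
            out["reproducibility"] = {
                "median_train": self.reproducibility.median_train,
                "median_test": self.reproducibility.median_test,
            }
        if self.de_groups:
            out["de_groups"] = {
                "upregulated_ad": len(self.de_groups.upregulated_ad),
                "stepwise": len(self.de_groups.stepwise),
                "unique": len(self.de_groups.unique),
            }
        if self.network:
            out["network"] = {"power": self.network.power}
        if self.modules:
            out["module_sizes"] = {k: int(v) for k, v in self.modules.sizes().items()}
        if self.oob_accuracy is not None:
            out["clinical_oob_accuracy"] = self.oob_accuracy
        return out


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial: ReportBundle):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


def run_pipeline(config: PipelineConfig, write_outputs: bool = False) -> ReportBundle:
    """Execute the full analysis; deterministic for a fixed config + seed."""
    bundle = ReportBundle(
        provenance={
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
    )
    stage = "load"
    try:
        truth = None
        if config.simulate is not None:
            npx, clinical, truth = sim.simulate_cohort(config.simulate)
        else:
            npx = io.read_npx(config.npx_path, layout=config.layout)
            clinical = io.read_clinical(config.clinical_path) if config.clinical_path else None

        stage = "qc"
        npx = io.impute_missing(npx)
        npx, bundle.qc = io.cov_filter(
            npx, threshold=config.cov_threshold, scale=config.cov_scale, mode=config.cov_mode
        )
        scaled = io.zscale(npx)

        stage = "cluster"
        seed_cl = _stage_seed(config.seed, "cluster")
        patients = scaled.sample_ids[scaled.group == "AD"]
        hc_ids = scaled.sample_ids[scaled.group == "HC"]
        Xp = scaled.values.loc[patients]
        bundle.scree = cl.wcss_scree(Xp, k_max=min(10, len(patients)), restarts=config.restarts, seed=seed_cl)
        bundle.cluster_patients = cl.kmeans_fit(Xp, config.k_patients, restarts=config.restarts, seed=seed_cl)
        if config.run_stability and len(hc_ids):
            bundle.cluster_all = cl.kmeans_fit(
                scaled.values, config.k_all, restarts=config.restarts, seed=seed_cl
            )
            bundle.stability = cl.stability_compare(bundle.cluster_patients, bundle.cluster_all, hc_ids)
        if config.run_reproducibility:
            bundle.reproducibility = cl.reproducibility(
                Xp, k=config.k_patients, iterations=config.iterations,
                split_fraction=config.split_fraction,
                seed=_stage_seed(config.seed, "reproducibility"), restarts=config.restarts,
            )
        if config.run_embedding and len(scaled.sample_ids) >= 4:
            emb, _ = cl.embed_2d(
                scaled.values, seed=_stage_seed(config.seed, "embed"),
                labels=bundle.cluster_patients.assignments,
            )
            bundle.embedding = emb

        stage = "diffexp"
        # C1 = the high-inflammatory cluster: higher mean scaled expression
        assign = bundle.cluster_patients.assignments
        cluster_means = {
            c: float(scaled.values.loc[assign.index[assign == c]].mean().mean())
            for c in range(bundle.cluster_patients.k)
        }
        hi_cluster = max(cluster_means, key=cluster_means.get)
        labels = pd.Series("HC", index=npx.sample_ids)
        labels[patients] = "C2"
        labels[assign.index[assign == hi_cluster]] = "C1"
        ad_vs_hc = pd.Series(np.where(npx.group == "AD", 1.0, 0.0), index=npx.sample_ids)
        bundle.de_ad_vs_hc = de.run_contrast(npx, clinical, ad_vs_hc, lfc=config.lfc, alpha=config.alpha)
        c1_vs_c2 = pd.Series(np.nan, index=npx.sample_ids)
        c1_vs_c2[labels == "C1"] = 1.0
        c1_vs_c2[labels == "C2"] = 0.0
        bundle.de_c1_vs_c2 = de.run_contrast(npx, clinical, c1_vs_c2, lfc=config.lfc, alpha=config.alpha)
        up_all = de.threshold_de(bundle.de_ad_vs_hc, config.lfc, config.alpha, "up")
        up_c1 = de.threshold_de(bundle.de_c1_vs_c2, config.lfc, config.alpha, "up")
        bundle.de_groups = de.venn_trichotomy(up_all, up_c1)

        stage = "wgcna"
        power, fit_table = wg.pick_soft_power(scaled.values, r2_target=config.r2_target)
        adjacency = wg.signed_adjacency(scaled.values, power)
        tom = wg.tom_similarity(adjacency)
        bundle.network = wg.NetworkModel(power=power, adjacency=adjacency, tom=tom, fit_table=fit_table)
        bundle.modules = wg.detect_modules(
            tom, scaled.values, min_module_size=config.min_module_size,
            cut_quantile=config.cut_quantile, merge_height=config.merge_height,
            kme_rescue=config.kme_rescue,
        )
        bundle.eigen = wg.module_eigenproteins(scaled.values, bundle.modules)
        if clinical is not None:
            trait_data = clinical.data.copy()
            trait_data["AD_HI"] = (labels == "C1").astype(float)
            trait_idx = patients if config.trait_samples == "ad" else npx.sample_ids
            bundle.module_trait = wg.module_trait_correlation(
                bundle.eigen, trait_data, samples=trait_idx
            )

        stage = "networks"
        for mod in bundle.modules.modules()[:3]:
            hub = bundle.eigen.hubs.get(mod)
            if hub is None:
                continue
            bundle.hub_networks[mod] = nw.hub_network(
                mod, bundle.modules, adjacency, bundle.de_groups, hub=hub, top_k=config.top_k
            )

        if config.run_enrichment and config.gmt_path:
            stage = "enrichment"
            sets = en.read_gmt(config.gmt_path)
            universe = set(npx.protein_ids)
            seed_en = _stage_seed(config.seed, "enrich")
            for mod in bundle.modules.modules():
                ranked = en.rank_by_me_correlation(npx.values, bundle.eigen.me[mod])
                bundle.enrichment[mod] = {
                    "gsea": en.gsea_preranked(ranked, sets, nperm=config.nperm, seed=seed_en),
                    "ora": en.hypergeometric_ora(
                        set(bundle.modules.members(mod)), sets, universe
                    ),
                }

        stage = "clinical"
        if clinical is not None:
            patient_labels = labels[patients]
            _, bundle.importance, bundle.oob_accuracy = cm.fit_rf_predictor(
                clinical.data.loc[patients], patient_labels,
                seed=_stage_seed(config.seed, "clinical"),
            )
            bundle.comparisons = cm.compare_groups(clinical.data.loc[patients], patient_labels)
    except Exception as exc:
        raise StageError(stage, exc, bundle) from exc

    if write_outputs:
        _write_bundle(bundle, config, truth)
    return bundle


def _write_bundle(bundle: ReportBundle, config: PipelineConfig, truth) -> None:
    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "graphs").mkdir(exist_ok=True)
    if bundle.qc:
        bundle.qc.write_tsv(out / "tables" / "qc_report.tsv")
    if bundle.scree is not None:
        bundle.scree.to_csv(out / "tables" / "scree.tsv", sep="\t", index=False)
    if bundle.cluster_patients:
        bundle.cluster_patients.assignments.to_csv(out / "tables" / "clusters.tsv", sep="\t")
    for name, res in (("ad_vs_hc", bundle.de_ad_vs_hc), ("c1_vs_c2", bundle.de_c1_vs_c2)):
        if res:
            res.table.to_csv(out / "tables" / f"de_{name}.tsv", sep="\t", index_label="protein")
    if bundle.modules is not None:
        pd.DataFrame({"module": bundle.modules.labels}).to_csv(
            out / "tables" / "modules.tsv", sep="\t", index_label="protein"
        )
    if bundle.module_trait is not None:
        bundle.module_trait.r.to_csv(out / "tables" / "module_trait_r.tsv", sep="\t")
        bundle.module_trait.p_adj.to_csv(out / "tables" / "module_trait_p_adj.tsv", sep="\t")
    if bundle.importance is not None:
        bundle.importance.table.to_csv(out / "tables" / "importance.tsv", sep="\t")
    if bundle.comparisons is not None and len(bundle.comparisons.table):
        bundle.comparisons.table.to_csv(out / "tables" / "comparisons.tsv", sep="\t")
    for mod, net in bundle.hub_networks.items():
        nw.export_graph(net, out / "graphs" / f"hub_{mod}.graphml")
    if truth is not None:
        truth.to_json(out / "truth.json")
    with open(out / "report.json", "w") as fh:
        json.dump(bundle.summary(), fh, indent=1, default=str)
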