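"""End-to-end orchestration: preprocess → differential → network enrichment.

:func:`run_full_analysis` executes the whole chain from a
:class:`PipelineConfig`, writing deterministic TSV artifacts for every stage
plus a JSON run report.  All stochastic stages draw sub-seeds from the single
top-level ``rng_seed`` via a seed sequence, so reruns with the same config
are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import DesignSpec, fit_differential_lmm, select_significant
from .feature_io import (
    AbundanceMatrix,
    FeatureTableError,
    filter_cv,
    filter_missingness,
    log2_transform,
    normalize_and_impute,
    read_feature_table,
)
from .network_enrichment import (
    FingerprintSet,
    PathwayDatabase,
    build_chemical_network,
    build_pathway_network,
    build_universe,
    enrich_clusters,
    extract_subnetwork,
    fuse_networks,
    louvain_partition,
    map_seeds,
    permutation_percentiles,
    random_walk_restart,
    write_edge_list,
)

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full run.

    Threshold defaults are the analysis constants: 50% missingness, CV 150,
    FDR 0.05, |log2FC| 0.75, chemical-similarity percentile 90, node
    percentile 97, 10,000 permutations, restart probability 0.7.
    """

    feature_table: str = ""
    sample_metadata: str = ""
    pathways_gmt: str = ""
    fingerprints: str = ""
    output_dir: str = "results/run"

    group_variable: str = "mdm2_status"
    reference_level: str = "low"
    comparison_level: str = "high"

    max_missing_frac: float = 0.5
    cv_threshold: float = 150.0
    fdr: float = 0.05
    min_abs_log2fc: float = 0.75
    chem_percentile: float = 90.0
    node_percentile: float = 97.0
    n_perm: int = 10000
    restart_prob: float = 0.7
    rng_seed: int = 17

    def validate(self) -> None:
        for name in ("feature_table", "sample_metadata", "pathways_gmt",
                     "fingerprints"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{name} not found: {path!r}")
        if not 0 < self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac out of range")
        for name, lo, hi in (("fdr", 0, 1), ("chem_percentile", 0, 100),
                             ("node_percentile", 0, 100)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} out of range: {v}")
        if not 0 < self.restart_prob <= 1:
            raise ValueError("restart_prob out of range")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    """Counts, manifest and configuration echo for one pipeline run."""

    config: dict
    version: str = __version__
    stage_counts: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    enriched_pathways: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def run_full_analysis(cfg: PipelineConfig) -> RunReport:
    """Run preprocess → differential → enrichment and write all artifacts."""
    cfg.validate()  # fail fast, before any compute
    t0 = time.perf_counter()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(cfg))
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(2)
    perm_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    louvain_seed = int(seeds[1].generate_state(1)[0] % (2 ** 31))

    try:
        # ---- preprocess ----
        m = read_feature_table(cfg.feature_table, cfg.sample_metadata,
                               scale="raw")
        report.stage_counts["features_read"] = m.n_features
        report.stage_counts["samples_read"] = m.n_samples
        m, miss_report = filter_missingness(m, cfg.max_missing_frac)
        m = normalize_and_impute(m, impute=False)
        m, cv_report = filter_cv(m, cfg.cv_threshold)
        from .feature_io import impute_minimum
        m = impute_minimum(m)
        m = log2_transform(m)
        report.stage_counts["removed_missingness"] = len(miss_report.removed)
        report.stage_counts["removed_cv"] = len(cv_report.removed)
        report.stage_counts["features_after_filters"] = m.n_features
        miss_report.to_tsv(out / "filter_missingness.tsv")
        cv_report.to_tsv(out / "filter_cv.tsv")
        report.manifest["filter_missingness"] = str(out / "filter_missingness.tsv")
        report.manifest["filter_cv"] = str(out / "filter_cv.tsv")

        # ---- differential ----
        design = DesignSpec(
            group_variable=cfg.group_variable,
            group_levels=(cfg.reference_level, cfg.comparison_level),
        )
        stats_table = fit_differential_lmm(m, design)
        stats_table = stats_table.join(
            m.features[["display_name", "superclass"]])
        _write_tsv(stats_table, out / "differential_stats.tsv")
        report.manifest["differential_stats"] = str(out / "differential_stats.tsv")
        volcano = stats_table[["log2fc"]].copy()
        with np.errstate(divide="ignore"):
            volcano["neg_log10_q"] = -np.log10(stats_table["q_value"])
        _write_tsv(volcano, out / "volcano.tsv")
        report.manifest["volcano"] = str(out / "volcano.tsv")
        selected = select_significant(stats_table, cfg.fdr, cfg.min_abs_log2fc)
        _write_tsv(selected, out / "selected_features.tsv")
        report.manifest["selected_features"] = str(out / "selected_features.tsv")
        report.stage_counts["selected_features"] = len(selected)

        # ---- network enrichment ----
        db = PathwayDatabase.from_gmt(cfg.pathways_gmt)
        fps = FingerprintSet.from_tsv(cfg.fingerprints)
        candidates = list(selected["display_name"])
        enrichment = network_enrichment_stage(
            candidates, db, fps,
            restart_prob=cfg.restart_prob,
            chem_percentile=cfg.chem_percentile,
            node_percentile=cfg.node_percentile,
            n_perm=cfg.n_perm, fdr=cfg.fdr,
            perm_seed=perm_seed, louvain_seed=louvain_seed,
        )
        for layer, net in enrichment["networks"].items():
            path = out / f"network_{layer}.tsv"
            write_edge_list(net, path)
            report.manifest[f"network_{layer}"] = str(path)
        scores = pd.DataFrame({
            "rwr_score": pd.Series(enrichment["propagation"].scores),
            "percentile": pd.Series(enrichment["permutation"].percentiles),
        })
        scores.index.name = "metabolite_id"
        _write_tsv(scores.sort_index(), out / "rwr_scores.tsv")
        report.manifest["rwr_scores"] = str(out / "rwr_scores.tsv")
        clusters = pd.DataFrame(
            sorted(enrichment["partition"].items()),
            columns=["metabolite_id", "cluster_id"])
        _write_tsv(clusters, out / "clusters.tsv", index=False)
        report.manifest["clusters"] = str(out / "clusters.tsv")
        _write_tsv(enrichment["enrichment"], out / "enrichment.tsv", index=False)
        report.manifest["enrichment"] = str(out / "enrichment.tsv")
        report.stage_counts["seeds_mapped"] = len(enrichment["seeds"].mapped)
        report.stage_counts["seeds_unmapped"] = len(enrichment["seeds"].unmapped)
        report.stage_counts["universe_size"] = len(enrichment["universe"])
        report.stage_counts["subnetwork_size"] = (
            enrichment["networks"]["subnetwork"].number_of_nodes())
        report.stage_counts["n_clusters"] = len(set(
            enrichment["partition"].values()))
        enr = enrichment["enrichment"]
        if len(enr):
            hits = enr[enr["enriched"]]
            report.enriched_pathways = {
                str(cid): sorted(sub["pathway_id"])
                for cid, sub in hits.groupby("cluster_id")
            }
    except Exception:
        (out / "FAILED").write_text("run failed; partial outputs retained\n")
        raise

    cfg.to_yaml(out / "config_echo.yaml")
    report.manifest["config_echo"] = str(out / "config_echo.yaml")
    report.wall_time_s = time.perf_counter() - t0
    report.to_json(out / "run_report.json")
    return report


def network_enrichment_stage(candidates, db: PathwayDatabase,
                             fps: FingerprintSet, *, restart_prob: float = 0.7,
                             chem_percentile: float = 90.0,
                             node_percentile: float = 97.0,
                             n_perm: int = 10000, fdr: float = 0.05,
                             perm_seed: int = 0, louvain_seed: int = 0) -> dict:
    """The full network-enrichment chain on a candidate metabolite list.

    Returns a dict with the seed set, universe, all network layers, the
    propagation and permutation results, the Louvain partition and the
    enrichment table.
    """
    seeds = map_seeds(candidates, db)
    pathway_ids, universe = build_universe(seeds, db)
    pathway_net = build_pathway_network(universe, db)
    chemical_net = build_chemical_network(universe, fps, chem_percentile)
    fused = fuse_networks(pathway_net, chemical_net)
    prop = random_walk_restart(fused, seeds.mapped, restart_prob)
    perms = permutation_percentiles(fused, prop, seed_size=len(seeds.mapped),
                                    n_perm=n_perm, rng_seed=perm_seed)
    sub = extract_subnetwork(fused, perms, seeds.mapped, node_percentile)
    partition = louvain_partition(sub, louvain_seed)
    enrichment = enrich_clusters(partition, db, universe, fdr)
    return {
        "seeds": seeds,
        "pathway_ids": pathway_ids,
        "universe": universe,
        "networks": {"pathway": pathway_net, "chemical": chemical_net,
                     "fused": fused, "subnetwork": sub},
        "propagation": prop,
        "permutation": perms,
        "partition": partition,
        "enrichment": enrichment,
    }


# ===================================================================== #
# QC
# ===================================================================== #

@dataclass
class QCSummary:
    """Sample-level quality summary: PCA, dendrogram, replicate agreement."""

    pca_coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    linkage: np.ndarray
    sample_order: list
    replicate_silhouette: float


def qc_summary(m: AbundanceMatrix) -> QCSummary:
    """PCA + hierarchical clustering of samples with a replicate-agreement score.

    Features are centered; PCA coordinates come from the SVD of the sample ×
    feature matrix; the dendrogram uses correlation distance with average
    linkage; the replicate-agreement score is the mean silhouette of
    replicate groups (cell line × treatment) under correlation distance.
    """
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist, squareform
    from sklearn.metrics import silhouette_score

    if m.scale != "log2":
        raise FeatureTableError("qc_summary expects log2 scale")
    if m.currently_missing().to_numpy().any():
        raise FeatureTableError("missing values present; impute before QC")
    x = m.values.to_numpy(dtype=float).T  # samples × features
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    coords = u * s
    n_pc = min(10, coords.shape[1])
    pca = pd.DataFrame(coords[:, :n_pc], index=m.values.columns,
                       columns=[f"PC{i + 1}" for i in range(n_pc)])
    evr = (s ** 2) / (s ** 2).sum()

    dist = pdist(x, metric="correlation")
    link = average(dist)
    order = [m.values.columns[i] for i in leaves_list(link)]
    labels = (m.samples["cell_line"].astype(str) + "|"
              + m.samples["treatment"].astype(str))
    sil = float("nan")
    if labels.nunique() > 1 and labels.duplicated().any():
        sil = float(silhouette_score(squareform(dist), labels,
                                     metric="precomputed"))
    return QCSummary(
        pca_coordinates=pca,
        explained_variance_ratio=evr,
        linkage=link,
        sample_order=order,
        replicate_silhouette=sil,
    )
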