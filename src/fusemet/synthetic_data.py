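"""Synthetic studies with planted ground truth.

The generators emulate the structure of a two-group cell-line study: six
patient-derived lines in two MDM2-amplification groups with three replicates
each, log2-scale group effects on a planted subset of features, cell-line
random intercepts, replicate noise, left-censored missingness, a block of
heavily missing features and a block of technically noisy (high-CV)
features, an overlapping pathway database with one planted module, and
chemical fingerprints whose similarity is elevated within pathways.

Every generator is a pure function of its configuration and ``rng_seed``, so
synthetic studies are bit-reproducible, and all outputs satisfy the type
invariants of the consuming modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_io import AbundanceMatrix, write_feature_table
from .network_enrichment import FingerprintSet, PathwayDatabase


@dataclass
class SyntheticStudyConfig:
    """Study-shape and noise parameters for the abundance generator.

    Dimensions default to the shape of the emulated study: 2 × 3 cell lines
    × 3 replicates, 480 clean features plus 33 heavily missing and 28
    high-CV features (541 total before filtering), 17 features with planted
    group effects of |log2FC| = 1.5.  ``sd_cellline`` and ``sd_noise`` are
    log2-scale standard deviations (0.25 ≈ 19% cell-line intercepts, 0.30 ≈
    23% replicate noise).  ``missing_mode`` is ``censor`` (left-censored,
    low-abundance entries preferentially missing) or ``mcar``.
    """

    n_cell_lines_per_group: int = 3
    n_replicates: int = 3
    n_features: int = 480
    n_differential: int = 17
    effect_log2: float = 1.5
    sd_cellline: float = 0.25
    sd_noise: float = 0.30
    missing_rate: float = 0.05
    missing_mode: str = "censor"
    n_high_missing_features: int = 33
    n_high_cv_features: int = 28
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_differential > self.n_features:
            raise ValueError("n_differential exceeds n_features")
        if self.sd_cellline <= 0 or self.sd_noise <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_mode not in ("censor", "mcar"):
            raise ValueError("missing_mode must be censor or mcar")
        if self.n_cell_lines_per_group < 1 or self.n_replicates < 2:
            raise ValueError("need ≥1 cell line per group and ≥2 replicates")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators."""

    differential_effects: dict = field(default_factory=dict)  # id -> signed log2 effect
    high_missing_ids: list = field(default_factory=list)
    high_cv_ids: list = field(default_factory=list)
    planted_pathway_id: str | None = None
    planted_module_members: list = field(default_factory=list)

    @property
    def differential_feature_ids(self) -> list:
        return list(self.differential_effects)


# ===================================================================== #
# abundance study
# ===================================================================== #

def simulate_abundance_study(cfg: SyntheticStudyConfig
                             ) -> tuple[AbundanceMatrix, PlantedTruth]:
    """Simulate a raw-scale abundance study with planted effects.

    Log2 abundances follow y = mu_f + beta_f*group + u_cellline + eps with
    u ~ N(0, sd_cellline²) and eps ~ N(0, sd_noise²); beta_f = ±effect_log2
    for the planted differential features and 0 otherwise.  Values are
    exponentiated to raw scale and multiplied by each sample's normalization
    factor (emulating protein-content differences).  Heavily missing and
    high-CV features are appended per the configuration.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    # ---- samples ----
    lines, status = [], []
    for grp, tag in (("high", "H"), ("low", "L")):
        for i in range(cfg.n_cell_lines_per_group):
            lines.append(f"CL{tag}{i + 1}")
            status.append(grp)
    sample_rows = []
    for line, grp in zip(lines, status):
        for rep in range(1, cfg.n_replicates + 1):
            sample_rows.append({
                "sample_id": f"{line}_r{rep}",
                "cell_line": line,
                "mdm2_status": grp,
                "treatment": "untreated",
                "replicate": rep,
                "ion_mode": "none",
                "normalization_factor": float(rng.uniform(0.8, 1.2)),
            })
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    n_samples = len(samples)
    group = (samples["mdm2_status"] == "high").to_numpy(dtype=float)
    line_idx = pd.Categorical(samples["cell_line"], categories=lines).codes

    # ---- clean features ----
    nf = cfg.n_features
    feature_ids = [f"F{i + 1:04d}" for i in range(nf)]
    diff_ids = list(rng.choice(feature_ids, size=cfg.n_differential,
                               replace=False))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_differential)
    beta = pd.Series(0.0, index=feature_ids)
    beta.loc[diff_ids] = signs * cfg.effect_log2

    mu = rng.uniform(4.0, 10.0, size=nf)
    u = rng.normal(0.0, cfg.sd_cellline, size=(nf, len(lines)))
    eps = rng.normal(0.0, cfg.sd_noise, size=(nf, n_samples))
    y = (mu[:, None] + np.outer(beta.to_numpy(), group)
         + u[:, line_idx] + eps)
    raw = (2.0 ** y) * samples["normalization_factor"].to_numpy()[None, :]

    # left-censored (or MCAR) missingness on clean features
    miss = np.zeros_like(raw, dtype=bool)
    if cfg.missing_rate > 0:
        if cfg.missing_mode == "mcar":
            prob = np.full_like(raw, cfg.missing_rate)
        else:
            order = np.argsort(np.argsort(y, axis=1), axis=1)  # within-feature rank
            weight = 2.0 * (n_samples - 1 - order) / (n_samples - 1)
            prob = np.clip(cfg.missing_rate * weight, 0.0, 1.0)
        miss = rng.random(raw.shape) < prob
    raw = np.where(miss, np.nan, raw)

    # ---- heavily missing features ----
    hm_ids = [f"HM{i + 1:04d}" for i in range(cfg.n_high_missing_features)]
    hm_raw = np.empty((len(hm_ids), n_samples))
    half = int(np.ceil(n_samples / 2))
    for i in range(len(hm_ids)):
        base = 2.0 ** rng.uniform(3.0, 6.0)
        hm_raw[i] = base * 2.0 ** rng.normal(0.0, cfg.sd_noise, size=n_samples)
        n_miss = int(rng.integers(half, min(n_samples, int(0.8 * n_samples)) + 1))
        cols = rng.choice(n_samples, size=n_miss, replace=False)
        hm_raw[i, cols] = np.nan

    # ---- high-CV features (one large spike per replicate group) ----
    hc_ids = [f"HC{i + 1:04d}" for i in range(cfg.n_high_cv_features)]
    hc_raw = np.empty((len(hc_ids), n_samples))
    groups_of = samples.groupby(["cell_line", "treatment"], sort=False)
    col_of = {s: j for j, s in enumerate(samples.index)}
    for i in range(len(hc_ids)):
        base = 2.0 ** rng.uniform(4.0, 8.0)
        hc_raw[i] = base * 2.0 ** rng.normal(0.0, cfg.sd_noise, size=n_samples)
        for _, members in groups_of.groups.items():
            spike_col = col_of[members[int(rng.integers(len(members)))]]
            hc_raw[i, spike_col] *= rng.uniform(500.0, 1500.0)

    all_ids = feature_ids + hm_ids + hc_ids
    values = pd.DataFrame(
        np.vstack([raw, hm_raw, hc_raw]), index=pd.Index(all_ids, name="feature_id"),
        columns=samples.index,
    )
    features = pd.DataFrame(
        {
            "display_name": all_ids,
            "superclass": "synthetic",
            "adduct": None,
            "ion_mode": "none",
            "ms_level_identified": None,
        },
        index=values.index,
    )
    matrix = AbundanceMatrix(
        values=values, missing_mask=values.isna(), features=features,
        samples=samples, scale="raw",
    )
    truth = PlantedTruth(
        differential_effects={fid: float(b) for fid, b in
                              beta.loc[diff_ids].items()},
        high_missing_ids=hm_ids,
        high_cv_ids=hc_ids,
    )
    return matrix, truth


# ===================================================================== #
# pathway database and fingerprints
# ===================================================================== #

def simulate_pathway_db(n_pathways: int = 20, size_range: tuple = (8, 15),
                        overlap_frac: float = 0.2, planted_seed_ids=(),
                        rng_seed: int = 0
                        ) -> tuple[PathwayDatabase, PlantedTruth]:
    """Overlapping pathway database with one planted module.

    Pathway sizes are uniform in ``size_range``; a fraction ``overlap_frac``
    of each pathway's members is drawn from the pool of metabolites already
    used by earlier pathways (so metabolites carry multiple annotations, as
    in curated pathway databases), the rest are fresh metabolites.  The
    planted pathway contains every id in ``planted_seed_ids``.
    """
    if size_range[0] < 3:
        raise ValueError("minimum pathway size is 3")
    rng = np.random.default_rng(rng_seed)
    planted_seed_ids = list(planted_seed_ids)
    counter = 0

    def fresh(k):
        nonlocal counter
        out = [f"MET{counter + j + 1:04d}" for j in range(k)]
        counter += k
        return out

    pathways, names = {}, {}
    planted_id = "PW00_planted"
    size = int(rng.integers(size_range[0], size_range[1] + 1))
    if len(planted_seed_ids) > size:
        size = max(size, len(planted_seed_ids))
        if size > size_range[1]:
            raise ValueError("planted seeds exceed planted pathway size")
    members = planted_seed_ids + fresh(size - len(planted_seed_ids))
    pathways[planted_id] = set(members)
    names[planted_id] = "planted module"
    pool = list(members)
    for p in range(1, n_pathways):
        pid = f"PW{p:02d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        n_shared = min(int(round(overlap_frac * size)), len(pool))
        shared = list(rng.choice(pool, size=n_shared, replace=False))
        members = shared + fresh(size - n_shared)
        pathways[pid] = set(members)
        names[pid] = f"synthetic pathway {p}"
        pool.extend(m for m in members if m not in pool)
    db = PathwayDatabase(pathways=pathways, names=names)
    truth = PlantedTruth(
        planted_pathway_id=planted_id,
        planted_module_members=sorted(pathways[planted_id]),
    )
    return db, truth


def simulate_fingerprints(db: PathwayDatabase, length: int = 256,
                          within_noise: float = 0.1, rng_seed: int = 0
                          ) -> FingerprintSet:
    """Fingerprints with elevated similarity within pathways.

    Each pathway gets a random template bitvector; members inherit the
    template of their first (lexicographic) pathway with per-bit flip
    probability ``within_noise``.
    """
    if length < 64:
        raise ValueError("fingerprint length must be ≥ 64")
    if not 0 <= within_noise < 0.5:
        raise ValueError("within_noise must be in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    templates = {pid: (rng.random(length) < 0.3).astype(np.uint8)
                 for pid in sorted(db.pathways)}
    bits = {}
    for mid in sorted(db.annotations):
        pid = sorted(db.annotations[mid])[0]
        flips = rng.random(length) < within_noise
        vec = templates[pid] ^ flips.astype(np.uint8)
        if vec.sum() == 0:
            vec[int(rng.integers(length))] = 1
        bits[mid] = vec
    return FingerprintSet(length=length, bits=bits)


# ===================================================================== #
# dose-response
# ===================================================================== #

def simulate_dose_response(m: float, Dm: float, doses, noise_sd: float = 0.0,
                           rng_seed: int = 0, drug: str = "drug"):
    """Dose-response from the median-effect curve fa = 1/(1+(Dm/D)^m).

    Optional Gaussian noise is added on the logit scale and the result is
    kept strictly inside (0, 1).
    """
    from .drug_combination import DoseResponse

    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any() or Dm <= 0:
        raise ValueError("doses and Dm must be positive")
    rng = np.random.default_rng(rng_seed)
    logit = m * (np.log10(doses) - np.log10(Dm))
    if noise_sd > 0:
        logit = logit + rng.normal(0.0, noise_sd, size=doses.shape)
    fa = 1.0 / (1.0 + 10.0 ** (-logit))
    fa = np.clip(fa, 1e-9, 1 - 1e-9)
    return DoseResponse(drug=drug, doses=doses, fraction_affected=fa)


# ===================================================================== #
# file emission
# ===================================================================== #

def write_study(outdir, matrix: AbundanceMatrix, db: PathwayDatabase = None,
                fps: FingerprintSet = None) -> dict:
    """Write a synthetic study in the pipeline's input formats.

    Returns a manifest of the written paths (feature table, sample metadata,
    optional GMT and fingerprint TSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "feature_table": str(outdir / "features.tsv"),
        "sample_metadata": str(outdir / "samples.tsv"),
    }
    write_feature_table(matrix, manifest["feature_table"],
                        manifest["sample_metadata"])
    if db is not None:
        manifest["pathways_gmt"] = str(outdir / "pathways.gmt")
        db.to_gmt(manifest["pathways_gmt"])
    if fps is not None:
        manifest["fingerprints"] = str(outdir / "fingerprints.tsv")
        fps.to_tsv(manifest["fingerprints"])
    return manifest
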