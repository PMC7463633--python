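"""Feature-table I/O and preprocessing for metabolomic/lipidomic studies.

The central container is :class:`AbundanceMatrix`: a features × samples table
of abundances with explicit missingness, sample metadata (cell line, MDM2
amplification status, treatment, replicate, ionization mode) and feature
metadata (identification, adduct, MS identification level).

Preprocessing mirrors a standard targeted-MS workflow:

* missingness filter (features missing in ≥ 50% of samples are dropped),
* coefficient-of-variation filter (features whose within-replicate-group CV
  exceeds 150 are dropped as technical artifacts),
* per-sample normalization (protein concentration), per-feature median
  scaling, imputation of remaining missing values to the feature minimum,
* per-ionization-mode total-ion-current normalization and log2 transform,
* merging of positive/negative ionization mode tables into one row per
  identified lipid with adduct-preference rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("raw", "normalized", "log2")
MDM2_LEVELS = ("high", "low")
ION_MODES = ("positive", "negative", "none")

#: default tokens recognised as missing values on read (case-insensitive)
NA_TOKENS = ("", "na", "nan")

#: columns of a feature table that are feature metadata, not samples
FEATURE_META_COLUMNS = (
    "display_name",
    "superclass",
    "adduct",
    "ion_mode",
    "ms_level_identified",
)

SAMPLE_META_COLUMNS = (
    "cell_line",
    "mdm2_status",
    "treatment",
    "replicate",
    "ion_mode",
    "normalization_factor",
)


class FeatureTableError(ValueError):
    """Raised for malformed feature tables or invalid preprocessing state."""


@dataclass
class AbundanceMatrix:
    """Features × samples abundance table with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by ``feature_id`` with one column per ``sample_id``.
        Currently-missing entries are ``NaN``.
    missing_mask
        Boolean DataFrame of the same shape marking entries that were missing
        in the *original* data.  Imputation fills ``values`` but leaves the
        mask untouched, so provenance is never lost.
    features
        Feature metadata indexed by ``feature_id`` (``display_name``,
        ``superclass``, ``adduct``, ``ion_mode``, ``ms_level_identified``).
    samples
        Sample metadata indexed by ``sample_id`` (``cell_line``,
        ``mdm2_status``, ``treatment``, ``replicate``, ``ion_mode``,
        ``normalization_factor``).
    scale
        One of ``raw``, ``normalized``, ``log2``.  Raw/normalized values must
        be nonnegative.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if self.scale not in SCALES:
            raise FeatureTableError(f"unknown scale {self.scale!r}")
        if self.values.shape != self.missing_mask.shape:
            raise FeatureTableError("values and missing_mask shapes differ")
        if not self.values.index.equals(self.missing_mask.index) or not (
            self.values.columns.equals(self.missing_mask.columns)
        ):
            raise FeatureTableError("values and missing_mask not aligned")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FeatureTableError(f"duplicate feature id: {list(dupes)}")
        if self.values.columns.has_duplicates:
            raise FeatureTableError("duplicate sample ids")
        if not self.values.index.equals(self.features.index):
            raise FeatureTableError("feature metadata does not match matrix rows")
        if not self.values.columns.equals(self.samples.index):
            raise FeatureTableError("sample metadata does not match matrix columns")
        if self.scale in ("raw", "normalized"):
            if (self.values.to_numpy() < 0).any():
                raise FeatureTableError(f"negative values at scale {self.scale!r}")
        bad = set(self.samples["mdm2_status"]) - set(MDM2_LEVELS)
        if bad:
            raise FeatureTableError(f"unknown mdm2_status levels {bad}")
        # MDM2 status is a property of the cell line
        per_line = self.samples.groupby("cell_line")["mdm2_status"].nunique()
        if (per_line > 1).any():
            raise FeatureTableError("mdm2_status varies within a cell line")

    # ------------------------------------------------------------------ #
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def currently_missing(self) -> pd.DataFrame:
        """Boolean mask of entries missing *now* (NaN in ``values``)."""
        return self.values.isna()

    def subset_features(self, feature_ids) -> "AbundanceMatrix":
        idx = pd.Index(feature_ids)
        return AbundanceMatrix(
            values=self.values.loc[idx],
            missing_mask=self.missing_mask.loc[idx],
            features=self.features.loc[idx],
            samples=self.samples,
            scale=self.scale,
        )

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        idx = pd.Index(sample_ids)
        return AbundanceMatrix(
            values=self.values[idx],
            missing_mask=self.missing_mask[idx],
            features=self.features,
            samples=self.samples.loc[idx],
            scale=self.scale,
        )


@dataclass
class FilterReport:
    """Record of features removed by a filter, with the statistic that did it."""

    reason: str
    threshold: float
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)
    # removed: DataFrame indexed by feature_id with columns reason, statistic,
    # threshold; deterministic input row order.

    @property
    def removed_feature_ids(self) -> list:
        return list(self.removed.index)

    def to_tsv(self, path) -> None:
        out = self.removed.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.17g")


def _empty_report(reason: str, threshold: float) -> pd.DataFrame:
    return pd.DataFrame(
        {"reason": pd.Series(dtype=str),
         "statistic": pd.Series(dtype=float),
         "threshold": pd.Series(dtype=float)}
    )


# ===================================================================== #
# reading / writing
# ===================================================================== #

def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(path, metadata_path, scale: str = "raw",
                       na_tokens=NA_TOKENS) -> AbundanceMatrix:
    """Read a feature table (rows = features) plus its sample-metadata TSV.

    The first column of the table is ``feature_id``; columns whose names are
    in :data:`FEATURE_META_COLUMNS` are feature metadata; every other column
    is a sample and must have a row in the metadata file.  Cells equal to one
    of ``na_tokens`` (case-insensitive) are flagged missing; any other
    non-numeric cell is a hard error.
    """
    na_set = {t.lower() for t in na_tokens}
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if raw.columns[0] != "feature_id":
        raw = raw.rename(columns={raw.columns[0]: "feature_id"})
    if raw["feature_id"].duplicated().any():
        dupes = raw.loc[raw["feature_id"].duplicated(), "feature_id"].tolist()
        raise FeatureTableError(f"duplicate feature id: {dupes}")
    raw = raw.set_index("feature_id")

    meta_cols = [c for c in raw.columns if c in FEATURE_META_COLUMNS]
    sample_cols = [c for c in raw.columns if c not in FEATURE_META_COLUMNS]

    samples = pd.read_csv(metadata_path, sep=_sep_for(metadata_path))
    if "sample_id" not in samples.columns:
        raise FeatureTableError("sample metadata must have a sample_id column")
    samples = samples.set_index("sample_id")
    missing_meta = [c for c in sample_cols if c not in samples.index]
    if missing_meta:
        raise FeatureTableError(f"sample column without metadata: {missing_meta}")
    samples = samples.loc[sample_cols]
    if "normalization_factor" not in samples.columns:
        samples["normalization_factor"] = np.nan
    if "ion_mode" not in samples.columns:
        samples["ion_mode"] = "none"

    def parse_cell(cell: str, feature: str, column: str) -> float:
        if cell.strip().lower() in na_set:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise FeatureTableError(
                f"non-numeric cell {cell!r} at feature {feature!r}, "
                f"sample {column!r}"
            ) from None

    values = pd.DataFrame(
        {c: [parse_cell(v, f, c) for f, v in raw[c].items()] for c in sample_cols},
        index=raw.index, dtype=float,
    )

    features = pd.DataFrame(index=raw.index)
    for c in FEATURE_META_COLUMNS:
        if c in meta_cols:
            features[c] = raw[c].replace({t: None for t in ("", "NA", "NaN")})
        else:
            features[c] = None
    if features["ms_level_identified"].notna().any():
        lvl = pd.to_numeric(features["ms_level_identified"], errors="coerce")
        bad = lvl.dropna()[~lvl.dropna().isin([1, 2])]
        if len(bad):
            raise FeatureTableError(f"ms_level_identified must be 1 or 2: {dict(bad)}")
        features["ms_level_identified"] = lvl
    if features["display_name"].isna().all():
        features["display_name"] = features.index

    return AbundanceMatrix(
        values=values,
        missing_mask=values.isna(),
        features=features,
        samples=samples,
        scale=scale,
    )


def write_feature_table(m: AbundanceMatrix, path, metadata_path) -> None:
    """Write a feature table + sample metadata that round-trip bit-exactly."""
    sep = _sep_for(path)
    out = m.features.copy()
    vals = m.values.copy()
    # repr round-trips float64 exactly
    cells = vals.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    table = pd.concat([out, cells], axis=1)
    table.index.name = "feature_id"
    table.to_csv(path, sep=sep, na_rep="")
    meta = m.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep=_sep_for(metadata_path), float_format="%.17g")


# ===================================================================== #
# filters
# ===================================================================== #

def filter_missingness(m: AbundanceMatrix, max_missing_frac: float = 0.5
                       ) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop features missing in at least ``max_missing_frac`` of samples.

    The boundary is inclusive: a feature missing in exactly half the samples
    is removed.
    """
    if m.n_features == 0 or m.n_samples == 0:
        raise FeatureTableError("cannot filter an empty matrix")
    if not 0 < max_missing_frac <= 1:
        raise FeatureTableError("max_missing_frac must be in (0, 1]")
    if m.scale not in ("raw", "normalized"):
        raise FeatureTableError("missingness filter applies before log transform")
    frac = m.currently_missing().mean(axis=1)
    removed_ids = frac.index[frac >= max_missing_frac]
    report = FilterReport(
        reason="missingness",
        threshold=max_missing_frac,
        removed=pd.DataFrame(
            {
                "reason": "missingness",
                "statistic": frac.loc[removed_ids],
                "threshold": max_missing_frac,
            },
            index=removed_ids,
        ),
    )
    kept = frac.index[frac < max_missing_frac]
    return m.subset_features(kept), report


def _replicate_groups(samples: pd.DataFrame):
    return samples.groupby(["cell_line", "treatment"], sort=False).groups


def filter_cv(m: AbundanceMatrix, cv_threshold: float = 150.0
              ) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop features with extreme within-replicate-group variability.

    CV = 100 · sd / mean is computed per feature within each replicate group
    (samples sharing cell line and treatment), over observed values only; a
    feature is removed when its *maximum* group CV strictly exceeds the
    threshold.  A group with zero mean but nonzero signal counts as infinite
    CV.  Groups with fewer than two observed values are skipped.
    """
    if m.n_features == 0:
        raise FeatureTableError("cannot filter an empty matrix")
    if m.scale not in ("raw", "normalized"):
        raise FeatureTableError("CV filter applies before log transform")
    vals = m.values.to_numpy(dtype=float)
    max_cv = np.full(m.n_features, -np.inf)
    for _, sample_ids in _replicate_groups(m.samples).items():
        cols = m.values.columns.get_indexer(sample_ids)
        sub = vals[:, cols]
        obs = ~np.isnan(sub)
        n = obs.sum(axis=1)
        filled = np.where(obs, sub, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = filled.sum(axis=1) / n
            ssd = (np.where(obs, (sub - mean[:, None]) ** 2, 0.0)).sum(axis=1)
            sd = np.sqrt(ssd / (n - 1))
            cv = 100.0 * sd / mean
        ok = n >= 2
        cv[ok & (mean == 0)] = np.inf  # no signal in the group
        cv[~ok] = np.nan
        max_cv = np.fmax(max_cv, np.where(np.isnan(cv), -np.inf, cv))
    stat = pd.Series(max_cv, index=m.values.index)
    removed_ids = stat.index[stat > cv_threshold]
    n_inf = int(np.isinf(stat.loc[removed_ids]).sum())
    if n_inf:
        logger.warning("%d features removed with zero-mean groups (infinite CV)", n_inf)
    report = FilterReport(
        reason="cv",
        threshold=cv_threshold,
        removed=pd.DataFrame(
            {"reason": "cv", "statistic": stat.loc[removed_ids],
             "threshold": cv_threshold},
            index=removed_ids,
        ),
    )
    kept = stat.index[~(stat > cv_threshold)]
    return m.subset_features(kept), report


# ===================================================================== #
# normalization
# ===================================================================== #

def normalize_and_impute(m: AbundanceMatrix, impute: bool = True
                         ) -> AbundanceMatrix:
    """Sample normalization, per-feature median scaling, minimum imputation.

    In order: each sample column is divided by its ``normalization_factor``
    (e.g. Bradford protein concentration; skipped with a warning when factors
    are absent); each feature is rescaled so its across-sample median of
    observed values equals 1; each remaining missing entry is replaced by the
    feature's observed minimum.  The original missing mask is preserved.
    ``impute=False`` defers the imputation step (see :func:`impute_minimum`),
    so that variability filters can still exclude missing entries.
    """
    if m.scale != "raw":
        raise FeatureTableError("normalize_and_impute expects raw scale")
    vals = m.values.copy()
    factors = m.samples["normalization_factor"]
    if factors.isna().any():
        logger.warning("normalization_factor absent for some samples; "
                       "sample normalization skipped")
    else:
        if (factors <= 0).any():
            raise FeatureTableError("normalization factors must be positive")
        vals = vals.div(factors, axis=1)
    medians = vals.median(axis=1, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise FeatureTableError(f"feature missing in all samples: {bad}")
    if (medians == 0).any():
        bad = list(medians.index[medians == 0])
        raise FeatureTableError(f"feature with zero median cannot be scaled: {bad}")
    vals = vals.div(medians, axis=0)
    out = AbundanceMatrix(
        values=vals,
        missing_mask=m.missing_mask,
        features=m.features,
        samples=m.samples,
        scale="normalized",
    )
    return impute_minimum(out) if impute else out


def impute_minimum(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace missing entries by the feature's observed minimum.

    The missing mask is preserved as provenance.  A feature missing in every
    sample is an error (it should have been filtered).
    """
    vals = m.values.copy()
    mins = vals.min(axis=1, skipna=True)
    if mins.isna().any():
        bad = list(mins.index[mins.isna()])
        raise FeatureTableError(f"feature missing in all samples: {bad}")
    arr = vals.to_numpy()
    nan = np.isnan(arr)
    arr[nan] = np.broadcast_to(mins.to_numpy()[:, None], arr.shape)[nan]
    vals = pd.DataFrame(arr, index=vals.index, columns=vals.columns)
    return AbundanceMatrix(
        values=vals,
        missing_mask=m.missing_mask,
        features=m.features,
        samples=m.samples,
        scale=m.scale,
    )


def tic_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Total-ion-current normalization, each ionization mode independently.

    Every sample column is divided by its column sum and multiplied by the
    median column sum of its mode, so within-mode column sums are equal while
    magnitudes stay interpretable.
    """
    if m.scale != "raw":
        raise FeatureTableError("tic_normalize expects raw scale")
    modes = m.samples["ion_mode"]
    if not set(modes) <= {"positive", "negative"}:
        raise FeatureTableError("every sample needs ion_mode positive or negative")
    vals = m.values.copy()
    for mode in sorted(set(modes)):
        cols = modes.index[modes == mode]
        tic = vals[cols].sum(axis=0, skipna=True)
        zero = tic.index[tic == 0]
        if len(zero):
            raise FeatureTableError(f"sample with zero total signal: {list(zero)}")
        vals[cols] = vals[cols].div(tic, axis=1) * tic.median()
    return AbundanceMatrix(
        values=vals, missing_mask=m.missing_mask, features=m.features,
        samples=m.samples, scale="normalized",
    )


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform normalized abundances; refuses nonpositive values."""
    if m.scale != "normalized":
        raise FeatureTableError("log2_transform expects normalized scale")
    arr = m.values.to_numpy(dtype=float)
    if arr.size and not np.isnan(arr).all() and np.nanmin(arr) <= 0:
        raise FeatureTableError("non-positive abundance; impute or filter first")
    return AbundanceMatrix(
        values=np.log2(m.values),
        missing_mask=m.missing_mask,
        features=m.features,
        samples=m.samples,
        scale="log2",
    )


# ===================================================================== #
# ion-mode merging
# ===================================================================== #

def _is_sodium(adduct) -> bool:
    return adduct is not None and not pd.isna(adduct) and "Na" in str(adduct)


def merge_ion_modes(pos: AbundanceMatrix, neg: AbundanceMatrix) -> AbundanceMatrix:
    """Merge positive- and negative-mode tables into one row per lipid.

    Rules, applied in order: only MS2-identified features are kept; within a
    mode, a sodium adduct is used only when no other adduct carries the same
    identification, and duplicate identifications collapse to the highest
    mean abundance; identifications present in both modes keep the
    negative-mode adduct.  Samples are aligned on (cell_line, treatment,
    replicate).
    """
    if pos.scale != "log2" or neg.scale != "log2":
        raise FeatureTableError("merge_ion_modes expects log2 scale")

    def sample_key(samples: pd.DataFrame) -> pd.Series:
        return (samples["cell_line"].astype(str) + "|"
                + samples["treatment"].astype(str) + "|r"
                + samples["replicate"].astype(str))

    pos_key, neg_key = sample_key(pos.samples), sample_key(neg.samples)
    if set(pos_key) != set(neg_key) or pos_key.duplicated().any() or (
            neg_key.duplicated().any()):
        raise FeatureTableError(
            "positive/negative sample sets not alignable by "
            "(cell_line, treatment, replicate)")
    keys = sorted(pos_key)

    def candidates(m: AbundanceMatrix, mode: str, key: pd.Series) -> pd.DataFrame:
        feats = m.features
        ms2 = feats.index[pd.to_numeric(feats["ms_level_identified"],
                                        errors="coerce") == 2]
        rows = []
        for fid in ms2:
            vals = m.values.loc[fid]
            vals.index = key.loc[vals.index]
            rows.append({
                "feature_id": fid,
                "identification": feats.loc[fid, "display_name"],
                "adduct": feats.loc[fid, "adduct"],
                "superclass": feats.loc[fid, "superclass"],
                "mode": mode,
                "mean_abundance": vals.mean(skipna=True),
                "values": vals.reindex(keys),
            })
        return pd.DataFrame(rows)

    cand = pd.concat(
        [candidates(pos, "positive", pos_key), candidates(neg, "negative", neg_key)],
        ignore_index=True,
    )
    if cand.empty:
        raise FeatureTableError("no MS2-identified features to merge")

    kept = []
    for ident, grp in cand.groupby("identification", sort=False):
        # per-mode collapse with sodium as last resort
        per_mode = {}
        for mode, sub in grp.groupby("mode", sort=False):
            non_na = sub[~sub["adduct"].map(_is_sodium)]
            pool = non_na if len(non_na) else sub
            per_mode[mode] = pool.loc[pool["mean_abundance"].idxmax()]
        # cross-mode: sodium only if no other adduct anywhere for this lipid
        chosen = per_mode.get("negative", per_mode.get("positive"))
        if _is_sodium(chosen["adduct"]):
            alt = [r for r in per_mode.values() if not _is_sodium(r["adduct"])]
            if alt:
                chosen = alt[0]
        kept.append(chosen)

    features = pd.DataFrame(
        {
            "display_name": [r["identification"] for r in kept],
            "superclass": [r["superclass"] for r in kept],
            "adduct": [r["adduct"] for r in kept],
            "ion_mode": [r["mode"] for r in kept],
            "ms_level_identified": 2,
            "source_feature_id": [r["feature_id"] for r in kept],
        },
        index=pd.Index([r["identification"] for r in kept], name="feature_id"),
    )
    values = pd.DataFrame(
        [r["values"].to_numpy() for r in kept],
        index=features.index, columns=keys, dtype=float,
    )

    tmpl = pos.samples.copy()
    tmpl.index = pos_key
    tmpl = tmpl.loc[keys]
    samples = pd.DataFrame(
        {
            "cell_line": tmpl["cell_line"],
            "mdm2_status": tmpl["mdm2_status"],
            "treatment": tmpl["treatment"],
            "replicate": tmpl["replicate"],
            "ion_mode": "none",
            "normalization_factor": np.nan,
        },
        index=pd.Index(keys, name="sample_id"),
    )
    merged = AbundanceMatrix(
        values=values,
        missing_mask=values.isna(),
        features=features,
        samples=samples,
        scale="log2",
    )
    return merged
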