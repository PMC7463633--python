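"""Per-feature mixed-model differential abundance.

Each feature's log2 abundance is modelled as

    y = beta0 + beta1 * group + u_cellline + eps,
    u ~ N(0, sigma_u^2),  eps ~ N(0, sigma^2),

with the cell line of origin as a random intercept, fitted by restricted
maximum likelihood.  ``beta1`` is the log2 fold change (comparison minus
reference) and its Wald z test gives the p-value.  P-values are corrected by
Benjamini-Hochberg, and features are called significant when q < 0.05 and
|log2FC| > 0.75.

For the common balanced complete design (every cell line with the same number
of replicates, group constant within cell line, no missing values) the REML
estimates have an exact closed form via the between/within cell-line mean
squares, which this module vectorizes across all features; any other design
falls back to a per-feature ``statsmodels`` MixedLM fit.  When the
random-intercept variance estimate degenerates to zero (or a fit fails), the
feature is refitted by ordinary least squares and marked ``fallback_fixed``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_io import AbundanceMatrix

logger = logging.getLogger(__name__)

STAT_COLUMNS = ["log2fc", "se", "p_value", "q_value", "direction", "model_note"]


@dataclass
class DesignSpec:
    """Two-group comparison with a random grouping factor.

    ``group_levels`` is ``(reference, comparison)``; log2FC is comparison
    minus reference.  ``subset`` optionally restricts samples first (callable
    on the sample-metadata frame returning a boolean mask).
    """

    group_variable: str = "mdm2_status"
    group_levels: tuple[str, str] = ("low", "high")
    random_grouping: str = "cell_line"
    subset: Optional[Callable[[pd.DataFrame], pd.Series]] = None

    def design_frame(self, samples: pd.DataFrame) -> pd.DataFrame:
        sub = samples
        if self.subset is not None:
            sub = samples[self.subset(samples).astype(bool)]
        sub = sub[sub[self.group_variable].isin(self.group_levels)]
        ref, comp = self.group_levels
        for level in (ref, comp):
            if (sub[self.group_variable] == level).sum() < 2:
                raise ValueError(f"group level absent or <2 samples: {level!r}")
        if sub[self.random_grouping].nunique() < 2:
            raise ValueError("random grouping needs at least 2 levels")
        out = pd.DataFrame(index=sub.index)
        out["group"] = (sub[self.group_variable] == comp).astype(float)
        out["cluster"] = sub[self.random_grouping].astype(str)
        return out


# --------------------------------------------------------------------- #
# closed-form REML for the balanced one-way random-intercept design
# --------------------------------------------------------------------- #

def _is_balanced(design: pd.DataFrame, y: np.ndarray) -> bool:
    if np.isnan(y).any():
        return False
    counts = design.groupby("cluster", sort=False)["group"].agg(
        ["size", "nunique", "first"])
    return (
        counts["size"].nunique() == 1
        and (counts["nunique"] == 1).all()
        and counts["size"].iloc[0] >= 2
        and len(counts) >= 3
        and counts["first"].nunique() == 2
    )


def _fit_balanced(y: np.ndarray, design: pd.DataFrame) -> pd.DataFrame:
    """Vectorized exact REML for a features × samples block (balanced design).

    ``y`` is (n_features, n_samples).  Returns log2fc, se, p, model_note.
    """
    clusters = design["cluster"].to_numpy()
    group = design["group"].to_numpy()
    uniq, cl_idx = np.unique(clusters, return_inverse=True)
    n_lines = len(uniq)
    r = len(clusters) // n_lines
    line_group = np.array(
        [group[cl_idx == i][0] for i in range(n_lines)])
    n1 = int((line_group == 0).sum())
    n2 = int((line_group == 1).sum())
    if min(n1, n2) < 1 or n_lines < 3:
        raise ValueError("balanced fit needs cell lines in both groups")

    nf, ns = y.shape
    # cell-line means per feature
    line_sums = np.zeros((nf, n_lines))
    for i in range(n_lines):
        line_sums[:, i] = y[:, cl_idx == i].sum(axis=1)
    line_means = line_sums / r

    beta1 = line_means[:, line_group == 1].mean(axis=1) - (
        line_means[:, line_group == 0].mean(axis=1))

    # within-line mean square (residual), df = N - n_lines
    fitted_within = line_means[:, cl_idx]
    ssw = ((y - fitted_within) ** 2).sum(axis=1)
    df_w = ns - n_lines
    msw = ssw / df_w
    # between-line (within group) mean square, df = n_lines - 2
    gmean = np.zeros((nf, n_lines))
    gmean[:, line_group == 0] = line_means[:, line_group == 0].mean(
        axis=1, keepdims=True)
    gmean[:, line_group == 1] = line_means[:, line_group == 1].mean(
        axis=1, keepdims=True)
    ssb = (r * (line_means - gmean) ** 2).sum(axis=1)
    df_b = n_lines - 2
    msb = ssb / df_b

    sigma_u2 = (msb - msw) / r
    mixed = sigma_u2 > 0

    se = np.empty(nf)
    # mixed: var(beta1) = (sigma_u^2 + sigma^2/r) * (1/n1 + 1/n2) = MSB/r * (...)
    se[mixed] = np.sqrt(msb[mixed] / r * (1.0 / n1 + 1.0 / n2))
    # degenerate: OLS on all observations
    if (~mixed).any():
        x = group
        xbar = x.mean()
        sxx = ((x - xbar) ** 2).sum()
        resid = y[~mixed] - y[~mixed].mean(axis=1, keepdims=True) - (
            np.outer(beta1[~mixed], x - xbar))
        sse = (resid ** 2).sum(axis=1)
        s2 = sse / (ns - 2)
        se[~mixed] = np.sqrt(s2 / sxx)

    out = pd.DataFrame({
        "log2fc": beta1,
        "se": se,
        "model_note": np.where(mixed, "mixed", "fallback_fixed"),
    })
    zero_var = (y.std(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = out["log2fc"] / out["se"]
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[zero_var] = 1.0
    out.loc[zero_var, "se"] = np.nan
    out["p_value"] = p
    return out


def _fit_mixedlm_single(y: np.ndarray, design: pd.DataFrame) -> dict:
    import statsmodels.api as sm

    ok = ~np.isnan(y)
    yy = y[ok]
    dd = design[ok]
    if np.nanstd(yy) == 0:
        return {"log2fc": 0.0, "se": np.nan, "p_value": 1.0,
                "model_note": "fallback_fixed"}
    exog = np.column_stack([np.ones(len(yy)), dd["group"].to_numpy()])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(yy, exog, groups=dd["cluster"].to_numpy())
            res = model.fit(reml=True)
        sigma_u2 = float(np.asarray(res.cov_re).ravel()[0])
        if not np.isfinite(res.bse[1]) or sigma_u2 <= 1e-10:
            raise ValueError("degenerate random effect")
        return {"log2fc": float(res.params[1]), "se": float(res.bse[1]),
                "p_value": float(res.pvalues[1]), "model_note": "mixed"}
    except Exception:
        slope, _, _, p, se = stats.linregress(dd["group"].to_numpy(), yy)
        return {"log2fc": float(slope), "se": float(se), "p_value": float(p),
                "model_note": "fallback_fixed"}


# --------------------------------------------------------------------- #

def fit_differential_lmm(m: AbundanceMatrix, design: DesignSpec) -> pd.DataFrame:
    """Fit the per-feature mixed model and return a FeatureStats table.

    Returns a DataFrame indexed by feature_id with columns log2fc, se,
    p_value, q_value (BH across all fitted features), direction, model_note.
    """
    if m.scale != "log2":
        raise ValueError("differential analysis expects log2 scale")
    dframe = design.design_frame(m.samples)
    y = m.values[dframe.index].to_numpy(dtype=float)

    if _is_balanced(dframe, y):
        out = _fit_balanced(y, dframe)
        out.index = m.values.index
    else:
        rows = [_fit_mixedlm_single(y[i], dframe) for i in range(y.shape[0])]
        out = pd.DataFrame(rows, index=m.values.index)

    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out.index.name = "feature_id"
    return out[STAT_COLUMNS]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant(stats_table: pd.DataFrame, fdr: float = 0.05,
                       min_abs_log2fc: float = 0.75) -> pd.DataFrame:
    """Apply the significance rule: q < fdr and |log2FC| > min_abs_log2fc."""
    sel = stats_table[
        (stats_table["q_value"] < fdr)
        & (stats_table["log2fc"].abs() > min_abs_log2fc)
    ].copy()
    return sel.sort_values(["direction", "q_value"], ascending=[False, True])
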