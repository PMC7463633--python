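"""Median-effect dose-response modelling and Chou-Talalay combination index.

The median-effect equation fa/(1-fa) = (D/Dm)^m linearizes as

    log10(fa/(1-fa)) = m * log10(D) - m * log10(Dm),

so a straight-line fit of the logit of fraction affected on log dose gives
the slope ``m`` and the median-effect dose ``Dm``.  For a two-drug
combination reaching fraction affected ``fa`` at doses (d1, d2), the
combination index in the mutually exclusive form is

    CI = d1/Dx1 + d2/Dx2,   Dx_i = Dm_i * (fa/(1-fa))^(1/m_i),

with CI < 1 synergy, CI ≈ 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DoseResponse:
    """Single-agent dose-response: doses (µM) and fractions affected in (0,1)."""

    drug: str
    doses: np.ndarray
    fraction_affected: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fraction_affected = np.asarray(self.fraction_affected, dtype=float)
        if self.doses.shape != self.fraction_affected.shape:
            raise ValueError("doses and fractions must have equal length")
        if (self.doses <= 0).any():
            raise ValueError("doses must be strictly positive")
        fa = self.fraction_affected
        if ((fa <= 0) | (fa >= 1)).any():
            raise ValueError("fraction affected must be in (0, 1)")


@dataclass
class MedianEffectFit:
    """Median-effect parameters: slope m, median-effect dose Dm (µM), R²."""

    drug: str
    m: float
    Dm: float
    r_squared: float

    def fa_at(self, dose: float) -> float:
        """Fraction affected predicted at ``dose`` by the fitted curve."""
        return 1.0 / (1.0 + (self.Dm / dose) ** self.m)

    def dose_for(self, fa: float) -> float:
        """Dose producing fraction affected ``fa`` on the fitted curve (Dx)."""
        if not 0 < fa < 1:
            raise ValueError("fa must be in (0, 1)")
        return self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass
class ComboResult:
    """Combination index for one dose pair, with its qualitative call."""

    d1: float
    d2: float
    ci: float
    classification: str


def fit_median_effect(dr: DoseResponse) -> MedianEffectFit:
    """Least-squares fit of the median-effect plot (logit fa vs log10 dose)."""
    if len(dr.doses) < 3:
        raise ValueError("need at least 3 dose points")
    x = np.log10(dr.doses)
    if np.ptp(x) == 0:
        raise ValueError("doses have zero variance")
    y = np.log10(dr.fraction_affected / (1.0 - dr.fraction_affected))
    res = stats.linregress(x, y)
    m = res.slope
    if m == 0:
        raise ValueError("flat dose-response; Dm undefined")
    dm = 10.0 ** (-res.intercept / m)
    return MedianEffectFit(drug=dr.drug, m=float(m), Dm=float(dm),
                           r_squared=float(res.rvalue ** 2))


def combination_index(fit1: MedianEffectFit, fit2: MedianEffectFit,
                      d1: float, d2: float, fa_combo: float,
                      additive_tol: float = 0.1) -> ComboResult:
    """Two-term (mutually exclusive) Chou-Talalay combination index.

    ``fa_combo`` is the observed fraction affected of the combination at
    doses (d1, d2).  Classification uses a tolerance band of ``additive_tol``
    around CI = 1.
    """
    if not 0 < fa_combo < 1:
        raise ValueError("fa_combo must be in (0, 1)")
    if d1 <= 0 or d2 <= 0:
        raise ValueError("doses must be positive")
    ci = d1 / fit1.dose_for(fa_combo) + d2 / fit2.dose_for(fa_combo)
    if ci > 1 + additive_tol:
        cls = "antagonism"
    elif ci < 1 - additive_tol:
        cls = "synergy"
    else:
        cls = "additive"
    return ComboResult(d1=d1, d2=d2, ci=float(ci), classification=cls)


def combination_table(fit1: MedianEffectFit, fit2: MedianEffectFit,
                      combos: pd.DataFrame,
                      additive_tol: float = 0.1) -> pd.DataFrame:
    """CI table over a grid of combination measurements.

    ``combos`` needs columns ``dose1_uM``, ``dose2_uM``, ``fraction_affected``.
    """
    rows = []
    for _, rec in combos.iterrows():
        res = combination_index(fit1, fit2, rec["dose1_uM"], rec["dose2_uM"],
                                rec["fraction_affected"], additive_tol)
        rows.append({
            "drug1": fit1.drug, "dose1_uM": res.d1,
            "drug2": fit2.drug, "dose2_uM": res.d2,
            "fraction_affected": rec["fraction_affected"],
            "ci": res.ci, "classification": res.classification,
        })
    return pd.DataFrame(rows)


def read_dose_response_tsv(path) -> dict:
    """Read the dose-response TSV (drug, dose_uM, fraction_affected) into
    one :class:`DoseResponse` per drug."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for drug, grp in df.groupby("drug", sort=False):
        out[drug] = DoseResponse(
            drug=drug,
            doses=grp["dose_uM"].to_numpy(),
            fraction_affected=grp["fraction_affected"].to_numpy(),
        )
    return out
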