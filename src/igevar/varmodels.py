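"""Sire models for inherited variability of final body weight.

The direct response of a sire-dam family is the natural log of the
unbiased sample variance of the family's final weights; the indirect
response is the log variance of the final weights of those offspring's
social partners.  Each is analysed with a one-way sire model

    y = mu + Z s + e,    s ~ N(0, sigma2_sire I),  e ~ N(0, sigma2_e I),

fit by REML.  Sire BLUPs estimate (half) the sire's breeding value for
the direct, respectively indirect, component of inherited variability.
The same individuals legitimately appear both in a direct record (as
family members) and in indirect records of other families (as partners):
the two models are fit separately in a two-step analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .reml import reml_fit
from .simulate import OffspringCohort

__all__ = [
    "SireModelFit",
    "build_variance_records",
    "fit_sire_model",
    "anova_oneway_balanced",
]


@dataclass
class SireModelFit:
    sigma2_sire: float
    sigma2_e: float
    mu: float
    loglik_reml: float
    #: predicted sire effects, indexed by sire_id
    blup: pd.Series
    converged: bool


def build_variance_records(
    cohort: OffspringCohort, final_weight: np.ndarray
) -> pd.DataFrame:
    """Log family-variance records, one row per sire-dam family.

    Columns: sire_id, dam_id, family_size, y_direct (log of the unbiased
    variance of the family's final weights) and y_indirect (log variance
    of the family members' partners' final weights).
    """
    if cohort.partner is None:
        raise ValueError("cohort has no partner assignment")
    df = pd.DataFrame(
        {
            "sire_id": cohort.sire_id,
            "dam_id": cohort.dam_id,
            "w": final_weight,
            "w_partner": final_weight[cohort.partner],
        }
    )
    g = df.groupby(["sire_id", "dam_id"], sort=True)
    out = g.agg(
        family_size=("w", "size"),
        var_direct=("w", "var"),
        var_indirect=("w_partner", "var"),
    ).reset_index()
    if (out["family_size"] < 2).any():
        raise ValueError("every sire-dam family needs at least 2 offspring")
    if (out[["var_direct", "var_indirect"]] <= 0).any().any():
        raise ValueError("zero within-family variance: cannot take its log")
    out["y_direct"] = np.log(out.pop("var_direct"))
    out["y_indirect"] = np.log(out.pop("var_indirect"))
    return out


def _sire_design(records: pd.DataFrame, response: str):
    if response not in ("direct", "indirect"):
        raise ValueError("response must be 'direct' or 'indirect'")
    y = records[f"y_{response}"].to_numpy(dtype=float)
    codes, sires = pd.factorize(records["sire_id"], sort=True)
    if len(sires) < 2:
        raise ValueError("need at least 2 sires")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("need at least 2 records per sire")
    n = len(y)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(sires))
    )
    return y, Z, codes, sires, counts


def fit_sire_model(records: pd.DataFrame, response: str = "direct") -> SireModelFit:
    """REML fit of the one-way sire model on a family-variance response.

    ``response`` selects the direct ("y_direct") or indirect
    ("y_indirect") log family variance.  On a balanced design the REML
    estimates coincide with the one-way ANOVA closed form (see
    :func:`anova_oneway_balanced`) whenever that is interior; negative
    between-sire estimates are truncated at zero.
    """
    y, Z, codes, sires, counts = _sire_design(records, response)
    fit = reml_fit(y, Z)
    return SireModelFit(
        sigma2_sire=fit.sigma2_u,
        sigma2_e=fit.sigma2_e,
        mu=fit.mu,
        loglik_reml=fit.loglik,
        blup=pd.Series(fit.blup, index=sires, name=f"blup_{response}"),
        converged=fit.converged,
    )


def anova_oneway_balanced(y: np.ndarray, group: np.ndarray):
    """Closed-form REML for the balanced one-way random-effects model.

    With s groups of equal size n: sigma2_e = MSW, and
    sigma2_group = (MSB - MSW) / n truncated at zero.  BLUP of group g is
    n (ybar_g - ybar) / (n + sigma2_e / sigma2_group).  Serves as the
    documented cross-check for :func:`fit_sire_model` on balanced data.
    """
    y = np.asarray(y, dtype=float)
    codes, levels = pd.factorize(pd.Series(group), sort=True)
    s = len(levels)
    counts = np.bincount(codes)
    if not np.all(counts == counts[0]):
        raise ValueError("design is not balanced")
    n = int(counts[0])
    means = np.bincount(codes, weights=y) / n
    grand = y.mean()
    msb = n * np.sum((means - grand) ** 2) / (s - 1)
    msw = np.sum((y - means[codes]) ** 2) / (s * (n - 1))
    sigma2_g = max((msb - msw) / n, 0.0)
    if sigma2_g == 0.0:
        sigma2_e = np.sum((y - grand) ** 2) / (len(y) - 1)
        blup = np.zeros(s)
    else:
        sigma2_e = msw
        blup = n * (means - grand) / (n + sigma2_e / sigma2_g)
    return sigma2_g, sigma2_e, pd.Series(blup, index=levels)
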