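"""Sire-dam mixed models on individual final body weight.

Both models put every sire and dam into one random-effect vector with a
single shared variance (parents are unrelated; no relationship matrix):

    y = mu + Z p + e,   p ~ N(0, sigma2_parent I),  e ~ N(0, sigma2_e I).

In the direct model each record's incidence row has a 1 for the
offspring's own sire and dam; in the indirect model, for the sire and
dam of the offspring's social partner.  Parent BLUPs estimate (half)
parental breeding values for, respectively, the direct effect on growth
and the indirect (social) effect on the partner's growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .reml import reml_fit
from .simulate import OffspringCohort

__all__ = ["ParentDesign", "ParentModelFit", "build_parent_design", "fit_parent_model"]


@dataclass
class ParentDesign:
    """Response and sparse parent incidence for one sire-dam model.

    Parents are indexed 0..n_sires-1 (sires) then n_sires..n_sires+
    n_dams-1 (dams); ``parent_label`` gives "sire"/"dam" per column and
    ``parent_id`` the original id within its role.  Every incidence row
    has exactly two ones.
    """

    y: np.ndarray
    Z: sparse.csr_matrix
    mode: str
    n_sires: int
    n_dams: int

    @property
    def parent_label(self) -> np.ndarray:
        return np.array(["sire"] * self.n_sires + ["dam"] * self.n_dams)

    @property
    def parent_id(self) -> np.ndarray:
        return np.concatenate([np.arange(self.n_sires), np.arange(self.n_dams)])


@dataclass
class ParentModelFit:
    sigma2_parent: float
    sigma2_e: float
    mu: float
    loglik_reml: float
    #: predicted parent effects, ordered as the design's parent columns
    blup: np.ndarray
    converged: bool


def build_parent_design(
    cohort: OffspringCohort, final_weight: np.ndarray, mode: str = "direct"
) -> ParentDesign:
    """Build the sparse incidence linking records to parent columns.

    ``mode="direct"`` links each offspring's final weight to its own sire
    and dam; ``mode="indirect"`` to its partner's sire and dam.
    """
    if mode not in ("direct", "indirect"):
        raise ValueError("mode must be 'direct' or 'indirect'")
    if cohort.partner is None:
        raise ValueError("cohort has no partner assignment")
    n = cohort.n
    if mode == "direct":
        sire, dam = cohort.sire_id, cohort.dam_id
    else:
        sire, dam = cohort.sire_id[cohort.partner], cohort.dam_id[cohort.partner]
    if np.min(sire) < 0 or np.min(dam) < 0:
        raise ValueError("missing parent id")
    n_sires = int(cohort.sire_id.max()) + 1
    n_dams = int(cohort.dam_id.max()) + 1
    rows = np.repeat(np.arange(n), 2)
    cols = np.empty(2 * n, dtype=np.int64)
    cols[0::2] = sire
    cols[1::2] = n_sires + dam
    Z = sparse.csr_matrix(
        (np.ones(2 * n), (rows, cols)), shape=(n, n_sires + n_dams)
    )
    return ParentDesign(
        y=np.asarray(final_weight, dtype=float),
        Z=Z,
        mode=mode,
        n_sires=n_sires,
        n_dams=n_dams,
    )


def fit_parent_model(design: ParentDesign) -> ParentModelFit:
    """REML fit of the sire-dam model on a sparse crossed design.

    The restricted likelihood is profiled down to a 1-D search over the
    variance ratio; log-determinants and BLUP solves use a sparse LU
    factorization of Z'Z + lambda I.
    """
    fit = reml_fit(design.y, design.Z)
    return ParentModelFit(
        sigma2_parent=fit.sigma2_u,
        sigma2_e=fit.sigma2_e,
        mu=fit.mu,
        loglik_reml=fit.loglik,
        blup=fit.blup,
        converged=fit.converged,
    )
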