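"""Correlate predicted genetic effects with simulated breeding values.

For each scenario and replicate the relevant pair of models is fit and
Pearson correlations are computed between predicted effects and the
simulated breeding values:

* variability purpose — sire BLUPs from the direct and indirect log
  family-variance models against the sires' own (A_GR, A_D, A_I);
* trait purpose — pooled sire+dam BLUPs from the direct and indirect
  sire-dam models against the corresponding parental triples.

Correlations are scale-invariant, so whether BLUPs estimate half or
whole breeding values does not affect them.  Reports carry both the
across-replicate mean of per-replicate correlations (the headline
statistic) and the pooled-data correlation over all replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scenarios import ScenarioSpec
from .simulate import simulate_scenario
from .traitmodels import build_parent_design, fit_parent_model
from .varmodels import build_variance_records, fit_sire_model

__all__ = ["CorrelationReport", "pearson", "run_scenario", "reports_to_frame"]

log = logging.getLogger(__name__)

_BV_COLS = ("corr_AGR", "corr_AD", "corr_AI")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationReport:
    """Correlations between one model's predictions and simulated BVs."""

    scenario_id: int
    label: str
    model: str
    n_replicates: int
    #: one row per successful replicate: corr_AGR, corr_AD, corr_AI
    per_replicate: pd.DataFrame
    n_failed: int = 0
    #: pooled predictions/truths over replicates, for pooled correlations
    pooled: dict = field(default_factory=dict, repr=False)

    @property
    def mean_corr(self) -> pd.Series:
        return self.per_replicate[list(_BV_COLS)].mean()

    @property
    def se_corr(self) -> pd.Series:
        k = len(self.per_replicate)
        return self.per_replicate[list(_BV_COLS)].std(ddof=1) / np.sqrt(k)

    @property
    def pooled_corr(self) -> pd.Series:
        vals = {}
        for col, (pred, truth) in self.pooled.items():
            vals[col] = pearson(pred, truth)
        return pd.Series(vals)


def _correlate(pred: np.ndarray, truths: np.ndarray) -> dict:
    return {col: pearson(pred, truths[:, k]) for k, col in enumerate(_BV_COLS)}


def run_scenario(
    spec: ScenarioSpec,
    n_replicates: int,
    seed: int | np.random.SeedSequence,
) -> list[CorrelationReport]:
    """Simulate-and-fit replicates of one scenario.

    Returns two reports (direct and indirect model of the purpose-
    appropriate kind).  A replicate whose fit fails is logged, counted
    and excluded from the aggregates.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if spec.purpose == "variability":
        models = ["direct-variability", "indirect-variability"]
    else:
        models = ["direct-trait", "indirect-trait"]
    rows: dict[str, list] = {m: [] for m in models}
    pooled: dict[str, dict] = {m: {c: [[], []] for c in _BV_COLS} for m in models}
    n_failed = {m: 0 for m in models}

    for child in ss.spawn(n_replicates):
        parents, cohort, growth = simulate_scenario(spec, child)
        if spec.purpose == "variability":
            records = build_variance_records(cohort, growth.final_weight)
            truths = parents.sire_bv
            for model, response in zip(models, ("direct", "indirect")):
                try:
                    fit = fit_sire_model(records, response)
                except Exception:
                    log.exception("sire-model fit failed (%s)", model)
                    n_failed[model] += 1
                    continue
                pred = fit.blup.reindex(np.arange(spec.n_sires)).to_numpy()
                rows[model].append(_correlate(pred, truths))
                for k, c in enumerate(_BV_COLS):
                    pooled[model][c][0].append(pred)
                    pooled[model][c][1].append(truths[:, k])
        else:
            truths = np.vstack([parents.sire_bv, parents.dam_bv])
            for model, mode in zip(models, ("direct", "indirect")):
                try:
                    design = build_parent_design(cohort, growth.final_weight, mode)
                    fit = fit_parent_model(design)
                except Exception:
                    log.exception("parent-model fit failed (%s)", model)
                    n_failed[model] += 1
                    continue
                rows[model].append(_correlate(fit.blup, truths))
                for k, c in enumerate(_BV_COLS):
                    pooled[model][c][0].append(fit.blup)
                    pooled[model][c][1].append(truths[:, k])

    reports = []
    for model in models:
        reports.append(
            CorrelationReport(
                scenario_id=spec.scenario_id,
                label=spec.label,
                model=model,
                n_replicates=len(rows[model]),
                per_replicate=pd.DataFrame(rows[model], columns=list(_BV_COLS)),
                n_failed=n_failed[model],
                pooled={
                    c: (np.concatenate(p), np.concatenate(t))
                    for c, (p, t) in pooled[model].items()
                    if p
                },
            )
        )
    return reports


def reports_to_frame(reports: list[CorrelationReport]) -> pd.DataFrame:
    """Tidy summary, one row per (scenario, model), mirroring the layout
    of the study's correlation tables (mean, SE and pooled variant of the
    correlation with each of A_GR, A_D, A_I)."""
    out = []
    for rep in reports:
        row = {
            "scenario_id": rep.scenario_id,
            "label": rep.label,
            "model": rep.model,
            "n_replicates": rep.n_replicates,
            "n_failed": rep.n_failed,
        }
        mean, se, pooled = rep.mean_corr, rep.se_corr, rep.pooled_corr
        for col in _BV_COLS:
            row[f"{col}_mean"] = mean.get(col, np.nan)
            row[f"{col}_se"] = se.get(col, np.nan)
            row[f"{col}_pooled"] = pooled.get(col, np.nan)
        out.append(row)
    return pd.DataFrame(out)
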