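"""Synthetic population and paired-growth simulation.

Builds a base population of unrelated sires and dams with trivariate
normal breeding values (growth A_GR; direct A_D and indirect A_I effects
on the interaction coefficient b), produces half-sib/full-sib offspring
with Mendelian sampling, pairs offspring at random into groups of two,
and iterates the growth recursion

    P[t,i] - P[t-1,i] = mu_GR + A_GR,i + Ep,i + Et,t,i
                        + b_ij * (P[t-1,j] - P[t-1,i])

with b_ij = b_bar + A_D,i + E_D,i + A_I,j + E_I,j fixed for life per
ordered pair.  Both members of a pair update synchronously from the
previous step's weights.  Et is redrawn independently at every step;
Ep, E_D and E_I are drawn once per individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenarios import DerivedVariances, GeneticParams, ScenarioSpec, derive_variances

__all__ = [
    "ParentPopulation",
    "OffspringCohort",
    "GrowthResult",
    "sample_base_population",
    "sample_offspring",
    "pair_individuals",
    "interaction_coefficient",
    "simulate_growth",
    "simulate_scenario",
    "cohort_to_frame",
]


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """A factor F with F @ F.T = cov, tolerating singular (PSD) inputs."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("covariance matrix is not positive semi-definite")
        return v * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class ParentPopulation:
    """Unrelated base parents; columns of each array are (A_GR, A_D, A_I)."""

    sire_bv: np.ndarray  # (n_sires, 3)
    dam_bv: np.ndarray  # (n_dams, 3)

    @property
    def n_sires(self) -> int:
        return self.sire_bv.shape[0]

    @property
    def n_dams(self) -> int:
        return self.dam_bv.shape[0]


@dataclass
class OffspringCohort:
    """Per-offspring genetic and environmental state, plus pedigree links.

    Offspring are ordered by sire then dam, so each full-sib family is a
    contiguous block.  ``partner`` is a fixed-point-free involution over
    0..n-1 assigning each offspring its social partner.
    """

    sire_id: np.ndarray
    dam_id: np.ndarray
    a_gr: np.ndarray
    a_d: np.ndarray
    a_i: np.ndarray
    ep: np.ndarray
    e_d: np.ndarray
    e_i: np.ndarray
    partner: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.sire_id.shape[0]


@dataclass
class GrowthResult:
    """Body-weight trajectories; final weight is the analysis trait.

    ``weights`` has shape (n, n_steps + 1) when the trajectory is kept,
    else None (only ``final_weight`` is retained for large cohorts).
    ``n_negative`` is a diagnostic count of weight values below zero over
    the whole run (never triggered at the study's parameter values;
    weights are deliberately not clamped).
    """

    final_weight: np.ndarray
    weights: np.ndarray | None
    n_negative: int


def sample_base_population(
    spec: ScenarioSpec, rng: np.random.Generator
) -> ParentPopulation:
    """Draw breeding-value triples for all sires and dams.

    Triples are i.i.d. trivariate normal with mean zero, SDs from the
    scenario's :class:`GeneticParams` and correlation ``genetic_corr``.
    """
    factor = _psd_factor(spec.params.genetic_covariance())
    sire_bv = rng.standard_normal((spec.n_sires, 3)) @ factor.T
    dam_bv = rng.standard_normal((spec.n_dams, 3)) @ factor.T
    return ParentPopulation(sire_bv=sire_bv, dam_bv=dam_bv)


def sample_offspring(
    parents: ParentPopulation, spec: ScenarioSpec, rng: np.random.Generator
) -> OffspringCohort:
    """Create the offspring generation.

    Each sire is mated to ``n_dams_per_sire`` dams (dam k belongs to sire
    k // n_dams_per_sire; dams are i.i.d. so this allocation is
    distributionally identical to a random draw), and each dam produces
    ``n_offspring_per_dam`` offspring.  An offspring's breeding-value
    triple is the midparent mean plus a Mendelian sampling term with half
    the additive (co)variance.  Permanent environmental effects on growth
    (Ep) and on b (E_D, E_I) are drawn once per offspring.
    """
    if parents.n_dams != spec.n_dams:
        raise ValueError(
            f"base population has {parents.n_dams} dams but the design mates "
            f"{spec.n_dams}; every dam must be mated exactly once"
        )
    n = spec.cohort_size
    dam_id = np.repeat(np.arange(spec.n_dams), spec.n_offspring_per_dam)
    sire_id = dam_id // spec.n_dams_per_sire

    midparent = 0.5 * (parents.sire_bv[sire_id] + parents.dam_bv[dam_id])
    mend_factor = _psd_factor(0.5 * spec.params.genetic_covariance())
    bv = midparent + rng.standard_normal((n, 3)) @ mend_factor.T

    derived = derive_variances(spec.params)
    ep = rng.normal(0.0, np.sqrt(derived.sigma_ep2), n)
    e_d = rng.normal(0.0, spec.params.sigma_ed, n)
    e_i = rng.normal(0.0, spec.params.sigma_ei, n)
    return OffspringCohort(
        sire_id=sire_id,
        dam_id=dam_id,
        a_gr=bv[:, 0],
        a_d=bv[:, 1],
        a_i=bv[:, 2],
        ep=ep,
        e_d=e_d,
        e_i=e_i,
    )


def pair_individuals(n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform random perfect matching on ``n`` individuals.

    Returns the partner map: a fixed-point-free involution as an integer
    array of length n.  A uniformly random permutation read off in
    consecutive pairs induces the uniform distribution over perfect
    matchings.
    """
    if n % 2:
        raise ValueError("cannot pair an odd number of individuals")
    order = rng.permutation(n)
    partner = np.empty(n, dtype=np.int64)
    partner[order[0::2]] = order[1::2]
    partner[order[1::2]] = order[0::2]
    return partner


def interaction_coefficient(b_bar, a_d_focal, e_d_focal, a_i_partner, e_i_partner):
    """The interaction coefficient b_ij of a focal individual.

    b_ij = b_bar + A_D,i + E_D,i + A_I,j + E_I,j with i the focal and j
    its partner; constant over time for a given ordered pair and in
    general asymmetric (b_ij != b_ji).  Accepts scalars or arrays.
    """
    return b_bar + a_d_focal + e_d_focal + a_i_partner + e_i_partner


def simulate_growth(
    cohort: OffspringCohort,
    params: GeneticParams,
    derived: DerivedVariances,
    rng: np.random.Generator,
    store_trajectory: bool = True,
) -> GrowthResult:
    """Iterate the growth recursion over ``params.n_steps`` increments.

    Updates are synchronous: both pair members' step-t increments use the
    step t-1 weights.  The temporary environmental effect Et is redrawn
    independently for every individual at every step with variance
    ``derived.sigma_et2``.
    """
    if cohort.partner is None:
        raise ValueError("cohort has no partner assignment; pair it first")
    n = cohort.n
    j = cohort.partner
    b = interaction_coefficient(
        params.b_bar, cohort.a_d, cohort.e_d, cohort.a_i[j], cohort.e_i[j]
    )
    base_increment = params.mu_gr + cohort.a_gr + cohort.ep
    sd_et = np.sqrt(derived.sigma_et2)

    w = np.full(n, float(params.start_weight))
    traj = None
    if store_trajectory:
        traj = np.empty((n, params.n_steps + 1))
        traj[:, 0] = w
    n_negative = int(np.count_nonzero(w < 0))
    for t in range(1, params.n_steps + 1):
        et = rng.normal(0.0, sd_et, n) if sd_et > 0 else 0.0
        w = w + base_increment + et + b * (w[j] - w)
        n_negative += int(np.count_nonzero(w < 0))
        if traj is not None:
            traj[:, t] = w
    return GrowthResult(final_weight=w, weights=traj, n_negative=n_negative)


def simulate_scenario(
    spec: ScenarioSpec,
    seed: int | np.random.SeedSequence,
    store_trajectory: bool = False,
) -> tuple[ParentPopulation, OffspringCohort, GrowthResult]:
    """Run one full replicate of a scenario from a single master seed.

    Sub-streams for the base population, offspring sampling, pairing and
    growth noise are spawned deterministically from the master seed, so
    each stage is independently reproducible.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_base, s_off, s_pair, s_growth = ss.spawn(4)
    parents = sample_base_population(spec, np.random.default_rng(s_base))
    cohort = sample_offspring(parents, spec, np.random.default_rng(s_off))
    cohort.partner = pair_individuals(cohort.n, np.random.default_rng(s_pair))
    growth = simulate_growth(
        cohort,
        spec.params,
        derive_variances(spec.params),
        np.random.default_rng(s_growth),
        store_trajectory=store_trajectory,
    )
    return parents, cohort, growth


def cohort_to_frame(cohort: OffspringCohort, growth: GrowthResult | None = None) -> pd.DataFrame:
    """Tidy per-offspring table (one row per individual) for CSV export."""
    df = pd.DataFrame(
        {
            "id": np.arange(cohort.n),
            "sire_id": cohort.sire_id,
            "dam_id": cohort.dam_id,
            "partner_id": cohort.partner if cohort.partner is not None else -1,
            "A_GR": cohort.a_gr,
            "A_D": cohort.a_d,
            "A_I": cohort.a_i,
            "Ep": cohort.ep,
            "E_D": cohort.e_d,
            "E_I": cohort.e_i,
        }
    )
    if growth is not None:
        if growth.weights is not None:
            for t in range(growth.weights.shape[1]):
                df[f"weight_t{t}"] = growth.weights[:, t]
        else:
            df["final_weight"] = growth.final_weight
    return df
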