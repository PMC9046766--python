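"""Simulation parameters and the canonical scenario grid.

The study system is a family-structured fish population grown in pairs.
Growth of a focal individual is reduced (competition) or boosted
(cooperation) in proportion to the body-weight difference with its
partner; the regression coefficient ``b`` of that term carries direct
(resistance, A_D) and indirect (cooperativeness, A_I) genetic components
in addition to environmental ones.  The scenario grid crosses the mean
interaction ``b_bar`` (-0.05 competition / 0 neutral / +0.05 cooperation)
with 3x larger or smaller genetic SDs for A_D, A_I and growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GeneticParams",
    "DerivedVariances",
    "ScenarioSpec",
    "derive_variances",
    "canonical_scenarios",
    "scenario_table",
    "SCALE_PRESETS",
]

#: Cohort-size presets: (n_sires, n_dams_per_sire, n_offspring_per_dam)
#: keyed by (preset, purpose).  "paper" is the full design (10^6 offspring
#: for variability records, 10^5 for trait records); "reduced" trades
#: family-variance precision for speed; "tiny" is a smoke-test size.
SCALE_PRESETS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("paper", "variability"): (100, 100, 100),
    ("paper", "trait"): (100, 100, 10),
    ("reduced", "variability"): (100, 20, 50),
    ("reduced", "trait"): (100, 20, 10),
    ("tiny", "variability"): (20, 5, 10),
    ("tiny", "trait"): (20, 5, 4),
}


@dataclass(frozen=True, eq=False)
class GeneticParams:
    """Parameters of the paired-growth model.

    Units: weights and growth in grams; the interaction coefficient ``b``
    and its components are dimensionless regressions of a growth
    increment on a weight difference.
    """

    b_bar: float = -0.05
    sigma_a_gr: float = 1.0
    sigma_ad: float = 0.015
    sigma_ai: float = 0.015
    sigma_ed: float = 0.015
    sigma_ei: float = 0.015
    mu_gr: float = 10.0
    start_weight: float = 10.0
    h2: float = 0.5
    repeatability: float = 0.7
    n_steps: int = 10
    #: 3x3 correlation matrix over (A_GR, A_D, A_I); identity by default.
    genetic_corr: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        for name in ("sigma_a_gr", "sigma_ad", "sigma_ai", "sigma_ed", "sigma_ei"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        if self.repeatability < self.h2:
            raise ValueError("repeatability must be >= h2")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        corr = np.asarray(self.genetic_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("genetic_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("genetic_corr must have a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("genetic_corr must be positive semi-definite")
        object.__setattr__(self, "genetic_corr", corr)

    def genetic_covariance(self) -> np.ndarray:
        """Covariance of the breeding-value triple (A_GR, A_D, A_I)."""
        d = np.diag([self.sigma_a_gr, self.sigma_ad, self.sigma_ai])
        return d @ self.genetic_corr @ d


@dataclass(frozen=True)
class DerivedVariances:
    """Variance budget of growth rate implied by h2 and repeatability.

    sigma_p2 is the phenotypic variance of the growth increment at b=0;
    the permanent (Ep) and temporary (Et) environmental variances are the
    (repeatability - h2) and (1 - repeatability) shares of it.
    """

    sigma_p2: float
    sigma_ep2: float
    sigma_et2: float


def derive_variances(params: GeneticParams) -> DerivedVariances:
    """Split phenotypic variance of growth rate into its components.

    At the defaults (h2=0.5, repeatability=0.7, sigma_a_gr=1) this gives
    sigma_p2=2, sigma_ep2=0.4, sigma_et2=0.6 g^2.
    """
    sigma_p2 = params.sigma_a_gr**2 / params.h2
    sigma_ep2 = (params.repeatability - params.h2) * sigma_p2
    sigma_et2 = (1.0 - params.repeatability) * sigma_p2
    return DerivedVariances(sigma_p2, sigma_ep2, sigma_et2)


_LABELS = {-0.05: "competition", 0.0: "neutral", 0.05: "cooperation"}


@dataclass(frozen=True)
class ScenarioSpec:
    """One fully parameterized simulation run."""

    scenario_id: int
    label: str
    params: GeneticParams
    purpose: str = "variability"
    n_sires: int = 100
    n_dams_per_sire: int = 100
    n_offspring_per_dam: int = 100

    def __post_init__(self) -> None:
        if self.purpose not in ("variability", "trait"):
            raise ValueError("purpose must be 'variability' or 'trait'")
        for name in ("n_sires", "n_dams_per_sire", "n_offspring_per_dam"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_dams(self) -> int:
        return self.n_sires * self.n_dams_per_sire

    @property
    def cohort_size(self) -> int:
        return self.n_dams * self.n_offspring_per_dam

    def with_scale(self, preset: str) -> "ScenarioSpec":
        """Return a copy with cohort sizes from a named preset."""
        try:
            s, d, o = SCALE_PRESETS[(preset, self.purpose)]
        except KeyError:
            raise ValueError(f"unknown scale preset {preset!r}") from None
        return replace(self, n_sires=s, n_dams_per_sire=d, n_offspring_per_dam=o)


# (scenario_id, b_bar, sigma_ad, sigma_ai, sigma_a_gr); the grid varies one
# block of parameters at a time around the default (0.015, 0.015, 1).
_GRID: list[tuple[int, float, float, float, float]] = [
    (1, -0.05, 0.015, 0.015, 1.0),
    (2, 0.0, 0.015, 0.015, 1.0),
    (3, 0.05, 0.015, 0.015, 1.0),
    (4, -0.05, 0.045, 0.015, 1.0),
    (5, 0.0, 0.045, 0.015, 1.0),
    (6, 0.05, 0.045, 0.015, 1.0),
    (7, -0.05, 0.005, 0.015, 1.0),
    (8, 0.0, 0.005, 0.015, 1.0),
    (9, 0.05, 0.005, 0.015, 1.0),
    (10, -0.05, 0.015, 0.045, 1.0),
    (11, 0.0, 0.015, 0.045, 1.0),
    (12, 0.05, 0.015, 0.045, 1.0),
    (13, -0.05, 0.015, 0.005, 1.0),
    (14, 0.0, 0.015, 0.005, 1.0),
    (15, 0.05, 0.015, 0.005, 1.0),
    (16, -0.05, 0.015, 0.015, 3.0),
    (17, 0.0, 0.015, 0.015, 3.0),
    (18, 0.05, 0.015, 0.015, 3.0),
    (19, -0.05, 0.015, 0.015, 0.3),
    (20, 0.0, 0.015, 0.015, 0.3),
    (21, 0.05, 0.015, 0.015, 0.3),
]


def canonical_scenarios(
    purpose: str = "variability",
    scale: str = "paper",
    genetic_corr: np.ndarray | None = None,
) -> list[ScenarioSpec]:
    """The 21 canonical scenarios.

    Parameters
    ----------
    purpose
        "variability" (100 offspring per dam at paper scale, feeding the
        log family-variance sire models) or "trait" (10 per dam, feeding
        the sire-dam models on final weight).
    scale
        Cohort-size preset; see :data:`SCALE_PRESETS`.
    genetic_corr
        Optional non-identity correlation matrix over (A_GR, A_D, A_I),
        applied to every scenario (used for the +/-0.5 correlation runs).
    """
    specs = []
    for sid, b_bar, sad, sai, sagr in _GRID:
        kwargs = dict(b_bar=b_bar, sigma_ad=sad, sigma_ai=sai, sigma_a_gr=sagr)
        if genetic_corr is not None:
            kwargs["genetic_corr"] = genetic_corr
        spec = ScenarioSpec(
            scenario_id=sid,
            label=_LABELS[b_bar],
            params=GeneticParams(**kwargs),
            purpose=purpose,
        )
        specs.append(spec.with_scale(scale))
    return specs


def scenario_table() -> pd.DataFrame:
    """The canonical grid as a tidy table (one row per scenario)."""
    rows = [
        {
            "scenario_id": sid,
            "label": _LABELS[b_bar],
            "b_bar": b_bar,
            "sigma_ad": sad,
            "sigma_ai": sai,
            "sigma_a_gr": sagr,
        }
        for sid, b_bar, sad, sai, sagr in _GRID
    ]
    return pd.DataFrame(rows)


def load_scenario_table() -> pd.DataFrame:
    """Load the scenario catalogue shipped with the package."""
    with resources.files("igevar.data").joinpath("scenarios.csv").open() as fh:
        return pd.read_csv(fh)
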