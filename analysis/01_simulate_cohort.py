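#!/usr/bin/env python
"""Simulate one paired-growth cohort and summarize what the model does.

Runs a single replicate of the default competition scenario (b_bar =
-0.05) at reduced scale (100 sires x 20 dams x 10 offspring), reports
the realized variance budget of final body weight, and shows that
competition amplifies within-pair divergence relative to a neutral
population.  Writes a per-family summary table and a small cohort
sample under results/.
"""

import dataclasses
from pathlib import Path

import numpy as np

from igevar import canonical_scenarios, simulate_scenario
from igevar.simulate import cohort_to_frame

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20220308


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = {s.scenario_id: s for s in canonical_scenarios("trait", "reduced")}[1]
    parents, cohort, growth = simulate_scenario(spec, SEED, store_trajectory=True)
    w = growth.final_weight

    print(f"scenario 1 (competition), {spec.cohort_size} offspring, "
          f"{cohort.n // 2} pairs, seed {SEED}")
    print(f"final weight: mean {w.mean():.2f} g, variance {w.var(ddof=1):.1f} g^2")
    print(f"negative weights encountered: {growth.n_negative}")

    # neutral comparison: same design, b_bar = 0
    neutral = dataclasses.replace(
        spec, params=dataclasses.replace(spec.params, b_bar=0.0)
    )
    _, ncoh, ngrow = simulate_scenario(neutral, SEED, store_trajectory=False)
    div_c = np.abs(w - w[cohort.partner]).mean()
    div_n = np.abs(ngrow.final_weight - ngrow.final_weight[ncoh.partner]).mean()
    print(f"mean |within-pair weight difference|: {div_c:.2f} g under "
          f"competition vs {div_n:.2f} g at b = 0 "
          f"(competition amplifies divergence)")

    frame = cohort_to_frame(cohort, growth)
    frame.head(100).round(4).to_csv(OUT / "cohort_sample_scenario1.csv", index=False)
    fam = (
        frame.assign(final=w)
        .groupby(["sire_id", "dam_id"])["final"]
        .agg(["size", "mean", "var"])
        .reset_index()
        .round(3)
    )
    fam.head(500).to_csv(OUT / "family_summary_scenario1.csv", index=False)
    print(f"wrote {OUT / 'cohort_sample_scenario1.csv'} (100-row sample) and "
          f"{OUT / 'family_summary_scenario1.csv'} (500 of {len(fam)} families)")


if __name__ == "__main__":
    main()
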