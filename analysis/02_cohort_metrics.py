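#!/usr/bin/env python
"""Generate synthetic WT and KO cohorts and compare their trace metrics.

Emulates the in vivo design — n = 4 wild-type and 5 knockout animals, one
evoked recording each (10 Hz, 12 s), between-animal CV 0.1 on the free
parameters and 0.05 μM measurement noise — then tests the clearance
half-time difference with Welch's t-test.
"""

from pathlib import Path

import pandas as pd

from dakinetics.metrics import trace_metrics, welch_t
from dakinetics.presets import ko_parameters, standard_protocol, wt_parameters
from dakinetics.synthetic import CohortSpec, animal_seed, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 0


def main() -> None:
    protocol = standard_protocol()
    rows = []
    half_times = {}
    for idx, (name, params, n) in enumerate(
        [("wt", wt_parameters(), 4), ("ko", ko_parameters(), 5)]
    ):
        spec = CohortSpec(
            genotype=name,
            mean_params=params,
            n_animals=n,
            between_animal_cv=0.1,
            noise_sd=0.05,
            seed=animal_seed(SEED, idx),
        )
        recs = generate_cohort(spec, protocol)
        half_times[name] = []
        for i, rec in enumerate(recs):
            m = trace_metrics(rec, protocol)
            half_times[name].append(m.t_half)
            rows.append(
                {
                    "animal": f"{name}_{i:02d}",
                    "genotype": name,
                    "peak_um": m.peak_amplitude,
                    "t_half_s": m.t_half,
                    "baseline_um": m.baseline,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "cohort_metrics.csv", index=False, float_format="%.6g")
    print(df.groupby("genotype")[["peak_um", "t_half_s"]].agg(["mean", "std"]).round(3))
    t, dof, p = welch_t(half_times["ko"], half_times["wt"])
    print(
        f"\nWelch test on t1/2 (KO - WT): t = {t:.2f}, df = {dof:.1f}, p = {p:.4g}"
    )
    print(
        "clearance is significantly delayed in the KO cohort"
        if p < 0.05
        else "no significant t1/2 difference at this sample size"
    )
    print(f"per-animal metrics written to {OUT / 'cohort_metrics.csv'}")


if __name__ == "__main__":
    main()
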