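#!/usr/bin/env python
"""Link ROI activity residuals to learning performance.

Reads the cohort written by 02_fit_trajectories.py (regenerating it when
absent), residualizes activity against each stratum's selected age model,
and runs: hierarchical mixed regressions of performance on the residuals
(with the correlated-variables Bonferroni correction), the same battery
after removing 100%-scorers, and the standardized lagged regressions
predicting wave-2/3 performance from earlier-wave activity.

Writes results/brain_behavior.json.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from feedlearn import brain_behavior as bb
from feedlearn.pipeline import _jsonable
from feedlearn.synthetic_cohort import CohortConfig, generate_cohort
from feedlearn.trajectory_models import fit_ladder_by


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    parser.add_argument("--age-adjust", action="store_true",
                        help="add predictor-wave age to the lagged regressions")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort_path = Path("scratch") / "cohort_long.csv"
    if cohort_path.exists():
        long_df = pd.read_csv(cohort_path)
    else:  # same config + seed as 02_fit_trajectories.py -> identical cohort
        long_df, _ = generate_cohort(CohortConfig(), seed=args.seed)

    correction = bb.mc_adjust(6, 0.66, 0.05)
    measured_r = bb.mean_pairwise_correlation(long_df)
    print(f"adjusted alpha {correction.alpha_adjusted_rounded} "
          f"(m_eff {correction.m_eff:.2f}); measured mean correlation {measured_r:.2f}")

    ladders = fit_ladder_by(long_df, "activity")
    resid = bb.residualize(long_df, ladders)
    battery = bb.run_hierarchical_battery(resid, correction)
    for r in battery:
        mark = "**" if r.significant_adjusted else ("*" if r.significant_unadjusted else "")
        print(f"  {r.roi}/{r.contrast}: B = {r.b:.2f} (SE {r.se:.2f}), p = {r.p:.4f} {mark}")

    filtered, removed = bb.ceiling_filter(resid)
    battery_nc = bb.run_hierarchical_battery(filtered, correction)
    print(f"ceiling exclusion removed per wave: {removed}")

    lagged = []
    for pw, ow in ((1, 2), (2, 3), (1, 3)):
        for roi, contrast in resid[["roi", "contrast"]].drop_duplicates().itertuples(index=False):
            try:
                res = bb.lagged_prediction(long_df, pw, ow, roi, contrast,
                                           age_adjust=args.age_adjust)
            except bb.SampleSizeError:
                continue
            lagged.append(res)
            if contrast == "informative_value":
                print(f"  wave {pw} {roi} -> wave {ow} performance: "
                      f"beta = {res.beta:.2f}, p = {res.p:.4f}, N = {res.n}")

    report = {
        "mc_correction": {**dataclasses.asdict(correction),
                          "alpha_adjusted_rounded": correction.alpha_adjusted_rounded,
                          "measured_mean_pairwise_correlation": measured_r},
        "hierarchical": [dataclasses.asdict(r) for r in battery],
        "ceiling_sensitivity": {"removed_per_wave": removed,
                                "results": [dataclasses.asdict(r) for r in battery_nc]},
        "lagged": [dataclasses.asdict(r) for r in lagged],
    }
    (args.out_dir / "brain_behavior.json").write_text(
        json.dumps(_jsonable(report), indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
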