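"""Fit per-subject volumetric atrophy rates and summarize by group.

Reads the manifest written by 01_simulate_cohort.py, applies the 2.5-SD
outlier rule, fits OLS rates per subject x structure, and prints the pooled
group means — the expected pattern is ERC > amygdala > hippocampus in both
groups, elevated in MCI.
"""

import pandas as pd

from mtlmorph.pipeline import RunConfig, run_pipeline


def main() -> None:
    cfg = RunConfig(output_dir="results/demo", seed=11, n_subjects=5)
    run_pipeline(cfg, stages=("volumetry",))
    summary = pd.read_csv("results/demo/group_rates.csv")
    pooled = summary[summary.hemisphere == "pooled"]
    print("\nPooled group-mean atrophy rates (%/yr):")
    print(pooled.pivot(index="region", columns="group", values="mean_rate_pct_per_yr").round(2))


if __name__ == "__main__":
    main()
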