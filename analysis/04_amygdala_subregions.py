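"""Two-stage subregion mapping of the amygdala atlas.

Jointly aligns each phantom subject's timepoints, builds the midpoint
template from the averaged initial momenta, maps it to every timepoint with
volume LDDMM and fits per-subregion rates. The medial subregions (BMA, BLA,
CMA) should show markedly higher loss than the spared lateral amygdala.
"""

import pandas as pd

from mtlmorph.pipeline import RunConfig, run_pipeline


def main() -> None:
    cfg = RunConfig(output_dir="results/demo", seed=11, n_subjects=5)
    run_pipeline(cfg, stages=("subregions",))
    rates = pd.read_csv("results/demo/subregion_rates.csv")
    print("\nSubregional amygdala atrophy (%/yr), recovered vs generative:")
    print(
        rates[["subject_id", "subregion", "atrophy_rate_pct_per_yr", "generative_rate_pct_per_yr"]]
        .round(2)
        .to_string(index=False)
    )


if __name__ == "__main__":
    main()
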