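"""Simulate the synthetic longitudinal MTL cohort.

Writes NIfTI label volumes (plus baseline PET phantoms and reference masks),
a cohort manifest CSV and the generative ground-truth rate table under
results/demo/. Control and MCI generative regimes follow the group-ordered
pattern ERC > amygdala > hippocampus.
"""

import sys

from mtlmorph.pipeline import RunConfig, run_pipeline


def main(seed: int = 11) -> None:
    cfg = RunConfig(output_dir="results/demo", seed=seed, n_subjects=5)
    run_pipeline(cfg, stages=("simulate",))
    print(f"cohort written to {cfg.output_dir} (seed={seed}, 2 groups x {cfg.n_subjects} subjects)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 11)
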