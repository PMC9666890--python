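#!/usr/bin/env python
"""Generate the synthetic two-sample study used by the downstream steps.

One binary exposure GWAS at FinnGen-hypertension scale (218,754 samples,
70 genome-wide-significant candidate SNPs in AR(1) LD blocks) paired
with four quantitative cardiac-phenotype outcomes: two at LA-GWAS scale
(35,648 samples; causal effects +0.126 and -0.105) and two at LV-GWAS
scale (16,923 samples; +0.171 with directional pleiotropy, and a null
effect 0).  Everything is written as plain TSV/JSON under
results/synthetic_study/.
"""

from pathlib import Path

import pandas as pd

from mrkit.simulate import (SimulationConfig, scramble_outcome_representation,
                            simulate_additional_outcome, simulate_study,
                            write_study)

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"
SEED = 20260920

OUTCOME_PLAN = [
    # (name, beta_causal, n_outcome, pleio_fraction, pleio_mean, pleio_sd)
    ("la_volume_like", None, None, 0.0, 0.0, 0.0),    # comes with the base study
    ("la_function_like", -0.105, 35_648, 0.0, 0.0, 0.0),
    ("lv_mass_like", 0.171, 16_923, 0.2, 0.01, 0.005),
    ("lv_null_like", 0.0, 16_923, 0.0, 0.0, 0.0),
]


def main() -> None:
    # 60 LD blocks over 70 SNPs: ten correlated pairs plus independent
    # singletons, so clumping has real work but the post-clump panel
    # stays at the tens-of-instruments scale typical of a strong
    # binary-trait GWAS
    cfg = SimulationConfig(n_snps=70, beta_causal=0.126, n_outcome=35_648,
                           ld_blocks=60, ld_rho=0.6, seed=SEED)
    study = simulate_study(cfg)
    # re-express the base outcome's allele coding at random so step 03
    # exercises the harmonization truth table
    study = scramble_outcome_representation(study, seed=SEED + 1)
    write_study(study, OUTDIR)
    study.outcome.to_frame().to_csv(OUTDIR / "outcome_la_volume_like.tsv",
                                    sep="\t", index=False)

    for i, (name, beta, n, pf, pm, ps) in enumerate(OUTCOME_PLAN[1:], start=2):
        table = simulate_additional_outcome(study, name, beta_causal=beta,
                                            n_outcome=n, seed=SEED + i,
                                            pleio_fraction=pf, pleio_mean=pm,
                                            pleio_sd=ps)
        table.to_frame().to_csv(OUTDIR / f"outcome_{name}.tsv", sep="\t", index=False)

    exp = study.exposure.to_frame()
    print(f"wrote synthetic study to {OUTDIR}")
    print(f"  exposure: {len(exp)} SNPs, all p < 5e-8 "
          f"(min p {exp.pvalue.min():.2e}, median F "
          f"{((exp.beta / exp.se) ** 2).median():.0f})")
    for name, beta, *_ in OUTCOME_PLAN:
        b = study.truth.beta_causal if beta is None else beta
        print(f"  outcome {name}: true causal effect {b:+.3f}")


if __name__ == "__main__":
    main()
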