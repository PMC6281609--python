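#!/usr/bin/env python
"""Causal inference study: expression quantification and the four-test CIT.

From the F2 intercross, 12 heterozygous and 12 wildtype males are profiled
by simulated triplicate qPCR; relative expression comes from the 2^-ddCt
transform with the heterozygote group as calibrator (its mean is exactly 1
by construction).  Each of 20 fat/organ traits (raw and body-weight-
adjusted, all litter-residualized) then passes through the four component
tests; the causal label requires association of genotype with trait,
genotype with expression given trait, expression with trait given genotype,
and *no* residual genotype effect given expression.

Tables land in results/cit/; the calibration block reports false-causal
rate and power of the conjunction over replicates.
"""

import warnings

from qtgtest import RunConfig, cit_false_causal_rate, cit_power, run_cit_study

SEED = 2029


def main() -> None:
    warnings.simplefilter("ignore")
    cfg = RunConfig(seed=SEED, outdir="results/cit")
    bundle = run_cit_study(cfg)

    print("relative liver expression by genotype (calibrator KO/B6J):")
    print(bundle["expression_summary"].round(3).to_string())

    table = bundle["table"].set_index("trait")
    called = table[table["label"] != "not_causal"]
    print(f"\ntraits on the causal path ({len(called)}/{len(table)}):")
    if len(called):
        print(called[["p1", "p2", "p3", "p4", "r_squared", "label"]]
              .round(4).to_string())
    print(f"\nfocal trait: expression explains "
          f"R^2 = {bundle['focal_r_squared']:.2f} of variance "
          f"({'negative' if bundle['focal_slope_sign'] < 0 else 'positive'}"
          " correlation)")

    false_rate = cit_false_causal_rate(n_replicates=300, seed=SEED + 1)
    power = cit_power(n_replicates=300, seed=SEED + 2)
    print(f"\ncalibration over 300 replicates at n = 12 + 12: "
          f"false-causal rate {false_rate.rate:.3f} "
          f"(independent model), causal-call power {power.rate:.3f} "
          f"(mediated model, expression ratio ~2, population R^2 ~0.29)")


if __name__ == "__main__":
    main()
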