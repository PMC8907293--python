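"""Parameter-recovery experiment for the five-cohort pooled odds ratio.

Simulates the five cohorts at the per-stage sample sizes with a true
per-allele OR of 1.41, pools each replicate's sex/age-adjusted per-cohort
log ORs by inverse variance (and the raw allele-count tables by
Mantel-Haenszel), and summarizes bias and 95% CI coverage. Per-replicate
estimates go to results/pooled_or_replicates.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from enhscreen.study import pooled_or_recovery


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=500)
    parser.add_argument(
        "--out", type=Path, default=Path("results/pooled_or_replicates.tsv")
    )
    args = parser.parse_args()

    df = pooled_or_recovery(args.replicates, seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)

    truth = df.attrs["truth_log_or"]
    for label, col in (("inverse-variance", "iv"), ("Mantel-Haenszel", "mh")):
        betas = df[f"{col}_beta"]
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        print(
            f"{label}: mean pooled OR = {np.exp(betas.mean()):.4f} "
            f"(truth 1.41), mean log OR = {betas.mean():.4f} "
            f"(truth {truth:.4f}, MC SE {mc_se:.4f}), "
            f"coverage = {df[f'{col}_covered'].mean():.1%}"
        )
    print(f"replicate table: {args.out}")


if __name__ == "__main__":
    main()
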