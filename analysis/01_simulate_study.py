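"""Generate the synthetic five-cohort study the downstream analyses run on.

Writes genotype/phenotype TSVs for the discovery stage and the four
replication cohorts at the study's per-stage sample sizes, plus the
variant table, expression matrix, gene-TSS table, enhancer-mark/motif BED
tracks, promoter FASTA, and the pipeline YAML config, under
results/study/.
"""

import argparse
from pathlib import Path

import yaml

from enhscreen.cli import _config_to_dict
from enhscreen.study import StudyDesign, build_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/study"))
    args = parser.parse_args()

    design = StudyDesign(seed=args.seed)
    config = build_study(args.out, design)
    with open(args.out / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)

    total_cases = sum(a for a, _ in design.stage_sizes.values())
    total_controls = sum(b for _, b in design.stage_sizes.values())
    print(f"wrote study to {args.out} (seed {args.seed})")
    print(f"  cohorts: {', '.join(design.stage_sizes)}")
    print(f"  subjects: {total_cases} cases / {total_controls} controls")
    print(
        f"  variants: 1 planted (OR {design.planted_or}, MAF {design.planted_maf}) "
        f"+ {design.n_null_variants} null"
    )
    print(f"  config: {args.out / 'pipeline.yaml'}")


if __name__ == "__main__":
    main()
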