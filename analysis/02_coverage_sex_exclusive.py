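#!/usr/bin/env python
"""Coverage summaries and sex-exclusive coverage calls on the simulated
cohort (run 01_simulate_cohort.py first).

Writes results/coverage_summary.tsv and results/sex_exclusive_sites.tsv and
reports the per-group coverage fractions and the contig counts carrying
sex-exclusive positions.
"""

import argparse
from pathlib import Path

import pandas as pd

from sexvarscan.depth import (
    DepthMatrix,
    coverage_summary,
    sex_exclusive_positions,
    summaries_to_frame,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    if not args.cohort_dir.exists():
        raise SystemExit(f"{args.cohort_dir} missing - run 01_simulate_cohort.py first")

    tables = {p.name.replace(".depth.tsv", ""): p
              for p in sorted(args.cohort_dir.glob("*.depth.tsv"))}
    matrix = DepthMatrix.from_files(tables)
    males = [s for s in matrix.samples if s.startswith("male")]
    females = [s for s in matrix.samples if s.startswith("female")]

    summaries = [coverage_summary(matrix, [s], name=s) for s in matrix.samples]
    summaries += [
        coverage_summary(matrix, males, name="males"),
        coverage_summary(matrix, females, name="females"),
        coverage_summary(matrix, matrix.samples, name="all"),
    ]
    frame = summaries_to_frame(summaries)
    frame.to_csv(args.out_dir / "coverage_summary.tsv", sep="\t", index=False)
    pooled = frame[frame.group.isin(["males", "females", "all"])]
    print("pooled coverage:")
    print(pooled.to_string(index=False))

    rows = []
    for zero_sex, zero, covered in (("female", females, males), ("male", males, females)):
        sites, n_contigs = sex_exclusive_positions(matrix, zero, covered, zero_sex=zero_sex)
        rows += [(s.contig, s.pos, s.zero_sex, s.supporting_samples) for s in sites]
        print(f"{zero_sex}-zero exclusive positions: {len(sites)} on {n_contigs} contig(s)")
    pd.DataFrame(rows, columns=["contig", "pos", "zero_sex", "supporting_samples"]).to_csv(
        args.out_dir / "sex_exclusive_sites.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
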