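#!/usr/bin/env python
"""Pairwise NG86 dN/dS over the simulated ortholog pairs (run
01_simulate_cohort.py first).

Builds gap-free codon alignments from the protein/CDS FASTAs, estimates
dN, dS and omega per pair, applies the dS plausibility filter
(0.01 <= dS <= 2) and classifies selection. Writes results/dnds.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from sexvarscan.dnds import classify_selection, codon_align, ds_filter, ng86_dnds


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    cds_path = args.cohort_dir / "cds_pairs.fna"
    if not cds_path.exists():
        raise SystemExit(f"{cds_path} missing - run 01_simulate_cohort.py first")

    prot = {r.id: str(r.seq) for r in SeqIO.parse(args.cohort_dir / "protein_pairs.faa", "fasta")}
    nucs = {r.id: str(r.seq) for r in SeqIO.parse(cds_path, "fasta")}
    pair_ids = sorted({rid[:-2] for rid in nucs if rid.endswith("_a")})

    results = []
    for pid in pair_ids:
        aln = codon_align(prot[f"{pid}_a"], prot[f"{pid}_b"],
                          nucs[f"{pid}_a"], nucs[f"{pid}_b"], pair_id=pid)
        results.append(ng86_dnds(aln))
    kept, dropped = ds_filter(results)

    frame = pd.DataFrame(
        [
            {"pair_id": r.pair_id, "S": r.counts.S, "N": r.counts.N,
             "Sd": r.counts.Sd, "Nd": r.counts.Nd, "dN": r.dN, "dS": r.dS,
             "omega": r.omega, "kept": r.kept_by_ds_filter,
             "class": classify_selection(r.omega)}
            for r in results
        ]
    )
    frame.to_csv(args.out_dir / "dnds.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    print(f"\nkept {len(kept)} / dropped {len(dropped)} by the dS filter "
          f"(0.01 <= dS <= 2)")


if __name__ == "__main__":
    main()
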