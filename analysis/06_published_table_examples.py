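#!/usr/bin/env python
"""Worked examples over the published 15-cluster table shipped with the
package: threshold filtering, the column maximum and distinct-gene
deduplication (one gene flanks two adjacent clusters, so 15 peaks name 14
distinct genes)."""

from sexvarscan.tables import clusters_at_threshold, distinct_short_names, load_published_clusters


def main() -> None:
    table = load_published_clusters()
    at30 = clusters_at_threshold(table, threshold=30)
    print(f"published table rows: {len(table)}")
    print(f"clusters with >= 30 variants: {len(at30)}")
    print(f"largest cluster: {int(table['variants'].max())} variants "
          f"({table.loc[table['variants'].idxmax(), 'reference_sequence']})")
    print(f"distinct nearest-gene short names: {distinct_short_names(table)}")
    dup = table["short_name"].value_counts()
    print(f"shared gene(s): {', '.join(dup[dup > 1].index)}")


if __name__ == "__main__":
    main()
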