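"""Access to the published top-cluster table shipped with the package.

The table lists the 15 strongest 10 kb clusters of sex-associated variation
found in the Russian sturgeon cohort against the sterlet female reference
(first/last variant position, variant count, nearest gene, in-gene flag).
It serves as a printed-data input for worked examples: threshold filtering,
column maxima and distinct-gene deduplication can be recomputed from it
without any sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_published_clusters() -> pd.DataFrame:
    """The published 15-row sex-variable cluster table as a DataFrame with
    columns reference_sequence, start, end, variants, nearest_gene,
    short_name, in_gene ('+'/'-')."""
    ref = resources.files("sexvarscan").joinpath("data/published_sex_clusters.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def clusters_at_threshold(
    table: pd.DataFrame, threshold: int = 30, strict: bool = False
) -> pd.DataFrame:
    """Rows whose variant count reaches the cluster threshold (>= by
    default, > when strict), mirroring scan_clusters comparators."""
    col = table["variants"]
    return table[col > threshold] if strict else table[col >= threshold]


def distinct_short_names(table: pd.DataFrame) -> int:
    """Number of unique nearest-gene short names over the table rows."""
    return int(table["short_name"].nunique())
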