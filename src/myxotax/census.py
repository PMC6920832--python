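"""Published suborder-level census of myxobacterial 16S diversity.

Bundles the per-suborder taxon and sequence counts from the published
meta-analysis of 4997 public near-full-length myxobacterial 16S rRNA
gene sequences (20 suborders, 58 families, 445 genera, 998 species),
for consistency checks of the summary arithmetic without refetching
thousands of database accessions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import RANKS

#: How many suborders/families/genera/species the validly described
#: type strains of the order *Myxococcales* fall into when reclassified
#: under the same identity thresholds.  Subtracting these from the
#: census totals gives the number of newly delineated taxa per rank.
TYPE_STRAIN_RECLASSIFICATION: dict[str, int] = {
    "suborder": 4,
    "family": 7,
    "genus": 13,
    "species": 24,
}


def load_suborder_census() -> pd.DataFrame:
    """The 20 published per-suborder count rows (no totals row)."""
    ref = resources.files("myxotax.data") / "myxococcales_suborder_census.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def census_totals() -> dict[str, int]:
    """Rank-wise totals of the published census, plus sequence count."""
    df = load_suborder_census()
    return {
        "suborder": len(df),
        "family": int(df["families"].sum()),
        "genus": int(df["genera"].sum()),
        "species": int(df["species"].sum()),
        "sequences": int(df["sequences"].sum()),
    }
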