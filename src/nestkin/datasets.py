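"""Packaged reference tables.

``spain_nests_2016_2019.tsv`` holds the published per-nest summary record of
the 2016-2019 sporadic loggerhead nesting events on the Spanish Mediterranean
coast: laying/emergence dates, number of genotyped hatchlings, mtDNA D-loop
haplotype and its regional origin, and the per-nest genomic summaries
(percent polymorphic loci, mean observed heterozygosity, mean within-nest
Manichaikul relatedness).  Nests without genetic data carry NA in the genomic
columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_spanish_nest_table() -> pd.DataFrame:
    """Published per-nest summaries for the 2016-2019 Spanish sporadic nests."""
    with resources.files("nestkin.data").joinpath(
        "spain_nests_2016_2019.tsv"
    ).open("r") as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])
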