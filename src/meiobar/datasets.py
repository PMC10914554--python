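"""Bundled small tabular datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def levantine_specimen_counts() -> pd.DataFrame:
    """Published per-station sorted-specimen counts from the south-eastern
    Levantine basin survey (hard-bodied groups, summed over replicate cores
    and horizons; grand total 56,231 specimens).

    Columns: station, then one column per counted group.
    """
    with resources.files("meiobar.data").joinpath("levantine_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def levantine_counts_long() -> pd.DataFrame:
    """Same data in long (station, taxon_group, count) form."""
    wide = levantine_specimen_counts()
    long = wide.melt(id_vars="station", var_name="taxon_group", value_name="count")
    long = long.dropna(subset=["count"])
    long["count"] = long["count"].astype(int)
    return long.reset_index(drop=True)
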