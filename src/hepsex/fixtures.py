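"""Packaged gene-list fixtures: published sex-chromosome, X-escape and chr19 panels."""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    "table1": "table1_sex_chromosome_genes.tsv",
    "table2": "table2_escape_panel.tsv",
    "escape_panel": "table2_escape_panel.tsv",
    "table3": "table3_chr19_genes.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged gene-list table.

    Known names: ``table1`` (sex-chromosome genes with signed fold-changes),
    ``table2``/``escape_panel`` (the 15-gene X-inactivation escape panel with
    composite array scores), ``table3`` (chromosome-19 genes).
    """
    try:
        fname = _FILES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; known: {sorted(set(_FILES))}") from None
    with resources.files("hepsex.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])
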