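"""Bundled published reference tables.

Two small TSVs ship with the package:

* ``genome_annotation_counts.tsv`` — per species, the Ensembl gene count and
  the Swiss-Prot reviewed protein-coding gene (PCG) count (UniProt release
  2024_04 / Ensembl 2024_05), with the percentage as printed in the source
  table.
* ``proteome_width_totals.tsv`` — per species, the PCG count and the printed
  proteoform totals under the three width models, with the printed per-PCG
  ratios.

These are *inputs*: the package recomputes the ratio columns from the count
columns and compares against the printed values. The printed percentage
column mixes truncation with rounding in a handful of rows; recomputation is
expected to match only where the two conventions agree.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_annotation_counts", "load_width_totals"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("proteowidth.data").joinpath(name).open("r") as fh:
        # printed columns keep their printed form (e.g. "11", not 11.0)
        return pd.read_csv(fh, sep="\t", dtype={"percent_printed": str})


def load_annotation_counts() -> pd.DataFrame:
    """Species, taxon, Ensembl gene count, reviewed PCG count, printed %."""
    return _load("genome_annotation_counts.tsv")


def load_width_totals() -> pd.DataFrame:
    """Species, PCG and printed proteoform totals/ratios for the 3 models."""
    return _load("proteome_width_totals.tsv")
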