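"""Packaged reference tables for Eubacterium/Roseburia flagellins.

Two small tab-separated tables ship with the package:

* ``reference_flagellins.tsv`` — one row per annotated flagellin CDS in the
  nine study genomes/strains: species, locus tag, phylogenetic clade, protein
  size (aa and kDa) and the first ten residues of the predicted protein.
* ``reference_promoters.tsv`` — one row per predicted promoter call (a gene
  may have two, one per sigma factor) with the observed -35/-10 elements,
  the spacer length, the distance from the -10 element to the start codon
  and the predicted ribosome binding site with its start-codon spacing.

Dashes mark genes for which no promoter (or RBS) could be predicted.  These
tables are reference inputs for the summary and N-terminal comparison
utilities; they are not produced by scanning (no genome sequences ship with
the package).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with (files("flagmet") / "data" / name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_reference_flagellins() -> pd.DataFrame:
    df = _load("reference_flagellins.tsv")
    df["size_aa"] = df["size_aa"].astype(int)
    df["size_kda"] = df["size_kda"].astype(float)
    return df


def load_reference_promoters() -> pd.DataFrame:
    """Promoter calls with numeric columns coerced; dash rows keep NaN."""
    df = _load("reference_promoters.tsv")
    for col in ("sigma", "spacing_35_10", "dist_10_to_start", "rbs_spacing"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
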