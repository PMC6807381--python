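"""Bundled published reference tables.

Three small ISFinder-derived tables ship with the package:

* the catalogue of the 65 short bacterial IS6/IS26-family elements
  (clades I-VI plus the ISFal2 outlier) with their recorded element and
  transposase lengths, TIR/TSD lengths, clade and accession;
* the 8x8 pairwise nucleotide-identity matrix of the IS257/IS431 isoform
  group;
* the matching 8x8 transposase amino-acid-similarity matrix.

These are the printed inputs of the comparator-dependence and summary
analyses; full sequences are not redistributed here and, where needed, are
loaded from user-supplied accession FASTA files instead.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("isfamily.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kw)


def load_short_bacterial_catalog() -> pd.DataFrame:
    """The 65 curated short bacterial family members (lengths, clades)."""
    return _read("short_bacterial_catalog.tsv")


def load_is257_nt_identity() -> pd.DataFrame:
    """Pairwise DNA identity (%) within the IS257/IS431 group."""
    return _read("is257_group_nt_identity.tsv", index_col=0)


def load_is257_aa_similarity() -> pd.DataFrame:
    """Pairwise transposase amino-acid similarity (%) within the IS257/IS431 group."""
    return _read("is257_group_aa_similarity.tsv", index_col=0)
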