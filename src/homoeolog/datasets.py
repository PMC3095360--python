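"""Published summary tables bundled as package data.

Two small TSVs ship with the package: per-BAC characteristics of the
eight sequenced white clover clones (length, gene incidence, gene-space
fraction) and the per-homoeologue identity/similarity/Ks/Ka table for
the 18 homoeologous gene pairs.  They are the reference inputs for the
clock and aggregate-statistics reproductions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_bac_summary", "load_homoeolog_gene_stats"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("homoeolog.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_bac_summary() -> pd.DataFrame:
    """Per-BAC summary statistics of the eight sequenced clover clones."""
    return _read("bac_characteristics.tsv")


def load_homoeolog_gene_stats() -> pd.DataFrame:
    """Identity, similarity, Ks and Ka for the 18 homoeologous gene pairs.

    ``complete`` flags rows with a full set of statistics; the two rows
    with exon-structure differences carry an exon identity computed on
    matched exons only and are excluded from aggregate means.
    """
    df = _read("homoeolog_gene_stats.tsv")
    df["complete"] = df["complete"].astype(bool)
    return df
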