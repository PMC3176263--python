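"""Packaged reference data: the published annotation tables, codon-usage
counts, per-gene divergences and base compositions of the F- and M-type
*Musculista senhousia* mitochondrial genomes (GenBank GU001953-GU001954).

These carry coordinates and counts only, no sequence; sequence-level work
runs on synthetic genomes from :mod:`mitopair.simulate`.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .codon_usage import CodonCountTable
from .genomes import FeatureTable, read_feature_table


def _data_path(name: str):
    return resources.files("mitopair.data").joinpath(name)


def feature_table_f() -> FeatureTable:
    """Annotation of the female (F-type) genome, 21,557 bp."""
    with resources.as_file(_data_path("msenhousia_F_features.tsv")) as p:
        return read_feature_table(p)


def feature_table_m() -> FeatureTable:
    """Annotation of the male (M-type) genome, 20,612 bp."""
    with resources.as_file(_data_path("msenhousia_M_features.tsv")) as p:
        return read_feature_table(p)


def _read_tsv(name: str) -> pd.DataFrame:
    text = _data_path(name).read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")


def codon_counts(lineage: str) -> CodonCountTable:
    """Published 64-codon usage counts ('F' sums to 3792, 'M' to 4098)."""
    if lineage not in ("F", "M"):
        raise ValueError("lineage must be 'F' or 'M'")
    df = _read_tsv("msenhousia_codon_counts.tsv")
    return CodonCountTable(lineage, dict(zip(df["Codon"], df[lineage])))


def gene_divergence() -> pd.DataFrame:
    """Published per-gene residue counts, pD, Ks, Ka and Ka/Ks."""
    return _read_tsv("msenhousia_gene_divergence.tsv")


def composition_rows() -> pd.DataFrame:
    """Published per-region base compositions (percent T, C, A, G)."""
    return _read_tsv("msenhousia_composition.tsv")


def table_fixtures() -> dict:
    """Everything at once, keyed by content."""
    return {
        "features_f": feature_table_f(),
        "features_m": feature_table_m(),
        "codons_f": codon_counts("F"),
        "codons_m": codon_counts("M"),
        "gene_divergence": gene_divergence(),
        "composition": composition_rows(),
    }
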