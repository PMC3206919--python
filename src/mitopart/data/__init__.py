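"""Bundled worked-example datasets.

Small published summary tables from a cetacean mitogenome partition study:
per-gene clade posterior probabilities for killer-whale (Orcinus) ecotype
clades with each gene's clock coefficient of rate variation, and per-gene
median TMRCA summaries with bias values for the Transient killer-whale and
Globicephalinae nodes. They serve as ready-made inputs for the gene-selection
and date-comparison examples; they are printed summaries, not raw traces.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..geneselect import SupportMatrix


def _path(name: str):
    return resources.files(__package__) / name


def killer_whale_support() -> SupportMatrix:
    """Genes x clades PP matrix for the eight killer-whale ecotype clades.

    Includes the per-gene coefficient of rate variation used for greedy
    tie-breaking.
    """
    return SupportMatrix.from_csv(_path("killer_whale_support.csv"))


def killer_whale_subset_pp() -> dict[str, float]:
    """Clade PPs of the concatenated informative subset (COX1+ATP6+ND3+CYTB)."""
    df = pd.read_csv(_path("killer_whale_subset_support.csv"))
    return dict(zip(df["clade"], df["pp"]))


def tmrca_table() -> pd.DataFrame:
    """Median TMRCA, 95% HPD and bias per (node, partition).

    Nodes: ``Transient`` (killer whales, ages in My) and ``Globicephalinae``
    (delphinids). The ``mitogenome`` rows are the reference estimates the
    other partitions are compared against.
    """
    return pd.read_csv(_path("tmrca_bias_table.csv"))
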