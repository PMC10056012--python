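"""Readers for the packaged reference tables and the TSV dialects.

All tabular interchange is plain TSV readable/writable with pandas; junction
tables follow a STAR SJ-style dialect (donor, acceptor, reads) with
transcript-space coordinates and symbolic intronic offsets ("2811-20").
"""

from __future__ import annotations

from importlib import resources
from io import StringIO
from pathlib import Path

import pandas as pd

__all__ = [
    "load_splice_table",
    "load_classification_table",
    "load_cohort_cases",
    "read_tsv",
]


def _packaged(name: str) -> pd.DataFrame:
    ref = resources.files("dysfrna.data").joinpath(name)
    return pd.read_csv(StringIO(ref.read_text()), sep="\t")


def load_splice_table() -> pd.DataFrame:
    """The published catalogue of splice-altering variants: one row per
    transcript product (consequence, percent of transcripts or ND,
    homozygosity, whether the variant was originally called missense)."""
    return _packaged("splice_events_table.tsv")


def load_classification_table() -> pd.DataFrame:
    """The published 111-variant classification table: prior call, study
    classification, novelty flag."""
    return _packaged("variant_classifications.tsv")


def load_cohort_cases() -> pd.DataFrame:
    """Synthetic per-case cohort table reproducing the study's published
    case-mix counts (starting stratum, post-study P/LP count, phase)."""
    return _packaged("synthetic_cohort_cases.tsv")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
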