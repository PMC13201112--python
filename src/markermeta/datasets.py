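"""Bundled evidence tables for the PLK1/MYCN colorectal-cancer synthesis.

Three curated tables ship with the package:

* ``plk1_contingency.csv`` — 18 per-cohort diagnostic 2x2 tables
  (TP/FP/FN/TN) for median-dichotomized PLK1 expression
  (2259 tumor, 1260 non-tumor samples in total);
* ``mycn_contingency.csv`` — the analogous 22 tables for MYCN
  (2307 tumor, 1306 non-tumor);
* ``plk1_mycn_correlation.csv`` — per-cohort Pearson correlations between
  PLK1 and MYCN expression with raw p-values and BH-FDR values (17 rows).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .correlation import CohortCorrelation, read_cohort_correlations
from .io import ContingencyTable, read_contingency_csv


def _data_path(name: str):
    return resources.files("markermeta") / "data" / name


def load_plk1_contingency() -> list[ContingencyTable]:
    """18 per-cohort diagnostic tables for PLK1 in colorectal cancer."""
    with resources.as_file(_data_path("plk1_contingency.csv")) as p:
        return read_contingency_csv(p)


def load_mycn_contingency() -> list[ContingencyTable]:
    """22 per-cohort diagnostic tables for MYCN in colorectal cancer."""
    with resources.as_file(_data_path("mycn_contingency.csv")) as p:
        return read_contingency_csv(p)


def load_plk1_mycn_correlations() -> list[CohortCorrelation]:
    """Per-cohort PLK1-MYCN Pearson correlations (R, raw p, published FDR)."""
    with resources.as_file(_data_path("plk1_mycn_correlation.csv")) as p:
        return read_cohort_correlations(p)


def load_plk1_mycn_correlation_frame() -> pd.DataFrame:
    """The correlation table as a raw DataFrame (Cohort, R, p.value, FDR)."""
    with resources.as_file(_data_path("plk1_mycn_correlation.csv")) as p:
        return pd.read_csv(p)
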