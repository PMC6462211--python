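"""Bundled reference data.

``load_epiphyte_survey`` returns the published per-network summary of 12
quantitative epiphyte-phorophyte surveys from tropical and subtropical
forests (locality, habitat code, sampling method, network size, and the
NODF, H2' and Q values with their fixed-fixed null-model significance
flags).  Two networks lack a published interaction matrix, so their Q (and
for these the metrics marked as taken from the original source) carry
missing values; summary statistics therefore use n = 12 for H2' and n = 10
for Q.

Habitat codes: TMF tropical montane forest, TDF tropical dry forest, LIF
low inundated forest, TRF temperate rainforest, ECF evergreen cloud forest.
Sampling: GR ground-based survey, CA canopy-based survey.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_epiphyte_survey() -> pd.DataFrame:
    """Per-network metric summary of the 12-network epiphyte-phorophyte survey."""
    with resources.files("epinet.data").joinpath("epiphyte_survey.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["na"])
    return df


def survey_summary(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean and sample SD of each metric column, ignoring missing entries."""
    if df is None:
        df = load_epiphyte_survey()
    out = []
    for metric in ("NODF", "H2prime", "Q"):
        col = df[metric].dropna()
        out.append({
            "metric": metric, "n": len(col),
            "mean": col.mean(), "sd": col.std(ddof=1),
        })
    return pd.DataFrame(out)
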