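"""Bundled reference data.

``load_donor_cohort`` returns the 14-donor skeletal-muscle-derived-cell
cohort used throughout the examples and the cohort-statistics layer: one
row per donor with age, sex, ethnicity, tissue of origin, diabetes flag,
BMI, lifestyle flags (tobacco, alcohol, non-IV drug use), the fusion
index measured after 5 days of differentiation, and the flow-cytometry
CD56-positive percentage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_donor_cohort"]


def load_donor_cohort() -> pd.DataFrame:
    with resources.files("myoshape.data").joinpath("donor_cohort.csv").open() as fh:
        return pd.read_csv(fh)
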