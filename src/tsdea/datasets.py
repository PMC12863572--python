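"""Packaged reference tables from the Yunnan 2023 county-level study.

Two small CSVs ship with the package:

* ``yunnan2023_stage3_scores.csv`` — the published per-DMU stage-3
  efficiency scores and ranks for the 129 county-level administrative
  divisions (17 municipal districts, 112 county areas) under three DEA
  models: BCC (variable returns), CCR (constant returns) and the
  slacks-based measure (SBM).  Scores are the 2-decimal printed values;
  ranks are integers 1..129 within each model column.
* ``yunnan2023_variable_summary.csv`` — the published descriptive
  statistics (mean, SD, min, max, CV) of the four inputs, two outputs
  and four environmental variables.

The per-DMU raw inputs and outputs of the study were never published;
these summary tables are the only study data the package carries.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_stage3_fixture", "load_variable_summary"]

_DATA = resources.files("tsdea") / "data"

#: Number of county-level divisions in the study and the group split.
N_DMU = 129
N_DISTRICT = 17
N_COUNTY = 112


def load_stage3_fixture() -> pd.DataFrame:
    """Published stage-3 scores and ranks for the 129 DMUs.

    Returns a frame with columns ``prefecture``, ``dmu``, ``group``
    ("district" for the 17 municipal districts, "county area" otherwise),
    and paired score/rank columns ``bcc_te``/``bcc_rank``,
    ``ccr_te``/``ccr_rank``, ``sbm_eff``/``sbm_rank``.
    """
    with (_DATA / "yunnan2023_stage3_scores.csv").open() as fh:
        df = pd.read_csv(fh)
    n = len(df)
    for col in ("bcc_rank", "ccr_rank", "sbm_rank"):
        if sorted(df[col]) != list(range(1, n + 1)):
            raise RuntimeError(f"fixture column {col} is not a 1..{n} permutation")
    return df


def load_variable_summary() -> pd.DataFrame:
    """Published descriptive statistics of all study variables."""
    with (_DATA / "yunnan2023_variable_summary.csv").open() as fh:
        return pd.read_csv(fh, index_col="variable")
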