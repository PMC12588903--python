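"""Packaged reference datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_combination_table"]


def load_combination_table() -> pd.DataFrame:
    """The published THSG + EG combination-ray table.

    Ten dose pairs with the predicted additive effects from both drugs'
    perspectives (``f_additive``, ``g_additive``), the observed effect
    ``y_obs`` (all percent inhibition), the reported 4-dp combination indices
    and the reported interaction judgment.  Used as a regression fixture for
    the combination-index and judgment rules.
    """
    ref = resources.files("pmtox.data") / "thsg_eg_combination_table.csv"
    with ref.open("r") as fh:
        return pd.read_csv(fh)
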