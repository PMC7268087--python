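"""Bundled published summary statistics for worked examples and checks.

``reference_group_means.csv`` holds per-state group means and SDs of the
four temporal measures (fractional occupancy in %, number of occurrences,
mean lifetime in ms, mean interval in s) from a published MEG case-control
study of ZDHHC9-associated intellectual disability: 7 controls vs 8 cases,
8 envelope-HMM states, resting-state and auditory-oddball protocols. The
table is an input: applying the control-minus-case difference-of-means
operation to it reproduces that study's reported group differences, which
makes it a convenient exact check of the group-summary arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import MEASURES, difference_of_means

__all__ = ["load_reference_group_means", "reference_differences"]


def load_reference_group_means() -> pd.DataFrame:
    """The bundled per-(protocol, state, group) summary table."""
    with resources.files("netdyn.data").joinpath("reference_group_means.csv").open() as fh:
        return pd.read_csv(fh)


def reference_differences() -> pd.DataFrame:
    """Control-minus-case differences of the bundled group means, one row per
    (protocol, state) with one column per measure."""
    table = load_reference_group_means()
    rows = []
    for (protocol, state), chunk in table.groupby(["protocol", "state"], sort=False):
        control = chunk[chunk["group"] == "control"].iloc[0]
        case = chunk[chunk["group"] == "case"].iloc[0]
        row = {"protocol": protocol, "state": state, "network": control["network"]}
        for measure in MEASURES:
            row[f"{measure}_diff"] = difference_of_means(
                control[f"{measure}_mean"], case[f"{measure}_mean"]
            )
        rows.append(row)
    return pd.DataFrame(rows)
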