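"""Bundled reference data.

The corticosteroid binding-affinity benchmark is the classic validation set
for grid-based 3D-QSAR: 21 training and 10 test steroids with pKi values for
binding to corticosteroid-binding globulin.  The activity table (names, pKi,
train/test split) ships with the package; the pre-aligned 3D structures are
distributed externally and are not bundled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_steroid_activity_table"]


def load_steroid_activity_table() -> pd.DataFrame:
    """Steroid benchmark activities: columns name, pKi, set (train|test)."""
    with resources.files("comsia.data").joinpath("steroid_activities.csv").open() as fh:
        df = pd.read_csv(fh)
    df["pKi"] = df["pKi"].astype(float)
    return df
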