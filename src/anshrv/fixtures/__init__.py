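"""Packaged reference tables (values exactly as printed in the source study).

``load_progression_table`` returns the published 10-state simulated
feature trajectory used as the calibration target; ``load_group_table``
returns the published control-vs-AD group medians with their
Mann–Whitney statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_progression_table", "load_group_table"]

# printed column name -> canonical feature column
_CANONICAL = {"sd1": "sd1_ms", "sd2": "sd2_ms", "sdnn": "sdnn_ms", "rmssd": "rmssd_ms"}


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_progression_table() -> pd.DataFrame:
    """The published 10-state progression feature table."""
    return _read("progression_states.csv").rename(columns=_CANONICAL)


def load_group_table() -> pd.DataFrame:
    """The published control-vs-AD median comparison (p values as printed,
    including the '<0.001' entries, hence strings)."""
    return _read("group_comparison.csv")
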