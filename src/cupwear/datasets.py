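"""Packaged reference datasets.

The published hip-simulator study these fixtures come from reports, for
nine polyethylene acetabular cups (three per material), the CT-derived and
gravimetric mass losses at two million cycles, and per-material mean +/- SD
gravimetric losses at each 0.4 Mc weighing stop.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .agreement import MethodPair, pairs_from_dataframe

__all__ = [
    "load_table1",
    "load_table2_frame",
    "load_table2_pairs",
    "load_table2_printed_differences",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("cupwear.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Per-material mean +/- SD gravimetric loss (mg) at each 0.4 Mc stop."""
    return _read("table1_gravimetric_loss.csv")


def load_table2_frame() -> pd.DataFrame:
    """Nine specimens x (CT mass loss, gravimetric mass loss), mg, at 2 Mc."""
    return _read("table2_method_pairs.csv")


def load_table2_pairs() -> list[MethodPair]:
    """The nine CT/gravimetric pairs as :class:`MethodPair` objects."""
    return pairs_from_dataframe(load_table2_frame())


def load_table2_printed_differences() -> pd.DataFrame:
    """The Difference column as printed in the source table (mg, 2 d.p.)."""
    return _read("table2_printed_differences.csv")
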