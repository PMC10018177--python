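"""Packaged reference tables and the China province contiguity matrix.

The six result tables from the provincial long-term care facility study
(2020 efficiency scores, 2013-2020 Malmquist decomposition, two-period
Markov matrices, spatial-Markov matrices, yearly Moran's I, and the Tobit
coefficient table) are shipped as CSV exactly as printed, for use in
reporting checks and worked examples.

The contiguity fixture encodes first-order land borders between the 31
mainland Chinese provinces, with the island province Hainan joined to
Guangdong — the standard convention in China spatial econometrics.  It is
a documented convention, not a reconstruction of any particular study's
matrix.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .panel import SpatialWeights, read_weights

_TABLE_FILES = {
    "T1": "table1_efficiency_2020.csv",
    "T2": "table2_malmquist_2013_2020.csv",
    "T3": "table3_markov_two_periods.csv",
    "T4": "table4_spatial_markov.csv",
    "T5": "table5_morans_i.csv",
    "T6": "table6_tobit.csv",
}

#: series-name prefixes used in the T3/T4 probability tables
SERIES = ("sbm", "human", "nonhuman")
STATES = ("L", "ML", "MH", "H")


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one of the packaged result tables (``T1`` .. ``T6``)."""
    try:
        fname = _TABLE_FILES[table_id]
    except KeyError:
        raise KeyError(
            f"unknown fixture {table_id!r}; choose from {sorted(_TABLE_FILES)}"
        ) from None
    ref = resources.files("effdyn.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def china_contiguity(standardize: bool = False) -> SpatialWeights:
    """First-order contiguity weights for the 31 Chinese provinces."""
    ref = resources.files("effdyn.data").joinpath("china_contiguity.gal")
    with resources.as_file(ref) as path:
        return read_weights(path, format="gal", standardize=standardize)
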