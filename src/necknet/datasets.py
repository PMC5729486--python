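"""Packaged datasets.

``load_neck_parameters`` returns the published species x parameter table
of neck musculoskeletal networks for 48 mammalian species (columns N, K,
D, C, L, H, P plus the taxonomic order), transcribed at its printed
3-decimal precision.  It drives the variability and multivariate analyses
and serves as the reference for the parameter formulas.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_neck_parameters", "PARAMETER_COLUMNS"]

PARAMETER_COLUMNS = ["N", "K", "D", "C", "L", "H", "P"]


def load_neck_parameters(with_order: bool = False) -> pd.DataFrame:
    """Species x parameter table for the 48-species mammalian neck dataset.

    Indexed by species name; ``with_order=True`` keeps the taxonomic-order
    column.
    """
    ref = resources.files("necknet").joinpath("data/neck_network_parameters.csv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    df = df.set_index("species")
    return df if with_order else df[PARAMETER_COLUMNS]
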