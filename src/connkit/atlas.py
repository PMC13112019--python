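"""Packaged 116-region AAL lookup table.

The table partitions the parcellation into 78 cortical, 12 subcortical
and 26 cerebellar labels and carries a lobe and a coarse canonical
functional-network assignment per region, used to annotate degree tables
and exported edge lists.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_atlas", "category_counts"]

_COLUMNS = ["region_id", "name", "hemisphere", "lobe", "category", "canonical_network"]


def load_atlas(path=None) -> pd.DataFrame:
    """Load the region table (packaged AAL-116 by default).

    A user table must provide at least ``region_id`` and ``name``;
    missing annotation columns are filled with ``"unknown"``.
    """
    if path is None:
        with resources.files("connkit.data").joinpath("aal116.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    if not {"region_id", "name"}.issubset(df.columns):
        raise ValueError("atlas table needs 'region_id' and 'name' columns")
    for col in _COLUMNS:
        if col not in df.columns:
            df[col] = "unknown"
    return df[_COLUMNS]


def category_counts(atlas: pd.DataFrame | None = None) -> dict[str, int]:
    """Region counts per anatomical category (cortical/subcortical/cerebellar)."""
    if atlas is None:
        atlas = load_atlas()
    return atlas["category"].value_counts().to_dict()
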