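"""Reading the tabular inputs: trait matrices and predictor tables.

CSV/TSV, species in rows (first column), traits/predictors in columns.
Species labels are canonicalised exactly as tip labels are, so
underscores and spaces interchange freely across files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SpeciesMismatchError, ValidationError
from .tree import PhyloTree, canonical_label

__all__ = [
    "read_table",
    "read_trait_matrix",
    "read_predictor_table",
    "align_to_tree",
]

_NA_VALUES = ["NA", "na", "NaN", "nan", "?", ""]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_table(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0,
                     na_values=_NA_VALUES, keep_default_na=True)
    df.index = [canonical_label(i) for i in df.index]
    df.index.name = "species"
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate species rows: {', '.join(dupes)}")
    return df


def read_trait_matrix(path, sep: str | None = None) -> pd.DataFrame:
    """Species x binary-trait matrix; cells in {0, 1, NA}."""
    df = read_table(path, sep=sep)
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        cell = next(iter(zip(*np.where(bad))))
        raise ValidationError(
            f"non-numeric trait cell at row {out.index[cell[0]]!r}, "
            f"column {out.columns[cell[1]]!r}")
    values = out.to_numpy(dtype=float)
    ok = np.isnan(values) | (values == 0) | (values == 1)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValidationError(
            f"trait cell must be 0, 1 or NA; got {values[i, j]!r} at "
            f"{out.index[i]!r} / {out.columns[j]!r}")
    return out


def read_predictor_table(path, sep: str | None = None) -> pd.DataFrame:
    return read_table(path, sep=sep)


def align_to_tree(tree: PhyloTree, frame: pd.DataFrame,
                  name: str = "table") -> pd.DataFrame:
    """Reorder a species-indexed frame to the tree's tip order.

    Raises :class:`SpeciesMismatchError` listing the symmetric
    difference when the species sets disagree.
    """
    tips = set(tree.tip_labels)
    rows = set(frame.index)
    if tips != rows:
        raise SpeciesMismatchError(tips - rows, rows - tips,
                                   left_name="tree", right_name=name)
    return frame.loc[tree.tip_labels]
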