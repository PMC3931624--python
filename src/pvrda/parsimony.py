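"""Fitch parsimony and retention indices for binary characters.

A binary character maps species to states 0/1, with missing values
allowed.  Phylogenetic signal is summarised per character by the
retention index

    RI = (G - S) / (G - M),

where S is the observed parsimony step count on the tree, M the minimum
conceivable number of steps (0 for a constant character, otherwise 1)
and G the maximum conceivable number on a star phylogeny (the smaller
of the two observed state counts).  RI = 1 means the character fits the
tree perfectly; RI = 0 means it fits no better than on a star tree.
Characters with G = M carry no information about the tree and their RI
is undefined; ensembles exclude them.

Step counts come from a unit-cost minimum-change dynamic program (the
two-state Sankoff recursion), exact for polytomies and identical to
classic Fitch counting on bifurcating trees.  Missing tips enter with
the full state set {0, 1} and never add steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tree import PhyloTree, canonical_label

__all__ = [
    "CharacterFit",
    "EnsembleRI",
    "fitch_steps",
    "retention_index",
    "ensemble_retention_index",
    "retention_report",
]

_MISSING_SET = 0b11  # ambiguity set {0, 1}


@dataclass(frozen=True)
class CharacterFit:
    """Parsimony summary of one binary character on one tree."""

    trait: str | None
    steps: int          # S
    min_steps: int      # M
    max_steps: int      # G
    retention_index: float  # NaN when G == M
    informative: bool

    def as_dict(self) -> dict:
        return {
            "trait": self.trait, "S": self.steps, "M": self.min_steps,
            "G": self.max_steps, "RI": self.retention_index,
            "informative": self.informative,
        }


@dataclass(frozen=True)
class EnsembleRI:
    """Ensemble retention index over the informative characters."""

    retention_index: float
    n_characters: int
    n_informative: int
    n_excluded: int
    sum_steps: int
    sum_min: int
    sum_max: int


def _state_sets(tree: PhyloTree, char: Mapping) -> np.ndarray:
    """Bitmask state set per node index (1 = {0}, 2 = {1}, 3 = {0,1})."""
    if isinstance(char, pd.Series):
        items = char.items()
    else:
        items = dict(char).items()
    sets = np.full(tree.n_nodes, _MISSING_SET, dtype=np.uint8)
    seen = set()
    n_observed = 0
    for raw_label, value in items:
        label = canonical_label(raw_label)
        if label not in tree.tip_index:
            raise ValidationError(
                f"character references unknown species {label!r}")
        if label in seen:
            raise ValidationError(f"duplicate species {label!r} in character")
        seen.add(label)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        state = int(value)
        if state not in (0, 1):
            raise ValidationError(
                f"state for {label!r} must be 0, 1 or missing; got {value!r}")
        sets[tree.tip_index[label]] = 1 << state
        n_observed += 1
    if n_observed == 0:
        raise ValidationError("character has no non-missing states")
    return sets


def _observed_counts(tree: PhyloTree, sets: np.ndarray) -> tuple[int, int]:
    tip_sets = sets[tree.is_tip]
    n0 = int(np.sum(tip_sets == 0b01))
    n1 = int(np.sum(tip_sets == 0b10))
    return n0, n1


def fitch_steps(tree: PhyloTree, char: Mapping) -> int:
    """Minimum number of state changes of ``char`` on ``tree``.

    Exact for arbitrary out-degree: a unit-cost minimum-change dynamic
    program (the two-state Sankoff recursion), which on strictly
    bifurcating trees coincides with classic Fitch counting.  A naive
    pairwise intersection/union fold can undercount on polytomies, so
    it is not used.  Missing tips carry the full ambiguity set and
    contribute no steps.  Requires at least two non-missing tips.
    """
    sets = _state_sets(tree, char)
    n0, n1 = _observed_counts(tree, sets)
    if n0 + n1 < 2:
        raise ValidationError("need >= 2 non-missing tips for a step count")
    inf = tree.n_tips + 1  # safe infinity: steps never exceed tip count
    cost = np.zeros((tree.n_nodes, 2), dtype=np.int64)
    for i in tree.postorder:
        kids = tree.children[i]
        if not kids:
            cost[i, 0] = 0 if sets[i] & 0b01 else inf
            cost[i, 1] = 0 if sets[i] & 0b10 else inf
            continue
        c0 = c1 = 0
        for c in kids:
            c0 += min(cost[c, 0], cost[c, 1] + 1)
            c1 += min(cost[c, 1], cost[c, 0] + 1)
        cost[i] = (c0, c1)
    return int(cost[tree.root_index].min())


def retention_index(tree: PhyloTree, char: Mapping,
                    trait: str | None = None) -> CharacterFit:
    """Per-character S, M, G and retention index (NaN if uninformative)."""
    sets = _state_sets(tree, char)
    n0, n1 = _observed_counts(tree, sets)
    if n0 + n1 < 2:
        raise ValidationError("need >= 2 non-missing tips")
    s = fitch_steps(tree, char)
    m = 0 if (n0 == 0 or n1 == 0) else 1
    g = min(n0, n1)
    if g > m:
        ri = (g - s) / (g - m)
        informative = True
    else:
        ri = float("nan")
        informative = False
    return CharacterFit(trait=trait, steps=s, min_steps=m, max_steps=g,
                        retention_index=ri, informative=informative)


def ensemble_retention_index(tree: PhyloTree,
                             traits: pd.DataFrame) -> EnsembleRI:
    """Ensemble RI = (sum G - sum S) / (sum G - sum M) over informative characters.

    Characters with G = M (constant, autapomorphic, or effectively so
    after missing data) carry no homoplasy information and are excluded;
    the count of exclusions is reported.
    """
    fits = [retention_index(tree, traits[col], trait=str(col))
            for col in traits.columns]
    informative = [f for f in fits if f.informative]
    if not informative:
        raise ValidationError("no parsimony-informative characters")
    ss = sum(f.steps for f in informative)
    sm = sum(f.min_steps for f in informative)
    sg = sum(f.max_steps for f in informative)
    return EnsembleRI(
        retention_index=(sg - ss) / (sg - sm),
        n_characters=len(fits),
        n_informative=len(informative),
        n_excluded=len(fits) - len(informative),
        sum_steps=ss, sum_min=sm, sum_max=sg,
    )


def retention_report(tree: PhyloTree, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-trait table of S, M, G, RI and the informative flag."""
    rows = [retention_index(tree, traits[col], trait=str(col)).as_dict()
            for col in traits.columns]
    return pd.DataFrame(rows).set_index("trait")
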