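"""Per-trait Evol/Ecol variance partition and the global corrected test.

For each binary trait the report separates

* **Evol%** — the share of trait variance explained by the selected
  principal-coordinate axes of the patristic distance matrix, i.e. the
  component attributable to phylogenetic relatedness, and
* **Ecol%** — the share explained by an ecological predictor after the
  phylogenetic axes have been partialled out (the phylogeny-corrected,
  "PC" model); the ahistorical ("AH") model tests the same predictor
  without correction.

Both percentages are taken relative to the trait's total (pre-covariate)
sum of squares, so Evol% + Ecol% cannot exceed 100 within one
predictor's partition.  p-values are Bonferroni-adjusted within test
families, one family per (predictor x correction-mode) column across
the reported traits; adjusted p >= 0.10 renders as "ns" and smaller
values with three decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ordination import RDA, build_design, permutation_test, single_trait_test

__all__ = [
    "TraitTestRow",
    "PartitionReport",
    "GlobalResult",
    "evol_fraction",
    "build_table",
    "global_analysis",
    "render_p",
]

NS_THRESHOLD = 0.10


def render_p(p_adj: float) -> str:
    """Table rendering: 'ns' at adjusted p >= 0.10, else three decimals."""
    if np.isnan(p_adj):
        return "na"
    if p_adj >= NS_THRESHOLD:
        return "ns"
    return f"{p_adj:.3f}"


def render_sign(sign) -> str:
    if sign is None:
        return ""
    return "+" if sign > 0 else ("-" if sign < 0 else "0")


def evol_fraction(trait: pd.Series, selected_axes: pd.DataFrame) -> float:
    """Percent of trait variance explained by the selected PCo axes.

    The R-squared of the trait regressed on the axes, times 100.
    Zero-variance traits are undefined (NaN).
    """
    t = trait.dropna()
    if t.nunique() < 2:
        return float("nan")
    if selected_axes.shape[1] == 0:
        return 0.0
    model = RDA().fit(selected_axes.loc[t.index], t.to_frame("trait"))
    return 100.0 * model.explained_fraction_total_


@dataclass(frozen=True)
class TraitTestRow:
    trait: str
    evol_pct: float
    cells: dict  # predictor -> dict with sign/p_ah/p_pc (raw+adj)/ecol_pct
    excluded: bool = False


@dataclass
class PartitionReport:
    rows: list
    predictors: tuple
    nperm: int
    master_seed: int
    family_sizes: dict = field(default_factory=dict)

    def to_frame(self, rendered: bool = True) -> pd.DataFrame:
        """Tabular report; rendered=True applies the ns/decimal rules."""
        records = []
        for row in self.rows:
            rec = {"trait": row.trait, "Evol%": round(row.evol_pct, 1)
                   if np.isfinite(row.evol_pct) else np.nan}
            for pred in self.predictors:
                cell = row.cells.get(pred, {})
                tag = pred
                if rendered:
                    rec[f"{tag}:Res"] = render_sign(cell.get("sign"))
                    rec[f"{tag}:AH"] = render_p(cell.get("p_ah_adj", np.nan))
                    rec[f"{tag}:PC"] = render_p(cell.get("p_pc_adj", np.nan))
                else:
                    rec[f"{tag}:sign"] = cell.get("sign")
                    rec[f"{tag}:p_ah"] = cell.get("p_ah", np.nan)
                    rec[f"{tag}:p_ah_adj"] = cell.get("p_ah_adj", np.nan)
                    rec[f"{tag}:p_pc"] = cell.get("p_pc", np.nan)
                    rec[f"{tag}:p_pc_adj"] = cell.get("p_pc_adj", np.nan)
                ecol = cell.get("ecol_pct", np.nan)
                rec[f"{tag}:Ecol%"] = (round(ecol, 1)
                                       if rendered and np.isfinite(ecol)
                                       else ecol)
            records.append(rec)
        return pd.DataFrame(records)

    def to_tsv(self, path) -> None:
        self.to_frame(rendered=True).to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "predictors": list(self.predictors),
            "nperm": self.nperm,
            "master_seed": self.master_seed,
            "family_sizes": self.family_sizes,
            "rows": [
                {"trait": r.trait, "evol_pct": _num(r.evol_pct),
                 "excluded": r.excluded,
                 "cells": {p: {k: _num(v) for k, v in c.items()}
                           for p, c in r.cells.items()}}
                for r in self.rows
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _num(v):
    if v is None:
        return None
    if isinstance(v, (np.floating, float)):
        return None if np.isnan(v) else float(v)
    if isinstance(v, (np.integer, int)):
        return int(v)
    return v


def _test_seed(master_seed: int, trait_idx: int, pred_idx: int,
               mode_idx: int):
    """Per-test seed: SeedSequence(master, spawn_key=(trait, pred, mode))."""
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(trait_idx, pred_idx, mode_idx)))


def build_table(traits: pd.DataFrame, predictors: pd.DataFrame,
                axes: pd.DataFrame, nperm: int = 1999,
                master_seed: int = 0,
                predictor_columns: tuple = ("height", "elevation"),
                scheme: str = "reduced") -> PartitionReport:
    """Assemble the per-trait Evol/Ecol partition table.

    For every trait and every continuous predictor named in
    ``predictor_columns`` an ahistorical test (predictor alone) and a
    phylogeny-corrected test (predictor given the selected axes) are
    run; Ecol% is the corrected model's explained share of the trait's
    total SS.  Per-test permutation seeds derive from ``master_seed``
    by the (trait index, predictor index, mode index) counter scheme,
    so the table is reproducible and insensitive to trait additions at
    the end.
    """
    for col in predictor_columns:
        if col not in predictors.columns:
            raise ValidationError(f"predictor column {col!r} not found")
    rows = []
    raw_p = {(pred, mode): [] for pred in predictor_columns
             for mode in ("ah", "pc")}
    results = {}
    for ti, trait_name in enumerate(traits.columns):
        trait = traits[trait_name]
        for pi, pred in enumerate(predictor_columns):
            ah = single_trait_test(
                trait, predictors[pred], covariates=None, nperm=nperm,
                seed=_test_seed(master_seed, ti, pi, 0), scheme=scheme,
                trait_name=str(trait_name), predictor_name=pred)
            pc = single_trait_test(
                trait, predictors[pred], covariates=axes, nperm=nperm,
                seed=_test_seed(master_seed, ti, pi, 1), scheme=scheme,
                trait_name=str(trait_name), predictor_name=pred)
            results[(trait_name, pred)] = (ah, pc)
            if not ah.excluded:
                raw_p[(pred, "ah")].append(ah.pvalue)
                raw_p[(pred, "pc")].append(pc.pvalue)

    family_sizes = {f"{pred}:{mode}": len(raw_p[(pred, mode)])
                    for pred in predictor_columns for mode in ("ah", "pc")}

    for trait_name in traits.columns:
        cells = {}
        excluded = False
        for pred in predictor_columns:
            ah, pc = results[(trait_name, pred)]
            excluded = excluded or ah.excluded
            m_ah = family_sizes[f"{pred}:ah"]
            m_pc = family_sizes[f"{pred}:pc"]
            cells[pred] = {
                "sign": pc.sign,
                "p_ah": ah.pvalue,
                "p_ah_adj": (min(1.0, ah.pvalue * m_ah)
                             if not ah.excluded else np.nan),
                "p_pc": pc.pvalue,
                "p_pc_adj": (min(1.0, pc.pvalue * m_pc)
                             if not pc.excluded else np.nan),
                "ecol_pct": 100.0 * pc.explained_fraction,
                "n_used": pc.n_used,
            }
        evol = evol_fraction(traits[trait_name], axes)
        rows.append(TraitTestRow(trait=str(trait_name), evol_pct=evol,
                                 cells=cells, excluded=excluded))
    return PartitionReport(rows=rows, predictors=tuple(predictor_columns),
                           nperm=nperm, master_seed=int(master_seed),
                           family_sizes=family_sizes)


@dataclass(frozen=True)
class GlobalResult:
    """Global multivariate test of all traits against all predictors."""

    uncorrected_explained_pct: float     # % of total trait SS
    corrected_explained_pct_total: float  # % of pre-covariate total
    corrected_explained_pct_partial: float  # % of post-covariate total
    axes_explained_pct: float            # % explained by the axes alone
    pvalue_uncorrected: float
    pvalue_corrected: float
    n_axes: int
    nperm: int

    def as_dict(self) -> dict:
        return {k: _num(v) for k, v in self.__dict__.items()}


def global_analysis(traits: pd.DataFrame, predictors: pd.DataFrame,
                    axes: pd.DataFrame, nperm: int = 1999, seed=None,
                    scheme: str = "reduced",
                    standardize: bool = False) -> GlobalResult:
    """Global RDA of the full trait matrix, with and without correction.

    With an empty axis set the corrected analysis reduces exactly to
    the uncorrected one.
    """
    X = build_design(predictors)
    Y = traits.loc[:, traits.nunique() > 1].astype(float)
    if Y.isna().any().any():
        raise ValidationError(
            "global analysis needs a complete trait matrix; impute or "
            "drop missing traits first (the pipeline does this)")
    seed_seq = np.random.SeedSequence(entropy=int(seed) if seed is not None
                                      else 0)
    rng_u = np.random.default_rng(np.random.SeedSequence(
        entropy=seed_seq.entropy, spawn_key=(0,)))
    rng_c = np.random.default_rng(np.random.SeedSequence(
        entropy=seed_seq.entropy, spawn_key=(1,)))
    uncor = permutation_test(Y, X, covariates=None, nperm=nperm, seed=rng_u,
                             scheme=scheme, standardize=standardize)
    use_axes = axes is not None and axes.shape[1] > 0
    if use_axes:
        cor = permutation_test(Y, X, covariates=axes, nperm=nperm,
                               seed=rng_c, scheme=scheme,
                               standardize=standardize)
        axes_model = RDA(standardize=standardize).fit(axes, Y)
        axes_pct = 100.0 * axes_model.explained_fraction_total_
        n_axes = axes.shape[1]
    else:
        cor = uncor
        axes_pct = 0.0
        n_axes = 0
    return GlobalResult(
        uncorrected_explained_pct=100.0 * uncor.explained_fraction_total,
        corrected_explained_pct_total=100.0 * cor.explained_fraction_total,
        corrected_explained_pct_partial=100.0 * cor.explained_fraction,
        axes_explained_pct=axes_pct,
        pvalue_uncorrected=uncor.pvalue,
        pvalue_corrected=cor.pvalue,
        n_axes=n_axes,
        nperm=nperm,
    )
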