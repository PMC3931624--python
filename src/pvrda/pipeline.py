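"""End-to-end pipeline: distances → PCoA → axis selection → RDA → report.

One :class:`PipelineConfig` drives the whole analysis; every stage
derives its own seed from the master seed by a fixed spawn-key scheme
(stage index, then sub-indices), so a fused run and stage-by-stage
reruns agree exactly and two runs with the same config are
byte-identical.  The output directory receives every artifact, the
resolved config, a deterministic log and a MANIFEST of completed
stages (kept even when a later stage fails).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as pio
from .mk2 import Mk2Model
from .ordination import PCoA, ForwardAxisSelector, build_design, rda
from .parsimony import ensemble_retention_index, retention_report
from .partition import build_table, global_analysis
from .tree import PhyloTree, nexus_document

__all__ = ["PipelineConfig", "run_pipeline"]

# stage spawn-key registry (documented seed derivation)
_STAGE_SEEDS = {"select_axes": 0, "global": 1, "trait_table": 2, "asr": 3}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Defaults follow the analysis conventions: 1999 permutations for
    final tests, 999 for axis selection at alpha 0.05, flat root prior
    and a decision threshold of 2.0 natural-log units for ancestral
    states, centred (unstandardised) responses and reduced-model
    residual permutation.
    """

    tree_path: str = ""
    traits_path: str = ""
    predictors_path: str = ""
    out_dir: str = "pvrda_out"
    nperm: int = 1999
    selection_nperm: int = 999
    alpha: float = 0.05
    asr_threshold: float = 2.0
    root_prior: str = "flat"
    standardize: bool = False
    permutation_scheme: str = "reduced"
    master_seed: int = 0
    missing_trait_max_fraction: float = 0.2
    predictor_columns: tuple = ("height", "elevation")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["predictor_columns"] = list(self.predictor_columns)
        return json.dumps(d, indent=2, sort_keys=True)


class _Log:
    """Deterministic plain-text run log (no wall-clock timestamps)."""

    def __init__(self):
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path) -> None:
        pathlib.Path(path).write_text("\n".join(self.lines) + "\n")


def _stage_rng(config: PipelineConfig, stage: str):
    return np.random.SeedSequence(entropy=int(config.master_seed),
                                  spawn_key=(_STAGE_SEEDS[stage],))


def _prepare_global_traits(traits: pd.DataFrame, max_missing: float,
                           log: _Log) -> pd.DataFrame:
    """Complete trait matrix for ordination: drop then mean-impute.

    Traits with zero variance or with a missing fraction above
    ``max_missing`` are dropped (logged); remaining missing cells are
    mean-imputed (logged).
    """
    keep = []
    for col in traits.columns:
        s = traits[col]
        frac = s.isna().mean()
        if frac > max_missing:
            log.info(f"trait {col}: dropped from ordination "
                     f"(missing fraction {frac:.2f} > {max_missing})")
            continue
        if s.dropna().nunique() < 2:
            log.info(f"trait {col}: dropped from ordination (zero variance)")
            continue
        keep.append(col)
    out = traits[keep].astype(float)
    n_imputed = int(out.isna().sum().sum())
    if n_imputed:
        log.info(f"mean-imputed {n_imputed} missing trait cells "
                 f"for the ordination")
        out = out.fillna(out.mean())
    return out


def run_pipeline(config: PipelineConfig) -> pathlib.Path:
    """Run the full analysis; returns the output directory.

    Artifacts: patristic.csv, pcoa_coordinates.csv, pcoa.json,
    axis_selection.json, global_rda.json, ordination_scores.csv,
    trait_table.tsv/.json, retention_index.tsv, retention_index.json,
    asr.tsv, asr_rates.json, asr_annotated.nex, pipeline.log,
    config.json, MANIFEST.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log()
    completed: list[str] = []
    manifest = out / "MANIFEST"

    def finish_stage(name: str) -> None:
        completed.append(name)
        manifest.write_text("\n".join(completed) + "\n")

    (out / "config.json").write_text(config.to_json())
    try:
        # -- load ---------------------------------------------------------
        tree = PhyloTree.from_file(config.tree_path)
        traits = pio.align_to_tree(
            tree, pio.read_trait_matrix(config.traits_path), "trait matrix")
        predictors = pio.align_to_tree(
            tree, pio.read_predictor_table(config.predictors_path),
            "predictor table")
        log.info(f"loaded tree with {tree.n_tips} tips, "
                 f"{traits.shape[1]} traits, "
                 f"{predictors.shape[1]} predictors")
        log.info(f"master seed {config.master_seed}; stage seed registry "
                 f"{_STAGE_SEEDS}")
        finish_stage("load")

        # -- distances ----------------------------------------------------
        dist = tree.patristic_matrix()
        dist.to_csv(out / "patristic.csv")
        finish_stage("distances")

        # -- pcoa ---------------------------------------------------------
        pc = PCoA().fit(dist)
        pc.coordinates_.to_csv(out / "pcoa_coordinates.csv",
                               index_label="species")
        (out / "pcoa.json").write_text(json.dumps({
            "eigenvalues": pc.eigenvalues_.tolist(),
            "n_negative_eigenvalues": pc.n_negative_eigenvalues_,
            "negative_inertia": pc.negative_inertia_,
            "positive_inertia": pc.positive_inertia_,
        }, indent=2, sort_keys=True))
        log.info(f"PCoA: {pc.coordinates_.shape[1]} positive axes, "
                 f"{pc.n_negative_eigenvalues_} negative eigenvalues "
                 f"(inertia share "
                 f"{pc.negative_inertia_ / max(pc.positive_inertia_, 1e-300):.3g})")
        finish_stage("pcoa")

        # -- axis selection -----------------------------------------------
        global_traits = _prepare_global_traits(
            traits, config.missing_trait_max_fraction, log)
        selector = ForwardAxisSelector(
            alpha=config.alpha, nperm=config.selection_nperm,
            seed=_stage_rng(config, "select_axes"),
            scheme=config.permutation_scheme,
        ).fit(pc.coordinates_, global_traits)
        selection = selector.selection_
        (out / "axis_selection.json").write_text(
            json.dumps(selection.as_dict(), indent=2, sort_keys=True))
        axes = selector.coordinates_
        log.info(f"selected axes: {list(selection.axes)} "
                 f"(cumulative R2 {list(np.round(selection.cumulative_r2, 4))})")
        finish_stage("select_axes")

        # -- global RDA ---------------------------------------------------
        glob = global_analysis(
            global_traits, predictors, axes, nperm=config.nperm,
            seed=_seed_for_stage(config, "global"),
            scheme=config.permutation_scheme,
            standardize=config.standardize)
        (out / "global_rda.json").write_text(
            json.dumps(glob.as_dict(), indent=2, sort_keys=True))
        _write_scores(out, global_traits, predictors, axes, config)
        finish_stage("global")

        # -- trait table --------------------------------------------------
        report = build_table(
            traits, predictors, axes, nperm=config.nperm,
            master_seed=_seed_for_stage(config, "trait_table"),
            predictor_columns=tuple(config.predictor_columns),
            scheme=config.permutation_scheme)
        report.to_tsv(out / "trait_table.tsv")
        report.to_json(out / "trait_table.json")
        finish_stage("trait_table")

        # -- retention indices --------------------------------------------
        rep = retention_report(tree, traits)
        rep.to_csv(out / "retention_index.tsv", sep="\t")
        ens = ensemble_retention_index(tree, traits)
        (out / "retention_index.json").write_text(json.dumps({
            "ensemble_ri": ens.retention_index,
            "n_characters": ens.n_characters,
            "n_informative": ens.n_informative,
            "n_excluded": ens.n_excluded,
            "sum_S": ens.sum_steps, "sum_M": ens.sum_min,
            "sum_G": ens.sum_max,
        }, indent=2, sort_keys=True))
        log.info(f"ensemble RI {ens.retention_index:.4f} over "
                 f"{ens.n_informative} informative characters "
                 f"({ens.n_excluded} excluded)")
        finish_stage("ri")

        # -- ancestral state reconstruction -------------------------------
        asr_rows = []
        rates_out = {}
        annotated = {}
        for col in traits.columns:
            s = traits[col]
            if s.dropna().nunique() < 2:
                log.info(f"trait {col}: ASR skipped (not variable)")
                continue
            model = Mk2Model(root_prior=config.root_prior,
                             decision_threshold=config.asr_threshold)
            model.fit(tree, s)
            rec = model.reconstruct(tree, s)
            frame = rec.to_frame().reset_index()
            frame.insert(0, "trait", str(col))
            asr_rows.append(frame)
            rates_out[str(col)] = {
                "q01": model.q01_, "q10": model.q10_,
                "logL": model.loglik_, "converged": model.converged_,
            }
            annotated[str(col)] = (tree, rec.annotations())
        if asr_rows:
            pd.concat(asr_rows, ignore_index=True).to_csv(
                out / "asr.tsv", sep="\t", index=False)
            (out / "asr_annotated.nex").write_text(nexus_document(annotated))
        (out / "asr_rates.json").write_text(
            json.dumps(rates_out, indent=2, sort_keys=True))
        finish_stage("asr")
    except Exception as exc:
        log.info(f"FAILED after stages {completed}: {exc}")
        log.write(out / "pipeline.log")
        raise
    log.info("pipeline complete")
    log.write(out / "pipeline.log")
    finish_stage("done")
    return out


def _seed_for_stage(config: PipelineConfig, stage: str) -> int:
    # an integer seed (< 2^32) derived from the master seed and stage key
    return int(_stage_rng(config, stage).generate_state(1, dtype=np.uint32)[0])


def _write_scores(out, traits, predictors, axes, config) -> None:
    """Biplot-ready scores of the phylogeny-corrected global RDA."""
    X = build_design(predictors)
    model = rda(traits, X, covariates=axes if axes.shape[1] else None,
                standardize=config.standardize)
    species = model.species_scores_.copy()
    species["kind"] = "species"
    traits_sc = model.trait_scores_.copy()
    traits_sc["kind"] = "trait"
    parts = [species, traits_sc]
    if "habitat" in predictors.columns:
        cent = model.factor_centroids(predictors["habitat"])
        cent["kind"] = "habitat_centroid"
        parts.append(cent)
    pd.concat(parts).to_csv(out / "ordination_scores.csv",
                            index_label="name")
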