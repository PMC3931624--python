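"""Synthetic trees, binary traits and ecological predictors.

The generator emulates the statistical structure the analysis assumes,
at the scale of the motivating study system (≈39 species of herbaceous
bellflowers scored for 49 binary stem-anatomical characters, with an
8-level habitat factor, elevation between 20 and 3000 m and adult
height between 5 and 100 cm):

* Trees are pure-birth (Yule) with the root-to-tip height rescaled
  to 1, so rates are expressed per total tree depth.
* Continuous predictors are Brownian motion along the branches
  (variance ``sigma2_phylo`` per unit length) plus i.i.d. noise
  (variance ``sigma2_ind``), affine-mapped onto their output ranges;
  the habitat factor cuts another Brownian latent variable into k
  equal-frequency levels.
* Binary traits come in two modes: (a) direct Mk2 evolution with
  configured asymmetric rates (pure phylogenetic signal), and (b) a
  liability-threshold construction — latent liability = beta times the
  standardised predictor, plus a Brownian component, plus Gaussian
  noise — thresholded at its realised median so prevalence stays near
  one half regardless of the effect size beta.

Everything is reproducible from (config, master seed); per-trait
sub-seeds are spawned from the master seed by trait index, so adding
traits never perturbs earlier ones.  Ground truth (true rates, betas,
internal node states, liabilities) is kept alongside the data so any
recovery test can be scored without re-simulation.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .errors import ValidationError
from .mk2 import Mk2Rates, simulate_character
from .tree import PhyloTree

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_predictors",
    "simulate_traits",
    "make_study_scale_dataset",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator (all units documented).

    Defaults reproduce the study scale: 39 tips, 49 traits, 8 habitat
    levels, elevation 20–3000 m, height 5–100 cm.  Rates are per unit
    tree height (trees are rescaled to height 1).
    """

    n_tips: int = 39
    n_traits: int = 49
    habitat_levels: int = 8
    elevation_range: tuple = (20.0, 3000.0)
    height_range: tuple = (5.0, 100.0)
    # predictor latents: Brownian + independent noise
    sigma2_phylo: float = 1.0
    sigma2_ind: float = 0.25
    # Mk2 mode (a): asymmetric default rates
    q01: float = 1.0
    q10: float = 2.0
    # liability mode (b)
    beta: float = 1.0
    sigma2_liability_phylo: float = 1.0
    sigma_e: float = 0.5
    # trait mix for the study-scale dataset
    n_mk2_traits: int = 25
    n_height_traits: int = 12
    n_elevation_traits: int = 12

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValidationError("n_tips must be >= 4")
        if self.habitat_levels < 2:
            raise ValidationError("habitat_levels must be >= 2")
        for name in ("sigma2_phylo", "sigma2_ind", "sigma2_liability_phylo"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.sigma_e < 0:
            raise ValidationError("sigma_e must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    """A complete simulated study: tree, traits, predictors, ground truth."""

    tree: PhyloTree
    traits: pd.DataFrame
    predictors: pd.DataFrame
    ground_truth: dict
    config: SimulationConfig

    def write(self, out_dir) -> None:
        """Write tree.nwk, traits.csv, predictors.csv, truth.json, config.json."""
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        self.traits.to_csv(out / "traits.csv", index_label="species")
        self.predictors.to_csv(out / "predictors.csv", index_label="species")
        (out / "truth.json").write_text(
            json.dumps(_jsonable(self.ground_truth), indent=2,
                       sort_keys=True))
        (out / "config.json").write_text(self.config.to_json())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0])


def simulate_tree(n_tips: int, seed=None) -> PhyloTree:
    """Pure-birth (Yule) tree on ``n_tips`` tips, height rescaled to 1.

    Tips are labelled ``sp01`` … in the order dendropy assigns them.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    if isinstance(seed, np.random.SeedSequence):
        seed = _seed_int(seed)
    elif isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2 ** 32))
    rng = random.Random(seed)
    dtree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng)
    # the process stops exactly at the n-th speciation, leaving the last
    # cherry with zero-length tips; run the clock on to the (unperformed)
    # next event so every terminal branch is positive and the tree stays
    # ultrametric
    dt = rng.expovariate(n_tips * 1.0)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    width = max(2, len(str(n_tips)))
    for k, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{k:0{width}d}"
    tree = PhyloTree(dtree, missing_length="zero")
    h = tree.height
    if h <= 0:
        raise ValidationError("degenerate simulated tree")
    return tree.rescale(1.0 / h)


def _brownian_tips(tree: PhyloTree, sigma2: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Brownian-motion values at the tips (root value 0)."""
    vals = np.zeros(tree.n_nodes)
    for i in reversed(tree.postorder):  # preorder
        p = tree.parent[i]
        if p >= 0:
            t = tree.branch_lengths[i]
            vals[i] = vals[p] + rng.normal(0.0, np.sqrt(sigma2 * t))
    tip_idx = [tree.tip_index[lab] for lab in tree.tip_labels]
    return vals[tip_idx]


def _affine_to_range(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.full_like(x, 0.5 * (lo + hi))
    return lo + (x - x.min()) * (hi - lo) / span


def simulate_predictors(tree: PhyloTree, config: SimulationConfig,
                        seed=None) -> tuple[pd.DataFrame, dict]:
    """Phylogenetically structured habitat, elevation and height.

    Returns the predictor table and the latent (pre-mapping) values.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    latents = {}
    out = {}
    for j, name in enumerate(("habitat", "elevation", "height")):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=ss.spawn_key + (j,)))
        lat = _brownian_tips(tree, config.sigma2_phylo, rng)
        lat = lat + rng.normal(0.0, np.sqrt(config.sigma2_ind),
                               size=lat.shape)
        latents[name] = lat
    k = config.habitat_levels
    hab = pd.qcut(pd.Series(latents["habitat"], index=tree.tip_labels),
                  q=k, labels=[f"H{i + 1}" for i in range(k)])
    table = pd.DataFrame({
        "habitat": hab.astype(str),
        "elevation": _affine_to_range(latents["elevation"],
                                      *config.elevation_range),
        "height": _affine_to_range(latents["height"], *config.height_range),
    }, index=pd.Index(tree.tip_labels, name="species"))
    truth = {"latents": {k_: pd.Series(v, index=tree.tip_labels)
                         for k_, v in latents.items()}}
    return table, truth


def simulate_traits(tree: PhyloTree, predictors: pd.DataFrame | None,
                    config: SimulationConfig, seed=None,
                    modes: list | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate a binary trait matrix.

    ``modes`` is a per-trait list of either ``("mk2", q01, q10)`` or
    ``("liability", predictor_name, beta)``; by default all traits are
    Mk2 with the configured rates.  Per-trait sub-seeds derive from the
    master seed by trait index.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    n = config.n_traits if modes is None else len(modes)
    if modes is None:
        modes = [("mk2", config.q01, config.q10)] * n
    cols = {}
    truth: dict = {"modes": {}, "node_states": {}, "liabilities": {},
                   "betas": {}, "rates": {}}
    labels = tree.tip_labels
    for ti, mode in enumerate(modes):
        name = f"trait{ti + 1:02d}"
        sub = np.random.SeedSequence(entropy=ss.entropy,
                                     spawn_key=ss.spawn_key + (ti,))
        rng = np.random.default_rng(sub)
        if mode[0] == "mk2":
            _, q01, q10 = mode
            sim = simulate_character(tree, Mk2Rates(q01, q10),
                                     root_prior="stationary", seed=rng)
            cols[name] = sim.tip_states
            truth["modes"][name] = "mk2"
            truth["rates"][name] = (q01, q10)
            truth["node_states"][name] = sim.node_states
        elif mode[0] == "liability":
            _, pred_name, beta = mode
            if predictors is None:
                raise ValidationError(
                    "liability traits need a predictor table")
            x = predictors[pred_name].loc[labels].to_numpy(dtype=float)
            z = (x - x.mean()) / x.std(ddof=0)
            bm = _brownian_tips(tree, config.sigma2_liability_phylo, rng)
            noise = rng.normal(0.0, config.sigma_e, size=len(labels))
            liab = beta * z + bm + noise
            states = (liab > np.median(liab)).astype(int)
            cols[name] = pd.Series(states, index=labels)
            truth["modes"][name] = "liability"
            truth["betas"][name] = {"predictor": pred_name, "beta": beta}
            truth["liabilities"][name] = pd.Series(liab, index=labels)
        else:
            raise ValidationError(f"unknown trait mode {mode[0]!r}")
    traits = pd.DataFrame(cols, index=pd.Index(labels, name="species"))
    return traits, truth


def make_study_scale_dataset(master_seed: int = 0,
                             config: SimulationConfig | None = None
                             ) -> SyntheticDataset:
    """One call producing the full study-scale dataset.

    39 tips, 49 traits (25 pure-Mk2, 12 height-linked and 12
    elevation-linked liability traits), 8 habitat levels, elevation in
    [20, 3000] m, height in [5, 100] cm.
    """
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(entropy=int(master_seed))
    tree = simulate_tree(cfg.n_tips,
                         np.random.SeedSequence(entropy=ss.entropy,
                                                spawn_key=(0,)))
    predictors, pred_truth = simulate_predictors(
        tree, cfg, np.random.SeedSequence(entropy=ss.entropy, spawn_key=(1,)))
    modes = ([("mk2", cfg.q01, cfg.q10)] * cfg.n_mk2_traits
             + [("liability", "height", cfg.beta)] * cfg.n_height_traits
             + [("liability", "elevation", cfg.beta)] * cfg.n_elevation_traits)
    extra = cfg.n_traits - len(modes)
    if extra > 0:
        modes += [("mk2", cfg.q01, cfg.q10)] * extra
    elif extra < 0:
        modes = modes[:cfg.n_traits]
    traits, trait_truth = simulate_traits(
        tree, predictors, cfg,
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=(2,)),
        modes=modes)
    truth = {"predictors": pred_truth, "traits": trait_truth,
             "master_seed": int(master_seed)}
    return SyntheticDataset(tree=tree, traits=traits, predictors=predictors,
                            ground_truth=truth, config=cfg)
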