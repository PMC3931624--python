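"""Asymmetric two-rate Markov (Mk2) model for binary characters on a tree.

The model is a continuous-time Markov chain on states {0, 1} with a
forward rate ``q01`` (0 to 1) and an independent backward rate ``q10``,
both per unit branch length.  With s = q01 + q10 and stationary
frequencies pi0 = q10/s, pi1 = q01/s, the transition probabilities over
a branch of length t have the closed form

    P(t) = [[pi0 + pi1*e^(-st),  pi1*(1 - e^(-st))],
            [pi0*(1 - e^(-st)),  pi1 + pi0*e^(-st)]].

Tip data enter Felsenstein's pruning algorithm as partial likelihoods;
missing tips contribute (1, 1).  Rates are estimated by maximising the
log-likelihood in log-rate space from a deterministic multi-start grid.
Marginal ancestral states are computed with the standard up-down pass,
so each internal node's proportional likelihoods condition on all tips.
A node is called unequivocal when the absolute log-likelihood
difference between its two states reaches the decision threshold
(2.0 natural-log units by default; Mesquite's convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, ValidationError
from .tree import PhyloTree, canonical_label

__all__ = [
    "Mk2Rates",
    "AncestralReconstruction",
    "Mk2Model",
    "transition_matrix",
    "loglik",
    "fit_rates",
    "marginal_asr",
    "simulate_character",
    "SimulatedCharacter",
]


@dataclass(frozen=True)
class Mk2Rates:
    """Transition rates per unit branch length."""

    q01: float
    q10: float

    def __post_init__(self):
        if not (np.isfinite(self.q01) and np.isfinite(self.q10)):
            raise ValidationError("rates must be finite")
        if self.q01 < 0 or self.q10 < 0:
            raise ValidationError("rates must be non-negative")

    @property
    def total(self) -> float:
        return self.q01 + self.q10

    def stationary(self) -> np.ndarray:
        s = self.total
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / s, self.q01 / s])


def transition_matrix(rates: Mk2Rates, t: float) -> np.ndarray:
    """2x2 stochastic matrix of state-change probabilities over length ``t``."""
    if t < 0:
        raise ValidationError("branch length must be non-negative")
    s = rates.total
    if s == 0 or t == 0:
        return np.eye(2)
    pi0 = rates.q10 / s
    pi1 = rates.q01 / s
    e = np.exp(-s * t)
    return np.array([
        [pi0 + pi1 * e, pi1 * (1.0 - e)],
        [pi0 * (1.0 - e), pi1 + pi0 * e],
    ])


def _root_prior(rates: Mk2Rates, kind: str) -> np.ndarray:
    if kind == "flat":
        return np.array([0.5, 0.5])
    if kind == "stationary":
        return rates.stationary()
    raise ValidationError("root_prior must be 'flat' or 'stationary'")


def _tip_partials(tree: PhyloTree, data) -> np.ndarray:
    """Partial-likelihood array (n_nodes, n_chars, 2) seeded at the tips.

    ``data`` is a mapping/Series (one character) or a DataFrame
    (species x characters).  Missing values give (1, 1).
    """
    if isinstance(data, pd.DataFrame):
        df = data
    elif isinstance(data, pd.Series):
        df = data.to_frame()
    else:
        df = pd.Series(dict(data)).to_frame()
    n_chars = df.shape[1]
    part = np.ones((tree.n_nodes, n_chars, 2))
    seen_any = np.zeros(n_chars, dtype=bool)
    for raw_label, row in df.iterrows():
        label = canonical_label(raw_label)
        if label not in tree.tip_index:
            raise ValidationError(
                f"character data references unknown species {label!r}")
        i = tree.tip_index[label]
        vals = row.to_numpy(dtype=float)
        for j, v in enumerate(vals):
            if np.isnan(v):
                continue
            state = int(v)
            if state not in (0, 1):
                raise ValidationError(
                    f"state for {label!r} must be 0, 1 or missing")
            part[i, j, :] = 0.0
            part[i, j, state] = 1.0
            seen_any[j] = True
    if not seen_any.all():
        raise ValidationError("character with all states missing")
    return part


def _pruning(tree: PhyloTree, tip_partials: np.ndarray, rates: Mk2Rates,
             root_prior: str = "flat", keep_partials: bool = False):
    """Scaled postorder pass.

    Returns (per-character log-likelihood array, partials, logscale) —
    the latter two only populated when ``keep_partials``.
    """
    part = tip_partials.copy()
    n_chars = part.shape[1]
    logscale = np.zeros(n_chars)
    for i in tree.postorder:
        kids = tree.children[i]
        if not kids:
            continue
        prod = np.ones((n_chars, 2))
        for c in kids:
            p_mat = transition_matrix(rates, tree.branch_lengths[c])
            prod *= part[c] @ p_mat.T
        mx = prod.max(axis=1)
        nz = mx > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            part[i] = np.where(nz[:, None], prod / np.where(nz, mx, 1.0)[:, None], 0.0)
        logscale += np.where(nz, np.log(np.where(nz, mx, 1.0)), -np.inf)
    prior = _root_prior(rates, root_prior)
    lk = part[tree.root_index] @ prior
    with np.errstate(divide="ignore"):
        ll = np.log(lk) + logscale
    if keep_partials:
        return ll, part, logscale
    return ll, None, None


def loglik(tree: PhyloTree, data, rates: Mk2Rates,
           root_prior: str = "flat"):
    """Log-likelihood of one character (scalar) or a matrix (summed).

    A variable character under ``q01 = q10 = 0`` has zero likelihood;
    ``-inf`` is returned rather than raising.
    """
    part = _tip_partials(tree, data)
    ll, _, _ = _pruning(tree, part, rates, root_prior)
    return float(ll.sum()) if ll.size > 1 or isinstance(data, pd.DataFrame) \
        else float(ll[0])


@dataclass
class Mk2FitResult:
    rates: Mk2Rates
    loglik: float
    converged: bool
    degenerate: bool
    n_characters: int
    per_character_loglik: np.ndarray | None = None


_GRID_POINTS = 5
_GRID_LO = 1e-3
_GRID_HI = 1e2
_N_LOCAL_STARTS = 3


def fit_rates(tree: PhyloTree, data, shared: bool = True,
              root_prior: str = "flat") -> Mk2FitResult:
    """Maximum-likelihood Mk2 rates by deterministic multi-start search.

    The objective is maximised over (log q01, log q10).  A 5x5 grid
    spanning [1e-3, 1e2] per unit tree height is evaluated first; local
    simplex optimisation then starts from the best three grid points
    and the best final point wins.  ``shared=True`` pools all columns
    of a DataFrame under one rate pair (product likelihood).
    """
    if isinstance(data, pd.DataFrame) and not shared:
        raise ValidationError(
            "fit_rates with shared=False expects a single character; "
            "loop over columns instead")
    part = _tip_partials(tree, data)
    n_chars = part.shape[1]
    # degenerate = no variable character (all observed states identical)
    tips = part[tree.is_tip]
    has0 = ((tips[:, :, 0] == 1) & (tips[:, :, 1] == 0)).any(axis=0)
    has1 = ((tips[:, :, 1] == 1) & (tips[:, :, 0] == 0)).any(axis=0)
    degenerate = not bool((has0 & has1).any())

    height = tree.height
    if height <= 0:
        raise ValidationError("tree height must be positive")
    grid = np.log(np.geomspace(_GRID_LO, _GRID_HI, _GRID_POINTS) / height)

    def neg_ll(x):
        q01, q10 = np.exp(np.clip(x, -700, 700))
        ll, _, _ = _pruning(tree, part, Mk2Rates(q01, q10), root_prior)
        total = ll.sum()
        return 1e300 if not np.isfinite(total) else -total

    starts = [(a, b) for a in grid for b in grid]
    values = [neg_ll(np.array(p)) for p in starts]
    order = np.argsort(values)
    best_x, best_v, converged = None, np.inf, False
    for k in order[:_N_LOCAL_STARTS]:
        res = minimize(neg_ll, np.array(starts[k]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9,
                                "maxiter": 2000})
        if res.fun < best_v:
            best_v, best_x = res.fun, res.x
        converged = converged or bool(res.success)
    if best_x is None or not np.isfinite(best_v):
        k = order[0]
        raise ConvergenceError(
            "Mk2 rate optimisation failed from every start",
            best_point=np.exp(np.array(starts[k])), best_value=-values[k],
            gradient_norm=_grad_norm(neg_ll, np.array(starts[k])))
    if not converged:
        raise ConvergenceError(
            "Mk2 rate optimisation did not converge",
            best_point=np.exp(best_x), best_value=-best_v,
            gradient_norm=_grad_norm(neg_ll, best_x))
    rates = Mk2Rates(*np.exp(best_x))
    ll, _, _ = _pruning(tree, part, rates, root_prior)
    return Mk2FitResult(rates=rates, loglik=float(ll.sum()), converged=True,
                        degenerate=degenerate, n_characters=n_chars,
                        per_character_loglik=ll)


def _grad_norm(f, x, eps=1e-5) -> float:
    g = np.zeros_like(x)
    f0 = f(x)
    for i in range(len(x)):
        xp = x.copy()
        xp[i] += eps
        g[i] = (f(xp) - f0) / eps
    return float(np.linalg.norm(g))


@dataclass
class AncestralReconstruction:
    """Marginal ancestral-state reconstruction of one binary character."""

    node_ids: list[str]            # internal nodes, postorder; root last
    proportional_likelihoods: np.ndarray  # (n_internal, 2); rows sum to 1
    unequivocal: np.ndarray        # bool per internal node
    best_state: np.ndarray         # argmax state per internal node
    rates: Mk2Rates
    loglik: float
    threshold: float
    root_prior: str = "flat"

    @property
    def root_pl(self) -> np.ndarray:
        return self.proportional_likelihoods[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.node_ids,
            "PL0": self.proportional_likelihoods[:, 0],
            "PL1": self.proportional_likelihoods[:, 1],
            "state": self.best_state,
            "unequivocal": self.unequivocal,
        }).set_index("node")

    def annotations(self) -> dict:
        """Node-id keyed annotation dict for the tree serialiser."""
        out = {}
        for k, nid in enumerate(self.node_ids):
            out[nid] = {
                "PL0": round(float(self.proportional_likelihoods[k, 0]), 6),
                "PL1": round(float(self.proportional_likelihoods[k, 1]), 6),
                "unequivocal": str(bool(self.unequivocal[k])).lower(),
            }
        return out


def marginal_asr(tree: PhyloTree, char, rates: Mk2Rates,
                 root_prior: str = "flat",
                 threshold: float = 2.0) -> AncestralReconstruction:
    """Marginal (up-down) ancestral states under fixed Mk2 rates.

    Every internal node's proportional likelihoods condition on all tip
    data, not only the node's subtree.  ``threshold`` is the decision
    threshold in natural-log-likelihood units.
    """
    if isinstance(char, pd.DataFrame):
        if char.shape[1] != 1:
            raise ValidationError("marginal_asr reconstructs one character")
        char = char.iloc[:, 0]
    part = _tip_partials(tree, char)
    ll, up, _ = _pruning(tree, part, rates, root_prior, keep_partials=True)
    up = up[:, 0, :]  # single character
    prior = _root_prior(rates, root_prior)

    # outside message: probability weight of everything not below a node
    out = np.zeros((tree.n_nodes, 2))
    out[tree.root_index] = prior
    # child->parent messages, computed once per node
    msg = np.zeros((tree.n_nodes, 2))
    p_mats = {}
    for i in tree.postorder:
        if tree.parent[i] >= 0:
            p_mats[i] = transition_matrix(rates, tree.branch_lengths[i])
            msg[i] = p_mats[i] @ up[i]
    for i in reversed(tree.postorder):  # preorder
        kids = tree.children[i]
        for c in kids:
            pre = out[i].copy()
            for sib in kids:
                if sib != c:
                    pre *= msg[sib]
            vec = pre @ p_mats[c]
            tot = vec.sum()
            out[c] = vec / tot if tot > 0 else vec

    internal = [i for i in tree.postorder if not tree.is_tip[i]]
    pl = np.empty((len(internal), 2))
    for k, i in enumerate(internal):
        w = up[i] * out[i]
        s = w.sum()
        if s <= 0:
            raise ValidationError(
                "zero marginal likelihood at an internal node "
                "(both rates zero with a variable character?)")
        pl[k] = w / s
    with np.errstate(divide="ignore"):
        logratio = np.abs(np.log(pl[:, 0]) - np.log(pl[:, 1]))
    return AncestralReconstruction(
        node_ids=[tree.node_ids[i] for i in internal],
        proportional_likelihoods=pl,
        unequivocal=logratio >= threshold,
        best_state=pl.argmax(axis=1),
        rates=rates, loglik=float(ll[0]), threshold=threshold,
        root_prior=root_prior,
    )


@dataclass
class SimulatedCharacter:
    """A simulated binary character with its full internal-state history."""

    tip_states: pd.Series          # canonical tip label -> 0/1
    node_states: pd.Series         # node id -> 0/1 (internal nodes)
    root_state: int


def simulate_character(tree: PhyloTree, rates: Mk2Rates,
                       root_state: int | None = None,
                       root_prior: str = "flat",
                       seed=None) -> SimulatedCharacter:
    """Draw one character by sampling states along the tree.

    The root state is drawn from ``root_prior`` unless fixed; each
    child's state is then drawn from the transition matrix of its
    branch.  Reproducible for a fixed ``seed`` (int or Generator).
    """
    rng = np.random.default_rng(seed)
    states = np.full(tree.n_nodes, -1, dtype=int)
    if root_state is None:
        prior = _root_prior(rates, root_prior)
        states[tree.root_index] = rng.choice(2, p=prior)
    else:
        if root_state not in (0, 1):
            raise ValidationError("root_state must be 0 or 1")
        states[tree.root_index] = root_state
    for i in reversed(tree.postorder):  # preorder
        for c in tree.children[i]:
            p = transition_matrix(rates, tree.branch_lengths[c])
            states[c] = rng.choice(2, p=p[states[i]])
    tips = {tree.node_ids[i]: int(states[i])
            for i in tree.postorder if tree.is_tip[i]}
    nodes = {tree.node_ids[i]: int(states[i])
             for i in tree.postorder if not tree.is_tip[i]}
    return SimulatedCharacter(
        tip_states=pd.Series(tips).loc[tree.tip_labels],
        node_states=pd.Series(nodes),
        root_state=int(states[tree.root_index]),
    )


class Mk2Model(BaseEstimator):
    """Scikit-learn style estimator for the asymmetric Mk2 model.

    Parameters
    ----------
    root_prior : {"flat", "stationary"}
        Weighting of root states in likelihoods and reconstructions.
        Flat (0.5, 0.5) matches Mesquite's proportional-likelihood
        reporting and is the default.
    shared : bool
        Pool all characters under one rate pair (product likelihood)
        when fitting a DataFrame.
    decision_threshold : float
        Log-likelihood-difference threshold for calling a node
        unequivocal; 2.0 is the Mesquite convention, 1.0 is also in use.

    Attributes (after :meth:`fit`)
    ------------------------------
    rates_ : Mk2Rates
    q01_, q10_, loglik_ : float
    converged_, degenerate_ : bool
    """

    def __init__(self, root_prior: str = "flat", shared: bool = True,
                 decision_threshold: float = 2.0):
        self.root_prior = root_prior
        self.shared = shared
        self.decision_threshold = decision_threshold

    def fit(self, tree: PhyloTree, data) -> "Mk2Model":
        result = fit_rates(tree, data, shared=self.shared,
                           root_prior=self.root_prior)
        self.rates_ = result.rates
        self.q01_ = result.rates.q01
        self.q10_ = result.rates.q10
        self.loglik_ = result.loglik
        self.converged_ = result.converged
        self.degenerate_ = result.degenerate
        self.fit_result_ = result
        return self

    def score(self, tree: PhyloTree, data) -> float:
        """Log-likelihood of ``data`` under the fitted rates."""
        return loglik(tree, data, self.rates_, root_prior=self.root_prior)

    def reconstruct(self, tree: PhyloTree, char) -> AncestralReconstruction:
        """Marginal ancestral states under the fitted rates."""
        return marginal_asr(tree, char, self.rates_,
                            root_prior=self.root_prior,
                            threshold=self.decision_threshold)

    def simulate(self, tree: PhyloTree, seed=None,
                 root_state: int | None = None) -> SimulatedCharacter:
        return simulate_character(tree, self.rates_, root_state=root_state,
                                  root_prior=self.root_prior, seed=seed)
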