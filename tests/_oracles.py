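"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — per-pair path walks, exhaustive
enumeration over internal-state assignments — and shares no code with
the implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from pvrda import Mk2Rates, PhyloTree
from scipy.linalg import expm


def random_tree_newick(rng: np.random.Generator, n_tips: int,
                       polytomy_prob: float = 0.2,
                       max_bl: float = 2.0) -> str:
    """A random rooted topology (with occasional polytomies) as Newick."""
    groups = [f"t{i}" for i in range(n_tips)]
    while len(groups) > 1:
        k = 3 if (len(groups) > 2 and rng.random() < polytomy_prob) else 2
        pick = rng.choice(len(groups), size=k, replace=False)
        merged = sorted(pick, reverse=True)
        parts = []
        for idx in merged:
            parts.append(groups.pop(idx))
        joined = "(" + ",".join(
            f"{sub}:{rng.uniform(0.05, max_bl):.6f}" for sub in parts) + ")"
        groups.append(joined)
    return groups[0] + ";"


def pairwise_path_distance(tree: PhyloTree, tip_a: str, tip_b: str) -> float:
    """Patristic distance by walking both tips' paths to the root."""
    def updists(lab):
        d = {}
        i = tree.tip_index[lab]
        acc = 0.0
        d[i] = 0.0
        while tree.parent[i] >= 0:
            acc += tree.branch_lengths[i]
            i = tree.parent[i]
            d[i] = acc
        return d

    da, db = updists(tip_a), updists(tip_b)
    common = set(da) & set(db)
    return min(da[c] + db[c] for c in common)


def brute_force_fitch(tree: PhyloTree, char: dict) -> int:
    """Exhaustive minimum over all internal-state assignments."""
    internal = [i for i in tree.postorder if not tree.is_tip[i]]
    missing_tips = [i for i in tree.postorder if tree.is_tip[i]
                    and char.get(tree.node_ids[i]) is None]
    best = np.inf
    free = internal + missing_tips
    for assign in itertools.product([0, 1], repeat=len(free)):
        st = dict(zip(free, assign))
        for lab, v in char.items():
            if v is not None:
                st[tree.tip_index[lab]] = v
        steps = 0
        for i in tree.postorder:
            p = tree.parent[i]
            if p >= 0 and st[i] != st[p]:
                steps += 1
        best = min(best, steps)
    return int(best)


def _prior(rates: Mk2Rates, kind: str) -> np.ndarray:
    return np.array([0.5, 0.5]) if kind == "flat" else rates.stationary()


def transition_via_expm(rates: Mk2Rates, t: float) -> np.ndarray:
    q = np.array([[-rates.q01, rates.q01], [rates.q10, -rates.q10]])
    return expm(q * t)


def enum_loglik(tree: PhyloTree, char: dict, rates: Mk2Rates,
                root_prior: str = "flat") -> float:
    """Likelihood by summing over every internal-state assignment."""
    internal = [i for i in tree.postorder if not tree.is_tip[i]]
    pr = _prior(rates, root_prior)
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        st = dict(zip(internal, assign))
        for lab, v in char.items():
            st[tree.tip_index[lab]] = v
        prob = pr[st[tree.root_index]]
        for i in tree.postorder:
            if tree.parent[i] >= 0:
                P = transition_via_expm(rates, tree.branch_lengths[i])
                prob *= P[st[tree.parent[i]], st[i]]
        total += prob
    return float(np.log(total))


def enum_marginals(tree: PhyloTree, char: dict, rates: Mk2Rates,
                   root_prior: str = "flat") -> dict:
    """Per-internal-node state probabilities by restricted enumeration."""
    internal = [i for i in tree.postorder if not tree.is_tip[i]]
    pr = _prior(rates, root_prior)
    weight = {i: np.zeros(2) for i in internal}
    for assign in itertools.product([0, 1], repeat=len(internal)):
        st = dict(zip(internal, assign))
        for lab, v in char.items():
            st[tree.tip_index[lab]] = v
        prob = pr[st[tree.root_index]]
        for i in tree.postorder:
            if tree.parent[i] >= 0:
                P = transition_via_expm(rates, tree.branch_lengths[i])
                prob *= P[st[tree.parent[i]], st[i]]
        for i in internal:
            weight[i][st[i]] += prob
    return {tree.node_ids[i]: w / w.sum() for i, w in weight.items()}
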