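"""Exact interventional Shapley attributions for sklearn decision-tree ensembles.

For a single decision tree and a (foreground x, background z) pair, the
interventional Shapley value of feature ``i`` has a closed form obtained by
enumerating the tree paths consistent with mixing x's and z's feature
values.  Along a root-to-leaf path, features where x and z take the same
branch impose no constraint; each feature where they diverge must either
take x's branch (it belongs to the coalition, set ``D_x``) or z's branch
(``D_z``).  A leaf with value v reached under |D_x| = a, |D_z| = b
contributes

    +v * (a-1)! b! / (a+b)!   to every feature in D_x, and
    -v * a! (b-1)! / (a+b)!   to every feature in D_z,

which is the Shapley kernel restricted to the distinguishing features (all
others are dummies for this leaf).  Summing over leaves and averaging over a
background sample yields the interventional attribution; attributions are
averaged over trees because the forest probability is the mean of tree
probabilities.

The enumeration is a depth-first traversal with backtracking over a
per-feature branch-commitment state, compiled with numba.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_VISIT = 0
_SET = 1


@njit(cache=True)
def _pair_shap(children_left, children_right, feature, threshold, leaf_value,
               x, z, state, phi):
    n_nodes = children_left.shape[0]
    p = x.shape[0]
    cap = 5 * n_nodes + 16
    s_kind = np.empty(cap, dtype=np.int64)
    s_node = np.empty(cap, dtype=np.int64)  # node id, or feature id for _SET
    s_a = np.empty(cap, dtype=np.int64)     # |D_x| so far, or state value for _SET
    s_b = np.empty(cap, dtype=np.int64)
    sp = 0
    s_kind[sp] = _VISIT; s_node[sp] = 0; s_a[sp] = 0; s_b[sp] = 0
    sp += 1
    while sp > 0:
        sp -= 1
        kind = s_kind[sp]
        if kind == _SET:
            state[s_node[sp]] = s_a[sp]
            continue
        node = s_node[sp]
        a = s_a[sp]
        b = s_b[sp]
        if children_left[node] < 0:  # leaf
            if a + b > 0:
                v = leaf_value[node]
                lg_ab = math.lgamma(a + b + 1.0)
                for f in range(p):
                    st = state[f]
                    if st == 1:
                        phi[f] += v * math.exp(
                            math.lgamma(a + 0.0) + math.lgamma(b + 1.0) - lg_ab)
                    elif st == 2:
                        phi[f] -= v * math.exp(
                            math.lgamma(a + 1.0) + math.lgamma(b + 0.0) - lg_ab)
            continue
        f = feature[node]
        cx = children_left[node] if x[f] <= threshold[node] else children_right[node]
        cz = children_left[node] if z[f] <= threshold[node] else children_right[node]
        if state[f] == 1:
            s_kind[sp] = _VISIT; s_node[sp] = cx; s_a[sp] = a; s_b[sp] = b; sp += 1
        elif state[f] == 2:
            s_kind[sp] = _VISIT; s_node[sp] = cz; s_a[sp] = a; s_b[sp] = b; sp += 1
        elif cx == cz:
            s_kind[sp] = _VISIT; s_node[sp] = cx; s_a[sp] = a; s_b[sp] = b; sp += 1
        else:
            # pops in order: state[f]=1, x-subtree, state[f]=2, z-subtree, state[f]=0
            s_kind[sp] = _SET; s_node[sp] = f; s_a[sp] = 0; sp += 1
            s_kind[sp] = _VISIT; s_node[sp] = cz; s_a[sp] = a; s_b[sp] = b + 1; sp += 1
            s_kind[sp] = _SET; s_node[sp] = f; s_a[sp] = 2; sp += 1
            s_kind[sp] = _VISIT; s_node[sp] = cx; s_a[sp] = a + 1; s_b[sp] = b; sp += 1
            s_kind[sp] = _SET; s_node[sp] = f; s_a[sp] = 1; sp += 1


@njit(cache=True)
def _tree_shap_matrix(children_left, children_right, feature, threshold,
                      leaf_value, X_fore, X_back, out):
    n_fore = X_fore.shape[0]
    n_back = X_back.shape[0]
    p = X_fore.shape[1]
    state = np.zeros(p, dtype=np.int64)
    phi = np.zeros(p, dtype=np.float64)
    for i in range(n_fore):
        for j in range(n_back):
            phi[:] = 0.0
            _pair_shap(children_left, children_right, feature, threshold,
                       leaf_value, X_fore[i], X_back[j], state, phi)
            for f in range(p):
                out[i, f] += phi[f]
    for i in range(n_fore):
        for f in range(p):
            out[i, f] /= n_back


def _leaf_class1_probability(tree) -> np.ndarray:
    value = tree.tree_.value  # (n_nodes, 1, n_classes)
    v = value[:, 0, :]
    totals = v.sum(axis=1, keepdims=True)
    frac = v / np.where(totals > 0, totals, 1.0)
    if frac.shape[1] == 1:
        # single-class tree: probability of class 1 is 0 or 1 everywhere
        cls = tree.classes_[0]
        return np.full(frac.shape[0], float(cls))
    return frac[:, 1].astype(np.float64)


def forest_interventional_shap(trees, X_fore: np.ndarray, X_back: np.ndarray) -> np.ndarray:
    """Per-row interventional Shapley attributions of P(class 1) for a tree ensemble.

    Parameters
    ----------
    trees : iterable of fitted ``DecisionTreeClassifier``
        Each may have been trained on a column subset; pass trees trained on
        the full column set here (the unweighted domain classifier).
    X_fore : (n, p) array — rows to explain.
    X_back : (m, p) array — background (interventional reference) rows.

    Returns
    -------
    (n, p) array of attributions, averaged over background rows and trees.
    """
    trees = list(trees)
    X_fore = np.ascontiguousarray(X_fore, dtype=np.float64)
    X_back = np.ascontiguousarray(X_back, dtype=np.float64)
    total = np.zeros(X_fore.shape, dtype=np.float64)
    acc = np.zeros(X_fore.shape, dtype=np.float64)
    for tree in trees:
        t = tree.tree_
        acc[:] = 0.0
        _tree_shap_matrix(
            np.ascontiguousarray(t.children_left, dtype=np.int64),
            np.ascontiguousarray(t.children_right, dtype=np.int64),
            np.ascontiguousarray(t.feature, dtype=np.int64),
            np.ascontiguousarray(t.threshold, dtype=np.float64),
            np.ascontiguousarray(_leaf_class1_probability(tree)),
            X_fore, X_back, acc)
        total += acc
    return total / max(len(trees), 1)
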