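"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package's vectorized paths: the
network oracle unrolls the message-passing sums with explicit Python loops
over (v, w, k) triples on an adjacency dictionary, and the metric oracles
count pairs and confusion cells one element at a time.
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem

from molactive.featurization import atom_features, bond_features


def _relu(x):
    return np.maximum(x, 0.0)


def oracle_forward(smiles: str, scaled_desc, params, config) -> float:
    """Explicit-loop forward pass of the directed message-passing network."""
    mol = Chem.MolFromSmiles(smiles)
    xs = {a.GetIdx(): atom_features(a) for a in mol.GetAtoms()}
    neighbors = {a.GetIdx(): [] for a in mol.GetAtoms()}
    edge_feats = {}
    for bond in mol.GetBonds():
        v, w = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = bond_features(bond)
        neighbors[v].append(w)
        neighbors[w].append(v)
        edge_feats[(v, w)] = f
        edge_feats[(w, v)] = f

    # h0_vw = relu(Wi [x_v ; e_vw])
    h0 = {
        (v, w): _relu(params.Wi @ np.concatenate([xs[v], f]))
        for (v, w), f in edge_feats.items()
    }
    h = dict(h0)
    for _ in range(config.depth):
        h_new = {}
        for (v, w) in h:
            m = np.zeros(config.hidden_size)
            for k in neighbors[v]:
                if k != w:
                    m = m + h[(k, v)]
            h_new[(v, w)] = _relu(h0[(v, w)] + params.Wm @ m)
        h = h_new

    hmol = np.zeros(config.hidden_size)
    for v in xs:
        m_v = np.zeros(config.hidden_size)
        for w in neighbors[v]:
            if config.readout_direction == "incoming":
                m_v = m_v + h[(w, v)]
            else:
                m_v = m_v + h[(v, w)]
        hmol = hmol + _relu(params.Wa @ np.concatenate([xs[v], m_v]) + params.ba)

    z = np.concatenate([hmol, np.asarray(scaled_desc)]) if config.use_descriptors else hmol
    for i, (W, b) in enumerate(zip(params.ffn_W, params.ffn_b)):
        z = W @ z + b
        if i < len(params.ffn_W) - 1:
            z = _relu(z)
    return 1.0 / (1.0 + math.exp(-z[0]))


def oracle_confusion(labels, probs, threshold=0.5):
    tp = tn = fp = fn = 0
    for y, p in zip(labels, probs):
        pred = 1 if p >= threshold else 0
        if pred == 1 and y == 1:
            tp += 1
        elif pred == 0 and y == 0:
            tn += 1
        elif pred == 1 and y == 0:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def oracle_acc(tp, tn, fp, fn):
    return (tp + tn) / (tp + tn + fp + fn)


def oracle_mcc(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def oracle_f1(tp, tn, fp, fn):
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def oracle_auc(labels, scores):
    """All-pairs Mann-Whitney comparison; ties count half."""
    wins = 0.0
    n_pairs = 0
    for yi, si in zip(labels, scores):
        if yi != 1:
            continue
        for yj, sj in zip(labels, scores):
            if yj != 0:
                continue
            n_pairs += 1
            if si > sj:
                wins += 1.0
            elif si == sj:
                wins += 0.5
    return wins / n_pairs


def oracle_enrichment(labels, scores, gamma):
    """Re-sort and recount the actives in the top ceil(gamma*N)."""
    n = len(labels)
    n_top = math.ceil(gamma * n)
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    top = order[:n_top]
    ntb_gamma = sum(1 for i in top if labels[i] == 1)
    ntb_total = sum(1 for y in labels if y == 1)
    return (ntb_gamma / ntb_total) / gamma


def oracle_top_k_uncertain(probs, k):
    """Exhaustive sort by 1 - max(p, 1-p), stable on the original index."""
    unc = [1 - max(p, 1 - p) for p in probs]
    order = sorted(range(len(probs)), key=lambda i: (-unc[i], i))
    return order[:k]
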