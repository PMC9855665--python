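"""Directed message-passing neural network for binary molecular classification.

Hidden states live on *directed* bonds. For bond v->w at step t+1 the message
is the sum of incoming bond states at v excluding the reverse edge,

    m^{t+1}_{vw} = sum_{k in N(v) \\ w} h^t_{kv},

and the update is the skip-connected

    h^{t+1}_{vw} = tau(h^0_{vw} + W_m m^{t+1}_{vw}),

with h^0_{vw} = tau(W_i [x_v ; e_vw]). After T steps, atom vectors are read
out from incoming final bond states, m_v = sum_{w in N(v)} h^T_{wv},
h_v = tau(W_a [x_v ; m_v]), molecules are sum-pooled, h = sum_v h_v, and a
feed-forward head over [h ; scaled global descriptors] produces
y_hat = sigmoid(f(...)). The network, its backpropagation and the Adam
optimizer are implemented directly in NumPy and run on a single CPU.
"""

from __future__ import annotations

import functools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_data import CompoundRecord
from .featurization import (
    ATOM_FDIM,
    BOND_FDIM,
    N_DESCRIPTORS,
    DescriptorScaler,
    MolGraph,
    compute_global_descriptors,
    smiles_to_graph,
)

logger = logging.getLogger(__name__)


@dataclass
class DMPNNConfig:
    """Hyperparameters.

    The full-scale preset used for the stage-wise drug-likeness tasks is
    hidden 300 / batch 500 / depth 2 / ffn_depth 2 with learning rates 1e-3
    (in vivo, IND) or 5e-4 (market); the desk-scale default below trains in
    seconds on small synthetic tasks.
    """

    hidden_size: int = 64
    depth: int = 2
    ffn_depth: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    activation: str = "relu"
    dropout: float = 0.0
    max_epochs: int = 30
    patience: int = 10
    seed: int = 0
    use_descriptors: bool = True
    readout_direction: str = "incoming"  # "outgoing" preserves the printed variant

    def __post_init__(self) -> None:
        if self.hidden_size <= 0 or self.depth <= 0 or self.ffn_depth <= 0:
            raise ValueError("hidden_size, depth and ffn_depth must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")
        if self.readout_direction not in ("incoming", "outgoing"):
            raise ValueError("readout_direction must be 'incoming' or 'outgoing'")


@dataclass
class DMPNNParams:
    """Learned weights. ``Wi``/``Wm`` follow the no-bias convention of the
    reference directed-MPNN implementations; the readout and head carry biases."""

    Wi: np.ndarray  # (h, ATOM_FDIM + BOND_FDIM)
    Wm: np.ndarray  # (h, h)
    Wa: np.ndarray  # (h, ATOM_FDIM + h)
    ba: np.ndarray  # (h,)
    ffn_W: list[np.ndarray]
    ffn_b: list[np.ndarray]

    def named_arrays(self):
        yield "Wi", self.Wi
        yield "Wm", self.Wm
        yield "Wa", self.Wa
        yield "ba", self.ba
        for i, (W, b) in enumerate(zip(self.ffn_W, self.ffn_b)):
            yield f"ffn_W{i}", W
            yield f"ffn_b{i}", b

    def copy(self) -> "DMPNNParams":
        return DMPNNParams(
            Wi=self.Wi.copy(),
            Wm=self.Wm.copy(),
            Wa=self.Wa.copy(),
            ba=self.ba.copy(),
            ffn_W=[W.copy() for W in self.ffn_W],
            ffn_b=[b.copy() for b in self.ffn_b],
        )


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: DMPNNConfig, rng: np.random.Generator | None = None) -> DMPNNParams:
    rng = rng or np.random.default_rng(config.seed)
    h = config.hidden_size
    ffn_in = h + (N_DESCRIPTORS if config.use_descriptors else 0)
    sizes = [ffn_in] + [h] * (config.ffn_depth - 1) + [1]
    return DMPNNParams(
        Wi=_glorot(rng, (h, ATOM_FDIM + BOND_FDIM)),
        Wm=_glorot(rng, (h, h)),
        Wa=_glorot(rng, (h, ATOM_FDIM + h)),
        ba=np.zeros(h),
        ffn_W=[_glorot(rng, (sizes[i + 1], sizes[i])) for i in range(config.ffn_depth)],
        ffn_b=[np.zeros(sizes[i + 1]) for i in range(config.ffn_depth)],
    )


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# Batched graphs


class BatchGraph:
    """Several molecular graphs concatenated into flat arrays."""

    def __init__(self, graphs: Sequence[MolGraph]):
        self.n_mols = len(graphs)
        a_off, b_off = 0, 0
        afs, bfs, src, dst, rev, amol = [], [], [], [], [], []
        for i, g in enumerate(graphs):
            afs.append(g.atom_feats)
            bfs.append(g.bond_feats)
            src.append(g.src + a_off)
            dst.append(g.dst + a_off)
            rev.append(g.reverse_index + b_off)
            amol.append(np.full(g.n_atoms, i, dtype=np.int64))
            a_off += g.n_atoms
            b_off += g.n_directed_bonds
        self.atom_feats = np.concatenate(afs) if afs else np.zeros((0, ATOM_FDIM))
        self.bond_feats = (
            np.concatenate(bfs) if b_off else np.zeros((0, BOND_FDIM))
        )
        self.src = np.concatenate(src) if b_off else np.zeros(0, dtype=np.int64)
        self.dst = np.concatenate(dst) if b_off else np.zeros(0, dtype=np.int64)
        self.rev = np.concatenate(rev) if b_off else np.zeros(0, dtype=np.int64)
        self.atom_mol = np.concatenate(amol) if amol else np.zeros(0, dtype=np.int64)
        self.n_atoms = a_off
        self.n_bonds = b_off


def _scatter_sum(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, values.shape[1]))
    np.add.at(out, index, values)
    return out


def _encode(bg: BatchGraph, params: DMPNNParams, config: DMPNNConfig) -> dict:
    """Message passing + readout + sum pooling; returns cache for backprop."""
    inp = np.concatenate([bg.atom_feats[bg.src], bg.bond_feats], axis=1) \
        if bg.n_bonds else np.zeros((0, ATOM_FDIM + BOND_FDIM))
    h0 = _relu(inp @ params.Wi.T)
    h = h0
    steps = []
    for _ in range(config.depth):
        s = _scatter_sum(h, bg.dst, bg.n_atoms) if bg.n_bonds else np.zeros((bg.n_atoms, config.hidden_size))
        m = s[bg.src] - h[bg.rev] if bg.n_bonds else h[:0]
        h_new = _relu(h0 + m @ params.Wm.T)
        steps.append({"m": m, "h": h_new})
        h = h_new
    agg_index = bg.dst if config.readout_direction == "incoming" else bg.src
    m_atom = _scatter_sum(h, agg_index, bg.n_atoms) if bg.n_bonds else np.zeros(
        (bg.n_atoms, config.hidden_size)
    )
    cat = np.concatenate([bg.atom_feats, m_atom], axis=1)
    atom_h = _relu(cat @ params.Wa.T + params.ba)
    mol_h = _scatter_sum(atom_h, bg.atom_mol, bg.n_mols)
    return {
        "inp": inp, "h0": h0, "steps": steps, "agg_index": agg_index,
        "m_atom": m_atom, "cat": cat, "atom_h": atom_h, "mol_h": mol_h,
    }


def _ffn_forward(
    z: np.ndarray,
    params: DMPNNParams,
    config: DMPNNConfig,
    dropout_rng: np.random.Generator | None = None,
) -> dict:
    acts = [z]
    masks = []
    x = z
    p = config.dropout
    for i, (W, b) in enumerate(zip(params.ffn_W, params.ffn_b)):
        if dropout_rng is not None and p > 0:
            mask = (dropout_rng.random(x.shape) >= p) / (1 - p)
            x = x * mask
            masks.append(mask)
        else:
            masks.append(None)
        x = x @ W.T + b
        if i < len(params.ffn_W) - 1:
            x = _relu(x)
        acts.append(x)
    return {"acts": acts, "masks": masks, "logits": x[:, 0]}


def _forward_batch(
    bg: BatchGraph,
    descriptors: np.ndarray | None,
    params: DMPNNParams,
    config: DMPNNConfig,
    dropout_rng: np.random.Generator | None = None,
) -> dict:
    enc = _encode(bg, params, config)
    z = enc["mol_h"]
    if config.use_descriptors:
        if descriptors is None:
            raise ValueError("config.use_descriptors is set but no descriptors given")
        z = np.concatenate([z, np.atleast_2d(descriptors)], axis=1)
    ffn = _ffn_forward(z, params, config, dropout_rng)
    enc["z"] = z
    enc.update(ffn)
    enc["proba"] = 1.0 / (1.0 + np.exp(-enc["logits"]))
    return enc


def _backprop(
    bg: BatchGraph,
    cache: dict,
    dlogits: np.ndarray,
    params: DMPNNParams,
    config: DMPNNConfig,
) -> dict[str, np.ndarray]:
    grads = {name: np.zeros_like(arr) for name, arr in params.named_arrays()}
    # FFN
    acts, masks = cache["acts"], cache["masks"]
    dx = dlogits[:, None]
    for i in range(len(params.ffn_W) - 1, -1, -1):
        a_in = acts[i]
        if masks[i] is not None:
            a_in = a_in * masks[i]
        if i < len(params.ffn_W) - 1:
            dx = dx * (acts[i + 1] > 0)
        grads[f"ffn_W{i}"] += dx.T @ a_in
        grads[f"ffn_b{i}"] += dx.sum(axis=0)
        dx = dx @ params.ffn_W[i]
        if masks[i] is not None:
            dx = dx * masks[i]
    h = config.hidden_size
    dmol_h = dx[:, :h]
    # sum pooling adjoint
    datom_h = dmol_h[bg.atom_mol]
    dpre_a = datom_h * (cache["atom_h"] > 0)
    grads["Wa"] += dpre_a.T @ cache["cat"]
    grads["ba"] += dpre_a.sum(axis=0)
    dcat = dpre_a @ params.Wa
    dm_atom = dcat[:, ATOM_FDIM:]
    if bg.n_bonds == 0:
        return grads
    # readout aggregation adjoint
    dh = dm_atom[cache["agg_index"]]
    dh0_total = np.zeros_like(cache["h0"])
    for t in range(config.depth - 1, -1, -1):
        step = cache["steps"][t]
        dpre = dh * (step["h"] > 0)
        dh0_total += dpre
        grads["Wm"] += dpre.T @ step["m"]
        dm = dpre @ params.Wm
        g_src = _scatter_sum(dm, bg.src, bg.n_atoms)
        dh = g_src[bg.dst] - dm[bg.rev]
    dh0_total += dh  # flow into h0 through step 1's message
    dpre0 = dh0_total * (cache["h0"] > 0)
    grads["Wi"] += dpre0.T @ cache["inp"]
    return grads


# ---------------------------------------------------------------------------
# Single-graph contract (thin wrappers over the batched path)


@dataclass
class BondStates:
    """Hidden states of one molecule's directed bonds at step ``t``."""

    h0: np.ndarray
    h_t: np.ndarray
    m_t: np.ndarray
    t: int = 0


def init_bond_states(graph: MolGraph, params: DMPNNParams) -> BondStates:
    """h0_vw = tau(W_i [x_v ; e_vw]); messages start at zero."""
    expected = params.Wi.shape[1]
    got = ATOM_FDIM + BOND_FDIM
    if expected != got:
        raise ValueError(f"W_i expects input size {expected}, features give {got}")
    if graph.n_directed_bonds == 0:
        h0 = np.zeros((0, params.Wi.shape[0]))
    else:
        inp = np.concatenate([graph.atom_feats[graph.src], graph.bond_feats], axis=1)
        h0 = _relu(inp @ params.Wi.T)
    return BondStates(h0=h0, h_t=h0.copy(), m_t=np.zeros_like(h0), t=0)


def message_step(graph: MolGraph, states: BondStates, params: DMPNNParams) -> BondStates:
    """One update: m^{t+1}_vw = sum over incoming-at-v excluding reverse; then
    h^{t+1}_vw = tau(h0_vw + W_m m^{t+1}_vw)."""
    if graph.n_directed_bonds == 0:
        return BondStates(h0=states.h0, h_t=states.h_t.copy(), m_t=states.m_t.copy(), t=states.t + 1)
    s = _scatter_sum(states.h_t, graph.dst, graph.n_atoms)
    m = s[graph.src] - states.h_t[graph.reverse_index]
    h_new = _relu(states.h0 + m @ params.Wm.T)
    return BondStates(h0=states.h0, h_t=h_new, m_t=m, t=states.t + 1)


def readout(
    graph: MolGraph,
    states: BondStates,
    params: DMPNNParams,
    direction: str = "incoming",
) -> np.ndarray:
    """Atom vectors from final bond states, sum-pooled into a molecule vector."""
    h = params.Wa.shape[0]
    if graph.n_directed_bonds == 0:
        m_atom = np.zeros((graph.n_atoms, h))
    else:
        idx = graph.dst if direction == "incoming" else graph.src
        m_atom = _scatter_sum(states.h_t, idx, graph.n_atoms)
    cat = np.concatenate([graph.atom_feats, m_atom], axis=1)
    atom_h = _relu(cat @ params.Wa.T + params.ba)
    return atom_h.sum(axis=0)


def forward(
    graph: MolGraph,
    descriptors: np.ndarray | None,
    params: DMPNNParams,
    config: DMPNNConfig,
) -> float:
    """Full forward pass for one molecule; returns the probability in (0, 1)."""
    bg = BatchGraph([graph])
    desc = None
    if config.use_descriptors:
        desc = np.atleast_2d(np.asarray(descriptors, dtype=np.float64))
        if desc.shape[1] != N_DESCRIPTORS:
            raise ValueError(
                f"expected a scaled {N_DESCRIPTORS}-descriptor vector, got {desc.shape[1]}"
            )
    out = _forward_batch(bg, desc, params, config)
    return float(out["proba"][0])


# ---------------------------------------------------------------------------
# Training


@functools.lru_cache(maxsize=200_000)
def _graph_cached(smiles: str) -> MolGraph:
    return smiles_to_graph(smiles)


def featurize_records(records: Sequence[CompoundRecord]) -> tuple[list[MolGraph], np.ndarray]:
    """Graphs plus raw (unscaled) descriptor matrix for a record list."""
    graphs = [_graph_cached(r.smiles) for r in records]
    desc = np.stack([compute_global_descriptors(r.smiles).values for r in records])
    return graphs, desc


@dataclass
class TrainedModel:
    params: DMPNNParams
    config: DMPNNConfig
    scaler: DescriptorScaler | None
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    stopped_epoch: int = 0
    best_epoch: int = 0

    def predict_proba(
        self, records: Sequence[CompoundRecord], on_error: str = "raise"
    ) -> np.ndarray:
        return predict_proba(self, records, on_error=on_error)

    def save(self, path: str | Path) -> None:
        payload = {
            "schema": "molactive-dmpnn-v1",
            "config": asdict(self.config),
            "params": {name: arr.tolist() for name, arr in self.params.named_arrays()},
            "ffn_depth": len(self.params.ffn_W),
            "scaler": self.scaler.to_dict() if self.scaler else None,
            "history": self.history,
            "stopped_epoch": self.stopped_epoch,
            "best_epoch": self.best_epoch,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        if d.get("schema") != "molactive-dmpnn-v1":
            raise ValueError(f"unrecognized checkpoint schema in {path}")
        cfg = DMPNNConfig(**d["config"])
        p = d["params"]
        params = DMPNNParams(
            Wi=np.asarray(p["Wi"]),
            Wm=np.asarray(p["Wm"]),
            Wa=np.asarray(p["Wa"]),
            ba=np.asarray(p["ba"]),
            ffn_W=[np.asarray(p[f"ffn_W{i}"]) for i in range(d["ffn_depth"])],
            ffn_b=[np.asarray(p[f"ffn_b{i}"]) for i in range(d["ffn_depth"])],
        )
        scaler = DescriptorScaler.from_dict(d["scaler"]) if d["scaler"] else None
        return cls(
            params=params,
            config=cfg,
            scaler=scaler,
            history=d["history"],
            stopped_epoch=d["stopped_epoch"],
            best_epoch=d["best_epoch"],
        )


def _bce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    # numerically stable binary cross-entropy with logits
    loss = float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
    dlogits = (1.0 / (1.0 + np.exp(-logits)) - y) / len(y)
    return loss, dlogits


def _dataset_loss(
    graphs: list[MolGraph],
    desc: np.ndarray | None,
    y: np.ndarray,
    params: DMPNNParams,
    config: DMPNNConfig,
    batch_size: int = 256,
) -> float:
    total = 0.0
    for lo in range(0, len(graphs), batch_size):
        hi = min(lo + batch_size, len(graphs))
        bg = BatchGraph(graphs[lo:hi])
        d = desc[lo:hi] if desc is not None else None
        out = _forward_batch(bg, d, params, config)
        loss, _ = _bce_loss_and_grad(out["logits"], y[lo:hi])
        total += loss * (hi - lo)
    return total / len(graphs)


class _Adam:
    def __init__(self, params: DMPNNParams, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {name: np.zeros_like(a) for name, a in params.named_arrays()}
        self.v = {name: np.zeros_like(a) for name, a in params.named_arrays()}

    def step(self, params: DMPNNParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, arr in params.named_arrays():
            g = grads[name]
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    train_records: Sequence[CompoundRecord],
    val_records: Sequence[CompoundRecord],
    config: DMPNNConfig,
) -> TrainedModel:
    """Minibatch Adam on binary cross-entropy with early stopping.

    The descriptor scaler is fit on the training records only. Training
    stops when validation loss has not improved for ``patience`` epochs and
    the best-validation parameters are restored. Deterministic under
    ``config.seed``.
    """
    y_train = np.asarray([r.label for r in train_records], dtype=np.float64)
    y_val = np.asarray([r.label for r in val_records], dtype=np.float64)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training set contains a single class")

    graphs_tr, desc_tr = featurize_records(train_records)
    graphs_va, desc_va = featurize_records(val_records)

    scaler = None
    sd_tr = sd_va = None
    if config.use_descriptors:
        scaler = DescriptorScaler().fit(desc_tr)
        sd_tr = scaler.transform(desc_tr)
        sd_va = scaler.transform(desc_va)

    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)
    opt = _Adam(params, config.learning_rate)

    model = TrainedModel(params=params, config=config, scaler=scaler)
    best_val = np.inf
    best_params = params.copy()
    bad_epochs = 0

    n = len(train_records)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            bg = BatchGraph([graphs_tr[i] for i in idx])
            d = sd_tr[idx] if sd_tr is not None else None
            drop_rng = rng if config.dropout > 0 else None
            out = _forward_batch(bg, d, params, config, dropout_rng=drop_rng)
            loss, dlogits = _bce_loss_and_grad(out["logits"], y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch} "
                    f"(lr={config.learning_rate}, batch of {len(idx)})"
                )
            grads = _backprop(bg, out, dlogits, params, config)
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        val_loss = _dataset_loss(graphs_va, sd_va, y_val, params, config)
        model.history["train_loss"].append(epoch_loss)
        model.history["val_loss"].append(val_loss)
        model.stopped_epoch = epoch
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = params.copy()
            model.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    model.params = best_params
    return model


def predict_proba(
    model: TrainedModel,
    records: Sequence[CompoundRecord],
    on_error: str = "raise",
    batch_size: int = 256,
) -> np.ndarray:
    """Predicted probabilities per record, order-preserving.

    ``on_error='nan'`` records a NaN for unparseable SMILES instead of
    raising, so batch jobs can report per-record failures.
    """
    probs = np.full(len(records), np.nan)
    ok_idx, graphs, descs = [], [], []
    for i, r in enumerate(records):
        try:
            graphs.append(_graph_cached(r.smiles))
            descs.append(compute_global_descriptors(r.smiles).values)
            ok_idx.append(i)
        except ValueError:
            if on_error == "raise":
                raise
    if ok_idx:
        desc = np.stack(descs)
        sd = model.scaler.transform(desc) if model.config.use_descriptors else None
        vals = []
        for lo in range(0, len(ok_idx), batch_size):
            hi = min(lo + batch_size, len(ok_idx))
            bg = BatchGraph(graphs[lo:hi])
            d = sd[lo:hi] if sd is not None else None
            out = _forward_batch(bg, d, model.params, model.config)
            vals.append(out["proba"])
        probs[ok_idx] = np.concatenate(vals)
    return probs
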