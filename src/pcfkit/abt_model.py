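"""Atom-bond transformer regressor for per-kilogram carbon footprints.

Pipeline (per molecule): directed-bond message passing -> multi-head
self-attention over bonds (encoder) -> atom states as sums of incoming bond
states fused with projected raw atom features -> multi-head self-attention
over atoms whose pre-softmax logits carry an additive bias
lambda * (A + s(Dist) + s(Coul)) built from the interatomic matrices
(decoder) -> mean pooling -> concatenation with precalculated molecular
descriptors -> feed-forward head.

There are no positional encodings anywhere, so predictions are invariant
under atom reordering.  The network runs on a small NumPy reverse-mode
autodiff core (`pcfkit._autodiff`); molecules are processed in padded
mini-batches (padded keys are masked out of every softmax and padded atoms
out of the pooling, so batching never changes a molecule's value).  Training
uses adaptive moment estimation on the raw-PCF mean-squared error and keeps
the weights of the epoch with the lowest validation RMSE.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, concat, layer_norm, no_grad, relu, softmax_rows
from .datakit import Dataset
from .featurize import (
    ATOM_FEATURE_DIM,
    BOND_FEATURE_DIM,
    ELEMENTS,
    MANIFEST_VERSION,
    MolGraph,
    compute_descriptors,
    featurize_graph,
)

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "PredictionResult",
    "DivergenceError",
    "init_params",
    "message_passing",
    "encode",
    "train",
    "predict",
]

_MASK = -1e9  # additive key mask; exp underflows to exactly 0 after shift


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """The four tuned hyperparameters plus fixed architecture constants.

    `mp_iterations`, `interatomic_scaler`, `dropout` and `hidden_dim` are the
    search dimensions; six attention heads and single encoder/decoder blocks
    are architecture defaults.
    """

    mp_iterations: int = 3
    interatomic_scaler: float = 0.1
    dropout: float = 0.0
    hidden_dim: int = 200
    n_heads: int = 6
    n_encoder_blocks: int = 1
    n_decoder_blocks: int = 1
    ffn_mult: int = 4
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    patience: int = 50
    use_descriptors: bool = True
    log_target: bool = False
    masked_bond_attention: bool = False

    def __post_init__(self):
        if not 1 <= self.mp_iterations <= 10:
            raise ValueError("mp_iterations must lie in [1, 10]")
        if not 0.0 <= self.interatomic_scaler <= 0.5:
            raise ValueError("interatomic_scaler must lie in [0, 0.5]")
        if not 0.0 <= self.dropout <= 0.5:
            raise ValueError("dropout must lie in [0, 0.5]")
        if self.hidden_dim < self.n_heads:
            raise ValueError("hidden_dim must be at least n_heads")
        if self.n_encoder_blocks < 1 or self.n_decoder_blocks < 1:
            raise ValueError("need at least one encoder and one decoder block")

    @property
    def head_dim(self) -> int:
        return max(1, self.hidden_dim // self.n_heads)


# -------------------------------------------------------------- initialization
def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _block_params(rng, prefix: str, cfg: ModelConfig) -> dict[str, Tensor]:
    h, dh, f = cfg.hidden_dim, cfg.head_dim, cfg.ffn_mult
    p: dict[str, Tensor] = {}
    for name in ("Wq", "Wk", "Wv"):
        p[f"{prefix}.{name}"] = Tensor(_glorot(rng, h, cfg.n_heads * dh), requires_grad=True)
    p[f"{prefix}.Wo"] = Tensor(_glorot(rng, cfg.n_heads * dh, h), requires_grad=True)
    p[f"{prefix}.bo"] = Tensor(np.zeros(h), requires_grad=True)
    p[f"{prefix}.ln1_g"] = Tensor(np.ones(h), requires_grad=True)
    p[f"{prefix}.ln1_b"] = Tensor(np.zeros(h), requires_grad=True)
    p[f"{prefix}.W1"] = Tensor(_glorot(rng, h, f * h), requires_grad=True)
    p[f"{prefix}.b1"] = Tensor(np.zeros(f * h), requires_grad=True)
    p[f"{prefix}.W2"] = Tensor(_glorot(rng, f * h, h), requires_grad=True)
    p[f"{prefix}.b2"] = Tensor(np.zeros(h), requires_grad=True)
    p[f"{prefix}.ln2_g"] = Tensor(np.ones(h), requires_grad=True)
    p[f"{prefix}.ln2_b"] = Tensor(np.zeros(h), requires_grad=True)
    return p


def init_params(cfg: ModelConfig, n_descriptors: int,
                rng: np.random.Generator | None = None) -> dict[str, Tensor]:
    """Seeded Glorot initialization of every weight in the network."""
    rng = rng or np.random.default_rng(cfg.seed)
    h = cfg.hidden_dim
    p: dict[str, Tensor] = {
        "W_in": Tensor(_glorot(rng, ATOM_FEATURE_DIM + BOND_FEATURE_DIM, h), requires_grad=True),
        "b_in": Tensor(np.zeros(h), requires_grad=True),
        "W_m": Tensor(_glorot(rng, h, h), requires_grad=True),
        "b_m": Tensor(np.zeros(h), requires_grad=True),
        "W_atom": Tensor(_glorot(rng, ATOM_FEATURE_DIM, h), requires_grad=True),
        "b_atom": Tensor(np.zeros(h), requires_grad=True),
    }
    for i in range(cfg.n_encoder_blocks):
        p.update(_block_params(rng, f"enc{i}", cfg))
    for i in range(cfg.n_decoder_blocks):
        p.update(_block_params(rng, f"dec{i}", cfg))
    head_in = h + (n_descriptors if cfg.use_descriptors else 0)
    p["Wh1"] = Tensor(_glorot(rng, head_in, h), requires_grad=True)
    p["bh1"] = Tensor(np.zeros(h), requires_grad=True)
    p["Wh2"] = Tensor(_glorot(rng, h, 1), requires_grad=True)
    p["bh2"] = Tensor(np.zeros(1), requires_grad=True)
    return p


# ------------------------------------------------------- per-graph constants
def _minmax01(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    return np.zeros_like(m) if hi <= lo else (m - lo) / (hi - lo)


@dataclass
class GraphTensors:
    """Constant arrays derived from one MolGraph, reused across epochs."""

    graph: MolGraph
    x_in: np.ndarray        # (nb, d_atom + d_bond) concat(source atom, bond)
    msg: np.ndarray         # (nb, nb) message-aggregation matrix
    incoming: np.ndarray    # (n, nb) indicator of bonds ending at each atom
    attn_bias: np.ndarray   # (n, n) additive decoder logit bias
    bond_mask: np.ndarray | None  # (nb, nb) 0/-1e9 shared-atom mask

    @property
    def n(self) -> int:
        return self.graph.n_atoms

    @property
    def nb(self) -> int:
        return self.graph.n_bonds


def prepare_graph(g: MolGraph, cfg: ModelConfig) -> GraphTensors:
    n, nb = g.n_atoms, g.n_bonds
    lam = cfg.interatomic_scaler
    bias = lam * (g.adjacency + _minmax01(g.topo_dist) + _minmax01(g.coulomb)) \
        if lam > 0 else np.zeros((n, n))
    if nb == 0:
        return GraphTensors(g, np.zeros((0, ATOM_FEATURE_DIM + BOND_FEATURE_DIM)),
                            np.zeros((0, 0)), np.zeros((n, 0)), bias, None)
    src, tgt = g.bond_index[:, 0], g.bond_index[:, 1]
    x_in = np.concatenate([g.atom_feats[src], g.bond_feats], axis=1)
    # msg[b, b'] = 1 when bond b' = (k -> i) feeds bond b = (i -> j), k != j
    msg = np.zeros((nb, nb))
    for b in range(nb):
        feeds = tgt == src[b]
        feeds[b ^ 1] = False  # directions are stored pairwise; exclude reverse
        msg[b, feeds] = 1.0
    incoming = np.zeros((n, nb))
    incoming[tgt, np.arange(nb)] = 1.0
    bond_mask = None
    if cfg.masked_bond_attention:
        share = (src[:, None] == src[None, :]) | (src[:, None] == tgt[None, :]) \
            | (tgt[:, None] == src[None, :]) | (tgt[:, None] == tgt[None, :])
        bond_mask = np.where(share, 0.0, _MASK)
    return GraphTensors(g, x_in, msg, incoming, bias, bond_mask)


@dataclass
class Batch:
    """Padded constants for a mini-batch of molecules."""

    size: int
    x_in: Tensor        # (B, NB, d_in)
    msg: Tensor         # (B, NB, NB)
    incoming: Tensor    # (B, N, NB)
    atom_feats: Tensor  # (B, N, d_atom)
    bond_bias: np.ndarray  # (B, 1, NB, NB) key mask (+ shared-atom mask)
    atom_bias: np.ndarray  # (B, 1, N, N) interatomic bias + key mask
    pool: Tensor        # (B, N, 1) atom indicator scaled by 1/n_atoms
    desc: Tensor | None  # (B, D) standardized descriptors
    n_atoms: list[int]


def make_batch(graphs: list[GraphTensors], desc: np.ndarray | None) -> Batch:
    b = len(graphs)
    nb_max = max(1, max(g.nb for g in graphs))
    n_max = max(g.n for g in graphs)
    d_in = ATOM_FEATURE_DIM + BOND_FEATURE_DIM
    x_in = np.zeros((b, nb_max, d_in))
    msg = np.zeros((b, nb_max, nb_max))
    inc = np.zeros((b, n_max, nb_max))
    af = np.zeros((b, n_max, ATOM_FEATURE_DIM))
    bond_bias = np.full((b, 1, nb_max, nb_max), _MASK)
    atom_bias = np.full((b, 1, n_max, n_max), _MASK)
    pool = np.zeros((b, n_max, 1))
    for i, g in enumerate(graphs):
        n, nb = g.n, g.nb
        x_in[i, :nb] = g.x_in
        msg[i, :nb, :nb] = g.msg
        inc[i, :n, :nb] = g.incoming
        af[i, :n] = g.graph.atom_feats
        bond_bias[i, 0, :, :nb] = 0.0
        if g.bond_mask is not None:
            bond_bias[i, 0, :nb, :nb] = g.bond_mask
        atom_bias[i, 0, :, :n] = 0.0
        atom_bias[i, 0, :n, :n] = g.attn_bias
        pool[i, :n, 0] = 1.0 / n
    return Batch(
        size=b,
        x_in=Tensor(x_in),
        msg=Tensor(msg),
        incoming=Tensor(inc),
        atom_feats=Tensor(af),
        bond_bias=bond_bias,
        atom_bias=atom_bias,
        pool=Tensor(pool),
        desc=None if desc is None else Tensor(desc),
        n_atoms=[g.n for g in graphs],
    )


# ------------------------------------------------------------------- forward
def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if p <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def _attention_block(x: Tensor, params, prefix: str, cfg: ModelConfig,
                     bias: np.ndarray, rng) -> tuple[Tensor, np.ndarray]:
    """Post-norm transformer block on (B, M, H); returns output and the
    (B, heads, M, M) attention maps."""
    b, m, _ = x.shape
    heads, dh = cfg.n_heads, cfg.head_dim

    def split(t: Tensor) -> Tensor:  # (B, M, heads*dh) -> (B, heads, M, dh)
        return t.reshape(b, m, heads, dh).transpose(0, 2, 1, 3)

    q = split(x @ params[f"{prefix}.Wq"])
    k = split(x @ params[f"{prefix}.Wk"])
    v = split(x @ params[f"{prefix}.Wv"])
    logits = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh)) + Tensor(bias)
    a = softmax_rows(logits)
    ctx = (a @ v).transpose(0, 2, 1, 3).reshape(b, m, heads * dh)
    mha = ctx @ params[f"{prefix}.Wo"] + params[f"{prefix}.bo"]
    y = layer_norm(x + _dropout(mha, cfg.dropout, rng),
                   params[f"{prefix}.ln1_g"], params[f"{prefix}.ln1_b"])
    ffn = relu(y @ params[f"{prefix}.W1"] + params[f"{prefix}.b1"])
    ffn = _dropout(ffn, cfg.dropout, rng) @ params[f"{prefix}.W2"] + params[f"{prefix}.b2"]
    z = layer_norm(y + _dropout(ffn, cfg.dropout, rng),
                   params[f"{prefix}.ln2_g"], params[f"{prefix}.ln2_b"])
    return z, a.data


def _message_passing(batch: Batch, params, cfg: ModelConfig) -> Tensor:
    """T rounds of directed-bond updates:
    h0 = relu(W_in . concat(atom_i, bond_ij));
    h(t+1)_ij = relu(h0_ij + W_m . sum_{k in N(i) \\ j} h(t)_ki)."""
    h0 = relu(batch.x_in @ params["W_in"] + params["b_in"])
    h = h0
    for _ in range(cfg.mp_iterations - 1):
        h = relu(h0 + (batch.msg @ h) @ params["W_m"] + params["b_m"])
    return h


def _forward(batch: Batch, params, cfg: ModelConfig,
             rng=None) -> tuple[Tensor, list[np.ndarray]]:
    """Batched forward pass: returns (B,) predictions and per-decoder-block
    (B, heads, N, N) attention maps."""
    h = _message_passing(batch, params, cfg)
    for i in range(cfg.n_encoder_blocks):
        h, _ = _attention_block(h, params, f"enc{i}", cfg, batch.bond_bias, rng)
    atoms = batch.incoming @ h + batch.atom_feats @ params["W_atom"] + params["b_atom"]
    attn_out: list[np.ndarray] = []
    for i in range(cfg.n_decoder_blocks):
        atoms, maps = _attention_block(atoms, params, f"dec{i}", cfg, batch.atom_bias, rng)
        attn_out.append(maps)
    pooled = (atoms * batch.pool).sum(axis=1)  # (B, H) mean over real atoms
    emb = concat([pooled, batch.desc], axis=1) if cfg.use_descriptors else pooled
    hidden = _dropout(relu(emb @ params["Wh1"] + params["bh1"]), cfg.dropout, rng)
    out = hidden @ params["Wh2"] + params["bh2"]
    return out.reshape(batch.size), attn_out


# ---------------------------------------------------------------- single-mol
def message_passing(g: MolGraph, cfg: ModelConfig,
                    params: dict[str, Tensor] | None = None) -> np.ndarray:
    """Bond hidden-state matrix after `mp_iterations` rounds (inference)."""
    if params is None:
        params = init_params(cfg, 0)
    if g.n_bonds == 0:
        return np.zeros((0, cfg.hidden_dim))
    batch = make_batch([prepare_graph(g, cfg)], None)
    with no_grad():
        return _message_passing(batch, params, cfg).data[0]


def encode(g: MolGraph, desc: np.ndarray | None, cfg: ModelConfig,
           params: dict[str, Tensor] | None = None) -> tuple[np.ndarray, list[np.ndarray]]:
    """Prediction-ready embedding (pooled atoms [+ descriptors]) and the
    decoder attention tensor, under fixed (possibly freshly seeded) weights."""
    use_desc = cfg.use_descriptors and desc is not None
    if params is None:
        params = init_params(cfg, len(desc) if use_desc else 0)
    if not use_desc and cfg.use_descriptors:
        cfg = ModelConfig(**{**asdict(cfg), "use_descriptors": False})
    batch = make_batch([prepare_graph(g, cfg)],
                       np.asarray(desc)[None, :] if use_desc else None)
    with no_grad():
        return _encode_batch(batch, desc, params, cfg, use_desc)


def _encode_batch(batch, desc, params, cfg, use_desc):
    h = _message_passing(batch, params, cfg)
    for i in range(cfg.n_encoder_blocks):
        h, _ = _attention_block(h, params, f"enc{i}", cfg, batch.bond_bias, None)
    atoms = batch.incoming @ h + batch.atom_feats @ params["W_atom"] + params["b_atom"]
    attn_out = []
    for i in range(cfg.n_decoder_blocks):
        atoms, maps = _attention_block(atoms, params, f"dec{i}", cfg, batch.atom_bias, None)
        attn_out.append(maps[0])
    pooled = (atoms * batch.pool).sum(axis=1).data[0]
    emb = np.concatenate([pooled, desc]) if use_desc else pooled
    return emb, attn_out


# ------------------------------------------------------------- trained model
@dataclass
class PredictionResult:
    value: float
    out_of_vocabulary: bool = False


@dataclass
class TrainedModel:
    config: ModelConfig
    params: dict[str, Tensor]
    desc_mean: np.ndarray
    desc_std: np.ndarray
    manifest_version: str = MANIFEST_VERSION
    training_history: list[dict] = field(default_factory=list)

    def __post_init__(self):
        # featurization cache keyed by the SMILES string as given
        self._cache: dict[str, tuple[GraphTensors, np.ndarray | None]] = {}

    def _prepared(self, smiles: str) -> tuple[GraphTensors, np.ndarray | None]:
        hit = self._cache.get(smiles)
        if hit is None:
            g = featurize_graph(smiles)
            desc = None
            if self.config.use_descriptors:
                raw = compute_descriptors(smiles).values
                desc = (raw - self.desc_mean) / self.desc_std
            hit = (prepare_graph(g, self.config), desc)
            self._cache[smiles] = hit
        return hit

    def predict(self, smiles: str) -> float:
        return self.predict_detailed(smiles).value

    def predict_many(self, smiles_list: list[str]) -> np.ndarray:
        prepared = [self._prepared(s) for s in smiles_list]
        desc = np.vstack([d for _, d in prepared]) if self.config.use_descriptors else None
        out = np.empty(len(prepared))
        with no_grad():
            for lo in range(0, len(prepared), 64):
                chunk = prepared[lo: lo + 64]
                batch = make_batch([g for g, _ in chunk],
                                   None if desc is None else desc[lo: lo + 64])
                preds, _ = _forward(batch, self.params, self.config, rng=None)
                out[lo: lo + len(chunk)] = preds.data
        return np.expm1(out) if self.config.log_target else out

    def predict_detailed(self, smiles: str) -> PredictionResult:
        gt, _ = self._prepared(smiles)
        oov = bool(gt.graph.atom_feats[:, len(ELEMENTS)].any())  # "other" element slot
        value = float(self.predict_many([smiles])[0])
        return PredictionResult(value=value, out_of_vocabulary=oov)

    def attention(self, smiles: str) -> list[np.ndarray]:
        """Decoder self-attention maps, one (heads, n_atoms, n_atoms)
        row-stochastic array per decoder block."""
        gt, desc = self._prepared(smiles)
        batch = make_batch([gt], None if desc is None else desc[None, :])
        with no_grad():
            _, attn = _forward(batch, self.params, self.config, rng=None)
        n = gt.n
        return [maps[0][:, :n, :n] for maps in attn]

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        """Single-archive checkpoint: weights (exact float64) + JSON header."""
        meta = {
            "format": "pcfkit-abt-checkpoint-1",
            "config": asdict(self.config),
            "manifest_version": self.manifest_version,
            "training_history": self.training_history,
        }
        buf = io.BytesIO()
        arrays = {f"param::{k}": v.data for k, v in self.params.items()}
        arrays["desc_mean"] = self.desc_mean
        arrays["desc_std"] = self.desc_std
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
                arrays = {k: npz[k] for k in npz.files}
        params = {
            k.removeprefix("param::"): Tensor(v, requires_grad=True)
            for k, v in arrays.items() if k.startswith("param::")
        }
        return cls(
            config=ModelConfig(**meta["config"]),
            params=params,
            desc_mean=arrays["desc_mean"],
            desc_std=arrays["desc_std"],
            manifest_version=meta["manifest_version"],
            training_history=meta["training_history"],
        )


def predict(model: TrainedModel, smiles: str) -> float:
    return model.predict(smiles)


# ------------------------------------------------------------------ training
def train(train_ds: Dataset, val_ds: Dataset, cfg: ModelConfig) -> TrainedModel:
    """Fit the transformer with Adam on the mean-squared error.

    Fully seeded (weight init, shuffling, dropout).  Keeps the weights of the
    epoch with the lowest validation RMSE; stops early after `cfg.patience`
    epochs without improvement.  A non-finite loss aborts with a
    DivergenceError naming the epoch.
    """
    if len(train_ds) < 16:
        raise ValueError(f"need at least 16 training records, got {len(train_ds)}")
    if len(val_ds) == 0:
        raise ValueError("validation set must not be empty")
    overlap = set(train_ds.smiles) & set(val_ds.smiles)
    if overlap:
        raise ValueError(f"train/validation sets overlap on {len(overlap)} molecules")

    rng = np.random.default_rng(cfg.seed)

    tr_graphs = [prepare_graph(featurize_graph(s), cfg) for s in train_ds.smiles]
    va_graphs = [prepare_graph(featurize_graph(s), cfg) for s in val_ds.smiles]
    if cfg.use_descriptors:
        tr_raw = np.vstack([compute_descriptors(s).values for s in train_ds.smiles])
        va_raw = np.vstack([compute_descriptors(s).values for s in val_ds.smiles])
        desc_mean = tr_raw.mean(axis=0)
        desc_std = tr_raw.std(axis=0)
        desc_std[desc_std == 0] = 1.0
        tr_desc = (tr_raw - desc_mean) / desc_std
        va_desc = (va_raw - desc_mean) / desc_std
        n_desc = tr_desc.shape[1]
    else:
        desc_mean, desc_std = np.zeros(0), np.ones(0)
        tr_desc = va_desc = None
        n_desc = 0

    y_tr = np.log1p(train_ds.targets) if cfg.log_target else train_ds.targets
    y_va = np.log1p(val_ds.targets) if cfg.log_target else val_ds.targets

    params = init_params(cfg, n_desc, rng)
    opt = Adam(params, lr=cfg.learning_rate)

    val_batches = [
        make_batch(va_graphs[lo: lo + 64],
                   None if va_desc is None else va_desc[lo: lo + 64])
        for lo in range(0, len(va_graphs), 64)
    ]

    def val_rmse() -> float:
        with no_grad():
            preds = np.concatenate(
                [_forward(b, params, cfg, rng=None)[0].data for b in val_batches])
        return float(np.sqrt(np.mean((preds - y_va) ** 2)))

    history: list[dict] = []
    best: tuple[float, dict | None] = (np.inf, None)
    stale = 0
    n = len(tr_graphs)
    sizes = np.array([g.nb for g in tr_graphs])
    for epoch in range(cfg.epochs):
        # bucketed shuffle: random order, then a stable size sort, keeps
        # padding small while equal-size molecules still mix across batches
        order = rng.permutation(n)
        order = order[np.argsort(sizes[order], kind="stable")]
        starts = np.arange(0, n, cfg.batch_size)
        epoch_loss = 0.0
        for lo in rng.permutation(starts):
            idx = order[lo: lo + cfg.batch_size]
            batch = make_batch([tr_graphs[i] for i in idx],
                               None if tr_desc is None else tr_desc[idx])
            opt.zero_grad()
            preds, _ = _forward(batch, params, cfg, rng=rng)
            loss = (preds - Tensor(y_tr[idx])).pow(2.0).mean()
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n
        v = val_rmse()
        history.append({"epoch": epoch, "train_mse": epoch_loss, "val_rmse": v})
        if v < best[0]:
            best = (v, {k: p.data.copy() for k, p in params.items()})
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    if best[1] is not None:
        for k, p in params.items():
            p.data = best[1][k]
    return TrainedModel(
        config=cfg,
        params=params,
        desc_mean=desc_mean,
        desc_std=desc_std,
        training_history=history,
    )
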