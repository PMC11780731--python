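"""A minimal invariant message-passing potential, trainable and LRP-tractable.

The architecture is a small continuous-filter convolution network in the
SchNet family.  Atoms start from learned element embeddings; ``depth`` message
passing layers then update each atom's m-dimensional feature vector

    H_t,k = act( C_t H_{t-1,k}  +  Σ_{j in neigh(k)} Γ_t(r_kj) ⊙ U_t H_{t-1,j} )

where Γ_t(r) is a filter network over a Gaussian radial-basis expansion of the
interatomic distance (optionally damped by a cosine cutoff), C_t mixes the
atom's own state (the combine step) and U_t transforms incoming neighbor
states (the messages).  An atom-wise readout MLP maps H_T,k to a per-atom
energy contribution; the total energy is their sum.

Two properties are deliberate:

* all inputs are interatomic distances, so the prediction is exactly invariant
  under rigid motions and equivariant under atom permutations;
* every trainable layer outside the filter networks is bias-free, so
  layer-wise relevance redistribution conserves the output exactly (the filter
  values act as constant gates during propagation).

Everything runs in NumPy; gradients for training are hand-written backprop.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .conformer import Conformer
from .graph import NeighborGraph, build_neighbor_graph

__all__ = [
    "ModelConfig",
    "ModelParams",
    "ForwardTrace",
    "TrainingDivergedError",
    "rbf_expand",
    "cosine_cutoff",
    "shifted_softplus",
    "init_params",
    "forward_energy",
    "MessagePassingPotential",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    """Hyperparameters of the toy potential.

    depth
        Number of message-passing layers T; relevance walks have T+1 atoms.
    cutoff
        Neighbor-graph cutoff c in Å.
    n_rbf
        Number of Gaussian radial basis functions with centers evenly spaced
        on [0, cutoff].  ``None`` means ``round(4 * cutoff)``, which keeps the
        center spacing identical across cutoffs (0.25 Å).
    embedding_dim
        Neurons per atom, m.
    """

    depth: int = 2
    cutoff: float = 5.0
    n_rbf: int | None = None
    embedding_dim: int = 16
    filter_hidden: int = 16
    readout_hidden: int = 16
    elements: tuple[str, ...] = ("C",)
    activation: str = "ssp"
    cosine_cutoff_enabled: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.n_rbf is None:
            self.n_rbf = int(round(4 * self.cutoff))
        if self.n_rbf < 2:
            raise ValueError("n_rbf must be >= 2")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.activation not in ("ssp", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")
        self.elements = tuple(self.elements)

    def element_index(self, symbol: str) -> int:
        try:
            return self.elements.index(symbol)
        except ValueError:
            raise KeyError(
                f"element {symbol!r} outside model vocabulary {self.elements}"
            ) from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["elements"] = list(self.elements)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["elements"] = tuple(d.get("elements", ("C",)))
        return cls(**d)


@dataclass
class ModelParams:
    """Weight container; shapes follow the owning :class:`ModelConfig`."""

    emb: np.ndarray  # (n_elements, m)
    layers: list[dict]  # per layer: C (m,m), U (m,m), W1 (F,R), b1 (F), W2 (m,F), b2 (m)
    Wr: np.ndarray  # (H, m)
    wout: np.ndarray  # (H,)
    y_mean: float = 0.0  # target standardisation, applied outside the network
    y_std: float = 1.0

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)


@dataclass
class ForwardTrace:
    """Every intermediate needed by relevance propagation and backprop."""

    graph: NeighborGraph
    elem_idx: np.ndarray
    h: list  # length T+1, each (n, m); h[0] is the embedding layer
    z: list  # length T, each (n, m) pre-activations
    gamma: list  # length T, each (E, m) filter gates (cosine cutoff included)
    uh: list = field(repr=False)  # length T, each (n, m): U_t applied to h[t-1]
    s: list = field(repr=False)  # filter hidden activations, (E, F) per layer
    pre1: list = field(repr=False)  # filter hidden pre-activations
    G: np.ndarray = None  # (E, n_rbf) radial features
    fcut: np.ndarray = None  # (E,) cosine cutoff weights (ones if disabled)
    zr: np.ndarray = None  # (n, H) readout pre-activations
    q: np.ndarray = None  # (n, H) readout hidden activations
    atom_energies: np.ndarray = None  # (n,)
    y: float = 0.0  # network scalar (standardised units)


def shifted_softplus(x: np.ndarray) -> np.ndarray:
    """softplus(x) - log 2; zero at zero, smooth, standard for this family."""
    return np.logaddexp(0.0, x) - np.log(2.0)


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return shifted_softplus(x) if kind == "ssp" else x


def _act_grad(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "ssp":
        return 1.0 / (1.0 + np.exp(-x))
    return np.ones_like(x)


def rbf_expand(r: float | np.ndarray, config: ModelConfig) -> np.ndarray:
    """Gaussian radial basis values; centers evenly spaced on [0, cutoff].

    The Gaussian width equals the center spacing, so a distance sitting on a
    center maximises that basis function.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be >= 0")
    centers = np.linspace(0.0, config.cutoff, config.n_rbf)
    sigma = centers[1] - centers[0]
    return np.exp(-((r[..., None] - centers) ** 2) / (2.0 * sigma**2))


def rbf_spacing(config: ModelConfig) -> float:
    return config.cutoff / (config.n_rbf - 1)


def cosine_cutoff(r: float | np.ndarray, c: float) -> np.ndarray:
    """Smooth cutoff weight ½(1 + cos(πr/c)) on [0, c]; 0 beyond c."""
    r = np.asarray(r, dtype=float)
    w = 0.5 * (1.0 + np.cos(np.pi * np.clip(r, 0.0, c) / c))
    return np.where(r > c, 0.0, w)


def init_params(config: ModelConfig, seed: int = 0) -> ModelParams:
    """Seeded Gaussian initialisation, scaled by fan-in."""
    rng = np.random.default_rng(seed)
    m, f, h = config.embedding_dim, config.filter_hidden, config.readout_hidden
    layers = []
    for _ in range(config.depth):
        layers.append(
            dict(
                C=rng.normal(0.0, 1.0 / np.sqrt(m), (m, m)),
                U=rng.normal(0.0, 1.0 / np.sqrt(m), (m, m)),
                W1=rng.normal(0.0, 1.0 / np.sqrt(config.n_rbf), (f, config.n_rbf)),
                b1=np.zeros(f),
                W2=rng.normal(0.0, 1.0 / np.sqrt(f), (m, f)),
                b2=np.zeros(m),
            )
        )
    return ModelParams(
        emb=rng.normal(0.0, 1.0, (len(config.elements), m)),
        layers=layers,
        Wr=rng.normal(0.0, 1.0 / np.sqrt(m), (h, m)),
        wout=rng.normal(0.0, 1.0 / np.sqrt(h), h),
    )


def _prepare(conformer: Conformer, config: ModelConfig):
    graph = build_neighbor_graph(conformer, config.cutoff)
    elem_idx = np.array([config.element_index(s) for s in conformer.elements])
    G = (
        rbf_expand(graph.distances, config)
        if graph.n_edges
        else np.zeros((0, config.n_rbf))
    )
    fcut = (
        cosine_cutoff(graph.distances, config.cutoff)
        if config.cosine_cutoff_enabled
        else np.ones(graph.n_edges)
    )
    return graph, elem_idx, G, fcut


def forward_energy(
    params: ModelParams,
    config: ModelConfig,
    conformer: Conformer,
    _prepared=None,
) -> ForwardTrace:
    """Run the network on one conformer, caching every activation.

    The returned trace's ``y`` is the raw network scalar (standardised target
    units); multiply by ``params.y_std`` and add ``params.y_mean`` for an
    energy prediction.
    """
    graph, elem_idx, G, fcut = (
        _prepared if _prepared is not None else _prepare(conformer, config)
    )
    src, dst = (
        (graph.edges[:, 0], graph.edges[:, 1])
        if graph.n_edges
        else (np.array([], int), np.array([], int))
    )
    act = config.activation
    h = [params.emb[elem_idx]]
    zs, gammas, uhs, ss, pre1s = [], [], [], [], []
    for layer in params.layers:
        pre1 = G @ layer["W1"].T + layer["b1"]
        s = shifted_softplus(pre1)
        gamma = (s @ layer["W2"].T + layer["b2"]) * fcut[:, None]
        uh = h[-1] @ layer["U"].T
        z = h[-1] @ layer["C"].T
        if graph.n_edges:
            np.add.at(z, dst, gamma * uh[src])
        h.append(_act(z, act))
        zs.append(z)
        gammas.append(gamma)
        uhs.append(uh)
        ss.append(s)
        pre1s.append(pre1)
    zr = h[-1] @ params.Wr.T
    q = _act(zr, act)
    atom_energies = q @ params.wout
    return ForwardTrace(
        graph=graph,
        elem_idx=elem_idx,
        h=h,
        z=zs,
        gamma=gammas,
        uh=uhs,
        s=ss,
        pre1=pre1s,
        G=G,
        fcut=fcut,
        zr=zr,
        q=q,
        atom_energies=atom_energies,
        y=float(atom_energies.sum()),
    )


def _zero_grads(params: ModelParams) -> dict:
    g = dict(
        emb=np.zeros_like(params.emb),
        Wr=np.zeros_like(params.Wr),
        wout=np.zeros_like(params.wout),
        layers=[{k: np.zeros_like(v) for k, v in lay.items()} for lay in params.layers],
    )
    return g


def _backward(
    params: ModelParams, config: ModelConfig, trace: ForwardTrace, dy: float, grads: dict
) -> None:
    """Accumulate d(dy·y)/dθ into ``grads`` (reverse-mode, hand-written)."""
    act = config.activation
    graph = trace.graph
    src, dst = (
        (graph.edges[:, 0], graph.edges[:, 1])
        if graph.n_edges
        else (np.array([], int), np.array([], int))
    )
    n = graph.n_atoms
    # readout
    grads["wout"] += dy * trace.q.sum(axis=0)
    dq = np.full((n, len(params.wout)), 0.0) + dy * params.wout
    dzr = dq * _act_grad(trace.zr, act)
    grads["Wr"] += dzr.T @ trace.h[-1]
    dh = dzr @ params.Wr
    for t in range(config.depth - 1, -1, -1):
        layer, glayer = params.layers[t], grads["layers"][t]
        dz = dh * _act_grad(trace.z[t], act)
        glayer["C"] += dz.T @ trace.h[t]
        dh_prev = dz @ layer["C"]
        if graph.n_edges:
            dz_k = dz[dst]
            dgamma = dz_k * trace.uh[t][src]
            duh_edge = dz_k * trace.gamma[t]
            duh = np.zeros_like(trace.uh[t])
            np.add.at(duh, src, duh_edge)
            glayer["U"] += duh.T @ trace.h[t]
            dh_prev += duh @ layer["U"]
            draw = dgamma * trace.fcut[:, None]
            glayer["b2"] += draw.sum(axis=0)
            glayer["W2"] += draw.T @ trace.s[t]
            ds = draw @ layer["W2"]
            dpre1 = ds * (1.0 / (1.0 + np.exp(-trace.pre1[t])))
            glayer["b1"] += dpre1.sum(axis=0)
            glayer["W1"] += dpre1.T @ trace.G
        dh = dh_prev
    np.add.at(grads["emb"], trace.elem_idx, dh)


def _param_items(params: ModelParams):
    yield "emb", params.emb
    yield "Wr", params.Wr
    yield "wout", params.wout
    for t, lay in enumerate(params.layers):
        for k in ("C", "U", "W1", "b1", "W2", "b2"):
            yield f"layer{t}.{k}", lay[k]


def _grad_items(grads: dict):
    yield grads["emb"]
    yield grads["Wr"]
    yield grads["wout"]
    for lay in grads["layers"]:
        for k in ("C", "U", "W1", "b1", "W2", "b2"):
            yield lay[k]


class MessagePassingPotential(RegressorMixin, BaseEstimator):
    """Scikit-learn style regressor wrapping the toy message-passing potential.

    ``fit(X, y)`` takes a list of :class:`Conformer` and energies in kcal/mol;
    training minimises the mean squared error of the standardised energies by
    full-batch Adam.  Fitted state lives in trailing-underscore attributes
    (``params_``, ``config_``, ``history_``, ``checkpoints_``).

    Parameters mirror :class:`ModelConfig` plus the training schedule.  With
    ``epochs=0`` the model keeps its seeded initialisation (an "untrained"
    network, useful as an analysis baseline).
    """

    def __init__(
        self,
        depth: int = 2,
        cutoff: float = 5.0,
        n_rbf: int | None = None,
        embedding_dim: int = 16,
        filter_hidden: int = 16,
        readout_hidden: int = 16,
        elements: tuple[str, ...] | None = None,
        activation: str = "ssp",
        cosine_cutoff_enabled: bool = True,
        epochs: int = 400,
        lr: float = 5e-3,
        val_fraction: float = 0.15,
        seed: int = 0,
        checkpoint_epochs: tuple[int, ...] = (),
    ):
        self.depth = depth
        self.cutoff = cutoff
        self.n_rbf = n_rbf
        self.embedding_dim = embedding_dim
        self.filter_hidden = filter_hidden
        self.readout_hidden = readout_hidden
        self.elements = elements
        self.activation = activation
        self.cosine_cutoff_enabled = cosine_cutoff_enabled
        self.epochs = epochs
        self.lr = lr
        self.val_fraction = val_fraction
        self.seed = seed
        self.checkpoint_epochs = checkpoint_epochs

    def _make_config(self, X: list[Conformer]) -> ModelConfig:
        elements = self.elements
        if elements is None:
            elements = tuple(sorted({s for c in X for s in c.elements}))
        return ModelConfig(
            depth=self.depth,
            cutoff=self.cutoff,
            n_rbf=self.n_rbf,
            embedding_dim=self.embedding_dim,
            filter_hidden=self.filter_hidden,
            readout_hidden=self.readout_hidden,
            elements=elements,
            activation=self.activation,
            cosine_cutoff_enabled=self.cosine_cutoff_enabled,
        )

    def fit(self, X: list[Conformer], y) -> "MessagePassingPotential":
        if len(X) == 0:
            raise ValueError("empty training set")
        y = np.asarray(y, dtype=float)
        if y.shape != (len(X),):
            raise ValueError("y must be one energy per conformer")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")
        config = self._make_config(X)
        params = init_params(config, seed=self.seed)
        y_mean = float(y.mean())
        y_std = float(y.std()) if y.std() > 0 else 1.0
        params.y_mean, params.y_std = y_mean, y_std
        ystd = (y - y_mean) / y_std

        # deterministic split, derived from the seed
        perm = np.random.default_rng(self.seed + 1).permutation(len(X))
        n_val = int(round(self.val_fraction * len(X)))
        val_idx = set(perm[:n_val].tolist()) if n_val else set()
        train_idx = [i for i in range(len(X)) if i not in val_idx]
        val_list = sorted(val_idx)

        prepared = [_prepare(c, config) for c in X]

        def rmse(idx) -> float:
            if not idx:
                return float("nan")
            err = [
                forward_energy(params, config, X[i], prepared[i]).y - ystd[i]
                for i in idx
            ]
            return float(np.sqrt(np.mean(np.square(err))))

        checkpoints: dict[int, ModelParams] = {}
        want_ckpt = set(self.checkpoint_epochs)
        history = []
        # Adam state
        mstate = [np.zeros_like(a) for _, a in _param_items(params)]
        vstate = [np.zeros_like(a) for _, a in _param_items(params)]
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8

        if 0 in want_ckpt or self.epochs == 0:
            checkpoints[0] = params.copy()
        for epoch in range(1, self.epochs + 1):
            grads = _zero_grads(params)
            total = 0.0
            for i in train_idx:
                trace = forward_energy(params, config, X[i], prepared[i])
                err = trace.y - ystd[i]
                total += err * err
                _backward(params, config, trace, 2.0 * err / len(train_idx), grads)
            loss = total / len(train_idx)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            for slot, (garr, (_, parr)) in enumerate(
                zip(_grad_items(grads), _param_items(params))
            ):
                mstate[slot] = beta1 * mstate[slot] + (1 - beta1) * garr
                vstate[slot] = beta2 * vstate[slot] + (1 - beta2) * garr * garr
                mhat = mstate[slot] / (1 - beta1**epoch)
                vhat = vstate[slot] / (1 - beta2**epoch)
                parr -= self.lr * mhat / (np.sqrt(vhat) + adam_eps)
            history.append(
                dict(
                    epoch=epoch,
                    train_rmse=float(np.sqrt(loss)) * y_std,
                    val_rmse=rmse(val_list) * y_std,
                )
            )
            if epoch in want_ckpt:
                checkpoints[epoch] = params.copy()

        checkpoints[self.epochs] = params.copy()
        self.config_ = config
        self.params_ = params
        self.history_ = pd.DataFrame(
            history, columns=["epoch", "train_rmse", "val_rmse"]
        )
        self.checkpoints_ = checkpoints
        return self

    def predict(self, X: list[Conformer]) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        return np.array(
            [
                forward_energy(self.params_, self.config_, c).y * self.params_.y_std
                + self.params_.y_mean
                for c in X
            ]
        )


def train_model(
    dataset: list[Conformer],
    config: ModelConfig,
    seed: int = 0,
    epochs: int = 400,
    lr: float = 5e-3,
    val_fraction: float = 0.15,
    checkpoint_epochs: tuple[int, ...] = (),
) -> tuple[ModelParams, pd.DataFrame]:
    """Train on energy-labelled conformers; thin wrapper over the estimator."""
    y = np.array([c.energy for c in dataset], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("dataset has missing or non-finite energy labels")
    est = MessagePassingPotential(
        depth=config.depth,
        cutoff=config.cutoff,
        n_rbf=config.n_rbf,
        embedding_dim=config.embedding_dim,
        filter_hidden=config.filter_hidden,
        readout_hidden=config.readout_hidden,
        elements=config.elements,
        activation=config.activation,
        cosine_cutoff_enabled=config.cosine_cutoff_enabled,
        epochs=epochs,
        lr=lr,
        val_fraction=val_fraction,
        seed=seed,
        checkpoint_epochs=checkpoint_epochs,
    ).fit(dataset, y)
    return est.params_, est.history_


def save_checkpoint(path: str | Path, params: ModelParams, config: ModelConfig) -> None:
    """Serialise params + config to a single JSON checkpoint (lossless floats)."""
    payload = dict(
        format_version=CHECKPOINT_FORMAT_VERSION,
        config=config.to_dict(),
        y_mean=params.y_mean,
        y_std=params.y_std,
        params=dict(
            emb=params.emb.tolist(),
            Wr=params.Wr.tolist(),
            wout=params.wout.tolist(),
            layers=[{k: v.tolist() for k, v in lay.items()} for lay in params.layers],
        ),
    )
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValueError("unsupported checkpoint format version")
    config = ModelConfig.from_dict(payload["config"])
    p = payload["params"]
    params = ModelParams(
        emb=np.array(p["emb"]),
        layers=[{k: np.array(v) for k, v in lay.items()} for lay in p["layers"]],
        Wr=np.array(p["Wr"]),
        wout=np.array(p["wout"]),
        y_mean=payload["y_mean"],
        y_std=payload["y_std"],
    )
    return params, config
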