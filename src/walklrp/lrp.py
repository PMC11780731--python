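"""Walk-level relevance propagation (GNN-LRP) for the toy potential.

Layer-wise relevance propagation decomposes a network's scalar output onto
lower-layer neurons by redistributing relevance proportionally to each
neuron's contribution to the upper pre-activation,

    R_j = Σ_c  z_jc / (Σ_j' z_j'c)  R_c ,

with an ε-stabilised denominator.  The walk-level variant keeps the *atom*
index at every layer instead of pooling over it: starting from one atom's
energy contribution at the readout, relevance is redistributed one layer at a
time while fixing which predecessor atom (a neighbor, or the atom itself via
the combine step) it flows through.  Following a fixed sequence of atoms
through all T message-passing layers yields the relevance R_W of the walk
W = (v_0, ..., v_T); summed over all walks these recover the prediction y
(conservation), up to the ε stabilisation.

Distance-dependent filter values are treated as constant gates during
propagation: relevance flows through the node features only.  Elementwise
nonlinearities pass relevance through unchanged, the standard LRP treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conformer import Conformer
from .graph import NeighborGraph
from .model import ModelConfig, ModelParams, ForwardTrace, forward_energy

__all__ = [
    "RuleConfig",
    "Walk",
    "WalkRelevanceMap",
    "WalkCapExceededError",
    "NonlinearModelError",
    "enumerate_walks",
    "walk_count",
    "walk_relevances",
    "conservation_residual",
    "linear_oracle_relevances",
]

Walk = tuple[int, ...]

DEFAULT_WALK_CAP = 10**7


class WalkCapExceededError(RuntimeError):
    """Walk enumeration grows exponentially with depth; refuse above the cap."""


class NonlinearModelError(RuntimeError):
    pass


@dataclass
class RuleConfig:
    """LRP rule selection.

    rule
        ``epsilon`` (default): contributions divided by the ε-stabilised
        pre-activation; near-exact conservation for small ε.
        ``gamma``: positive weight parts boosted by ``gamma`` before
        redistribution (denominators recomputed accordingly).
    epsilon
        Sign-matched stabiliser added to denominators; ≥ 0.
    """

    rule: str = "epsilon"
    epsilon: float = 1e-6
    gamma: float = 0.0
    filter_as_constant: bool = True

    def __post_init__(self) -> None:
        if self.rule not in ("epsilon", "gamma"):
            raise ValueError(f"unknown LRP rule {self.rule!r}")
        if self.epsilon < 0 or self.gamma < 0:
            raise ValueError("epsilon and gamma must be >= 0")
        if not self.filter_as_constant:
            raise ValueError(
                "relevance flow through the filter network is not supported; "
                "filters are treated as constant edge gates"
            )

    def modify_weights(self, W: np.ndarray) -> np.ndarray:
        if self.rule == "gamma" and self.gamma > 0:
            return W + self.gamma * np.maximum(W, 0.0)
        return W


@dataclass
class WalkRelevanceMap:
    """Scalar relevance per walk, plus the prediction it decomposes."""

    walks: list[Walk]
    relevances: np.ndarray
    y: float
    depth: int
    rule: RuleConfig
    conformer: Conformer | None = None
    n_zero_denominators: int = 0

    def __post_init__(self) -> None:
        self.relevances = np.asarray(self.relevances, dtype=float)
        if len(self.walks) != self.relevances.shape[0]:
            raise ValueError("one relevance per walk required")

    def to_dict(self) -> dict[Walk, float]:
        return {w: float(r) for w, r in zip(self.walks, self.relevances)}

    def total(self) -> float:
        return float(self.relevances.sum())

    def to_csv(self, path: str | Path) -> None:
        """One row per walk: T+1 atom indices then the relevance (full precision)."""
        lines = [
            f"# y={self.y!r}",
            f"# T={self.depth}",
            f"# rule={self.rule.rule}",
            f"# epsilon={self.rule.epsilon!r}",
            f"# gamma={self.rule.gamma!r}",
            ",".join([f"atom{i}" for i in range(self.depth + 1)] + ["relevance"]),
        ]
        for w, r in zip(self.walks, self.relevances):
            lines.append(",".join(str(v) for v in w) + f",{float(r)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "WalkRelevanceMap":
        meta: dict[str, str] = {}
        walks, rel = [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
            elif line and not line.startswith("atom"):
                parts = line.split(",")
                walks.append(tuple(int(p) for p in parts[:-1]))
                rel.append(float(parts[-1]))
        rule = RuleConfig(
            rule=meta.get("rule", "epsilon"),
            epsilon=float(meta.get("epsilon", 1e-6)),
            gamma=float(meta.get("gamma", 0.0)),
        )
        return cls(
            walks=walks,
            relevances=np.array(rel),
            y=float(meta["y"]),
            depth=int(meta["T"]),
            rule=rule,
        )


def _successors(graph: NeighborGraph, v: int) -> list[int]:
    # self-transition first, then neighbors; sorted for deterministic order
    return [v] + sorted(graph.neighbors[v])


def walk_count(graph: NeighborGraph, depth: int) -> int:
    """Number of walks of ``depth`` steps on the graph with self-loops added.

    Equals the total of the (depth)-th power of the adjacency-plus-identity
    matrix; for a complete graph on n atoms this is n**(depth+1).
    """
    A = np.eye(graph.n_atoms, dtype=object)
    for j, k in graph.edges:
        A[j, k] = 1
    return int(np.sum(np.linalg.matrix_power(A, depth)))


def enumerate_walks(
    graph: NeighborGraph, depth: int, cap: int = DEFAULT_WALK_CAP
) -> list[Walk]:
    """All walks of ``depth + 1`` atoms whose steps are edges or self-transitions."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n_walks = walk_count(graph, depth)
    if n_walks > cap:
        raise WalkCapExceededError(
            f"{n_walks} walks exceed the cap of {cap}; walk enumeration grows "
            "exponentially with network depth"
        )
    walks: list[Walk] = []

    def extend(prefix: tuple[int, ...]) -> None:
        if len(prefix) == depth + 1:
            walks.append(prefix)
            return
        for nxt in _successors(graph, prefix[-1]):
            extend(prefix + (nxt,))

    for start in range(graph.n_atoms):
        extend((start,))
    return walks


def _stabilize(z: np.ndarray, eps: float) -> np.ndarray:
    # sign-matched, dimensionless stabiliser: z (1 + ε).  Keeps the per-step
    # conservation factor at exactly 1/(1+ε) regardless of activation scale;
    # exact zeros stay zero and their relevance share is dropped and counted.
    return z * (1.0 + eps)


class _Propagator:
    """Precomputed per-layer redistribution matrices for one forward trace.

    For layer t and target node k the contribution of predecessor j's neuron b
    to neuron c of h_{t+1,k} is

        self (j = k):       C_t[c, b] * h_t[k, b]
        neighbor (j -> k):  Γ_t(r_kj)[c] * U_t[c, b] * h_t[j, b]

    Denominators are the per-neuron sums of these contributions over all
    predecessors (equal to the cached pre-activation for the ε rule, since the
    network is bias-free outside the constant filter gates).
    """

    def __init__(
        self,
        params: ModelParams,
        config: ModelConfig,
        trace: ForwardTrace,
        rule: RuleConfig,
    ):
        self.trace = trace
        self.rule = rule
        self.depth = config.depth
        graph = trace.graph
        eidx = graph.edge_index()
        self.contrib: list[dict[tuple[int, int], np.ndarray]] = []
        self.inv_den: list[np.ndarray] = []
        self.n_zero_den = 0
        for t in range(config.depth):
            layer = params.layers[t]
            Cmod = rule.modify_weights(layer["C"])
            ztab: dict[tuple[int, int], np.ndarray] = {}
            den = np.zeros((graph.n_atoms, config.embedding_dim))
            for k in range(graph.n_atoms):
                Z = Cmod * trace.h[t][k][None, :]
                ztab[(k, k)] = Z
                den[k] += Z.sum(axis=1)
                for j in graph.neighbors[k]:
                    W = trace.gamma[t][eidx[(j, k)]][:, None] * layer["U"]
                    Z = rule.modify_weights(W) * trace.h[t][j][None, :]
                    ztab[(j, k)] = Z
                    den[k] += Z.sum(axis=1)
            stab = _stabilize(den, rule.epsilon)
            self.n_zero_den += int(np.sum(stab == 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                inv = np.where(stab != 0.0, 1.0 / np.where(stab == 0, 1.0, stab), 0.0)
            self.contrib.append(ztab)
            self.inv_den.append(inv)

        # readout initialisation: relevance of atom k over h_T neurons
        Wrmod = rule.modify_weights(params.Wr)
        woutmod = rule.modify_weights(params.wout[None, :])[0]
        self.readout_R: list[np.ndarray] = []
        for k in range(graph.n_atoms):
            zq = woutmod * trace.q[k]  # hidden-neuron contributions to e_k
            ek = zq.sum()
            stab_e = _stabilize(np.array([ek]), rule.epsilon)[0]
            if stab_e == 0.0:
                self.n_zero_den += 1
                Rq = np.zeros_like(zq)
            else:
                Rq = zq * (trace.atom_energies[k] / stab_e)
            # through the activation unchanged, then over the linear readout
            Zr = Wrmod * trace.h[-1][k][None, :]
            den_r = _stabilize(Zr.sum(axis=1), rule.epsilon)
            zero = den_r == 0.0
            self.n_zero_den += int(zero.sum())
            inv_r = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, den_r))
            self.readout_R.append(Zr.T @ (Rq * inv_r))

    def step(self, t: int, j: int, k: int, R: np.ndarray) -> np.ndarray:
        """Redistribute relevance R at (layer t+1, node k) onto node j at layer t."""
        Z = self.contrib[t][(j, k)]
        return Z.T @ (R * self.inv_den[t][k])


def walk_relevances(
    params: ModelParams,
    config: ModelConfig,
    conformer: Conformer,
    rule: RuleConfig | None = None,
    cap: int = DEFAULT_WALK_CAP,
    trace: ForwardTrace | None = None,
) -> WalkRelevanceMap:
    """GNN-LRP relevances for every walk of the cutoff graph.

    Deterministic for fixed inputs.  The sum of all walk relevances equals the
    network scalar ``y`` up to the ε stabilisation (see
    :func:`conservation_residual`).
    """
    rule = rule or RuleConfig()
    if trace is None:
        trace = forward_energy(params, config, conformer)
    graph = trace.graph
    walks = enumerate_walks(graph, config.depth, cap=cap)
    prop = _Propagator(params, config, trace, rule)

    rel: dict[Walk, float] = {}

    def descend(t: int, node: int, R: np.ndarray, suffix: tuple[int, ...]) -> None:
        if t == 0:
            rel[(node,) + suffix] = float(R.sum())
            return
        for j in _successors(graph, node):
            descend(t - 1, j, prop.step(t - 1, j, node, R), (node,) + suffix)

    for k in range(graph.n_atoms):
        descend(config.depth, k, prop.readout_R[k], ())

    if set(rel) != set(walks):  # pragma: no cover - internal consistency
        raise AssertionError("walk enumeration and propagation disagree")
    return WalkRelevanceMap(
        walks=walks,
        relevances=np.array([rel[w] for w in walks]),
        y=trace.y,
        depth=config.depth,
        rule=rule,
        conformer=conformer,
        n_zero_denominators=prop.n_zero_den,
    )


def conservation_residual(rmap: WalkRelevanceMap) -> float:
    """|Σ_W R_W − y| / |y|; absolute residual (with a warning) if y = 0."""
    diff = abs(rmap.total() - rmap.y)
    if rmap.y == 0.0:
        warnings.warn("y = 0: returning the absolute conservation residual")
        return diff
    return diff / abs(rmap.y)


def linear_oracle_relevances(
    params: ModelParams,
    config: ModelConfig,
    conformer: Conformer,
    cap: int = DEFAULT_WALK_CAP,
) -> WalkRelevanceMap:
    """Exact walk relevances of a *linear* model by algebraic expansion.

    With identity activations the network output is a sum over walks of
    weight-product terms: following walk (v_0, ..., v_T), the embedding of
    v_0 is successively multiplied by C_t (self-transitions) or
    diag(Γ_t(r)) U_t (neighbor steps) and finally projected through the
    readout.  This is an independent oracle used to validate the propagation
    engine; it fails loudly on nonlinear models.
    """
    if config.activation != "identity":
        raise NonlinearModelError(
            "the algebraic-expansion oracle requires identity activations"
        )
    trace = forward_energy(params, config, conformer)
    graph = trace.graph
    eidx = graph.edge_index()
    walks = enumerate_walks(graph, config.depth, cap=cap)
    w_read = params.Wr.T @ params.wout
    rel = np.empty(len(walks))
    for idx, walk in enumerate(walks):
        vec = params.emb[trace.elem_idx[walk[0]]].copy()
        for t in range(config.depth):
            j, k = walk[t], walk[t + 1]
            if j == k:
                vec = params.layers[t]["C"] @ vec
            else:
                vec = trace.gamma[t][eidx[(j, k)]] * (params.layers[t]["U"] @ vec)
        rel[idx] = w_read @ vec
    return WalkRelevanceMap(
        walks=walks,
        relevances=rel,
        y=trace.y,
        depth=config.depth,
        rule=RuleConfig(epsilon=0.0),
        conformer=conformer,
    )
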