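"""Interaction metrics over walk relevances.

Given the walk-level decomposition of a model's prediction, this module
computes the quantities used to judge whether the model's learned interactions
behave physically:

* walk importance p_w — normalised absolute walk relevances, a probability
  distribution over the walk set;
* walk extent d(W) — diameter of the smallest sphere enclosing the atoms a
  walk visits;
* interaction range — the largest extent among walks above an importance
  threshold p_min, or the generalised expectation (Σ p_w d(W)^a)^(1/a);
* pairwise interaction strength — summed importance of walks traversing an
  atom pair, either in context (inclusive) or in isolation (exclusive);
* element-pair matrices of mean log10 strength, split into bonded/nonbonded;
* many-bodyness γ(R) = log10(P100 / P10) of the strengths of equally distant
  pairs, and its average γ̄ — zero for a strict 2-body potential;
* decay-law fits (exponential vs power law) of strength against distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformer import Conformer
from .geometry import walk_extent_points
from .lrp import Walk, WalkRelevanceMap

__all__ = [
    "ImportanceDistribution",
    "RangeSummary",
    "ManyBodyProfile",
    "DecayFitReport",
    "ElementPairMatrices",
    "ZeroRelevanceError",
    "walk_importance",
    "walk_extent",
    "interaction_range",
    "summarize_ranges",
    "pair_interaction_strength",
    "self_strength",
    "element_pair_matrix",
    "many_bodyness",
    "decay_fit",
]


class ZeroRelevanceError(ValueError):
    """All walk relevances are zero: no importance distribution exists."""


def walk_extent(walk: Walk, positions: np.ndarray) -> float:
    """Extent d(W): diameter (Å) of the smallest sphere enclosing the
    (deduplicated) atoms the walk visits."""
    idx = sorted(set(walk))
    if len(idx) == 1:
        return 0.0
    return walk_extent_points(np.asarray(positions, float)[idx])


@dataclass
class ImportanceDistribution:
    """Normalised walk importances with their extents."""

    walks: list[Walk]
    p: np.ndarray
    extents: np.ndarray
    conformer: Conformer | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, float)
        self.extents = np.asarray(self.extents, float)
        if not (len(self.walks) == len(self.p) == len(self.extents)):
            raise ValueError("walks, p and extents must align")
        if np.any(self.p < 0) or np.any(self.extents < 0):
            raise ValueError("p and extents must be nonnegative")


def walk_importance(rmap: WalkRelevanceMap) -> ImportanceDistribution:
    """p_w = |R_W| / Σ_W' |R_W'| over the walk set, with extents attached."""
    absr = np.abs(rmap.relevances)
    total = absr.sum()
    if total == 0.0:
        raise ZeroRelevanceError("all walk relevances are zero")
    if rmap.conformer is None:
        raise ValueError("relevance map carries no conformer (extents unavailable)")
    pos = rmap.conformer.positions
    cache: dict[frozenset, float] = {}
    extents = np.empty(len(rmap.walks))
    for i, w in enumerate(rmap.walks):
        key = frozenset(w)
        if key not in cache:
            cache[key] = walk_extent(w, pos)
        extents[i] = cache[key]
    return ImportanceDistribution(
        walks=rmap.walks, p=absr / total, extents=extents, conformer=rmap.conformer
    )


def interaction_range(
    dist: ImportanceDistribution,
    method: str = "threshold",
    p_min: float = 0.001,
    a: float = 4.0,
) -> float:
    """Interaction range (Å) of one importance distribution.

    ``threshold``: max d(W) over walks with p_w ≥ p_min (p_min must be > 0,
    otherwise the result is just the geometric maximum, independent of the
    model).  Returns 0 with a warning when no walk qualifies.
    ``power``: generalised expectation (Σ p_w d(W)^a)^(1/a); a = 1 is the
    expected distance and a → ∞ approaches the maximum.
    """
    if method == "threshold":
        if p_min <= 0:
            raise ValueError("p_min must be > 0 (p_min = 0 ignores the model)")
        mask = dist.p >= p_min
        if not mask.any():
            warnings.warn(f"no walk reaches p_min = {p_min}; range reported as 0")
            return 0.0
        return float(dist.extents[mask].max())
    if method == "power":
        if a <= 0:
            raise ValueError("a must be > 0")
        # log-scaled accumulation to keep large a numerically stable
        dmax = dist.extents.max()
        if dmax == 0.0:
            return 0.0
        scaled = (dist.extents / dmax) ** a
        return float(dmax * (dist.p @ scaled) ** (1.0 / a))
    raise ValueError(f"unknown range method {method!r}")


@dataclass
class RangeSummary:
    """Per-conformer interaction ranges plus their mean/SD."""

    table: pd.DataFrame  # columns: conformer, lambda_thresh, p_min, lambda_pow, a
    p_min: float
    a: float

    @property
    def mean_thresh(self) -> float:
        return float(self.table["lambda_thresh"].mean())

    @property
    def sd_thresh(self) -> float:
        return float(self.table["lambda_thresh"].std(ddof=0))

    @property
    def mean_pow(self) -> float:
        return float(self.table["lambda_pow"].mean())


def summarize_ranges(
    dists: list[ImportanceDistribution], p_min: float = 0.001, a: float = 4.0
) -> RangeSummary:
    rows = [
        dict(
            conformer=i,
            lambda_thresh=interaction_range(d, "threshold", p_min=p_min),
            p_min=p_min,
            lambda_pow=interaction_range(d, "power", a=a),
            a=a,
        )
        for i, d in enumerate(dists)
    ]
    return RangeSummary(table=pd.DataFrame(rows), p_min=p_min, a=a)


def pair_interaction_strength(
    rmap: WalkRelevanceMap, mode: str = "inclusive"
) -> pd.DataFrame:
    """Per-pair interaction strengths from one relevance map.

    inclusive: s_ij = Σ p_w over walks whose visited-atom set contains both
    i and j (other atoms allowed).  exclusive: visited set equals exactly
    {i, j}.  The table has one row per unordered pair i < j (symmetric by
    construction) with the pair distance and element symbols; pairs no walk
    traverses get strength 0.
    """
    if mode not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    dist = walk_importance(rmap)
    conf = rmap.conformer
    n = conf.n_atoms
    strength = {(i, j): 0.0 for i in range(n) for j in range(i + 1, n)}
    for w, p in zip(dist.walks, dist.p):
        visited = sorted(set(w))
        if mode == "exclusive":
            if len(visited) == 2:
                strength[tuple(visited)] += p
        else:
            for ai in range(len(visited)):
                for bi in range(ai + 1, len(visited)):
                    strength[(visited[ai], visited[bi])] += p
    dmat = conf.distance_matrix()
    rows = [
        dict(
            i=i,
            j=j,
            elem_i=conf.elements[i],
            elem_j=conf.elements[j],
            distance=dmat[i, j],
            mode=mode,
            strength=s,
        )
        for (i, j), s in strength.items()
    ]
    return pd.DataFrame(
        rows, columns=["i", "j", "elem_i", "elem_j", "distance", "mode", "strength"]
    )


def self_strength(rmap: WalkRelevanceMap, i: int) -> float:
    """Σ p_w over walks visiting only atom i (the i = j extension)."""
    dist = walk_importance(rmap)
    return float(
        sum(p for w, p in zip(dist.walks, dist.p) if set(w) == {i})
    )


@dataclass
class ElementPairMatrices:
    """Mean log10 interaction strength per element pair, split by distance."""

    bonded: pd.DataFrame
    nonbonded: pd.DataFrame
    bonded_counts: pd.DataFrame
    nonbonded_counts: pd.DataFrame
    split: float
    n_nonpositive: int = 0


def _as_table(tables) -> pd.DataFrame:
    if isinstance(tables, pd.DataFrame):
        return tables
    return pd.concat(list(tables), ignore_index=True)


def element_pair_matrix(tables, split: float = 1.6) -> ElementPairMatrices:
    """Element×element matrices of mean log10 strength.

    Pairs closer than ``split`` Å count as bonded, farther as nonbonded
    (default 1.6 Å).  Cells with no pairs are NaN (flagged by the count
    matrices), never zero-filled; non-positive strengths are excluded from the
    log statistics and counted.
    """
    table = _as_table(tables)
    elems = sorted(set(table["elem_i"]) | set(table["elem_j"]))
    pos = table[table["strength"] > 0]
    n_nonpos = len(table) - len(pos)
    out = {}
    for name, sel in (
        ("bonded", pos[pos["distance"] < split]),
        ("nonbonded", pos[pos["distance"] >= split]),
    ):
        mat = pd.DataFrame(np.nan, index=elems, columns=elems)
        cnt = pd.DataFrame(0, index=elems, columns=elems)
        key = sel.apply(lambda r: tuple(sorted((r["elem_i"], r["elem_j"]))), axis=1)
        if len(sel):
            grouped = np.log10(sel["strength"]).groupby(key)
            for (a, b), grp in grouped:
                mat.loc[a, b] = mat.loc[b, a] = grp.mean()
                cnt.loc[a, b] = cnt.loc[b, a] = len(grp)
        out[name] = (mat, cnt)
    return ElementPairMatrices(
        bonded=out["bonded"][0],
        nonbonded=out["nonbonded"][0],
        bonded_counts=out["bonded"][1],
        nonbonded_counts=out["nonbonded"][1],
        split=split,
        n_nonpositive=n_nonpos,
    )


@dataclass
class ManyBodyProfile:
    """Binned many-bodyness profile γ(R) and its scalar average γ̄."""

    table: pd.DataFrame  # columns: center, width, count, p10, p100, gamma
    gamma_bar: float
    dropped_bins: int
    n_nonpositive: int
    percentile_convention: str = "linear interpolation between order statistics"


def _bin_edges_from(distances: np.ndarray, bin_width: float) -> np.ndarray:
    # bins are half-open [lo, hi): extend one step past the largest distance
    top = float(distances.max())
    n_bins = int(top / bin_width) + 1
    return bin_width * np.arange(n_bins + 1)


def many_bodyness(
    tables,
    bin_width: float = 0.5,
    bin_edges: np.ndarray | None = None,
    min_count: int = 20,
) -> ManyBodyProfile:
    """Many-bodyness profile of pair strengths.

    Per retained distance bin, γ(R) = log10(P100(S_R) / P10(S_R)) where S_R is
    the set of strengths of pairs falling in the bin; γ̄ is the unweighted mean
    over retained bins.  Bins with fewer than ``min_count`` pairs are dropped
    and counted; non-positive strengths are excluded and counted.  Explicit
    ``bin_edges`` override the regular ``bin_width`` grid: a 1-D array gives
    consecutive bins, an (n, 2) array gives disjoint windows (e.g. narrow
    windows at exactly repeated distances).
    """
    table = _as_table(tables)
    good = table[table["strength"] > 0]
    n_nonpos = len(table) - len(good)
    if len(good) == 0:
        raise ValueError("no positive strengths: empty many-bodyness profile")
    d = good["distance"].to_numpy()
    s = good["strength"].to_numpy()
    if bin_edges is None:
        edges = _bin_edges_from(d, bin_width)
        windows = list(zip(edges[:-1], edges[1:]))
    else:
        arr = np.asarray(bin_edges, float)
        windows = [tuple(row) for row in arr] if arr.ndim == 2 else list(
            zip(arr[:-1], arr[1:])
        )
    rows, dropped = [], 0
    for lo, hi in windows:
        inside = s[(d >= lo) & (d < hi)]
        if len(inside) == 0:
            continue
        if len(inside) < min_count:
            dropped += 1
            continue
        p10 = float(np.percentile(inside, 10))
        p100 = float(np.percentile(inside, 100))
        rows.append(
            dict(
                center=0.5 * (lo + hi),
                width=hi - lo,
                count=len(inside),
                p10=p10,
                p100=p100,
                gamma=float(np.log10(p100 / p10)),
            )
        )
    if not rows:
        raise ValueError("no bins retained: empty many-bodyness profile")
    prof = pd.DataFrame(rows, columns=["center", "width", "count", "p10", "p100", "gamma"])
    return ManyBodyProfile(
        table=prof,
        gamma_bar=float(prof["gamma"].mean()),
        dropped_bins=dropped,
        n_nonpositive=n_nonpos,
    )


@dataclass
class DecayFitReport:
    """Exponential vs power-law fit of binned median strength against distance."""

    exp_rate: float  # s ≈ A exp(-rate · r)
    exp_prefactor: float
    exp_residual: float  # SSE in log space
    pow_exponent: float  # s ≈ A r^exponent
    pow_prefactor: float
    pow_residual: float
    preferred: str  # "exponential" | "power"
    degenerate: bool
    medians: pd.DataFrame = field(repr=False)  # columns: center, count, median
    excluded_bins: int = 0


def decay_fit(
    tables=None,
    bin_width: float = 0.5,
    min_count: int = 1,
    distances: np.ndarray | None = None,
    strengths: np.ndarray | None = None,
) -> DecayFitReport:
    """Fit the distance decay of interaction strength.

    Pairs are binned by distance; per-bin medians with non-positive values
    excluded (and counted) are fitted by least squares as log s vs r
    (exponential) and log s vs log r (power law).  The model with the smaller
    log-space squared residual is preferred.  Requires at least five occupied
    bins; a near-constant profile sets the ``degenerate`` flag.
    """
    if tables is not None:
        table = _as_table(tables)
        d = table["distance"].to_numpy(float)
        s = table["strength"].to_numpy(float)
    else:
        d = np.asarray(distances, float)
        s = np.asarray(strengths, float)
    edges = _bin_edges_from(d, bin_width)
    centers, meds, counts = [], [], []
    excluded = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        inside = s[(d >= lo) & (d < hi)]
        if len(inside) < min_count or len(inside) == 0:
            continue
        med = float(np.median(inside))
        if med <= 0:
            excluded += 1
            continue
        centers.append(0.5 * (lo + hi))
        meds.append(med)
        counts.append(len(inside))
    if len(centers) < 5:
        raise ValueError(
            f"decay fit needs >= 5 occupied distance bins, got {len(centers)}"
        )
    r = np.array(centers)
    logs = np.log(np.array(meds))
    # exponential: log s = log A - rate * r
    slope_e, icpt_e = np.polyfit(r, logs, 1)
    res_e = float(np.sum((logs - (slope_e * r + icpt_e)) ** 2))
    # power law: log s = log A + exponent * log r
    slope_p, icpt_p = np.polyfit(np.log(r), logs, 1)
    res_p = float(np.sum((logs - (slope_p * np.log(r) + icpt_p)) ** 2))
    degenerate = float(np.std(logs)) < 1e-9
    return DecayFitReport(
        exp_rate=float(-slope_e),
        exp_prefactor=float(np.exp(icpt_e)),
        exp_residual=res_e,
        pow_exponent=float(slope_p),
        pow_prefactor=float(np.exp(icpt_p)),
        pow_residual=res_p,
        preferred="exponential" if res_e <= res_p else "power",
        degenerate=degenerate,
        medians=pd.DataFrame(
            dict(center=r, count=counts, median=np.array(meds))
        ),
        excluded_bins=excluded,
    )
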