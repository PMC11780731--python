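"""Synthetic molecular systems with analytic energy labels.

Every downstream stage of the package (model training, relevance extraction,
interaction metrics) is validated against conformers generated here, labelled
with closed-form potentials whose interaction structure is known exactly:

* a strictly pairwise-additive Morse potential — by construction the
  interaction strength between two atoms depends only on their element pair
  and distance, so the many-bodyness of its strengths is exactly zero;
* an optional three-body term (angle-dependent, exponentially damped) that
  injects a controlled amount of many-bodyness.

Units are Å and kcal/mol throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .conformer import Conformer

__all__ = [
    "PairPotentialParams",
    "ThreeBodyParams",
    "GeneratorSpec",
    "PackingError",
    "generate_conformers",
    "pairwise_energy",
    "three_body_energy",
    "analytic_pair_strengths",
    "label_conformers",
]


class PackingError(RuntimeError):
    """Rejection sampling could not satisfy the minimum-distance constraint."""


@dataclass
class PairPotentialParams:
    """Morse pair potential ``u(r) = D (1 - exp(-a (r - r_e)))^2 - D``.

    ``well_depth`` D (kcal/mol), ``equilibrium_distance`` r_e (Å) and ``width``
    a (1/Å) apply to every element pair unless overridden via ``overrides``,
    keyed by an (unordered) element-symbol pair.
    """

    well_depth: float = 3.0
    equilibrium_distance: float = 1.5
    width: float = 1.2
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.well_depth <= 0 or self.equilibrium_distance <= 0 or self.width <= 0:
            raise ValueError("well_depth, equilibrium_distance and width must be > 0")

    def for_pair(self, elem_a: str, elem_b: str) -> tuple[float, float, float]:
        key = tuple(sorted((elem_a, elem_b)))
        d, re_, a = self.overrides.get(
            key, (self.well_depth, self.equilibrium_distance, self.width)
        )
        return float(d), float(re_), float(a)

    def energy(self, elem_a: str, elem_b: str, r: float) -> float:
        if not np.isfinite(r):
            raise ValueError("non-finite interatomic distance")
        d, re_, a = self.for_pair(elem_a, elem_b)
        return d * (1.0 - np.exp(-a * (r - re_))) ** 2 - d


@dataclass
class ThreeBodyParams:
    """Angle-dependent three-body term.

    For each unordered triple the term sums ``sin^2`` of the vertex angle at
    every atom, each damped by ``exp(-(r1 + r2) / range_scale)`` over the two
    legs meeting at that vertex, scaled by ``amplitude`` (kcal/mol).  The term
    is identically zero on exactly collinear triples (every vertex angle is 0
    or π) and ``amplitude = 0`` disables it.
    """

    amplitude: float = 0.0
    form: str = "sin2"
    range_scale: float = 3.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.form != "sin2":
            raise ValueError(f"unknown three-body form {self.form!r}")
        if self.range_scale <= 0:
            raise ValueError("range_scale must be > 0")

    def energy(self, pi: np.ndarray, pj: np.ndarray, pk: np.ndarray) -> float:
        if self.amplitude == 0.0:
            return 0.0
        total = 0.0
        pts = (np.asarray(pi, float), np.asarray(pj, float), np.asarray(pk, float))
        for c in range(3):
            center = pts[c]
            a, b = pts[(c + 1) % 3], pts[(c + 2) % 3]
            v1, v2 = a - center, b - center
            r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if r1 <= 0.0 or r2 <= 0.0:
                raise ValueError("degenerate triple: coincident atoms")
            cos = np.clip(v1 @ v2 / (r1 * r2), -1.0, 1.0)
            total += (1.0 - cos**2) * np.exp(-(r1 + r2) / self.range_scale)
        return self.amplitude * total


@dataclass
class GeneratorSpec:
    """Declarative description of a conformer ensemble.

    topology: ``chain`` (regular chain along z, optional jitter), ``random_cluster``
    (rejection-sampled points in a cubic box) or ``dimer_scan`` (two atoms at a
    grid of separations).
    """

    topology: str = "random_cluster"
    n_atoms: int = 6
    elements: tuple[str, ...] = ("C",)
    min_distance: float = 1.0
    spacing: float = 1.5
    jitter: float = 0.0
    box_length: float | None = None
    scan_range: tuple[float, float] = (1.0, 6.0)
    n_samples: int = 1
    seed: int = 0
    max_retries: int = 10_000

    def __post_init__(self) -> None:
        if self.topology not in ("chain", "random_cluster", "dimer_scan"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["elements"] = list(self.elements)
        d["scan_range"] = list(self.scan_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        if "elements" in d:
            d["elements"] = tuple(d["elements"])
        if "scan_range" in d:
            d["scan_range"] = tuple(d["scan_range"])
        return cls(**d)

    def default_box_length(self) -> float:
        # box sized so the target number density matches loosely packed
        # spheres of diameter min_distance (~0.15 packing fraction)
        vol_per_atom = (4.0 / 3.0) * np.pi * (self.min_distance / 2.0) ** 3 / 0.15
        return max((self.n_atoms * vol_per_atom) ** (1.0 / 3.0), self.min_distance)


def _pick_elements(spec: GeneratorSpec, rng: np.random.Generator, n: int) -> list[str]:
    if len(spec.elements) == 1:
        return [spec.elements[0]] * n
    return [spec.elements[i] for i in rng.integers(0, len(spec.elements), size=n)]


def _sample_cluster(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    box = spec.box_length if spec.box_length is not None else spec.default_box_length()
    pts: list[np.ndarray] = []
    retries = 0
    while len(pts) < spec.n_atoms:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= spec.min_distance for p in pts):
            pts.append(cand)
        else:
            retries += 1
            if retries > spec.max_retries:
                raise PackingError(
                    f"could not place {spec.n_atoms} atoms with min distance "
                    f"{spec.min_distance} Å in a box of {box:.2f} Å after "
                    f"{spec.max_retries} retries"
                )
    return np.array(pts)


def generate_conformers(spec: GeneratorSpec) -> list[Conformer]:
    """Generate ``spec.n_samples`` conformers; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    out: list[Conformer] = []
    for idx in range(spec.n_samples):
        if spec.topology == "chain":
            z = np.arange(spec.n_atoms) * spec.spacing
            pos = np.column_stack([np.zeros_like(z), np.zeros_like(z), z]).astype(float)
            if spec.jitter > 0:
                pos = pos + rng.normal(0.0, spec.jitter, size=pos.shape)
            elements = _pick_elements(spec, rng, spec.n_atoms)
        elif spec.topology == "random_cluster":
            pos = _sample_cluster(spec, rng)
            elements = _pick_elements(spec, rng, spec.n_atoms)
        else:  # dimer_scan
            lo, hi = spec.scan_range
            r = lo if spec.n_samples == 1 else lo + (hi - lo) * idx / (spec.n_samples - 1)
            pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
            elements = _pick_elements(spec, rng, 2)
        out.append(Conformer(elements=elements, positions=pos, info={"sample": idx}))
    return out


def pairwise_energy(
    conformer: Conformer, params: PairPotentialParams
) -> tuple[float, pd.DataFrame]:
    """Total 2-body energy and the per-pair term table.

    The total is exactly the sum of the tabulated terms; each term depends only
    on the element pair and the distance.
    """
    rows = []
    n = conformer.n_atoms
    dmat = conformer.distance_matrix()
    for i, j in itertools.combinations(range(n), 2):
        e = params.energy(conformer.elements[i], conformer.elements[j], dmat[i, j])
        rows.append(
            dict(
                i=i,
                j=j,
                elem_i=conformer.elements[i],
                elem_j=conformer.elements[j],
                distance=dmat[i, j],
                energy=e,
            )
        )
    table = pd.DataFrame(
        rows, columns=["i", "j", "elem_i", "elem_j", "distance", "energy"]
    )
    return float(table["energy"].sum()) if rows else 0.0, table


def three_body_energy(
    conformer: Conformer, params: ThreeBodyParams
) -> tuple[float, pd.DataFrame]:
    """Total 3-body energy and the per-triple term table."""
    rows = []
    pos = conformer.positions
    for i, j, k in itertools.combinations(range(conformer.n_atoms), 3):
        rows.append(dict(i=i, j=j, k=k, energy=params.energy(pos[i], pos[j], pos[k])))
    table = pd.DataFrame(rows, columns=["i", "j", "k", "energy"])
    return float(table["energy"].sum()) if rows else 0.0, table


def analytic_pair_strengths(
    conformer: Conformer,
    params: PairPotentialParams,
    three_body: ThreeBodyParams | None = None,
) -> pd.DataFrame:
    """Ground-truth per-pair interaction strengths of the analytic potential.

    For the strict 2-body potential the strength of pair (i, j) is the absolute
    Morse term |u(r_ij)|: a function of the element pair and distance only, so
    same-element pairs at equal distances have exactly equal strengths and the
    many-bodyness of the resulting strength sets is zero.  When ``three_body``
    is given, each triple's absolute term is shared equally (1/3) among its
    three pairs, which makes the strength depend on the neighbourhood.
    """
    _, table = pairwise_energy(conformer, params)
    table = table.rename(columns={"energy": "strength"})
    table["strength"] = table["strength"].abs()
    if three_body is not None and three_body.amplitude > 0 and conformer.n_atoms >= 3:
        _, triples = three_body_energy(conformer, three_body)
        extra = {}
        for row in triples.itertuples(index=False):
            share = abs(row.energy) / 3.0
            for a, b in ((row.i, row.j), (row.i, row.k), (row.j, row.k)):
                extra[(a, b)] = extra.get((a, b), 0.0) + share
        table["strength"] = table["strength"] + [
            extra.get((i, j), 0.0) for i, j in zip(table["i"], table["j"])
        ]
    return table


def embedded_pair_conformers(
    n_samples: int = 50,
    pair_distances: tuple[float, ...] = (2.0, 3.0),
    n_background: int = 4,
    element: str = "C",
    min_distance: float = 1.0,
    box_length: float | None = None,
    seed: int = 0,
    max_retries: int = 10_000,
) -> list[Conformer]:
    """Conformers with atom pairs at *exactly* repeated separations.

    Each conformer contains, per requested distance d, one same-element pair
    placed at exactly d Å (random position and orientation), plus
    ``n_background`` randomly packed atoms.  Because the marked pairs repeat
    the same separation in different neighbourhoods across the ensemble, they
    probe many-bodyness directly: a strict 2-body potential assigns them all
    identical strengths (γ = 0 in a narrow bin at d), while any neighbourhood-
    dependent term spreads the strengths (γ > 0).

    ``info['marked_pairs']`` records the constructed pair indices per frame
    as a compact string (``"0-1;2-3"``), safe for the extxyz comment line.
    """
    rng = np.random.default_rng(seed)
    box = box_length if box_length is not None else max(pair_distances) + 3.0
    out = []
    for idx in range(n_samples):
        pts: list[np.ndarray] = []
        marked = []
        retries = 0

        def try_place(new_pts) -> bool:
            nonlocal retries
            for q in new_pts:
                for p in pts:
                    if np.linalg.norm(q - p) < min_distance:
                        retries += 1
                        if retries > max_retries:
                            raise PackingError(
                                f"could not embed pairs with min distance "
                                f"{min_distance} Å after {max_retries} retries"
                            )
                        return False
            pts.extend(new_pts)
            return True

        for d in pair_distances:
            while True:
                center = rng.uniform(0.0, box, size=3)
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                p1, p2 = center - 0.5 * d * u, center + 0.5 * d * u
                if try_place([p1, p2]):
                    marked.append((len(pts) - 2, len(pts) - 1))
                    break
        placed = 0
        while placed < n_background:
            if try_place([rng.uniform(0.0, box, size=3)]):
                placed += 1
        out.append(
            Conformer(
                elements=[element] * len(pts),
                positions=np.array(pts),
                info={
                    "sample": idx,
                    "marked_pairs": ";".join(f"{a}-{b}" for a, b in marked),
                },
            )
        )
    return out


def label_conformers(
    conformers: list[Conformer],
    params: PairPotentialParams,
    three_body: ThreeBodyParams | None = None,
) -> list[Conformer]:
    """Attach analytic energies (2-body plus optional 3-body) in place."""
    for conf in conformers:
        e2, _ = pairwise_energy(conf, params)
        e3 = 0.0
        if three_body is not None and three_body.amplitude > 0:
            e3, _ = three_body_energy(conf, three_body)
        conf.energy = e2 + e3
    return conformers
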