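"""Molecular conformers and extended-XYZ file I/O.

A :class:`Conformer` is one molecular geometry: element symbols plus Cartesian
coordinates in Ångström, optionally labelled with a scalar energy (kcal/mol).
The extended-XYZ dialect used here is deliberately small: the per-frame comment
line carries ``key=value`` tokens (``energy=<float>`` being the one the rest of
the package reads back).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["Conformer", "read_extxyz", "write_extxyz"]


@dataclass
class Conformer:
    """One molecular geometry.

    Parameters
    ----------
    elements : list of str
        Element symbol per atom.
    positions : (N, 3) array
        Cartesian coordinates in Å.
    energy : float, optional
        Scalar energy label in kcal/mol.
    info : dict
        Free-form per-frame metadata (round-tripped through the comment line).
    """

    elements: list[str]
    positions: np.ndarray
    energy: float | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (N, 3), got {self.positions.shape}")
        if len(self.elements) != self.positions.shape[0]:
            raise ValueError("elements and positions disagree on atom count")
        if self.n_atoms < 1:
            raise ValueError("a conformer needs at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.n_atoms > 1 and self.distance_matrix()[
            ~np.eye(self.n_atoms, dtype=bool)
        ].min() <= 0.0:
            raise ValueError("coincident atoms: zero interatomic distance")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def distances(self) -> np.ndarray:
        """Condensed pairwise distance vector (Å), scipy ``pdist`` order."""
        return pdist(self.positions)

    def distance_matrix(self) -> np.ndarray:
        if self.n_atoms == 1:
            return np.zeros((1, 1))
        return squareform(self.distances())

    def permuted(self, perm: np.ndarray) -> "Conformer":
        """Return a copy with atoms relabelled by ``perm`` (new[i] = old[perm[i]])."""
        perm = np.asarray(perm)
        return Conformer(
            elements=[self.elements[p] for p in perm],
            positions=self.positions[perm].copy(),
            energy=self.energy,
            info=dict(self.info),
        )


def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def write_extxyz(path: str | Path, conformers: "Conformer | list[Conformer]") -> None:
    """Write conformers to an extended-XYZ file (energy on the comment line)."""
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    lines: list[str] = []
    for conf in conformers:
        lines.append(str(conf.n_atoms))
        tokens = []
        if conf.energy is not None:
            tokens.append(f"energy={_format_value(float(conf.energy))}")
        tokens.extend(f"{k}={_format_value(v)}" for k, v in conf.info.items())
        lines.append(" ".join(tokens))
        for sym, (x, y, z) in zip(conf.elements, conf.positions):
            lines.append(f"{sym} {float(x)!r} {float(y)!r} {float(z)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_extxyz(path: str | Path) -> list[Conformer]:
    """Read all frames from an extended-XYZ file."""
    raw = Path(path).read_text().splitlines()
    out: list[Conformer] = []
    i = 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        n = int(raw[i].strip())
        comment = raw[i + 1] if i + 1 < len(raw) else ""
        info = {}
        for tok in comment.split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                info[k] = _parse_value(v)
        energy = info.pop("energy", None)
        elements, coords = [], []
        for line in raw[i + 2 : i + 2 + n]:
            parts = line.split()
            elements.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        out.append(
            Conformer(
                elements=elements,
                positions=np.array(coords),
                energy=None if energy is None else float(energy),
                info=info,
            )
        )
        i += 2 + n
    return out
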