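"""Canonical 25-atom Fe-porphine skeleton and bond-graph utilities.

The porphyrin core used for distortion analysis consists of the iron, the four
pyrrole nitrogens and twenty ring carbons.  This module defines the fixed atom
nomenclature, builds an idealized planar reference structure with exact D4h
symmetry from a handful of bond parameters, and derives bonded pairs, bond
lengths and bond angles with the field's 2.2 A distance rule.

Coordinate frame convention: Fe at the origin, pyrrole nitrogens on the +/-x
and +/-y axes, z the out-of-plane normal.  Atom order is fixed (FE; NA..ND;
ring carbons in A,B,C,D order; meso carbons last) so that flattened
75-component vectors are comparable across modules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    ConstructiveGeometryError,
    GeometryError,
    IncompleteSkeletonError,
)

# --------------------------------------------------------------------------
# Nomenclature
# --------------------------------------------------------------------------

#: Canonical order of the 25 skeleton atoms (1 Fe + 4 N + 20 C).
SKELETON_LABELS: tuple[str, ...] = (
    "FE",
    "NA", "NB", "NC", "ND",
    "C1A", "C2A", "C3A", "C4A",
    "C1B", "C2B", "C3B", "C4B",
    "C1C", "C2C", "C3C", "C4C",
    "C1D", "C2D", "C3D", "C4D",
    "CHA", "CHB", "CHC", "CHD",
)

#: Sidechain labels consumed by descriptor code (propionates at C2A / C3D).
SIDECHAIN_LABELS: tuple[str, ...] = ("CAA", "CBA", "CGA", "CAD", "CBD", "CGD")

LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(SKELETON_LABELS)}

RING_IDS = ("A", "B", "C", "D")


def element_of(label: str) -> str:
    """Element symbol for a skeleton or sidechain atom label."""
    if label == "FE":
        return "Fe"
    if label.startswith("N") and len(label) == 2:
        return "N"
    return "C"


#: Atomic masses in unified amu (heavy atoms only; the model has no hydrogens).
ATOMIC_MASSES: dict[str, float] = {"Fe": 55.845, "C": 12.011, "N": 14.007}


def mass_vector(elements: tuple[str, ...] | list[str]) -> np.ndarray:
    """Per-coordinate mass vector (each atom mass repeated for x, y, z)."""
    m = np.array([ATOMIC_MASSES[e] for e in elements], dtype=float)
    if np.any(m <= 0):
        raise ValueError("atomic masses must be strictly positive")
    return np.repeat(m, 3)


# --------------------------------------------------------------------------
# Reference structure
# --------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ReferenceStructure:
    """An ordered 25-atom skeleton with coordinates in Angstrom."""

    labels: tuple[str, ...]
    coords: np.ndarray  # (25, 3)
    elements: tuple[str, ...]
    provenance: str = "built-in"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if tuple(self.labels) != SKELETON_LABELS:
            raise IncompleteSkeletonError(
                "reference structure must contain the 25 skeleton labels "
                "in canonical order"
            )
        if self.coords.shape != (25, 3):
            raise IncompleteSkeletonError("coordinates must be (25, 3)")

    @property
    def flat(self) -> np.ndarray:
        """Coordinates flattened to a 75-component vector."""
        return self.coords.reshape(-1)

    def index(self, label: str) -> int:
        return LABEL_INDEX[label]

    def xyz(self, label: str) -> np.ndarray:
        return self.coords[LABEL_INDEX[label]]

    # -- xyz-format round trip ------------------------------------------------

    def to_xyz(self, path: str | Path) -> None:
        """Write as an xyz file; the comment line records the label order."""
        lines = [f"{len(self.labels)}", "labels: " + " ".join(self.labels)]
        for lab, el, (x, y, z) in zip(self.labels, self.elements, self.coords):
            lines.append(f"{el:<2s} {x: .12f} {y: .12f} {z: .12f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_xyz(cls, path: str | Path) -> "ReferenceStructure":
        text = Path(path).read_text().strip().splitlines()
        n = int(text[0])
        comment = text[1]
        labels = tuple(comment.split("labels:")[1].split())
        rows = [line.split() for line in text[2 : 2 + n]]
        coords = np.array([[float(v) for v in r[1:4]] for r in rows])
        elements = tuple(r[0] for r in rows)
        if labels != SKELETON_LABELS:
            order = [labels.index(lab) for lab in SKELETON_LABELS]
            coords = coords[order]
            elements = tuple(elements[i] for i in order)
            labels = SKELETON_LABELS
        return cls(labels=labels, coords=coords, elements=elements,
                   provenance="loaded")


#: Default bond parameters (Angstrom / degrees): canonical porphine values.
#: The pyrrole angle is the Calpha-N-Calpha interior angle; 108 deg keeps the
#: cross-pyrrole Calpha..Calpha separation (2.23 A) above the 2.2 A bonded
#: cutoff so the 32-pair bond graph is stable.
DEFAULT_BOND_PARAMS: dict[str, float] = {
    "fe_n": 2.00,       # Fe - pyrrole N
    "n_ca": 1.38,       # N - Calpha
    "ca_cb": 1.44,      # Calpha - Cbeta
    "cb_cb": 1.35,      # Cbeta - Cbeta
    "ca_cm": 1.39,      # Calpha - Cmeso
    "pyrrole_angle_deg": 108.0,
}


def build_reference_porphine(
    bond_params: dict[str, float] | None = None,
) -> ReferenceStructure:
    """Construct the idealized planar D4h Fe-porphine.

    The structure is assembled in closed form: pyrrole A is placed on the +x
    axis with its nitrogen at the Fe-N distance and the two alpha/beta carbon
    pairs mirror-symmetric about the axis; rings B, C, D follow by exact 90
    degree rotations; each meso carbon sits on a diagonal at the radius that
    realizes the Calpha-Cmeso bond length.  All coordinates have z = 0.

    Raises
    ------
    ConstructiveGeometryError
        If the parameters cannot close the macrocycle (no meso-carbon radius
        satisfies the Calpha-Cmeso distance within 1e-3 A).
    """
    p = dict(DEFAULT_BOND_PARAMS)
    if bond_params:
        p.update(bond_params)
    for key, val in p.items():
        if val <= 0:
            raise ConstructiveGeometryError(f"bond parameter {key} must be > 0")

    d = p["fe_n"]
    half = math.radians(p["pyrrole_angle_deg"] / 2.0)
    # alpha carbons of ring A, symmetric about +x
    xa = d + p["n_ca"] * math.cos(half)
    ya = p["n_ca"] * math.sin(half)
    # beta carbons: Cbeta-Cbeta bond fixes the y offset
    yb = p["cb_cb"] / 2.0
    disc = p["ca_cb"] ** 2 - (yb - ya) ** 2
    if disc <= 0:
        raise ConstructiveGeometryError(
            "Calpha-Cbeta bond too short to bridge the beta-carbon pair"
        )
    xb = xa + math.sqrt(disc)

    # meso carbon CHA on the -45 degree diagonal, bonded to C1A at (xa, -ya)
    u = np.array([math.cos(-math.pi / 4), math.sin(-math.pi / 4)])
    c1a = np.array([xa, -ya])
    along = float(c1a @ u)
    perp2 = float(c1a @ c1a) - along**2
    disc_m = p["ca_cm"] ** 2 - perp2
    if disc_m <= 0:
        raise ConstructiveGeometryError(
            "Calpha-Cmeso bond cannot reach the diagonal: macrocycle does "
            "not close"
        )
    r_meso = along + math.sqrt(disc_m)

    def rot(v: np.ndarray, quarter_turns: int) -> np.ndarray:
        ang = quarter_turns * math.pi / 2
        c, s = math.cos(ang), math.sin(ang)
        return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])

    coords2d: dict[str, np.ndarray] = {"FE": np.zeros(2)}
    ring_a = {
        "N": np.array([d, 0.0]),
        "C1": np.array([xa, -ya]),
        "C2": np.array([xb, -yb]),
        "C3": np.array([xb, yb]),
        "C4": np.array([xa, ya]),
    }
    for k, ring in enumerate(RING_IDS):
        for key, v in ring_a.items():
            lab = f"{key}{ring}" if key != "N" else f"N{ring}"
            coords2d[lab] = rot(v, k)
    # CHA on -45 diagonal (between rings D and A); CHB..CHD by rotation
    cha = r_meso * u
    for k, ring in enumerate(RING_IDS):
        coords2d[f"CH{ring}"] = rot(cha, k)

    coords = np.zeros((25, 3))
    for i, lab in enumerate(SKELETON_LABELS):
        coords[i, :2] = coords2d[lab]
    elements = tuple(element_of(lab) for lab in SKELETON_LABELS)

    ref = ReferenceStructure(
        labels=SKELETON_LABELS, coords=coords, elements=elements,
        provenance="built-in", params=p,
    )
    # closure sanity: both meso bonds realize the requested length
    closure = abs(
        np.linalg.norm(ref.xyz("CHA") - ref.xyz("C4D")) - p["ca_cm"]
    )
    if closure > 1e-3:
        raise ConstructiveGeometryError(
            f"macrocycle closure residual {closure:.2e} A exceeds 1e-3 A"
        )
    return ref


# --------------------------------------------------------------------------
# Bond graph
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BondGraph:
    """Unordered bonded pairs of skeleton labels with the generating cutoff."""

    pairs: frozenset[frozenset[str]]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self.pairs)

    def neighbors(self, label: str) -> list[str]:
        out = []
        for p in self.pairs:
            if label in p:
                (other,) = p - {label}
                out.append(other)
        return sorted(out)


def _skeleton_coords(s) -> np.ndarray:
    """Accept a ReferenceStructure, HemeEntry-like object or (25,3) array."""
    if hasattr(s, "coords") and getattr(s, "coords").shape == (25, 3):
        return np.asarray(s.coords, dtype=float)
    arr = np.asarray(s, dtype=float)
    if arr.shape != (25, 3):
        raise IncompleteSkeletonError(
            f"expected 25 skeleton atoms, got shape {arr.shape}"
        )
    return arr


def pairs_within(coords: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Index pairs of an arbitrary (n, 3) point set within ``cutoff``."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    n = len(coords)
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if dist[i, j] <= cutoff]


def bonded_pairs(s, cutoff: float = 2.2) -> BondGraph:
    """All unordered skeleton-atom pairs within ``cutoff`` Angstrom.

    Pairs of atoms within 2.2 A of each other are treated as bonded; on the
    idealized reference this yields the 32 covalent bonds of the Fe-porphine
    core (4 Fe-N, 8 N-Calpha, 8 Calpha-Cbeta, 4 Cbeta-Cbeta, 8 Calpha-Cmeso).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = _skeleton_coords(s)
    if not np.all(np.isfinite(coords)):
        raise IncompleteSkeletonError("non-finite skeleton coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    pairs = set()
    for i, j in itertools.combinations(range(25), 2):
        if dist[i, j] <= cutoff:
            pairs.add(frozenset((SKELETON_LABELS[i], SKELETON_LABELS[j])))
    return BondGraph(pairs=frozenset(pairs), cutoff=cutoff)


def bond_lengths_and_angles(
    s, g: BondGraph
) -> tuple[list[tuple[tuple[str, str], float]],
           list[tuple[tuple[str, str, str], float]]]:
    """Bond lengths and bond angles implied by a bond graph.

    Returns one length per bonded pair and one angle (degrees, in [0, 180])
    per unordered pair of bonds sharing a common atom, e.g. the C1A-CHA and
    CHA-C4D bonds define the angle at CHA.
    """
    coords = _skeleton_coords(s)

    def xyz(lab: str) -> np.ndarray:
        return coords[LABEL_INDEX[lab]]

    lengths = []
    for a, b in g.sorted_pairs():
        r = float(np.linalg.norm(xyz(a) - xyz(b)))
        if r < 1e-9:
            raise GeometryError(f"coincident atoms {a}/{b}")
        lengths.append(((a, b), r))

    angles = []
    for center in SKELETON_LABELS:
        nbrs = g.neighbors(center)
        for a, b in itertools.combinations(nbrs, 2):
            v1 = xyz(a) - xyz(center)
            v2 = xyz(b) - xyz(center)
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-9 or n2 < 1e-9:
                raise GeometryError(f"degenerate angle at {center}")
            cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
            angles.append(((a, center, b), float(np.degrees(np.arccos(cosang)))))
    return lengths, angles
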