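"""Model harmonic valence force field on the Fe-porphine skeleton.

Normal-coordinate structural decomposition needs only the *shapes* of the
low-frequency normal modes of the planar D4h core, never their frequencies:
the projection amplitudes downstream are plain inner products with unit
vectors.  A simple valence force field — harmonic bond stretches, angle
bends at every pair of bonds sharing an atom, and harmonic torsions around
every bonded path — is therefore sufficient, provided it is exactly
minimized at the reference structure (every internal coordinate's rest
value is taken from the reference itself) and invariant under rigid motion
(it depends only on internal coordinates).

Force constants are in consistent internal units; their absolute scale is
irrelevant to the mode shapes and only fixes the eigenvalue scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ForceFieldError
from .reference_geometry import (
    LABEL_INDEX,
    SKELETON_LABELS,
    BondGraph,
    ReferenceStructure,
    bonded_pairs,
)

#: Default force constants (internal units): uniform stretch, bend and
#: torsional (out-of-plane) stiffness.
DEFAULT_FORCE_CONSTANTS = {"k_r": 1.0, "k_theta": 0.3, "k_phi": 0.1}


def _angle_triples(graph: BondGraph) -> list[tuple[int, int, int]]:
    triples = []
    for center in SKELETON_LABELS:
        nbrs = graph.neighbors(center)
        c = LABEL_INDEX[center]
        for a, b in itertools.combinations(nbrs, 2):
            triples.append((LABEL_INDEX[a], c, LABEL_INDEX[b]))
    return triples


def _torsion_quads(graph: BondGraph) -> list[tuple[int, int, int, int]]:
    adj: dict[str, list[str]] = {lab: graph.neighbors(lab) for lab in SKELETON_LABELS}
    quads = []
    for pair in graph.sorted_pairs():
        j, k = pair
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                quads.append(
                    (LABEL_INDEX[i], LABEL_INDEX[j], LABEL_INDEX[k], LABEL_INDEX[l])
                )
    return quads


def _dihedrals(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral angles (radians) for a batch of coordinate frames.

    ``coords``: (..., 25, 3); ``quads``: (m, 4) atom indices.
    """
    p0 = coords[..., quads[:, 0], :]
    p1 = coords[..., quads[:, 1], :]
    p2 = coords[..., quads[:, 2], :]
    p3 = coords[..., quads[:, 3], :]
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return np.arctan2(y, x)


@dataclass
class HarmonicValenceForceField:
    """Quadratic valence potential minimized at a reference structure."""

    reference: ReferenceStructure
    k_r: float = DEFAULT_FORCE_CONSTANTS["k_r"]
    k_theta: float = DEFAULT_FORCE_CONSTANTS["k_theta"]
    k_phi: float = DEFAULT_FORCE_CONSTANTS["k_phi"]
    cutoff: float = 2.2
    _terms: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        graph = bonded_pairs(self.reference, self.cutoff)
        bonds = np.array(
            [(LABEL_INDEX[a], LABEL_INDEX[b]) for a, b in graph.sorted_pairs()],
            dtype=int,
        )
        angles = np.array(_angle_triples(graph), dtype=int)
        torsions = np.array(_torsion_quads(graph), dtype=int)
        ref = self.reference.coords
        # drop torsions whose inner triples are (near-)collinear at the
        # reference (e.g. NC-FE-NA): their dihedral is singular there
        keep = np.ones(len(torsions), dtype=bool)
        for cols in ((0, 1, 2), (1, 2, 3)):
            tri = torsions[:, cols]
            ang = self._angles(ref[None], tri)[0]
            keep &= np.sin(ang) > 0.1
        torsions = torsions[keep]
        r0 = np.linalg.norm(ref[bonds[:, 0]] - ref[bonds[:, 1]], axis=-1)
        theta0 = self._angles(ref[None], angles)[0]
        phi_ref = _dihedrals(ref[None], torsions)[0]
        # planar reference: torsion rest values are exactly 0 or pi
        phi0 = np.where(np.abs(np.abs(phi_ref) - np.pi) < 1e-6,
                        np.pi, 0.0)
        if np.max(np.minimum(np.abs(phi_ref), np.abs(np.abs(phi_ref) - np.pi))) > 1e-6:
            raise ForceFieldError("reference torsions are not planar")
        self._terms = {
            "bonds": bonds, "r0": r0,
            "angles": angles, "theta0": theta0,
            "torsions": torsions, "phi0": phi0,
        }

    @staticmethod
    def _angles(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
        v1 = coords[..., triples[:, 0], :] - coords[..., triples[:, 1], :]
        v2 = coords[..., triples[:, 2], :] - coords[..., triples[:, 1], :]
        dot = np.einsum("...i,...i->...", v1, v2)
        n1 = np.linalg.norm(v1, axis=-1)
        n2 = np.linalg.norm(v2, axis=-1)
        return np.arccos(np.clip(dot / (n1 * n2), -1.0, 1.0))

    def energy(self, coords: np.ndarray) -> np.ndarray:
        """Potential energy for (..., 25, 3) coordinates; vectorized."""
        t = self._terms
        coords = np.asarray(coords, dtype=float)
        r = np.linalg.norm(
            coords[..., t["bonds"][:, 0], :] - coords[..., t["bonds"][:, 1], :],
            axis=-1,
        )
        e_bond = 0.5 * self.k_r * ((r - t["r0"]) ** 2).sum(-1)
        theta = self._angles(coords, t["angles"])
        e_angle = 0.5 * self.k_theta * ((theta - t["theta0"]) ** 2).sum(-1)
        phi = _dihedrals(coords, t["torsions"])
        dphi = np.arctan2(np.sin(phi - t["phi0"]), np.cos(phi - t["phi0"]))
        e_tors = 0.5 * self.k_phi * (dphi**2).sum(-1)
        e = e_bond + e_angle + e_tors
        if not np.all(np.isfinite(e)):
            raise ForceFieldError("non-finite energy during evaluation")
        return e

    def gradient(self, coords: np.ndarray, step: float = 1e-6) -> np.ndarray:
        """Central finite-difference gradient, (25, 3)."""
        coords = np.asarray(coords, dtype=float)
        n = coords.size
        plus = np.repeat(coords.reshape(1, 25, 3), n, axis=0)
        minus = plus.copy()
        flat_idx = np.arange(n)
        plus.reshape(n, -1)[flat_idx, flat_idx] += step
        minus.reshape(n, -1)[flat_idx, flat_idx] -= step
        g = (self.energy(plus) - self.energy(minus)) / (2 * step)
        return g.reshape(25, 3)
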