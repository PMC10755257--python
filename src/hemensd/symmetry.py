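"""D4h point-group operations and irreducible-representation projectors.

The idealized Fe-porphine is exactly D4h-symmetric in the package's frame
(Fe at origin, N atoms on the x/y axes).  Each of the 16 group operations is
represented on the 75-dimensional displacement space as a label permutation
combined with a 3x3 orthogonal matrix; irrep projectors built from the
character table assign every vibrational eigenvector a symmetry species.

Irrep naming convention for the two in-plane g modes the literature leaves
unlabelled: radial nitrogen motion (x^2-y^2 pattern, N on axes) is B1g and
is called N-pyrrole stretching; radial meso-carbon motion (xy pattern, meso
on diagonals) is B2g, called meso-stretching.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .reference_geometry import SKELETON_LABELS, ReferenceStructure

# Character table of D4h.  Class order:
#   E, 2C4, C2, 2C2', 2C2'', i, 2S4, sigma_h, 2sigma_v, 2sigma_d
CHARACTER_TABLE: dict[str, tuple[float, ...]] = {
    "A1g": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1),
    "A2g": (1, 1, 1, -1, -1, 1, 1, 1, -1, -1),
    "B1g": (1, -1, 1, 1, -1, 1, -1, 1, 1, -1),
    "B2g": (1, -1, 1, -1, 1, 1, -1, 1, -1, 1),
    "Eg": (2, 0, -2, 0, 0, 2, 0, -2, 0, 0),
    "A1u": (1, 1, 1, 1, 1, -1, -1, -1, -1, -1),
    "A2u": (1, 1, 1, -1, -1, -1, -1, -1, 1, 1),
    "B1u": (1, -1, 1, 1, -1, -1, 1, -1, -1, 1),
    "B2u": (1, -1, 1, -1, 1, -1, 1, -1, 1, -1),
    "Eu": (2, 0, -2, 0, 0, -2, 0, 2, 0, 0),
}

IRREP_DIMENSION = {name: int(chars[0]) for name, chars in CHARACTER_TABLE.items()}


def _rz(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _c2_inplane(deg: float) -> np.ndarray:
    """Two-fold rotation about an in-plane axis at angle ``deg`` from x."""
    a = math.radians(2 * deg)
    return np.array(
        [[math.cos(a), math.sin(a), 0.0],
         [math.sin(a), -math.cos(a), 0.0],
         [0.0, 0.0, -1.0]]
    )


def _sigma_v(deg: float) -> np.ndarray:
    """Mirror through the vertical plane containing the in-plane axis."""
    a = math.radians(2 * deg)
    return np.array(
        [[math.cos(a), math.sin(a), 0.0],
         [math.sin(a), -math.cos(a), 0.0],
         [0.0, 0.0, 1.0]]
    )


_SIGMA_H = np.diag([1.0, 1.0, -1.0])
_INV = -np.eye(3)


def group_operations() -> list[tuple[np.ndarray, int]]:
    """(matrix, class_index) for all 16 operations, class order as above."""
    ops: list[tuple[np.ndarray, int]] = [(np.eye(3), 0)]
    ops += [(_rz(90), 1), (_rz(-90), 1)]
    ops += [(_rz(180), 2)]
    ops += [(_c2_inplane(0), 3), (_c2_inplane(90), 3)]        # C2' through N
    ops += [(_c2_inplane(45), 4), (_c2_inplane(-45), 4)]      # C2'' diagonals
    ops += [(_INV, 5)]
    ops += [(_SIGMA_H @ _rz(90), 6), (_SIGMA_H @ _rz(-90), 6)]  # S4
    ops += [(_SIGMA_H, 7)]
    ops += [(_sigma_v(0), 8), (_sigma_v(90), 8)]
    ops += [(_sigma_v(45), 9), (_sigma_v(-45), 9)]
    return ops


def _permutation_for(ref: ReferenceStructure, mat: np.ndarray) -> np.ndarray:
    """perm[i] = index of the atom onto which atom i is mapped by ``mat``."""
    moved = ref.coords @ mat.T
    perm = np.empty(25, dtype=int)
    for i in range(25):
        dist = np.linalg.norm(ref.coords - moved[i], axis=1)
        j = int(np.argmin(dist))
        if dist[j] > 1e-6:
            raise ValueError(
                "structure is not symmetric under the requested operation "
                f"(atom {SKELETON_LABELS[i]} maps {dist[j]:.2e} A from any site)"
            )
        perm[i] = j
    if len(set(perm.tolist())) != 25:
        raise ValueError("operation does not permute atoms bijectively")
    return perm


def operator_matrix(ref: ReferenceStructure, mat: np.ndarray) -> np.ndarray:
    """75x75 action of a point-group operation on displacement vectors."""
    perm = _permutation_for(ref, mat)
    op = np.zeros((75, 75))
    for i in range(25):
        j = perm[i]
        op[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = mat
    return op


@lru_cache(maxsize=8)
def displacement_operators(ref: ReferenceStructure) -> tuple[tuple[np.ndarray, int], ...]:
    """All 16 (75x75 operator, class index) pairs for the reference frame."""
    return tuple(
        (operator_matrix(ref, mat), cls) for mat, cls in group_operations()
    )


@lru_cache(maxsize=64)
def irrep_projector(ref: ReferenceStructure, irrep: str) -> np.ndarray:
    """Projector onto the ``irrep`` subspace of the displacement space."""
    chars = CHARACTER_TABLE[irrep]
    dim = IRREP_DIMENSION[irrep]
    proj = np.zeros((75, 75))
    for op, cls in displacement_operators(ref):
        proj += chars[cls] * op
    return (dim / 16.0) * proj


def irrep_scores(ref: ReferenceStructure, vec: np.ndarray) -> dict[str, float]:
    """Fraction of ``vec``'s norm lying in each irrep subspace (cosines)."""
    v = np.asarray(vec, dtype=float)
    norm = np.linalg.norm(v)
    out = {}
    for irrep in CHARACTER_TABLE:
        out[irrep] = float(np.linalg.norm(irrep_projector(ref, irrep) @ v) / norm)
    return out
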