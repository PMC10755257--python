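"""Normal-coordinate structural decomposition of heme skeletons.

Each heme's 25-atom skeleton is rigidly superposed onto the planar
reference by an unweighted least-squares (Kabsch) fit over all 25 atoms
— proper rotations only, never a reflection — and the residual
displacement D_heme = fitted - reference (a 75-component vector) is
projected onto the 12 normalized mode vectors:

    d_k = Q_k . D_heme        (amplitudes in Angstrom, signed)

The basis is not re-orthogonalized: the projection is the plain inner
product, so tiny non-orthogonality between modes appears as cross-talk
bounded by the basis Gram matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .exceptions import DimensionError, GeometryError
from .mode_basis import (
    IN_PLANE_MODES,
    MODE_NAMES,
    OUT_OF_PLANE_MODES,
    ModeBasis,
    default_mode_basis,
)
from .reference_geometry import ReferenceStructure, build_reference_porphine


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping a heme onto the reference frame."""

    rotation: np.ndarray       # (3, 3), det = +1
    translation: np.ndarray    # (3,), applied after rotation
    rmsd: float                # over the 25 skeleton atoms, Angstrom
    fitted: np.ndarray         # (25, 3) heme coordinates in reference frame

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class NSDResult:
    """Signed mode amplitudes (Angstrom) for one heme."""

    amplitudes: dict[str, float]
    rmsd: float

    @property
    def out_of_plane_total(self) -> float:
        return float(np.sqrt(sum(self.amplitudes[n] ** 2
                                 for n in OUT_OF_PLANE_MODES)))

    @property
    def in_plane_total(self) -> float:
        return float(np.sqrt(sum(self.amplitudes[n] ** 2
                                 for n in IN_PLANE_MODES)))

    def as_series(self) -> pd.Series:
        s = pd.Series({n: self.amplitudes[n] for n in MODE_NAMES})
        s["fit_rmsd"] = self.rmsd
        s["out_of_plane_total"] = self.out_of_plane_total
        s["in_plane_total"] = self.in_plane_total
        return s


def _heme_coords(heme) -> np.ndarray:
    coords = np.asarray(getattr(heme, "coords", heme), dtype=float)
    if coords.shape != (25, 3):
        raise DimensionError(f"expected (25, 3) skeleton, got {coords.shape}")
    return coords


def kabsch_fit(mobile: np.ndarray, target: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper-rotation least-squares fit of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``target``.
    Works for any (n, 3) point sets with n >= 3 and non-degenerate geometry.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DimensionError("point sets must share an (n, 3) shape")
    c_m = mobile.mean(axis=0)
    c_t = target.mean(axis=0)
    a = mobile - c_m
    if np.linalg.matrix_rank(a, tol=1e-9) < 2:
        raise GeometryError("degenerate (collinear or coincident) point set")
    rot, _ = Rotation.align_vectors(target - c_t, a)
    mat = rot.as_matrix()
    fitted = a @ mat.T + c_t
    rmsd = float(np.sqrt(((fitted - target) ** 2).sum() / len(mobile)))
    translation = c_t - c_m @ mat.T
    return mat, translation, rmsd


def superpose(heme, ref: ReferenceStructure) -> SuperpositionResult:
    """Unweighted least-squares rigid fit of a heme onto the reference.

    Minimizes the RMSD over the 25 skeleton atoms with a proper rotation
    (det +1); a mirror-image heme is fitted as well as possible without
    reflection and simply shows a larger residual.
    """
    coords = _heme_coords(heme)
    mat, translation, rmsd = kabsch_fit(coords, ref.coords)
    fitted = coords @ mat.T + translation
    return SuperpositionResult(rotation=mat, translation=translation,
                               rmsd=rmsd, fitted=fitted)


def displacement_vector(sup: SuperpositionResult,
                        ref: ReferenceStructure) -> np.ndarray:
    """D_heme: fitted minus reference coordinates, flattened to length 75."""
    return (sup.fitted - ref.coords).reshape(-1)


def project_modes(displacement: np.ndarray, basis: ModeBasis,
                  rmsd: float = 0.0) -> NSDResult:
    """Plain inner products of the displacement with the 12 mode vectors."""
    d = np.asarray(displacement, dtype=float)
    if d.shape != (75,):
        raise DimensionError(f"displacement must have 75 components, "
                             f"got {d.shape}")
    amps = basis.matrix @ d
    return NSDResult(
        amplitudes={name: float(a) for name, a in zip(MODE_NAMES, amps)},
        rmsd=rmsd,
    )


def nsd_pipeline(heme, ref: ReferenceStructure | None = None,
                 basis: ModeBasis | None = None) -> NSDResult:
    """superpose -> displacement -> project, with shipped defaults."""
    if ref is None:
        ref = build_reference_porphine()
    if basis is None:
        basis = default_mode_basis()
    sup = superpose(heme, ref)
    return project_modes(displacement_vector(sup, ref), basis, rmsd=sup.rmsd)


def nsd_table(hemes, ref: ReferenceStructure | None = None,
              basis: ModeBasis | None = None) -> pd.DataFrame:
    """Per-heme NSD amplitudes as a DataFrame (12 mode columns + RMSD)."""
    if ref is None:
        ref = build_reference_porphine()
    if basis is None:
        basis = default_mode_basis()
    rows = []
    index = []
    for heme in hemes:
        res = nsd_pipeline(heme, ref, basis)
        rows.append(res.as_series())
        ident = getattr(heme, "identity", None)
        index.append("/".join(str(x) for x in ident) if ident else len(index))
    return pd.DataFrame(rows, index=index)
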