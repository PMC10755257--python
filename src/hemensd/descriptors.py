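"""Non-NSD structural descriptors of heme entries.

* Out-of-plane iron displacement d_OOP: distance from FE to the
  least-squares plane of the four pyrrole nitrogens, computed from the
  eigenvectors of the nitrogen coordinate covariance (the plane normal is
  the third eigenvector).
* Propionate dihedrals: signed torsions C1A-C2A-CAA-CBA (dihedral1) and
  C4D-C3D-CAD-CBD (dihedral2), classified "up" for negative angles and
  "down" for positive ones (0 and 180 degrees fall on "down" with the
  half-open convention).
* Coverage c: the fraction of the porphyrin skeleton's solvent-accessible
  surface area buried by the surrounding protein,
  c = (sum_i S_heme,i - sum_i S_complex,i) / sum_i S_heme,i over the 25
  skeleton atoms, with SASA from the Shrake-Rupley algorithm (mdtraj);
  only C, N, O, S and Fe atoms enter the calculation.

SASA parameters default to the field's standard values: probe radius
1.4 A, 960 sphere points, Bondi-type van der Waals radii (mdtraj's table);
hydrogens are absent from the heavy-atom model.
"""

from __future__ import annotations

from dataclasses import dataclass

import mdtraj as md
import numpy as np
from mdtraj.core import element as md_element

from .exceptions import GeometryError, IncompleteSkeletonError
from .heme_extraction import AtomRecord, HemeEntry
from .reference_geometry import LABEL_INDEX, SKELETON_LABELS, element_of

#: Elements retained for SASA (all others are dropped as occluders too).
SASA_ELEMENTS = frozenset({"C", "N", "O", "S", "Fe"})


@dataclass
class DescriptorSet:
    d_oop: float | None = None
    d_oop_sign_resolved: bool = False
    dihedral1: float | None = None
    dihedral2: float | None = None
    orientation1: str | None = None
    orientation2: str | None = None
    coverage: float | None = None


# --------------------------------------------------------------------------
# Out-of-plane displacement
# --------------------------------------------------------------------------


def out_of_plane_displacement(
    heme, toward: np.ndarray | None = None
) -> tuple[float, bool]:
    """Signed distance of FE from the least-squares N4 plane.

    The plane is spanned by the first two eigenvectors of the covariance of
    the four nitrogen coordinates; d_OOP is the projection of FE (relative
    to the nitrogen centroid) on the normalized third eigenvector.  The
    eigenvector's sign is arbitrary, so the normal is oriented toward
    ``toward`` (typically axial ligand #1) when given; otherwise the
    magnitude is returned with the sign flagged unresolved.

    Returns ``(d_oop, sign_resolved)``.
    """
    coords = np.asarray(getattr(heme, "coords", heme), dtype=float)
    if coords.shape != (25, 3):
        raise IncompleteSkeletonError("need the 25-atom skeleton")
    fe = coords[LABEL_INDEX["FE"]]
    n4 = coords[[LABEL_INDEX[f"N{r}"] for r in "ABCD"]]
    centroid = n4.mean(axis=0)
    cov = np.cov((n4 - centroid).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending: normal is column 0
    if evals[1] < 1e-12:
        raise GeometryError("nitrogen atoms are collinear; plane undefined")
    normal = evecs[:, 0]
    normal /= np.linalg.norm(normal)
    d = float((fe - centroid) @ normal)
    if toward is not None:
        if (np.asarray(toward) - centroid) @ normal < 0:
            normal, d = -normal, -d
        return d, True
    return abs(d), False


# --------------------------------------------------------------------------
# Propionate dihedrals
# --------------------------------------------------------------------------


def torsion(p0, p1, p2, p3) -> float:
    """Standard signed dihedral in degrees, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("three collinear atoms: torsion undefined")
    b1n = b1 / np.linalg.norm(b1)
    x = float(n1 @ n2)
    y = float(np.cross(n1, b1n) @ n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def classify_orientation(dihedral: float | None) -> str | None:
    """'up' for negative dihedrals, 'down' for positive (and exactly 0)."""
    if dihedral is None:
        return None
    return "up" if dihedral < 0.0 else "down"


_PROPIONATE_QUADS = (
    ("C1A", "C2A", "CAA", "CBA"),   # dihedral1
    ("C4D", "C3D", "CAD", "CBD"),   # dihedral2
)


def propionate_dihedrals(
    heme: HemeEntry,
) -> tuple[float | None, float | None, str | None, str | None]:
    """(dihedral1, dihedral2, orientation1, orientation2); nulls if atoms absent."""

    def atom(lab: str) -> np.ndarray | None:
        if lab in LABEL_INDEX:
            return heme.coords[LABEL_INDEX[lab]]
        return heme.sidechain.get(lab)

    out: list[float | None] = []
    for quad in _PROPIONATE_QUADS:
        pts = [atom(lab) for lab in quad]
        out.append(None if any(p is None for p in pts) else torsion(*pts))
    d1, d2 = out
    return d1, d2, classify_orientation(d1), classify_orientation(d2)


# --------------------------------------------------------------------------
# Coverage (SASA)
# --------------------------------------------------------------------------


def _trajectory(coords: np.ndarray, elements: list[str]) -> md.Trajectory:
    top = md.Topology()
    chain = top.add_chain()
    res = top.add_residue("HET", chain)
    for k, el in enumerate(elements):
        top.add_atom(f"{el}{k}", md_element.get_by_symbol(el), res)
    return md.Trajectory(xyz=coords[None] / 10.0, topology=top)  # A -> nm


def _per_atom_sasa(coords: np.ndarray, elements: list[str],
                   probe_radius: float, n_sphere_points: int) -> np.ndarray:
    traj = _trajectory(np.asarray(coords, dtype=float), elements)
    return md.shrake_rupley(
        traj, probe_radius=probe_radius / 10.0,
        n_sphere_points=n_sphere_points, mode="atom",
    )[0] * 100.0  # nm^2 -> A^2


def coverage(
    heme: HemeEntry,
    complex_atoms: list[AtomRecord],
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """Buried fraction of the skeleton's solvent-accessible surface.

    ``complex_atoms`` are the non-heme atoms of the complex (the heme's own
    atoms are added automatically); atoms outside C/N/O/S/Fe are excluded
    from the calculation entirely.  With no protein at all the coverage is
    exactly 0; full occlusion approaches 1.
    """
    heme_coords = [heme.coords[i] for i in range(25)]
    heme_elements = [element_of(lab) for lab in SKELETON_LABELS]
    for lab, xyz in sorted(heme.sidechain.items()):
        el = "O" if lab.startswith("O") else element_of(lab)
        if el in SASA_ELEMENTS:
            heme_coords.append(xyz)
            heme_elements.append(el)

    s_heme = _per_atom_sasa(np.array(heme_coords), heme_elements,
                            probe_radius, n_sphere_points)
    total_heme = float(s_heme[:25].sum())
    if total_heme <= 0:
        raise GeometryError("isolated heme has zero SASA: malformed input")

    extra_coords = []
    extra_elements = []
    for a in complex_atoms:
        if a.element in SASA_ELEMENTS:
            extra_coords.append(a.coords)
            extra_elements.append(a.element)
    if not extra_coords:
        return 0.0
    all_coords = np.vstack([np.array(heme_coords), np.array(extra_coords)])
    all_elements = heme_elements + extra_elements
    s_complex = _per_atom_sasa(all_coords, all_elements,
                               probe_radius, n_sphere_points)
    c = (total_heme - float(s_complex[:25].sum())) / total_heme
    return float(np.clip(c, 0.0, 1.0))


# --------------------------------------------------------------------------
# Bundle
# --------------------------------------------------------------------------


def compute_descriptors(
    heme: HemeEntry,
    complex_atoms: list[AtomRecord] | None = None,
    ligand_direction: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> DescriptorSet:
    """All descriptors for one heme; coverage only if neighbors are given."""
    d_oop, resolved = out_of_plane_displacement(heme, toward=ligand_direction)
    d1, d2, o1, o2 = propionate_dihedrals(heme)
    cov = None
    if complex_atoms is not None:
        cov = coverage(heme, complex_atoms, probe_radius=probe_radius,
                       n_sphere_points=n_sphere_points)
    return DescriptorSet(
        d_oop=d_oop, d_oop_sign_resolved=resolved,
        dihedral1=d1, dihedral2=d2, orientation1=o1, orientation2=o2,
        coverage=cov,
    )
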