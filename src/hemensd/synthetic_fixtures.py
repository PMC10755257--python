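"""Synthetic test-input generators with known ground truth.

Everything the test suite consumes is generated here: porphyrins distorted
along named modes by known amplitudes, propionate stubs at prescribed
torsions, axial-ligand candidate atoms at prescribed iron distances,
quasi-uniform occluding shells for SASA tests, and minimal — but
standards-conformant — mmCIF files that exercise the extraction rules
(model numbers, altlocs, missing atoms).

All randomness flows through explicitly seeded generators; there is no
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .descriptors import torsion
from .heme_extraction import AtomRecord, EntryMetadata, HemeEntry
from .mode_basis import MODE_NAMES, ModeBasis, default_mode_basis
from .reference_geometry import (
    LABEL_INDEX,
    SKELETON_LABELS,
    ReferenceStructure,
    build_reference_porphine,
    element_of,
)


@dataclass(frozen=True)
class DistortionSpec:
    """Recipe for a distorted heme with known mode amplitudes."""

    amplitudes: dict[str, float] = field(default_factory=dict)
    sigma: float = 0.0                      # isotropic coordinate noise, A
    rotation: tuple[float, float, float] | None = None   # rotation vector, rad
    translation: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.amplitudes) - set(MODE_NAMES)
        if unknown:
            raise KeyError(f"unknown mode name(s): {sorted(unknown)}")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def make_distorted_heme(
    spec: DistortionSpec,
    ref: ReferenceStructure | None = None,
    basis: ModeBasis | None = None,
    pdb_id: str = "SYN1",
    asym_id: str = "H",
    chain_id: str = "X",
    residue_index: int = 201,
    comp_id: str = "HEM",
) -> HemeEntry:
    """reference + sum(amplitude * mode) + noise, then optional rigid move.

    The realized ground-truth amplitudes are stored in
    ``entry.metadata["ground_truth"]``.
    """
    if ref is None:
        ref = build_reference_porphine()
    if basis is None:
        basis = default_mode_basis()
    rng = np.random.default_rng(spec.seed)
    disp = np.zeros(75)
    for name, amp in spec.amplitudes.items():
        disp += amp * basis[name].vector
    coords = ref.coords + disp.reshape(25, 3)
    if spec.sigma > 0:
        coords = coords + rng.normal(0.0, spec.sigma, size=(25, 3))
    if spec.rotation is not None:
        coords = coords @ Rotation.from_rotvec(spec.rotation).as_matrix().T
    if spec.translation is not None:
        coords = coords + np.asarray(spec.translation)
    return HemeEntry(
        pdb_id=pdb_id, asym_id=asym_id, chain_id=chain_id,
        residue_index=residue_index, comp_id=comp_id, coords=coords,
        metadata={"ground_truth": dict(spec.amplitudes), "sigma": spec.sigma},
    )


# --------------------------------------------------------------------------
# Propionate stubs
# --------------------------------------------------------------------------


def _place_by_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                       bond: float, angle_deg: float,
                       torsion_deg: float) -> np.ndarray:
    """Place atom D given A-B-C with bond |CD|, angle BCD and torsion ABCD."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = -math.radians(torsion_deg)  # frame handedness vs IUPAC sign
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor),
         math.sin(ang) * math.sin(tor)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def add_propionate_stubs(
    heme: HemeEntry,
    dihedral1: float,
    dihedral2: float,
    bond: float = 1.52,
    angle_deg: float = 113.0,
) -> HemeEntry:
    """Attach CAA/CBA and CAD/CBD stubs realizing the requested torsions.

    CAA is placed in the porphyrin plane off C2A (so the C1A-C2A-CAA-CBA
    torsion is controlled purely by CBA), and symmetrically for ring D.
    The realized torsions match the request to ~1e-9 degrees.
    """
    coords = heme.coords

    def ring_stub(c1: str, c2: str, c3: str, dihedral: float
                  ) -> dict[str, np.ndarray]:
        p1 = coords[LABEL_INDEX[c1]]
        p2 = coords[LABEL_INDEX[c2]]
        p3 = coords[LABEL_INDEX[c3]]
        # alpha stub carbon: in the local ring plane, away from the ring
        ca = _place_by_internal(p3, p1, p2, bond, 120.0, 180.0)
        cb = _place_by_internal(p1, p2, ca, bond, angle_deg, dihedral)
        return {"CA": ca, "CB": cb}

    s1 = ring_stub("C1A", "C2A", "C3A", dihedral1)
    s2 = ring_stub("C4D", "C3D", "C2D", dihedral2)
    sidechain = dict(heme.sidechain)
    sidechain.update({"CAA": s1["CA"], "CBA": s1["CB"],
                      "CAD": s2["CA"], "CBD": s2["CB"]})
    realized1 = torsion(coords[LABEL_INDEX["C1A"]], coords[LABEL_INDEX["C2A"]],
                        sidechain["CAA"], sidechain["CBA"])
    realized2 = torsion(coords[LABEL_INDEX["C4D"]], coords[LABEL_INDEX["C3D"]],
                        sidechain["CAD"], sidechain["CBD"])
    md = dict(heme.metadata) if isinstance(heme.metadata, dict) else {}
    md["requested_dihedrals"] = (dihedral1, dihedral2)
    md["realized_dihedrals"] = (realized1, realized2)
    return HemeEntry(
        pdb_id=heme.pdb_id, asym_id=heme.asym_id, chain_id=heme.chain_id,
        residue_index=heme.residue_index, comp_id=heme.comp_id,
        coords=coords, sidechain=sidechain, metadata=md,
    )


# --------------------------------------------------------------------------
# Complex fixtures: ligands and occluding shells
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LigandSpec:
    """A candidate axial-ligand atom on the heme normal."""

    element: str = "N"
    distance: float = 2.1          # from FE, Angstrom
    face: str = "+z"               # "+z" or "-z"
    comp_id: str = "HIS"
    chain_id: str = "A"
    residue_index: int = 42
    atom_name: str = "NE2"
    entity_id: str = "1"


@dataclass(frozen=True)
class ShellSpec:
    """Quasi-uniform (Fibonacci) sphere of dummy atoms centered on FE."""

    radius: float = 6.0   # close enough to occlude (Shrake-Rupley is local)
    n_atoms: int = 800
    element: str = "C"
    comp_id: str = "DUM"
    chain_id: str = "S"
    first_residue_index: int = 900


@dataclass
class FixtureComplex:
    heme: HemeEntry
    neighbors: list[AtomRecord] = field(default_factory=list)
    resolution: float | None = 1.80
    method: str = "X-RAY DIFFRACTION"
    keywords: str = "OXIDOREDUCTASE"


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_complex_fixture(
    heme: HemeEntry,
    ligands: list[LigandSpec] | None = None,
    shell: ShellSpec | None = None,
) -> FixtureComplex:
    """Surround a heme with declared ligand atoms and an occluding shell.

    Ligand atoms sit exactly on the N4-plane normal through FE at the
    declared distance (realized to 1e-9 A); the shell must clear every heme
    atom by at least 1 A.
    """
    fe = heme.coords[LABEL_INDEX["FE"]]
    n4 = heme.coords[[LABEL_INDEX[f"N{r}"] for r in "ABCD"]]
    centroid = n4.mean(axis=0)
    cov = np.cov((n4 - centroid).T, bias=True)
    _, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0] / np.linalg.norm(evecs[:, 0])
    if normal[2] < 0:
        normal = -normal

    neighbors: list[AtomRecord] = []
    for spec in ligands or []:
        if spec.distance <= 0:
            raise ValueError("ligand distance must be positive")
        direction = normal if spec.face == "+z" else -normal
        pos = fe + spec.distance * direction
        neighbors.append(
            AtomRecord(
                label=spec.atom_name, element=spec.element,
                xyz=tuple(float(v) for v in pos), altloc=".",
                entity_id=spec.entity_id, asym_id=spec.chain_id,
                chain_id=spec.chain_id, residue_index=spec.residue_index,
                comp_id=spec.comp_id,
            )
        )

    if shell is not None and shell.n_atoms > 0:
        all_heme = np.vstack(
            [heme.coords] + [v[None] for v in heme.sidechain.values()]
        )
        max_r = float(np.linalg.norm(all_heme - fe, axis=1).max())
        if shell.radius < max_r + 1.0:
            raise ValueError(
                f"shell radius {shell.radius} collides with heme atoms "
                f"(max heme radius {max_r:.2f})"
            )
        pts = fe + shell.radius * fibonacci_sphere(shell.n_atoms)
        for k, p in enumerate(pts):
            neighbors.append(
                AtomRecord(
                    label=f"C{k}", element=shell.element,
                    xyz=tuple(float(v) for v in p), altloc=".",
                    entity_id="9", asym_id=shell.chain_id,
                    chain_id=shell.chain_id,
                    residue_index=shell.first_residue_index + k,
                    comp_id=shell.comp_id,
                )
            )
    return FixtureComplex(heme=heme, neighbors=neighbors)


# --------------------------------------------------------------------------
# Minimal mmCIF writer
# --------------------------------------------------------------------------


def write_fixture_mmcif(
    fx: FixtureComplex,
    path: str | Path,
    drop_atoms: tuple[str, ...] = (),
    altloc_variants: dict[str, tuple[str, ...]] | None = None,
    extra_models: int = 0,
    organism: str | None = "Physeter macrocephalus (sperm whale)",
    ec: str | None = "1.14.13.39",
) -> Path:
    """Write a minimal standards-conformant mmCIF for a fixture complex.

    ``drop_atoms``: heme atom labels to omit (intactness-rule tests).
    ``altloc_variants``: heme atom label -> altloc IDs; the atom is written
    once per ID with a small offset for every ID other than the first
    (selection-rule tests).  ``extra_models`` appends shifted copies of all
    atoms with higher model numbers.
    """
    heme = fx.heme
    lines = [
        f"data_{heme.pdb_id}",
        f"_entry.id {heme.pdb_id}",
        "_struct_keywords.pdbx_keywords "
        + (f"'{fx.keywords}'" if fx.keywords else "?"),
        "_exptl.method '" + fx.method + "'",
    ]
    if fx.resolution is not None:
        lines.append(f"_refine.ls_d_res_high {fx.resolution:.2f}")
    lines.append("_pdbx_database_status.recvd_initial_deposition_date 2020-01-15")
    lines += [
        "loop_",
        "_entity.id",
        "_entity.pdbx_description",
        "_entity.pdbx_ec",
        "1 'model protein domain' " + (f"'{ec}'" if ec else "?"),
        "2 'heme' ?",
        "9 'dummy shell' ?",
    ]
    if organism:
        lines += [
            "loop_",
            "_entity_src_gen.entity_id",
            "_entity_src_gen.pdbx_gene_src_scientific_name",
            f"1 '{organism}'",
        ]
    lines += [
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.pdbx_PDB_model_num",
    ]

    counter = [0]
    rows: list[str] = []

    def emit(label: str, element: str, xyz, altloc: str, comp: str,
             asym: str, entity: str, seq: int, chain: str, model: int) -> None:
        counter[0] += 1
        x, y, z = (float(v) for v in xyz)
        rows.append(
            f"HETATM {counter[0]} {element} {label} {altloc} {comp} {asym} "
            f"{entity} . {seq} {chain} {x:.6f} {y:.6f} {z:.6f} 1.00 {model}"
        )

    def emit_heme(model: int, shift: float) -> None:
        for i, lab in enumerate(SKELETON_LABELS):
            if lab in drop_atoms:
                continue
            xyz = heme.coords[i] + shift
            variants = (altloc_variants or {}).get(lab, (".",))
            for v_i, alt in enumerate(variants):
                emit(lab, element_of(lab), xyz + 0.25 * v_i, alt,
                     heme.comp_id, heme.asym_id, "2", heme.residue_index,
                     heme.chain_id, model)
        for lab, xyz in sorted(heme.sidechain.items()):
            if lab in drop_atoms:
                continue
            emit(lab, "O" if lab.startswith("O") else element_of(lab),
                 np.asarray(xyz) + shift, ".", heme.comp_id, heme.asym_id,
                 "2", heme.residue_index, heme.chain_id, model)

    for model in range(1, 2 + extra_models):
        shift = 5.0 * (model - 1)
        emit_heme(model, shift)
        for a in fx.neighbors:
            emit(a.label, a.element, np.asarray(a.xyz) + shift,
                 a.altloc, a.comp_id, a.asym_id, a.entity_id,
                 a.residue_index, a.chain_id, model)

    path = Path(path)
    path.write_text("\n".join(lines + rows) + "\n")
    return path
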