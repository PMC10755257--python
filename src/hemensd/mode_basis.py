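"""Construction of the 12-mode projection basis for porphyrin distortion.

The normal modes of the planar D4h Fe-porphine follow from the secular
equation |M^(-1/2) (grad^2 E) M^(-1/2) - lambda I| = 0: the mass-weighted
Hessian of the potential is diagonalized, its eigenvectors are classified by
D4h irreducible representation, and the lowest-frequency mode of each
relevant symmetry species is kept.  The twelve retained modes are the
canonical porphyrin deformations: saddling (B2u), ruffling (B1u), doming
(A2u), waving(x)/waving(y) (Eg), propellering (A1u) out of plane, and
meso-stretching (B2g), N-pyrrole stretching (B1g), translation(x)/
translation(y) (Eu), breathing (A1g) and rotation (A2g) in plane.

For projection the mass-weighted eigenvectors are converted to Cartesian
heavy-atom displacements and normalized to unit Euclidean length.  Modes of
different irreps are then exactly orthogonal by symmetry, so the basis is
"almost orthogonal" in the strongest sense: the pairwise inner products
vanish to numerical precision while each self-inner product is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import scipy.linalg

from .exceptions import BasisFormatError, DimensionError, ModeIdentificationError
from .forcefield import HarmonicValenceForceField
from .reference_geometry import (  # noqa: F401  (mass_vector used in templates)
    LABEL_INDEX,
    RING_IDS,
    SKELETON_LABELS,
    ReferenceStructure,
    build_reference_porphine,
    mass_vector,
)
from .symmetry import irrep_projector, irrep_scores

#: The 12 mode names in canonical order, with their D4h irreps.
MODE_REGISTRY: tuple[tuple[str, str], ...] = (
    ("saddling", "B2u"),
    ("ruffling", "B1u"),
    ("doming", "A2u"),
    ("waving(x)", "Eg"),
    ("waving(y)", "Eg"),
    ("propellering", "A1u"),
    ("meso-stretching", "B2g"),
    ("N-pyrrole stretching", "B1g"),
    ("translation(x)", "Eu"),
    ("translation(y)", "Eu"),
    ("breathing", "A1g"),
    ("rotation", "A2g"),
)

MODE_NAMES: tuple[str, ...] = tuple(name for name, _ in MODE_REGISTRY)

#: Out-of-plane deformations (z-displacements on the planar reference).
OUT_OF_PLANE_MODES = (
    "saddling", "ruffling", "doming", "waving(x)", "waving(y)", "propellering",
)
IN_PLANE_MODES = tuple(n for n in MODE_NAMES if n not in OUT_OF_PLANE_MODES)


# --------------------------------------------------------------------------
# Hessian and secular equation
# --------------------------------------------------------------------------


def build_hessian(ff, ref_coords: np.ndarray | None = None,
                  step: float = 1e-4) -> np.ndarray:
    """Finite-difference Hessian of ``ff.energy`` at ``ref_coords``.

    Uses the symmetric four-point central-difference formula

        H_ij = [E(+i+j) - E(+i-j) - E(-i+j) + E(-i-j)] / (4 h^2),

    which is exact through O(h^2) and symmetric in (i, j) by construction;
    the matrix is nevertheless returned as (H + H^T)/2.
    """
    if not (1e-5 < step < 1e-2):
        raise ValueError("step must lie in (1e-5, 1e-2) Angstrom")
    if ref_coords is None:
        ref_coords = ff.reference.coords
    x0 = np.asarray(ref_coords, dtype=float)
    n = x0.size
    natoms = x0.shape[0]

    iu, ju = np.triu_indices(n)
    npairs = iu.size
    signs = np.array([(1, 1), (1, -1), (-1, 1), (-1, -1)], dtype=float)
    configs = np.tile(x0.reshape(1, -1), (4 * npairs, 1))
    for s, (si, sj) in enumerate(signs):
        block = slice(s * npairs, (s + 1) * npairs)
        rows = np.arange(npairs)
        configs[block][rows, iu] += si * step
        # += on the same flat index must accumulate when i == j
        np.add.at(configs[block], (rows, ju), sj * step)
    energies = ff.energy(configs.reshape(-1, natoms, 3))
    epp, epm, emp, emm = np.split(energies, 4)
    vals = (epp - epm - emp + emm) / (4.0 * step**2)

    hess = np.zeros((n, n))
    hess[iu, ju] = vals
    hess[ju, iu] = vals
    return 0.5 * (hess + hess.T)


def solve_secular_equation(
    hessian: np.ndarray, masses: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the mass-weighted Hessian M^(-1/2) H M^(-1/2).

    ``masses`` is the per-coordinate mass vector (atom mass repeated for
    x, y, z).  Returns eigenvalues sorted ascending and the matrix whose
    columns are the corresponding mass-weighted eigenvectors (orthonormal).
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.shape[0] != hessian.shape[1]:
        raise DimensionError("Hessian must be square")
    if masses.shape[0] != hessian.shape[0]:
        raise DimensionError("mass vector length must match Hessian size")
    rel_asym = np.linalg.norm(hessian - hessian.T) / max(np.linalg.norm(hessian), 1e-300)
    if rel_asym > 1e-8:
        raise ValueError(f"Hessian asymmetry {rel_asym:.2e} exceeds 1e-8")
    inv_sqrt_m = 1.0 / np.sqrt(masses)
    mw = hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    mw = 0.5 * (mw + mw.T)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(mw)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise ModeIdentificationError(
            f"eigen-solver failed on {mw.shape} matrix "
            f"(norm {np.linalg.norm(mw):.3e}): {exc}"
        ) from exc
    return eigvals, eigvecs


# --------------------------------------------------------------------------
# Analytic symmetry templates
# --------------------------------------------------------------------------


def _set_z(vec: np.ndarray, label: str, value: float) -> None:
    vec[3 * LABEL_INDEX[label] + 2] = value


def _set_xy(vec: np.ndarray, label: str, value: np.ndarray) -> None:
    vec[3 * LABEL_INDEX[label] : 3 * LABEL_INDEX[label] + 2] = value


def analytic_template(ref: ReferenceStructure, name: str) -> np.ndarray:
    """Normalized physically-motivated displacement pattern for a mode.

    Each template is a hand-written sketch of the classical deformation
    (e.g. saddling = alternate pyrrole tilts) cleaned by projection onto the
    exact irrep subspace, so it is pure in symmetry even though the radial
    profile is approximate.  Used to orient degenerate pairs, fix signs and
    cross-check classified modes.
    """
    try:
        irrep = dict(MODE_REGISTRY)[name]
    except KeyError:
        raise KeyError(f"unknown mode name {name!r}") from None
    coords = ref.coords
    d_fe_n = float(np.linalg.norm(ref.xyz("NA")))
    vec = np.zeros(75)
    ring_sign = {"A": 1.0, "B": -1.0, "C": 1.0, "D": -1.0}
    axes = {"A": np.array([1.0, 0.0]), "B": np.array([0.0, 1.0]),
            "C": np.array([-1.0, 0.0]), "D": np.array([0.0, -1.0])}

    if name == "saddling":
        # alternate rings tilt about the in-plane axis through their N
        for ring in RING_IDS:
            a = axes[ring]
            for k in (1, 2, 3, 4):
                lab = f"C{k}{ring}"
                radial = float(coords[LABEL_INDEX[lab], :2] @ a)
                _set_z(vec, lab, ring_sign[ring] * (radial - d_fe_n))
    elif name == "ruffling":
        for i, ring in enumerate(RING_IDS):
            _set_z(vec, f"CH{ring}", 1.0 if i % 2 == 0 else -1.0)
    elif name == "doming":
        _set_z(vec, "FE", 1.0)
        for ring in RING_IDS:
            _set_z(vec, f"N{ring}", 0.5)
            _set_z(vec, f"CH{ring}", -0.3)
            for k in (2, 3):
                _set_z(vec, f"C{k}{ring}", -0.3)
    elif name in ("waving(x)", "waving(y)"):
        # z ~ u*(r^2 - c): an Eg pattern made orthogonal (mass-weighted) to
        # the rigid rotation z ~ u, which on a planar structure is exactly
        # the tilt about the in-plane axis
        axis = 0 if name == "waving(x)" else 1
        masses = mass_vector(ref.elements)[::3]
        u = coords[:, axis]
        r2 = (coords[:, :2] ** 2).sum(1)
        c = float((masses * u**2 * r2).sum() / (masses * u**2).sum())
        for i in range(25):
            vec[3 * i + 2] = u[i] * (r2[i] - c)
    elif name == "propellering":
        # every ring twists the same way about its own radial axis
        for ring in RING_IDS:
            a = axes[ring]
            for k in (1, 2, 3, 4):
                lab = f"C{k}{ring}"
                x, y = coords[LABEL_INDEX[lab], :2]
                _set_z(vec, lab, a[0] * y - a[1] * x)
    elif name == "meso-stretching":
        for i, ring in enumerate(RING_IDS):
            lab = f"CH{ring}"
            p = coords[LABEL_INDEX[lab], :2]
            _set_xy(vec, lab, (1.0 if i % 2 == 0 else -1.0) * p / np.linalg.norm(p))
    elif name == "N-pyrrole stretching":
        for i, ring in enumerate(RING_IDS):
            lab = f"N{ring}"
            p = coords[LABEL_INDEX[lab], :2]
            _set_xy(vec, lab, (1.0 if i % 2 == 0 else -1.0) * p / np.linalg.norm(p))
    elif name in ("translation(x)", "translation(y)"):
        # iron translates against the ring (mass-weighted net momentum zero)
        axis = 0 if name == "translation(x)" else 1
        masses = mass_vector(ref.elements)[::3]
        total = masses.sum()
        for i, lab in enumerate(SKELETON_LABELS):
            vec[3 * i + axis] = (1.0 if lab == "FE" else 0.0) - masses[LABEL_INDEX["FE"]] / total
    elif name == "breathing":
        for i, lab in enumerate(SKELETON_LABELS):
            if lab == "FE":
                continue
            p = coords[i, :2]
            _set_xy(vec, lab, p / np.linalg.norm(p))
    elif name == "rotation":
        # meso carbons rotate against the rest of the ring: tangential on
        # meso, minus the rigid z-rotation share (mass-weighted)
        masses = mass_vector(ref.elements)[::3]
        tang = np.zeros((25, 2))
        for ring in RING_IDS:
            i = LABEL_INDEX[f"CH{ring}"]
            x, y = coords[i, :2]
            tang[i] = np.array([-y, x])
        rigid = np.stack([-coords[:, 1], coords[:, 0]], axis=1)
        c = float((masses[:, None] * tang * rigid).sum()
                  / (masses[:, None] * rigid * rigid).sum())
        tang -= c * rigid
        vec[0::3] = tang[:, 0]
        vec[1::3] = tang[:, 1]

    projected = irrep_projector(ref, irrep) @ vec
    norm = np.linalg.norm(projected)
    if norm < 1e-9:
        raise ModeIdentificationError(
            f"template for {name} vanishes under {irrep} projection"
        )
    return projected / norm


# --------------------------------------------------------------------------
# Mode selection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalMode:
    """One named porphyrin normal mode as a unit heavy-atom displacement."""

    name: str
    irrep: str
    eigenvalue: float
    vector: np.ndarray  # (75,), unit Euclidean norm

    @property
    def self_inner_product(self) -> float:
        return float(self.vector @ self.vector)


@dataclass(frozen=True)
class ModeBasis:
    """Ordered collection of the 12 named modes (the projection basis)."""

    modes: tuple[NormalMode, ...]
    provenance: str = "computed"

    def __post_init__(self):
        names = [m.name for m in self.modes]
        if sorted(names) != sorted(MODE_NAMES):
            raise BasisFormatError(
                f"basis must contain the 12 canonical modes exactly once; "
                f"got {names}"
            )

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, name: str) -> NormalMode:
        for m in self.modes:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def matrix(self) -> np.ndarray:
        """(12, 75) array of mode vectors in canonical order."""
        return np.array([self[name].vector for name in MODE_NAMES])

    def gram(self) -> np.ndarray:
        """Pairwise inner-product matrix of the 12 mode vectors."""
        m = self.matrix
        return m @ m.T

    def validate(self) -> None:
        g = self.gram()
        if np.any(np.abs(np.diag(g)) < 0.99):
            raise BasisFormatError("a mode vector is not normalized")
        off = g - np.diag(np.diag(g))
        if np.max(np.abs(off)) > 0.10:
            raise BasisFormatError(
                f"mode vectors are not almost orthogonal: max off-diagonal "
                f"inner product {np.max(np.abs(off)):.3f} > 0.10"
            )


def _rigid_space(ref: ReferenceStructure) -> np.ndarray:
    """Orthonormal basis (75, 6) of rigid translations and rotations."""
    coords = ref.coords - ref.coords.mean(axis=0)
    cols = []
    for ax in range(3):
        t = np.zeros((25, 3))
        t[:, ax] = 1.0
        cols.append(t.reshape(-1))
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        cols.append(np.cross(omega, coords).reshape(-1))
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def _mass_weighted_to_cartesian(u: np.ndarray, masses: np.ndarray,
                                rigid: np.ndarray | None = None) -> np.ndarray:
    """Unweight, remove any rigid-body component, and normalize.

    Mass-weighted eigenvectors are orthogonal to rigid motions in the
    mass-weighted metric, but dividing by sqrt(m) re-introduces a rigid
    component in plain Cartesian space (notably along z for doming).  The
    least-squares superposition later discards exactly that component of
    any displacement, so it is projected out of the basis vectors here;
    this keeps projection amplitudes rigid-motion invariant and makes
    injected amplitudes recover exactly.
    """
    c = u / np.sqrt(masses)
    if rigid is not None:
        c = c - rigid @ (rigid.T @ c)
    return c / np.linalg.norm(c)


def classify_and_select(
    eigvals: np.ndarray,
    eigvecs: np.ndarray,
    ref: ReferenceStructure,
    masses: np.ndarray,
    min_overlap: float = 0.5,
    zero_tol_factor: float = 1e-6,
) -> ModeBasis:
    """Assign irreps to eigenvectors and keep the lowest mode of each name.

    Rigid motions (eigenvalues below ``zero_tol_factor * max eigenvalue``)
    are discarded; every remaining eigenvector is scored against each D4h
    irrep projector.  For the ten one-dimensional species the internal mode
    of lowest eigenvalue wins; the two-dimensional Eg and Eu species yield
    degenerate pairs whose orientation within the pair is fixed by maximal
    overlap with x/y-aligned analytic templates followed by Gram-Schmidt.
    Vectors are returned as unit-norm Cartesian displacements with signs
    fixed by positive overlap with the analytic templates.
    """
    zero_tol = zero_tol_factor * float(np.max(np.abs(eigvals)))
    internal = [i for i in range(len(eigvals)) if eigvals[i] > zero_tol]

    # irrep assignment for internal modes (mass weighting commutes with the
    # group action, so scores are identical in either representation)
    assignment: dict[str, list[int]] = {}
    best_scores: dict[int, tuple[str, float]] = {}
    for i in internal:
        scores = irrep_scores(ref, eigvecs[:, i])
        irrep = max(scores, key=scores.get)
        best_scores[i] = (irrep, scores[irrep])
        assignment.setdefault(irrep, []).append(i)
    for idxs in assignment.values():
        idxs.sort(key=lambda i: eigvals[i])

    rigid = _rigid_space(ref)
    selected: list[NormalMode] = []
    for name, irrep in MODE_REGISTRY:
        if irrep in ("Eg", "Eu"):
            continue  # handled pairwise below
        candidates = [
            i for i in assignment.get(irrep, []) if best_scores[i][1] >= min_overlap
        ]
        if not candidates:
            report = {i: best_scores[i] for i in internal[:8]}
            raise ModeIdentificationError(
                f"no eigenvector matches {name} ({irrep}) with overlap >= "
                f"{min_overlap}; best assignments: {report}"
            )
        i = candidates[0]
        cart = _mass_weighted_to_cartesian(eigvecs[:, i], masses, rigid)
        template = analytic_template(ref, name)
        if cart @ template < 0:
            cart = -cart
        selected.append(NormalMode(name, irrep, float(eigvals[i]), cart))

    for irrep, (name_x, name_y) in (
        ("Eg", ("waving(x)", "waving(y)")),
        ("Eu", ("translation(x)", "translation(y)")),
    ):
        idxs = [
            i for i in assignment.get(irrep, []) if best_scores[i][1] >= min_overlap
        ]
        if len(idxs) < 2:
            raise ModeIdentificationError(
                f"fewer than two {irrep} eigenvectors found for "
                f"{name_x}/{name_y}"
            )
        pair = idxs[:2]
        span = eigvecs[:, pair]  # (75, 2), orthonormal columns
        t_x = analytic_template(ref, name_x)
        t_y = analytic_template(ref, name_y)
        # mass-weight the templates so the in-span algebra is orthonormal
        mt_x = span @ (span.T @ (t_x * np.sqrt(masses)))
        v_x = mt_x / np.linalg.norm(mt_x)
        mt_y = span @ (span.T @ (t_y * np.sqrt(masses)))
        w = mt_y - (mt_y @ v_x) * v_x
        v_y = w / np.linalg.norm(w)
        lam = float(np.mean([eigvals[i] for i in pair]))
        for name, u, t in ((name_x, v_x, t_x), (name_y, v_y, t_y)):
            cart = _mass_weighted_to_cartesian(u, masses, rigid)
            if cart @ t < 0:
                cart = -cart
            selected.append(NormalMode(name, irrep, lam, cart))

    order = {name: k for k, name in enumerate(MODE_NAMES)}
    selected.sort(key=lambda m: order[m.name])
    basis = ModeBasis(modes=tuple(selected), provenance="computed")
    basis.validate()
    return basis


# --------------------------------------------------------------------------
# Top-level builder and file round trip
# --------------------------------------------------------------------------


def compute_mode_basis(
    ref: ReferenceStructure | None = None,
    k_r: float = 1.0,
    k_theta: float = 0.3,
    k_phi: float = 0.1,
    step: float = 1e-4,
) -> ModeBasis:
    """Build the 12-mode basis from scratch on a reference structure."""
    if ref is None:
        ref = build_reference_porphine()
    ff = HarmonicValenceForceField(ref, k_r=k_r, k_theta=k_theta, k_phi=k_phi)
    hessian = build_hessian(ff, step=step)
    masses = mass_vector(ref.elements)
    eigvals, eigvecs = solve_secular_equation(hessian, masses)
    return classify_and_select(eigvals, eigvecs, ref, masses)


@lru_cache(maxsize=1)
def default_mode_basis() -> ModeBasis:
    """The shipped default basis (default reference + force field), cached."""
    return compute_mode_basis()


def save_mode_basis(basis: ModeBasis, path: str | Path) -> None:
    """Write a basis as multi-block xyz-like text (1e-9 round trip)."""
    lines = ["# hemensd mode basis v1",
             "# atoms: " + " ".join(SKELETON_LABELS)]
    for name in MODE_NAMES:
        m = basis[name]
        lines.append(f"mode: {m.name} | {m.irrep} | {m.eigenvalue:.12e}")
        v = m.vector.reshape(25, 3)
        for lab, (dx, dy, dz) in zip(SKELETON_LABELS, v):
            lines.append(f"{lab:<4s} {dx: .15e} {dy: .15e} {dz: .15e}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_mode_basis(path: str | Path) -> ModeBasis:
    """Read a basis file, restore canonical atom order, and re-validate."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    atom_order: list[str] | None = None
    blocks: list[tuple[str, str, float, list[tuple[str, np.ndarray]]]] = []
    current: list[tuple[str, np.ndarray]] | None = None
    for ln in lines:
        if ln.startswith("# atoms:"):
            atom_order = ln.split(":", 1)[1].split()
        elif ln.startswith("mode:"):
            head = [t.strip() for t in ln.split(":", 1)[1].split("|")]
            if len(head) != 3:
                raise BasisFormatError(f"malformed mode header: {ln!r}")
            current = []
            blocks.append((head[0], head[1], float(head[2]), current))
        elif ln.startswith("#") or not ln.strip():
            continue
        else:
            if current is None:
                raise BasisFormatError("displacement row before any mode header")
            parts = ln.split()
            if len(parts) != 4:
                raise BasisFormatError(f"malformed displacement row: {ln!r}")
            current.append((parts[0], np.array([float(x) for x in parts[1:]])))

    if atom_order is None:
        raise BasisFormatError("missing '# atoms:' header line")
    if sorted(atom_order) != sorted(SKELETON_LABELS):
        raise BasisFormatError("atom header does not list the 25 skeleton labels")
    if len(blocks) != 12:
        raise BasisFormatError(f"expected 12 mode blocks, found {len(blocks)}")

    modes = []
    for name, irrep, eigval, rows in blocks:
        if name not in MODE_NAMES:
            raise BasisFormatError(f"unknown mode name {name!r}")
        if len(rows) != 25:
            raise BasisFormatError(
                f"mode {name!r} has {len(rows)} atom rows, expected 25"
            )
        row_map = {lab: vec for lab, vec in rows}
        if sorted(row_map) != sorted(SKELETON_LABELS):
            raise BasisFormatError(f"mode {name!r} rows do not match skeleton")
        vec = np.concatenate([row_map[lab] for lab in SKELETON_LABELS])
        norm = np.linalg.norm(vec)
        if norm < 1e-9:
            raise BasisFormatError(f"mode {name!r} vector is unnormalizable")
        modes.append(NormalMode(name, irrep, eigval, vec / norm))

    names = [m.name for m in modes]
    if len(set(names)) != 12:
        raise BasisFormatError("duplicate mode names in file")
    order = {name: k for k, name in enumerate(MODE_NAMES)}
    modes.sort(key=lambda m: order[m.name])
    basis = ModeBasis(modes=tuple(modes), provenance="loaded")
    basis.validate()
    return basis
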