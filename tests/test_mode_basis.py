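"""Hessian construction, secular equation and 12-mode basis selection."""

import numpy as np
import pytest

from hemensd.exceptions import BasisFormatError
from hemensd.forcefield import HarmonicValenceForceField
from hemensd.mode_basis import (
    IN_PLANE_MODES,
    MODE_NAMES,
    OUT_OF_PLANE_MODES,
    analytic_template,
    build_hessian,
    compute_mode_basis,
    load_mode_basis,
    save_mode_basis,
    solve_secular_equation,
)
from hemensd.reference_geometry import LABEL_INDEX, mass_vector


class _SpringToy:
    """Two atoms joined by one harmonic spring (closed-form eigenvalues)."""

    def __init__(self, k=1.0, r0=1.0):
        self.k, self.r0 = k, r0
        self.reference = type("R", (), {})()
        self.reference.coords = np.array([[0.0, 0, 0], [r0, 0, 0]])

    def energy(self, coords):
        coords = np.asarray(coords, dtype=float)
        r = np.linalg.norm(coords[..., 0, :] - coords[..., 1, :], axis=-1)
        return 0.5 * self.k * (r - self.r0) ** 2


class TestHessian:
    def test_two_atom_spring_closed_form(self):
        """Mass-weighted eigenvalues of one spring are {0 (x5), 2k/m}."""
        k, m = 2.5, 4.0
        toy = _SpringToy(k=k)
        h = build_hessian(toy, toy.reference.coords, step=1e-4)
        vals, _ = solve_secular_equation(h, np.full(6, m))
        assert np.sum(np.abs(vals) < 1e-6 * vals.max()) == 5
        assert vals[-1] == pytest.approx(2 * k / m, rel=1e-6)

    def test_symmetric_before_symmetrization(self, ref):
        ff = HarmonicValenceForceField(ref)
        h = build_hessian(ff)
        assert np.linalg.norm(h - h.T) / np.linalg.norm(h) < 1e-6

    def test_doubling_force_constants_doubles_eigenvalues(self, ref):
        masses = mass_vector(ref.elements)
        v1, _ = solve_secular_equation(
            build_hessian(HarmonicValenceForceField(ref)), masses
        )
        v2, _ = solve_secular_equation(
            build_hessian(
                HarmonicValenceForceField(ref, k_r=2.0, k_theta=0.6, k_phi=0.2)
            ),
            masses,
        )
        nz = v1 > 1e-6 * v1.max()
        assert np.allclose(v2[nz] / v1[nz], 2.0, rtol=1e-6)

    def test_bad_step_rejected(self, ref):
        ff = HarmonicValenceForceField(ref)
        with pytest.raises(ValueError):
            build_hessian(ff, step=0.5)


class TestSecularEquation:
    def test_rigid_body_null_space_and_internal_mode_count(self, ref):
        """6 near-zero eigenvalues; 69 = 3N-6 internal modes for N = 25."""
        ff = HarmonicValenceForceField(ref)
        vals, _ = solve_secular_equation(
            build_hessian(ff), mass_vector(ref.elements)
        )
        tol = 1e-6 * vals.max()
        assert np.sum(np.abs(vals) < tol) == 6
        assert np.sum(vals > tol) == 69

    def test_eigenvector_orthonormality(self, ref):
        ff = HarmonicValenceForceField(ref)
        _, vecs = solve_secular_equation(
            build_hessian(ff), mass_vector(ref.elements)
        )
        assert np.max(np.abs(vecs.T @ vecs - np.eye(75))) < 1e-8

    def test_eigenvalues_match_characteristic_polynomial_roots(self):
        """Independent oracle: char-poly roots of the 6x6 spring problem."""
        toy = _SpringToy(k=1.7, r0=1.3)
        h = build_hessian(toy, toy.reference.coords, step=1e-4)
        masses = np.array([1.0, 1.0, 1.0, 3.0, 3.0, 3.0])
        vals, _ = solve_secular_equation(h, masses)
        mw = h / np.sqrt(np.outer(masses, masses))
        roots = np.sort(np.real(np.roots(np.poly(mw))))
        assert np.allclose(np.sort(vals), roots, atol=1e-9)


class TestModeBasis:
    def test_exactly_twelve_named_modes(self, basis):
        assert sorted(m.name for m in basis) == sorted(MODE_NAMES)

    def test_self_inner_products_near_unity(self, basis):
        for m in basis:
            assert abs(m.self_inner_product) >= 0.99

    def test_basis_almost_orthogonal(self, basis):
        g = basis.gram()
        off = g - np.diag(np.diag(g))
        assert np.max(np.abs(off)) <= 0.10

    def test_saddling_matches_analytic_pattern(self, ref, basis):
        """Saddling: B2u template overlap, no in-plane motion, and
        beta-carbon z displacements alternating in sign around the ring."""
        sad = basis["saddling"]
        t = analytic_template(ref, "saddling")
        assert abs(sad.vector @ t) >= 0.9
        v = sad.vector.reshape(25, 3)
        assert np.max(np.abs(v[:, :2])) < 1e-8
        beta_z = [v[LABEL_INDEX[f"C{k}{ring}"], 2]
                  for ring in "ABCD" for k in (2, 3)]
        signs = np.sign(beta_z)
        assert np.all(signs[0:2] == signs[0])
        assert np.all(signs[2:4] == -signs[0])
        assert np.all(signs[4:6] == signs[0])
        assert np.all(signs[6:8] == -signs[0])

    def test_out_of_plane_and_in_plane_purity(self, basis):
        for name in OUT_OF_PLANE_MODES:
            v = basis[name].vector.reshape(25, 3)
            assert np.max(np.abs(v[:, :2])) < 1e-8, name
        for name in IN_PLANE_MODES:
            v = basis[name].vector.reshape(25, 3)
            assert np.max(np.abs(v[:, 2])) < 1e-8, name

    @pytest.mark.parametrize(
        "kwargs", [{"k_r": 1.2}, {"k_theta": 0.24}, {"k_phi": 0.12}]
    )
    def test_mode_shapes_stable_to_force_constant_perturbation(
        self, ref, basis, kwargs
    ):
        """+/-20% on any constant keeps every named mode's direction."""
        perturbed = compute_mode_basis(ref, **kwargs)
        for name in MODE_NAMES:
            cos = abs(basis[name].vector @ perturbed[name].vector)
            assert cos >= 0.95, f"{name}: |cos| = {cos:.3f}"


class TestBasisFile:
    def test_round_trip_exact(self, basis, tmp_path):
        path = tmp_path / "basis.txt"
        save_mode_basis(basis, path)
        loaded = load_mode_basis(path)
        for name in MODE_NAMES:
            assert np.max(
                np.abs(loaded[name].vector - basis[name].vector)
            ) < 1e-9
        assert loaded.provenance == "loaded"

    def test_eleven_modes_rejected(self, basis, tmp_path):
        path = tmp_path / "basis.txt"
        save_mode_basis(basis, path)
        text = path.read_text()
        head, _, _ = text.rpartition("mode:")
        path.write_text(head)
        with pytest.raises(BasisFormatError):
            load_mode_basis(path)

    def test_shuffled_atom_order_restores_canonical(self, basis, tmp_path):
        """Permuting rows and the header consistently is harmless."""
        path = tmp_path / "basis.txt"
        save_mode_basis(basis, path)
        lines = path.read_text().splitlines()
        rng = np.random.default_rng(7)
        perm = rng.permutation(25)
        out = []
        block: list[str] = []

        def flush():
            if block:
                out.extend(block[i] for i in perm)
                block.clear()

        for ln in lines:
            if ln.startswith("# atoms:"):
                labels = ln.split(":", 1)[1].split()
                out.append("# atoms: " + " ".join(labels[i] for i in perm))
            elif ln.startswith(("#", "mode:")):
                flush()
                out.append(ln)
            else:
                block.append(ln)
        flush()
        shuffled = tmp_path / "shuffled.txt"
        shuffled.write_text("\n".join(out) + "\n")
        loaded = load_mode_basis(shuffled)
        for name in MODE_NAMES:
            assert np.max(
                np.abs(loaded[name].vector - basis[name].vector)
            ) < 1e-9
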