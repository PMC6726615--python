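import math

import numpy as np
import pytest

from distfold.structio import (Model, backbone_from_torsions,
                               cb_distance_matrix, detect_hbonds, dihedral,
                               hbond_precision, kabsch, phi_psi, read_pdb,
                               tm_d0, tm_score, write_pdb)


def rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * k @ k


class TestPdbIO:
    def test_round_trip(self, toy_fold_small):
        text = write_pdb(toy_fold_small)
        back = read_pdb(text)
        assert back.sequence == toy_fold_small.sequence
        for name in ("n", "ca", "c", "o", "cb"):
            np.testing.assert_allclose(getattr(back, name),
                                       getattr(toy_fold_small, name),
                                       atol=1.5e-3)

    def test_glycine_has_no_cb_record(self):
        L = 12
        m = backbone_from_torsions("AAAGAAAAAAAA",
                                   np.full(L, -1.0), np.full(L, -0.8))
        text = write_pdb(m)
        gly_lines = [ln for ln in text.splitlines() if " GLY " in ln]
        assert gly_lines and all(" CB " not in ln for ln in gly_lines)
        back = read_pdb(text)
        assert np.isnan(back.cb[3]).all()

    def test_malformed_line_skipped_and_counted(self, toy_fold_small):
        lines = write_pdb(toy_fold_small).splitlines()
        lines.insert(3, "ATOM     99  CA  ALA A  99    garbage-coordinates")
        m, report = read_pdb("\n".join(lines), return_report=True)
        assert report.skipped_lines == 1
        assert len(m) == len(toy_fold_small)

    def test_missing_ca_residue_rejected(self, toy_fold_small):
        lines = [ln for ln in write_pdb(toy_fold_small).splitlines()
                 if not (ln.startswith("ATOM") and ln[13:16].strip() == "CA"
                         and int(ln[22:26]) == 1)]
        m, report = read_pdb("\n".join(lines), return_report=True)
        assert report.rejected_residues == 1
        assert len(m) == len(toy_fold_small) - 1

    def test_empty_chain_errors(self):
        with pytest.raises(ValueError, match="empty"):
            read_pdb("END\n")

    def test_bfactor_column_carries_scores(self, toy_fold_small):
        scores = np.arange(len(toy_fold_small), dtype=float) / 10
        text = write_pdb(toy_fold_small, bfactors=scores)
        line = next(ln for ln in text.splitlines()
                    if ln.startswith("ATOM") and int(ln[22:26]) == 5)
        assert float(line[60:66]) == pytest.approx(scores[4], abs=0.005)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        sup, rmsd = kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        sup, rmsd = kabsch(pts, pts + [1.0, -2.0, 3.0])
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(sup.translation, [1, -2, 3], atol=1e-9)

    def test_recovers_90_degree_rotation(self):
        pts = np.random.default_rng(2).normal(size=(10, 3))
        r = rotation([0, 0, 1], math.pi / 2)
        sup, rmsd = kabsch(pts, pts @ r.T)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(sup.rotation, r, atol=1e-6)

    def test_never_reflects(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(7, 3))
        b = a * np.array([1, 1, -1.0])  # mirror image
        sup, rmsd = kabsch(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(pts, pts)

    def test_beats_any_explicit_rotation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(9, 3))
        b = a @ rotation([1, 1, 0], 0.7).T + rng.normal(0, 0.3, (9, 3))
        _, best = kabsch(a, b)
        for _ in range(20):
            r = rotation(rng.normal(size=3), rng.uniform(0, math.pi))
            ar = a @ r.T
            shift = b.mean(0) - ar.mean(0)
            rmsd = np.sqrt(((ar + shift - b) ** 2).sum(axis=1).mean())
            assert best <= rmsd + 1e-9


class TestTMScore:
    def test_identical_is_one(self, toy_fold_small):
        assert tm_score(toy_fold_small, toy_fold_small) == pytest.approx(1.0)

    def test_rigid_motion_invariant(self, toy_fold_small):
        r = rotation([1, 2, 3], 1.1)
        moved = toy_fold_small.transformed(r, np.array([5.0, -3.0, 2.0]))
        assert tm_score(moved, toy_fold_small) == pytest.approx(1.0, abs=1e-6)

    def test_mirror_scores_below_one(self, toy_fold_60):
        assert tm_score(toy_fold_60.mirrored(), toy_fold_60) < 0.9

    def test_d0_floor(self):
        assert tm_d0(10) == 0.5
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)

    def test_length_mismatch_rejected(self, toy_fold_small, toy_fold_60):
        with pytest.raises(ValueError):
            tm_score(toy_fold_small, toy_fold_60)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rotation_grid_oracle_small(self, seed):
        """On tiny toys, fragment-seeded refinement must match an exhaustive
        rotation-grid + Kabsch-subset search."""
        rng = np.random.default_rng(seed)
        L = 6
        ca_ref = rng.normal(size=(L, 3)) * 3
        ca_mod = ca_ref + rng.normal(0, 1.0, (L, 3))
        seq = "A" * L
        z = np.zeros((L, 3))
        ref = Model(seq, z, ca_ref, z, z, z)
        mod = Model(seq, z, ca_mod, z, z, z)
        got = tm_score(mod, ref)

        d0 = tm_d0(L)
        def score(rot, trans):
            d2 = ((ca_mod @ rot.T + trans - ca_ref) ** 2).sum(axis=1)
            return (1 / (1 + d2 / d0 ** 2)).sum() / L

        best = 0.0
        # exhaustive subset Kabsch seeds plus iterative regrowth
        from itertools import combinations
        for size in range(3, L + 1):
            for subset in combinations(range(L), size):
                idx = np.array(subset)
                for _ in range(10):
                    try:
                        sup, _ = kabsch(ca_mod[idx], ca_ref[idx])
                    except ValueError:
                        break
                    best = max(best, score(sup.rotation, sup.translation))
                    d2 = ((ca_mod @ sup.rotation.T + sup.translation
                           - ca_ref) ** 2).sum(axis=1)
                    new = np.flatnonzero(d2 <= max(4 * d0 ** 2,
                                                   np.sort(d2)[2]))
                    if len(new) < 3 or np.array_equal(new, idx):
                        break
                    idx = new
        # coarse rotation grid with optimal centroid shift
        for ax in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]):
            for ang in np.linspace(0, 2 * math.pi, 12, endpoint=False):
                r = rotation(ax, ang)
                t = ca_ref.mean(0) - (ca_mod @ r.T).mean(0)
                best = max(best, score(r, t))
        assert got == pytest.approx(best, abs=1e-3)


class TestHbonds:
    def test_helix_pattern(self, helix30):
        pairs = detect_hbonds(helix30)
        offs = [i - j for i, j in pairs]
        # dominated by the i -> i-4 alpha-helical pattern
        assert offs.count(4) == 30 - 4
        assert all(2 <= o <= 4 for o in offs)

    def test_extended_chain_empty(self, strand20):
        assert detect_hbonds(strand20) == []

    def test_monotone_in_cutoff(self, helix30):
        tight = set(detect_hbonds(helix30, cutoff=3.2))
        loose = set(detect_hbonds(helix30, cutoff=3.5))
        assert tight <= loose

    def test_precision_exact_sets(self, helix30):
        detected = detect_hbonds(helix30)
        assert hbond_precision(detected, helix30) == 1.0
        disjoint = [(0, 20), (1, 25)]
        assert hbond_precision(disjoint, helix30) == 0.0

    def test_precision_half_overlap(self, helix30):
        detected = detect_hbonds(helix30)
        half = detected[: len(detected) // 2] \
            + [(0, 20)] * (len(detected) - len(detected) // 2)
        assert hbond_precision(half, helix30) == pytest.approx(
            (len(detected) // 2) / len(detected))

    def test_empty_prediction_reported_absent(self, helix30):
        assert hbond_precision([], helix30) is None


class TestGeometryHelpers:
    def test_phi_psi_round_trip(self):
        L = 25
        rng = np.random.default_rng(5)
        phi = rng.uniform(-math.pi, 0, L)
        psi = rng.uniform(-math.pi, math.pi, L)
        m = backbone_from_torsions("A" * L, phi, psi)
        got_phi, got_psi = phi_psi(m)
        np.testing.assert_allclose(got_phi[1:], phi[1:], atol=1e-9)
        np.testing.assert_allclose(got_psi[:-1], psi[:-1], atol=1e-9)

    def test_cb_distance_matrix_invariances(self, toy_fold_small):
        d = cb_distance_matrix(toy_fold_small)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        moved = toy_fold_small.transformed(np.eye(3), np.array([10., 0., 0.]))
        np.testing.assert_allclose(cb_distance_matrix(moved), d, atol=1e-9)

    def test_cb_matrix_uses_ca_for_glycine(self):
        L = 12
        m = backbone_from_torsions("AAAGAAAAAAAA",
                                   np.full(L, -1.2), np.full(L, -0.8))
        d = cb_distance_matrix(m)
        cb = m.cb.copy()
        cb[3] = m.ca[3]
        expect = np.linalg.norm(cb[:, None] - cb[None, :], axis=2)
        np.testing.assert_allclose(d, expect)

    def test_helix_adjacent_cb_range(self, helix30):
        d = cb_distance_matrix(helix30)
        adj = np.diagonal(d, offset=1)
        assert np.all(adj > 4.5) and np.all(adj < 6.5)

    def test_dihedral_sign_convention(self):
        # trans (180 deg) butane-like quadruple
        p = np.array([[0, 1, 0.], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        assert abs(dihedral(*p)) == pytest.approx(math.pi)
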