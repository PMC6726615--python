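import numpy as np
import pytest

from distfold.builder import (BuilderConfig, _dihedral_and_grad, _EnergyModel,
                              backbone_on_trace, build_ensemble,
                              embed_distances, embed_initial, energy_breakdown,
                              refine, smooth_bounds, trace_handedness_penalty)
from distfold.restraints import (DistanceBound, RestraintSet,
                                 distogram_to_bounds, hbond_map_to_restraints,
                                 torsions_to_restraints)
from distfold.structio import kabsch
from distfold.synthetic import (oracle_distogram, oracle_hbonds,
                                oracle_torsions)


def quick_cfg(**kw):
    """Reduced schedule for unit tests (full defaults are exercised in the
    acceptance suite)."""
    base = dict(n_stages=4, steps_per_stage=20, polish_iterations=150,
                ensemble_size=2)
    base.update(kw)
    return BuilderConfig(**base)


def zero_noise_restraints(native, oracle_cfg):
    d = oracle_distogram(native, oracle_cfg)
    return RestraintSet(
        bounds=distogram_to_bounds(d, native.sequence),
        hbonds=hbond_map_to_restraints(oracle_hbonds(native, oracle_cfg)),
        torsions=torsions_to_restraints(oracle_torsions(native, oracle_cfg)),
    )


class TestSmoothBounds:
    def test_triangle_inequality(self):
        lower, upper = smooth_bounds([], 3)
        assert upper[0, 2] <= upper[0, 1] + upper[1, 2] + 1e-12

    def test_shortest_path_tightens(self):
        b = [DistanceBound(1, 3, 3.5, 19.0, 0.5)]
        lower, upper = smooth_bounds(b, 3)
        assert upper[0, 2] <= 8.0  # two chain steps of 4.0

    def test_tight_input_unchanged(self):
        b = [DistanceBound(1, 5, 5.0, 5.5, 0.9)]
        lower, upper = smooth_bounds(b, 6)
        assert upper[0, 4] == 5.5
        assert lower[0, 4] == 5.0

    def test_contradiction_relaxed_with_warning(self, caplog):
        # a lower bound the chain ladder cannot reach
        b = [DistanceBound(1, 3, 12.0, 18.0, 0.5)]
        import logging
        with caplog.at_level(logging.WARNING, logger="distfold"):
            lower, upper = smooth_bounds(b, 3)
        assert "contradictory" in caplog.text
        assert np.all(lower <= upper + 1e-12)

    def test_inconsistent_bound_rejected(self):
        bad = DistanceBound(1, 4, 5.0, 6.0, 0.5)
        bad.lower, bad.upper = 7.0, 6.0  # corrupt after construction
        with pytest.raises(ValueError, match="lower > upper"):
            smooth_bounds([bad], 5)


class TestEmbedding:
    def test_exact_distances_reproduced(self, toy_fold_small):
        ca = toy_fold_small.ca
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
        x = embed_distances(d)
        # up to rigid motion and reflection
        rmsds = []
        for mirror in (False, True):
            y = x * np.array([1, 1, -1.0]) if mirror else x
            _, rmsd = kabsch(y, ca)
            rmsds.append(rmsd)
        assert min(rmsds) <= 0.1

    def test_mirror_flag_reflects(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3)) * 4
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        a = embed_distances(d, mirror=False)
        b = embed_distances(d, mirror=True)
        np.testing.assert_allclose(a[:, :2], b[:, :2])
        np.testing.assert_allclose(a[:, 2], -b[:, 2])

    def test_seeded_determinism(self):
        lower, upper = smooth_bounds([], 12)
        a = embed_initial(lower, upper, rng_seed=3)
        b = embed_initial(lower, upper, rng_seed=3)
        np.testing.assert_array_equal(a, b)

    def test_degenerate_spectrum_reported(self):
        # all distances zero cannot embed in rank 3
        d = np.zeros((6, 6))
        with pytest.raises(np.linalg.LinAlgError):
            embed_distances(d)


class TestDihedralGradient:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 3)) * 2
        quads = np.array([[0, 1, 2, 3], [2, 3, 4, 5], [4, 5, 6, 7]])
        phi, grads = _dihedral_and_grad(x, quads, True)
        eps = 1e-6
        for qi in range(len(quads)):
            for k in range(4):
                for dim in range(3):
                    xp = x.copy(); xp[quads[qi, k], dim] += eps
                    xm = x.copy(); xm[quads[qi, k], dim] -= eps
                    num = (_dihedral_and_grad(xp, quads[qi:qi + 1], False)[0][0]
                           - _dihedral_and_grad(xm, quads[qi:qi + 1], False)[0][0]
                           ) / (2 * eps)
                    assert grads[k][qi, dim] == pytest.approx(num, abs=1e-5)


class TestEnergyModel:
    def test_total_gradient_matches_finite_differences(self, toy_fold_small,
                                                       zero_noise_oracle):
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        em = _EnergyModel(toy_fold_small.sequence, rset, BuilderConfig())
        rng = np.random.default_rng(2)
        x = em.pack(toy_fold_small) + rng.normal(0, 0.3, (em.n_atoms, 3))
        terms, g = em.energy_grad(x)
        eps = 1e-6
        for k in rng.choice(em.n_atoms, 8, replace=False):
            for dim in range(3):
                xp = x.copy(); xp[k, dim] += eps
                xm = x.copy(); xm[k, dim] -= eps
                num = (em.energy_grad(xp, False)["total"]
                       - em.energy_grad(xm, False)["total"]) / (2 * eps)
                assert g[k, dim] == pytest.approx(num, abs=1e-5)

    def test_single_violated_bound_energy(self, helix30):
        from distfold.structio import cb_distance_matrix
        d = cb_distance_matrix(helix30)
        i, j = 0, 6
        # a bound violated by exactly 1 A with unit weight -> energy 1
        lo = d[i, j] - 3.0
        hi = d[i, j] - 1.0
        rset = RestraintSet(bounds=[DistanceBound(i + 1, j + 1, lo, hi, 0.9)])
        cfg = BuilderConfig(restraint_margin=0.0)
        terms = energy_breakdown(helix30, rset, cfg)
        assert terms["distance"] == pytest.approx(1.0, abs=1e-9)

    def test_energy_terms_nonnegative_and_sum(self, toy_fold_small,
                                              zero_noise_oracle):
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        terms = energy_breakdown(toy_fold_small, rset)
        assert all(v >= 0 for k, v in terms.items() if k != "total")
        assert terms["total"] == pytest.approx(
            sum(v for k, v in terms.items() if k != "total"))


class TestRefine:
    def test_native_start_stays_put(self, toy_fold_small, zero_noise_oracle):
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        out = refine(toy_fold_small.copy(), rset, quick_cfg(), rng_seed=0)
        # only hairline margin-narrowing residuals may remain
        assert out.energy["distance"] <= 0.01
        _, rmsd = kabsch(out.ca, toy_fold_small.ca)
        assert rmsd <= 0.5

    def test_checkpoints_non_increasing_within_stage(self, toy_fold_small,
                                                     zero_noise_oracle):
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        lower, upper = smooth_bounds(rset.bounds, len(toy_fold_small),
                                     chain_upper=6.9, chain_lower=3.8)
        ca = embed_initial(lower, upper, rng_seed=1)
        _, checkpoints = refine(ca, rset, quick_cfg(),
                                sequence=toy_fold_small.sequence,
                                rng_seed=1, return_checkpoints=True)
        for stage in checkpoints:
            for a, b in zip(stage, stage[1:]):
                assert b <= a + 1e-9

    def test_deterministic(self, toy_fold_small, zero_noise_oracle):
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        a = refine(toy_fold_small.copy(), rset, quick_cfg(), rng_seed=5)
        b = refine(toy_fold_small.copy(), rset, quick_cfg(), rng_seed=5)
        np.testing.assert_array_equal(a.ca, b.ca)
        assert a.energy == b.energy


class TestMirrorDiscrimination:
    def test_mirror_energies(self, toy_fold_small, zero_noise_oracle):
        """Reflection preserves every pairwise distance, so the distance
        term is identical; the chirality term is strictly higher for the
        mirror of a refined right-handed model."""
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        model = refine(toy_fold_small.copy(), rset, quick_cfg(), rng_seed=0)
        mirrored = model.mirrored()
        e = energy_breakdown(model, rset)
        em = energy_breakdown(mirrored, rset)
        assert em["distance"] == pytest.approx(e["distance"], abs=1e-9)
        assert em["hbond"] == pytest.approx(e["hbond"], abs=1e-9)
        assert em["chirality"] > e["chirality"] + 1.0

    def test_trace_handedness_penalty_flips(self, helix30):
        plain = trace_handedness_penalty(helix30.ca)
        mirror = trace_handedness_penalty(helix30.ca * np.array([1, 1, -1.0]))
        assert plain == pytest.approx(0.0, abs=1e-9)
        assert mirror > 1.0


class TestEnsemble:
    def test_single_model(self, toy_fold_small, zero_noise_oracle):
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        ens = build_ensemble(rset, quick_cfg(ensemble_size=1),
                             toy_fold_small.sequence)
        assert len(ens) == 1

    def test_deterministic(self, toy_fold_small, zero_noise_oracle):
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        cfg = quick_cfg(ensemble_size=2, rng_seed=11)
        a = build_ensemble(rset, cfg, toy_fold_small.sequence)
        b = build_ensemble(rset, cfg, toy_fold_small.sequence)
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.ca, mb.ca)

    def test_sorted_by_energy(self, toy_fold_small, zero_noise_oracle):
        rset = zero_noise_restraints(toy_fold_small, zero_noise_oracle)
        ens = build_ensemble(rset, quick_cfg(ensemble_size=3),
                             toy_fold_small.sequence)
        energies = [m.energy["total"] for m in ens.models]
        assert energies == sorted(energies)

    def test_backbone_on_trace_geometry(self, toy_fold_small):
        m = backbone_on_trace(toy_fold_small.sequence, toy_fold_small.ca)
        np.testing.assert_array_equal(m.ca, toy_fold_small.ca)
        assert np.all(np.isfinite(m.n)) and np.all(np.isfinite(m.o))
        # glycine-free sequence: CB present everywhere
        assert np.all(np.isfinite(m.cb))
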