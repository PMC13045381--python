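"""Fixture construction, latent simulation, Brownian toy, toy complexes."""

import numpy as np
import pytest

from openmsm import (
    KineticFixture,
    ToyComplexSpec,
    ToyLandscape,
    build_fixture,
    build_toy_complex,
    simulate_brownian,
    simulate_latent,
)
from openmsm.synthetic import kramers_escape_time, mfpt_frames, mfpt_matrix_frames


class TestBuildFixture:
    def test_popc_stationary_matches_reported_percentages(self, popc_fixture):
        raw = np.array([19.9, 19.5, 53.2, 7.3])  # printed values sum to 99.9
        np.testing.assert_allclose(popc_fixture.stationary, raw / raw.sum(), atol=1e-12)
        assert abs(popc_fixture.stationary.sum() - 1.0) < 1e-12

    def test_pops_stationary_renormalized(self, pops_fixture):
        raw = np.array([0.5, 0.3, 39.8, 59.2])
        np.testing.assert_allclose(pops_fixture.stationary, raw / raw.sum(), atol=1e-12)

    @pytest.mark.parametrize("name", ["popc", "pops"])
    def test_detailed_balance(self, name):
        f = build_fixture(name)
        flux = f.stationary[:, None] * f.transition_matrix
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_accessibility_means_strictly_increasing_popc(self, popc_fixture):
        acc = popc_fixture.emission_means[:, popc_fixture.accessibility_dim]
        assert np.all(np.diff(acc) > 0)
        np.testing.assert_allclose(acc, [20.0, 27.5, 65.0, 100.0])

    def test_pops_accessibility_centers(self, pops_fixture):
        acc = pops_fixture.emission_means[:, pops_fixture.accessibility_dim]
        np.testing.assert_allclose(acc, [20.0, 20.0, 50.0, 75.0])

    def test_pops_io_eo_mfpt_below_half_microsecond(self, pops_fixture):
        M = pops_fixture.mfpt_matrix_us()
        assert max(M[2, 3], M[3, 2]) < 0.5

    def test_popc_mfpt_anchors(self, popc_fixture):
        M = popc_fixture.mfpt_matrix_us()
        assert 20.0 / 1.5 < M[0, 3] < 20.0 * 1.5  # Closed -> Eo ~ 20 us
        compact = M[:3, :3][~np.eye(3, dtype=bool)]
        assert np.all(compact <= 4.1)  # rapid exchange among compact states

    def test_time_scale_multiplies_mfpts_exactly(self):
        base = build_fixture("popc", 1.0)
        scaled = build_fixture("popc", 0.25)
        np.testing.assert_allclose(
            scaled.mfpt_matrix_us(), 0.25 * base.mfpt_matrix_us(), rtol=1e-12
        )
        np.testing.assert_allclose(scaled.transition_matrix, base.transition_matrix)

    def test_unknown_name_and_bad_scale_rejected(self):
        with pytest.raises(ValueError):
            build_fixture("dopc")
        with pytest.raises(ValueError):
            build_fixture("popc", time_scale=0.0)


class TestMfptOracle:
    def test_two_state_closed_form(self):
        T = np.array([[0.9, 0.1], [0.5, 0.5]])
        assert mfpt_frames(T, 0, 1) == pytest.approx(10.0)
        assert mfpt_frames(T, 1, 0) == pytest.approx(2.0)

    def test_matrix_against_simulation(self, rng):
        T = np.array([[0.8, 0.15, 0.05], [0.1, 0.85, 0.05], [0.2, 0.2, 0.6]])
        M = mfpt_matrix_frames(T)
        n_chains = 20_000
        state = np.zeros(n_chains, dtype=int)
        cum = np.cumsum(T, axis=1)
        hit = np.full(n_chains, -1)
        for t in range(1, 2000):
            state = (rng.random(n_chains)[:, None] > cum[state]).sum(axis=1)
            newly = (state == 1) & (hit < 0)
            hit[newly] = t
            if (hit > 0).all():
                break
        sim = hit[hit > 0].mean()
        se = hit[hit > 0].std() / np.sqrt((hit > 0).sum())
        assert abs(sim - M[0, 1]) < 3 * se + 0.05


class TestSimulateLatent:
    def test_identity_chain_freezes_labels(self, popc_fixture):
        frozen = KineticFixture(
            name="frozen",
            state_names=popc_fixture.state_names,
            transition_matrix=np.eye(4),
            stationary=popc_fixture.stationary,
            frame_interval=1.0,
            emission_means=popc_fixture.emission_means,
            emission_sds=popc_fixture.emission_sds,
        )
        trajs = simulate_latent(frozen, n_frames=50, n_traj=5, seed=9)
        for t in trajs:
            assert np.all(t.macrostate_labels == t.macrostate_labels[0])

    def test_occupancy_converges_to_stationary(self, popc_fixture):
        trajs = simulate_latent(popc_fixture, n_frames=200_000, n_traj=1, seed=5)
        occ = np.bincount(trajs[0].macrostate_labels, minlength=4) / 200_000
        # binomial SE inflated by the chain correlation time (~60 frames)
        n_eff = 200_000 / 120
        se = np.sqrt(popc_fixture.stationary * (1 - popc_fixture.stationary) / n_eff)
        assert np.all(np.abs(occ - popc_fixture.stationary) < 3 * se + 0.005)

    def test_convergence_rate_improves_with_n(self, popc_fixture):
        errs = []
        for n in (5_000, 80_000):
            t = simulate_latent(popc_fixture, n_frames=n, n_traj=4, seed=11)
            occ = np.bincount(
                np.concatenate([x.macrostate_labels for x in t]), minlength=4
            ) / (4 * n)
            errs.append(np.abs(occ - popc_fixture.stationary).max())
        assert errs[1] < errs[0]

    def test_per_state_feature_means(self, small_latents, popc_fixture):
        labels = np.concatenate([t.macrostate_labels for t in small_latents])
        feats = np.concatenate([t.features for t in small_latents])
        for s in range(4):
            sel = labels == s
            if sel.sum() < 100:
                continue
            mean = feats[sel].mean(axis=0)
            sd = popc_fixture.emission_sds[s]
            se = sd / np.sqrt(sel.sum() / 20)  # AR(0.9) -> ~19x variance inflation
            assert np.all(np.abs(mean - popc_fixture.emission_means[s]) < 4 * se + 0.3)

    def test_bitwise_reproducibility(self, popc_fixture):
        a = simulate_latent(popc_fixture, 100, 3, seed=7)
        b = simulate_latent(popc_fixture, 100, 3, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.features, y.features)
            assert np.array_equal(x.macrostate_labels, y.macrostate_labels)

    def test_requires_explicit_seed_and_valid_counts(self, popc_fixture):
        with pytest.raises(ValueError):
            simulate_latent(popc_fixture, 100, 2, seed=None)
        with pytest.raises(ValueError):
            simulate_latent(popc_fixture, 1, 2, seed=0)


class TestBrownian:
    def make_double_well(self, depth=5.0, **kw):
        return ToyLandscape(
            well_centers=[(-1.0, 0.0), (1.0, 0.0)],
            well_depths=[depth, depth],
            barrier_widths=[0.45, 0.45],
            **kw,
        )

    def test_zero_temperature_stays_at_center(self):
        # wells far enough apart that the cross-well pull is numerically zero
        land = ToyLandscape(
            well_centers=[(0.0, 0.0), (50.0, 0.0)],
            well_depths=[5.0, 5.0],
            barrier_widths=[1.0, 1.0],
        )
        traj = simulate_brownian(land, 100, kT=0.0, seed=1, start=(0.0, 0.0))
        np.testing.assert_allclose(traj, np.zeros((101, 2)), atol=1e-12)

    def test_equipartition_in_harmonic_well(self):
        # deep well: the walker stays harmonic near the bottom (the
        # Gaussian well softens at ~3 sigma, a ~1-2% variance inflation)
        land = ToyLandscape(
            well_centers=[(0.0, 0.0), (50.0, 0.0)],
            well_depths=[100.0, 100.0],
            barrier_widths=[1.0, 1.0],
            timestep=5e-5,
        )
        kT = 1.0
        traj = simulate_brownian(land, 400_000, kT=kT, seed=2, start=(0.0, 0.0))
        var = traj[2000:, 0].var()
        assert var == pytest.approx(kT / land.stiffness(0), rel=0.08)

    def test_escape_time_order_of_magnitude_vs_kramers(self):
        land = self.make_double_well(depth=3.0, timestep=5e-4)
        tau_pred = kramers_escape_time(land, 0, kT=1.0)
        escapes = []
        for seed in range(40):
            traj = simulate_brownian(land, 30_000, kT=1.0, seed=seed, start=(-1.0, 0.0))
            crossed = np.flatnonzero(traj[:, 0] > 0.5)
            escapes.append(crossed[0] * land.timestep if len(crossed) else np.nan)
        tau_sim = np.nanmean(escapes)
        assert np.isfinite(tau_sim)
        assert tau_pred / 10 < tau_sim < tau_pred * 10

    def test_divergence_aborts(self):
        land = self.make_double_well()
        land.timestep = 10.0  # drift per step above barrier width
        with pytest.raises(ValueError):
            simulate_brownian(land, 10, kT=1.0, seed=0, start=(0.0, 0.0))


class TestToyComplex:
    def test_placed_lipid_within_cutoff_is_contact(self):
        from openmsm import count_lipid_contacts

        frame = build_toy_complex(
            ToyComplexSpec(lipid_counts={}, explicit_lipids=[]), seed=1
        )
        crd_atom = frame.coords[frame.select(molecule_class="CrD")][0]
        spec = ToyComplexSpec(
            lipid_counts={},
            explicit_lipids=[("POPS", crd_atom + np.array([3.9, 0, 0]))],
        )
        frame = build_toy_complex(spec, seed=1)
        assert count_lipid_contacts(frame, "CrD", species_filter="POPS") == 1

    def test_fab_above_slab_never_clashes(self):
        from openmsm import membrane_clash

        spec = ToyComplexSpec(fab_size=10, fab_offset=(0, 0, 200.0))
        frame = build_toy_complex(spec, seed=2)
        flag, count = membrane_clash(frame, "fab")
        assert flag is False and count == 0

    def test_determinism_and_molecule_partition(self):
        a = build_toy_complex(ToyComplexSpec(fab_size=8), seed=5)
        b = build_toy_complex(ToyComplexSpec(fab_size=8), seed=5)
        assert np.array_equal(a.coords, b.coords)
        # molecule ids partition atoms: every atom belongs to exactly one id
        assert a.molecule_id.min() == 0
        assert len(np.unique(a.molecule_id)) == a.molecule_id.max() + 1
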