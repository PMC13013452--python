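"""Monte Carlo inversion: sampling, NNLS weighting, search, bootstrap."""

import numpy as np
import pytest

import mdrc
from mdrc.forward import IDX
from mdrc.inversion import mutate_components, voxel_rng

from conftest import weighted_median


FAST = dict(n_proliferation=8, n_mutation=8, n_in=60, n_bootstrap=4)


class TestSampleComponents:
    def test_within_limits_and_d0_dominates(self, limits, rng):
        p = mdrc.sample_components(limits, 200, rng)
        assert p.shape == (200, 9)
        assert limits.contains(p).all()
        assert np.all(p[:, IDX["D0"]] >= p[:, IDX["D_par"]] - 1e-30)
        assert np.all(p[:, IDX["D0"]] >= p[:, IDX["D_perp"]] - 1e-30)
        assert np.all((p[:, IDX["theta"]] >= 0)
                      & (p[:, IDX["theta"]] <= np.pi / 2 + 1e-12))

    def test_degenerate_point_limits(self, rng):
        lim = mdrc.InversionLimits(d_min=1e-9, d_max=1e-9, gamma_min=100,
                                   gamma_max=100, r1_min=1, r1_max=1,
                                   r2_min=10, r2_max=10)
        p = mdrc.sample_components(lim, 5, rng)
        np.testing.assert_allclose(p[:, IDX["D0"]], 1e-9)
        np.testing.assert_allclose(p[:, IDX["R2"]], 10.0)

    def test_log_uniform_median(self, limits):
        # log-median of D0 approaches the geometric mean of the bounds;
        # D0 is the max of three log-uniform draws so test a plain column
        rng = np.random.default_rng(0)
        p = mdrc.sample_components(limits, 100_000, rng)
        geo = np.sqrt(limits.r2_min * limits.r2_max)
        assert np.median(p[:, IDX["R2"]]) == pytest.approx(geo, rel=0.05)

    def test_mutation_respects_limits(self, limits, rng):
        p = mdrc.sample_components(limits, 100, rng)
        q = mutate_components(p, 0.5, limits, rng)
        assert limits.contains(q).all()
        assert np.all(q[:, IDX["D0"]] >= q[:, IDX["D_par"]] - 1e-30)


class TestFitWeights:
    def test_single_known_component_recovered(self, protocol, rng,
                                              single_component_truth):
        params, w_true = single_component_truth
        data = mdrc.signal(params, w_true * 0.8, protocol)
        candidates = np.vstack([params,
                                mdrc.sample_components(
                                    mdrc.InversionLimits(), 30, rng)])
        w, resid = mdrc.fit_weights(candidates, protocol, data)
        assert w[0] == pytest.approx(0.8, rel=1e-6)
        assert np.all(w[1:] < 1e-8 * 0.8)
        assert resid < 1e-8

    def test_two_separated_components(self, protocol, rng):
        a = np.array([[0.6e-9, 0.1e-9, 1.0, 0.5, 0.7e-9, 5e4, 5e4, 1.2, 35]])
        b = np.array([[2e-9, 2e-9, 0.0, 0.0, 2.1e-9, 5e4, 5e4, 0.35, 4.0]])
        data = mdrc.signal(np.vstack([a, b]), [0.6, 0.4], protocol)
        cands = np.vstack([a, b, mdrc.sample_components(
            mdrc.InversionLimits(), 20, rng)])
        w, _ = mdrc.fit_weights(cands, protocol, data)
        assert w[0] == pytest.approx(0.6, rel=1e-4)
        assert w[1] == pytest.approx(0.4, rel=1e-4)

    def test_zero_data_zero_weights(self, protocol, rng):
        cands = mdrc.sample_components(mdrc.InversionLimits(), 10, rng)
        w, _ = mdrc.fit_weights(cands, protocol, np.zeros(len(protocol)))
        np.testing.assert_array_equal(w, 0.0)

    def test_nan_data_rejected(self, protocol, rng):
        cands = mdrc.sample_components(mdrc.InversionLimits(), 5, rng)
        bad = np.zeros(len(protocol))
        bad[3] = np.nan
        with pytest.raises(ValueError):
            mdrc.fit_weights(cands, protocol, bad)

    def test_length_mismatch(self, protocol, rng):
        cands = mdrc.sample_components(mdrc.InversionLimits(), 5, rng)
        with pytest.raises(ValueError):
            mdrc.fit_weights(cands, protocol, np.zeros(3))


class TestInvertVoxel:
    def test_residual_monotone_and_limits(self, protocol, limits,
                                          single_component_truth):
        params, w_true = single_component_truth
        data = mdrc.signal(params, w_true, protocol)
        cfg = mdrc.InversionConfig(seed=0, **FAST)
        hist = []
        out_p, out_w = mdrc.invert_voxel(protocol, data, limits, cfg,
                                         np.random.default_rng(0),
                                         history=hist)
        assert len(hist) == cfg.n_proliferation + cfg.n_mutation
        assert np.all(np.diff(hist) <= 1e-12)
        assert limits.contains(out_p).all()
        assert np.all(out_w > 0)
        assert len(out_w) <= cfg.n_out

    def test_free_water_voxel_isotropic(self, protocol, limits):
        # pure fast isotropic voxel: recovered mode has negligible
        # anisotropy
        fw = np.array([[2e-9, 2e-9, 0.0, 0.0, 2.1e-9, 5e4, 5e4, 0.35, 4.0]])
        data = mdrc.signal(fw, [1.0], protocol)
        cfg = mdrc.InversionConfig(seed=1, **FAST)
        p, w = mdrc.invert_voxel(protocol, data, limits, cfg,
                                 np.random.default_rng(1))
        m = mdrc.shape_metrics(p, float(np.percentile(protocol.omega, 10)))
        assert weighted_median(m["D_delta_sq"], w) < 0.05

    def test_too_few_rows(self, limits):
        p = mdrc.Protocol(b=[0.0], b_delta=[0.0], theta=[0.0], phi=[0.0],
                          omega=[100.0], tau_r=[1.0], tau_e=[0.0])
        with pytest.raises(ValueError):
            mdrc.invert_voxel(p, np.zeros(1), limits,
                              mdrc.InversionConfig(), np.random.default_rng())

    def test_identifiability_improves_with_proliferation(
            self, protocol, limits, single_component_truth):
        # doubling the proliferation depth shrinks the median absolute
        # D_iso error over repeated seeds
        params, w_true = single_component_truth
        data = mdrc.signal(params, w_true, protocol)
        omega = float(np.percentile(protocol.omega, 10))
        truth = mdrc.shape_metrics(params, omega)["D_iso"][0]
        errors = {}
        for n_prolif in (2, 12):
            errs = []
            for seed in range(8):
                cfg = mdrc.InversionConfig(n_proliferation=n_prolif,
                                           n_mutation=4, n_in=60,
                                           seed=seed)
                p, w = mdrc.invert_voxel(protocol, data, limits, cfg,
                                         np.random.default_rng(seed))
                got = weighted_median(mdrc.shape_metrics(p, omega)["D_iso"],
                                      w)
                errs.append(abs(got - truth))
            errors[n_prolif] = np.median(errs)
        assert errors[12] < errors[2]


class TestBootstrapEnsemble:
    def test_seed_determinism(self, protocol, limits,
                              single_component_truth):
        params, w_true = single_component_truth
        data = mdrc.signal(params, w_true, protocol)
        cfg = mdrc.InversionConfig(seed=5, **FAST)
        a = mdrc.bootstrap_ensemble(protocol, data, limits, cfg)
        b = mdrc.bootstrap_ensemble(protocol, data, limits, cfg)
        assert a.S0 == b.S0
        for (pa, wa), (pb, wb) in zip(a.solutions, b.solutions):
            np.testing.assert_array_equal(pa, pb)
            np.testing.assert_array_equal(wa, wb)

    def test_single_bootstrap_structure(self, protocol, limits,
                                        single_component_truth):
        params, w_true = single_component_truth
        data = mdrc.signal(params, w_true, protocol)
        cfg = mdrc.InversionConfig(seed=2, n_bootstrap=1, n_proliferation=6,
                                   n_mutation=6, n_in=60)
        ens = mdrc.bootstrap_ensemble(protocol, data, limits, cfg)
        assert len(ens.solutions) == 1
        assert ens.S0 == pytest.approx(ens.solutions[0][1].sum())
        assert ens.n_components == len(ens.solutions[0][1])

    def test_noise_widens_bootstrap_spread(self, protocol, limits,
                                           single_component_truth):
        # parameter spread across bootstraps grows with measurement noise
        params, w_true = single_component_truth
        clean = mdrc.signal(params, w_true, protocol)
        noisy = mdrc.add_noise(clean, 20.0, seed=0)
        omega = float(np.percentile(protocol.omega, 10))
        spreads = {}
        for name, data in [("clean", clean), ("noisy", noisy)]:
            cfg = mdrc.InversionConfig(seed=3, n_bootstrap=8,
                                       n_proliferation=8, n_mutation=8,
                                       n_in=60)
            ens = mdrc.bootstrap_ensemble(protocol, data, limits, cfg)
            per_sol = [weighted_median(mdrc.shape_metrics(p, omega)["D_iso"],
                                       w)
                       for p, w in ens.solutions if len(w)]
            spreads[name] = np.std(per_sol)
        assert spreads["noisy"] > spreads["clean"]


class TestInvertImage:
    def _small_volume(self, protocol, rng):
        truth = mdrc.make_phantom((2, 2, 1), tissues=["gm_like", "fw_like"],
                                  seed=0)
        return mdrc.simulate_dataset(truth, protocol, snr=np.inf), truth

    def test_worker_count_invariance(self, protocol, limits, rng):
        vol, _ = self._small_volume(protocol, rng)
        cfg = mdrc.InversionConfig(seed=4, n_proliferation=4, n_mutation=4,
                                   n_in=40, n_bootstrap=2)
        serial = mdrc.invert_image(vol, protocol, limits, cfg, n_workers=1)
        parallel = mdrc.invert_image(vol, protocol, limits, cfg, n_workers=2)
        assert serial.keys() == parallel.keys()
        for ix in serial:
            for (pa, wa), (pb, wb) in zip(serial[ix].solutions,
                                          parallel[ix].solutions):
                np.testing.assert_array_equal(pa, pb)
                np.testing.assert_array_equal(wa, wb)

    def test_mask_respected(self, protocol, limits, rng):
        vol, _ = self._small_volume(protocol, rng)
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        cfg = mdrc.InversionConfig(seed=4, n_proliferation=3, n_mutation=3,
                                   n_in=30, n_bootstrap=1)
        out = mdrc.invert_image(vol, protocol, limits, cfg, mask=mask)
        assert list(out.keys()) == [(0, 0, 0)]

    def test_shape_mismatch_error(self, protocol, limits):
        with pytest.raises(ValueError):
            mdrc.invert_image(np.zeros((2, 2, 1, 7)), protocol, limits,
                              mdrc.InversionConfig())

    def test_voxel_rng_independent_of_order(self):
        a = voxel_rng(1, (0, 1, 2)).uniform(size=3)
        b = voxel_rng(1, (0, 1, 2)).uniform(size=3)
        c = voxel_rng(1, (2, 1, 0)).uniform(size=3)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)


class TestEstimatorInterface:
    def test_fit_transform_and_params(self, protocol, limits,
                                      single_component_truth):
        params, w_true = single_component_truth
        X = mdrc.signal(params, w_true, protocol)[None, :]
        est = mdrc.MonteCarloInverter(protocol=protocol, limits=limits,
                                      n_proliferation=4, n_mutation=4,
                                      n_in=40, n_bootstrap=2, random_state=0)
        got = est.get_params()
        assert got["n_bootstrap"] == 2
        est.set_params(n_bootstrap=3).fit(X)
        assert len(est.ensembles_) == 1
        assert len(est.ensembles_[0].solutions) == 3
        assert est.transform() is est.ensembles_

    def test_unfitted_transform_raises(self):
        with pytest.raises(AttributeError):
            mdrc.MonteCarloInverter().transform()
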