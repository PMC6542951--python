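import itertools
import math

import numpy as np
import pytest

import flairseg as fs
from flairseg.mrf import EnergyModel, _M
from oracles import (
    clique_config_counts_bruteforce,
    cliques_bruteforce,
    literal_total_energy,
    literal_voxel_energy,
    random_mrf_model,
    random_problem,
)


class TestAlpha:
    def test_clinical_flair_spacing(self):
        assert fs.compute_alpha((0.7, 0.7, 5.0)) == pytest.approx(0.14, rel=1e-12)

    def test_isotropic_spacing(self):
        assert fs.compute_alpha((1.0, 1.0, 1.0)) == 1.0

    def test_anisotropic_in_plane_rejected(self):
        with pytest.raises(ValueError, match="isotropic"):
            fs.compute_alpha((0.5, 1.0, 5.0))


class TestCliques:
    def test_in_plane_pairs(self):
        spec = fs.NeighborhoodSpec(through_plane="none", clique_sizes=(2,))
        cliques = fs.enumerate_cliques(spec)
        assert cliques.count(2) == 8

    def test_in_plane_quadruples_are_squares(self):
        spec = fs.NeighborhoodSpec(through_plane="none", clique_sizes=(4,))
        cliques = fs.enumerate_cliques(spec)
        assert cliques.count(4) == 4
        for members in cliques.by_size[4]:
            xs = {0} | {m[0] for m in members}
            ys = {0} | {m[1] for m in members}
            assert len(xs) == 2 and len(ys) == 2  # a 2x2 in-plane square

    @pytest.mark.parametrize("through_plane", ["none", "axial", "full"])
    def test_matches_subset_enumeration_oracle(self, through_plane):
        spec = fs.NeighborhoodSpec(through_plane=through_plane)
        cliques = fs.enumerate_cliques(spec)
        oracle = cliques_bruteforce(spec.offsets(), spec.adjacent)
        for k in (2, 3, 4):
            got = {frozenset(c) for c in cliques.by_size[k]}
            assert got == oracle[k]

    def test_no_duplicates_and_canonical_partition(self):
        cliques = fs.enumerate_cliques(fs.NeighborhoodSpec())
        for k, group in cliques.by_size.items():
            assert len(group) == len(set(group))
        # a physical size-k clique appears in the pattern list of each of its
        # k members and in exactly one canonical (lex-min center) pattern
        canonical = cliques.canonical_by_size()
        for k in cliques.sizes:
            assert len(cliques.by_size[k]) == k * len(canonical[k])


def _training_case(rng, shape=(10, 10, 4), spacing=(1.0, 1.0, 2.0)):
    """Labels covering all four classes with class-dependent intensities."""
    labels = rng.integers(0, 4, size=shape).astype(np.int16)
    means = np.array([30.0, 60.0, 90.0, 140.0])
    vol = fs.Volume(means[labels] + rng.normal(0, 5.0, shape), spacing)
    feats = fs.FeatureVolume(
        labels[..., None] * 1.0 + rng.normal(0, 0.5, shape + (2,)),
        spacing,
        (("r", 0, 0), ("r", 0, 1)),
    )
    return vol, feats, fs.LabelMap(labels, "quaternary", spacing)


class TestTraining:
    def test_recovers_class_intensity_means(self):
        rng = np.random.default_rng(20)
        cases = [_training_case(rng, shape=(20, 20, 10)) for _ in range(2)]
        model = fs.train_mrf(
            [c[0] for c in cases], [c[1] for c in cases], [c[2] for c in cases]
        )
        means = np.array([30.0, 60.0, 90.0, 140.0])
        for c in range(4):
            n_c = sum((case[2].labels == c).sum() for case in cases)
            se = 5.0 / math.sqrt(n_c)
            assert abs(model.intensity_mean[c] - means[c]) < 3 * se

    def test_delta_parameters_are_role_symmetric(self):
        rng = np.random.default_rng(21)
        vol, feats, labels = _training_case(rng)
        model = fs.train_mrf([vol], [feats], [labels])
        np.testing.assert_allclose(model.delta_mean, -model.delta_mean.T, atol=1e-9)
        np.testing.assert_allclose(model.delta_var, model.delta_var.T, atol=1e-9)

    def test_four_coloring_has_no_same_label_pairs(self):
        # (x + 2y) mod 4 gives every in-plane neighbor a different label
        shape = (12, 12, 1)
        x, y = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        labels = ((x + 2 * y) % 4).astype(np.int16)[:, :, None] * np.ones((1, 1, 1), np.int16)
        spec = fs.NeighborhoodSpec(through_plane="none")
        cliques = fs.enumerate_cliques(spec)
        counts = fs.clique_config_counts([labels], cliques)
        same = sum(counts[2][(c, c)] for c in range(4))
        assert same == 0
        oracle = clique_config_counts_bruteforce(labels, cliques.by_size)
        assert sum(oracle[2].get((c, c), 0) for c in range(4)) == 0

    def test_config_counts_match_bruteforce_oracle(self):
        rng = np.random.default_rng(22)
        labels = rng.integers(0, 4, size=(6, 6, 3)).astype(np.int16)
        labels[0, 0, 0] = -1  # a background voxel must drop its cliques
        cliques = fs.enumerate_cliques(fs.NeighborhoodSpec())
        counts = fs.clique_config_counts([labels], cliques)
        oracle = clique_config_counts_bruteforce(labels, cliques.by_size)
        for k in (2, 3, 4):
            for config, n in counts[k].items():
                assert n == oracle[k].get(config, 0)

    def test_missing_class_rejected_by_name(self):
        rng = np.random.default_rng(23)
        vol, feats, labels = _training_case(rng)
        lab = labels.labels.copy()
        lab[lab == fs.LES] = fs.WM
        with pytest.raises(ValueError, match="Les"):
            fs.train_mrf([vol], [feats], [fs.LabelMap(lab, "quaternary", labels.spacing)])

    def test_never_cooccurring_pair_with_zero_ridge_rejected(self):
        rng = np.random.default_rng(24)
        shape = (8, 8, 2)
        labels = np.zeros(shape, dtype=np.int16)
        labels[:2] = fs.CSF
        labels[2:4] = fs.GM
        labels[4:6] = fs.WM
        labels[6] = fs.BACKGROUND  # moat: Les never neighbors another class
        labels[7:] = fs.LES
        vol = fs.Volume(rng.uniform(0, 1, shape), (1, 1, 1))
        feats = fs.FeatureVolume(rng.uniform(0, 1, shape + (1,)), (1, 1, 1), (("r", 0, 0),))
        with pytest.raises(ValueError, match="never co-occurs"):
            fs.train_mrf([vol], [feats],
                         [fs.LabelMap(labels, "quaternary", (1, 1, 1))], ridge=0.0)


class TestInitialLabels:
    def _priors(self, shape, wm=0.9):
        p = np.zeros((4,) + shape)
        p[fs.CSF] = (1 - wm) / 2
        p[fs.GM] = (1 - wm) / 2
        p[fs.WM] = wm
        return fs.PriorMaps(p, (1, 1, 1))

    def test_lesion_overrides_priors(self):
        shape = (2, 2, 1)
        lesion = np.zeros(shape, dtype=np.int16)
        lesion[0, 0, 0] = 1
        out = fs.initial_labels(
            fs.LabelMap(lesion, "binary", (1, 1, 1)),
            self._priors(shape),
            fs.LabelMap(np.ones(shape, dtype=np.int16), "binary", (1, 1, 1)),
        )
        assert out.labels[0, 0, 0] == fs.LES
        assert out.labels[1, 1, 0] == fs.WM

    def test_outside_brain_gets_background_sentinel(self):
        shape = (2, 2, 1)
        brain = np.ones(shape, dtype=np.int16)
        brain[0, 0, 0] = 0
        out = fs.initial_labels(
            fs.LabelMap(np.zeros(shape, dtype=np.int16), "binary", (1, 1, 1)),
            self._priors(shape),
            fs.LabelMap(brain, "binary", (1, 1, 1)),
        )
        assert out.labels[0, 0, 0] == fs.BACKGROUND

    def test_exact_prior_tie_breaks_by_class_order(self):
        shape = (1, 1, 1)
        p = np.zeros((4,) + shape)
        p[fs.CSF] = p[fs.GM] = 0.5
        out = fs.initial_labels(
            fs.LabelMap(np.zeros(shape, dtype=np.int16), "binary", (1, 1, 1)),
            fs.PriorMaps(p, (1, 1, 1)),
            fs.LabelMap(np.ones(shape, dtype=np.int16), "binary", (1, 1, 1)),
        )
        assert out.labels[0, 0, 0] == fs.CSF


class TestVoxelEnergy:
    def test_single_voxel_closed_form(self):
        rng = np.random.default_rng(30)
        model = random_mrf_model(rng, D=2)
        vol, feats, priors = random_problem(rng, (1, 1, 1))
        model = model.with_priors(priors)
        c = 2
        labels = np.full((1, 1, 1), c, dtype=np.int64)
        got = fs.voxel_energy((0, 0, 0), labels, vol, feats, model)
        v = model.intensity_var[c]
        expected = 0.5 * (math.log(2 * math.pi * v)
                          + (vol.data[0, 0, 0] - model.intensity_mean[c]) ** 2 / v)
        cov = model.texture_cov[c]
        diff = feats.data[0, 0, 0] - model.texture_mean[c]
        expected += 0.5 * (2 * math.log(2 * math.pi)
                           + math.log(np.linalg.det(cov))
                           + diff @ np.linalg.solve(cov, diff))
        expected += -math.log(priors.data[c, 0, 0, 0])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_alpha_zero_removes_clique_potentials(self):
        rng = np.random.default_rng(31)
        spec = fs.NeighborhoodSpec(alpha=0.0)
        model = random_mrf_model(rng, D=2, spec=spec)
        vol, feats, priors = random_problem(rng, (3, 3, 2))
        model = model.with_priors(priors)
        other = random_mrf_model(rng, D=2, spec=spec)
        # same observation models, different configuration tables
        import dataclasses
        model2 = dataclasses.replace(model, config_tables=other.config_tables)
        labels = rng.integers(0, 4, (3, 3, 2))
        ws1 = EnergyModel(vol, feats, model, brain_mask=np.ones((3, 3, 2), bool))
        ws2 = EnergyModel(vol, feats, model2, brain_mask=np.ones((3, 3, 2), bool))
        for i in itertools.product(range(3), range(3), range(2)):
            q = np.ravel_multi_index(i, (3, 3, 2))
            e1 = ws1.voxel_energy(q, labels.ravel())
            e2 = ws2.voxel_energy(q, labels.ravel())
            assert e1 == pytest.approx(e2, abs=1e-12)

    @pytest.mark.parametrize("shape", [(2, 2, 2), (3, 3, 2)])
    def test_matches_literal_equation_oracle(self, shape):
        rng = np.random.default_rng(32)
        for _ in range(3):
            model = random_mrf_model(rng, D=2)
            vol, feats, priors = random_problem(rng, shape)
            model = model.with_priors(priors)
            alpha = fs.compute_alpha(vol.spacing)
            labels = rng.integers(0, 4, shape).astype(np.int64)
            for i in itertools.product(*(range(n) for n in shape)):
                got = fs.voxel_energy(i, labels, vol, feats, model)
                expected = literal_voxel_energy(
                    i, labels[i], labels, vol.data, feats.data, model,
                    priors.data, alpha,
                )
                assert got == pytest.approx(expected, abs=1e-9)
            got_total = fs.total_energy(labels, vol, feats, model)
            exp_total = literal_total_energy(
                labels, vol.data, feats.data, model, priors.data, alpha
            )
            assert got_total == pytest.approx(exp_total, abs=1e-9)


class TestICM:
    def _workspace(self, rng, shape=(6, 6, 3)):
        model = random_mrf_model(rng, D=2)
        vol, feats, priors = random_problem(rng, shape)
        ws = EnergyModel(vol, feats, model.with_priors(priors),
                         brain_mask=np.ones(shape, bool))
        return ws, shape

    def test_converged_labelling_is_a_fixed_point(self):
        rng = np.random.default_rng(40)
        ws, shape = self._workspace(rng)
        init = rng.integers(0, 4, np.prod(shape)).astype(np.int64)
        labels, trace = ws.icm(init, max_iter=30, seed=0)
        assert trace.converged
        again, trace2 = ws.icm(labels, max_iter=10, seed=1)
        assert trace2.n_sweeps == 1 and trace2.changes == [0]
        assert np.array_equal(again, labels)

    def test_energy_never_increases_across_sweeps(self):
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            ws, shape = self._workspace(rng)
            init = rng.integers(0, 4, np.prod(shape)).astype(np.int64)
            _, trace = ws.icm(init, max_iter=10, seed=s)
            energies = [trace.initial_energy] + trace.energies
            assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_final_energy_brackets_global_minimum_on_tiny_problem(self):
        rng = np.random.default_rng(41)
        model = random_mrf_model(rng, D=2)
        vol, feats, priors = random_problem(rng, (2, 2, 2))
        ws = EnergyModel(vol, feats, model.with_priors(priors),
                         brain_mask=np.ones((2, 2, 2), bool))
        batch = np.array(list(itertools.product(range(4), repeat=8)), dtype=np.int64)
        global_min = ws.total_energy_batch(batch).min()
        for s in range(5):
            init = np.random.default_rng(s).integers(0, 4, 8).astype(np.int64)
            e0 = ws.total_energy(init)
            _, trace = ws.icm(init, max_iter=10, seed=s)
            assert global_min - 1e-9 <= trace.energies[-1] <= e0 + 1e-9

    def test_max_iter_caps_sweeps(self):
        rng = np.random.default_rng(42)
        ws, shape = self._workspace(rng)
        init = rng.integers(0, 4, np.prod(shape)).astype(np.int64)
        _, trace = ws.icm(init, max_iter=2, seed=0)
        assert trace.n_sweeps <= 2


class TestSegment:
    def test_deterministic_end_to_end(self, mini_cohort, mini_bank, trained_mini):
        case = mini_cohort[0]
        kwargs = dict(brain_mask=case.brain_mask, max_iter=5, seed=9)
        m1 = fs.segment(case.flair, case.priors, mini_bank,
                        trained_mini["bayes"], trained_mini["mrf"], **kwargs)
        m2 = fs.segment(case.flair, case.priors, mini_bank,
                        trained_mini["bayes"], trained_mini["mrf"], **kwargs)
        assert np.array_equal(m1.labels, m2.labels)

    def test_recovers_phantom_lesion(self, mini_cohort, mini_bank, trained_mini):
        case = mini_cohort[1]
        mask = fs.segment(case.flair, case.priors, mini_bank,
                          trained_mini["bayes"], trained_mini["mrf"],
                          brain_mask=case.brain_mask, seed=2)
        dice, _, _ = fs.overlap_metrics(mask, case.lesion_mask)
        assert dice > 0.7

    def test_model_yaml_roundtrip(self, trained_mini, tmp_path):
        model = trained_mini["mrf"]
        path = tmp_path / "mrf.yaml"
        model.to_yaml(path)
        back = fs.MRFModel.from_yaml(path)
        np.testing.assert_allclose(back.intensity_mean, model.intensity_mean)
        np.testing.assert_allclose(back.texture_cov, model.texture_cov)
        np.testing.assert_allclose(back.delta_mean, model.delta_mean)
        for k in model.config_tables:
            for cfg, p in model.config_tables[k].items():
                assert back.config_tables[k][cfg] == pytest.approx(p)
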