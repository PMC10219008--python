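"""Architecture handling, network forward/backward, training, search."""

import numpy as np
import pytest

from modsense import model as M
from modsense import synthetic_data as S

SR = 8000.0


def micro_corpus(seed=5, n=16, centers=(16.0, 64.0), tilts=(-8.0, 8.0)):
    spec = S.SyntheticCorpusSpec(
        n_categories=len(centers), clips_per_category=n, sample_rate=SR,
        clip_duration_s=0.25, noise_floor=0.02,
        categories=tuple(S.CategoryParams(c, 0.3, 1.0, t)
                         for c, t in zip(centers, tilts)),
        rng_seed=seed)
    return S.generate_corpus(spec)


def tiny_arch(n_categories=2, units=16):
    return M.Architecture(n_layers=2, units_per_layer=units, filter_sizes=(5, 5),
                          dilations=(40, 60), n_categories=n_categories,
                          input_window_samples=600)


class TestReceptiveField:
    def test_all_unit_filters_give_one(self):
        a = M.Architecture(2, 16, (1, 1), (3, 9), 2, 100)
        assert M.receptive_field(a) == 1

    def test_single_layer_formula(self):
        a = M.Architecture(2, 16, (3, 1), (10, 1), 2, 100)
        assert M.receptive_field(a) == 21

    def test_reference_architectures_fit_the_200ms_window(self):
        # oracle: sum the printed per-layer (k-1)*d terms directly
        for arch in M.REFERENCE_ARCHITECTURES:
            expected = 1 + sum((k - 1) * d for k, d in
                               zip(arch.filter_sizes, arch.dilations))
            assert M.receptive_field(arch) == expected
            assert expected <= 8820  # 0.2 s at 44.1 kHz

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            M.Architecture(1, 16, (0,), (1,), 2, 100)

    def test_overlarge_receptive_field_rejected(self):
        with pytest.raises(ValueError):
            M.Architecture(1, 16, (5,), (100,), 2, 100)


class TestSampleArchitecture:
    def test_samples_always_satisfy_constraint(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            nl = int(rng.choice(M.ALLOWED_N_LAYERS))
            a = M.sample_architecture(nl, 8820, rng)
            assert M.receptive_field(a) <= 8820
            assert all(2 <= k <= 8 for k in a.filter_sizes)
            assert a.units_per_layer in M.ALLOWED_UNITS

    def test_deterministic_for_fixed_seed(self):
        a = M.sample_architecture(13, 8820, rng_seed=11)
        b = M.sample_architecture(13, 8820, rng_seed=11)
        assert a == b

    def test_disallowed_layer_count_rejected(self):
        with pytest.raises(ValueError):
            M.sample_architecture(5, 8820, 0)

    def test_unsatisfiable_window_rejected(self):
        with pytest.raises(ValueError):
            M.sample_architecture(13, 10, 0)


class TestForward:
    def test_zero_weight_model_gives_zero_activity_and_uniform_softmax(self):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=0)
        for w in net.weights:
            w[:] = 0
        net.w_cls[:] = 0
        scores, recorded = net.forward(np.ones(1000), record_layers=(1, 2))
        assert all(np.all(r.activity == 0) for r in recorded)
        p = np.exp(scores) / np.exp(scores).sum(axis=0)
        assert np.allclose(p, 1 / net.architecture.n_categories)

    def test_elu_definition(self):
        z = np.array([-2.0, -0.5, 0.5, 3.0])
        out = M._elu(z)
        assert np.allclose(out[z > 0], z[z > 0])
        assert np.allclose(out[z <= 0], np.expm1(z[z <= 0]))

    def test_translation_equivariance_in_interior(self):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=1)
        x = np.random.default_rng(2).standard_normal(1200)
        shift = 7
        _, (r0,) = net.forward(x, record_layers=(2,))
        _, (r1,) = net.forward(x[shift:], record_layers=(2,))
        assert np.allclose(r0.activity[:, shift:], r1.activity, atol=1e-10)

    def test_too_short_input_rejected(self):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros(net.receptive_field - 1))

    def test_classification_layer_not_recordable(self):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros(1000), record_layers=(3,))

    def test_activation_time_extent_is_input_minus_trim(self):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=0)
        n = 900
        _, (r1, r2) = net.forward(np.zeros(n), record_layers=(1, 2))
        assert r1.activity.shape == (16, n - 4 * 40)
        assert r2.activity.shape == (16, n - 4 * 40 - 4 * 60)


class TestEvaluateRecognition:
    class OneHotNet:
        """Always outputs the clip's true category with margin."""
        def __init__(self, labels):
            self.labels, self.i = labels, 0
        def forward(self, clip, record_layers=(), stimulus_id=""):
            scores = np.zeros((3, 5))
            scores[self.labels[self.i]] = 1.0
            self.i += 1
            return scores, []

    def test_perfect_scorer_gets_accuracy_one(self):
        labels = [0, 2, 1, 1]
        net = self.OneHotNet(labels)
        assert M.evaluate_recognition(net, [None] * 4, labels) == 1.0

    def test_single_frame_equals_per_frame_argmax(self):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=3)
        clip = np.random.default_rng(0).standard_normal(net.receptive_field)
        scores, _ = net.forward(clip)
        assert scores.shape[1] == 1
        acc = M.evaluate_recognition(net, [clip], [int(np.argmax(scores[:, 0]))])
        assert acc == 1.0

    def test_span_outside_clip_rejected(self):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=3)
        clip = np.zeros(1000)
        with pytest.raises(ValueError):
            M.evaluate_recognition(net, [clip], [0], segment_spans=[[(0, 10**6)]])

    def test_chance_level_arithmetic(self):
        assert M.chance_level(50) == 0.02
        assert round(M.chance_level(39), 3) == 0.026


class TestTraining:
    def test_patience_one_with_no_improvement_stops_after_two_epochs(self):
        corpus = micro_corpus(n=6)
        up_c, up_l = corpus.split("update")
        es_c, es_l = corpus.split("early_stop")
        net = M.DilatedConvNet(tiny_arch(), rng_seed=0)
        cfg = M.TrainingConfig(learning_rate=1e-30, patience_epochs=1,
                               max_epochs=50, rng_seed=0)
        tm = M.train(net, up_c, up_l, es_c, es_l, cfg)
        # frozen loss: epoch 1 sets the best, epoch 2 fails to improve
        assert len(tm.training_log) == 2

    def test_empty_split_rejected(self):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=0)
        with pytest.raises(ValueError):
            M.train(net, [], [], [np.zeros(700)], [0], M.TrainingConfig())

    def test_untrained_model_near_chance(self):
        corpus = micro_corpus(seed=9, n=20)
        clips = corpus.clips
        labels = corpus.manifest["category"].to_numpy()
        accs = [M.evaluate_recognition(M.DilatedConvNet(tiny_arch(), rng_seed=s),
                                       clips, labels) for s in range(6)]
        assert abs(np.mean(accs) - 0.5) < 0.25

    def test_training_improves_over_nonoptimized(self):
        # paired over 3 seeds on the same AM-separable corpus
        wins = 0
        for seed in range(3):
            corpus = micro_corpus(seed=seed, n=16)
            up_c, up_l = corpus.split("update")
            es_c, es_l = corpus.split("early_stop")
            va_c, va_l = corpus.split("validation")
            net = M.DilatedConvNet(tiny_arch(), rng_seed=seed)
            before = M.evaluate_recognition(net, va_c, va_l)
            cfg = M.TrainingConfig(learning_rate=3e-3, patience_epochs=8,
                                   max_epochs=30, windows_per_clip=4,
                                   batch_size=32, rng_seed=seed)
            tm = M.train(net, up_c, up_l, es_c, es_l, cfg)
            after = M.evaluate_recognition(tm, va_c, va_l)
            wins += int(after > before)
        assert wins >= 2

    def test_checkpoint_roundtrip(self, tmp_path):
        net = M.DilatedConvNet(tiny_arch(), rng_seed=4)
        net.save(tmp_path / "ckpt.npz")
        loaded = M.DilatedConvNet.load(tmp_path / "ckpt.npz")
        assert loaded.architecture == net.architecture
        x = np.random.default_rng(1).standard_normal(800)
        assert np.allclose(loaded.forward(x)[0], net.forward(x)[0])


class TestArchitectureSearch:
    def test_better_group_wins_controlled_search(self):
        corpus = micro_corpus(seed=5, n=16)
        up_c, up_l = corpus.split("update")
        es_c, es_l = corpus.split("early_stop")
        good = [M.Architecture(2, 16, (5, 5), (40, 60), 2, 600),
                M.Architecture(2, 16, (5, 5), (30, 50), 2, 600)]
        # receptive field of one sample: cannot integrate envelope at all
        bad = [M.Architecture(2, 16, (1, 1), (1, 1), 2, 600),
               M.Architecture(2, 16, (1, 1), (1, 2), 2, 600)]
        cfg = M.TrainingConfig(learning_rate=3e-3, patience_epochs=4,
                               max_epochs=15, windows_per_clip=4,
                               batch_size=32, rng_seed=0)
        winners = M.architecture_search(
            up_c, up_l, es_c, es_l, input_window_samples=600, n_categories=2,
            rng_seed=0, candidates={2: good, 9: bad}, best_k=2,
            patience_step1=3, patience_step2=6, config=cfg)
        assert len(winners) == 2
        assert all(w.architecture.filter_sizes == (5, 5) for w in winners)
        assert winners[0].best_accuracy >= winners[1].best_accuracy

    def test_fewer_candidates_than_best_k_rejected(self):
        with pytest.raises(ValueError):
            M.architecture_search([], [], [], [], 600, 2, 0,
                                  candidates={2: []}, best_k=2)
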