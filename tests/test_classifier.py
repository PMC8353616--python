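import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpas.annotation import PASRecord, PASSet
from scpas.classifier import (
    SequenceExample,
    decode_one_hot,
    encode_batch,
    evaluate_internal_priming,
    evaluate_position_tolerance,
    extract_filter_motifs,
    make_fixed_positives,
    make_shifted_positives,
    one_hot,
    predict,
    sample_negatives,
    train,
)
from scpas.nn import ModelSpec, SequenceClassifier, cross_entropy
from scpas.simulate import SimulationConfig, simulate_genome


class TestOneHot:
    @pytest.mark.parametrize(
        "base,row",
        [("A", (1, 0, 0, 0)), ("T", (0, 1, 0, 0)), ("G", (0, 0, 1, 0)),
         ("C", (0, 0, 0, 1)), ("N", (0, 0, 0, 0))],
    )
    def test_channel_order(self, base, row):
        mat = one_hot(base * 200)
        assert tuple(mat[0]) == row

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            one_hot("X" * 200)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            one_hot("ACGT")

    @given(st.text(alphabet="ACGT", min_size=200, max_size=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_decode_inverts_encode(self, seq):
        assert decode_one_hot(one_hot(seq)) == seq


class TestGradient:
    def test_backprop_matches_numerical_gradient(self):
        spec = ModelSpec(seq_len=24, conv1_filters=5, conv1_width=4, conv2_filters=4,
                         conv2_width=3, pool=2, lstm_units=3, dense_units=6, dropout=0.0)
        model = SequenceClassifier(spec, seed=1)
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(3, 24, 4))
        y = np.array([0, 1, 1])
        probs, cache = model.forward(x)
        grads = model.backward(probs, y, cache)

        def loss():
            p, _ = model.forward(x)
            return cross_entropy(p, y)

        eps = 1e-6
        for name, grad in grads.items():
            arr = model.params[name]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss()
                arr[idx] = orig - eps
                lm = loss()
                arr[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-7)


class TestTrainingSets:
    @pytest.fixture(scope="class")
    def tiny_world(self):
        cfg = SimulationConfig(n_chroms=1, n_genes=6, internal_priming_rate=0.0, seed=5)
        return simulate_genome(cfg)

    def test_shifted_offsets_distinct_and_bounded(self, tiny_world):
        genome, _genes, truth = tiny_world
        pas = truth.pas_set()
        examples = make_shifted_positives(pas, genome, n_per_pas=10, seed=0)
        by_pas = {}
        for e in examples:
            by_pas.setdefault(e.origin_pas.key(), []).append(e.offset)
        for offsets in by_pas.values():
            assert len(offsets) == len(set(offsets))
            assert all(abs(o) <= 90 for o in offsets)

    def test_sigma_zero_errors(self, tiny_world):
        genome, _genes, truth = tiny_world
        with pytest.raises(ValueError):
            make_shifted_positives(truth.pas_set(), genome, sigma=0, seed=0)

    def test_offset_moments_match_generator(self):
        cfg = SimulationConfig(n_chroms=2, n_genes=100, internal_priming_rate=0.0, seed=5)
        genome, _genes, truth = simulate_genome(cfg)
        examples = make_shifted_positives(truth.pas_set(), genome, n_per_pas=10, sigma=10, seed=1)
        offsets = np.array([e.offset for e in examples], dtype=float)
        assert len(offsets) > 2000
        assert abs(offsets.mean()) < 0.5
        # per-site distinctness inflates the spread slightly; 5% band
        assert abs(offsets.std() - 10) / 10 < 0.05

    def test_fixed_windows_centered_and_deduplicated(self, tiny_world):
        genome, _genes, truth = tiny_world
        pas = truth.pas_set()
        doubled = PASSet(pas.records + pas.records, tier="known")
        examples = make_fixed_positives(doubled, genome)
        assert len(examples) == len(pas.records)
        e = examples[0]
        site = e.origin_pas
        window = genome.fetch(
            site.chrom, site.site - 100, site.site + 100, site.strand
        )
        assert e.sequence == window and e.offset == 0

    def test_negatives_avoid_genes_and_sites(self, tiny_world):
        genome, genes, truth = tiny_world
        pas = truth.pas_set()
        negs = sample_negatives(genome, pas, genes, n=50, seed=2)
        assert len(negs) == 50
        spans = [(g.span.chrom, g.span.start, g.span.end) for g in genes]
        for e in negs:
            iv = e.region
            assert iv is not None
            for chrom, lo, hi in spans:
                if chrom == iv.chrom:
                    assert iv.end <= lo or iv.start >= hi
            for r in pas:  # exhaustive site scan
                if r.chrom == iv.chrom:
                    assert not (iv.start <= r.site < iv.end)


class TestTrainPredict:
    def test_single_class_rejected(self):
        spec = ModelSpec().scaled(0.05)
        examples = [SequenceExample("A" * 200, 1) for _ in range(10)]
        with pytest.raises(ValueError):
            train(spec, examples, batch_size=4, max_epochs=1, seed=0)

    def test_early_stopping_keeps_best_epoch(self):
        rng = np.random.default_rng(0)
        spec = ModelSpec(seq_len=200, conv1_filters=4, conv1_width=4, conv2_filters=4,
                         conv2_width=3, pool=4, lstm_units=4, dense_units=8, dropout=0.0)
        examples = [
            SequenceExample("".join(rng.choice(list("ACGT"), 200)), int(i % 2))
            for i in range(60)
        ]
        result = train(spec, examples, batch_size=16, max_epochs=6, patience=2, seed=0)
        assert len(result.history) <= 6
        monitored = [h["monitor_loss"] for h in result.history]
        assert result.best_epoch == int(np.argmin(monitored)) + 1

    def test_probability_threshold_strict(self, shifted_model):
        from scpas.classifier import Prediction

        assert Prediction(0.5).label == 0
        assert Prediction(0.51).label == 1

    def test_softmax_outputs_normalised(self, shifted_model, bench):
        x = encode_batch([e.sequence for e in bench.negatives[:8]])
        probs, _ = shifted_model.model.forward(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_checkpoint_round_trip(self, shifted_model, bench, tmp_path):
        path = str(tmp_path / "model.npz")
        shifted_model.model.save(path)
        loaded = SequenceClassifier.load(path)
        seqs = [e.sequence for e in bench.negatives[:16]]
        a = shifted_model.model.predict_proba(encode_batch(seqs))
        b = loaded.predict_proba(encode_batch(seqs))
        assert np.allclose(a, b)


class TestTrainedModelProperties:
    def test_benchmark_auc(self, shifted_model, bench):
        from scpas.evaluation import roc_auc

        val_pos = make_fixed_positives(bench.pas_validation, bench.genome)
        val_neg = sample_negatives(
            bench.genome, bench.pas_train, bench.gene_models, n=len(val_pos), seed=99
        )
        seqs = [e.sequence for e in val_pos + val_neg]
        labels = [1] * len(val_pos) + [0] * len(val_neg)
        probs = shifted_model.model.predict_proba(encode_batch(seqs))
        _, auc = roc_auc(labels, probs)
        assert auc >= 0.95

    def test_position_tolerance_grid(self, shifted_model, bench):
        tol = evaluate_position_tolerance(
            shifted_model.model, bench.pas_validation, bench.genome
        )
        offsets = sorted(tol)
        assert offsets == list(range(-50, 55, 5))
        assert all(0.0 <= v <= 1.0 for v in tol.values())
        far = np.mean([tol[o] for o in offsets if abs(o) >= 25])
        assert tol[0] >= far - 0.05  # centre at least as good as far offsets

    def test_shifted_training_more_tolerant_than_fixed(
        self, shifted_model, fixed_model, bench
    ):
        tol_s = evaluate_position_tolerance(
            shifted_model.model, bench.pas_validation, bench.genome
        )
        tol_f = evaluate_position_tolerance(
            fixed_model.model, bench.pas_validation, bench.genome
        )
        far = [o for o in tol_s if 25 <= abs(o) <= 50]
        assert np.mean([tol_s[o] for o in far]) > np.mean([tol_f[o] for o in far])

    def test_internal_priming_rejected_at_all_run_lengths(self, shifted_model, bench):
        tnr = evaluate_internal_priming(
            shifted_model.model, bench.genome, bench.pas_train, bench.gene_models,
            n_per_length=40, seed=3,
        )
        assert set(tnr) == set(range(8, 16))
        assert all(0.0 <= v <= 1.0 for v in tnr.values())
        assert min(tnr.values()) >= 0.9

    def test_filter_motifs_recover_planted_signal(self, shifted_model, bench):
        motifs = extract_filter_motifs(
            shifted_model.model, bench.shifted_positives[:800]
        )
        assert len(motifs) <= shifted_model.model.spec.conv1_filters
        for m in motifs:
            assert m.ppm.shape == (12, 4)
            assert np.allclose(m.ppm.sum(axis=1), 1.0)
        assert motifs == sorted(motifs, key=lambda m: -m.entropy)

        def best_match(consensus):
            target = "AATAAA"
            return max(
                sum(a == b for a, b in zip(consensus[i : i + 6], target))
                for i in range(len(consensus) - 5)
            )

        assert any(best_match(m.consensus()) >= 5 for m in motifs[:10])
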