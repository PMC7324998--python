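"""CRF exactness against brute-force enumeration, training, span decoding."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from tcmaid import ner
from tcmaid import preprocess as pp
from tcmaid import synthetic_corpus as sc


def random_instance(rng, T, K):
    e = rng.normal(size=(T, K))
    A = rng.normal(size=(K + 2, K + 2))
    A[:, K] = -np.inf  # into START
    A[K + 1, :] = -np.inf  # out of STOP
    return e, A


def enumerate_scores(e, A):
    T, K = e.shape
    return {
        y: ner.path_score(e, A, list(y)) for y in itertools.product(range(K), repeat=T)
    }


class TestCrfPrimitives:
    def test_path_score_single_token_closed_form(self):
        e = np.array([[2.5]])
        A = np.zeros((3, 3))
        assert ner.path_score(e, A, [0]) == pytest.approx(2.5)

    def test_all_zero_scores_zero_for_every_path(self):
        e = np.zeros((4, 3))
        A = np.zeros((5, 5))
        for y in itertools.product(range(3), repeat=4):
            assert ner.path_score(e, A, list(y)) == 0.0

    def test_path_score_matches_hand_sum(self):
        rng = np.random.default_rng(0)
        e, A = random_instance(rng, 3, 3)
        y = [2, 0, 1]
        hand = A[3, 2] + e[0, 2] + A[2, 0] + e[1, 0] + A[0, 1] + e[2, 1] + A[1, 4]
        assert ner.path_score(e, A, y) == pytest.approx(hand)

    def test_length_mismatch_rejected(self):
        e = np.zeros((2, 2))
        A = np.zeros((4, 4))
        with pytest.raises(ValueError):
            ner.path_score(e, A, [0])

    def test_log_partition_single_path(self):
        e = np.array([[1.7]])
        A = np.zeros((3, 3))
        assert ner.log_partition(e, A) == pytest.approx(ner.path_score(e, A, [0]))

    def test_log_partition_brute_force_and_bound(self):
        rng = np.random.default_rng(1)
        e, A = random_instance(rng, 3, 3)
        scores = enumerate_scores(e, A)
        Z = ner.log_partition(e, A)
        assert Z == pytest.approx(logsumexp(list(scores.values())), abs=1e-8)
        assert all(Z >= s - 1e-12 for s in scores.values())

    def test_path_distribution_normalizes(self):
        rng = np.random.default_rng(2)
        e, A = random_instance(rng, 4, 2)
        Z = ner.log_partition(e, A)
        mass = sum(np.exp(s - Z) for s in enumerate_scores(e, A).values())
        assert mass == pytest.approx(1.0, abs=1e-10)

    def test_viterbi_brute_force(self):
        rng = np.random.default_rng(3)
        e, A = random_instance(rng, 4, 3)
        scores = enumerate_scores(e, A)
        path, score = ner.viterbi(e, A)
        assert score == pytest.approx(max(scores.values()), abs=1e-8)
        assert score == pytest.approx(scores[tuple(path)], abs=1e-8)

    def test_viterbi_single_tag(self):
        e = np.array([[0.5], [0.1]])
        A = np.zeros((3, 3))
        path, _ = ner.viterbi(e, A)
        assert path == [0, 0]

    def test_viterbi_empty_sequence(self):
        assert ner.viterbi(np.zeros((0, 2)), np.zeros((4, 4))) == ([], 0.0)

    def test_viterbi_decoupled_rowwise_argmax(self):
        rng = np.random.default_rng(4)
        e = rng.normal(size=(5, 3)) + 10 * np.eye(3)[rng.integers(3, size=5)]
        A = np.zeros((5, 5))
        path, _ = ner.viterbi(e, A)
        assert path == list(np.argmax(e, axis=1))

    def test_viterbi_tie_breaks_to_lowest_tag_index(self):
        e = np.zeros((3, 3))
        A = np.zeros((5, 5))
        path, score = ner.viterbi(e, A)
        assert path == [0, 0, 0] and score == 0.0


class TestNll:
    def make_model(self, seed=0):
        scheme = ner.TagScheme(("sym",))
        vocab = {ner.UNK: 0, "a": 1, "b": 2, "c": 3}
        return ner.NerModel.init(scheme, vocab, emb_dim=5, hidden=4, seed=seed)

    def test_single_tag_scheme_zero_loss(self):
        # with one possible path the likelihood is 1 regardless of weights
        scheme = ner.TagScheme(())
        model = ner.NerModel.init(scheme, {ner.UNK: 0, "a": 1}, emb_dim=3, hidden=3, seed=1)
        assert ner.nll(model, [(["a", "a"], ["O", "O"])]) == pytest.approx(0.0, abs=1e-10)

    def test_nonnegative(self):
        model = self.make_model()
        batch = [(["a", "b", "c"], ["B-sym", "I-sym", "O"])]
        assert ner.nll(model, batch) >= 0

    def test_matches_enumerated_cross_entropy(self):
        model = self.make_model(seed=5)
        tokens = ["a", "b", "c"]
        gold = ["B-sym", "O", "I-sym"]
        e = model.emissions(tokens)
        A = model.params["A"]
        scores = enumerate_scores(e, A)
        y = tuple(model.scheme.encode(gold))
        expected = -(scores[y] - logsumexp(list(scores.values())))
        assert ner.nll(model, [(tokens, gold)]) == pytest.approx(expected, abs=1e-8)

    def test_exact_gradients_by_finite_differences(self):
        model = self.make_model(seed=7)
        tokens = ["a", "b", "c", "a"]
        gold = model.scheme.encode(["B-sym", "I-sym", "O", "B-sym"])
        loss, grads = model._seq_grads(tokens, gold)
        rng = np.random.default_rng(11)
        eps = 1e-6
        for name, G in grads.items():
            P = model.params[name]
            for _ in range(3):
                ij = tuple(int(v) for v in (rng.integers(s) for s in P.shape))
                if not np.isfinite(P[ij]):
                    continue
                orig = P[ij]
                P[ij] = orig + eps
                lp, _ = model._seq_grads(tokens, gold)
                P[ij] = orig - eps
                lm, _ = model._seq_grads(tokens, gold)
                P[ij] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(G[ij], abs=1e-4)


class TestTraining:
    @pytest.fixture(scope="class")
    def split(self, small_corpus):
        _, notes = small_corpus
        notes = [pp.preprocess_note(n) for n in notes]
        return notes[:50], notes[50:]

    def test_separable_corpus_reaches_high_span_f1(self, split):
        train, val = split
        model, _ = ner.fit(train, val, {"epochs": 4}, seed=0)
        assert ner.span_f1(model, val) >= 0.95

    def test_zero_epochs_returns_initialization(self, split):
        train, val = split
        model, trace = ner.fit(train, val, {"epochs": 0}, seed=3)
        ref = ner.NerModel.init(
            model.scheme, model.vocab, model.emb_dim, model.hidden, seed=3
        )
        assert trace == []
        for k in model.params:
            assert np.array_equal(
                model.params[k], ref.params[k], equal_nan=True
            ), k

    def test_same_seed_identical_f1_trace(self, split):
        train, val = split
        _, t1 = ner.fit(train, val[:10], {"epochs": 2}, seed=5)
        _, t2 = ner.fit(train, val[:10], {"epochs": 2}, seed=5)
        assert t1 == t2

    def test_nll_decreases_from_initialization(self, split):
        train, val = split
        batch = []
        for n in train[:10]:
            for sec, text in n.sections.items():
                if sec in ("admission", "discharge") or not text:
                    continue
                toks, tags = sc.spans_to_tags(text, [s for s in n.spans if s.section == sec])
                batch.append((toks, tags))
        init, _ = ner.fit(train, val, {"epochs": 0}, seed=2)
        trained, _ = ner.fit(train, val, {"epochs": 2}, seed=2)
        assert ner.nll(trained, batch) < ner.nll(init, batch)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            ner.fit([], [], seed=0)

    def test_char_features_flag_trains(self, split):
        train, val = split
        model, _ = ner.fit(train[:20], val[:5], {"epochs": 1, "char_features": True}, seed=1)
        assert "Ec" in model.params

    def test_save_load_round_trip_predictions(self, split, tmp_path):
        train, val = split
        model, _ = ner.fit(train, val[:5], {"epochs": 1}, seed=0)
        model.save(tmp_path / "m.npz")
        back = ner.NerModel.load(tmp_path / "m.npz")
        toks = ["sym-D000c0", "3days", "w1"]
        assert back.predict_tags(toks) == model.predict_tags(toks)


class TestDecodeEntities:
    @pytest.mark.parametrize(
        "tags,expected",
        [
            (["B-sym", "I-sym", "O"], [(0, 2, "sym")]),
            (["O", "O", "O"], []),
            (["I-sym", "O", "B-sym"], [(0, 1, "sym"), (2, 3, "sym")]),
            (["B-a", "I-b"], [(0, 1, "a"), (1, 2, "b")]),
            (["B-a", "B-a"], [(0, 1, "a"), (1, 2, "a")]),
        ],
    )
    def test_bio_decoding(self, tags, expected):
        tokens = ["t"] * len(tags)
        assert ner.decode_entities(tokens, tags) == expected

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            ner.decode_entities(["t"], ["X-sym"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ner.decode_entities(["t", "t"], ["O"])


class TestStructure:
    def _note(self, text, spans):
        return sc.AnnotatedNote("n", {"chief_complaint": text}, spans, "D", "S")

    def test_symptom_duration_pairing(self):
        text = "coughing 3days phlegm 2days"
        spans = [
            sc.Span("chief_complaint", 0, 8, "symptom", "coughing"),
            sc.Span("chief_complaint", 9, 14, "duration", "3days"),
            sc.Span("chief_complaint", 15, 21, "symptom", "phlegm"),
            sc.Span("chief_complaint", 22, 27, "duration", "2days"),
        ]
        rec = ner.structure(self._note(text, spans), spans)
        pairs = [(e.surface, e.duration) for e in rec.entities]
        assert pairs == [("coughing", "3days"), ("phlegm", "2days")]

    def test_no_durations_all_unpaired(self):
        text = "fever chills"
        spans = [
            sc.Span("chief_complaint", 0, 5, "symptom", "fever"),
            sc.Span("chief_complaint", 6, 12, "symptom", "chills"),
        ]
        rec = ner.structure(self._note(text, spans), spans)
        assert all(e.duration is None for e in rec.entities)

    def test_duration_before_any_symptom_logged_unpaired(self, caplog):
        text = "3days fever"
        spans = [
            sc.Span("chief_complaint", 0, 5, "duration", "3days"),
            sc.Span("chief_complaint", 6, 11, "symptom", "fever"),
        ]
        with caplog.at_level("INFO"):
            rec = ner.structure(self._note(text, spans), spans)
        assert len(rec.unpaired_durations) == 1
        assert rec.entities[0].duration is None
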