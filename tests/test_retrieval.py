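import numpy as np
import pytest

from _oracles import cosine
from conftest import make_vocab
from vonorm.extraction import Mention
from vonorm.retrieval import (
    CallableBackend,
    TrainingConfig,
    build_concept_index,
    build_pair_corpus,
    mock_encoder,
    rank_candidates,
)
from vonorm.vocabulary import VocabularyIndex


class TestMockEncoder:
    def test_deterministic(self):
        enc = mock_encoder(dimension=64, seed=5)
        assert np.array_equal(enc.embed("abc"), enc.embed("abc"))
        # a fresh instance with the same seed agrees too
        assert np.array_equal(enc.embed("abc"), mock_encoder(64, 5).embed("abc"))

    def test_self_cosine_one_and_unit_norm(self):
        enc = mock_encoder(dimension=64, seed=0)
        v = enc.embed("influenza vaccine")
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
        assert float(v @ enc.embed("influenza vaccine")) == pytest.approx(1.0)

    def test_empty_text_is_zero_vector(self):
        assert np.all(mock_encoder(32, 0).embed("") == 0)

    def test_trigram_overlap_orders_similarity(self):
        # shared trigrams ("flumist") must beat a disjoint string; verified
        # directly against a raw trigram-overlap cosine
        enc = mock_encoder(dimension=512, seed=1)

        def trigrams(text):
            padded = f"#{text.lower()}#"
            return [padded[i:i + 3] for i in range(len(padded) - 2)]

        def overlap_cosine(a, b):
            ta, tb = trigrams(a), trigrams(b)
            keys = sorted(set(ta) | set(tb))
            return cosine([ta.count(k) for k in keys], [tb.count(k) for k in keys])

        near = float(enc.embed("flumist") @ enc.embed("flumist vaccine"))
        far = float(enc.embed("flumist") @ enc.embed("rabies immunoglobulin"))
        assert overlap_cosine("flumist", "flumist vaccine") > \
            overlap_cosine("flumist", "rabies immunoglobulin")
        assert near > far

    def test_dimension_floor(self):
        with pytest.raises(ValueError):
            mock_encoder(dimension=8, seed=0)

    def test_seed_changes_hashing(self):
        a = mock_encoder(64, 0).embed("flumist")
        b = mock_encoder(64, 1).embed("flumist")
        assert not np.array_equal(a, b)


class TestConceptIndex:
    def test_row_counts(self):
        vocab = make_vocab({
            "VO:1": ("a vax", [], []),
            "VO:2": ("b vax", [], []),
            "VO:3": ("c vax", [], []),
        })
        index = build_concept_index(vocab, mock_encoder(32, 0))
        assert len(index) == 3

        vocab2 = make_vocab({"VO:1": ("a vax", ["alpha vax", "vax a"], [])})
        index2 = build_concept_index(vocab2, mock_encoder(32, 0))
        assert len(index2) == 3
        assert set(index2.concept_ids) == {"VO:1"}

    def test_empty_vocab_is_usage_error(self):
        with pytest.raises(ValueError):
            build_concept_index(VocabularyIndex(), mock_encoder(32, 0))

    def test_failing_backend_reports_label(self):
        vocab = make_vocab({"VO:1": ("bad label", [], [])})

        def boom(text):
            raise RuntimeError("backend down")

        backend = CallableBackend("broken", 16, boom)
        with pytest.raises(RuntimeError, match="bad label"):
            build_concept_index(vocab, backend)


class TestRankCandidates:
    def test_exact_label_ranks_first_with_score_one(self, toy_vocab):
        enc = mock_encoder(256, 0)
        index = build_concept_index(toy_vocab, enc)
        out = rank_candidates(Mention("Menveo", "m1"), index, enc, k=5)
        assert out.entries[0][0] == "VO:4"
        assert out.entries[0][1] == pytest.approx(1.0)

    def test_k_truncation(self, toy_vocab):
        enc = mock_encoder(64, 0)
        index = build_concept_index(toy_vocab, enc)
        assert len(rank_candidates("flu", index, enc, k=100)) == len(toy_vocab)
        assert len(rank_candidates("flu", index, enc, k=2)) == 2

    def test_matches_brute_force_cosine_scan(self, toy_vocab):
        enc = mock_encoder(128, 3)
        index = build_concept_index(toy_vocab, enc)
        for text in ["flumist", "conjugate", "menacwy", "aidsvax be"]:
            got = rank_candidates(text, index, enc, k=10)
            q = enc.embed(text)
            best = {}
            for cid, concept in toy_vocab.concepts.items():
                best[cid] = max(cosine(q, enc.embed(lab)) for lab in concept.labels)
            key = lambda kv: (-round(kv[1], 9), kv[0])
            assert [cid for cid, _ in sorted(got.entries, key=key)] == \
                [cid for cid, _ in sorted(best.items(), key=key)]
            for cid, s_got in got.entries:
                assert s_got == pytest.approx(best[cid], abs=1e-9)

    @pytest.mark.parametrize("backend_factory", [
        lambda: mock_encoder(64, 0),
        lambda: mock_encoder(256, 9),
        lambda: CallableBackend("wrapped", 64, mock_encoder(64, 4).embed),
    ])
    def test_contract_invariants_across_backends(self, toy_vocab, backend_factory):
        backend = backend_factory()
        index = build_concept_index(toy_vocab, backend)
        out = rank_candidates("trivalent influenza dose", index, backend, k=4)
        scores = [s for _, s in out.entries]
        ids = [cid for cid, _ in out.entries]
        assert len(out) <= 4
        assert all(-1.0 - 1e-9 <= s <= 1.0 + 1e-9 for s in scores)
        assert scores == sorted(scores, reverse=True)
        assert len(ids) == len(set(ids))

    def test_empty_index_and_bad_k(self, toy_vocab):
        enc = mock_encoder(32, 0)
        index = build_concept_index(toy_vocab, enc)
        with pytest.raises(ValueError):
            rank_candidates("x", index, enc, k=0)

    def test_noise_free_top1_is_perfect(self):
        vocab = make_vocab({f"VO:{i}": (f"disease{i} vaccine", [], [])
                            for i in range(1, 11)})
        enc = mock_encoder(256, 2)
        index = build_concept_index(vocab, enc)
        for cid, concept in vocab.concepts.items():
            out = rank_candidates(concept.preferred_label, index, enc, k=1)
            assert out.entries[0][0] == cid


class TestPairCorpus:
    def test_counts(self):
        vocab = make_vocab({"VO:1": ("a vax", [], [])})
        lines, skipped = build_pair_corpus(
            vocab, [Mention("the a vax shot", "m1", gold_ids=["VO:1"])])
        assert len(lines) == 2
        assert skipped == 0
        assert lines == ["VO:1||a vax", "VO:1||the a vax shot"]

    def test_dedup(self):
        vocab = make_vocab({"VO:1": ("a vax", [], [])})
        mentions = [Mention("a vax", "m1", gold_ids=["VO:1"]),
                    Mention("a vax", "m2", gold_ids=["VO:1"])]
        lines, _ = build_pair_corpus(vocab, mentions)
        assert lines == ["VO:1||a vax"]

    def test_multi_gold_mention_emits_one_line_per_gold(self):
        vocab = make_vocab({"VO:1": ("a vax", [], []), "VO:2": ("b vax", [], [])})
        lines, _ = build_pair_corpus(
            vocab, [Mention("a and b shot", "m1", gold_ids=["VO:1", "VO:2"])])
        assert "VO:1||a and b shot" in lines and "VO:2||a and b shot" in lines

    def test_unknown_gold_skipped_and_counted(self, caplog):
        vocab = make_vocab({"VO:1": ("a vax", [], [])})
        with caplog.at_level("WARNING"):
            lines, skipped = build_pair_corpus(
                vocab, [Mention("mystery shot", "m1", gold_ids=["VO:404"])])
        assert skipped == 1
        assert lines == ["VO:1||a vax"]


def test_training_config_defaults_and_validation():
    cfg = TrainingConfig()
    assert (cfg.epochs, cfg.train_batch_size, cfg.learning_rate, cfg.max_seq_length) == \
        (1, 256, 2e-5, 25)
    with pytest.raises(ValueError):
        TrainingConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainingConfig(learning_rate=-1.0)
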