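
import pytest

from medrqe.corpus import QARecord, Question
from medrqe.retrieval import (
    build_index,
    load_index,
    retrieve,
    retrieve_fused,
    save_index,
    score_inexpb2,
    score_tfidf,
)

NO_STOP = frozenset()


def _record(qid, text, answer="answer text", qtypes=(), synonyms=(), focus=None):
    return QARecord(
        question=Question(
            identifier=qid, text=text, qtypes=set(qtypes),
            focus=focus, focus_synonyms=set(synonyms),
        ),
        answer=answer,
        source="toy",
    )


@pytest.fixture
def toy_index():
    # d1 holds "zib" twice, d2 holds "qor" once; no stopword removal
    records = [_record("d1", "zib zib"), _record("d2", "qor")]
    return build_index(records, taxonomy=None, stopwords=NO_STOP)


def test_tfidf_hand_computed(toy_index):
    # tf=2, N=2, n_t=1, qtf=1 -> 2 * log2(2) = 2.0
    assert score_tfidf(toy_index, ["zib"], "d1") == pytest.approx(2.0)
    assert score_tfidf(toy_index, ["nonexistent"], "d1") == 0.0
    # additivity over query terms
    both = score_tfidf(toy_index, ["zib", "qor"], "d1")
    assert both == pytest.approx(
        score_tfidf(toy_index, ["zib"], "d1") + score_tfidf(toy_index, ["qor"], "d1")
    )
    with pytest.raises(KeyError):
        score_tfidf(toy_index, ["zib"], "missing")


def test_inexpb2_hand_computed():
    # N=2, dl=avgdl=1, c=1, F_t=n_t=tf=1:
    # tfn = log2(2) = 1, n_e = 2*(1-0.5) = 1,
    # weight = (1+1)/(1*(1+1)) * 1 * log2(3/1.5) = 1.0
    records = [_record("d1", "zib"), _record("d2", "qor")]
    index = build_index(records, taxonomy=None, stopwords=NO_STOP)
    assert score_inexpb2(index, ["zib"], "d1") == pytest.approx(1.0)
    assert score_inexpb2(index, ["zib"], "d2") == 0.0


def test_inexpb2_nonnegative_on_varied_corpus():
    records = [
        _record("a", "zib qor dal dal"),
        _record("b", "zib zib zib"),
        _record("c", "dal mek"),
        _record("d", "qor mek zib dal"),
    ]
    index = build_index(records, taxonomy=None, stopwords=NO_STOP)
    for doc in "abcd":
        for query in (["zib"], ["dal", "mek"], ["zib", "zib", "qor"]):
            assert score_inexpb2(index, query, doc) >= 0.0


def test_index_expansion_with_synonyms_and_triggers(taxonomy):
    rec = _record(
        "t1",
        "What are the treatments for Torticollis?",
        answer="Physical therapy options and botulinum toxin.",
        qtypes={"Treatment"},
        synonyms={"Spasmodic torticollis", "Wry neck", "Loxia", "Cervical dystonia"},
        focus="Torticollis",
    )
    index = build_index([rec], taxonomy=taxonomy)
    for stem in ("wry", "neck", "loxia", "cure", "remedi", "therapi", "torticolli"):
        assert stem in index.postings, stem
    # answers are never indexed
    assert "botulinum" not in index.postings
    assert "toxin" not in index.postings


def test_empty_collection_and_duplicate_ids():
    index = build_index([], taxonomy=None, stopwords=NO_STOP)
    assert index.n_docs == 0
    with pytest.raises(ValueError, match="duplicate"):
        build_index(
            [_record("x", "one"), _record("x", "two")],
            taxonomy=None, stopwords=NO_STOP,
        )


def test_retrieve_out_of_vocabulary_query_is_empty(toy_index):
    assert retrieve_fused(toy_index, ["unseen", "terms"]).ranking == ()


def test_fused_score_equals_sum_of_models_exhaustive():
    """CombSUM oracle: with n >= corpus size, every fused score equals the
    sum of the document's two single-model scores."""
    records = [
        _record("a", "zib qor dal"),
        _record("b", "zib zib mek"),
        _record("c", "dal mek pon"),
        _record("d", "qor pon zib dal"),
        _record("e", "mek mek"),
    ]
    index = build_index(records, taxonomy=None, stopwords=NO_STOP)
    for query in (["zib"], ["dal", "mek"], ["zib", "qor", "pon"]):
        fused = dict(retrieve_fused(index, query, n=20).ranking)
        for doc in "abcde":
            expected = score_tfidf(index, query, doc) + score_inexpb2(index, query, doc)
            assert fused.get(doc, 0.0) == pytest.approx(expected)


def test_fused_ranking_sorted_and_deterministic():
    records = [
        _record("a", "zib qor"), _record("b", "zib"), _record("c", "qor dal"),
    ]
    i1 = build_index(records, taxonomy=None, stopwords=NO_STOP)
    i2 = build_index(list(reversed(records)), taxonomy=None, stopwords=NO_STOP)
    r1 = retrieve_fused(i1, ["zib", "qor"], n=10).ranking
    r2 = retrieve_fused(i2, ["zib", "qor"], n=10).ranking
    assert r1 == r2  # insertion-order independence
    scores = [s for _, s in r1]
    assert scores == sorted(scores, reverse=True)


def test_unrelated_document_preserves_tfidf_order():
    base = [_record("a", "zib zib qor"), _record("b", "zib dal qor qor")]
    extended = base + [_record("z", "mek pon")]  # shares no query term
    q = ["zib", "qor"]
    before = retrieve(
        build_index(base, taxonomy=None, stopwords=NO_STOP), q, 10, score_tfidf
    )
    after = retrieve(
        build_index(extended, taxonomy=None, stopwords=NO_STOP), q, 10, score_tfidf
    )
    # growing N rescales IDF, so scores change, but the relative order of the
    # documents present in both rankings is preserved
    before_ids = [d for d, _ in before.ranking]
    after_ids = [d for d, _ in after.ranking if d in before_ids]
    assert after_ids == before_ids


def test_index_persistence_roundtrip(tmp_path, toy_index):
    path = tmp_path / "index.json"
    save_index(toy_index, path)
    loaded = load_index(path)
    assert loaded.postings == toy_index.postings
    assert loaded.doc_lengths == toy_index.doc_lengths
    assert loaded.c == toy_index.c
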