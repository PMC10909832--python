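"""Containment, cANI conversion, matching-material arithmetic, search."""

import logging

import numpy as np
import pytest

from fracmap import (
    SearchHit,
    SignatureCollection,
    SketchParams,
    Signature,
    ani_from_containment,
    batch_search,
    build_signature,
    containment,
    est_matching_bp,
    est_matching_kmers,
    mutate_to_ani,
    search,
)
from fracmap.search import (
    ParameterMismatchError,
    hits_to_frame,
    read_hits,
    write_hits,
)

from conftest import brute_containment, random_dna


def _sig(hashes, name="s", length=100, **params):
    return Signature(
        name, name, length, SketchParams(**params),
        hashes=np.array(sorted(hashes), dtype=np.uint64),
    )


class TestContainment:
    def test_identity(self, small_genome):
        sig = build_signature([small_genome], SketchParams(ksize=21, scaled=1),
                              name="g")
        assert containment(sig, sig) == 1.0

    def test_disjoint(self):
        a = _sig({1, 2, 3}, "a", scaled=1)
        b = _sig({4, 5, 6}, "b", scaled=1)
        assert containment(a, b) == 0.0

    def test_hand_intersection(self):
        q = _sig({10, 20, 30, 40}, "q", scaled=1)
        s = _sig({20, 40, 90}, "s", scaled=1)
        assert containment(q, s) == 0.5

    def test_parameter_mismatch(self):
        a = _sig({1}, "a", ksize=21, scaled=1)
        b = _sig({1}, "b", ksize=31, scaled=1)
        with pytest.raises(ParameterMismatchError, match="ksize"):
            containment(a, b)
        c = _sig({1}, "c", ksize=21, scaled=1, hash_seed=7)
        with pytest.raises(ParameterMismatchError, match="hash_seed"):
            containment(a, c)

    def test_empty_query_after_harmonizing(self):
        q = _sig({2**63}, "q", scaled=1)  # vanishes once downsampled
        s = build_signature([random_dna(100_000, 1)],
                            SketchParams(ksize=31, scaled=1000), name="s")
        with pytest.raises(ValueError, match="undetectable query"):
            containment(q, s)

    def test_scaled_harmonization_is_exact(self):
        genome = random_dna(50_000, seed=2)
        relative = mutate_to_ani(genome, 0.97, seed=3)
        k = 31
        fine = build_signature([genome], SketchParams(k, scaled=100), name="q")
        coarse = build_signature([relative], SketchParams(k, scaled=1000), name="s")
        both_coarse = build_signature([genome], SketchParams(k, scaled=1000),
                                      name="q")
        assert containment(fine, coarse) == containment(both_coarse, coarse)

    def test_matches_bruteforce_at_scaled_1(self):
        genome = random_dna(30_000, seed=4)
        relative = mutate_to_ani(genome, 0.96, seed=5)
        k = 31
        q = build_signature([genome], SketchParams(k, scaled=1), name="q")
        s = build_signature([relative], SketchParams(k, scaled=1), name="s")
        assert containment(q, s) == pytest.approx(
            brute_containment(genome, relative, k), abs=0
        )

    def test_monotonicity(self):
        q = _sig({10, 20, 30, 40}, "q", scaled=1)
        s = _sig({20, 40}, "s", scaled=1)
        base = containment(q, s)
        grown = _sig({20, 40, 99}, "s", scaled=1)  # extra subject hash
        assert containment(q, grown) >= base
        widened = _sig({10, 20, 30, 40, 55}, "q", scaled=1)  # extra query hash
        assert containment(widened, s) <= base


class TestAniConversion:
    @pytest.mark.parametrize(
        "c,k,pct",
        [(0.05, 31, 91), (0.30, 31, 96)],
    )
    def test_published_anchors(self, c, k, pct):
        assert round(100 * ani_from_containment(c, k)) == pct

    def test_identity_and_zero(self):
        assert ani_from_containment(1.0, 31) == 1.0
        assert ani_from_containment(0.0, 31) == 0.0

    @pytest.mark.parametrize("a", [0.80, 0.90, 0.95, 0.99])
    @pytest.mark.parametrize("k", [21, 31, 51])
    def test_inversion(self, a, k):
        assert ani_from_containment(a**k, k) == pytest.approx(a, abs=1e-9)

    def test_monotone(self):
        grid = [ani_from_containment(c, 31) for c in np.linspace(0, 1, 50)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ani_from_containment(1.5, 31)
        with pytest.raises(ValueError):
            ani_from_containment(-0.1, 31)


class TestMatchingMaterial:
    @pytest.mark.parametrize(
        "c,bp,kmers",
        [(0.05, 2_700_000, 135_000), (0.05, 6_070_000, 303_500), (0.0, 99, 0)],
    )
    def test_matching_kmers(self, c, bp, kmers):
        assert est_matching_kmers(c, bp) == kmers

    @pytest.mark.parametrize(
        "m,k,bp",
        [(135_000, 31, 4_185_000), (303_500, 31, 9_408_500), (0, 31, 0)],
    )
    def test_matching_bp(self, m, k, bp):
        assert est_matching_bp(m, k) == bp

    def test_hit_field_consistency(self):
        hit = SearchHit.from_containment("q", "s", 0.3173, 2_700_000, 31)
        assert hit.est_matching_kmers == round(0.3173 * 2_700_000)
        assert hit.est_matching_bp == hit.est_matching_kmers * 31
        assert hit.cani == pytest.approx(0.3173 ** (1 / 31), abs=1e-12)


class TestSearch:
    @pytest.fixture()
    def corpus(self):
        genome = random_dna(20_000, seed=6)
        params = SketchParams(ksize=31, scaled=10)
        query = build_signature([genome], params, name="q", source_id="q")
        subjects = {
            "self": build_signature([genome], params, name="self"),
            "related": build_signature([mutate_to_ani(genome, 0.95, 7)], params,
                                       name="related"),
            "unrelated": build_signature([random_dna(20_000, 8)], params,
                                         name="unrelated"),
        }
        return query, SignatureCollection(subjects)

    def test_self_retrieval_and_order(self, corpus):
        query, collection = corpus
        hits = search(query, collection, threshold=0.0)
        assert hits[0].subject_id == "self"
        assert hits[0].containment == 1.0
        assert [h.containment for h in hits] == sorted(
            (h.containment for h in hits), reverse=True
        )

    def test_unrelated_subjects_excluded(self, corpus):
        query, collection = corpus
        hits = search(query, collection, threshold=0.05)
        assert all(h.subject_id != "unrelated" for h in hits)

    def test_threshold_is_strict(self):
        q = _sig({1, 2, 3, 4}, "q", scaled=1)
        s = _sig({1, 2}, "s", scaled=1)  # containment exactly 0.5
        coll = SignatureCollection({"s": s})
        assert search(q, coll, threshold=0.5) == []
        assert len(search(q, coll, threshold=0.49)) == 1

    def test_tie_break_by_subject_id(self):
        q = _sig({1, 2}, "q", scaled=1)
        coll = SignatureCollection(
            {"b": _sig({1, 2}, "b", scaled=1), "a": _sig({1, 2}, "a", scaled=1)}
        )
        assert [h.subject_id for h in search(q, coll, 0.0)] == ["a", "b"]

    def test_incompatible_subject_skipped_with_warning(self, corpus, caplog):
        query, collection = corpus
        collection.add("wrong_k", _sig({1, 2}, "wrong_k", ksize=21, scaled=1))
        with caplog.at_level(logging.WARNING, logger="fracmap.search"):
            hits = search(query, collection, threshold=0.0)
        assert "wrong_k" in caplog.text
        assert all(h.subject_id != "wrong_k" for h in hits)

    def test_batch_matches_single(self, corpus):
        query, collection = corpus
        single = search(query, collection, 0.05)
        batch = batch_search([query, query], collection, 0.05)
        assert batch[: len(single)] == single
        assert batch[len(single) :] == single  # duplicate query, duplicate block

    def test_hit_table_roundtrip(self, corpus, tmp_path):
        query, collection = corpus
        hits = search(query, collection, 0.0)
        path = tmp_path / "hits.tsv"
        write_hits(hits, path)
        table = read_hits(path)
        assert list(table["subject_id"]) == [h.subject_id for h in hits]
        frame = hits_to_frame(hits)
        assert np.allclose(table["containment"], frame["containment"], atol=5e-5)
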