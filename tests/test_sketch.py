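"""Sketching: canonicalisation, hashing, scaled retention, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracmap import (
    SketchParams,
    Signature,
    build_signature,
    canonicalize,
    downsample,
    extract_kmers,
    hash_kmer,
    load_signatures,
    merge,
    save_signatures,
)
from fracmap.sketch import SignatureFormatError, read_sequences

from conftest import brute_canonical_stream, random_dna, revcomp

dna = st.text(alphabet="ACGT", min_size=3, max_size=40)


@pytest.mark.parametrize(
    "kmer,expected",
    [
        ("ACG", "ACG"),       # already smaller than its reverse complement CGT
        ("TTT", "AAA"),       # reverse-complement case
        ("ACGT", "ACGT"),     # palindrome (self reverse complement)
    ],
)
def test_canonicalize_examples(kmer, expected):
    assert canonicalize(kmer) == expected


def test_canonicalize_rejects_ambiguous():
    with pytest.raises(ValueError, match="non-ACGT"):
        canonicalize("ACN")


@settings(derandomize=True, max_examples=100, deadline=None)
@given(dna)
def test_canonicalize_idempotent_and_strand_neutral(kmer):
    c = canonicalize(kmer)
    assert canonicalize(c) == c
    assert canonicalize(revcomp(kmer)) == c


def test_extract_kmers_hand_enumeration():
    # windows of ACGTA at k=3: ACG -> ACG, CGT -> ACG (rc), GTA -> GTA
    assert list(extract_kmers("ACGTA", 3)) == ["ACG", "ACG", "GTA"]
    assert set(extract_kmers("ACGTA", 3)) == {"ACG", "GTA"}


@pytest.mark.parametrize("seq", ["ACNGT", "AC", ""])
def test_extract_kmers_degenerate(seq):
    assert list(extract_kmers(seq, 3)) == []


def test_extract_kmers_matches_bruteforce():
    rng = np.random.default_rng(7)
    seq = list(random_dna(500, seed=7))
    for pos in rng.integers(0, 500, 10):  # sprinkle ambiguity
        seq[pos] = "N"
    seq = "".join(seq)
    for k in (5, 21):
        assert list(extract_kmers(seq, k)) == brute_canonical_stream(seq, k)


def test_hash_kmer_deterministic_and_seed_dependent():
    assert hash_kmer("ACGTACGTACG", 42) == hash_kmer("ACGTACGTACG", 42)
    assert hash_kmer("ACGTACGTACG", 42) != hash_kmer("ACGTACGTACG", 43)
    # strand neutrality at the hash level
    assert hash_kmer(canonicalize("TTTTTTTTGGG")) == hash_kmer(
        canonicalize(revcomp("TTTTTTTTGGG"))
    )


def _random_kmers(n, k, seed):
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, 4, (n, k))
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [lut[row].tobytes().decode() for row in rows]


def test_hash_uniformity_binomial():
    """Fraction of hashes below the scaled=1000 cut matches 1/1000 to 3 sigma."""
    kmers = _random_kmers(10_000, 31, seed=11)
    hashes = np.array([hash_kmer(canonicalize(k)) for k in kmers], dtype=np.uint64)
    n = len(hashes)
    below = int((hashes < np.uint64(2**64 // 1000)).sum())
    expect = n / 1000
    assert abs(below - expect) <= 3 * np.sqrt(n * (1 / 1000) * (1 - 1 / 1000))


def test_hash_collision_free_at_1e5():
    from fracmap._hashing import hash_sequence

    kmers = _random_kmers(100_000, 31, seed=13)
    canon = {min(k, revcomp(k)) for k in kmers}
    # hash all windows at once via the vectorised path (N separators keep
    # spurious windows out), then compare cardinalities
    hashes = hash_sequence("N".join(kmers), 31, 42)
    assert len(hashes) == len(kmers)
    assert len(set(hashes.tolist())) == len(canon)  # birthday bound ~1e-10


def test_build_signature_scaled1_is_exact_kmer_set(small_genome):
    params = SketchParams(ksize=21, scaled=1)
    sig = build_signature([small_genome], params, name="g", source_id="g")
    assert len(sig) == len(set(brute_canonical_stream(small_genome, 21)))


def test_build_signature_tiny_example():
    sig = build_signature(["ACGTA"], SketchParams(ksize=3, scaled=1), name="t")
    assert len(sig) == 2
    assert sig.source_length_bp == 5


def test_build_signature_retention_fraction():
    genome = random_dna(100_000, seed=5)
    n_distinct = len(set(brute_canonical_stream(genome, 31)))
    sig = build_signature([genome], SketchParams(ksize=31, scaled=50), name="g")
    p = 1 / 50
    sd = np.sqrt(n_distinct * p * (1 - p))
    assert abs(len(sig) - n_distinct * p) <= 3 * sd


def test_build_signature_order_invariant():
    records = [random_dna(3000, seed=s) for s in range(5)]
    params = SketchParams(ksize=31, scaled=5, track_abundance=True)
    a = build_signature(records, params, name="x")
    b = build_signature(records[::-1], params, name="x")
    assert np.array_equal(a.hashes, b.hashes)
    assert np.array_equal(a.abundances, b.abundances)
    assert a.source_length_bp == b.source_length_bp


def test_build_signature_empty_warns():
    with pytest.warns(UserWarning, match="empty input"):
        sig = build_signature([], SketchParams(), name="void")
    assert len(sig) == 0 and sig.source_length_bp == 0


def test_downsample_equals_direct_build():
    genome = random_dna(50_000, seed=9)
    fine = build_signature([genome], SketchParams(ksize=31, scaled=100), name="g")
    coarse = build_signature([genome], SketchParams(ksize=31, scaled=1000), name="g")
    assert np.array_equal(downsample(fine, 1000).hashes, coarse.hashes)


def test_downsample_identity_and_upsample_error():
    sig = build_signature(["ACGT" * 100], SketchParams(ksize=5, scaled=2), name="g")
    assert downsample(sig, 2) is sig
    with pytest.raises(ValueError, match="upsample"):
        downsample(sig, 1)


def test_downsample_extreme_bound():
    sig = build_signature([random_dna(1000, 3)], SketchParams(ksize=21, scaled=1),
                          name="g")
    tiny = downsample(sig, 2**62)
    assert len(tiny) <= len(sig)  # near-empty, no crash
    tiny.validate()


def test_merge_behaviour():
    params = SketchParams(ksize=21, scaled=1, track_abundance=True)
    a = build_signature([random_dna(500, 1)], params, name="a", source_id="a")
    b = build_signature([random_dna(500, 2)], params, name="b", source_id="b")
    assert merge([a]) is a
    ab = merge([a, b])
    shared = np.intersect1d(a.hashes, b.hashes).size
    assert len(ab) == len(a) + len(b) - shared
    doubled = merge([a, a])
    assert np.array_equal(doubled.hashes, a.hashes)
    assert np.array_equal(doubled.abundances, 2 * a.abundances)


def test_merge_rejects_parameter_mismatch():
    a = build_signature(["ACGT" * 50], SketchParams(ksize=21, scaled=1), name="a")
    b = build_signature(["ACGT" * 50], SketchParams(ksize=31, scaled=1), name="b")
    with pytest.raises(ValueError, match="ksize"):
        merge([a, b])


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(2, 50), st.integers(1, 20))
def test_scaled_consistency_property(s1_mult, ratio):
    """downsample(build(X, s1), s2) == build(X, s2) for any s2 >= s1."""
    genome = random_dna(5000, seed=1234)
    s1, s2 = s1_mult, s1_mult * ratio
    fine = build_signature([genome], SketchParams(ksize=21, scaled=s1), name="g")
    direct = build_signature([genome], SketchParams(ksize=21, scaled=s2), name="g")
    assert np.array_equal(downsample(fine, s2).hashes, direct.hashes)


def test_signature_validation_rejects_bad_invariants():
    params = SketchParams(ksize=21, scaled=1)
    with pytest.raises(ValueError, match="strictly increasing"):
        Signature("x", "x", 10, params, hashes=np.array([5, 5], dtype=np.uint64))
    with pytest.raises(ValueError, match="abundances"):
        Signature("x", "x", 10, params, hashes=np.array([5], dtype=np.uint64),
                  abundances=np.array([0]))
    with pytest.raises(ValueError, match="source_length_bp"):
        Signature("x", "x", 0, params, hashes=np.array([5], dtype=np.uint64))


def test_signature_io_roundtrip(tmp_path):
    params = SketchParams(ksize=31, scaled=10, track_abundance=True)
    sig = build_signature([random_dna(5000, 6)], params, name="g", source_id="acc1")
    path = tmp_path / "g.sig"
    save_signatures(sig, path)
    (loaded,) = load_signatures(path)
    assert loaded.name == sig.name and loaded.source_id == "acc1"
    assert loaded.params == sig.params
    assert np.array_equal(loaded.hashes, sig.hashes)
    assert np.array_equal(loaded.abundances, sig.abundances)


def test_signature_io_rejects_malformed(tmp_path):
    params = SketchParams(ksize=31, scaled=10)
    sig = build_signature([random_dna(5000, 6)], params, name="g")
    path = tmp_path / "g.sig"
    save_signatures(sig, path)

    # shrinking the retention bound leaves stored hashes above it
    tampered = path.read_text().replace('"scaled": 10', '"scaled": 100000000000')
    bad = tmp_path / "bad.sig"
    bad.write_text(tampered)
    with pytest.raises(SignatureFormatError, match="max_hash"):
        load_signatures(bad)

    import json

    doc = json.loads(path.read_text())
    del doc["signatures"][0]["checksum"]
    bad.write_text(json.dumps(doc))
    with pytest.raises(SignatureFormatError, match="checksum"):
        load_signatures(bad)

    bad.write_text("not json {")
    with pytest.raises(SignatureFormatError, match="JSON"):
        load_signatures(bad)


def test_read_sequences_fasta_fastq_gzip(tmp_path):
    import gzip

    fasta = tmp_path / "x.fasta"
    fasta.write_text(">a\nACGTACGT\nACGT\n>b\nTTTT\n")
    assert list(read_sequences(fasta)) == ["ACGTACGTACGT", "TTTT"]

    fastq = tmp_path / "x.fastq.gz"
    with gzip.open(fastq, "wt") as fh:
        fh.write("@r1\nACGTA\n+\nIIIII\n")
    assert list(read_sequences(fastq)) == ["ACGTA"]


def test_long_kmer_sizes_supported(small_genome):
    """k=51 uses the two-word packing; scaled=1 still matches brute force."""
    sig = build_signature([small_genome], SketchParams(ksize=51, scaled=1), name="g")
    assert len(sig) == len(set(brute_canonical_stream(small_genome, 51)))
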