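"""FracMinHash sketching of DNA sequence sets.

A FracMinHash (scaled) sketch retains exactly the canonical-k-mer hashes
that fall below ``2**64 / scaled``, i.e. a fixed fraction ~1/scaled of the
hash space.  Unlike a fixed-size bottom sketch this gives unbiased
containment estimates between sketches of very different input sizes,
which is what makes querying a genome against a metagenome work.

The module covers k-mer canonicalisation, hashing (see
:mod:`fracmap._hashing`), sketch construction from sequences or
FASTA/FASTQ files (plain or gzipped), exact downsampling to a coarser
scaled value, merging, and a validated structured-text (JSON) signature
file format.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._hashing import (
    MAX_KSIZE,
    encode,
    hash_sequence,
    kmer_hashes,
    reverse_complement,
)

__all__ = [
    "SketchParams",
    "Signature",
    "SignatureFormatError",
    "canonicalize",
    "extract_kmers",
    "hash_kmer",
    "build_signature",
    "build_signature_from_files",
    "downsample",
    "merge",
    "read_sequences",
    "save_signatures",
    "load_signatures",
]

SIGNATURE_FORMAT = "fracmap-signature"
SIGNATURE_VERSION = 1

# Sequences are hashed in buffered chunks joined by 'N' so that read sets with
# millions of records still go through the vectorised path; the separator can
# never form a valid window, so chunking does not change the k-mer stream.
_CHUNK_BASES = 1 << 21


class SignatureFormatError(ValueError):
    """Raised when a signature file violates the schema or its invariants."""


@dataclass(frozen=True)
class SketchParams:
    """Parameters of a FracMinHash sketch.

    ksize
        k-mer length in bases (>= 3).
    scaled
        downsampling divisor s; the sketch keeps hashes below
        ``floor(2**64 / s)``, i.e. ~1/s of distinct k-mers.
    hash_seed
        seed of the 64-bit hash; all compared signatures must share it.
    track_abundance
        whether per-hash occurrence counts are recorded.
    """

    ksize: int = 31
    scaled: int = 1000
    hash_seed: int = 42
    track_abundance: bool = False

    def __post_init__(self) -> None:
        if not 3 <= self.ksize <= MAX_KSIZE:
            raise ValueError(f"ksize must be in [3, {MAX_KSIZE}], got {self.ksize}")
        if self.scaled < 1:
            raise ValueError(f"scaled must be >= 1, got {self.scaled}")

    @property
    def max_hash(self) -> int:
        """Exclusive retention bound floor(2**64 / scaled); derived, never stored."""
        return 2**64 // self.scaled


@dataclass
class Signature:
    """A FracMinHash sketch plus parameters and provenance."""

    name: str
    source_id: str
    source_length_bp: int
    params: SketchParams
    hashes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    abundances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.abundances is not None:
            self.abundances = np.asarray(self.abundances, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        h = self.hashes
        if h.ndim != 1:
            raise ValueError("hashes must be a 1-D array")
        if h.size > 1 and not np.all(h[1:] > h[:-1]):
            raise ValueError("hashes must be strictly increasing (sorted, unique)")
        if self.params.scaled > 1 and h.size and int(h[-1]) >= self.params.max_hash:
            raise ValueError(
                f"hash {int(h[-1])} >= max_hash {self.params.max_hash} "
                f"for scaled={self.params.scaled}"
            )
        if self.abundances is not None:
            if len(self.abundances) != h.size:
                raise ValueError("abundances length must match hashes length")
            if self.abundances.size and self.abundances.min() < 1:
                raise ValueError("abundances must all be >= 1")
        if self.source_length_bp < 0:
            raise ValueError("source_length_bp must be >= 0")
        if self.source_length_bp == 0 and h.size:
            raise ValueError("source_length_bp is 0 but hashes are non-empty")

    def __len__(self) -> int:
        return int(self.hashes.size)

    def flatten(self) -> "Signature":
        """Presence/absence view: drop abundances (containment is set-based)."""
        if self.abundances is None:
            return self
        return Signature(
            name=self.name,
            source_id=self.source_id,
            source_length_bp=self.source_length_bp,
            params=replace(self.params, track_abundance=False),
            hashes=self.hashes,
        )

    def checksum(self) -> str:
        """sha256 over the decimal hash list — integrity check in the file format."""
        payload = ",".join(str(int(h)) for h in self.hashes)
        return hashlib.sha256(payload.encode("ascii")).hexdigest()


def canonicalize(kmer: str) -> str:
    """Strand-neutral form: the lexicographically smaller of kmer and its
    reverse complement (A<C<G<T).  Raises ValueError on ambiguous bases."""
    kmer = kmer.upper()
    if any(b not in "ACGT" for b in kmer):
        raise ValueError(f"k-mer contains non-ACGT base: {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def extract_kmers(sequence: str, ksize: int) -> Iterator[str]:
    """Yield the canonical k-mer of every all-ACGT window, in order.

    Windows containing any other symbol are skipped; sequences shorter than
    ksize yield nothing.  String-level reference path — sketch construction
    uses the vectorised equivalent.
    """
    if ksize < 3:
        raise ValueError(f"ksize must be >= 3, got {ksize}")
    seq = sequence.upper()
    for i in range(len(seq) - ksize + 1):
        window = seq[i : i + ksize]
        try:
            yield canonicalize(window)
        except ValueError:
            continue


def hash_kmer(kmer: str, hash_seed: int = 42) -> int:
    """Stable 64-bit hash of a single canonical k-mer."""
    out = hash_sequence(kmer, len(kmer), hash_seed)
    if out.size != 1:
        raise ValueError(f"not a valid k-mer: {kmer!r}")
    return int(out[0])


def _iter_hash_chunks(
    records: Iterable[str | bytes], ksize: int, hash_seed: int
) -> Iterator[tuple[np.ndarray, int]]:
    """Yield (hash stream, residue count) per buffered chunk of records."""
    buf: list[bytes] = []
    buflen = 0
    total = 0
    for rec in records:
        b = rec.encode("ascii") if isinstance(rec, str) else bytes(rec)
        total += len(b)
        buf.append(b)
        buflen += len(b) + 1
        if buflen >= _CHUNK_BASES:
            yield kmer_hashes(encode(b"N".join(buf)), ksize, hash_seed), total
            buf, buflen, total = [], 0, 0
    if buf or total:
        yield kmer_hashes(encode(b"N".join(buf)), ksize, hash_seed), total


def build_signature(
    records: Iterable[str | bytes],
    params: SketchParams,
    name: str = "",
    source_id: str = "",
) -> Signature:
    """Sketch a collection of sequences.

    Retains the sorted set of canonical-k-mer hashes below
    ``floor(2**64/scaled)``; abundances (if tracked) count occurrences of
    each retained hash in the k-mer stream.  The result is independent of
    record order.
    """
    retained: list[np.ndarray] = []
    total_bp = 0
    if params.scaled > 1:
        bound = np.uint64(params.max_hash)
    else:
        bound = None
    for hashes, chunk_bp in _iter_hash_chunks(records, params.ksize, params.hash_seed):
        total_bp += chunk_bp
        if bound is not None:
            hashes = hashes[hashes < bound]
        retained.append(hashes)

    stream = (
        np.concatenate(retained) if retained else np.empty(0, dtype=np.uint64)
    )
    if stream.size == 0:
        if total_bp == 0:
            warnings.warn(
                f"empty input for signature {name!r}; sketch has no hashes",
                stacklevel=2,
            )
        uniq = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    else:
        uniq, counts = np.unique(stream, return_counts=True)
    return Signature(
        name=name,
        source_id=source_id,
        source_length_bp=total_bp,
        params=params,
        hashes=uniq,
        abundances=counts.astype(np.int64) if params.track_abundance else None,
    )


def downsample(sig: Signature, new_scaled: int) -> Signature:
    """Exact downsampling: keep hashes below the new retention bound.

    Equals building the sketch at ``new_scaled`` directly; upsampling
    (new_scaled < current) is impossible and raises.
    """
    if new_scaled < sig.params.scaled:
        raise ValueError(
            f"cannot upsample: new_scaled={new_scaled} < current "
            f"scaled={sig.params.scaled}"
        )
    if new_scaled == sig.params.scaled:
        return sig
    new_params = replace(sig.params, scaled=new_scaled)
    mask = sig.hashes < np.uint64(new_params.max_hash)
    return Signature(
        name=sig.name,
        source_id=sig.source_id,
        source_length_bp=sig.source_length_bp,
        params=new_params,
        hashes=sig.hashes[mask],
        abundances=None if sig.abundances is None else sig.abundances[mask],
    )


def merge(sigs: Sequence[Signature]) -> Signature:
    """Union of sketches built with identical parameters.

    Hash sets are unioned, abundances summed per hash, lengths summed.
    """
    if not sigs:
        raise ValueError("merge requires at least one signature")
    ref = sigs[0].params
    for s in sigs[1:]:
        for fld in ("ksize", "scaled", "hash_seed", "track_abundance"):
            if getattr(s.params, fld) != getattr(ref, fld):
                raise ValueError(
                    f"parameter mismatch in merge: {fld} differs "
                    f"({getattr(s.params, fld)} != {getattr(ref, fld)})"
                )
    if len(sigs) == 1:
        return sigs[0]
    all_hashes = np.concatenate([s.hashes for s in sigs])
    uniq, inverse = np.unique(all_hashes, return_inverse=True)
    abundances = None
    if all(s.abundances is not None for s in sigs):
        counts = np.concatenate([s.abundances for s in sigs])
        abundances = np.bincount(inverse, weights=counts.astype(float)).astype(
            np.int64
        )
    return Signature(
        name=" + ".join(dict.fromkeys(s.name for s in sigs)),
        source_id=";".join(dict.fromkeys(s.source_id for s in sigs)),
        source_length_bp=sum(s.source_length_bp for s in sigs),
        params=ref,
        hashes=uniq,
        abundances=abundances,
    )


# ---------------------------------------------------------------------------
# sequence file input

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn", ".frn"}
_FASTQ_EXT = {".fq", ".fastq"}


def _sniff_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes if s.lower() != ".gz"]
    ext = suffixes[-1] if suffixes else ""
    if ext in _FASTQ_EXT:
        return "fastq"
    if ext in _FASTA_EXT:
        return "fasta"
    return "fasta"


def read_sequences(path: str | Path) -> Iterator[str]:
    """Yield sequences from a FASTA/FASTQ file, transparently gunzipping."""
    from Bio import SeqIO

    path = Path(path)
    fmt = _sniff_format(path)
    opener = gzip.open if path.suffix.lower() == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, fmt):
            yield str(record.seq)


def build_signature_from_files(
    paths: Sequence[str | Path],
    params: SketchParams,
    name: str = "",
    source_id: str = "",
) -> Signature:
    """Sketch one or more FASTA/FASTQ files as a single signature."""
    def _all_records() -> Iterator[str]:
        for p in paths:
            yield from read_sequences(p)

    if not name:
        name = Path(paths[0]).name
    if not source_id:
        source_id = ";".join(Path(p).name for p in paths)
    return build_signature(_all_records(), params, name=name, source_id=source_id)


# ---------------------------------------------------------------------------
# signature file format (structured text, one JSON document per file)


def _sig_to_obj(sig: Signature) -> dict:
    obj = {
        "name": sig.name,
        "source_id": sig.source_id,
        "source_length_bp": int(sig.source_length_bp),
        "ksize": sig.params.ksize,
        "scaled": sig.params.scaled,
        "hash_seed": sig.params.hash_seed,
        "track_abundance": sig.params.track_abundance,
        "hashes": [int(h) for h in sig.hashes],
        "checksum": sig.checksum(),
    }
    if sig.abundances is not None:
        obj["abundances"] = [int(a) for a in sig.abundances]
    return obj


def save_signatures(sigs: Sequence[Signature] | Signature, path: str | Path) -> None:
    """Write signatures to a JSON signature file (sorted hashes, checksummed)."""
    if isinstance(sigs, Signature):
        sigs = [sigs]
    doc = {
        "format": SIGNATURE_FORMAT,
        "version": SIGNATURE_VERSION,
        "signatures": [_sig_to_obj(s) for s in sigs],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _parse_sig_obj(obj: dict, where: str) -> Signature:
    required = (
        "name",
        "source_id",
        "source_length_bp",
        "ksize",
        "scaled",
        "hash_seed",
        "hashes",
        "checksum",
    )
    for key in required:
        if key not in obj:
            raise SignatureFormatError(f"{where}: missing field {key!r}")
    try:
        params = SketchParams(
            ksize=int(obj["ksize"]),
            scaled=int(obj["scaled"]),
            hash_seed=int(obj["hash_seed"]),
            track_abundance=bool(obj.get("track_abundance", "abundances" in obj)),
        )
    except ValueError as exc:
        raise SignatureFormatError(f"{where}: invalid parameters: {exc}") from exc
    try:
        sig = Signature(
            name=str(obj["name"]),
            source_id=str(obj["source_id"]),
            source_length_bp=int(obj["source_length_bp"]),
            params=params,
            hashes=np.array(obj["hashes"], dtype=np.uint64),
            abundances=(
                np.array(obj["abundances"], dtype=np.int64)
                if "abundances" in obj
                else None
            ),
        )
    except (ValueError, OverflowError) as exc:
        raise SignatureFormatError(f"{where}: {exc}") from exc
    if sig.checksum() != obj["checksum"]:
        raise SignatureFormatError(f"{where}: hash-list checksum mismatch")
    return sig


def load_signatures(path: str | Path) -> list[Signature]:
    """Read and validate a signature file; malformed input raises
    :class:`SignatureFormatError` with a field diagnostic."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SignatureFormatError(f"{path}: not valid JSON (line {exc.lineno})") from exc
    if not isinstance(doc, dict) or doc.get("format") != SIGNATURE_FORMAT:
        raise SignatureFormatError(f"{path}: not a {SIGNATURE_FORMAT} file")
    if doc.get("version") != SIGNATURE_VERSION:
        raise SignatureFormatError(f"{path}: unsupported version {doc.get('version')!r}")
    sigs = doc.get("signatures")
    if not isinstance(sigs, list):
        raise SignatureFormatError(f"{path}: field 'signatures' must be a list")
    return [
        _parse_sig_obj(obj, f"{path}: signature[{i}]") for i, obj in enumerate(sigs)
    ]
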