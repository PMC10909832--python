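"""Containment search of query sketches against metagenome sketches.

Containment C = |query ∩ subject| / |query| over canonical-k-mer hash
sets; the point ANI estimate is C^(1/k) ("cANI").  With k = 31, 5%
containment corresponds to ~91% ANI and 30% to ~96%, which is what makes
a containment threshold an ANI detection bound.  Matching-material
estimates use the field's back-of-envelope arithmetic: ~C·L matching
k-mers for a query of L bp, each spanning k bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .sketch import Signature, downsample, load_signatures, save_signatures

__all__ = [
    "SearchHit",
    "SignatureCollection",
    "containment",
    "ani_from_containment",
    "est_matching_kmers",
    "est_matching_bp",
    "search",
    "batch_search",
    "hits_to_frame",
    "write_hits",
    "read_hits",
]

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "query_name",
    "subject_id",
    "containment",
    "cani",
    "est_matching_kmers",
    "est_matching_bp",
    "query_bp",
    "ksize",
]


class ParameterMismatchError(ValueError):
    """Query and subject sketches were built with incompatible parameters."""


@dataclass(frozen=True)
class SearchHit:
    """One query-vs-metagenome containment result."""

    query_name: str
    subject_id: str
    containment: float
    cani: float
    est_matching_kmers: int
    est_matching_bp: int
    query_bp: int
    ksize: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.containment <= 1.0:
            raise ValueError(f"containment out of [0,1]: {self.containment}")
        if not 0.0 <= self.cani <= 1.0:
            raise ValueError(f"cani out of [0,1]: {self.cani}")

    @classmethod
    def from_containment(
        cls, query_name: str, subject_id: str, c: float, query_bp: int, ksize: int
    ) -> "SearchHit":
        m = est_matching_kmers(c, query_bp)
        return cls(
            query_name=query_name,
            subject_id=subject_id,
            containment=c,
            cani=ani_from_containment(c, ksize),
            est_matching_kmers=m,
            est_matching_bp=est_matching_bp(m, ksize),
            query_bp=query_bp,
            ksize=ksize,
        )


def containment(query: Signature, subject: Signature) -> float:
    """Fraction of the query's sketch hashes found in the subject's sketch.

    Sketches are harmonized to the coarser (larger) scaled of the pair —
    the only direction with exact semantics — and flattened to
    presence/absence before intersecting.
    """
    if query.params.ksize != subject.params.ksize:
        raise ParameterMismatchError(
            f"ksize mismatch: {query.params.ksize} != {subject.params.ksize}"
        )
    if query.params.hash_seed != subject.params.hash_seed:
        raise ParameterMismatchError(
            f"hash_seed mismatch: {query.params.hash_seed} != {subject.params.hash_seed}"
        )
    target = max(query.params.scaled, subject.params.scaled)
    q = downsample(query.flatten(), target)
    s = downsample(subject.flatten(), target)
    if len(q) == 0:
        raise ValueError(
            f"undetectable query at this scaled: {query.name!r} has no hashes "
            f"at scaled={target}"
        )
    shared = np.intersect1d(q.hashes, s.hashes, assume_unique=True).size
    return shared / len(q)


def ani_from_containment(c: float, ksize: int) -> float:
    """Point ANI estimate C^(1/k); 0 at C=0, 1 at C=1, monotone in C."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"containment out of [0,1]: {c}")
    if ksize < 3:
        raise ValueError(f"ksize must be >= 3, got {ksize}")
    if c == 0.0:
        return 0.0
    return float(c ** (1.0 / ksize))


def est_matching_kmers(c: float, query_bp: int) -> int:
    """Estimated matching k-mers: round(C × L), approximating the query's
    k-mer count by its length in bp."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"containment out of [0,1]: {c}")
    if query_bp < 0:
        raise ValueError(f"query_bp must be >= 0, got {query_bp}")
    return int(round(c * query_bp))


def est_matching_bp(matching_kmers: int, ksize: int) -> int:
    """Estimated matching base pairs: m × k."""
    if matching_kmers < 0:
        raise ValueError(f"matching_kmers must be >= 0, got {matching_kmers}")
    if ksize < 3:
        raise ValueError(f"ksize must be >= 3, got {ksize}")
    return matching_kmers * ksize


class SignatureCollection:
    """A searchable set of metagenome signatures keyed by accession.

    Members are expected to share ksize and hash_seed; incompatible members
    are skipped (with a warning) at query time rather than at load time, so
    a mixed manifest is still usable.
    """

    def __init__(self, signatures: Mapping[str, Signature] | None = None) -> None:
        self._sigs: dict[str, Signature] = dict(signatures or {})

    @classmethod
    def from_signatures(
        cls, sigs: Sequence[Signature], subject_ids: Sequence[str] | None = None
    ) -> "SignatureCollection":
        if subject_ids is None:
            subject_ids = [s.source_id or s.name for s in sigs]
        if len(set(subject_ids)) != len(subject_ids):
            raise ValueError("duplicate subject_id in collection")
        return cls(dict(zip(subject_ids, sigs)))

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "SignatureCollection":
        """Load from a tab-separated manifest with columns subject_id, path
        (paths resolved relative to the manifest's directory)."""
        manifest_path = Path(manifest_path)
        table = pd.read_csv(manifest_path, sep="\t", dtype=str)
        for col in ("subject_id", "path"):
            if col not in table.columns:
                raise ValueError(f"manifest missing column {col!r}")
        if table["subject_id"].duplicated().any():
            dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id in manifest: {dup!r}")
        base = manifest_path.parent
        sigs: dict[str, Signature] = {}
        for row in table.itertuples(index=False):
            p = Path(row.path)
            if not p.is_absolute():
                p = base / p
            loaded = load_signatures(p)
            if len(loaded) != 1:
                raise ValueError(
                    f"{p}: expected exactly one signature, found {len(loaded)}"
                )
            sigs[row.subject_id] = loaded[0]
        return cls(sigs)

    @classmethod
    def from_directory(cls, directory: str | Path) -> "SignatureCollection":
        """Load every ``*.sig`` file in a directory; subject_id is the stem."""
        directory = Path(directory)
        sigs: dict[str, Signature] = {}
        for p in sorted(directory.glob("*.sig")):
            loaded = load_signatures(p)
            if len(loaded) != 1:
                raise ValueError(
                    f"{p}: expected exactly one signature, found {len(loaded)}"
                )
            sigs[p.stem] = loaded[0]
        return cls(sigs)

    def add(self, subject_id: str, sig: Signature) -> None:
        if subject_id in self._sigs:
            raise ValueError(f"duplicate subject_id: {subject_id!r}")
        self._sigs[subject_id] = sig

    def write(self, directory: str | Path, manifest_name: str = "manifest.tsv") -> Path:
        """Save each member as ``<subject_id>.sig`` plus a manifest TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for subject_id in sorted(self._sigs):
            fname = f"{subject_id}.sig"
            save_signatures(self._sigs[subject_id], directory / fname)
            rows.append((subject_id, fname))
        manifest = directory / manifest_name
        pd.DataFrame(rows, columns=["subject_id", "path"]).to_csv(
            manifest, sep="\t", index=False
        )
        return manifest

    def __len__(self) -> int:
        return len(self._sigs)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._sigs

    def __getitem__(self, subject_id: str) -> Signature:
        return self._sigs[subject_id]

    def __iter__(self) -> Iterator[tuple[str, Signature]]:
        yield from sorted(self._sigs.items())

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self._sigs)


def search(
    query: Signature,
    collection: SignatureCollection,
    threshold: float = 0.05,
) -> list[SearchHit]:
    """All subjects whose containment of ``query`` strictly exceeds
    ``threshold``, sorted by containment descending then subject_id.

    Parameter-incompatible subjects are skipped with a logged warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold out of [0,1]: {threshold}")
    if len(collection) == 0:
        raise ValueError("collection is empty")
    hits: list[SearchHit] = []
    for subject_id, subject in collection:
        try:
            c = containment(query, subject)
        except ParameterMismatchError as exc:
            logger.warning(
                "skipping subject %s for query %s: %s", subject_id, query.name, exc
            )
            continue
        if c > threshold:
            hits.append(
                SearchHit.from_containment(
                    query.name, subject_id, c, query.source_length_bp,
                    query.params.ksize,
                )
            )
    hits.sort(key=lambda h: (-h.containment, h.subject_id))
    return hits


def batch_search(
    queries: Sequence[Signature],
    collection: SignatureCollection,
    threshold: float = 0.05,
) -> list[SearchHit]:
    """Concatenated per-query search results in stable query order.

    A failing query is logged and skipped; it does not abort the others.
    """
    all_hits: list[SearchHit] = []
    for query in queries:
        try:
            all_hits.extend(search(query, collection, threshold))
        except ValueError as exc:
            logger.warning("query %s failed: %s", query.name, exc)
    return all_hits


def hits_to_frame(hits: Sequence[SearchHit]) -> pd.DataFrame:
    """Hit table as a DataFrame with the documented column order."""
    if not hits:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return pd.DataFrame([h.__dict__ for h in hits])[HIT_COLUMNS]


def write_hits(hits: Sequence[SearchHit] | pd.DataFrame, path: str | Path) -> None:
    """Write a tab-separated hit table (containment/cANI at 4 decimals)."""
    frame = hits if isinstance(hits, pd.DataFrame) else hits_to_frame(hits)
    frame = frame.copy()
    for col in ("containment", "cani"):
        frame[col] = frame[col].map(lambda v: f"{v:.4f}")
    frame.to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS[:6] if c not in table.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return table
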