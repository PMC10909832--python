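"""Synthetic genomes, metagenomes and metadata with known ground truth.

The simulation model is deliberately simple enough to have closed-form
expectations:

* genomes are i.i.d. bases with a chosen GC fraction;
* relatives at a target ANI ``a`` are produced by per-base substitution
  with probability ``1 - a`` (no indels), so the expected fraction of
  intact k-mers is ``a**k``;
* a query planted at genome fraction ``f`` and identity ``a`` has
  expected k-mer containment ``f * a**k`` in the sample;
* reads are uniformly placed substrings with optional substitution
  errors, and carry their true origin interval, so mapping-validation
  fixtures (ground-truth PAF) need no aligner.

Everything is reproducible from a single integer seed: per-stream
generators are derived with ``numpy`` SeedSequence spawn keys, so one
number regenerates an entire experiment bit-identically.

:func:`build_benchmark` assembles the package's reference study: a
collection of synthetic metagenome signatures with planted components at
containment levels chosen far (>=5 standard errors) from the reporting
thresholds, plus a geographic metadata table, so threshold and
distinct-location counts are deterministic and recorded in the truth
manifest.
"""

from __future__ import annotations

import gzip
import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._hashing import encode
from .sketch import Signature, SketchParams, build_signature
from .search import SignatureCollection

__all__ = [
    "SimulationConfig",
    "ReadSet",
    "Component",
    "TruthManifest",
    "MetagenomeSample",
    "generate_genome",
    "mutate_to_ani",
    "expected_containment",
    "containment_sd",
    "simulate_reads",
    "plant_query",
    "compose_metagenome",
    "generate_metadata_fixture",
    "build_benchmark",
    "Benchmark",
]

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, *stream: int | str) -> np.random.Generator:
    """Deterministic sub-stream generator: one global seed, named streams."""
    key = tuple(
        zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in stream
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class SimulationConfig:
    """Default conditions for synthetic data.

    Desk-scale genome lengths (100 kb) stand in for the multi-Mbp genomes
    a real study queries; read length and error rate emulate short-read
    shotgun data (substitutions only).
    """

    genome_length_bp: int = 100_000
    gc_fraction: float = 0.5
    read_length: int = 150
    error_rate: float = 0.001
    depth: float = 10.0
    seed: int = 0
    background_genomes: int = 2

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.genome_length_bp < 1:
            raise ValueError("genome_length_bp must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


def generate_genome(length_bp: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random genome of i.i.d. bases with P(G)+P(C) = gc_fraction."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0,1]")
    rng = _rng(seed, "genome")
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    codes = rng.choice(4, size=length_bp, p=[at, gc, gc, at]).astype(np.uint8)
    return _BASE_LUT[codes].tobytes().decode("ascii")


def mutate_to_ani(sequence: str, target_ani: float, seed: int = 0) -> str:
    """Substitute each base with probability 1 - target_ani (no indels)."""
    if not 0.0 <= target_ani <= 1.0:
        raise ValueError("target_ani must be in [0,1]")
    if target_ani == 1.0:
        return sequence
    rng = _rng(seed, "mutate")
    codes = encode(sequence).copy()
    if (codes > 3).any():
        raise ValueError("sequence contains non-ACGT bases")
    hit = rng.random(codes.size) < (1.0 - target_ani)
    shift = rng.integers(1, 4, size=codes.size, dtype=np.uint8)
    codes[hit] = (codes[hit] + shift[hit]) % 4
    return _BASE_LUT[codes].tobytes().decode("ascii")


def expected_containment(ani: float, fraction: float, ksize: int) -> float:
    """Closed-form expected containment f * a**k under the substitution
    model (independent-site approximation; approximate for real genomes)."""
    if not 0.0 <= ani <= 1.0 or not 0.0 <= fraction <= 1.0:
        raise ValueError("ani and fraction must be in [0,1]")
    if ksize < 3:
        raise ValueError("ksize must be >= 3")
    return fraction * ani**ksize


def containment_sd(
    ani: float,
    fraction: float,
    ksize: int,
    n_kmers: int,
    sketch_size: int,
) -> float:
    """Standard error of measured containment around f * a**k.

    Two sources: FracMinHash sampling (binomial over the harmonized query
    sketch of ``sketch_size`` hashes) and the mutation process itself,
    whose k-mer survival indicators are positively correlated across the
    2k-1 overlapping windows (Cov(X_i, X_{i+t}) = a**(k+t) - a**(2k) for
    t < k), evaluated over the ``n_kmers`` genome windows.
    """
    c = expected_containment(ani, fraction, ksize)
    var = c * (1.0 - c) / max(sketch_size, 1)
    if 0.0 < ani < 1.0:
        p = ani**ksize
        geo = ani * (1.0 - ani ** (ksize - 1)) / (1.0 - ani)
        bracket = (1.0 - p) + 2.0 * (geo - (ksize - 1) * p)
        var += fraction * p * bracket / max(n_kmers, 1)
    return math.sqrt(var)


@dataclass
class ReadSet:
    """Simulated reads from one source sequence, with true origins.

    ``origins`` holds the 0-based half-open interval each read was drawn
    from on the source, enabling ground-truth alignment fixtures without
    running an aligner.
    """

    source_id: str
    ids: list[str]
    sequences: list[str]
    origins: np.ndarray  # (n, 2) start/end on the source

    def __len__(self) -> int:
        return len(self.ids)

    def total_bases(self) -> int:
        return sum(len(s) for s in self.sequences)

    def write_fastq(self, path: str | Path, compress: bool | None = None) -> None:
        path = Path(path)
        if compress is None:
            compress = path.suffix == ".gz"
        opener = gzip.open if compress else open
        with opener(path, "wt") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def to_paf(self, target_id: str, target_length: int) -> str:
        """Ground-truth PAF: each read mapped at its true origin interval."""
        lines = []
        for rid, seq, (start, end) in zip(self.ids, self.sequences, self.origins):
            rlen = len(seq)
            lines.append(
                f"{rid}\t{rlen}\t0\t{rlen}\t+\t{target_id}\t{target_length}"
                f"\t{int(start)}\t{int(end)}\t{rlen}\t{rlen}\t60\ttp:A:P"
            )
        return "\n".join(lines) + ("\n" if lines else "")

    def write_paf(self, path: str | Path, target_id: str, target_length: int) -> None:
        Path(path).write_text(self.to_paf(target_id, target_length))


def simulate_reads(
    genome: str,
    depth: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    source_id: str = "genome",
    id_prefix: str | None = None,
) -> ReadSet:
    """Uniformly placed substitution-error reads totalling ~depth × length.

    The read count is Poisson with mean depth × L / read_length; start
    positions are uniform over valid placements.
    """
    length = len(genome)
    if read_length > length:
        raise ValueError(f"read_length {read_length} exceeds genome length {length}")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0,1]")
    rng = _rng(seed, "reads", source_id)
    n_reads = int(rng.poisson(depth * length / read_length))
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    codes = encode(genome)
    matrix = codes[starts[:, None] + np.arange(read_length)]
    if error_rate > 0.0 and n_reads:
        hit = rng.random(matrix.shape) < error_rate
        shift = rng.integers(1, 4, size=matrix.shape, dtype=np.uint8)
        matrix = np.where(hit, (matrix + shift) % 4, matrix)
    seqs = _BASE_LUT[matrix]
    prefix = id_prefix if id_prefix is not None else source_id
    return ReadSet(
        source_id=source_id,
        ids=[f"{prefix}|r{i}" for i in range(n_reads)],
        sequences=[seqs[i].tobytes().decode("ascii") for i in range(n_reads)],
        origins=np.column_stack([starts, starts + read_length]).astype(np.int64),
    )


@dataclass
class Component:
    """One organism in a synthetic metagenome, with its provenance."""

    genome_id: str
    sequence: str
    depth: float
    query_id: str | None = None  # query genome this derives from, if any
    ani: float = 1.0
    genome_fraction: float = 1.0


def plant_query(
    query_id: str,
    query_sequence: str,
    ani: float,
    fraction: float,
    depth: float,
    seed: int,
) -> Component:
    """Derive a planted relative of a query: mutate to ``ani``, keep the
    leading ``fraction`` of the genome, sequence at ``depth``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0,1]")
    mutant = mutate_to_ani(query_sequence, ani, seed=seed)
    keep = int(round(fraction * len(mutant)))
    return Component(
        genome_id=f"{query_id}~ani{ani:g}~f{fraction:g}",
        sequence=mutant[:keep],
        depth=depth,
        query_id=query_id,
        ani=ani,
        genome_fraction=fraction,
    )


@dataclass
class TruthManifest:
    """Ground-truth composition of one synthetic metagenome."""

    subject_id: str
    seed: int
    components: list[dict] = field(default_factory=list)

    def expected_containment_for(self, query_id: str, ksize: int) -> float:
        return sum(
            expected_containment(c["ani"], c["genome_fraction"], ksize)
            for c in self.components
            if c.get("query_id") == query_id
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MetagenomeSample:
    """A composed synthetic metagenome: reads per component plus its truth."""

    subject_id: str
    parts: list[ReadSet]
    manifest: TruthManifest

    def sequences(self) -> Iterator[str]:
        for part in self.parts:
            yield from part.sequences

    def part(self, source_id: str) -> ReadSet:
        for p in self.parts:
            if p.source_id == source_id:
                return p
        raise KeyError(source_id)

    def sketch(self, params: SketchParams, name: str | None = None) -> Signature:
        return build_signature(
            self.sequences(), params,
            name=name or self.subject_id, source_id=self.subject_id,
        )

    def write_fastq(self, path: str | Path) -> None:
        path = Path(path)
        compress = path.suffix == ".gz"
        opener = gzip.open if compress else open
        with opener(path, "wt") as fh:
            for part in self.parts:
                for rid, seq in zip(part.ids, part.sequences):
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def compose_metagenome(
    subject_id: str,
    components: Sequence[Component],
    seed: int,
    read_length: int = 150,
    error_rate: float = 0.0,
) -> MetagenomeSample:
    """Sequence every component into one read set with a truth manifest."""
    if not components:
        raise ValueError("at least one component required")
    parts = []
    manifest = TruthManifest(subject_id=subject_id, seed=seed)
    for i, comp in enumerate(components):
        parts.append(
            simulate_reads(
                comp.sequence,
                depth=comp.depth,
                read_length=read_length,
                error_rate=error_rate,
                seed=seed,
                source_id=comp.genome_id,
                id_prefix=f"{subject_id}|{comp.genome_id}",
            )
        )
        manifest.components.append(
            {
                "genome_id": comp.genome_id,
                "query_id": comp.query_id,
                "ani": comp.ani,
                "genome_fraction": comp.genome_fraction,
                "depth": comp.depth,
                "read_length": read_length,
                "error_rate": error_rate,
            }
        )
    return MetagenomeSample(subject_id=subject_id, parts=parts, manifest=manifest)


# ---------------------------------------------------------------------------
# metadata fixture

# Base sites spanning polar and temperate latitudes; labels repeat across
# samples so distinct-location counting is actually exercised.
_SITES = [
    ("Lake Fryxell, Antarctica", -77.36, 162.60),
    ("Lake Vanda, Antarctica", -77.53, 161.58),
    ("Ace Lake, Antarctica", -68.47, 78.19),
    ("Rauer Islands, Antarctica", -68.85, 77.84),
    ("Nunavut, Canada", 64.67, -98.06),
    ("Svalbard, Norway", 78.22, 15.63),
    ("Puca Glacier, Peru", -13.77, -70.99),
    ("Moab Desert, Utah, USA", 38.57, -109.55),
    ("Negev Desert, Israel", 30.61, 34.80),
    ("Salar del Huasco, Chile", -20.27, -68.88),
    ("Etang de Berre, France", 43.45, 5.10),
    ("Big Soda Lake, Nevada, USA", 39.52, -118.88),
    ("Lake Mendota, Wisconsin, USA", 43.11, -89.42),
    ("Yanghu Wetland, China", 30.47, 114.22),
]


def generate_metadata_fixture(
    n_samples: int,
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Plausible geographic metadata for n samples (duplicated labels and
    polar-to-temperate coordinate spread included by construction)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if subject_ids is None:
        subject_ids = [f"SYN{i:04d}" for i in range(n_samples)]
    elif len(subject_ids) != n_samples:
        raise ValueError("subject_ids length must equal n_samples")
    rng = _rng(seed, "metadata")
    rows = []
    for i, sid in enumerate(subject_ids):
        label, lat, lon = _SITES[int(rng.integers(0, len(_SITES)))]
        rows.append(
            {
                "subject_id": sid,
                "location_label": label,
                "latitude": lat,
                "longitude": lon,
                "environment_note": "synthetic sample",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference benchmark


@dataclass
class Benchmark:
    """Paths and ground truth of a generated benchmark study."""

    root: Path
    query_fastas: dict[str, Path]
    query_genomes: dict[str, str]
    collection_manifest: Path
    metadata_csv: Path
    manifests: dict[str, TruthManifest]
    expected_summary: pd.DataFrame
    ksize: int
    scaled: int


# Planted containment levels. Expected containment f * a**k for k = 31 sits
# >= 5 standard errors from every reporting threshold (0.75/0.50/0.25/0.05)
# at the benchmark's sketch sizes, so planned counts are deterministic.
_PLAN_LEVELS = [
    ("full", 1.0, 1.0),      # C ~ 1.0      -> counted at >75%
    ("strong", 1.0, 0.62),   # C ~ 0.62     -> counted at >50%
    ("strong", 1.0, 0.62),
    ("medium", 1.0, 0.37),   # C ~ 0.37     -> counted at >25%
    ("medium", 1.0, 0.37),
    ("weak", 0.94, 1.0),     # C ~ 0.147    -> counted at >5%
    ("weak", 0.94, 1.0),
    ("weak", 0.94, 1.0),
    ("trace", 1.0, 0.02),    # C ~ 0.02     -> counted in total only
    ("trace", 1.0, 0.02),
]


def build_benchmark(
    root: str | Path,
    n_samples: int = 200,
    n_queries: int = 3,
    seed: int = 0,
    genome_length_bp: int = 100_000,
    ksize: int = 31,
    scaled: int = 100,
    read_length: int = 150,
    component_depth: float = 6.0,
    background_depth: float = 2.0,
) -> Benchmark:
    """Generate the package's reference synthetic study on disk.

    ``n_queries`` query genomes are each planted in 10 samples at the
    levels of ``_PLAN_LEVELS``; the remaining samples carry only unrelated
    background genomes.  Reads are error-free (the exact-recovery
    condition) at modest depth, and every sample gets geographic metadata
    arranged so the per-query count of distinct locations above 25%
    containment is exactly 4 (five qualifying samples, two sharing a
    site).  Writes query FASTAs, one signature file per sample plus a
    manifest, the metadata table, per-sample truth manifests, and the
    planned summary table.
    """
    n_planted = n_queries * len(_PLAN_LEVELS)
    if n_samples < n_planted:
        raise ValueError(
            f"n_samples={n_samples} < {n_planted} planted samples required"
        )
    root = Path(root)
    (root / "queries").mkdir(parents=True, exist_ok=True)
    sig_dir = root / "collection"
    sig_dir.mkdir(parents=True, exist_ok=True)

    params = SketchParams(ksize=ksize, scaled=scaled)

    query_genomes: dict[str, str] = {}
    query_fastas: dict[str, Path] = {}
    for qi in range(n_queries):
        qname = f"query_{qi}"
        genome = generate_genome(
            genome_length_bp, gc_fraction=0.5, seed=seed * 1000 + 17 + qi
        )
        query_genomes[qname] = genome
        fasta = root / "queries" / f"{qname}.fasta"
        with open(fasta, "w") as fh:
            fh.write(f">{qname}\n")
            for i in range(0, len(genome), 80):
                fh.write(genome[i : i + 80] + "\n")
        query_fastas[qname] = fasta

    n_background_pool = 12
    background_pool = [
        generate_genome(genome_length_bp, 0.5, seed=seed * 1000 + 101 + j)
        for j in range(n_background_pool)
    ]

    bg_rng = _rng(seed, "benchmark", "background-choice")
    collection = SignatureCollection()
    manifests: dict[str, TruthManifest] = {}
    planted_of: dict[str, list[tuple[str, str]]] = {q: [] for q in query_genomes}

    sample_ids = [f"SYN{i:04d}" for i in range(n_samples)]
    for i, sid in enumerate(sample_ids):
        components: list[Component] = []
        if i < n_planted:
            qname = f"query_{i // len(_PLAN_LEVELS)}"
            level, ani, fraction = _PLAN_LEVELS[i % len(_PLAN_LEVELS)]
            components.append(
                plant_query(
                    qname,
                    query_genomes[qname],
                    ani=ani,
                    fraction=fraction,
                    depth=component_depth,
                    seed=seed * 100_000 + i,
                )
            )
            planted_of[qname].append((sid, level))
        bg_idx = int(bg_rng.integers(0, n_background_pool))
        components.append(
            Component(
                genome_id=f"bg_{bg_idx}",
                sequence=background_pool[bg_idx],
                depth=background_depth,
            )
        )
        sample = compose_metagenome(
            sid, components, seed=seed * 100_000 + i,
            read_length=read_length, error_rate=0.0,
        )
        collection.add(sid, sample.sketch(params))
        manifests[sid] = sample.manifest

    manifest_path = collection.write(sig_dir)

    # metadata: qualifying (>25%) samples per query sit at 5 sites of which
    # two share a label -> 4 distinct locations per query by construction
    site_rng = _rng(seed, "benchmark", "sites")
    meta_rows = []
    assigned: dict[str, tuple[str, float, float]] = {}
    for qi, qname in enumerate(sorted(planted_of)):
        qualifying = [
            sid for sid, level in planted_of[qname] if level in ("full", "strong", "medium")
        ]
        # rotate the site pool per query; first two qualifying samples share
        sites = [_SITES[(3 * qi + j) % len(_SITES)] for j in range(len(qualifying))]
        if len(qualifying) >= 2:
            sites[1] = sites[0]
        for sid, site in zip(qualifying, sites):
            assigned[sid] = site
    for sid in sample_ids:
        label, lat, lon = assigned.get(
            sid, _SITES[int(site_rng.integers(0, len(_SITES)))]
        )
        meta_rows.append(
            {
                "subject_id": sid,
                "location_label": label,
                "latitude": lat,
                "longitude": lon,
                "environment_note": "synthetic sample",
            }
        )
    metadata_csv = root / "metadata.csv"
    pd.DataFrame(meta_rows).to_csv(metadata_csv, index=False)

    truth_path = root / "truth.json"
    truth_path.write_text(
        json.dumps(
            {sid: m.to_dict() for sid, m in manifests.items()},
            indent=1,
            sort_keys=True,
        )
    )

    # planned per-query summary (what a correct pipeline must report)
    level_counts = {"full": 0, "strong": 0, "medium": 0, "weak": 0, "trace": 0}
    for level, _, _ in _PLAN_LEVELS:
        level_counts[level] += 1
    n_full = level_counts["full"]
    n_ge50 = n_full + level_counts["strong"]
    n_ge25 = n_ge50 + level_counts["medium"]
    n_ge5 = n_ge25 + level_counts["weak"]
    total = len(_PLAN_LEVELS)
    expected_summary = pd.DataFrame(
        [
            {
                "query_name": q,
                "hits_gt_75pct": n_full,
                "hits_gt_50pct": n_ge50,
                "hits_gt_25pct": n_ge25,
                "hits_gt_5pct": n_ge5,
                "total_hits": total,
                "distinct_locations_gt_25pct": n_ge25 - 1,
            }
            for q in sorted(query_genomes)
        ]
    )

    return Benchmark(
        root=root,
        query_fastas=query_fastas,
        query_genomes=query_genomes,
        collection_manifest=manifest_path,
        metadata_csv=metadata_csv,
        manifests=manifests,
        expected_summary=expected_summary,
        ksize=ksize,
        scaled=scaled,
    )
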