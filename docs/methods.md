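# Methods

## FracMinHash sketching

A sketch of a DNA sequence set is the sorted set of 64-bit hashes of its
canonical k-mers that fall strictly below `floor(2⁶⁴ / s)`, where `s` is
the *scaled* divisor. Because retention depends only on a k-mer's hash
value, two sketches built at the same `(k, s, seed)` sample the same
fraction of k-mer space, and the containment of one hash set in another
is an unbiased estimate of the containment of the underlying k-mer sets.
The strict `<` retention bound makes downsampling exact:
`downsample(build(X, s₁), s₂) == build(X, s₂)` for any `s₂ ≥ s₁`, which
is how sketches built at different resolutions are harmonized (always to
the coarser scaled — the only direction with exact semantics).

**Canonicalisation.** Each window is compared with its reverse complement
and the lexicographically smaller string (A<C<G<T) is kept, so matching
is strand-neutral. Windows containing any non-ACGT symbol are skipped
outright (no expansion of IUPAC ambiguity codes); input case is ignored.

**Hashing.** k-mers are packed big-endian into 2-bit codes (numeric
order = lexicographic order, so the canonical choice is an elementwise
minimum) and passed through the splitmix64 output permutation, a
bijective 64-bit finisher with strong avalanche behaviour, after XOR
with a pre-mixed seed word (default seed 42). Uniformity over the 64-bit
range — the property scaled retention relies on — is checked by a
binomial test in the suite. `k ≤ 32` uses one word; `33 ≤ k ≤ 64` packs
into a (hi, lo) pair and folds both words into the hash. Any stable,
well-mixed 64-bit hash would serve; hash values themselves carry no
meaning beyond equality and uniformity.

**Abundance.** Per-hash occurrence counts can be recorded (and survive
merges, which sum them), but containment always flattens sketches to
presence/absence: containment is a set proportion by definition.

**Defaults.** `k = 31`, `scaled = 1000`, seed 42. The pipeline sketches
queries at k ∈ {21, 31, 51} and analyses at 31; k=21 is more sensitive
but less specific, k=51 the reverse, and all quantitative anchors
(cANI conversion in particular) are stated at k=31.

## Containment, cANI, and matching material

For query sketch Q and subject sketch S (same k and seed, harmonized
scaled): `C = |Q ∩ S| / |Q|`. An empty harmonized query is an error
("undetectable query at this scaled") rather than a silent zero.

The ANI point estimate is `cANI = C^(1/k)`, the inversion of the
independent-site survival probability `a^k`; it is exact on the
synthetic substitution model and a well-behaved approximation on real
genomes. No confidence interval is attached: the point estimate is what
the reporting thresholds act on. Matching-material arithmetic uses
`m = round(C·L)` k-mers and `m·k` bp, approximating the k-mer count of
an L-bp genome by L (not `L − k + 1`); for multi-Mbp genomes the
difference is below the precision anything downstream uses.

Search returns subjects with `C > t` (strict, default `t = 0.05`),
sorted by containment descending with ties broken by subject accession;
parameter-incompatible collection members are skipped with a warning
rather than silently dropped.

## Biogeography report

Threshold counts use strict `>` at 0.75/0.50/0.25/0.05 plus a total over
`C > 0`. To make the total computable, the end-to-end runs search at
threshold 0 and let the report stage apply the 5% cut; searching
directly at 0.05 yields identical columns except the total.

"Geographically distinct" has no universal definition; this package
counts distinct location keys, where a key is the case-folded,
whitespace-normalized location label when present, else the (latitude,
longitude) pair rounded to 0.1° (~11 km), else a shared "unknown"
bucket. The rule is deliberately metadata-tolerant: archive metadata is
frequently incomplete, so missing metadata flags a row but never drops
it. Map export emits a GeoJSON FeatureCollection (WGS84 lon-lat) of
hits with coordinates above 10% containment.

## Mapping validation

Given alignments of sample reads to a query genome (PAF or SAM),
per-position depth is the interval union of target spans; breadth of
coverage (`detection_pct`) is the share of positions with depth ≥ 1.
**Effective coverage** is defined here as total aligned bases divided by
covered positions — mean depth over the detected region — which is ≥ 1
whenever anything is detected. Secondary/supplementary alignments
contribute to depth but not to the mapped-read count. Coordinates are
0-based half-open internally; SAM's 1-based coordinates are converted at
parse time, and aligned bases come from CIGAR M/=/X operations (PAF:
block length clipped to the target span).

Read mapping tolerates the substitutions that destroy exact 31-mers, so
for genuinely present organisms detection percentage generally meets or
exceeds containment percentage; the comparison row flags
`detection_pct ≥ containment%` to surface the (rare, high-containment)
exceptions.

## Synthetic data model

* **Genomes**: i.i.d. bases at a chosen GC fraction. Default desk-scale
  length 100 kb (real query genomes are tens of times larger; sketch
  statistics scale with sketch size, not genome size, so conclusions
  about estimator calibration transfer).
* **Relatives at ANI a**: per-base substitution with probability
  `1 − a`, no indels — chosen so expected containment stays closed-form
  (`f·a^k` for a fraction-f planting). Real divergence includes indels
  and rearrangements; the model is documented as optimistic in that
  respect.
* **Reads**: Poisson-count, uniformly placed, fixed-length, with
  substitution errors at `error_rate` (default 0.001; exact-recovery
  tests and the benchmark use 0). Each read carries its true origin
  interval, from which ground-truth PAF alignments are emitted — no
  aligner is run or wrapped.
* **Sampling noise**: measured containment scatters around `f·a^k` with
  variance from two sources — binomial sketch sampling
  (`C(1−C)/|Q|`) and the mutation process itself, whose k-mer survival
  indicators are correlated across the 2k−1 overlapping windows
  (`Cov(Xᵢ, Xᵢ₊ₜ) = a^(k+t) − a^(2k)`, t < k). `containment_sd`
  implements the combined closed form used by every tolerance test.
  Finite read depth d additionally caps the fraction of genome k-mers
  captured at `1 − exp(−d·(R−k+1)/R)` for read length R; benchmark
  depths are chosen so this factor never moves a planted level across a
  reporting threshold.
* **Reproducibility**: one integer seed; each consumer derives a named
  sub-stream via SeedSequence spawn keys, so any artifact regenerates
  bit-identically.

### Reference benchmark

`build_benchmark` creates 3 query genomes and 200 metagenome
signatures: per query, 10 planted samples at containment levels
{≈1.0, 0.62, 0.62, 0.37, 0.37, 0.147, 0.147, 0.147, 0.02, 0.02}
(fraction-based levels are exact; 0.147 comes from ANI 0.94), the rest
background-only. Every level sits ≥ ~5 combined standard errors from
the nearest reporting threshold, so the planned per-query summary —
1 / 3 / 5 / 8 hits above 75/50/25/5%, 10 total, 4 distinct locations
above 25% (five qualifying samples, two sharing a site) — is
deterministic. Passing this benchmark demonstrates correct threshold
accounting and estimator calibration under the simulation model; it
does not demonstrate robustness to indels, uneven community abundance,
GC bias, or contaminated references, none of which the generator
emulates.

## Pipeline

A run is a pure function of (inputs, config, seed): fixed float
formatting (4 decimals for containment fractions, 2 for percentages),
sorted outputs, and a run manifest with input/output SHA-256 checksums
make reruns byte-identical. Stage failures halt with the stage name.
Defaults: k sizes [21, 31, 51] (analysis 31), scaled 1000, search
threshold 0.05, report thresholds [0.75, 0.50, 0.25, 0.05], map floor
0.10, distinct-location threshold 0.25.

## Known limitations

* Substitution-only divergence and error models; no indels or
  structural variation, so `a^k` is exact here but approximate in vivo.
* cANI is a point estimate; no interval.
* "Effective coverage" and "geographically distinct" are this package's
  operational definitions (stated above), not community standards.
* The signature collection is loaded in memory; there is no inverted
  index, so searching archive-scale collections (10⁵–10⁶ samples) is
  out of scope.
* Low containment never demonstrates absence: it reflects relatedness,
  abundance, and sequencing depth jointly.
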