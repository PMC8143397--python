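# Methods

## The federation model

`fedvar` models a federation of *platforms*: independent relational query
engines, each owning its tables, metering its own scans, and exchanging
data only through an explicit transfer path. Each platform is one embedded
sqlite engine instance (file-backed or in-memory); two engine instances
constitute two "clouds". The abstraction mirrors serverless warehouse
billing — a query is charged by the bytes it reads — without reproducing
any vendor's internals; remote adapters would slot in behind the same
`Platform` interface.

Queries come in two kinds. A **stat query** fans out to every platform
holding a shard of a cohort, computes matched-record counts and allele
counts (AC, AN) locally, and merges the integers exactly. A **data query**
is a cross-platform join: it estimates both sides' matching subsets,
moves the smaller one (compressed, optionally encrypted) to the platform
hosting the larger, joins there, and cleans up.

## Schema normalization

All inputs are normalized to a BED-style relational schema in 0-based
half-open coordinates: `chromosome_name, start_position, end_position,
reference_bases, alternate_bases`, remaining fields passed through
unchanged in an `extra`/`attributes` map. VCF `POS` (1-based) maps to
`start_position = POS − 1`, `end_position = start_position + len(REF)`.
Multi-allelic sites are split into one row per alternate allele so that
AC — and hence allele frequency — is per-alternate. Monomorphic sites
(`ALT = .`) are dropped.

AC/AN come from genotype columns when present (missing "." alleles are
excluded from AN; half-calls contribute their called allele; `|` is
treated like `/`; non-diploid calls are rejected naming the sample),
otherwise from INFO `AC`/`AN`, otherwise 0/0 — such rows then contribute
nothing to frequency denominators. Chromosome names are matched as exact
strings; no "chr"-prefix harmonization is attempted (a caller can
normalize names before ingest if two sources disagree).

## Partitioning, clustering, scan accounting

Tables are partitioned by integer-range binning of the start position:
`bin_id = ⌊start_position / bin_width⌋`, chromosome-agnostic, with the
(chromosome, bin) pair as the pruning unit. The default
`bin_width = 62 500 bp` keeps positions up to 250 Mb (the longest human
chromosome) within 4 000 bins, the partition-count ceiling typical of
serverless warehouses; it is configurable per table. Whether such a
partition budget should be global or per chromosome is a genuinely open
choice; binning on position alone was chosen because it makes bin ids
comparable across tables regardless of chromosome composition.

Rows are stored physically ordered by (chromosome, start) — "clustering"
emulated as insertion order. Per-(chromosome, bin) row counts and
serialized byte sizes are computed at load time; `bytes_scanned` for a
query is the summed size of the partitions its predicate can touch
(`bytes_of_partitions_read`), or that figure scaled by the projected
columns' share of the table's bytes when a platform declares
`bytes_of_columns_read`. The two modes bracket plausible metering
semantics of real engines, and each platform logs which one it uses. The
canonical serialization (tab-delimited row text, JSON for the passthrough
map) is used for *all* byte figures — partition stats, temp tables,
transfer payloads — so ledger arithmetic is internally consistent.

Region predicates are widened on the left by the table's longest stored
interval (`max_interval_span`) before bin-range computation; otherwise a
record whose interval starts in an earlier bin but overlaps the query
region could be pruned away. Soundness (pruned row multiset == full-scan
row multiset) is property-tested. rsID predicates prune through a small
rsID → (chromosome, bin) side index maintained at ingest — the moral
equivalent of querying with a known binID predicate; index lookups are
treated as metadata reads and not metered.

## Exact federated statistics

For a cohort split by *sample* across shards (every site row present on
every shard), the merged frequency is Σ AC / Σ AN over shards — exact
integer pooling, reported as a rational plus a 6-significant-digit
decimal. Averaging shard frequencies would be wrong under unequal shard
sizes. A shard that lacks a site row contributes nothing to AN there; the
bundled cohort splitter therefore always writes all site rows to both
halves, which is also the natural shape of a sample-sharded warehouse
table. Any unreachable shard aborts the query with a partial-failure
error listing completed shards — no silent partial merges.

## Transfer planning and the join

Subset estimates are made *before* extraction: an exact pruned row count
times the table's mean serialized row width. Bytes, not row counts, drive
the plan (rows of the two tables can differ in width by orders of
magnitude); the estimate-vs-actual gap is visible in the ledger. The
smaller side moves; ties break to the lexicographically smaller platform
name; `move_larger` inverts the choice for deployments whose policy pins
one side in place. Two-party joins only.

The payload is the canonical row serialization, zlib-compressed, with a
SHA-256 checksum verified end-to-end. Optional encryption uses a
lightweight stdlib authenticated scheme — SHA-256 counter-mode keystream
with an HMAC-SHA256 tag, encrypt-then-MAC, random nonce — suitable for
the in-process deployments this package targets; a production deployment
across real network boundaries should substitute a vetted AEAD behind the
same `pack`/`unpack` interface. Encryption is off by default for
in-process backends.

The receiving platform materializes the payload as a temporary table
(`fed_tmp_<query>_<suffix>`, suffix drawn from the federation seed for
reproducibility), joins, and drops it in a `finally` block, so cleanup
survives join failures. The join itself is strict half-open interval
intersection — `max(starts) < min(ends)` on the same chromosome, variant
restricted to the query region; boundary-touching intervals do not join.
Output order is deterministic: (chromosome, variant start, annotation
start, alternate allele, annotation end).

## Cost ledger

Append-only entries: scans (raw bytes, wire 0) and transfer_out/
transfer_in pairs sharing a query id and wire size. Derived figures:
`egress_reduction_percent = 100·(1 − scanned/full)` at 2 decimals;
`fraction_moved_percent = 100·moved/full` at one significant digit;
`break_even_queries = ⌊full/per_query⌋` in exact rational arithmetic.
Sizes are stored in bytes; display helpers use the binary convention
(1 GB = 1024 MB). Dollar pricing is a user-supplied multiplier in
`report`, not a modeled quantity.

## Synthetic data

The simulator emulates the split-cohort study design: diploid genotypes
drawn as two independent Bernoulli(p) alleles per sample (Hardy–Weinberg)
at per-variant frequencies sampled uniform(0.01, 0.5) by default (common
variants, the informative regime for frequency estimation) or supplied
explicitly; unique sorted positions; default genome two 10 Mb
chromosomes — a scaled-down stand-in chosen so a 5 000-variant cohort
populates a few hundred 62.5 kb bins. It deliberately omits linkage
disequilibrium, population structure, phasing and sequencing error: no
tested operation depends on them, so passing tests demonstrate exact
federation arithmetic and join/pruning correctness, not robustness to
real-data artifacts such as chromosome-name drift, structural variants or
genotype-quality filtering. The annotation generator gives each synthetic
gene a region (20–120 kb) and a fixed number of overlapping intervals
with symbol/score/id attributes; "TP53" can be requested by name for the
worked annotation scenario. The four-variant rsID fixture carries
hand-set genotypes (one half-missing call included) so AC/AN bookkeeping
has frozen expected values.

All randomness flows from explicit seeds (numpy `default_rng` in the
simulator, the federation seed for temp-table suffixes); outputs are
byte-identical across runs.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 20–2 000 samples × 5 000 variants,
annotation tables of a few genes × a handful of records, and 20-seed join
sweeps — sizes chosen so the full suite completes in well under a minute
on a single core while still populating hundreds of partitions and
exercising every pipeline stage. Equality assertions on federated
statistics are exact (integer/rational), not tolerance-based. Simulator
calibration is checked against the central 99.9 % binomial interval at
4 000 allele draws.

## Known limitations

- Two-platform data queries only; k-way federation is out of scope.
- No variant normalization (left-alignment), liftover, or
  reference-genome validation; coordinates are trusted as given.
- Per-alternate frequency reporting at multi-allelic sites; an rsID
  selector matching several split alternates sums their rows' AC and AN,
  so per-site AN is double-counted in that one reporting path.
- The stat-query layer supports rsID/site selectors; stratified
  (per-population) frequencies and association testing are non-goals.
- Scan metering is modeled (partition/column bytes), not measured from a
  vendor billing API.
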