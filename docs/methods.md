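# Methods

This note records the data model, the algorithmic choices, the defaults,
and the limits of what the test suite demonstrates.

## Coordinate conventions

All in-memory coordinates are 0-based, half-open — the convention of
`chromStart`/`chromEnd` storage columns. The browser's 1-based
fully-closed convention exists only at the string boundary:
`parse_interval("chr1:123,456-456,789")` yields internal
`start = 123455`, `end = 456789`, and `format_interval` inverts this
exactly (commas accepted on input, never emitted). Keeping a single
internal convention removes the classic off-by-one hazards from bin
arithmetic and SQL predicates. Chromosome names are opaque strings — no
normalization between `1` and `chr1` is attempted — and intervals carry
no strand: positional queries are strand-agnostic, and strand ordering
belongs to gene models.

Empty and inverted intervals are rejected at construction, so every
downstream operation may assume `start < end`.

## The bin index

The standard five-level scheme partitions positions 0 … 2²⁹ into bins of
span 2²⁹, 2²⁶, 2²³, 2²⁰ and 2¹⁷ bp (512 Mb down to 128 kb), numbered
level by level with offsets 0, 1, 9, 73, 585 (4681 bins total).
`bin_from_interval` finds the smallest enclosing bin by right-shifting
both `start` and `end − 1` by 17 bits and, while they disagree, by 3
more bits per level. `bins_overlapping` emits, per level, the inclusive
bin range between the shifted endpoints. The central soundness property
— any stored feature overlapping a window has its bin in the window's
candidate list — is what makes a `bin IN (...)` clause a pure
optimization, and is asserted against an explicit bin-extent enumeration
oracle in the tests.

Coordinates at or beyond 2²⁹ raise an error rather than engaging the
extended (sixth-level) scheme: no chromosome this package targets needs
it, and a loud failure beats a silently different bin numbering.

## 2bit archives

The reader detects byte order from the magic number and accepts only
format version 0 (32-bit offsets). Sequence records are parsed lazily on
first access and cached; truncation at any point names the structure
being read. The writer always emits little-endian — the layout produced
by common tooling — while the reader stays general. Bases under N blocks
are packed as code 0 (T); since readers must overlay `N` there, the
choice is unobservable, which the round-trip property tests pin down
(write→read with `masked=True` is the identity on {A,C,G,T,N} in both
cases). `masked` defaults to true because real archives carry
repeat-masking and silently discarding case would lose information.
Subsequence extraction decodes only the byte range covering the request,
so extraction cost is proportional to the slice, not the sequence.

## Reflection and query building

`connect` opens a handle without touching any schema; each table is
reflected once per handle on first access (column names, declared types,
primary key) and cached. Caches are per-handle so two simultaneously
open databases with different schemas cannot collide. Positional columns
are detected by trying `(chrom, chromStart, chromEnd)`, then
`(chrom, txStart, txEnd)`, then `(tName, tStart, tEnd)` — the snp/BED,
genePred and PSL schema families — with no per-table configuration.

`QueryExpression` is immutable; every chain step returns a new
expression and validates referenced columns immediately, before any
execution. Filters only conjoin (AND); there is deliberately no OR
surface. A terminal executes exactly one statement, with every user
value bound as a parameter — never interpolated — which a test asserts
by round-tripping values containing quote characters.

Two semantics are exposed for interval filtering: *overlap*
(`start < window.end AND end > window.start`; a feature spanning the
whole window counts, abutment does not) and *containment*
(`start >= window.start AND end <= window.end`; a feature exactly equal
to the window counts). When the table has a `bin` column both conjoin
the candidate-bin list; `use_bin=False` disables it so the equivalence
is directly testable.

Result ordering: when no `order()` is given, terminals append the
table's primary key (or, absent one, its first reflected column)
ascending, making `first()` and repeated queries deterministic rather
than backend-plan-dependent. The surface is read-only toward annotation
databases. The embedded backend is SQLite through the standard library;
MySQL-style server locators are recognized syntactically but raise a
configuration error because no client driver ships with this build.

## genePred accessors

`exons` materializes the parallel start/end lists (comma blobs tolerate
the UCSC trailing comma); `cdss` intersects each exon with
`[cdsStart, cdsEnd)`, dropping empty pieces, and returns an empty list
for non-coding transcripts (`cdsStart == cdsEnd`); `introns` are the
gaps between consecutive exons, with zero-length gaps omitted. All three
lists are ordered 5′→3′ along the gene — genomic-descending for `-`
strand — while each interval itself keeps `start < end`. Records that
violate the structural invariants (unsorted/overlapping exons, exons
outside the transcript, CDS outside the transcript) are rejected with
the offending field named, never repaired: dumps that disagree with
their own counts are data bugs worth surfacing.

## Joiner schema

The supported grammar is: comment lines, `set name value`, stanza
headers `identifier name`, an optional quoted description line, and
indented `db.table.field [options…]` members with `$var` substitution.
Everything else — `chopBefore`/`chopAfter`, `splitPrefix`, `exclude`,
`dupeOk`, unindented exotic directives — is retained inert, without
semantics. Substitution runs at association-definition time, after any
overwrites, so reassigning a database-list variable re-scopes which
databases a link search considers; a database component that expands to
a comma-separated list fans out to one member per database.

`define_association` creates a link from each of the table's stanza
members to every other member whose database is open, whose table
exists, and whose field is reflected; everything unavailable is silently
skipped — skipping is the contract. Navigation always returns a list
(empty for no partners); `has_one` returns the deterministic first
partner as a one-element list. When two stanzas define the same link
twice, both associations are kept and the `navigate` helper
deduplicates result rows.

## Synthetic fixtures

The generators define the test conditions and are seeded end to end:
the same `FixtureSpec` always regenerates identical content.

- snp-style tables: 500 features by default, uniform over three
  chromosomes of 4 Mb / 2 Mb / 1 Mb, lengths uniform on 1–10,000 bp
  (the short-variant regime of dbSNP-like tables), `bin` computed by
  `bin_from_interval`, strand a fair coin. The chromosome lengths keep
  queries spanning several 128 kb and 1 Mb bins while staying fast.
- genePred tables: 1–20 exons with exon/intron lengths up to 2 kb/5 kb
  (scaled down on short chromosomes so 20 exons always fit), CDS
  uniform within the transcript, 10% non-coding.
- genomes: uniform random bases with N runs and soft-masked runs of
  roughly one each per 50 kb; an exact plain-text truth FASTA is written
  alongside for oracle comparison.
- association fixtures: a configurable fraction (default 0.5) of snp
  keys receives 1–3 xref partners, plus orphan xref keys matching
  nothing; the expected equijoin is computed by brute force and stored
  with the fixture.

What the fixtures do **not** emulate: real annotation content,
organism-specific chromosome counts or sizes, realistic length or GC
distributions, or the table counts of production databases. Passing
tests therefore demonstrate structural and algebraic correctness
(coordinate algebra, bin soundness, format round-trips, SQL
equivalence), not biological plausibility of any analysis built on top.

## Problem sizes and numerics

The default suites use 500 features × 50 query windows for SQL oracle
equivalence, 10,000 random intervals for bin-oracle agreement, 1,000
random sequences (lengths 1–5,000) for 2bit round-trips, and 200 random
gene models for the partition laws — sizes at which the brute-force
oracles are exact and the whole suite runs in seconds. All comparisons
are exact (integer coordinates, string identity); there are no floating
tolerances anywhere in the core.

## Known limitations

- No extended bin scheme: chromosomes longer than 512 Mb are rejected.
- 2bit version 1 (64-bit offsets) and `.nib` files are not read.
- No OR/NOT filter composition and no joins inside the query chain;
  cross-table navigation goes through associations.
- Joiner exceptional directives are parsed but carry no semantics;
  chromosome-split tables and field transformations are not resolved.
- BigWig/BigBed/BAM-backed tables are out of scope.
- The server (MySQL) backend is a locator-level stub pending a driver;
  all supported behavior is exercised on the embedded backend.
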