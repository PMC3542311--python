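# goldenpath

A Python toolkit for working with genome-annotation data organized the way
the UCSC genome databases organize it: relational tables of positional
features (`bin`, `chrom`, `chromStart`, `chromEnd`, …), genePred gene-model
tables, packed `*.2bit` genome sequence archives, and the `all.joiner`
schema that declares which table fields across databases can be joined.
It is written for bioinformaticians who want to query such data
programmatically — from Python or a shell — without composing raw SQL, and
without any network access: a deterministic synthetic-fixture generator
makes every capability testable offline.

## What it provides

- **Intervals** — a 0-based half-open `GenomicInterval` value type plus
  parsing of browser-style strings (`"chr1:123,456-456,789"`, 1-based
  fully-closed, commas allowed). The conversion rule is
  `internal start = printed start − 1`, `internal end = printed end`.
- **Bin index** — the five-level hierarchical bin scheme (bins of 512 Mb,
  64 Mb, 8 Mb, 1 Mb and 128 kb; exact powers of two, 2²⁹ … 2¹⁷). A feature
  `[s, e)` is stored in the smallest bin containing it, found by comparing
  `s >> shift` with `(e − 1) >> shift` from the finest level up; a query
  window touches at most a handful of bins per level, so a
  `bin IN (...)` clause narrows a range scan without changing its result.
- **2bit archives** — a reader *and* writer for the packed sequence format
  (T=0, C=1, A=2, G=3, four bases per byte, N blocks and soft-mask blocks
  as side lists; both byte orders read, little-endian written).
- **Reflected queries** — `connect()` a database, reflect any table lazily,
  and chain `with_interval / with_interval_excl / select / where / order /
  limit / group` into exactly one parameterized SQL statement executed on
  `all() / first() / count()`. Interval queries use the bin index
  automatically whenever the table has a `bin` column.
- **genePred models** — `exons()`, `cdss()` and `introns()` derived from
  transcript rows, ordered 5′→3′ along the gene strand.
- **Joiner associations** — parse `all.joiner`-format text, overwrite its
  variables to re-scope the search, and derive or manually declare
  navigable `has_one`/`has_many` table associations.
- **Fixtures** — seeded generators for all of the above, with brute-force
  truth returned alongside.

## Worked example

```python
from goldenpath import connect, fixtures, parse_interval

fixtures.make_snp_table("hgToy.db", fixtures.FixtureSpec(seed=3, feature_count=500))
db = connect("hgToy.db")
snp = db.table("snpToy")                       # schema reflected lazily, once

window = parse_interval("chr1:1,000,000-1,400,000")
print(len(snp.with_interval(window).all()))    # features overlapping the window
print(len(snp.with_interval_excl(window).all()))  # features fully inside it
top = snp.with_interval(window).where("strand = ?", "+").select("name").limit(3).all()
print([r.name for r in top])
print(snp.where("strand = ?", "+").count())
```

prints

```
13
13
['rs328', 'rs324', 'rs66']
224
```

— 13 of the 500 synthetic features overlap the 400 kb window (here all 13
also lie completely within it), three of the overlapping `+`-strand
features are projected by name, and 224 of the 500 features genome-wide
are on the `+` strand. The same query runs from the shell:

```sh
goldenpath query hgToy.db snpToy --interval chr1:1,000,000-1,400,000 --select name,strand --limit 3
```

The `examples/` directory holds one narrative script per capability
(intervals/bins, 2bit archives, interval queries, gene models, table
association); each builds its own small input and prints what it computes.

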