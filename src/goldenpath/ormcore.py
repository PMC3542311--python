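"""Connection handling, lazy schema reflection, and the chainable query builder.

Tables following UCSC genome-database schemas are exposed as
:class:`TableHandle` objects whose columns are reflected from the live
schema the first time the table is touched (and cached thereafter).
Queries are built by chaining immutable :class:`QueryExpression` steps
— ``select``, ``where``, ``order``, ``limit``, ``group``,
``with_interval`` — none of which touches the backend; a terminal call
(``all``, ``first``, ``count``) assembles exactly one SQL statement with
every user value passed as a bound parameter.

Interval queries use the hierarchical bin index automatically: when the
table has a ``bin`` column, a ``bin IN (...)`` clause computed by
:func:`goldenpath.binindex.bins_overlapping` is conjoined with the
coordinate predicates.  The bin clause is purely an optimization — the
result set is provably identical with or without it.

The embedded backend is SQLite; ``mysql://`` server locators are
recognized syntactically but require a server driver that this build
does not ship, and raise a configuration error saying so.  The API is
read-only toward annotation databases.
"""

from __future__ import annotations

import os
import re
import sqlite3
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Sequence

from .binindex import bins_overlapping
from .errors import (
    CapabilityError,
    ConfigurationError,
    ConnectionFailedError,
    UnknownFieldError,
    UnknownTableError,
)
from .intervals import GenomicInterval

__all__ = [
    "DatabaseHandle",
    "TableHandle",
    "QueryExpression",
    "Record",
    "connect",
]

# (chrom, start, end) column-name triples tried in order when detecting
# positional columns; covers the snp/BED-like, genePred and PSL families.
_POSITIONAL_TRIPLES = (
    ("chrom", "chromStart", "chromEnd"),
    ("chrom", "txStart", "txEnd"),
    ("tName", "tStart", "tEnd"),
)

# words allowed in raw where() fragments besides column names
_SQL_WORDS = frozenset(
    """and or not null is like glob in between exists case when then else end
    cast as collate distinct asc desc escape""".split()
)

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_QUOTED_RE = re.compile(r"'(?:[^']|'')*'")


def _quote_ident(name: str) -> str:
    return '"' + name.replace('"', '""') + '"'


class Record:
    """One row: a value per reflected column, accessible by field name.

    Values keep their storage types (integers stay integers, text stays
    text, blobs stay bytes).  Accessing a column that does not exist
    raises :class:`UnknownFieldError` rather than returning a silent null.
    """

    __slots__ = ("_names", "_values")

    def __init__(self, names: tuple[str, ...], values: tuple[Any, ...]):
        object.__setattr__(self, "_names", names)
        object.__setattr__(self, "_values", values)

    def __getattr__(self, name: str) -> Any:
        try:
            return self._values[self._names.index(name)]
        except ValueError:
            raise UnknownFieldError(
                f"record has no field {name!r} (fields: {', '.join(self._names)})"
            ) from None

    def __getitem__(self, name: str) -> Any:
        return self.__getattr__(name)

    def keys(self) -> tuple[str, ...]:
        return self._names

    def as_dict(self) -> dict[str, Any]:
        return dict(zip(self._names, self._values))

    def as_tuple(self) -> tuple[Any, ...]:
        return self._values

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Record):
            return NotImplemented
        return self._names == other._names and self._values == other._values

    def __hash__(self) -> int:
        return hash((self._names, self._values))

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}={v!r}" for n, v in zip(self._names, self._values))
        return f"Record({inner})"


class DatabaseHandle:
    """An open connection to one annotation database.

    Multiple handles may be open simultaneously and are fully
    independent: reflection caches are per-handle, never global.
    ``reflection_count`` and ``query_count`` count schema reads and
    executed statements, mainly so tests can assert laziness.
    """

    def __init__(self, conn: sqlite3.Connection, uri: str, name: str):
        self._conn = conn
        self.uri = uri
        self.name = name
        self._tables: dict[str, TableHandle] = {}
        self.reflection_count = 0
        self.query_count = 0

    # -- schema -----------------------------------------------------------

    def table_names(self) -> list[str]:
        cur = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type IN ('table','view') ORDER BY name"
        )
        return [r[0] for r in cur.fetchall()]

    def has_table(self, name: str) -> bool:
        return name in self.table_names()

    def table(self, name: str) -> "TableHandle":
        """Reflect (once) and return the handle for ``name``."""
        if name in self._tables:
            return self._tables[name]
        cur = self._conn.execute(f"PRAGMA table_info({_quote_ident(name)})")
        info = cur.fetchall()
        if not info:
            raise UnknownTableError(
                f"no table {name!r} in {self.name!r} "
                f"(available: {', '.join(self.table_names()) or 'none'})"
            )
        self.reflection_count += 1
        columns = tuple((row[1], row[2]) for row in info)  # (name, declared type)
        pk = tuple(row[1] for row in sorted(info, key=lambda r: r[5]) if row[5] > 0)
        handle = TableHandle(self, name, columns, pk)
        self._tables[name] = handle
        return handle

    # -- execution --------------------------------------------------------

    def execute(self, sql: str, params: Sequence[Any] = ()) -> list[tuple]:
        self.query_count += 1
        cur = self._conn.execute(sql, tuple(params))
        return cur.fetchall()

    def close(self) -> None:
        self._conn.close()

    def __repr__(self) -> str:
        return f"DatabaseHandle(name={self.name!r}, uri={self.uri!r})"


def connect(uri: str | os.PathLike[str], name: str | None = None) -> DatabaseHandle:
    """Open a database given a connection locator.

    Supported locators: a SQLite file path (bare or ``sqlite:///path``)
    for the embedded backend.  ``mysql://`` server locators are parsed
    but need a MySQL client driver, which this build does not include,
    so they raise :class:`ConfigurationError`.  Any other scheme is a
    configuration error; a missing database file is a connection error.

    No table reflection happens here — schemas are read lazily on first
    access to each table.
    """
    uri = os.fspath(uri)
    if "://" in uri:
        scheme, _, rest = uri.partition("://")
        if scheme == "sqlite":
            path = rest.lstrip("/")
            if rest.startswith("/"):
                path = "/" + path if os.name != "nt" else path
        elif scheme in ("mysql", "mysql2"):
            raise ConfigurationError(
                "MySQL server locators are recognized but no MySQL client driver "
                "is installed in this build; use an embedded SQLite database"
            )
        else:
            raise ConfigurationError(f"unknown connection scheme {scheme!r} in {uri!r}")
    else:
        path = uri
    if path != ":memory:" and not os.path.exists(path):
        raise ConnectionFailedError(f"database file {path!r} does not exist")
    try:
        conn = sqlite3.connect(path)
    except sqlite3.Error as exc:  # pragma: no cover - hard to trigger portably
        raise ConnectionFailedError(f"could not open {path!r}: {exc}") from exc
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0] or path
    return DatabaseHandle(conn, uri, name)


class TableHandle:
    """A lazily reflected table: column metadata plus query entry points."""

    def __init__(
        self,
        database: DatabaseHandle,
        table_name: str,
        columns: tuple[tuple[str, str], ...],
        primary_key: tuple[str, ...],
    ):
        self.database = database
        self.table_name = table_name
        self.columns = columns
        self.primary_key = primary_key
        self.column_names = tuple(c for c, _ in columns)
        self.has_bin = "bin" in self.column_names
        self.positional_columns: tuple[str, str, str] | None = None
        names = set(self.column_names)
        for triple in _POSITIONAL_TRIPLES:
            if all(c in names for c in triple):
                self.positional_columns = triple
                break

    # -- helpers ----------------------------------------------------------

    def check_field(self, name: str) -> str:
        if name not in self.column_names:
            raise UnknownFieldError(
                f"table {self.table_name!r} has no column {name!r} "
                f"(columns: {', '.join(self.column_names)})"
            )
        return name

    @property
    def default_order(self) -> tuple[str, ...]:
        """Deterministic ordering used when no order() is given: the
        primary key if present, else the first reflected column."""
        return self.primary_key if self.primary_key else (self.column_names[0],)

    # -- query entry points -------------------------------------------------

    def query(self) -> "QueryExpression":
        """A fresh expression over all rows (no backend access yet)."""
        return QueryExpression(table=self)

    def find_by(self, field_name: str, value: Any) -> Record | None:
        """First record with ``field == value`` under deterministic
        ordering, or None when there is no match."""
        return self.query().where_field(field_name, "=", value).first()

    def find_all_by(self, field_name: str, value: Any) -> list[Record]:
        """All records with ``field == value``."""
        return self.query().where_field(field_name, "=", value).all()

    def with_interval(self, iv: GenomicInterval, use_bin: bool = True) -> "QueryExpression":
        """Rows overlapping ``iv`` (half-open overlap; abutment excluded)."""
        return self.query().with_interval(iv, use_bin=use_bin)

    def with_interval_excl(
        self, iv: GenomicInterval, use_bin: bool = True
    ) -> "QueryExpression":
        """Rows lying completely within ``iv`` (partial overlaps excluded)."""
        return self.query().with_interval_excl(iv, use_bin=use_bin)

    # chaining conveniences that start from the full table
    def select(self, *columns: str) -> "QueryExpression":
        return self.query().select(*columns)

    def where(self, condition: str, *bindings: Any) -> "QueryExpression":
        return self.query().where(condition, *bindings)

    def order(self, column: str, direction: str = "asc") -> "QueryExpression":
        return self.query().order(column, direction)

    def limit(self, n: int) -> "QueryExpression":
        return self.query().limit(n)

    def group(self, *columns: str) -> "QueryExpression":
        return self.query().group(*columns)

    def all(self) -> list[Record]:
        return self.query().all()

    def first(self) -> Record | None:
        return self.query().first()

    def count(self) -> int:
        return self.query().count()

    def __repr__(self) -> str:
        return (
            f"TableHandle({self.database.name}.{self.table_name}, "
            f"{len(self.columns)} columns, has_bin={self.has_bin})"
        )


@dataclass(frozen=True)
class QueryExpression:
    """An immutable, lazily executed conjunction of query clauses.

    Every chaining method returns a *new* expression; nothing touches
    the backend until ``all()``, ``first()`` or ``count()`` runs, and a
    terminal executes exactly one statement.  All filters conjoin with
    AND — there is deliberately no OR surface.
    """

    table: TableHandle
    filters: tuple[tuple[str, tuple[Any, ...]], ...] = ()
    projection: tuple[str, ...] | None = None
    ordering: tuple[tuple[str, str], ...] = ()
    limit_n: int | None = None
    offset_n: int | None = None
    grouping: tuple[str, ...] = ()

    # -- chaining ---------------------------------------------------------

    def where_field(self, column: str, comparator: str, value: Any) -> "QueryExpression":
        """Add a single ``column <comparator> value`` filter (bound value)."""
        self.table.check_field(column)
        if comparator not in ("=", "!=", "<", "<=", ">", ">="):
            raise ValueError(f"unsupported comparator {comparator!r}")
        frag = f"{_quote_ident(column)} {comparator} ?"
        return replace(self, filters=self.filters + ((frag, (value,)),))

    def where(self, condition: str, *bindings: Any) -> "QueryExpression":
        """Add a raw condition fragment with ``?`` placeholders.

        Every value must arrive through ``bindings`` (the placeholder
        count is checked); identifiers in the fragment must be reflected
        columns.
        """
        if condition.count("?") != len(bindings):
            raise ValueError(
                f"condition has {condition.count('?')} placeholders "
                f"but {len(bindings)} bindings were supplied"
            )
        stripped = _QUOTED_RE.sub("''", condition)
        for tok in _IDENT_RE.findall(stripped):
            if tok.lower() not in _SQL_WORDS:
                self.table.check_field(tok)
        return replace(self, filters=self.filters + ((f"({condition})", tuple(bindings)),))

    def with_interval(self, iv: GenomicInterval, use_bin: bool = True) -> "QueryExpression":
        """Filter to rows overlapping ``iv`` (0-based half-open).

        Overlap means ``chrom == iv.chrom AND start < iv.end AND
        end > iv.start``; a feature spanning the whole window counts as
        overlapping.  When the table has a ``bin`` column the candidate
        bin list is conjoined as ``bin IN (...)`` — an optimization that
        never changes the result set.
        """
        return self._positional(iv, use_bin, containment=False)

    def with_interval_excl(
        self, iv: GenomicInterval, use_bin: bool = True
    ) -> "QueryExpression":
        """Filter to rows lying completely within ``iv``.

        Containment means ``start >= iv.start AND end <= iv.end``; a row
        exactly equal to the window is included, partial overlaps are not.
        """
        return self._positional(iv, use_bin, containment=True)

    def _positional(
        self, iv: GenomicInterval, use_bin: bool, containment: bool
    ) -> "QueryExpression":
        cols = self.table.positional_columns
        if cols is None:
            raise CapabilityError(
                f"table {self.table.table_name!r} has no recognized positional "
                "columns (chrom/chromStart/chromEnd family); interval queries "
                "are unavailable"
            )
        chrom_c, start_c, end_c = (_quote_ident(c) for c in cols)
        filters = list(self.filters)
        filters.append((f"{chrom_c} = ?", (iv.chrom,)))
        if containment:
            filters.append((f"{start_c} >= ?", (iv.start,)))
            filters.append((f"{end_c} <= ?", (iv.end,)))
        else:
            filters.append((f"{start_c} < ?", (iv.end,)))
            filters.append((f"{end_c} > ?", (iv.start,)))
        if use_bin and self.table.has_bin:
            bins = bins_overlapping(iv.start, iv.end)
            marks = ",".join("?" * len(bins))
            filters.append((f'"bin" IN ({marks})', tuple(bins)))
        return replace(self, filters=tuple(filters))

    def select(self, *columns: str) -> "QueryExpression":
        for c in columns:
            self.table.check_field(c)
        return replace(self, projection=tuple(columns))

    def order(self, column: str, direction: str = "asc") -> "QueryExpression":
        self.table.check_field(column)
        if direction.lower() not in ("asc", "desc"):
            raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
        return replace(self, ordering=self.ordering + ((column, direction.lower()),))

    def limit(self, n: int) -> "QueryExpression":
        if n < 0:
            raise ValueError("limit must be non-negative")
        return replace(self, limit_n=n)

    def offset(self, n: int) -> "QueryExpression":
        if n < 0:
            raise ValueError("offset must be non-negative")
        return replace(self, offset_n=n)

    def group(self, *columns: str) -> "QueryExpression":
        for c in columns:
            self.table.check_field(c)
        return replace(self, grouping=tuple(columns))

    # -- SQL assembly -------------------------------------------------------

    def _assemble(self, count_only: bool = False) -> tuple[str, tuple[Any, ...]]:
        if count_only:
            cols_sql = "COUNT(*)"
        elif self.projection:
            cols_sql = ", ".join(_quote_ident(c) for c in self.projection)
        else:
            cols_sql = ", ".join(_quote_ident(c) for c in self.table.column_names)
        sql = [f"SELECT {cols_sql} FROM {_quote_ident(self.table.table_name)}"]
        params: list[Any] = []
        if self.filters:
            sql.append("WHERE " + " AND ".join(f for f, _ in self.filters))
            for _, p in self.filters:
                params.extend(p)
        if self.grouping:
            sql.append("GROUP BY " + ", ".join(_quote_ident(c) for c in self.grouping))
        if not count_only:
            ordering = self.ordering
            if not ordering and not self.grouping:
                # deterministic default: repeated identical queries must
                # return identically ordered results
                ordering = tuple((c, "asc") for c in self.table.default_order)
            if ordering:
                sql.append(
                    "ORDER BY "
                    + ", ".join(f"{_quote_ident(c)} {d.upper()}" for c, d in ordering)
                )
            if self.limit_n is not None:
                sql.append("LIMIT ?")
                params.append(self.limit_n)
                if self.offset_n is not None:
                    sql.append("OFFSET ?")
                    params.append(self.offset_n)
            elif self.offset_n is not None:
                sql.append("LIMIT -1 OFFSET ?")
                params.append(self.offset_n)
        return " ".join(sql), tuple(params)

    # -- terminals ----------------------------------------------------------

    def all(self) -> list[Record]:
        """Execute and return every matching record."""
        sql, params = self._assemble()
        names = self.projection or self.table.column_names
        rows = self.table.database.execute(sql, params)
        return [Record(tuple(names), tuple(r)) for r in rows]

    def first(self) -> Record | None:
        """Execute with LIMIT 1 and return the first record or None."""
        results = self.limit(1).all()
        return results[0] if results else None

    def count(self) -> int:
        """Execute a COUNT(*) over the accumulated filters."""
        sql, params = self._assemble(count_only=True)
        rows = self.table.database.execute(sql, params)
        return int(rows[0][0])

    def __iter__(self) -> Iterator[Record]:
        return iter(self.all())
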