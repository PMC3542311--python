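"""all.joiner schema parsing and table association.

The joiner schema is UCSC's declarative text format recording which
``database.table.field`` members across genome databases share an
identifier namespace and can therefore be equijoined.  This module
parses the subset of the grammar needed for association discovery —
``set`` variable lines, ``identifier`` stanzas with member lines and
``$var`` substitution — and turns stanzas into navigable
:class:`Association` objects against open databases.

Variable substitution is applied at association-definition time, after
any overwrites, so re-assigning a variable such as ``gbd`` (the stanza
authors' catch-all list of genome databases) re-scopes which databases a
link search considers.  Exceptional directives (chopBefore/chopAfter,
splitPrefix, exclude, dupeOk, ...) are retained as inert option tokens
with no semantics.

Navigation always returns a list — an empty list when a record has no
partners, never an absent value.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

from .errors import JoinerParseError, UnknownFieldError
from .ormcore import DatabaseHandle, Record, TableHandle

__all__ = [
    "JoinerSchema",
    "IdentifierStanza",
    "Association",
    "load_joiner",
    "define_association",
    "declare_association",
    "navigate",
]

_VAR_RE = re.compile(r"\$(\w+)")


@dataclass
class IdentifierStanza:
    """One ``identifier`` stanza: a name plus raw member references.

    Members stay unsubstituted until association definition; each is
    ``(line_number, first_token, option_tokens)`` where the first token
    is the ``db.table.field`` reference (possibly containing ``$var``).
    """

    name: str
    description: str = ""
    raw_members: list[tuple[int, str, tuple[str, ...]]] = field(default_factory=list)


@dataclass
class JoinerSchema:
    """Parsed joiner text: variables, identifier stanzas, inert directives."""

    variables: dict[str, str] = field(default_factory=dict)
    identifiers: list[IdentifierStanza] = field(default_factory=list)
    raw_directives: list[tuple[int, str]] = field(default_factory=list)

    def set_variable(self, name: str, value: str) -> None:
        """Overwrite a variable; takes effect for later member resolution."""
        self.variables[name] = value

    def _substitute(self, text: str, lineno: int) -> str:
        def repl(m: re.Match) -> str:
            var = m.group(1)
            if var not in self.variables:
                raise JoinerParseError(
                    f"line {lineno}: undefined variable ${var} in {text!r}"
                )
            return self.variables[var]

        return _VAR_RE.sub(repl, text)

    def resolve_members(
        self, stanza: IdentifierStanza
    ) -> list[tuple[str, str, str, tuple[str, ...]]]:
        """Expand a stanza's members with current variables.

        Returns ``(database, table, field, options)`` tuples.  A database
        component that substitutes to a comma-separated list (the ``gbd``
        convention) fans out to one member per database.
        """
        members: list[tuple[str, str, str, tuple[str, ...]]] = []
        for lineno, ref, options in stanza.raw_members:
            expanded = self._substitute(ref, lineno)
            parts = expanded.split(".")
            if len(parts) < 3 or any(not p for p in parts[:3]) or not parts[-1]:
                raise JoinerParseError(
                    f"line {lineno}: member {expanded!r} is not db.table.field"
                )
            db_part, table, fld = parts[0], ".".join(parts[1:-1]), parts[-1]
            for db in db_part.split(","):
                db = db.strip()
                if db:
                    members.append((db, table, fld, options))
        return members


def load_joiner(source: str | os.PathLike[str]) -> JoinerSchema:
    """Parse all.joiner-format text.

    ``source`` is either the schema text itself (anything containing a
    newline) or the path of a local file.  Comment and blank lines are
    skipped; ``set`` lines define variables; ``identifier`` headers open
    stanzas whose indented lines are members (an indented quoted line is
    kept as the stanza description).  Unindented lines that are neither
    ``set`` nor ``identifier`` are retained verbatim with no semantics.
    """
    text = str(source)
    if "\n" not in text and os.path.exists(text):
        with open(text, "r", encoding="utf-8") as fh:
            text = fh.read()

    schema = JoinerSchema()
    stanza: IdentifierStanza | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        indented = line[:1] in (" ", "\t")
        if not indented:
            stanza = None
            tokens = stripped.split()
            if tokens[0] == "set":
                if len(tokens) < 3:
                    raise JoinerParseError(
                        f"line {lineno}: 'set' needs a name and a value"
                    )
                schema.variables[tokens[1]] = " ".join(tokens[2:])
            elif tokens[0] == "identifier":
                if len(tokens) < 2:
                    raise JoinerParseError(f"line {lineno}: 'identifier' needs a name")
                stanza = IdentifierStanza(name=tokens[1])
                schema.identifiers.append(stanza)
            else:
                schema.raw_directives.append((lineno, stripped))
        else:
            if stanza is None:
                schema.raw_directives.append((lineno, stripped))
                continue
            if stripped.startswith('"'):
                stanza.description = stripped.strip('"')
                continue
            tokens = stripped.split()
            ref, options = tokens[0], tuple(tokens[1:])
            # structural check on the raw reference (before substitution):
            # it must already show the db.table.field shape
            if len(ref.split(".")) < 3 or any(not p for p in ref.split(".")):
                raise JoinerParseError(
                    f"line {lineno}: member {ref!r} has fewer than the "
                    "db.table.field components"
                )
            stanza.raw_members.append((lineno, ref, options))
    return schema


@dataclass(frozen=True)
class Association:
    """A navigable link from one table's field to another's.

    ``cardinality`` is ``"many"`` (all partners) or ``"one"`` (the first
    partner under the target table's deterministic ordering).  Navigation
    always yields a list; ``"one"`` yields a list of at most one record.
    """

    from_table: TableHandle
    from_field: str
    to_table: TableHandle
    to_field: str
    cardinality: str = "many"
    identifier: str | None = None

    def navigate(self, record: Record) -> list[Record]:
        """Partner records of ``record`` in the target table, as a list."""
        key = record[self.from_field]
        if self.cardinality == "one":
            hit = self.to_table.find_by(self.to_field, key)
            return [hit] if hit is not None else []
        return self.to_table.find_all_by(self.to_field, key)


def define_association(
    schema: JoinerSchema,
    table: TableHandle,
    open_dbs: list[DatabaseHandle] | dict[str, DatabaseHandle],
) -> list[Association]:
    """Derive every association of ``table`` from the joiner stanzas.

    For each identifier stanza with a member on ``table`` (matching the
    handle's database name and table name), an association is created to
    every *other* member whose database is among ``open_dbs``, whose
    table exists there, and whose field is reflected.  Members on
    unconnected databases or undefined tables/fields are silently
    skipped — skipping is the contract, not an error.  The function is
    stateless, hence idempotent.
    """
    if isinstance(open_dbs, dict):
        db_map = dict(open_dbs)
    else:
        db_map = {db.name: db for db in open_dbs}

    out: list[Association] = []
    for stanza in schema.identifiers:
        members = schema.resolve_members(stanza)
        local = [
            m
            for m in members
            if m[0] == table.database.name
            and m[1] == table.table_name
            and m[2] in table.column_names
        ]
        if not local:
            continue
        for _, _, local_field, _ in local:
            for db, tbl, fld, _ in members:
                if (db, tbl) == (table.database.name, table.table_name):
                    continue
                handle = db_map.get(db)
                if handle is None or not handle.has_table(tbl):
                    continue
                target = handle.table(tbl)
                if fld not in target.column_names:
                    continue
                out.append(
                    Association(
                        from_table=table,
                        from_field=local_field,
                        to_table=target,
                        to_field=fld,
                        cardinality="many",
                        identifier=stanza.name,
                    )
                )
    return out


def declare_association(
    table: TableHandle,
    kind: str,
    target: TableHandle,
    foreign_key: tuple[str, str],
) -> Association:
    """Manually declare a has_one / has_many style association.

    ``foreign_key`` is ``(local field, remote field)``: navigation from a
    record of ``table`` yields target records whose remote field equals
    the record's local field value.  ``kind`` is ``"one"`` or ``"many"``.
    """
    if kind not in ("one", "many"):
        raise ValueError(f"kind must be 'one' or 'many', got {kind!r}")
    local_field, remote_field = foreign_key
    table.check_field(local_field)
    target.check_field(remote_field)
    return Association(
        from_table=table,
        from_field=local_field,
        to_table=target,
        to_field=remote_field,
        cardinality=kind,
    )


def navigate(record: Record, associations: list[Association]) -> list[Record]:
    """Follow several associations from one record, deduplicating rows.

    Two stanzas may define the same link twice; results are merged in
    order of first appearance with duplicate rows removed.
    """
    seen: set[Record] = set()
    out: list[Record] = []
    for assoc in associations:
        for rec in assoc.navigate(record):
            if rec not in seen:
                seen.add(rec)
                out.append(rec)
    return out
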