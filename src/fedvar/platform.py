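"""Logical query platforms: independent embedded engines with scan accounting.

A Platform wraps one sqlite engine instance (file-backed or in-memory) and
models an independent "cloud": it owns its tables, answers declarative
selector queries, meters bytes scanned under a serverless-style billing
model, and hosts short-lived temporary tables for transferred subsets.  Two
Platform objects never share a connection; all cross-platform movement goes
through the explicit transfer path in :mod:`fedvar.data_query`.

Scan accounting follows the partition-pruning model: a query reads only the
(chromosome, bin) partitions its predicate can touch, and ``bytes_scanned``
is the serialized size of those partitions (optionally scaled to the
projected columns when the platform declares column-level accounting).
Region predicates widen the pruned bin range by the table's longest stored
interval so records starting in an earlier bin are never missed.
"""

from __future__ import annotations

import json
import logging
import random
import re
import sqlite3
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cost_model import CostLedger
from .errors import (
    DuplicatePlatformError,
    DuplicateTableError,
    NotTempTableError,
    SchemaError,
    SelectorError,
    UnknownPlatformError,
    UnknownTableError,
)
from .variant_store import (
    ANNOTATION_LAYOUT,
    DEFAULT_BIN_WIDTH,
    TableHandle,
    VARIANT_LAYOUT,
    parse_serialized_row,
    row_byte_size,
    serialize_field,
)

log = logging.getLogger("fedvar")

TEMP_PREFIX = "fed_tmp_"

_IDENT = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

_SQL_TYPES = {
    "start_position": "INTEGER",
    "end_position": "INTEGER",
    "ac": "INTEGER",
    "an": "INTEGER",
    "bin_id": "INTEGER",
}

_SCHEMA_SEMANTICS = {
    "chromosome_name": "string",
    "start_position": "int0based",
    "end_position": "intExclusive",
    "reference_bases": "string",
    "alternate_bases": "string",
    "rsid": "string?",
    "ac": "int",
    "an": "int",
    "bin_id": "int?",
    "extra": "map",
    "attributes": "map",
}


# ---------------------------------------------------------------------------
# Selector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selector:
    """A typed query predicate: rsID, exact site, region or gene symbol.

    Exactly the fields of the active mode are set; gene selectors must be
    resolved to regions (via the gene model) before reaching a platform.
    """

    mode: str
    rsid_value: Optional[str] = None
    chromosome_name: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    reference_bases: Optional[str] = None
    alternate_bases: Optional[str] = None
    gene_symbol: Optional[str] = None

    def __post_init__(self):
        if self.mode == "rsid":
            if not self.rsid_value:
                raise SelectorError("rsid selector needs an rsID")
        elif self.mode == "site":
            if self.chromosome_name is None or self.start is None:
                raise SelectorError("site selector needs chromosome and start")
        elif self.mode == "region":
            if self.chromosome_name is None or self.start is None or self.end is None:
                raise SelectorError("region selector needs chromosome, start, end")
            if self.end <= self.start:
                raise SelectorError("region must satisfy end > start")
        elif self.mode == "gene":
            if not self.gene_symbol:
                raise SelectorError("gene selector needs a symbol")
        else:
            raise SelectorError(f"unknown selector mode {self.mode!r}")

    @classmethod
    def rsid(cls, rsid: str) -> "Selector":
        return cls(mode="rsid", rsid_value=rsid)

    @classmethod
    def site(cls, chromosome_name: str, start: int,
             reference_bases: Optional[str] = None,
             alternate_bases: Optional[str] = None) -> "Selector":
        return cls(mode="site", chromosome_name=chromosome_name, start=start,
                   reference_bases=reference_bases, alternate_bases=alternate_bases)

    @classmethod
    def region(cls, chromosome_name: str, start: int, end: int) -> "Selector":
        return cls(mode="region", chromosome_name=chromosome_name,
                   start=start, end=end)

    @classmethod
    def gene(cls, symbol: str) -> "Selector":
        return cls(mode="gene", gene_symbol=symbol)


@dataclass
class ResultSet:
    rows: list
    bytes_scanned: int
    partitions_touched: int

    def __post_init__(self):
        if self.bytes_scanned < 0 or self.partitions_touched < 0:
            raise ValueError("accounting fields must be >= 0")


# ---------------------------------------------------------------------------
# Platform
# ---------------------------------------------------------------------------

class Platform:
    """One independent embedded query engine with its own storage."""

    def __init__(self, name: str, backend_spec: str = ":memory:",
                 scan_accounting: str = "bytes_of_partitions_read"):
        if scan_accounting not in ("bytes_of_partitions_read",
                                   "bytes_of_columns_read"):
            raise ValueError(f"unknown scan_accounting {scan_accounting!r}")
        self.name = name
        self.backend_spec = backend_spec
        self.scan_accounting = scan_accounting
        self.conn = sqlite3.connect(backend_spec)
        self.tables: "OrderedDict[str, TableHandle]" = OrderedDict()
        self._init_meta()
        self._load_catalog()

    # -- storage bootstrap -------------------------------------------------

    def _init_meta(self):
        cur = self.conn.cursor()
        cur.execute(
            """CREATE TABLE IF NOT EXISTS _catalog (
                   table_name TEXT PRIMARY KEY, kind TEXT, layout TEXT,
                   row_count INTEGER, byte_size INTEGER, bin_width INTEGER,
                   clustered INTEGER, max_interval_span INTEGER,
                   column_bytes TEXT)"""
        )
        cur.execute(
            """CREATE TABLE IF NOT EXISTS _partition_stats (
                   table_name TEXT, chromosome_name TEXT, bin_id INTEGER,
                   row_count INTEGER, byte_size INTEGER)"""
        )
        cur.execute(
            """CREATE INDEX IF NOT EXISTS _partition_stats_ix
                   ON _partition_stats (table_name, chromosome_name, bin_id)"""
        )
        cur.execute(
            """CREATE TABLE IF NOT EXISTS _rsid_bins (
                   table_name TEXT, rsid TEXT, chromosome_name TEXT,
                   bin_id INTEGER)"""
        )
        cur.execute(
            """CREATE INDEX IF NOT EXISTS _rsid_bins_ix
                   ON _rsid_bins (table_name, rsid)"""
        )
        self.conn.commit()

    def _load_catalog(self):
        for (table_name, kind, layout, row_count, byte_size, bin_width,
             clustered, span, _cb) in self.conn.execute(
                 "SELECT * FROM _catalog ORDER BY rowid"):
            layout = tuple(json.loads(layout))
            self.tables[table_name] = TableHandle(
                platform_name=self.name, table_name=table_name, kind=kind,
                schema=tuple((c, _SCHEMA_SEMANTICS.get(c, "string")) for c in layout),
                row_count=row_count, byte_size=byte_size, bin_width=bin_width,
                clustered=bool(clustered), max_interval_span=span, layout=layout,
            )

    # -- loading -----------------------------------------------------------

    def load_table(self, table_name: str, kind: str, layout: Sequence[str],
                   rows: Sequence[dict], bin_width: Optional[int],
                   clustered: bool = True) -> TableHandle:
        """Create and populate a table; compute all accounting metadata."""
        if not _IDENT.match(table_name) or table_name.startswith("_"):
            raise ValueError(f"invalid table name {table_name!r}")
        if table_name in self.tables:
            raise DuplicateTableError(
                f"table {table_name!r} already exists on platform {self.name!r}"
            )
        layout = tuple(layout)
        for row in rows:
            missing = [c for c in layout if c not in row and c != "bin_id"]
            if missing:
                raise SchemaError(
                    f"record missing columns {missing} for table {table_name!r}"
                )

        columns_sql = ", ".join(
            f'"{c}" {_SQL_TYPES.get(c, "TEXT")}' for c in layout
        )
        cur = self.conn.cursor()
        cur.execute(f'CREATE TABLE "{table_name}" ({columns_sql})')
        if bin_width is not None:
            cur.execute(
                f'CREATE INDEX "{table_name}_bin_ix" ON "{table_name}" '
                f'(chromosome_name, bin_id)'
            )

        part_stats = {}
        column_bytes = {c: 0 for c in layout}
        max_span = 0
        byte_size = 0
        insert_sql = (
            f'INSERT INTO "{table_name}" VALUES '
            f'({", ".join("?" * len(layout))})'
        )
        to_insert = []
        for row in rows:
            serialized = [serialize_field(c, row.get(c)) for c in layout]
            stored = [
                row.get(c) if c not in ("extra", "attributes") else s
                for c, s in zip(layout, serialized)
            ]
            to_insert.append(stored)
            size = sum(len(s) for s in serialized) + len(layout)
            byte_size += size
            for c, s in zip(layout, serialized):
                column_bytes[c] += len(s) + 1
            span = row["end_position"] - row["start_position"]
            if span > max_span:
                max_span = span
            key = (row["chromosome_name"],
                   row.get("bin_id") if bin_width is not None else None)
            n, b = part_stats.get(key, (0, 0))
            part_stats[key] = (n + 1, b + size)
        if not rows:
            part_stats = {}
        if bin_width is None and rows:
            # one pseudo-partition spanning the whole table
            part_stats = {("", None): (len(rows), byte_size)}
        cur.executemany(insert_sql, to_insert)

        cur.execute(
            "INSERT INTO _catalog VALUES (?,?,?,?,?,?,?,?,?)",
            (table_name, kind, json.dumps(list(layout)), len(rows), byte_size,
             bin_width, int(clustered), max_span, json.dumps(column_bytes)),
        )
        cur.executemany(
            "INSERT INTO _partition_stats VALUES (?,?,?,?,?)",
            [(table_name, chrom, bin_id, n, b)
             for (chrom, bin_id), (n, b) in part_stats.items()],
        )
        if kind == "variant":
            cur.executemany(
                "INSERT INTO _rsid_bins VALUES (?,?,?,?)",
                sorted({
                    (table_name, row["rsid"], row["chromosome_name"],
                     row.get("bin_id"))
                    for row in rows if row.get("rsid")
                }),
            )
        self.conn.commit()

        handle = TableHandle(
            platform_name=self.name, table_name=table_name, kind=kind,
            schema=tuple((c, _SCHEMA_SEMANTICS.get(c, "string")) for c in layout),
            row_count=len(rows), byte_size=byte_size, bin_width=bin_width,
            clustered=clustered, max_interval_span=max_span, layout=layout,
        )
        self.tables[table_name] = handle
        log.info("platform=%s loaded table=%s kind=%s rows=%d bytes=%d",
                 self.name, table_name, kind, len(rows), byte_size)
        return handle

    # -- internals ---------------------------------------------------------

    def _handle(self, table) -> TableHandle:
        name = table.table_name if isinstance(table, TableHandle) else table
        try:
            return self.tables[name]
        except KeyError:
            raise UnknownTableError(
                f"no table {name!r} on platform {self.name!r}"
            ) from None

    def _column_fraction(self, handle: TableHandle,
                         projection: Optional[Sequence[str]]) -> float:
        if (self.scan_accounting != "bytes_of_columns_read"
                or not projection):
            return 1.0
        raw = self.conn.execute(
            "SELECT column_bytes FROM _catalog WHERE table_name=?",
            (handle.table_name,),
        ).fetchone()
        column_bytes = json.loads(raw[0]) if raw else {}
        total = sum(column_bytes.values()) or 1
        picked = sum(column_bytes.get(c, 0) for c in projection)
        return picked / total

    def _candidate_partitions(self, handle: TableHandle, selector: Selector,
                              prune: bool):
        """(rows of (chrom, bin_id, row_count, byte_size)) a query must read."""
        cur = self.conn.cursor()
        base = ("SELECT chromosome_name, bin_id, row_count, byte_size "
                "FROM _partition_stats WHERE table_name=?")
        if not prune or handle.bin_width is None:
            return cur.execute(base, (handle.table_name,)).fetchall()
        w = handle.bin_width
        if selector.mode == "rsid":
            pairs = cur.execute(
                "SELECT DISTINCT chromosome_name, bin_id FROM _rsid_bins "
                "WHERE table_name=? AND rsid=?",
                (handle.table_name, selector.rsid_value),
            ).fetchall()
            out = []
            for chrom, bin_id in pairs:
                out.extend(cur.execute(
                    base + " AND chromosome_name=? AND bin_id=?",
                    (handle.table_name, chrom, bin_id)).fetchall())
            return out
        if selector.mode == "site":
            bin_id = selector.start // w
            return cur.execute(
                base + " AND chromosome_name=? AND bin_id=?",
                (handle.table_name, selector.chromosome_name, bin_id),
            ).fetchall()
        if selector.mode == "region":
            lo = max(0, selector.start - handle.max_interval_span) // w
            hi = (selector.end - 1) // w
            return cur.execute(
                base + " AND chromosome_name=? AND bin_id BETWEEN ? AND ?",
                (handle.table_name, selector.chromosome_name, lo, hi),
            ).fetchall()
        raise SelectorError(
            f"selector mode {selector.mode!r} must be resolved before querying"
        )

    def _selector_sql(self, handle: TableHandle, selector: Selector,
                      candidates, prune: bool):
        where = []
        params = []
        if selector.mode == "rsid":
            where.append("rsid = ?")
            params.append(selector.rsid_value)
        elif selector.mode == "site":
            where.append("chromosome_name = ? AND start_position = ?")
            params.extend([selector.chromosome_name, selector.start])
            if selector.reference_bases is not None:
                where.append("reference_bases = ?")
                params.append(selector.reference_bases)
            if selector.alternate_bases is not None:
                where.append("alternate_bases = ?")
                params.append(selector.alternate_bases)
        elif selector.mode == "region":
            where.append(
                "chromosome_name = ? AND start_position < ? AND end_position > ?"
            )
            params.extend([selector.chromosome_name, selector.end, selector.start])
        if prune and handle.bin_width is not None:
            pairs = sorted({(c, b) for c, b, _n, _s in candidates})
            if not pairs:
                where.append("0")
            else:
                clause = " OR ".join(
                    "(chromosome_name = ? AND bin_id = ?)" for _ in pairs
                )
                where.append(f"({clause})")
                for c, b in pairs:
                    params.extend([c, b])
        return " AND ".join(where) or "1", params


def _accounting(platform: Platform, handle: TableHandle, candidates,
                projection) -> tuple:
    bytes_scanned = sum(b for _c, _b2, _n, b in candidates)
    fraction = platform._column_fraction(handle, projection)
    return int(round(bytes_scanned * fraction)), len(candidates)


def run_selector_query(platform: Platform, table, selector: Selector,
                       projection: Optional[Sequence[str]] = None,
                       prune: bool = True,
                       ledger: Optional[CostLedger] = None,
                       query_id: Optional[str] = None) -> ResultSet:
    """Answer a selector query, reading only the partitions it can touch.

    Matching semantics: rsID equality; site = exact chromosome/start (and
    REF/ALT when given); region = half-open interval overlap with the stored
    [start, end).  ``bytes_scanned`` and ``partitions_touched`` reflect the
    pruned partition set; unpartitioned tables report a full-table scan.
    With ``prune=False`` the same rows are returned at full-scan cost (the
    soundness oracle).
    """
    handle = platform._handle(table)
    candidates = platform._candidate_partitions(handle, selector, prune)
    bytes_scanned, touched = _accounting(platform, handle, candidates, projection)
    columns = list(projection) if projection else list(handle.layout)
    where, params = platform._selector_sql(handle, selector, candidates, prune)
    sql = (
        f'SELECT {", ".join(chr(34) + c + chr(34) for c in columns)} '
        f'FROM "{handle.table_name}" WHERE {where} '
        f"ORDER BY chromosome_name, start_position, rowid"
    )
    rows = []
    if candidates or not prune or handle.bin_width is None:
        for fetched in platform.conn.execute(sql, params):
            row = dict(zip(columns, fetched))
            for jc in ("extra", "attributes"):
                if jc in row:
                    row[jc] = json.loads(row[jc]) if row[jc] else {}
            rows.append(row)
    if ledger is not None:
        ledger.record_scan(platform.name, bytes_scanned, query_id)
    log.info("platform=%s query table=%s mode=%s rows=%d bytes=%d parts=%d",
             platform.name, handle.table_name, selector.mode, len(rows),
             bytes_scanned, touched)
    return ResultSet(rows=rows, bytes_scanned=bytes_scanned,
                     partitions_touched=touched)


def count_selector_query(platform: Platform, table, selector: Selector,
                         prune: bool = True,
                         ledger: Optional[CostLedger] = None,
                         query_id: Optional[str] = None) -> tuple:
    """(matching row count, bytes_scanned) without materializing rows."""
    handle = platform._handle(table)
    candidates = platform._candidate_partitions(handle, selector, prune)
    bytes_scanned, _touched = _accounting(platform, handle, candidates, None)
    where, params = platform._selector_sql(handle, selector, candidates, prune)
    if not candidates and prune and handle.bin_width is not None:
        n = 0
    else:
        n = platform.conn.execute(
            f'SELECT COUNT(*) FROM "{handle.table_name}" WHERE {where}', params
        ).fetchone()[0]
    if ledger is not None:
        ledger.record_scan(platform.name, bytes_scanned, query_id)
    return n, bytes_scanned


def full_table_rows(platform: Platform, table) -> list:
    """Every stored row in clustered order (no predicate, full scan)."""
    handle = platform._handle(table)
    columns = list(handle.layout)
    rows = []
    for fetched in platform.conn.execute(
        f'SELECT {", ".join(chr(34) + c + chr(34) for c in columns)} '
        f'FROM "{handle.table_name}" ORDER BY chromosome_name, start_position'
    ):
        row = dict(zip(columns, fetched))
        for jc in ("extra", "attributes"):
            if jc in row:
                row[jc] = json.loads(row[jc]) if row[jc] else {}
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Temporary tables
# ---------------------------------------------------------------------------

def materialize_temp(platform: Platform, records: Sequence[dict],
                     layout: Sequence[str], ttl_tag: str,
                     suffix: Optional[str] = None) -> TableHandle:
    """Materialize transferred records as a short-lived table.

    The table name carries ``ttl_tag`` plus a (seed-controllable) suffix so
    cleanup can find and drop it.  Records must conform to ``layout``.
    """
    suffix = suffix if suffix is not None else f"{random.randrange(16**8):08x}"
    safe_tag = re.sub(r"[^A-Za-z0-9]", "", ttl_tag) or "t"
    name = f"{TEMP_PREFIX}{safe_tag}_{suffix}"
    handle = platform.load_table(
        name, kind="temp", layout=layout, rows=list(records),
        bin_width=None, clustered=True,
    )
    return handle


def drop_temp(platform: Platform, handle: TableHandle) -> bool:
    """Drop a temporary table; idempotent (second drop warns and no-ops)."""
    if handle.kind != "temp":
        raise NotTempTableError(
            f"refusing to drop non-temp table {handle.table_name!r}"
        )
    if handle.table_name not in platform.tables:
        warnings.warn(
            f"temp table {handle.table_name!r} already dropped", stacklevel=2
        )
        return False
    cur = platform.conn.cursor()
    cur.execute(f'DROP TABLE "{handle.table_name}"')
    cur.execute("DELETE FROM _catalog WHERE table_name=?", (handle.table_name,))
    cur.execute("DELETE FROM _partition_stats WHERE table_name=?",
                (handle.table_name,))
    cur.execute("DELETE FROM _rsid_bins WHERE table_name=?",
                (handle.table_name,))
    platform.conn.commit()
    del platform.tables[handle.table_name]
    return True


def temp_tables(platform: Platform) -> list:
    return [h for h in platform.tables.values() if h.kind == "temp"]


# ---------------------------------------------------------------------------
# Federation registry
# ---------------------------------------------------------------------------

class Federation:
    """A deterministic registry of platforms sharing one cost ledger.

    All randomness (temp-table suffixes) flows from ``seed``; registry
    iteration order is insertion order.
    """

    def __init__(self, seed: int = 0):
        self.platforms: "OrderedDict[str, Platform]" = OrderedDict()
        self.ledger = CostLedger()
        self.seed = seed
        self._rng = random.Random(seed)
        self._query_counter = 0

    def register_platform(self, name: str, backend_spec: str = ":memory:",
                          scan_accounting: str = "bytes_of_partitions_read"
                          ) -> Platform:
        if name in self.platforms:
            raise DuplicatePlatformError(f"platform {name!r} already registered")
        platform = Platform(name, backend_spec, scan_accounting)
        self.platforms[name] = platform
        return platform

    def platform(self, name: str) -> Platform:
        try:
            return self.platforms[name]
        except KeyError:
            raise UnknownPlatformError(f"no platform named {name!r}") from None

    def resolve(self, target) -> tuple:
        """(Platform, TableHandle) from 'platform.table' or a (p, t) pair."""
        if isinstance(target, str):
            if "." not in target:
                raise UnknownTableError(
                    f"target {target!r} must be 'platform.table'"
                )
            pname, tname = target.split(".", 1)
        else:
            pname, tname = target
        platform = self.platform(pname)
        return platform, platform._handle(tname)

    def new_query_id(self) -> str:
        self._query_counter += 1
        return f"q{self._query_counter:06d}"

    def temp_suffix(self) -> str:
        return f"{self._rng.randrange(16**8):08x}"
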