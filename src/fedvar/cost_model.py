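"""Data-motion and scan accounting: the egress cost ledger.

Under the serverless billing model this framework emulates, each query is
charged by the bytes it scans in place, while moving a table across
platforms is charged by the bytes that leave the storage boundary (egress).
The ledger records both, append-only, and derives the two summary figures
the accounting supports: the egress saved by computing in situ instead of
exporting the table, and the break-even point — how many in-situ queries
cumulatively scan as many bytes as one full-table export.

All sizes are stored in bytes.  Display helpers accept/render GB and MB.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .errors import UnknownQueryError


@dataclass(frozen=True)
class LedgerEntry:
    timestamp: float
    platform_name: str
    kind: str  # "scan" | "transfer_out" | "transfer_in"
    raw_bytes: int
    wire_bytes: int
    query_id: Optional[str]


@dataclass
class CostLedger:
    """Append-only record of bytes scanned per platform and bytes moved.

    A transfer writes a ``transfer_out``/``transfer_in`` pair sharing the
    same query id and wire size (conservation); scans carry wire_bytes = 0.
    """

    entries: list = field(default_factory=list)

    def record_scan(self, platform_name: str, raw_bytes: int,
                    query_id: Optional[str] = None) -> LedgerEntry:
        entry = LedgerEntry(time.time(), platform_name, "scan",
                            int(raw_bytes), 0, query_id)
        self.entries.append(entry)
        return entry

    def record_transfer(self, from_platform: str, to_platform: str,
                        raw_bytes: int, wire_bytes: int,
                        query_id: Optional[str] = None) -> tuple:
        out = LedgerEntry(time.time(), from_platform, "transfer_out",
                          int(raw_bytes), int(wire_bytes), query_id)
        into = LedgerEntry(out.timestamp, to_platform, "transfer_in",
                           int(raw_bytes), int(wire_bytes), query_id)
        self.entries.extend([out, into])
        return out, into

    # -- views -------------------------------------------------------------

    def select(self, query_id: Optional[str] = None) -> list:
        if query_id is None:
            return list(self.entries)
        picked = [e for e in self.entries if e.query_id == query_id]
        if not picked:
            raise UnknownQueryError(f"no ledger entries for query {query_id!r}")
        return picked

    def scanned_by_platform(self, query_id: Optional[str] = None) -> dict:
        out: dict = {}
        for e in self.select(query_id):
            if e.kind == "scan":
                out[e.platform_name] = out.get(e.platform_name, 0) + e.raw_bytes
        return out

    def transferred_bytes(self, query_id: Optional[str] = None) -> dict:
        """Totals over transfer_out entries: raw and wire bytes moved."""
        raw = wire = 0
        for e in self.select(query_id):
            if e.kind == "transfer_out":
                raw += e.raw_bytes
                wire += e.wire_bytes
        return {"raw": raw, "wire": wire}


# ---------------------------------------------------------------------------
# Derived arithmetic
# ---------------------------------------------------------------------------

def egress_reduction_percent(per_query_scanned_bytes, full_table_bytes) -> float:
    """Egress saved by scanning in place: 100 x (1 - scanned/full), 2 dp."""
    if full_table_bytes <= 0:
        raise ValueError("full_table_bytes must be positive")
    if per_query_scanned_bytes > full_table_bytes:
        raise ValueError("per-query scan cannot exceed the full table")
    return round(100.0 * (1.0 - per_query_scanned_bytes / full_table_bytes), 2)


def fraction_moved_percent(moved_bytes, full_table_bytes) -> float:
    """Moved share of the full table as a percentage, one significant digit."""
    if full_table_bytes <= 0:
        raise ValueError("full_table_bytes must be positive")
    value = 100.0 * moved_bytes / full_table_bytes
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))))


def break_even_queries(full_table_bytes, per_query_scanned_bytes) -> int:
    """In-situ queries whose cumulative scans equal one full-table egress.

    floor(full / per-query), in exact rational arithmetic so integer byte
    inputs never lose to floating-point rounding.
    """
    if per_query_scanned_bytes <= 0:
        raise ValueError("per_query_scanned_bytes must be positive")
    return int(Fraction(full_table_bytes) / Fraction(per_query_scanned_bytes))


def report(ledger: CostLedger, query_id: Optional[str] = None,
           price_per_tb: Optional[float] = None) -> dict:
    """Pure summary of the ledger: per-platform scans, moved bytes, totals.

    With ``price_per_tb`` set, adds a cost figure treating scanned plus
    wire-moved bytes as billable at that rate (decimal TB).
    """
    entries = ledger.select(query_id)
    scanned = {}
    for e in entries:
        if e.kind == "scan":
            scanned[e.platform_name] = scanned.get(e.platform_name, 0) + e.raw_bytes
    raw = sum(e.raw_bytes for e in entries if e.kind == "transfer_out")
    wire = sum(e.wire_bytes for e in entries if e.kind == "transfer_out")
    summary = {
        "query_id": query_id,
        "scanned_bytes_by_platform": scanned,
        "total_scanned_bytes": sum(scanned.values()),
        "moved_raw_bytes": raw,
        "moved_wire_bytes": wire,
        "n_transfers": sum(1 for e in entries if e.kind == "transfer_out"),
        "n_entries": len(entries),
    }
    if price_per_tb is not None:
        billable = summary["total_scanned_bytes"] + wire
        summary["billable_cost"] = round(billable / 1e12 * price_per_tb, 6)
    return summary


# ---------------------------------------------------------------------------
# Unit helpers (binary convention for display: 1 GB = 1024 MB)
# ---------------------------------------------------------------------------

GB = 1024 ** 3
MB = 1024 ** 2


def format_bytes(n: int) -> str:
    if n >= GB:
        return f"{n / GB:.2f} GB"
    if n >= MB:
        return f"{n / MB:.2f} MB"
    return f"{n} B"
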