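"""Zero-motion statistics queries: local allele counts, exact merge.

A cohort split across platforms (samples partitioned, every site row present
on each side) can answer allele-frequency queries without moving genotypes:
each platform computes its shard's matched-record count and AC/AN locally,
and the integers are pooled exactly.  The merged frequency is

    AF = (sum of shard AC) / (sum of shard AN)

— not the mean of shard frequencies, which would be biased under unequal
shard sizes.  No bytes cross platforms; the ledger records scans only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

from .errors import (
    FedvarError,
    PartialFailureError,
    SelectorError,
)
from .platform import Federation, Platform, Selector, run_selector_query


@dataclass
class ShardStat:
    """One platform's local contribution to a federated statistic."""

    platform_name: str
    table_name: str
    n_matched: int
    ac: int
    an: int
    bytes_scanned: int

    def __post_init__(self):
        if not (0 <= self.ac <= self.an):
            raise ValueError("require 0 <= ac <= an")
        if self.n_matched < 0:
            raise ValueError("n_matched must be >= 0")


@dataclass
class MergedStat:
    """Exact pooled statistic over shards.

    ``allele_frequency`` is an exact rational (None when no alleles were
    observed); ``af`` renders it as a decimal at 6 significant digits.
    """

    shards: list = field(default_factory=list)
    total_ac: int = 0
    total_an: int = 0
    total_matched: int = 0

    @property
    def allele_frequency(self) -> Optional[Fraction]:
        if self.total_an == 0:
            return None
        return Fraction(self.total_ac, self.total_an)

    @property
    def af(self) -> Optional[float]:
        f = self.allele_frequency
        if f is None:
            return None
        return float(f"{float(f):.6g}")

    def to_dict(self) -> dict:
        return {
            "total_ac": self.total_ac,
            "total_an": self.total_an,
            "total_matched": self.total_matched,
            "allele_frequency": self.af,
            "shards": [vars(s).copy() for s in self.shards],
        }


def local_allele_stats(platform: Platform, table, selector: Selector,
                       ledger=None, query_id: Optional[str] = None) -> ShardStat:
    """One shard's matched rows and allele counts for an rsID/site selector."""
    if selector.mode not in ("rsid", "site"):
        raise SelectorError(
            f"{selector.mode!r} selectors are unsupported for allele statistics;"
            " use rsid or site"
        )
    handle = platform._handle(table)
    if handle.kind != "variant":
        raise SelectorError(
            f"allele statistics need a variant table, got kind={handle.kind!r}"
        )
    result = run_selector_query(platform, handle, selector,
                                ledger=ledger, query_id=query_id)
    return ShardStat(
        platform_name=platform.name,
        table_name=handle.table_name,
        n_matched=len(result.rows),
        ac=sum(r["ac"] for r in result.rows),
        an=sum(r["an"] for r in result.rows),
        bytes_scanned=result.bytes_scanned,
    )


def merge_stats(shards: Sequence[ShardStat]) -> MergedStat:
    """Pool shard counts exactly; shards with an = 0 contribute nothing."""
    if not shards:
        raise ValueError("merge_stats needs at least one shard")
    return MergedStat(
        shards=list(shards),
        total_ac=sum(s.ac for s in shards),
        total_an=sum(s.an for s in shards),
        total_matched=sum(s.n_matched for s in shards),
    )


def stat_query(federation: Federation, selector: Selector,
               targets: Sequence) -> MergedStat:
    """Fan a statistics query out to every target shard and merge exactly.

    ``targets`` are (platform_name, table_name) pairs or "platform.table"
    strings.  A shard that cannot be reached aborts the query with a
    partial-failure error listing the shards already completed; there is no
    silent partial merge.  Zero bytes move between platforms.
    """
    if not targets:
        raise ValueError("stat_query needs at least one target")
    query_id = federation.new_query_id()
    completed = []
    for target in targets:
        try:
            platform, handle = federation.resolve(target)
            shard = local_allele_stats(platform, handle, selector,
                                       ledger=federation.ledger,
                                       query_id=query_id)
        except FedvarError as exc:
            raise PartialFailureError(
                f"shard {target!r} failed ({exc}); "
                f"completed shards: {[s.platform_name + '.' + s.table_name for s in completed]}",
                completed=completed,
            ) from exc
        completed.append(shard)
    merged = merge_stats(completed)
    merged.query_id = query_id
    return merged
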