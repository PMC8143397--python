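"""Cross-platform joins with minimal data motion.

A data query joins a variant table on one platform against an annotation
table on another.  Rather than exporting either table wholesale, the
pipeline (i) resolves the request to a genomic region, (ii) estimates the
size of each side's matching subset with pruned count queries, (iii) moves
the provably smaller subset — compressed, optionally encrypted — to the
platform hosting the larger side, (iv) materializes it there as a temporary
table, (v) runs the half-open interval-overlap join where the large data
lives, and (vi) drops the temporary table, returning the joined rows with a
full cost accounting.  An explicit ``move_larger`` flag inverts the choice
of moving side (for deployments whose policy forbids moving one side).
"""

from __future__ import annotations

import hashlib
import hmac
import json
import os
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import (
    AmbiguousGeneError,
    DecryptionError,
    GeneNotFoundError,
    MustTransferFirstError,
    TransferIntegrityError,
)
from .platform import (
    Federation,
    Platform,
    Selector,
    count_selector_query,
    drop_temp,
    materialize_temp,
    run_selector_query,
)
from .variant_store import GeneRegion, TableHandle, parse_serialized_row, serialize_row


@dataclass
class TransferPlan:
    """The moving-side decision for one data query."""

    selector: Selector
    side_estimates: dict  # platform_name -> (rows, bytes)
    moving_side: str
    receiving_side: str
    move_larger: bool
    codec: str
    encrypt: bool

    def __post_init__(self):
        if self.moving_side == self.receiving_side:
            raise ValueError("moving and receiving side must differ")


@dataclass
class TransferReceipt:
    raw_bytes: int
    wire_bytes: int
    checksum: str
    temp_handle: Optional[TableHandle] = None


@dataclass
class DataQueryResult:
    rows: list
    plan: TransferPlan
    receipt: TransferReceipt
    query_id: str
    bytes_scanned_join: int
    ledger_entries: list


# ---------------------------------------------------------------------------
# Gene resolution
# ---------------------------------------------------------------------------

def resolve_gene(platform: Platform, symbol: str, gene_model) -> GeneRegion:
    """Resolve an HGNC symbol to its unique region in the gene-model table.

    Input is uppercased before the (case-sensitive) match, so "tp53" and
    "TP53" resolve identically.
    """
    from .platform import full_table_rows

    wanted = symbol.upper()
    hits = [
        row for row in full_table_rows(platform, gene_model)
        if row.get("attributes", {}).get("symbol") == wanted
    ]
    if not hits:
        raise GeneNotFoundError(f"gene symbol {wanted!r} not in gene model")
    if len(hits) > 1:
        raise AmbiguousGeneError(
            f"gene symbol {wanted!r} matches {len(hits)} gene-model rows",
            candidates=[
                (h["chromosome_name"], h["start_position"], h["end_position"])
                for h in hits
            ],
        )
    hit = hits[0]
    return GeneRegion(
        symbol=wanted,
        chromosome_name=hit["chromosome_name"],
        start_position=hit["start_position"],
        end_position=hit["end_position"],
    )


# ---------------------------------------------------------------------------
# Subset estimation and transfer planning
# ---------------------------------------------------------------------------

def estimate_subset(platform: Platform, table, selector: Selector,
                    ledger=None, query_id: Optional[str] = None) -> tuple:
    """(rows, bytes) a selector would pull from a table.

    The row count is exact (a pruned count query); the byte figure is an
    estimate — rows times the table's mean serialized row width — so the
    plan can be made before any rows are extracted.
    """
    handle = platform._handle(table)
    rows, _scanned = count_selector_query(platform, handle, selector,
                                          ledger=ledger, query_id=query_id)
    mean_width = handle.byte_size / handle.row_count if handle.row_count else 0.0
    return rows, int(round(rows * mean_width))


def plan_transfer(estimates: dict, move_larger: bool = False,
                  selector: Optional[Selector] = None,
                  codec: str = "zlib", encrypt: bool = False) -> TransferPlan:
    """Choose the moving side: smaller estimated bytes (larger on request).

    Exactly two platforms; ties break to the lexicographically smaller
    platform name.
    """
    if len(estimates) != 2:
        raise ValueError("transfer planning supports exactly two platforms")
    names = sorted(estimates)  # lexicographic tie-break baked into sort order
    key = (lambda n: (-estimates[n][1], n)) if move_larger \
        else (lambda n: (estimates[n][1], n))
    moving = min(names, key=key)
    receiving = names[0] if moving == names[1] else names[1]
    return TransferPlan(
        selector=selector, side_estimates=dict(estimates),
        moving_side=moving, receiving_side=receiving,
        move_larger=move_larger, codec=codec, encrypt=encrypt,
    )


# ---------------------------------------------------------------------------
# Pack / unpack (compress + authenticate-encrypt + checksum)
# ---------------------------------------------------------------------------

_MAGIC = b"FEDV1\n"


def _derive_keys(key) -> tuple:
    material = key.encode() if isinstance(key, str) else bytes(key)
    return (hashlib.sha256(material + b"|enc").digest(),
            hashlib.sha256(material + b"|mac").digest())


def _keystream_xor(data: bytes, enc_key: bytes, nonce: bytes) -> bytes:
    out = bytearray(len(data))
    block = 0
    offset = 0
    while offset < len(data):
        pad = hashlib.sha256(enc_key + nonce + block.to_bytes(8, "big")).digest()
        chunk = data[offset:offset + len(pad)]
        for i, byte in enumerate(chunk):
            out[offset + i] = byte ^ pad[i]
        offset += len(pad)
        block += 1
    return bytes(out)


def _encrypt(data: bytes, key) -> bytes:
    enc_key, mac_key = _derive_keys(key)
    nonce = os.urandom(16)
    ciphertext = _keystream_xor(data, enc_key, nonce)
    tag = hmac.new(mac_key, nonce + ciphertext, hashlib.sha256).digest()
    return nonce + tag + ciphertext

def _decrypt(blob: bytes, key) -> bytes:
    enc_key, mac_key = _derive_keys(key)
    if len(blob) < 48:
        raise DecryptionError("encrypted payload too short")
    nonce, tag, ciphertext = blob[:16], blob[16:48], blob[48:]
    expect = hmac.new(mac_key, nonce + ciphertext, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expect):
        raise DecryptionError("authentication tag mismatch (wrong key or tampering)")
    return _keystream_xor(ciphertext, enc_key, nonce)


def pack(records: Sequence[dict], layout: Sequence[str], codec: str = "zlib",
         encrypt: bool = False, key=None) -> tuple:
    """Serialize records for transfer; returns (payload, receipt).

    ``raw_bytes`` is the canonical serialized size of the records — the same
    per-row serialization the platforms use for byte accounting — so ledger
    arithmetic and payload sizes agree exactly.  The payload is a small JSON
    header plus the (compressed, optionally encrypted) body; the header
    carries the SHA-256 of the raw serialization for end-to-end integrity.
    """
    if codec != "zlib":
        raise ValueError(f"unsupported codec {codec!r}")
    if encrypt and key is None:
        raise ValueError("encryption requested without a key")
    raw = ("".join(serialize_row(r, layout) + "\n" for r in records)).encode()
    checksum = hashlib.sha256(raw).hexdigest()
    body = zlib.compress(raw, 6)
    if encrypt:
        body = _encrypt(body, key)
    header = json.dumps({
        "layout": list(layout), "codec": codec, "encrypted": encrypt,
        "checksum": checksum, "raw_bytes": len(raw), "n_records": len(records),
    }, separators=(",", ":")).encode()
    payload = _MAGIC + header + b"\n" + body
    receipt = TransferReceipt(raw_bytes=len(raw), wire_bytes=len(payload),
                              checksum=checksum)
    return payload, receipt


def unpack(payload: bytes, key=None) -> tuple:
    """Inverse of :func:`pack`; returns (records, layout, checksum)."""
    if not payload.startswith(_MAGIC):
        raise TransferIntegrityError("payload missing transfer magic")
    try:
        header_line, body = payload[len(_MAGIC):].split(b"\n", 1)
        header = json.loads(header_line)
    except (ValueError, json.JSONDecodeError):
        raise TransferIntegrityError("payload header unreadable") from None
    if header.get("encrypted"):
        if key is None:
            raise DecryptionError("payload is encrypted; no key supplied")
        body = _decrypt(body, key)
    try:
        raw = zlib.decompress(body)
    except zlib.error:
        raise TransferIntegrityError("payload body failed to decompress") from None
    if hashlib.sha256(raw).hexdigest() != header["checksum"]:
        raise TransferIntegrityError("payload checksum mismatch")
    layout = tuple(header["layout"])
    records = [parse_serialized_row(line, layout)
               for line in raw.decode().splitlines()]
    return records, layout, header["checksum"]


def unpack_and_materialize(platform: Platform, payload: bytes, ttl_tag: str,
                           key=None, suffix: Optional[str] = None) -> TableHandle:
    """Verify, unpack and materialize a transferred payload as a temp table.

    Nothing is created unless the checksum (and, when encrypted, the
    authentication tag) verifies.
    """
    records, layout, _checksum = unpack(payload, key=key)
    return materialize_temp(platform, records, layout, ttl_tag, suffix=suffix)


# ---------------------------------------------------------------------------
# Overlap join
# ---------------------------------------------------------------------------

def _region_tuple(region) -> tuple:
    if isinstance(region, GeneRegion):
        return region.chromosome_name, region.start_position, region.end_position
    if isinstance(region, Selector) and region.mode == "region":
        return region.chromosome_name, region.start, region.end
    raise ValueError("region must be a GeneRegion or a region Selector")


def overlap_join(platform: Platform, variant_table, annotation_table,
                 region, ledger=None, query_id: Optional[str] = None) -> tuple:
    """Half-open interval-overlap join of variants with annotations.

    Emits one row per (variant, annotation) pair on the same chromosome with
    ``max(starts) < min(ends)``, the variant restricted to ``region``;
    output columns are the variant columns followed by the annotation
    interval and attributes.  Boundary-touching intervals do not join.
    Both tables must live on ``platform`` (transfer first otherwise).
    Returns (rows, bytes_scanned).
    """
    for table in (variant_table, annotation_table):
        if isinstance(table, TableHandle) and table.platform_name != platform.name:
            raise MustTransferFirstError(
                f"table {table.table_name!r} lives on {table.platform_name!r},"
                f" not {platform.name!r}; transfer it first"
            )
    v_handle = platform._handle(variant_table)
    a_handle = platform._handle(annotation_table)
    chrom, start, end = _region_tuple(region)
    region_sel = Selector.region(chrom, start, end)

    # Scan accounting: the pruned region partitions of each joined table.
    bytes_scanned = 0
    for handle in (v_handle, a_handle):
        candidates = platform._candidate_partitions(handle, region_sel, True)
        bytes_scanned += sum(b for _c, _b2, _n, b in candidates)

    sql = (
        'SELECT v.chromosome_name, v.start_position, v.end_position,'
        ' v.reference_bases, v.alternate_bases, v.rsid, v.ac, v.an, v."extra",'
        ' a.start_position, a.end_position, a."attributes"'
        f' FROM "{v_handle.table_name}" v JOIN "{a_handle.table_name}" a'
        ' ON v.chromosome_name = a.chromosome_name'
        ' AND v.start_position < a.end_position'
        ' AND a.start_position < v.end_position'
        ' WHERE v.chromosome_name = ? AND v.start_position < ?'
        ' AND v.end_position > ?'
        ' ORDER BY v.chromosome_name, v.start_position, a.start_position,'
        ' v.alternate_bases, a.end_position'
    )
    rows = []
    for fetched in platform.conn.execute(sql, (chrom, end, start)):
        (v_chrom, v_start, v_end, ref, alt, rsid, ac, an, extra,
         a_start, a_end, attrs) = fetched
        row = {
            "chromosome_name": v_chrom,
            "start_position": v_start,
            "end_position": v_end,
            "reference_bases": ref,
            "alternate_bases": alt,
            "rsid": rsid,
            "ac": ac,
            "an": an,
            "extra": json.loads(extra) if extra else {},
            "annotation_start_position": a_start,
            "annotation_end_position": a_end,
        }
        for k, v in (json.loads(attrs) if attrs else {}).items():
            row[k if k not in row else f"annotation_{k}"] = v
        rows.append(row)
    if ledger is not None:
        ledger.record_scan(platform.name, bytes_scanned, query_id)
    return rows, bytes_scanned


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------

def data_query(federation: Federation, selector: Selector,
               variant_target, annotation_target,
               gene_model_target=None, move_larger: bool = False,
               codec: str = "zlib", encrypt: bool = False,
               key=None) -> DataQueryResult:
    """Run a federated annotation join end to end.

    ``selector`` is a gene or region selector; gene selectors are resolved
    against ``gene_model_target`` first.  The two targets must live on
    distinct platforms.  The result multiset is independent of which side
    moves; cleanup of the temporary table is guaranteed even when the join
    fails after materialization.
    """
    v_platform, v_handle = federation.resolve(variant_target)
    a_platform, a_handle = federation.resolve(annotation_target)
    if v_platform.name == a_platform.name:
        raise ValueError(
            "data_query targets must live on two distinct platforms"
        )
    query_id = federation.new_query_id()
    ledger = federation.ledger
    entries_start = len(ledger.entries)

    if selector.mode == "gene":
        if gene_model_target is None:
            raise ValueError("gene selectors need a gene_model_target")
        g_platform, g_handle = federation.resolve(gene_model_target)
        gene = resolve_gene(g_platform, selector.gene_symbol, g_handle)
        region_sel = Selector.region(gene.chromosome_name,
                                     gene.start_position, gene.end_position)
    elif selector.mode == "region":
        region_sel = selector
    else:
        raise ValueError("data_query needs a gene or region selector")

    estimates = {
        v_platform.name: estimate_subset(v_platform, v_handle, region_sel,
                                         ledger=ledger, query_id=query_id),
        a_platform.name: estimate_subset(a_platform, a_handle, region_sel,
                                         ledger=ledger, query_id=query_id),
    }
    plan = plan_transfer(estimates, move_larger=move_larger,
                         selector=region_sel, codec=codec, encrypt=encrypt)

    if plan.moving_side == v_platform.name:
        moving_platform, moving_handle = v_platform, v_handle
        receiving_platform = a_platform
    else:
        moving_platform, moving_handle = a_platform, a_handle
        receiving_platform = v_platform

    subset = run_selector_query(moving_platform, moving_handle, region_sel,
                                ledger=ledger, query_id=query_id)
    payload, receipt = pack(subset.rows, moving_handle.layout, codec=codec,
                            encrypt=encrypt, key=key)
    ledger.record_transfer(moving_platform.name, receiving_platform.name,
                           receipt.raw_bytes, receipt.wire_bytes, query_id)
    temp = unpack_and_materialize(receiving_platform, payload, query_id,
                                  key=key, suffix=federation.temp_suffix())
    receipt.temp_handle = temp
    try:
        if plan.moving_side == v_platform.name:
            rows, join_bytes = overlap_join(receiving_platform, temp, a_handle,
                                            region_sel, ledger=ledger,
                                            query_id=query_id)
        else:
            rows, join_bytes = overlap_join(receiving_platform, v_handle, temp,
                                            region_sel, ledger=ledger,
                                            query_id=query_id)
    finally:
        drop_temp(receiving_platform, temp)

    return DataQueryResult(
        rows=rows, plan=plan, receipt=receipt, query_id=query_id,
        bytes_scanned_join=join_bytes,
        ledger_entries=ledger.entries[entries_start:],
    )
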