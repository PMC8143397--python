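"""Normalization of VCF/BED inputs into the federation's table schema.

Every platform stores variants and annotations in one harmonized, BED-style
relational schema: ``chromosome_name, start_position, end_position,
reference_bases, alternate_bases`` (0-based, half-open coordinates), with the
remaining VCF fields carried through unchanged in an ``extra`` map.  This
module converts VCF data lines (1-based POS) into that schema, splits
multi-allelic sites into one row per alternate allele, computes per-record
allele counts (AC/AN), assigns integer-range partition bins, and loads the
resulting tables onto a platform.

Coordinate convention: VCF POS p with reference allele REF maps to
``start_position = p - 1`` and ``end_position = start_position + len(REF)``.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    IngestError,
    RowValidationError,
    VcfParseError,
)

#: Default partition width in bp.  Positions on the longest human chromosome
#: (~250 Mb) then occupy at most 4,000 bins, the partition-count ceiling of
#: the serverless engines this layer emulates.  Configurable per table.
DEFAULT_BIN_WIDTH = 62_500

# Storage layouts: ordered column lists shared by the platform layer, the
# transfer serializer and the byte-accounting code.
VARIANT_LAYOUT = (
    "chromosome_name",
    "start_position",
    "end_position",
    "reference_bases",
    "alternate_bases",
    "rsid",
    "ac",
    "an",
    "bin_id",
    "extra",
)
ANNOTATION_LAYOUT = (
    "chromosome_name",
    "start_position",
    "end_position",
    "bin_id",
    "attributes",
)

_JSON_COLUMNS = {"extra", "attributes"}
_INT_COLUMNS = {"start_position", "end_position", "ac", "an", "bin_id"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One normalized bi-allelic variant row.

    ``ac`` counts this record's alternate allele over the cohort's
    non-missing called alleles; ``an`` counts all non-missing called alleles
    at the site.  Multi-allelic sites are represented by several records
    sharing the same interval, one per alternate allele.
    """

    chromosome_name: str
    start_position: int
    end_position: int
    reference_bases: str
    alternate_bases: str
    rsid: Optional[str] = None
    ac: int = 0
    an: int = 0
    bin_id: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start_position < 0:
            raise ValueError("start_position must be >= 0")
        if self.end_position != self.start_position + len(self.reference_bases):
            raise ValueError("end_position must equal start + len(REF)")
        if not (0 <= self.ac <= self.an):
            raise ValueError("require 0 <= ac <= an")

    def to_row(self) -> dict:
        return {
            "chromosome_name": self.chromosome_name,
            "start_position": self.start_position,
            "end_position": self.end_position,
            "reference_bases": self.reference_bases,
            "alternate_bases": self.alternate_bases,
            "rsid": self.rsid,
            "ac": self.ac,
            "an": self.an,
            "bin_id": self.bin_id,
            "extra": dict(self.extra),
        }


@dataclass
class AnnotationRecord:
    """One interval row of a functional-annotation table."""

    chromosome_name: str
    start_position: int
    end_position: int
    attributes: dict = field(default_factory=dict)
    bin_id: Optional[int] = None

    def __post_init__(self):
        if not (self.end_position > self.start_position >= 0):
            raise ValueError("require end > start >= 0")

    def to_row(self) -> dict:
        return {
            "chromosome_name": self.chromosome_name,
            "start_position": self.start_position,
            "end_position": self.end_position,
            "bin_id": self.bin_id,
            "attributes": dict(self.attributes),
        }


@dataclass(frozen=True)
class GeneRegion:
    """A named gene interval (HGNC symbol) in 0-based half-open coordinates."""

    symbol: str
    chromosome_name: str
    start_position: int
    end_position: int

    def __post_init__(self):
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.end_position <= self.start_position:
            raise ValueError("require end > start")


@dataclass
class TableHandle:
    """A registered table on a named platform.

    ``bin_width`` is the integer-range partition width in bp (``None`` for an
    unpartitioned table); ``clustered`` reports whether stored rows are
    physically ordered by (chromosome_name, start_position).
    ``max_interval_span`` is the longest stored interval (bp), used to widen
    pruned bin ranges so region queries never miss a record whose interval
    starts in an earlier bin.
    """

    platform_name: str
    table_name: str
    kind: str  # "variant" | "annotation" | "temp"
    schema: tuple
    row_count: int
    byte_size: int
    bin_width: Optional[int]
    clustered: bool
    max_interval_span: int = 0
    layout: tuple = VARIANT_LAYOUT

    def __post_init__(self):
        if self.row_count < 0 or self.byte_size < 0:
            raise ValueError("row_count and byte_size must be >= 0")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ValueError("bin_width must be positive or None")


# ---------------------------------------------------------------------------
# Row serialization (canonical on-wire / byte-accounting form)
# ---------------------------------------------------------------------------

def serialize_field(column: str, value) -> str:
    if value is None:
        return ""
    if column in _JSON_COLUMNS:
        return json.dumps(value, separators=(",", ":")) if value else ""
    return str(value)


def serialize_row(row: Mapping, layout: Sequence[str]) -> str:
    """Canonical tab-delimited serialization of one stored row."""
    return "\t".join(serialize_field(c, row.get(c)) for c in layout)


def parse_serialized_row(line: str, layout: Sequence[str]) -> dict:
    parts = line.split("\t")
    if len(parts) != len(layout):
        raise ValueError(
            f"serialized row has {len(parts)} fields, layout needs {len(layout)}"
        )
    row = {}
    for column, text in zip(layout, parts):
        if text == "":
            row[column] = {} if column in _JSON_COLUMNS else None
        elif column in _JSON_COLUMNS:
            row[column] = json.loads(text)
        elif column in _INT_COLUMNS:
            row[column] = int(text)
        else:
            row[column] = text
    return row


def row_byte_size(row: Mapping, layout: Sequence[str]) -> int:
    """Stored size of one row: serialized length plus a newline."""
    return len(serialize_row(row, layout).encode()) + 1


# ---------------------------------------------------------------------------
# Allele-count bookkeeping
# ---------------------------------------------------------------------------

def compute_ac_an(genotype_calls: Sequence[str], alt_index: int) -> tuple:
    """Count one alternate allele over diploid genotype strings.

    ``an`` is the number of non-missing allele calls, ``ac`` the number equal
    to ``alt_index`` (>= 1, identifying which alternate of the site is being
    counted).  ``.`` denotes a missing allele and is excluded from ``an``;
    half-calls contribute their called allele only.  ``|`` is treated like
    ``/`` (phasing carries no meaning here).
    """
    if alt_index < 1:
        raise ValueError("alt_index must be >= 1")
    target = str(alt_index)
    ac = 0
    an = 0
    for i, call in enumerate(genotype_calls):
        alleles = call.replace("|", "/").split("/")
        if len(alleles) != 2:
            raise ValueError(
                f"sample {i}: non-diploid genotype {call!r} is unsupported"
            )
        for allele in alleles:
            if allele == ".":
                continue
            an += 1
            if allele == target:
                ac += 1
    return ac, an


def _site_allele_counts(genotype_calls: Sequence[str], n_alts: int) -> tuple:
    """(an, [ac per alternate]) for one site, all alternates in one pass.

    Fast path: when every call is a single-character diploid pair
    ("a/b" or "a|b" with single-digit alleles), counts are character counts
    over the joined string.  Anything else falls back to per-sample parsing.
    """
    joined = "/".join(genotype_calls)
    if len(joined) == 4 * len(genotype_calls) - 1 and n_alts <= 9:
        an = 2 * len(genotype_calls) - joined.count(".")
        return an, [joined.count(str(k)) for k in range(1, n_alts + 1)]
    acs = []
    an = 0
    for k in range(1, n_alts + 1):
        ac_k, an = compute_ac_an(genotype_calls, k)
        acs.append(ac_k)
    return an, acs


# ---------------------------------------------------------------------------
# Partition binning
# ---------------------------------------------------------------------------

def assign_bin(start_position: int, bin_width: int) -> int:
    """Integer-range bin of a start position: floor(start / bin_width).

    Deterministic and chromosome-independent; a (chromosome, bin_id) pair is
    the unit of partition pruning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if start_position < 0:
        raise ValueError("start_position must be >= 0")
    return start_position // bin_width


# ---------------------------------------------------------------------------
# VCF normalization
# ---------------------------------------------------------------------------

def normalize_vcf_record(
    vcf_fields: Sequence[str],
    sample_names: Optional[Sequence[str]] = None,
    line_number: Optional[int] = None,
    keep_genotypes: bool = False,
) -> list:
    """Normalize one parsed VCF data line into VariantRecords.

    Returns one record per alternate allele (multi-allelic sites are split).
    AC/AN come from the genotype columns when present, otherwise from INFO
    AC/AN, otherwise 0/0.  QUAL, FILTER, INFO (and, with ``keep_genotypes``,
    FORMAT plus the sample columns) are preserved in ``extra``.
    """
    where = f"line {line_number}" if line_number is not None else "record"
    if len(vcf_fields) < 5:
        raise VcfParseError(f"{where}: expected at least 5 VCF columns")
    chrom, pos_text, vid, ref, alt_text = vcf_fields[:5]
    try:
        pos = int(pos_text)
    except ValueError:
        raise VcfParseError(f"{where}: malformed POS {pos_text!r}") from None
    if pos <= 0:
        raise VcfParseError(f"{where}: malformed POS {pos} (must be positive)")
    if not ref or ref == ".":
        raise VcfParseError(f"{where}: empty REF")
    if alt_text == ".":
        return []  # monomorphic site: nothing to represent
    if not alt_text:
        raise VcfParseError(f"{where}: empty ALT")

    alts = alt_text.split(",")
    if any(not a for a in alts):
        raise VcfParseError(f"{where}: empty ALT allele in {alt_text!r}")
    start = pos - 1
    end = start + len(ref)
    rsid = vid if vid not in (".", "") else None

    extra = {}
    if len(vcf_fields) > 5:
        extra["QUAL"] = vcf_fields[5]
    if len(vcf_fields) > 6:
        extra["FILTER"] = vcf_fields[6]
    if len(vcf_fields) > 7:
        extra["INFO"] = vcf_fields[7]

    genotypes = None
    if len(vcf_fields) > 9:
        format_keys = vcf_fields[8].split(":")
        try:
            gt_at = format_keys.index("GT")
        except ValueError:
            gt_at = None
        if gt_at is not None:
            cols = vcf_fields[9:]
            if gt_at == 0 and len(format_keys) == 1:
                genotypes = cols
            else:
                genotypes = [c.split(":")[gt_at] for c in cols]
        if keep_genotypes:
            extra["FORMAT"] = vcf_fields[8]
            names = sample_names or [f"S{i+1}" for i in range(len(vcf_fields) - 9)]
            for name, value in zip(names, vcf_fields[9:]):
                extra[name] = value

    if genotypes is not None:
        try:
            an, acs = _site_allele_counts(genotypes, len(alts))
        except ValueError as exc:
            raise VcfParseError(f"{where}: {exc}") from None
    else:
        an, acs = _info_ac_an(vcf_fields[7] if len(vcf_fields) > 7 else "", len(alts))

    records = []
    for alt, ac in zip(alts, acs):
        records.append(
            VariantRecord(
                chromosome_name=chrom,
                start_position=start,
                end_position=end,
                reference_bases=ref,
                alternate_bases=alt,
                rsid=rsid,
                ac=ac,
                an=an,
                extra=dict(extra),
            )
        )
    return records


def _info_ac_an(info: str, n_alts: int) -> tuple:
    """AC/AN fallback from the INFO column; (0, zeros) when absent."""
    ac_text = an_text = None
    for item in info.split(";"):
        if item.startswith("AC="):
            ac_text = item[3:]
        elif item.startswith("AN="):
            an_text = item[3:]
    if ac_text is None or an_text is None:
        return 0, [0] * n_alts
    try:
        an = int(an_text)
        acs = [int(x) for x in ac_text.split(",")]
    except ValueError:
        return 0, [0] * n_alts
    if len(acs) < n_alts:
        acs = acs + [0] * (n_alts - len(acs))
    return an, acs[:n_alts]


# ---------------------------------------------------------------------------
# File ingestion
# ---------------------------------------------------------------------------

def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":  # gzip/bgzip
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def iter_vcf_records(path, keep_genotypes: bool = False):
    """Yield VariantRecords from a plain or bgzip VCF file."""
    if not os.path.exists(path):
        raise IngestError(f"cannot read VCF: {path!r} does not exist")
    sample_names = None
    with _open_text(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.split("\t")
                if len(header) > 9:
                    sample_names = header[9:]
                continue
            if line.startswith("#"):
                continue
            yield from normalize_vcf_record(
                line.split("\t"),
                sample_names=sample_names,
                line_number=line_number,
                keep_genotypes=keep_genotypes,
            )


def ingest_vcf(
    path,
    platform,
    table_name: str,
    bin_width: Optional[int] = DEFAULT_BIN_WIDTH,
    keep_genotypes: bool = False,
) -> TableHandle:
    """Normalize a VCF and load it as a variant table on ``platform``.

    Rows are stored clustered (ordered by chromosome then start position);
    when ``bin_width`` is set every row gets a partition bin and the platform
    records per-(chromosome, bin) statistics for pruning.
    """
    records = list(iter_vcf_records(path, keep_genotypes=keep_genotypes))
    return load_variant_records(records, platform, table_name, bin_width)


def load_variant_records(
    records: Iterable[VariantRecord],
    platform,
    table_name: str,
    bin_width: Optional[int] = DEFAULT_BIN_WIDTH,
) -> TableHandle:
    rows = []
    for record in records:
        if bin_width is not None:
            record.bin_id = assign_bin(record.start_position, bin_width)
        rows.append(record.to_row())
    rows.sort(key=lambda r: (r["chromosome_name"], r["start_position"],
                             r["alternate_bases"]))
    return platform.load_table(
        table_name, kind="variant", layout=VARIANT_LAYOUT, rows=rows,
        bin_width=bin_width, clustered=True,
    )


def iter_annotation_records(path):
    """Yield AnnotationRecords from a BED file or a headered TSV.

    The first three columns must be chromosome_name, 0-based start_position
    and (exclusive) end_position; remaining columns become named attributes.
    A leading ``#`` line or a first row whose positional columns are not
    integers is taken as the header naming the attribute columns; otherwise
    attributes are named attr_1, attr_2, ...
    """
    if not os.path.exists(path):
        raise IngestError(f"cannot read annotation file: {path!r} does not exist")
    with _open_text(path) as handle:
        attr_names = None
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if line.startswith("#"):
                cols[0] = cols[0].lstrip("#")
                attr_names = cols[3:]
                continue
            if attr_names is None:
                try:
                    int(cols[1]), int(cols[2])
                except (ValueError, IndexError):
                    attr_names = cols[3:]
                    continue
                attr_names = [f"attr_{i+1}" for i in range(len(cols) - 3)]
            if len(cols) < 3:
                raise RowValidationError(
                    f"line {line_number}: need >= 3 columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise RowValidationError(
                    f"line {line_number}: non-integer interval bounds"
                ) from None
            if not (end > start >= 0):
                raise RowValidationError(
                    f"line {line_number}: invalid interval [{start}, {end})"
                )
            attributes = {}
            for i, value in enumerate(cols[3:]):
                name = attr_names[i] if i < len(attr_names) else f"attr_{i+1}"
                attributes[name] = value
            yield AnnotationRecord(
                chromosome_name=cols[0],
                start_position=start,
                end_position=end,
                attributes=attributes,
            )


def ingest_annotation(
    path,
    platform,
    table_name: str,
    bin_width: Optional[int] = DEFAULT_BIN_WIDTH,
) -> TableHandle:
    """Load a BED/TSV annotation file as an annotation table on ``platform``."""
    records = list(iter_annotation_records(path))
    return load_annotation_records(records, platform, table_name, bin_width)


def load_annotation_records(
    records: Iterable[AnnotationRecord],
    platform,
    table_name: str,
    bin_width: Optional[int] = DEFAULT_BIN_WIDTH,
) -> TableHandle:
    rows = []
    for record in records:
        if bin_width is not None:
            record.bin_id = assign_bin(record.start_position, bin_width)
        rows.append(record.to_row())
    rows.sort(key=lambda r: (r["chromosome_name"], r["start_position"],
                             r["end_position"]))
    return platform.load_table(
        table_name, kind="annotation", layout=ANNOTATION_LAYOUT, rows=rows,
        bin_width=bin_width, clustered=True,
    )


def ingest_gene_model(path, platform, table_name: str) -> TableHandle:
    """Load a gene-model TSV (symbol, chrom, start, end) for symbol lookup.

    Stored as an (unpartitioned) annotation table whose single attribute is
    the HGNC symbol; gene models are small enough that full scans are cheap.
    """
    if not os.path.exists(path):
        raise IngestError(f"cannot read gene model: {path!r} does not exist")
    records = []
    with _open_text(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if line.startswith("#") or (line_number == 1 and not cols[2].isdigit()):
                continue  # header
            if len(cols) < 4:
                raise RowValidationError(
                    f"line {line_number}: gene model needs 4 columns"
                )
            symbol, chrom = cols[0], cols[1]
            try:
                start, end = int(cols[2]), int(cols[3])
            except ValueError:
                raise RowValidationError(
                    f"line {line_number}: non-integer gene bounds"
                ) from None
            if not (end > start >= 0) or not symbol:
                raise RowValidationError(
                    f"line {line_number}: invalid gene row {cols!r}"
                )
            records.append(
                AnnotationRecord(
                    chromosome_name=chrom,
                    start_position=start,
                    end_position=end,
                    attributes={"symbol": symbol},
                )
            )
    return load_annotation_records(records, platform, table_name, bin_width=None)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_rows(platform, table_name: str) -> list:
    """All stored rows of a table, in clustered order, as plain dicts."""
    from .platform import full_table_rows

    return full_table_rows(platform, table_name)


def export_partition_files(platform, table_name: str, out_dir, fmt: str = "auto"):
    """Write one columnar file per (chromosome, bin) partition.

    Uses Parquet when pyarrow is importable (``fmt="auto"`` or ``"parquet"``),
    otherwise gzip-compressed delimited text with identical pruning
    semantics.  Returns the list of written paths.
    """
    rows = export_rows(platform, table_name)
    handle = platform.tables[table_name]
    groups = {}
    for row in rows:
        groups.setdefault((row["chromosome_name"], row.get("bin_id")), []).append(row)
    os.makedirs(out_dir, exist_ok=True)
    use_parquet = fmt == "parquet"
    if fmt == "auto":
        try:
            import pyarrow  # noqa: F401
            use_parquet = True
        except ImportError:
            use_parquet = False
    paths = []
    for (chrom, bin_id), group in sorted(
        groups.items(), key=lambda kv: (kv[0][0], -1 if kv[0][1] is None else kv[0][1])
    ):
        stem = f"{table_name}.chr{chrom}.bin{'none' if bin_id is None else bin_id}"
        if use_parquet:
            import pyarrow as pa
            import pyarrow.parquet as pq

            columns = {
                c: [serialize_field(c, r.get(c)) if c in _JSON_COLUMNS else r.get(c)
                    for r in group]
                for c in handle.layout
            }
            path = os.path.join(out_dir, stem + ".parquet")
            pq.write_table(pa.table(columns), path)
        else:
            path = os.path.join(out_dir, stem + ".tsv.gz")
            with gzip.open(path, "wt", encoding="utf-8") as out:
                out.write("\t".join(handle.layout) + "\n")
                for row in group:
                    out.write(serialize_row(row, handle.layout) + "\n")
        paths.append(path)
    return paths
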