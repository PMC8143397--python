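"""Service front end: config, a REST-style JSON handler, structured logging.

The query layers are exposed through a small typed JSON contract:

    GET  /tables                               -> registered table handles
    GET  /stat_query?rsid=...&tables=p.t,p.t   -> per-shard + merged stats
    POST /data_query {gene|region, variant_table, annotation_table, ...}
    POST /ingest     {kind, path, platform, table, ...}
    GET  /cost[?query_id=...]                  -> ledger summary

``handle_request`` is a pure function from (method, path, params, body) to a
(status, document) pair; :func:`serve` wraps it in a stdlib HTTP server.
Every response embeds the elapsed time and the ledger delta the request
produced, so timing and data volumes can be scraped from output messages.
Identical requests against the same config and seed produce identical
response documents apart from timing fields.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import variant_store
from .cost_model import report as cost_report
from .errors import FedvarError, UnknownQueryError
from .platform import Federation, Selector
from .stat_query import stat_query
from .data_query import data_query

log = logging.getLogger("fedvar")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PlatformSpec:
    name: str
    backend: str = ":memory:"
    scan_accounting: str = "bytes_of_partitions_read"


@dataclass
class ServiceConfig:
    """Validated service configuration.

    ``seed`` drives every source of randomness in the service (temp-table
    suffixes); ``bin_width`` is the default partition width for ingests.
    """

    platforms: list = field(default_factory=list)
    bin_width: int = variant_store.DEFAULT_BIN_WIDTH
    move_larger: bool = False
    encrypt: bool = False
    key: Optional[str] = None
    log_destination: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if not self.platforms:
            raise ValueError("config needs at least one platform")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.encrypt and not self.key:
            raise ValueError("encrypt: true requires a key")


def load_config(path) -> ServiceConfig:
    """Parse a YAML/JSON key-value config document into a ServiceConfig.

    Invalid content raises with the offending key named.
    """
    with open(path, "r", encoding="utf-8") as handle:
        doc = yaml.safe_load(handle) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a key-value document")
    platforms = []
    for i, entry in enumerate(doc.get("platforms", [])):
        if "name" not in entry:
            raise ValueError(f"{path}: platforms[{i}] is missing 'name'")
        platforms.append(PlatformSpec(
            name=entry["name"],
            backend=entry.get("backend", ":memory:"),
            scan_accounting=entry.get("scan_accounting",
                                      "bytes_of_partitions_read"),
        ))
    try:
        return ServiceConfig(
            platforms=platforms,
            bin_width=int(doc.get("bin_width", variant_store.DEFAULT_BIN_WIDTH)),
            move_larger=bool(doc.get("move_larger", False)),
            encrypt=bool(doc.get("encrypt", False)),
            key=doc.get("key"),
            log_destination=doc.get("log"),
            seed=int(doc.get("seed", 0)),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def build_federation(config: ServiceConfig) -> Federation:
    federation = Federation(seed=config.seed)
    for spec in config.platforms:
        federation.register_platform(spec.name, spec.backend,
                                     spec.scan_accounting)
    if config.log_destination:
        handler = logging.FileHandler(config.log_destination)
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    return federation


# ---------------------------------------------------------------------------
# Request handling
# ---------------------------------------------------------------------------

class App:
    """The service: a federation plus the JSON request contract (v1)."""

    def __init__(self, config: ServiceConfig,
                 federation: Optional[Federation] = None):
        self.config = config
        self.federation = federation or build_federation(config)

    # -- endpoint implementations -----------------------------------------

    def _tables(self, _params, _body):
        out = []
        for platform in self.federation.platforms.values():
            for handle in platform.tables.values():
                out.append({
                    "platform_name": handle.platform_name,
                    "table_name": handle.table_name,
                    "kind": handle.kind,
                    "row_count": handle.row_count,
                    "byte_size": handle.byte_size,
                    "bin_width": handle.bin_width,
                    "clustered": handle.clustered,
                })
        return {"tables": out}

    def _selector_from(self, params):
        if params.get("rsid"):
            return Selector.rsid(params["rsid"])
        if params.get("gene"):
            return Selector.gene(params["gene"])
        region = params.get("region")
        if isinstance(region, dict):
            return Selector.region(region["chromosome_name"],
                                   int(region["start"]), int(region["end"]))
        if params.get("chromosome_name") is not None:
            if params.get("end") is not None:
                return Selector.region(params["chromosome_name"],
                                       int(params["start"]), int(params["end"]))
            return Selector.site(params["chromosome_name"],
                                 int(params["start"]),
                                 params.get("reference_bases"),
                                 params.get("alternate_bases"))
        raise FedvarError("request carries no selector "
                          "(rsid, gene, region or site fields)")

    def _stat_query(self, params, _body):
        tables = params.get("tables", "")
        targets = [t for t in tables.split(",") if t] \
            if isinstance(tables, str) else list(tables)
        merged = stat_query(self.federation, self._selector_from(params), targets)
        return merged.to_dict()

    def _data_query(self, _params, body):
        result = data_query(
            self.federation,
            self._selector_from(body),
            body["variant_table"],
            body["annotation_table"],
            gene_model_target=body.get("gene_model"),
            move_larger=bool(body.get("move_larger", self.config.move_larger)),
            encrypt=bool(body.get("encrypt", self.config.encrypt)),
            key=body.get("key", self.config.key),
        )
        return {
            "rows": result.rows,
            "n_rows": len(result.rows),
            "moving_side": result.plan.moving_side,
            "receiving_side": result.plan.receiving_side,
            "side_estimates": {
                p: {"rows": r, "bytes": b}
                for p, (r, b) in result.plan.side_estimates.items()
            },
            "raw_bytes": result.receipt.raw_bytes,
            "wire_bytes": result.receipt.wire_bytes,
            "checksum": result.receipt.checksum,
            "query_id": result.query_id,
        }

    def _ingest(self, _params, body):
        platform = self.federation.platform(body["platform"])
        kind = body.get("kind", "vcf")
        bin_width = body.get("bin_width", self.config.bin_width)
        if bin_width is not None:
            bin_width = int(bin_width)
        if kind == "vcf":
            handle = variant_store.ingest_vcf(
                body["path"], platform, body["table"], bin_width=bin_width,
                keep_genotypes=bool(body.get("keep_genotypes", False)),
            )
        elif kind == "annotation":
            handle = variant_store.ingest_annotation(
                body["path"], platform, body["table"], bin_width=bin_width,
            )
        elif kind == "gene_model":
            handle = variant_store.ingest_gene_model(
                body["path"], platform, body["table"],
            )
        else:
            raise FedvarError(f"unknown ingest kind {kind!r}")
        return {
            "platform_name": handle.platform_name,
            "table_name": handle.table_name,
            "kind": handle.kind,
            "row_count": handle.row_count,
            "byte_size": handle.byte_size,
        }

    def _cost(self, params, _body):
        price = params.get("price_per_tb")
        return cost_report(
            self.federation.ledger,
            query_id=params.get("query_id") or None,
            price_per_tb=float(price) if price is not None else None,
        )

    _ROUTES = {
        ("GET", "/tables"): "_tables",
        ("GET", "/stat_query"): "_stat_query",
        ("POST", "/data_query"): "_data_query",
        ("POST", "/ingest"): "_ingest",
        ("GET", "/cost"): "_cost",
    }

    def handle_request(self, method: str, path: str,
                       params: Optional[dict] = None,
                       body: Optional[dict] = None) -> tuple:
        """Dispatch one request; returns (status, response document)."""
        started = time.time()
        ledger_mark = len(self.federation.ledger.entries)
        route = self._ROUTES.get((method.upper(), path))
        if route is None:
            return 404, {"error": f"no route {method} {path}"}
        try:
            result = getattr(self, route)(params or {}, body or {})
            status = 200
        except (KeyError, ValueError) as exc:
            result = {"error": str(exc)}
            status = 400
        except UnknownQueryError as exc:
            result = {"error": str(exc)}
            status = 404
        except FedvarError as exc:
            result = {"error": str(exc)}
            status = 404 if "no table" in str(exc) or "no platform" in str(exc) \
                else 400
        delta = self.federation.ledger.entries[ledger_mark:]
        envelope = {
            "status": status,
            "result": result,
            "elapsed_s": round(time.time() - started, 6),
            "ledger_delta": [
                {"platform": e.platform_name, "kind": e.kind,
                 "raw_bytes": e.raw_bytes, "wire_bytes": e.wire_bytes,
                 "query_id": e.query_id}
                for e in delta
            ],
        }
        return status, envelope


def serve(config: ServiceConfig, host: str = "127.0.0.1", port: int = 8080):
    """Run the JSON service on a stdlib HTTP server (blocking)."""
    from http.server import BaseHTTPRequestHandler, HTTPServer
    from urllib.parse import parse_qsl, urlparse

    app = App(config)

    class Handler(BaseHTTPRequestHandler):
        def _dispatch(self, method):
            parsed = urlparse(self.path)
            params = dict(parse_qsl(parsed.query))
            body = None
            length = int(self.headers.get("Content-Length") or 0)
            if length:
                body = json.loads(self.rfile.read(length))
            status, doc = app.handle_request(method, parsed.path, params, body)
            payload = json.dumps(doc).encode()
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(payload)))
            self.end_headers()
            self.wfile.write(payload)

        def do_GET(self):
            self._dispatch("GET")

        def do_POST(self):
            self._dispatch("POST")

        def log_message(self, fmt, *args):
            log.info("http %s", fmt % args)

    server = HTTPServer((host, port), Handler)
    log.info("serving on %s:%d", host, port)
    server.serve_forever()
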