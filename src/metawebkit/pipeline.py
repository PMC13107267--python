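"""End-to-end pipeline: records -> scaled links -> metaweb -> summaries.

One call validates the inputs, scales every link, assembles the seasonal
multilayer metaweb, drops unresolved layers, scores node knowledge, and
writes the output bundle atomically (nothing appears in the output
directory unless every stage succeeded). A manifest records the config
hash and row counts so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import knowledge as kb
from . import network as net
from . import records as rio
from . import scaling

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


@dataclass
class PipelineConfig:
    records_path: str = "records.csv"
    nodes_path: str = "nodes.csv"
    out_dir: str = "out"
    season: str = "both"
    min_links: int = 3
    bin_edges: tuple[float, float, float] = scaling.DEFAULT_BIN_EDGES
    case_floor: float = scaling.DEFAULT_CASE_FLOOR
    rounding_decimals: int = 1
    extrapolate_links: list = field(default_factory=list)
    allow_self_loops: bool = False

    def validate(self) -> None:
        if self.season not in net.SEASON_FILTERS:
            raise ValueError(f"season {self.season!r} not in {net.SEASON_FILTERS}")
        if self.min_links < 1:
            raise ValueError("min_links must be >= 1")
        if self.case_floor <= 0 or self.case_floor > 1:
            raise ValueError("case_floor must lie in (0, 1]")
        if self.rounding_decimals < 0:
            raise ValueError("rounding_decimals must be >= 0")
        e = tuple(self.bin_edges)
        if len(e) != 3 or not 0 < e[0] < e[1] < e[2] < 100:
            raise ValueError(f"bin_edges {e!r} must be 3 increasing values in (0, 100)")
        for item in self.extrapolate_links:
            if isinstance(item, Mapping):
                missing = {"consumer", "resource", "layer"} - set(item)
                if missing:
                    raise ValueError(f"extrapolation entry {item!r} missing {missing}")
            elif len(item) != 3:
                raise ValueError(f"extrapolation entry {item!r} is not a triple")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.bin_edges, list):
            cfg.bin_edges = tuple(cfg.bin_edges)
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the output bundle; returns the manifest.

    Outputs: scaled_links.csv, metaweb_edges.csv, metaweb.graphml,
    knowledge.csv, network_summary.csv, layer_report.json, manifest.json.
    Any stage failure removes partial outputs and raises ``StageError``.
    """
    try:
        config.validate()
    except ValueError as exc:
        raise StageError("config", exc) from exc

    out_dir = Path(config.out_dir)
    tmp = Path(tempfile.mkdtemp(prefix=".metawebkit-", dir=out_dir.parent or "."))
    try:
        try:
            records, nodes = rio.read_records(
                config.records_path, config.nodes_path,
                allow_self_loops=config.allow_self_loops,
            )
        except (rio.ValidationError, OSError) as exc:
            raise StageError("validate", exc) from exc

        usable = rio.drop_excluded_reviews(records)
        try:
            links = scaling.scale_records(
                usable,
                bin_edges=config.bin_edges,
                case_floor=config.case_floor,
                rounding_decimals=config.rounding_decimals,
                extrapolate_links=config.extrapolate_links,
            )
        except ValueError as exc:
            raise StageError("scale", exc) from exc
        scaling.write_links(links, tmp / "scaled_links.csv")

        try:
            metaweb = net.build_metaweb(links, nodes, season=config.season)
            metaweb, layer_report = net.exclude_sparse_layers(
                metaweb, min_links=config.min_links
            )
        except ValueError as exc:
            raise StageError("build", exc) from exc
        net.write_edge_csv(metaweb, tmp / "metaweb_edges.csv")
        net.write_graphml(metaweb, tmp / "metaweb.graphml")
        net.network_summary(metaweb).to_csv(tmp / "network_summary.csv", index=False)
        with open(tmp / "layer_report.json", "w") as fh:
            json.dump(layer_report, fh, indent=2, sort_keys=True)

        try:
            know = kb.knowledge_score(records, nodes)
        except ValueError as exc:
            raise StageError("knowledge", exc) from exc
        kb.write_knowledge(know, tmp / "knowledge.csv")

        manifest = {
            "config_hash": config.config_hash(),
            "config": json.loads(json.dumps(asdict(config), default=list)),
            "n_records": len(records),
            "n_records_used": len(usable),
            "n_nodes": len(nodes),
            "n_scaled_links": len(links),
            "n_metaweb_edges": metaweb.n_edges,
            "included_layers": sorted(metaweb.included_layers),
            "dropped_layers": sorted(
                l for l, rep in layer_report.items() if rep["dropped"]
            ),
            "outputs": sorted(p.name for p in tmp.iterdir()) + ["manifest.json"],
        }
        with open(tmp / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

        out_dir.mkdir(parents=True, exist_ok=True)
        for path in sorted(tmp.iterdir()):
            shutil.move(str(path), out_dir / path.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    logger.info("pipeline complete: %d links, %d metaweb edges",
                manifest["n_scaled_links"], manifest["n_metaweb_edges"])
    return manifest
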