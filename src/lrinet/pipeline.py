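"""End-to-end pipeline: build → score → salient → deg → compare → enrich.

Each stage writes its table under the output directory and the run closes
with a machine-readable manifest (package/library versions, configuration
hash, seed, per-stage timings and record counts), so any stage can be
re-run individually from its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from . import io
from .build import MicroarrayExperimentSituation, NetworkBuildConfig, build_network, network_summary
from .deg import compute_deg
from .errors import ValidationError
from .game import lri_closed
from .saliency import hypergeom_enrichment, score_distribution, select_salient, set_overlap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression: str
    metadata: str
    out_dir: str
    network: NetworkBuildConfig = field(default_factory=NetworkBuildConfig)
    deg_alpha: float = 0.05
    deg_lfc_min: float = 2.0
    salient_threshold: float = 0.0
    gmt: str | None = None
    universe: str | None = None
    enrich_alpha: float = 0.05
    enrich_min_genes: int = 3
    precision: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.network, dict):
            self.network = NetworkBuildConfig(**self.network)
        for label, p in (("expression", self.expression), ("metadata", self.metadata)):
            if not Path(p).is_file():
                raise ValidationError(f"{label} file not found: {p}")
        if (self.gmt is None) != (self.universe is None):
            raise ValidationError("gmt and universe must be given together")
        for p in (self.gmt, self.universe):
            if p is not None and not Path(p).is_file():
                raise ValidationError(f"file not found: {p}")
        if not 1 <= self.precision <= 17:
            raise ValidationError("precision must lie in [1, 17]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(name: str, t0: float, **info) -> None:
        entry = {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **info}
        stages.append(entry)
        logger.info("stage %s done in %.3fs: %s", name, entry["seconds"], info)

    t0 = time.perf_counter()
    expr = io.read_expression(config.expression)
    meta = io.read_metadata(config.metadata)
    mes = MicroarrayExperimentSituation.from_frames(expr, meta)
    record("load", t0, n_genes=len(mes.genes),
           n_case=len(mes.diseased_samples), n_control=len(mes.reference_samples))

    t0 = time.perf_counter()
    network = build_network(mes, config.network)
    io.write_edge_list(network, out / "edges.tsv")
    record("build", t0, **network_summary(network))

    t0 = time.perf_counter()
    scores = lri_closed(network)
    io.write_scores(scores, out / "scores.tsv", config.precision)
    record("score", t0, n_scored=len(scores.genes))

    t0 = time.perf_counter()
    salient = select_salient(scores, config.salient_threshold)
    io.write_gene_list(salient, out / "salient.txt")
    dist = score_distribution(scores) if salient else {"count": 0}
    record("salient", t0, n_salient=len(salient), distribution=dist)

    t0 = time.perf_counter()
    deg = compute_deg(mes, config.deg_alpha, config.deg_lfc_min)
    io.write_deg(deg, out / "deg.tsv")
    deg_genes = list(deg.index[deg["is_deg"]])
    record("deg", t0, n_deg=len(deg_genes))

    t0 = time.perf_counter()
    overlap = set_overlap(salient, deg_genes)
    io.write_json(overlap, out / "salient_vs_deg.json")
    record("compare", t0, n_common=overlap["n_common"])

    if config.gmt is not None:
        t0 = time.perf_counter()
        sets = io.read_gmt(config.gmt, io.read_gene_list(config.universe))
        enr = hypergeom_enrichment(
            salient, sets, config.enrich_alpha, config.enrich_min_genes
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")
        record("enrich", t0, n_terms=len(enr),
               n_significant=int(enr["significant"].sum()))

    manifest = {
        "lrinet_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
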