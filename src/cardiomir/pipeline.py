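"""End-to-end orchestration: ingest/generate -> network + hubs -> disease
statistics -> association-rule mining -> reports.

Every artifact is written with deterministic ordering, and the run report
records SHA-256 checksums, so identical config + seed gives identical files.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cio
from .mining import (
    ARMConfig,
    annotate_rule,
    encode_transactions,
    generate_rules,
    itemsets_to_frame,
    mine_frequent_itemsets,
    rules_to_frame,
)
from .network import HubCriteria, build_network, find_hubs
from .records import AssociationDataset, summarize_dataset
from .stats import run_all_diseases, summaries_to_frame
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One end-to-end run: exactly one input source, thresholds, output dir."""

    out_dir: Path
    input_tsv: Path | None = None
    synthetic: SyntheticConfig | None = None
    hub_criteria: HubCriteria = field(default_factory=HubCriteria)
    arm: ARMConfig = field(default_factory=ARMConfig)
    bh_adjust: bool = False
    signed_items: bool = False

    def __post_init__(self) -> None:
        if (self.input_tsv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_tsv or synthetic must be given")
        self.out_dir = Path(self.out_dir)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def _write(path: Path, text: str, manifest: dict[str, str]) -> None:
    path.write_text(text, encoding="utf-8")
    manifest[path.name] = _sha256(text)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages, write artifacts under ``cfg.out_dir`` and return the
    machine-readable run report (also written as ``report.json``).

    Any stage error aborts with a stage-labeled :class:`PipelineError`; the
    report written so far is flagged as partial.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {"stages": [], "files": manifest, "partial": False}

    def stage(name: str):
        logger.info("stage %s", name)
        report["stages"].append(name)

    try:
        stage("ingest")
        if cfg.input_tsv is not None:
            ds = cio.parse_associations(cfg.input_tsv)
        else:
            ds = generate_dataset(cfg.synthetic)
        ingest_tsv = cio.dataset_to_tsv(ds)
        ingest_checksum = _sha256(ingest_tsv)
        _write(out / "associations.tsv", ingest_tsv, manifest)
        summary = summarize_dataset(ds)
        report["dataset"] = {
            "n_mirnas": summary.n_mirnas,
            "n_diseases": summary.n_diseases,
            "n_incidences": summary.n_incidences,
            "n_up": summary.n_up,
            "n_down": summary.n_down,
        }
    except PipelineError:
        raise
    except Exception as exc:
        report["partial"] = True
        raise PipelineError("ingest", str(exc)) from exc

    try:
        stage("network")
        net = build_network(ds)
        hubs = find_hubs(net, cfg.hub_criteria)
        _write(out / "network.sif", cio.write_network_interchange(net, "SIF"), manifest)
        _write(
            out / "network.graphml",
            cio.write_network_interchange(net, "GraphML", hub_nodes=hubs.hub_nodes()),
            manifest,
        )
        _write(
            out / "hubs.tsv",
            hubs.to_frame(net).to_csv(sep="\t", index=False),
            manifest,
        )
        report["network"] = {
            "n_edges": net.n_edges,
            "n_mirna_hubs": len(hubs.mirna_hubs),
            "n_disease_hubs": len(hubs.disease_hubs),
        }
    except Exception as exc:
        report["partial"] = True
        raise PipelineError("network", str(exc)) from exc

    try:
        stage("stats")
        summaries = run_all_diseases(ds, bh_adjust=cfg.bh_adjust)
        _write(
            out / "disease_stats.tsv",
            summaries_to_frame(summaries).to_csv(sep="\t", index=False),
            manifest,
        )
        report["stats"] = {"n_diseases_tested": len(summaries)}
    except Exception as exc:
        report["partial"] = True
        raise PipelineError("stats", str(exc)) from exc

    try:
        stage("mine")
        db = encode_transactions(ds, signed_items=cfg.signed_items)
        itemsets = mine_frequent_itemsets(db, cfg.arm)
        rules = generate_rules(itemsets, db, cfg.arm)
        if not cfg.signed_items:
            rules = [annotate_rule(r, ds) for r in rules]
        _write(
            out / "itemsets.tsv",
            itemsets_to_frame(itemsets).to_csv(sep="\t", index=False),
            manifest,
        )
        _write(
            out / "rules.tsv",
            rules_to_frame(rules).to_csv(sep="\t", index=False),
            manifest,
        )
        report["mining"] = {
            "n_transactions": db.n_transactions,
            "n_frequent_itemsets": len(itemsets),
            "n_rules": len(rules),
            "min_support": cfg.arm.min_support,
            "min_confidence": cfg.arm.min_confidence,
        }
    except Exception as exc:
        report["partial"] = True
        raise PipelineError("mine", str(exc)) from exc

    # ingestion immutability: the dataset serialization is unchanged by stages
    if _sha256(cio.dataset_to_tsv(ds)) != ingest_checksum:  # pragma: no cover
        raise PipelineError("report", "dataset mutated during the run")
    report["dataset_checksum"] = ingest_checksum

    report_text = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(report_text, encoding="utf-8")
    return report
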