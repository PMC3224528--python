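"""End-to-end orchestration: config parsing, staged execution, artifacts.

A run reads an alignment (and optionally a tree), masks gap-rich
columns, fits or accepts the backbone tree, enumerates every re-graft of
the query clade, computes the site log-likelihood matrix, runs the
BP/KH/SH/AU battery, scans for group-specific indels, and leaves every
intermediate as a plain-text artifact plus a JSON manifest in the run
directory.  Re-running with the same config and seed reproduces the
artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .alignment import Alignment, mask_columns, read_alignment, write_alignment
from .indels import group_specific_blocks, signals_to_frame
from .likelihood import optimize_model
from .placement import (
    edge_label,
    enumerate_placements,
    evaluate_placements,
    prune_clade,
)
from .substmodel import SubstitutionModel, empirical_frequencies
from .toptests import (
    DEFAULT_REPLICATES,
    DEFAULT_SCALES,
    topology_test_report,
    write_site_lnl_matrix,
)
from .tree import PhyloTree, read_newick, write_newick
from .treesearch import bootstrap_support, ml_tree

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


@dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    alignment: str
    query_taxa: list[str]
    output_dir: str = "regraft_run"
    seed: int = 0
    alignment_format: str = "fasta"
    tree: str | None = None  # fixed input tree; fitted if absent
    # model block
    plus_f: bool = True
    gamma_categories: int = 4
    alpha: float | str = "estimate"
    p_inv: float | str = "estimate"
    # masking block
    max_gap_fraction: float = 0.5
    drop_ambiguous: bool = True
    # placement block
    optimize: str = "all_branches"
    graft_length: float = 0.1
    # test block
    scales: list[float] = field(default_factory=lambda: list(DEFAULT_SCALES))
    replicates: int = DEFAULT_REPLICATES
    # indel block
    groups: dict[str, list[str]] = field(default_factory=dict)
    indel_min_len: int = 2
    boundary_slack: int = 1
    reference_taxon: str | None = None
    # bootstrap block (optional stage)
    bootstrap_replicates: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"alignment", "query_taxa"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def validate_against(self, aln: Alignment) -> None:
        absent = [t for t in self.query_taxa if t not in aln.taxa]
        if absent:
            raise ConfigError(f"query taxa not in alignment: {absent}")
        for g, members in self.groups.items():
            bad = [t for t in members if t not in aln.taxa]
            if bad:
                raise ConfigError(f"group {g!r} taxa not in alignment: {bad}")
        if self.optimize not in ("all_branches", "graft_only"):
            raise ConfigError(f"bad optimize mode {self.optimize!r}")


def _build_model(cfg: RunConfig, aln: Alignment) -> tuple[SubstitutionModel, set[str]]:
    pi = empirical_frequencies(aln) if cfg.plus_f else None
    free = set()
    alpha = cfg.alpha
    if alpha == "estimate":
        alpha, free = 1.0, free | {"alpha"}
    p_inv = cfg.p_inv
    if p_inv == "estimate":
        p_inv, free = 0.0, free | {"p_inv"}
    model = SubstitutionModel.wag(
        alpha=float(alpha), p_inv=float(p_inv), n_cat=cfg.gamma_categories, pi=pi
    )
    return model, free


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": asdict(cfg),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name: str):
        logger.info("stage %s: start", name)
        manifest["stages"][name] = {"status": "running"}

        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is None:
                    manifest["stages"][name]["status"] = "ok"
                    logger.info("stage %s: ok", name)
                    return False
                manifest["stages"][name]["status"] = f"failed: {exc}"
                (out / "FAILED").write_text(f"{name}: {exc}\n")
                _write_manifest(out, manifest)
                raise StageError(name, exc) from exc

        return _Ctx()

    with stage("read"):
        aln = read_alignment(cfg.alignment, cfg.alignment_format)
        cfg.validate_against(aln)

    with stage("mask"):
        masked, mask = mask_columns(aln, cfg.max_gap_fraction, cfg.drop_ambiguous)
        write_alignment(masked, out / "masked.fasta")
        mask.to_tsv(out / "mask.tsv")
        manifest["stages"]["mask"]["kept_columns"] = len(mask.kept)

    with stage("model"):
        model, free = _build_model(cfg, masked)

    with stage("tree"):
        if cfg.tree:
            tree = read_newick(Path(cfg.tree))
            tree.floor_lengths()
        else:
            tree, _ = ml_tree(masked, model)
        if free:
            model, lnl = optimize_model(tree, masked, model, free=free)
            manifest["stages"]["tree"]["alpha"] = model.alpha
            manifest["stages"]["tree"]["p_inv"] = model.p_inv
            manifest["stages"]["tree"]["lnL"] = lnl
        write_newick(tree, out / "tree.nwk")

    if cfg.bootstrap_replicates > 0:
        with stage("bootstrap"):
            support = bootstrap_support(
                masked, model, replicates=cfg.bootstrap_replicates,
                seed=cfg.seed, tree=tree,
            )
            write_newick(support, out / "support.nwk", support=True)

    with stage("place"):
        backbone, clade, attach, pendant = prune_clade(tree, set(cfg.query_taxa))
        pset = enumerate_placements(backbone, clade, graft_length=cfg.graft_length)
        write_newick(backbone, out / "backbone.nwk")
        M, table = evaluate_placements(pset, masked, model, optimize=cfg.optimize)
        table.to_csv(out / "placements.tsv", sep="\t", index=False)
        write_site_lnl_matrix(M, out / "site_lnl.mt", [edge_label(e) for e in pset.edge_labels])
        manifest["stages"]["place"].update(
            n_topologies=len(pset), original_edge=edge_label(attach)
        )

    with stage("tests"):
        report = topology_test_report(
            M,
            labels=[edge_label(e) for e in pset.edge_labels],
            scales=tuple(cfg.scales),
            B=cfg.replicates,
            seed=cfg.seed,
        )
        report.to_csv(out / "topology_tests.tsv", sep="\t", index=False)
        best = report.loc[report["lnL"].idxmax()]
        manifest["stages"]["tests"].update(
            best_edge=str(best["topology"]),
            n_rejected=int(report["rejected"].sum()),
            original_edge_au=float(
                report.loc[report["topology"] == edge_label(attach), "au"].iloc[0]
            ),
        )

    if cfg.groups:
        with stage("indels"):
            signals = group_specific_blocks(
                masked,
                cfg.groups,
                min_len=cfg.indel_min_len,
                boundary_slack=cfg.boundary_slack,
                ref_taxon=cfg.reference_taxon,
            )
            signals_to_frame(signals).to_csv(out / "indels.tsv", sep="\t", index=False)
            manifest["stages"]["indels"]["n_signals"] = len(signals)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict[str, Any]) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
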