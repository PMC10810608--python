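"""Pipeline orchestration: simulate -> annotate -> stats -> network.

Each stage reads and writes plain-text artifacts (FASTA, TSV, JSON) under a
run directory and records a resolved-config manifest for provenance. A
two-genotype comparison reproduces the full repertoire-skew analysis
(usage tables, Pearson correlations per gene class, V-J pairing matrices,
productivity fractions, network summaries) on synthetic data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import network as _network
from . import stats as _stats
from .annotate import AnnotationParams, annotate_repertoire
from .germline import GermlineSet, build_default_germline, write_germline_fasta
from .simulate import GenotypePreset, get_preset, simulate_repertoire

log = logging.getLogger("bcrep")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    seed: int
    n_cells: int = 1000
    preset: str = "ctrl"            # built-in name or a YAML preset file
    out_dir: str = "bcrep_run"
    # germline
    n_ighv: int = 20
    n_igkv: int = 15
    n_ighd: int = 10
    germline_seed: int = 0
    # annotation
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0
    min_ig_score: float = 36.0
    # stats
    min_cdr3_aa_len: int = 4
    min_occurrence: int = 2
    # network
    min_cluster_size: int = 3
    metric: str = "levenshtein"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def resolve_preset(self) -> GenotypePreset:
        if Path(self.preset).suffix in (".yml", ".yaml") and Path(self.preset).exists():
            return GenotypePreset.from_file(self.preset)
        return get_preset(self.preset)

    def germline(self) -> GermlineSet:
        return build_default_germline(
            n_ighv=self.n_ighv,
            n_igkv=self.n_igkv,
            seed=self.germline_seed,
            n_ighd=self.n_ighd,
        )

    def annotation_params(self) -> AnnotationParams:
        return AnnotationParams(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            min_ig_score=self.min_ig_score,
        )

    def write_manifest(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = dataclasses.asdict(self)
        (out_dir / "run_config.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )


def cmd_simulate(cfg: RunConfig) -> tuple[Path, Path]:
    """Simulate a repertoire; returns (reads FASTA path, manifest path)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.write_manifest(out)
    gs = cfg.germline()
    preset = cfg.resolve_preset()
    fasta = out / "reads.fasta"
    manifest = out / "truth_manifest.tsv"
    write_germline_fasta(gs, out / "germline.fasta")
    cells, reads, _ = simulate_repertoire(
        gs, preset, cfg.n_cells, cfg.seed, fasta_path=fasta, manifest_path=manifest
    )
    log.info(
        "simulate: %d cells, %d reads (preset=%s, seed=%d)",
        len(cells), len(reads), preset.name, cfg.seed,
    )
    return fasta, manifest


def cmd_annotate(reads_fasta: str | Path, cfg: RunConfig) -> Path:
    """Annotate reads; writes the AIRR-style TSV and returns its path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gs = cfg.germline()
    table = annotate_repertoire(reads_fasta, gs, cfg.annotation_params())
    path = out / "rearrangements.tsv"
    table.to_csv(path, sep="\t", index=False)
    log.info("annotate: %d records from %s", len(table), reads_fasta)
    return path


def _stats_report(records: pd.DataFrame, cfg: RunConfig, gs: GermlineSet) -> dict:
    raw = records
    filtered = _stats.preprocess(
        records, cfg.min_cdr3_aa_len, cfg.min_occurrence
    )
    log.info("preprocess: %d -> %d records", len(raw), len(filtered))
    iso, fam = _stats.isotype_family_frequencies(raw, gs)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_records_raw": int(len(raw)),
        "n_records_preprocessed": int(len(filtered)),
        "isotype": dict(zip(iso.labels, iso.frequencies.tolist())),
        "lambda_family": dict(zip(fam.labels, fam.frequencies.tolist())),
        "usage": {},
        "pairing": {},
        "productivity": _stats.productivity_fractions(raw).to_dict("records"),
    }
    for locus in ("IGH", "IGK", "IGL"):
        for axis in ("v_gene", "j_gene"):
            t = _stats.gene_usage(raw, axis, locus, gs)
            report["usage"][f"{locus}_{axis}"] = dict(
                zip(t.labels, t.frequencies.tolist())
            )
    _, jk5 = _stats.editing_signature(raw)
    report["igkj5_fraction"] = None if np.isnan(jk5) else float(jk5)
    for locus in ("IGK", "IGL"):
        counts, _, cross = _stats.vj_pairing_matrix(raw, locus, gs)
        report["pairing"][locus] = {
            "counts": {
                f"{v}|{j}": int(counts.loc[v, j])
                for v in counts.index
                for j in counts.columns
                if counts.loc[v, j]
            },
            "cross_cassette_mass": None if np.isnan(cross) else float(cross),
        }
    return report


def cmd_stats(rearrangements_tsv: str | Path, cfg: RunConfig) -> Path:
    """Compute the full statistics report; writes JSON + TSV tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gs = cfg.germline()
    records = pd.read_csv(rearrangements_tsv, sep="\t", keep_default_na=False)
    records["productive"] = records["productive"].astype(bool)
    report = _stats_report(records, cfg, gs)
    path = out / "stats_report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    filtered = _stats.preprocess(records, cfg.min_cdr3_aa_len, cfg.min_occurrence)
    for definition in ("heavy_cdr3", "kappa_cdr3", "lambda_cdr3", "paired_hl"):
        table = _stats.clonotype_table(filtered, definition)
        table.to_csv(out / f"clonotypes_{definition}.tsv", sep="\t", index=False)
    return path


def cmd_network(rearrangements_tsv: str | Path, cfg: RunConfig) -> dict[str, Path]:
    """Build per-chain Levenshtein-1 networks; writes edge/node TSVs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(rearrangements_tsv, sep="\t", keep_default_na=False)
    records["productive"] = records["productive"].astype(bool)
    filtered = _stats.preprocess(records, cfg.min_cdr3_aa_len, cfg.min_occurrence)
    paths: dict[str, Path] = {}
    for chain, locus in (("heavy", "IGH"), ("kappa", "IGK"), ("lambda", "IGL")):
        sub = filtered[filtered["locus"] == locus]
        counts = sub["cdr3_aa"].value_counts().to_dict()
        net = _network.build_network(
            counts, min_cluster_size=cfg.min_cluster_size, metric=cfg.metric
        )
        ep, np_ = out / f"network_{chain}_edges.tsv", out / f"network_{chain}_nodes.tsv"
        _network.export_network(net, ep, np_)
        log.info(
            "network[%s]: %d nodes, %d edges, %d expanded components",
            chain, len(net.nodes), len(net.edges), len(net.expanded_components),
        )
        paths[chain] = np_
    return paths


def run_pipeline(cfg: RunConfig) -> Path:
    """simulate -> annotate -> stats -> network for a single genotype."""
    fasta, _ = cmd_simulate(cfg)
    tsv = cmd_annotate(fasta, cfg)
    report = cmd_stats(tsv, cfg)
    cmd_network(tsv, cfg)
    return report


def _network_summary(records: pd.DataFrame, cfg: RunConfig) -> dict:
    out = {}
    filtered = _stats.preprocess(records, cfg.min_cdr3_aa_len, cfg.min_occurrence)
    for chain, locus in (("heavy", "IGH"), ("kappa", "IGK"), ("lambda", "IGL")):
        sub = filtered[filtered["locus"] == locus]
        counts = sub["cdr3_aa"].value_counts().to_dict()
        net = _network.build_network(counts, cfg.min_cluster_size, cfg.metric)
        mass = net.component_mass()
        total = sum(mass.values()) or 1
        out[chain] = {
            "n_nodes": len(net.nodes),
            "n_edges": len(net.edges),
            "n_components": net.n_components,
            "n_expanded": len(net.expanded_components),
            "max_component_mass": max(mass.values()) / total if mass else 0.0,
        }
    return out


def cmd_compare(cfg_a: RunConfig, cfg_b: RunConfig) -> Path:
    """Run both genotypes end-to-end and emit a joint comparison report."""
    base = Path(cfg_a.out_dir)
    reports = {}
    tables = {}
    for tag, cfg in (("a", cfg_a), ("b", cfg_b)):
        cfg = dataclasses.replace(cfg, out_dir=str(base / tag))
        fasta, _ = cmd_simulate(cfg)
        tsv = cmd_annotate(fasta, cfg)
        records = pd.read_csv(tsv, sep="\t", keep_default_na=False)
        records["productive"] = records["productive"].astype(bool)
        gs = cfg.germline()
        reports[tag] = _stats_report(records, cfg, gs)
        reports[tag]["network"] = _network_summary(records, cfg)
        tables[tag] = records

    gs = cfg_a.germline()
    pearson: dict[str, dict] = {}
    for locus in ("IGH", "IGK", "IGL"):
        for axis in ("v_gene", "j_gene"):
            a = _stats.gene_usage(tables["a"], axis, locus, gs)
            b = _stats.gene_usage(tables["b"], axis, locus, gs)
            if a.empty or b.empty:
                continue
            r, p = _stats.pearson_usage(a, b)
            pearson[f"{locus}_{axis}"] = {"r": r, "p": p}

    joint = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "genotype_a": cfg_a.preset,
        "genotype_b": cfg_b.preset,
        "reports": reports,
        "pearson": pearson,
    }
    base.mkdir(parents=True, exist_ok=True)
    path = base / "compare_report.json"
    path.write_text(json.dumps(joint, indent=2, sort_keys=True) + "\n")
    log.info("compare: wrote %s", path)
    return path
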