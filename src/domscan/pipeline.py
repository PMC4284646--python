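"""End-to-end orchestration of the mapping workflow from one config file.

Stages run in a fixed order — simulate/ingest, QC, family genome scan,
dominant/breed-contrast variant filtering, concordance check, haplotype
fine-mapping — each writing TSV outputs and appending a manifest record
(stage, parameters, input hashes, wall time). A failure aborts the
downstream stages, leaves the manifest intact, and suffixes any
partially written outputs with ``.partial``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np
import yaml

from . import __version__
from .datamodel import AFFECTED, DomscanError, QcThresholds
from .family import build_clusters, genome_scan
from .filters import (
    FilterCriteria,
    Region,
    audit_frame,
    breed_contrast_filter,
    concordance_check,
    dominant_candidate_filter,
)
from .haplotypes import WindowSpec, haplotype_dominance_scan
from .io import read_ped_map, read_phenotypes, read_vcf, write_ped_map, write_phenotypes, write_table
from .qc import qc_filter
from .simulate import (
    PanelConfig,
    SimConfig,
    SlickConfig,
    observed_in_group,
    simulate_cohort,
    simulate_crossbred_slick,
    simulate_variant_panels,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "dfam_scan", "variant_filter", "concordance", "haplotype_scan")


class ConfigError(DomscanError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``inputs`` (paths to PED/MAP/phenotypes/VCF) or
    ``simulation`` (generator settings) must be present.
    """

    output_dir: Path
    seed: int = 0
    inputs: Optional[dict[str, str]] = None
    simulation: Optional[dict[str, dict]] = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    dfam_alpha: float = 0.05
    count_informative_only: bool = False
    window: WindowSpec = field(default_factory=WindowSpec)
    min_carriers: int = 5
    hap_alpha: float = 0.05
    hap_score: str = "coat_score"
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data, base_dir=Path(path).resolve().parent)

    @classmethod
    def from_dict(cls, data: dict, base_dir: Optional[Path] = None) -> "RunConfig":
        if ("inputs" in data) == ("simulation" in data):
            raise ConfigError("config must contain exactly one of 'inputs' or 'simulation'")
        out = data.get("output_dir")
        if not out:
            raise ConfigError("config requires 'output_dir'")
        out_path = Path(out)
        if base_dir is not None and not out_path.is_absolute():
            out_path = base_dir / out_path
        qc_block = data.get("qc", {})
        dfam_block = data.get("dfam", {})
        hap_block = data.get("haplotype", {})
        cfg = cls(
            output_dir=out_path,
            seed=int(data.get("seed", 0)),
            inputs=data.get("inputs"),
            simulation=data.get("simulation"),
            qc=QcThresholds(
                maf_min=float(qc_block.get("maf_min", 0.01)),
                call_rate_min=float(qc_block.get("call_rate_min", 0.90)),
            ),
            dfam_alpha=float(dfam_block.get("alpha", 0.05)),
            count_informative_only=bool(dfam_block.get("count_informative_only", False)),
            window=WindowSpec(
                size=int(hap_block.get("size", 6)), step=int(hap_block.get("step", 3))
            ),
            min_carriers=int(hap_block.get("min_carriers", 5)),
            hap_alpha=float(hap_block.get("alpha", 0.05)),
            hap_score=str(hap_block.get("score", "coat_score")),
            raw=data,
        )
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is not
        part of the scientific configuration)."""
        payload = {k: v for k, v in self.raw.items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class Manifest:
    path: Path

    def append(self, record: dict) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")

    def records(self) -> list[dict]:
        if not self.path.exists():
            return []
        return [json.loads(line) for line in self.path.read_text().splitlines() if line]


def run_pipeline(cfg: RunConfig) -> Manifest:
    """Execute all stages; returns the manifest. Raises on stage failure
    after recording it (partial outputs suffixed ``.partial``)."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.jsonl")
    manifest.append(
        {"stage": "start", "version": __version__, "config_hash": cfg.config_hash(),
         "seed": cfg.seed}
    )
    state: dict[str, Any] = {"meta": {"config_hash": cfg.config_hash()}}

    def run_stage(name: str, fn: Callable[[dict], list[Path]]) -> None:
        t0 = time.perf_counter()
        outputs: list[Path] = []
        try:
            outputs = fn(state)
        except Exception as exc:
            for p in outputs:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            manifest.append(
                {"stage": name, "status": "failed", "error": str(exc),
                 "wall_time_s": round(time.perf_counter() - t0, 4)}
            )
            raise
        manifest.append(
            {
                "stage": name,
                "status": "completed",
                "wall_time_s": round(time.perf_counter() - t0, 4),
                "outputs": {str(p): _sha256(p) for p in outputs},
            }
        )

    run_stage("simulate", lambda st: _stage_acquire(cfg, st))
    run_stage("qc", lambda st: _stage_qc(cfg, st))
    run_stage("dfam_scan", lambda st: _stage_dfam(cfg, st))
    run_stage("variant_filter", lambda st: _stage_filter(cfg, st))
    run_stage("concordance", lambda st: _stage_concordance(cfg, st))
    run_stage("haplotype_scan", lambda st: _stage_haplo(cfg, st))

    report = _final_report(state)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    manifest.append({"stage": "done", "report": str(report_path)})
    return manifest


def _stage_acquire(cfg: RunConfig, state: dict) -> list[Path]:
    out = cfg.output_dir
    meta = state["meta"]
    outputs: list[Path] = []
    if cfg.simulation is not None:
        sim = cfg.simulation
        cohort_cfg = SimConfig(seed=cfg.seed, **sim.get("cohort", {}))
        ped, geno, phen, truth = simulate_cohort(cohort_cfg)
        write_ped_map(ped, geno, out / "cohort.ped", out / "cohort.map", phen)
        write_phenotypes(phen, out / "cohort_phenotypes.tsv", **meta)
        truth.write(out / "cohort_truth.jsonl")
        state.update(pedigree=ped, genotypes=geno, phenotypes=phen, cohort_truth=truth)
        outputs += [out / "cohort.ped", out / "cohort.map",
                    out / "cohort_phenotypes.tsv", out / "cohort_truth.jsonl"]

        slick_cfg = SlickConfig(seed=cfg.seed + 1, **sim.get("slick", {}))
        sgeno, sphen, struth = simulate_crossbred_slick(slick_cfg)
        write_phenotypes(sphen, out / "slick_phenotypes.tsv", **meta)
        struth.write(out / "slick_truth.jsonl")
        state.update(slick_genotypes=sgeno, slick_phenotypes=sphen, slick_truth=struth)
        outputs += [out / "slick_phenotypes.tsv", out / "slick_truth.jsonl"]

        panel_cfg = PanelConfig(seed=cfg.seed + 2, **sim.get("panels", {}))
        panel, seen_sets, ptruth = simulate_variant_panels(panel_cfg)
        ptruth.write(out / "panel_truth.jsonl")
        state.update(panel=panel, seen_sets=seen_sets, panel_truth=ptruth,
                     panel_cfg=panel_cfg)
        outputs += [out / "panel_truth.jsonl"]
    else:
        inputs = cfg.inputs or {}
        for key in ("ped", "map", "phenotypes"):
            if key not in inputs:
                raise ConfigError(f"inputs block missing {key!r}")
        ped, geno = read_ped_map(inputs["ped"], inputs["map"])
        phen = read_phenotypes(inputs["phenotypes"])
        state.update(pedigree=ped, genotypes=geno, phenotypes=phen)
        if "vcf" in inputs:
            state["panel"] = read_vcf(inputs["vcf"])
    return outputs


def _stage_qc(cfg: RunConfig, state: dict) -> list[Path]:
    filtered, report = qc_filter(state["genotypes"], cfg.qc)
    state["genotypes_qc"] = filtered
    path = cfg.output_dir / "qc_exclusions.tsv"
    write_table(report.exclusions, path, **state["meta"])
    return [path]


def _stage_dfam(cfg: RunConfig, state: dict) -> list[Path]:
    geno = state["genotypes_qc"]
    clusters = build_clusters(state["pedigree"], state["phenotypes"], geno.samples)
    scan = genome_scan(geno, clusters, alpha=cfg.dfam_alpha,
                       count_informative_only=cfg.count_informative_only)
    state["dfam_scan"] = scan
    path = cfg.output_dir / "dfam_scan.tsv"
    write_table(
        scan.table, path,
        bonferroni_threshold=f"{scan.threshold:.6e}", n_tests=str(scan.n_tests),
        **state["meta"],
    )
    return [path]


def _stage_filter(cfg: RunConfig, state: dict) -> list[Path]:
    if "panel" not in state:
        raise ConfigError("variant_filter stage requires a VCF input or panel simulation")
    panel = state["panel"]
    outputs: list[Path] = []
    if "panel_cfg" in state:
        pc = state["panel_cfg"]
        region = Region(pc.chromosome, pc.region_start, pc.region_end)
        target = panel.group(pc.target_breed)
        out_group = [
            s for g, members in panel.sample_groups.items()
            if g not in (pc.target_breed, "population_db")
            for s in members
        ]
        kept, audits = breed_contrast_filter(panel, target, out_group, region)
        path = cfg.output_dir / "breed_contrast_candidates.tsv"
        write_table(audit_frame(audits), path, **state["meta"])
        outputs.append(path)
        state["breed_contrast_kept"] = kept

        seen = dict(state.get("seen_sets", {}))
        seen["population_db"] = observed_in_group(panel, "population_db")
        crit = FilterCriteria(
            required_het=frozenset(target[:2]),
            required_absent=frozenset(out_group[:2]),
            exclude_seen_in=seen,
            region=region,
        )
        kept2, audits2 = dominant_candidate_filter(panel, crit)
        path2 = cfg.output_dir / "dominant_candidates.tsv"
        write_table(audit_frame(audits2), path2, **state["meta"])
        outputs.append(path2)
        state["dominant_kept"] = kept2
    else:
        filt = (cfg.raw or {}).get("filter", {})
        crit = FilterCriteria(
            required_het=frozenset(filt.get("required_het", [])),
            required_absent=frozenset(filt.get("required_absent", [])),
        )
        kept, audits = dominant_candidate_filter(panel, crit)
        path = cfg.output_dir / "dominant_candidates.tsv"
        write_table(audit_frame(audits), path, **state["meta"])
        outputs.append(path)
        state["dominant_kept"] = kept
    return outputs


def _stage_concordance(cfg: RunConfig, state: dict) -> list[Path]:
    import pandas as pd

    results = {}
    if "slick_truth" in state:
        truth = state["slick_truth"]
        phen = state["slick_phenotypes"]
        phenotype = {
            s: phen.affection(s) == AFFECTED for s in phen.samples
        }
        res = concordance_check(truth.causal_classes, phenotype)
        results["slick_cohort"] = res
    # cohort-level concordance of the causal marker under dominance
    if "cohort_truth" in state:
        geno = state["genotypes"]
        truth = state["cohort_truth"]
        col = geno.dosages_for(truth.causal_key)
        classes = {
            s: (-1 if np.isnan(d) else (0 if d == 0 else (1 if d == 1 else 2)))
            for s, d in col.items()
        }
        phen = state["phenotypes"]
        phenotype = {s: phen.affection(s) == AFFECTED for s in geno.samples}
        results["mapping_pedigree"] = concordance_check(classes, phenotype)
    state["concordance"] = results
    rows = [
        {"cohort": name, "n_concordant": r.n_concordant, "n_discordant": r.n_discordant,
         "discordant_ids": ",".join(r.discordant_ids)}
        for name, r in results.items()
    ]
    path = cfg.output_dir / "concordance.tsv"
    write_table(pd.DataFrame(rows), path, **state["meta"])
    return [path]


def _stage_haplo(cfg: RunConfig, state: dict) -> list[Path]:
    geno = state.get("slick_genotypes", state.get("genotypes_qc"))
    phen = state.get("slick_phenotypes", state.get("phenotypes"))
    if cfg.hap_score not in phen.frame.columns:
        raise ConfigError(f"phenotype table has no column {cfg.hap_score!r}")
    scan = haplotype_dominance_scan(
        geno, phen.score(cfg.hap_score), spec=cfg.window,
        min_carriers=cfg.min_carriers, alpha=cfg.hap_alpha,
    )
    state["hap_scan"] = scan
    path = cfg.output_dir / "haplotype_scan.tsv"
    write_table(
        scan.table, path,
        bonferroni_threshold=f"{scan.threshold:.6e}", n_tests=str(scan.n_tests),
        **state["meta"],
    )
    return [path]


def _final_report(state: dict) -> dict:
    report: dict[str, Any] = {}
    if "dfam_scan" in state:
        scan = state["dfam_scan"]
        top = scan.top()
        report["dfam"] = {
            "n_tests": scan.n_tests,
            "bonferroni_threshold": scan.threshold,
            "top_marker": top["id"],
            "top_p": float(top["p"]),
            "n_significant": int(len(scan.significant())),
        }
        if "cohort_truth" in state:
            report["dfam"]["causal_marker"] = state["cohort_truth"].causal_key
            report["dfam"]["causal_is_top"] = bool(
                top["id"] == state["cohort_truth"].causal_key
            )
    if "breed_contrast_kept" in state:
        report["breed_contrast"] = [str(k) for k in state["breed_contrast_kept"]]
    if "dominant_kept" in state:
        report["dominant_filter"] = [str(k) for k in state["dominant_kept"]]
    if "concordance" in state:
        report["concordance"] = {
            name: {"n_concordant": r.n_concordant, "n_discordant": r.n_discordant}
            for name, r in state["concordance"].items()
        }
    if "hap_scan" in state:
        scan = state["hap_scan"]
        entry = {"n_tests": scan.n_tests, "bonferroni_threshold": scan.threshold}
        if len(scan.table):
            top = scan.top()
            entry.update(top_window=top["window_id"], top_haplotype=top["haplotype"],
                         top_p=float(top["p"]))
        report["haplotype_scan"] = entry
    return report
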