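"""One-shot screening analysis: count -> qc -> diff -> select -> simnet.

Given a design, a sample sheet and a directory of FASTQ files, the runner
executes every analysis stage, writes per-stage tabular outputs and a
machine-readable manifest (package version, parameters, input checksums,
stages completed, timings).  Reruns with identical inputs produce
byte-identical non-timestamp outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .counting import count_fastq
from .design import LibraryDesign
from .diffabund import differential_table, read_samplesheet
from .hitselect import HitCriteria, select_hits
from .qc import qc_report
from .seqsim import (
    build_network,
    cluster_motifs,
    communities,
    community_summary,
    write_network,
    write_pwm_jaspar,
)

logger = logging.getLogger("riboscreen")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    design_path: Path
    samplesheet_path: Path
    fastq_dir: Path
    out_dir: Path
    strand_mode: str = "both"
    criteria: HitCriteria = field(default_factory=HitCriteria)
    rank_by: str = "log2FC"
    network_fdr: float = 0.01
    identity_threshold: float = 0.75
    make_plots: bool = False

    def __post_init__(self) -> None:
        for attr in ("design_path", "samplesheet_path", "fastq_dir", "out_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        for p in (self.design_path, self.samplesheet_path, self.fastq_dir):
            if not p.exists():
                raise FileNotFoundError(f"{p} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fastq_for(sheet: pd.DataFrame, fastq_dir: Path) -> dict[str, list[Path]]:
    out: dict[str, list[Path]] = {}
    for sample in sheet["sample"]:
        paths = sorted(fastq_dir.glob(f"{sample}.fastq*"))
        if not paths:
            raise FileNotFoundError(f"no FASTQ for sample {sample!r} in {fastq_dir}")
        out[sample] = paths
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            "strand_mode": config.strand_mode,
            "direction": config.criteria.direction,
            "lfc_threshold": config.criteria.lfc_threshold,
            "fdr_threshold": config.criteria.fdr_threshold,
            "require_dose_dependency": config.criteria.require_dose_dependency,
            "rank_by": config.rank_by,
            "network_fdr": config.network_fdr,
            "identity_threshold": config.identity_threshold,
        },
        "inputs": {},
        "stages": [],
    }
    stage = "validate"
    try:
        design = LibraryDesign.from_yaml(config.design_path)
        sheet = read_samplesheet(config.samplesheet_path)
        fastqs = _fastq_for(sheet, config.fastq_dir)
        manifest["inputs"][str(config.design_path)] = _sha256(config.design_path)
        manifest["inputs"][str(config.samplesheet_path)] = _sha256(config.samplesheet_path)
        for paths in fastqs.values():
            for p in paths:
                manifest["inputs"][str(p)] = _sha256(p)

        def _done(name: str, t0: float) -> None:
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            logger.info("stage %s done", name)

        stage = "count"
        t0 = time.perf_counter()
        matchers = design.compile_matcher()
        counts = count_fastq(fastqs, matchers, strand_mode=config.strand_mode)
        counts.to_tsv(out / "counts.tsv", out / "match_stats.tsv")
        _done(stage, t0)

        stage = "qc"
        t0 = time.perf_counter()
        report = qc_report(counts.drop_spike(), design)
        report.to_json(out / "qc.json")
        report.sample_summary.to_csv(out / "qc_samples.tsv", sep="\t")
        _done(stage, t0)

        stage = "diff"
        t0 = time.perf_counter()
        table = differential_table(counts, sheet)
        table.to_tsv(out / "differential.tsv")
        table.wide().to_csv(out / "differential_wide.tsv", sep="\t", index=False)
        for dose in table.doses:
            c = table.contrast(dose)
            c.to_csv(out / f"volcano_{dose:g}uM.tsv", sep="\t", index=False)
            if config.make_plots:
                from .plots import volcano

                volcano(c, out / f"volcano_{dose:g}uM.png")
        _done(stage, t0)

        stage = "select"
        t0 = time.perf_counter()
        hits = select_hits(table, config.criteria, rank_by=config.rank_by)
        hits.to_tsv(out / "hits.tsv")
        hits.negatives.to_csv(out / "negative_list.tsv", sep="\t", index=False)
        hits.to_json(out / "hits_summary.json")
        _done(stage, t0)

        stage = "simnet"
        t0 = time.perf_counter()
        top = table.contrast(max(table.doses))
        sig = top[top["fdr"] <= config.network_fdr]
        net_rows = []
        for sublib, group in sig.groupby("sublib"):
            motifs = dict(zip(group["motif"], group["log2fc"]))
            if not motifs:
                continue
            clusters = cluster_motifs(motifs, config.identity_threshold)
            write_pwm_jaspar(clusters, out / f"pwm_{sublib}.txt")
            g = build_network(motifs)
            part = communities(g)
            write_network(g, out / f"network_{sublib}.graphml", out / f"network_{sublib}_edges.tsv")
            summ = community_summary(g, part)
            summ.insert(0, "sublib", sublib)
            net_rows.append(summ)
        if net_rows:
            pd.concat(net_rows).to_csv(out / "communities.tsv", sep="\t", index=False)
        _done(stage, t0)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
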