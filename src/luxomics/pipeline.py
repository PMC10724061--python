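"""End-to-end orchestration: cohort -> per-layer photoresponse -> m6A profile
-> type-1/2/3 selection -> CHR candidate report, with a JSON run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .discovery import (
    ChrCandidateReport,
    ChrCriteria,
    intersect_and_report,
    select_type1,
    select_type2,
    select_type3,
    write_report,
)
from .io import compute_rpkm
from .m6a import metagene_profile
from .photoresponse import (
    Gates,
    peak_photoresponse_table,
    photoresponse_table,
    translation_state_matrix,
)
from .simulate import GENOTYPES, Cohort, GeneratorConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Run settings: either a generator config (simulate mode) or a cohort
    directory (file mode), plus gates, criteria and the output directory."""

    out_dir: str | Path = "luxomics_run"
    simulate: GeneratorConfig | None = None
    cohort_dir: str | Path | None = None
    gates: Gates = field(default_factory=Gates)
    criteria: ChrCriteria = field(default_factory=ChrCriteria)
    write_artifacts: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.cohort_dir is None):
            raise ValueError("exactly one of simulate / cohort_dir must be set")
        if self.cohort_dir is not None and not Path(self.cohort_dir).is_dir():
            raise FileNotFoundError(f"cohort directory not found: {self.cohort_dir}")


@dataclass
class RunResult:
    report: ChrCandidateReport
    manifest: dict
    tables: dict[str, pd.DataFrame]
    cohort: Cohort


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                logger.info("stage %s", name)
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("photoresponse")
def _photoresponse_tables(cohort: Cohort, gates: Gates) -> dict[str, pd.DataFrame]:
    genotypes = [g for g in GENOTYPES if any(s.genotype == g for s in cohort.design)]
    rpkm = compute_rpkm(cohort.matrices["transcriptome"], cohort.models)
    ts = translation_state_matrix(cohort.matrices["trap"], cohort.matrices["trap_input"])
    return {
        "transcriptome": photoresponse_table(rpkm, genotypes, gates, pseudocount=1.0),
        # translation states already carry unit pseudocounts, so none is added
        "ts": photoresponse_table(ts, genotypes, gates, pseudocount=0.0),
        "proteome": photoresponse_table(cohort.matrices["proteome"], genotypes, gates, pseudocount=1.0),
        "m6a_peaks": peak_photoresponse_table(cohort.peaks, genotypes, gates, pseudocount=1.0),
    }


@_stage("discover_chr")
def _discover(tables: dict[str, pd.DataFrame], criteria: ChrCriteria, universe: set[str]) -> ChrCandidateReport:
    t1 = select_type1(tables["m6a_peaks"], criteria)
    t2 = select_type2(tables["ts"], criteria)
    t3 = select_type3(tables["proteome"], criteria)
    evidence = {k: tables[k] for k in ("ts", "proteome")}
    return intersect_and_report(t1, t2, t3, evidence_tables=evidence, universe=universe)


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if config.simulate is not None:
            cohort = generate_cohort(config.simulate)
            if config.write_artifacts:
                write_cohort(cohort, out / "cohort")
        else:
            cohort = read_cohort(config.cohort_dir)
    except Exception as exc:
        raise PipelineError("load_cohort", exc) from exc

    tables = _photoresponse_tables(cohort, config.gates)
    report = _discover(tables, config.criteria, set(cohort.gene_ids))

    artifacts: dict[str, str] = {}
    if config.write_artifacts:
        for name, table in tables.items():
            p = out / f"photoresponse_{name}.tsv"
            table.to_csv(p, sep="\t", index=False)
            artifacts[f"photoresponse_{name}"] = str(p)
        try:
            for cond in ("blue", "dark"):
                prof = metagene_profile(cohort.peaks, cohort.models, ("WT", cond))
                p = out / f"metagene_WT_{cond}.tsv"
                prof.to_frame().to_csv(p, sep="\t", index=False)
                artifacts[f"metagene_WT_{cond}"] = str(p)
        except KeyError:
            pass  # cohort without WT merip samples
        write_report(report, out / "report")
        artifacts["report"] = str(out / "report")

    manifest = {
        "luxomics_version": __version__,
        "mode": "simulate" if config.simulate is not None else "files",
        "seed": config.simulate.seed if config.simulate is not None else None,
        "gates": vars(config.gates).copy(),
        "criteria": vars(config.criteria).copy(),
        "n_genes": len(cohort.gene_ids),
        "n_peaks": len(cohort.peaks.frame),
        "counts": report.to_json_dict(),
        "artifacts": artifacts,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return RunResult(report=report, manifest=manifest, tables=tables, cohort=cohort)
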