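"""Multi-omics CHR candidate discovery.

Four-step selection over the photoresponse tables:

* type 1 — genes with at least one m6A peak showing a light-induced gain of
  methylation in WT (B/D > 1.5, p < 0.05);
* type 2 — genes with light-induced translation gain in WT and mta but not in
  cry1cry2 or fio1, expressed through the WT fold change and mutant/WT fold
  change ratios plus a significance gate on the WT contrast;
* type 3 — genes with light-induced protein gain in WT and mta but a light-
  induced protein loss in cry1cry2 and fio1 (direction constraints), with the
  mutant/WT ratio constraints and a significance gate on the WT contrast;
* the triple intersection of the three sets nominates the candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["ChrCriteria", "ChrCandidateReport", "select_type1", "select_type2", "select_type3", "intersect_and_report"]

MUTANTS = ("cry1cry2", "fio1", "mta")


@dataclass(frozen=True)
class ChrCriteria:
    """Thresholds of the three selection steps (all comparisons strict)."""

    # type 1: per-peak WT m6A photoresponse
    t1_fc: float = 1.5
    t1_p: float = 0.05
    # type 2: translation state
    t2_fc_wt: float = 1.5
    t2_ratio_cry_max: float = 0.8
    t2_ratio_fio1_max: float = 0.8
    t2_ratio_mta_min: float = 0.8
    t2_p: float = 0.05
    t2_q: float = 0.05
    #: 'p', 'q' or 'either' significance gate on the WT translation contrast
    t2_gate_mode: str = "either"
    # type 3: protein abundance
    t3_ratio_cry_max: float = 1.0
    t3_ratio_fio1_max: float = 1.0
    t3_ratio_mta_min: float = 1.0
    t3_p: float = 0.05
    #: also require the narrated direction constraints
    #: (B/D)^WT > 1, (B/D)^mta > 1, (B/D)^cry1cry2 < 1, (B/D)^fio1 < 1
    t3_directions: bool = True

    def __post_init__(self) -> None:
        vals = [self.t1_fc, self.t1_p, self.t2_fc_wt, self.t2_ratio_cry_max,
                self.t2_ratio_fio1_max, self.t2_ratio_mta_min, self.t2_p, self.t2_q,
                self.t3_ratio_cry_max, self.t3_ratio_fio1_max, self.t3_ratio_mta_min, self.t3_p]
        if min(vals) <= 0:
            raise ValueError("criteria thresholds must be positive")
        if self.t2_gate_mode not in ("p", "q", "either"):
            raise ValueError(f"unknown t2_gate_mode {self.t2_gate_mode!r}")


def _genotype_pivot(table: pd.DataFrame, column: str) -> pd.DataFrame:
    """Pivot a long photoresponse table (id, genotype, ...) to id x genotype."""
    return table.pivot(index="id", columns="genotype", values=column)


def _require_genotypes(fc: pd.DataFrame, needed: Sequence[str]) -> None:
    missing = [g for g in needed if g not in fc.columns]
    if missing:
        raise KeyError(f"photoresponse table missing genotype(s): {missing}")


def select_type1(m6a_pr: pd.DataFrame, criteria: ChrCriteria = ChrCriteria()) -> set[str]:
    """Genes with >= 1 assigned peak passing the WT m6A gate.

    ``m6a_pr`` is a per-peak table with columns id (peak), gene_id, genotype,
    fc_bd, p (from :func:`luxomics.photoresponse.peak_photoresponse_table`).
    """
    wt = m6a_pr[m6a_pr["genotype"] == "WT"]
    if wt.empty:
        raise KeyError("no WT contrast in the m6A photoresponse table")
    hit = wt[(wt["fc_bd"] > criteria.t1_fc) & (wt["p"] < criteria.t1_p) & (wt["gene_id"] != "")]
    return set(hit["gene_id"])


def select_type2(ts_pr: pd.DataFrame, criteria: ChrCriteria = ChrCriteria()) -> set[str]:
    """Genes whose translation-state photoresponse matches the CRY/FIO1-
    dependent, MTA-independent pattern.

    ``ts_pr`` is a per-gene table with columns id, genotype, fc_bd, p, q
    covering WT and the three mutants.
    """
    fc = _genotype_pivot(ts_pr, "fc_bd")
    _require_genotypes(fc, ("WT",) + MUTANTS)
    p = _genotype_pivot(ts_pr, "p")["WT"]
    q = _genotype_pivot(ts_pr, "q")["WT"]
    if criteria.t2_gate_mode == "p":
        sig = p < criteria.t2_p
    elif criteria.t2_gate_mode == "q":
        sig = q < criteria.t2_q
    else:
        sig = (p < criteria.t2_p) | (q < criteria.t2_q)
    ok = (
        (fc["WT"] > criteria.t2_fc_wt)
        & (fc["cry1cry2"] / fc["WT"] < criteria.t2_ratio_cry_max)
        & (fc["fio1"] / fc["WT"] < criteria.t2_ratio_fio1_max)
        & (fc["mta"] / fc["WT"] > criteria.t2_ratio_mta_min)
        & sig
    )
    return set(ok.index[ok])


def select_type3(prot_pr: pd.DataFrame, criteria: ChrCriteria = ChrCriteria()) -> set[str]:
    """Genes whose protein photoresponse matches the signature: gains in WT
    and mta, losses in cry1cry2 and fio1, with the printed ratio constraints."""
    fc = _genotype_pivot(prot_pr, "fc_bd")
    _require_genotypes(fc, ("WT",) + MUTANTS)
    p = _genotype_pivot(prot_pr, "p")["WT"]
    ok = (
        (fc["cry1cry2"] / fc["WT"] < criteria.t3_ratio_cry_max)
        & (fc["fio1"] / fc["WT"] < criteria.t3_ratio_fio1_max)
        & (fc["mta"] / fc["WT"] > criteria.t3_ratio_mta_min)
        & (p < criteria.t3_p)
    )
    if criteria.t3_directions:
        ok = ok & (fc["WT"] > 1.0) & (fc["mta"] > 1.0) & (fc["cry1cry2"] < 1.0) & (fc["fio1"] < 1.0)
    return set(ok.index[ok])


@dataclass
class ChrCandidateReport:
    type1: set[str]
    type2: set[str]
    type3: set[str]
    venn: dict[str, int]
    intersection: list[str]
    evidence: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "type1_count": len(self.type1),
            "type2_count": len(self.type2),
            "type3_count": len(self.type3),
            "venn": dict(self.venn),
            "intersection": list(self.intersection),
        }


def venn_counts(type1: set, type2: set, type3: set) -> dict[str, int]:
    """Seven-region Venn counts; key '110' = in type1 and type2 only, etc."""
    out = {}
    for k1 in (0, 1):
        for k2 in (0, 1):
            for k3 in (0, 1):
                if not (k1 or k2 or k3):
                    continue
                members = set.intersection(
                    *[s for s, k in ((type1, k1), (type2, k2), (type3, k3)) if k]
                )
                for s, k in ((type1, k1), (type2, k2), (type3, k3)):
                    if not k:
                        members = members - s
                out[f"{k1}{k2}{k3}"] = len(members)
    return out


def intersect_and_report(
    type1: set[str],
    type2: set[str],
    type3: set[str],
    evidence_tables: Mapping[str, pd.DataFrame] | None = None,
    universe: set[str] | None = None,
) -> ChrCandidateReport:
    """Venn counts plus the triple intersection with per-layer evidence.

    ``evidence_tables`` maps layer name -> per-gene photoresponse table
    (columns id, genotype, fc_bd, p, q); evidence rows are collected for the
    intersection genes, sorted by gene_id.
    """
    if universe is not None:
        stray = (type1 | type2 | type3) - universe
        if stray:
            raise ValueError(f"gene sets reference ids outside the universe: {sorted(stray)[:10]}")
    inter = sorted(type1 & type2 & type3)
    rows = []
    for layer, table in (evidence_tables or {}).items():
        sub = table[table["id"].isin(inter)].copy()
        sub.insert(0, "layer", layer)
        rows.append(sub)
    evidence = (
        pd.concat(rows, ignore_index=True).sort_values(["id", "layer", "genotype"]).reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=["layer", "id", "genotype", "fc_bd", "p", "q"])
    )
    return ChrCandidateReport(
        type1=set(type1),
        type2=set(type2),
        type3=set(type3),
        venn=venn_counts(type1, type2, type3),
        intersection=inter,
        evidence=evidence,
    )


def write_report(report: ChrCandidateReport, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in ("type1", "type2", "type3"):
        pd.Series(sorted(getattr(report, name)), name="gene_id").to_csv(
            d / f"{name}_genes.tsv", sep="\t", index=False
        )
    report.evidence.to_csv(d / "intersection_evidence.tsv", sep="\t", index=False)
    (d / "venn.json").write_text(json.dumps(report.to_json_dict(), indent=2) + "\n")
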