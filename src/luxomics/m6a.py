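"""Peak-level m6A geometry: gene assignment, density, region annotation and
metagene profiles in transcript coordinates (5'UTR | CDS | 3'UTR)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, PeakTable

logger = logging.getLogger(__name__)

__all__ = [
    "assign_peaks",
    "m6a_density",
    "enrichment_profile",
    "annotate_region",
    "MetageneProfile",
    "metagene_profile",
]


def assign_peaks(peaks: PeakTable, models: Sequence[GeneModel]) -> PeakTable:
    """Fill in each peak's gene_id.

    A peak already carrying a gene_id keeps it if the interval overlaps that
    gene's transcript; otherwise (or when the id is empty) the peak goes to
    the model with the largest overlap, ties broken by the lexicographically
    smaller gene_id. Peaks overlapping no model stay unassigned (logged).
    """
    by_id = {m.gene_id: m for m in models}
    frame = peaks.frame.copy()
    unassigned = 0
    new_ids = []
    for _, row in frame.iterrows():
        start, end = int(row["start"]), int(row["end"])
        gid = row["gene_id"]
        if gid and gid in by_id:
            ov = min(end, by_id[gid].transcript_len) - max(start, 0)
            new_ids.append(gid if ov > 0 else "")
            if ov <= 0:
                unassigned += 1
            continue
        best, best_ov = "", 0
        for m in sorted(models, key=lambda m: m.gene_id):
            ov = min(end, m.transcript_len) - max(start, 0)
            if ov > best_ov:
                best, best_ov = m.gene_id, ov
        new_ids.append(best)
        if not best:
            unassigned += 1
    frame["gene_id"] = new_ids
    if unassigned:
        logger.warning("%d peak(s) overlap no gene model and remain unassigned", unassigned)
    return PeakTable(frame=frame, ip_samples=peaks.ip_samples, input_samples=peaks.input_samples)


def m6a_density(
    peaks: PeakTable, models: Sequence[GeneModel], sample_id: str
) -> pd.Series:
    """m6A deposition per unit length: summed peak IP signal of a gene divided
    by its transcript length in kb. Genes without peaks get density 0."""
    by_id = {m.gene_id: m for m in models}
    col = f"ip:{sample_id}"
    if col not in peaks.frame.columns:
        raise KeyError(f"no IP signal column for sample {sample_id!r}")
    dens = pd.Series(0.0, index=[m.gene_id for m in models], name="m6a_density")
    assigned = peaks.frame[peaks.frame["gene_id"] != ""]
    for gid, sub in assigned.groupby("gene_id"):
        if gid not in by_id:
            raise KeyError(f"peak assigned to unknown gene {gid!r}")
        dens[gid] = sub[col].astype(float).sum() / (by_id[gid].transcript_len / 1e3)
    return dens


def enrichment_profile(
    ip_signal, input_signal, size_factors=(1.0, 1.0), pseudocount: float = 0.5
) -> np.ndarray:
    """Per-peak log2 IP/input enrichment after size-factor scaling:
    log2((ip/sf_ip + p) / (input/sf_input + p))."""
    sf_ip, sf_input = size_factors
    if sf_ip <= 0 or sf_input <= 0:
        raise ValueError("size factors must be positive")
    ip = np.asarray(ip_signal, dtype=float) / sf_ip + pseudocount
    inp = np.asarray(input_signal, dtype=float) / sf_input + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((ip == 0) & (inp == 0), 0.0, np.log2(ip) - np.log2(inp))
    return out


def annotate_region(start: int, end: int, model: GeneModel, stop_window: int = 100) -> str:
    """Classify a peak by its midpoint: utr5, cds, utr3, or stop_proximal when
    the midpoint lies within +/- stop_window nt of the CDS/3'UTR junction
    (stop_proximal takes precedence)."""
    mid = (start + end) / 2.0
    if mid < 0 or mid > model.transcript_len:
        raise ValueError(
            f"peak midpoint {mid} outside transcript [0, {model.transcript_len}) of {model.gene_id}"
        )
    junction = model.utr5_len + model.cds_len  # CDS / 3'UTR boundary
    if abs(mid - junction) <= stop_window:
        return "stop_proximal"
    if mid < model.utr5_len:
        return "utr5"
    if mid < junction:
        return "cds"
    return "utr3"


@dataclass
class MetageneProfile:
    """Mean per-bin signal along relative mRNA position.

    The transcript is rescaled region-by-region onto a fixed bin layout
    (utr5_bins | cds_bins | utr3_bins), so bin edges run over [0, 1] with the
    5'UTR ending at utr5_bins/total and the CDS at (utr5_bins+cds_bins)/total.
    """

    bin_means: np.ndarray
    n_genes: int
    utr5_bins: int = 25
    cds_bins: int = 50
    utr3_bins: int = 25

    @property
    def n_bins(self) -> int:
        return self.utr5_bins + self.cds_bins + self.utr3_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    @property
    def region_boundaries(self) -> tuple[float, float]:
        return (self.utr5_bins / self.n_bins, (self.utr5_bins + self.cds_bins) / self.n_bins)

    def total_signal(self) -> float:
        return float(self.bin_means.sum() * self.n_genes)

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        return pd.DataFrame(
            {
                "bin_start": edges[:-1],
                "bin_end": edges[1:],
                "region": (["utr5"] * self.utr5_bins + ["cds"] * self.cds_bins + ["utr3"] * self.utr3_bins),
                "mean_signal": self.bin_means,
            }
        )


def _gene_bin_vector(
    sub: pd.DataFrame, model: GeneModel, signal: np.ndarray, bins: tuple[int, int, int]
) -> np.ndarray:
    """Distribute each peak's signal over the bins its interval covers,
    proportionally to overlap, after per-region rescaling to the bin layout."""
    u5, cds, u3 = bins
    out = np.zeros(u5 + cds + u3)
    regions = [
        (0, model.utr5_len, 0, u5),
        (model.utr5_len, model.utr5_len + model.cds_len, u5, cds),
        (model.utr5_len + model.cds_len, model.transcript_len, u5 + cds, u3),
    ]
    for (start, end, sig) in zip(sub["start"], sub["end"], signal):
        length = end - start
        if length <= 0:
            continue
        for r_start, r_end, bin0, nbins in regions:
            if nbins == 0 or r_end <= r_start:
                continue
            ov_start, ov_end = max(start, r_start), min(end, r_end)
            if ov_end <= ov_start:
                continue
            # fraction of the peak falling in this region
            frac_region = (ov_end - ov_start) / length
            # rescale the overlap into bin coordinates of the region
            scale = nbins / (r_end - r_start)
            b0 = (ov_start - r_start) * scale
            b1 = (ov_end - r_start) * scale
            for b in range(int(np.floor(b0)), min(int(np.ceil(b1)), nbins)):
                ov_bins = min(b1, b + 1) - max(b0, b)
                if ov_bins > 0:
                    out[bin0 + b] += sig * frac_region * ov_bins / (b1 - b0)
    return out


def metagene_profile(
    peaks: PeakTable,
    models: Sequence[GeneModel],
    group: tuple[str, str],
    bins: tuple[int, int, int] = (25, 50, 25),
    gene_ids: Sequence[str] | None = None,
) -> MetageneProfile:
    """Metagene profile of mean per-replicate IP signal for one
    (genotype, condition) group.

    Every gene in ``gene_ids`` (default: all modelled genes) enters the mean,
    genes without peaks contributing zeros, so that
    sum(bin_means) * n_genes equals the total assigned signal. Genes with a
    zero-length UTR contribute only to the bins of their nonempty regions
    (logged).
    """
    genotype, condition = group
    by_id = {m.gene_id: m for m in models}
    if gene_ids is None:
        gene_ids = [m.gene_id for m in models]
    cols = [
        f"ip:{s.sample_id}"
        for s in peaks.ip_samples
        if s.genotype == genotype and s.condition == condition
    ]
    if not cols:
        raise KeyError(f"no merip_ip samples for group {group}")
    frame = peaks.frame
    group_signal = frame[cols].astype(float).mean(axis=1)
    total = np.zeros(sum(bins))
    n_degenerate = 0
    gene_set = set(gene_ids)
    assigned = frame["gene_id"].isin(gene_set) & (frame["gene_id"] != "")
    for gid, sub in frame[assigned].groupby("gene_id"):
        if gid not in by_id:
            raise KeyError(f"peak assigned to unknown gene {gid!r}")
        model = by_id[gid]
        if model.utr5_len == 0 or model.utr3_len == 0:
            n_degenerate += 1
        total += _gene_bin_vector(sub, model, group_signal.loc[sub.index].to_numpy(), bins)
    if n_degenerate:
        logger.info("%d gene(s) with an empty UTR contribute only to their nonempty regions", n_degenerate)
    n_genes = len(gene_ids)
    return MetageneProfile(
        bin_means=total / n_genes,
        n_genes=n_genes,
        utr5_bins=bins[0],
        cds_bins=bins[1],
        utr3_bins=bins[2],
    )
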