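"""Blue/dark photoresponse contrasts.

The unit of analysis is the B/D fold change: the ratio of a quantity (mRNA
abundance, per-peak m6A signal, translation state, protein intensity) between
blue-light-grown and dark-grown seedlings of one genotype. A gene or peak is
called photoresponsive when B/D clears a fold-change threshold and an
unequal-variance t-test on log2(x+1) replicate values clears a significance
gate (raw p, BH-adjusted q, or either). The translation state of a gene is
TS = (RPKM in TRAP + 1)/(RPKM in input + 1), ribosome-associated over total
mRNA with unit pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PeakTable

__all__ = [
    "translation_state",
    "translation_state_matrix",
    "fold_change_bd",
    "welch_test",
    "bh_adjust",
    "Gates",
    "classify_photoresponse",
    "classify_m6a_hyper",
    "photoresponse_table",
    "peak_photoresponse_table",
]


def translation_state(trap_rpkm, input_rpkm):
    """TS = (TRAP RPKM + 1) / (input RPKM + 1); equals 1 when the two agree."""
    trap = np.asarray(trap_rpkm, dtype=float)
    inp = np.asarray(input_rpkm, dtype=float)
    if np.any(trap < 0) or np.any(inp < 0):
        raise ValueError("translation_state requires nonnegative RPKM values")
    return (trap + 1.0) / (inp + 1.0)


def translation_state_matrix(trap: ExpressionMatrix, trap_input: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene, per-replicate TS from paired TRAP and input matrices.

    Samples are paired by (genotype, condition, replicate); both matrices must
    cover the same genes in the same order.
    """
    if trap.gene_ids != trap_input.gene_ids:
        raise ValueError("TRAP and input matrices must cover the same genes in the same order")
    pair_of = {(s.genotype, s.condition, s.replicate): j for j, s in enumerate(trap_input.samples)}
    cols = []
    for s in trap.samples:
        key = (s.genotype, s.condition, s.replicate)
        if key not in pair_of:
            raise ValueError(f"no trap_input sample paired with {s.sample_id}")
        cols.append(pair_of[key])
    ts = translation_state(trap.values, trap_input.values[:, cols])
    return ExpressionMatrix(
        gene_ids=list(trap.gene_ids), samples=list(trap.samples), values=ts, unit="intensity"
    )


def fold_change_bd(values_blue, values_dark, pseudocount: float = 1.0) -> float | np.ndarray:
    """B/D fold change: (mean(blue) + eps) / (mean(dark) + eps).

    Accepts 1-D replicate vectors (returns a scalar) or (n, r) arrays
    (returns length-n vector). ``pseudocount`` may be 0 when the values are
    already bounded away from zero (e.g. translation states).
    """
    b = np.atleast_2d(np.asarray(values_blue, dtype=float))
    d = np.atleast_2d(np.asarray(values_dark, dtype=float))
    if b.shape[-1] == 0 or d.shape[-1] == 0:
        raise ValueError("fold_change_bd requires at least one replicate per condition")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mb = b.mean(axis=-1) + pseudocount
    md = d.mean(axis=-1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where((mb == 0) & (md == 0), 1.0, mb / md)
    return float(fc[0]) if np.ndim(values_blue) == 1 else fc


def welch_test(group1, group2, log_transform: bool = False):
    """Two-tailed unequal-variance (Welch) t-test.

    With ``log_transform`` the test runs on log2(x+1), the scale on which
    multiplicative replicate noise is approximately Gaussian. Degenerate
    groups (both variances zero) give p=1 when the means agree and p=0
    otherwise. Accepts (n, r) arrays row-wise.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.shape[-1] < 2 or g2.shape[-1] < 2:
        raise ValueError("welch_test requires >= 2 replicates per group")
    if log_transform:
        if np.any(g1 < 0) or np.any(g2 < 0):
            raise ValueError("log_transform requires nonnegative values")
        g1 = np.log2(g1 + 1.0)
        g2 = np.log2(g2 + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(g1, g2, axis=-1, equal_var=False).pvalue
    p = np.atleast_1d(np.asarray(p, dtype=float))
    # zero-variance convention
    degenerate = (g1.var(axis=-1) == 0) & (g2.var(axis=-1) == 0)
    if np.any(degenerate):
        equal = np.isclose(g1.mean(axis=-1), g2.mean(axis=-1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    return float(p[0]) if np.ndim(group1) == 1 else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone in rank, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Gates:
    """Thresholds for the photoresponsiveness call.

    ``gate_mode``: 'p' (p < p_threshold), 'q' (q < q_threshold) or 'either'
    (p < p_threshold OR q < q_threshold, the disjunctive gate used for the
    headline photoresponsiveness definition). All comparisons are strict.
    """

    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    gate_mode: Literal["p", "q", "either"] = "either"

    def __post_init__(self) -> None:
        if min(self.fc_threshold, self.p_threshold, self.q_threshold) <= 0:
            raise ValueError("gate thresholds must be positive")
        if self.gate_mode not in ("p", "q", "either"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")

    def significant(self, p, q) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        if self.gate_mode == "p":
            return p < self.p_threshold
        if self.gate_mode == "q":
            return q < self.q_threshold
        return (p < self.p_threshold) | (q < self.q_threshold)


def classify_photoresponse(fc_bd, p, q, gates: Gates = Gates()):
    """'up' if fc_bd > fc_threshold and the significance gate holds, 'down' if
    1/fc_bd > fc_threshold and the gate holds, else 'ns'. Strict inequalities."""
    fc = np.atleast_1d(np.asarray(fc_bd, dtype=float))
    sig = np.atleast_1d(gates.significant(p, q))
    out = np.where(
        (fc > gates.fc_threshold) & sig,
        "up",
        np.where((fc > 0) & (1.0 / fc > gates.fc_threshold) & sig, "down", "ns"),
    )
    return str(out[0]) if np.ndim(fc_bd) == 0 else out


def classify_m6a_hyper(fc_wt: float, fc_mut: float, p_wt: float | None = None) -> str:
    """Hyper/non-hyper classification of a peak's m6A photoresponse.

    'WT m6A hyper' means B/D in WT > 1.5 (and p_wt < 0.05 when a p is given);
    'non-hyper in the mutant' additionally requires mutant B/D < 1.5.
    """
    if fc_wt <= 0 or fc_mut <= 0:
        raise ValueError("fold changes must be positive")
    wt_hyper = fc_wt > 1.5 and (p_wt is None or p_wt < 0.05)
    if not wt_hyper:
        return "not_wt_hyper"
    return "wt_hyper_mut_nonhyper" if fc_mut < 1.5 else "wt_hyper_mut_hyper"


def _contrast_frame(
    ids: Sequence[str],
    blue: np.ndarray,
    dark: np.ndarray,
    genotype: str,
    gates: Gates,
    pseudocount: float,
    log_transform: bool = True,
) -> pd.DataFrame:
    fc = fold_change_bd(blue, dark, pseudocount=pseudocount)
    p = welch_test(blue, dark, log_transform=log_transform)
    q = bh_adjust(p)
    cls = classify_photoresponse(fc, p, q, gates)
    return pd.DataFrame(
        {"id": list(ids), "genotype": genotype, "fc_bd": fc, "p": p, "q": q, "class": cls}
    )


def photoresponse_table(
    matrix: ExpressionMatrix,
    genotypes: Sequence[str],
    gates: Gates = Gates(),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene B/D contrast table for one layer, one row per gene x genotype.

    Columns: id, genotype, fc_bd, p, q, class. BH adjustment is applied within
    each genotype across all genes of the layer.
    """
    frames = []
    for gt in genotypes:
        blue = matrix.columns_for(gt, "blue")
        dark = matrix.columns_for(gt, "dark")
        frames.append(
            _contrast_frame(matrix.gene_ids, blue, dark, gt, gates, pseudocount)
        )
    return pd.concat(frames, ignore_index=True)


def peak_photoresponse_table(
    peaks: PeakTable,
    genotypes: Sequence[str],
    gates: Gates = Gates(),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-peak B/D contrast of the IP signal, one row per peak x genotype.

    Columns: id (peak_id), gene_id, genotype, fc_bd, p, q, class.
    """
    frames = []
    for gt in genotypes:
        blue = peaks.ip_signal(gt, "blue")
        dark = peaks.ip_signal(gt, "dark")
        f = _contrast_frame(peaks.frame["peak_id"], blue, dark, gt, gates, pseudocount)
        f.insert(1, "gene_id", peaks.frame["gene_id"].to_numpy())
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
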