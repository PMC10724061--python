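"""Truth-labelled synthetic multi-omics cohort.

The generator emulates an 8-sample factorial cohort — four genotypes
(WT, cry1cry2, fio1, mta) x two light conditions (dark, blue) — with four
measurement layers per gene: transcript counts (negative binomial),
MeRIP IP/input signal, TRAP + input RPKM, and protein intensity.
Planted gene classes carry the CRY/FIO1-dependent, MTA-independent
signature the discovery stage is built to recover: light-induced m6A,
translation and protein gains present in WT and mta but absent (m6A,
translation) or inverted (protein) in cry1cry2 and fio1.

Effects enter as multiplicative factors on the blue-condition means only;
dark means are shared across genotypes. Replicate noise is multiplicative
log-normal with a fixed coefficient of variation; counts are negative
binomial. Effect sizes are calibration choices: margins are set by a power
analysis (see docs/methods.md) so that the planted signature clears every
selection gate with per-gene miss probability ~1e-5 at the default three
replicates and 8% CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from . import io as omio
from .io import ExpressionMatrix, GeneModel, PeakTable, SampleDesign

GENOTYPES = ("WT", "cry1cry2", "fio1", "mta")
CONDITIONS = ("dark", "blue")
CLASSES = (
    "chr_signature",
    "shared_methyl",
    "mta_specific",
    "fio1_specific",
    "cry_transcriptional",
    "cse_like",
    "decoy",
)
#: effect axes: multiplier applied to the blue-condition mean of that layer
AXES = ("transcript", "m6a", "ts", "protein")


def default_effects() -> dict:
    """Blue/dark effect multipliers per class, axis and genotype.

    chr_signature is the planted CHR signature: light-induced m6A in WT and
    mta only; light-induced translation and protein gain in WT and mta, lost
    (translation) or inverted (protein) in cry1cry2 and fio1. The mta
    responses sit above WT because the selection requires the strict ratios
    (B/D)^mta/(B/D)^WT > 0.8 (translation) and > 1 (protein) and the margin
    must absorb replicate sampling noise.
    """
    one = {g: 1.0 for g in GENOTYPES}
    return {
        "chr_signature": {
            "m6a": {"WT": 3.0, "mta": 3.0, "cry1cry2": 1.0, "fio1": 1.0},
            "ts": {"WT": 2.5, "mta": 3.2, "cry1cry2": 1.0, "fio1": 1.05},
            "protein": {"WT": 2.2, "mta": 3.3, "cry1cry2": 0.7, "fio1": 0.7},
        },
        "shared_methyl": {"m6a": {"WT": 3.0, "cry1cry2": 1.0, "fio1": 1.0, "mta": 1.0}},
        "mta_specific": {"m6a": {"WT": 3.0, "cry1cry2": 3.0, "fio1": 3.0, "mta": 1.0}},
        "fio1_specific": {"m6a": {"WT": 3.0, "cry1cry2": 3.0, "fio1": 1.0, "mta": 3.0}},
        "cry_transcriptional": {
            "transcript": {"WT": 2.0, "cry1cry2": 1.0, "fio1": 2.0, "mta": 2.0}
        },
        "cse_like": {"protein": dict(one, **{g: 2.0 for g in GENOTYPES})},
        "decoy": {},
    }


def null_effects() -> dict:
    """All multipliers 1: no planted signal (null cohort)."""
    return {cls: {} for cls in CLASSES}


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_genes: int = 2000
    replicates: int = 3
    seed: int = 42
    n_chr_signature: int = 7
    n_shared_methyl: int = 60
    n_mta_specific: int = 30
    n_fio1_specific: int = 30
    n_cry_transcriptional: int = 100
    n_cse_like: int = 20
    noise_cv: float = 0.08
    nb_dispersion: float = 0.05
    #: fraction of decoy genes with constitutive (light-independent) m6A peaks
    frac_background_methylated: float = 0.3
    #: baseline IP/input enrichment of methylated genes
    base_enrichment: float = 4.0
    #: median baseline abundance, RPKM-like units
    baseline_median: float = 20.0
    baseline_sigma: float = 1.0
    #: sequencing depth factor linking abundance to expected counts
    depth_factor: float = 10.0
    effects: dict = field(default_factory=default_effects)

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        if self.noise_cv <= 0:
            raise ConfigError("noise_cv must be > 0")
        if self.class_total > self.n_genes:
            raise ConfigError(
                f"class sizes sum to {self.class_total} > n_genes = {self.n_genes}"
            )

    @property
    def class_total(self) -> int:
        return (
            self.n_chr_signature
            + self.n_shared_methyl
            + self.n_mta_specific
            + self.n_fio1_specific
            + self.n_cry_transcriptional
            + self.n_cse_like
        )

    def class_sizes(self) -> dict[str, int]:
        return {
            "chr_signature": self.n_chr_signature,
            "shared_methyl": self.n_shared_methyl,
            "mta_specific": self.n_mta_specific,
            "fio1_specific": self.n_fio1_specific,
            "cry_transcriptional": self.n_cry_transcriptional,
            "cse_like": self.n_cse_like,
            "decoy": self.n_genes - self.class_total,
        }

    def null(self) -> "GeneratorConfig":
        """Copy of this config with every effect multiplier set to 1."""
        return replace(self, effects=null_effects())


@dataclass
class Cohort:
    """In-memory synthetic cohort: design, gene models, one matrix per layer,
    the peak table and the generating truth (gene_id -> class)."""

    config: GeneratorConfig
    design: list[SampleDesign]
    models: list[GeneModel]
    matrices: dict[str, ExpressionMatrix]
    peaks: PeakTable
    truth: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.models]

    def genes_of_class(self, cls: str) -> list[str]:
        return sorted(self.truth.index[self.truth == cls])


def _make_design(cfg: GeneratorConfig) -> list[SampleDesign]:
    layers = ("transcriptome", "merip_ip", "merip_input", "trap", "trap_input", "proteome")
    out = []
    for layer in layers:
        for gt in GENOTYPES:
            for cond in CONDITIONS:
                for rep in range(1, cfg.replicates + 1):
                    out.append(
                        SampleDesign(
                            sample_id=f"{gt}_{cond}_r{rep}_{layer}",
                            genotype=gt,
                            condition=cond,
                            replicate=rep,
                            layer=layer,
                        )
                    )
    return out


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit median and coefficient of variation cv."""
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=shape)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def _multiplier(effects: dict, cls: str, axis: str, genotype: str) -> float:
    return float(effects.get(cls, {}).get(axis, {}).get(genotype, 1.0))


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw one cohort. Deterministic given ``config.seed``."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(1, n + 1)]

    # class labels, shuffled over genes
    labels = np.array(
        sum(([cls] * size for cls, size in cfg.class_sizes().items()), []), dtype=object
    )
    labels = labels[rng.permutation(n)]
    truth = pd.Series(labels, index=gene_ids, name="class")

    # gene geometry: region lengths log-normal with medians 150/1200/300 nt
    utr5 = np.maximum(1, np.round(rng.lognormal(np.log(150), 0.5, n))).astype(int)
    cds = np.maximum(3, np.round(rng.lognormal(np.log(1200), 0.4, n) / 3).astype(int) * 3)
    utr3 = np.maximum(1, np.round(rng.lognormal(np.log(300), 0.5, n))).astype(int)
    models = [
        GeneModel(g, int(u5), int(c), int(u3))
        for g, u5, c, u3 in zip(gene_ids, utr5, cds, utr3)
    ]
    tlen = np.array([m.transcript_len for m in models], dtype=float)

    # baseline abundance (RPKM-like); planted signature genes are kept at or
    # above the median so the pseudocounts in downstream statistics stay mild
    base = rng.lognormal(np.log(cfg.baseline_median), cfg.baseline_sigma, n)
    is_chr = labels == "chr_signature"
    base[is_chr] = np.maximum(base[is_chr], cfg.baseline_median)
    tf0 = rng.lognormal(0.0, 0.2, n)  # baseline translation factor

    # methylation status and peak geometry
    methylated = np.isin(labels, ["chr_signature", "shared_methyl", "mta_specific", "fio1_specific"])
    decoy_idx = np.nonzero(labels == "decoy")[0]
    n_bg = int(round(cfg.frac_background_methylated * len(decoy_idx)))
    bg_idx = rng.choice(decoy_idx, size=n_bg, replace=False) if n_bg else np.array([], dtype=int)
    methylated = methylated.copy()
    methylated[bg_idx] = True

    # per-axis, per-genotype multiplier matrices (applied to blue means only)
    mult = {
        axis: {
            gt: np.array([_multiplier(cfg.effects, cls, axis, gt) for cls in labels], dtype=float)
            for gt in GENOTYPES
        }
        for axis in AXES
    }

    reps = cfg.replicates
    cv = cfg.noise_cv
    matrices: dict[str, ExpressionMatrix] = {}
    design = _make_design(cfg)
    by_layer = {
        layer: [d for d in design if d.layer == layer]
        for layer in ("transcriptome", "merip_ip", "merip_input", "trap", "trap_input", "proteome")
    }

    def sample_order(layer: str):
        return by_layer[layer]

    # build per-layer value arrays column by column in design order
    cols: dict[str, dict[str, np.ndarray]] = {layer: {} for layer in by_layer}
    enr_base = np.where(methylated, cfg.base_enrichment, 1.0)
    for gt in GENOTYPES:
        for cond in CONDITIONS:
            blue = cond == "blue"
            mrna = base * (mult["transcript"][gt] if blue else 1.0)
            enr = enr_base * (mult["m6a"][gt] if blue else 1.0)
            tsf = tf0 * (mult["ts"][gt] if blue else 1.0)
            prot = base * tf0 * 100.0 * (mult["protein"][gt] if blue else 1.0)
            for rep in range(1, reps + 1):
                key = f"{gt}_{cond}_r{rep}"
                counts_mean = mrna * (tlen / 1500.0) * cfg.depth_factor
                cols["transcriptome"][key] = _nb_counts(rng, counts_mean, cfg.nb_dispersion)
                inp = mrna * _lognormal_noise(rng, cv, n)
                cols["merip_input"][key] = inp
                cols["merip_ip"][key] = inp * enr * _lognormal_noise(rng, cv, n)
                tinp = mrna * _lognormal_noise(rng, cv, n)
                cols["trap_input"][key] = tinp
                cols["trap"][key] = tinp * tsf * _lognormal_noise(rng, cv, n)
                cols["proteome"][key] = prot * _lognormal_noise(rng, cv, n)

    units = {
        "transcriptome": "raw_count",
        "merip_ip": "intensity",
        "merip_input": "intensity",
        "trap": "rpkm",
        "trap_input": "rpkm",
        "proteome": "intensity",
    }
    for layer, samples in by_layer.items():
        values = np.column_stack(
            [cols[layer][f"{s.genotype}_{s.condition}_r{s.replicate}"] for s in samples]
        )
        matrices[layer] = ExpressionMatrix(
            gene_ids=list(gene_ids), samples=samples, values=values, unit=units[layer]
        )

    # one peak per methylated gene, near the stop codon / 3'UTR (RRACH-like site)
    peak_rows = []
    ip_samples = by_layer["merip_ip"]
    input_samples = by_layer["merip_input"]
    ip_vals = matrices["merip_ip"].values
    input_vals = matrices["merip_input"].values
    meth_idx = np.nonzero(methylated)[0]
    for k, i in enumerate(meth_idx):
        m = models[i]
        junction = m.utr5_len + m.cds_len
        lo = max(junction - min(150, m.cds_len), m.utr5_len)
        hi = min(junction + m.utr3_len, m.transcript_len)
        mid = int(rng.integers(lo, max(hi, lo + 1)))
        half = 50
        start = max(0, mid - half)
        end = min(m.transcript_len, mid + half)
        if end <= start:
            start, end = 0, m.transcript_len
        peak_rows.append(
            [f"p{k + 1:05d}", m.gene_id, start, end]
            + list(ip_vals[i])
            + list(input_vals[i])
        )
    cols_peaks = (
        omio.PEAK_FIXED_COLUMNS
        + [f"ip:{s.sample_id}" for s in ip_samples]
        + [f"input:{s.sample_id}" for s in input_samples]
    )
    peak_frame = pd.DataFrame(peak_rows, columns=cols_peaks)
    if len(peak_frame):
        peak_frame = peak_frame.astype({"start": int, "end": int})
    peaks = PeakTable(frame=peak_frame, ip_samples=ip_samples, input_samples=input_samples)

    return Cohort(
        config=cfg, design=design, models=models, matrices=matrices, peaks=peaks, truth=truth
    )


LAYER_FILES = {
    "transcriptome": "transcriptome.tsv",
    "merip_ip": "merip_ip.tsv",
    "merip_input": "merip_input.tsv",
    "trap": "trap.tsv",
    "trap_input": "trap_input.tsv",
    "proteome": "proteome.tsv",
}


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort in the standard formats; returns the file manifest."""
    if not str(directory):
        raise OSError("empty directory path")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    omio.write_design(cohort.design, d / "design.tsv")
    manifest["design"] = d / "design.tsv"
    for layer, fname in LAYER_FILES.items():
        omio.write_matrix(cohort.matrices[layer], d / fname)
        manifest[layer] = d / fname
    omio.write_gene_models(cohort.models, d / "gene_models.tsv")
    manifest["gene_models"] = d / "gene_models.tsv"
    omio.write_peaks(cohort.peaks, d / "peaks.bed")
    manifest["peaks"] = d / "peaks.bed"
    truth = cohort.truth.rename_axis("gene_id").reset_index()
    truth.to_csv(d / "truth.tsv", sep="\t", index=False)
    manifest["truth"] = d / "truth.tsv"
    return manifest


def read_cohort(directory: str | Path, config: GeneratorConfig | None = None) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    d = Path(directory)
    design = omio.read_design(d / "design.tsv")
    models = omio.read_gene_models(d / "gene_models.tsv")
    units = {
        "transcriptome": "raw_count",
        "merip_ip": "intensity",
        "merip_input": "intensity",
        "trap": "rpkm",
        "trap_input": "rpkm",
        "proteome": "intensity",
    }
    matrices = {}
    for layer, fname in LAYER_FILES.items():
        layer_design = [s for s in design if s.layer == layer]
        matrices[layer] = omio.read_matrix(d / fname, layer_design, units[layer])
    peaks = omio.read_peaks(d / "peaks.bed", design)
    truth_df = pd.read_csv(d / "truth.tsv", sep="\t")
    truth = pd.Series(truth_df["class"].to_numpy(), index=truth_df["gene_id"], name="class")
    return Cohort(
        config=config or GeneratorConfig(),
        design=design,
        models=models,
        matrices=matrices,
        peaks=peaks,
        truth=truth,
    )
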