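"""Readers and writers for the tabular formats the pipeline consumes.

All tables are plain TSV (tab-separated, UTF-8, ``#`` comment lines ignored,
``.`` decimal separator); m6A peaks travel as BED6+ with per-sample signal
columns appended. Transcript coordinates are 0-based half-open throughout and
gene models live in strandless transcript space (5'UTR | CDS | 3'UTR), the
coordinate system in which MeRIP metagene profiles are drawn.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "cry1cry2", "fio1", "mta", "spa123", "spa134", "other")
CONDITIONS = ("dark", "blue")
LAYERS = ("transcriptome", "merip_ip", "merip_input", "trap", "trap_input", "proteome")
UNITS = ("raw_count", "rpkm", "intensity")

DESIGN_COLUMNS = ["sample_id", "genotype", "condition", "replicate", "layer"]


class FormatError(ValueError):
    """A file does not have the expected layout (missing header, bad columns)."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing/MS sample: its genotype, light condition, replicate and omics layer."""

    sample_id: str
    genotype: str
    condition: str
    replicate: int
    layer: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate}")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.genotype, self.condition, self.replicate, self.layer)


@dataclass
class ExpressionMatrix:
    """Gene x sample quantification for one omics layer.

    ``values`` is a nonnegative (n_genes, n_samples) array whose columns follow
    ``samples``; ``unit`` records the scale (raw_count, rpkm or intensity).
    """

    gene_ids: list[str]
    samples: list[SampleDesign]
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if np.any(self.values < 0):
            raise ValidationError("expression values must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def columns_for(self, genotype: str, condition: str) -> np.ndarray:
        """Replicate submatrix (genes x replicates) of one genotype/condition group."""
        idx = [
            j
            for j, s in enumerate(self.samples)
            if s.genotype == genotype and s.condition == condition
        ]
        if not idx:
            raise KeyError(f"no samples for ({genotype}, {condition})")
        order = np.argsort([self.samples[j].replicate for j in idx])
        return self.values[:, [idx[k] for k in order]]


@dataclass(frozen=True)
class GeneModel:
    """Transcript-space gene geometry: 5'UTR, CDS and 3'UTR lengths in nt."""

    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValidationError(f"{self.gene_id}: negative region length")
        if self.cds_len and self.cds_len < 3:
            raise ValidationError(f"{self.gene_id}: cds_len must be >= 3 when present")
        if self.transcript_len <= 0:
            raise ValidationError(f"{self.gene_id}: transcript_len must be > 0")

    @property
    def transcript_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len


#: Columns identifying a peak; signal columns follow.
PEAK_FIXED_COLUMNS = ["peak_id", "gene_id", "start", "end"]


@dataclass
class PeakTable:
    """m6A peak intervals in transcript coordinates plus per-sample IP/input signal.

    ``frame`` holds one row per peak with columns peak_id, gene_id (may be ""),
    start, end, then ``ip:<sample_id>`` and ``input:<sample_id>`` signal columns.
    ``ip_samples`` / ``input_samples`` give the corresponding designs in order.
    """

    frame: pd.DataFrame
    ip_samples: list[SampleDesign]
    input_samples: list[SampleDesign]

    def __post_init__(self) -> None:
        f = self.frame
        for col in PEAK_FIXED_COLUMNS:
            if col not in f.columns:
                raise FormatError(f"peak table missing column {col!r}")
        if len(f) and not (f["start"] < f["end"]).all():
            bad = f.loc[f["start"] >= f["end"], "peak_id"].tolist()
            raise ValidationError(f"peaks with start >= end: {bad}")
        for s in self.ip_samples:
            if f"ip:{s.sample_id}" not in f.columns:
                raise FormatError(f"missing signal column ip:{s.sample_id}")
        for s in self.input_samples:
            if f"input:{s.sample_id}" not in f.columns:
                raise FormatError(f"missing signal column input:{s.sample_id}")
        sig = f[self.signal_columns()].to_numpy(dtype=float)
        if sig.size and np.any(sig < 0):
            raise ValidationError("peak signals must be nonnegative")

    def signal_columns(self) -> list[str]:
        return [f"ip:{s.sample_id}" for s in self.ip_samples] + [
            f"input:{s.sample_id}" for s in self.input_samples
        ]

    def ip_signal(self, genotype: str, condition: str) -> np.ndarray:
        """(n_peaks, n_replicates) IP signal for one genotype/condition group."""
        cols = [
            f"ip:{s.sample_id}"
            for s in sorted(
                (s for s in self.ip_samples if s.genotype == genotype and s.condition == condition),
                key=lambda s: s.replicate,
            )
        ]
        if not cols:
            raise KeyError(f"no merip_ip samples for ({genotype}, {condition})")
        return self.frame[cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# TSV helpers

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, header=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected a header line") from None


# ---------------------------------------------------------------------------
# Readers

def read_design(path: str | Path) -> list[SampleDesign]:
    """Parse a sample design TSV with columns sample_id/genotype/condition/replicate/layer."""
    df = _read_tsv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: design file missing columns {missing}")
    designs: list[SampleDesign] = []
    seen_keys: set[tuple] = set()
    seen_ids: set[str] = set()
    for row in df.itertuples(index=False):
        d = SampleDesign(
            sample_id=str(row.sample_id),
            genotype=str(row.genotype),
            condition=str(row.condition),
            replicate=int(row.replicate),
            layer=str(row.layer),
        )
        if d.key in seen_keys:
            raise ValidationError(f"duplicate design row for {d.key}")
        if d.sample_id in seen_ids:
            raise ValidationError(f"duplicate sample_id {d.sample_id!r}")
        seen_keys.add(d.key)
        seen_ids.add(d.sample_id)
        designs.append(d)
    return designs


def read_matrix(path: str | Path, design: Sequence[SampleDesign], unit: str) -> ExpressionMatrix:
    """Parse a gene x sample TSV; columns are reordered to follow ``design``."""
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    by_id = {d.sample_id: d for d in design}
    unknown = [c for c in df.columns[1:] if c not in by_id]
    if unknown:
        raise ValidationError(f"{path}: sample columns not in design: {unknown}")
    samples = [by_id[c] for c in df.columns[1:] if c in by_id]
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"{path}: negative expression values")
    # order columns as in the design
    order = sorted(range(len(samples)), key=lambda j: design.index(samples[j]))
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df["gene_id"]],
        samples=[samples[j] for j in order],
        values=values[:, order],
        unit=unit,
    )


def _gene_model_from_lengths(gene_id, utr5, cds, utr3, stated_total=None) -> GeneModel:
    m = GeneModel(gene_id=gene_id, utr5_len=int(utr5), cds_len=int(cds), utr3_len=int(utr3))
    if stated_total is not None and int(stated_total) != m.transcript_len:
        raise ValidationError(
            f"{gene_id}: stated transcript_len {stated_total} != "
            f"utr5+cds+utr3 = {m.transcript_len}"
        )
    return m


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene models from a TSV (gene_id, utr5_len, cds_len, utr3_len[, transcript_len])
    or a BED12-like file (12 whitespace-separated columns, thickStart/thickEnd
    delimiting the CDS on the transcript and blockSizes summing to its length)."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty gene model file")
    first = lines[0].split("\t")
    models: list[GeneModel] = []
    if "gene_id" in first:  # header TSV
        df = _read_tsv(_stdio.StringIO(text))
        needed = ["gene_id", "utr5_len", "cds_len", "utr3_len"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: gene model file missing columns {missing}")
        for row in df.itertuples(index=False):
            total = getattr(row, "transcript_len", None)
            models.append(
                _gene_model_from_lengths(str(row.gene_id), row.utr5_len, row.cds_len, row.utr3_len, total)
            )
    else:  # BED12-like, transcript space: chromStart=0, thickStart/thickEnd = CDS
        for ln in lines:
            parts = ln.split()
            if len(parts) < 12:
                raise FormatError(f"{path}: BED12-like line with {len(parts)} fields: {ln!r}")
            name = parts[3]
            start, end = int(parts[1]), int(parts[2])
            thick_start, thick_end = int(parts[6]), int(parts[7])
            block_sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            total = sum(block_sizes)
            if total != end - start:
                raise ValidationError(
                    f"{name}: blockSizes sum {total} != chromEnd-chromStart {end - start}"
                )
            models.append(
                _gene_model_from_lengths(
                    name, thick_start - start, thick_end - thick_start, end - thick_end, total
                )
            )
    seen: set[str] = set()
    for m in models:
        if m.gene_id in seen:
            raise ValidationError(f"duplicate gene model {m.gene_id}")
        seen.add(m.gene_id)
    return models


def read_peaks(path: str | Path, design: Sequence[SampleDesign]) -> PeakTable:
    """Parse a BED6+ peak file.

    Columns: chrom (= gene_id in transcript space, '.' if unassigned), start,
    end, name, score, strand, then one signal column per merip_ip sample
    followed by one per merip_input sample, in design order.
    """
    ip_samples = [d for d in design if d.layer == "merip_ip"]
    input_samples = [d for d in design if d.layer == "merip_input"]
    n_extra = len(ip_samples) + len(input_samples)
    rows = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 6 + n_extra:
            raise FormatError(
                f"{path}: expected 6 + {n_extra} columns "
                f"({len(ip_samples)} IP + {len(input_samples)} input signals), got {len(parts)}"
            )
        gene = "" if parts[0] == "." else parts[0]
        start, end = int(parts[1]), int(parts[2])
        sig = [float(x) for x in parts[6:]]
        rows.append([parts[3], gene, start, end] + sig)
    cols = PEAK_FIXED_COLUMNS + [f"ip:{s.sample_id}" for s in ip_samples] + [
        f"input:{s.sample_id}" for s in input_samples
    ]
    frame = pd.DataFrame(rows, columns=cols)
    if len(frame):
        frame = frame.astype({"start": int, "end": int})
    return PeakTable(frame=frame, ip_samples=ip_samples, input_samples=input_samples)


# ---------------------------------------------------------------------------
# Writers (round-trip bit-identically with the readers for valid inputs)

def write_design(designs: Sequence[SampleDesign], path: str | Path) -> None:
    df = pd.DataFrame(
        [[d.sample_id, d.genotype, d.condition, d.replicate, d.layer] for d in designs],
        columns=DESIGN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.10g") -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=float_format)


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [[m.gene_id, m.utr5_len, m.cds_len, m.utr3_len, m.transcript_len] for m in models],
        columns=["gene_id", "utr5_len", "cds_len", "utr3_len", "transcript_len"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_peaks(peaks: PeakTable, path: str | Path, float_format: str = "%.10g") -> None:
    lines = []
    sig_cols = peaks.signal_columns()
    for _, row in peaks.frame.iterrows():
        fields = [
            row["gene_id"] or ".",
            str(int(row["start"])),
            str(int(row["end"])),
            row["peak_id"],
            ".",
            "+",
        ] + [float_format % float(row[c]) for c in sig_cols]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Normalization

def compute_rpkm(matrix: ExpressionMatrix, models: Sequence[GeneModel]) -> ExpressionMatrix:
    """Reads/fragments per kilobase of transcript per million mapped.

    value = count / ((transcript_len/1e3) * (library_size/1e6)), with the
    library size taken as the column sum over the genes present in the matrix
    (the mapped-read total is not recoverable from a quantification table).
    """
    if matrix.unit != "raw_count":
        raise ValidationError(f"compute_rpkm expects raw_count input, got {matrix.unit}")
    by_id = {m.gene_id: m for m in models}
    missing = [g for g in matrix.gene_ids if g not in by_id]
    if missing:
        raise ValidationError(f"genes without a model: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    lengths = np.array([by_id[g].transcript_len for g in matrix.gene_ids], dtype=float)
    lib = matrix.values.sum(axis=0)
    if np.any(lib <= 0):
        bad = [matrix.samples[j].sample_id for j in np.nonzero(lib <= 0)[0]]
        raise ValidationError(f"zero library size in samples: {bad}")
    rpkm = matrix.values / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids), samples=list(matrix.samples), values=rpkm, unit="rpkm"
    )
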