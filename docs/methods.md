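# Methods

## The analysis in one paragraph

The pipeline asks which genes respond to blue light coherently across four
omics layers — transcript abundance, m⁶A methylation of mRNA, ribosome
association (translation state), and protein abundance — in a factorial
design of four *Arabidopsis* genotypes (wild type, the *cry1cry2*
photoreceptor mutant, and the two m⁶A writer mutants *fio1* and *mta*) grown
in darkness or blue light. The unit of analysis throughout is the **B/D fold
change**, the ratio of a quantity between blue-grown and dark-grown
seedlings of one genotype. Candidate chlorophyll-homeostasis regulators
(CHRs) are genes whose light responses are CRY- and FIO1-dependent but
MTA-independent in all three downstream layers simultaneously.

## Per-layer statistics

**Translation state.** For each gene and replicate,
`TS = (RPKM_TRAP + 1) / (RPKM_input + 1)`: ribosome-associated over total
mRNA with unit pseudocounts, so TS = 1 when the two agree and TS is strictly
increasing in the TRAP signal and decreasing in the input.

**Fold change.** `B/D = (mean(blue) + ε) / (mean(dark) + ε)` over
replicates. ε = 1 on RPKM/intensity scales. Translation states already
carry the +1 pseudocounts inside the TS formula and sit near 1 on their
natural scale, so TS fold changes use ε = 0; re-applying ε = 1 to values of
order 1 would shrink a true 2× ratio to 1.5 and bias every TS gate.

**Significance.** One bespoke, oracle-checkable test is used for every
layer: a two-tailed unequal-variance (Welch) *t*-test on log2(x+1)
replicate values, the scale on which the multiplicative replicate noise is
approximately Gaussian. When both groups are constant the convention is
p = 1 for equal means, p = 0 otherwise. False-discovery control is
Benjamini–Hochberg step-up within each genotype across all genes of a
layer. Count-model (negative-binomial GLM) testing is deliberately out of
scope; the Welch-on-logs test is exchangeable with it at these effect sizes
and is exactly reproducible against an independent oracle.

**Photoresponsiveness gate.** A gene/peak is called *up* when
B/D > 1.5 **and** the significance gate holds; *down* when 1/(B/D) > 1.5
with the gate. The gate is configurable: `p` (p < 0.05), `q` (q < 0.05), or
`either` (p < 0.05 OR q < 0.05). The disjunctive `either` gate is the
default. The reason is statistical: at desk scale the cohort contains only
a handful of genes with true translation effects among 2000, and BH-adjusted
q-values have essentially no power in that regime (q ≈ p·m/rank with rank
bounded by the handful of true positives), whereas a full-scale experiment
with thousands of true effects gives the FDR gate its usual power. The
q-only gate remains available for data where it is appropriate.

**Hyper / non-hyper.** A peak is "WT m⁶A hyper" when its WT B/D > 1.5
(plus p < 0.05 when a p-value is supplied); "non-hyper in a mutant"
additionally requires the mutant B/D < 1.5.

## CHR candidate selection

All comparisons are strict inequalities, matching the printed thresholds.

* **Type 1** (m⁶A): a gene qualifies if **any** of its assigned peaks has
  WT B/D > 1.5 with p < 0.05. The any-peak rule reflects that peaks
  outnumber genes in real data.
* **Type 2** (translation state): WT B/D > 1.5;
  (B/D)^cry1cry2/(B/D)^WT < 0.8; (B/D)^fio1/(B/D)^WT < 0.8;
  (B/D)^mta/(B/D)^WT > 0.8; significance gate on the WT contrast
  (default `either`, see above).
* **Type 3** (protein): the ratio constraints
  (B/D)^cry1cry2/(B/D)^WT < 1, (B/D)^fio1/(B/D)^WT < 1,
  (B/D)^mta/(B/D)^WT > 1 and p < 0.05 on the WT contrast, **plus** the
  direction constraints (B/D)^WT > 1, (B/D)^mta > 1, (B/D)^cry1cry2 < 1,
  (B/D)^fio1 < 1. Directions and ratios are enforced jointly
  (`t3_directions=False` disables the former).
* **Intersection**: the seven-region Venn decomposition of the three sets;
  the triple intersection, sorted by gene id, is the candidate list, reported
  with its per-layer fold-change/p/q evidence.

Genes absent from a layer are simply absent from that type set; no
imputation is performed. Relaxing any threshold can only grow a type set
(tested as a monotonicity property).

## m⁶A geometry

Transcript coordinates are 0-based half-open and strandless
(5′UTR | CDS | 3′UTR); metagene analysis operates on mature mRNA
coordinates. Peaks are assigned to the overlapping gene model (largest
overlap, ties to the lexicographically smaller id; non-overlapping peaks
stay unassigned and are logged). Per-gene **m⁶A density** is summed peak IP
signal per kilobase of transcript — signal, not peak count, since the
measured quantity is intensity-like. Region annotation uses the peak
midpoint with a ±100 nt *stop-proximal* window around the CDS/3′UTR
junction that takes precedence over cds/utr3. The **metagene profile** uses
a fixed 25/50/25 bin layout over 5′UTR/CDS/3′UTR; each peak's signal is
distributed over the bins its interval covers proportionally to overlap
after per-region linear rescaling, and the bin value is the mean over all
genes in the group (peakless genes contribute zeros). This makes the
profile exactly conservative: `sum(bin_means) × n_genes` equals the total
assigned signal (checked to 1e-9 relative tolerance).

## The synthetic cohort

The generator emulates the factorial study: 4 genotypes × 2 conditions ×
3 replicates × 6 sample layers over 2000 genes (defaults; all
configurable).

* **Geometry**: UTR5/CDS/UTR3 lengths log-normal with medians 150/1200/300
  nt (CDS forced to a multiple of 3).
* **Baseline abundance**: log-normal, median 20 RPKM-like units, σ(ln) = 1.
  Planted signature genes are floored at the median so downstream
  pseudocounts stay mild — real CHRs are well-expressed chloroplast-protein
  genes, not borderline transcripts.
* **Noise**: multiplicative log-normal with CV = 0.08 for signals
  (unit median); negative binomial with dispersion 0.05 for transcript
  counts. TRAP values are generated from the same replicate's input
  (TRAP = input × translation factor × noise), so TS cancels the shared
  mRNA-level noise, as paired sequencing of an aliquot does.
* **Effects** multiply blue-condition means only; dark means are shared
  across genotypes, making B/D the natural contrast.
* **Peaks**: one per methylated gene (the four methyl-bearing classes plus a
  30% background fraction of decoys with constitutive, light-independent
  methylation), 100 nt wide, centred in the last 150 nt of CDS or the
  3′UTR — an RRACH-like placement that exercises the stop-proximal
  annotation and the metagene layout. Baseline IP/input enrichment is 4.

Planted classes: `chr_signature` (7 genes, the full three-layer signature),
`shared_methyl` (60, WT-only m⁶A gain), `mta_specific` / `fio1_specific`
(30 each, m⁶A gain in every genotype except the named writer mutant),
`cry_transcriptional` (100, transcript gain except in *cry1cry2*),
`cse_like` (20, protein gain in **all** genotypes — decoys that must never
be nominated because the selection requires the protein loss in *cry1cry2*
and *fio1*), and decoys.

**Effect-size calibration.** Effect sizes are calibration choices, not
measured values. They were fixed once by a pre-implementation power
analysis (2×10⁵–5×10⁵ Monte-Carlo draws per gate at CV 0.08, 3 replicates):
the standard deviation of a log2 B/D estimate is ≈0.094 and of a log2
mutant/WT fold-change ratio ≈0.133, and the binding constraints turn out to
be the strict ratio gates involving *mta* and the Welch p < 0.05 gate
(whose df ≈ 4 *t* statistic has heavy tails). The planted signature is
m⁶A ×3 (WT, mta), TS ×2.5 (WT) / ×3.2 (mta) / ×1.0–1.05 (cry, fio1), and
protein ×2.2 (WT) / ×3.3 (mta) / ×0.7 (cry, fio1). The *mta* responses sit
above WT because the selection demands (B/D)^mta/(B/D)^WT strictly above
its threshold; planting the ratio at 1 would put half the signature on the
wrong side of the gate in every draw. With these margins the per-gene
probability of missing any gate is ~1e-5, so exact recovery of all seven
genes holds across seeds. Halving an effect or doubling the CV moves the
design out of this strong-effect regime by construction, and the
recovery-based tests would correctly fail there.

**What the generator does not emulate**: read-level sampling, isoform
structure, peak-calling uncertainty, batch effects, missing proteome
values, or correlated genes. Passing tests therefore demonstrate that the
selection arithmetic, thresholds and plumbing are correct under the stated
noise model — not that the thresholds are optimal for any real dataset.

**Null calibration.** With all multipliers at 1, per-layer WT positive
rates at p < 0.05 run slightly *below* the nominal 5% (typically
0.032–0.047 at n = 2000): the Welch approximation at n = 3 plus the mild
skew that the log2(x+1) transform leaves are conservative, never
anticonservative. The fold-change gate only reduces the up-call rate
further, and the null triple intersection is empty.

## Assay models

**Michaelis–Menten.** Net rates are `max(rate − background, 0)` (clipping
logged). The fit is nonlinear least squares of v = Vmax·S/(Km+S) on
replicate-mean rates, initialized from a Hanes–Woolf linearization
(S/v vs S), with Km bounded positive; kcat = Vmax/[E] and catalytic
efficiency kcat/Km are derived. Identifiability needs ≥4 distinct
substrate concentrations spanning sub-Km and saturating points. Effector
activity is summarized as the catalytic-efficiency fold change over the
basal enzyme (basal ≡ 1.0).

**FRAP.** Raw traces are double-normalized against the reference ROI
(correcting acquisition photobleaching — an equal multiplicative fade of
both ROIs cancels exactly) and then full-scale normalized so the pre-bleach
plateau maps to 1 and the first post-bleach frame to 0. The recovery is fit
with I(t) = I₀ − α·e^(−βt) − γ·e^(−δt) by bounded least squares with
multi-start initialization (bleach depth split 30/50/70% between
components; rate starts from the half-recovery time and the trace span);
the fast/slow labelling β ≥ δ ≥ 0 is imposed by relabelling after the fit,
which is exact because the model is symmetric under component swap. For a
full-scale-normalized curve the mobile fraction equals I₀. Because "recovery
rate" is ambiguous between β, δ and a half-time, the package reports the
time to recover 50% of (I₀ − I(0)) as a neutral speed summary.

**Chlorophyll.** chl a = 12.21·A₆₆₃ − 2.81·A₆₄₆ and
chl b = 20.13·A₆₄₆ − 5.03·A₆₆₃ (µg/ml, 80% acetone);
per fresh weight, total·volume/weight/1000 (mg/g). The equations are exactly
linear; a negative concentration (mis-set blank) is returned with a warning
flag rather than suppressed.

**MeRIP-qPCR.** ΔΔCt = (Ct_target,IP − Ct_spike,IP) −
(Ct_target,input − Ct_spike,input); relative level 2^(−ΔΔCt). The m⁶A
spike-in normalizes the IP fraction and the non-m⁶A spike-in the input;
the record structure keeps the pairing explicit and overridable.
LC–MS/MS m⁶A/A ratios are normalized to the wild type (WT ≡ 1).

## Problem sizes and tolerances

Default analyses run on 2000-gene cohorts with 3 replicates; robustness
checks use 10–20 seeds; oracle equivalence uses 1000 random p-vectors (BH,
exact equality) and 200 random group pairs (Welch, 1e-10); fit-recovery
checks use noiseless series (≤1e-6 relative for Michaelis–Menten, ≤1e-4 for
FRAP) and 50–100 noisy replicates (≤15% median Km error at 5% noise; ≤10%
median I₀ error at σ = 0.02). These sizes keep the full suite and the
acceptance script in the seconds-to-minutes range while leaving every
statistical margin analysis valid.

## Known limitations

* The significance machinery is a single Welch-on-logs test; it is not a
  count-model test and should not be used as a differential-expression
  method on real read counts.
* Peak assignment operates in transcript space; genomic (chromosomal)
  coordinates, spliced models and GTF parsing are out of scope.
* The generator's planted margins are deliberately strong; the pipeline's
  behaviour near the thresholds is characterized by the null cohort, not by
  borderline-effect cohorts.
* Headline gene counts from the full-scale experiment (thousands of
  photoresponsive accessions) are functions of real sequencing depth and
  proteome coverage and are not reproduced by the desk-scale cohort; the
  pipeline reproduces the selection *logic*, verified against planted
  truth.
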