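"""Generate the default truth-labelled cohort and write it under results/cohort.

The cohort mirrors an 8-sample factorial design (WT, cry1cry2, fio1, mta x
dark, blue; 3 replicates) with transcriptome counts, MeRIP IP/input signal,
TRAP + input RPKM and protein intensities for 2000 genes, 7 of which carry
the planted CRY/FIO1-dependent, MTA-independent CHR signature.
"""

from pathlib import Path

from luxomics.simulate import GeneratorConfig, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = GeneratorConfig()
    cohort = generate_cohort(cfg)
    manifest = write_cohort(cohort, OUT)
    print(f"wrote {len(manifest)} files to {OUT}")
    print("class sizes:")
    print(cohort.truth.value_counts().to_string())
    print("planted signature genes:", ", ".join(cohort.genes_of_class("chr_signature")))


if __name__ == "__main__":
    main()
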