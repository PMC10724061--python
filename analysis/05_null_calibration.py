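"""Null-cohort calibration: no planted effects, so positive calls are noise.

Generates a cohort with every effect multiplier at 1 and reports, per layer,
the fraction of WT blue-vs-dark tests with p < 0.05 (nominally at or below
5%) and the size of the triple intersection (nominally 0).
"""

from pathlib import Path

from luxomics.pipeline import RunConfig, run_pipeline
from luxomics.simulate import GeneratorConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = GeneratorConfig(seed=13).null()
    res = run_pipeline(RunConfig(out_dir=RESULTS / "null", simulate=cfg, write_artifacts=False))
    for layer in ("transcriptome", "ts", "proteome", "m6a_peaks"):
        wt = res.tables[layer].query("genotype == 'WT'")
        print(
            f"{layer}: n={len(wt)}  p<0.05 fraction={(wt['p'] < 0.05).mean():.4f}  "
            f"up-calls={(wt['class'] == 'up').sum()}"
        )
    print(f"triple intersection size: {len(res.report.intersection)}")


if __name__ == "__main__":
    main()
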