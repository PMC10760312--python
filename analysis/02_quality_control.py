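"""Quality control.

Applies the three-stage QC pass to the simulated cohort: pre-stage
variant filters (call rate < 98%, exact HWE p <= 0.001), sample filters
(missingness > 3%, heterozygosity outliers at 3 SD), and the final
variant missingness filter (> 5%). Writes the filtered genotype table
and the removal report.
"""

import argparse
from pathlib import Path

from homburden import io_model as io
from homburden import qc


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = args.results_dir / "cohort"
    gm = io.read_genotypes(bundle / "genotypes.tsv", "raw_table")
    filtered, report = qc.run_qc(gm)

    out_g = args.results_dir / "genotypes_qc.tsv"
    out_r = args.results_dir / "qc_report.tsv"
    io.write_raw_table(filtered, out_g)
    report.to_frame().to_csv(out_r, sep="\t", index=False)

    counts = report.counts()
    print(f"input:    {gm.n_samples} samples x {gm.n_variants} variants")
    print(f"retained: {filtered.n_samples} samples x {filtered.n_variants} variants")
    print(f"removed by reason: {counts if counts else 'nothing'}")
    print(f"wrote {out_g} and {out_r}")


if __name__ == "__main__":
    main()
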