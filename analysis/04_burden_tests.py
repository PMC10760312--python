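"""Burden testing.

Produces the demographics summary and runs both burden approaches
(overall rate comparison with BH adjustment across the context panel;
above-1SD relative burden with exact 2x2 inference) for the four
contrasts of interest: NDD and ASD against non-NDD on common variants,
their cancer-free subsets against the cancer group, and the cancer group
against NDD on ultra-rare variants in the cell-death context.
"""

import argparse
from pathlib import Path

import pandas as pd

from homburden import burden
from homburden import io_model as io
from homburden.io_model import COMMON, ULTRA_RARE


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = args.results_dir / "cohort"
    prof = pd.read_csv(args.results_dir / "profiles.tsv", sep="\t")
    records = io.read_phenotypes(bundle / "phenotypes.tsv")

    summary = burden.cohort_summary(records)
    summary.to_csv(args.results_dir / "cohort_summary.tsv", sep="\t")
    print("cohort summary (n, % male, % pathogenic/likely pathogenic):")
    for g in summary.index:
        print(f"  {g:6s} n={summary.loc[g, 'n']:<4} male%={summary.loc[g, 'male_pct']:<4} "
              f"plp%={summary.loc[g, 'pathogenic_lp_pct']}")

    gene_panel = ["differentiation", "inflammatory", "chromatin_regulation",
                  "candidate_ndd", "highconf_ndd", "pathogenic_cnv"]
    contrasts = [
        ("NDD", "non_NDD", gene_panel, COMMON),
        ("ASD", "non_NDD", gene_panel, COMMON),
        ("NDD_only", "CANCER", gene_panel, COMMON),
        ("ASD_only", "CANCER", gene_panel, COMMON),
        ("CANCER", "NDD", ["cell_death"], ULTRA_RARE),
    ]
    panels = []
    for group_a, group_b, contexts, stratum in contrasts:
        panel = burden.run_burden_panel(prof, records, group_a, group_b,
                                        contexts, stratum)
        panels.append(panel)
        hits = panel[panel["p_adjusted"] < 0.05]
        print(f"\n{group_a} vs {group_b} ({stratum} variants): "
              f"{len(hits)}/{len(panel)} contexts at BH-adjusted p < 0.05")
        for _, row in panel.iterrows():
            print(f"  {row['context']:22s} {row['test_used']:13s} "
                  f"p={row['p_raw']:.4f} adj={row['p_adjusted']:.4f} "
                  f"rel_p={row['rel_p']:.4f} rel_OR={row['rel_or']:.2f}")

    out = args.results_dir / "burden_panels.tsv"
    pd.concat(panels, ignore_index=True).to_csv(out, sep="\t", index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
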