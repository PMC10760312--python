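"""Collapsing analysis.

Applies the two-stage qualifying-variant filtration (homozygous common
exonic/splice variants, then SIFT < 0.05 and/or PolyPhen > 0.9),
collapses qualifying variants to a binary gene-carrier matrix, and tests
each gene's carrier counts for association with the NDD and ASD
phenotypes against the non-NDD group. Genes with unadjusted p < 0.05 are
reported as suggestive modifiers.
"""

import argparse
from pathlib import Path

from homburden import collapsing
from homburden import io_model as io
from homburden.burden import select_group


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = args.results_dir / "cohort"
    gm = io.read_genotypes(args.results_dir / "genotypes_qc.tsv", "raw_table")
    annots = io.read_annotation(bundle / "annotation.tsv")
    records = io.read_phenotypes(bundle / "phenotypes.tsv")

    primary = collapsing.primary_filter(annots, gm)
    qualifying = collapsing.secondary_filter(primary)
    gcm = collapsing.collapse(qualifying)
    gcm.to_csv(args.results_dir / "carrier_matrix.tsv", sep="\t")
    print(f"primary filter:   {len(primary)} (sample, variant) pairs")
    print(f"secondary filter: {len(qualifying)} qualifying pairs "
          f"across {gcm.shape[1]} genes")

    non_ndd = select_group(records, "non_NDD")
    for case_label, fname in (("NDD", "modifiers_ndd.tsv"),
                              ("ASD", "modifiers_asd.tsv")):
        res = collapsing.gene_association(gcm, select_group(records, case_label),
                                          non_ndd)
        res.to_csv(args.results_dir / fname, sep="\t", index=False)
        hits = res[res["suggestive"]]
        print(f"\n{case_label} vs non-NDD: {len(hits)} suggestive modifier genes")
        for _, row in hits.iterrows():
            ci = f"({row['ci_low']:.2f}-{row['ci_high']:.2f})"
            print(f"  {row['gene']:16s} carriers {row['n_carriers_case']}/"
                  f"{row['n_carriers_comparison']}  OR={row['odds_ratio']:.2f} "
                  f"{ci}  p={row['p']:.3f}  {row['direction']}")
        print(f"wrote {args.results_dir / fname}")


if __name__ == "__main__":
    main()
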