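"""Homozygosity profiling.

Computes per-individual homozygosity rates genome-wide and within every
context, stratified by MAF class (all / common / rare / ultra-rare), and
summarizes the genome-wide group comparison: one-way ANOVA across the
phenotype groups and the pairwise NDD-vs-cancer contrast.
"""

import argparse
from pathlib import Path

from homburden import burden
from homburden import homozygosity as hz
from homburden import io_model as io
from homburden.io_model import ALL, COMMON, GENOME_WIDE, RARE, ULTRA_RARE


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = args.results_dir / "cohort"
    gm = io.read_genotypes(args.results_dir / "genotypes_qc.tsv", "raw_table")
    annots = io.read_annotation(bundle / "annotation.tsv")
    beds = sorted(bundle.glob("*.bed"))
    contexts = io.read_contexts(
        gmt_path=bundle / "contexts.gmt",
        bed_path=beds[0] if beds else None,
    )
    records = io.read_phenotypes(bundle / "phenotypes.tsv")

    prof = hz.profile_cohort(gm, annots, [GENOME_WIDE, *contexts],
                             [ALL, COMMON, RARE, ULTRA_RARE])
    out = args.results_dir / "profiles.tsv"
    prof.to_csv(out, sep="\t", index=False)

    rates = prof[(prof["context"] == GENOME_WIDE) & (prof["stratum"] == ALL)]
    rates = rates.set_index("sample_id")["rate"]
    groups = {g: rates.reindex(burden.select_group(records, g)).dropna()
              for g in ("NDD", "CANCER", "OTHER")}
    anova_p = burden.anova_screen(*groups.values())
    pairwise = burden.overall_burden_test(groups["NDD"], groups["CANCER"],
                                          "NDD", "CANCER")
    print(f"profiles: {len(prof)} rows "
          f"({prof['context'].nunique()} contexts x {prof['stratum'].nunique()} strata)")
    for g, r in groups.items():
        print(f"  genome-wide mean rate, {g:6s}: {r.mean():.4f}")
    print(f"one-way ANOVA across groups: p = {anova_p:.3f}")
    print(f"NDD vs cancer ({pairwise.test_used}): p = {pairwise.p_raw:.3f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
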