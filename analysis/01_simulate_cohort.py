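"""Generate the study cohort.

Draws a synthetic SNP-array cohort at the modeled study conditions:
117 NDD participants (57 of them ASD, 14 cancer-comorbid), 175 cancer,
84 other; gene-set contexts for the biological processes under test with
homozygosity inflation planted where the analysis is expected to find it
(inflammatory genes in NDD; differentiation, chromatin-regulation and
pathogenic-CNV regions in ASD); and three carrier genes planted with the
case-only qualifying-variant patterns the collapsing stage must recover.
Writes the plain-text file bundle consumed by the later steps.
"""

import argparse
from pathlib import Path

from homburden import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-variants", type=int, default=20_000)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = sd.SimConfig(
        seed=args.seed,
        n_variants=args.n_variants,
        contexts=[
            sd.PlantedContext("differentiation", "ASD", 0.04, n_genes=30),
            sd.PlantedContext("inflammatory", "NDD", 0.05, n_genes=30),
            sd.PlantedContext("chromatin_regulation", "ASD", 0.04, n_genes=30),
            sd.PlantedContext("candidate_ndd", "NDD", 0.0, n_genes=40),
            sd.PlantedContext("highconf_ndd", "ASD", 0.0, n_genes=25),
            sd.PlantedContext("cell_death", "CANCER", 0.0, n_genes=30),
            sd.PlantedContext("pathogenic_cnv", "ASD", 0.04, n_genes=25,
                              kind="regionset"),
        ],
        planted_qv_genes=[
            sd.PlantedQvGene("MODIFIER_NDD_A", "NDD", 3),
            sd.PlantedQvGene("MODIFIER_ASD_A", "ASD", 2),
            sd.PlantedQvGene("MODIFIER_ASD_B", "ASD", 2),
        ],
    )
    cohort = sd.generate_cohort(cfg)
    out = args.results_dir / "cohort"
    paths = sd.write_fixture_bundle(cohort, out, force=True)

    print(f"cohort: {cohort.genotypes.n_samples} samples x "
          f"{cohort.genotypes.n_variants} variants (seed {args.seed})")
    print(f"contexts: {[c.name for c in cohort.contexts]}")
    print(f"wrote bundle to {out}/ ({', '.join(p.name for p in paths.values())})")


if __name__ == "__main__":
    main()
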