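"""Phenotype prediction.

Builds the four burden-based logistic models: NDD and ASD versus non-NDD
(sex added after predictor selection) and their cancer-free subsets
versus the cancer group (no sex adjustment, given the opposed sex skews
of those groups). Predictors are the common-variant context burdens;
selection is backward stepwise by AIC; internal validation is a
stratified 80/20 split with 10-fold CV on the training portion and
accuracy/ROC/AUC on the hold-out.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from homburden import io_model as io
from homburden import predict
from homburden.io_model import COMMON


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = args.results_dir / "cohort"
    prof = pd.read_csv(args.results_dir / "profiles.tsv", sep="\t")
    records = io.read_phenotypes(bundle / "phenotypes.tsv")

    contexts = ["differentiation", "inflammatory", "chromatin_regulation",
                "candidate_ndd", "highconf_ndd", "pathogenic_cnv"]
    models = [
        ("NDD_vs_non_NDD", "NDD", "non_NDD", True),
        ("ASD_vs_non_NDD", "ASD", "non_NDD", True),
        ("NDD_only_vs_cancer", "NDD_only", "CANCER", False),
        ("ASD_only_vs_cancer", "ASD_only", "CANCER", False),
    ]
    reports = {}
    for name, case, comparison, include_sex in models:
        X, y = predict.burden_design(prof, records, case, comparison,
                                     contexts, COMMON)
        report = predict.validate(X, y, name, include_sex, seed=args.seed)
        reports[name] = report.to_dict()
        report.roc_points.to_csv(args.results_dir / f"roc_{name}.tsv",
                                 sep="\t", index=False)
        sex_note = "+sex" if include_sex else "no sex"
        print(f"{name} ({sex_note}): selected {report.selected or '[intercept only]'}")
        print(f"  hold-out accuracy {report.accuracy:.0%}, AUC {report.auc:.0%}; "
              f"CV fold-mean accuracy {report.cv_accuracy:.0%}"
              + (f"  [{','.join(report.flags)}]" if report.flags else ""))

    out = args.results_dir / "model_reports.json"
    with open(out, "w") as fh:
        json.dump(reports, fh, indent=2)
    print(f"wrote {out} and per-model ROC tables")


if __name__ == "__main__":
    main()
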