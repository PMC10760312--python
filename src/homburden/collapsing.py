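"""Qualifying-variant filtration and non-weighted gene-level collapsing.

Two filtration stages select qualifying variants (QVs) from an annotated,
QC'd genotype matrix:

* primary: homozygous non-reference calls at *common* variants whose
  consequence is exonic or splice-relevant intronic;
* secondary: additionally deleterious/damaging — SIFT < 0.05 and/or
  PolyPhen > 0.9 (the disjunctive reading is the default; a conjunctive
  mode is available). Absent scores satisfy neither arm.

QVs are collapsed per gene into a binary carrier indicator (1 = at least
one QV in that gene), and each gene's carrier counts are tested between a
case and a comparison group with the exact 2x2 engine. Genes with
unadjusted p < 0.05 are flagged suggestive; BH-adjusted p-values are
emitted for transparency but not thresholded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import exact_assoc
from .homozygosity import align_annotation
from .io_model import COMMON, EXONIC, INTRONIC_SPLICE, GenotypeMatrix, in_stratum

logger = logging.getLogger(__name__)

SIFT_DELETERIOUS_MAX = 0.05
POLYPHEN_DAMAGING_MIN = 0.9
SUGGESTIVE_ALPHA = 0.05

PRIMARY_CONSEQUENCES = (EXONIC, INTRONIC_SPLICE)


@dataclass
class QualifyingPairs:
    """Qualifying (sample, variant) pairs over a fixed matrix/annotation.

    ``pairs`` is an (n_pairs, 2) int array of (sample_index, variant_index);
    ``aligned`` is the annotation frame aligned to the matrix's variant
    order (used by the later stages).
    """

    gm: GenotypeMatrix
    aligned: pd.DataFrame
    pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def primary_filter(annots: pd.DataFrame, gm: GenotypeMatrix) -> QualifyingPairs:
    """Stage 1: homozygous calls at common exonic/splice-intronic variants."""
    aligned = align_annotation(gm, annots)
    eligible = (
        np.asarray(in_stratum(aligned["af_effective"], COMMON))
        & aligned["consequence"].isin(PRIMARY_CONSEQUENCES).to_numpy()
    )
    hom = (gm.calls == 2) & eligible[np.newaxis, :]
    pairs = np.argwhere(hom)
    return QualifyingPairs(gm, aligned, pairs)


def secondary_filter(qp: QualifyingPairs, and_mode: bool = False) -> QualifyingPairs:
    """Stage 2: keep pairs whose variant is SIFT-deleterious and/or
    PolyPhen-damaging. ``and_mode`` requires both arms; absent scores
    fail the arm they belong to."""
    sift = qp.aligned["sift"].to_numpy(dtype=float)
    poly = qp.aligned["polyphen"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        sift_hit = (~np.isnan(sift)) & (sift < SIFT_DELETERIOUS_MAX)
        poly_hit = (~np.isnan(poly)) & (poly > POLYPHEN_DAMAGING_MIN)
    keep_variant = (sift_hit & poly_hit) if and_mode else (sift_hit | poly_hit)
    if len(qp.pairs) == 0:
        return QualifyingPairs(qp.gm, qp.aligned, qp.pairs)
    keep = keep_variant[qp.pairs[:, 1]]
    return QualifyingPairs(qp.gm, qp.aligned, qp.pairs[keep])


def collapse(qp: QualifyingPairs) -> pd.DataFrame:
    """Binary samples x genes carrier matrix (1 = >= 1 QV in the gene).

    Variants without a gene symbol are dropped with a warning; only genes
    with at least one carrier get a column. Idempotent under duplicated
    input pairs.
    """
    genes = qp.aligned["gene"]
    carrier: dict[str, set[int]] = {}
    n_dropped = 0
    for si, vi in qp.pairs:
        gene = genes.iat[vi]
        if pd.isna(gene):
            n_dropped += 1
            continue
        for g in str(gene).split("|"):  # overlapping annotations: every listed gene
            carrier.setdefault(g, set()).add(int(si))
    if n_dropped:
        logger.warning("dropped %d qualifying pairs with no gene symbol", n_dropped)
    out = pd.DataFrame(
        0, index=pd.Index(qp.gm.sample_ids, name="sample_id"),
        columns=sorted(carrier), dtype=np.int8,
    )
    for g, samples in carrier.items():
        out.iloc[list(samples), out.columns.get_loc(g)] = 1
    return out


def gene_association(
    gcm: pd.DataFrame,
    case_ids,
    comparison_ids,
    confidence: float = exact_assoc.DEFAULT_CONFIDENCE,
) -> pd.DataFrame:
    """Per-gene exact association of carrier status with group membership.

    Returns one row per gene: carrier counts and percentages, conditional
    OR with exact CI, two-sided p, directionality, and the suggestive
    flag (unadjusted p < 0.05). Zero cells are handled exactly (infinite
    or zero OR with a finite one-sided bound).
    """
    case_ids, comparison_ids = list(case_ids), list(comparison_ids)
    if set(case_ids) & set(comparison_ids):
        raise ValueError("case and comparison groups overlap")
    cases = gcm.reindex(case_ids).fillna(0)
    comps = gcm.reindex(comparison_ids).fillna(0)
    n_case, n_comp = len(case_ids), len(comparison_ids)
    rows = []
    for gene in gcm.columns:
        a = int(cases[gene].sum())
        c = int(comps[gene].sum())
        t = exact_assoc.Table2x2(a, n_case - a, c, n_comp - c)
        res = exact_assoc.associate(t, confidence)
        cross = a * (n_comp - c) - c * (n_case - a)
        direction = "positive" if cross > 0 else ("negative" if cross < 0 else "none")
        rows.append(
            {
                "gene": gene,
                "n_carriers_case": a,
                "pct_case": 100 * a / n_case if n_case else float("nan"),
                "n_carriers_comparison": c,
                "pct_comparison": 100 * c / n_comp if n_comp else float("nan"),
                "odds_ratio": res.or_cmle,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p_two_sided,
                "direction": direction,
                "suggestive": res.p_two_sided < SUGGESTIVE_ALPHA,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "n_carriers_case", "pct_case", "n_carriers_comparison",
                 "pct_comparison", "odds_ratio", "ci_low", "ci_high", "p",
                 "direction", "suggestive"],
    )
    if len(out):
        from .burden import adjust_bh

        out.insert(out.columns.get_loc("p") + 1, "p_bh", adjust_bh(out["p"]))
    return out.sort_values("p", kind="stable").reset_index(drop=True)
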