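"""Per-individual homozygosity rates, genome-wide and context-restricted.

The statistic is the count of homozygous non-reference calls divided by
the number of non-missing genotyped loci, computed over an eligible
variant set: the intersection of a context (gene set, interval set, or
the whole genome) with a minor-allele-frequency stratum. Homozygous
*reference* calls never count toward the numerator; missing calls are
excluded from both numerator and denominator, so denominators differ
between samples. A sample with no genotyped eligible locus gets an NA
rate (propagated, never zero-filled).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_model import (
    ALL,
    GENESET,
    GENOME_WIDE,
    MISSING,
    REGIONSET,
    ContextSet,
    GenotypeMatrix,
    in_stratum,
)

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["sample_id", "context", "stratum", "n_hom", "n_genotyped", "rate"]


def homozygosity_rate(calls) -> float:
    """Rate for one sample's eligible calls: (# calls == 2) / (# non-missing).

    Returns NaN when every call is missing (or the call vector is empty).
    """
    calls = np.asarray(calls)
    n_genotyped = int((calls != MISSING).sum())
    if n_genotyped == 0:
        return float("nan")
    return float((calls == 2).sum() / n_genotyped)


def align_annotation(gm: GenotypeMatrix, annots: pd.DataFrame) -> pd.DataFrame:
    """Annotation rows aligned to the matrix's variant order.

    Variants without an annotation record are treated as gene-less with
    effective frequency 0 (non-reported).
    """
    key_cols = ["chrom", "pos", "ref", "alt"]
    aligned = gm.variants.merge(annots, on=key_cols, how="left", validate="1:1")
    aligned["af_effective"] = aligned["af_effective"].fillna(0.0)
    return aligned


def context_mask(aligned: pd.DataFrame, context) -> np.ndarray:
    """Boolean eligibility by context membership over aligned annotation rows.

    Gene sets match by annotated symbol (case-sensitive, trimmed);
    interval sets use 0-based half-open coordinates, so a 1-based variant
    position ``pos`` is inside (start, end] iff ``start < pos <= end``.
    """
    n = len(aligned)
    if context is None or context == GENOME_WIDE:
        return np.ones(n, dtype=bool)
    if not isinstance(context, ContextSet):
        raise TypeError("context must be a ContextSet or GENOME_WIDE")
    if context.kind == GENESET:
        return aligned["gene"].isin(context.genes).to_numpy()
    assert context.kind == REGIONSET
    mask = np.zeros(n, dtype=bool)
    chrom = aligned["chrom"].to_numpy()
    pos = aligned["pos"].to_numpy()
    for c, start, end in context.intervals:
        mask |= (chrom == c) & (start < pos) & (pos <= end)
    return mask


def eligible_variants(
    aligned: pd.DataFrame, context=GENOME_WIDE, stratum: str = ALL
) -> np.ndarray:
    """Boolean mask of variants eligible under context x stratum."""
    return context_mask(aligned, context) & np.asarray(
        in_stratum(aligned["af_effective"], stratum)
    )


def profile_cohort(
    gm: GenotypeMatrix,
    annots: pd.DataFrame,
    contexts=(GENOME_WIDE,),
    strata=(ALL,),
) -> pd.DataFrame:
    """Homozygosity profile: one row per sample x context x stratum.

    ``contexts`` may mix :data:`GENOME_WIDE` and ContextSets. Expects a
    QC'd matrix. Contexts with zero eligible genotyped loci yield NA
    rates with a logged warning.
    """
    aligned = align_annotation(gm, annots)
    hom = gm.calls == 2
    genotyped = gm.calls != MISSING
    rows = []
    for context in contexts:
        cname = context if isinstance(context, str) else context.name
        cmask = context_mask(aligned, context)
        for stratum in strata:
            mask = cmask & np.asarray(in_stratum(aligned["af_effective"], stratum))
            n_hom = hom[:, mask].sum(axis=1)
            n_gt = genotyped[:, mask].sum(axis=1)
            if not mask.any():
                logger.warning("context %r x stratum %r has no eligible variants",
                               cname, stratum)
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(n_gt > 0, n_hom / np.maximum(n_gt, 1), np.nan)
            for i, sid in enumerate(gm.sample_ids):
                rows.append((sid, cname, stratum, int(n_hom[i]), int(n_gt[i]),
                             float(rate[i])))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
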