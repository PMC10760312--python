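"""Sample- and variant-level genotype quality control.

Mirrors a standard SNP-array QC pass: a pre-stage variant filter (call
rate < 98% or exact Hardy-Weinberg p <= 0.001), then sample filters
(missingness > 3%, heterozygosity-rate outliers at >= 3 SD from the
cohort mean, optional sex-discordance predicate), then a final variant
missingness filter (> 5%) with the post-sample-QC denominator.

The HWE test is the exact conditional test: given the observed allele
counts, the heterozygote count is enumerated over its parity-constrained
support and the two-sided p sums the probabilities of all configurations
no more likely than the observed one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io_model import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

# removal reason codes
CALL_RATE = "call_rate"
HWE = "hwe"
MISSINGNESS = "missingness"
HET_OUTLIER = "het_outlier"
SEX_DISCORDANT = "sex_discordant"


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds (all rates are fractions in [0,1])."""

    snp_call_rate_prestage: float = 0.98
    hwe_p_max: float = 0.001
    sample_missing_max: float = 0.03
    snp_missing_max: float = 0.05
    het_sd_cut: float = 3.0

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_prestage", "sample_missing_max", "snp_missing_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0 < self.hwe_p_max <= 1:
            raise ValueError("hwe_p_max must be in (0,1]")
        if self.het_sd_cut <= 0:
            raise ValueError("het_sd_cut must be positive")


@dataclass
class QcReport:
    """Removed samples/variants with reason codes, plus per-reason counts."""

    samples_removed: dict = field(default_factory=dict)  # id -> reason
    variants_removed: dict = field(default_factory=dict)  # key tuple -> reason

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for reason in list(self.samples_removed.values()) + list(self.variants_removed.values()):
            out[reason] = out.get(reason, 0) + 1
        return out

    def merge(self, other: "QcReport") -> "QcReport":
        merged = QcReport(dict(self.samples_removed), dict(self.variants_removed))
        merged.samples_removed.update(other.samples_removed)
        merged.variants_removed.update(other.variants_removed)
        return merged

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"axis": "sample", "item": str(k), "reason": v}
            for k, v in self.samples_removed.items()
        ] + [
            {"axis": "variant", "item": ":".join(map(str, k)), "reason": v}
            for k, v in self.variants_removed.items()
        ]
        return pd.DataFrame(rows, columns=["axis", "item", "reason"])


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Enumerates every heterozygote count compatible with the observed
    allele counts (same parity as the minor-allele count) and sums the
    probabilities of configurations with probability <= the observed
    one. Monomorphic sites return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no individuals")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    log_probs = _hwe_log_probs(n, n_minor, hets)
    obs = log_probs[hets == n_het][0]
    return float(min(1.0, math.exp(logsumexp(log_probs[log_probs <= obs + 1e-12]))))


def _hwe_log_probs(n: int, n_minor: int, hets: np.ndarray) -> np.ndarray:
    """Log P(het-count) conditional on n diploids carrying n_minor minor alleles."""
    n_major = 2 * n - n_minor
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    lw = (
        hets * math.log(2)
        + gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
    )
    # constant terms: gammaln(n_minor+1)+gammaln(n_major+1)-gammaln(2n+1)
    return lw - logsumexp(lw)


def _variant_callrate(gm: GenotypeMatrix) -> np.ndarray:
    return (gm.calls != MISSING).mean(axis=0)


def _variant_hwe_p(gm: GenotypeMatrix) -> np.ndarray:
    ps = np.empty(gm.n_variants)
    for j in range(gm.n_variants):
        col = gm.calls[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        ps[j] = 1.0 if n0 + n1 + n2 == 0 else hwe_exact_test(n0, n1, n2)
    return ps


def filter_variants(
    gm: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    stage: str = "pre",
) -> tuple[GenotypeMatrix, QcReport]:
    """Variant filters for one QC stage.

    ``stage="pre"`` removes variants with call rate below
    ``snp_call_rate_prestage`` or exact HWE p <= ``hwe_p_max``;
    ``stage="final"`` removes variants with missingness above
    ``snp_missing_max`` (run after sample QC so the denominator reflects
    the retained samples).
    """
    if gm.n_variants == 0 or gm.n_samples == 0:
        return gm, QcReport()
    report = QcReport()
    keys = gm.variant_keys()
    keep = np.ones(gm.n_variants, dtype=bool)
    if stage == "pre":
        callrate = _variant_callrate(gm)
        low = callrate < thresholds.snp_call_rate_prestage
        hwe_p = _variant_hwe_p(gm)
        off_hwe = hwe_p <= thresholds.hwe_p_max
        for j in np.nonzero(low)[0]:
            report.variants_removed[keys[j]] = CALL_RATE
        for j in np.nonzero(off_hwe & ~low)[0]:
            report.variants_removed[keys[j]] = HWE
        keep = ~(low | off_hwe)
    elif stage == "final":
        missing = 1.0 - _variant_callrate(gm)
        drop = missing > thresholds.snp_missing_max
        for j in np.nonzero(drop)[0]:
            report.variants_removed[keys[j]] = MISSINGNESS
        keep = ~drop
    else:
        raise ValueError(f"unknown stage {stage!r}")
    if not keep.all():
        logger.info("variant QC (%s): removed %d of %d", stage,
                    int((~keep).sum()), gm.n_variants)
    return gm.subset(variant_mask=keep), report


def filter_samples(
    gm: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    sex_discordant: Callable[[str], bool] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Sample filters: missingness, heterozygosity outliers, sex discordance.

    The heterozygosity rate is the fraction of non-missing calls equal
    to 1; samples whose distance from the cohort mean is >= ``het_sd_cut``
    sample standard deviations are removed (with SD 0 no sample is an
    outlier). ``sex_discordant`` is an injectable predicate on sample id,
    since sex-chromosome markers are outside the modeled array.
    """
    if gm.n_samples < 3:
        raise ValueError("sample QC needs at least 3 samples (SD undefined)")
    report = QcReport()
    nonmiss = (gm.calls != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het_rate = np.where(nonmiss > 0,
                            (gm.calls == 1).sum(axis=1) / np.maximum(nonmiss, 1), np.nan)
    miss_rate = 1.0 - nonmiss / gm.n_variants if gm.n_variants else np.zeros(gm.n_samples)

    drop = np.zeros(gm.n_samples, dtype=bool)
    for i in np.nonzero(miss_rate > thresholds.sample_missing_max)[0]:
        report.samples_removed[gm.sample_ids[i]] = MISSINGNESS
        drop[i] = True

    mean = float(np.nanmean(het_rate))
    sd = float(np.nanstd(het_rate, ddof=1))
    if sd > 0:
        outlier = np.abs(het_rate - mean) >= thresholds.het_sd_cut * sd
        for i in np.nonzero(outlier & ~drop)[0]:
            report.samples_removed[gm.sample_ids[i]] = HET_OUTLIER
            drop[i] = True

    if sex_discordant is not None:
        for i, sid in enumerate(gm.sample_ids):
            if not drop[i] and sex_discordant(sid):
                report.samples_removed[sid] = SEX_DISCORDANT
                drop[i] = True

    return gm.subset(sample_mask=~drop), report


def run_qc(
    gm: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    sex_discordant: Callable[[str], bool] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC pass: pre-stage variant filters, sample filters, final
    variant missingness filter. Idempotent: re-running on its own output
    removes nothing."""
    gm1, rep1 = filter_variants(gm, thresholds, stage="pre")
    gm2, rep2 = filter_samples(gm1, thresholds, sex_discordant)
    gm3, rep3 = filter_variants(gm2, thresholds, stage="final")
    return gm3, rep1.merge(rep2).merge(rep3)
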