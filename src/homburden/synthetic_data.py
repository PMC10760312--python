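"""Synthetic SNP-array cohorts with the statistical structure the
pipeline assumes.

The generator emulates the study design end-to-end with no external
data: four phenotype groups sized like the real cohort (117 NDD of whom
57 ASD, 175 cancer, 84 other, with 14 NDD cancer-comorbid of whom 3
ASD), Table-style sex ratios and variant-classification mixes, a
biallelic autosomal genotype matrix drawn under Hardy-Weinberg
equilibrium from a configurable MAF spectrum, uniform missingness, and
two kinds of planted effects:

* *context inflation*: for samples of one group and the variants of one
  named context, the homozygous-non-reference probability is raised from
  q^2 to q^2 + delta (heterozygote mass reduced accordingly); an
  inbreeding-style mode instead uses P(hom-alt) = q^2 + F q(1-q).
* *qualifying-variant planting*: a designated common, exonic,
  SIFT-deleterious variant is made homozygous in exactly ``n_carriers``
  samples of one group and non-homozygous everywhere else — the
  infinite-odds-ratio carrier pattern.

Annotations expose the simulation's true allele frequency on the
genome-frequency track (optionally perturbed for robustness tests), so
MAF stratification in tests is exact.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_model
from .burden import select_group
from .io_model import (
    ASD,
    BENIGN_LB,
    CANCER,
    EXONIC,
    FEMALE,
    GENESET,
    INTERGENIC,
    INTRONIC_OTHER,
    INTRONIC_SPLICE,
    MALE,
    MISSING,
    NDD,
    OTHER,
    OTHER_GROUP,
    PATHOGENIC_LP,
    REGIONSET,
    VUS,
    ContextSet,
    GenotypeMatrix,
    SampleRecord,
)

N_AUTOSOMES = 22

# consequence mix for unplanted variants (roughly array-like: mostly
# intronic/intergenic, a manageable exonic fraction)
CONSEQUENCE_PROBS = {
    EXONIC: 0.30,
    INTRONIC_SPLICE: 0.05,
    INTRONIC_OTHER: 0.45,
    INTERGENIC: 0.15,
    OTHER: 0.05,
}


@dataclass(frozen=True)
class PlantedContext:
    """A named context whose member genes get hom-alt inflation ``delta``
    in ``group`` (delta 0 plants nothing: a null context)."""

    name: str
    group: str
    delta: float
    n_genes: int = 20
    kind: str = GENESET

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass(frozen=True)
class PlantedQvGene:
    """A gene with exactly ``n_carriers`` qualifying-variant carriers in
    ``group`` and none outside it."""

    gene: str
    group: str
    n_carriers: int


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the modeled cohort: group sizes and sex ratios from
    the demographics table, a MAF spectrum with 60% common / 30% rare /
    10% ultra-rare variants, and 0.2% missingness.
    """

    seed: int = 0
    group_sizes: dict = field(
        default_factory=lambda: {NDD: 117, ASD: 57, CANCER: 175, OTHER_GROUP: 84}
    )
    comorbid_cancer_in_ndd: int = 14
    comorbid_cancer_in_asd: int = 3
    sex_male_fraction: dict = field(
        default_factory=lambda: {NDD: 0.69, ASD: 0.74, CANCER: 0.18, OTHER_GROUP: 0.54}
    )
    variant_class_counts: dict = field(
        default_factory=lambda: {
            NDD: {PATHOGENIC_LP: 108, BENIGN_LB: 0, VUS: 9},
            CANCER: {PATHOGENIC_LP: 131, BENIGN_LB: 11, VUS: 33},
            OTHER_GROUP: {PATHOGENIC_LP: 73, BENIGN_LB: 1, VUS: 10},
        }
    )
    n_variants: int = 20_000
    variants_per_gene: int = 10
    # (weight, af_low, af_high) uniform mixture components
    maf_spectrum: tuple = ((0.60, 0.01, 0.50), (0.30, 1e-4, 0.01), (0.10, 0.0, 1e-4))
    missing_rate: float = 0.002
    contexts: list = field(default_factory=list)  # PlantedContext
    planted_qv_genes: list = field(default_factory=list)  # PlantedQvGene
    use_inbreeding_f: bool = False
    af_annotation_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if self.group_sizes[ASD] > self.group_sizes[NDD]:
            raise ValueError("ASD must be a subset of NDD")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate in [0,1)")
        w = sum(c[0] for c in self.maf_spectrum)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError("maf_spectrum weights must sum to 1")


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    annotations: pd.DataFrame
    contexts: list
    records: list
    config: SimConfig


def _allocate_counts(total: int, counts: dict) -> list[str]:
    """Expand target counts (scaled to ``total`` by largest remainder)."""
    labels = list(counts)
    base = sum(counts.values())
    exact = {k: counts[k] * total / base for k in labels}
    floors = {k: int(math.floor(v)) for k, v in exact.items()}
    short = total - sum(floors.values())
    for k in sorted(labels, key=lambda k: exact[k] - floors[k], reverse=True)[:short]:
        floors[k] += 1
    out: list[str] = []
    for k in labels:
        out.extend([k] * floors[k])
    return out


def _build_records(cfg: SimConfig) -> list[SampleRecord]:
    n_ndd = cfg.group_sizes[NDD]
    n_asd = cfg.group_sizes[ASD]
    n_cancer = cfg.group_sizes[CANCER]
    n_other = cfg.group_sizes[OTHER_GROUP]
    records: list[SampleRecord] = []

    # NDD block: first n_asd are ASD; cancer comorbidity spread over the
    # first comorbid_cancer_in_asd ASD samples and the first non-ASD slots
    ndd_classes = _allocate_counts(n_ndd, cfg.variant_class_counts[NDD])
    male_asd = round(cfg.sex_male_fraction[ASD] * n_asd)
    male_ndd_rest = round(cfg.sex_male_fraction[NDD] * n_ndd) - male_asd
    comorbid_rest = cfg.comorbid_cancer_in_ndd - cfg.comorbid_cancer_in_asd
    for i in range(n_ndd):
        is_asd = i < n_asd
        flags = {NDD}
        if is_asd:
            flags.add(ASD)
            sex = MALE if i < male_asd else FEMALE
            if i < cfg.comorbid_cancer_in_asd:
                flags.add(CANCER)
        else:
            j = i - n_asd
            sex = MALE if j < male_ndd_rest else FEMALE
            if j < comorbid_rest:
                flags.add(CANCER)
        records.append(SampleRecord(f"S{i + 1:04d}", sex, frozenset(flags),
                                    ndd_classes[i]))

    offset = n_ndd
    for label, n in ((CANCER, n_cancer), (OTHER_GROUP, n_other)):
        classes = _allocate_counts(n, cfg.variant_class_counts[label])
        n_male = round(cfg.sex_male_fraction[label] * n)
        for i in range(n):
            records.append(
                SampleRecord(
                    f"S{offset + i + 1:04d}",
                    MALE if i < n_male else FEMALE,
                    frozenset({label}),
                    classes[i],
                )
            )
        offset += n
    return records


def build_demographics(cfg: SimConfig | None = None) -> list[SampleRecord]:
    """Deterministic sample records for the configured demographics.

    With the default configuration this reproduces the modeled cohort's
    composition exactly: 117 NDD (57 ASD, 14 cancer-comorbid of whom 3
    ASD), 175 cancer, 84 other, with the per-group sex and
    variant-classification counts."""
    return _build_records(cfg or SimConfig())


def _draw_afs(rng: np.random.Generator, n: int, spectrum) -> np.ndarray:
    weights = np.array([c[0] for c in spectrum])
    comp = rng.choice(len(spectrum), size=n, p=weights)
    lo = np.array([c[1] for c in spectrum])[comp]
    hi = np.array([c[2] for c in spectrum])[comp]
    return lo + (hi - lo) * rng.random(n)


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Draw one cohort under ``cfg``; deterministic given the config."""
    rng = np.random.default_rng(cfg.seed)
    records = _build_records(cfg)
    n_samples = len(records)
    m = cfg.n_variants

    # gene map: contiguous blocks of variants_per_gene variants
    n_genes = m // cfg.variants_per_gene
    gene_of_variant = np.minimum(
        np.arange(m) // cfg.variants_per_gene, n_genes - 1
    )
    gene_names = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)

    # reserve genes for planted QV genes (one each, renamed), then contexts
    next_gene = 0
    qv_gene_index: dict[str, int] = {}
    for qv in cfg.planted_qv_genes:
        gene_names[next_gene] = qv.gene
        qv_gene_index[qv.gene] = next_gene
        next_gene += 1
    context_gene_idx: dict[str, np.ndarray] = {}
    for ctx in cfg.contexts:
        if next_gene + ctx.n_genes > n_genes:
            raise ValueError("not enough genes to allocate planted contexts")
        context_gene_idx[ctx.name] = np.arange(next_gene, next_gene + ctx.n_genes)
        next_gene += ctx.n_genes

    # coordinates: equal-size chromosome blocks, increasing 1-based positions
    chrom = np.arange(m) * N_AUTOSOMES // m + 1
    pos = np.zeros(m, dtype=int)
    for c in range(1, N_AUTOSOMES + 1):
        idx = np.nonzero(chrom == c)[0]
        pos[idx] = 10_001 + 1_000 * np.arange(len(idx))
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}
    )

    # allele frequencies; planted-context genes are forced common so that
    # hom-alt inflation has heterozygote mass to draw from
    q = _draw_afs(rng, m, cfg.maf_spectrum)
    for ctx in cfg.contexts:
        if ctx.delta > 0:
            vmask = np.isin(gene_of_variant, context_gene_idx[ctx.name])
            q[vmask] = 0.05 + 0.45 * rng.random(int(vmask.sum()))
            max_delta = float((2 * q[vmask] * (1 - q[vmask])).min())
            if not cfg.use_inbreeding_f and ctx.delta > max_delta:
                raise ValueError(
                    f"context {ctx.name!r}: delta {ctx.delta} exceeds available "
                    f"heterozygote mass {max_delta:.3f}"
                )

    # consequences / functional scores
    cons_labels = list(CONSEQUENCE_PROBS)
    consequence = rng.choice(
        cons_labels, size=m, p=list(CONSEQUENCE_PROBS.values())
    ).astype(object)
    sift = np.full(m, np.nan)
    polyphen = np.full(m, np.nan)
    exonic_mask = consequence == EXONIC
    sift[exonic_mask] = rng.random(int(exonic_mask.sum()))
    polyphen[exonic_mask] = rng.random(int(exonic_mask.sum()))

    # genotypes under HWE
    p_hom_ref = (1 - q) ** 2
    p_het = 2 * q * (1 - q)
    u = rng.random((n_samples, m))
    calls = (u > p_hom_ref).astype(np.int8) + (u > p_hom_ref + p_het).astype(np.int8)

    # planted context inflation
    id_index = {r.id: i for i, r in enumerate(records)}
    for ctx in cfg.contexts:
        if ctx.delta == 0:
            continue
        vmask = np.isin(gene_of_variant, context_gene_idx[ctx.name])
        smask = np.zeros(n_samples, dtype=bool)
        smask[[id_index[i] for i in select_group(records, ctx.group)]] = True
        qv_ = q[vmask]
        if cfg.use_inbreeding_f:
            f = ctx.delta
            p2 = qv_**2 + f * qv_ * (1 - qv_)
            p1 = 2 * qv_ * (1 - qv_) * (1 - f)
        else:
            p2 = qv_**2 + ctx.delta
            p1 = 2 * qv_ * (1 - qv_) - ctx.delta
        p0 = 1 - p1 - p2
        u2 = rng.random((int(smask.sum()), int(vmask.sum())))
        block = (u2 > p0).astype(np.int8) + (u2 > p0 + p1).astype(np.int8)
        calls[np.ix_(smask, vmask)] = block

    # missingness
    if cfg.missing_rate > 0:
        calls[rng.random((n_samples, m)) < cfg.missing_rate] = MISSING

    # QV planting (last, so carriers are never masked or missing)
    for qv in cfg.planted_qv_genes:
        gi = qv_gene_index[qv.gene]
        gene_variants = np.nonzero(gene_of_variant == gi)[0]
        vqv = int(gene_variants[0])
        # the qualifying variant: common, exonic, deleterious
        q[vqv] = 0.1
        consequence[vqv] = EXONIC
        sift[vqv], polyphen[vqv] = 0.01, 0.95
        # the gene's other variants cannot qualify
        for v in gene_variants[1:]:
            consequence[v] = INTRONIC_OTHER
            sift[v], polyphen[v] = np.nan, np.nan
        members = select_group(records, qv.group)
        if qv.n_carriers > len(members):
            raise ValueError(
                f"gene {qv.gene!r}: cannot plant {qv.n_carriers} carriers in "
                f"group {qv.group!r} of size {len(members)}"
            )
        carrier_rows = rng.choice(
            [id_index[i] for i in members], size=qv.n_carriers, replace=False
        )
        # non-carriers: hom-ref/het only, conditional HWE proportions
        p_het_cond = 2 * 0.1 * 0.9 / (1 - 0.1**2)
        calls[:, vqv] = (rng.random(n_samples) < p_het_cond).astype(np.int8)
        calls[carrier_rows, vqv] = 2

    # annotations (genome track carries the true q, optionally perturbed)
    af_ann = q.copy()
    if cfg.af_annotation_noise_sd > 0:
        af_ann = np.clip(
            af_ann + rng.normal(0, cfg.af_annotation_noise_sd, m), 0.0, 1.0
        )
    gene_col = gene_names[gene_of_variant].copy()
    gene_col[consequence == INTERGENIC] = pd.NA
    annotations = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "pos": variants["pos"],
            "ref": variants["ref"],
            "alt": variants["alt"],
            "af_genome": af_ann,
            "af_exome": np.nan,
            "af_effective": af_ann,
            "gene": gene_col,
            "consequence": consequence,
            "sift": sift,
            "polyphen": polyphen,
        }
    )

    # materialize context sets
    contexts: list[ContextSet] = []
    for ctx in cfg.contexts:
        gidx = context_gene_idx[ctx.name]
        if ctx.kind == GENESET:
            contexts.append(
                ContextSet(ctx.name, GENESET, genes=frozenset(gene_names[gidx]))
            )
        else:
            vmask = np.isin(gene_of_variant, gidx)
            intervals = []
            for c in np.unique(chrom[vmask]):
                sel = vmask & (chrom == c)
                intervals.append((int(c), int(pos[sel].min() - 1), int(pos[sel].max())))
            contexts.append(ContextSet(ctx.name, REGIONSET, intervals=tuple(intervals)))

    gm = GenotypeMatrix([r.id for r in records], variants, calls)
    return Cohort(gm, annotations, contexts, records, cfg)


def write_fixture_bundle(cohort: Cohort, out_dir, force: bool = False) -> dict:
    """Write the cohort as a plain-text file bundle + manifest.

    Refuses a non-empty directory unless ``force``. Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")

    gm = cohort.genotypes
    paths = {
        "genotypes": out / "genotypes.tsv",
        "map": out / "variants.map",
        "annotation": out / "annotation.tsv",
        "gmt": out / "contexts.gmt",
        "phenotypes": out / "phenotypes.tsv",
        "manifest": out / "manifest.json",
    }
    io_model.write_raw_table(gm, paths["genotypes"])
    with open(paths["map"], "w") as fh:
        for (chrom, pos, ref, alt) in gm.variant_keys():
            fh.write(f"{chrom}\tv{chrom}_{pos}\t0\t{pos}\t{ref}\t{alt}\n")
    io_model.write_annotation(cohort.annotations, paths["annotation"])
    io_model.write_gmt(cohort.contexts, paths["gmt"])
    regionsets = [c for c in cohort.contexts if c.kind == REGIONSET]
    if regionsets:
        # BED carries no set name, so the file is named after the context
        paths["bed"] = out / f"{regionsets[0].name}.bed"
        io_model.write_bed(regionsets[0], paths["bed"])
    io_model.write_phenotypes(cohort.records, paths["phenotypes"])
    io_model.write_manifest(dataclasses.asdict(cohort.config), paths["manifest"])
    return paths
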