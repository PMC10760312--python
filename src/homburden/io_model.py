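"""Domain types and file I/O for the homozygosity-burden pipeline.

This module is the single place where coordinate and encoding conventions
are fixed:

* Genotype calls count non-reference alleles: 0 (hom-ref), 1 (het),
  2 (hom-alt), :data:`MISSING` (-1) for failed or half-missing calls.
  "Homozygous non-reference" is exactly ``call == 2``.
* Variant positions are 1-based; BED intervals are 0-based half-open, so a
  variant at 1-based position ``pos`` lies in interval ``(start, end)`` iff
  ``start < pos <= end``.
* Allele-frequency fallback: the genome-sequencing track is consulted
  first, then the exome track, and variants absent from both are treated
  as frequency 0 (hence ultra-rare).
* MAF strata: common (AF >= 0.01), rare (AF < 0.01), ultra-rare
  (AF < 1e-4, a subset of rare).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

# consequence categories, most severe first
EXONIC = "exonic"
INTRONIC_SPLICE = "intronic_splice"
INTRONIC_OTHER = "intronic_other"
INTERGENIC = "intergenic"
OTHER = "other"
CONSEQUENCE_SEVERITY: tuple[str, ...] = (
    EXONIC,
    INTRONIC_SPLICE,
    INTRONIC_OTHER,
    OTHER,
    INTERGENIC,
)

# MAF strata
ALL = "all"
COMMON = "common"
RARE = "rare"
ULTRA_RARE = "ultra_rare"
STRATA: tuple[str, ...] = (ALL, COMMON, RARE, ULTRA_RARE)
COMMON_MIN_AF = 0.01
ULTRA_RARE_MAX_AF = 1e-4

GENOME_WIDE = "genome_wide"

MALE = "male"
FEMALE = "female"

NDD = "NDD"
ASD = "ASD"
CANCER = "CANCER"
OTHER_GROUP = "OTHER"

PATHOGENIC_LP = "pathogenic_lp"
BENIGN_LB = "benign_lb"
VUS = "vus"

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "af_genome",
    "af_exome",
    "af_effective",
    "gene",
    "consequence",
    "sift",
    "polyphen",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants, values in {0, 1, 2, MISSING}.

    ``variants`` is a DataFrame with columns chrom, pos, ref, alt (one row
    per variant, in file order); ``calls`` is an int8 array of shape
    (n_samples, n_variants).
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")
        keys = self.variant_keys()
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    # -- accessors ----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[tuple]:
        return list(
            zip(
                self.variants["chrom"].tolist(),
                self.variants["pos"].tolist(),
                self.variants["ref"].tolist(),
                self.variants["alt"].tolist(),
            )
        )

    def key_strings(self) -> list[str]:
        return [f"{c}:{p}:{r}:{a}" for c, p, r, a in self.variant_keys()]

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        vm = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask, bool)
        return GenotypeMatrix(
            sample_ids=[s for s, keep in zip(self.sample_ids, sm) if keep],
            variants=self.variants.loc[vm].reset_index(drop=True),
            calls=self.calls[np.ix_(sm, vm)].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variant_keys() == other.variant_keys()
            and np.array_equal(self.calls, other.calls)
        )


def _parse_key_string(token: str) -> tuple:
    parts = token.split(":")
    if len(parts) != 4:
        raise ParseError(f"bad variant key {token!r}; expected chrom:pos:ref:alt")
    chrom, pos, ref, alt = parts
    return int(chrom), int(pos), ref, alt


def read_genotypes(path, dialect: str, map_path=None) -> GenotypeMatrix:
    """Read a genotype matrix from one of the supported text dialects.

    Parameters
    ----------
    path:
        The genotype file (.ped, raw table TSV, or VCF).
    dialect:
        One of ``"ped_map"``, ``"raw_table"``, ``"vcf"``.
    map_path:
        For ``ped_map``: a 6-column map (chrom, id, cM, pos, ref, alt);
        defaults to ``path`` with the suffix replaced by ``.map``.
    """
    path = Path(path)
    if dialect == "raw_table":
        return _read_raw_table(path)
    if dialect == "ped_map":
        if map_path is None:
            map_path = path.with_suffix(".map")
        return _read_ped_map(path, Path(map_path))
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_raw_table(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "sample_id":
        raise ParseError(f"{path}: first raw-table column must be 'sample_id'")
    # header parsed by hand: pandas would silently mangle duplicate keys
    keys = [_parse_key_string(c) for c in header[1:]]
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, dtype={0: str})
    if df.shape[1] != len(header):
        raise ParseError(f"{path}: ragged raw table")
    calls = df.iloc[:, 1:].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    variants = pd.DataFrame(keys, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(df.iloc[:, 0].astype(str).tolist(), variants, calls)


def write_raw_table(gm: GenotypeMatrix, path) -> None:
    """Write the documented RAW_TABLE TSV (cells 0/1/2/NA); round-trips exactly."""
    cols = gm.key_strings()
    body = gm.calls.astype(object)
    df = pd.DataFrame(body, columns=cols)
    df = df.mask(df == MISSING, other=pd.NA)
    df.insert(0, "sample_id", gm.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_ped_map(ped_path: Path, map_path: Path) -> GenotypeMatrix:
    try:
        mp = pd.read_csv(
            map_path,
            sep=r"\s+",
            header=None,
            names=["chrom", "id", "cm", "pos", "ref", "alt"],
            dtype={"ref": str, "alt": str},
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ParseError(f"{map_path}: cannot parse 6-column map ({exc})") from exc
    if mp[["ref", "alt"]].isna().any().any():
        raise ParseError(f"{map_path}: map must carry ref and alt alleles (6 columns)")
    variants = pd.DataFrame(
        {"chrom": mp["chrom"].astype(int), "pos": mp["pos"].astype(int),
         "ref": mp["ref"], "alt": mp["alt"]}
    )
    m = len(variants)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            calls = np.empty(m, dtype=np.int8)
            for j in range(m):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                calls[j] = _ped_call(a1, a2, variants["ref"].iat[j],
                                     variants["alt"].iat[j], ped_path, lineno)
            rows.append(calls)
    return GenotypeMatrix(sample_ids, variants, np.vstack(rows) if rows else
                          np.empty((0, m), dtype=np.int8))


def _ped_call(a1: str, a2: str, ref: str, alt: str, path, lineno: int) -> int:
    if a1 == "0" or a2 == "0":
        return MISSING  # PLINK missing-allele code; half-missing also maps here
    count = 0
    for a in (a1, a2):
        if a == alt:
            count += 1
        elif a != ref:
            raise ParseError(f"{path}:{lineno}: allele {a!r} matches neither "
                             f"ref {ref!r} nor alt {alt!r}")
    return count


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    keys: list[tuple] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}; "
                             "split upstream")
        keys.append((int(rec.CHROM.removeprefix("chr")), rec.POS, rec.REF, rec.ALT[0]))
        gt = rec.gt_types.astype(np.int8)  # gts012: 0,1,2 and 3=unknown
        gt[gt == 3] = MISSING
        cols.append(gt)
    variants = pd.DataFrame(keys, columns=["chrom", "pos", "ref", "alt"])
    calls = (np.column_stack(cols) if cols
             else np.empty((len(sample_ids), 0), dtype=np.int8))
    return GenotypeMatrix(sample_ids, variants, calls)


# ---------------------------------------------------------------------------
# variant annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant's annotation record (frequencies, gene, consequence, scores)."""

    chrom: int
    pos: int
    ref: str
    alt: str
    af_genome: float | None = None
    af_exome: float | None = None
    gene: str | None = None
    consequence: str = INTERGENIC
    sift: float | None = None
    polyphen: float | None = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def af_effective(self) -> float:
        return resolve_af_effective(self.af_genome, self.af_exome)


def resolve_af_effective(af_genome, af_exome) -> float:
    """Genome-track frequency first, exome second, else 0 (non-reported)."""
    if af_genome is not None and not pd.isna(af_genome):
        return float(af_genome)
    if af_exome is not None and not pd.isna(af_exome):
        return float(af_exome)
    return 0.0


def collapse_consequence(raw: str) -> str:
    """Collapse a (possibly multi-token) consequence string to one category.

    Tokens are ';'- or ','-separated; the most severe category wins under
    the fixed order exonic > intronic_splice > intronic_other > other >
    intergenic. Unknown tokens map to ``other`` with a logged warning.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return INTERGENIC
    tokens = [t.strip().lower() for t in str(raw).replace(",", ";").split(";") if t.strip()]
    if not tokens:
        return INTERGENIC
    cats = []
    for t in tokens:
        if t in CONSEQUENCE_SEVERITY:
            cats.append(t)
        else:
            logger.warning("unknown consequence token %r mapped to 'other'", t)
            cats.append(OTHER)
    return min(cats, key=CONSEQUENCE_SEVERITY.index)


def maf_stratum(af: float) -> str:
    """Assign the partitioning stratum: common (>= 0.01) or rare (< 0.01)."""
    return COMMON if af >= COMMON_MIN_AF else RARE


def in_stratum(af, stratum: str):
    """Vectorized stratum membership; ultra-rare is a subset of rare."""
    af = np.asarray(af, dtype=float)
    if stratum == ALL:
        return np.ones_like(af, dtype=bool)
    if stratum == COMMON:
        return af >= COMMON_MIN_AF
    if stratum == RARE:
        return af < COMMON_MIN_AF
    if stratum == ULTRA_RARE:
        return af < ULTRA_RARE_MAX_AF
    raise ValueError(f"unknown stratum {stratum!r}")


def read_annotation(path) -> pd.DataFrame:
    """Read the annotation TSV into a standardized frame.

    Required headers: chrom, pos, ref, alt, af_genome, af_exome, gene,
    consequence, sift, polyphen (empty cells = absent). The returned frame
    additionally carries ``af_effective`` resolved by the fallback rule and
    a single collapsed ``consequence`` category per variant.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str, "gene": str})
    required = {"chrom", "pos", "ref", "alt", "af_genome", "af_exome",
                "gene", "consequence", "sift", "polyphen"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    for col in ("af_genome", "af_exome", "sift", "polyphen"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if ((vals < 0) | (vals > 1)).any():
            raise ParseError(f"{path}: {col} outside [0,1]")
        df[col] = vals
    df["gene"] = df["gene"].str.strip()
    df.loc[df["gene"] == "", "gene"] = pd.NA
    df["consequence"] = df["consequence"].map(collapse_consequence)
    df["af_effective"] = [
        resolve_af_effective(g, e) for g, e in zip(df["af_genome"], df["af_exome"])
    ]
    return df[ANNOTATION_COLUMNS].astype({"chrom": int, "pos": int})


def write_annotation(df: pd.DataFrame, path) -> None:
    cols = [c for c in ANNOTATION_COLUMNS if c != "af_effective"]
    df[cols].to_csv(path, sep="\t", index=False)


def annotation_frame(variants: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    """Build a standardized annotation frame from dataclass records."""
    rows = [
        {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "af_genome": v.af_genome, "af_exome": v.af_exome,
            "af_effective": v.af_effective, "gene": v.gene,
            "consequence": v.consequence, "sift": v.sift, "polyphen": v.polyphen,
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# contexts (gene sets and region sets)
# ---------------------------------------------------------------------------

GENESET = "geneset"
REGIONSET = "regionset"


@dataclass(frozen=True)
class ContextSet:
    """A named restriction of the genome: gene symbols or genomic intervals.

    Intervals are (chrom, start, end) with 0-based half-open coordinates.
    """

    name: str
    kind: str
    genes: frozenset = field(default_factory=frozenset)
    intervals: tuple = ()

    def __post_init__(self) -> None:
        if self.kind == GENESET:
            if not self.genes:
                raise ValueError(f"gene set {self.name!r} has no members")
        elif self.kind == REGIONSET:
            if not self.intervals:
                raise ValueError(f"region set {self.name!r} has no intervals")
            for chrom, start, end in self.intervals:
                if start >= end:
                    raise ValueError(
                        f"region set {self.name!r}: degenerate interval "
                        f"{chrom}:{start}-{end}"
                    )
        else:
            raise ValueError(f"unknown context kind {self.kind!r}")


def read_gmt(path) -> list[ContextSet]:
    """One gene-set context per GMT row (name, description, members...)."""
    contexts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT row needs name, "
                                 "description and at least one member")
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: empty member list")
            contexts.append(ContextSet(name=fields[0], kind=GENESET, genes=members))
    return contexts


def read_bed(path, name: str | None = None) -> ContextSet:
    """All intervals of one BED file form a single region-set context."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED row needs chrom, start, end")
            chrom = int(fields[0].removeprefix("chr"))
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            intervals.append((chrom, start, end))
    if not intervals:
        raise ParseError(f"{path}: no intervals")
    return ContextSet(name=name or path.stem, kind=REGIONSET, intervals=tuple(intervals))


def read_contexts(gmt_path=None, bed_path=None) -> list[ContextSet]:
    contexts: list[ContextSet] = []
    if gmt_path is not None:
        contexts.extend(read_gmt(gmt_path))
    if bed_path is not None:
        contexts.append(read_bed(bed_path))
    return contexts


def write_gmt(contexts: Sequence[ContextSet], path) -> None:
    with open(path, "w") as fh:
        for ctx in contexts:
            if ctx.kind != GENESET:
                continue
            fh.write("\t".join([ctx.name, "na", *sorted(ctx.genes)]) + "\n")


def write_bed(context: ContextSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in context.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# samples / phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """One participant: sex, phenotype-group flags, and variant classification.

    Group semantics mirror the cohort design: ASD is a subset of NDD (with or
    without cancer comorbidity); CANCER and OTHER samples carry no
    neurodevelopmental flags; OTHER excludes CANCER.
    """

    id: str
    sex: str
    groups: frozenset
    variant_class: str = VUS

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sample {self.id}: sex must be male/female")
        g = self.groups
        bad = g - {NDD, ASD, CANCER, OTHER_GROUP}
        if bad:
            raise ValueError(f"sample {self.id}: unknown groups {sorted(bad)}")
        if ASD in g and NDD not in g:
            raise ValueError(f"sample {self.id}: ASD implies NDD")
        if OTHER_GROUP in g and g != {OTHER_GROUP}:
            raise ValueError(f"sample {self.id}: OTHER excludes all other groups")
        if CANCER in g and NDD not in g and g != {CANCER}:
            raise ValueError(f"sample {self.id}: inconsistent group flags")
        if self.variant_class not in (PATHOGENIC_LP, BENIGN_LB, VUS):
            raise ValueError(f"sample {self.id}: bad variant_class")

    @property
    def is_ndd(self) -> bool:
        return NDD in self.groups

    @property
    def is_asd(self) -> bool:
        return ASD in self.groups

    @property
    def has_cancer(self) -> bool:
        return CANCER in self.groups


def read_phenotypes(path) -> list[SampleRecord]:
    """Read the phenotype TSV (headers id, sex, group, variant_class).

    The ``group`` cell is a '+'-joined flag set, e.g. ``NDD``, ``ASD``
    (implying NDD), ``NDD+CANCER``, ``CANCER``, ``OTHER``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sex", "group", "variant_class"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: phenotype table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        flags = {t.strip().upper() for t in str(row.group).split("+") if t.strip()}
        if ASD in flags:
            flags.add(NDD)
        records.append(
            SampleRecord(
                id=str(row.id),
                sex=row.sex.strip().lower(),
                groups=frozenset(flags),
                variant_class=row.variant_class.strip().lower(),
            )
        )
    if len({r.id for r in records}) != len(records):
        raise ParseError(f"{path}: duplicate sample ids")
    return records


def write_phenotypes(records: Sequence[SampleRecord], path) -> None:
    def group_cell(r: SampleRecord) -> str:
        if OTHER_GROUP in r.groups:
            return OTHER_GROUP
        flags = []
        if r.is_asd:
            flags.append(ASD)
        elif r.is_ndd:
            flags.append(NDD)
        if r.has_cancer:
            flags.append(CANCER)
        return "+".join(flags)

    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sex": [r.sex for r in records],
            "group": [group_cell(r) for r in records],
            "variant_class": [r.variant_class for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_manifest(config_dict: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(config_dict, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
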