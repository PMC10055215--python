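"""Ingest a multi-sample VCF plus annotations and build per-pair genotype counts.

The pipeline mirrors how a reference cohort is turned into phasing evidence:
variants are loaded from a pre-split biallelic VCF together with a TSV of
functional annotations and per-group allele numbers; genotypes failing quality
control are set missing; variants are filtered to rare (global AF < 5%)
coding / flanking-intronic / UTR sites; all unordered pairs of variants within
a gene are enumerated; and for each pair the 3x3 joint genotype table is
tabulated per sample group, excluding individuals missing either genotype.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pairmodel import (PairGenotypeCounts, Thresholds, TwoLocusHaplotypeModel,
                        HAPLOTYPES)

logger = logging.getLogger(__name__)

__all__ = [
    "BiallelicVariant",
    "VariantPair",
    "VariantDataset",
    "load_variants",
    "apply_genotype_qc",
    "filter_variants",
    "enumerate_pairs",
    "count_pair_genotypes",
    "flag_singleton_singleton",
    "build_pair_table",
    "DEFAULT_CLASSES",
]

#: consequence classes admitted by the default rare-coding filter
DEFAULT_CLASSES = frozenset(
    {"pLoF", "missense", "synonymous", "flanking_intronic", "utr"}
)

_SEX_CONTIGS = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class BiallelicVariant:
    """One biallelic site with its annotation and per-group allele counts."""

    contig: str
    position: int
    ref: str
    alt: str
    gene_id: str
    consequence_class: str = "other"
    revel: float | None = None
    methylation: float | None = None
    context: str | None = None
    # group -> (AC, AN)
    af_by_group: dict = field(default_factory=dict)
    annotated: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be 1-based and >= 1")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("ref and alt must be non-empty and different")
        for group, (ac, an) in self.af_by_group.items():
            if ac > an:
                raise ValueError(f"AC > AN for group {group!r} at {self.key}")

    @property
    def key(self) -> str:
        return f"{self.contig}-{self.position}-{self.ref}-{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def af(self, group: str = "global") -> float | None:
        pair = self.af_by_group.get(group)
        if pair is None:
            return None
        ac, an = pair
        return ac / an if an else None

    def ac(self, group: str = "global") -> int | None:
        pair = self.af_by_group.get(group)
        return None if pair is None else pair[0]

    @property
    def sort_key(self) -> tuple:
        return (self.contig, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class VariantPair:
    """Canonically ordered pair of variants sharing a gene."""

    v1: BiallelicVariant
    v2: BiallelicVariant

    def __post_init__(self) -> None:
        if self.v1.gene_id != self.v2.gene_id:
            raise ValueError("pair must share a gene")
        if not self.v1.sort_key < self.v2.sort_key:
            raise ValueError("pair must be canonically ordered (v1 < v2)")

    @property
    def gene_id(self) -> str:
        return self.v1.gene_id

    @property
    def distance_bp(self) -> int | None:
        if self.v1.contig != self.v2.contig:
            return None
        return self.v2.position - self.v1.position

    @property
    def key(self) -> tuple[str, str]:
        return (self.v1.key, self.v2.key)


@dataclass
class VariantDataset:
    """Variants + sample-by-variant genotype matrix and FORMAT metrics.

    ``genotypes`` holds minor (ALT) allele dosages in {0, 1, 2} with -1 for
    missing. ``gq``/``dp``/``ad_ref``/``ad_alt`` are parallel arrays (or None
    when the VCF lacked the fields).
    """

    variants: list[BiallelicVariant]
    genotypes: np.ndarray
    samples: list[str]
    group_of: dict[str, str]
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self._col = {v.key: i for i, v in enumerate(self.variants)}
        self._row = {s: i for i, s in enumerate(self.samples)}

    def column(self, variant: BiallelicVariant | str) -> int:
        key = variant if isinstance(variant, str) else variant.key
        return self._col[key]

    def row(self, sample_id: str) -> int:
        return self._row[sample_id]

    def sample_indices(self, group: str | None = None) -> np.ndarray:
        """Row indices for one group; ``None``/"all" selects every sample."""
        if group is None or group == "all":
            return np.arange(len(self.samples))
        idx = [i for i, s in enumerate(self.samples)
               if self.group_of.get(s) == group]
        return np.asarray(idx, dtype=int)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_of.values()))


def _read_annotation(path) -> tuple[dict, list[str]]:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str})
    required = {"chrom", "pos", "ref", "alt", "gene_id", "consequence_class"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    groups = sorted(c[3:] for c in ann.columns if c.startswith("AC_"))
    table: dict = {}
    for row in ann.itertuples(index=False):
        key = f"{row.chrom}-{row.pos}-{row.ref}-{row.alt}"
        if key in table:
            raise ValueError(f"annotation key collision for {key}")
        af_by_group = {}
        for g in groups:
            ac = getattr(row, f"AC_{g}")
            an = getattr(row, f"AN_{g}")
            if pd.notna(ac) and pd.notna(an):
                af_by_group[g] = (int(ac), int(an))
        table[key] = {
            "gene_id": row.gene_id,
            "consequence_class": row.consequence_class,
            "revel": None if pd.isna(getattr(row, "revel", np.nan)) else float(row.revel),
            "methylation": None if pd.isna(getattr(row, "methylation", np.nan)) else float(row.methylation),
            "context": None if pd.isna(getattr(row, "context", np.nan)) else str(row.context),
            "af_by_group": af_by_group,
        }
    return table, groups


def load_variants(vcf_path, annotation_path=None, group_path=None) -> VariantDataset:
    """Read a pre-split biallelic VCF and join annotations and group labels.

    Multiallelic records are a hard error: the minor/major dichotomy behind
    the 3x3 genotype table requires biallelic sites, so split them upstream
    (e.g. ``bcftools norm -m -``). Unannotated variants are retained with
    ``consequence_class='other'`` and ``annotated=False``.
    """
    from cyvcf2 import VCF

    annotation, _ = _read_annotation(annotation_path) if annotation_path else ({}, [])
    group_of: dict[str, str] = {}
    if group_path is not None:
        gdf = pd.read_csv(group_path, sep="\t")
        group_of = dict(zip(gdf["sample_id"], gdf["group"]))

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    variants: list[BiallelicVariant] = []
    geno_cols, gq_cols, dp_cols, ad_r_cols, ad_a_cols = [], [], [], [], []
    header = vcf.raw_header
    has_fmt = all(f"##FORMAT=<ID={f}," in header for f in ("GQ", "DP", "AD"))
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split to biallelic records first"
            )
        key = f"{rec.CHROM}-{rec.POS}-{rec.REF}-{rec.ALT[0]}"
        ann = annotation.get(key)
        if ann is None:
            logger.warning("variant %s has no annotation; kept with class 'other'", key)
            variants.append(BiallelicVariant(rec.CHROM, rec.POS, rec.REF,
                                             rec.ALT[0], gene_id="", annotated=False))
        else:
            variants.append(BiallelicVariant(rec.CHROM, rec.POS, rec.REF,
                                             rec.ALT[0], **ann))
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = rec.gt_types.astype(np.int16)
        gt[gt == 3] = -1
        geno_cols.append(gt)
        if has_fmt:
            # raw FORMAT fields (gt_depths would recompute DP from AD)
            gq_cols.append(rec.format("GQ").reshape(-1).astype(np.float32))
            dp_cols.append(rec.format("DP").reshape(-1).astype(np.int32))
            ad = rec.format("AD").astype(np.int32)
            ad_r_cols.append(ad[:, 0])
            ad_a_cols.append(ad[:, 1])

    genotypes = (np.column_stack(geno_cols) if geno_cols
                 else np.zeros((len(samples), 0), dtype=np.int16))
    kw = {}
    if has_fmt and gq_cols:
        kw = {"gq": np.column_stack(gq_cols), "dp": np.column_stack(dp_cols),
              "ad_ref": np.column_stack(ad_r_cols), "ad_alt": np.column_stack(ad_a_cols)}
    if not group_of:
        group_of = {s: "all" for s in samples}
    return VariantDataset(variants, genotypes, samples, group_of, **kw)


def apply_genotype_qc(dataset: VariantDataset, gq_min: float = 20,
                      dp_min: float = 10, ab_min: float = 0.2,
                      on_missing_format: str = "warn") -> VariantDataset:
    """Set low-quality genotypes missing.

    A genotype is kept only when GQ > ``gq_min`` and DP > ``dp_min`` (strict
    inequalities), and heterozygotes additionally require allele balance
    (alt reads / total reads) > ``ab_min``. When the VCF lacked FORMAT fields
    the behaviour is governed by ``on_missing_format``: "warn" skips the
    filter, "error" raises.
    """
    if dataset.gq is None:
        if on_missing_format == "error":
            raise ValueError("VCF lacks GQ/DP/AD FORMAT fields; cannot apply genotype QC")
        warnings.warn("VCF lacks GQ/DP/AD FORMAT fields; genotype QC skipped")
        return dataset
    g = dataset.genotypes.copy()
    present = g >= 0
    fail = present & ((dataset.gq <= gq_min) | (dataset.dp <= dp_min))
    with np.errstate(divide="ignore", invalid="ignore"):
        total = dataset.ad_ref + dataset.ad_alt
        ab = np.where(total > 0, dataset.ad_alt / np.maximum(total, 1), 0.0)
    fail |= present & (g == 1) & (ab <= ab_min)
    g[fail] = -1
    return replace(dataset, variants=dataset.variants, genotypes=g,
                   samples=dataset.samples, group_of=dataset.group_of,
                   gq=dataset.gq, dp=dataset.dp,
                   ad_ref=dataset.ad_ref, ad_alt=dataset.ad_alt)


def filter_variants(variants, af_max: float = 0.05,
                    allowed_classes=DEFAULT_CLASSES,
                    population: str | None = None,
                    exclude_sex_chromosomes: bool = False) -> list[BiallelicVariant]:
    """Rare-variant filter: global AF < ``af_max`` (strict) and admitted class.

    When ``population`` is given its AF must also be < ``af_max``. Variants
    without a global AF entry are dropped.
    """
    out = []
    for v in variants:
        if exclude_sex_chromosomes and v.contig in _SEX_CONTIGS:
            continue
        if v.consequence_class not in allowed_classes:
            continue
        af = v.af("global")
        if af is None or af >= af_max:
            continue
        if population is not None:
            paf = v.af(population)
            if paf is not None and paf >= af_max:
                continue
        out.append(v)
    return out


def enumerate_pairs(variants) -> list[VariantPair]:
    """All unordered within-gene pairs; a variant in two genes pairs in each."""
    by_gene: dict[str, list[BiallelicVariant]] = {}
    for v in variants:
        if v.gene_id:
            by_gene.setdefault(v.gene_id, []).append(v)
    pairs = []
    for gene in sorted(by_gene):
        vs = sorted(by_gene[gene], key=lambda v: v.sort_key)
        for v1, v2 in itertools.combinations(vs, 2):
            pairs.append(VariantPair(v1, v2))
    return pairs


def count_pair_genotypes(pair: VariantPair, dataset: VariantDataset,
                         group: str | None = None) -> PairGenotypeCounts:
    """3x3 joint genotype table for one pair over one sample group.

    Individuals with a missing genotype at either site are excluded from every
    cell and from ``n_total``.
    """
    rows = dataset.sample_indices(group)
    g1 = dataset.genotypes[rows, dataset.column(pair.v1)]
    g2 = dataset.genotypes[rows, dataset.column(pair.v2)]
    ok = (g1 >= 0) & (g2 >= 0)
    table = np.bincount(g1[ok] * 3 + g2[ok], minlength=9).reshape(3, 3)
    return PairGenotypeCounts(table)


def flag_singleton_singleton(counts: PairGenotypeCounts) -> bool:
    """True when both variants are group singletons carried by one individual."""
    return counts.is_singleton_singleton_same_individual()


def build_pair_table(dataset: VariantDataset, pairs=None,
                     group: str | None = None,
                     thresholds: Thresholds | None = None,
                     af_max: float = 0.05,
                     allowed_classes=DEFAULT_CLASSES,
                     require_cocarrier: bool = True,
                     tol: float = 1e-7, max_iter: int = 1000) -> pd.DataFrame:
    """Phase every within-gene variant pair: counts, EM estimates, Ptrans, label.

    One row per pair with the nine genotype counts, four estimated haplotype
    counts and frequencies, Ptrans and the classification under ``thresholds``.
    By default only pairs carried jointly by at least one individual are
    emitted (``require_cocarrier``), mirroring a manageable downloadable table.
    """
    thresholds = thresholds or Thresholds()
    if pairs is None:
        kept = filter_variants(dataset.variants, af_max=af_max,
                               allowed_classes=allowed_classes,
                               population=None if group in (None, "all") else group)
        pairs = enumerate_pairs(kept)
    rows = []
    cell_names = ["AABB", "AaBB", "aaBB", "AABb", "AaBb", "aaBb",
                  "AAbb", "Aabb", "aabb"]
    cell_idx = [(0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (2, 1),
                (0, 2), (1, 2), (2, 2)]
    for pair in pairs:
        counts = count_pair_genotypes(pair, dataset, group)
        if counts.n_total == 0:
            continue
        both_carried = int(counts.table[1:, 1:].sum()) > 0
        if require_cocarrier and not both_carried:
            continue
        est = TwoLocusHaplotypeModel(counts).fit(tol=tol, max_iter=max_iter)
        pred = est.classify(
            thresholds,
            singleton_same_individual=counts.is_singleton_singleton_same_individual(),
            both_present=counts.allele_count_a > 0 and counts.allele_count_b > 0,
        )
        row = {
            "gene_id": pair.gene_id,
            "variant1": pair.v1.key,
            "variant2": pair.v2.key,
            "contig": pair.v1.contig,
            "distance_bp": pair.distance_bp,
            "group": group or "all",
            "n_total": counts.n_total,
        }
        for name, idx in zip(cell_names, cell_idx):
            row[f"n_{name}"] = int(counts.table[idx])
        for name, cnt, f in zip(HAPLOTYPES, est.expected_haplotype_counts, est.freqs):
            row[f"hap_count_{name}"] = cnt
            row[f"freq_{name}"] = f
        row["em_iterations"] = est.iterations
        row["em_converged"] = est.converged
        row["p_trans"] = np.nan if pred.p_trans is None else pred.p_trans
        row["label"] = pred.label
        row["reason"] = pred.reason or ""
        rows.append(row)
    return pd.DataFrame(rows)
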