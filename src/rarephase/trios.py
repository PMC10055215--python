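"""Gold-standard phasing of variant pairs by Mendelian transmission in trios.

For a child heterozygous at a site, the parent of origin of the minor allele
is determined whenever Mendelian transmission forces it: a parent can donate a
minor allele only if they carry one, and a major allele only if they carry
one. Sites heterozygous in all three members are ambiguous and yield no phase
information. A child doubly heterozygous for a variant pair is then in cis
when both minor alleles came from the same parent and in trans when they came
from different parents; pairs with an ambiguous, Mendelian-violating or
missing site are unphaseable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcf_pairs import VariantDataset, VariantPair

logger = logging.getLogger(__name__)

__all__ = [
    "Trio",
    "TrioPhaseCall",
    "read_pedigree",
    "phase_site_by_transmission",
    "phase_pair_by_transmission",
    "phase_trio_pairs",
    "evaluate_against_trios",
]

MATERNAL = "maternal"
PATERNAL = "paternal"
AMBIGUOUS = "ambiguous"
VIOLATION = "violation"
MISSING = "missing"


@dataclass(frozen=True)
class Trio:
    child_id: str
    mother_id: str
    father_id: str
    family_id: str = ""

    def __post_init__(self) -> None:
        if len({self.child_id, self.mother_id, self.father_id}) != 3:
            raise ValueError("trio members must be three distinct samples")


@dataclass(frozen=True)
class TrioPhaseCall:
    """Transmission-resolved phase for one double-het pair in one child."""

    pair: VariantPair
    child_id: str
    truth_label: str  # cis | trans | unphaseable
    origin1: str
    origin2: str


def read_pedigree(path) -> list[Trio]:
    """Parse a 6-column PED file into complete trios.

    Rows whose father or mother id is "0" (founders) are skipped; a child id
    appearing twice is an error.
    """
    trios: list[Trio] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"malformed PED line {lineno}: expected 6 columns, "
                                 f"got {len(fields)}")
            fam, iid, father, mother = fields[0], fields[1], fields[2], fields[3]
            if father == "0" or mother == "0":
                logger.debug("PED line %d: %s has missing parent(s); skipped", lineno, iid)
                continue
            if iid in seen:
                raise ValueError(f"duplicated child id {iid!r} at PED line {lineno}")
            seen.add(iid)
            trios.append(Trio(child_id=iid, mother_id=mother, father_id=father,
                              family_id=fam))
    if not trios:
        logger.warning("pedigree %s contains no complete trios", path)
    return trios


def phase_site_by_transmission(child_gt: int, mother_gt: int,
                               father_gt: int) -> str:
    """Parental origin of the child's single minor allele at one site.

    Genotypes are minor-allele dosages (0/1/2, -1 missing); the child must be
    heterozygous. Returns ``maternal``/``paternal`` when transmission is
    forced, ``ambiguous`` when both assignments are Mendelian-consistent
    (notably the all-heterozygous trio), ``violation`` when neither is, and
    ``missing`` when a parental genotype is missing.
    """
    if child_gt != 1:
        raise ValueError(f"child genotype must be heterozygous (1), got {child_gt}")
    if mother_gt < 0 or father_gt < 0:
        return MISSING
    maternal_ok = mother_gt >= 1 and father_gt <= 1  # mother gives a, father A
    paternal_ok = father_gt >= 1 and mother_gt <= 1
    if maternal_ok and paternal_ok:
        return AMBIGUOUS
    if maternal_ok:
        return MATERNAL
    if paternal_ok:
        return PATERNAL
    return VIOLATION


def phase_pair_by_transmission(pair: VariantPair, trio: Trio,
                               dataset: VariantDataset) -> TrioPhaseCall:
    """Phase one double-het pair in a trio child.

    cis when both minor alleles share a parental origin, trans when they
    differ; unphaseable when either site is ambiguous, violating or missing.
    """
    c = dataset.row(trio.child_id)
    m = dataset.row(trio.mother_id)
    f = dataset.row(trio.father_id)
    j1, j2 = dataset.column(pair.v1), dataset.column(pair.v2)
    g = dataset.genotypes
    if g[c, j1] != 1 or g[c, j2] != 1:
        raise ValueError("child must be heterozygous at both sites of the pair")
    o1 = phase_site_by_transmission(1, int(g[m, j1]), int(g[f, j1]))
    o2 = phase_site_by_transmission(1, int(g[m, j2]), int(g[f, j2]))
    if o1 in (MATERNAL, PATERNAL) and o2 in (MATERNAL, PATERNAL):
        label = "cis" if o1 == o2 else "trans"
    else:
        label = "unphaseable"
    return TrioPhaseCall(pair, trio.child_id, label, o1, o2)


def _phase_parental_pair(pair: VariantPair, trio: Trio, parent: str,
                         dataset: VariantDataset) -> TrioPhaseCall | None:
    """Phase a parent's own double-het pair through the transmitted haplotype.

    The allele the parent transmitted at each site is deducible when exactly
    one choice is consistent with the child's genotype and the other parent's
    possible contributions; the parent's two haplotypes are then the
    transmitted alleles and their complements.
    """
    p = dataset.row(getattr(trio, f"{parent}_id"))
    other = dataset.row(trio.father_id if parent == "mother" else trio.mother_id)
    c = dataset.row(trio.child_id)
    g = dataset.genotypes
    j1, j2 = dataset.column(pair.v1), dataset.column(pair.v2)
    if g[p, j1] != 1 or g[p, j2] != 1:
        return None
    transmitted = []
    for j in (j1, j2):
        cg, og = int(g[c, j]), int(g[other, j])
        if cg < 0 or og < 0:
            transmitted.append(None)
            continue
        options = [x for x in (0, 1)
                   if 0 <= cg - x <= 1 and (og >= 1 if cg - x == 1 else og <= 1)]
        transmitted.append(options[0] if len(options) == 1 else None)
    if transmitted[0] is None or transmitted[1] is None:
        return TrioPhaseCall(pair, trio.child_id, "unphaseable", AMBIGUOUS, AMBIGUOUS)
    label = "cis" if transmitted[0] == transmitted[1] else "trans"
    return TrioPhaseCall(pair, trio.child_id, label, parent, parent)


def phase_trio_pairs(dataset: VariantDataset, trios, pairs,
                     unit: str = "child_pairs") -> pd.DataFrame:
    """Phase-by-transmission over many trios and pairs.

    ``unit="child_pairs"`` (default) phases every pair at which a child is
    doubly heterozygous. ``unit="parental_pairs"`` instead phases pairs at
    which a parent is doubly heterozygous, through the haplotype that parent
    transmitted to the child. Returns a tidy frame with one row per
    (pair, individual) occurrence.
    """
    if unit not in ("child_pairs", "parental_pairs"):
        raise ValueError(f"unknown unit {unit!r}")
    g = dataset.genotypes
    rows = []
    for trio in trios:
        if unit == "child_pairs":
            c = dataset.row(trio.child_id)
            for pair in pairs:
                j1, j2 = dataset.column(pair.v1), dataset.column(pair.v2)
                if g[c, j1] == 1 and g[c, j2] == 1:
                    call = phase_pair_by_transmission(pair, trio, dataset)
                    rows.append(call)
        else:
            for parent in ("mother", "father"):
                for pair in pairs:
                    call = _phase_parental_pair(pair, trio, parent, dataset)
                    if call is not None:
                        rows.append(call)
    return pd.DataFrame(
        {
            "variant1": [c.pair.v1.key for c in rows],
            "variant2": [c.pair.v2.key for c in rows],
            "gene_id": [c.pair.gene_id for c in rows],
            "contig": [c.pair.v1.contig for c in rows],
            "individual": [c.child_id for c in rows],
            "truth_label": [c.truth_label for c in rows],
            "origin1": [c.origin1 for c in rows],
            "origin2": [c.origin2 for c in rows],
        }
    )


def evaluate_against_trios(records: pd.DataFrame,
                           unit: str = "unique_pair") -> dict:
    """Score phase predictions against trio truth.

    ``records`` needs columns ``truth_label`` (cis/trans/unphaseable),
    ``predicted_label`` (cis/trans/indeterminate/no_prediction) and, for
    ``unit="unique_pair"``, ``variant1``/``variant2`` to deduplicate on.
    Accuracy is correct / (correct + incorrect) over pairs with a cis/trans
    truth and a cis/trans prediction; the phaseable fraction counts
    predictions in {cis, trans, indeterminate} among pairs with truth, and the
    indeterminate fraction is reported among those phaseable.
    """
    required = {"truth_label", "predicted_label"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    df = records
    if unit == "unique_pair":
        if not {"variant1", "variant2"} <= set(df.columns):
            raise ValueError("unique_pair mode needs variant1/variant2 columns")
        df = df.drop_duplicates(subset=["variant1", "variant2"])
    elif unit != "occurrence":
        raise ValueError(f"unknown unit {unit!r}")

    truthful = df[df["truth_label"].isin(["cis", "trans"])]
    n = len(truthful)
    amenable = truthful[truthful["predicted_label"] != "no_prediction"]
    decided = truthful[truthful["predicted_label"].isin(["cis", "trans"])]
    correct = decided[decided["predicted_label"] == decided["truth_label"]]
    incorrect = decided[decided["predicted_label"] != decided["truth_label"]]

    def _acc(sub: pd.DataFrame) -> float:
        dec = sub[sub["predicted_label"].isin(["cis", "trans"])]
        if len(dec) == 0:
            return float("nan")
        return float((dec["predicted_label"] == dec["truth_label"]).mean())

    return {
        "unit": unit,
        "n_truth_pairs": n,
        "n_phaseable": len(amenable),
        "frac_phaseable": len(amenable) / n if n else float("nan"),
        "frac_indeterminate": (
            float((amenable["predicted_label"] == "indeterminate").mean())
            if len(amenable) else float("nan")
        ),
        "n_correct": len(correct),
        "n_incorrect": len(incorrect),
        "accuracy": _acc(truthful),
        "accuracy_cis": _acc(truthful[truthful["truth_label"] == "cis"]),
        "accuracy_trans": _acc(truthful[truthful["truth_label"] == "trans"]),
    }
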