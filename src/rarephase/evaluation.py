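"""Stratified accuracy analyses: AF bins, distance, mutation classes, ROC.

Phasing accuracy (correct / (correct + incorrect)) is reported per stratum
and per truth class. Strata of interest are pairwise allele-frequency bins,
physical distance (log10 bp), interpolated genetic distance (centiMorgans
from a HapMap-style recombination map) and mutation-class pairs, where each
SNV is a transversion, a non-CpG transition, or a CpG transition tiered by
mean DNA methylation (low: missing or < 0.2; medium: 0.2-0.6; high: > 0.6).
CpG transitions at heavily methylated sites mutate recurrently at the highest
rates of any single-nucleotide change, which is why they matter for phasing:
a recurrent mutation can re-create one variant of a pair on a new haplotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MUTATION_CLASSES",
    "classify_mutation",
    "GeneticMap",
    "stratified_accuracy",
    "assign_af_bin",
    "pair_af_bin",
    "pair_mutation_class",
    "roc_curve",
    "precision_recall",
    "auc_trapezoid",
]

MUTATION_CLASSES = (
    "transversion",
    "transition_nonCpG",
    "CpG_low",
    "CpG_medium",
    "CpG_high",
    "not_applicable",
)

_PURINES = {"A", "G"}
_BASES = {"A", "C", "G", "T"}


def classify_mutation(ref: str, alt: str, context: str | None = None,
                      methylation: float | None = None) -> str:
    """Mutation class of one SNV.

    Transitions exchange bases within the purine or pyrimidine class. A CpG
    transition is C>T with a 3' G neighbour, or its reverse-complement G>A
    with a 5' C neighbour, read from the 3-mer reference ``context`` centred
    on the site; CpG transitions are tiered by ``methylation``. Indels and
    other non-SNVs return ``not_applicable``.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
        return "not_applicable"
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if (ref in _PURINES) != (alt in _PURINES):
        return "transversion"
    if context is not None:
        if len(context) != 3 or context[1] != ref or not set(context) <= _BASES:
            raise ValueError(f"malformed 3-mer context {context!r} for ref {ref!r}")
        cpg = (ref == "C" and alt == "T" and context[2] == "G") or \
              (ref == "G" and alt == "A" and context[0] == "C")
        if cpg:
            if methylation is None or methylation < 0.2:
                return "CpG_low"
            if methylation <= 0.6:
                return "CpG_medium"
            return "CpG_high"
    return "transition_nonCpG"


class GeneticMap:
    """Piecewise-linear genetic map: physical position -> cumulative cM.

    Built from a HapMap-style table with columns ``position`` (1-based bp),
    ``rate`` (cM/Mb, unused by interpolation) and ``cm`` (cumulative cM), per
    contig. Positions outside the mapped range clamp to the terminal cM
    values.
    """

    def __init__(self, tables: dict[str, tuple[np.ndarray, np.ndarray]]) -> None:
        self._tables = {}
        for contig, (pos, cm) in tables.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"map positions for {contig} must strictly increase")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cumulative cM for {contig} must be non-decreasing")
            self._tables[contig] = (pos, cm)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, contig: str | None = None) -> "GeneticMap":
        cols = {c.lower(): c for c in df.columns}
        pos_col = cols.get("position", cols.get("pos"))
        cm_col = cols.get("cm", cols.get("genetic_map(cm)"))
        if pos_col is None or cm_col is None:
            raise ValueError("genetic map needs 'position' and 'cm' columns")
        if contig is not None:
            return cls({contig: (df[pos_col].to_numpy(), df[cm_col].to_numpy())})
        contig_col = cols.get("contig", cols.get("chrom"))
        if contig_col is None:
            raise ValueError("multi-contig map needs a 'contig' column")
        tables = {}
        for name, sub in df.groupby(contig_col, sort=False):
            sub = sub.sort_values(pos_col)
            tables[str(name)] = (sub[pos_col].to_numpy(), sub[cm_col].to_numpy())
        return cls(tables)

    @classmethod
    def from_tsv(cls, path, contig: str | None = None) -> "GeneticMap":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), contig=contig)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._tables)

    def interpolate(self, contig: str, positions) -> np.ndarray:
        """Cumulative cM at physical positions (clamped beyond map ends)."""
        if contig not in self._tables:
            raise KeyError(f"contig {contig!r} absent from genetic map")
        pos, cm = self._tables[contig]
        return np.interp(np.asarray(positions, dtype=float), pos, cm)

    def distance(self, contig: str, pos1, pos2) -> np.ndarray | float:
        """Genetic distance in cM between two positions on one contig."""
        out = np.abs(self.interpolate(contig, pos2) - self.interpolate(contig, pos1))
        return float(out) if np.isscalar(pos1) and np.isscalar(pos2) else out


# ---------------------------------------------------------------------------
# Stratified accuracy

#: default AF bin edges; landmarks at 1e-4, 1e-3, 1e-2 and the 5% rarity cap
DEFAULT_AF_BINS = ((1e-4, "<1e-4"), (1e-3, "[1e-4,1e-3)"),
                   (1e-2, "[1e-3,1e-2)"), (5e-2, "[1e-2,5e-2)"))


def assign_af_bin(af: float, ac: int | None = None, bins=DEFAULT_AF_BINS) -> str:
    """AF bin label for one variant; allele count 1 is its own 'singleton' bin."""
    if ac == 1:
        return "singleton"
    for edge, label in bins:
        if af < edge:
            return label
    return f">={bins[-1][0]:g}"


def pair_af_bin(af1: float, af2: float, ac1: int | None = None,
                ac2: int | None = None) -> tuple[str, str]:
    """(rarer bin, more frequent bin) for a variant pair."""
    if (af2, 1 if ac2 == 1 else 0) < (af1, 1 if ac1 == 1 else 0):
        af1, af2, ac1, ac2 = af2, af1, ac2, ac1
    return (assign_af_bin(af1, ac1), assign_af_bin(af2, ac2))


def pair_mutation_class(class1: str, class2: str) -> tuple[str, str]:
    """Unordered mutation-class pair label."""
    return tuple(sorted((class1, class2)))


def stratified_accuracy(records: pd.DataFrame, by) -> pd.DataFrame:
    """Accuracy and phaseability per stratum.

    ``records`` needs ``truth_label`` (cis/trans) and ``predicted_label``
    columns plus the stratum column(s) named by ``by``. Returns one row per
    stratum with n, accuracy overall and per truth class, the fraction of
    pairs amenable to phasing, and the indeterminate fraction among those.
    Strata partition the records: the per-stratum counts sum to the total.
    """
    if isinstance(by, str):
        by = [by]
    missing = [c for c in list(by) + ["truth_label", "predicted_label"]
               if c not in records.columns]
    if missing:
        raise ValueError(f"unknown stratum or required column(s): {missing}")
    rows = []
    for key, sub in records.groupby(list(by), dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        amen = sub[sub["predicted_label"] != "no_prediction"]
        decided = sub[sub["predicted_label"].isin(["cis", "trans"])]
        correct = decided["predicted_label"] == decided["truth_label"]

        def _acc(d: pd.DataFrame) -> float:
            d = d[d["predicted_label"].isin(["cis", "trans"])]
            return float((d["predicted_label"] == d["truth_label"]).mean()) if len(d) else np.nan

        rows.append({
            **dict(zip(by, key)),
            "n": len(sub),
            "n_decided": len(decided),
            "accuracy": float(correct.mean()) if len(decided) else np.nan,
            "accuracy_cis": _acc(sub[sub["truth_label"] == "cis"]),
            "accuracy_trans": _acc(sub[sub["truth_label"] == "trans"]),
            "frac_phaseable": len(amen) / len(sub) if len(sub) else np.nan,
            "frac_indeterminate": (
                float((amen["predicted_label"] == "indeterminate").mean())
                if len(amen) else np.nan
            ),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / precision-recall

def _check_binary(truth: np.ndarray) -> np.ndarray:
    truth = np.asarray(truth)
    if truth.dtype.kind in "OUS":
        truth = (truth == "trans").astype(int)
    truth = truth.astype(int)
    if truth.min() == truth.max():
        raise ValueError("ROC/PR need both classes present in the truth labels")
    return truth


def roc_curve(scores, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Receiver-operator curve for 'is this pair in trans'.

    ``truth`` may be binary or cis/trans labels (trans = positive). Scores
    tied at the same value are grouped into a single operating point. Returns
    (fpr, tpr, thresholds, auc) with AUC by the trapezoidal rule.
    """
    scores = np.asarray(scores, dtype=float)
    truth = _check_binary(truth)
    order = np.argsort(-scores, kind="mergesort")
    s, t = scores[order], truth[order]
    # operating point after each distinct score value
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(t)[distinct]
    fp = np.cumsum(1 - t)[distinct]
    n_pos, n_neg = t.sum(), (1 - t).sum()
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds, auc_trapezoid(fpr, tpr)


def auc_trapezoid(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(y, x))


def precision_recall(scores, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision/recall over the sweep of observed score thresholds."""
    scores = np.asarray(scores, dtype=float)
    truth = _check_binary(truth)
    order = np.argsort(-scores, kind="mergesort")
    s, t = scores[order], truth[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(t)[distinct]
    predicted = distinct + 1.0
    precision = tp / predicted
    recall = tp / t.sum()
    return precision, recall, s[distinct]
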