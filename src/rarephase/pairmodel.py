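"""Two-locus haplotype frequency estimation and phase classification.

Consider two biallelic variants in the same gene, with major alleles A and B
and minor alleles a and b. An individual's joint genotype at the two sites is
one of nine classes (AABB, AaBB, aaBB, AABb, AaBb, aaBb, AAbb, Aabb, aabb);
every class except the double heterozygote AaBb resolves unambiguously into a
pair of two-locus haplotypes drawn from {AB, Ab, aB, ab}. Under Hardy-Weinberg
random mating the genotype-class probabilities are products of haplotype
frequencies, e.g. P(AaBb) = 2 f_AB f_ab + 2 f_Ab f_aB, and the haplotype
frequencies can be estimated from a table of genotype counts by
expectation-maximization.

The quantity of clinical interest is Ptrans, the probability that a doubly
heterozygous individual carries the two minor alleles on opposite haplotypes
(compound heterozygosity) rather than on the same haplotype:

    Ptrans = f_Ab * f_aB / (f_AB * f_ab + f_Ab * f_aB)

Pairs are then classified as cis (Ptrans <= t_cis), trans (Ptrans >= t_trans)
or indeterminate, with calibrated default thresholds t_cis = 0.02 and
t_trans = 0.55.

The module follows a model/results layout: :class:`TwoLocusHaplotypeModel`
wraps a :class:`PairGenotypeCounts` table, ``fit()`` runs the EM and returns a
:class:`HaplotypeEstimate` results object carrying the frequency estimates,
expected haplotype counts, log-likelihood trace and convergence diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HAPLOTYPES",
    "PairGenotypeCounts",
    "TwoLocusHaplotypeModel",
    "HaplotypeEstimate",
    "Thresholds",
    "PhasePrediction",
    "em_haplotype_frequencies",
    "p_trans",
    "classify",
]

#: Haplotype order used throughout: index = 2 * (a allele) + (b allele).
HAPLOTYPES = ("AB", "Ab", "aB", "ab")

# Number of copies of the minor allele at locus A / locus B carried by each
# haplotype, in HAPLOTYPES order.
_HAP_A = np.array([0, 0, 1, 1])
_HAP_B = np.array([0, 1, 0, 1])

# Haplotype contributions of the eight unambiguous genotype cells.
# _UNAMBIG[gA, gB] is a length-4 vector of haplotype counts per individual;
# the (1, 1) cell is all zeros because the double heterozygote is ambiguous.
_UNAMBIG = np.zeros((3, 3, 4), dtype=float)
_UNAMBIG[0, 0] = (2, 0, 0, 0)
_UNAMBIG[1, 0] = (1, 0, 1, 0)
_UNAMBIG[2, 0] = (0, 0, 2, 0)
_UNAMBIG[0, 1] = (1, 1, 0, 0)
_UNAMBIG[2, 1] = (0, 0, 1, 1)
_UNAMBIG[0, 2] = (0, 2, 0, 0)
_UNAMBIG[1, 2] = (0, 1, 0, 1)
_UNAMBIG[2, 2] = (0, 0, 0, 2)

_CELL_NAMES = {
    "AABB": (0, 0), "AaBB": (1, 0), "aaBB": (2, 0),
    "AABb": (0, 1), "AaBb": (1, 1), "aaBb": (2, 1),
    "AAbb": (0, 2), "Aabb": (1, 2), "aabb": (2, 2),
}


def hwe_genotype_probs(freqs: np.ndarray) -> np.ndarray:
    """3x3 genotype-class probabilities under random union of haplotypes.

    ``probs[gA, gB]`` is the probability an individual carries ``gA`` copies of
    minor allele a and ``gB`` copies of minor allele b.
    """
    f_ab_, f_aB, f_Ab, f_AB = freqs[3], freqs[2], freqs[1], freqs[0]
    p = np.empty((3, 3))
    p[0, 0] = f_AB * f_AB
    p[1, 0] = 2 * f_AB * f_aB
    p[2, 0] = f_aB * f_aB
    p[0, 1] = 2 * f_AB * f_Ab
    p[1, 1] = 2 * f_AB * f_ab_ + 2 * f_Ab * f_aB
    p[2, 1] = 2 * f_aB * f_ab_
    p[0, 2] = f_Ab * f_Ab
    p[1, 2] = 2 * f_Ab * f_ab_
    p[2, 2] = f_ab_ * f_ab_
    return p


@dataclass(frozen=True)
class PairGenotypeCounts:
    """3x3 table of joint genotype counts for one variant pair.

    ``table[gA, gB]`` counts individuals carrying ``gA`` copies of the minor
    allele at the first locus and ``gB`` copies at the second. Individuals
    with a missing genotype at either locus are excluded entirely.
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table)
        if t.shape != (3, 3):
            raise ValueError(f"genotype table must be 3x3, got {t.shape}")
        if np.any(t < 0):
            raise ValueError("genotype counts must be non-negative")
        if not np.allclose(t, np.round(t)):
            raise ValueError("genotype counts must be integers")
        object.__setattr__(self, "table", t.astype(np.int64))

    @classmethod
    def from_dict(cls, cells: dict[str, int]) -> "PairGenotypeCounts":
        """Build from named cells, e.g. ``{"AABB": 98, "AaBb": 2}``."""
        t = np.zeros((3, 3), dtype=np.int64)
        for name, count in cells.items():
            if name not in _CELL_NAMES:
                raise ValueError(f"unknown genotype cell {name!r}")
            t[_CELL_NAMES[name]] = count
        return cls(t)

    @property
    def n_total(self) -> int:
        return int(self.table.sum())

    @property
    def allele_count_a(self) -> int:
        """Minor-allele count at the first locus."""
        return int((self.table.sum(axis=1) * np.arange(3)).sum())

    @property
    def allele_count_b(self) -> int:
        """Minor-allele count at the second locus."""
        return int((self.table.sum(axis=0) * np.arange(3)).sum())

    @property
    def n_double_het(self) -> int:
        return int(self.table[1, 1])

    def swap_loci(self) -> "PairGenotypeCounts":
        """Exchange the two loci (transpose the table)."""
        return PairGenotypeCounts(self.table.T)

    def relabel_locus(self, locus: int) -> "PairGenotypeCounts":
        """Exchange major/minor alleles at one locus (0 or 1)."""
        if locus == 0:
            return PairGenotypeCounts(self.table[::-1, :])
        if locus == 1:
            return PairGenotypeCounts(self.table[:, ::-1])
        raise ValueError("locus must be 0 or 1")

    def is_singleton_singleton_same_individual(self) -> bool:
        """True when both minor alleles are singletons carried by one person."""
        return (
            self.n_double_het == 1
            and self.allele_count_a == 1
            and self.allele_count_b == 1
        )


@dataclass(frozen=True)
class Thresholds:
    """Ptrans classification cut points: cis at ``<= t_cis``, trans at ``>= t_trans``."""

    t_cis: float = 0.02
    t_trans: float = 0.55

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_cis < self.t_trans <= 1.0):
            raise ValueError(
                f"require 0 <= t_cis < t_trans <= 1, got ({self.t_cis}, {self.t_trans})"
            )


@dataclass(frozen=True)
class PhasePrediction:
    """Classification of one variant pair for one (implicit) carrier."""

    p_trans: float | None
    label: str  # cis | trans | indeterminate | no_prediction
    reason: str | None = None


class HaplotypeEstimate:
    """EM results: haplotype frequencies, counts and fit diagnostics.

    Attributes
    ----------
    freqs : ndarray shape (4,)
        Estimated frequencies in :data:`HAPLOTYPES` order (AB, Ab, aB, ab).
    expected_haplotype_counts : ndarray shape (4,)
        ``2 * n_total * freqs``; what a haplotype-count table would display.
    log_likelihood : float
        Multinomial log-likelihood of the genotype table at the estimate
        (constant combinatorial term omitted).
    loglike_trace : ndarray
        Log-likelihood after each M-step, non-decreasing.
    iterations, converged
        EM iteration count and whether the tolerance was reached before
        ``max_iter``.
    """

    def __init__(self, model: "TwoLocusHaplotypeModel", freqs: np.ndarray,
                 trace: np.ndarray, converged: bool) -> None:
        self.model = model
        self.freqs = np.asarray(freqs, dtype=float)
        self.loglike_trace = np.asarray(trace, dtype=float)
        self.converged = bool(converged)

    @property
    def f_AB(self) -> float:
        return float(self.freqs[0])

    @property
    def f_Ab(self) -> float:
        return float(self.freqs[1])

    @property
    def f_aB(self) -> float:
        return float(self.freqs[2])

    @property
    def f_ab(self) -> float:
        return float(self.freqs[3])

    @property
    def expected_haplotype_counts(self) -> np.ndarray:
        return 2.0 * self.model.counts.n_total * self.freqs

    @property
    def log_likelihood(self) -> float:
        return float(self.loglike_trace[-1])

    @property
    def iterations(self) -> int:
        return len(self.loglike_trace)

    @property
    def p_trans(self) -> float | None:
        """Probability the pair is in trans; None when undefined (0/0)."""
        return p_trans(self.freqs)

    @property
    def p_cis(self) -> float | None:
        pt = self.p_trans
        return None if pt is None else 1.0 - pt

    def classify(self, thresholds: Thresholds | None = None, *,
                 singleton_same_individual: bool | None = None,
                 both_present: bool | None = None) -> PhasePrediction:
        """Classify this pair; presence/singleton flags default from the table."""
        c = self.model.counts
        if singleton_same_individual is None:
            singleton_same_individual = c.is_singleton_singleton_same_individual()
        if both_present is None:
            both_present = c.allele_count_a > 0 and c.allele_count_b > 0
        return classify(self.p_trans, thresholds or Thresholds(),
                        singleton_same_individual=singleton_same_individual,
                        both_present=both_present)

    def summary(self) -> str:
        c = self.model.counts
        pt = self.p_trans
        lines = [
            "Two-locus haplotype frequency estimate (EM)",
            "=" * 47,
            f"individuals (n_total)      {c.n_total}",
            f"double heterozygotes       {c.n_double_het}",
            f"log-likelihood             {self.log_likelihood:.6f}",
            f"iterations                 {self.iterations}"
            f"   converged: {self.converged}",
            "-" * 47,
            f"{'haplotype':<12}{'frequency':>14}{'est. count':>14}",
        ]
        for name, f, n in zip(HAPLOTYPES, self.freqs,
                              self.expected_haplotype_counts):
            lines.append(f"{name:<12}{f:>14.6g}{n:>14.4f}")
        lines.append("-" * 47)
        lines.append("Ptrans                     "
                     + ("undefined" if pt is None else f"{pt:.6g}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        f = ", ".join(f"{n}={v:.4g}" for n, v in zip(HAPLOTYPES, self.freqs))
        return f"<HaplotypeEstimate {f}, llf={self.log_likelihood:.4f}>"


class TwoLocusHaplotypeModel:
    """Multinomial HWE model for a 3x3 genotype-count table.

    ``fit()`` runs EM from the conventional start that splits the double
    heterozygotes equally between the cis (AB|ab) and trans (Ab|aB)
    configurations, iterating until the log-likelihood changes by less than
    ``tol`` or ``max_iter`` is reached.
    """

    def __init__(self, counts: PairGenotypeCounts) -> None:
        if not isinstance(counts, PairGenotypeCounts):
            counts = PairGenotypeCounts(np.asarray(counts))
        if counts.n_total == 0:
            raise ValueError("empty genotype table: n_total must be >= 1")
        self.counts = counts

    def loglike(self, freqs: np.ndarray) -> float:
        """Multinomial log-likelihood of the table at haplotype frequencies."""
        probs = hwe_genotype_probs(np.asarray(freqs, dtype=float))
        t = self.counts.table
        mask = t > 0
        if np.any(probs[mask] <= 0):
            return -math.inf
        return float((t[mask] * np.log(probs[mask])).sum())

    def _m_step(self, p_cis: float) -> np.ndarray:
        t = self.counts.table.astype(float)
        hap = (t[:, :, None] * _UNAMBIG).sum(axis=(0, 1))
        n11 = t[1, 1]
        hap += p_cis * n11 * np.array([1.0, 0.0, 0.0, 1.0])
        hap += (1.0 - p_cis) * n11 * np.array([0.0, 1.0, 1.0, 0.0])
        return hap / (2.0 * self.counts.n_total)

    @staticmethod
    def _e_step(freqs: np.ndarray) -> float:
        """Posterior probability a double het is in the cis configuration."""
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        denom = cis + trans
        if denom == 0.0:
            return 0.5  # no information: keep the equal split
        return cis / denom

    def fit(self, tol: float = 1e-7, max_iter: int = 1000) -> HaplotypeEstimate:
        """Run EM; returns a :class:`HaplotypeEstimate` results object."""
        if tol <= 0:
            raise ValueError("tol must be positive")
        freqs = self._m_step(0.5)  # equal split of AaBb between cis and trans
        trace = [self.loglike(freqs)]
        converged = False
        if self.counts.n_double_het == 0:
            # Every genotype resolves unambiguously: the single M-step is the MLE.
            converged = True
        else:
            for _ in range(max_iter):
                freqs = self._m_step(self._e_step(freqs))
                trace.append(self.loglike(freqs))
                if abs(trace[-1] - trace[-2]) < tol:
                    converged = True
                    break
        return HaplotypeEstimate(self, freqs, np.array(trace), converged)


def em_haplotype_frequencies(counts: PairGenotypeCounts, tol: float = 1e-7,
                             max_iter: int = 1000) -> HaplotypeEstimate:
    """Functional wrapper: EM haplotype frequencies for a genotype table."""
    return TwoLocusHaplotypeModel(counts).fit(tol=tol, max_iter=max_iter)


def p_trans(freqs: np.ndarray | HaplotypeEstimate) -> float | None:
    """Probability that a doubly heterozygous pair is in trans.

    ``f_Ab * f_aB / (f_AB * f_ab + f_Ab * f_aB)``; None when the denominator
    is zero (neither haplotype configuration has support), which callers map
    to a ``no_prediction`` outcome.
    """
    if isinstance(freqs, HaplotypeEstimate):
        freqs = freqs.freqs
    f = np.asarray(freqs, dtype=float)
    cis = f[0] * f[3]
    trans = f[1] * f[2]
    denom = cis + trans
    if denom == 0.0:
        return None
    return float(trans / denom)


def classify(p: float | None, thresholds: Thresholds | None = None, *,
             singleton_same_individual: bool = False,
             both_present: bool = True) -> PhasePrediction:
    """Map a Ptrans value to a phase label under the given thresholds.

    ``no_prediction`` takes precedence: when either variant is absent from the
    reference group, when both variants are singletons carried by the same
    reference individual, or when Ptrans is undefined. Otherwise the closed
    intervals ``p <= t_cis`` and ``p >= t_trans`` give cis/trans and the open
    interval between them is indeterminate.
    """
    th = thresholds or Thresholds()
    if not both_present:
        return PhasePrediction(p, "no_prediction", "variant_absent")
    if singleton_same_individual:
        return PhasePrediction(p, "no_prediction",
                               "singleton_singleton_same_individual")
    if p is None:
        return PhasePrediction(None, "no_prediction", "undefined_denominator")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"Ptrans must lie in [0, 1], got {p}")
    if p <= th.t_cis:
        return PhasePrediction(p, "cis")
    if p >= th.t_trans:
        return PhasePrediction(p, "trans")
    return PhasePrediction(p, "indeterminate")
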