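"""Per-gene counts of individuals carrying two rare, damaging variants.

For each gene, AF threshold and functional-severity tier, count the number of
individuals carrying a qualifying heterozygous variant pair, stratified by
predicted phase (trans / unphased / cis) — singleton-singleton pairs and
indeterminate Ptrans are reported as unphased. Severity forms a total order

    pLoF > strong_revel_missense > moderate_to_strong_revel_missense
         > weak_to_strong_revel_missense > missense_any > synonymous

and a pair counts toward a tier when its *least* damaging variant is at least
that severe, so a pLoF/pLoF pair appears under every tier. AF qualification
takes the worse of the global and "popmax" AF of each variant (popmax being
the highest AF among the non-bottlenecked ancestry groups, i.e. excluding
ASJ, FIN and Remaining), and any variant exceeding 5% in a bottlenecked group
disqualifies its pairs outright. In the default exclusive mode each
individual is counted once per (gene, tier, threshold), in their best cell
with priority trans > unphased > cis; multi mode counts them in every phase
cell in which they carry a pair. Homozygote counts are the analogous
single-variant tabulation.
"""

from __future__ import annotations

import enum
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SeverityTier",
    "assign_tier",
    "variant_af_qualifies",
    "af_qualifies",
    "count_cooccurrence",
    "count_homozygotes",
    "DEFAULT_AF_THRESHOLDS",
    "BOTTLENECKED_GROUPS",
    "DEFAULT_POPMAX_GROUPS",
]

DEFAULT_AF_THRESHOLDS = (0.005, 0.01, 0.015, 0.02, 0.05)
BOTTLENECKED_GROUPS = frozenset({"asj", "fin", "remaining"})
DEFAULT_POPMAX_GROUPS = frozenset({"afr", "amr", "eas", "nfe", "sas"})
BOTTLENECK_AF_CAP = 0.05

_PHASE_PRIORITY = {"trans": 2, "unphased": 1, "cis": 0}


class SeverityTier(enum.IntEnum):
    """Functional severity, ordered; greater is more damaging."""

    synonymous = 1
    missense_any = 2
    weak_to_strong_revel_missense = 3
    moderate_to_strong_revel_missense = 4
    strong_revel_missense = 5
    pLoF = 6


#: REVEL cut points (inclusive), strongest first
_REVEL_TIERS = (
    (0.932, SeverityTier.strong_revel_missense),
    (0.773, SeverityTier.moderate_to_strong_revel_missense),
    (0.644, SeverityTier.weak_to_strong_revel_missense),
)


def assign_tier(consequence_class: str, revel: float | None = None) -> SeverityTier | None:
    """Severity tier of one variant; None for consequences outside the lattice.

    High-confidence loss-of-function maps to pLoF; missense is tiered by
    REVEL with inclusive cut points 0.932 / 0.773 / 0.644; missense without a
    REVEL score falls back to ``missense_any`` with a warning.
    """
    if consequence_class == "pLoF":
        return SeverityTier.pLoF
    if consequence_class == "missense":
        if revel is None:
            warnings.warn("missense variant without REVEL score counted as missense_any")
            return SeverityTier.missense_any
        for cut, tier in _REVEL_TIERS:
            if revel >= cut:
                return tier
        return SeverityTier.missense_any
    if consequence_class == "synonymous":
        return SeverityTier.synonymous
    return None


def variant_af_qualifies(global_af: float, popmax_af: float | None,
                         threshold: float,
                         bottleneck_max_af: float | None = None) -> bool:
    """One variant's AF qualification at one threshold.

    The variant qualifies when the worse of its global and popmax AF is
    ``<= threshold`` and no bottlenecked-group AF exceeds 5%.
    """
    worst = global_af if popmax_af is None else max(global_af, popmax_af)
    if worst > threshold:
        return False
    if bottleneck_max_af is not None and bottleneck_max_af > BOTTLENECK_AF_CAP:
        return False
    return True


def af_qualifies(pair_afs, threshold: float) -> bool:
    """Both variants of a pair must qualify.

    ``pair_afs`` is a sequence of two (global_af, popmax_af,
    bottleneck_max_af) triples.
    """
    return all(variant_af_qualifies(g, p, threshold, b) for g, p, b in pair_afs)


def popmax_af(af_by_group: dict, popmax_groups=DEFAULT_POPMAX_GROUPS) -> float | None:
    """Highest AF among non-bottlenecked ancestry groups, if any are present."""
    afs = [ac / an for g, (ac, an) in af_by_group.items()
           if g in popmax_groups and an > 0]
    return max(afs) if afs else None


def bottleneck_max_af(af_by_group: dict,
                      bottleneck_groups=BOTTLENECKED_GROUPS) -> float | None:
    afs = [ac / an for g, (ac, an) in af_by_group.items()
           if g in bottleneck_groups and an > 0]
    return max(afs) if afs else None


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"input table missing columns: {missing}")


def count_cooccurrence(pairs: pd.DataFrame,
                       af_thresholds=DEFAULT_AF_THRESHOLDS,
                       mode: str = "exclusive_priority") -> pd.DataFrame:
    """Gene-wise co-occurrence table across tiers, AF thresholds and phase.

    ``pairs`` has one row per (individual, qualifying variant pair) with
    columns ``gene_id``, ``individual``, ``phase`` (trans/unphased/cis),
    ``min_tier`` (int value of the pair's least severe variant's tier),
    ``pair_max_af`` (worse of the two variants' max(global, popmax) AF) and
    ``bottleneck_fail`` (bool: some variant exceeds 5% in a bottlenecked
    group). Returns rows (gene_id, tier, af_threshold) with phase-stratified
    individual counts; ``n_individuals_total`` deduplicates individuals
    irrespective of phase and ``n_pair_occurrences`` does not.
    """
    if mode not in ("exclusive_priority", "multi"):
        raise ValueError(f"unknown counting mode {mode!r}")
    _require_columns(pairs, ["gene_id", "individual", "phase", "min_tier",
                             "pair_max_af", "bottleneck_fail"])
    bad = set(pairs["phase"].unique()) - set(_PHASE_PRIORITY)
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")

    rows = []
    genes = sorted(pairs["gene_id"].unique())
    for gene in genes:
        gsub = pairs[pairs["gene_id"] == gene]
        for tier in SeverityTier:
            tsub = gsub[gsub["min_tier"] >= int(tier)]
            for thr in af_thresholds:
                q = tsub[(tsub["pair_max_af"] <= thr) & (~tsub["bottleneck_fail"])]
                counts = {"trans": 0, "unphased": 0, "cis": 0}
                if len(q):
                    if mode == "exclusive_priority":
                        best = (q.assign(_p=q["phase"].map(_PHASE_PRIORITY))
                                 .groupby("individual")["_p"].max())
                        inv = {v: k for k, v in _PHASE_PRIORITY.items()}
                        for p, n in best.map(inv).value_counts().items():
                            counts[p] = int(n)
                    else:
                        for p in counts:
                            counts[p] = int(q.loc[q["phase"] == p, "individual"].nunique())
                rows.append({
                    "gene_id": gene,
                    "tier": tier.name,
                    "af_threshold": thr,
                    "n_individuals_total": int(q["individual"].nunique()),
                    "n_pair_occurrences": int(len(q)),
                    "n_trans": counts["trans"],
                    "n_unphased": counts["unphased"],
                    "n_cis": counts["cis"],
                    "mode": mode,
                })
    return pd.DataFrame(rows)


def count_homozygotes(variants: pd.DataFrame,
                      af_thresholds=DEFAULT_AF_THRESHOLDS) -> pd.DataFrame:
    """Gene-wise homozygote counts by tier and AF threshold.

    ``variants`` has one row per (individual, homozygous qualifying variant)
    with columns ``gene_id``, ``individual``, ``tier`` (int), ``max_af``
    (max of global and popmax AF) and ``bottleneck_fail``.
    """
    _require_columns(variants, ["gene_id", "individual", "tier", "max_af",
                                "bottleneck_fail"])
    rows = []
    for gene in sorted(variants["gene_id"].unique()):
        gsub = variants[variants["gene_id"] == gene]
        for tier in SeverityTier:
            tsub = gsub[gsub["tier"] >= int(tier)]
            for thr in af_thresholds:
                q = tsub[(tsub["max_af"] <= thr) & (~tsub["bottleneck_fail"])]
                rows.append({
                    "gene_id": gene,
                    "tier": tier.name,
                    "af_threshold": thr,
                    "n_hom": int(q["individual"].nunique()),
                })
    return pd.DataFrame(rows)
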