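"""Derivation of cis/trans Ptrans thresholds from trio-truth agreement.

Variant pairs carrying both a Ptrans value and a trio truth label are binned
in Ptrans increments of 0.01; the trans threshold is the lower edge of the
lowest bin in which at least 90% of pairs are in trans by transmission, and
the cis threshold is the upper edge of the highest bin in which at least 90%
are in cis. Calibration conventionally uses pairs on odd-numbered autosomes
(accuracy is then measured on even autosomes) and is restricted to pairs
where both variants have population AF >= 1e-4.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .pairmodel import Thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "bin_ptrans",
    "derive_thresholds",
    "split_by_chromosome_parity",
    "chromosome_parity",
    "MIN_CALIBRATION_AF",
]

#: both variants of a calibration pair must reach this population AF
MIN_CALIBRATION_AF = 1e-4


def bin_ptrans(records: pd.DataFrame, bin_width: float = 0.01) -> pd.DataFrame:
    """Per-bin counts and cis/trans proportions of truth-labelled pairs.

    ``records`` needs columns ``p_trans`` (defined values in [0, 1]) and
    ``truth_label`` in {cis, trans}. Bins are half-open ``[k*w, (k+1)*w)``
    with the top bin closed at 1. Empty input is an error.
    """
    if len(records) == 0:
        raise ValueError("cannot bin an empty calibration set")
    p = np.asarray(records["p_trans"], dtype=float)
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p_trans values must be defined and in [0, 1]")
    truth = np.asarray(records["truth_label"])
    if not set(np.unique(truth)) <= {"cis", "trans"}:
        raise ValueError("truth_label must be 'cis' or 'trans'")
    n_bins = int(round(1.0 / bin_width))
    idx = np.minimum((p / bin_width).astype(int), n_bins - 1)
    rows = []
    for k in range(n_bins):
        in_bin = idx == k
        n = int(in_bin.sum())
        n_trans = int((truth[in_bin] == "trans").sum())
        rows.append({
            "bin_low": k * bin_width,
            "bin_high": min((k + 1) * bin_width, 1.0),
            "n": n,
            "prop_trans": n_trans / n if n else np.nan,
            "prop_cis": (n - n_trans) / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def derive_thresholds(bins: pd.DataFrame, target: float = 0.90,
                      min_bin_count: int = 10) -> Thresholds:
    """Thresholds from binned trio agreement.

    trans: lower edge of the minimum-Ptrans bin whose trans proportion
    reaches ``target``; cis: upper edge of the maximum-Ptrans bin whose cis
    proportion reaches ``target``. Bins with fewer than ``min_bin_count``
    pairs are skipped as unstable. Raises when either threshold has no
    qualifying bin or the thresholds do not satisfy t_cis < t_trans.
    """
    usable = bins[bins["n"] >= min_bin_count]
    skipped = len(bins) - len(usable)
    if skipped:
        logger.warning("derive_thresholds: skipped %d bins with n < %d",
                       skipped, min_bin_count)
    trans_bins = usable[usable["prop_trans"] >= target]
    cis_bins = usable[usable["prop_cis"] >= target]
    if len(trans_bins) == 0:
        raise ValueError(f"no bin reaches a trans proportion of {target}")
    if len(cis_bins) == 0:
        raise ValueError(f"no bin reaches a cis proportion of {target}")
    t_trans = float(trans_bins["bin_low"].min())
    t_cis = float(cis_bins["bin_high"].max())
    if not t_cis < t_trans:
        raise ValueError(
            f"derived thresholds are not ordered: t_cis={t_cis}, t_trans={t_trans}"
        )
    return Thresholds(t_cis=t_cis, t_trans=t_trans)


_CONTIG_RE = re.compile(r"^(chr)?(\d+)$")


def chromosome_parity(contig: str) -> str | None:
    """'odd'/'even' for autosomes 1-22 (chr prefix allowed), else None."""
    m = _CONTIG_RE.match(str(contig))
    if not m:
        return None
    num = int(m.group(2))
    if not 1 <= num <= 22:
        return None
    return "odd" if num % 2 == 1 else "even"


def split_by_chromosome_parity(records: pd.DataFrame,
                               contig_column: str = "contig"
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (odd, even) autosome sets.

    Non-autosomal contigs (sex chromosomes, unplaced scaffolds) are excluded
    with a warning.
    """
    parity = records[contig_column].map(chromosome_parity)
    n_dropped = int(parity.isna().sum())
    if n_dropped:
        logger.warning("split_by_chromosome_parity: excluded %d non-autosomal records",
                       n_dropped)
    return (records[parity == "odd"].copy(), records[parity == "even"].copy())
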