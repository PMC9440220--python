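"""Fold changes, exact Mann-Whitney testing, and FDR per tissue.

Differential abundance between germ-free (GF) and conventionally-raised
(MPF) mice is assessed tissue by tissue.  The fold change for a feature is
the mean GF abundance divided by the mean MPF abundance, so FC > 1 means
higher in GF.  With five replicates per group an asymptotic rank test is
badly calibrated, so the two-sided Mann-Whitney p value is computed exactly
by complete enumeration of all C(n1+n2, n1) relabelings of the pooled
values, with mid-ranks for ties; q values are Benjamini-Hochberg adjusted
within each tissue's batch of tested features.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError
from .feature_table import GROUPS, FeatureTable

Presence = Literal["both", "gf_only", "mpf_only", "absent"]

#: Columns of the per-tissue differential table.
RECORD_COLUMNS = (
    "feature_id",
    "tissue",
    "mean_gf",
    "mean_mpf",
    "fc",
    "log2fc",
    "p",
    "q",
    "presence",
    "max_abundance",
)


@dataclass(frozen=True)
class FCConvention:
    """Fold-change convention: which group is the numerator and how zero
    group means are handled.

    ``zero_handling="flag"`` (default) marks group-exclusive features instead
    of producing an infinite ratio; ``"floor"`` substitutes ``floor_eps`` for
    a zero mean so every feature gets a finite FC.
    """

    numerator: str = "GF"
    denominator: str = "MPF"
    zero_handling: str = "flag"
    floor_eps: float = 1.0

    def __post_init__(self) -> None:
        if {self.numerator, self.denominator} != set(GROUPS):
            raise ConfigurationError("FCConvention must use the two group labels exactly once")
        if self.zero_handling not in ("flag", "floor"):
            raise ConfigurationError("zero_handling must be 'flag' or 'floor'")
        if self.floor_eps <= 0:
            raise ConfigurationError("floor_eps must be positive")


DEFAULT_CONVENTION = FCConvention()


class FoldChange(NamedTuple):
    """Result of :func:`fold_change`: the ratio (NaN when flagged) plus the
    presence flag that explains why."""

    fc: float
    log2fc: float
    flag: Presence


def fold_change(
    mean_gf: float, mean_mpf: float, convention: FCConvention = DEFAULT_CONVENTION
) -> FoldChange:
    """GF/MPF ratio of group means, or an exclusivity flag on a zero mean."""
    if mean_gf < 0 or mean_mpf < 0:
        raise InputError("group means must be non-negative")
    if mean_gf == 0 and mean_mpf == 0:
        return FoldChange(np.nan, np.nan, "absent")
    if mean_mpf == 0:
        if convention.zero_handling == "floor":
            fc = mean_gf / convention.floor_eps
            return FoldChange(fc, np.log2(fc), "gf_only")
        return FoldChange(np.nan, np.nan, "gf_only")
    if mean_gf == 0:
        if convention.zero_handling == "floor":
            fc = convention.floor_eps / mean_mpf
            return FoldChange(fc, np.log2(fc), "mpf_only")
        return FoldChange(np.nan, np.nan, "mpf_only")
    fc = mean_gf / mean_mpf
    return FoldChange(fc, np.log2(fc), "both")


# ------------------------------------------------------------- exact U test
def _label_matrix(n1: int, n2: int) -> np.ndarray:
    """Indicator matrix (n1+n2 x L) over all C(n1+n2, n1) group-1 labelings."""
    n = n1 + n2
    combos = list(combinations(range(n), n1))
    mat = np.zeros((n, len(combos)), dtype=float)
    for j, c in enumerate(combos):
        mat[list(c), j] = 1.0
    return mat


_LABEL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _labels(n1: int, n2: int) -> np.ndarray:
    key = (n1, n2)
    if key not in _LABEL_CACHE:
        _LABEL_CACHE[key] = _label_matrix(n1, n2)
    return _LABEL_CACHE[key]


def exact_mw_p_batch(values: np.ndarray, n1: int) -> np.ndarray:
    """Exact two-sided Mann-Whitney p for many features at once.

    ``values`` is (features x (n1+n2)) with the first ``n1`` columns forming
    group 1.  Each row is mid-ranked; the rank sum of group 1 is compared
    against its value under every relabeling, and the two-sided p is the
    fraction of relabelings whose rank sum is at least as far from the null
    mean as the observed one.  Ties are handled by mid-ranks within the
    enumeration, so the null distribution conditions on the observed ties.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    n2 = n - n1
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs at least 2 replicates")
    ranks = rankdata(values, axis=1)
    labels = _labels(n1, n2)  # (n x L)
    w_all = ranks @ labels  # (features x L) rank sums under every labeling
    mu = n1 * (n + 1) / 2.0
    observed = ranks[:, :n1].sum(axis=1)
    # tolerance: mid-ranks are multiples of 1/2, so deviations are too
    dev_obs = np.abs(observed - mu)[:, None]
    extreme = np.abs(w_all - mu) >= dev_obs - 1e-9
    return extreme.sum(axis=1) / labels.shape[1]


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p for one pair of replicate vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each group needs at least 2 replicates")
    pooled = np.concatenate([x, y])[None, :]
    return float(exact_mw_p_batch(pooled, x.size)[0])


def min_attainable_p(n1: int, n2: int) -> float:
    """Smallest two-sided p reachable without ties: 2 / C(n1+n2, n1)."""
    return 2.0 / comb(n1 + n2, n1)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------- per-tissue records
def differential_table(
    table: FeatureTable,
    tissue: str,
    convention: FCConvention = DEFAULT_CONVENTION,
) -> pd.DataFrame:
    """Differential records for every feature in one tissue.

    The input table must already be imputed.  Features absent in both groups
    of the tissue are recorded with ``presence="absent"`` and excluded from
    the test and from the tissue's FDR batch; group-exclusive features are
    still tested (their imputed vector is zeros vs non-zeros), so they can be
    counted among significant features.
    """
    if tissue not in set(table.sample_meta["tissue"]):
        raise KeyError(f"unknown tissue {tissue!r}")
    gf = table.group_matrix(tissue, convention.numerator)
    mpf = table.group_matrix(tissue, convention.denominator)

    mean_gf = gf.mean(axis=1)
    mean_mpf = mpf.mean(axis=1)
    gf_present = (gf > 0).any(axis=1)
    mpf_present = (mpf > 0).any(axis=1)
    presence = np.select(
        [
            gf_present & mpf_present,
            gf_present & ~mpf_present,
            ~gf_present & mpf_present,
        ],
        ["both", "gf_only", "mpf_only"],
        default="absent",
    )

    fc = np.full(len(mean_gf), np.nan)
    both = presence == "both"
    fc[both] = mean_gf[both] / mean_mpf[both]
    if convention.zero_handling == "floor":
        gfo = presence == "gf_only"
        mpo = presence == "mpf_only"
        fc[gfo] = mean_gf[gfo] / convention.floor_eps
        fc[mpo] = convention.floor_eps / mean_mpf[mpo]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc)

    tested = presence != "absent"
    p = np.full(len(mean_gf), np.nan)
    if tested.any():
        pooled = np.concatenate([gf[tested], mpf[tested]], axis=1)
        p[tested] = exact_mw_p_batch(pooled, gf.shape[1])
    q = np.full(len(mean_gf), np.nan)
    if tested.any():
        q[tested] = bh_fdr(p[tested])

    max_abundance = np.concatenate([gf, mpf], axis=1).max(axis=1)
    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "tissue": tissue,
            "mean_gf": mean_gf,
            "mean_mpf": mean_mpf,
            "fc": fc,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "presence": presence,
            "max_abundance": max_abundance,
        }
    ).reset_index(drop=True)


def differential_all_tissues(
    table: FeatureTable, convention: FCConvention = DEFAULT_CONVENTION
) -> pd.DataFrame:
    """Concatenated differential records for every tissue in the table."""
    parts = [differential_table(table, t, convention) for t in table.tissues]
    return pd.concat(parts, ignore_index=True)
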