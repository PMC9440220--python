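"""False-zero imputation for replicate intensity vectors.

Zeros in untargeted LC-MS feature tables are ambiguous: a metabolite may be
truly absent from a tissue/group (structural zero) or present but missed by
the instrument (dropout).  Before any statistics, each (feature, tissue,
group) replicate vector is resolved by a three-rule decision procedure built
on two thresholds: a zero-fraction cut (default 60% of replicates) and an
arbitrary raw-abundance cut (default 10,000 counts):

rule 1
    Zeros in more than 60% of the replicates: the zeros are taken as true
    absence and the remaining non-zero values are also set to zero.
rule 2
    Zeros in less than 60% of replicates but the non-zero values sit below
    the abundance threshold: still treated as true absence; everything is
    set to zero.
rule 3
    Zeros in less than 60% of replicates and the non-zero values sit above
    the abundance threshold: the zeros are judged false (dropout) and each
    is replaced by the arithmetic mean of the non-zero replicates.

Two cases the rules leave open are configurable: a zero fraction exactly
equal to the cut (default: routed to rule 1, the conservative choice), and
non-zero values straddling the abundance cut (default: the mean of the
non-zero values is compared against the cut, consistent with the rule-3
imputed value being that same mean).

Imputation is applied independently per mouse group within each tissue, and
the imputed matrix is the only matrix downstream stages see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .feature_table import FeatureTable

Rule = Literal["rule1", "rule2", "rule3", "none"]

BOUNDARY_RULES = ("rule1", "rule3_branch")
MIXED_RULES = ("mean", "all_above", "any_above")


@dataclass(frozen=True)
class ImputationPolicy:
    """Thresholds and tie-break conventions of the three-rule procedure.

    Parameters
    ----------
    zero_fraction_threshold
        Fraction of replicates that must be zero for rule 1 (default 0.60).
    abundance_threshold
        Raw-intensity cut separating rule 2 from rule 3 (default 10,000).
    boundary_rule
        Where a zero fraction *exactly equal* to the threshold is routed:
        ``"rule1"`` (default, treat as true zeros) or ``"rule3_branch"``
        (fall through to the rule-2/3 decision).
    mixed_rule
        How non-zero values straddling ``abundance_threshold`` are resolved:
        ``"mean"`` (default) compares their mean against the threshold,
        ``"all_above"`` requires every non-zero value at/above it for rule 3,
        ``"any_above"`` requires only one.
    """

    zero_fraction_threshold: float = 0.60
    abundance_threshold: float = 10_000.0
    boundary_rule: str = "rule1"
    mixed_rule: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.zero_fraction_threshold <= 1:
            raise ConfigurationError("zero_fraction_threshold must be in (0, 1]")
        if self.abundance_threshold <= 0:
            raise ConfigurationError("abundance_threshold must be positive")
        if self.boundary_rule not in BOUNDARY_RULES:
            raise ConfigurationError(f"boundary_rule must be one of {BOUNDARY_RULES}")
        if self.mixed_rule not in MIXED_RULES:
            raise ConfigurationError(f"mixed_rule must be one of {MIXED_RULES}")


DEFAULT_POLICY = ImputationPolicy()

#: Columns of the audit report produced by :func:`impute_table`.
REPORT_COLUMNS = (
    "feature_id",
    "tissue",
    "group",
    "rule_fired",
    "n_zeros_before",
    "n_zeros_after",
    "imputed_value",
)


def impute_group(
    values: np.ndarray | list[float], policy: ImputationPolicy = DEFAULT_POLICY
) -> tuple[np.ndarray, Rule]:
    """Apply the three-rule procedure to one replicate vector.

    Returns the imputed vector and which rule fired (``"none"`` when the
    vector holds no zeros and is passed through unchanged).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InputError("replicate vector must be 1-D with at least 2 values")
    if np.isnan(v).any() or (v < 0).any():
        raise InputError("replicate intensities must be non-negative and finite")

    n_zero = int((v == 0).sum())
    if n_zero == 0:
        return v.copy(), "none"

    zero_frac = n_zero / v.size
    thr = policy.zero_fraction_threshold
    if zero_frac > thr or (zero_frac == thr and policy.boundary_rule == "rule1"):
        return np.zeros_like(v), "rule1"

    nonzero = v[v > 0]
    if policy.mixed_rule == "mean":
        above = nonzero.mean() >= policy.abundance_threshold
    elif policy.mixed_rule == "all_above":
        above = bool((nonzero >= policy.abundance_threshold).all())
    else:  # any_above
        above = bool((nonzero >= policy.abundance_threshold).any())

    if not above:
        return np.zeros_like(v), "rule2"
    out = v.copy()
    out[out == 0] = nonzero.mean()
    return out, "rule3"


def _impute_block(block: np.ndarray, policy: ImputationPolicy):
    """Vectorized three-rule imputation over a (features x replicates) block.

    Returns the imputed block plus, per row, the rule fired and the rule-3
    imputed value (NaN elsewhere).  Semantics match :func:`impute_group`
    row-for-row.
    """
    block = np.asarray(block, dtype=float)
    n = block.shape[1]
    zeros = block == 0
    n_zero = zeros.sum(axis=1)
    has_zero = n_zero > 0

    zero_frac = n_zero / n
    thr = policy.zero_fraction_threshold
    rule1 = zero_frac > thr
    if policy.boundary_rule == "rule1":
        rule1 |= zero_frac == thr
    rule1 &= has_zero

    with np.errstate(invalid="ignore", divide="ignore"):
        nz_sum = block.sum(axis=1)
        nz_count = n - n_zero
        nz_mean = np.where(nz_count > 0, nz_sum / np.maximum(nz_count, 1), np.nan)
    masked = np.where(zeros, np.nan, block)
    if policy.mixed_rule == "mean":
        above = nz_mean >= policy.abundance_threshold
    elif policy.mixed_rule == "all_above":
        above = np.nanmin(np.where(nz_count[:, None] > 0, masked, np.inf), axis=1) >= (
            policy.abundance_threshold
        )
    else:  # any_above
        above = np.nanmax(np.where(nz_count[:, None] > 0, masked, -np.inf), axis=1) >= (
            policy.abundance_threshold
        )

    branch = has_zero & ~rule1
    rule2 = branch & ~above
    rule3 = branch & above

    out = block.copy()
    out[rule1 | rule2] = 0.0
    fill = np.where(rule3, nz_mean, np.nan)
    fill_at = zeros & rule3[:, None]
    out[fill_at] = np.broadcast_to(fill[:, None], out.shape)[fill_at]

    rules = np.full(block.shape[0], "none", dtype=object)
    rules[rule1] = "rule1"
    rules[rule2] = "rule2"
    rules[rule3] = "rule3"
    imputed_value = np.where(rule3, nz_mean, np.nan)
    return out, rules, n_zero, imputed_value


def impute_table(
    table: FeatureTable, policy: ImputationPolicy = DEFAULT_POLICY
) -> tuple[FeatureTable, pd.DataFrame]:
    """Impute every (feature, tissue, group) cell of a table independently.

    Returns the imputed table and an audit report with one row per cell in
    which any zero occurred, recording the rule fired, zero counts before
    and after, and the rule-3 imputed value.
    """
    vals = table.abundance.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any():
        raise InputError("abundance matrix must be non-negative and finite")

    out = table.abundance.copy()
    records: list[pd.DataFrame] = []
    col_pos = {s: i for i, s in enumerate(table.abundance.columns)}
    for tissue in table.tissues:
        for group in table.groups:
            cols = table.samples_for(tissue, group)
            if not cols:
                continue
            idx = [col_pos[c] for c in cols]
            block = vals[:, idx]
            imputed, rules, n_zero, imputed_value = _impute_block(block, policy)
            out.iloc[:, idx] = imputed
            touched = n_zero > 0
            if touched.any():
                records.append(
                    pd.DataFrame(
                        {
                            "feature_id": table.feature_ids[touched],
                            "tissue": tissue,
                            "group": group,
                            "rule_fired": rules[touched],
                            "n_zeros_before": n_zero[touched],
                            "n_zeros_after": (imputed[touched] == 0).sum(axis=1),
                            "imputed_value": imputed_value[touched],
                        }
                    )
                )
    if records:
        report = pd.concat(records, ignore_index=True)
    else:
        report = pd.DataFrame(columns=list(REPORT_COLUMNS))
    imputed_table = FeatureTable(out, table.feature_meta.copy(), table.sample_meta.copy())
    return imputed_table, report
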