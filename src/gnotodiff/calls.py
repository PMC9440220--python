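"""Inclusion filtering, volcano classification, presence calls, summaries.

After tissue-wise testing, differential records pass through a conjunctive
inclusion filter (fold change, p, q, raw-abundance, MS/MS and retention-time
criteria), are classified for volcano display with tissue-class-specific FC
windows, and are tallied per tissue into GF-only / MPF-only / shared counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .feature_table import FeatureTable
from .stats import Presence


@dataclass(frozen=True)
class InclusionPolicy:
    """Conjunctive significance filter applied to differential records.

    A record passes iff all of: fold change at least ``fc_min`` in either
    direction (``fc >= fc_min`` or ``fc <= 1/fc_min``; group-exclusive
    features count as passing the FC criterion), ``p <= p_max``,
    ``q <= q_max``, maximum raw abundance across the tissue's samples at
    least ``abundance_min``, an MS/MS spectrum present (if ``require_msms``),
    and retention time at least ``rt_min`` minutes.

    ``two_sided=False`` restores a literal one-sided reading of the FC
    criterion (``fc >= fc_min`` only).
    """

    fc_min: float = 1.3
    p_max: float = 0.05
    q_max: float = 0.05
    abundance_min: float = 100_000.0
    require_msms: bool = True
    rt_min: float = 0.7
    two_sided: bool = True

    def __post_init__(self) -> None:
        for name in ("fc_min", "p_max", "q_max", "abundance_min", "rt_min"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


DEFAULT_INCLUSION = InclusionPolicy()

#: Tissue classes for volcano FC windows: the large intestine shows the most
#: extreme fold changes, the small intestine the next most, everything else
#: a milder window.
VOLCANO_CLASSES: dict[str, tuple[str, ...]] = {
    "large_intestine": ("cecum", "colon"),
    "small_intestine": ("duodenum", "jejunum", "ileum"),
}


@dataclass(frozen=True)
class VolcanoPolicy:
    """Tissue-class FC windows and the q cut used for volcano highlighting.

    A feature is highlighted iff ``q < q_max`` and its FC falls outside the
    ``[fc_lo, fc_hi]`` window of its tissue's class.  Group-exclusive
    features are placed at the plot extremes by capping their FC at
    (non-zero group mean) / ``cap_eps``.
    """

    fc_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "large_intestine": (0.005, 200.0),
            "small_intestine": (0.01, 100.0),
            "other": (0.033, 30.0),
        }
    )
    q_max: float = 0.1
    cap_eps: float = 1.0

    def __post_init__(self) -> None:
        for cls, (lo, hi) in self.fc_windows.items():
            if not lo < 1 < hi:
                raise ConfigurationError(f"FC window for {cls!r} must satisfy lo < 1 < hi")
        if self.q_max <= 0:
            raise ConfigurationError("q_max must be positive")
        if self.cap_eps <= 0:
            raise ConfigurationError("cap_eps must be positive")

    def tissue_class(self, tissue: str) -> str:
        for cls, members in VOLCANO_CLASSES.items():
            if tissue in members:
                return cls
        return "other"

    def window(self, tissue: str) -> tuple[float, float]:
        return self.fc_windows[self.tissue_class(tissue)]


DEFAULT_VOLCANO = VolcanoPolicy()

REQUIRED_RECORD_FIELDS = ("feature_id", "tissue", "fc", "p", "q", "presence", "max_abundance")


def call_presence(gf_values: Sequence[float], mpf_values: Sequence[float]) -> Presence:
    """Presence call for one feature in one tissue from imputed vectors."""
    gf = np.asarray(gf_values, dtype=float)
    mpf = np.asarray(mpf_values, dtype=float)
    if gf.size < 2 or mpf.size < 2:
        raise InputError("each group needs at least 2 replicates")
    gf_present = bool((gf > 0).any())
    mpf_present = bool((mpf > 0).any())
    if gf_present and mpf_present:
        return "both"
    if gf_present:
        return "gf_only"
    if mpf_present:
        return "mpf_only"
    return "absent"


def _check_record_fields(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_RECORD_FIELDS if c not in records.columns]
    if missing:
        raise InputError(f"records missing required field(s) {missing}")


def apply_inclusion_filter(
    records: pd.DataFrame,
    feature_meta: pd.DataFrame,
    policy: InclusionPolicy = DEFAULT_INCLUSION,
) -> pd.DataFrame:
    """Subset of ``records`` passing every inclusion criterion.

    ``feature_meta`` supplies ``rt`` and ``has_msms`` per feature id;
    ``records`` must carry the per-tissue ``max_abundance`` computed by the
    differential stage.
    """
    _check_record_fields(records)
    for col in ("rt", "has_msms"):
        if col not in feature_meta.columns:
            raise InputError(f"feature_meta missing required column {col!r}")

    rec = records.merge(
        feature_meta[["rt", "has_msms"]],
        left_on="feature_id",
        right_index=True,
        how="left",
    )
    if rec["rt"].isna().any():
        missing = rec.loc[rec["rt"].isna(), "feature_id"].unique().tolist()[:5]
        raise InputError(f"records reference feature id(s) absent from feature_meta: {missing}")

    exclusive = rec["presence"].isin(["gf_only", "mpf_only"])
    fc_pass = rec["fc"] >= policy.fc_min
    if policy.two_sided:
        fc_pass |= rec["fc"] <= 1.0 / policy.fc_min
    fc_pass |= exclusive

    keep = (
        fc_pass
        & (rec["p"] <= policy.p_max)
        & (rec["q"] <= policy.q_max)
        & (rec["max_abundance"] >= policy.abundance_min)
        & (rec["rt"] >= policy.rt_min)
    )
    if policy.require_msms:
        keep &= rec["has_msms"].astype(bool)
    keep &= rec["presence"] != "absent"
    return records.loc[keep.to_numpy()].reset_index(drop=True)


def _capped_fc(rec: pd.DataFrame, cap_eps: float) -> np.ndarray:
    """FC with group-exclusive features mapped to the plot extremes."""
    fc = rec["fc"].to_numpy(dtype=float).copy()
    gfo = (rec["presence"] == "gf_only").to_numpy()
    mpo = (rec["presence"] == "mpf_only").to_numpy()
    fc[gfo] = rec.loc[gfo, "mean_gf"].to_numpy() / cap_eps
    fc[mpo] = cap_eps / rec.loc[mpo, "mean_mpf"].to_numpy()
    return fc


def volcano_classify(
    record: Mapping, tissue: str, policy: VolcanoPolicy = DEFAULT_VOLCANO
) -> str:
    """Classify one record as ``"highlighted"`` or ``"background"``."""
    lo, hi = policy.window(tissue)
    fc = record["fc"]
    presence = record.get("presence", "both")
    if presence == "gf_only":
        fc = record["mean_gf"] / policy.cap_eps
    elif presence == "mpf_only":
        fc = policy.cap_eps / record["mean_mpf"]
    if np.isnan(fc) or np.isnan(record["q"]):
        return "background"
    if record["q"] < policy.q_max and (fc > hi or fc < lo):
        return "highlighted"
    return "background"


def volcano_table(records: pd.DataFrame, policy: VolcanoPolicy = DEFAULT_VOLCANO) -> pd.DataFrame:
    """Volcano coordinates and highlight flags for a batch of records.

    Coordinates are (log2(FC), -log10(q)); exclusive features use the capped
    FC so they land at the extremes, but their presence flag is preserved for
    any downstream accounting.
    """
    _check_record_fields(records)
    rec = records[records["presence"] != "absent"].reset_index(drop=True)
    fc = _capped_fc(rec, policy.cap_eps)
    lohi = np.array([policy.window(t) for t in rec["tissue"]])
    q = rec["q"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        out = pd.DataFrame(
            {
                "feature_id": rec["feature_id"],
                "tissue": rec["tissue"],
                "log2fc": np.log2(fc),
                "neg_log10_q": -np.log10(q),
                "highlighted": (q < policy.q_max) & ((fc > lohi[:, 1]) | (fc < lohi[:, 0])),
            }
        )
    return out


def tabulate_tissue_summary(
    filtered: pd.DataFrame,
    all_records: pd.DataFrame,
    table: FeatureTable,
    uniqueness_among: str = "significant",
) -> pd.DataFrame:
    """Per-tissue detection and significance accounting.

    "Detected in a tissue" means any non-zero value after imputation in
    either group (presence != absent).  The GF-only / MPF-only / shared
    partition is taken over the filter-passing significant records by
    default (``uniqueness_among="significant"``, so the partition sums to
    ``n_significant``) or, with ``uniqueness_among="detected"``, over every
    detected feature (summing to ``n_detected``).  Two percentage
    denominators are reported: the union feature count
    (``pct_of_all_features``, ``pct_significant_of_union``) and the tissue's
    detected count (``pct_significant``).
    """
    _check_record_fields(all_records)
    if uniqueness_among not in ("significant", "detected"):
        raise ConfigurationError("uniqueness_among must be 'significant' or 'detected'")
    n_union = table.n_features
    rows = []
    for tissue in table.tissues:
        rec = all_records[all_records["tissue"] == tissue]
        sig = filtered[filtered["tissue"] == tissue]
        n_detected = int((rec["presence"] != "absent").sum())
        base = sig if uniqueness_among == "significant" else rec[rec["presence"] != "absent"]
        n_gf_only = int((base["presence"] == "gf_only").sum())
        n_mpf_only = int((base["presence"] == "mpf_only").sum())
        n_shared = int((base["presence"] == "both").sum())
        n_sig = len(sig)
        rows.append(
            {
                "tissue": tissue,
                "n_detected": n_detected,
                "pct_of_all_features": 100.0 * n_detected / n_union if n_union else 0.0,
                "n_significant": n_sig,
                "n_gf_only": n_gf_only,
                "n_mpf_only": n_mpf_only,
                "n_shared": n_shared,
                "pct_significant": 100.0 * n_sig / n_detected if n_detected else 0.0,
                "pct_significant_of_union": 100.0 * n_sig / n_union if n_union else 0.0,
            }
        )
    return pd.DataFrame(rows)


def heatmap_matrix(
    records: pd.DataFrame, metabolite_groups: Mapping[str, str]
) -> pd.DataFrame:
    """Direction-of-change matrix (metabolite label x tissue).

    ``records`` should already be filtered to significant features.  Cells
    take 1 where the metabolite is more abundant in GF mice (FC > 1 or
    GF-exclusive), -1 where more abundant in MPF, and 0 where not found.
    When several features share a display label, the cell takes the majority
    direction, broken by the mean log2 fold change.
    """
    _check_record_fields(records)
    unmapped = set(records["feature_id"]) - set(metabolite_groups)
    if unmapped:
        raise KeyError(f"feature id(s) without a metabolite label: {sorted(unmapped)[:5]}")

    rec = records[records["presence"] != "absent"].copy()
    rec["label"] = rec["feature_id"].map(metabolite_groups)
    sign = np.zeros(len(rec))
    sign[(rec["presence"] == "gf_only").to_numpy() | (rec["fc"] > 1).to_numpy()] = 1
    sign[(rec["presence"] == "mpf_only").to_numpy() | (rec["fc"] < 1).to_numpy()] = -1
    rec["sign"] = sign

    labels = sorted(set(metabolite_groups.values()))
    tissues = list(dict.fromkeys(records["tissue"]))
    out = pd.DataFrame(0, index=pd.Index(labels, name="metabolite"), columns=tissues, dtype=int)
    for (label, tissue), grp in rec.groupby(["label", "tissue"], sort=False):
        total = grp["sign"].sum()
        if total == 0:
            with np.errstate(invalid="ignore"):
                mean_l2 = np.nanmean(grp["log2fc"].to_numpy(dtype=float))
            total = 0.0 if np.isnan(mean_l2) else mean_l2
        out.loc[label, tissue] = int(np.sign(total))
    return out
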