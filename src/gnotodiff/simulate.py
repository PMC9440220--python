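"""Synthetic multi-tissue feature tables with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: four analytical modes with realistic feature counts, 13 tissues x
2 mouse groups (GF, MPF) x 5 replicates, log-normal intensities with
additive tissue and group effects on the log scale, tissue effects larger
than group effects, structural zeros (true absence of a feature in a
tissue or in one group), and intensity-dependent dropout zeros (a logistic
miss probability on log-intensity plus a hard detection floor).

Every feature x tissue combination carries a planted status recorded in a
:class:`GroundTruth` table, which is the oracle for scoring the presence
caller, the differential tests and the significance accounting.

Randomness is organized as one stream per feature, spawned from the single
global seed, so the output is bit-identical regardless of how features are
iterated or batched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .feature_table import DEFAULT_TISSUES, GROUPS, MODES, FeatureTable

#: Per-mode feature counts of the study design this generator emulates.
DEFAULT_FEATURES_PER_MODE: dict[str, int] = {
    "HILIC+": 5961,
    "HILIC-": 3946,
    "RP+": 9256,
    "RP-": 5131,
}

STATUSES = ("null", "up_in_GF", "down_in_GF", "GF_only", "MPF_only", "absent")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Intensity model (natural-log scale): each feature draws a baseline from
    N(``log_mean``, ``log_sd``); each tissue adds an offset from
    N(0, ``tissue_effect_sd``); replicates add N(0, ``replicate_sd``) noise.
    Differential features shift the GF group by +/- ``group_effect_log2fc``
    binary-log units.  A measured value is zeroed by dropout with logistic
    probability 1 / (1 + exp(``dropout_steepness`` * (ln x -
    ``dropout_midpoint``))) — monotonically non-increasing in intensity —
    and whenever it falls below ``detection_floor``.  Setting
    ``dropout_midpoint`` to None disables stochastic dropout.
    """

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    groups: tuple[str, str] = GROUPS
    n_replicates: int = 5
    n_features_per_mode: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURES_PER_MODE)
    )
    frac_differential: float = 0.10
    frac_exclusive: float = 0.05
    frac_absent: float = 0.30
    log_mean: float = 12.0
    log_sd: float = 1.0
    tissue_effect_sd: float = 1.2
    group_effect_log2fc: float = 2.0
    replicate_sd: float = 0.35
    dropout_midpoint: float | None = 7.6
    dropout_steepness: float = 2.5
    detection_floor: float = 500.0
    msms_prob: float = 0.8
    rt_range: tuple[float, float] = (0.2, 14.0)
    mz_range: tuple[float, float] = (70.0, 1500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.tissues = tuple(self.tissues)
        self.groups = tuple(self.groups)
        self.n_features_per_mode = dict(self.n_features_per_mode)
        self.rt_range = tuple(self.rt_range)
        self.mz_range = tuple(self.mz_range)
        self.validate()

    def validate(self) -> None:
        if not self.tissues:
            raise ConfigurationError("tissues: need at least one tissue")
        if len(set(self.tissues)) != len(self.tissues):
            raise ConfigurationError("tissues: names must be unique")
        if len(self.groups) != 2 or len(set(self.groups)) != 2:
            raise ConfigurationError("groups: exactly two distinct labels required")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates: need at least 2 replicates per group")
        if not self.n_features_per_mode:
            raise ConfigurationError("n_features_per_mode: need at least one mode")
        for mode, count in self.n_features_per_mode.items():
            if mode not in MODES:
                raise ConfigurationError(f"n_features_per_mode: unknown mode {mode!r}")
            if count < 1:
                raise ConfigurationError(f"n_features_per_mode: count for {mode!r} must be positive")
        for name in ("frac_differential", "frac_exclusive", "frac_absent", "msms_prob"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ConfigurationError(f"{name}: must lie in [0, 1]")
        if self.frac_differential + self.frac_exclusive + self.frac_absent > 1:
            raise ConfigurationError(
                "frac_differential + frac_exclusive + frac_absent must not exceed 1"
            )
        for name in ("log_sd", "tissue_effect_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be non-negative")
        if self.group_effect_log2fc < 0:
            raise ConfigurationError("group_effect_log2fc: must be non-negative")
        if self.dropout_steepness <= 0:
            raise ConfigurationError("dropout_steepness: must be positive")
        if self.detection_floor < 0:
            raise ConfigurationError("detection_floor: must be non-negative")
        if not 0 <= self.rt_range[0] < self.rt_range[1]:
            raise ConfigurationError("rt_range: need 0 <= lo < hi")
        if not 0 < self.mz_range[0] < self.mz_range[1]:
            raise ConfigurationError("mz_range: need 0 < lo < hi")

    @property
    def n_features(self) -> int:
        return sum(self.n_features_per_mode.values())

    # ------------------------------------------------------------- file I/O
    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["groups"] = list(self.groups)
        d["rt_range"] = list(self.rt_range)
        d["mz_range"] = list(self.mz_range)
        return d


@dataclass
class GroundTruth:
    """Planted status of every feature x tissue combination.

    ``table`` columns: feature_id, tissue, status, true_log2fc.  Statuses:
    ``null`` (no group effect; true_log2fc = 0), ``up_in_GF`` /
    ``down_in_GF`` (planted shift of +/- the configured log2 effect),
    ``GF_only`` / ``MPF_only`` (structural zeros in the other group;
    true_log2fc +/- inf), ``absent`` (structural zeros in both groups;
    true_log2fc NaN).
    """

    table: pd.DataFrame

    def status_of(self, feature_id: str, tissue: str) -> str:
        sel = self.table[
            (self.table["feature_id"] == feature_id) & (self.table["tissue"] == tissue)
        ]
        if sel.empty:
            raise KeyError(f"no ground truth for {feature_id!r} in {tissue!r}")
        return str(sel["status"].iloc[0])

    def counts(self, tissue: str | None = None) -> pd.Series:
        t = self.table if tissue is None else self.table[self.table["tissue"] == tissue]
        return t["status"].value_counts()


def dropout_probability(log_intensity: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Logistic miss probability on natural-log intensity (0 when disabled)."""
    x = np.asarray(log_intensity, dtype=float)
    if config.dropout_midpoint is None:
        return np.zeros_like(x)
    return 1.0 / (1.0 + np.exp(config.dropout_steepness * (x - config.dropout_midpoint)))


def _feature_rng(seed: int, index: int) -> np.random.Generator:
    """Independent stream for one feature, keyed by the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_feature_table(config: SimulationConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table plus the ground truth of every planted effect.

    Sample columns are ordered tissue-major (all replicates of GF, then MPF,
    within each tissue); feature rows are ordered by mode, already namespaced
    ``mode:F<index>``.  Every zero in the output is attributable either to a
    structural absence recorded in the ground truth or to dropout (stochastic
    miss or detection-floor censoring).
    """
    config.validate()
    tissues, groups = config.tissues, config.groups
    n_t, n_rep = len(tissues), config.n_replicates
    ln2 = np.log(2.0)

    sample_ids, sm_rows = [], []
    for tissue in tissues:
        for group in groups:
            for r in range(1, n_rep + 1):
                sample_ids.append(f"{tissue}_{group}_{r}")
                sm_rows.append({"tissue": tissue, "group": group, "replicate": r})
    sample_meta = pd.DataFrame(sm_rows, index=pd.Index(sample_ids, name="sample_id"))

    feature_ids: list[str] = []
    modes: list[str] = []
    for mode in MODES:
        count = config.n_features_per_mode.get(mode, 0)
        for j in range(count):
            feature_ids.append(f"{mode}:F{j:05d}")
            modes.append(mode)
    n_f = len(feature_ids)

    fa, fe, fd = config.frac_absent, config.frac_exclusive, config.frac_differential
    abundance = np.zeros((n_f, n_t * 2 * n_rep))
    mz = np.zeros(n_f)
    rt = np.zeros(n_f)
    has_msms = np.zeros(n_f, dtype=bool)
    gt_status = np.empty((n_f, n_t), dtype=object)
    gt_l2fc = np.zeros((n_f, n_t))

    for i in range(n_f):
        rng = _feature_rng(config.seed, i)
        mz[i] = rng.uniform(*config.mz_range)
        rt[i] = rng.uniform(*config.rt_range)
        has_msms[i] = rng.random() < config.msms_prob
        baseline = rng.normal(config.log_mean, config.log_sd)
        tissue_eff = rng.normal(0.0, config.tissue_effect_sd, n_t)
        u_status = rng.random(n_t)
        u_dir = rng.random(n_t)
        noise = rng.normal(0.0, config.replicate_sd, (n_t, 2, n_rep))
        u_drop = rng.random((n_t, 2, n_rep))

        # planted status per tissue
        absent = u_status < fa
        exclusive = ~absent & (u_status < fa + fe)
        differential = ~absent & ~exclusive & (u_status < fa + fe + fd)
        gf_side = u_dir < 0.5

        # natural-log intensities: tissue-major, group-major, replicate
        log_x = baseline + tissue_eff[:, None, None] + noise
        shift = np.zeros((n_t, 2))
        shift[differential & gf_side, 0] = ln2 * config.group_effect_log2fc
        shift[differential & ~gf_side, 0] = -ln2 * config.group_effect_log2fc
        log_x = log_x + shift[:, :, None]

        x = np.exp(log_x)
        if config.dropout_midpoint is not None:
            x[u_drop < dropout_probability(log_x, config)] = 0.0
        if config.detection_floor > 0:
            x[x < config.detection_floor] = 0.0

        # structural zeros
        x[absent] = 0.0
        x[exclusive & gf_side, 1] = 0.0  # GF-only: zero the MPF block
        x[exclusive & ~gf_side, 0] = 0.0  # MPF-only: zero the GF block

        abundance[i] = x.reshape(-1)

        status = np.full(n_t, "null", dtype=object)
        status[absent] = "absent"
        status[exclusive & gf_side] = "GF_only"
        status[exclusive & ~gf_side] = "MPF_only"
        status[differential & gf_side] = "up_in_GF"
        status[differential & ~gf_side] = "down_in_GF"
        gt_status[i] = status
        l2 = np.zeros(n_t)
        l2[differential & gf_side] = config.group_effect_log2fc
        l2[differential & ~gf_side] = -config.group_effect_log2fc
        l2[exclusive & gf_side] = np.inf
        l2[exclusive & ~gf_side] = -np.inf
        l2[absent] = np.nan
        gt_l2fc[i] = l2

    index = pd.Index(feature_ids, name="feature_id")
    abundance_df = pd.DataFrame(abundance, index=index, columns=sample_ids)
    feature_meta = pd.DataFrame(
        {"mode": modes, "mz": mz, "rt": rt, "has_msms": has_msms}, index=index
    )
    table = FeatureTable(abundance_df, feature_meta, sample_meta)

    gt = pd.DataFrame(
        {
            "feature_id": np.repeat(feature_ids, n_t),
            "tissue": np.tile(tissues, n_f),
            "status": gt_status.reshape(-1),
            "true_log2fc": gt_l2fc.reshape(-1),
        }
    )
    return table, GroundTruth(gt)


def plant_exclusive(
    table: FeatureTable, tissue: str, group: str, feature_ids: Sequence[str]
) -> FeatureTable:
    """Force the listed features to be exclusive to ``group`` in ``tissue``.

    All replicates of the *complementary* group are set to zero; the listed
    group's values are untouched.  Returns a new table.
    """
    missing = [f for f in feature_ids if f not in table.feature_ids]
    if missing:
        raise KeyError(f"unknown feature id(s): {missing}")
    groups = table.groups
    if group not in groups:
        raise KeyError(f"unknown group {group!r}")
    if tissue not in set(table.sample_meta["tissue"]):
        raise KeyError(f"unknown tissue {tissue!r}")
    other = [g for g in groups if g != group][0]
    out = table.copy()
    cols = out.samples_for(tissue, other)
    out.abundance.loc[list(feature_ids), cols] = 0.0
    return out
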