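"""Feature-table data model and delimited-text I/O.

The universal exchange object of the pipeline is the :class:`FeatureTable`:
a non-negative intensity matrix (molecular features x samples) together with
feature metadata (analytical mode, m/z, retention time, MS/MS flag) and
sample metadata (tissue, mouse group, replicate index).  Untargeted LC-MS
experiments acquire several analytical modes (reversed-phase and HILIC
chromatography, positive and negative ionization); per-mode tables are merged
into one combined matrix before any statistics.

On disk a table is a pair of delimited files: a feature table with one row
per molecular feature (metadata columns followed by one column per sample)
and a companion sample sheet keyed by sample id.  Intensities are serialized
at full ``repr`` precision so that threshold rules applied downstream cannot
flip on an I/O round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError

#: The four LC-MS acquisition configurations used throughout.
MODES: tuple[str, ...] = ("RP+", "RP-", "HILIC+", "HILIC-")

#: Mouse groups: germ-free ("treatment") and murine-pathogen-free ("control").
GROUPS: tuple[str, str] = ("GF", "MPF")

#: The thirteen tissues profiled in the study design this pipeline targets.
DEFAULT_TISSUES: tuple[str, ...] = (
    "plasma",
    "heart",
    "liver",
    "pancreas",
    "muscle",
    "duodenum",
    "jejunum",
    "ileum",
    "cecum",
    "colon",
    "VAT",
    "SAT",
    "BAT",
)

FEATURE_META_COLUMNS = ("mode", "mz", "rt", "has_msms")
SAMPLE_META_COLUMNS = ("tissue", "group", "replicate")


@dataclass(frozen=True)
class TableSchema:
    """Column layout of the delimited dialect.

    The feature file carries ``feature_id``, the metadata columns, then one
    column per sample id; the sample sheet carries ``sample_id`` plus the
    sample metadata columns.
    """

    feature_id_column: str = "feature_id"
    sample_id_column: str = "sample_id"
    feature_meta_columns: tuple[str, ...] = FEATURE_META_COLUMNS
    sample_meta_columns: tuple[str, ...] = SAMPLE_META_COLUMNS
    version: str = "1"


DEFAULT_SCHEMA = TableSchema()


@dataclass
class FeatureTable:
    """In-memory feature table: intensities plus feature and sample metadata.

    Parameters
    ----------
    abundance
        DataFrame of non-negative intensities, indexed by ``feature_id`` with
        one column per ``sample_id``.
    feature_meta
        DataFrame indexed by ``feature_id`` with columns
        ``mode, mz, rt, has_msms``.
    sample_meta
        DataFrame indexed by ``sample_id`` with columns
        ``tissue, group, replicate``.
    """

    abundance: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    # ------------------------------------------------------------------ views
    @property
    def n_features(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["tissue"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["group"]))

    def samples_for(self, tissue: str | None = None, group: str | None = None) -> list[str]:
        """Sample ids matching the given tissue and/or group, in sheet order."""
        mask = pd.Series(True, index=self.sample_meta.index)
        if tissue is not None:
            mask &= self.sample_meta["tissue"] == tissue
        if group is not None:
            mask &= self.sample_meta["group"] == group
        return list(self.sample_meta.index[mask])

    def group_matrix(self, tissue: str, group: str) -> np.ndarray:
        """Replicate intensity matrix (features x replicates) for one cell."""
        cols = self.samples_for(tissue, group)
        if not cols:
            raise KeyError(f"no samples for tissue={tissue!r}, group={group!r}")
        return self.abundance[cols].to_numpy()

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.abundance.copy(), self.feature_meta.copy(), self.sample_meta.copy()
        )

    # ------------------------------------------------------------- validation
    def validate(self) -> list[str]:
        """Check every schema invariant; return all violations, not just the first."""
        problems: list[str] = []
        ab, fm, sm = self.abundance, self.feature_meta, self.sample_meta

        if ab.index.has_duplicates:
            dups = ab.index[ab.index.duplicated()].unique().tolist()
            problems.append(f"duplicate feature_id(s): {dups}")
        if ab.columns.has_duplicates:
            dups = ab.columns[ab.columns.duplicated()].unique().tolist()
            problems.append(f"duplicate sample_id(s): {dups}")
        if not ab.index.equals(fm.index):
            problems.append("abundance rows and feature_meta index disagree")
        if not ab.columns.equals(pd.Index(sm.index)):
            problems.append("abundance columns and sample_meta index disagree")

        vals = ab.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            problems.append("abundance matrix is not numeric")
        else:
            if np.isnan(vals).any():
                rows = ab.index[np.isnan(vals).any(axis=1)].tolist()[:5]
                problems.append(f"NaN intensities in feature(s) {rows}")
            neg = np.asarray(vals < 0)
            if neg.any():
                r, c = np.argwhere(neg)[0]
                problems.append(
                    f"negative intensity at feature {ab.index[r]!r}, sample {ab.columns[c]!r}"
                )

        missing_cols = [c for c in FEATURE_META_COLUMNS if c not in fm.columns] + [
            c for c in SAMPLE_META_COLUMNS if c not in sm.columns
        ]
        if missing_cols:
            problems.extend(f"metadata missing column {c!r}" for c in missing_cols)
            return problems

        bad_mode = ~fm["mode"].isin(MODES)
        if bad_mode.any():
            problems.append(
                f"unknown analytical mode(s) {sorted(fm.loc[bad_mode, 'mode'].unique())}"
            )
        if (fm["mz"] <= 0).any():
            problems.append("non-positive m/z in feature_meta")
        if (fm["rt"] < 0).any():
            problems.append("negative retention time in feature_meta")

        bad_group = ~sm["group"].isin(GROUPS)
        if bad_group.any():
            problems.append(f"unknown group label(s) {sorted(sm.loc[bad_group, 'group'].unique())}")
        if (pd.to_numeric(sm["replicate"], errors="coerce").fillna(0) < 1).any():
            problems.append("replicate indices must be positive integers")

        key = sm[["tissue", "group", "replicate"]].astype(str).agg("/".join, axis=1)
        if key.duplicated().any():
            problems.append(
                f"duplicate (tissue, group, replicate) assignment(s): "
                f"{key[key.duplicated()].unique().tolist()}"
            )
        cell_sizes = sm.groupby(["tissue", "group"], sort=False).size()
        small = cell_sizes[cell_sizes < 2]
        if len(small):
            problems.append(
                f"(tissue, group) cells with fewer than 2 replicates: {small.index.tolist()}"
            )
        return problems

    def require_valid(self) -> "FeatureTable":
        problems = self.validate()
        if problems:
            raise SchemaError("; ".join(problems))
        return self


def tables_equal(a: FeatureTable, b: FeatureTable) -> bool:
    """Exact equality of matrices and metadata (used for round-trip checks)."""
    try:
        pd.testing.assert_frame_equal(a.abundance, b.abundance, check_exact=True)
        pd.testing.assert_frame_equal(a.feature_meta, b.feature_meta, check_exact=True)
        pd.testing.assert_frame_equal(a.sample_meta, b.sample_meta, check_exact=True)
    except AssertionError:
        return False
    return True


# ---------------------------------------------------------------------- I/O
def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


_BOOL_MAP = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    mapped = series.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if mapped.isna().any():
        bad = series[mapped.isna()].unique().tolist()
        raise SchemaError(f"column {column!r} holds non-boolean value(s) {bad}")
    return mapped.astype(bool)


def read_table(
    features_path: str | Path,
    samples_path: str | Path,
    schema: TableSchema = DEFAULT_SCHEMA,
) -> FeatureTable:
    """Read and validate a feature table from its two delimited files.

    Raises :class:`SchemaError` listing every violation found.
    """
    features_path, samples_path = Path(features_path), Path(samples_path)
    feat = pd.read_csv(features_path, sep=_sep_for(features_path), float_precision="round_trip")
    samp = pd.read_csv(samples_path, sep=_sep_for(samples_path))

    problems = []
    if schema.feature_id_column not in feat.columns:
        problems.append(f"feature file missing column {schema.feature_id_column!r}")
    for col in schema.feature_meta_columns:
        if col not in feat.columns:
            problems.append(f"feature file missing column {col!r}")
    if schema.sample_id_column not in samp.columns:
        problems.append(f"sample sheet missing column {schema.sample_id_column!r}")
    for col in schema.sample_meta_columns:
        if col not in samp.columns:
            problems.append(f"sample sheet missing column {col!r}")
    if problems:
        raise SchemaError("; ".join(problems))

    feat = feat.set_index(schema.feature_id_column)
    samp = samp.set_index(schema.sample_id_column)
    feature_meta = feat[list(schema.feature_meta_columns)].copy()
    feature_meta["has_msms"] = _parse_bool(feature_meta["has_msms"], "has_msms")
    sample_cols = [c for c in feat.columns if c not in schema.feature_meta_columns]
    missing = [s for s in samp.index if s not in sample_cols]
    if missing:
        raise SchemaError(f"feature file lacks column(s) for sample(s) {missing}")
    abundance = feat[list(samp.index)].astype(float)

    table = FeatureTable(abundance, feature_meta, samp[list(schema.sample_meta_columns)].copy())
    return table.require_valid()


def write_table(
    table: FeatureTable,
    features_path: str | Path,
    samples_path: str | Path,
    schema: TableSchema = DEFAULT_SCHEMA,
) -> None:
    """Write a table to its two delimited files at full float precision."""
    features_path, samples_path = Path(features_path), Path(samples_path)
    out = pd.concat([table.feature_meta, table.abundance], axis=1)
    out.index.name = schema.feature_id_column
    out.to_csv(features_path, sep=_sep_for(features_path))
    sm = table.sample_meta.copy()
    sm.index.name = schema.sample_id_column
    sm.to_csv(samples_path, sep=_sep_for(samples_path))


# ------------------------------------------------------------------- algebra
def namespace_feature_ids(table: FeatureTable) -> FeatureTable:
    """Prefix each feature id with its analytical mode (``mode:id``).

    Ids already carrying their mode prefix are left untouched, so the
    operation is idempotent.
    """
    fm = table.feature_meta
    new_ids = [
        fid if str(fid).startswith(f"{mode}:") else f"{mode}:{fid}"
        for fid, mode in zip(fm.index, fm["mode"])
    ]
    ab = table.abundance.copy()
    fm = fm.copy()
    ab.index = pd.Index(new_ids, name=ab.index.name)
    fm.index = pd.Index(new_ids, name=fm.index.name)
    return FeatureTable(ab, fm, table.sample_meta.copy())


def merge_modes(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Concatenate per-mode tables into one combined matrix.

    All inputs must describe the same samples (the same sample sheet up to
    row order); feature ids are namespaced by mode so the merged index is
    unique.  The merged feature count is the sum of the input feature counts.
    """
    if not tables:
        raise AlignmentError("merge_modes needs at least one table")
    ref = tables[0].sample_meta.sort_index()
    for i, t in enumerate(tables[1:], start=2):
        sm = t.sample_meta.sort_index()
        if not ref.index.equals(sm.index):
            missing = sorted(set(ref.index).symmetric_difference(sm.index))
            raise AlignmentError(f"table {i} sample set differs; offending samples: {missing}")
        if not ref.equals(sm):
            diff = ref.compare(sm)
            raise AlignmentError(f"table {i} sample metadata differs for: {list(diff.index)}")

    order = list(tables[0].sample_meta.index)
    parts = [namespace_feature_ids(t) for t in tables]
    abundance = pd.concat([p.abundance[order] for p in parts], axis=0)
    feature_meta = pd.concat([p.feature_meta for p in parts], axis=0)
    if abundance.index.has_duplicates:
        dups = abundance.index[abundance.index.duplicated()].unique().tolist()
        raise AlignmentError(f"feature ids collide across tables even after namespacing: {dups}")
    merged = FeatureTable(abundance, feature_meta, tables[0].sample_meta.copy())
    return merged.require_valid()


def subset(
    table: FeatureTable, tissue: str | None = None, group: str | None = None
) -> FeatureTable:
    """Restrict the table to one tissue and/or group; feature rows unchanged."""
    if tissue is not None and tissue not in set(table.sample_meta["tissue"]):
        raise KeyError(f"unknown tissue {tissue!r}")
    if group is not None and group not in set(table.sample_meta["group"]):
        raise KeyError(f"unknown group {group!r}")
    cols = table.samples_for(tissue, group)
    return FeatureTable(
        table.abundance[cols].copy(),
        table.feature_meta.copy(),
        table.sample_meta.loc[cols].copy(),
    )
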