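"""Abundance tables, sample metadata and compositional transforms.

Taxon-by-sample abundance matrices are the universal input of every
downstream stage.  Tables carry a feature ``level`` (species, genus or
pathway) and a ``scale`` describing what the numbers mean:

* ``counts`` -- nonnegative read counts,
* ``relative`` -- per-sample proportions summing to one,
* ``clr`` -- centered log-ratio transformed values summing to zero per sample,
* ``range_scaled`` -- per-taxon affine rescaling to [0, 1].

The centered log-ratio transform is the default normalisation for all
abundance-association analyses: for a composition ``x`` (with an additive
pseudocount ``c`` replacing zeros),

    clr_i(x) = ln(x_i + c) - mean_j ln(x_j + c)

which removes the unit-sum constraint that otherwise induces spurious
negative correlations between taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "SCALES",
    "AbundanceTable",
    "SampleMetadata",
    "StudyCollection",
    "ParseError",
    "ValidationError",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "to_relative",
    "clr_transform",
    "auto_pseudocount",
    "filter_prevalent_taxa",
    "range_scale",
    "range_scale_table",
]

LEVELS = ("species", "genus", "pathway")
SCALES = ("counts", "relative", "clr", "range_scaled")

METADATA_COLUMNS = ("sample_id", "study_id", "age", "data_type", "health_status")
DATA_TYPES = ("shotgun", "amplicon")
HEALTH_STATUSES = ("control", "case", "unknown")

_REL_TOL = 1e-9


class ParseError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when a table or metadata object violates its invariants."""


@dataclass
class AbundanceTable:
    """A taxon-by-sample abundance matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are taxa, columns are samples.
    level : str
        One of ``species``, ``genus``, ``pathway``.
    scale : str
        One of ``counts``, ``relative``, ``clr``, ``range_scaled``.
    """

    values: pd.DataFrame
    level: str = "species"
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        vals = self.values
        if not isinstance(vals, pd.DataFrame):
            vals = pd.DataFrame(vals)
            self.values = vals
        if vals.shape[0] == 0 or vals.shape[1] == 0:
            raise ValidationError("empty abundance table")
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if vals.columns.has_duplicates:
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("abundance values must be numeric")
        if np.isnan(arr).any():
            raise ValidationError("abundance values must not contain NaN")
        if self.scale in ("counts", "relative", "range_scaled") and (arr < 0).any():
            raise ValidationError(f"{self.scale} values must be nonnegative")
        if self.scale == "relative":
            sums = arr.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > _REL_TOL)[0]
            if bad.size:
                raise ValidationError(
                    f"relative columns must sum to 1; offending samples: "
                    f"{list(vals.columns[bad[:5]])}"
                )
        if self.scale == "clr":
            sums = arr.sum(axis=0)
            bad = np.where(np.abs(sums) > _REL_TOL * max(1, arr.shape[0]))[0]
            if bad.size:
                raise ValidationError(
                    f"clr columns must sum to 0; offending samples: "
                    f"{list(vals.columns[bad[:5]])}"
                )

    @property
    def taxon_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[:, list(sample_ids)], self.level, self.scale)

    def subset_taxa(self, taxon_ids: Iterable) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[list(taxon_ids)], self.level, self.scale)


@dataclass
class SampleMetadata:
    """Per-sample metadata: study assignment, age, profiling type, clinical measures.

    Any column beyond the required five is treated as a clinical measure
    (continuous or binary; missing values allowed).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups[:5]}")
        age = pd.to_numeric(df["age"], errors="coerce")
        ok = age.isna() | ((age >= 0) & (age <= 130))
        if not ok.all():
            raise ValidationError("age values must be missing or within [0, 130]")
        self.frame = df.copy()
        self.frame["age"] = age
        bad_dt = set(df["data_type"].dropna()) - set(DATA_TYPES)
        if bad_dt:
            raise ValidationError(f"unknown data_type values: {sorted(bad_dt)}")
        bad_hs = set(df["health_status"].dropna()) - set(HEALTH_STATUSES)
        if bad_hs:
            raise ValidationError(f"unknown health_status values: {sorted(bad_hs)}")
        for col in self.clinical_columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            self.frame[col] = vals
        self.frame = self.frame.set_index("sample_id", drop=False)

    @property
    def clinical_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in METADATA_COLUMNS]

    @property
    def sample_ids(self) -> list:
        return list(self.frame["sample_id"])

    def for_samples(self, sample_ids: Iterable) -> pd.DataFrame:
        return self.frame.loc[list(sample_ids)]


@dataclass
class StudyCollection:
    """A set of per-study abundance tables sharing one metadata frame.

    Every per-study computation downstream (summary indices, robust fits,
    networks) iterates over ``tables``; the metadata supplies age, profiling
    type, health status and clinical measures for each sample.
    """

    tables: dict
    metadata: SampleMetadata
    repository: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        meta_studies = set(self.metadata.frame["study_id"])
        table_studies = set(self.tables)
        if table_studies != meta_studies:
            raise ValidationError(
                f"study ids disagree between tables ({sorted(table_studies)}) "
                f"and metadata ({sorted(meta_studies)})"
            )
        known = set(self.metadata.frame["sample_id"])
        for study, table in self.tables.items():
            unknown = [s for s in table.sample_ids if s not in known]
            if unknown:
                raise ValidationError(
                    f"study {study!r} contains samples without metadata: {unknown[:5]}"
                )
        if not self.repository:
            self.repository = {s: s for s in self.tables}

    @property
    def study_ids(self) -> list[str]:
        return sorted(self.tables)

    def study_metadata(self, study_id: str) -> pd.DataFrame:
        return self.metadata.for_samples(self.tables[study_id].sample_ids)

    def sample_to_study(self) -> pd.Series:
        pairs = []
        for study, table in self.tables.items():
            pairs.extend((s, study) for s in table.sample_ids)
        idx, vals = zip(*pairs)
        return pd.Series(vals, index=pd.Index(idx, name="sample_id"), name="study_id")


# ---------------------------------------------------------------------------
# I/O


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ParseError(f"{path}: header row is neither tab- nor comma-delimited")


def read_abundance_table(path, level: str = "species", scale: str = "counts") -> AbundanceTable:
    """Read a taxon-by-sample abundance TSV (first column ``taxon_id``).

    Both tab and comma dialects are accepted; tab is canonical on write.
    Strict numeric parsing: any non-numeric cell is a :class:`ParseError`
    naming its location.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty table")
    try:
        # float() per cell: correctly-rounded parsing (bitwise round-trip)
        numeric = df.astype(float)
    except (ValueError, TypeError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        rows = bad.any(axis=1)
        row = bad.index[rows][0]
        col = bad.columns[bad.loc[row]][0]
        raise ParseError(f"{path}: non-numeric cell at taxon {row!r}, sample {col!r}") from None
    if numeric.isna().any().any():
        rows = numeric.isna().any(axis=1)
        row = numeric.index[rows][0]
        raise ParseError(f"{path}: missing value in row {row!r}")
    try:
        return AbundanceTable(numeric, level=level, scale=scale)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write a table as tab-delimited text with a ``taxon_id`` index column."""
    out = table.values.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_sample_metadata(path) -> SampleMetadata:
    """Read a metadata TSV (required columns: sample_id, study_id, age,
    data_type, health_status; extra columns become clinical measures)."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype={"sample_id": str})
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Transforms


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample (column) by its total. Idempotent on relative input."""
    if table.scale not in ("counts", "relative"):
        raise ValidationError(f"to_relative requires counts or relative scale, got {table.scale}")
    arr = table.values.to_numpy(dtype=float)
    sums = arr.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValidationError(
            f"all-zero samples cannot be normalised: {list(table.values.columns[zero[:5]])}"
        )
    rel = pd.DataFrame(arr / sums, index=table.values.index, columns=table.values.columns)
    return AbundanceTable(rel, level=table.level, scale="relative")


def auto_pseudocount(table: AbundanceTable) -> float:
    """Half the smallest nonzero relative abundance in the table.

    The conventional additive replacement for zeros before a log-ratio
    transform: it sits below every observed value, preserving rank order.
    """
    rel = table if table.scale == "relative" else to_relative(table)
    arr = rel.values.to_numpy()
    nz = arr[arr > 0]
    if nz.size == 0:
        raise ValidationError("table has no nonzero entries")
    return float(nz.min() / 2.0)


def clr_transform(table: AbundanceTable, pseudocount: float | str = "auto") -> AbundanceTable:
    """Centered log-ratio transform, per sample.

    Counts are first closed to relative abundances; the pseudocount is then
    added on the relative scale.  ``pseudocount="auto"`` uses
    :func:`auto_pseudocount`.  A zero pseudocount is only valid when the
    table has no zeros.
    """
    if table.scale not in ("counts", "relative"):
        raise ValidationError(f"clr requires counts or relative scale, got {table.scale}")
    rel = to_relative(table)
    arr = rel.values.to_numpy(dtype=float)
    if pseudocount == "auto":
        pc = auto_pseudocount(rel)
    else:
        pc = float(pseudocount)
    if pc < 0:
        raise ValidationError("pseudocount must be nonnegative")
    if pc == 0 and (arr == 0).any():
        raise ValidationError("pseudocount must be positive when zeros are present")
    logs = np.log(arr + pc)
    clr = logs - logs.mean(axis=0, keepdims=True)
    out = pd.DataFrame(clr, index=rel.values.index, columns=rel.values.columns)
    return AbundanceTable(out, level=table.level, scale="clr")


def filter_prevalent_taxa(
    collection: StudyCollection,
    min_sample_frac: float = 0.05,
    min_study_frac: float = 0.60,
    per_data_type: bool = True,
) -> list:
    """Taxa detected in >= ``min_sample_frac`` of samples within >=
    ``min_study_frac`` of studies.

    With ``per_data_type`` the criterion must hold separately within each
    profiling-type stratum (shotgun and amplicon), so that only taxa robustly
    observed under both technologies survive.  Detection means abundance > 0
    on the counts or relative scale.
    """
    for name, val in (("min_sample_frac", min_sample_frac), ("min_study_frac", min_study_frac)):
        if not 0 <= val <= 1:
            raise ValidationError(f"{name} must lie in [0, 1], got {val}")
    meta = collection.metadata.frame
    study_dt = meta.groupby("study_id")["data_type"].agg(lambda s: s.mode().iat[0])
    all_taxa = sorted({t for tab in collection.tables.values() for t in tab.taxon_ids})

    strata: dict[str, list[str]] = {}
    if per_data_type:
        for study in collection.study_ids:
            strata.setdefault(str(study_dt.get(study, "shotgun")), []).append(study)
    else:
        strata["all"] = list(collection.study_ids)

    keep = []
    for taxon in all_taxa:
        ok_all = True
        for studies in strata.values():
            n_pass = 0
            for study in studies:
                table = collection.tables[study]
                if table.scale not in ("counts", "relative"):
                    raise ValidationError("prevalence filtering requires counts or relative scale")
                if taxon in table.values.index:
                    frac = float((table.values.loc[taxon] > 0).mean())
                else:
                    frac = 0.0
                if frac >= min_sample_frac:
                    n_pass += 1
            if n_pass < min_study_frac * len(studies):
                ok_all = False
                break
        if ok_all:
            keep.append(taxon)
    return keep


def range_scale(values) -> np.ndarray:
    """Affine rescaling of a vector to [0, 1].

    Degenerate constant vectors map to all zeros with a warning so that
    group means over rosters stay defined.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("range_scale requires a vector of length >= 2")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn("range_scale: constant vector mapped to zeros", RuntimeWarning, stacklevel=2)
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def range_scale_table(table: AbundanceTable) -> AbundanceTable:
    """Range-scale every taxon (row) across the table's samples."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scaled = np.vstack([range_scale(row) for row in table.values.to_numpy()])
    out = pd.DataFrame(scaled, index=table.values.index, columns=table.values.columns)
    return AbundanceTable(out, level=table.level, scale="range_scaled")
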