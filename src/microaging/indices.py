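"""Shannon diversity, pairwise microbiome distances and uniqueness.

Uniqueness of a sample is its distance to the nearest other sample in a
reference population (here: the sample's own study).  Four distance schemes
are supported, each sensitive to a different aspect of community variation:

* Bray-Curtis  ``d = sum |x_i - y_i| / sum (x_i + y_i)`` -- abundance shifts,
* Jaccard      ``d = 1 - |presence intersection| / |presence union|`` -- detection,
* Aitchison    Euclidean distance between clr vectors -- compositional shifts,
* Kendall      ``d = (1 - tau_b) / 2`` -- reordering of the abundance
  hierarchy, computed over the taxa detected in at least one of the two
  samples (taxa absent from both are dropped so that shared zeros do not
  dilute the rank correlation).

High Bray-Curtis/Jaccard/Aitchison uniqueness tracks gain of rare content;
high Kendall uniqueness tracks loss of the community's internal rank
structure, which is why it can move opposite to Shannon diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profiles import AbundanceTable, StudyCollection, ValidationError, clr_transform

__all__ = [
    "METRICS",
    "DistanceMatrix",
    "shannon_diversity",
    "pairwise_distances",
    "kendall_tau_b_matrix",
    "uniqueness",
    "diversity_adjusted_uniqueness",
    "compute_summary_indices",
]

METRICS = ("bray_curtis", "jaccard", "aitchison", "kendall")

#: short column suffixes used in output tables
METRIC_ABBREV = {"bray_curtis": "bc", "jaccard": "jac", "aitchison": "ait", "kendall": "ken"}


@dataclass
class DistanceMatrix:
    """A symmetric pairwise sample-distance matrix for one metric."""

    values: np.ndarray
    sample_ids: list
    metric: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError("distance matrix must be square")
        if arr.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix does not match sample ids")
        if np.abs(np.diag(arr)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix must have a zero diagonal")
        if np.abs(arr - arr.T).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix must be symmetric")
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if (arr < -1e-12).any():
            raise ValidationError("distances must be nonnegative")
        if self.metric != "aitchison" and (arr > 1 + 1e-9).any():
            raise ValidationError(f"{self.metric} distances must lie in [0, 1]")
        self.values = arr

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def shannon_diversity(table: AbundanceTable) -> pd.Series:
    """Shannon index H = -sum p_i ln p_i (natural log) per sample."""
    if table.scale not in ("counts", "relative"):
        raise ValidationError(f"shannon requires counts or relative scale, got {table.scale}")
    arr = table.values.to_numpy(dtype=float)
    sums = arr.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValidationError(
            f"all-zero samples have undefined diversity: "
            f"{list(table.values.columns[zero[:5]])}"
        )
    p = arr / sums
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return pd.Series(terms.sum(axis=0), index=table.values.columns, name="shannon")


def kendall_tau_b_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs tie-corrected Kendall ``tau_b`` between the columns of ``X``.

    For each pair of samples the correlation is computed over the union of
    taxa detected in at least one of the two samples.  Rather than looping
    over pairs, the concordance counts are obtained from an inner product of
    per-sample pairwise sign matrices, with a closed-form correction removing
    the contribution of taxa absent from both samples:

    with ``A_x[i,j] = sign(x_i - x_j)`` flattened into a row of ``M``,
    ``(M M^T)_{xy} = 2 (C - D)`` over the full taxon set and
    ``(M M^T)_{xx} = 2 (#pairs not tied in x)``.  A pair of taxa both absent
    from x and y contributes nothing to the numerator; pairs formed by one
    both-absent taxon and one detected taxon are removed by counting
    both-absent taxa (``m``) against shared-presence (``p``) and per-sample
    richness (``n_x``):

        C - D (union)  = (M M^T)_{xy} / 2 - m * p
        ties term for x = (M M^T)_{xx} / 2 - m * n_x

    giving ``tau_b = (C - D) / sqrt(tx * ty)`` exactly, fully vectorised.
    """
    X = np.asarray(X, dtype=float)
    S, n = X.shape
    if S < 2:
        raise ValidationError("kendall distance requires at least 2 taxa")
    const = np.where(np.ptp(X, axis=0) == 0)[0]
    if const.size:
        raise ValidationError(f"constant-rank samples (column indices): {const[:5].tolist()}")
    iu, ju = np.triu_indices(S, k=1)
    # sign matrices, flattened upper triangles: shape (n, S*(S-1)/2)
    signs = np.sign(X[iu, :] - X[ju, :]).T.astype(np.float32)
    # float32 matmul of +/-1/0 entries sums exact integers (S*(S-1)/2 < 2^24);
    # cast to float64 before any division
    N = (signs @ signs.T).astype(np.float64)
    tx_full = np.diag(N).copy()  # # non-tied pairs in each sample (full set)

    present = (X > 0).astype(np.float64)
    n_present = present.sum(axis=0)
    p_shared = present.T @ present  # both-present counts
    absent = 1.0 - present
    m_both = absent.T @ absent  # both-absent counts

    num = N - m_both * p_shared
    tx = tx_full[:, None] - m_both * n_present[:, None]
    ty = tx_full[None, :] - m_both * n_present[None, :]
    denom = np.sqrt(np.maximum(tx, 0.0) * np.maximum(ty, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tau, 1.0)
    tau = np.clip(tau, -1.0, 1.0)
    return ((tau + tau.T) / 2.0).astype(float)


def pairwise_distances(
    table: AbundanceTable, metric: str, pseudocount: float | str = "auto"
) -> DistanceMatrix:
    """Pairwise sample distances under one of the four supported metrics.

    Aitchison distance computes the clr transform internally (with
    ``pseudocount``) unless the table is already on the clr scale.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    if table.shape[0] < 2:
        raise ValidationError("pairwise distances require at least 2 taxa")
    ids = table.sample_ids
    arr = table.values.to_numpy(dtype=float)
    if metric == "bray_curtis":
        if table.scale not in ("counts", "relative"):
            raise ValidationError("bray_curtis requires counts or relative scale")
        d = squareform(pdist(arr.T, metric="braycurtis"))
    elif metric == "jaccard":
        if table.scale not in ("counts", "relative"):
            raise ValidationError("jaccard requires counts or relative scale")
        d = squareform(pdist(arr.T > 0, metric="jaccard"))
    elif metric == "aitchison":
        clr = table if table.scale == "clr" else clr_transform(table, pseudocount)
        d = squareform(pdist(clr.values.to_numpy().T, metric="euclidean"))
    else:  # kendall
        if table.scale not in ("counts", "relative", "clr"):
            raise ValidationError("kendall requires counts, relative or clr scale")
        tau = kendall_tau_b_matrix(arr)
        d = (1.0 - tau) / 2.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids, metric)


def uniqueness(dist: DistanceMatrix, grouping) -> pd.Series:
    """Distance to the nearest other sample within the same study.

    ``grouping`` maps sample id to study id; every study needs at least two
    samples for the minimum to exist.
    """
    groups = pd.Series(grouping)
    groups = groups.reindex(dist.sample_ids)
    if groups.isna().any():
        missing = [s for s, g in zip(dist.sample_ids, groups) if pd.isna(g)]
        raise ValidationError(f"samples without study assignment: {missing[:5]}")
    sizes = groups.value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        raise ValidationError(f"singleton studies (no reference neighbour): {singletons}")
    out = np.empty(dist.n)
    idx = np.arange(dist.n)
    for study in sizes.index:
        members = idx[(groups == study).to_numpy()]
        sub = dist.values[np.ix_(members, members)].copy()
        np.fill_diagonal(sub, np.inf)
        out[members] = sub.min(axis=1)
    return pd.Series(out, index=dist.sample_ids, name=f"uniq_{METRIC_ABBREV[dist.metric]}")


def diversity_adjusted_uniqueness(
    shannon: pd.Series, uniq: pd.Series, grouping
) -> pd.Series:
    """Residual uniqueness after a per-study robust regression on Shannon.

    Within each study the uniqueness values are regressed on Shannon
    diversity by a Huber M-estimated linear fit and the residuals returned;
    this removes the (often strong) diversity component of uniqueness.  A
    study with constant Shannon degenerates to centered uniqueness.
    """
    from .meta import robust_linear_fit  # local import: avoids module cycle

    groups = pd.Series(grouping).reindex(shannon.index)
    out = pd.Series(np.nan, index=shannon.index, dtype=float)
    for study in groups.dropna().unique():
        mask = (groups == study).to_numpy()
        x = shannon[mask].to_numpy(dtype=float)
        y = uniq[mask].to_numpy(dtype=float)
        if x.size < 3:
            raise ValidationError(f"study {study!r} has fewer than 3 samples")
        if np.ptp(x) == 0:
            warnings.warn(
                f"constant Shannon in study {study!r}; residuals are centered uniqueness",
                RuntimeWarning,
                stacklevel=2,
            )
            out[mask] = y - y.mean()
            continue
        fit = robust_linear_fit(y, x)
        out[mask] = y - (fit.intercept + fit.estimate * x)
    return out.rename(f"adj_{uniq.name}" if uniq.name else "adjusted")


def compute_summary_indices(
    collection: StudyCollection,
    metrics=METRICS,
    pseudocount: float | str = "auto",
) -> pd.DataFrame:
    """Per-sample summary-index table across every study of a collection.

    Returns one row per sample with columns ``shannon``, ``uniq_<metric>``
    and ``adj_uniq_<metric>`` (the diversity-adjusted residuals), plus
    ``study_id``.  All indices are computed separately within each study.
    """
    rows = []
    for study in collection.study_ids:
        table = collection.tables[study]
        sh = shannon_diversity(table)
        block = pd.DataFrame({"shannon": sh})
        block["study_id"] = study
        grouping = pd.Series(study, index=table.sample_ids)
        for metric in metrics:
            dist = pairwise_distances(table, metric, pseudocount=pseudocount)
            u = uniqueness(dist, grouping)
            block[u.name] = u
            block[f"adj_{u.name}"] = diversity_adjusted_uniqueness(sh, u, grouping)
        rows.append(block)
    out = pd.concat(rows)
    out.index.name = "sample_id"
    return out
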