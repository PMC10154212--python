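"""Taxon-group classification, grouped abundances, the two-step age screen
and disease-marker replication.

Species are partitioned by their pooled association with Kendall uniqueness:
taxa with a significantly negative pooled slope (q <= 0.05, directional
consistency >= 2/3) form the health-associated group, significantly positive
taxa the disease-associated group, and the rest are "other".  Grouped
abundances summarise a roster as the per-sample mean of range-scaled clr
abundances.  The age screen retains taxa whose post-60-year slope is
sign-consistent in at least two-thirds of qualifying studies before pooling
and FDR control, deliberately trading a little power for cross-study
reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import (
    EffectEstimate,
    MetaSummary,
    bh_adjust,
    consistency_score,
    random_effects_pool,
    robust_linear_fit,
)
from .profiles import (
    AbundanceTable,
    StudyCollection,
    ValidationError,
    clr_transform,
    range_scale,
)

__all__ = [
    "TaxonGroupAssignment",
    "GROUPS",
    "associate_taxa_with_index",
    "classify_by_kendall_association",
    "group_abundance",
    "group_abundance_collection",
    "age_association_screen",
    "rank_sum_test",
    "replicate_disease_markers",
]

logger = logging.getLogger(__name__)

GROUPS = ("kendall_negative", "kendall_positive", "other")


@dataclass
class TaxonGroupAssignment:
    taxon: str
    group: str
    q_value: float
    consistency: float
    pooled_estimate: float


def _study_clr_tables(collection: StudyCollection, pseudocount) -> dict:
    out = {}
    for study in collection.study_ids:
        table = collection.tables[study]
        out[study] = table if table.scale == "clr" else clr_transform(table, pseudocount)
    return out


def associate_taxa_with_index(
    collection: StudyCollection,
    indices: pd.DataFrame,
    index_name: str,
    taxa=None,
    min_n: int = 10,
    pseudocount: float | str = "auto",
) -> list[MetaSummary]:
    """Meta-analytic association of each taxon's clr abundance with a
    per-sample summary index.

    Per study: robust linear fit of clr abundance on the index, with BH
    correction within the study across taxa (per index family).  Across
    studies: DerSimonian-Laird pooling, directional consistency, and BH
    across taxa on the pooled z-test p-values (stored as ``q_value``).
    Studies with fewer than ``min_n`` samples are skipped with a log entry.
    """
    if index_name not in indices.columns:
        raise ValidationError(f"index {index_name!r} not in indices table")
    clr_tables = _study_clr_tables(collection, pseudocount)
    per_taxon: dict[str, list[EffectEstimate]] = {}
    for study in collection.study_ids:
        table = clr_tables[study]
        samples = [s for s in table.sample_ids if s in indices.index]
        if len(samples) < min_n:
            logger.info("study %s skipped (n=%d < %d)", study, len(samples), min_n)
            continue
        x = indices.loc[samples, index_name].to_numpy(dtype=float)
        roster = taxa if taxa is not None else table.taxon_ids
        study_effects, study_p = [], []
        for taxon in roster:
            if taxon not in table.values.index:
                continue
            y = table.values.loc[taxon, samples].to_numpy(dtype=float)
            try:
                fit = robust_linear_fit(y, x)
            except ValidationError:
                continue
            eff = EffectEstimate(taxon, study, fit.estimate, fit.std_error, fit.p_value, fit.n)
            study_effects.append(eff)
            study_p.append(fit.p_value)
        if study_p:
            qs = bh_adjust(study_p)  # per-study, per-index-family correction
            for eff, q in zip(study_effects, qs):
                eff.q_within_study = float(q)
                per_taxon.setdefault(eff.feature, []).append(eff)
    summaries = []
    for taxon in sorted(per_taxon):
        effects = per_taxon[taxon]
        ms = random_effects_pool(effects)
        if ms.pooled_estimate != 0:
            ms.consistency = consistency_score(effects, ms.pooled_estimate)
        else:
            ms.consistency = 0.0
        summaries.append(ms)
    if summaries:
        qs = bh_adjust([ms.p_value for ms in summaries])
        for ms, q in zip(summaries, qs):
            ms.q_value = float(q)
    return summaries


def classify_by_kendall_association(
    meta: list[MetaSummary], q_max: float = 0.05, min_consistency: float = 2 / 3
) -> list[TaxonGroupAssignment]:
    """Partition taxa into Kendall-negative / Kendall-positive / other.

    A taxon joins a signed group when its pooled estimate has that sign with
    q <= ``q_max`` and directional consistency >= ``min_consistency``;
    otherwise it is "other".  The partition is exhaustive and exclusive.
    """
    for name, val in (("q_max", q_max), ("min_consistency", min_consistency)):
        if not 0 < val <= 1:
            raise ValidationError(f"{name} must lie in (0, 1], got {val}")
    out = []
    for ms in meta:
        significant = ms.q_value <= q_max and ms.consistency >= min_consistency
        if significant and ms.pooled_estimate < 0:
            group = "kendall_negative"
        elif significant and ms.pooled_estimate > 0:
            group = "kendall_positive"
        else:
            group = "other"
        out.append(
            TaxonGroupAssignment(ms.feature, group, ms.q_value, ms.consistency, ms.pooled_estimate)
        )
    return out


def group_abundance(table: AbundanceTable, roster) -> pd.Series:
    """Mean range-scaled abundance of a taxon roster, per sample.

    Each roster taxon is range-scaled to [0, 1] across the table's samples
    (the per-study scope when called per study table), then averaged within
    each sample.  Taxa absent from the table contribute nothing.
    """
    if table.scale != "clr":
        raise ValidationError("group abundances are computed on clr tables")
    present = [t for t in roster if t in table.values.index]
    if not present:
        raise ValidationError(f"no roster taxa present in table: {list(roster)[:5]}")
    sub = table.values.loc[sorted(present)].to_numpy(dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scaled = np.vstack([range_scale(row) for row in sub])
    return pd.Series(scaled.mean(axis=0), index=table.values.columns, name="group_abundance")


def group_abundance_collection(
    collection: StudyCollection, roster, pseudocount: float | str = "auto"
) -> pd.Series:
    """Grouped abundance per sample, computed study by study (range-scaling
    within each study cohort)."""
    clr_tables = _study_clr_tables(collection, pseudocount)
    parts = [group_abundance(clr_tables[s], roster) for s in collection.study_ids]
    return pd.concat(parts)


def age_association_screen(
    collection: StudyCollection,
    taxa,
    min_age: float = 60.0,
    min_n_old: int = 50,
    direction_frac: float = 2 / 3,
    q_max: float = 0.1,
    pseudocount: float | str = "auto",
) -> pd.DataFrame:
    """Two-step screen for taxa whose clr abundance changes with age past
    ``min_age``.

    Step 1: within each study with at least ``min_n_old`` samples aged
    >= ``min_age``, fit clr abundance ~ age restricted to those samples, and
    keep only taxa whose slope sign agrees in >= ``direction_frac`` of
    studies.  Step 2: pool the survivors' slopes with random-effects models
    and BH-correct across survivors; taxa with q <= ``q_max`` are flagged
    with the pooled sign.

    Returns a frame indexed by taxon with columns ``retained``, ``flagged``,
    ``direction``, ``pooled_estimate``, ``q_value``, ``consistency``, ``k``.
    """
    taxa = list(taxa)
    if not taxa:
        return pd.DataFrame(
            columns=["retained", "flagged", "direction", "pooled_estimate",
                     "q_value", "consistency", "k"]
        )
    clr_tables = _study_clr_tables(collection, pseudocount)
    qualifying = []
    for study in collection.study_ids:
        meta = collection.study_metadata(study)
        old = meta.index[(meta["age"] >= min_age).fillna(False)]
        old = [s for s in old if s in clr_tables[study].sample_ids]
        if len(old) >= min_n_old:
            qualifying.append((study, old))
    if not qualifying:
        raise ValidationError(
            f"no studies with >= {min_n_old} samples aged >= {min_age}"
        )
    effects: dict[str, list[EffectEstimate]] = {t: [] for t in taxa}
    for study, old in qualifying:
        table = clr_tables[study]
        ages = collection.metadata.for_samples(old)["age"].to_numpy(dtype=float)
        for taxon in taxa:
            if taxon not in table.values.index:
                continue
            y = table.values.loc[taxon, old].to_numpy(dtype=float)
            try:
                fit = robust_linear_fit(y, ages)
            except ValidationError:
                continue
            effects[taxon].append(
                EffectEstimate(taxon, study, fit.estimate, fit.std_error, fit.p_value, fit.n)
            )
    rows = {}
    survivors = []
    for taxon in taxa:
        effs = effects[taxon]
        if not effs:
            rows[taxon] = dict(retained=False, flagged=False, direction=0, pooled_estimate=np.nan,
                               q_value=np.nan, consistency=np.nan, k=0)
            continue
        signs = np.sign([e.estimate for e in effs])
        k = len(effs)
        frac_pos = float((signs > 0).mean())
        frac_neg = float((signs < 0).mean())
        retained = max(frac_pos, frac_neg) >= direction_frac
        rows[taxon] = dict(retained=retained, flagged=False, direction=0, pooled_estimate=np.nan,
                           q_value=np.nan, consistency=np.nan, k=k)
        if retained:
            survivors.append(taxon)
    if survivors:
        pooled = {t: random_effects_pool(effects[t]) for t in survivors}
        qs = bh_adjust([pooled[t].p_value for t in survivors])
        for taxon, q in zip(survivors, qs):
            ms = pooled[taxon]
            cons = (
                consistency_score(effects[taxon], ms.pooled_estimate)
                if ms.pooled_estimate != 0
                else 0.0
            )
            rows[taxon].update(
                pooled_estimate=ms.pooled_estimate,
                q_value=float(q),
                consistency=cons,
                flagged=bool(q <= q_max),
                direction=int(np.sign(ms.pooled_estimate)) if q <= q_max else 0,
            )
    out = pd.DataFrame.from_dict(rows, orient="index").loc[taxa]
    out.index.name = "taxon"
    return out


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns (U, p).

    Exact enumeration for combined n <= 12 without ties, otherwise the
    normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank-sum test requires non-empty groups")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def replicate_disease_markers(
    collection: StudyCollection,
    marker_roster: dict,
    q_max: float = 0.1,
    min_per_arm: int = 20,
) -> pd.DataFrame:
    """Replication verdicts for markers with expected disease directions.

    ``marker_roster`` maps taxon -> expected sign (+1 disease-enriched, -1
    disease-depleted).  Scenarios are repository x disease combinations:
    within multi-study repositories cases are compared against matched
    controls from the same studies; in single-cohort repositories against
    the pooled non-disease controls.  Per scenario, relative abundances are
    compared by two-sided rank-sum tests with BH correction across the
    roster; scenarios with fewer than ``min_per_arm`` microbiomes per arm
    are skipped with a log entry.

    A marker is ``replicated`` if it hits the expected direction (q <=
    ``q_max``) in more than two scenarios with at most two opposite hits, or
    hits at most two expected scenarios with zero opposite hits.
    """
    from .profiles import to_relative

    meta = collection.metadata.frame
    disease_cols = [
        c
        for c in collection.metadata.clinical_columns
        if set(meta[c].dropna().unique()) <= {0, 1, 0.0, 1.0}
    ]
    rel_tables = {
        s: to_relative(t) if t.scale in ("counts",) else t
        for s, t in collection.tables.items()
        if t.scale in ("counts", "relative")
    }
    if len(rel_tables) != len(collection.tables):
        raise ValidationError("disease replication requires counts or relative tables")
    study_repo = collection.repository
    repo_studies: dict[str, list[str]] = {}
    for study, repo in study_repo.items():
        repo_studies.setdefault(repo, []).append(study)

    records = []
    for repo, studies in sorted(repo_studies.items()):
        multi = len(studies) > 1
        for disease in disease_cols:
            case_vals: dict[str, list[float]] = {t: [] for t in marker_roster}
            ctrl_vals: dict[str, list[float]] = {t: [] for t in marker_roster}
            n_case = n_ctrl = 0
            for study in studies:
                table = rel_tables[study]
                smeta = collection.study_metadata(study)
                flags = smeta[disease]
                cases = [s for s in table.sample_ids if flags.get(s) == 1]
                if multi:
                    # matched controls: same study, explicitly disease-free
                    ctrls = [s for s in table.sample_ids if flags.get(s) == 0]
                    if not cases:
                        continue  # study does not cover this disease
                else:
                    ctrls = [
                        s
                        for s in table.sample_ids
                        if flags.get(s) == 0
                        and smeta.loc[s, "health_status"] != "case"
                    ]
                n_case += len(cases)
                n_ctrl += len(ctrls)
                for taxon in marker_roster:
                    if taxon in table.values.index:
                        case_vals[taxon].extend(table.values.loc[taxon, cases])
                        ctrl_vals[taxon].extend(table.values.loc[taxon, ctrls])
            if n_case < min_per_arm or n_ctrl < min_per_arm:
                logger.info(
                    "scenario %s/%s skipped (cases=%d, controls=%d)", repo, disease, n_case, n_ctrl
                )
                continue
            ps, dirs, taxa_here = [], [], []
            for taxon in sorted(marker_roster):
                ca, co = np.asarray(case_vals[taxon]), np.asarray(ctrl_vals[taxon])
                if ca.size == 0 or co.size == 0:
                    continue
                _, p = rank_sum_test(ca, co)
                direction = np.sign(np.median(ca) - np.median(co))
                if direction == 0:
                    direction = np.sign(ca.mean() - co.mean())
                ps.append(p)
                dirs.append(direction)
                taxa_here.append(taxon)
            if not ps:
                continue
            qs = bh_adjust(ps)
            for taxon, q, direction in zip(taxa_here, qs, dirs):
                records.append(
                    dict(taxon=taxon, repository=repo, disease=disease, q_value=float(q),
                         direction=int(direction))
                )
    hits = pd.DataFrame(records)
    verdicts = {}
    for taxon, expected in marker_roster.items():
        if hits.empty:
            expected_hits = opposite_hits = 0
        else:
            sub = hits[(hits["taxon"] == taxon) & (hits["q_value"] <= q_max)]
            expected_hits = int((sub["direction"] == np.sign(expected)).sum())
            opposite_hits = int((sub["direction"] == -np.sign(expected)).sum())
        replicated = (expected_hits > 2 and opposite_hits <= 2) or (
            expected_hits <= 2 and opposite_hits == 0
        )
        verdicts[taxon] = dict(
            expected_sign=int(np.sign(expected)),
            expected_hits=expected_hits,
            opposite_hits=opposite_hits,
            replicated=replicated,
        )
    out = pd.DataFrame.from_dict(verdicts, orient="index")
    out.index.name = "taxon"
    return out
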