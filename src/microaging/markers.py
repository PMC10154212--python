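"""Unhealthy-aging marker ranking.

Clinical measures are first oriented so that larger always means less
healthy: positive indices of decline (frailty scores, inflammation,
depression scales, comorbidity counts, disease status coded case=1) are left
alone, while measures where higher is better (functional independence,
Barthel, grip strength, gait speed, MMSE and other cognitive scores) are
negated.  Each microbiome feature is then associated with each oriented
measure within each data repository -- robust linear regression for
continuous measures, two-sided rank-sum tests for binary ones -- with BH
correction per repository-measure combination.  A feature is called a
marker when it hits one direction (q at or below the threshold) in enough
distinct repositories with at most a small number of opposite-direction
hits anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groups import rank_sum_test
from .meta import bh_adjust, robust_linear_fit
from .profiles import ValidationError

__all__ = [
    "ClinicalMeasure",
    "MarkerAssociation",
    "DEFAULT_POLARITY",
    "orient_clinical_measure",
    "associate_feature_with_measure",
    "associate_panel",
    "rank_consistent_markers",
]

logger = logging.getLogger(__name__)

#: polarity registry seeded with conventional geriatric measures; additional
#: measures must be declared explicitly, never guessed.
DEFAULT_POLARITY = {
    "fried": "unhealthy_positive",
    "inflammation": "unhealthy_positive",
    "crp": "unhealthy_positive",
    "depression": "unhealthy_positive",
    "gds": "unhealthy_positive",
    "comorbidity": "unhealthy_positive",
    "fim": "unhealthy_negative",
    "barthel": "unhealthy_negative",
    "grip": "unhealthy_negative",
    "gait": "unhealthy_negative",
    "mmse": "unhealthy_negative",
    "praxis": "unhealthy_negative",
    "fluency": "unhealthy_negative",
    "memory": "unhealthy_negative",
}


@dataclass
class ClinicalMeasure:
    name: str
    kind: str  # continuous | binary
    polarity: str  # unhealthy_positive | unhealthy_negative
    repository: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValidationError(f"unknown measure kind {self.kind!r}")
        if self.polarity not in ("unhealthy_positive", "unhealthy_negative"):
            raise ValidationError(
                f"polarity for measure {self.name!r} must be declared as "
                "unhealthy_positive or unhealthy_negative"
            )


@dataclass
class MarkerAssociation:
    feature: str
    measure: str
    repository: str
    direction: float  # sign of the association with the oriented measure
    estimate: float
    p_value: float
    q_value: float
    n: int


def orient_clinical_measure(measure: ClinicalMeasure, values) -> np.ndarray:
    """Return values oriented so larger = less healthy.

    Unhealthy-negative measures are negated; binary measures must already be
    coded case=1 / control=0 and are validated as such.
    """
    arr = np.asarray(values, dtype=float)
    if measure.kind == "binary":
        finite = arr[np.isfinite(arr)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValidationError(f"binary measure {measure.name!r} must be coded 0/1")
    if measure.polarity == "unhealthy_negative":
        return -arr
    return arr


def associate_feature_with_measure(
    feature_values, measure: ClinicalMeasure, oriented, min_n: int = 20
) -> MarkerAssociation | None:
    """Association of one microbiome feature with one oriented measure.

    Continuous measures: Huber robust regression of the feature on the
    measure, slope sign and robust F p-value.  Binary measures: two-sided
    rank-sum test with direction given by the sign of the case-control
    median difference.  Scenarios below the ``min_n`` sample floor are
    skipped (returns None, logged).
    """
    y = np.asarray(feature_values, dtype=float)
    x = np.asarray(oriented, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if measure.kind == "binary":
        cases, ctrls = y[x == 1], y[x == 0]
        if min(cases.size, ctrls.size) < min_n:
            logger.info(
                "scenario %s/%s skipped (cases=%d, controls=%d)",
                measure.repository, measure.name, cases.size, ctrls.size,
            )
            return None
        _, p = rank_sum_test(cases, ctrls)
        direction = float(np.sign(np.median(cases) - np.median(ctrls)))
        if direction == 0:
            direction = float(np.sign(cases.mean() - ctrls.mean()))
            if direction == 0:
                p = 1.0
        estimate = float(np.median(cases) - np.median(ctrls))
    else:
        if y.size < min_n:
            logger.info("scenario %s/%s skipped (n=%d)", measure.repository, measure.name, y.size)
            return None
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return MarkerAssociation(
                "", measure.name, measure.repository, 0.0, 0.0, 1.0, np.nan, int(y.size)
            )
        fit = robust_linear_fit(y, x)
        p = fit.p_value
        direction = float(np.sign(fit.estimate))
        estimate = float(fit.estimate)
    return MarkerAssociation(
        feature="",
        measure=measure.name,
        repository=measure.repository,
        direction=direction,
        estimate=estimate,
        p_value=float(p),
        q_value=float("nan"),
        n=int(y.size),
    )


def associate_panel(
    features: pd.DataFrame, measures: list[ClinicalMeasure], metadata: pd.DataFrame,
    min_n: int = 20,
) -> list[MarkerAssociation]:
    """Associate every feature column with every measure, BH-correcting
    within each repository-measure combination.

    ``features``: samples x features; ``metadata`` must carry the measure
    columns and a ``repository`` column restricting each measure's samples.
    """
    out: list[MarkerAssociation] = []
    for measure in measures:
        if measure.name not in metadata.columns:
            raise ValidationError(f"measure {measure.name!r} missing from metadata")
        in_repo = metadata["repository"] == measure.repository
        samples = metadata.index[in_repo]
        samples = [s for s in samples if s in features.index]
        if not samples:
            continue
        raw = metadata.loc[samples, measure.name]
        oriented = orient_clinical_measure(measure, raw.to_numpy())
        scenario: list[MarkerAssociation] = []
        for feat in features.columns:
            assoc = associate_feature_with_measure(
                features.loc[samples, feat].to_numpy(), measure, oriented, min_n=min_n
            )
            if assoc is None:
                break  # sample floor fails for every feature in this scenario
            assoc.feature = feat
            scenario.append(assoc)
        if scenario:
            qs = bh_adjust([a.p_value for a in scenario])
            for a, q in zip(scenario, qs):
                a.q_value = float(q)
            out.extend(scenario)
    return out


def rank_consistent_markers(
    associations: list[MarkerAssociation],
    q_max: float = 0.10,
    min_repositories: int = 3,
    max_opposite: int = 2,
    use_p: bool = False,
) -> pd.DataFrame:
    """Rank features by cross-repository consistency of their associations.

    A feature is a marker in a direction when it has significant hits
    (q <= ``q_max``; or raw p for the younger-adult variant, ``use_p``) in
    that direction in at least ``min_repositories`` distinct repositories,
    with at most ``max_opposite`` opposite-direction hits across all
    scenarios.  Output sorted by hit count, descending; verdict is one of
    ``unhealthy_positive_marker``, ``unhealthy_negative_marker``, ``none``.
    """
    rows = {}
    feats = sorted({a.feature for a in associations})
    for feat in feats:
        mine = [a for a in associations if a.feature == feat]
        sig = [
            a
            for a in mine
            if (a.p_value if use_p else a.q_value) <= q_max and a.direction != 0
        ]
        pos = [a for a in sig if a.direction > 0]
        neg = [a for a in sig if a.direction < 0]
        n_pos, n_neg = len(pos), len(neg)
        pos_repos = {a.repository for a in pos}
        neg_repos = {a.repository for a in neg}
        verdict = "none"
        n_repos = 0
        if len(pos_repos) >= min_repositories and n_neg <= max_opposite:
            verdict = "unhealthy_positive_marker"
            n_repos = len(pos_repos)
        elif len(neg_repos) >= min_repositories and n_pos <= max_opposite:
            verdict = "unhealthy_negative_marker"
            n_repos = len(neg_repos)
        rows[feat] = dict(
            n_positive_hits=n_pos,
            n_negative_hits=n_neg,
            n_repositories_supporting=n_repos,
            verdict=verdict,
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature"
    out["_hits"] = out[["n_positive_hits", "n_negative_hits"]].max(axis=1)
    out = out.sort_values(["_hits"], ascending=False, kind="stable").drop(columns="_hits")
    return out
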