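"""Taxon-group classification, grouped abundances, the two-step age screen
and disease-marker replication."""

import numpy as np
import pandas as pd
import pytest

from microaging.groups import (
    age_association_screen,
    associate_taxa_with_index,
    classify_by_kendall_association,
    group_abundance,
    rank_sum_test,
    replicate_disease_markers,
)
from microaging.indices import compute_summary_indices
from microaging.meta import MetaSummary
from microaging.profiles import AbundanceTable, ValidationError, clr_transform, range_scale
from microaging.simulate import SyntheticConfig, generate_cohorts
from tests.conftest import make_collection


def _ms(feature, pooled, q, consistency):
    ms = MetaSummary(feature=feature, pooled_estimate=pooled, tau2=0.0, cochran_q=0.0,
                     p_value=q, k=5)
    ms.q_value = q
    ms.consistency = consistency
    return ms


class TestClassification:
    def test_threshold_rules(self):
        meta = [
            _ms("neg", -0.2, 0.04, 0.70),
            _ms("pos_low_consistency", +0.2, 0.04, 0.50),
            _ms("pos", +0.2, 0.04, 0.70),
            _ms("ns", +0.2, 0.30, 1.00),
        ]
        got = {a.taxon: a.group for a in classify_by_kendall_association(meta)}
        assert got == {
            "neg": "kendall_negative",
            "pos_low_consistency": "other",
            "pos": "kendall_positive",
            "ns": "other",
        }

    def test_all_nonsignificant_are_other(self):
        meta = [_ms(f"t{i}", (-1) ** i * 0.3, 1.0, 1.0) for i in range(6)]
        assert all(a.group == "other" for a in classify_by_kendall_association(meta))

    def test_exhaustive_and_exclusive(self, rng):
        meta = [
            _ms(f"t{i}", rng.normal(), float(rng.uniform(0.001, 1)), float(rng.uniform()))
            for i in range(40)
        ]
        out = classify_by_kendall_association(meta)
        assert len(out) == 40
        assert {a.taxon for a in out} == {m.feature for m in meta}
        assert all(a.group in ("kendall_negative", "kendall_positive", "other") for a in out)

    def test_threshold_domain(self):
        with pytest.raises(ValidationError):
            classify_by_kendall_association([], q_max=0.0)


class TestGroupAbundance:
    @staticmethod
    def _clr_table(rng, n_taxa=8, n_samples=10):
        arr = rng.integers(1, 200, size=(n_taxa, n_samples)).astype(float)
        t = AbundanceTable(
            pd.DataFrame(arr, index=[f"t{i}" for i in range(n_taxa)],
                         columns=[f"s{j}" for j in range(n_samples)]),
            scale="counts",
        )
        return clr_transform(t, pseudocount=0)

    def test_single_taxon_roster_equals_range_scaled(self, rng):
        clr = self._clr_table(rng)
        ga = group_abundance(clr, ["t3"])
        expected = range_scale(clr.values.loc["t3"].to_numpy())
        np.testing.assert_allclose(ga.to_numpy(), expected, atol=1e-12)

    def test_matches_bruteforce_mean(self, rng):
        clr = self._clr_table(rng)
        roster = ["t1", "t4", "t6"]
        ga = group_abundance(clr, roster)
        manual = np.mean(
            [range_scale(clr.values.loc[t].to_numpy()) for t in roster], axis=0
        )
        np.testing.assert_allclose(ga.to_numpy(), manual, atol=1e-12)

    def test_roster_order_invariant_and_bounded(self, rng):
        clr = self._clr_table(rng)
        a = group_abundance(clr, ["t1", "t2", "t5"])
        b = group_abundance(clr, ["t5", "t1", "t2"])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())
        assert (a >= 0).all() and (a <= 1).all()

    def test_empty_intersection_rejected(self, rng):
        clr = self._clr_table(rng)
        with pytest.raises(ValidationError, match="roster"):
            group_abundance(clr, ["absent1", "absent2"])


class TestAssociateTaxaWithIndex:
    @staticmethod
    def _collection_with_planted_taxon(rng):
        """Inject a taxon whose abundance tracks Kendall uniqueness."""
        tables = {}
        for s in range(3):
            n = 80
            arr = rng.gamma(1.0, 50.0, size=(12, n))
            arr[rng.random(arr.shape) < 0.2] = 0
            arr[0] += 10
            cols = [f"st{s}_x{j}" for j in range(n)]
            df = pd.DataFrame(arr, index=[f"t{i}" for i in range(12)], columns=cols)
            base = AbundanceTable(df, scale="counts")
            idx = compute_summary_indices(
                make_collection({f"st{s}": df}), metrics=("kendall",), pseudocount=1e-6
            )
            u = idx["uniq_ken"].loc[cols].to_numpy()
            z = (u - u.mean()) / u.std()
            df.loc["t_sig"] = np.exp(3.0 + 2.0 * z)
            tables[f"st{s}"] = df
        return make_collection(tables)

    def test_planted_signal_recovered(self, rng):
        coll = self._collection_with_planted_taxon(rng)
        indices = compute_summary_indices(coll, metrics=("kendall",), pseudocount=1e-6)
        meta = associate_taxa_with_index(coll, indices, "uniq_ken", pseudocount=1e-6)
        sig = next(m for m in meta if m.feature == "t_sig")
        assert sig.pooled_estimate > 0
        assert sig.q_value <= 0.05
        assert sig.consistency == 1.0

    def test_null_association_rate_controlled(self, rng):
        coll = self._collection_with_planted_taxon(rng)
        indices = compute_summary_indices(coll, metrics=("kendall",), pseudocount=1e-6)
        # permuting index values within study breaks every true association
        shuffled = indices.copy()
        for study, block in indices.groupby("study_id"):
            vals = block["uniq_ken"].to_numpy().copy()
            rng.shuffle(vals)
            shuffled.loc[block.index, "uniq_ken"] = vals
        meta = associate_taxa_with_index(coll, shuffled, "uniq_ken", pseudocount=1e-6)
        frac = np.mean([m.q_value <= 0.05 for m in meta])
        assert frac <= 0.1

    def test_single_study_consistency_is_one(self, rng):
        arr = rng.gamma(1.0, 50.0, size=(8, 40)) + 1
        df = pd.DataFrame(arr, index=[f"t{i}" for i in range(8)],
                          columns=[f"st0_x{j}" for j in range(40)])
        coll = make_collection({"st0": df})
        indices = compute_summary_indices(coll, metrics=("kendall",), pseudocount=1e-6)
        meta = associate_taxa_with_index(coll, indices, "uniq_ken", pseudocount=1e-6)
        assert meta and all(m.consistency == 1.0 for m in meta if m.pooled_estimate != 0)


class TestAgeScreen:
    def test_planted_slopes_recovered(self):
        cfg = SyntheticConfig(
            n_studies=5, samples_per_study=(80, 80), n_taxa=20,
            n_health_core=4, n_disease_subhub_1=2, n_disease_subhub_2=2,
            age_range=(60.0, 100.0), age_slope_disease=0.5, age_slope_health=-0.5,
            disruption_attenuation=0.0, disruption_jitter=0.0, depth=20_000, seed=3,
        )
        coll, truth = generate_cohorts(cfg)
        screen = age_association_screen(
            coll, coll.tables["study01"].taxon_ids, min_age=60, min_n_old=50
        )
        flagged_pos = set(screen.index[(screen["flagged"]) & (screen["direction"] > 0)])
        flagged_neg = set(screen.index[(screen["flagged"]) & (screen["direction"] < 0)])
        assert len(flagged_pos & set(truth.disease_roster)) >= 3
        assert len(flagged_neg & set(truth.health_core)) >= 3

    def test_sign_split_taxon_dropped_at_step_one(self, rng):
        tables, ages = {}, {}
        for s in range(6):
            n = 40
            cols = [f"st{s}_x{j}" for j in range(n)]
            a = rng.uniform(60, 100, size=n)
            ages.update(dict(zip(cols, a)))
            slope = 0.5 if s < 3 else -0.5  # positive in exactly half the studies
            base = rng.gamma(2.0, 30.0, size=(5, n)) + 1
            base[0] = np.exp(3 + slope * (a - 60) / 10 + rng.normal(0, 0.05, n)) * 10
            tables[f"st{s}"] = pd.DataFrame(
                base, index=[f"t{i}" for i in range(5)], columns=cols
            )
        coll = make_collection(tables, ages=ages)
        screen = age_association_screen(coll, ["t0"], min_age=60, min_n_old=30)
        assert not screen.loc["t0", "retained"]
        assert not screen.loc["t0", "flagged"]

    def test_empty_taxon_list_gives_empty_result(self, small_collection):
        coll, _ = small_collection
        out = age_association_screen(coll, [], min_age=60, min_n_old=10)
        assert out.empty

    def test_no_qualifying_studies_rejected(self, small_collection):
        coll, _ = small_collection
        with pytest.raises(ValidationError, match="no studies"):
            age_association_screen(coll, ["sp000"], min_age=60, min_n_old=10_000)


class TestDiseaseReplication:
    def test_rank_sum_exact_enumeration(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @staticmethod
    def _replication_collection(rng):
        """Three single-study repositories with one binary disease.

        ``mk_up`` is strongly case-enriched everywhere (expected +), ``mk_opp``
        is case-enriched but declared disease-depleted (expected -), and
        ``mk_flat`` shows no difference (expected +).
        """
        tables, disease = {}, {}
        for s in range(3):
            n = 60
            cols = [f"st{s}_x{j}" for j in range(n)]
            case = np.array([1.0] * 25 + [0.0] * 35)
            disease.update(dict(zip(cols, case)))
            up = np.where(case == 1, 200, 20) + rng.normal(0, 2, n)
            opp = np.where(case == 1, 200, 20) + rng.normal(0, 2, n)
            flat = 50 + rng.normal(0, 2, n)
            filler = 1000.0 - up - opp - flat  # constant totals: no closure artifact
            arr = np.vstack([up, opp, flat, filler])
            tables[f"st{s}"] = pd.DataFrame(
                arr, index=["mk_up", "mk_opp", "mk_flat", "filler"], columns=cols
            )
        repos = {f"st{s}": f"repo{s}" for s in range(3)}
        return make_collection(tables, extra_cols={"diseaseA": disease}, repository=repos)

    def test_replication_verdicts(self, rng):
        coll = self._replication_collection(rng)
        roster = {"mk_up": +1, "mk_opp": -1, "mk_flat": +1}
        out = replicate_disease_markers(coll, roster, q_max=0.1, min_per_arm=20)
        # enriched in the expected direction in 3 (> 2) scenarios, 0 opposite
        assert out.loc["mk_up", "replicated"]
        assert out.loc["mk_up", "expected_hits"] == 3
        # consistently opposite to the declared direction
        assert not out.loc["mk_opp", "replicated"]
        assert out.loc["mk_opp", "opposite_hits"] == 3
        # no signal anywhere: <= 2 expected and zero opposite
        assert out.loc["mk_flat", "replicated"]

    def test_small_arm_scenarios_skipped(self, rng):
        coll = self._replication_collection(rng)
        out = replicate_disease_markers(coll, {"mk_up": +1}, q_max=0.1, min_per_arm=30)
        # 25 cases < 30 per arm: every scenario skipped, no hits either way
        assert out.loc["mk_up", "expected_hits"] == 0
        assert out.loc["mk_up", "opposite_hits"] == 0
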