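import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import molo
from molo.embedding import Embedding2D


def make_embedding(coords, ids=None):
    ids = ids or [f"c{i}" for i in range(len(coords))]
    df = pd.DataFrame(np.asarray(coords, dtype=float), columns=["x", "y"],
                      index=pd.Index(ids, name="cell_id"))
    return Embedding2D(df, input_kind="surface_markers", perplexity=5, seed=0, init_dims=2)


def index_table(values, prefix, channels=("A", "B", "C")):
    ids = [f"{prefix}{i}" for i in range(len(values))]
    chan = pd.DataFrame(np.asarray(values, dtype=float), columns=list(channels), index=ids)
    return molo.IndexSortTable(chan, pd.Series("b", index=chan.index))


class TestJointMarkerEmbedding:
    def test_identical_vectors_coincide(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 3))
        seq = index_table(base, "s")
        tx = index_table(base[:10], "t")  # duplicates of the first 10 seq cells
        emb = molo.joint_marker_embedding(seq, tx, perplexity=10, seed=0)
        xy = emb.xy
        span = np.linalg.norm(xy.max(0) - xy.min(0))
        for i in range(10):
            assert np.linalg.norm(xy[i] - xy[30 + i]) < 0.01 * span
        assert list(emb.coords["source"]) == ["seq"] * 30 + ["tx"] * 10

    def test_channel_shuffle_invariance(self):
        rng = np.random.default_rng(1)
        seq = index_table(rng.normal(size=(40, 3)), "s")
        tx_vals = rng.normal(size=(15, 3))
        tx1 = index_table(tx_vals, "t")
        tx2 = molo.IndexSortTable(tx1.channels[["C", "A", "B"]], tx1.batch_id)
        e1 = molo.joint_marker_embedding(seq, tx1, perplexity=10, seed=0)
        e2 = molo.joint_marker_embedding(seq, tx2, perplexity=10, seed=0)
        assert np.array_equal(e1.xy, e2.xy)

    def test_channel_mismatch_is_error(self):
        rng = np.random.default_rng(2)
        seq = index_table(rng.normal(size=(20, 3)), "s", channels=("A", "B", "C"))
        tx = index_table(rng.normal(size=(20, 3)), "t", channels=("A", "B", "D"))
        with pytest.raises(ValueError, match="mismatch"):
            molo.joint_marker_embedding(seq, tx, perplexity=5, seed=0)


class TestSumoAxis:
    def test_collinear_points_project_in_order(self):
        t = np.linspace(0, 10, 12)
        emb = make_embedding(np.column_stack([t, 2 * t]))
        s = molo.fit_sumo_axis(emb)
        rho, _ = molo.spearman_test(s.scores.to_numpy(), t)
        assert abs(rho) == pytest.approx(1.0)

    def test_orientation_rule_flips_sign(self):
        t = np.linspace(0, 10, 12)
        emb = make_embedding(np.column_stack([t, 0.1 * np.random.default_rng(3).normal(size=12)]))
        molo_scores = pd.Series(-t, index=emb.coords.index)  # decreasing along axis
        s = molo.fit_sumo_axis(emb, molo_scores)
        rho, _ = molo.spearman_test(s.scores.loc[emb.coords.index].to_numpy(), molo_scores.to_numpy())
        assert rho >= 0
        assert s.oriented

    def test_axis_matches_eigen_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.multivariate_normal([0, 0], [[4.0, 1.5], [1.5, 1.0]], size=200)
        emb = make_embedding(pts)
        s = molo.fit_sumo_axis(emb)
        evals, evecs = np.linalg.eigh(np.cov((pts - pts.mean(0)).T))
        lead = evecs[:, np.argmax(evals)]
        assert abs(abs(s.axis @ lead) - 1.0) < 1e-8

    def test_rotation_invariance_up_to_sign(self):
        rng = np.random.default_rng(5)
        pts = rng.multivariate_normal([3, -2], [[4.0, 1.5], [1.5, 1.0]], size=80)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        s1 = molo.fit_sumo_axis(make_embedding(pts))
        s2 = molo.fit_sumo_axis(make_embedding(pts @ rot.T + 5.0))
        a, b = s1.scores.to_numpy(), s2.scores.to_numpy()
        assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)

    def test_isotropic_cloud_warns(self):
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])  # exactly isotropic
        with pytest.warns(UserWarning, match="isotropic"):
            molo.fit_sumo_axis(make_embedding(pts))


class TestRegionEnrichment:
    def test_separated_values_match_exact_p(self):
        coords = np.vstack([np.random.default_rng(7).normal(0, 0.2, (6, 2)),
                            np.random.default_rng(8).normal(10, 0.2, (6, 2))])
        emb = make_embedding(coords)
        part = molo.ward_partition(emb, k=2)
        assert part.nunique() == 2
        vals = pd.DataFrame({"v": np.concatenate([np.arange(6), np.arange(6) + 50.0])},
                            index=emb.coords.index)
        out = molo.region_enrichment(emb, part, vals)
        assert out.loc["v", "p"] == pytest.approx(2.0 / math.comb(12, 6), rel=1e-9)

    def test_binary_outcome_uses_fisher(self):
        rng = np.random.default_rng(9)
        emb = make_embedding(np.vstack([rng.normal(0, 0.3, (10, 2)),
                                        rng.normal(8, 0.3, (10, 2))]))
        part = molo.ward_partition(emb, k=2)
        vals = pd.DataFrame({"flag": [True] * 10 + [False] * 10}, index=emb.coords.index)
        out = molo.region_enrichment(emb, part, vals)
        assert out.loc["flag", "test"] == "fisher"
        assert out.loc["flag", "p"] < 0.001

    def test_null_pvalues_uniform(self):
        """Region-independent values give calibrated p-values."""
        pvals = []
        for s in range(200):
            rng = np.random.default_rng(30000 + s)
            emb = make_embedding(rng.normal(size=(24, 2)))
            part = molo.ward_partition(emb, k=2)
            if part.value_counts().min() < 2:
                continue
            vals = pd.DataFrame({"v": rng.normal(size=24)}, index=emb.coords.index)
            pvals.append(molo.region_enrichment(emb, part, vals).loc["v", "p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_cells_ignored_and_empty_region_error(self):
        rng = np.random.default_rng(10)
        emb = make_embedding(np.vstack([rng.normal(0, 0.3, (5, 2)),
                                        rng.normal(8, 0.3, (5, 2))]))
        part = molo.ward_partition(emb, k=2)
        vals = pd.DataFrame({"v": [1.0, 2, 3, 4, 5] + [np.nan] * 5}, index=emb.coords.index)
        with pytest.raises(ValueError, match="empty region"):
            molo.region_enrichment(emb, part, vals)


class TestCallRepopulation:
    @staticmethod
    def record(wbc16, wbc24=None, gm=None, b=None, t=None, mouse="m1"):
        rows = []
        lineage_vals = {"WBC": wbc16, "GM": gm, "B": b, "T": t}
        for lineage, pct in lineage_vals.items():
            if pct is None:
                continue
            rows.append({"week": 16, "lineage": lineage,
                         "donor": pct, "recipient": 100.0 - pct})
        if wbc24 is not None:
            rows.append({"week": 24, "lineage": "WBC", "donor": wbc24,
                         "recipient": 100.0 - wbc24})
        return molo.TransplantRecord(mouse, 1, pd.DataFrame(rows))

    def test_zero_donor_not_repopulated(self):
        rec = molo.TransplantRecord("m0", 1, pd.DataFrame(
            {"week": [16], "lineage": ["WBC"], "donor": [0.0], "recipient": [100.0]}))
        call = molo.call_repopulation([rec])[0]
        assert not call.repopulated and call.subtype == "none"

    def test_five_percent_wbc_repopulated(self):
        """Donor 500 of 10,000 WBC = 5% chimerism, repopulated."""
        rec = molo.TransplantRecord("m1", 1, pd.DataFrame(
            {"week": [16], "lineage": ["WBC"], "donor": [500.0], "recipient": [9500.0]}))
        call = molo.call_repopulation([rec])[0]
        assert call.donor_wbc_pct[16.0] == pytest.approx(5.0)
        assert call.repopulated

    def test_threshold_is_inclusive(self):
        call = molo.call_repopulation([self.record(wbc16=1.0)])[0]
        assert call.repopulated
        call2 = molo.call_repopulation([self.record(wbc16=0.999)])[0]
        assert not call2.repopulated

    def test_week24_alone_suffices(self):
        call = molo.call_repopulation([self.record(wbc16=0.2, wbc24=3.0)])[0]
        assert call.repopulated

    def test_subtype_classification(self):
        alpha = molo.call_repopulation([self.record(5.0, gm=10.0, b=2.0, t=2.0)])[0]
        assert alpha.subtype == "alpha"
        beta = molo.call_repopulation([self.record(5.0, gm=4.0, b=4.0, t=4.0)])[0]
        assert beta.subtype == "beta"
        gamma = molo.call_repopulation([self.record(5.0, gm=0.5, b=10.0, t=10.0)])[0]
        assert gamma.subtype == "gamma"

    def test_missing_lineage_flags_none(self):
        call = molo.call_repopulation([self.record(5.0, gm=10.0)])[0]
        assert call.repopulated and call.subtype == "none"

    def test_monotone_in_donor_counts(self):
        """Raising donor counts never flips repopulated -> not."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            base = float(rng.uniform(0, 3))
            call_lo = molo.call_repopulation([self.record(base, gm=1.0, b=1.0, t=1.0)])[0]
            call_hi = molo.call_repopulation([self.record(base + rng.uniform(0, 5),
                                                          gm=1.0, b=1.0, t=1.0)])[0]
            assert not (call_lo.repopulated and not call_hi.repopulated)


class TestLimitingDilution:
    def test_all_negative_gives_zero(self):
        res = molo.limiting_dilution([10], [5], [5])
        assert res.frequency == 0.0
        assert res.ci_low == 0.0 and res.ci_high > 0

    def test_single_dose_closed_form(self):
        """dose 10, 1 of 5 negative: f = -ln(1/5)/10 ~ 0.1609 ('1 in 6.2')."""
        res = molo.limiting_dilution([10], [5], [1])
        assert res.frequency == pytest.approx(-math.log(1 / 5) / 10, rel=1e-6)
        assert res.one_in == pytest.approx(6.2, abs=0.05)
        assert res.ci_low < res.frequency < res.ci_high

    def test_two_dose_matches_grid_oracle(self):
        doses, mice, neg = [1, 5], [10, 10], [7, 2]
        res = molo.limiting_dilution(doses, mice, neg)
        grid = np.linspace(1e-4, 1.0, 10000)
        d = np.array(doses, dtype=float)
        n = np.array(neg)
        p = np.array(mice) - n
        ll = (n[None, :] * (-grid[:, None] * d) +
              p[None, :] * np.log1p(-np.exp(-grid[:, None] * d))).sum(1)
        assert res.frequency == pytest.approx(grid[np.argmax(ll)], abs=1e-4)

    def test_all_positive_reports_lower_bound(self):
        res = molo.limiting_dilution([1], [10], [0])
        assert res.unbounded
        assert res.frequency == 1.0
        assert 0 < res.ci_low < 1.0

    def test_dose_zero_with_positive_is_error(self):
        with pytest.raises(ValueError, match="dose 0|single-hit"):
            molo.limiting_dilution([0, 5], [3, 3], [1, 1])

    def test_invalid_negative_counts(self):
        with pytest.raises(ValueError):
            molo.limiting_dilution([5], [3], [4])

    def test_concave_likelihood_unique_mle(self):
        """The MLE matches a grid search on random multi-dose designs."""
        rng = np.random.default_rng(12)
        grid = np.linspace(1e-4, 1.0, 5000)
        for _ in range(25):
            f_true = rng.uniform(0.05, 0.6)
            doses = rng.choice([1, 2, 5, 10], size=3, replace=False).astype(float)
            mice = rng.integers(5, 15, 3)
            neg = rng.binomial(mice, np.exp(-f_true * doses))
            if neg.sum() == 0 or (mice - neg).sum() == 0:
                continue
            res = molo.limiting_dilution(list(doses.astype(int)), list(mice), list(neg))
            ll = (neg[None, :] * (-grid[:, None] * doses) +
                  (mice - neg)[None, :] * np.log1p(-np.exp(-grid[:, None] * doses))).sum(1)
            assert res.frequency == pytest.approx(grid[np.argmax(ll)], abs=3e-4)


class TestMammaryPipeline:
    def test_per_patient_zscore_and_planted_recovery(self):
        spec = molo.SimSpec(seed=33)
        col = molo.simulate_colonies(spec, n_patients=3, wells_per_patient=80)
        res = molo.mammary_pipeline(col, k_clusters=2, perplexity=20, seed=0)
        top2 = set(res.marker_tests.index[:2])
        assert top2 == {"EpCAM", "SSC"}
        assert res.marker_tests.loc["EpCAM", "direction"] == "up_in_cluster"
        assert res.marker_tests.loc["SSC", "direction"] == "down_in_cluster"
        assert (res.cfe_fold["fold"] > 1).all()

    def test_null_colony_outcome_independent_of_clusters(self):
        """Uniform colony probability: colony status is independent of the
        marker-derived partition (calibrated Fisher test over seeds), and
        the best-cluster fold shows nothing beyond max-selection noise."""
        from scipy.stats import fisher_exact

        hits, folds = 0, []
        n_seeds = 15
        for s in range(n_seeds):
            spec = molo.SimSpec(seed=40000 + s, colony_effect={},
                                colony_prob=(0.2, 0.2))
            col = molo.simulate_colonies(spec, n_patients=2, wells_per_patient=60)
            res = molo.mammary_pipeline(col, k_clusters=2, perplexity=10, seed=s)
            in1 = (res.clusters == 1).to_numpy()
            colony = col["colony"].to_numpy() > 0
            tab = [[int((in1 & colony).sum()), int((in1 & ~colony).sum())],
                   [int((~in1 & colony).sum()), int((~in1 & ~colony).sum())]]
            hits += fisher_exact(tab)[1] < 0.05
            folds.append(res.cfe_fold["fold"].mean())
        # 3 binomial SDs above the nominal 5% false-positive rate
        assert hits <= n_seeds * 0.05 + 3 * np.sqrt(n_seeds * 0.05 * 0.95)
        # selecting the max-CFE cluster biases the fold upward by at most
        # ~the CFE sampling noise; anything near 2x would signal leakage
        assert np.mean(folds) < 1.5

    def test_too_few_wells_is_error(self):
        spec = molo.SimSpec(seed=34)
        col = molo.simulate_colonies(spec, n_patients=2, wells_per_patient=10)
        with pytest.raises(ValueError, match="20"):
            molo.mammary_pipeline(col, perplexity=3)

    def test_zero_colony_patient_flagged(self):
        spec = molo.SimSpec(seed=35, colony_prob=(0.3, 0.5))
        col = molo.simulate_colonies(spec, n_patients=2, wells_per_patient=40)
        col.loc[col["patient_id"] == "patient1", "colony"] = 0
        with pytest.warns(UserWarning, match="patient1"):
            res = molo.mammary_pipeline(col, k_clusters=2, perplexity=10, seed=0)
        assert np.isnan(res.cfe_fold.loc["patient1", "fold"])
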