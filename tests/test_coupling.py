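import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from nichemet.coupling import (
    correlation_partner_sets,
    pairwise_pathway_network,
    pathway_overrepresentation,
    pathway_slope_summary,
    proliferation_correlations,
    segmentation_gain,
)
from nichemet.exceptions import DegenerateDataError, ValidationError
from nichemet.io import PathwayMap


def _coupled_frame(rng, n=10, r=0.9):
    s = rng.normal(size=n)
    met = r * s + math.sqrt(1 - r**2) * rng.normal(size=n)
    return (
        pd.DataFrame({"hit": met, "null": rng.normal(size=n)},
                     index=[f"S{i}" for i in range(n)]),
        pd.Series(s, index=[f"S{i}" for i in range(n)]),
    )


class TestProliferationCorrelations:
    def test_copy_of_sphase_has_unit_correlation(self):
        idx = [f"S{i}" for i in range(8)]
        s = pd.Series(np.arange(8, dtype=float), index=idx)
        tm = pd.DataFrame({"met": s})
        out = proliferation_correlations(
            tm, s, pd.Series(["A"] * 8, index=idx)
        )
        row = out.iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["spearman_rho"] == pytest.approx(1.0)

    def test_planted_correlation_recovered(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            tm, s = _coupled_frame(r, n=10, r=0.9)
            groups = pd.Series(["A"] * 10, index=tm.index)
            out = proliferation_correlations(tm, s, groups).set_index("metabolite")
            if abs(out.loc["hit", "pearson_r"] - 0.9) <= 0.15:
                hits += 1
        assert hits >= 0.7 * 50  # generous: sampling error of r at n=10

    def test_beta1_sign_matches_pearson_sign(self, rng):
        tm = pd.DataFrame(
            rng.normal(size=(12, 6)), columns=[f"m{i}" for i in range(6)],
            index=[f"S{i}" for i in range(12)],
        )
        s = pd.Series(rng.normal(size=12), index=tm.index)
        out = proliferation_correlations(
            tm, s, pd.Series(["A"] * 12, index=tm.index)
        )
        assert np.all(np.sign(out["beta1"]) == np.sign(out["pearson_r"]))

    def test_standardized_slope_equals_r_times_sd(self, rng):
        # beta1 of y ~ z(x) equals pearson_r * sd(y): algebraic identity
        tm = pd.DataFrame({"m": rng.normal(size=10)}, index=[f"S{i}" for i in range(10)])
        s = pd.Series(rng.normal(size=10), index=tm.index)
        out = proliferation_correlations(
            tm, s, pd.Series(["A"] * 10, index=tm.index)
        ).iloc[0]
        assert out["beta1"] == pytest.approx(
            out["pearson_r"] * s.to_numpy().std(ddof=0), rel=1e-9
        )

    def test_small_group_rejected(self, rng):
        tm = pd.DataFrame({"m": rng.normal(size=3)}, index=list("abc"))
        s = pd.Series(rng.normal(size=3), index=list("abc"))
        with pytest.raises(ValidationError):
            proliferation_correlations(tm, s, pd.Series(["A"] * 3, index=list("abc")))


class TestSegmentationGain:
    def test_definitions(self):
        out = segmentation_gain(
            pd.Series({"a": 0.8, "b": -0.9}), pd.Series({"a": 0.5, "b": 0.2})
        )
        assert out.loc["a", "delta_abs_rho"] == pytest.approx(0.3)
        assert out.loc["b", "delta_abs_rho"] == pytest.approx(0.7)
        assert list(out.index) == ["b", "a"]  # sorted descending

    def test_sign_invariance(self, rng):
        rho_n = pd.Series(rng.uniform(-1, 1, 20), index=range(20))
        rho_w = pd.Series(rng.uniform(-1, 1, 20), index=range(20))
        a = segmentation_gain(rho_n, rho_w)["delta_abs_rho"]
        b = segmentation_gain(-rho_n, -rho_w)["delta_abs_rho"]
        pd.testing.assert_series_equal(a, b)

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValidationError):
            segmentation_gain(pd.Series({"a": 0.1}), pd.Series({"b": 0.1}))

    def test_niche_restricted_coupling_yields_positive_gain(self, default_cohort):
        """Planted proliferation coupling lives in the niche; whole-marrow
        averages dilute it, so Delta|rho| is positive for the planted
        features in the MGUS group (tiny niches, maximal dilution)."""
        from nichemet.io import subject_frame
        from nichemet.pipeline import compartment_means

        params = default_cohort["params"]
        meta = subject_frame(default_cohort["records"])
        niche_rows, whole_rows = {}, {}
        for d in default_cohort["datasets"]:
            seg = default_cohort["segs"][d.section_id]
            n, _, w = compartment_means(d, seg)
            niche_rows[d.subject_id] = n
            whole_rows[d.subject_id] = w
        cols = list(params.feature_ids)
        niche = pd.DataFrame(niche_rows, index=cols).T
        whole = pd.DataFrame(whole_rows, index=cols).T
        out_n = proliferation_correlations(niche, meta["sphase"], meta["group"])
        out_w = proliferation_correlations(whole, meta["sphase"], meta["group"])
        rn = out_n[out_n["group"] == "MGUS"].set_index("metabolite")["spearman_rho"]
        rw = out_w[out_w["group"] == "MGUS"].set_index("metabolite")["spearman_rho"]
        gain = segmentation_gain(rn, rw)
        planted = gain.loc[params.prolif_features, "delta_abs_rho"]
        assert planted.median() > 0


class TestPartnerSets:
    def test_duplicate_and_negation_of_anchor(self, rng):
        a = rng.normal(size=10)
        m = pd.DataFrame({"anchor": a, "dup": a.copy(), "neg": -a,
                          "noise": rng.normal(size=10)})
        pos, neg = correlation_partner_sets(m, "anchor")
        assert "dup" in pos and "neg" in neg

    def test_null_occupancy_matches_tail_probability(self):
        # P(|r| > 0.30) for independent normals at n=10 via the exact
        # Pearson null distribution; compare Monte-Carlo set occupancy.
        from scipy import stats

        n = 10
        tail = 2 * stats.beta(n / 2 - 1, n / 2 - 1, loc=-1, scale=2).cdf(-0.30)
        counts = 0
        trials = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            m = pd.DataFrame(
                r.normal(size=(n, 51)), columns=["anchor"] + [f"m{i}" for i in range(50)]
            )
            pos, neg = correlation_partner_sets(m, "anchor")
            counts += len(pos) + len(neg)
            trials += 50
        rate = counts / trials
        assert rate == pytest.approx(tail, abs=0.05)

    def test_constant_anchor_rejected(self, rng):
        m = pd.DataFrame({"anchor": np.ones(10), "x": rng.normal(size=10)})
        with pytest.raises(DegenerateDataError):
            correlation_partner_sets(m, "anchor")


class TestEnrichment:
    def test_exact_hand_case(self):
        # background 10, pathway of 5, set of 4 all inside:
        # p = C(5,4)*C(5,0)/C(10,4) = 5/210
        bg = [f"m{i}" for i in range(10)]
        pmap = PathwayMap(
            {m: (("pw", "pw") if i < 5 else ("other", "other"))
             for i, m in enumerate(bg)}
        )
        out = pathway_overrepresentation(bg[:4], bg, pmap, level="super")
        p = out.set_index("pathway").loc["pw", "p"]
        assert p == pytest.approx(5 / 210)

    def test_matches_enumeration_oracle(self, rng):
        bg = [f"m{i}" for i in range(11)]
        pw_members = set(bg[:4])
        pmap = PathwayMap(
            {m: ("A", "A") if m in pw_members else ("B", "B") for m in bg}
        )
        hits = list(rng.choice(bg, size=5, replace=False))
        out = pathway_overrepresentation(hits, bg, pmap, level="super")
        k = len(set(hits) & pw_members)
        ge = sum(
            1 for c in combinations(bg, 5) if len(set(c) & pw_members) >= k
        )
        total = math.comb(11, 5)
        assert out.set_index("pathway").loc["A", "p"] == pytest.approx(ge / total)

    def test_absent_pathway_p_near_one(self):
        bg = [f"m{i}" for i in range(10)]
        pmap = PathwayMap(
            {m: ("A", "A") if i < 5 else ("B", "B") for i, m in enumerate(bg)}
        )
        out = pathway_overrepresentation(bg[5:9], bg, pmap, level="super")
        row = out.set_index("pathway").loc["A"]
        assert row["overlap"] == 0
        assert row["p"] == pytest.approx(1.0)

    def test_empty_set_empty_result(self):
        out = pathway_overrepresentation([], ["a"], PathwayMap({"a": ("A", "A")}))
        assert out.empty


class TestNetwork:
    def test_identical_members_edge_flagged(self, rng):
        a = rng.normal(size=10)
        m = pd.DataFrame({"t1": a, "t2": a.copy()})
        out = pairwise_pathway_network(m, ["t1", "t2"])
        edge = out.iloc[0]
        assert edge["r"] == pytest.approx(1.0)
        assert edge["significant"]

    def test_null_flag_rate_near_alpha(self):
        flagged = total = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            m = pd.DataFrame(
                r.normal(size=(10, 6)), columns=[f"t{i}" for i in range(6)]
            )
            out = pairwise_pathway_network(m, list(m.columns))
            flagged += out["significant"].sum()
            total += len(out)
        assert flagged / total == pytest.approx(0.05, abs=0.03)

    def test_unequal_member_panels_across_groups(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(12, 8)), columns=[f"t{i}" for i in range(8)]
        )
        four = pairwise_pathway_network(m.iloc[:6], [f"t{i}" for i in range(4)])
        five = pairwise_pathway_network(m.iloc[6:], [f"t{i}" for i in range(5)])
        assert four["internal"].sum() == 6  # C(4,2)
        assert five["internal"].sum() == 10  # C(5,2)


class TestSlopeSummary:
    def test_counts_and_omission(self, rng):
        coupling = pd.DataFrame(
            {
                "group": ["MGUS"] * 4,
                "metabolite": ["a", "b", "c", "d"],
                "beta1": [0.5, 0.2, -0.1, np.nan],
            }
        )
        pmap = PathwayMap(
            {"a": ("nucleotide", "p"), "b": ("nucleotide", "p"),
             "c": ("lipid", "s"), "d": ("energy", "e")}
        )
        out = pathway_slope_summary(coupling, pmap)
        nuc = out[out["super_pathway"] == "nucleotide"].iloc[0]
        assert nuc["n_positive"] == 2 and nuc["n_negative"] == 0
        assert "energy" not in set(out["super_pathway"])  # NaN row dropped

    def test_stage_reversal_of_planted_nucleotide_features(self, default_cohort):
        """Planted proliferation-coupled (nucleotide-like) features couple
        negatively in MGUS and positively in MM; the per-group summaries
        must flip the majority sign."""
        from nichemet.io import subject_frame
        from nichemet.pipeline import compartment_means
        from nichemet.simulate import synthetic_pathway_map

        params = default_cohort["params"]
        meta = subject_frame(default_cohort["records"])
        rows = {}
        for d in default_cohort["datasets"]:
            seg = default_cohort["segs"][d.section_id]
            rows[d.subject_id], _, _ = compartment_means(d, seg)
        niche = pd.DataFrame(rows, index=list(params.feature_ids)).T
        coup = proliferation_correlations(niche, meta["sphase"], meta["group"])
        sub = coup[coup["metabolite"].isin(params.prolif_features)]
        mgus = sub[sub["group"] == "MGUS"]["beta1"]
        mm = sub[sub["group"] == "MM"]["beta1"]
        assert (mgus < 0).sum() > len(mgus) / 2
        assert (mm > 0).sum() > len(mm) / 2
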