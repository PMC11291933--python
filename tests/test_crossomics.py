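"""Cross-omics candidate construction, edge testing, and summaries."""

import logging

import numpy as np
import pandas as pd
import pytest

from deconfound.cohort import (CohortSpec, CovariateSpec, EffectPlan,
                               generate_features, generate_metadata)
from deconfound.crossomics import (CrossOmicsIntegration,
                                   build_cross_candidates,
                                   summarize_association_classes)
from deconfound.model import ConfounderAnalysis
from deconfound.simulations import _mediation_rep


def frame(index, features, rng):
    return pd.DataFrame(rng.normal(size=(len(index), len(features))),
                        index=index, columns=features)


class TestCandidates:
    def test_product_count_with_empty_space(self, rng):
        idx = [f"s{i}" for i in range(10)]
        tables = {"a": frame(idx, ["a1", "a2", "a3"], rng),
                  "b": frame(idx, ["b1", "b2", "b3", "b4"], rng),
                  "c": frame(idx, ["c1"], rng)}
        robust = {"a": ["a1", "a2", "a3"], "b": ["b1", "b2", "b3", "b4"],
                  "c": []}
        pairs = build_cross_candidates(robust, tables)
        assert len(pairs) == 12  # 3 x 4; empty space contributes nothing

    def test_single_feature_per_space(self, rng):
        idx = [f"s{i}" for i in range(10)]
        tables = {s: frame(idx, [f"{s}1"], rng) for s in "abc"}
        robust = {s: [f"{s}1"] for s in "abc"}
        assert len(build_cross_candidates(robust, tables)) == 3

    def test_disjoint_samples_yield_no_pairs(self, rng, caplog):
        tables = {"a": frame(["s1", "s2"], ["a1"], rng),
                  "b": frame(["t1", "t2"], ["b1"], rng)}
        with caplog.at_level(logging.WARNING, logger="deconfound.crossomics"):
            pairs = build_cross_candidates({"a": ["a1"], "b": ["b1"]}, tables)
        assert pairs == []
        assert "share no samples" in caplog.text

    def test_self_pair_guard(self, rng):
        idx = [f"s{i}" for i in range(10)]
        tables = {"a": frame(idx, ["shared"], rng),
                  "b": frame(idx, ["shared"], rng)}
        pairs = build_cross_candidates({"a": ["shared"], "b": ["shared"]},
                                       tables)
        assert pairs == []


@pytest.fixture(scope="module")
def mediation_fit():
    """One planted taxon -> metabolite -> cytokine chain, fitted."""
    seed = 4321
    covs = (CovariateSpec("dummy", "binary", strength=0.0, base=0.3),)
    spec = CohortSpec(n_controls=0, n_mild=22, n_severe=23,
                      covariates=covs, seed=seed)
    meta = generate_metadata(spec)
    plans = ([EffectPlan("tax_a", "gut_taxa", "direct", "severity", 0.9),
              EffectPlan("met_m", "metabolite", "mediated", "tax_a", 0.8),
              EffectPlan("cyt_c", "cytokine", "mediated", "met_m", 0.8)]
             + [EffectPlan(f"m{i}", "metabolite") for i in range(4)]
             + [EffectPlan(f"c{i}", "cytokine") for i in range(3)])
    tables, _ = generate_features(meta, plans, seed=seed)
    processed = {"metabolite": np.log(tables["metabolite"].data),
                 "cytokine": np.log(tables["cytokine"].data)}
    results = {s: ConfounderAnalysis(df, meta, contrast="severity",
                                     space=s).fit()
               for s, df in processed.items()}
    return CrossOmicsIntegration(results, processed, meta).fit()


class TestIntegration:
    def test_true_edge_retained_with_both_orientations(self, mediation_fit):
        ed = mediation_fit.edges
        hit = ed[((ed["feature_a"] == "met_m") & (ed["feature_b"] == "cyt_c"))
                 | ((ed["feature_a"] == "cyt_c")
                    & (ed["feature_b"] == "met_m"))]
        assert len(hit) == 1
        assert {"verdict_ab", "verdict_ba"} <= set(hit.columns)
        assert abs(hit["rho"].iloc[0]) > 0.4

    def test_downstream_feature_reclassified(self, mediation_fit):
        rec = mediation_fit.updated_records["cytokine"]
        status = rec[(rec["Y_dep.var"] == "cyt_c")
                     & (rec["X_ind.var"] == "severity")
                     ]["AssocStatus"].iloc[0]
        assert status.startswith("confounded") and "met_m" in status

    def test_mixed_contrasts_rejected(self, mediation_fit, rng):
        meta = generate_metadata(CohortSpec(seed=5))
        df = frame(meta.index, ["x"], rng)
        other = ConfounderAnalysis(df, meta, contrast="status").fit()
        results = {"cytokine":
                   list(mediation_fit.model.results_by_space.values())[0],
                   "metabolite": other}
        with pytest.raises(ValueError, match="contrast"):
            CrossOmicsIntegration(results, {}, meta)

    def test_non_robust_features_cannot_leak_into_edges(self, rng):
        """Adding or removing a non-robust feature leaves every edge
        among robust features unchanged."""
        seed = 90
        meta = generate_metadata(CohortSpec(seed=seed))
        plans = [EffectPlan("met_d", "metabolite", "direct", "severity", 0.9),
                 EffectPlan("cyt_d", "cytokine", "direct", "severity", 0.9)]
        tables, _ = generate_features(meta, plans, seed=seed)
        processed = {"metabolite": np.log(tables["metabolite"].data),
                     "cytokine": np.log(tables["cytokine"].data)}
        results = {s: ConfounderAnalysis(df, meta, contrast="severity",
                                         space=s).fit()
                   for s, df in processed.items()}
        cross_a = CrossOmicsIntegration(results, processed, meta).fit()
        padded = dict(processed)
        padded["metabolite"] = processed["metabolite"].assign(
            lurker=rng.normal(size=len(meta)))
        cross_b = CrossOmicsIntegration(results, padded, meta).fit()
        pd.testing.assert_frame_equal(cross_a.edges, cross_b.edges)

    def test_mediation_rep_is_deterministic(self):
        assert _mediation_rep(777) == _mediation_rep(777)


class TestSummaries:
    @staticmethod
    def records(rows):
        return pd.DataFrame(rows, columns=["Y_dep.var", "X_ind.var",
                                           "XY_eff.size", "XY_p.adj",
                                           "AssocStatus"])

    def test_all_ns_summary(self):
        rec = self.records([(f"f{i}", "severity", 0.0, 1.0, "NS")
                            for i in range(4)])
        fractions, tally = summarize_association_classes(
            {"metabolite": rec}, "severity")
        assert fractions.loc["metabolite", "NS"] == 1.0
        assert len(tally) == 0

    def test_fractions_sum_to_one(self):
        rec = self.records([
            ("a", "severity", 0.5, 0.01, "D"),
            ("b", "severity", 0.4, 0.01, "confounded: antibiotics"),
            ("c", "severity", 0.1, 0.9, "NS"),
            ("d", "severity", 0.3, 0.02, "ambiguous")])
        fractions, tally = summarize_association_classes(
            {"gut_taxa": rec}, "severity")
        assert fractions.loc["gut_taxa"].sum() == pytest.approx(1.0)
        assert tally.idxmax() == "antibiotics"

    def test_confounder_tally_counts_each_mention(self):
        rec = self.records([
            ("a", "severity", 0.4, 0.01, "confounded: abx, hosp"),
            ("b", "severity", 0.4, 0.01, "confounded: abx")])
        _, tally = summarize_association_classes({"op_taxa": rec}, "severity")
        assert tally["abx"] == 2 and tally["hosp"] == 1
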