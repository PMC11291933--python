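"""The synthetic cohort generator and its ground-truth ledger."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from deconfound.cohort import (CohortSpec, CovariateSpec, EffectPlan,
                               PlantedTruth, evaluate_recovery,
                               generate_features, generate_metadata)
from deconfound.stats import cliffs_delta


class TestMetadata:
    def test_reference_cohort_shape(self, reference_metadata):
        meta = reference_metadata
        assert len(meta) == 90
        assert meta["subject_id"].nunique() == 45
        counts = meta.groupby("status")["subject_id"].nunique()
        assert counts.to_dict() == {"control": 15, "mild": 22, "severe": 8}

    def test_controls_untreated_and_not_hospitalized(self, reference_metadata):
        controls = reference_metadata[reference_metadata["status"] == "control"]
        assert (controls["antibiotics"] == 0).all()
        assert (controls["hospital_days"] == 0).all()

    def test_covariates_constant_within_subject(self, reference_metadata):
        per_subject = reference_metadata.groupby("subject_id")["antibiotics"]
        assert (per_subject.nunique() == 1).all()

    def test_deterministic_given_seed(self):
        a = generate_metadata(CohortSpec(seed=5))
        b = generate_metadata(CohortSpec(seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = generate_metadata(CohortSpec(seed=6))
        assert not a["hospital_days"].equals(c["hospital_days"])

    def test_empty_spec_keeps_schema(self):
        meta = generate_metadata(CohortSpec(0, 0, 0))
        assert len(meta) == 0
        assert {"subject_id", "timepoint", "status"} <= set(meta.columns)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_controls=-1)

    def test_zero_strength_gives_independence(self):
        covs = (CovariateSpec("drug", "binary", strength=0.0, base=0.3),)
        meta = generate_metadata(CohortSpec(3000, 4000, 3000, 1,
                                            covariates=covs, seed=11))
        sev = meta["status"].map({"control": 0, "mild": 1, "severe": 2})
        r = np.corrcoef(meta["drug"], sev)[0, 1]
        assert abs(r) < 0.05

    def test_marginal_frequencies_converge(self):
        covs = (CovariateSpec("drug", "binary", strength=0.0, base=0.3),)
        meta = generate_metadata(CohortSpec(0, 10_000, 0, 1,
                                            covariates=covs, seed=2))
        assert meta["drug"].mean() == pytest.approx(0.3, abs=0.03)

    def test_exact_counts_pin_prevalence(self):
        covs = (CovariateSpec("abx", "binary", strength=0.625, base=0.2,
                              exact_counts=True),)
        meta = generate_metadata(CohortSpec(0, 22, 23, 1, covariates=covs,
                                            seed=3))
        by_group = meta.groupby("status")["abx"].sum()
        assert by_group["mild"] == round(0.2 * 22)
        assert by_group["severe"] == round(0.7 * 23)


class TestFeatureGeneration:
    def test_null_features_have_small_deltas(self, reference_metadata):
        plans = [EffectPlan(f"n{i}", "metabolite") for i in range(100)]
        tables, _ = generate_features(reference_metadata, plans, seed=3)
        data = np.log(tables["metabolite"].data)
        mild = data[(reference_metadata["status"] == "mild").to_numpy()]
        sev = data[(reference_metadata["status"] == "severe").to_numpy()]
        deltas = [abs(cliffs_delta(sev[c], mild[c])) for c in data.columns]
        assert np.median(deltas) < 0.15

    def test_maximal_delta_separates_completely(self, reference_metadata):
        plans = [EffectPlan("y", "cytokine", "direct", "severity", 1.0)]
        tables, _ = generate_features(reference_metadata, plans, seed=4)
        vals = tables["cytokine"].data["y"]
        mild = vals[(reference_metadata["status"] == "mild").to_numpy()]
        sev = vals[(reference_metadata["status"] == "severe").to_numpy()]
        assert sev.min() > mild.max()

    def test_zero_slope_mediation_is_independence(self):
        meta = generate_metadata(CohortSpec(0, 1000, 0, 1, seed=5))
        plans = [EffectPlan("tax", "gut_taxa", "direct", "status", 0.5),
                 EffectPlan("met", "metabolite", "mediated", "tax", 0.0)]
        tables, _ = generate_features(meta, plans, seed=5)
        rho = spearmanr(tables["gut_taxa"].data["tax"],
                        tables["metabolite"].data["met"])[0]
        assert abs(rho) < 0.1

    def test_planted_delta_recovered_on_average(self, reference_metadata):
        plans = [EffectPlan(f"d{i}", "metabolite", "direct", "severity", 0.5)
                 for i in range(200)]
        tables, _ = generate_features(reference_metadata, plans, seed=6)
        data = np.log(tables["metabolite"].data)
        mild = data[(reference_metadata["status"] == "mild").to_numpy()]
        sev = data[(reference_metadata["status"] == "severe").to_numpy()]
        est = np.mean([cliffs_delta(sev[c], mild[c]) for c in data.columns])
        assert est == pytest.approx(0.5, abs=0.15)

    def test_taxa_tables_are_integral_counts(self, reference_metadata):
        plans = [EffectPlan(f"t{i}", "gut_taxa") for i in range(10)]
        tables, _ = generate_features(reference_metadata, plans, seed=7)
        table = tables["gut_taxa"]
        assert table.state == "counts"
        vals = table.data.to_numpy()
        assert (vals >= 0).all() and np.allclose(vals, np.round(vals))

    def test_byte_identical_given_seed(self, reference_metadata):
        plans = [EffectPlan(f"t{i}", "gut_taxa") for i in range(5)]
        a, _ = generate_features(reference_metadata, plans, seed=8)
        b, _ = generate_features(reference_metadata, plans, seed=8)
        assert a["gut_taxa"].data.to_csv() == b["gut_taxa"].data.to_csv()

    def test_cyclic_mediation_rejected(self, reference_metadata):
        plans = [EffectPlan("a", "metabolite", "mediated", "b", 0.5),
                 EffectPlan("b", "metabolite", "mediated", "a", 0.5)]
        with pytest.raises(ValueError, match="cycl"):
            generate_features(reference_metadata, plans, seed=9)

    def test_unresolvable_driver_rejected(self, reference_metadata):
        plans = [EffectPlan("a", "metabolite", "confounded", "ghost", 0.5)]
        with pytest.raises(KeyError):
            generate_features(reference_metadata, plans, seed=9)

    def test_duplicate_feature_ids_rejected(self, reference_metadata):
        plans = [EffectPlan("a", "metabolite"), EffectPlan("a", "metabolite")]
        with pytest.raises(ValueError, match="duplicate"):
            generate_features(reference_metadata, plans, seed=9)

    def test_truth_ledger_covers_every_feature(self, reference_metadata):
        plans = [EffectPlan(f"t{i}", "gut_taxa") for i in range(6)]
        tables, truth = generate_features(
            reference_metadata, plans, seed=10,
            diversity_effects={"gut_taxa": ("severity", 0.8)})
        assert set(tables["gut_taxa"].data.columns) == set(truth.plans)


class TestRecoveryScoring:
    @staticmethod
    def records(rows):
        return pd.DataFrame(rows, columns=["Y_dep.var", "X_ind.var",
                                           "XY_eff.size", "XY_p.adj",
                                           "AssocStatus"])

    def test_all_null_all_ns(self):
        truth = PlantedTruth({f"n{i}": EffectPlan(f"n{i}", "metabolite")
                              for i in range(5)})
        rec = self.records([(f"n{i}", "severity", 0.0, 1.0, "NS")
                            for i in range(5)])
        rep = evaluate_recovery(truth, rec)
        assert np.isnan(rep.sensitivity)
        assert rep.false_robust_rate == 0.0

    def test_perfect_direct_recovery(self):
        truth = PlantedTruth({f"d{i}": EffectPlan(f"d{i}", "cytokine",
                                                  "direct", "severity", 0.8)
                              for i in range(10)})
        rec = self.records([(f"d{i}", "severity", 0.7, 0.001, "D")
                            for i in range(10)])
        rep = evaluate_recovery(truth, rec)
        assert rep.sensitivity == 1.0
        assert np.isnan(rep.confounder_detection_rate)

    def test_confounder_naming_required(self):
        truth = PlantedTruth({"c0": EffectPlan("c0", "cytokine", "confounded",
                                               "antibiotics", 0.8)})
        hit = self.records([("c0", "severity", 0.5, 0.01,
                             "confounded: antibiotics")])
        miss = self.records([("c0", "severity", 0.5, 0.01,
                              "confounded: hospital_days")])
        assert evaluate_recovery(truth, hit).confounder_detection_rate == 1.0
        assert evaluate_recovery(truth, miss).confounder_detection_rate == 0.0

    def test_false_robust_rate_on_a_real_null_run(self):
        """End-to-end scoring: null features through the full analysis
        are almost never classified robust at FDR 0.05."""
        from deconfound.model import ConfounderAnalysis
        meta = generate_metadata(CohortSpec(seed=14))
        plans = [EffectPlan(f"n{i}", "metabolite") for i in range(300)]
        tables, truth = generate_features(meta, plans, seed=14)
        res = ConfounderAnalysis.from_tables(tables["metabolite"], meta,
                                             contrast="status").fit()
        rep = evaluate_recovery(truth, res.records, contrast_label="status")
        assert rep.false_robust_rate <= 0.07

    def test_unknown_feature_rejected(self):
        truth = PlantedTruth({"a": EffectPlan("a", "metabolite")})
        rec = self.records([("ghost", "severity", 0.0, 1.0, "NS")])
        with pytest.raises(KeyError):
            evaluate_recovery(truth, rec)
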