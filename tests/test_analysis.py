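"""Construct-level statistics: scores, grouping, stratification, correlations."""

import numpy as np
import pandas as pd
import pytest

from foldability.analysis import (
    RmsdThresholdClassifier,
    assign_labels_from_precipitant,
    classify_by_threshold,
    contingency_summary,
    inter_model_rmsd,
    mean_plddt,
    round_percentage,
    score_construct,
    solubility_analysis,
    spearman,
    stratify_sites,
    unpaired_t_test,
)
from foldability.errors import ValidationError
from foldability.structio import AnnotationTable, Atom, ModelSet, StructureModel
from foldability.superpose import pair_by_map
from foldability.synthetic import make_toy_structure


def radial_model(reference, target_rmsd, residue_map, atom_set=("CA", "CB", "C", "O"),
                 model_id="scaled"):
    """Displace every atom radially from the centroid of the paired subset.

    The cross-covariance against the reference stays symmetric positive
    definite, so the optimal rotation is the identity and the superposed RMSD
    equals epsilon times the RMS radius of the paired reference atoms --
    giving a model with an exactly known RMSD.
    """
    pairing = pair_by_map(reference, reference, residue_map, atom_set)
    sub = pairing.reference_coords
    centroid = sub.mean(axis=0)
    rms = np.sqrt(((sub - centroid) ** 2).sum(axis=1).mean())
    max_r = np.sqrt(((sub - centroid) ** 2).sum(axis=1).max())
    assert max_r < 2.0 * rms, "fixture would trigger outlier rejection"
    eps = target_rmsd / rms
    xyz = reference.coords()
    new = centroid + (1.0 + eps) * (xyz - centroid)
    return reference.with_coords(new, model_id=model_id)


@pytest.fixture(scope="module")
def ref_structure():
    return make_toy_structure("MKVLEAIRKQWERTYIPSDF", "H" * 20, seed=3, model_id="ref")


IDENTITY_MAP_20 = list(range(1, 21))


class TestScoreConstruct:
    def test_identical_copies_score_zero(self, ref_structure):
        ms = ModelSet("c", "A", [ref_structure] * 5)
        sc = score_construct(ms, ref_structure, residue_map=IDENTITY_MAP_20)
        assert sc.mean_rmsd == pytest.approx(0.0, abs=1e-12)
        assert sc.sd_rmsd == 0.0

    def test_known_per_model_rmsds_give_exact_mean_sd(self, ref_structure):
        targets = [1.0, 1.0, 2.0]
        models = [
            radial_model(ref_structure, t, IDENTITY_MAP_20, model_id=f"m{i}")
            for i, t in enumerate(targets)
        ]
        sc = score_construct(ModelSet("c", "A", models), ref_structure,
                             residue_map=IDENTITY_MAP_20)
        assert sc.per_model == pytest.approx(targets, abs=1e-9)
        assert sc.mean_rmsd == pytest.approx(4.0 / 3.0, abs=1e-9)
        assert sc.sd_rmsd == pytest.approx(np.std(targets, ddof=1), abs=1e-9)

    def test_single_model_flagged_with_zero_sd(self, ref_structure):
        ms = ModelSet("c", "A", [ref_structure])
        with pytest.warns(UserWarning, match="single-model"):
            sc = score_construct(ms, ref_structure, residue_map=IDENTITY_MAP_20)
        assert sc.single_model and sc.sd_rmsd == 0.0

    def test_failing_model_named_in_error(self, ref_structure):
        ms = ModelSet("c", "A", [ref_structure])
        with pytest.raises(ValidationError, match="construct 'c'"):
            score_construct(ms, ref_structure, residue_map=[None] * 20)


class TestMeanPlddt:
    def test_uniform_and_mixed(self):
        atoms = [Atom(1, "ALA", "CA", 0, 0, 0, 80.0), Atom(2, "ALA", "CA", 1, 0, 0, 100.0)]
        assert mean_plddt(StructureModel("m", "A", atoms)) == pytest.approx(90.0)

    def test_residue_without_ca_excluded(self):
        atoms = [
            Atom(1, "ALA", "CA", 0, 0, 0, 80.0),
            Atom(2, "ALA", "N", 1, 0, 0, 0.0),  # no CA on residue 2
        ]
        assert mean_plddt(StructureModel("m", "A", atoms)) == pytest.approx(80.0)

    def test_no_ca_atoms_rejected(self):
        atoms = [Atom(1, "ALA", "N", 0, 0, 0, 80.0)]
        with pytest.raises(ValidationError):
            mean_plddt(StructureModel("m", "A", atoms))


class TestInterModelRmsd:
    def test_single_identical_models(self, ref_structure):
        a = ModelSet("c", "A", [ref_structure])
        b = ModelSet("c", "B", [ref_structure])
        assert inter_model_rmsd(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_schemes_on_known_cross_rmsds(self, ref_structure):
        # pairwise RMSDs {0, d, d, 0} -> all_pairs_mean d/2, best 0, ranked 0
        d = 1.0
        scaled = radial_model(ref_structure, d, IDENTITY_MAP_20)
        a = ModelSet("c", "A", [ref_structure, scaled])
        b = ModelSet("c", "B", [ref_structure, scaled])
        assert inter_model_rmsd(a, b, "all_pairs_mean") == pytest.approx(d / 2, abs=1e-9)
        assert inter_model_rmsd(a, b, "best_pair") == pytest.approx(0.0, abs=1e-9)
        assert inter_model_rmsd(a, b, "rank_matched") == pytest.approx(0.0, abs=1e-9)

    def test_all_pairs_mean_at_least_best_pair(self, ref_structure):
        a = ModelSet("c", "A", [radial_model(ref_structure, t, IDENTITY_MAP_20)
                                for t in (0.3, 0.9)])
        b = ModelSet("c", "B", [radial_model(ref_structure, t, IDENTITY_MAP_20)
                                for t in (0.5, 1.4)])
        assert inter_model_rmsd(a, b, "all_pairs_mean") >= inter_model_rmsd(a, b, "best_pair")


class TestLabels:
    def make_table(self, ratios, overrides=None):
        df = pd.DataFrame(
            {"precipitant_ratio": ratios},
            index=[f"X-{i}" for i in range(len(ratios))],
        )
        return AnnotationTable(df=df, overrides=overrides or {})

    def test_strict_cutoff(self):
        table = assign_labels_from_precipitant(self.make_table([0.59, 0.60]))
        assert table.labels().tolist() == ["foldable", "unfoldable"]

    def test_override_beats_ratio(self):
        table = assign_labels_from_precipitant(
            self.make_table([0.95], overrides={"X-0": "foldable"})
        )
        assert table.labels().loc["X-0"] == "foldable"

    def test_missing_ratio_stays_unknown(self):
        table = assign_labels_from_precipitant(self.make_table([None]))
        assert table.labels().loc["X-0"] == "unknown"


class TestThresholdClassification:
    def records(self, scores, labels=None):
        idx = [f"X-{i}" for i in range(len(scores))]
        df = pd.DataFrame({"mean_rmsd": scores}, index=idx)
        df["label"] = labels if labels is not None else "unknown"
        return df

    def test_median_split(self):
        gs = classify_by_threshold(self.records([1, 2, 3, 4]), mode="median")
        assert gs.threshold_value == 2.5
        assert gs.assignment.tolist() == ["Low", "Low", "High", "High"]

    def test_all_equal_scores_all_low(self):
        gs = classify_by_threshold(self.records([2, 2, 2]), mode="mean")
        assert (gs.assignment == "Low").all()

    def test_reference_construct_is_in_low_group(self):
        gs = classify_by_threshold(
            self.records([3, 1, 2]), mode="reference_construct", reference_name="X-0"
        )
        assert gs.threshold_value == 3
        assert gs.assignment.loc["X-0"] == "Low"

    def test_fixed_infinite_thresholds(self):
        rec = self.records([1.0, 5.0, 9.0])
        low = classify_by_threshold(rec, mode="fixed", fixed_value=np.inf)
        high = classify_by_threshold(rec, mode="fixed", fixed_value=-np.inf)
        assert (low.assignment == "Low").all()
        assert (high.assignment == "High").all()

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            classify_by_threshold(
                self.records([1, 2]), mode="reference_construct", reference_name="nope"
            )

    def test_counts_partition_and_percentages_recompute(self):
        labels = ["foldable", "unfoldable", "foldable", "unknown", "unfoldable"]
        rec = self.records([1, 2, 3, 4, 5], labels)
        gs = classify_by_threshold(rec, mode="median")
        total_labeled = sum(g["labeled"] for g in gs.groups.values())
        assert total_labeled == 4
        assert sum(g["total"] for g in gs.groups.values()) == 5
        for g in gs.groups.values():
            if g["labeled"]:
                assert g["percent_foldable"] == round_percentage(g["foldable"], g["labeled"])[0]
                assert g["percent_foldable"] + g["percent_unfoldable"] == pytest.approx(
                    100.0, abs=0.1
                )

    def test_sklearn_estimator_protocol(self):
        clf = RmsdThresholdClassifier(mode="median")
        assert clf.get_params()["mode"] == "median"
        clf.set_params(mode="mean").fit(self.records([1, 2, 3]))
        assert clf.threshold_ == 2.0
        assert list(clf.predict(self.records([1.5, 2.5]))) == ["Low", "High"]


class TestContingency:
    @pytest.mark.parametrize(
        "f,n,expected",
        [(15, 44, 34.1), (3, 29, 10.3), (59, 68, 86.8), (46, 58, 79.3),
         (15, 17, 88.2), (0, 7, 0.0), (25, 79, 31.6), (5, 11, 45.5)],
    )
    def test_rounded_percentages(self, f, n, expected):
        assert contingency_summary(f, n)["percent"] == expected

    def test_zero_denominator_not_applicable(self):
        assert contingency_summary(0, 0)["percent"] is None

    def test_half_rounds_away_from_zero(self):
        assert round_percentage(1, 8)[0] == 12.5
        assert round_percentage(5, 16)[0] == 31.3  # 31.25 -> 31.3


class TestStratify:
    def records(self, kind, sites):
        df = pd.DataFrame(
            {"kind": kind, "site": sites},
            index=[f"X-{s}" for s in sites],
        )
        return df

    def test_permutant_uses_residue_at_site(self):
        rec = stratify_sites(self.records("permutant", [1, 2, 3, 4]), "CHHC")
        assert rec["ss_category"].tolist() == [
            "outside_SS", "within_SS", "within_SS", "outside_SS",
        ]

    def test_insertion_flank_rules(self):
        rec_r = stratify_sites(self.records("insertion", [1]), "CHHC", "flank_right")
        rec_l = stratify_sites(self.records("insertion", [1]), "CHHC", "flank_left")
        assert rec_r["ss_category"].iloc[0] == "within_SS"  # residue 2 = H
        assert rec_l["ss_category"].iloc[0] == "outside_SS"  # residue 1 = C

    def test_both_strict_requires_both_flanks(self):
        rec = stratify_sites(self.records("insertion", [1, 2]), "CHHC", "both_strict")
        assert rec["ss_category"].tolist() == ["outside_SS", "within_SS"]

    def test_missing_ss_all_unknown_with_warning(self):
        with pytest.warns(UserWarning):
            rec = stratify_sites(self.records("permutant", [1, 2]), None)
        assert (rec["ss_category"] == "unknown").all()

    def test_categories_partition_the_library(self):
        ss = "CCHHHHEEEC"
        rec = stratify_sites(self.records("permutant", list(range(1, 11))), ss)
        counts = rec["ss_category"].value_counts()
        assert counts.get("within_SS", 0) + counts.get("outside_SS", 0) == 10
        assert counts["within_SS"] == sum(s in "HE" for s in ss)


class TestCorrelationAndTests:
    def test_spearman_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [2, 4, 6, 8, 10])[0] == pytest.approx(1.0)
        assert spearman(x, [10, 8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_spearman_hand_computed_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_spearman_constant_vector_undefined(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_t_identical_groups(self):
        t, p = unpaired_t_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_t_separated_groups(self):
        t, p = unpaired_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert abs(t) > 5 and p < 0.01

    def test_t_matches_hand_pooled_formula(self):
        a = np.array([2.1, 2.5, 2.3, 2.2])
        b = np.array([2.8, 3.0, 2.9])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        t, _ = unpaired_t_test(a, b)
        assert t == pytest.approx(expected, abs=1e-6)


class TestSolubility:
    def records(self, scores, solubilities, lengths=None):
        df = pd.DataFrame(
            {
                "inter_model_rmsd": scores,
                "solubility": solubilities,
                "length": lengths if lengths is not None else 100,
            },
            index=[f"X-{i}" for i in range(len(scores))],
        )
        return df

    def test_all_soluble_fraction_one_everywhere(self):
        rec = self.records([0.5, 1.5, 2.5, 3.5], [0.9, 0.8, 0.7, 0.95])
        out = solubility_analysis(rec, cutoffs=[1, 2, 3, 4])
        assert all(row["fraction_soluble"] == 1.0 for row in out["cutoff_sweep"])

    def test_quartiles_linear_interpolation(self):
        rec = self.records([1.0, 1.0, 1.0, 1.0], [0.2, 0.4, 0.7, 0.9])
        out = solubility_analysis(rec, cutoffs=[2.0])
        q = out["group_quartiles"]["median"]["Low"]
        assert q["median"] == pytest.approx(0.55)
        assert q["q1"] == pytest.approx(0.35)
        assert q["q3"] == pytest.approx(0.75)

    def test_empty_subset_reported_not_applicable(self):
        rec = self.records([5.0, 6.0], [0.7, 0.8])
        out = solubility_analysis(rec, cutoffs=[1.0])
        assert out["cutoff_sweep"][0]["fraction_soluble"] is None

    def test_noise_free_monotone_link(self):
        # solubility strictly decreasing in score: the soluble fraction cannot
        # increase as the cutoff grows
        scores = np.linspace(0.2, 4.0, 20)
        sol = 1.0 - 0.2 * scores
        rec = self.records(scores, np.clip(sol, 0, 1))
        out = solubility_analysis(rec, cutoffs=[1, 2, 3, 4])
        fr = [row["fraction_soluble"] for row in out["cutoff_sweep"]]
        assert all(a >= b for a, b in zip(fr, fr[1:]))
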