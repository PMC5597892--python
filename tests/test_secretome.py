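import numpy as np
import pandas as pd
import pytest

from postprandial import secretome
from postprandial.io import ValidationError
from postprandial.simulate import ProteomePlantSpec, simulate_protein_tables


def protein_table(rows):
    return pd.DataFrame(rows, columns=["protein_id", "annotation", "unique_peptides", "empai"])


class TestEmpai:
    def test_full_coverage_gives_nine(self):
        assert secretome.compute_empai(8, 8) == pytest.approx(9.0)

    def test_zero_observed_gives_zero(self):
        assert secretome.compute_empai(0, 5) == 0.0

    def test_half_coverage_closed_form(self):
        assert secretome.compute_empai(4, 8) == pytest.approx(10**0.5 - 1)

    def test_strictly_increasing_in_observed(self):
        values = [secretome.compute_empai(i, 10) for i in range(11)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_zero_observable_rejected(self):
        with pytest.raises(ValidationError):
            secretome.compute_empai(0, 0)

    def test_from_sequence_uses_digestion(self):
        # two observable tryptic peptides of length 6-35
        seq = "AAAAAGK" + "CCCCCCR" + "WW"
        value = secretome.empai_from_sequence(seq, 1)
        assert value == pytest.approx(10**0.5 - 1)


class TestPeptideFilter:
    def test_threshold_two(self):
        t = protein_table(
            [(f"p{i}", "x", n, 1.0) for i, n in enumerate([1, 2, 3, 1, 5])]
        )
        stage = secretome.filter_min_peptides(t)
        assert len(stage.retained) == 3
        assert stage.audit(previous_n=5)

    def test_min_one_is_identity(self):
        t = protein_table([("p1", "x", 1, 1.0), ("p2", "y", 7, 2.0)])
        stage = secretome.filter_min_peptides(t, min_unique=1)
        assert len(stage.retained) == 2 and len(stage.removed) == 0


class TestPlasmaSubtraction:
    def test_overlap_removed_with_reason(self):
        dig = protein_table([(f"p{i}", "x", 3, 1.0) for i in range(5)])
        pla = protein_table([("p1", "alb", 3, 1.0), ("p3", "apo", 2, 1.0)])
        stage = secretome.subtract_plasma(dig, pla)
        assert set(stage.removed["protein_id"]) == {"p1", "p3"}
        assert stage.reasons["p1"] == "plasma"

    def test_disjoint_tables_identity(self):
        dig = protein_table([("a", "x", 3, 1.0)])
        pla = protein_table([("b", "y", 3, 1.0)])
        stage = secretome.subtract_plasma(dig, pla)
        assert len(stage.removed) == 0

    def test_idempotent(self):
        dig = protein_table([(f"p{i}", "x", 3, 1.0) for i in range(4)])
        pla = protein_table([("p0", "alb", 3, 1.0)])
        once = secretome.subtract_plasma(dig, pla)
        twice = secretome.subtract_plasma(once.retained, pla)
        assert len(twice.removed) == 0


class TestBaseNames:
    @pytest.mark.parametrize(
        "annotation,base",
        [
            ("Collagen alpha-1(I) chain", "collagen"),
            ("Keratin, type II cytoskeletal 1", "keratin"),
            ("Actin, cytoplasmic 1", "actin"),
            ("Hemoglobin subunit beta", "hemoglobin"),
            ("Serum albumin", "serum albumin"),
            ("Desmin", "desmin"),
        ],
    )
    def test_head_noun_phrase(self, annotation, base):
        assert secretome.derive_base_name(annotation) == base

    def test_prey_homolog_removal(self):
        dig = protein_table(
            [
                ("p1", "collagen alpha-2(I) chain-like", 3, 1.0),
                ("p2", "keratin-like protein 4", 3, 1.0),
                ("p3", "mucin-6-like", 3, 1.0),
            ]
        )
        prey = protein_table(
            [
                ("m1", "Collagen alpha-1(I) chain", 3, 1.0),
                ("m2", "Keratin, type II cytoskeletal 1", 3, 1.0),
            ]
        )
        stage = secretome.subtract_prey_homologs(dig, prey)
        assert set(stage.retained["protein_id"]) == {"p3"}
        assert "collagen" in stage.reasons["p1"]
        assert "keratin" in stage.reasons["p2"]

    def test_no_match_is_identity(self):
        dig = protein_table([("p1", "mucin-6-like", 3, 1.0)])
        prey = protein_table([("m1", "Vimentin", 3, 1.0)])
        stage = secretome.subtract_prey_homologs(dig, prey)
        assert len(stage.removed) == 0


class TestCategorisation:
    def test_category_exemplars(self):
        t = protein_table(
            [
                ("p1", "mucin-6-like", 3, 1.0),
                ("p2", "gastricsin-like precursor", 3, 1.0),
                ("p3", "phospholipase A2", 3, 1.0),
                ("p4", "gastric intrinsic factor", 3, 1.0),
            ]
        )
        out, counts = secretome.categorize_secretome(t)
        assert out.set_index("protein_id")["category"].to_dict() == {
            "p1": "mucosal",
            "p2": "proteolytic",
            "p3": "other_hydrolytic",
            "p4": "other",
        }
        assert counts["not_secreted"] == 0

    def test_intracellular_protease_not_secreted(self):
        # the stomach-specific calpain is a protease but stays intracellular
        t = protein_table([("p1", "calpain 9", 3, 1.0)])
        out, counts = secretome.categorize_secretome(t)
        assert out.iloc[0].category == "not_secreted"
        assert counts["not_secreted"] == 1


class TestCorrelation:
    def test_exact_line_r2_one(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        fit = secretome.correlate_expression_protein(2 * x + 1, x)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["intercept"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x = pd.Series([1.0, 2.0, 4.0, 7.0, 11.0], index=list("abcde"))
        y = pd.Series([2.0, 1.0, 5.0, 4.0, 9.0], index=list("abcde"))
        fit = secretome.correlate_expression_protein(y, x)
        xm = np.vstack([np.ones(5), x.to_numpy()]).T
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y.to_numpy())
        resid = y.to_numpy() - xm @ beta
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert fit["intercept"] == pytest.approx(beta[0], abs=1e-12)
        assert fit["slope"] == pytest.approx(beta[1], abs=1e-12)
        assert fit["r_squared"] == pytest.approx(r2, abs=1e-12)

    def test_independent_values_near_zero_r2(self, rng):
        x = pd.Series(rng.lognormal(size=64))
        y = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
        r2s = []
        for _ in range(50):
            y = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
            r2s.append(secretome.correlate_expression_protein(y, x)["r_squared"])
        assert np.mean(r2s) < 0.05

    def test_zero_variance_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            secretome.correlate_expression_protein(x, x * 0 + 2)


class TestChain:
    def test_planted_composition_recovered(self):
        dig, pla, prey, truth = simulate_protein_tables(seed=7)
        report, categorized, counts = secretome.run_secretome_chain(dig, pla, prey)
        stages = dict(report.counts())
        assert stages == {"min_peptides": 314, "plasma": 264, "prey_homolog": 114}
        assert counts == {
            "mucosal": 18,
            "proteolytic": 7,
            "other_hydrolytic": 4,
            "other": 8,
            "not_secreted": 77,
        }
        # removed sets match the planted strata exactly
        by_stage = {s.name: set(s.removed["protein_id"]) for s in report.stages}
        strata = truth.groupby("stratum")["protein_id"].agg(set)
        assert by_stage["min_peptides"] == strata["single"]
        assert by_stage["plasma"] == strata["plasma"]
        assert by_stage["prey_homolog"] == strata["prey_homolog"]

    def test_audit_identity_every_stage(self):
        dig, pla, prey, _ = simulate_protein_tables(seed=3)
        report, _, _ = secretome.run_secretome_chain(dig, pla, prey)
        previous = len(dig)
        for stage in report.stages:
            assert len(stage.retained) + len(stage.removed) == previous
            assert all(stage.reasons[pid] for pid in stage.removed["protein_id"])
            previous = len(stage.retained)

    def test_retained_sets_nested(self):
        dig, pla, prey, _ = simulate_protein_tables(seed=5)
        report, _, _ = secretome.run_secretome_chain(dig, pla, prey)
        previous = set(dig["protein_id"])
        for stage in report.stages:
            current = set(stage.retained["protein_id"])
            assert current <= previous
            previous = current

    def test_empty_digestive_table(self):
        empty = protein_table([])
        report, categorized, counts = secretome.run_secretome_chain(empty, empty, empty)
        assert all(n == 0 for _, n in report.counts())
        assert len(categorized) == 0

    def test_scaled_spec(self):
        spec = ProteomePlantSpec(
            n_single=20, n_plasma=5, n_prey=10, n_intracellular=7, n_secreted=(3, 2, 1, 2)
        )
        dig, pla, prey, _ = simulate_protein_tables(spec, seed=1)
        report, _, counts = secretome.run_secretome_chain(dig, pla, prey)
        assert dict(report.counts()) == {"min_peptides": 30, "plasma": 25, "prey_homolog": 15}
        assert counts["mucosal"] == 3 and counts["not_secreted"] == 7
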