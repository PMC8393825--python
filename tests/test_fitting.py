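"""Fitting, information quantities, statistical tests, lattice search."""

import math

import numpy as np
import pytest

from rabn import (
    ContingencyTable,
    JointDistribution,
    VariableSystem,
    degrees_of_freedom,
    entropy,
    fit_bn,
    fit_maxent,
    information_criteria,
    lr_test,
    parse_structure,
    predict_dv,
    ra_lattice,
    search,
    transmission,
)
from rabn.bn import Dag
from rabn.fitting import closed_form_fit, evaluate, loglik, margin
from rabn.io import SyntheticSpec, random_distribution, sample_from_model


def S(text, system):
    return parse_structure(text, system).plain


def random_table(system, seed, n=1000.0):
    return ContingencyTable(
        system, random_distribution(system, seed).probabilities * n
    )


class TestFitBn:
    def test_empty_dag_on_uniform_counts(self, sys4):
        table = ContingencyTable(sys4, np.full(sys4.shape, 3.0))
        fitted = fit_bn(Dag(sys4, []), table)
        assert np.allclose(fitted.probabilities, 1 / 16)

    def test_saturated_dag_reproduces_the_data(self, sys4):
        table = random_table(sys4, 0)
        dag = Dag(
            sys4,
            [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")],
        )
        assert np.allclose(
            fit_bn(dag, table).probabilities, table.counts / table.n
        )

    def test_single_edge_assembles_margins(self, sys4):
        table = random_table(sys4, 1)
        p = table.counts / table.n
        fitted = fit_bn(Dag(sys4, [("C", "D")]), table)
        want = (  # p(A) p(B) p(C) p(D|C) = m_A m_B m_CD
            margin(p, sys4, "A", keepdims=True)
            * margin(p, sys4, "B", keepdims=True)
            * margin(p, sys4, "CD", keepdims=True)
        )
        assert np.allclose(fitted.probabilities, want)

    def test_zero_parent_state_gets_uniform_conditional(self, sys2):
        counts = np.array([[4.0, 4.0], [0.0, 0.0]])  # A=1 never observed
        fitted = fit_bn(Dag(sys2, [("A", "B")]), ContingencyTable(sys2, counts))
        assert fitted.probabilities.sum() == pytest.approx(1.0)


class TestFitMaxent:
    def test_chain_closed_form(self, sys3):
        table = random_table(sys3, 2)
        p = table.counts / table.n
        fitted, sweeps = fit_maxent(S("AB:BC", sys3), table)
        want = (
            margin(p, sys3, "AB", keepdims=True)
            * margin(p, sys3, "BC", keepdims=True)
            / margin(p, sys3, "B", keepdims=True)
        )
        assert np.allclose(fitted.probabilities, want)
        assert sweeps <= 3

    def test_independence_is_product_of_margins(self, sys4):
        table = random_table(sys4, 3)
        fitted, _ = fit_maxent(S("A:B:C:D", sys4), table)
        p = table.counts / table.n
        want = np.ones(sys4.shape)
        for v in sys4.names:
            want = want * margin(p, sys4, v, keepdims=True)
        assert np.allclose(fitted.probabilities, want)

    def test_loop_margins_match_and_entropy_is_maximal(self, sys3):
        """IPF on the triangle reproduces every margin and agrees with a
        generic convex-optimization maximum-entropy oracle."""
        table = random_table(sys3, 4, n=100.0)
        structure = S("AB:BC:CA", sys3)
        fitted, _ = fit_maxent(structure, table)
        p = table.counts / table.n
        for r in structure.relations:
            assert np.allclose(
                margin(fitted.probabilities, sys3, r), margin(p, sys3, r), atol=1e-8
            )

        # independent oracle: the margin-constrained maximum-entropy
        # distribution is the no-three-way-interaction log-linear model,
        # fitted here as a Poisson GLM with all main effects and two-way
        # interaction columns
        import statsmodels.api as sm

        a, b, c = np.meshgrid([0, 1], [0, 1], [0, 1], indexing="ij")
        design = np.column_stack(
            [
                np.ones(8),
                a.ravel(),
                b.ravel(),
                c.ravel(),
                (a * b).ravel(),
                (b * c).ravel(),
                (a * c).ravel(),
            ]
        )
        glm = sm.GLM(table.counts.ravel(), design, family=sm.families.Poisson())
        oracle = glm.fit(tol=1e-12).fittedvalues / table.n
        assert np.allclose(fitted.probabilities.ravel(), oracle, atol=1e-7)

    def test_loopless_ipf_equals_closed_form(self, sys4):
        from rabn.ra import has_loop

        table = random_table(sys4, 5)
        for s in ra_lattice(sys4).structures:
            if has_loop(s):
                continue
            via_ipf, _ = fit_maxent(s, table)
            direct = closed_form_fit(s, table)
            tv = np.abs(via_ipf.probabilities - direct.probabilities).sum()
            assert tv < 1e-10

    def test_projection_never_loses_entropy(self, sys4):
        table = random_table(sys4, 6)
        data_h = entropy(table.distribution())
        for text in ("AB:BC:CD:AD", "AD:BD:CD", "ABC:D", "A:B:C:D"):
            fitted, _ = fit_maxent(S(text, sys4), table)
            assert entropy(fitted) >= data_h - 1e-12

    def test_subscripted_notation_is_rejected(self, sys4):
        table = random_table(sys4, 7)
        with pytest.raises(ValueError):
            fit_maxent(parse_structure("BCD_B:C_:A", sys4), table)


class TestInformation:
    def test_uniform_entropy_is_four_bits(self, sys4):
        assert entropy(JointDistribution(sys4, np.full(sys4.shape, 1 / 16))) == 4.0

    def test_transmission_identity_and_positivity(self, sys4):
        p = random_distribution(sys4, 8)
        q = random_distribution(sys4, 9)
        assert transmission(p, p) == 0.0
        assert transmission(p, q) > 0.0

    def test_transmission_infinite_on_support_mismatch(self, sys2):
        p = JointDistribution(sys2, np.array([[0.5, 0.5], [0.0, 0.0]]))
        q = JointDistribution(sys2, np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert transmission(p, q) == float("inf")

    def test_transmission_shrinks_down_a_hierarchy_chain(self, sys4):
        table = random_table(sys4, 10)
        data = table.distribution()
        chain = ["A:B:C:D", "CD:A:B", "BD:CD:A", "AD:BD:CD", "ACD:BCD", "ABCD"]
        values = [
            transmission(data, fit_maxent(S(t, sys4), table)[0]) for t in chain
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(0.0, abs=1e-12)

    def test_conditional_independence_makes_transmission_vanish(self, sys3):
        sample = sample_from_model(
            SyntheticSpec(S("AC:BC", sys3), n=100_000, seed=21)
        )
        fitted, _ = fit_maxent(S("AC:BC", sys3), sample.contingency)
        t = transmission(sample.contingency.distribution(), fitted)
        assert t < 0.001


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "text, df",
        [("ABCD", 15), ("A:B:C:D", 4), ("AD:BD:CD", 7), ("ACD:BCD", 11)],
    )
    def test_ra_binary(self, sys4, text, df):
        assert degrees_of_freedom(S(text, sys4)) == df

    def test_bn_star_matches_equivalent_ra(self, sys4):
        star = Dag(sys4, [("D", "A"), ("D", "B"), ("D", "C")])
        assert degrees_of_freedom(star) == degrees_of_freedom(S("AD:BD:CD", sys4)) == 7

    def test_nonbinary_cardinalities(self):
        system = VariableSystem(("A", "B"), (3, 2))
        assert degrees_of_freedom(S("AB", system)) == 5
        assert degrees_of_freedom(S("A:B", system)) == 3
        assert degrees_of_freedom(Dag(system, [("A", "B")])) == 2 + 3


class TestStatistics:
    def test_identical_models_are_untestable(self, sys4):
        table = random_table(sys4, 11)
        fit = evaluate(S("AD:BD:CD", sys4), table)
        with pytest.raises(ValueError):
            lr_test(fit, fit, table)

    def test_saturated_fit_statistic_is_zero(self, sys4):
        table = random_table(sys4, 12)
        top = evaluate(S("ABCD", sys4), table)
        assert top.transmission_bits == pytest.approx(0.0, abs=1e-12)
        assert top.p_value == 1.0

    def test_lr_stat_equals_transmission_identity(self, sys4):
        table = random_table(sys4, 13)
        fit = evaluate(S("AD:BD:CD", sys4), table)
        assert fit.lr_stat == pytest.approx(
            2 * table.n * math.log(2) * fit.transmission_bits
        )

    def test_information_criteria_arithmetic(self, sys4):
        table = random_table(sys4, 14)
        fit = evaluate(S("ABC:D", sys4), table)
        ll = loglik(table, fit.fitted)
        aic, bic = information_criteria(fit, table)
        assert aic == pytest.approx(-2 * ll + 2 * fit.df)
        assert bic == pytest.approx(-2 * ll + fit.df * math.log(table.n))
        assert (fit.aic, fit.bic) == (pytest.approx(aic), pytest.approx(bic))

    def test_bic_penalizes_df_harder_than_aic(self, sys4):
        # with equal log-likelihoods the lower-df fit must win under both,
        # and the BIC gap exceeds the AIC gap once ln(n) > 2
        table = ContingencyTable(sys4, np.full(sys4.shape, 100.0))
        simple = evaluate(S("A:B:C:D", sys4), table)
        complex_ = evaluate(S("ABCD", sys4), table)
        assert simple.bic < complex_.bic
        assert (complex_.bic - simple.bic) > (complex_.aic - simple.aic)


class TestPrediction:
    def test_independence_model_predicts_the_margin(self, sys4):
        table = random_table(sys4, 15)
        fitted, _ = fit_maxent(S("A:B:C:D", sys4), table)
        cond = predict_dv(fitted, "D")
        md = margin(table.counts / table.n, sys4, "D")
        assert np.allclose(cond, md.reshape(1, 1, 1, 2))

    def test_equivalent_bn_and_ra_predict_identically(self, sysz):
        table = random_table(sysz, 16)
        bn17 = Dag(sysz, [("B", "Z"), ("C", "Z")])
        ra = S("ABC:BCZ", sysz)
        c1 = predict_dv(fit_bn(bn17, table), "Z")
        c2 = predict_dv(fit_maxent(ra, table)[0], "Z")
        assert np.allclose(c1, c2, atol=1e-10)

    def test_zero_mass_iv_state_is_undefined(self, sys2):
        dist = JointDistribution(sys2, np.array([[0.5, 0.5], [0.0, 0.0]]))
        cond = predict_dv(dist, "B")
        assert np.isnan(cond[1]).all()
        assert np.allclose(cond[0], [0.5, 0.5])


@pytest.fixture(scope="module")
def lattice(sys4):
    return ra_lattice(sys4)


class TestSearch:
    def test_recovers_strong_star_generator(self, sys4, lattice):
        sample = sample_from_model(
            SyntheticSpec(S("AD:BD:CD", sys4), n=100_000, seed=3, alpha=0.2)
        )
        up = search(lattice, sample.contingency, direction="up", criterion="bic")
        assert up.selected == S("AD:BD:CD", sys4)
        down = search(lattice, sample.contingency, direction="down", criterion="bic")
        assert down.selected == S("AD:BD:CD", sys4)

    def test_recovers_independence_generator(self, sys4, lattice):
        sample = sample_from_model(
            SyntheticSpec(S("A:B:C:D", sys4), n=100_000, seed=3)
        )
        result = search(lattice, sample.contingency, direction="up", criterion="bic")
        assert result.selected == S("A:B:C:D", sys4)

    def test_chi2_walk_and_path_logging(self, sys4, lattice):
        sample = sample_from_model(
            SyntheticSpec(S("AD:BD:CD", sys4), n=50_000, seed=5, alpha=0.2)
        )
        result = search(
            lattice, sample.contingency, direction="up", criterion="chi2"
        )
        assert len(result.path) >= 2
        assert result.path[0].model == S("A:B:C:D", sys4)

    def test_bn_and_joint_lattices_are_searchable(self, sys4):
        from rabn.bn import bn_notation, class_lattice
        from rabn import build_joint, canonical_text

        sample = sample_from_model(
            SyntheticSpec(S("AD:BD:CD", sys4), n=100_000, seed=3, alpha=0.2)
        )
        bn_result = search(
            class_lattice(sys4), sample.contingency, direction="up", criterion="bic"
        )
        assert (
            canonical_text(bn_notation(bn_result.selected.representative))
            == "AD:BD:CD"
        )
        joint_result = search(
            build_joint(sys4).search_space(),
            sample.contingency,
            direction="up",
            criterion="bic",
        )
        assert joint_result.selected == S("AD:BD:CD", sys4)

    def test_rejects_bad_arguments(self, sys4, lattice):
        table = random_table(sys4, 17)
        with pytest.raises(ValueError):
            search(lattice, table, criterion="mdl")
        with pytest.raises(ValueError):
            search(lattice, table, direction="sideways")
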