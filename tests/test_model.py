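"""Design construction, mixed-model equations, PCG, model simulation."""

import numpy as np
import pytest
from scipy import sparse

import amaci
from amaci import (
    NationalModelSpec,
    Pedigree,
    VarianceComponents,
    assemble_mme,
    build_A_inverse,
    build_design,
    simulate_from_model,
    solve_pcg,
)
from amaci.model import BlockJacobiPreconditioner, MMESystem
from amaci import simulate as sim
from amaci.reference import dense_mme, tabular_A
from conftest import make_phenotypes


@pytest.fixture
def two_animal_design():
    ped = Pedigree.from_records([("a1", "", ""), ("a2", "", "")])
    phen = make_phenotypes(
        [("a1", "A", "M", "h", "c", "", 1.0), ("a2", "A", "M", "h", "c", "", 3.0)]
    )
    specs = [NationalModelSpec("A", fixed_effects=[], has_pe=False)]
    vc = VarianceComponents(["A"], np.diag([1.0, 1.0]), {}, {}, {"A": 1.0})
    return ped, phen, specs, vc


class TestDesign:
    def test_dimensions(self, two_animal_design):
        ped, phen, specs, _ = two_animal_design
        d = build_design(phen, ped, specs)
        assert d.X.shape == (2, 1)            # intercept only
        assert d.Zg.shape == (2, 2 * 1 * 2)   # 2 animals x (direct+maternal)
        assert d.n_genetic == 4

    def test_unknown_dam_gives_empty_maternal_row(self, two_animal_design):
        ped, phen, specs, _ = two_animal_design
        d = build_design(phen, ped, specs)
        # only direct incidences present
        assert d.Zg.nnz == 2
        assert d.Pmat.shape[1] == 0

    def test_genetic_effect_count_two_populations(self):
        ped = Pedigree.from_records(
            [("a", "", ""), ("b", "", ""), ("c", "a", "b")]
        )
        phen = make_phenotypes(
            [("c", "A", "M", "h", "c1", "", 1.0), ("a", "B", "M", "g", "c2", "", 2.0)]
        )
        specs = [NationalModelSpec(p, fixed_effects=[]) for p in ["A", "B"]]
        d = build_design(phen, ped, specs)
        assert d.n_genetic == 2 * 2 * 3

    def test_dam_absent_from_pedigree_errors(self, two_animal_design):
        ped, phen, specs, _ = two_animal_design
        bad = phen.copy()
        bad.loc[0, "dam"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            build_design(bad, ped, specs)

    def test_missing_spec_errors(self, two_animal_design):
        ped, phen, specs, _ = two_animal_design
        bad = phen.copy()
        bad.loc[0, "population"] = "Z"
        with pytest.raises(ValueError, match="Z"):
            build_design(bad, ped, specs)


class TestMME:
    def test_hand_solved_two_animal_system(self, two_animal_design):
        ped, phen, specs, vc = two_animal_design
        d = build_design(phen, ped, specs)
        system = assemble_mme(d, build_A_inverse(ped), vc)
        x, it, crit = solve_pcg(system, tol=1e-10, max_iter=100)
        assert x[0] == pytest.approx(2.0, abs=1e-6)          # mean
        u = d.genetic_matrix(x)[:, 0]
        assert u == pytest.approx([-0.5, 0.5], abs=1e-6)

    def test_symmetry(self, two_animal_design):
        ped, phen, specs, vc = two_animal_design
        d = build_design(phen, ped, specs)
        system = assemble_mme(d, build_A_inverse(ped), vc)
        assert abs(system.coefficient - system.coefficient.T).max() < 1e-12

    def test_zero_cross_covariance_block_separates(self):
        ped = Pedigree.from_records([("a", "", ""), ("b", "", "")])
        phen = make_phenotypes(
            [("a", "A", "M", "h", "c", "", 1.0), ("b", "B", "M", "g", "d", "", 2.0)]
        )
        specs = [NationalModelSpec(p, fixed_effects=[]) for p in ["A", "B"]]
        vc = VarianceComponents(["A", "B"], np.eye(4), {}, {},
                                {"A": 1.0, "B": 1.0})
        d = build_design(phen, ped, specs)
        system = assemble_mme(d, build_A_inverse(ped), vc)
        C = system.coefficient.toarray()
        g = system.effect_map["genetic"].start
        # within-animal blocks are diagonal: no coupling between populations
        blk = C[g:g + 4, g:g + 4]
        assert np.allclose(blk - np.diag(np.diag(blk)), 0.0)

    def test_singular_genetic_matrix_rejected(self, two_animal_design):
        ped, phen, specs, _ = two_animal_design
        vc_bad = VarianceComponents(["A"], np.ones((2, 2)), {}, {}, {"A": 1.0})
        d = build_design(phen, ped, specs)
        with pytest.raises(np.linalg.LinAlgError, match="ridge|restart"):
            assemble_mme(d, build_A_inverse(ped), vc_bad)

    def test_matches_dense_assembly(self, rng):
        pops = [sim.PopulationConfig("A", 40, 2), sim.PopulationConfig("B", 40, 2)]
        vc = sim.make_variance_components(pops)
        cfg = sim.SimulationConfig(populations=pops, vc=vc, n_generations=3,
                                   international_sire_fraction=0.5)
        ped, phen, _ = sim.generate_dataset(cfg, seed=11)
        specs = [NationalModelSpec(p.name, ["contemporary_group"]) for p in pops]
        d = build_design(phen, ped, specs)
        system = assemble_mme(d, build_A_inverse(ped), vc)
        coef, rhs = dense_mme(d, tabular_A(ped), vc)
        assert np.abs(system.coefficient.toarray() - coef).max() < 1e-8
        assert np.abs(system.rhs - rhs).max() < 1e-8


class TestSolutionExport:
    def test_labels_and_values_round_trip(self, two_animal_design):
        ped, phen, specs, vc = two_animal_design
        d = build_design(phen, ped, specs)
        system = assemble_mme(d, build_A_inverse(ped), vc)
        x, _, _ = solve_pcg(system, tol=1e-10, max_iter=100)
        frame = d.solutions_frame(x)
        assert set(frame["effect"]) == {"fixed", "direct", "maternal"}
        mu = frame[(frame.effect == "fixed")]["value"].iloc[0]
        assert mu == pytest.approx(2.0, abs=1e-6)
        direct = frame[(frame.effect == "direct")
                       & (frame.level == "a2")]["value"].iloc[0]
        assert direct == pytest.approx(0.5, abs=1e-6)


class TestPCG:
    def test_identity_converges_immediately(self):
        system = MMESystem(sparse.eye(5, format="csr"), np.arange(5.0),
                           {"genetic": slice(0, 0)})
        x, it, crit = solve_pcg(system, tol=1e-8)
        np.testing.assert_allclose(x, np.arange(5.0))
        assert it == 1

    def test_two_by_two_closed_form(self):
        A = sparse.csr_matrix(np.array([[4.0, 1.0], [1.0, 3.0]]))
        system = MMESystem(A, np.array([1.0, 2.0]), {"genetic": slice(0, 0)})
        x, it, crit = solve_pcg(system, tol=1e-12, max_iter=10)
        np.testing.assert_allclose(x, [1 / 11, 7 / 11], atol=1e-10)

    def test_matches_dense_solve_on_model_system(self, rng):
        pops = [sim.PopulationConfig("A", 40, 2), sim.PopulationConfig("B", 40, 2)]
        vc = sim.make_variance_components(pops)
        cfg = sim.SimulationConfig(populations=pops, vc=vc, n_generations=3,
                                   international_sire_fraction=0.5)
        ped, phen, _ = sim.generate_dataset(cfg, seed=3)
        specs = [NationalModelSpec(p.name, ["contemporary_group"]) for p in pops]
        d = build_design(phen, ped, specs)
        system = assemble_mme(d, build_A_inverse(ped), vc)
        assert system.n_equations <= 900
        dense = np.linalg.solve(system.coefficient.toarray(), system.rhs)
        x, it, crit = solve_pcg(system, tol=1e-8, max_iter=5000)
        assert np.linalg.norm(x - dense) / np.linalg.norm(dense) < 1e-6

    def test_block_preconditioner_gives_same_solution_faster(self, rng):
        pops = [sim.PopulationConfig("A", 60, 2), sim.PopulationConfig("B", 60, 2)]
        vc = sim.make_variance_components(pops)
        cfg = sim.SimulationConfig(populations=pops, vc=vc, n_generations=3,
                                   international_sire_fraction=0.5)
        ped, phen, _ = sim.generate_dataset(cfg, seed=3)
        specs = [NationalModelSpec(p.name, ["contemporary_group"]) for p in pops]
        d = build_design(phen, ped, specs)
        A_inv = build_A_inverse(ped)
        system = assemble_mme(d, A_inv, vc)
        x1, it1, _ = solve_pcg(system, tol=1e-8, max_iter=5000)
        pre = BlockJacobiPreconditioner.from_parts(
            system, 4, A_inv.entries.diagonal(), np.linalg.inv(vc.genetic)
        )
        x2, it2, _ = solve_pcg(system, tol=1e-8, max_iter=5000, preconditioner=pre)
        assert np.linalg.norm(x1 - x2) / np.linalg.norm(x1) < 1e-5
        assert it2 <= it1


class TestSimulation:
    def test_pure_residual_variance(self, rng):
        n = 10000
        ped = Pedigree.from_records([(f"a{i}", "", "") for i in range(n)])
        phen = make_phenotypes(
            [(f"a{i}", "A", "M", "h", "c", "", 0.0) for i in range(n)]
        )
        specs = [NationalModelSpec("A", fixed_effects=[], has_pe=False)]
        vc = VarianceComponents(["A"], 1e-12 * np.eye(2), {}, {}, {"A": 7.0})
        d = build_design(phen, ped, specs)
        y, truth = simulate_from_model(d, ped, vc, rng)
        se = 7.0 * np.sqrt(2 / n)
        assert y.var() == pytest.approx(7.0, abs=3 * se)

    def test_same_seed_identical(self, two_animal_design):
        ped, phen, specs, vc = two_animal_design
        d = build_design(phen, ped, specs)
        y1, _ = simulate_from_model(d, ped, vc, np.random.default_rng(5))
        y2, _ = simulate_from_model(d, ped, vc, np.random.default_rng(5))
        np.testing.assert_array_equal(y1, y2)

    def test_founder_genetic_moments(self, rng):
        n = 5000
        ped = Pedigree.from_records([(f"a{i}", "", "") for i in range(n)])
        G = np.array([[2.0, -0.5], [-0.5, 1.0]])
        from amaci.model import simulate_genetic_effects

        U = simulate_genetic_effects(ped, G, rng)
        emp = np.cov(U, rowvar=False)
        assert emp[0, 0] == pytest.approx(2.0, abs=3 * 2.0 * np.sqrt(2 / n))
        assert emp[0, 1] == pytest.approx(-0.5, abs=3 * np.sqrt(2 * 2 / n))

    def test_offspring_parent_regression_half(self, rng):
        rows = [(f"s{i}", "", "") for i in range(800)]
        rows += [(f"d{i}", "", "") for i in range(800)]
        rows += [(f"o{i}", f"s{i}", f"d{i}") for i in range(800)]
        ped = Pedigree.from_records(rows)
        from amaci.model import simulate_genetic_effects

        U = simulate_genetic_effects(ped, np.array([[1.0]]), rng)
        sires = U[:800, 0]
        offs = U[1600:, 0]
        slope = np.polyfit(sires, offs, 1)[0]
        assert slope == pytest.approx(0.5, abs=0.1)

    def test_blup_invariant_to_true_fixed_effects(self, rng):
        pops = [sim.PopulationConfig("A", 50, 2)]
        vc = sim.make_variance_components(pops)
        cfg = sim.SimulationConfig(populations=pops, vc=vc, n_generations=3)
        ped, phen, _ = sim.generate_dataset(cfg, seed=2)
        specs = [NationalModelSpec("A", ["contemporary_group"])]
        d = build_design(phen, ped, specs)
        A_inv = build_A_inverse(ped)
        rng_state = np.random.default_rng(9)
        y0, truth = simulate_from_model(d, ped, vc, rng_state)
        b = 50.0 * np.ones(d.X.shape[1])
        y_shift = y0 + d.X @ b
        system = assemble_mme(d, A_inv, vc)
        T = d.full_incidence()
        r_inv = np.full(d.n_records, 1.0 / vc.resid["A"])
        from amaci.reml import MMELike

        TtR = T.T.multiply(r_inv).tocsr()
        x0, _, _ = solve_pcg(MMELike(system.coefficient, TtR @ y0,
                                     system.effect_map), 1e-9, 5000)
        x1, _, _ = solve_pcg(MMELike(system.coefficient, TtR @ y_shift,
                                     system.effect_map), 1e-9, 5000)
        u0 = d.genetic_matrix(x0)
        u1 = d.genetic_matrix(x1)
        assert np.abs(u0 - u1).max() < 1e-5
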