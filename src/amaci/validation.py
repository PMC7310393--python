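"""Self-validation studies: oracle comparisons and synthetic recovery runs.

These routines exercise the full pipeline against independent references —
the tabular relationship matrix, dense direct solves, the exact EM update,
the dense restricted likelihood — and run the synthetic three-population
recovery study.  They are used both by the test suite and by the
``scripts/acceptance.py`` entry point.
"""

from __future__ import annotations

import importlib.resources

import numpy as np

from . import reference, reml
from . import simulate as sim
from .connectedness import SireOffspringCounts, an_pop, bod
from .editing import SubsetPlan, subset_by_gs, subset_random
from .connectedness import build_report
from .model import (
    NationalModelSpec,
    assemble_mme,
    build_design,
    simulate_from_model,
    solve_pcg,
)
from .pedigree import Pedigree, build_A_inverse
from .reml import MMELike

__all__ = [
    "published_block_statistics",
    "balanced_offspring_values",
    "relationship_inverse_worst_deviation",
    "pcg_vs_dense_worst_deviation",
    "mc_em_vs_exact_em",
    "se_vs_fd_hessian",
    "recovery_replicate",
    "recovery_study",
    "subsetting_checks",
]


def published_block_statistics():
    """Block statistics of the packaged published 16x16 across-country
    correlation matrix (Limousin age-adjusted weaning weight)."""
    src = importlib.resources.files("amaci.data") / "limousin_aww_rg.csv"
    summary = reml.read_correlation_table(str(src))
    return reml.summarize_rg(summary)


def balanced_offspring_values(ks=(2, 3, 5), n_populations: int = 8):
    """BOD for a sire with equal offspring counts in k of ``n_populations``
    populations, for each k."""
    out = {}
    for k in ks:
        counts = SireOffspringCounts("s", {f"P{j}": 10 for j in range(k)})
        b = bod(counts, n_populations)
        if abs(an_pop(b, n_populations) - k) > 1e-12:
            raise AssertionError("AN_POP does not map back to the population count")
        out[k] = b
    return out


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    rows = []
    n_found = max(3, n // 8)
    for i in range(n):
        if i < n_found:
            rows.append((f"a{i}", "", ""))
        else:
            s = f"a{rng.integers(0, i)}"
            d = f"a{rng.integers(0, i)}"
            if s == d:
                d = ""
            rows.append((f"a{i}", s, d))
    return Pedigree.from_records(rows)


def relationship_inverse_worst_deviation(seed: int, n_pedigrees: int = 50,
                                         max_animals: int = 200) -> float:
    """Worst |A_inverse . A - I| entry over random pedigrees, with A from
    the independent tabular method."""
    rng = np.random.default_rng((seed, 1))
    worst = 0.0
    for _ in range(n_pedigrees):
        n = int(rng.integers(20, max_animals + 1))
        ped = random_pedigree(rng, n)
        A = reference.tabular_A(ped)
        M = build_A_inverse(ped).entries.toarray()
        worst = max(worst, float(np.abs(M @ A - np.eye(n)).max()))
    return worst


def pcg_vs_dense_worst_deviation(seed: int, n_systems: int = 3,
                                 ) -> tuple[float, int]:
    """Relative deviation of PCG solutions from dense direct solves on
    assembled mixed-model systems (a few hundred equations each)."""
    worst = 0.0
    n_eq = 0
    for rep in range(n_systems):
        pops = [sim.PopulationConfig("A", 36, 2), sim.PopulationConfig("B", 36, 2)]
        vc = sim.make_variance_components(pops)
        cfg = sim.SimulationConfig(populations=pops, vc=vc, n_generations=3,
                                   international_sire_fraction=0.5)
        ped, phen, _ = sim.generate_dataset(cfg, seed=seed + rep)
        specs = [NationalModelSpec(p.name, ["contemporary_group"]) for p in pops]
        design = build_design(phen, ped, specs)
        system = assemble_mme(design, build_A_inverse(ped), vc)
        dense = np.linalg.solve(system.coefficient.toarray(), system.rhs)
        x, _, _ = solve_pcg(system, tol=1e-5, max_iter=1000)
        x, _, _ = solve_pcg(system, tol=1e-9, max_iter=5000, x0=x)
        worst = max(worst, float(np.linalg.norm(x - dense)
                                 / np.linalg.norm(dense)))
        n_eq = max(n_eq, system.n_equations)
    return worst, n_eq


def mc_em_vs_exact_em(seed: int, n_replicates: int = 500,
                      ) -> tuple[float, int]:
    """Deviation of the MC EM genetic update, averaged over replicates,
    from the exact EM update (analytic traces via the dense MME inverse),
    plus the count of likelihood-descent rounds of the exact EM iteration.
    """
    pops = [sim.PopulationConfig("A", 50, 2), sim.PopulationConfig("B", 50, 2)]
    vc = sim.make_variance_components(pops, direct_var=100, maternal_var=50,
                                      pe_var=30, resid_var=200)
    cfg = sim.SimulationConfig(populations=pops, vc=vc, n_generations=3,
                               international_sire_fraction=0.5)
    ped, phen, _ = sim.generate_dataset(cfg, seed=seed)
    specs = [NationalModelSpec(p.name, ["contemporary_group"]) for p in pops]
    design = build_design(phen, ped, specs)
    A = reference.tabular_A(ped)
    A_inv = build_A_inverse(ped)
    exact = reference.exact_em_update(design, A, vc)

    system = assemble_mme(design, A_inv, vc)
    x_real, _, _ = solve_pcg(system, 1e-8, 5000)
    T = design.full_incidence()
    r_inv = np.array([1.0 / vc.resid[design.populations[c]]
                      for c in design.record_pop])
    TtR = T.T.multiply(r_inv).tocsr()
    sims = []
    x_sim = None
    for s in range(n_replicates):
        rng = np.random.default_rng((seed, 2, s))
        y_star, truth = simulate_from_model(design, ped, vc, rng)
        x_sim, _, _ = solve_pcg(
            MMELike(system.coefficient, TtR @ y_star, system.effect_map),
            1e-7, 5000, x0=x_sim,
        )
        sims.append({"truth": truth, "solution": x_sim, "y": y_star})
    mc = reml.em_update(design, A_inv, vc, x_real, sims)
    scale = float(np.abs(exact.genetic).max())
    dev = float(np.abs(mc.genetic - exact.genetic).max()) / scale

    start = sim.make_variance_components(
        pops, direct_var=60, maternal_var=90, dm_within_r=0.1,
        pe_var=60, resid_var=350,
    )
    vc_cur = start
    ll_prev = reference.reml_loglik(design, A, vc_cur)
    violations = 0
    for _ in range(12):
        vc_cur = reference.exact_em_update(design, A, vc_cur)
        ll = reference.reml_loglik(design, A, vc_cur)
        if ll < ll_prev - 1e-8:
            violations += 1
        ll_prev = ll
    return dev, violations


def two_population_instance(seed: int, n_per_pop: int = 250):
    """Well-connected two-population instance for dense-oracle comparisons."""
    pops = [sim.PopulationConfig("A", n_per_pop, 3, cg_sd=10.0),
            sim.PopulationConfig("B", n_per_pop, 3, cg_sd=10.0)]
    vc = sim.make_variance_components(
        pops, direct_var=100, maternal_var=50, direct_rg=0.6, maternal_rg=0.5,
        dm_within_r=-0.2, pe_var=30, resid_var=200,
    )
    cfg = sim.SimulationConfig(
        populations=pops, vc=vc, n_generations=4,
        international_sire_fraction=0.7, international_pool_size=10,
        dams_fraction=0.3, offspring_per_sire_group=10,
    )
    ped, phen, _ = sim.generate_dataset(cfg, seed=seed)
    specs = [NationalModelSpec(p.name, ["contemporary_group"], has_pe=True)
             for p in pops]
    return ped, phen, specs, vc


def se_vs_fd_hessian(seed: int, n_oracle_datasets: int = 96,
                     se_n_sim: int = 500) -> tuple[float, int]:
    """Worst relative deviation of the MC standard errors from a
    finite-difference restricted-likelihood Hessian oracle.

    A single dataset's observed Hessian fluctuates around the Fisher
    information the MC standard errors estimate, so the oracle averages the
    finite-difference Hessians of several independent datasets simulated at
    the same parameters.
    """
    ped, phen, specs, vc = two_population_instance(seed)
    design = build_design(phen, ped, specs)
    A = reference.tabular_A(ped)
    basis = reference.variance_basis(design, A, vc)
    rng = np.random.default_rng((seed, 5))
    H_bar = 0.0
    for _ in range(n_oracle_datasets):
        y, _ = simulate_from_model(design, ped, vc, rng)
        design.y = y
        H_bar = H_bar + reference.reml_fd_hessian(design, basis, vc)
    H_bar = H_bar / n_oracle_datasets
    se_oracle = np.sqrt(np.diag(np.linalg.inv(-H_bar)))
    settings = reml.REMLSettings(seed=seed, se_n_sim=se_n_sim)
    res = reml.approximate_se(phen, ped, specs, vc, settings)
    rel = float(np.max(np.abs(res.se - se_oracle) / se_oracle))
    return rel, len(se_oracle)


def recovery_replicate(seed: int, rep: int) -> dict:
    """One replicate of the recovery study: three well-connected
    populations, true direct rg 0.8, maternal 0.7, direct-maternal
    within-country -0.2; estimation started from routine-estimate-like
    values (truth mildly perturbed, as in an established evaluation)."""
    pops = [sim.PopulationConfig("A", 900, 6, cg_sd=20.0),
            sim.PopulationConfig("B", 700, 5, cg_sd=20.0),
            sim.PopulationConfig("C", 700, 5, cg_sd=20.0)]
    vc = sim.make_variance_components(
        pops, direct_var=150, maternal_var=80, direct_rg=0.8,
        maternal_rg=0.7, dm_within_r=-0.2, pe_var=30, resid_var=150,
    )
    cfg = sim.SimulationConfig(
        populations=pops, vc=vc, n_generations=6,
        international_sire_fraction=0.9, international_pool_size=40,
        dams_fraction=0.3, offspring_per_sire_group=12,
    )
    ped, phen, _ = sim.generate_dataset(cfg, seed=seed * 97 + rep)
    specs = [NationalModelSpec(p.name, ["contemporary_group"], has_pe=True)
             for p in pops]
    start = sim.make_variance_components(
        pops, direct_var=140, maternal_var=75, direct_rg=0.75,
        maternal_rg=0.65, dm_within_r=-0.15, pe_var=25, resid_var=165,
    )
    settings = reml.REMLSettings(
        seed=seed * 1000 + rep, max_rounds=120, n_sim_per_round=2,
        average_last=60, slope_window=60, se_n_sim=100,
    )
    final, _traj = reml.run_mcem_reml(phen, ped, specs, start, settings)
    cs = reml.genetic_correlations(final)
    se_res = reml.approximate_se(phen, ped, specs, final, settings)
    P = 3
    targets = (
        [(cs.rg[i, j], 0.8, i, j) for i in range(P) for j in range(i)]
        + [(cs.rg[P + i, P + j], 0.7, P + i, P + j)
           for i in range(P) for j in range(i)]
        + [(cs.rg[P + i, i], -0.2, P + i, i) for i in range(P)]
    )
    errs = [abs(v - t) for v, t, _, _ in targets]
    return {
        "max_err": max(errs),
        "within_band": max(errs) <= 0.15,
        "within_2se": all(
            abs(v - t) <= 2 * se_res.rg_se[a, b] for v, t, a, b in targets
        ),
        "positive_definite": bool(cs.positive_definite),
        "block_errors": {
            "direct": float(np.mean([cs.rg[i, j] for i in range(P)
                                     for j in range(i)]) - 0.8),
            "maternal": float(np.mean([cs.rg[P + i, P + j] for i in range(P)
                                       for j in range(i)]) - 0.7),
            "dm_within": float(np.mean([cs.rg[P + i, i]
                                        for i in range(P)]) + 0.2),
        },
    }


def recovery_study(seed: int, n_rep: int = 10) -> dict:
    reps = [recovery_replicate(seed, r) for r in range(n_rep)]
    return {
        "replicates": reps,
        "within_band_fraction": sum(r["within_band"] for r in reps) / n_rep,
        "within_band_and_2se_fraction": sum(
            r["within_band"] and r["within_2se"] for r in reps) / n_rep,
        "within_2se_fraction": sum(r["within_2se"] for r in reps) / n_rep,
        "positive_definite_fraction": sum(
            r["positive_definite"] for r in reps) / n_rep,
        "max_abs_error": max(r["max_err"] for r in reps),
        "mean_block_errors": {
            k: float(np.mean([r["block_errors"][k] for r in reps]))
            for k in ("direct", "maternal", "dm_within")
        },
    }


def subsetting_checks(seed: int) -> dict:
    """Record-target accuracy, the genetic-similarity selection effect, and
    reproducibility of the random partition, on preset-like data."""
    cfg = sim.preset_interbeef_like(12000)
    ped, phen, _ = sim.generate_dataset(cfg, seed=seed)
    report = build_report(phen, ped)
    fra = report.herd_table[report.herd_table["population"] == "FRA"]

    target = int(0.4 * fra["n_records"].sum())
    plan = SubsetPlan("GSCB", "FRA", target_records=target, seed=seed)
    selected, ranking = subset_by_gs(phen, ped, plan, "CB")
    got = int(ranking.set_index("herd").loc[selected, "n_records"].sum())
    largest_selected = int(
        ranking.set_index("herd").loc[selected, "n_records"].max()
    )
    within_one_herd = got >= target and (got - target) < largest_selected

    sel_gs = fra.set_index("herd").loc[selected, "gs_cb"].fillna(0.0).mean()
    all_gs = fra["gs_cb"].fillna(0.0).mean()

    plan_rnd = SubsetPlan("RND", "FRA", n_random_subsets=20, seed=seed)
    r1 = subset_random(phen, ped, plan_rnd)
    r2 = subset_random(phen, ped, plan_rnd)
    return {
        "target_within_one_herd": bool(within_one_herd),
        "gs_selection_gain": float(sel_gs - all_gs),
        "rnd_reproducible": [x["herds"] for x in r1] == [x["herds"] for x in r2],
        "n_selected": len(selected),
        "n_herds": len(fra),
    }
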