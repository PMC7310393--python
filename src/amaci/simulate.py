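"""Synthetic multi-population pedigree and phenotype generation.

The generator emulates the structure of a multi-country beef-cattle weaning
weight evaluation: several national populations of very unequal size (one
dominant population holding most of the records), persistent herds with
skewed sizes, year-based contemporary groups, overlapping generations, and
international sires — a shared sire pool used with configurable probability —
creating common-bull links across populations.  Phenotypes are drawn from
the same multi-trait maternal-effects animal model the estimation machinery
assumes, under a known genetic covariance matrix, so true parameters are
available for recovery studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import NationalModelSpec, VarianceComponents, build_design, simulate_from_model
from .pedigree import Pedigree

__all__ = [
    "PopulationConfig",
    "SimulationConfig",
    "make_genetic_matrix",
    "make_variance_components",
    "generate_structure",
    "generate_phenotypes",
    "generate_dataset",
    "preset_interbeef_like",
]


@dataclass
class PopulationConfig:
    """One national population.

    ``n_records`` phenotyped animals are spread over ``n_herds`` herds whose
    sizes follow a log-normal with spread ``herd_concentration`` (larger
    means a few big herds hold most records).  ``mean`` and ``cg_sd`` are the
    population mean and the contemporary-group effect standard deviation in
    kg.
    """

    name: str
    n_records: int
    n_herds: int
    mean: float = 250.0
    cg_sd: float = 25.0
    has_pe: bool = True
    herd_concentration: float = 0.8


@dataclass
class SimulationConfig:
    """Structure and true parameters of a synthetic evaluation."""

    populations: list[PopulationConfig]
    vc: VarianceComponents
    n_generations: int = 5
    international_sire_fraction: float = 0.25
    offspring_per_sire_group: int = 10
    dams_fraction: float = 1.0      # breeding dams per herd as a fraction of
                                    # its per-generation calf crop (<1 gives
                                    # dams several calves per generation)
    dam_lifespan: int = 2           # generations a dam keeps producing
    first_year: int = 1974
    years_per_generation: int = 4
    sex_ratio: float = 0.5
    international_pool_size: int = 0    # 0 -> scaled from data size

    def __post_init__(self) -> None:
        if not 0.0 <= self.international_sire_fraction <= 1.0:
            raise ValueError("international_sire_fraction must be in [0, 1]")
        names = [p.name for p in self.populations]
        if names != self.vc.populations:
            raise ValueError("vc populations must match the population configs")


def make_genetic_matrix(direct_var, maternal_var, direct_rg: float,
                        maternal_rg: float, dm_within_r: float,
                        dm_between_r: float = 0.0) -> np.ndarray:
    """Build a 2P x 2P genetic covariance matrix from per-population direct
    and maternal variances and homogeneous across-population correlations."""
    dv = np.asarray(direct_var, dtype=float)
    mv = np.asarray(maternal_var, dtype=float)
    P = len(dv)
    G = np.zeros((2 * P, 2 * P))
    ds, ms = np.sqrt(dv), np.sqrt(mv)
    for i in range(P):
        for j in range(P):
            G[i, j] = (1.0 if i == j else direct_rg) * ds[i] * ds[j]
            G[P + i, P + j] = (1.0 if i == j else maternal_rg) * ms[i] * ms[j]
            r = dm_within_r if i == j else dm_between_r
            G[i, P + j] = G[P + j, i] = r * ds[i] * ms[j]
    if np.linalg.eigvalsh(G).min() <= 0:
        raise ValueError("requested correlation structure is not positive definite")
    return G


def make_variance_components(pops: list[PopulationConfig], direct_var=120.0,
                             maternal_var=60.0, direct_rg=0.8, maternal_rg=0.7,
                             dm_within_r=-0.2, dm_between_r=0.0, pe_var=40.0,
                             resid_var=280.0) -> VarianceComponents:
    P = len(pops)
    G = make_genetic_matrix(
        np.full(P, direct_var), np.full(P, maternal_var),
        direct_rg, maternal_rg, dm_within_r, dm_between_r,
    )
    return VarianceComponents(
        [p.name for p in pops],
        G,
        pe={p.name: pe_var for p in pops if p.has_pe},
        extra={},
        resid={p.name: resid_var for p in pops},
    )


def _herd_sizes(pop: PopulationConfig, per_gen: int,
                rng: np.random.Generator) -> np.ndarray:
    w = rng.lognormal(0.0, pop.herd_concentration, pop.n_herds)
    sizes = np.maximum(1, np.round(per_gen * w / w.sum()).astype(int))
    while sizes.sum() > per_gen:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < per_gen:
        sizes[np.argmin(sizes)] += 1
    return sizes


def generate_structure(cfg: SimulationConfig, seed: int = 0,
                       ) -> tuple[Pedigree, pd.DataFrame]:
    """Generate an overlapping-generation pedigree and the herd/contemporary
    group skeleton of the phenotype table (without trait values).

    Every mating draws its sire from the shared international pool with
    probability ``international_sire_fraction`` and from the national male
    pool otherwise; dams are always national and stay in their herd.
    Phenotypes attach to every animal born in generations >= 1.
    """
    rng = np.random.default_rng((seed, 0))
    records_per_gen = {
        p.name: max(1, p.n_records // cfg.n_generations) for p in cfg.populations
    }
    total_per_gen = sum(records_per_gen.values())
    pool_target = cfg.international_pool_size or max(3, total_per_gen // 120)

    ped_rows: list[tuple] = []   # (id, sire, dam, year, origin)
    rec_rows: list[dict] = []
    counter = 0

    def new_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:07d}"

    # founder breeding stock per population
    males: dict[str, list[str]] = {}
    herd_dams: dict[str, dict[int, list[str]]] = {}
    herds_of: dict[str, np.ndarray] = {}
    founder_year = cfg.first_year - cfg.years_per_generation
    for pop in cfg.populations:
        per_gen = records_per_gen[pop.name]
        sizes = _herd_sizes(pop, per_gen, rng)
        herds_of[pop.name] = sizes
        herd_dams[pop.name] = {}
        for h, sz in enumerate(sizes):
            dams = []
            n_dams = max(1, int(round(sz * cfg.dams_fraction)))
            for _ in range(n_dams):
                d = new_id(f"{pop.name}_F")
                ped_rows.append((d, "", "", founder_year, pop.name))
                dams.append(d)
            herd_dams[pop.name][h] = dams
        n_sires = max(2, per_gen // (cfg.offspring_per_sire_group * 2))
        males[pop.name] = []
        for _ in range(n_sires):
            m = new_id(f"{pop.name}_M")
            ped_rows.append((m, "", "", founder_year, pop.name))
            males[pop.name].append(m)

    # shared international pool, founders sampled with population-size weights
    weights = np.array([p.n_records for p in cfg.populations], dtype=float)
    weights /= weights.sum()
    intl_pool: list[tuple[str, str]] = []  # (id, origin)
    for _ in range(pool_target):
        origin = cfg.populations[rng.choice(len(cfg.populations), p=weights)].name
        m = new_id("INT_M")
        ped_rows.append((m, "", "", founder_year, origin))
        intl_pool.append((m, origin))

    for g in range(1, cfg.n_generations + 1):
        year = cfg.first_year + (g - 1) * cfg.years_per_generation
        new_males: dict[str, list[str]] = {p.name: [] for p in cfg.populations}
        new_females: dict[str, dict[int, list[str]]] = {
            p.name: {} for p in cfg.populations
        }
        for pop in cfg.populations:
            sizes = herds_of[pop.name]
            for h, sz in enumerate(sizes):
                dams = herd_dams[pop.name][h]
                herd_name = f"{pop.name}_H{h:04d}"
                n_groups = max(1, math.ceil(sz / cfg.offspring_per_sire_group))
                group_sires = []
                for _ in range(n_groups):
                    if rng.random() < cfg.international_sire_fraction and intl_pool:
                        group_sires.append(intl_pool[rng.integers(len(intl_pool))][0])
                    else:
                        pool = males[pop.name]
                        group_sires.append(pool[rng.integers(len(pool))])
                females_here: list[str] = []
                for k in range(sz):
                    sire = group_sires[k % n_groups]
                    dam = dams[k % len(dams)]
                    a = new_id(f"{pop.name}_A")
                    byear = int(year + rng.integers(cfg.years_per_generation))
                    ped_rows.append((a, sire, dam, byear, pop.name))
                    sex = "F" if rng.random() < cfg.sex_ratio else "M"
                    rec_rows.append(
                        {
                            "animal": a,
                            "population": pop.name,
                            "sex": sex,
                            "herd": herd_name,
                            "contemporary_group": f"{herd_name}_y{year}",
                            "dam": dam,
                            "extra_random_level": "",
                            "birth_year": byear,
                        }
                    )
                    if sex == "F":
                        females_here.append(a)
                    else:
                        new_males[pop.name].append(a)
                new_females[pop.name][h] = females_here

        # advance breeding stock with overlap
        for pop in cfg.populations:
            sizes = herds_of[pop.name]
            for h, sz in enumerate(sizes):
                n_dams = max(1, int(round(sz * cfg.dams_fraction)))
                survivors = herd_dams[pop.name][h]
                if cfg.dam_lifespan > 1:
                    keep = max(0, n_dams - len(new_females[pop.name][h]))
                    survivors = survivors[:keep]
                else:
                    survivors = []
                dams = new_females[pop.name][h] + survivors
                while len(dams) < n_dams:   # immigrant founder dams if short
                    d = new_id(f"{pop.name}_F")
                    ped_rows.append((d, "", "", int(year), pop.name))
                    dams.append(d)
                herd_dams[pop.name][h] = dams[:n_dams]
            if new_males[pop.name]:
                n_keep = max(2, len(males[pop.name]))
                picks = rng.choice(
                    len(new_males[pop.name]),
                    size=min(n_keep, len(new_males[pop.name])),
                    replace=False,
                )
                males[pop.name] = [new_males[pop.name][i] for i in picks]
        # refresh part of the international pool from new males
        all_new = [
            (m, p.name) for p in cfg.populations for m in new_males[p.name]
        ]
        if all_new and intl_pool and g < cfg.n_generations:
            n_replace = max(1, len(intl_pool) // 4)
            picks = rng.choice(
                len(all_new),
                size=min(n_replace, len(all_new)),
                replace=False,
                p=None,
            )
            for j, i in enumerate(picks):
                intl_pool[j % len(intl_pool)] = all_new[i]

    ped = Pedigree.from_records(ped_rows)
    phen = pd.DataFrame(rec_rows)
    return ped, phen


def generate_phenotypes(ped: Pedigree, assignment: pd.DataFrame,
                        cfg: SimulationConfig, seed: int = 0,
                        ) -> tuple[pd.DataFrame, dict]:
    """Draw trait values for a generated structure under the true variance
    components.

    y = population mean + contemporary-group effect + direct genetic +
    dam's maternal genetic + dam's permanent environment + residual.
    Returns the completed phenotype table and a truth ledger holding every
    simulated effect.
    """
    rng = np.random.default_rng((seed, 1))
    phen = assignment.copy()
    phen["value"] = 0.0
    specs = [
        NationalModelSpec(p.name, fixed_effects=["contemporary_group"],
                          has_pe=p.has_pe)
        for p in cfg.populations
    ]
    design = build_design(phen, ped, specs)
    y0, truth = simulate_from_model(design, ped, cfg.vc, rng)

    cgs = phen["contemporary_group"].unique()
    cg_sd = {p.name: p.cg_sd for p in cfg.populations}
    pop_of_cg = phen.groupby("contemporary_group")["population"].first()
    cg_eff = {
        cg: rng.normal(0.0, cg_sd[pop_of_cg[cg]]) for cg in cgs
    }
    means = {p.name: p.mean for p in cfg.populations}
    phen["value"] = (
        y0
        + phen["population"].map(means).to_numpy()
        + phen["contemporary_group"].map(cg_eff).to_numpy()
    )
    truth["cg_effects"] = cg_eff
    truth["population_means"] = means
    truth["vc"] = cfg.vc
    return phen, truth


def generate_dataset(cfg: SimulationConfig, seed: int = 0,
                     ) -> tuple[Pedigree, pd.DataFrame, dict]:
    """Convenience wrapper: structure plus phenotypes in one call."""
    ped, skeleton = generate_structure(cfg, seed)
    phen, truth = generate_phenotypes(ped, skeleton, cfg, seed)
    return ped, phen, truth


#: record shares (%) by population, dominant population first
_PRESET_SHARES = [
    ("FRA", 87.1, 406), ("GBR", 4.1, 172), ("DFS", 2.9, 476), ("DEU", 2.8, 101),
    ("ESP", 1.1, 176), ("CHE", 1.0, 134), ("IRL", 0.7, 16), ("CZE", 0.3, 87),
]


def preset_interbeef_like(scale: int) -> SimulationConfig:
    """Eight-population configuration with the record-share skew of a real
    international Limousin weaning-weight evaluation (one population holding
    87.1% of the records) at a configurable total size.

    ``scale`` is the total number of phenotyped records (minimum 1,000).
    The DEU-analog population fits no maternal permanent environmental
    effect, mirroring its national model.
    """
    if scale < 1000:
        raise ValueError("preset requires scale >= 1000 records")
    pops = []
    assigned = 0
    for i, (name, share, herd_size) in enumerate(_PRESET_SHARES):
        if i == len(_PRESET_SHARES) - 1:
            n = scale - assigned
        else:
            n = int(round(scale * share / 100.0))
        assigned += n
        pops.append(
            PopulationConfig(
                name=name,
                n_records=n,
                n_herds=max(2, int(round(n / herd_size))),
                has_pe=(name != "DEU"),
            )
        )
    vc = make_variance_components(pops)
    return SimulationConfig(populations=pops, vc=vc)
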