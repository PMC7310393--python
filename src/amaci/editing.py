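"""National data edits and herd sub-setting strategies.

The edits mirror routine international-evaluation practice: records in
contemporary groups below the national minimum size are dropped, embryo
transfer animals are removed, and phenotypes further than three standard
deviations from their population-by-sex mean are discarded.

Sub-setting reduces the dominant population to a target record count by
keeping only its best connected herds, ranked by herd-level genetic
similarity (from common bulls alone, or averaged with the common
maternal-grand-sire version), by the herd harmonic-mean score, or at random.
Non-target populations are always kept whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectedness as conn
from .pedigree import Pedigree, prune_pedigree

__all__ = [
    "EditConfig",
    "SubsetPlan",
    "apply_data_edits",
    "subset_random",
    "subset_by_gs",
    "subset_by_hm",
    "finalize_subset",
]

PHENOTYPE_COLUMNS = [
    "animal", "population", "sex", "herd", "contemporary_group", "dam",
    "extra_random_level", "value",
]


@dataclass
class EditConfig:
    """Data-edit thresholds.

    ``min_cg_size`` maps population to its national minimum contemporary
    group size; ``et_flag_column`` names an optional 0/1 embryo-transfer
    column (no ET filter when absent); ``outlier_sd`` is the phenotype
    outlier multiplier (3 standard deviations by default).
    """

    min_cg_size: dict[str, int] = field(default_factory=dict)
    et_flag_column: str | None = None
    outlier_sd: float = 3.0


@dataclass
class SubsetPlan:
    """Configuration of a herd sub-setting run for the dominant population."""

    strategy: str                      # ALL|RND|GSCB|GSTOT|HM|DROP_POP|MIN_BIRTH_YEAR
    target_population: str
    target_records: int = 0
    n_random_subsets: int = 20
    n_top_subsets: int = 3
    top_fraction: float | None = None  # alternative to target_records
    min_birth_year: int | None = None
    seed: int = 0


def apply_data_edits(phen: pd.DataFrame, cfg: EditConfig,
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the sequential national edits; returns the edited table and a
    log of records removed per filter.

    Order: (1) minimum contemporary-group size, (2) embryo-transfer flag,
    (3) phenotype outliers beyond ``outlier_sd`` standard deviations of the
    population-by-sex mean, computed on the survivors of (1)-(2).
    Population-by-sex cells with fewer than 3 records skip the outlier
    filter (their standard deviation is not meaningfully estimable).
    """
    unknown = set(phen["population"].unique()) - set(cfg.min_cg_size)
    if cfg.min_cg_size and unknown:
        raise ValueError(f"populations without a configured minimum CG size: {sorted(unknown)}")
    log = {}

    cg_sizes = phen.groupby(["population", "contemporary_group"])["animal"].transform("size")
    min_sizes = phen["population"].map(lambda p: cfg.min_cg_size.get(p, 1))
    keep = cg_sizes >= min_sizes
    log["cg"] = int((~keep).sum())
    phen = phen[keep]

    if cfg.et_flag_column is not None and cfg.et_flag_column in phen.columns:
        flagged = phen[cfg.et_flag_column].astype(float).fillna(0) > 0
        log["et"] = int(flagged.sum())
        phen = phen[~flagged]
    else:
        log["et"] = 0

    grp = phen.groupby(["population", "sex"])["value"]
    mean = grp.transform("mean")
    sd = grp.transform("std")
    n = grp.transform("size")
    out = (n >= 3) & sd.gt(0) & ((phen["value"] - mean).abs() > cfg.outlier_sd * sd)
    log["outlier"] = int(out.sum())
    return phen[~out].reset_index(drop=True), log


def _herd_sizes(phen: pd.DataFrame, population: str) -> pd.Series:
    sub = phen[phen["population"] == population]
    return sub.groupby("herd")["animal"].size().sort_index()


def subset_random(phen: pd.DataFrame, ped: Pedigree, plan: SubsetPlan,
                  ) -> list[dict]:
    """Randomly partition the target population's herds into
    ``n_random_subsets`` groups and rank the groups by their average genetic
    similarity with the other populations.

    Returns the ``n_top_subsets`` best groups as dicts with keys
    ``herds``, ``mean_gs``, ``n_records``, sorted by decreasing similarity.
    """
    herds = _herd_sizes(phen, plan.target_population)
    if len(herds) < plan.n_random_subsets:
        raise ValueError(
            f"{len(herds)} herds cannot be split into {plan.n_random_subsets} subsets"
        )
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(herds))
    groups = np.array_split(order, plan.n_random_subsets)
    herd_ids = herds.index.to_numpy()

    counts = conn.tally_sire_offspring(phen, ped)
    other_pops = sorted(set(phen["population"].unique()) - {plan.target_population})

    results = []
    for g in groups:
        sel = set(herd_ids[g])
        gs_vals = [
            _subset_gs(counts, sel, plan.target_population, p) for p in other_pops
        ]
        gs_vals = [v for v in gs_vals if v is not None]
        results.append(
            {
                "herds": sorted(sel),
                "mean_gs": float(np.mean(gs_vals)) if gs_vals else 0.0,
                "n_records": int(herds.loc[sorted(sel)].sum()),
            }
        )
    results.sort(key=lambda r: -r["mean_gs"])
    return results[: plan.n_top_subsets]


def _subset_gs(counts, herd_set: set, target_pop: str, pop_b: str) -> float | None:
    """Genetic similarity between a group of target-population herds (acting
    as one pseudo-population) and population ``pop_b``."""
    num = den = 0
    for rec in counts:
        nh = sum(
            n for (h, p), n in rec.herd_counts.items()
            if p == target_pop and h in herd_set
        )
        nb = rec.counts.get(pop_b, 0)
        if nh + nb == 0:
            continue
        den += nh + nb
        if nh > 0 and nb > 0:
            num += nh + nb
    return None if den == 0 else num / den


def _rank_and_accumulate(scores: pd.DataFrame, plan: SubsetPlan,
                         ) -> tuple[list[str], pd.DataFrame]:
    """Select herds in decreasing score order until the cumulative record
    count first reaches the target (or take the top fraction of herds).

    Ties are broken by record count (larger first) then herd id.  Herds whose
    score is entirely missing (no sired offspring on either side) are ranked
    as zero and flagged as disconnected.
    """
    df = scores.copy()
    df["disconnected"] = df["score"].isna() | (df["score"] < 1e-3)
    df["score"] = df["score"].fillna(0.0)
    df = df.sort_values(
        ["score", "n_records", "herd"], ascending=[False, False, True]
    ).reset_index(drop=True)
    total = int(df["n_records"].sum())
    if plan.top_fraction is not None:
        k = max(1, int(round(plan.top_fraction * len(df))))
        sel = df.iloc[:k]
    else:
        if plan.target_records > total:
            raise ValueError(
                f"target_records={plan.target_records} exceeds population size {total}"
            )
        cum = df["n_records"].cumsum()
        k = int(np.searchsorted(cum.to_numpy(), plan.target_records) + 1)
        sel = df.iloc[:k]
    return sel["herd"].tolist(), df


def subset_by_gs(phen: pd.DataFrame, ped: Pedigree, plan: SubsetPlan,
                 ancestor_kind: str = "CB") -> tuple[list[str], pd.DataFrame]:
    """Select target-population herds ranked by average herd-level genetic
    similarity, from common bulls alone (``"CB"``) or the mean of the CB and
    CMGS coefficients (``"TOT"``)."""
    report = conn.build_report(phen, ped)
    ht = report.herd_table
    ht = ht[ht["population"] == plan.target_population]
    col = {"CB": "gs_cb", "TOT": "gs_tot"}[ancestor_kind.upper()]
    scores = ht[["herd", "n_records"]].assign(score=ht[col].to_numpy())
    return _rank_and_accumulate(scores, plan)


def subset_by_hm(phen: pd.DataFrame, ped: Pedigree, plan: SubsetPlan,
                 ) -> tuple[list[str], pd.DataFrame]:
    """Select target-population herds ranked by the herd harmonic-mean score."""
    report = conn.build_report(phen, ped)
    ht = report.herd_table
    ht = ht[ht["population"] == plan.target_population]
    scores = ht[["herd", "n_records"]].assign(score=ht["hm"].to_numpy())
    return _rank_and_accumulate(scores, plan)


def finalize_subset(phen: pd.DataFrame, ped: Pedigree, selected: list[str] | None,
                    plan: SubsetPlan) -> tuple[pd.DataFrame, Pedigree]:
    """Apply a selection to the data and re-prune the pedigree to phenotyped
    animals and their ancestors."""
    strategy = plan.strategy.upper()
    if strategy == "ALL":
        out = phen
    elif strategy == "DROP_POP":
        out = phen[phen["population"] != plan.target_population]
    elif strategy == "MIN_BIRTH_YEAR":
        if plan.min_birth_year is None:
            raise ValueError("MIN_BIRTH_YEAR strategy requires plan.min_birth_year")
        years = np.array(
            [ped.birth_year[ped.index_of[a]] for a in phen["animal"]], dtype=np.int64
        )
        out = phen[years >= plan.min_birth_year]
    else:
        sel = set(selected or [])
        out = phen[
            (phen["population"] != plan.target_population)
            | phen["herd"].isin(sel)
        ]
    out = out.reset_index(drop=True)
    pruned = prune_pedigree(ped, set(out["animal"]))
    return out, pruned
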