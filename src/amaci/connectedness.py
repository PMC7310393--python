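"""Across-population genetic connectedness measures.

Connections between populations in an international evaluation come from
common bulls (CB: sires with recorded offspring in two or more populations)
and common maternal grand-sires (CMGS: maternal grand-sires with recorded
grand-offspring in more than one population).  From the offspring tallies this
module computes:

* the coefficient of genetic similarity GS between two populations (or a herd
  and a population): the proportion of their combined offspring sired by
  common bulls;
* the balanced offspring distribution BOD of a sire and the adjusted number
  of populations AN_POP = N_P * BOD;
* the harmonic mean HM of a sire's progeny sizes in two units, and its
  herd-level sum over common bulls.

"Offspring" always means a phenotyped record in the edited dataset; the
population of an offspring is the population of its record.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "SireOffspringCounts",
    "ConnectednessReport",
    "tally_sire_offspring",
    "tally_mgs_grandoffspring",
    "genetic_similarity",
    "herd_genetic_similarity",
    "bod",
    "an_pop",
    "harmonic_mean_sire",
    "herd_harmonic_mean",
    "build_report",
]


@dataclass
class SireOffspringCounts:
    """Phenotyped offspring (or grand-offspring) tallies for one sire."""

    sire_id: str
    counts: dict[str, int] = field(default_factory=dict)
    herd_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    birth_year: int = -1
    origin: str = ""

    def total(self) -> int:
        return sum(self.counts.values())

    def mean_count(self, n_populations: int) -> float:
        """Average offspring count over all populations, zeros included."""
        return self.total() / n_populations

    def populations(self) -> set[str]:
        return {p for p, n in self.counts.items() if n > 0}


def _tally(phen: pd.DataFrame, ped: Pedigree, ancestor_index: np.ndarray,
           ) -> list[SireOffspringCounts]:
    anc_ids = np.array(ped.ids, dtype=object)
    valid = ancestor_index >= 0
    df = pd.DataFrame(
        {
            "sire": anc_ids[ancestor_index[valid]],
            "population": phen["population"].to_numpy()[valid],
            "herd": phen["herd"].to_numpy()[valid],
        }
    )
    out: dict[str, SireOffspringCounts] = {}
    by_pop = df.groupby(["sire", "population"], sort=False).size()
    by_herd = df.groupby(["sire", "herd", "population"], sort=False).size()
    for (s, p), n in by_pop.items():
        rec = out.get(s)
        if rec is None:
            i = ped.index_of[s]
            rec = out[s] = SireOffspringCounts(
                s, birth_year=int(ped.birth_year[i]), origin=ped.origin[i]
            )
        rec.counts[p] = int(n)
    for (s, h, p), n in by_herd.items():
        out[s].herd_counts[(h, p)] = int(n)
    return list(out.values())


def _animal_indices(phen: pd.DataFrame, ped: Pedigree) -> np.ndarray:
    missing = [a for a in phen["animal"] if a not in ped.index_of]
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped animals absent from pedigree "
            f"(first few: {sorted(set(missing))[:5]})"
        )
    return np.array([ped.index_of[a] for a in phen["animal"]], dtype=np.int64)


def tally_sire_offspring(phen: pd.DataFrame, ped: Pedigree) -> list[SireOffspringCounts]:
    """Per-sire counts of phenotyped offspring by population and by herd.

    Records with an unknown sire contribute to no sire.
    """
    idx = _animal_indices(phen, ped)
    return _tally(phen, ped, ped.sire[idx])


def tally_mgs_grandoffspring(phen: pd.DataFrame, ped: Pedigree) -> list[SireOffspringCounts]:
    """Per-maternal-grand-sire counts of phenotyped grand-offspring.

    The counted ancestor is the sire of the record's dam; records with an
    unknown dam (or a dam with unknown sire) contribute to no one.
    """
    idx = _animal_indices(phen, ped)
    dam_idx = ped.dam[idx]
    mgs = np.where(dam_idx >= 0, ped.sire[np.clip(dam_idx, 0, None)], -1)
    return _tally(phen, ped, mgs)


def genetic_similarity(counts: list[SireOffspringCounts], pop_a: str, pop_b: str,
                       ) -> float | None:
    """Coefficient of genetic similarity between two populations.

    Ratio of the offspring (in either population) of bulls present in *both*
    populations to the offspring of bulls present in *either*.  Returns
    ``None`` when no bull has offspring in either population.
    """
    num = den = 0
    for rec in counts:
        na, nb = rec.counts.get(pop_a, 0), rec.counts.get(pop_b, 0)
        if na + nb == 0:
            continue
        den += na + nb
        if na > 0 and nb > 0:
            num += na + nb
    return None if den == 0 else num / den


def herd_genetic_similarity(counts: list[SireOffspringCounts], herd: str, pop_b: str,
                            ) -> float | None:
    """Genetic similarity between one herd and a population, the herd playing
    the role of one of the two populations."""
    num = den = 0
    for rec in counts:
        nh = sum(n for (h, _p), n in rec.herd_counts.items() if h == herd)
        nb = rec.counts.get(pop_b, 0)
        if nh + nb == 0:
            continue
        den += nh + nb
        if nh > 0 and nb > 0:
            num += nh + nb
    return None if den == 0 else num / den


def bod(counts_for_sire: SireOffspringCounts, n_populations: int) -> float:
    """Balanced offspring distribution of a sire over all ``n_populations``
    (populations without offspring enter as zeros)."""
    total = counts_for_sire.total()
    if total <= 0:
        raise ValueError(f"sire {counts_for_sire.sire_id!r} has no offspring")
    nbar = total / n_populations
    nonzero = [n for n in counts_for_sire.counts.values() if n > 0]
    dev = sum(abs(n - nbar) for n in nonzero) + (n_populations - len(nonzero)) * nbar
    return 1.0 - dev / (2.0 * total)


def an_pop(bod_value: float, n_populations: int) -> float:
    """Adjusted number of populations: N_P * BOD."""
    return n_populations * bod_value


def harmonic_mean_sire(n1: float, n2: float) -> float:
    """Harmonic mean of a sire's progeny sizes in two units."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("progeny sizes must be positive")
    return 2.0 / (1.0 / n1 + 1.0 / n2)


def herd_harmonic_mean(counts: list[SireOffspringCounts], herd: str) -> float:
    """Herd connection score: sum over other populations and over common
    bulls of the harmonic mean of (offspring in the herd, offspring in the
    population)."""
    hm = 0.0
    herd_pop = _herd_population(counts, herd)
    pops = sorted({p for rec in counts for p in rec.populations()})
    for rec in counts:
        nh = sum(n for (h, _p), n in rec.herd_counts.items() if h == herd)
        if nh == 0:
            continue
        for p in pops:
            if p == herd_pop:
                continue
            nb = rec.counts.get(p, 0)
            if nb > 0:
                hm += harmonic_mean_sire(nh, nb)
    return hm


def _herd_population(counts: list[SireOffspringCounts], herd: str) -> str | None:
    for rec in counts:
        for (h, p), n in rec.herd_counts.items():
            if h == herd and n > 0:
                return p
    return None


@dataclass
class ConnectednessReport:
    """All pairwise, per-sire and per-herd connectedness coefficients."""

    populations: list[str]
    pair_table: pd.DataFrame       # population x population: totals on the
                                   # diagonal, CB counts above, GS below
    cb_pairs: pd.DataFrame         # pop_a, pop_b, n_cb, n_tb, gs
    cmgs_pairs: pd.DataFrame       # same for maternal grand-sires
    sire_table: pd.DataFrame       # sire, origin, birth_year, totals, BOD, AN_POP
    sire_pair_hm: pd.DataFrame     # sire, pop_a, pop_b, hm  (common bulls only)
    herd_table: pd.DataFrame       # herd, population, gs_cb, gs_cmgs, gs_tot, hm
    cb_by_year_origin: pd.DataFrame
    n_unique_cb: int
    cb_by_n_connected: pd.Series   # n connected populations -> count of CB
    cmgs_also_cb: pd.DataFrame     # connected pops x {yes, no}

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def write_csvs(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pair_table.to_csv(out / "pair_matrix.csv")
        self.cb_pairs.to_csv(out / "cb_pairs.csv", index=False)
        self.cmgs_pairs.to_csv(out / "cmgs_pairs.csv", index=False)
        self.sire_table.to_csv(out / "sire_coefficients.csv", index=False)
        self.herd_table.to_csv(out / "herd_coefficients.csv", index=False)
        self.cb_by_year_origin.to_csv(out / "cb_by_year_origin.csv", index=False)
        self.cmgs_also_cb.to_csv(out / "cmgs_also_cb.csv")


def _pair_frame(counts: list[SireOffspringCounts], pops: list[str]) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(pops, 2):
        n_cb = sum(1 for r in counts if r.counts.get(a, 0) > 0 and r.counts.get(b, 0) > 0)
        n_tb = sum(1 for r in counts if r.counts.get(a, 0) > 0 or r.counts.get(b, 0) > 0)
        rows.append(
            {"pop_a": a, "pop_b": b, "n_common": n_cb, "n_total": n_tb,
             "gs": genetic_similarity(counts, a, b)}
        )
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "n_common", "n_total", "gs"])


def build_report(phen: pd.DataFrame, ped: Pedigree,
                 populations: list[str] | None = None) -> ConnectednessReport:
    """Compute the full connectedness report for an edited dataset."""
    if populations is None:
        populations = sorted(phen["population"].unique())
    pops = list(populations)
    n_pop = len(pops)

    cb_counts = tally_sire_offspring(phen, ped)
    mgs_counts = tally_mgs_grandoffspring(phen, ped)

    cb_pairs = _pair_frame(cb_counts, pops)
    cmgs_pairs = _pair_frame(mgs_counts, pops)

    # population x population matrix: totals on diagonal, CB above, GS below
    mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    for p in pops:
        mat.loc[p, p] = sum(1 for r in cb_counts if r.counts.get(p, 0) > 0)
    for row in cb_pairs.itertuples():
        a, b = row.pop_a, row.pop_b
        first, second = (a, b) if pops.index(a) < pops.index(b) else (b, a)
        mat.loc[first, second] = row.n_common
        mat.loc[second, first] = row.gs

    sire_rows, hm_rows = [], []
    for rec in cb_counts:
        present = rec.populations()
        b = bod(rec, n_pop)
        sire_rows.append(
            {
                "sire": rec.sire_id,
                "origin": rec.origin,
                "birth_year": rec.birth_year,
                "n_offspring": rec.total(),
                "n_populations": len(present),
                "is_cb": len(present) >= 2,
                "bod": b,
                "an_pop": an_pop(b, n_pop),
            }
        )
        for a, c in itertools.combinations(sorted(present), 2):
            hm_rows.append(
                {"sire": rec.sire_id, "pop_a": a, "pop_b": c,
                 "hm": harmonic_mean_sire(rec.counts[a], rec.counts[c])}
            )
    sire_table = pd.DataFrame(
        sire_rows,
        columns=["sire", "origin", "birth_year", "n_offspring", "n_populations",
                 "is_cb", "bod", "an_pop"],
    )
    sire_pair_hm = pd.DataFrame(hm_rows, columns=["sire", "pop_a", "pop_b", "hm"])

    herd_rows = []
    herd_pop = (
        phen.groupby("herd", sort=False)["population"].first()
        if len(phen) else pd.Series(dtype=object)
    )
    for herd, hp in herd_pop.items():
        others = [p for p in pops if p != hp]
        gs_cb = [herd_genetic_similarity(cb_counts, herd, p) for p in others]
        gs_mg = [herd_genetic_similarity(mgs_counts, herd, p) for p in others]
        gs_tot = [
            (x + y) / 2.0 if x is not None and y is not None else None
            for x, y in zip(gs_cb, gs_mg)
        ]

        def avg(vals):
            vals = [v for v in vals if v is not None]
            return float(np.mean(vals)) if vals else np.nan

        herd_rows.append(
            {
                "herd": herd,
                "population": hp,
                "n_records": int((phen["herd"] == herd).sum()),
                "gs_cb": avg(gs_cb),
                "gs_cmgs": avg(gs_mg),
                "gs_tot": avg(gs_tot),
                "hm": herd_harmonic_mean(cb_counts, herd),
            }
        )
    herd_table = pd.DataFrame(
        herd_rows,
        columns=["herd", "population", "n_records", "gs_cb", "gs_cmgs", "gs_tot", "hm"],
    )

    cbs = [r for r in cb_counts if len(r.populations()) >= 2]
    cb_by_year_origin = (
        pd.DataFrame(
            [{"birth_year": r.birth_year, "origin": r.origin} for r in cbs]
        ).groupby(["birth_year", "origin"]).size().rename("n_cb").reset_index()
        if cbs else pd.DataFrame(columns=["birth_year", "origin", "n_cb"])
    )
    cb_by_n_connected = pd.Series(
        {k: sum(1 for r in cbs if len(r.populations()) == k)
         for k in range(2, n_pop + 1)},
        name="n_cb",
    )

    cb_ids = {r.sire_id for r in cbs}
    cross_rows = {}
    for rec in mgs_counts:
        k = len(rec.populations())
        if k < 2:
            continue
        row = cross_rows.setdefault(k, {"yes": 0, "no": 0})
        row["yes" if rec.sire_id in cb_ids else "no"] += 1
    cmgs_also_cb = pd.DataFrame.from_dict(cross_rows, orient="index").sort_index()
    if cmgs_also_cb.empty:
        cmgs_also_cb = pd.DataFrame(columns=["yes", "no"])
    cmgs_also_cb.index.name = "n_connected_populations"

    return ConnectednessReport(
        populations=pops,
        pair_table=mat,
        cb_pairs=cb_pairs,
        cmgs_pairs=cmgs_pairs,
        sire_table=sire_table,
        sire_pair_hm=sire_pair_hm,
        herd_table=herd_table,
        cb_by_year_origin=cb_by_year_origin,
        n_unique_cb=len(cb_ids),
        cb_by_n_connected=cb_by_n_connected,
        cmgs_also_cb=cmgs_also_cb,
    )
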