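"""Pedigree handling: reading, validation, pruning, inbreeding and the inverse
numerator relationship matrix.

A pedigree is a list of (animal, sire, dam, birth year, origin country) rows.
After reading, the pedigree is *completed* (parents that are referenced but not
listed become founders) and stored in topological order, so every parent's
dense index is smaller than each of its offspring's.  The numerator
relationship matrix ``A`` never needs to be formed explicitly at scale: its
sparse inverse is assembled directly from per-animal Mendelian-sampling
contributions, with inbreeding coefficients computed by ancestor tracing.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "RelationshipInverse",
    "PedigreeError",
    "read_pedigree",
    "prune_pedigree",
    "max_generation_depth",
    "inbreeding_coefficients",
    "build_A_inverse",
]

#: tokens accepted as "parent unknown" in input files
_MISSING_TOKENS = {"", "0", "na", "nan", "none", "."}


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (duplicates, cycles, bad ids)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree with dense integer indexing.

    Attributes
    ----------
    ids
        Animal identifiers in topological order (parents before offspring).
    sire, dam
        Dense parent indices per animal; ``-1`` encodes an unknown parent.
    birth_year
        Birth year per animal; ``-1`` when unknown.
    origin
        Country of first registration per animal; ``""`` when unknown.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    origin: list[str]
    index_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index_of = {a: i for i, a in enumerate(self.ids)}
        if len(self.index_of) != len(self.ids):
            seen: set[str] = set()
            dups = sorted({a for a in self.ids if a in seen or seen.add(a)})
            raise PedigreeError(f"duplicate animal ids: {dups}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records, validate: bool = True) -> "Pedigree":
        """Build a pedigree from an iterable of
        ``(animal, sire, dam[, birth_year[, origin]])`` tuples.

        Referenced but unlisted parents are appended as founders; rows are
        then topologically sorted (Kahn's scheme, ties broken by input order).
        """
        rows = []
        for rec in records:
            rec = tuple(rec) + (None,) * (5 - len(rec))
            rows.append(rec[:5])
        ids = [str(r[0]).strip() for r in rows]
        seen: set[str] = set()
        dups = sorted({a for a in ids if a in seen or seen.add(a)})
        if dups:
            raise PedigreeError(f"duplicate animal ids: {dups}")

        def norm(tok) -> str:
            if tok is None or (isinstance(tok, float) and np.isnan(tok)):
                return ""
            tok = str(tok).strip()
            return "" if tok.lower() in _MISSING_TOKENS else tok

        sire_tok = [norm(r[1]) for r in rows]
        dam_tok = [norm(r[2]) for r in rows]

        def year(tok) -> int:
            if tok is None or tok == "" or (isinstance(tok, float) and np.isnan(tok)):
                return -1
            return int(float(tok))

        years = [year(r[3]) for r in rows]
        origins = [norm(r[4]) for r in rows]

        known = set(ids)
        # completion: unlisted parents become founders, in first-reference order
        for tok in sire_tok + dam_tok:
            if tok and tok not in known:
                known.add(tok)
                ids.append(tok)
                sire_tok.append("")
                dam_tok.append("")
                years.append(-1)
                origins.append("")

        pos = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        sire_raw = np.array([pos[t] if t else -1 for t in sire_tok], dtype=np.int64)
        dam_raw = np.array([pos[t] if t else -1 for t in dam_tok], dtype=np.int64)

        for i in range(n):
            if sire_raw[i] == i or dam_raw[i] == i:
                raise PedigreeError(f"animal {ids[i]!r} is its own parent (cycle: [{ids[i]!r}])")

        order = _kahn_order(ids, sire_raw, dam_raw)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(n)

        def remap(p: np.ndarray) -> np.ndarray:
            out = np.full(n, -1, dtype=np.int64)
            for new_i, old_i in enumerate(order):
                old_p = p[old_i]
                out[new_i] = -1 if old_p < 0 else rank[old_p]
            return out

        ped = cls(
            ids=[ids[i] for i in order],
            sire=remap(sire_raw),
            dam=remap(dam_raw),
            birth_year=np.array([years[i] for i in order], dtype=np.int64),
            origin=[origins[i] for i in order],
        )
        if validate:
            ped.validate()
        return ped

    def validate(self) -> None:
        """Check referential integrity, acyclicity and topological order."""
        n = len(self)
        for p in (self.sire, self.dam):
            if p.shape != (n,):
                raise PedigreeError("parent index arrays must match pedigree size")
            bad = (p >= n) | ((p < 0) & (p != -1))
            if bad.any():
                raise PedigreeError("parent index out of range")
            forward = p >= np.arange(n)
            if forward.any():
                i = int(np.nonzero(forward)[0][0])
                raise PedigreeError(
                    f"pedigree not topologically ordered at {self.ids[i]!r}"
                )

    def parents_of(self, animal_id: str) -> tuple[str | None, str | None]:
        i = self.index_of[animal_id]
        s, d = self.sire[i], self.dam[i]
        return (self.ids[s] if s >= 0 else None, self.ids[d] if d >= 0 else None)

    def to_frame(self) -> pd.DataFrame:
        sire = ["" if s < 0 else self.ids[s] for s in self.sire]
        dam = ["" if d < 0 else self.ids[d] for d in self.dam]
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": sire,
                "dam": dam,
                "birth_year": self.birth_year,
                "origin_country": self.origin,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RelationshipInverse:
    """Sparse symmetric inverse of the numerator relationship matrix ``A``,
    together with the per-animal inbreeding coefficients used to build it."""

    entries: sparse.csr_matrix
    inbreeding: np.ndarray

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def write_coordinate(self, path) -> None:
        """Export the lower triangle in 1-based ``i j value`` text format."""
        coo = sparse.tril(self.entries).tocoo()
        with open(path, "w") as fh:
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i + 1} {j + 1} {v:.12g}\n")


def _kahn_order(ids, sire, dam) -> list[int]:
    """Topological order, parents first; ties broken by input position."""
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < n:
        cycle = _find_cycle(ids, sire, dam, set(order))
        raise PedigreeError(f"pedigree cycle detected: {cycle}")
    return order


def _find_cycle(ids, sire, dam, resolved: set[int]) -> list[str]:
    start = next(i for i in range(len(ids)) if i not in resolved)
    seen: dict[int, int] = {}
    path: list[int] = []
    i = start
    while i not in seen:
        seen[i] = len(path)
        path.append(i)
        s, d = sire[i], dam[i]
        i = s if (s >= 0 and s not in resolved) else d
    cyc = path[seen[i]:] + [i]
    return [ids[j] for j in cyc]


def read_pedigree(path, drop_invalid: bool = False) -> Pedigree:
    """Read a pedigree CSV with columns
    ``animal,sire,dam,birth_year,origin_country`` (header required).

    Unknown parents may be encoded as an empty field or ``0``.  Parents that
    are referenced but have no row of their own are added as founders.

    By default duplicate ids and cycles abort the read; with
    ``drop_invalid`` the offending animals are removed instead (duplicates
    keep their first row; every animal on a cycle is dropped and references
    to it become unknown parents) and a warning reports how many.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["animal", "sire", "dam", "birth_year", "origin_country"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree file {path} missing columns: {missing}")
    rows = list(df[required].itertuples(index=False, name=None))
    if not drop_invalid:
        return Pedigree.from_records(rows)

    import warnings

    seen: set[str] = set()
    unique_rows = []
    n_dup = 0
    for r in rows:
        a = str(r[0]).strip()
        if a in seen:
            n_dup += 1
            continue
        seen.add(a)
        unique_rows.append(r)
    n_cycle = 0
    while True:
        try:
            ped = Pedigree.from_records(unique_rows)
            break
        except PedigreeError as exc:
            if "cycle" not in str(exc):
                raise
            bad = set(_ids_from_cycle_message(str(exc)))
            n_cycle += len(bad)
            unique_rows = [
                (r[0],
                 "" if str(r[1]).strip() in bad else r[1],
                 "" if str(r[2]).strip() in bad else r[2],
                 r[3], r[4])
                for r in unique_rows if str(r[0]).strip() not in bad
            ]
    if n_dup or n_cycle:
        warnings.warn(
            f"dropped {n_dup} duplicate and {n_cycle} cycle-involved "
            f"pedigree rows from {path}", stacklevel=2,
        )
    return ped


def _ids_from_cycle_message(msg: str) -> list[str]:
    import ast

    return ast.literal_eval(msg[msg.index("["):msg.index("]") + 1])


def prune_pedigree(ped: Pedigree, keep_ids) -> Pedigree:
    """Restrict ``ped`` to ``keep_ids`` and all their ancestors (no generation
    limit), preserving the existing order."""
    keep_ids = set(keep_ids)
    unknown = sorted(k for k in keep_ids if k not in ped.index_of)
    if unknown:
        raise PedigreeError(f"keep_ids not in pedigree: {unknown}")
    keep = np.zeros(len(ped), dtype=bool)
    for k in keep_ids:
        keep[ped.index_of[k]] = True
    # ancestors close under a reverse sweep: parents precede offspring
    for i in range(len(ped) - 1, -1, -1):
        if keep[i]:
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    keep[p] = True
    idx = np.nonzero(keep)[0]
    new_of_old = {int(o): n for n, o in enumerate(idx)}

    def remap(p: np.ndarray) -> np.ndarray:
        return np.array(
            [-1 if p[o] < 0 else new_of_old[int(p[o])] for o in idx], dtype=np.int64
        )

    return Pedigree(
        ids=[ped.ids[o] for o in idx],
        sire=remap(ped.sire),
        dam=remap(ped.dam),
        birth_year=ped.birth_year[idx].copy(),
        origin=[ped.origin[o] for o in idx],
    )


def max_generation_depth(ped: Pedigree) -> int:
    """Longest founder-to-animal path length; founders count as depth 0."""
    if len(ped) == 0:
        return 0
    depth = np.zeros(len(ped), dtype=np.int64)
    for i in range(len(ped)):
        d = -1
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                d = max(d, depth[p])
        depth[i] = d + 1
    return int(depth.max())


def _mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance per animal, adjusted for
    parental inbreeding: 0.5 - 0.25 (F_s + F_d), with an unknown parent
    contributing F = 0 through a base-population term."""
    s, d = ped.sire, ped.dam
    Fs = np.where(s >= 0, F[np.clip(s, 0, None)], 0.0)
    Fd = np.where(d >= 0, F[np.clip(d, 0, None)], 0.0)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    dvar = np.ones(len(ped))
    dvar[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    dvar[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    return dvar


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient per animal by ancestor tracing.

    Uses the decomposition A = T D T': the diagonal A_ii is accumulated by
    walking the ancestor paths of animal i (youngest-first, merging duplicate
    path contributions), weighting each ancestor's squared path coefficient by
    its Mendelian-sampling variance; F_i = A_ii - 1.  Ancestors precede their
    offspring in a topologically sorted pedigree, so the parental F values
    needed for the variances are always available.
    """
    n = len(ped)
    F = np.zeros(n)
    dvar = np.ones(n)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            dvar_i = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            dvar_i = 0.75 - 0.25 * F[max(s, d)]
        else:
            dvar_i = 1.0
        dvar[i] = dvar_i
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # accumulate A_ii = sum_j t_ij^2 dvar_j over ancestors j (and i itself)
        coeff: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = coeff.pop(j, 0.0)
            if c == 0.0:
                continue
            a_ii += c * c * dvar[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in coeff:
                        heapq.heappush(heap, -p)
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * c
        F[i] = a_ii - 1.0
    return F


def build_A_inverse(ped: Pedigree, use_inbreeding: bool = True) -> RelationshipInverse:
    """Assemble the sparse inverse of the numerator relationship matrix by
    per-animal contributions.

    Each animal i contributes alpha = 1/d_i to (i,i), -alpha/2 to (i,parent)
    and alpha/4 to each known parent pair, where d_i is its Mendelian-sampling
    variance (adjusted for parental inbreeding when ``use_inbreeding``).
    """
    n = len(ped)
    F = inbreeding_coefficients(ped) if use_inbreeding else np.zeros(n)
    dvar = _mendelian_variances(ped, F if use_inbreeding else np.zeros(n))
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n)
    alpha = 1.0 / dvar

    def add(r, c, v):
        rows.append(np.asarray(r))
        cols.append(np.asarray(c))
        vals.append(np.asarray(v, dtype=float))

    add(idx, idx, alpha)
    for pname in ("sire", "dam"):
        p = getattr(ped, pname)
        m = p >= 0
        add(idx[m], p[m], -0.5 * alpha[m])
        add(p[m], idx[m], -0.5 * alpha[m])
        add(p[m], p[m], 0.25 * alpha[m])
    both = (ped.sire >= 0) & (ped.dam >= 0)
    add(ped.sire[both], ped.dam[both], 0.25 * alpha[both])
    add(ped.dam[both], ped.sire[both], 0.25 * alpha[both])

    A_inv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return RelationshipInverse(entries=A_inv, inbreeding=F)
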