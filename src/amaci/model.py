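"""Multi-trait maternal-effects animal model across populations.

Each population is modelled as a separate, genetically correlated trait.  A
record from population ``p`` is described by that population's national
model: its fixed effects, an optional extra national random environmental
effect, the animal's direct genetic effect, the dam's maternal genetic
effect, and (for populations fitting it) the dam's permanent environmental
effect.  Direct and maternal genetic effects of all populations span the
whole pedigree, with covariance ``G0 (x) A`` (Kronecker product of the
2*N_pop genetic covariance matrix with the numerator relationship matrix);
permanent environmental and residual effects are uncorrelated across
populations.

Equations are ordered fixed effects, extra random, permanent environment,
then genetic effects animal-major (the 2*N_pop within-animal block is
contiguous), so the genetic prior is ``A^-1 (x) G0^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import Pedigree, RelationshipInverse, inbreeding_coefficients
from .pedigree import _mendelian_variances

__all__ = [
    "NationalModelSpec",
    "VarianceComponents",
    "Design",
    "MMESystem",
    "build_design",
    "assemble_mme",
    "solve_pcg",
    "BlockJacobiPreconditioner",
    "simulate_from_model",
]


@dataclass
class NationalModelSpec:
    """National model of one population.

    ``fixed_effects`` lists categorical phenotype columns (an intercept is
    always included); ``extra_random`` optionally names the column holding
    the national random environmental effect level; ``has_pe`` controls
    whether a maternal permanent environmental effect is fitted.
    """

    population: str
    fixed_effects: list[str] = field(default_factory=lambda: ["contemporary_group"])
    extra_random: str | None = None
    has_pe: bool = True


class VarianceComponents:
    """Variance components of the across-country model.

    ``genetic`` is the symmetric 2*N_pop x 2*N_pop covariance matrix over
    effects ordered (direct_1..direct_P, maternal_1..maternal_P); ``pe``,
    ``extra`` and ``resid`` are per-population scalar variances (permanent
    environmental and national-random covariances across populations are
    structurally zero).
    """

    def __init__(self, populations, genetic, pe=None, extra=None, resid=None):
        self.populations = list(populations)
        P = len(self.populations)
        self.genetic = np.asarray(genetic, dtype=float)
        if self.genetic.shape != (2 * P, 2 * P):
            raise ValueError("genetic matrix must be 2*N_pop square")
        if not np.allclose(self.genetic, self.genetic.T, atol=1e-10):
            raise ValueError("genetic matrix must be symmetric")
        self.pe = dict(pe or {})
        self.extra = dict(extra or {})
        self.resid = dict(resid or {})
        for name, d in (("pe", self.pe), ("extra", self.extra), ("resid", self.resid)):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative {name} variance for {k}")

    # ----- effect indexing -------------------------------------------------
    @property
    def n_pop(self) -> int:
        return len(self.populations)

    def direct_index(self, pop: str) -> int:
        return self.populations.index(pop)

    def maternal_index(self, pop: str) -> int:
        return self.n_pop + self.populations.index(pop)

    def effect_labels(self) -> list[str]:
        return [f"direct_{p}" for p in self.populations] + [
            f"maternal_{p}" for p in self.populations
        ]

    # ----- flat parameter view (trajectories, SE machinery) ----------------
    def parameter_labels(self) -> list[str]:
        eff = self.effect_labels()
        labels = [
            f"g:{eff[k]}:{eff[l]}"
            for k in range(2 * self.n_pop)
            for l in range(k + 1)
        ]
        labels += [f"pe:{p}" for p in sorted(self.pe)]
        labels += [f"extra:{p}" for p in sorted(self.extra)]
        labels += [f"resid:{p}" for p in sorted(self.resid)]
        return labels

    def as_vector(self) -> np.ndarray:
        vals = [
            self.genetic[k, l]
            for k in range(2 * self.n_pop)
            for l in range(k + 1)
        ]
        vals += [self.pe[p] for p in sorted(self.pe)]
        vals += [self.extra[p] for p in sorted(self.extra)]
        vals += [self.resid[p] for p in sorted(self.resid)]
        return np.array(vals)

    @classmethod
    def from_vector(cls, template: "VarianceComponents", vec) -> "VarianceComponents":
        vec = np.asarray(vec, dtype=float)
        P2 = 2 * template.n_pop
        G = np.zeros((P2, P2))
        i = 0
        for k in range(P2):
            for l in range(k + 1):
                G[k, l] = G[l, k] = vec[i]
                i += 1
        pe = {}
        for p in sorted(template.pe):
            pe[p] = float(vec[i]); i += 1
        extra = {}
        for p in sorted(template.extra):
            extra[p] = float(vec[i]); i += 1
        resid = {}
        for p in sorted(template.resid):
            resid[p] = float(vec[i]); i += 1
        return cls(template.populations, G, pe, extra, resid)

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            self.populations, self.genetic.copy(), dict(self.pe),
            dict(self.extra), dict(self.resid),
        )

    def is_positive_definite(self, tol: float = 0.0) -> bool:
        return bool(np.linalg.eigvalsh(self.genetic).min() > tol)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": self.parameter_labels(), "value": self.as_vector()}
        )


@dataclass
class Design:
    """Incidence structures of the assembled multi-population model."""

    populations: list[str]
    specs: dict[str, NationalModelSpec]
    ped: Pedigree
    y: np.ndarray
    record_pop: np.ndarray          # population code per record
    X: sparse.csr_matrix
    fixed_labels: list[tuple]
    C: sparse.csr_matrix
    extra_index: list[tuple[str, str]]   # (population, level)
    Pmat: sparse.csr_matrix
    pe_index: list[tuple[str, str]]      # (population, dam id)
    Zg: sparse.csr_matrix
    inbreeding: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_pop(self) -> int:
        return len(self.populations)

    @property
    def n_animals(self) -> int:
        return len(self.ped)

    @property
    def n_genetic(self) -> int:
        return 2 * self.n_pop * self.n_animals

    def full_incidence(self) -> sparse.csr_matrix:
        return sparse.hstack([self.X, self.C, self.Pmat, self.Zg], format="csr")

    def offsets(self) -> dict[str, slice]:
        n_f, n_c, n_p = self.X.shape[1], self.C.shape[1], self.Pmat.shape[1]
        return {
            "fixed": slice(0, n_f),
            "extra": slice(n_f, n_f + n_c),
            "pe": slice(n_f + n_c, n_f + n_c + n_p),
            "genetic": slice(n_f + n_c + n_p, n_f + n_c + n_p + self.n_genetic),
        }

    def genetic_matrix(self, solution: np.ndarray) -> np.ndarray:
        """Genetic part of a solution vector as (n_animals, 2*N_pop)."""
        g = solution[self.offsets()["genetic"]]
        return g.reshape(self.n_animals, 2 * self.n_pop)

    def records_of(self, pop: str) -> np.ndarray:
        return np.nonzero(self.record_pop == self.populations.index(pop))[0]

    def solutions_frame(self, solution: np.ndarray) -> pd.DataFrame:
        """Label a solution vector as (effect, level, population, value)."""
        rows = []
        off = self.offsets()
        for j, (p, factor, lv) in enumerate(self.fixed_labels):
            rows.append(("fixed", f"{factor}:{lv}" if factor != "intercept"
                         else "intercept", p, solution[j]))
        for j, (p, lv) in enumerate(self.extra_index):
            rows.append(("extra_random", lv, p, solution[off["extra"].start + j]))
        for j, (p, dam) in enumerate(self.pe_index):
            rows.append(("permanent_environment", dam, p,
                         solution[off["pe"].start + j]))
        U = self.genetic_matrix(solution)
        for a, animal in enumerate(self.ped.ids):
            for pi, p in enumerate(self.populations):
                rows.append(("direct", animal, p, U[a, pi]))
                rows.append(("maternal", animal, p, U[a, self.n_pop + pi]))
        return pd.DataFrame(
            rows, columns=["effect", "level", "population", "value"]
        )


def build_design(phen: pd.DataFrame, ped: Pedigree,
                 specs: list[NationalModelSpec]) -> Design:
    """Build per-population incidence structures for a phenotype table.

    Direct and maternal genetic effects span the whole pedigree for every
    population; permanent environmental levels are the dams with records in
    populations fitting that effect; records with an unknown dam carry no
    maternal or permanent environmental incidence.
    """
    spec_of = {s.population: s for s in specs}
    pops = [s.population for s in specs]
    missing = set(phen["population"].unique()) - set(pops)
    if missing:
        raise ValueError(f"no national model spec for populations: {sorted(missing)}")

    n_rec = len(phen)
    animal_idx = np.array([ped.index_of[a] for a in phen["animal"]], dtype=np.int64)
    pop_code = np.array([pops.index(p) for p in phen["population"]], dtype=np.int64)

    dams = phen["dam"].fillna("").astype(str).to_numpy() if "dam" in phen else np.full(n_rec, "")
    dam_idx = np.full(n_rec, -1, dtype=np.int64)
    for r, d in enumerate(dams):
        if d and d != "0":
            if d not in ped.index_of:
                raise ValueError(f"record {phen['animal'].iloc[r]!r} cites dam {d!r} "
                                 "absent from pedigree")
            dam_idx[r] = ped.index_of[d]

    # --- fixed effects: per population, intercept + reference-constrained
    #     dummies for each categorical factor
    fixed_labels: list[tuple] = []
    x_rows, x_cols = [], []
    for pi, p in enumerate(pops):
        rows = np.nonzero(pop_code == pi)[0]
        col = len(fixed_labels)
        fixed_labels.append((p, "intercept", ""))
        x_rows.extend(rows.tolist())
        x_cols.extend([col] * len(rows))
        for factor in spec_of[p].fixed_effects:
            levels = sorted(pd.unique(phen[factor].iloc[rows].astype(str)))
            level_col = {lv: None for lv in levels}
            for lv in levels[1:]:  # first level is the reference
                level_col[lv] = len(fixed_labels)
                fixed_labels.append((p, factor, lv))
            vals = phen[factor].iloc[rows].astype(str).to_numpy()
            for r, lv in zip(rows, vals):
                c = level_col[lv]
                if c is not None:
                    x_rows.append(int(r))
                    x_cols.append(c)
    X = sparse.csr_matrix(
        (np.ones(len(x_rows)), (x_rows, x_cols)), shape=(n_rec, len(fixed_labels))
    )

    # --- extra national random environmental effects
    extra_index: list[tuple[str, str]] = []
    c_rows, c_cols = [], []
    for pi, p in enumerate(pops):
        col_name = spec_of[p].extra_random
        if col_name is None:
            continue
        rows = np.nonzero(pop_code == pi)[0]
        vals = phen[col_name].iloc[rows].fillna("").astype(str).to_numpy()
        level_col: dict[str, int] = {}
        for r, lv in zip(rows, vals):
            if lv == "":
                continue
            if lv not in level_col:
                level_col[lv] = len(extra_index)
                extra_index.append((p, lv))
            c_rows.append(int(r))
            c_cols.append(level_col[lv])
    C = sparse.csr_matrix(
        (np.ones(len(c_rows)), (c_rows, c_cols)),
        shape=(n_rec, max(len(extra_index), 0)),
    )

    # --- maternal permanent environment: one level per (population, dam)
    pe_index: list[tuple[str, str]] = []
    p_rows, p_cols = [], []
    for pi, p in enumerate(pops):
        if not spec_of[p].has_pe:
            continue
        rows = np.nonzero((pop_code == pi) & (dam_idx >= 0))[0]
        level_col = {}
        for r in rows:
            d = ped.ids[dam_idx[r]]
            if d not in level_col:
                level_col[d] = len(pe_index)
                pe_index.append((p, d))
            p_rows.append(int(r))
            p_cols.append(level_col[d])
    Pmat = sparse.csr_matrix(
        (np.ones(len(p_rows)), (p_rows, p_cols)),
        shape=(n_rec, max(len(pe_index), 0)),
    )

    # --- genetic incidence, animal-major columns
    n_pop = len(pops)
    width = 2 * n_pop
    g_rows = list(range(n_rec))
    g_cols = (animal_idx * width + pop_code).tolist()
    m_mask = dam_idx >= 0
    g_rows += np.nonzero(m_mask)[0].tolist()
    g_cols += (dam_idx[m_mask] * width + n_pop + pop_code[m_mask]).tolist()
    Zg = sparse.csr_matrix(
        (np.ones(len(g_rows)), (g_rows, g_cols)),
        shape=(n_rec, width * len(ped)),
    )

    return Design(
        populations=pops,
        specs=spec_of,
        ped=ped,
        y=phen["value"].to_numpy(dtype=float),
        record_pop=pop_code,
        X=X,
        fixed_labels=fixed_labels,
        C=C,
        extra_index=extra_index,
        Pmat=Pmat,
        pe_index=pe_index,
        Zg=Zg,
        inbreeding=inbreeding_coefficients(ped),
    )


@dataclass
class MMESystem:
    """Assembled mixed-model equations."""

    coefficient: sparse.csr_matrix
    rhs: np.ndarray
    effect_map: dict[str, slice]

    @property
    def n_equations(self) -> int:
        return self.coefficient.shape[0]


def _prior_diagonals(design: Design, vc: VarianceComponents) -> np.ndarray:
    d = np.zeros(design.C.shape[1] + design.Pmat.shape[1])
    for j, (p, _lv) in enumerate(design.extra_index):
        d[j] = 1.0 / vc.extra[p]
    off = design.C.shape[1]
    for j, (p, _dam) in enumerate(design.pe_index):
        d[off + j] = 1.0 / vc.pe[p]
    return d


def assemble_mme(design: Design, A_inv: RelationshipInverse,
                 vc: VarianceComponents) -> MMESystem:
    """Single-residual-weight mixed-model equations with rows scaled by the
    population-specific residual variances and the genetic prior
    ``A^-1 (x) G0^-1`` added to the animal-major genetic block."""
    try:
        L = np.linalg.cholesky(vc.genetic)
        G_inv = np.linalg.inv(vc.genetic)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "genetic covariance matrix is singular or not positive definite; "
            "add a small ridge to the starting values or restart (no "
            "automatic bending is applied)"
        ) from exc
    del L
    r_inv = np.array([1.0 / vc.resid[design.populations[c]] for c in design.record_pop])
    T = design.full_incidence()
    TtR = T.T.multiply(r_inv).tocsr()
    coef = (TtR @ T).tocsr()
    rhs = TtR @ design.y

    off = design.offsets()
    n_eq = coef.shape[0]
    prior = np.zeros(n_eq)
    n_f = design.X.shape[1]
    block = _prior_diagonals(design, vc)
    prior[n_f:n_f + len(block)] = block
    coef = coef + sparse.diags(prior, format="csr")

    g0 = off["genetic"].start
    kron = sparse.kron(A_inv.entries, sparse.csr_matrix(G_inv), format="coo")
    embedded = sparse.coo_matrix(
        (kron.data, (kron.row + g0, kron.col + g0)), shape=(n_eq, n_eq)
    ).tocsr()
    coef = coef + embedded
    return MMESystem(coefficient=coef.tocsr(), rhs=rhs, effect_map=off)


class BlockJacobiPreconditioner:
    """Preconditioner inverting the contiguous within-animal genetic blocks
    exactly and the remaining equations by their diagonal."""

    def __init__(self, start: int, scalar_inv: np.ndarray,
                 block_inv: np.ndarray, width: int):
        self.start = start
        self.scalar_inv = scalar_inv
        self.block_inv = block_inv
        self.width = width

    @classmethod
    def from_parts(cls, system: "MMESystem", width: int,
                   A_inv_diag: np.ndarray, G_inv: np.ndarray,
                   ) -> "BlockJacobiPreconditioner":
        """Fast construction exploiting that the only within-animal
        off-diagonal coupling comes from the A^-1 (x) G0^-1 prior."""
        start = system.effect_map["genetic"].start
        diag = system.coefficient.diagonal()
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError(
                "non-positive diagonal in the coefficient matrix"
            )
        blocks = A_inv_diag[:, None, None] * G_inv[None, :, :]
        gdiag = diag[start:].reshape(-1, width)
        idx = np.arange(width)
        blocks[:, idx, idx] = gdiag
        return cls(start, 1.0 / diag[:start], np.linalg.inv(blocks), width)

    def apply(self, r: np.ndarray) -> np.ndarray:
        z = np.empty_like(r)
        z[: self.start] = self.scalar_inv * r[: self.start]
        rg = r[self.start:].reshape(-1, self.width, 1)
        z[self.start:] = (self.block_inv @ rg).ravel()
        return z


class _JacobiPreconditioner:
    def __init__(self, diag: np.ndarray):
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive diagonal in the coefficient matrix")
        self.m_inv = 1.0 / diag

    def apply(self, r: np.ndarray) -> np.ndarray:
        return self.m_inv * r


def solve_pcg(system: MMESystem, tol: float = 1e-5, max_iter: int = 1000,
              x0: np.ndarray | None = None,
              preconditioner=None) -> tuple[np.ndarray, int, float]:
    """Preconditioned conjugate gradient (Jacobi preconditioner by default,
    or a supplied block preconditioner).

    The convergence criterion is the square root of the relative squared
    difference between the solutions of consecutive iterations,
    ``sqrt(sum((x_t - x_{t-1})^2) / sum(x_t^2))``; iteration stops when it
    falls below ``tol`` or after ``max_iter`` iterations.

    Returns ``(solution, iterations, achieved_criterion)``.
    """
    A = system.coefficient
    b = system.rhs
    n = len(b)
    if preconditioner is None:
        preconditioner = _JacobiPreconditioner(A.diagonal())
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    r = b - A @ x
    z = preconditioner.apply(r)
    p = z.copy()
    rz = r @ z
    crit = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        Ap = A @ p
        denom = p @ Ap
        if denom <= 0 or not np.isfinite(denom):
            raise np.linalg.LinAlgError(
                f"PCG breakdown at iteration {it}: curvature {denom!r}"
            )
        alpha = rz / denom
        dx = alpha * p
        x = x + dx
        xx = x @ x
        crit = np.sqrt((dx @ dx) / xx) if xx > 0 else 0.0
        if not np.isfinite(crit):
            raise np.linalg.LinAlgError(f"non-finite convergence criterion at {it}")
        if crit < tol:
            break
        r = r - alpha * Ap
        z = preconditioner.apply(r)
        rz_new = r @ z
        if rz_new <= 0:   # exact solution reached (up to roundoff)
            crit = 0.0
            break
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, it, crit


def simulate_genetic_effects(ped: Pedigree, genetic: np.ndarray,
                             rng: np.random.Generator,
                             inbreeding: np.ndarray | None = None) -> np.ndarray:
    """Draw (n_animals, 2*N_pop) genetic effects with covariance
    ``A (x) G0`` by pedigree recursion.

    Each animal is parent average plus Mendelian sampling, the within-animal
    2*N_pop covariance factorized once; sampling variances are adjusted for
    parental inbreeding.
    """
    eig = np.linalg.eigvalsh(genetic)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError("genetic covariance matrix is not positive semi-definite")
    w, V = np.linalg.eigh(genetic)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    if inbreeding is None:
        inbreeding = inbreeding_coefficients(ped)
    dvar = _mendelian_variances(ped, inbreeding)
    n, k = len(ped), genetic.shape[0]
    z = rng.standard_normal((n, k))
    U = np.zeros((n, k))
    sd = np.sqrt(dvar)
    ms = z @ L.T
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pa = np.zeros(k)
        if s >= 0:
            pa += 0.5 * U[s]
        if d >= 0:
            pa += 0.5 * U[d]
        U[i] = pa + sd[i] * ms[i]
    return U


def simulate_from_model(design: Design, ped: Pedigree, vc: VarianceComponents,
                        rng: np.random.Generator,
                        fixed_effects: np.ndarray | None = None,
                        ) -> tuple[np.ndarray, dict]:
    """Simulate a phenotype vector under the model and current variance
    components.

    Fixed effects are zero unless a coefficient vector is supplied (BLUP of
    the random effects is invariant to their true values, so zero is the
    Monte Carlo convention).  Returns ``(y_star, truth)`` where ``truth``
    holds every simulated effect and the full solution-ordered vector.
    """
    U = simulate_genetic_effects(ped, vc.genetic, rng, design.inbreeding)
    extra = np.array(
        [rng.normal(0.0, np.sqrt(vc.extra[p])) for p, _ in design.extra_index]
    )
    pe = np.array(
        [rng.normal(0.0, np.sqrt(vc.pe[p])) for p, _ in design.pe_index]
    )
    resid_sd = np.array(
        [np.sqrt(vc.resid[design.populations[c]]) for c in design.record_pop]
    )
    e = rng.standard_normal(design.n_records) * resid_sd
    b = (
        np.zeros(design.X.shape[1])
        if fixed_effects is None
        else np.asarray(fixed_effects, dtype=float)
    )
    theta = np.concatenate([b, extra, pe, U.ravel()])
    y_star = design.full_incidence() @ theta + e
    return y_star, {"u": U, "extra": extra, "pe": pe, "e": e, "theta": theta}
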