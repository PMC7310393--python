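"""Monte Carlo EM REML variance component estimation.

Each REML round performs two steps: BLUP solutions of the mixed-model
equations for the real data, and BLUP solutions for one or more datasets
simulated under the model at the current parameter values.  Components are
then updated from the sums of squares of the real-data solutions plus a
Monte Carlo estimate of the prediction-error contribution, obtained as the
average over simulated datasets of (true sum of squares minus estimated sum
of squares):

    G0[k,l] <- [u_k' A^-1 u_l + mean_s(u*_k' A^-1 u*_l - u^*_k' A^-1 u^*_l)] / q

with q the pedigree size; scalar components (permanent environment, extra
national random effects, residuals) update analogously with identity metric
and their level or record counts.

Convergence is monitored by the least-squares slope of each component over
the last rounds; sampling (co)variances of the estimates are approximated in
one extra round from many simulated datasets via Louis' missing-information
identity, and correlation standard errors follow by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    BlockJacobiPreconditioner,
    Design,
    NationalModelSpec,
    VarianceComponents,
    assemble_mme,
    build_design,
    simulate_from_model,
    solve_pcg,
)
from .pedigree import Pedigree, RelationshipInverse, build_A_inverse

__all__ = [
    "REMLSettings",
    "REMLTrajectory",
    "CorrelationSummary",
    "StandardErrorResult",
    "em_update",
    "genetic_block_update",
    "scalar_variance_update",
    "run_mcem_reml",
    "check_vce_convergence",
    "approximate_se",
    "genetic_correlations",
    "summarize_rg",
    "summary_difference",
    "read_correlation_table",
    "write_correlation_table",
]


@dataclass
class REMLSettings:
    """Algorithm settings.

    Defaults follow routine international-evaluation practice: at most 1000
    PCG iterations at tolerance 1e-5, one simulated dataset per REML round, a
    1e-9 slope criterion for variance-component convergence, and 500
    simulated datasets (with unlimited PCG iterations) in the standard-error
    round.

    On small datasets the per-round Monte Carlo noise is proportionally much
    larger than at the million-record scale these defaults come from; raise
    ``n_sim_per_round`` and report the mean of the last ``average_last``
    rounds (iterate averaging) to damp the resulting random walk of the
    estimates.
    """

    pcg_max_iter: int = 1000
    pcg_tol: float = 1e-5
    n_sim_per_round: int = 1
    vce_slope_tol: float = 1e-9
    slope_window: int = 100
    max_rounds: int = 500
    se_n_sim: int = 500
    average_last: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope_window < 2:
            raise ValueError("slope_window must be >= 2")
        for name in ("pcg_max_iter", "pcg_tol", "n_sim_per_round", "vce_slope_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class REMLTrajectory:
    """Per-round record of a variance-component estimation run."""

    labels: list[str]
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    pcg_diagnostics: list[dict] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    converged: bool = False
    final_slope: float = np.nan
    n_bent_rounds: int = 0

    @property
    def rounds_run(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        if self.rounds_run == 0:
            return pd.DataFrame(columns=["round", "component", "value"])
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "round", np.arange(1, self.rounds_run + 1))
        return df.melt(id_vars="round", var_name="component", value_name="value")


# ---------------------------------------------------------------------------
# EM update
# ---------------------------------------------------------------------------

def genetic_block_update(U_hat: np.ndarray, sim_pairs, A_inv, q: int | None = None,
                         ) -> np.ndarray:
    """EM update of the genetic covariance block.

    ``U_hat`` is the (q x k) matrix of real-data BLUPs; ``sim_pairs`` is a
    list of ``(U_true, U_blup)`` matrices from simulated datasets; ``A_inv``
    the sparse relationship inverse.  When the simulated BLUPs equal the
    simulated true effects the Monte Carlo correction vanishes and the
    update is the no-shrinkage limit ``U_hat' A^-1 U_hat / q``.
    """
    U_hat = np.atleast_2d(np.asarray(U_hat, dtype=float))
    if q is None:
        q = U_hat.shape[0]
    S = U_hat.T @ (A_inv @ U_hat)
    if sim_pairs:
        corr = np.zeros_like(S)
        for U_true, U_blup in sim_pairs:
            U_true = np.atleast_2d(np.asarray(U_true, dtype=float))
            U_blup = np.atleast_2d(np.asarray(U_blup, dtype=float))
            corr += U_true.T @ (A_inv @ U_true) - U_blup.T @ (A_inv @ U_blup)
        S = S + corr / len(sim_pairs)
    S = S / q
    return (S + S.T) / 2.0


def scalar_variance_update(real_sum_sq: float, sim_sums, n_levels: int) -> float:
    """EM update of an i.i.d. variance component from its sums of squares.

    ``sim_sums`` is a list of ``(true_sum_sq, blup_sum_sq)`` pairs from the
    simulated datasets.
    """
    corr = 0.0
    if sim_sums:
        corr = sum(t - b for t, b in sim_sums) / len(sim_sums)
    return (real_sum_sq + corr) / n_levels


def _residuals_by_pop(design: Design, solution: np.ndarray, y: np.ndarray,
                      ) -> dict[str, float]:
    e = y - design.full_incidence() @ solution
    return {
        p: float(e[design.records_of(p)] @ e[design.records_of(p)])
        for p in design.populations
    }


def em_update(design: Design, A_inv: RelationshipInverse, vc: VarianceComponents,
              real_solution: np.ndarray, sim_results: list[dict],
              ) -> VarianceComponents:
    """One full MC EM REML update of every variance component.

    ``sim_results`` entries are dicts with keys ``truth`` (the simulation
    ledger), ``solution`` (the BLUP solution of the simulated data) and
    ``y`` (the simulated records).
    """
    A = A_inv.entries
    q = len(design.ped)
    U_hat = design.genetic_matrix(real_solution)
    pairs = [
        (s["truth"]["u"], design.genetic_matrix(s["solution"])) for s in sim_results
    ]
    G_new = genetic_block_update(U_hat, pairs, A, q)

    off = design.offsets()
    pe_new, extra_new = {}, {}
    for kind, index, sl, store in (
        ("pe", design.pe_index, off["pe"], pe_new),
        ("extra", design.extra_index, off["extra"], extra_new),
    ):
        pops = sorted({p for p, _ in index})
        real = real_solution[sl]
        for p in pops:
            mask = np.array([pp == p for pp, _ in index])
            n_lev = int(mask.sum())
            real_ss = float(real[mask] @ real[mask])
            sims = []
            for s in sim_results:
                t = s["truth"][kind][mask]
                bl = s["solution"][sl][mask]
                sims.append((float(t @ t), float(bl @ bl)))
            store[p] = scalar_variance_update(real_ss, sims, n_lev)

    resid_new = {}
    real_res = _residuals_by_pop(design, real_solution, design.y)
    sim_res = [
        (
            {p: float(s["truth"]["e"][design.records_of(p)]
                      @ s["truth"]["e"][design.records_of(p)])
             for p in design.populations},
            _residuals_by_pop(design, s["solution"], s["y"]),
        )
        for s in sim_results
    ]
    for p in design.populations:
        n_rec = len(design.records_of(p))
        sims = [(t[p], b[p]) for t, b in sim_res]
        resid_new[p] = scalar_variance_update(real_res[p], sims, n_rec)

    return VarianceComponents(vc.populations, G_new, pe_new, extra_new, resid_new)


def _clip_to_psd(G: np.ndarray, rel_floor: float = 1e-8) -> tuple[np.ndarray, bool]:
    w, V = np.linalg.eigh(G)
    floor = rel_floor * max(w.max(), 1e-30)
    if w.min() > floor:
        return G, False
    w = np.clip(w, floor, None)
    return (V * w) @ V.T, True


def check_vce_convergence(values: np.ndarray | REMLTrajectory,
                          settings: REMLSettings) -> tuple[bool, float]:
    """Slope-based convergence check.

    For each component, the least-squares slope over the last
    ``slope_window`` rounds is standardized by the absolute window mean of
    that component; convergence is reached when the largest standardized
    slope magnitude falls below ``vce_slope_tol``.  Returns
    ``(converged, worst_slope)``; with fewer rounds than the window the
    check reports not-converged with a NaN slope.
    """
    if isinstance(values, REMLTrajectory):
        values = values.values
    w = settings.slope_window
    if values.shape[0] < w:
        return False, np.nan
    window = values[-w:]
    t = np.arange(w, dtype=float)
    t = t - t.mean()
    denom = float(t @ t)
    slopes = (t @ (window - window.mean(axis=0))) / denom
    scale = np.maximum(np.abs(window.mean(axis=0)), 1e-12)
    worst = float(np.max(np.abs(slopes / scale)))
    return worst < settings.vce_slope_tol, worst


def run_mcem_reml(phen: pd.DataFrame, ped: Pedigree,
                  specs: list[NationalModelSpec], start_vc: VarianceComponents,
                  settings: REMLSettings,
                  design: Design | None = None,
                  A_inv: RelationshipInverse | None = None,
                  ) -> tuple[VarianceComponents, REMLTrajectory]:
    """Run MC EM REML to convergence (or ``max_rounds``).

    Fully reproducible given ``settings.seed``: every simulated replicate
    draws from an independent, logged random stream.  Intermediate genetic
    matrices that drift off the positive-definite cone are projected back by
    eigenvalue clipping (a numerical guard only; the reported final-round
    estimate is never bent).
    """
    if design is None:
        design = build_design(phen, ped, specs)
    if A_inv is None:
        A_inv = build_A_inverse(ped)
    vc = start_vc.copy()
    traj = REMLTrajectory(labels=vc.parameter_labels())
    rows: list[np.ndarray] = []
    x_real = None
    x_sim = None
    T = design.full_incidence()
    width = 2 * len(design.populations)
    A_diag = A_inv.entries.diagonal()
    for rnd in range(1, settings.max_rounds + 1):
        system = assemble_mme(design, A_inv, vc)
        precond = BlockJacobiPreconditioner.from_parts(
            system, width, A_diag, np.linalg.inv(vc.genetic)
        )
        r_inv = np.array(
            [1.0 / vc.resid[design.populations[c]] for c in design.record_pop]
        )
        TtR = T.T.multiply(r_inv).tocsr()
        x_real, it_r, cc_r = solve_pcg(
            system, settings.pcg_tol, settings.pcg_max_iter, x0=x_real,
            preconditioner=precond,
        )
        sims = []
        its = []
        for s in range(settings.n_sim_per_round):
            rng = np.random.default_rng((settings.seed, rnd, s))
            y_star, truth = simulate_from_model(design, ped, vc, rng)
            sim_system = MMELike(system.coefficient, TtR @ y_star, system.effect_map)
            x_sim, it_s, _ = solve_pcg(
                sim_system, settings.pcg_tol, settings.pcg_max_iter, x0=x_sim,
                preconditioner=precond,
            )
            sims.append({"truth": truth, "solution": x_sim, "y": y_star})
            its.append(it_s)
        vc_raw = em_update(design, A_inv, vc, x_real, sims)
        rows.append(vc_raw.as_vector())
        traj.values = np.vstack(rows)
        traj.pcg_diagnostics.append(
            {"round": rnd, "pcg_iter_real": it_r, "pcg_crit_real": cc_r,
             "pcg_iter_sim": its}
        )
        traj.seeds.append(rnd)
        G_next, bent = _clip_to_psd(vc_raw.genetic)
        if bent:
            traj.n_bent_rounds += 1
            warnings.warn(
                f"round {rnd}: genetic matrix projected to the PSD cone "
                "(numerical guard)", RuntimeWarning, stacklevel=2,
            )
        vc = VarianceComponents(
            vc_raw.populations, G_next, vc_raw.pe, vc_raw.extra, vc_raw.resid
        )
        converged, worst = check_vce_convergence(traj.values, settings)
        traj.final_slope = worst
        if converged:
            traj.converged = True
            break
    if rows:
        k = max(1, min(settings.average_last, len(rows)))
        final = VarianceComponents.from_vector(
            vc, np.mean(rows[-k:], axis=0)
        )
    else:
        final = start_vc.copy()
    return final, traj


# ---------------------------------------------------------------------------
# Standard errors (Louis' missing-information identity)
# ---------------------------------------------------------------------------

@dataclass
class StandardErrorResult:
    labels: list[str]
    covariance: np.ndarray
    se: np.ndarray
    rg_se: np.ndarray
    used_pseudo_inverse: bool = False

    def se_of(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])


def _genetic_param_layout(n_eff: int) -> list[tuple[int, int]]:
    return [(k, l) for k in range(n_eff) for l in range(k + 1)]


def _score_vector(vc: VarianceComponents, design: Design, S_g: np.ndarray,
                  pe_ss: dict, extra_ss: dict, resid_ss: dict) -> np.ndarray:
    """Complete-data score at the current parameters, given the sufficient
    statistics of one (conditional) draw of all random effects."""
    G_inv = np.linalg.inv(vc.genetic)
    q = len(design.ped)
    M = G_inv @ S_g @ G_inv - q * G_inv
    layout = _genetic_param_layout(2 * vc.n_pop)
    score = [0.5 * (2.0 if k != l else 1.0) * M[k, l] for k, l in layout]
    for p in sorted(vc.pe):
        n = sum(1 for pp, _ in design.pe_index if pp == p)
        s2 = vc.pe[p]
        score.append(pe_ss[p] / (2 * s2 ** 2) - n / (2 * s2))
    for p in sorted(vc.extra):
        n = sum(1 for pp, _ in design.extra_index if pp == p)
        s2 = vc.extra[p]
        score.append(extra_ss[p] / (2 * s2 ** 2) - n / (2 * s2))
    for p in sorted(vc.resid):
        n = len(design.records_of(p))
        s2 = vc.resid[p]
        score.append(resid_ss[p] / (2 * s2 ** 2) - n / (2 * s2))
    return np.array(score)


def approximate_se(phen: pd.DataFrame, ped: Pedigree,
                   specs: list[NationalModelSpec], final_vc: VarianceComponents,
                   settings: REMLSettings,
                   design: Design | None = None,
                   A_inv: RelationshipInverse | None = None,
                   ) -> StandardErrorResult:
    """Approximate sampling (co)variances of the variance components and
    delta-method standard errors of the genetic correlations.

    One extra round is run with ``se_n_sim`` simulated datasets (PCG
    iterations unlimited).  For each replicate the observed-data REML score
    equals the conditional expectation of the complete-data score given that
    replicate — the complete-data score evaluated at the replicate's BLUP
    sufficient statistics, up to an additive constant that is identical for
    every replicate.  The Fisher information is the sampling variance of the
    observed-data score, so the empirical covariance of these per-replicate
    score vectors (in which the constant cancels) estimates the information
    matrix; its inverse is the sampling covariance of the estimates.
    """
    if design is None:
        design = build_design(phen, ped, specs)
    if A_inv is None:
        A_inv = build_A_inverse(ped)
    vc = final_vc
    A = A_inv.entries
    system = assemble_mme(design, A_inv, vc)
    precond = BlockJacobiPreconditioner.from_parts(
        system, 2 * len(design.populations), A_inv.entries.diagonal(),
        np.linalg.inv(vc.genetic),
    )
    off = design.offsets()
    T = design.full_incidence()
    r_inv = np.array(
        [1.0 / vc.resid[design.populations[c]] for c in design.record_pop]
    )
    TtR = T.T.multiply(r_inv).tocsr()

    scores = []
    x_sim = None
    for s in range(settings.se_n_sim):
        rng = np.random.default_rng((settings.seed, 10 ** 6, s))
        y_star, _truth = simulate_from_model(design, ped, vc, rng)
        sim_system = MMELike(system.coefficient, TtR @ y_star, system.effect_map)
        x_sim, _, _ = solve_pcg(
            sim_system, settings.pcg_tol, max_iter=max(settings.pcg_max_iter, 100000),
            x0=x_sim, preconditioner=precond,
        )
        U_b = design.genetic_matrix(x_sim)
        pe_b = x_sim[off["pe"]]
        extra_b = x_sim[off["extra"]]
        e_b = y_star - T @ x_sim

        S_g = U_b.T @ (A @ U_b)
        pe_ss = {
            p: float(np.sum(pe_b[[i for i, (pp, _) in enumerate(design.pe_index)
                                  if pp == p]] ** 2))
            for p in sorted(vc.pe)
        }
        extra_ss = {
            p: float(np.sum(extra_b[[i for i, (pp, _) in
                                     enumerate(design.extra_index) if pp == p]] ** 2))
            for p in sorted(vc.extra)
        }
        resid_ss = {
            p: float(np.sum(e_b[design.records_of(p)] ** 2))
            for p in sorted(vc.resid)
        }
        scores.append(_score_vector(vc, design, S_g, pe_ss, extra_ss, resid_ss))

    score_mat = np.vstack(scores)
    info = np.cov(score_mat, rowvar=False, ddof=1)
    used_pinv = False
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError("negative sampling variance")
    except np.linalg.LinAlgError:
        warnings.warn(
            "information matrix singular or indefinite; using pseudo-inverse",
            RuntimeWarning, stacklevel=2,
        )
        cov = np.linalg.pinv(info)
        used_pinv = True

    labels = vc.parameter_labels()
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    rg_se = _correlation_se(vc, cov)
    return StandardErrorResult(labels, cov, se, rg_se, used_pinv)


class MMELike:
    """Lightweight system sharing a coefficient matrix with a new RHS."""

    def __init__(self, coefficient, rhs, effect_map):
        self.coefficient = coefficient
        self.rhs = rhs
        self.effect_map = effect_map


def _correlation_se(vc: VarianceComponents, cov: np.ndarray) -> np.ndarray:
    """Delta-method standard errors of r_kl = s_kl / sqrt(s_kk s_ll)."""
    n_eff = 2 * vc.n_pop
    layout = _genetic_param_layout(n_eff)
    pos = {kl: i for i, kl in enumerate(layout)}
    G = vc.genetic
    out = np.zeros((n_eff, n_eff))
    for k in range(n_eff):
        for l in range(k):
            skk, sll, skl = G[k, k], G[l, l], G[k, l]
            r = skl / np.sqrt(skk * sll)
            idx = [pos[(k, l)], pos[(k, k)], pos[(l, l)]]
            grad = np.array(
                [1.0 / np.sqrt(skk * sll), -r / (2 * skk), -r / (2 * sll)]
            )
            sub = cov[np.ix_(idx, idx)]
            var = float(grad @ sub @ grad)
            out[k, l] = out[l, k] = np.sqrt(max(var, 0.0))
    return out


# ---------------------------------------------------------------------------
# Correlations and block summaries
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    """Genetic correlation matrix over (direct, maternal) x population
    effects, optional matching standard errors and heritabilities."""

    populations: list[str]
    rg: np.ndarray
    se: np.ndarray | None = None
    heritability: np.ndarray | None = None
    positive_definite: bool | None = None

    @property
    def n_pop(self) -> int:
        return len(self.populations)

    def effect_labels(self) -> list[str]:
        return [f"direct_{p}" for p in self.populations] + [
            f"maternal_{p}" for p in self.populations
        ]


def genetic_correlations(vc: VarianceComponents) -> CorrelationSummary:
    """Correlations r_kl = s_kl / sqrt(s_kk s_ll) from the genetic matrix;
    positive definiteness is checked and reported, never enforced."""
    d = np.diag(vc.genetic)
    if np.any(d <= 0):
        raise ValueError("nonpositive genetic variance on the diagonal")
    inv_sd = 1.0 / np.sqrt(d)
    rg = vc.genetic * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(rg, 1.0)
    return CorrelationSummary(
        populations=vc.populations,
        rg=rg,
        positive_definite=bool(np.linalg.eigvalsh(vc.genetic).min() > 0),
    )


def _blocks(M: np.ndarray, n_pop: int) -> dict[str, np.ndarray]:
    direct = np.array([M[k, l] for k in range(n_pop) for l in range(k)])
    maternal = np.array(
        [M[n_pop + k, n_pop + l] for k in range(n_pop) for l in range(k)]
    )
    within = np.array([M[n_pop + i, i] for i in range(n_pop)])
    between = np.array(
        [M[n_pop + i, j] for i in range(n_pop) for j in range(n_pop) if i != j]
    )
    return {
        "direct": direct,
        "maternal": maternal,
        "direct_maternal_within": within,
        "direct_maternal_between": between,
    }


def summarize_rg(summary: CorrelationSummary) -> pd.DataFrame:
    """Mean/min/max per correlation block (direct-direct, maternal-maternal,
    direct-maternal within- and between-country), with the same statistics
    for the standard errors when present."""
    rows = []
    rg_blocks = _blocks(summary.rg, summary.n_pop)
    se_blocks = (
        _blocks(summary.se, summary.n_pop) if summary.se is not None else None
    )
    for name, vals in rg_blocks.items():
        row = {
            "block": name,
            "n": len(vals),
            "rg_mean": float(np.mean(vals)),
            "rg_min": float(np.min(vals)),
            "rg_max": float(np.max(vals)),
        }
        if se_blocks is not None:
            sv = se_blocks[name]
            row.update(
                se_mean=float(np.mean(sv)),
                se_min=float(np.min(sv)),
                se_max=float(np.max(sv)),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("block")


def summary_difference(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Element-wise a - b of two block-summary tables (scenario minus
    baseline), excluding the count column."""
    cols = [c for c in a.columns if c != "n"]
    return a[cols] - b[cols]


def read_correlation_table(path, populations: list[str] | None = None,
                           ) -> CorrelationSummary:
    """Read a labeled matrix CSV in the conventional published layout:
    correlations below the diagonal, standard errors above, heritabilities
    on the diagonal."""
    df = pd.read_csv(path, index_col=0)
    labels = list(df.index)
    if list(df.columns) != labels:
        raise ValueError("correlation table rows and columns must match")
    n = len(labels)
    if populations is None:
        populations = [lb.split("_", 1)[1] for lb in labels[: n // 2]]
    M = df.to_numpy(dtype=float)
    rg = np.eye(n)
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            rg[i, j] = rg[j, i] = M[i, j]
            se[i, j] = se[j, i] = M[j, i]
    return CorrelationSummary(
        populations=populations, rg=rg, se=se, heritability=np.diag(M).copy()
    )


def write_correlation_table(summary: CorrelationSummary, path) -> None:
    """Write the published layout: correlations below, SEs above,
    heritabilities (when available) on the diagonal."""
    n = 2 * summary.n_pop
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            M[i, j] = summary.rg[i, j]
            M[j, i] = summary.se[i, j] if summary.se is not None else np.nan
    np.fill_diagonal(
        M, summary.heritability if summary.heritability is not None else 1.0
    )
    labels = summary.effect_labels()
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path)
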