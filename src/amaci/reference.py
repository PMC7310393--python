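"""Dense reference computations for small problems.

Everything here deliberately uses explicit dense linear algebra — the
tabular-method relationship matrix, the phenotypic covariance matrix ``V``,
the restricted log-likelihood, and the exact EM update with analytic trace
terms from the full inverse of the mixed-model equations.  These routines
are quadratic-to-cubic in problem size and exist to validate the sparse and
Monte Carlo production paths on instances of up to a few hundred animals.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .model import Design, VarianceComponents
from .pedigree import Pedigree

__all__ = [
    "tabular_A",
    "phenotypic_covariance",
    "reml_loglik",
    "dense_mme",
    "exact_em_update",
    "reml_hessian_covariance",
]

_DENSE_LIMIT = 2000


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    A[i,i] = 1 + 0.5 A[s,d]; A[i,j] = 0.5 (A[j,s] + A[j,d]) for j preceding i
    in topological order.
    """
    n = len(ped)
    if n > _DENSE_LIMIT:
        raise ValueError(f"tabular method limited to {_DENSE_LIMIT} animals")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def _scalar_prior_diagonals(design: Design, vc: VarianceComponents) -> np.ndarray:
    d = []
    d += [vc.extra[p] for p, _ in design.extra_index]
    d += [vc.pe[p] for p, _ in design.pe_index]
    return np.array(d, dtype=float)


def phenotypic_covariance(design: Design, A: np.ndarray,
                          vc: VarianceComponents) -> np.ndarray:
    """Dense covariance matrix of the records:
    V = Zg (A (x) G0) Zg' + C D_r C' + P D_pe P' + R."""
    # each record touches at most two genetic effects: (animal, direct_p)
    # and (dam, maternal_p); gather the four cross blocks directly instead
    # of forming the (2*P*q)^2 Kronecker product
    n_pop = len(design.populations)
    coo = design.Zg.tocoo()
    n = design.n_records
    a_idx = np.full(n, -1, dtype=np.int64)
    e_idx = np.zeros(n, dtype=np.int64)
    d_idx = np.full(n, -1, dtype=np.int64)
    f_idx = np.zeros(n, dtype=np.int64)
    width = 2 * n_pop
    for r, c in zip(coo.row, coo.col):
        animal, eff = divmod(c, width)
        if eff < n_pop:
            a_idx[r], e_idx[r] = animal, eff
        else:
            d_idx[r], f_idx[r] = animal, eff
    G0 = vc.genetic
    V = A[np.ix_(a_idx, a_idx)] * G0[np.ix_(e_idx, e_idx)]
    m = d_idx >= 0
    if m.any():
        dm = np.nonzero(m)[0]
        V[np.ix_(dm, dm)] += (
            A[np.ix_(d_idx[dm], d_idx[dm])] * G0[np.ix_(f_idx[dm], f_idx[dm])]
        )
        V[:, dm] += A[np.ix_(a_idx, d_idx[dm])] * G0[np.ix_(e_idx, f_idx[dm])]
        V[dm, :] += A[np.ix_(d_idx[dm], a_idx)] * G0[np.ix_(f_idx[dm], e_idx)]
    scalars = _scalar_prior_diagonals(design, vc)
    if len(scalars):
        U = sparse.hstack([design.C, design.Pmat]).toarray()
        V += (U * scalars) @ U.T
    r = np.array([vc.resid[design.populations[c]] for c in design.record_pop])
    V[np.diag_indices_from(V)] += r
    return V


def reml_loglik(design: Design, A: np.ndarray, vc: VarianceComponents) -> float:
    """Restricted log-likelihood (constants omitted):
    -1/2 [ log|V| + log|X'V^-1 X| + y' P y ]."""
    V = phenotypic_covariance(design, A, vc)
    X = design.X.toarray()
    y = design.y
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = y @ Vi_y - (X.T @ Vi_y) @ beta
    return -0.5 * (logdet_v + logdet_x + yPy)


def dense_mme(design: Design, A: np.ndarray, vc: VarianceComponents,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Dense mixed-model equations (coefficient matrix and right-hand side),
    assembled independently of the sparse path."""
    T = design.full_incidence().toarray()
    r_inv = np.array(
        [1.0 / vc.resid[design.populations[c]] for c in design.record_pop]
    )
    coef = T.T * r_inv @ T
    rhs = T.T @ (r_inv * design.y)
    off = design.offsets()
    scalars = _scalar_prior_diagonals(design, vc)
    n_f = design.X.shape[1]
    for j, v in enumerate(scalars):
        coef[n_f + j, n_f + j] += 1.0 / v
    g0 = off["genetic"].start
    G_prior = np.kron(np.linalg.inv(A), np.linalg.inv(vc.genetic))
    coef[g0:, g0:] += G_prior
    return coef, rhs


def exact_em_update(design: Design, A: np.ndarray, vc: VarianceComponents,
                    ) -> VarianceComponents:
    """Exact EM update: the conditional expectations that MC EM REML
    approximates by simulation are evaluated analytically through the dense
    inverse of the mixed-model coefficient matrix."""
    coef, rhs = dense_mme(design, A, vc)
    C = np.linalg.inv(coef)
    sol = C @ rhs
    off = design.offsets()
    q = len(design.ped)
    n_eff = 2 * len(design.populations)
    A_inv = np.linalg.inv(A)

    U_hat = design.genetic_matrix(sol)
    g0 = off["genetic"].start
    Cg = C[g0:, g0:].reshape(q, n_eff, q, n_eff)
    # tr(A^-1 C_kl) with C_kl[a,b] = Cov(u_k[a], u_l[b] | y)
    trace_term = np.einsum("ab,bkal->kl", A_inv, Cg)
    G_new = (U_hat.T @ A_inv @ U_hat + trace_term) / q
    G_new = (G_new + G_new.T) / 2.0

    pe_new, extra_new = {}, {}
    for index, sl, store in (
        (design.pe_index, off["pe"], pe_new),
        (design.extra_index, off["extra"], extra_new),
    ):
        for p in sorted({pp for pp, _ in index}):
            idx = [sl.start + i for i, (pp, _) in enumerate(index) if pp == p]
            ss = float(sol[idx] @ sol[idx]) + float(np.sum(C[idx, idx]))
            store[p] = ss / len(idx)

    T = design.full_incidence().toarray()
    e_hat = design.y - T @ sol
    TCT_diag = np.einsum("ij,jk,ik->i", T, C, T)
    resid_new = {}
    for p in design.populations:
        rec = design.records_of(p)
        resid_new[p] = float(
            (e_hat[rec] @ e_hat[rec] + TCT_diag[rec].sum()) / len(rec)
        )
    return VarianceComponents(vc.populations, G_new, pe_new, extra_new, resid_new)


def variance_basis(design: Design, A: np.ndarray,
                   vc: VarianceComponents) -> list[np.ndarray]:
    """Basis matrices B_i such that V(theta) = sum_i theta_i B_i, in the
    flat parameter order of ``vc.parameter_labels()``.

    The phenotypic covariance is linear in every variance parameter, which
    makes dense score, Fisher-information and Fisher-scoring REML
    computations straightforward on small instances.
    """
    n = design.n_records
    n_pop = len(design.populations)
    width = 2 * n_pop
    q = len(design.ped)
    # per-effect incidence Z_e (records x animals); B_(k,l) = Z_k A Z_l' (+ sym)
    cols = np.arange(q) * width
    Z_eff = [design.Zg[:, cols + e] for e in range(width)]
    ZA = [Z.toarray() @ A for Z in Z_eff]

    basis: list[np.ndarray] = []
    for k in range(width):
        for l in range(k + 1):
            B = ZA[k] @ Z_eff[l].T.toarray()
            if k != l:
                B = B + B.T
            else:
                B = (B + B.T) / 2.0
            basis.append(np.ascontiguousarray(B))
    for p in sorted(vc.pe):
        idx = [i for i, (pp, _) in enumerate(design.pe_index) if pp == p]
        U = design.Pmat.toarray()[:, idx]
        basis.append(U @ U.T)
    for p in sorted(vc.extra):
        idx = [i for i, (pp, _) in enumerate(design.extra_index) if pp == p]
        U = design.C.toarray()[:, idx]
        basis.append(U @ U.T)
    for p in sorted(vc.resid):
        B = np.zeros((n, n))
        rec = design.records_of(p)
        B[rec, rec] = 1.0
        basis.append(B)
    return basis


def _projection(design: Design, V: np.ndarray) -> np.ndarray:
    X = design.X.toarray()
    Vi = np.linalg.inv(V)
    ViX = Vi @ X
    return Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)


def reml_score(design: Design, basis: list[np.ndarray],
               vc: VarianceComponents) -> np.ndarray:
    """REML score (gradient of the restricted log-likelihood) from the dense
    projection matrix, without forming the information matrix."""
    theta = vc.as_vector()
    V = sum(t * B for t, B in zip(theta, basis))
    P = _projection(design, V)
    Py = P @ design.y
    return np.array(
        [-0.5 * (np.sum(P * B.T) - Py @ B @ Py) for B in basis]
    )


def reml_fd_hessian(design: Design, basis: list[np.ndarray],
                    vc: VarianceComponents, rel_step: float = 1e-4,
                    ) -> np.ndarray:
    """Hessian of the restricted log-likelihood by central finite
    differences of the analytic score."""
    theta0 = vc.as_vector()
    k = len(theta0)
    G = vc.genetic
    n_eff = G.shape[0]
    scales = [
        np.sqrt(G[kk, kk] * G[ll, ll])
        for kk in range(n_eff) for ll in range(kk + 1)
    ]
    scales += [vc.pe[p] for p in sorted(vc.pe)]
    scales += [vc.extra[p] for p in sorted(vc.extra)]
    scales += [vc.resid[p] for p in sorted(vc.resid)]
    steps = rel_step * np.maximum(np.abs(theta0), 0.3 * np.abs(scales))
    H = np.zeros((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        sp = reml_score(design, basis,
                        VarianceComponents.from_vector(vc, theta0 + e))
        sm = reml_score(design, basis,
                        VarianceComponents.from_vector(vc, theta0 - e))
        H[:, i] = (sp - sm) / (2 * steps[i])
    return (H + H.T) / 2.0


def reml_score_fisher(design: Design, basis: list[np.ndarray],
                      vc: VarianceComponents,
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """REML score vector, expected (Fisher) information, and log-likelihood
    at the current parameters, from the dense projection matrix."""
    theta = vc.as_vector()
    V = sum(t * B for t, B in zip(theta, basis))
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return None, None, -np.inf
    X = design.X.toarray()
    P = _projection(design, V)
    y = design.y
    Py = P @ y
    Vi_X = np.linalg.solve(V, X)
    sign2, logdet_x = np.linalg.slogdet(X.T @ Vi_X)
    ll = -0.5 * (logdet_v + logdet_x + y @ Py)
    k = len(basis)
    PB = [P @ B for B in basis]
    score = np.array(
        [-0.5 * (np.trace(PB[i]) - Py @ basis[i] @ Py) for i in range(k)]
    )
    info = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * np.sum(PB[i] * PB[j].T)
    return score, info, float(ll)


def fit_reml_dense(design: Design, A: np.ndarray, start: VarianceComponents,
                   max_iter: int = 60, tol: float = 1e-8,
                   ) -> tuple[VarianceComponents, float, np.ndarray]:
    """Fisher-scoring REML on a small instance.

    Returns the estimate, its restricted log-likelihood, and the Fisher
    information at the optimum.  Step-halving keeps each iterate inside the
    positive-definite region.
    """
    basis = variance_basis(design, A, start)
    vc = start.copy()
    score, info, ll = reml_score_fisher(design, basis, vc)
    if ll == -np.inf:
        raise ValueError("starting values give a singular covariance matrix")
    for _ in range(max_iter):
        step = np.linalg.solve(info + 1e-10 * np.eye(len(score)), score)
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.02, 0.005):
            try:
                cand = VarianceComponents.from_vector(
                    vc, vc.as_vector() + damp * step
                )
                s2, i2, ll2 = reml_score_fisher(design, basis, cand)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if ll2 > ll - 1e-12 and np.isfinite(ll2):
                vc, score, info, ll_prev, ll = cand, s2, i2, ll, ll2
                improved = True
                break
        if not improved:
            break
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
    return vc, ll, info


def reml_hessian_covariance(design: Design, A: np.ndarray,
                            vc: VarianceComponents, rel_step: float = 1e-3,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Sampling covariance of the variance components from a central
    finite-difference Hessian of the restricted log-likelihood.

    Returns ``(covariance, se)`` in the flat parameter order of
    ``vc.parameter_labels()``.
    """
    theta0 = vc.as_vector()
    k = len(theta0)
    # scale steps by the natural size of each parameter: sqrt of the product
    # of the corresponding variances for covariance entries, the value itself
    # for variances — a parameter sitting at zero still gets a usable step
    G = vc.genetic
    n_eff = G.shape[0]
    scales = [
        np.sqrt(G[kk, kk] * G[ll, ll])
        for kk in range(n_eff) for ll in range(kk + 1)
    ]
    scales += [vc.pe[p] for p in sorted(vc.pe)]
    scales += [vc.extra[p] for p in sorted(vc.extra)]
    scales += [vc.resid[p] for p in sorted(vc.resid)]
    steps = rel_step * np.maximum(np.abs(theta0), 0.3 * np.abs(scales))

    def ll(theta):
        return reml_loglik(design, A, VarianceComponents.from_vector(vc, theta))

    H = np.zeros((k, k))
    f0 = ll(theta0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                f1 = ll(theta0 + ei)
                f2 = ll(theta0 - ei)
                H[i, i] = (f1 - 2 * f0 + f2) / steps[i] ** 2
            else:
                fpp = ll(theta0 + ei + ej)
                fpm = ll(theta0 + ei - ej)
                fmp = ll(theta0 - ei + ej)
                fmm = ll(theta0 - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                    4 * steps[i] * steps[j]
                )
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return cov, se
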