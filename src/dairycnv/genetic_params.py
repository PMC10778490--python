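"""Pedigree relationship matrix and animal-model REML variance components.

The model is the intercept-only animal model ``y = 1*mu + Z*a + e`` with
``var(a) = A * sigma_a^2`` (A the pedigree numerator relationship matrix) and
independent residuals.  Two traits — typically the same milk trait recorded in
two parities — are fitted jointly, giving the additive covariance matrix G,
the residual matrix R, and from them heritabilities and the genetic and
phenotypic correlations

    rA = Cov(a1, a2) / sqrt(sa1^2 * sa2^2)
    rP = Cov(P1, P2) / sqrt(sP1^2 * sP2^2),    P = G + R.

Estimation maximises the restricted likelihood by average-information (AI)
REML with step-halving and eigenvalue bending, warm-started with exact EM-REML
steps when both traits share a record set.  Convergence follows the study's
tolerances: update-vector norm < 1e-7 or gradient norm < 1e-6, applied on
internally standardised data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve


class PedigreeError(ValueError):
    pass


def _toposort(ids: list, sire: dict, dam: dict) -> list:
    """Order individuals so parents precede offspring; raise on cycles with
    the offending cycle path in the message."""
    order: list = []
    state: dict = {}  # 0 visiting, 1 done

    for root in ids:
        if state.get(root) == 1:
            continue
        stack = [(root, iter([p for p in (sire.get(root), dam.get(root)) if p is not None]))]
        state[root] = 0
        path = [root]
        while stack:
            node, parents = stack[-1]
            advanced = False
            for p in parents:
                if state.get(p) == 0:
                    cycle = path[path.index(p):] + [p]
                    raise PedigreeError(
                        "pedigree contains a cycle: " + " -> ".join(map(str, cycle))
                    )
                if state.get(p) != 1:
                    state[p] = 0
                    stack.append(
                        (p, iter([q for q in (sire.get(p), dam.get(p)) if q is not None]))
                    )
                    path.append(p)
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                path.pop()
                state[node] = 1
                order.append(node)
    return order


def a_matrix(pedigree: pd.DataFrame) -> tuple[list, np.ndarray]:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` has columns id, sire, dam with 0 (or NaN) meaning unknown.
    Returns the ids in input order and the matching A matrix; the diagonal is
    1 + F with F the inbreeding coefficient.
    """
    ids = list(pedigree["id"])
    if len(set(ids)) != len(ids):
        raise PedigreeError("duplicate individual ids in pedigree")
    known = set(ids)

    def _clean(v):
        if pd.isna(v) or v == 0 or v == "0":
            return None
        return v

    sire = {}
    dam = {}
    for _, row in pedigree.iterrows():
        s, d = _clean(row["sire"]), _clean(row["dam"])
        if s is not None and s not in known:
            raise PedigreeError(f"sire {s} of {row['id']} not in pedigree")
        if d is not None and d not in known:
            raise PedigreeError(f"dam {d} of {row['id']} not in pedigree")
        sire[row["id"]] = s
        dam[row["id"]] = d

    order = _toposort(ids, sire, dam)
    pos = {ind: k for k, ind in enumerate(order)}
    q = len(order)
    A = np.zeros((q, q))
    for i, ind in enumerate(order):
        s = pos.get(sire[ind]) if sire[ind] is not None else None
        d = pos.get(dam[ind]) if dam[ind] is not None else None
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        if i:
            row = np.zeros(i)
            if s is not None:
                row += 0.5 * A[:i, s]
            if d is not None:
                row += 0.5 * A[:i, d]
            A[i, :i] = A[:i, i] = row
    # permute back to input order
    perm = np.array([pos[ind] for ind in ids])
    return ids, A[np.ix_(perm, perm)]


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """REML variance components for one or two traits."""

    G: np.ndarray  # additive (co)variance matrix
    R: np.ndarray  # residual (co)variance matrix
    converged: bool
    n_iter: int
    loglik: float
    se_G: np.ndarray | None = None
    se_R: np.ndarray | None = None
    messages: list[str] = field(default_factory=list)

    @property
    def P(self) -> np.ndarray:
        """Phenotypic (co)variance matrix, G + R elementwise."""
        return self.G + self.R

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.G) / np.diag(self.P)


def correlations(vc: VarianceComponents) -> tuple[float, float]:
    """Genetic and phenotypic correlation from a bivariate fit, clamped to
    [-1, 1] with a warning if numerically outside."""
    G, P = vc.G, vc.P
    if G.shape != (2, 2):
        raise ValueError("correlations require a bivariate fit")
    if min(G[0, 0], G[1, 1]) <= 0 or min(P[0, 0], P[1, 1]) <= 0:
        raise ValueError("zero or negative variance: correlation undefined")
    ra = G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])
    rp = P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    out = []
    for name, r in (("genetic", ra), ("phenotypic", rp)):
        if abs(r) > 1.0:
            warnings.warn(f"{name} correlation {r:.4f} outside [-1, 1]; clamped")
            r = float(np.clip(r, -1.0, 1.0))
        out.append(float(r))
    return out[0], out[1]


def _bend(M: np.ndarray, floor: float) -> np.ndarray:
    """Floor the eigenvalues of a symmetric matrix (bending)."""
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    if w.min() >= floor:
        return M
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def _param_layout(t: int) -> list[tuple[str, int, int]]:
    """Parameter order: G entries (upper triangle row-major) then R entries."""
    layout = []
    for kind in ("G", "R"):
        for s in range(t):
            for u in range(s, t):
                layout.append((kind, s, u))
    return layout


class _RemlProblem:
    """Precomputed structure for a 1- or 2-trait animal-model REML fit."""

    def __init__(self, ys, idxs, A):
        self.t = len(ys)
        self.ns = [len(y) for y in ys]
        self.N = sum(self.ns)
        self.offsets = np.cumsum([0] + self.ns)
        self.scales = [float(np.std(y, ddof=1)) or 1.0 for y in ys]
        self.y = np.concatenate([np.asarray(y, float) / sc for y, sc in zip(ys, self.scales)])
        self.idxs = [np.asarray(ix, int) for ix in idxs]
        self.K = {}
        self.Isame = {}
        for s in range(self.t):
            for u in range(s, self.t):
                self.K[(s, u)] = A[np.ix_(self.idxs[s], self.idxs[u])]
                self.Isame[(s, u)] = (
                    self.idxs[s][:, None] == self.idxs[u][None, :]
                ).astype(float)
        self.X = np.zeros((self.N, self.t))
        for s in range(self.t):
            self.X[self.offsets[s]: self.offsets[s + 1], s] = 1.0
        self.q = A.shape[0]
        self.layout = _param_layout(self.t)
        self.complete = self.t == 2 and self.ns[0] == self.ns[1] and np.array_equal(
            self.idxs[0], self.idxs[1]
        )

    def block(self, M, s, u):
        return M[self.offsets[s]: self.offsets[s + 1], self.offsets[u]: self.offsets[u + 1]]

    def build_V(self, G0, R0):
        V = np.zeros((self.N, self.N))
        for s in range(self.t):
            for u in range(s, self.t):
                B = G0[s, u] * self.K[(s, u)] + R0[s, u] * self.Isame[(s, u)]
                self.block(V, s, u)[:] = B
                if u != s:
                    self.block(V, u, s)[:] = B.T
        return V

    def decompose(self, G0, R0):
        """Return (P, w, loglik) for current components; None if V not PD."""
        V = self.build_V(G0, R0)
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vi = cho_solve(cf, np.eye(self.N))
        ViX = Vi @ self.X
        XtViX = self.X.T @ ViX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        w = P @ self.y
        loglik = -0.5 * (logdetV + logdetX + float(self.y @ w))
        return P, w, loglik

    def _Vk_dot(self, kind, s, u, vec):
        """Apply the derivative matrix dV/dtheta_k to a stacked vector."""
        out = np.zeros_like(vec)
        M = self.K[(s, u)] if kind == "G" else self.Isame[(s, u)]
        vs = vec[self.offsets[s]: self.offsets[s + 1]]
        vu = vec[self.offsets[u]: self.offsets[u + 1]]
        if s == u:
            out[self.offsets[s]: self.offsets[s + 1]] += M @ vs
        else:
            out[self.offsets[s]: self.offsets[s + 1]] += M @ vu
            out[self.offsets[u]: self.offsets[u + 1]] += M.T @ vs
        return out

    def score_and_ai(self, P, w):
        npar = len(self.layout)
        score = np.zeros(npar)
        sk = []
        for k, (kind, s, u) in enumerate(self.layout):
            M = self.K[(s, u)] if kind == "G" else self.Isame[(s, u)]
            Psu = self.block(P, s, u)
            tr = float(np.sum(Psu * M)) * (1.0 if s == u else 2.0)
            vk = self._Vk_dot(kind, s, u, w)
            score[k] = -0.5 * (tr - float(w @ vk))
            sk.append(vk)
        AI = np.zeros((npar, npar))
        Ps = [P @ v for v in sk]
        for k in range(npar):
            for l in range(k, npar):
                AI[k, l] = AI[l, k] = 0.5 * float(sk[k] @ Ps[l])
        return score, AI

    def em_step(self, G0, R0, P, w):
        """Exact EM-REML update; valid only when both traits share one record
        set (``self.complete``) or for a univariate fit."""
        t = self.t
        K = self.K[(0, 0)]
        n = self.ns[0]
        TrK = np.zeros((t, t))
        TrI = np.zeros((t, t))
        wKw = np.zeros((t, t))
        ww = np.zeros((t, t))
        wb = [w[self.offsets[s]: self.offsets[s + 1]] for s in range(t)]
        for s in range(t):
            for u in range(t):
                Psu = self.block(P, s, u)
                TrK[s, u] = float(np.sum(Psu * K))
                TrI[s, u] = float(np.trace(Psu))
                wKw[s, u] = float(wb[s] @ (K @ wb[u]))
                ww[s, u] = float(wb[s] @ wb[u])
        Gn = G0 - (G0 @ (TrK - wKw) @ G0) / self.q
        Rn = R0 - (R0 @ (TrI - ww) @ R0) / n
        return (Gn + Gn.T) / 2.0, (Rn + Rn.T) / 2.0


def _theta_to_mats(theta, layout, t):
    G0 = np.zeros((t, t))
    R0 = np.zeros((t, t))
    for val, (kind, s, u) in zip(theta, layout):
        M = G0 if kind == "G" else R0
        M[s, u] = M[u, s] = val
    return G0, R0


def _mats_to_theta(G0, R0, layout):
    return np.array([(G0 if kind == "G" else R0)[s, u] for kind, s, u in layout])


def _reml(
    ys,
    idxs,
    A,
    max_iter: int = 500,
    tol_update: float = 1e-7,
    tol_grad: float = 1e-6,
    n_em: int = 3,
    bend_floor: float = 1e-8,
    r_floor: float = 1e-6,
) -> VarianceComponents:
    prob = _RemlProblem(ys, idxs, A)
    t = prob.t
    layout = prob.layout

    # moment-based starting values on the standardised scale
    G0 = 0.5 * np.eye(t) + 0.05 * (np.ones((t, t)) - np.eye(t))
    R0 = 0.5 * np.eye(t) + 0.05 * (np.ones((t, t)) - np.eye(t))

    msgs: list[str] = []
    dec = prob.decompose(G0, R0)
    if dec is None:
        raise np.linalg.LinAlgError("initial variance structure not positive definite")
    P, w, loglik = dec

    # EM warm-up (exact updates; monotone in the restricted likelihood)
    n_em_eff = n_em if (t == 1 or prob.complete) else 0
    for _ in range(n_em_eff):
        G0, R0 = prob.em_step(G0, R0, P, w)
        G0 = _bend(G0, bend_floor)
        R0 = _bend(R0, r_floor)
        dec = prob.decompose(G0, R0)
        if dec is None:
            break
        P, w, loglik = dec

    converged = False
    it = 0
    stalls = 0
    for it in range(1, max_iter + 1):
        score, AI = prob.score_and_ai(P, w)
        if np.linalg.norm(score) < tol_grad:
            converged = True
            break
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(len(score)), score)
        except np.linalg.LinAlgError:
            delta = score
        theta = _mats_to_theta(G0, R0, layout)
        step = 1.0
        accepted = False
        for _ in range(25):
            G1, R1 = _theta_to_mats(theta + step * delta, layout, t)
            G1 = _bend(G1, bend_floor)
            R1 = _bend(R1, r_floor)
            dec = prob.decompose(G1, R1)
            if dec is not None and dec[2] > loglik + 1e-12:
                accepted = True
                break
            step /= 2.0
        if not accepted and (t == 1 or prob.complete):
            # AI step cannot ascend (typically a boundary): fall back to EM
            G1, R1 = prob.em_step(G0, R0, P, w)
            G1 = _bend(G1, bend_floor)
            R1 = _bend(R1, r_floor)
            dec = prob.decompose(G1, R1)
            accepted = dec is not None and dec[2] > loglik + 1e-12
        if not accepted:
            # no direction improves the restricted likelihood measurably:
            # treat the current point as the (possibly boundary) solution
            converged = np.linalg.norm(score) < 1e-2
            if not converged:
                msgs.append(f"iteration {it}: no ascent step found; stopping")
            break
        upd = _mats_to_theta(G1, R1, layout) - theta
        improvement = dec[2] - loglik
        G0, R0 = G1, R1
        P, w, loglik = dec
        if np.linalg.norm(upd) < tol_update:
            converged = True
            break
        # boundary solutions (e.g. rA pinned at 1) make only microscopic
        # likelihood progress per step: stop once flat for a few iterations
        stalls = stalls + 1 if improvement < 1e-9 else 0
        if stalls >= 3:
            converged = True
            msgs.append(f"iteration {it}: likelihood flat; boundary solution")
            break
    if not converged and not msgs:
        msgs.append(f"not converged in {it} iterations")

    # standard errors from the AI-matrix inverse at the solution
    score, AI = prob.score_and_ai(P, w)
    se = None
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        msgs.append("AI matrix singular at solution; no standard errors")

    # rescale to original units
    S = np.outer(prob.scales, prob.scales)
    se_G = se_R = None
    if se is not None:
        seG0 = np.zeros((t, t))
        seR0 = np.zeros((t, t))
        for v, (kind, s, u) in zip(se, layout):
            M = seG0 if kind == "G" else seR0
            M[s, u] = M[u, s] = v
        se_G, se_R = seG0 * S, seR0 * S
    return VarianceComponents(
        G=G0 * S,
        R=R0 * S,
        converged=converged,
        n_iter=it,
        loglik=loglik,
        se_G=se_G,
        se_R=se_R,
        messages=msgs,
    )


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    A: np.ndarray,
    **kwargs,
) -> VarianceComponents:
    """Bivariate animal-model REML.

    ``idx1``/``idx2`` map each record to its animal's row in ``A``; each
    animal has at most one record per trait.  The same trait measured in two
    parities is treated as two traits.
    """
    return _reml([np.asarray(y1, float), np.asarray(y2, float)], [idx1, idx2], A, **kwargs)


def reml_univariate(y: np.ndarray, idx: np.ndarray, A: np.ndarray, **kwargs) -> VarianceComponents:
    """Univariate animal-model REML (single trait)."""
    return _reml([np.asarray(y, float)], [idx], A, **kwargs)


def reml_loglik(
    G0: np.ndarray | float,
    R0: np.ndarray | float,
    ys,
    idxs,
    A: np.ndarray,
) -> float:
    """Restricted log-likelihood at fixed components, on the original scale
    of the data (no internal standardisation).  Useful as an independent
    surface for grid searches."""
    G0 = np.atleast_2d(np.asarray(G0, float))
    R0 = np.atleast_2d(np.asarray(R0, float))
    prob = _RemlProblem(ys, idxs, A)
    sc = np.outer(prob.scales, prob.scales)
    dec = prob.decompose(G0 / sc, R0 / sc)
    if dec is None:
        return -np.inf
    # convert the standardised-scale likelihood back to the data scale
    _, _, ll = dec
    n_eff = prob.N - prob.t
    # each record of trait s was divided by scales[s]: adjust the Jacobian and
    # the X'V^-1X determinant term
    jac = sum(n * np.log(s) for n, s in zip(prob.ns, prob.scales))
    # log|V_orig| = log|V_std| + 2*jac ; log|X'Vo^-1X| = log|X'Vs^-1X| - 2*sum(log s)
    # y'P y is scale-free in the quadratic form sense after matching; combine:
    return ll - jac + sum(np.log(s) for s in prob.scales)
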