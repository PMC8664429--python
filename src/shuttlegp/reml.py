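"""Restricted maximum likelihood for kernel variance-component models.

Fits ``y = X b + sum_i Z_i u_i + e`` with ``u_i ~ N(0, K_i s2_i)`` and a
residual variance that may differ between groups of records (here: sites),
``e ~ N(0, diag(s2_group))``.  Estimation works on Henderson's mixed-model
equations: each iteration factorises

    C = W' R^-1 W + diag(0_p, K_i^-1 / s2_i)     with  W = [X, Z_1, ...]

and updates the variance components by expectation-maximisation (EM) during
a short warm-up, then by average-information (AI) steps with step-halving
back to EM whenever an AI proposal would leave the parameter space or
decrease the restricted likelihood.  EM keeps components nonnegative; AI
gives fast terminal convergence.  The restricted log-likelihood is

    logREML = -1/2 [ (n-p) log 2pi + log|R| + log|G| + log|C| + y'Py ]

using the identity log|V| + log|X'V^-1 X| = log|R| + log|G| + log|C|.
Components are floored at ``floor_frac * var(y)`` rather than allowed to go
negative, so boundary estimates are reported as ~0.

The solver is deterministic: no randomness enters the iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, solve

logger = logging.getLogger(__name__)

__all__ = ["RandomTerm", "REMLResult", "VarianceComponentModel"]


def _chol_inverse(cf) -> np.ndarray:
    """Full inverse from a cho_factor, via LAPACK dpotri."""
    from scipy.linalg.lapack import dpotri

    inv, info = dpotri(cf[0], lower=True)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed with info={info}")
    tri = np.tril(inv)
    return tri + tri.T - np.diag(np.diag(tri))


@dataclass
class RandomTerm:
    """One random effect: incidence matrix, kernel inverse, level labels.

    ``kinv is None`` means an identity kernel (``logdet_k = 0``).
    """

    name: str
    z: sparse.csr_matrix
    labels: list[str]
    kinv: np.ndarray | None = None
    logdet_k: float = 0.0

    @property
    def q(self) -> int:
        return self.z.shape[1]


@dataclass
class REMLResult:
    varcomp: pd.Series
    fixed_effects: pd.Series
    fe_cov: np.ndarray
    blups: dict[str, pd.Series]
    loglik: float
    converged: bool
    n_iter: int
    varcomp_cov: pd.DataFrame | None
    floor: float
    n_records: int
    history: list[float] = field(default_factory=list, repr=False)


class VarianceComponentModel:
    """REML engine for one phenotype vector with arbitrary PSD kernels."""

    def __init__(
        self,
        y: np.ndarray,
        x: np.ndarray,
        fe_names: list[str],
        terms: list[RandomTerm],
        resid_group: np.ndarray | None = None,
        resid_labels: list[str] | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.n = self.y.size
        if self.x.shape[0] != self.n:
            raise ValueError("X and y must have the same number of records")
        self.p = self.x.shape[1]
        if np.linalg.matrix_rank(self.x) < self.p:
            raise ValueError("fixed-effect design matrix is rank deficient")
        self.fe_names = list(fe_names)
        self.terms = list(terms)
        if not self.terms:
            raise ValueError("at least one random term is required")
        if resid_group is None:
            resid_group = np.zeros(self.n, dtype=int)
            resid_labels = ["residual"]
        self.resid_group = np.asarray(resid_group, dtype=int)
        self.resid_labels = list(resid_labels)
        self.n_groups = len(self.resid_labels)
        self.group_n = np.array(
            [int(np.sum(self.resid_group == s)) for s in range(self.n_groups)]
        )
        if (self.group_n == 0).any():
            raise ValueError("every residual group needs at least one record")

        # column layout of W = [X | Z_1 | Z_2 | ...]
        self.offsets = [self.p]
        for t in self.terms:
            self.offsets.append(self.offsets[-1] + t.q)
        self.d = self.offsets[-1]

        w = sparse.hstack(
            [sparse.csr_matrix(self.x)] + [t.z for t in self.terms], format="csr"
        )
        self.w = w
        # per-group Gram matrices and right-hand sides (fixed across iterations)
        self.gram: list[np.ndarray] = []
        self.rhs_g: list[np.ndarray] = []
        self.yty_g: list[float] = []
        for s in range(self.n_groups):
            rows = np.where(self.resid_group == s)[0]
            ws = w[rows]
            ys = self.y[rows]
            self.gram.append(np.asarray((ws.T @ ws).todense()))
            self.rhs_g.append(np.asarray(ws.T @ ys).ravel())
            self.yty_g.append(float(ys @ ys))

        self.names = [t.name for t in self.terms] + [
            f"residual_{lbl}" if self.n_groups > 1 else "residual"
            for lbl in self.resid_labels
        ]
        self.k = len(self.terms)

    # ------------------------------------------------------------------
    def _assemble(self, theta: np.ndarray):
        s2_terms = theta[: self.k]
        s2_resid = theta[self.k :]
        c = np.zeros((self.d, self.d))
        rhs = np.zeros(self.d)
        for s in range(self.n_groups):
            inv = 1.0 / s2_resid[s]
            c += self.gram[s] * inv
            rhs += self.rhs_g[s] * inv
        logdet_g = 0.0
        for i, t in enumerate(self.terms):
            a, b = self.offsets[i], self.offsets[i + 1]
            if t.kinv is None:
                c[np.arange(a, b), np.arange(a, b)] += 1.0 / s2_terms[i]
            else:
                c[a:b, a:b] += t.kinv / s2_terms[i]
            logdet_g += t.q * np.log(s2_terms[i]) + t.logdet_k
        return c, rhs, logdet_g

    def _state(self, theta: np.ndarray) -> dict:
        c, rhs, logdet_g = self._assemble(theta)
        cf = cho_factor(c, lower=True, check_finite=False)
        sol = cho_solve(cf, rhs, check_finite=False)
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        s2_resid = theta[self.k :]
        ypy = sum(
            self.yty_g[s] / s2_resid[s] for s in range(self.n_groups)
        ) - float(sol @ rhs)
        logdet_r = float(np.sum(self.group_n * np.log(s2_resid)))
        ll = -0.5 * (
            (self.n - self.p) * np.log(2.0 * np.pi)
            + logdet_r + logdet_g + logdet_c + ypy
        )
        return {"theta": theta, "cf": cf, "sol": sol, "ll": ll}

    def _moments(self, state: dict) -> dict:
        """Residuals, EM traces and per-term quadratic forms at a state."""
        theta = state["theta"]
        cf = state["cf"]
        sol = state["sol"]
        cinv = _chol_inverse(cf)
        resid = self.y - np.asarray(self.w @ sol).ravel()
        quad = np.empty(self.k)  # u' Kinv u per term
        trace = np.empty(self.k)  # tr(Kinv C^{ii}) per term
        for i, t in enumerate(self.terms):
            a, b = self.offsets[i], self.offsets[i + 1]
            u = sol[a:b]
            block = cinv[a:b, a:b]
            if t.kinv is None:
                quad[i] = float(u @ u)
                trace[i] = float(np.trace(block))
            else:
                quad[i] = float(u @ t.kinv @ u)
                trace[i] = float(np.sum(t.kinv * block))
        sse = np.empty(self.n_groups)
        tr_g = np.empty(self.n_groups)
        for s in range(self.n_groups):
            rows = self.resid_group == s
            sse[s] = float(resid[rows] @ resid[rows])
            tr_g[s] = float(np.sum(self.gram[s] * cinv))
        return {
            "cinv": cinv, "resid": resid, "quad": quad, "trace": trace,
            "sse": sse, "tr_g": tr_g,
        }

    def _em_step(self, state: dict, mom: dict, floor: float) -> np.ndarray:
        theta = state["theta"]
        new = np.empty_like(theta)
        for i, t in enumerate(self.terms):
            new[i] = (mom["quad"][i] + mom["trace"][i]) / t.q
        for s in range(self.n_groups):
            new[self.k + s] = (mom["sse"][s] + mom["tr_g"][s]) / self.group_n[s]
        return np.maximum(new, floor)

    def _score_ai(self, state: dict, mom: dict):
        theta = state["theta"]
        s2_t = theta[: self.k]
        s2_r = theta[self.k :]
        score = np.empty(self.k + self.n_groups)
        f = np.zeros((self.n, self.k + self.n_groups))
        for i, t in enumerate(self.terms):
            a, b = self.offsets[i], self.offsets[i + 1]
            tr_pzkz = (t.q - mom["trace"][i] / s2_t[i]) / s2_t[i]
            score[i] = -0.5 * (tr_pzkz - mom["quad"][i] / s2_t[i] ** 2)
            f[:, i] = np.asarray(t.z @ state["sol"][a:b]).ravel() / s2_t[i]
        for s in range(self.n_groups):
            rows = self.resid_group == s
            tr_p = self.group_n[s] / s2_r[s] - mom["tr_g"][s] / s2_r[s] ** 2
            score[self.k + s] = -0.5 * (tr_p - mom["sse"][s] / s2_r[s] ** 2)
            f[rows, self.k + s] = mom["resid"][rows] / s2_r[s]
        rinv = 1.0 / s2_r[self.resid_group]
        rf = f * rinv[:, None]
        wtrf = np.asarray((self.w.T @ rf))
        pf = rf - rinv[:, None] * np.asarray(
            self.w @ cho_solve(state["cf"], wtrf, check_finite=False)
        )
        ai = 0.5 * (f.T @ pf)
        ai = (ai + ai.T) / 2.0
        return score, ai

    # ------------------------------------------------------------------
    def fit(
        self,
        start: np.ndarray | dict | None = None,
        max_iter: int = 500,
        rtol: float = 1e-8,
        ltol: float = 1e-9,
        n_em: int = 3,
        floor_frac: float = 1e-10,
        fixed_varcomp: np.ndarray | dict | None = None,
        compute_se: bool = True,
    ) -> REMLResult:
        """Run REML; ``fixed_varcomp`` skips estimation and solves the MME
        at the supplied variance components."""
        vary = float(np.var(self.y))
        if vary == 0:
            vary = 1.0
        floor = floor_frac * vary
        # residual variances get a larger floor (1e-8 x var(y)): R^-1 enters
        # the mixed-model equations directly and a residual at 1e-10 x var(y)
        # destroys their conditioning
        floor_vec = np.full(self.k + self.n_groups, floor)
        floor_vec[self.k:] = max(floor, 1e-8 * vary)

        def as_theta(v) -> np.ndarray:
            if isinstance(v, dict):
                return np.array([v[name] for name in self.names], dtype=float)
            return np.asarray(v, dtype=float)

        if fixed_varcomp is not None:
            theta = np.maximum(as_theta(fixed_varcomp), floor_vec)
            state = self._state(theta)
            return self._finish(state, None, True, 0, floor, [state["ll"]],
                                compute_se=False)

        if start is not None:
            theta = np.maximum(as_theta(start), floor_vec)
        else:
            theta = np.empty(self.k + self.n_groups)
            theta[: self.k] = 0.5 * vary / self.k
            theta[self.k :] = 0.5 * vary
        history: list[float] = []
        state = self._state(theta)
        converged = False
        it = 0
        ai = None
        tiny = floor_frac * vary * 1e5  # ~1e-5 x var(y): numerically zero
        pinned = np.zeros(self.k + self.n_groups, dtype=bool)
        for it in range(1, max_iter + 1):
            history.append(state["ll"])
            mom = self._moments(state)
            em_next = self._em_step(state, mom, floor_vec)
            just_pinned = False
            if it <= n_em:
                proposal = em_next
            else:
                score, ai = self._score_ai(state, mom)
                # release pinned components the likelihood wants positive
                pinned &= ~(score > 0)
                # pin components collapsing to the boundary: their EM path
                # decays geometrically and would never meet the tolerance
                collapse = (
                    (~pinned)
                    & (score <= 0)
                    & (em_next < state["theta"] * (1 - 1e-12))
                    & (state["theta"] < tiny)
                )
                if collapse.any():
                    pinned |= collapse
                    just_pinned = True
                free = ~pinned & ~(
                    em_next
                    < np.maximum(0.51 * state["theta"], floor_vec * (1 + 1e-9))
                )
                proposal = None
                if free.any():
                    ii = np.where(free)[0]
                    sub = ai[np.ix_(ii, ii)]
                    try:
                        step_f = solve(
                            sub + 1e-12 * np.eye(ii.size) * max(np.trace(sub), 1.0),
                            score[ii], assume_a="sym",
                        )
                    except np.linalg.LinAlgError:
                        step_f = None
                    if step_f is not None:
                        step = np.zeros_like(score)
                        step[ii] = step_f
                        cand = state["theta"] + step
                        cand[~free] = em_next[~free]
                        cand[pinned] = floor_vec[pinned]
                        # halve steps that exit the parameter space
                        for _ in range(20):
                            if (cand[ii] >= floor_vec[ii]).all():
                                break
                            step = step / 2.0
                            cand = state["theta"] + step
                            cand[~free] = em_next[~free]
                            cand[pinned] = floor_vec[pinned]
                        if (cand >= floor_vec).all():
                            proposal = cand
                if proposal is None:
                    proposal = em_next.copy()
                    proposal[pinned] = floor_vec[pinned]
            new_state = self._state(proposal)
            if (
                new_state["ll"] < state["ll"] - 1e-10
                and it > n_em
                and not just_pinned
            ):
                # AI overshoot: fall back to the guaranteed-ascent EM update
                proposal = em_next.copy()
                proposal[pinned] = floor_vec[pinned]
                new_state = self._state(proposal)
                if new_state["ll"] < state["ll"] - 1e-10 and pinned.any():
                    # pinning itself hurt: release everything, plain EM
                    pinned[:] = False
                    proposal = em_next
                    new_state = self._state(proposal)
            at_floor = proposal <= floor_vec * (1 + 1e-12)
            denom = np.maximum(np.abs(state["theta"]), floor_vec * 1e3)
            rel = np.abs(proposal - state["theta"]) / denom
            rel[at_floor & (state["theta"] <= floor_vec * (1 + 1e-12))] = 0.0
            rel[pinned] = 0.0
            dll = abs(new_state["ll"] - state["ll"])
            state = new_state
            if it > n_em and not just_pinned and rel.max() < rtol and dll < ltol:
                converged = True
                break
        history.append(state["ll"])
        if not converged:
            logger.warning(
                "REML did not reach tolerance in %d iterations "
                "(last rel change %.2e)", max_iter, float(rel.max()),
            )
        return self._finish(state, ai, converged, it, floor, history, compute_se)

    def _finish(self, state, ai, converged, n_iter, floor, history,
                compute_se=True) -> REMLResult:
        theta = state["theta"]
        sol = state["sol"]
        ep = np.zeros((self.d, self.p))
        ep[: self.p, : self.p] = np.eye(self.p)
        fe_cov = cho_solve(state["cf"], ep, check_finite=False)[: self.p, : self.p]
        blups = {}
        for i, t in enumerate(self.terms):
            a, b = self.offsets[i], self.offsets[i + 1]
            blups[t.name] = pd.Series(sol[a:b], index=t.labels, name=t.name)
        vc_cov = None
        if compute_se and ai is not None:
            try:
                cov = np.linalg.inv(ai)
                vc_cov = pd.DataFrame(cov, index=self.names, columns=self.names)
            except np.linalg.LinAlgError:
                vc_cov = None
        return REMLResult(
            varcomp=pd.Series(theta, index=self.names, name="variance"),
            fixed_effects=pd.Series(sol[: self.p], index=self.fe_names),
            fe_cov=fe_cov,
            blups=blups,
            loglik=float(state["ll"]),
            converged=bool(converged),
            n_iter=n_iter,
            varcomp_cov=vc_cov,
            floor=float(floor),
            n_records=self.n,
            history=history,
        )
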