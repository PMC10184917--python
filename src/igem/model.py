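r"""Geneset-embedded joint non-negative matrix factorization (iGEM).

Two nonnegative views sharing a subject axis — expression ``X1`` (subjects x
genes) and methylation ``X2`` (subjects x CpGs) — are factorized jointly as

    X1 ~ W @ H1,   H1 = alpha @ rho        (topics embedded in genesets)
    X2 ~ W @ H2

where ``W`` (subjects x topics) holds the patient meta-phenotype scores,
``alpha`` (topics x genesets) the geneset factor scores, ``rho`` (genesets x
genes) the fixed, row-normalized geneset membership design, and ``H2``
(topics x CpGs) the methylation basis.  ``H1`` is never a free parameter.

The objective adds a graph penalty coupling correlated proximal gene-CpG
pairs (the interaction adjacency ``B``) and L1 sparsity on each free block:

    L = ||X1 - W H1||_F^2 + ||X2 - W H2||_F^2
        + lambda_net * sum_{g,c} B[g,c] * sum_k (H1[k,g] - H2[k,c])^2
        + lambda_W * sum(W) + lambda_alpha * sum(alpha) + lambda_H * sum(H2)

Minimization uses multiplicative updates in the order W -> alpha -> H2, each
the ratio of the negative to the positive part of that block's gradient, so
non-negativity is preserved and the objective is non-increasing.  With all
lambdas zero and ``rho = I`` the updates reduce to the standard two-view
Lee-Seung rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger("igem")

__all__ = ["Hyperparams", "IgemState", "IgemFit", "objective", "gradients",
           "update_step", "initialize", "fit", "rank_diagnostics"]


@dataclass
class Hyperparams:
    """Tunable knobs of the factorization.

    ``n_topics`` is the latent factor count K (default 10).  The lambdas
    weight the graph penalty and the three L1 terms; ``epsilon_guard`` floors
    every multiplicative-update denominator.
    """

    n_topics: int = 10
    lambda_net: float = 1.0
    lambda_w: float = 1.0
    lambda_alpha: float = 1.0
    lambda_h: float = 1.0
    max_iter: int = 2000
    rel_tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0
    epsilon_guard: float = 1e-12
    init: str = "uniform"  # "uniform" | "nndsvd"

    def validate(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        for name in ("lambda_net", "lambda_w", "lambda_alpha", "lambda_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


@dataclass
class IgemState:
    """Free factor blocks; H1 = alpha @ rho is always derived."""

    W: np.ndarray
    alpha: np.ndarray
    H2: np.ndarray

    def h1(self, rho: np.ndarray) -> np.ndarray:
        return self.alpha @ rho

    def copy(self) -> "IgemState":
        return IgemState(self.W.copy(), self.alpha.copy(), self.H2.copy())


@dataclass
class IgemFit:
    W: np.ndarray
    alpha: np.ndarray
    H2: np.ndarray
    H1: np.ndarray
    objective_trajectory: np.ndarray
    converged: bool
    n_iter: int
    hyper: Hyperparams
    restart: int = 0


def _check(X1, X2, rho, B, state: IgemState | None = None) -> None:
    n1, g = X1.shape
    n2, c = X2.shape
    s, g2 = rho.shape
    if n1 != n2:
        raise ValueError(f"X1 and X2 subject counts differ: {n1} vs {n2}")
    if g2 != g:
        raise ValueError(f"rho has {g2} genes but X1 has {g}")
    if B.shape != (g, c):
        raise ValueError(f"B must be {g}x{c}, got {B.shape}")
    if np.min(X1) < 0 or np.min(X2) < 0:
        raise ValueError("data matrices must be nonnegative")
    if state is not None:
        if min(state.W.min(), state.alpha.min(), state.H2.min()) < 0:
            raise ValueError("factor matrices must be nonnegative")


def _graph_mats(B):
    """B as ndarray ops plus its row/column degree vectors."""
    if sp.issparse(B):
        B = B.tocsr()
        dg = np.asarray(B.sum(axis=1)).ravel()
        dc = np.asarray(B.sum(axis=0)).ravel()
    else:
        B = np.asarray(B, dtype=float)
        dg = B.sum(axis=1)
        dc = B.sum(axis=0)
    return B, dg, dc


def objective(X1, X2, rho, B, state: IgemState, hyper: Hyperparams) -> float:
    """Evaluate the penalized joint reconstruction loss at ``state``."""
    _check(X1, X2, rho, B, state)
    B, dg, dc = _graph_mats(B)
    H1 = state.h1(rho)
    r1 = X1 - state.W @ H1
    r2 = X2 - state.W @ state.H2
    L = float(np.sum(r1 * r1) + np.sum(r2 * r2))
    if hyper.lambda_net:
        # sum_{g,c} B[g,c] * ||H1[:,g] - H2[:,c]||^2 expanded in degree form
        cross = H1 @ (B @ state.H2.T) if not sp.issparse(B) else H1 @ (B @ state.H2.T)
        L += hyper.lambda_net * float(
            np.sum((H1 * H1) @ dg) - 2.0 * np.trace(cross) + np.sum((state.H2 * state.H2) @ dc)
        )
    L += (hyper.lambda_w * float(state.W.sum())
          + hyper.lambda_alpha * float(state.alpha.sum())
          + hyper.lambda_h * float(state.H2.sum()))
    return L


def gradients(X1, X2, rho, B, state: IgemState, hyper: Hyperparams):
    """Analytic gradients of the objective w.r.t. (W, alpha, H2)."""
    B, dg, dc = _graph_mats(B)
    W, alpha, H2 = state.W, state.alpha, state.H2
    H1 = alpha @ rho
    gW = 2.0 * ((W @ H1 - X1) @ H1.T + (W @ H2 - X2) @ H2.T) + hyper.lambda_w
    gH1 = 2.0 * (W.T @ (W @ H1 - X1))
    if hyper.lambda_net:
        gH1 = gH1 + 2.0 * hyper.lambda_net * (H1 * dg - H2 @ B.T)
    gA = gH1 @ rho.T + hyper.lambda_alpha
    gH2 = 2.0 * (W.T @ (W @ H2 - X2)) + hyper.lambda_h
    if hyper.lambda_net:
        gH2 = gH2 + 2.0 * hyper.lambda_net * (H2 * dc - H1 @ B)
    return gW, gA, gH2


def _guard_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite values appeared in block {name}")


def update_step(state: IgemState, X1, X2, rho, B, hyper: Hyperparams) -> IgemState:
    """One round of multiplicative updates, in the order W -> alpha -> H2."""
    B, dg, dc = _graph_mats(B)
    eps = hyper.epsilon_guard
    W, alpha, H2 = state.W, state.alpha, state.H2
    H1 = alpha @ rho

    num = X1 @ H1.T + X2 @ H2.T
    den = W @ (H1 @ H1.T + H2 @ H2.T) + hyper.lambda_w / 2.0 + eps
    W = W * (num / den)
    _guard_finite("W", W)

    rrt = rho @ rho.T
    num = W.T @ X1 @ rho.T
    den = W.T @ W @ alpha @ rrt + hyper.lambda_alpha / 2.0 + eps
    if hyper.lambda_net:
        num = num + hyper.lambda_net * (H2 @ (B.T @ rho.T))
        den = den + hyper.lambda_net * (((alpha @ rho) * dg) @ rho.T)
    alpha = alpha * (num / den)
    _guard_finite("alpha", alpha)
    H1 = alpha @ rho

    num = W.T @ X2
    den = W.T @ W @ H2 + hyper.lambda_h / 2.0 + eps
    if hyper.lambda_net:
        num = num + hyper.lambda_net * (H1 @ B)
        den = den + hyper.lambda_net * (H2 * dc)
    H2 = H2 * (num / den)
    _guard_finite("H2", H2)

    return IgemState(W, alpha, H2)


def initialize(hyper: Hyperparams, X1, X2, rho, rng: np.random.Generator) -> IgemState:
    """Random strictly-positive start scaled to the data magnitude.

    Uniform(0.1, 1.1) entries scaled by sqrt(mean(X)/K) so the initial
    reconstruction W@H has the data's order of magnitude; alpha additionally
    carries a G/S factor because each row of rho sums to 1, which shrinks
    mean(alpha @ rho) by S/G.
    """
    n, g = X1.shape
    c = X2.shape[1]
    s = rho.shape[0]
    k = hyper.n_topics
    m = float(np.mean(X1) + np.mean(X2)) / 2.0
    scale = np.sqrt(max(m, 1e-12) / k)
    if hyper.init == "nndsvd":
        X = np.hstack([np.asarray(X1, float), np.asarray(X2, float)])
        U, sv, Vt = np.linalg.svd(X, full_matrices=False)
        W = np.abs(U[:, :k]) * np.sqrt(sv[:k])
        H = np.sqrt(sv[:k])[:, None] * np.abs(Vt[:k])
        floor = max(1e-6 * scale, 1e-12)
        W = np.maximum(W, floor)
        H2 = np.maximum(H[:, g:], floor)
        # project the gene block onto the geneset design
        alpha = np.maximum(H[:, :g] @ rho.T * (g / s), floor)
        return IgemState(W, alpha, H2)
    W = rng.uniform(0.1, 1.1, size=(n, k)) * scale
    alpha = rng.uniform(0.1, 1.1, size=(k, s)) * scale * (g / s)
    H2 = rng.uniform(0.1, 1.1, size=(k, c)) * scale
    return IgemState(W, alpha, H2)


def fit(X1, X2, rho, B, hyper: Hyperparams) -> IgemFit:
    """Fit by multiplicative updates with restarts; keep the best restart.

    Convergence is declared when the relative objective decrease falls below
    ``rel_tol``.  Deterministic for a fixed ``hyper.seed``.
    """
    hyper.validate()
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    _check(X1, X2, rho, B)
    n, g = X1.shape
    c = X2.shape[1]
    if hyper.n_topics > min(n, g, c):
        raise ValueError(
            f"n_topics={hyper.n_topics} exceeds min(N, G, C)={min(n, g, c)}")

    best: IgemFit | None = None
    for r in range(hyper.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([hyper.seed, r]))
        state = initialize(hyper, X1, X2, rho, rng)
        traj = [objective(X1, X2, rho, B, state, hyper)]
        converged = False
        for it in range(hyper.max_iter):
            state = update_step(state, X1, X2, rho, B, hyper)
            L = objective(X1, X2, rho, B, state, hyper)
            traj.append(L)
            prev = traj[-2]
            if prev > 0 and (prev - L) / prev < hyper.rel_tol:
                converged = True
                break
        cand = IgemFit(
            W=state.W, alpha=state.alpha, H2=state.H2, H1=state.h1(rho),
            objective_trajectory=np.asarray(traj), converged=converged,
            n_iter=len(traj) - 1, hyper=hyper, restart=r)
        log.debug("restart %d: objective %.6g after %d iters (converged=%s)",
                  r, traj[-1], cand.n_iter, converged)
        if best is None or traj[-1] < best.objective_trajectory[-1]:
            best = cand
    assert best is not None
    return best


def reconstruction_errors(fitres: IgemFit, X1, X2) -> tuple[float, float]:
    """Relative Frobenius reconstruction error of each view."""
    e1 = np.linalg.norm(X1 - fitres.W @ fitres.H1) / max(np.linalg.norm(X1), 1e-300)
    e2 = np.linalg.norm(X2 - fitres.W @ fitres.H2) / max(np.linalg.norm(X2), 1e-300)
    return float(e1), float(e2)


def rank_diagnostics(X1, X2, rho, B, hyper: Hyperparams,
                     k_grid: list[int]) -> pd.DataFrame:
    """Fit once per K in ``k_grid``; the table supports an elbow choice.

    No automatic selection is made.  ``restart_dispersion`` is the spread of
    final objectives across restarts (max - min), a stability diagnostic.
    """
    if not len(k_grid):
        raise ValueError("k_grid must be nonempty")
    rows = []
    for k in k_grid:
        hk = replace(hyper, n_topics=int(k))
        finals = []
        best = None
        for r in range(hk.n_restarts):
            h1 = replace(hk, n_restarts=1, seed=int(
                np.random.SeedSequence([hk.seed, r]).generate_state(1)[0] % (2**31)))
            f = fit(X1, X2, rho, B, h1)
            finals.append(f.objective_trajectory[-1])
            if best is None or finals[-1] < best.objective_trajectory[-1]:
                best = f
        e1, e2 = reconstruction_errors(best, X1, X2)
        rows.append({"K": int(k), "objective": float(min(finals)),
                     "recon_err_x1": e1, "recon_err_x2": e2,
                     "restart_dispersion": float(max(finals) - min(finals))})
    return pd.DataFrame(rows)
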