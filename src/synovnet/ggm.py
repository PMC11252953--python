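"""Joint two-group Gaussian graphical model estimation.

The estimator is a node-wise regression with a two-level group-lasso
penalty, in the style of joint multi-dataset GGM methods: each group k has
a coefficient matrix Θ^(k) = Ω + Γ^(k), with Ω the structure common to all
groups and Γ^(k) the group-specific deviation. The objective is

    Σ_k (1/(2 n_k)) ‖X^(k) − X^(k)(Ω + Γ^(k))‖²_F
        + λ1 Σ_{i<j} ‖(Ω_ij, Ω_ji)‖₂
        + λ2 Σ_k Σ_{i<j} ‖(Γ^(k)_ij, Γ^(k)_ji)‖₂      (zero diagonals),

minimized by block coordinate descent with group soft-thresholding over
symmetric coefficient pairs, so edges enter or leave symmetrically and
jointly across groups. λ1 controls the shared backbone's sparsity, λ2 how
freely groups may deviate from it. Regularization strength is chosen by a
two-stage BIC scan; final graphs come from stability selection over random
variable subsets, retaining edges present in ≥ π of the refits in which
both endpoints were sampled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from numba import njit


@dataclass
class JewelConfig:
    """Tuning parameters of the joint GGM estimator."""

    lambda1: float = 0.1
    lambda2: float = 0.001
    B: int = 1000
    pi_thr: float = 0.8
    subset_fraction: float = 0.8
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be non-negative")
        if not 0 < self.subset_fraction <= 1:
            raise ValueError("subset_fraction must lie in (0, 1]")
        if not 0 < self.pi_thr <= 1:
            raise ValueError("pi_thr must lie in (0, 1]")
        if self.B < 1:
            raise ValueError("B must be ≥ 1")


# ---------------------------------------------------------------- kernels

@njit(cache=True)
def _solve_block(u: float, v: float, A: float, B: float, lam: float):
    """Minimize (A a² + B b²)/2 − u a − v b + λ‖(a,b)‖₂."""
    norm = math.sqrt(u * u + v * v)
    if norm <= lam:
        return 0.0, 0.0
    if lam == 0.0:
        return u / A, v / B
    if abs(A - B) < 1e-12:
        f = (1.0 - lam / norm) / A
        return u * f, v * f
    # general diagonal case: solve s·t(s) = λ for s = λ/‖(a,b)‖
    lo, hi = 0.0, 1.0
    for _ in range(200):
        t = math.sqrt((u / (A + hi)) ** 2 + (v / (B + hi)) ** 2)
        if hi * t >= lam:
            break
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        t = math.sqrt((u / (A + mid)) ** 2 + (v / (B + mid)) ** 2)
        if mid * t < lam:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    return u / (A + s), v / (B + s)


@njit(cache=True)
def _cd_fit(Xc, offs, nks, nrm, lam1, lam2, tol, max_iter, track_objective):
    """Block coordinate descent from zero initialization.

    ``Xc`` stacks the K group matrices row-wise; ``offs`` gives group row
    offsets. Residual matrices are maintained incrementally. Sweep order
    is fixed for determinism: common blocks in (i, j) lexicographic order,
    then each group's specific blocks.
    """
    K = len(nks)
    p = Xc.shape[1]
    Om = np.zeros((p, p))
    Ga = np.zeros((K, p, p))
    R = Xc.copy()
    obj_path = np.empty(max_iter)
    n_sweeps = 0
    converged = False

    for it in range(max_iter):
        delta = 0.0
        # common blocks
        for i in range(p):
            for j in range(i + 1, p):
                A = 0.0
                Bc = 0.0
                u = 0.0
                v = 0.0
                for k in range(K):
                    du = 0.0
                    dv = 0.0
                    for r in range(offs[k], offs[k + 1]):
                        du += Xc[r, i] * R[r, j]
                        dv += Xc[r, j] * R[r, i]
                    u += du / nks[k]
                    v += dv / nks[k]
                    A += nrm[k, i]
                    Bc += nrm[k, j]
                u += A * Om[i, j]
                v += Bc * Om[j, i]
                a, b = _solve_block(u, v, A, Bc, lam1)
                da = a - Om[i, j]
                db = b - Om[j, i]
                if da != 0.0:
                    for r in range(offs[0], offs[K]):
                        R[r, j] -= Xc[r, i] * da
                    Om[i, j] = a
                if db != 0.0:
                    for r in range(offs[0], offs[K]):
                        R[r, i] -= Xc[r, j] * db
                    Om[j, i] = b
                if abs(da) > delta:
                    delta = abs(da)
                if abs(db) > delta:
                    delta = abs(db)
        # group-specific blocks
        for k in range(K):
            for i in range(p):
                for j in range(i + 1, p):
                    du = 0.0
                    dv = 0.0
                    for r in range(offs[k], offs[k + 1]):
                        du += Xc[r, i] * R[r, j]
                        dv += Xc[r, j] * R[r, i]
                    u = du / nks[k] + nrm[k, i] * Ga[k, i, j]
                    v = dv / nks[k] + nrm[k, j] * Ga[k, j, i]
                    a, b = _solve_block(u, v, nrm[k, i], nrm[k, j], lam2)
                    da = a - Ga[k, i, j]
                    db = b - Ga[k, j, i]
                    if da != 0.0:
                        for r in range(offs[k], offs[k + 1]):
                            R[r, j] -= Xc[r, i] * da
                        Ga[k, i, j] = a
                    if db != 0.0:
                        for r in range(offs[k], offs[k + 1]):
                            R[r, i] -= Xc[r, j] * db
                        Ga[k, j, i] = b
                    if abs(da) > delta:
                        delta = abs(da)
                    if abs(db) > delta:
                        delta = abs(db)
        if track_objective:
            obj = 0.0
            for k in range(K):
                rss = 0.0
                for r in range(offs[k], offs[k + 1]):
                    for j in range(p):
                        rss += R[r, j] * R[r, j]
                obj += rss / (2.0 * nks[k])
            for i in range(p):
                for j in range(i + 1, p):
                    obj += lam1 * math.sqrt(Om[i, j] ** 2 + Om[j, i] ** 2)
                    for k in range(K):
                        obj += lam2 * math.sqrt(
                            Ga[k, i, j] ** 2 + Ga[k, j, i] ** 2
                        )
            obj_path[it] = obj
        n_sweeps = it + 1
        if delta < tol:
            converged = True
            break
    return Om, Ga, R, n_sweeps, converged, obj_path[:n_sweeps]


# ----------------------------------------------------------- public API

def standardize(
    Xs: Mapping[str, pd.DataFrame | np.ndarray]
) -> dict[str, np.ndarray]:
    """Per-group, per-column standardization (mean 0, sample SD 1)."""
    out = {}
    for g, X in Xs.items():
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
        arr = np.asarray(X, dtype=float)
        if arr.shape[0] < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        sd = arr.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [cols[i] for i in zero] if cols else list(zero)
            raise ValueError(f"zero-variance columns in group {g!r}: {names[:20]}")
        out[g] = (arr - arr.mean(axis=0)) / sd
    return out


@dataclass
class CoefficientSet:
    """Fitted common + group-specific node-wise regression coefficients."""

    omega: np.ndarray
    gamma: dict[str, np.ndarray]
    n_k: dict[str, int]
    residuals: dict[str, np.ndarray]
    n_iter: int
    converged: bool
    objective_path: np.ndarray | None = None
    var_names: list[str] | None = None

    @property
    def groups(self) -> list[str]:
        return list(self.gamma)

    def theta(self, group: str) -> np.ndarray:
        return self.omega + self.gamma[group]

    def adjacency(self, group: str) -> np.ndarray:
        """Symmetric boolean adjacency: block (i,j) active in this group."""
        th = self.theta(group)
        adj = (th != 0) | (th.T != 0)
        np.fill_diagonal(adj, False)
        return adj

    def edge_set(self, group: str) -> set[tuple[int, int]]:
        adj = self.adjacency(group)
        p = adj.shape[0]
        return {(i, j) for i in range(p) for j in range(i + 1, p) if adj[i, j]}


def _stack(Xs: Mapping[str, np.ndarray]):
    groups = list(Xs)
    mats = [np.ascontiguousarray(Xs[g], dtype=float) for g in groups]
    p = mats[0].shape[1]
    if any(m.shape[1] != p for m in mats):
        raise ValueError("all groups must share the same variable set")
    offs = np.zeros(len(mats) + 1, dtype=np.int64)
    for i, m in enumerate(mats):
        offs[i + 1] = offs[i] + m.shape[0]
    Xc = np.vstack(mats)
    nks = np.array([m.shape[0] for m in mats], dtype=float)
    nrm = np.vstack([(m**2).sum(axis=0) / m.shape[0] for m in mats])
    return groups, Xc, offs, nks, nrm


def fit_jewel(
    Xs: Mapping[str, np.ndarray],
    cfg: JewelConfig,
    track_objective: bool = False,
) -> CoefficientSet:
    """Fit the joint node-wise group-lasso model by coordinate descent.

    Inputs must be standardized (see :func:`standardize`). Deterministic:
    zero initialization and a fixed sweep order. Non-convergence within
    ``max_iter`` sweeps returns a flagged result rather than raising.
    """
    groups, Xc, offs, nks, nrm = _stack(Xs)
    means = np.abs(Xc.mean(axis=0))
    if means.max() > 1e-6:
        raise ValueError("inputs do not look standardized (nonzero column means)")
    Om, Ga, R, n_iter, converged, obj = _cd_fit(
        Xc, offs, nks, nrm, cfg.lambda1, cfg.lambda2, cfg.tol, cfg.max_iter,
        track_objective,
    )
    if not converged:
        warnings.warn(f"coordinate descent did not converge in {n_iter} sweeps")
    residuals = {
        g: R[offs[i] : offs[i + 1]] for i, g in enumerate(groups)
    }
    names = None
    first = Xs[groups[0]]
    if isinstance(first, pd.DataFrame):
        names = list(first.columns)
    return CoefficientSet(
        omega=Om,
        gamma={g: Ga[i] for i, g in enumerate(groups)},
        n_k={g: int(nks[i]) for i, g in enumerate(groups)},
        residuals=residuals,
        n_iter=n_iter,
        converged=converged,
        objective_path=obj if track_objective else None,
        var_names=names,
    )


def lambda1_max(Xs: Mapping[str, np.ndarray]) -> float:
    """Smallest λ1 zeroing every common block at the zero solution."""
    _, Xc, offs, nks, _ = _stack(Xs)
    p = Xc.shape[1]
    cors = np.zeros((p, p))
    for k in range(len(nks)):
        Xk = Xc[offs[k] : offs[k + 1]]
        cors += Xk.T @ Xk / nks[k]
    np.fill_diagonal(cors, 0.0)
    return float(np.sqrt(2.0) * np.abs(cors).max())


def kkt_check(
    Xs: Mapping[str, np.ndarray], fit: CoefficientSet, cfg: JewelConfig
) -> dict[str, float]:
    """Maximum KKT violation over common and specific blocks at a solution.

    For a zero block the subgradient condition requires the residual
    correlation norm ≤ λ; for an active block, stationarity must hold with
    equality. Returns the worst violation of each kind.
    """
    groups, Xc, offs, nks, nrm = _stack(Xs)
    p = Xc.shape[1]
    R = np.vstack([fit.residuals[g] for g in groups])
    viol_zero = 0.0
    viol_active = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            u = v = A = B = 0.0
            for k in range(len(groups)):
                Xk = Xc[offs[k] : offs[k + 1]]
                Rk = R[offs[k] : offs[k + 1]]
                u += Xk[:, i] @ Rk[:, j] / nks[k]
                v += Xk[:, j] @ Rk[:, i] / nks[k]
                A += nrm[k, i]
                B += nrm[k, j]
            a, b = fit.omega[i, j], fit.omega[j, i]
            if a == 0 and b == 0:
                viol_zero = max(viol_zero, math.hypot(u, v) - cfg.lambda1)
            else:
                t = math.hypot(a, b)
                viol_active = max(
                    viol_active,
                    abs(u - cfg.lambda1 * a / t),
                    abs(v - cfg.lambda1 * b / t),
                )
            for k, g in enumerate(groups):
                Xk = Xc[offs[k] : offs[k + 1]]
                Rk = R[offs[k] : offs[k + 1]]
                uk = Xk[:, i] @ Rk[:, j] / nks[k]
                vk = Xk[:, j] @ Rk[:, i] / nks[k]
                ga, gb = fit.gamma[g][i, j], fit.gamma[g][j, i]
                if ga == 0 and gb == 0:
                    viol_zero = max(viol_zero, math.hypot(uk, vk) - cfg.lambda2)
                else:
                    t = math.hypot(ga, gb)
                    viol_active = max(
                        viol_active,
                        abs(uk - cfg.lambda2 * ga / t),
                        abs(vk - cfg.lambda2 * gb / t),
                    )
    return {"zero": viol_zero, "active": viol_active}


def select_features(
    contrast_table: pd.DataFrame,
    n_aptamers: int = 800,
    contrast: str = "mild-healthy",
) -> tuple[list[str], int]:
    """Top-n aptamers by |log2fc| of the chosen contrast.

    Ties break by smaller SE, then lexicographic seq_id. Returns the
    selected seq_ids and the unique protein count when a ``uniprot`` column
    is present (else the aptamer count).
    """
    sub = contrast_table[contrast_table["contrast"] == contrast].copy()
    if sub.empty:
        raise ValueError(f"no rows for contrast {contrast!r}")
    if n_aptamers > len(sub):
        warnings.warn(
            f"requested {n_aptamers} aptamers but only {len(sub)} available; taking all"
        )
    sub["_absfc"] = sub["log2fc"].abs()
    sub = sub.sort_values(
        ["_absfc", "se", "seq_id"], ascending=[False, True, True], kind="stable"
    )
    chosen = sub.head(n_aptamers)
    if "uniprot" in chosen.columns:
        n_prot = int(chosen.loc[chosen["uniprot"] != "", "uniprot"].nunique())
    else:
        n_prot = len(chosen)
    return list(chosen["seq_id"]), n_prot


def bic(fit: CoefficientSet) -> float:
    """BIC of a fitted model: Σ_k [Σ_j n_k·log(RSS_jk/n_k) + log(n_k)·df_k].

    df_k counts nonzero symmetric coefficient blocks of Θ^(k) = Ω + Γ^(k).
    """
    total = 0.0
    for g in fit.groups:
        R = fit.residuals[g]
        n_k = fit.n_k[g]
        rss = (R**2).sum(axis=0)
        rss = np.maximum(rss, 1e-300)
        adj = fit.adjacency(g)
        df_k = int(adj.sum() // 2)
        total += float(n_k * np.log(rss / n_k).sum()) + math.log(n_k) * df_k
    return total


def bic_select(
    Xs: Mapping[str, np.ndarray],
    grid1: Sequence[float],
    grid2: Sequence[float],
    lambda2_fixed: float = 0.001,
    cfg: JewelConfig | None = None,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Two-stage BIC scan: λ1 with λ2 fixed, then λ2 with λ1 fixed.

    Stability selection is not applied during the scan. Returns the chosen
    (λ1, λ2) and the full BIC path with per-candidate edge counts (the
    sparsity the scan also weighs). Ties take the first (smallest) grid
    value.
    """
    if not len(grid1) or not len(grid2):
        raise ValueError("grids must be nonempty")
    base = cfg or JewelConfig()
    records = []

    def evaluate(l1, l2, stage):
        c = JewelConfig(
            lambda1=l1, lambda2=l2, tol=base.tol, max_iter=base.max_iter,
            B=base.B, pi_thr=base.pi_thr, subset_fraction=base.subset_fraction,
            seed=base.seed,
        )
        fit = fit_jewel(Xs, c)
        edges = {g: len(fit.edge_set(g)) for g in fit.groups}
        records.append(
            dict(stage=stage, lambda1=l1, lambda2=l2, bic=bic(fit),
                 converged=fit.converged, **{f"edges_{g}": e for g, e in edges.items()})
        )
        return records[-1]

    for l1 in grid1:
        evaluate(float(l1), float(lambda2_fixed), 1)
    stage1 = [r for r in records if r["stage"] == 1]
    if not any(r["converged"] for r in stage1):
        raise RuntimeError("no stage-1 fit converged")
    best1 = min(stage1, key=lambda r: r["bic"])["lambda1"]
    for l2 in grid2:
        evaluate(float(best1), float(l2), 2)
    stage2 = [r for r in records if r["stage"] == 2]
    best2 = min(stage2, key=lambda r: r["bic"])["lambda2"]
    return (best1, best2), pd.DataFrame(records)


@dataclass
class JointGraphEstimate:
    """Stability-selected per-group graphs with edge frequencies."""

    groups: list[str]
    adjacency: dict[str, np.ndarray]
    frequency: dict[str, np.ndarray]
    cooccurrence: np.ndarray
    var_names: list[str]
    node_labels: dict[str, str]
    lambdas: tuple[float, float]
    n_undefined_edges: int
    retained_nodes: list[int] = field(default_factory=list)

    def graph(self, group: str) -> nx.Graph:
        """Retained-node graph for one group, nodes named by variable."""
        G = nx.Graph()
        adj = self.adjacency[group]
        names = self.var_names
        for i in self.retained_nodes:
            G.add_node(names[i])
        for i in range(adj.shape[0]):
            for j in range(i + 1, adj.shape[1]):
                if adj[i, j]:
                    G.add_edge(names[i], names[j])
        return G

    def edge_frequencies(self, group: str) -> pd.DataFrame:
        freq = self.frequency[group]
        adj = self.adjacency[group]
        rows = [
            dict(node_a=self.var_names[i], node_b=self.var_names[j],
                 frequency=freq[i, j])
            for i in range(adj.shape[0])
            for j in range(i + 1, adj.shape[1])
            if adj[i, j]
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "frequency"])


def stability_selection(
    Xs: Mapping[str, np.ndarray],
    cfg: JewelConfig,
    var_names: Sequence[str] | None = None,
    node_labels: Mapping[str, str] | None = None,
) -> JointGraphEstimate:
    """Stability selection over random variable subsets.

    For each of B resamples, ⌈subset_fraction·p⌉ variables are drawn
    uniformly without replacement and the joint model refit on the
    restriction; an edge's frequency is its presence count divided by the
    number of resamples in which both endpoints co-occurred. Edges with
    frequency ≥ pi_thr are retained; nodes keep membership only with at
    least one retained edge in some group.
    """
    groups = list(Xs)
    arrays = {g: np.asarray(Xs[g], dtype=float) for g in groups}
    p = arrays[groups[0]].shape[1]
    if var_names is None:
        first = Xs[groups[0]]
        var_names = (
            list(first.columns)
            if isinstance(first, pd.DataFrame)
            else [f"v{i}" for i in range(p)]
        )
    q = max(2, math.ceil(cfg.subset_fraction * p))
    rng = np.random.default_rng(cfg.seed)
    presence = {g: np.zeros((p, p)) for g in groups}
    cooccur = np.zeros((p, p))

    for _ in range(cfg.B):
        idx = np.sort(rng.choice(p, size=min(q, p), replace=False))
        sub = {g: np.ascontiguousarray(arrays[g][:, idx]) for g in groups}
        fit = fit_jewel(sub, cfg)
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        cooccur[ii, jj] += 1
        for g in groups:
            adj = fit.adjacency(g)
            presence[g][ii, jj] += adj

    iu = np.triu_indices(p, 1)
    n_undef = int((cooccur[iu] == 0).sum())
    frequency = {}
    adjacency = {}
    for g in groups:
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(cooccur > 0, presence[g] / np.maximum(cooccur, 1), 0.0)
        frequency[g] = freq
        adj = freq >= cfg.pi_thr
        np.fill_diagonal(adj, False)
        adjacency[g] = adj

    any_adj = np.zeros((p, p), dtype=bool)
    for g in groups:
        any_adj |= adjacency[g]
    retained = [i for i in range(p) if any_adj[i].any()]

    return JointGraphEstimate(
        groups=groups,
        adjacency=adjacency,
        frequency=frequency,
        cooccurrence=cooccur,
        var_names=list(var_names),
        node_labels=dict(node_labels or {}),
        lambdas=(cfg.lambda1, cfg.lambda2),
        n_undefined_edges=n_undef,
        retained_nodes=retained,
    )


def collapse_by_label(G: nx.Graph, labels: Mapping[str, str]) -> nx.Graph:
    """Merge nodes sharing a label (aptamers of one protein) by edge union."""
    H = nx.Graph()
    for node in G.nodes:
        H.add_node(labels.get(node, node))
    for u, v in G.edges:
        lu, lv = labels.get(u, u), labels.get(v, v)
        if lu != lv:
            H.add_edge(lu, lv)
    return H
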