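"""Batched linear mixed-effect differential abundance.

Aptamers are analyzed in random batches (default 50 at a time, for
tractable model sizes while retaining pooled-variance shrinkage within a
batch). Each batch is one REML mixed model on long-format data: fixed
effects are aptamer, study group, sex and (centered) age plus the
aptamer-interactions of each; the random intercept is per subject,
accounting for the clustering of all of a donor's aptamer measurements.
Group contrasts (mild−healthy, lateOA−healthy) are adjusted means at the
mean age, averaged over sex — because no group×covariate interactions are
modeled these equal the group coefficient sums directly. 95% CIs use t
quantiles with Satterthwaite degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import _lmm
from .preprocess import IntensityMatrix

#: contrasts reported, as (group, reference) pairs
CONTRASTS = {
    "mild-healthy": ("mild", "healthy"),
    "lateOA-healthy": ("lateOA", "healthy"),
}

REFERENCE_GROUP = "healthy"


@dataclass
class BatchPlan:
    """A random partition of aptamers into model batches."""

    batch_size: int
    seed: int
    batches: list[list[str]]

    def __post_init__(self) -> None:
        sizes = [len(b) for b in self.batches]
        if any(s > self.batch_size for s in sizes):
            raise ValueError("a batch exceeds batch_size")
        flat = [s for b in self.batches for s in b]
        if len(flat) != len(set(flat)):
            raise ValueError("batches must partition the aptamer set")


def plan_batches(
    seq_ids: Sequence[str], batch_size: int = 50, seed: int = 0
) -> BatchPlan:
    """Randomly permute aptamers and chunk into ⌈p/batch_size⌉ batches."""
    if batch_size < 1:
        raise ValueError("batch_size must be ≥ 1")
    rng = np.random.default_rng(seed)
    perm = [seq_ids[i] for i in rng.permutation(len(seq_ids))]
    batches = [perm[i : i + batch_size] for i in range(0, len(perm), batch_size)]
    return BatchPlan(batch_size=batch_size, seed=seed, batches=batches)


@dataclass
class BatchFit:
    """One fitted batch model with everything needed for contrasts."""

    batch: list[str]
    colnames: list[str]
    params: np.ndarray
    cov: np.ndarray
    sigma_subject2: float
    sigma_resid2: float
    df_resid: float
    flagged: bool
    group_levels: list[str]
    lmm_data: _lmm.LMMData | None
    batch_id: int = 0
    n_iter_note: str = ""
    rowspace: np.ndarray | None = None


def _long_design(
    values: pd.DataFrame, samples: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Build the long-format design for one batch.

    Returns (X, y, subject, colnames, group_levels). Rows with missing
    responses are dropped (relevant for MS protein tables).
    """
    batch = list(values.columns)
    m = len(batch)
    meta = samples.set_index("sample_id").loc[values.index]
    present = [g for g in ("healthy", "mild", "lateOA") if (meta["group"] == g).any()]
    extra = sorted(set(meta["group"]) - set(present))
    group_levels = present + extra
    if group_levels[0] != REFERENCE_GROUP and REFERENCE_GROUP in group_levels:
        group_levels.remove(REFERENCE_GROUP)
        group_levels.insert(0, REFERENCE_GROUP)

    n = len(values)
    y = values.to_numpy(dtype=float).ravel()  # sample-major, aptamer fastest
    apt_idx = np.tile(np.arange(m), n)
    subject = np.repeat(meta["subject_id"].to_numpy(), m)

    # aptamer dummies (first aptamer is the reference)
    A = np.zeros((n * m, m - 1)) if m > 1 else np.zeros((n * m, 0))
    if m > 1:
        rows = np.arange(n * m)
        mask = apt_idx > 0
        A[rows[mask], apt_idx[mask] - 1] = 1.0

    sex_f = np.repeat((meta["sex"] == "F").to_numpy(dtype=float), m)
    age_c = np.repeat(
        meta["age"].to_numpy(dtype=float) - float(meta["age"].mean()), m
    )
    gcols = {
        g: np.repeat((meta["group"] == g).to_numpy(dtype=float), m)
        for g in group_levels[1:]
    }

    blocks = [np.ones((n * m, 1)), A]
    colnames = ["const"] + [f"apt[{s}]" for s in batch[1:]]
    for g in group_levels[1:]:
        blocks.append(gcols[g][:, None])
        colnames.append(f"group[{g}]")
    blocks += [sex_f[:, None], age_c[:, None]]
    colnames += ["sex[F]", "age_c"]
    if m > 1:
        for g in group_levels[1:]:
            blocks.append(gcols[g][:, None] * A)
            colnames += [f"group[{g}]:apt[{s}]" for s in batch[1:]]
        blocks.append(sex_f[:, None] * A)
        colnames += [f"sex[F]:apt[{s}]" for s in batch[1:]]
        blocks.append(age_c[:, None] * A)
        colnames += [f"age_c:apt[{s}]" for s in batch[1:]]
    X = np.hstack(blocks)

    ok = np.isfinite(y)
    return X[ok], y[ok], subject[ok], colnames, group_levels


def fit_batch(
    matrix_log2: IntensityMatrix,
    samples: pd.DataFrame,
    batch: Sequence[str],
    batch_id: int = 0,
) -> BatchFit:
    """REML fit of one batch's mixed model (random intercept per subject).

    Degenerate fits (zero residual variance, convergence failure) fall back
    to ordinary least squares with a residual-df flag rather than failing.
    """
    if matrix_log2.scale != "log2":
        raise ValueError("fit_batch requires a log2-scale matrix")
    missing = [s for s in batch if s not in matrix_log2.data.columns]
    if missing:
        raise ValueError(f"batch aptamers absent from the matrix: {missing}")
    values = matrix_log2.data[list(batch)]
    X, y, subject, colnames, group_levels = _long_design(values, samples)
    k = X.shape[1]
    df_resid = float(len(y) - np.linalg.matrix_rank(X))

    flagged = False
    note = ""
    su2 = se2 = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=subject)
            res = model.fit(reml=True, method="lbfgs")
        su2 = float(np.asarray(res.cov_re)[0, 0])
        se2 = float(res.scale)
        if not (np.isfinite(su2) and np.isfinite(se2)) or se2 <= 1e-10:
            raise ValueError("degenerate variance estimates")
    except Exception as exc:  # singular / non-converged fits
        flagged = True
        note = f"fallback OLS: {exc}"

    data = _lmm.prepare(X, y, subject)
    if flagged:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        se2 = rss / max(df_resid, 1.0)
        su2 = 0.0
    # closed-form GLS at the estimated variance components, so that the
    # coefficient covariance and Satterthwaite df come from one surface;
    # pseudoinverse handles rank-deficient designs (estimability is
    # checked per contrast)
    xtvx, xtvy, _, _ = _lmm._gls_mats(data, su2, se2)
    U, sv, Vt = np.linalg.svd(xtvx)
    rank_tol = sv.max() * max(xtvx.shape) * np.finfo(float).eps
    inv_sv = np.where(sv > rank_tol, 1.0 / np.maximum(sv, rank_tol), 0.0)
    cov = (Vt.T * inv_sv) @ U.T
    beta = cov @ xtvy
    rowspace = Vt[sv > rank_tol]
    return BatchFit(
        batch=list(batch),
        colnames=colnames,
        params=beta,
        cov=cov,
        sigma_subject2=su2,
        sigma_resid2=se2,
        df_resid=df_resid,
        flagged=flagged,
        group_levels=group_levels,
        lmm_data=data,
        batch_id=batch_id,
        n_iter_note=note,
        rowspace=rowspace,
    )


def _contrast_vector(fit: BatchFit, sid: str, group: str) -> np.ndarray | None:
    """Contrast (group − healthy) for one aptamer's adjusted means."""
    if group not in fit.group_levels:
        return None
    c = np.zeros(len(fit.colnames))
    try:
        c[fit.colnames.index(f"group[{group}]")] = 1.0
    except ValueError:
        return None
    inter = f"group[{group}]:apt[{sid}]"
    if inter in fit.colnames:
        c[fit.colnames.index(inter)] = 1.0
    elif sid != fit.batch[0] and len(fit.batch) > 1:
        return None
    return c


def contrasts(fit: BatchFit, level: float = 0.95) -> pd.DataFrame:
    """Per-aptamer group contrasts with Satterthwaite-t confidence intervals."""
    rows = []
    for sid in fit.batch:
        for cname, (group, _ref) in CONTRASTS.items():
            c = _contrast_vector(fit, sid, group)
            if c is None:
                continue
            est = float(c @ fit.params)
            var = float(c @ fit.cov @ c)
            estimable = True
            if fit.rowspace is not None:
                proj = fit.rowspace.T @ (fit.rowspace @ c)
                estimable = float(np.linalg.norm(c - proj)) < 1e-8 * max(
                    1.0, float(np.linalg.norm(c))
                )
            if var <= 0 or not estimable:
                rows.append(
                    dict(seq_id=sid, contrast=cname, log2fc=np.nan, se=np.nan,
                         df=np.nan, ci_low=np.nan, ci_high=np.nan,
                         batch_id=fit.batch_id)
                )
                continue
            se = float(np.sqrt(var))
            if fit.flagged or fit.lmm_data is None:
                df = fit.df_resid
            else:
                df = _lmm.satterthwaite_df(
                    fit.lmm_data, fit.sigma_subject2, fit.sigma_resid2, c,
                    fallback=fit.df_resid,
                )
            tq = float(scipy.stats.t.ppf(0.5 + level / 2, max(df, 1.0)))
            rows.append(
                dict(
                    seq_id=sid, contrast=cname, log2fc=est, se=se, df=df,
                    ci_low=est - tq * se, ci_high=est + tq * se,
                    batch_id=fit.batch_id,
                )
            )
    return pd.DataFrame(rows)


def run_differential(
    matrix_log2: IntensityMatrix,
    samples: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    batch_size: int = 50,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Plan batches, fit each, and assemble the full contrast table."""
    plan = plan_batches(matrix_log2.seq_ids, batch_size=batch_size, seed=seed)
    tables = []
    for b, batch in enumerate(plan.batches):
        fit = fit_batch(matrix_log2, samples, batch, batch_id=b)
        tables.append(contrasts(fit, level=level))
    out = pd.concat(tables, ignore_index=True)
    if annotations is not None:
        ann = annotations.set_index("seq_id")[["uniprot_ids", "gene_symbol"]]
        out = out.join(ann, on="seq_id")
        out = out.rename(columns={"uniprot_ids": "uniprot", "gene_symbol": "gene"})
    return out


def flag_differential(table: pd.DataFrame) -> pd.DataFrame:
    """Mark contrasts whose 95% CI excludes zero as up- or down-regulated."""
    out = table.copy()
    out["direction"] = "ns"
    out.loc[out["ci_low"] > 0, "direction"] = "up"
    out.loc[out["ci_high"] < 0, "direction"] = "down"
    return out


def protein_direction_counts(flagged: pd.DataFrame, contrast: str) -> dict[str, int]:
    """Collapse aptamer flags to protein counts (any qualifying aptamer counts).

    Requires a ``uniprot`` column (join annotations via ``run_differential``).
    """
    if "uniprot" not in flagged.columns:
        raise ValueError("table lacks a 'uniprot' column")
    sub = flagged[(flagged["contrast"] == contrast) & (flagged["uniprot"] != "")]
    up = sub.loc[sub["direction"] == "up", "uniprot"].nunique()
    down = sub.loc[sub["direction"] == "down", "uniprot"].nunique()
    return {"up": int(up), "down": int(down)}
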