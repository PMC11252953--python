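"""Aptamer-level quality control for affinity-proteomics intensity matrices.

Implements the platform's standard preprocessing: a per-aptamer limit of
detection (LOD) from buffer wells (log2 buffer mean + 5 buffer SDs),
sequential three-stage aptamer filtering (no UniProt mapping → non-human
target → any study sample below LOD), log2 transformation, and technical
repeatability coefficients from replicate sample pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: organisms accepted by the default filter (case-insensitive)
DEFAULT_ORGANISMS = frozenset({"human", "homo sapiens"})


@dataclass
class IntensityMatrix:
    """Samples × aptamers abundance matrix with an explicit scale flag.

    ``data`` rows are samples, columns are aptamer sequence IDs. ``scale``
    is ``"linear"`` (relative fluorescence units, strictly positive) or
    ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicated sample ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicated aptamer seq ids")
        if self.scale == "linear" and (self.data.to_numpy() <= 0).any():
            raise ValueError("linear-scale intensities must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def seq_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.data.loc[list(sample_ids)], scale=self.scale)

    def subset_aptamers(self, seq_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.data[list(seq_ids)], scale=self.scale)


@dataclass
class LODTable:
    """Per-aptamer limit of detection on the log2 scale."""

    lod: pd.Series
    n_buffer: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.lod.to_numpy()).all():
            raise ValueError("LOD values must be finite")


@dataclass
class FilterReport:
    """Stage-wise record of the sequential aptamer filter."""

    n_input: int
    removed_unmapped: list[str] = field(default_factory=list)
    removed_nonhuman: list[str] = field(default_factory=list)
    removed_below_lod: list[str] = field(default_factory=list)
    retained_seq_ids: list[str] = field(default_factory=list)
    retained_protein_count: int = 0

    @property
    def counts(self) -> dict[str, int]:
        return {
            "unmapped": len(self.removed_unmapped),
            "nonhuman": len(self.removed_nonhuman),
            "below_lod": len(self.removed_below_lod),
            "retained": len(self.retained_seq_ids),
        }

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "counts": self.counts,
            "retained_protein_count": self.retained_protein_count,
            "removed_unmapped": self.removed_unmapped,
            "removed_nonhuman": self.removed_nonhuman,
            "removed_below_lod": self.removed_below_lod,
        }


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2 of a linear-scale matrix.

    Refuses already-log2 input (double transformation is a silent and
    common preprocessing bug) and nonpositive values, reporting offending
    coordinates.
    """
    if matrix.scale == "log2":
        raise ValueError("matrix is already log2-scale; refusing to transform again")
    vals = matrix.data.to_numpy()
    if (vals <= 0).any():
        bad = np.argwhere(vals <= 0)
        coords = [
            (matrix.sample_ids[i], matrix.seq_ids[j]) for i, j in bad[:10]
        ]
        raise ValueError(f"nonpositive values at (sample, aptamer): {coords}")
    return IntensityMatrix(np.log2(matrix.data), scale="log2")


def _as_log2(matrix: IntensityMatrix) -> IntensityMatrix:
    return matrix if matrix.scale == "log2" else log2_transform(matrix)


def compute_lod(buffer_matrix: IntensityMatrix, k: float = 5.0) -> LODTable:
    """Per-aptamer LOD = log2 buffer mean + ``k`` × log2 buffer SD (ddof=1).

    Requires at least two buffer samples; the SD uses the n−1 denominator.
    """
    n = len(buffer_matrix.sample_ids)
    if n < 2:
        raise ValueError(
            f"need ≥2 buffer samples to compute an LOD for "
            f"{len(buffer_matrix.seq_ids)} aptamers; got {n}"
        )
    logm = _as_log2(buffer_matrix).data
    lod = logm.mean(axis=0) + k * logm.std(axis=0, ddof=1)
    return LODTable(lod=lod, n_buffer=n)


def filter_aptamers(
    matrix: IntensityMatrix,
    annotations: pd.DataFrame,
    lods: LODTable,
    organisms_allowed: Iterable[str] = DEFAULT_ORGANISMS,
) -> tuple[IntensityMatrix, FilterReport]:
    """Sequential three-stage aptamer filter on a study-sample matrix.

    Stages, applied in order so each aptamer is removed (and counted) at the
    first failing one: (1) empty UniProt mapping; (2) target organism not in
    the allow-list (case-insensitive); (3) any study-sample log2 value below
    the aptamer's LOD. Values of retained aptamers are never modified.
    """
    ann = annotations.set_index("seq_id")
    missing = [s for s in matrix.seq_ids if s not in ann.index]
    if missing:
        raise ValueError(f"aptamers missing from the annotation table: {missing[:20]}")
    allowed = {o.lower() for o in organisms_allowed}

    report = FilterReport(n_input=len(matrix.seq_ids))
    log2m = _as_log2(matrix).data
    keep: list[str] = []
    for sid in matrix.seq_ids:
        row = ann.loc[sid]
        uniprot = str(row["uniprot_ids"]).strip()
        if uniprot in ("", "nan"):
            report.removed_unmapped.append(sid)
        elif str(row["organism"]).strip().lower() not in allowed:
            report.removed_nonhuman.append(sid)
        elif sid in lods.lod.index and (log2m[sid] < lods.lod[sid]).any():
            report.removed_below_lod.append(sid)
        else:
            keep.append(sid)

    report.retained_seq_ids = keep
    report.retained_protein_count = int(
        ann.loc[keep, "uniprot_ids"].astype(str).str.strip().replace("nan", "").nunique()
    )
    return matrix.subset_aptamers(keep), report


def repeatability_coefficients(
    pairs: Sequence[tuple[str, str]],
    matrix: IntensityMatrix,
    lods: LODTable,
) -> pd.DataFrame:
    """Per-aptamer repeatability coefficient (RC) from replicate pairs.

    Eligible aptamers are those above LOD in *all* replicate samples. For m
    pairs with log2 differences d_i, the within-pair SD is
    s_w = sqrt(Σ d_i² / (2m)), RC(log2) = 1.96·√2·s_w, and the reported
    percentage is 100·(2^RC − 1) — the fold-scale half-width of the 95%
    repeatability interval. Ineligible aptamers are excluded, not zeroed.
    """
    if matrix.scale != "log2":
        raise ValueError("repeatability requires a log2-scale matrix")
    if not pairs:
        raise ValueError("need at least one replicate pair")
    rep_samples = [s for pair in pairs for s in pair]
    sub = matrix.data.loc[rep_samples]
    above = (sub >= lods.lod).all(axis=0)
    eligible = [s for s in matrix.seq_ids if bool(above.get(s, False))]
    if not eligible:
        warnings.warn("no aptamer is above LOD in all replicate samples")
        return pd.DataFrame(columns=["s_w", "rc_log2", "rc_percent"])

    diffs = np.vstack(
        [
            matrix.data.loc[a, eligible].to_numpy()
            - matrix.data.loc[b, eligible].to_numpy()
            for a, b in pairs
        ]
    )
    m = len(pairs)
    s_w = np.sqrt((diffs**2).sum(axis=0) / (2 * m))
    rc_log2 = 1.96 * np.sqrt(2.0) * s_w
    return pd.DataFrame(
        {
            "s_w": s_w,
            "rc_log2": rc_log2,
            "rc_percent": 100.0 * (np.exp2(rc_log2) - 1.0),
        },
        index=pd.Index(eligible, name="seq_id"),
    )
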