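"""Cross-platform validation against an MS protein quantification table.

Network proteins found on both platforms pass three sequential evidence
filters (proteotypic peptide present; more than one stripped peptide; more
than 50% non-missing values), then agreement is quantified two ways:
per-protein Pearson correlation of z-scored log2 values across matched
samples, and side-by-side group log2 fold changes from the same mixed
model refit on MS protein quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffabund
from .preprocess import IntensityMatrix


@dataclass
class OverlapReport:
    """Stage counts of the sequential MS evidence filter."""

    n_network: int
    n_overlap: int
    dropped_no_proteotypic: int
    dropped_single_peptide: int
    dropped_missingness: int
    retained: list[str]

    def to_dict(self) -> dict:
        return {
            "n_network": self.n_network,
            "n_overlap": self.n_overlap,
            "dropped_no_proteotypic": self.dropped_no_proteotypic,
            "dropped_single_peptide": self.dropped_single_peptide,
            "dropped_missingness": self.dropped_missingness,
            "n_retained": len(self.retained),
        }


def overlap_filter(
    ms_quant: pd.DataFrame,
    ms_meta: pd.DataFrame,
    network_proteins: list[str],
) -> tuple[list[str], OverlapReport]:
    """Intersect with network proteins, then apply the three evidence filters.

    Order matters and is fixed: (1) drop proteins without a proteotypic
    peptide, (2) drop proteins with ≤ 1 stripped peptide, (3) drop proteins
    with < strictly more than 50% non-missing values. Counts per stage are
    reported; a protein is counted at the first stage it fails.
    """
    overlap = [p for p in network_proteins if p in ms_meta.index]
    stage1, stage2, stage3, kept = [], [], [], []
    n_samples = ms_quant.shape[1]
    for prot in overlap:
        meta = ms_meta.loc[prot]
        if not bool(meta["proteotypic"]):
            stage1.append(prot)
        elif int(meta["n_stripped_peptides"]) <= 1:
            stage2.append(prot)
        else:
            nonmiss = ms_quant.loc[prot].notna().sum() / n_samples
            if nonmiss > 0.5:
                kept.append(prot)
            else:
                stage3.append(prot)
    if not overlap:
        warnings.warn("no overlap between MS table and network proteins")
    report = OverlapReport(
        n_network=len(network_proteins),
        n_overlap=len(overlap),
        dropped_no_proteotypic=len(stage1),
        dropped_single_peptide=len(stage2),
        dropped_missingness=len(stage3),
        retained=kept,
    )
    return kept, report


def cross_correlate(
    ms_quant: pd.DataFrame, soma_quant: pd.DataFrame
) -> pd.DataFrame:
    """Per-protein Pearson correlation of z-scored log2 values.

    Rows are proteins, columns samples, both on the log2 scale. Only shared
    samples enter; missing values are handled pairwise-complete; proteins
    with fewer than 3 complete pairs get an NA correlation.
    """
    shared_samples = [c for c in soma_quant.columns if c in ms_quant.columns]
    shared_proteins = [p for p in soma_quant.index if p in ms_quant.index]
    rows = []
    for prot in shared_proteins:
        x = ms_quant.loc[prot, shared_samples].to_numpy(dtype=float)
        y = soma_quant.loc[prot, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 3:
            rows.append(dict(protein=prot, r=np.nan, n=n))
            continue
        xs, ys = x[ok], y[ok]
        xs = (xs - xs.mean()) / xs.std(ddof=1)
        ys = (ys - ys.mean()) / ys.std(ddof=1)
        r = float((xs * ys).sum() / (n - 1))
        rows.append(dict(protein=prot, r=r, n=n))
    return pd.DataFrame(rows, columns=["protein", "r", "n"])


def compare_foldchanges(
    ms_quant: pd.DataFrame,
    samples: pd.DataFrame,
    soma_contrasts: pd.DataFrame,
    contrast: str = "mild-healthy",
    level: float = 0.95,
) -> pd.DataFrame:
    """Paired (MS, affinity-platform) log2 fold changes per protein.

    Refits the differential-abundance mixed model with protein-level MS
    quantities as the outcome (proteins in place of aptamers, same fixed
    and random structure), then merges with the platform contrast table.
    ``soma_contrasts`` must carry a ``uniprot`` column; proteins absent on
    one platform are dropped with a note column.
    """
    quant_t = ms_quant.T  # samples × proteins
    study = samples[samples["sample_type"] == "study"]
    quant_t = quant_t.loc[[s for s in quant_t.index if s in set(study["sample_id"])]]
    matrix = IntensityMatrix(quant_t, scale="log2")
    fit = diffabund.fit_batch(matrix, study, list(quant_t.columns))
    ms_table = diffabund.contrasts(fit, level=level)
    ms_table = ms_table[ms_table["contrast"] == contrast].rename(
        columns={"seq_id": "uniprot", "log2fc": "ms_log2fc",
                 "ci_low": "ms_ci_low", "ci_high": "ms_ci_high"}
    )[["uniprot", "ms_log2fc", "ms_ci_low", "ms_ci_high"]]

    soma = soma_contrasts[soma_contrasts["contrast"] == contrast]
    # proteins with several aptamers: keep the aptamer with smallest SE
    soma = soma.sort_values("se", kind="stable").drop_duplicates("uniprot")
    soma = soma.rename(
        columns={"log2fc": "soma_log2fc", "ci_low": "soma_ci_low",
                 "ci_high": "soma_ci_high"}
    )[["uniprot", "soma_log2fc", "soma_ci_low", "soma_ci_high"]]

    merged = ms_table.merge(soma, on="uniprot", how="inner")
    merged["sign_agree"] = np.sign(merged["ms_log2fc"]) == np.sign(
        merged["soma_log2fc"]
    )
    return merged
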