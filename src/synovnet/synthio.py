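"""Synthetic synovial-fluid aptamer-proteomics data with known network truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-group multivariate-normal log2 abundances whose inverse
covariance (precision) matrices share a common sparse edge backbone plus a
small number of group-unique edges; additive disease-group, sex and age
effects on a subset of aptamers; one random intercept per donor; buffer
(no-sample) wells near a noise floor; technical replicate pairs; and
annotation defects (aptamers without a UniProt mapping, or targeting
non-human proteins). Ground truth — the precision matrices, edge sets and
true mean shifts — is returned alongside so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import IntensityMatrix

#: canonical study groups, in fixed order
GROUPS = ("healthy", "mild", "lateOA")

#: cohort sizes of the study design the generator emulates
DEFAULT_N_PER_GROUP = {"healthy": 12, "mild": 13, "lateOA": 14}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic data generator.

    Defaults mirror the emulated study: three donor groups of 12/13/14
    independent subjects, ages ~ Normal(71, 8) truncated to [50, 95],
    balanced sex, 3 buffer wells, 6 replicate pairs, and a replicate noise
    SD chosen so repeatability coefficients land near the low-teens percent
    range typical of the platform.
    """

    p: int = 100
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    n_shared_edges: int = 60
    n_unique_edges_per_group: int = 8
    partial_corr_range: tuple[float, float] = (0.3, 0.5)
    n_differential: int = 20
    effect_range: tuple[float, float] = (0.5, 2.0)
    sigma_subject: float = 0.3
    sigma_resid_extra: float = 0.0
    n_buffer: int = 3
    buffer_floor_log2: float = 4.0
    buffer_sd_log2: float = 0.3
    n_replicate_pairs: int = 6
    replicate_sd_log2: float = 0.09
    frac_unmapped: float = 0.005
    frac_nonhuman: float = 0.035
    seed: int = 0
    # -- extra knobs beyond the core statistical structure --
    #: SD multiplier on the network (MVN) component; 0 gives noiseless means
    network_scale: float = 1.0
    #: number of aptamers with additive sex and age effects
    n_covariate_affected: int = 10
    sex_effect_range: tuple[float, float] = (0.2, 0.6)
    age_slope_range: tuple[float, float] = (0.005, 0.02)
    #: per-aptamer baseline log2 abundance drawn uniformly from this range;
    #: the floor sits ~3.5 SD above the buffer noise floor so only a few
    #: percent of aptamers dip below the LOD in any study sample, matching
    #: the platform's typical filtering rate
    baseline_log2_range: tuple[float, float] = (9.0, 15.0)
    #: fraction of aptamers assigned the UniProt ID of another aptamer,
    #: giving the many-to-one aptamer→protein mapping real panels have
    frac_shared_protein: float = 0.05

    def validate(self) -> None:
        if self.p < 2:
            raise ValueError("p must be at least 2")
        if not self.n_per_group:
            raise ValueError("n_per_group must name at least one group")
        max_edges = self.p * (self.p - 1) // 2
        k = len(self.n_per_group)
        total = self.n_shared_edges + k * self.n_unique_edges_per_group
        if self.n_shared_edges < 0 or self.n_unique_edges_per_group < 0:
            raise ValueError("edge counts must be non-negative")
        if total > max_edges:
            raise ValueError(
                f"requested {total} edges but only {max_edges} pairs exist for p={self.p}"
            )
        for name, val in [
            ("frac_unmapped", self.frac_unmapped),
            ("frac_nonhuman", self.frac_nonhuman),
            ("frac_shared_protein", self.frac_shared_protein),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        for name, val in [
            ("sigma_subject", self.sigma_subject),
            ("sigma_resid_extra", self.sigma_resid_extra),
            ("buffer_sd_log2", self.buffer_sd_log2),
            ("replicate_sd_log2", self.replicate_sd_log2),
            ("network_scale", self.network_scale),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be non-negative, got {val}")
        lo, hi = self.partial_corr_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("partial_corr_range magnitudes must lie in (0, 1)")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.n_per_group)


@dataclass
class SyntheticTruth:
    """Generating model: precision matrices, edge sets, effects, annotations."""

    precision_matrices: dict[str, np.ndarray]
    shared_edges: set[tuple[int, int]]
    unique_edges: dict[str, set[tuple[int, int]]]
    differential_aptamers: dict[str, dict[str, float]]
    annotations: pd.DataFrame
    baseline_log2: np.ndarray
    sex_effects: np.ndarray
    age_slopes: np.ndarray

    def edge_set(self, group: str) -> set[tuple[int, int]]:
        """All true edges (shared ∪ unique) of one group, as sorted index pairs."""
        return set(self.shared_edges) | set(self.unique_edges[group])

    def to_json(self) -> str:
        payload = {
            "shared_edges": sorted(map(list, self.shared_edges)),
            "unique_edges": {
                g: sorted(map(list, e)) for g, e in self.unique_edges.items()
            },
            "differential_aptamers": self.differential_aptamers,
            "seq_ids": list(self.annotations["seq_id"]),
        }
        return json.dumps(payload, indent=2)


def _edges_from_precision(omega: np.ndarray, tol: float = 1e-12) -> set[tuple[int, int]]:
    """Read the edge set back off a precision matrix (nonzero off-diagonals)."""
    p = omega.shape[0]
    return {
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(omega[i, j]) > tol
    }


def _make_annotations(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    p = cfg.p
    seq_ids = [f"seq.{i + 1:04d}" for i in range(p)]
    genes = [f"GENE{i + 1}" for i in range(p)]
    uniprot = [f"P{10000 + i + 1}" for i in range(p)]

    # many-to-one aptamer→protein mapping: some aptamers share a UniProt ID
    n_dup = int(round(cfg.frac_shared_protein * p))
    if n_dup and p >= 2:
        dup_idx = rng.choice(p, size=n_dup, replace=False)
        for i in dup_idx:
            donor = int(rng.integers(p))
            if donor != i:
                uniprot[i] = uniprot[donor]
                genes[i] = genes[donor]

    organism = ["Human"] * p
    n_unmapped = int(round(cfg.frac_unmapped * p))
    n_nonhuman = int(round(cfg.frac_nonhuman * p))
    defect_idx = rng.choice(p, size=min(p, n_unmapped + n_nonhuman), replace=False)
    for i in defect_idx[:n_unmapped]:
        uniprot[i] = ""
    for i in defect_idx[n_unmapped:]:
        organism[i] = "Mouse"

    return pd.DataFrame(
        {
            "seq_id": seq_ids,
            "uniprot_ids": uniprot,
            "gene_symbol": genes,
            "organism": organism,
            "dilution_bin": rng.choice(["20%", "0.5%", "0.005%"], size=p),
        }
    )


def make_precision_matrices(config: SyntheticConfig) -> SyntheticTruth:
    """Build K sparse precision matrices sharing a common edge backbone.

    Edge positions (shared and group-unique, mutually disjoint) are sampled
    uniformly without replacement; each edge gets a partial-correlation
    magnitude from ``partial_corr_range`` with random sign (identical across
    groups for shared edges). Off-diagonal precision entries are set to
    −ρ on a unit diagonal, then positive definiteness is enforced by
    diagonal loading: add δ·I with the smallest δ ≥ 0 making the minimum
    eigenvalue at least 0.1. Loading shrinks realized partial correlations
    but never changes the zero pattern, so edge sets are exact.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5157]))
    p = config.p
    groups = config.groups
    k = len(groups)

    all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    need = config.n_shared_edges + k * config.n_unique_edges_per_group
    chosen = rng.choice(len(all_pairs), size=need, replace=False)
    chosen_pairs = [all_pairs[c] for c in chosen]
    shared = set(chosen_pairs[: config.n_shared_edges])
    unique: dict[str, set[tuple[int, int]]] = {}
    pos = config.n_shared_edges
    for g in groups:
        unique[g] = set(chosen_pairs[pos : pos + config.n_unique_edges_per_group])
        pos += config.n_unique_edges_per_group

    lo, hi = config.partial_corr_range

    def draw_rho() -> float:
        return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))

    shared_rho = {e: draw_rho() for e in sorted(shared)}
    mats: dict[str, np.ndarray] = {}
    for g in groups:
        omega = np.eye(p)
        for (i, j), rho in shared_rho.items():
            omega[i, j] = omega[j, i] = -rho
        for i, j in sorted(unique[g]):
            rho = draw_rho()
            omega[i, j] = omega[j, i] = -rho
        lam_min = float(np.linalg.eigvalsh(omega)[0])
        delta = max(0.0, 0.1 - lam_min)
        omega = omega + delta * np.eye(p)
        assert np.linalg.eigvalsh(omega)[0] > 0, "diagonal loading must yield PD"
        mats[g] = omega

    annotations = _make_annotations(config, rng)
    seq_ids = list(annotations["seq_id"])

    diff_idx = rng.choice(p, size=min(config.n_differential, p), replace=False)
    elo, ehi = config.effect_range
    differential: dict[str, dict[str, float]] = {}
    for i in sorted(diff_idx):
        shifts = {}
        for g in groups:
            if g == "healthy":
                shifts[g] = 0.0
            else:
                shifts[g] = float(rng.uniform(elo, ehi) * rng.choice([-1.0, 1.0]))
        differential[seq_ids[i]] = shifts

    baseline = rng.uniform(*config.baseline_log2_range, size=p)
    sex_eff = np.zeros(p)
    age_slope = np.zeros(p)
    cov_idx = rng.choice(p, size=min(config.n_covariate_affected, p), replace=False)
    for i in cov_idx:
        sex_eff[i] = rng.uniform(*config.sex_effect_range) * rng.choice([-1.0, 1.0])
        age_slope[i] = rng.uniform(*config.age_slope_range) * rng.choice([-1.0, 1.0])

    return SyntheticTruth(
        precision_matrices=mats,
        shared_edges=shared,
        unique_edges=unique,
        differential_aptamers=differential,
        annotations=annotations,
        baseline_log2=baseline,
        sex_effects=sex_eff,
        age_slopes=age_slope,
    )


def sample_dataset(
    truth: SyntheticTruth, config: SyntheticConfig
) -> tuple[IntensityMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw one dataset (linear-scale RFU matrix, sample table, annotations).

    Per group the log2 signal is baseline + MVN(0, Ω⁻¹)·network_scale +
    group shift + sex/age effects + subject intercept + optional extra
    residual noise. Buffer wells are i.i.d. Normal(floor, sd) per aptamer;
    replicate rows re-noise existing study samples with technical noise.
    The returned matrix is on the linear scale (2^log2) so downstream log2
    transformation is exercised.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDA7A]))
    p = config.p
    seq_ids = list(truth.annotations["seq_id"])
    seq_index = {s: i for i, s in enumerate(seq_ids)}

    rows: list[np.ndarray] = []
    meta: list[dict] = []
    shift = np.zeros((len(config.groups), p))
    for gi, g in enumerate(config.groups):
        for sid, by_group in truth.differential_aptamers.items():
            shift[gi, seq_index[sid]] = by_group.get(g, 0.0)

    chol = {
        g: np.linalg.cholesky(np.linalg.inv(truth.precision_matrices[g]))
        for g in config.groups
    }

    counter = 0
    for gi, g in enumerate(config.groups):
        n_g = int(config.n_per_group[g])
        z = rng.standard_normal((n_g, p)) @ chol[g].T * config.network_scale
        sexes = rng.integers(0, 2, size=n_g)  # 1 = female
        ages = np.clip(rng.normal(71.0, 8.0, size=n_g), 50.0, 95.0)
        subj = rng.normal(0.0, config.sigma_subject, size=n_g)
        extra = (
            rng.normal(0.0, config.sigma_resid_extra, size=(n_g, p))
            if config.sigma_resid_extra > 0
            else 0.0
        )
        vals = (
            truth.baseline_log2[None, :]
            + z
            + shift[gi][None, :]
            + np.outer(sexes, truth.sex_effects)
            + np.outer(ages - 71.0, truth.age_slopes)
            + subj[:, None]
            + extra
        )
        for r in range(n_g):
            counter += 1
            sample_id = f"S{counter:03d}"
            rows.append(vals[r])
            meta.append(
                {
                    "sample_id": sample_id,
                    "subject_id": f"subj_{sample_id}",
                    "group": g,
                    "sex": "F" if sexes[r] else "M",
                    "age": float(ages[r]),
                    "sample_type": "study",
                    "replicate_of": "",
                }
            )

    # technical replicate pairs: re-noise existing study samples
    n_rep = min(config.n_replicate_pairs, len(rows))
    for r in range(n_rep):
        counter += 1
        noisy = rows[r] + rng.normal(0.0, config.replicate_sd_log2, size=p)
        src = meta[r]
        rows.append(noisy)
        meta.append(
            {
                "sample_id": f"S{counter:03d}",
                "subject_id": src["subject_id"],
                "group": src["group"],
                "sex": src["sex"],
                "age": src["age"],
                "sample_type": "replicate",
                "replicate_of": src["sample_id"],
            }
        )

    for b in range(config.n_buffer):
        counter += 1
        rows.append(
            rng.normal(config.buffer_floor_log2, config.buffer_sd_log2, size=p)
        )
        meta.append(
            {
                "sample_id": f"S{counter:03d}",
                "subject_id": f"buffer_{b + 1}",
                "group": "buffer",
                "sex": "",
                "age": np.nan,
                "sample_type": "buffer",
                "replicate_of": "",
            }
        )

    samples = pd.DataFrame(meta)
    log2_values = pd.DataFrame(
        np.vstack(rows), index=samples["sample_id"], columns=seq_ids
    )
    matrix = IntensityMatrix(
        data=np.exp2(log2_values), scale="linear"
    )
    return matrix, samples, truth.annotations.copy()


def replicate_pairs(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """Extract (original, replicate) sample-id pairs from a sample table."""
    reps = samples[samples["sample_type"] == "replicate"]
    return [
        (str(row["replicate_of"]), str(row["sample_id"]))
        for _, row in reps.iterrows()
    ]


def simulate_ms_platform(
    matrix_log2: IntensityMatrix,
    annotations: pd.DataFrame,
    *,
    seed: int,
    noise_sd: float = 0.5,
    missing_rate: float = 0.1,
    frac_nonproteotypic: float = 0.1,
    frac_single_peptide: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic second-platform (MS-like) protein quantification table.

    Collapses aptamers to proteins (mean of mapped aptamers), adds
    independent platform noise, injects missing values, and fabricates
    peptide-evidence metadata so the overlap filters have something to do.
    Returns ``(quant, meta)``: proteins × samples log2 quantities and
    per-protein metadata (n_stripped_peptides, proteotypic, coverage).
    """
    if matrix_log2.scale != "log2":
        raise ValueError("expected a log2-scale matrix")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3353]))
    ann = annotations[annotations["uniprot_ids"] != ""]
    quant_rows = {}
    for uniprot, grp in ann.groupby("uniprot_ids"):
        cols = [c for c in grp["seq_id"] if c in matrix_log2.data.columns]
        if cols:
            quant_rows[uniprot] = matrix_log2.data[cols].mean(axis=1)
    quant = pd.DataFrame(quant_rows).T
    quant = quant + rng.normal(0.0, noise_sd, size=quant.shape)
    mask = rng.random(quant.shape) < missing_rate
    quant = quant.mask(mask)

    n_prot = len(quant)
    proteotypic = np.ones(n_prot, dtype=bool)
    n_pep = rng.integers(2, 15, size=n_prot)
    idx = rng.permutation(n_prot)
    n_np = int(round(frac_nonproteotypic * n_prot))
    n_sp = int(round(frac_single_peptide * n_prot))
    proteotypic[idx[:n_np]] = False
    n_pep[idx[n_np : n_np + n_sp]] = 1
    meta = pd.DataFrame(
        {
            "uniprot": quant.index,
            "n_stripped_peptides": n_pep,
            "proteotypic": proteotypic,
            "coverage": rng.uniform(5, 80, size=n_prot),
        }
    ).set_index("uniprot")
    return quant, meta


def config_to_json(config: SyntheticConfig) -> str:
    return json.dumps(asdict(config), indent=2, default=list)
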