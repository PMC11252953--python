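"""End-to-end orchestration: simulate → preprocess → differential abundance
→ feature selection → joint GGM → network views → cross-platform check.

Each stage writes its outputs under the run directory and records them,
with SHA-256 checksums, parameters and sub-seeds, in a JSON manifest.
Per-stage sub-seeds are derived deterministically from the global seed by
hashing the stage name, so stages can be re-run in isolation and two runs
with the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossval, diffabund, ggm, io, netview, preprocess, synthio

log = logging.getLogger("synovnet")


@dataclass
class RunConfig:
    """One configuration object driving the whole pipeline."""

    out_dir: str = "run"
    seed: int = 0
    synth: synthio.SyntheticConfig = field(default_factory=synthio.SyntheticConfig)
    lod_k: float = 5.0
    batch_size: int = 50
    top_n: int = 800
    lambda1: float = 0.1
    lambda2: float = 0.001
    stability_B: int = 1000
    pi_thr: float = 0.8
    subset_fraction: float = 0.8
    louvain_runs: int = 20
    min_community_size: int = 3
    ggm_groups: tuple[str, str] = ("healthy", "mild")
    run_crossval: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = synthio.SyntheticConfig(**raw.pop("synth", {}))
        return cls(synth=synth, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "stages": {},
        "checksums": {},
    }

    def record(stage: str, files: dict[str, Path], **info) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            **info,
            "outputs": {k: str(v) for k, v in files.items()},
        }
        for v in files.values():
            manifest["checksums"][str(v)] = io.sha256_file(v)

    try:
        # ---- simulate -------------------------------------------------
        synth_cfg = config.synth
        synth_cfg.seed = stage_seed(config.seed, "simulate")
        truth = synthio.make_precision_matrices(synth_cfg)
        matrix, samples, annotations = synthio.sample_dataset(truth, synth_cfg)
        files = {
            "matrix": out / "intensity.csv",
            "samples": out / "samples.tsv",
            "annotations": out / "annotations.tsv",
            "truth": out / "truth.json",
        }
        io.write_intensity(matrix, files["matrix"])
        io.write_table(samples, files["samples"])
        io.write_table(annotations, files["annotations"])
        files["truth"].write_text(truth.to_json())
        record("simulate", files, n_samples=len(samples), p=synth_cfg.p)
        log.info("simulate: %d samples × %d aptamers", len(samples), synth_cfg.p)

        # ---- preprocess ----------------------------------------------
        buffer_ids = samples.loc[samples["sample_type"] == "buffer", "sample_id"]
        study_ids = samples.loc[samples["sample_type"] == "study", "sample_id"]
        lods = preprocess.compute_lod(
            matrix.subset_samples(list(buffer_ids)), k=config.lod_k
        )
        study = matrix.subset_samples(list(study_ids))
        filtered, report = preprocess.filter_aptamers(study, annotations, lods)
        log2m = preprocess.log2_transform(filtered)
        pairs = synthio.replicate_pairs(samples)
        rc = pd.DataFrame()
        if pairs:
            rep_matrix = preprocess.log2_transform(
                matrix.subset_samples([s for p_ in pairs for s in p_])
            )
            rc = preprocess.repeatability_coefficients(pairs, rep_matrix, lods)
        files = {
            "filtered": out / "filtered_log2.csv",
            "filter_report": out / "filter_report.json",
            "repeatability": out / "repeatability.tsv",
        }
        io.write_intensity(log2m, files["filtered"])
        io.write_json(report.to_dict(), files["filter_report"])
        rc.reset_index().to_csv(files["repeatability"], sep="\t", index=False)
        record("preprocess", files, **report.counts)
        log.info("preprocess: %s", report.counts)

        # ---- differential abundance ----------------------------------
        study_samples = samples[samples["sample_type"] == "study"]
        contrasts = diffabund.run_differential(
            log2m, study_samples, annotations,
            batch_size=config.batch_size,
            seed=stage_seed(config.seed, "diffabund"),
        )
        contrasts = diffabund.flag_differential(contrasts)
        files = {"contrasts": out / "contrasts.tsv"}
        io.write_table(contrasts, files["contrasts"])
        record("diffabund", files, n_contrasts=len(contrasts))
        log.info("diffabund: %d contrast rows", len(contrasts))

        # ---- feature selection ---------------------------------------
        selected, n_prot = ggm.select_features(contrasts, n_aptamers=config.top_n)
        files = {"selected": out / "selected_aptamers.txt"}
        files["selected"].write_text("\n".join(selected) + "\n")
        record("select", files, n_aptamers=len(selected), n_proteins=n_prot)

        # ---- joint GGM with stability selection ----------------------
        g1, g2 = config.ggm_groups
        Xs = {}
        for g in (g1, g2):
            ids = study_samples.loc[study_samples["group"] == g, "sample_id"]
            Xs[g] = log2m.data.loc[list(ids), selected]
        std = ggm.standardize(Xs)
        jcfg = ggm.JewelConfig(
            lambda1=config.lambda1, lambda2=config.lambda2,
            B=config.stability_B, pi_thr=config.pi_thr,
            subset_fraction=config.subset_fraction,
            seed=stage_seed(config.seed, "ggm"),
        )
        labels = dict(
            zip(annotations["seq_id"], annotations["gene_symbol"])
        )
        est = ggm.stability_selection(std, jcfg, var_names=selected,
                                      node_labels=labels)
        graphs = {
            g: ggm.collapse_by_label(est.graph(g), labels) for g in (g1, g2)
        }
        files = {"edges": out / "edges.tsv"}
        io.write_edges({g: est.graph(g) for g in (g1, g2)}, files["edges"],
                       frequencies={g: est.edge_frequencies(g) for g in (g1, g2)})
        for g in (g1, g2):
            path = out / f"graph_{g}.graphml"
            io.write_graphml(graphs[g], path)
            files[f"graphml_{g}"] = path
        record("ggm", files,
               retained_aptamers=len(est.retained_nodes),
               retained_proteins=len(set().union(*(graphs[g].nodes for g in (g1, g2)))))
        log.info("ggm: %d aptamers retained", len(est.retained_nodes))

        # ---- network views -------------------------------------------
        net = netview.partition_edges(graphs[g1], graphs[g2], names=(g1, g2))
        cent = netview.centrality_table(net)
        comm_rows = []
        for g in (g1, g2):
            part = netview.louvain_consensus(
                net.unique_subgraph[g], runs=config.louvain_runs,
                seed=stage_seed(config.seed, f"louvain:{g}"),
            )
            for letter, members in part.labeled().items():
                comm_rows.append(
                    dict(group=g, community=letter, size=len(members),
                         members=";".join(sorted(map(str, members))))
                )
        communities = pd.DataFrame(
            comm_rows, columns=["group", "community", "size", "members"]
        )
        files = {
            "centralities": out / "centralities.tsv",
            "communities": out / "communities.tsv",
        }
        io.write_table(cent, files["centralities"])
        io.write_table(communities, files["communities"])
        record("network", files, **net.summary(),
               **{f"communities_{g}": int((communities['group'] == g).sum())
                  for g in (g1, g2)})
        log.info("network: %s", net.summary())

        # ---- cross-platform validation -------------------------------
        if config.run_crossval:
            all_log2 = preprocess.log2_transform(matrix)
            ms_quant, ms_meta = synthio.simulate_ms_platform(
                all_log2.subset_samples(list(study_ids)), annotations,
                seed=stage_seed(config.seed, "crossval"),
            )
            gene_to_uniprot = dict(
                zip(annotations["gene_symbol"], annotations["uniprot_ids"])
            )
            network_proteins = sorted(
                {gene_to_uniprot.get(n, "") for g in (g1, g2)
                 for n in graphs[g].nodes} - {""}
            )
            kept, ov_report = crossval.overlap_filter(
                ms_quant, ms_meta, network_proteins
            )
            seq_by_prot = annotations[annotations["uniprot_ids"] != ""].groupby(
                "uniprot_ids"
            )["seq_id"].first()
            soma_quant = pd.DataFrame(
                {
                    prot: all_log2.data.loc[list(study_ids), seq_by_prot[prot]]
                    for prot in kept if prot in seq_by_prot.index
                }
            ).T
            corr = crossval.cross_correlate(ms_quant, soma_quant)
            fc = crossval.compare_foldchanges(
                ms_quant.loc[kept], samples, contrasts
            ) if kept else pd.DataFrame()
            files = {
                "overlap": out / "crossval_overlap.json",
                "correlations": out / "crossval_correlations.tsv",
                "foldchanges": out / "crossval_foldchanges.tsv",
            }
            io.write_json(ov_report.to_dict(), files["overlap"])
            io.write_table(corr, files["correlations"])
            io.write_table(fc, files["foldchanges"])
            record("crossval", files, **ov_report.to_dict())
            log.info("crossval: %s", ov_report.to_dict())
    except Exception as exc:
        stage = len(manifest["stages"])
        err = {"failed_after_stage": list(manifest["stages"]), "error": str(exc)}
        io.write_json(err, out / "error.json")
        raise RuntimeError(f"pipeline failed after {stage} stages: {exc}") from exc

    io.write_json(manifest, out / "manifest.json")
    return manifest
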