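"""End-to-end orchestration: simulate -> QC -> GWAS -> AWM -> network
-> variance partition -> across-breed comparison, with a run manifest.

A single config (YAML/JSON-compatible dict) governs every stage; each
stage writes its outputs under ``out_dir/<breed>/`` (or ``out_dir`` for
cross-breed results) and contributes counters to the manifest. A stage
failure aborts the run, leaving partial outputs marked with a
``.partial`` file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import awmnet
from awmnet import awm as awm_mod
from awmnet import data_io, gwas, multibreed, network, simulate, variance
from awmnet.datatypes import ConfigError, QcConfig


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = awmnet.__version__
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, breed: str | None, t0: float, **counters) -> None:
        self.stages.append(
            {
                "stage": name,
                "breed": breed,
                "wall_seconds": round(time.perf_counter() - t0, 3),
                **counters,
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def default_config() -> dict:
    """Desk-scale defaults for a full pipeline run."""
    return {
        "sim": {},  # SimConfig field overrides
        "qc": {"maf_min": 0.05},
        "awm": {"key_trait": "KEY", "alpha": 0.01, "gene_window_bp": 10_000},
        "network": {"k": 2.0},
        "varexp": {"n_reps": 200},
        "seed": 0,
    }


def validate_config(cfg: dict) -> dict:
    merged = default_config()
    for section, vals in (cfg or {}).items():
        if section in ("seed",):
            merged["seed"] = int(vals)
        elif section in merged and isinstance(vals, dict):
            merged[section].update(vals)
        else:
            raise ConfigError(f"unknown config section: {section}")
    if "key_trait" not in merged["awm"] or not merged["awm"]["key_trait"]:
        raise ConfigError("config must name awm.key_trait")
    return merged


def run_pipeline(cfg: dict, out_dir: str | Path) -> RunManifest:
    """Execute every stage for every breed, then the cross-breed stage."""
    cfg = validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(cfg), seed=cfg["seed"])
    partial = out / ".partial"
    partial.write_text("run in progress\n")

    try:
        # --- simulate ---------------------------------------------------
        t0 = time.perf_counter()
        sim_cfg = simulate.SimConfig(seed=cfg["seed"], **cfg["sim"])
        data = simulate.simulate_dataset(sim_cfg)
        simulate.write_dataset(data, out / "data")
        manifest.add(
            "simulate", None, t0,
            n_breeds=sim_cfg.n_breeds, n_snps=sim_cfg.n_snps,
            n_traits=sim_cfg.n_traits,
        )

        key_trait = cfg["awm"]["key_trait"]
        qc_cfg = QcConfig(**cfg["qc"])
        awms: dict[str, awm_mod.Awm] = {}
        panels: dict[str, object] = {}
        phenos: dict[str, np.ndarray] = {}

        for breed in sim_cfg.breed_names:
            bdir = out / breed
            bdir.mkdir(exist_ok=True)
            g = data.genotypes[breed]
            traits = data.traits[breed]

            t0 = time.perf_counter()
            g_qc, report = data_io.qc_filter(g, qc_cfg)
            manifest.add(
                "qc", breed, t0,
                snps_in=report.n_input, snps_removed_maf=report.n_removed_maf,
                snps_retained=report.n_retained,
            )

            t0 = time.perf_counter()
            grm = gwas.compute_grm(g_qc)
            eig = gwas.GrmEigen(grm)
            res, vcs = gwas.run_all_gwas(traits, g_qc, eig)
            for trait in res.traits:
                sub = res.table[res.table["trait"] == trait]
                sub.to_csv(
                    bdir / f"gwas.{trait}.tsv", sep="\t", index=False,
                    float_format="%.8g",
                )
            manifest.add(
                "gwas", breed, t0, n_tests=len(res.table),
                n_traits=len(res.traits),
            )

            t0 = time.perf_counter()
            acfg = awm_mod.AwmConfig(
                key_trait=key_trait,
                alpha=cfg["awm"]["alpha"],
                gene_window_bp=cfg["awm"]["gene_window_bp"],
            )
            breed_awm = awm_mod.build_awm(res, data.annotation, acfg)
            awm_mod.write_awm(breed_awm, bdir)
            awms[breed] = breed_awm
            manifest.add(
                "awm", breed, t0, ap=breed_awm.ap,
                n_genes=len(breed_awm.gene_ids),
            )

            t0 = time.perf_counter()
            corr = network.correlation_matrix(breed_awm)
            dec = network.pcit(corr)
            net = network.reduce_network(
                dec, k=cfg["network"]["k"], ann=data.annotation, awm=breed_awm
            )
            network.write_network(net, bdir, ann=data.annotation, awm=breed_awm)
            topo = network.topology_stats(net)
            manifest.add(
                "network", breed, t0,
                n_nodes=topo["n_nodes"], n_edges=topo["n_edges"],
                pcit_trios_skipped=dec.n_skipped_trios,
            )

            panels[breed] = g_qc
            phenos[breed] = traits.trait(key_trait)

        # --- cross-breed comparison ------------------------------------
        t0 = time.perf_counter()
        report = multibreed.intersect_genes(awms)
        (out / "overlap_report.json").write_text(
            json.dumps(report.to_json_dict(), indent=2)
        )
        (out / "common_genes.txt").write_text(
            "\n".join(report.common_genes) + "\n" if report.common_genes else ""
        )
        common_snps, _ = multibreed.common_gene_snp_list(
            report.common_genes, panels, data.annotation,
            window=cfg["awm"]["gene_window_bp"],
        )
        for breed, snps in common_snps.items():
            (out / breed / "common_gene_snps.txt").write_text(
                "\n".join(snps) + "\n" if snps else ""
            )
        manifest.add(
            "compare", None, t0, n_common_genes=len(report.common_genes),
            n_common_snps=len(report.common_snps),
        )

        # --- variance partition ----------------------------------------
        t0 = time.perf_counter()
        awm_snps = {b: a.snp_ids for b, a in awms.items()}
        vr = variance.variance_report(
            {b: (phenos[b], panels[b]) for b in panels},
            awm_snps, common_snps,
            n_reps=cfg["varexp"]["n_reps"], seed=cfg["seed"],
        )
        vr.to_csv(out / "variance_report.tsv", sep="\t", float_format="%.6g")
        manifest.add("varexp", None, t0, n_reps=cfg["varexp"]["n_reps"])

        partial.unlink(missing_ok=True)
        manifest.write(out / "manifest.json")
        return manifest
    except Exception:
        manifest.write(out / "manifest.partial.json")
        raise
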