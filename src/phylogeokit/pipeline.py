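"""End-to-end orchestration: simulate or load -> distances -> clustering ->
concordance -> variance partitioning -> barrier/LDD screen -> sequence tests
-> environmental scan, with every headline statistic collected in a
machine-readable summary."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .admixture import AdmixtureModel, delta_k, run_k_grid
from .distances import geographic_matrix, jaccard_matrix, fit_gtr_gamma, gtr_gamma_matrix
from .envscan import EnvAssociationScan
from .ordination import ClusterAssignment, gaussian_mixture_clusters, nmds
from .pairs import screen_pairs
from .seqstats import fu_fs, mcdonald_kreitman
from .simulate import SimulationConfig, simulate_dataset
from .spatial import anosim, anosim_pairwise, ibd_cluster_report

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("phylogeokit")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    # either explicit input paths ...
    markers_path: str | None = None
    metadata_path: str | None = None
    fasta_path: str | None = None
    env_path: str | None = None
    # ... or a simulation block
    simulation: dict | None = None

    k_min: int = 2
    k_max: int = 8
    n_admixture_runs: int = 5
    burn_in: int = 200
    sweeps: int = 400
    alpha: float = 1.0
    n_permutations: int = 9999
    anosim_permutations: int = 10000
    quartile: str = "nearest-rank"
    confidence: float = 0.99
    fs_simulations: int = 1000
    geographic_method: str = "great_circle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max - self.k_min < 2:
            raise ValueError("K grid must span at least 3 consecutive values")
        if self.n_permutations < 99 or self.anosim_permutations < 99:
            raise ValueError("permutation counts must be >= 99")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)


def validate_summary(summary: dict) -> None:
    """Check a run summary against the checked-in schema (raises on drift)."""
    import importlib.resources as resources

    schema = json.loads(
        resources.files("phylogeokit").joinpath("summary_schema.json").read_text()
    )
    types = {"int": int, "number": (int, float), "dict": dict}
    for key, kind in schema["required"].items():
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
        if not isinstance(summary[key], types[kind]):
            raise ValueError(f"summary key {key!r} has wrong type")
    known = set(schema["required"]) | set(schema["optional"])
    extra = set(summary) - known
    if extra:
        raise ValueError(f"summary keys outside the schema: {sorted(extra)}")
    for key, kind in schema["optional"].items():
        if key in summary and not isinstance(summary[key], types[kind]):
            raise ValueError(f"summary key {key!r} has wrong type")


def _stage_seed(master: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence(master, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing result tables and a summary JSON to outdir.

    Returns the summary dict.  Sequence stages are marked "skipped" when no
    alignment is available; any stage exception aborts with the stage name
    while earlier outputs stay on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}, "seeds": {}}
    t_start = time.time()

    def stage(name):
        log.info("stage %s", name)
        summary["stages"][name] = "running"
        return time.time()

    def done(name, t0):
        summary["stages"][name] = "done"
        log.info("stage %s finished in %.1fs", name, time.time() - t0)

    try:
        t0 = stage("inputs")
        if config.simulation is not None:
            sim_conf = SimulationConfig(**{**config.simulation,
                                           "seed": config.simulation.get("seed", config.seed)})
            bundle = simulate_dataset(sim_conf, outdir / "simulated")
            markers, samples = bundle["markers"], bundle["samples"]
            alignment, env = bundle["alignment"], bundle["env"]
        else:
            if not (config.markers_path and config.metadata_path):
                raise ValueError("either input paths or a simulation block required")
            markers, samples, alignment, env = pio.load_dataset(
                config.markers_path, config.metadata_path,
                config.fasta_path, config.env_path,
            )
        samples = samples.subset(markers.individual_ids)
        done("inputs", t0)

        t0 = stage("distances")
        d_jac = jaccard_matrix(markers)
        d_geo = geographic_matrix(samples, config.geographic_method)
        d_jac.to_tsv(outdir / "jaccard.tsv")
        d_geo.to_tsv(outdir / "geographic.tsv")
        done("distances", t0)

        t0 = stage("admixture")
        seed_adm = _stage_seed(config.seed, "admixture")
        summary["seeds"]["admixture"] = seed_adm
        run_log, fits = run_k_grid(
            markers, config.k_min, config.k_max, config.n_admixture_runs,
            config.burn_in, config.sweeps, config.alpha, seed_adm,
        )
        run_log.to_csv(outdir / "admixture_runs.tsv", sep="\t", index=False)
        dk = delta_k({k: g["model_lnp"].tolist()
                      for k, g in run_log.groupby("K")})
        dk.to_frame().to_csv(outdir / "delta_k.tsv", sep="\t", index=False)
        best_k = dk.best_k
        best_fit = max(fits[best_k], key=lambda r: r.model_lnp)
        best_fit.to_frame().to_csv(outdir / "admixture_q.tsv", sep="\t")
        labels = ClusterAssignment.from_array(
            markers.individual_ids, best_fit.hard_assignment().to_numpy(),
            source="admixture_argmax",
        )
        summary["delta_k_best"] = best_k
        done("admixture", t0)

        t0 = stage("ordination")
        seed_ord = _stage_seed(config.seed, "ordination")
        summary["seeds"]["ordination"] = seed_ord
        nm = nmds(d_jac, seed=seed_ord)
        nm.to_frame().to_csv(outdir / "nmds.tsv", sep="\t")
        gm_labels, bic = gaussian_mixture_clusters(
            nm, K_max=config.k_max, seed=seed_ord
        )
        bic.to_csv(outdir / "gaussian_bic.tsv", sep="\t", index=False)
        summary["nmds_stress"] = nm.stress
        summary["gaussian_k"] = gm_labels.n_clusters
        done("ordination", t0)

        t0 = stage("anosim")
        seed_an = _stage_seed(config.seed, "anosim")
        summary["seeds"]["anosim"] = seed_an
        res = anosim(d_geo, labels, config.anosim_permutations, seed_an)
        pio.write_table(res, outdir / "anosim_global.tsv")
        pw = anosim_pairwise(d_geo, labels, config.anosim_permutations,
                             seed=seed_an)
        pw.to_csv(outdir / "anosim_pairwise.tsv", sep="\t", index=False)
        summary["anosim_global_r"] = res.r
        summary["anosim_global_p"] = res.p_value
        done("anosim", t0)

        t0 = stage("dbrda")
        seed_db = _stage_seed(config.seed, "dbrda")
        summary["seeds"]["dbrda"] = seed_db
        report = ibd_cluster_report(
            d_jac, samples, labels, config.n_permutations, seed_db
        )
        report["ibd"].to_frame().to_csv(outdir / "dbrda_ibd.tsv", sep="\t",
                                        index=False)
        if report["clusters_given_space"] is not None:
            report["clusters_given_space"].to_frame().to_csv(
                outdir / "dbrda_clusters.tsv", sep="\t", index=False
            )
        report["per_cluster"].to_csv(outdir / "dbrda_per_cluster.tsv", sep="\t",
                                     index=False)
        summary["ibd_proportion"] = report["ibd"].proportion_explained
        summary["ibd_pseudo_f"] = report["ibd"].pseudo_f
        if report["clusters_given_space"] is not None:
            summary["clusters_proportion"] = report[
                "clusters_given_space"
            ].proportion_explained
        done("dbrda", t0)

        t0 = stage("barriers")
        for mode in ("barrier", "ldd"):
            scr = screen_pairs(d_jac, d_geo, mode, config.quartile)
            scr.to_frame().to_csv(outdir / f"pairs_{mode}.tsv", sep="\t",
                                  index=False)
            pio.write_geojson_pairs(scr, samples, outdir / f"pairs_{mode}.geojson")
            summary[f"{mode}_pairs"] = scr.n_flagged
        done("barriers", t0)

        if alignment is not None:
            t0 = stage("sequence_tests")
            seed_fs = _stage_seed(config.seed, "fs")
            summary["seeds"]["fu_fs"] = seed_fs
            fs = fu_fs(alignment, config.fs_simulations, seed_fs)
            pio.write_table(fs, outdir / "fu_fs.tsv")
            summary["fu_fs"] = fs.fs
            summary["fu_fs_p"] = fs.p_value
            if alignment.is_outgroup.any():
                mk = mcdonald_kreitman(alignment)
                pio.write_table(mk, outdir / "mk_test.tsv")
                mk.excluded_codons.to_csv(outdir / "mk_excluded.tsv", sep="\t",
                                          index=False)
                summary["mk_p"] = mk.p_value
            else:
                summary["stages"]["mk"] = "skipped"
            done("sequence_tests", t0)
        else:
            summary["stages"]["sequence_tests"] = "skipped"

        if env is not None:
            t0 = stage("env_scan")
            scan = EnvAssociationScan(markers, env, samples).fit(config.confidence)
            scan.table.to_csv(outdir / "env_scan.tsv", sep="\t", index=False)
            summary["env_significant_loci"] = len(scan.significant_loci)
            summary["env_threshold"] = scan.threshold
            summary["env_n_tests"] = scan.n_tests
            done("env_scan", t0)
        else:
            summary["stages"]["env_scan"] = "skipped"
    except Exception as exc:
        failed = [k for k, v in summary["stages"].items() if v == "running"]
        raise RuntimeError(
            f"pipeline failed in stage {failed[-1] if failed else '?'}: {exc}"
        ) from exc

    summary["runtime_s"] = round(time.time() - t_start, 2)
    validate_summary(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
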