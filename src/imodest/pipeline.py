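"""End-to-end orchestration: simulate -> preprocess -> fit -> decompose ->
cluster -> (enrich) -> export tracks, with a checksummed manifest.

Configured by one YAML file (see ``configs/small.yaml``); unknown keys are
rejected so typos fail fast.  Re-running with the same config and seed
reproduces byte-identical result files.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field, fields

import yaml

from . import io as iio
from .cluster import merge_across_cohorts
from .decompose import classify_transfer, gain_correlation, gains_table
from .enrich import read_gmt
from .model import RegulatorDecomposition
from .regulators import CLASS_ORDER
from .simulate import SimulationConfig, simulate_paired, write_cohort


@dataclass
class RunConfig:
    """Pipeline configuration: simulation block plus fit/cluster/report
    thresholds."""

    simulation: dict = field(default_factory=dict)
    seed: int = 0
    deflation_runs: int = 1000
    n_lambdas: int = 30
    cv_folds: int = 10
    window: int = 1_000_000
    k_clusters: int = 20
    transfer_threshold: float = 0.0
    enrichment_min_gain: float = 0.25
    gene_sets: str | None = None
    score: str = "deflated"           # deflated | raw clustering features
    write_cohorts: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in fields(SimulationConfig)}
        sim_unknown = set(raw.get("simulation", {})) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation keys: "
                             f"{sorted(sim_unknown)}")
        return cls(**raw)

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        sim = dict(self.simulation)
        for key in ("tumor_specific_classes", "normal_specific_classes"):
            if key in sim:
                sim[key] = frozenset(sim[key])
        if seed is not None:
            sim["seed"] = seed
        else:
            sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)


def run_pipeline(config: RunConfig, outdir: str,
                 seed: int | None = None) -> dict:
    """Execute all stages; returns the manifest dict.  A stage failure
    aborts with the stage name while earlier outputs stay on disk."""
    seed = config.seed if seed is None else int(seed)
    os.makedirs(outdir, exist_ok=True)
    stages: dict[str, float] = {}
    state: dict = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: "
                               f"{exc}") from exc
        stages[name] = round(time.perf_counter() - t0, 3)

    def _simulate():
        sim = config.simulation_config(seed)
        tumor, adjacent = simulate_paired(sim)
        state["tumor"], state["adjacent"] = tumor, adjacent
        if config.write_cohorts:
            write_cohort(tumor, os.path.join(outdir, "cohort_tumor"))
            if adjacent is not None:
                write_cohort(adjacent,
                             os.path.join(outdir, "cohort_adjacent"))

    def _fit():
        model = RegulatorDecomposition(
            state["tumor"], state["adjacent"], seed=seed,
            deflation_runs=config.deflation_runs,
            n_lambdas=config.n_lambdas, cv_folds=config.cv_folds,
            window=config.window)
        state["results"] = model.fit()
        iio.write_fits(state["results"].ensembles.values(), outdir,
                       cohort_id="tumor")

    def _decompose():
        res = state["results"]
        res.gains.to_csv(os.path.join(outdir, "gains.tsv"), sep="\t",
                         index=False, float_format="%.10g")
        res.coefficients().to_csv(
            os.path.join(outdir, "coefficients_summary.tsv"), sep="\t",
            index=False, float_format="%.10g")
        tc = res.transfer(config.transfer_threshold)
        tc.table.to_csv(os.path.join(outdir, "transfer_classes.tsv"),
                        sep="\t", index=False, float_format="%.10g")
        tc.summary.to_csv(os.path.join(outdir, "transfer_summary.tsv"),
                          sep="\t", float_format="%.10g")
        corr = {cls: gain_correlation(res.gains, cls)
                for cls in CLASS_ORDER}
        with open(os.path.join(outdir, "gain_correlations.tsv"), "w") as fh:
            fh.write("class\tpearson_r\n")
            for cls, r in corr.items():
                fh.write(f"{cls}\t{'' if r is None else f'{r:.10g}'}\n")

    def _cluster():
        res = state["results"]
        k = min(config.k_clusters, max(2, len(res.ensembles) - 1))
        cres = res.cluster(k=k, score=config.score)
        cres.to_frame().to_csv(os.path.join(outdir, "clusters.tsv"),
                               sep="\t", index=False)
        merge_across_cohorts([cres]).to_csv(
            os.path.join(outdir, "cluster_labels.tsv"), sep="\t",
            index=False, float_format="%.10g")

    def _enrich():
        if config.gene_sets is None:
            return
        res = state["results"]
        collection = read_gmt(config.gene_sets,
                              universe=frozenset(res.ensembles))
        res.enrich(collection, config.enrichment_min_gain).to_csv(
            os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False,
            float_format="%.10g")

    def _export():
        res = state["results"]
        iio.export_coefficient_tracks(
            res.coefficients(), state["tumor"].annotations,
            os.path.join(outdir, "tracks"))

    _stage("simulate", _simulate)
    _stage("fit", _fit)
    _stage("decompose", _decompose)
    _stage("cluster", _cluster)
    _stage("enrich", _enrich)
    _stage("export_tracks", _export)
    iio.write_manifest(outdir, seed, stages)
    import json
    with open(os.path.join(outdir, "manifest.json")) as fh:
        return json.load(fh)
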