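"""End-to-end orchestration: collapse → stats → AMOVA → network → MDS → correlations.

A run is driven by one flat TOML config; all randomness flows from a single
root seed through per-stage derived seeds, so reruns with the same config are
byte-identical.  Each stage writes its own TSV/JSON artifacts into a fresh
output directory and the run closes with a manifest and a parameter-echo log.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import Grouping, amova3, make_covariate_grouping
from .association import CovariateTable, correlation_report
from .errors import ConfigError
from .network import annotate_categories, median_joining, network_summary
from .ordination import nmds3
from .popgen import distance_result
from .seqio import collapse_haplotypes, read_alignment

_STAGES = ("collapse", "stats", "amova", "network", "mds", "correlations")
_DEPS = {
    "stats": ("collapse",),
    "amova": (),
    "network": ("collapse",),
    "mds": ("stats",),
    "correlations": ("collapse", "stats"),
}


@dataclass
class RunConfig:
    fasta: str
    popmap: str
    covariates: str | None = None
    outdir: str = "sawyerflow_out"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in _STAGES})
    distance_mode: str = "differences"
    gamma_shape: float | None = None
    n_perm: int = 1000
    n_boot: int = 1000
    epsilon: int = 0
    mds_restarts: int = 4
    rft_thresholds: tuple[float, ...] = (100.0, 200.0)
    seed: int | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        stages_raw = raw.pop("stages", {})
        stages = {s: bool(stages_raw.get(s, True)) for s in _STAGES}
        if "rft_thresholds" in raw:
            raw["rft_thresholds"] = tuple(raw["rft_thresholds"])
        return cls(stages=stages, **raw)

    def validate(self) -> None:
        for p in (self.fasta, self.popmap, self.covariates):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file {p} does not exist")
        stochastic = self.stages.get("stats") or self.stages.get("amova") or self.stages.get("mds")
        if stochastic and self.seed is None:
            raise ConfigError("a seed is required when stochastic stages are enabled")
        for s, on in self.stages.items():
            if not on:
                continue
            missing = [d for d in _DEPS.get(s, ()) if not self.stages.get(d)]
            if missing:
                raise ConfigError(f"stage {s!r} requires disabled stage(s) {missing}")
        if (self.stages.get("amova") or self.stages.get("correlations")) and not self.covariates:
            raise ConfigError("amova/correlations stages need a covariate table")


def _stage_seed(root: int | None, k: int) -> int | None:
    if root is None:
        return None
    return int(np.random.SeedSequence([root, k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict[str, list[str]]:
    """Execute the enabled stages in dependency order; returns the output manifest."""
    config.validate()
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()):
        raise ConfigError(f"output directory {outdir} exists and is not empty")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, list[str]] = {}

    def emit(stage: str, name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        manifest.setdefault(stage, []).append(name)

    seqs = read_alignment(config.fasta, config.popmap)
    cov = CovariateTable.from_tsv(config.covariates) if config.covariates else None

    table = None
    if config.stages["collapse"]:
        table = collapse_haplotypes(seqs)
        buf = Path(outdir / "haplotypes.tsv")
        table.to_tsv(buf)
        manifest.setdefault("collapse", []).append("haplotypes.tsv")

    dres = None
    if config.stages["stats"]:
        dres = distance_result(seqs, table, n_boot=config.n_boot,
                               n_perm=config.n_perm, seed=_stage_seed(config.seed, 1),
                               mode=config.distance_mode)
        for name in ("k2p", "k2p_se", "nei_between", "fst", "fst_p", "nm"):
            emit("stats", f"{name}.tsv", dres.matrix_tsv(name))
        emit("stats", "indices.tsv", dres.indices_tsv())

    if config.stages["amova"]:
        groupings = [
            make_covariate_grouping(cov, "port", [0.5], name="port"),
            make_covariate_grouping(cov, "pwn", [0.5], name="pwn"),
            make_covariate_grouping(cov, "rft", list(config.rft_thresholds), name="rft"),
        ]
        if "econ_status" in cov.df.columns:
            groupings.append(Grouping("econ", cov.df["econ_status"].to_dict(),
                                      "published economic-status ranking"))
        for k, g in enumerate(groupings):
            res = amova3(seqs, g, mode=config.distance_mode,
                         gamma_shape=config.gamma_shape, n_perm=config.n_perm,
                         seed=_stage_seed(config.seed, 10 + k))
            emit("amova", f"amova_{g.name}.tsv", res.to_tsv())

    if config.stages["network"]:
        net = median_joining(table, epsilon=config.epsilon)
        if cov is not None and "region" in cov.df.columns:
            annotate_categories(net, cov, "region", table)
        emit("network", "network_edges.tsv", net.edges_tsv())
        emit("network", "network_nodes.tsv", net.nodes_tsv())
        nmv, nloops = network_summary(net)
        emit("network", "network_summary.json",
             json.dumps({"n_median_vectors": nmv, "n_loops": nloops}) + "\n")

    if config.stages["mds"]:
        res = nmds3(dres.k2p, labels=dres.labels, n_restarts=config.mds_restarts,
                    seed=_stage_seed(config.seed, 2))
        emit("mds", "mds_coords.tsv", res.coords_tsv())
        emit("mds", "mds_diagnostics.json", json.dumps({
            "stress": res.stress, "rsq": res.rsq,
            "n_iterations": res.n_iterations, "converged": res.converged,
        }, indent=1) + "\n")

    if config.stages["correlations"]:
        indices = pd.DataFrame(
            {"rshr": dres.rshr, "K": dres.nei_within, "dhap": dres.dhap},
            index=pd.Index(dres.labels, name="population"),
        )
        report = correlation_report(indices, cov)
        emit("correlations", "correlations.tsv", report.to_tsv())
        emit("correlations", "correlations_long.tsv",
             report.table.to_csv(sep="\t", index=False))

    log = [
        f"sawyerflow {__version__}",
        f"seed = {config.seed}",
        f"distance_mode = {config.distance_mode}",
        f"gamma_shape = {config.gamma_shape}",
        f"n_perm = {config.n_perm}", f"n_boot = {config.n_boot}",
        f"epsilon = {config.epsilon}", f"mds_restarts = {config.mds_restarts}",
        f"stages = {[s for s in _STAGES if config.stages[s]]}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
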