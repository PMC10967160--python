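"""End-to-end reproducible pipeline: data -> descriptives -> network ->
centrality/bridge/layout -> bootstrap diagnostics -> report.

A run is fully described by a :class:`RunConfig` (read from YAML or JSON);
its resolved copy, an input hash and library versions go into a manifest
next to the outputs, so any artifact can be regenerated byte-identically
from config + seed alone.  Output files carry no timestamps for exactly
that reason; log lines go to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ggm import GGMNetwork, estimate_network
from .metrics import bridge_metrics, centrality_table, fruchterman_reingold
from .scales import DEFAULT_SCALES, ResponseTable, descriptive_table, load_responses
from .simulate import SimConfig, TrueGGM, default_communities, make_true_network, sample_likert
from .stability import (
    DEFAULT_DROP_GRID,
    EdgeBootstrapResult,
    StabilityResult,
    bootstrap_edges,
    case_drop_bootstrap,
)

__all__ = ["RunConfig", "RunBundle", "run_pipeline", "report_tables", "ALL_STAGES"]

ALL_STAGES = ("data", "describe", "network", "centrality", "bootstrap", "report")


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML/JSON."""

    seed: int = 0
    out_dir: str = "results/run"
    input_csv: str | None = None
    simulate: dict | None = None  # SimConfig field overrides; None -> must load
    method: str = "spearman"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    communities: dict[str, str] | None = None
    edge_bootstrap_enabled: bool = True
    edge_bootstrap_B: int = 1000
    case_drop_enabled: bool = True
    case_drop_B: int = 1000
    case_drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    case_drop_indices: tuple[str, ...] = ("strength", "bridge_expected_influence")
    layout_iterations: int = 50
    decimals: int = 3

    def __post_init__(self) -> None:
        if self.input_csv is None and self.simulate is None:
            self.simulate = {}  # default simulated cohort
        if self.input_csv is not None and self.simulate is not None:
            raise ValueError("give either input_csv or simulate, not both")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("case_drop_grid", "case_drop_indices"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["case_drop_grid"] = list(self.case_drop_grid)
        d["case_drop_indices"] = list(self.case_drop_indices)
        return d

    def sim_config(self) -> SimConfig:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        return SimConfig(**overrides)


@dataclass
class RunBundle:
    config: RunConfig
    table: ResponseTable | None = None
    truth: TrueGGM | None = None
    descriptives: pd.DataFrame | None = None
    network: GGMNetwork | None = None
    centrality: pd.DataFrame | None = None
    bridge: pd.DataFrame | None = None
    layout: pd.DataFrame | None = None
    edge_boot: EdgeBootstrapResult | None = None
    stability: StabilityResult | None = None
    manifest: dict = field(default_factory=dict)


def _log(msg: str) -> None:
    print(f"[nssinet] {msg}", file=sys.stderr)


def _write_csv(frame: pd.DataFrame, path: Path, decimals: int, index_label=None) -> None:
    frame.to_csv(
        path,
        index=index_label is not None,
        index_label=index_label,
        float_format=f"%.{decimals}f",
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig, stages: tuple[str, ...] = ALL_STAGES
) -> RunBundle:
    """Execute the enabled stages, writing artifacts + manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dec = config.decimals
    bundle = RunBundle(config=config)
    manifest: dict = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    bundle.manifest = manifest

    def finish_stage(name: str, status: str = "done") -> None:
        manifest["stages"][name] = status
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))

    def run_stage(name: str, fn) -> None:
        if name not in stages:
            finish_stage(name, "skipped")
            return
        try:
            fn()
        except Exception as err:
            finish_stage(name, f"failed: {err}")
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        finish_stage(name)

    # ---- data ------------------------------------------------------------
    def stage_data() -> None:
        if config.input_csv is not None:
            _log(f"loading responses from {config.input_csv}")
            bundle.table = load_responses(config.input_csv, DEFAULT_SCALES)
            manifest["input_sha256"] = _sha256(Path(config.input_csv))
        else:
            sim = config.sim_config()
            _log(f"simulating cohort (n={sim.n}, seed={sim.seed})")
            bundle.truth = make_true_network(sim)
            bundle.table = sample_likert(bundle.truth, sim)
            bundle.truth.to_json(out / "truth.json")
            bundle.table.to_csv(out / "data.csv")
            manifest["input_sha256"] = _sha256(out / "data.csv")
        _log(
            f"data: {bundle.table.n} participants retained "
            f"({bundle.table.retention:.2f}% of {bundle.table.n_input})"
        )

    run_stage("data", stage_data)

    # ---- descriptives ----------------------------------------------------
    def stage_describe() -> None:
        bundle.descriptives = descriptive_table(bundle.table)
        _write_csv(bundle.descriptives, out / "descriptives.csv", dec)

    run_stage("describe", stage_describe)

    # ---- network ---------------------------------------------------------
    def stage_network() -> None:
        comm = config.communities
        if comm is None and bundle.truth is not None:
            comm = bundle.truth.communities
        if comm is None:
            comm = default_communities()
        comm = {k: v for k, v in comm.items()}
        _log(
            f"estimating network (method={config.method}, gamma={config.gamma}, "
            f"{config.n_lambda}-point penalty path)"
        )
        bundle.network = estimate_network(
            bundle.table,
            method=config.method,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            communities=comm,
        )
        _write_csv(bundle.network.edge_list(), out / "edges.csv", dec)
        bundle.network.to_json(out / "network.json")
        _log(
            f"selected lambda={bundle.network.lambda_selected:.4f} "
            f"with {bundle.network.n_edges()} edges"
        )

    run_stage("network", stage_network)

    # ---- centrality / bridge / layout -------------------------------------
    def stage_centrality() -> None:
        net = bundle.network
        bundle.centrality = centrality_table(net)
        bundle.bridge = bridge_metrics(net)
        bundle.layout = fruchterman_reingold(
            net, seed=config.seed, iterations=config.layout_iterations
        )
        _write_csv(bundle.centrality, out / "centrality.csv", dec, index_label="node")
        _write_csv(bundle.bridge, out / "bridge.csv", dec, index_label="node")
        _write_csv(bundle.layout, out / "layout.csv", dec, index_label="node")

    run_stage("centrality", stage_centrality)

    # ---- bootstrap diagnostics --------------------------------------------
    def stage_bootstrap() -> None:
        est_kwargs = dict(
            method=config.method,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        if config.edge_bootstrap_enabled:
            _log(f"edge-weight bootstrap (B={config.edge_bootstrap_B})")
            bundle.edge_boot = bootstrap_edges(
                bundle.table,
                B=config.edge_bootstrap_B,
                seed=config.seed,
                **est_kwargs,
            )
            _write_csv(bundle.edge_boot.summary, out / "boot_edges.csv", dec)
        else:
            manifest["stages"]["edge_bootstrap"] = "disabled"
        if config.case_drop_enabled:
            _log(
                f"case-dropping bootstrap (B={config.case_drop_B}, "
                f"indices={list(config.case_drop_indices)})"
            )
            bundle.stability = case_drop_bootstrap(
                bundle.table,
                indices=config.case_drop_indices,
                drop_grid=config.case_drop_grid,
                B=config.case_drop_B,
                seed=config.seed,
                communities=bundle.network.communities,
                **est_kwargs,
            )
            _write_csv(bundle.stability.summary(), out / "stability.csv", dec)
            (out / "stability.json").write_text(
                json.dumps(bundle.stability.cs(), indent=1, sort_keys=True)
            )
        else:
            manifest["stages"]["case_drop"] = "disabled"

    if config.edge_bootstrap_enabled or config.case_drop_enabled:
        run_stage("bootstrap", stage_bootstrap)
    else:
        finish_stage("bootstrap", "disabled")

    # ---- report -----------------------------------------------------------
    def stage_report() -> None:
        text = report_tables(bundle)
        (out / "report.txt").write_text(text)

    run_stage("report", stage_report)
    return bundle


def _fmt(mean: float, sd: float, dec: int) -> str:
    return f"{mean:.{dec}f} ± {sd:.{dec}f}"


def report_tables(bundle: RunBundle) -> str:
    """Human-readable run summary: Mean ± SD descriptives, the strongest
    edges, and the top nodes by strength z-score and bridge expected
    influence."""
    dec = bundle.config.decimals
    lines: list[str] = ["# nssinet run report", ""]

    if bundle.descriptives is not None:
        lines.append("## Descriptives (Mean ± SD)")
        for _, row in bundle.descriptives.iterrows():
            lines.append(
                f"{row['variable']:<24}{_fmt(row['mean'], row['sd'], dec)}"
                f"  (n={int(row['n'])})"
            )
        lines.append("")

    if bundle.network is not None:
        edges = bundle.network.edge_list()
        lines.append(
            f"## Network: {bundle.network.n_edges()} edges, "
            f"lambda={bundle.network.lambda_selected:.4f}, "
            f"gamma={bundle.network.ebic_gamma}"
        )
        lines.append("Top edges by |weight|:")
        if len(edges):
            top = edges.reindex(
                edges["weight"].abs().sort_values(ascending=False, kind="stable").index
            )
            # ties broken lexicographically by (node_a, node_b)
            top = top.assign(absw=top["weight"].abs().round(12)).sort_values(
                ["absw", "node_a", "node_b"], ascending=[False, True, True]
            )
            for _, row in top.head(5).iterrows():
                lines.append(
                    f"  {row['node_a']} -- {row['node_b']}: "
                    f"{row['weight']:.{dec}f}"
                )
        else:
            lines.append("  (network is empty)")
        lines.append("")

    if bundle.centrality is not None:
        lines.append("## Strongest nodes (strength z-score)")
        top = bundle.centrality["z_strength"].sort_values(ascending=False).head(5)
        for node, z in top.items():
            lines.append(f"  {node}: z = {z:.{dec}f}")
        lines.append("")

    if bundle.bridge is not None:
        lines.append("## Bridge nodes (bridge expected influence)")
        top = (
            bundle.bridge["bridge_expected_influence"]
            .sort_values(ascending=False)
            .head(5)
        )
        for node, v in top.items():
            lines.append(f"  {node}: {v:.{dec}f}")
        lines.append("")

    if bundle.edge_boot is not None:
        w = bundle.edge_boot.summary
        width = (w["ci_upper"] - w["ci_lower"]).median()
        lines.append(
            f"## Edge-weight bootstrap: B={bundle.edge_boot.B}, "
            f"median 95% CI width {width:.{dec}f}"
        )
        lines.append("")

    if bundle.stability is not None:
        lines.append("## Correlation-stability (CS) coefficients")
        for index, cs in sorted(bundle.stability.cs().items()):
            lines.append(f"  {index}: CS = {cs}")
        lines.append("")

    return "\n".join(lines)
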