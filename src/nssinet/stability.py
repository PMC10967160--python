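"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two procedures, mirroring standard practice for psychometric networks:

* nonparametric bootstrap — resample participants with replacement,
  re-estimate the network, and report 95% percentile confidence intervals
  per edge (edge-weight accuracy);
* case-dropping bootstrap — re-estimate on subsamples of decreasing size
  and correlate each subsample's centrality values with the full-sample
  values.  The correlation-stability (CS) coefficient is the largest drop
  proportion at which that correlation stays >= ``r_threshold`` (default
  0.7) in at least ``coverage`` (default 95%) of replicates.  CS above
  0.50 is considered good, below 0.25 poor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ggm import GGMNetwork, ZeroVarianceError, estimate_network
from .metrics import (
    bridge_metrics,
    shortest_path_metrics,
    strength_and_ei,
)
from .scales import ResponseTable

__all__ = [
    "EdgeBootstrapResult",
    "StabilityResult",
    "DEFAULT_DROP_GRID",
    "INDEX_NAMES",
    "node_indices",
    "bootstrap_edges",
    "case_drop_bootstrap",
]

DEFAULT_DROP_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))

INDEX_NAMES = (
    "strength",
    "expected_influence",
    "closeness",
    "betweenness",
    "bridge_strength",
    "bridge_expected_influence",
)


def node_indices(
    net: GGMNetwork,
    indices: Sequence[str],
    communities: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Selected per-node centrality/bridge indices of a network."""
    unknown = [i for i in indices if i not in INDEX_NAMES]
    if unknown:
        raise ValueError(f"unknown indices: {unknown}")
    parts = []
    if {"strength", "expected_influence"} & set(indices):
        parts.append(strength_and_ei(net))
    if {"closeness", "betweenness"} & set(indices):
        parts.append(shortest_path_metrics(net))
    bridged = [i for i in indices if i.startswith("bridge_")]
    if bridged:
        if set(bridged) <= {"bridge_strength", "bridge_expected_influence"}:
            # cheap 1-step sums; skip the shortest-path bridge machinery
            comm = communities if communities is not None else net.communities
            if comm is None:
                raise ValueError("no community partition supplied")
            labels = np.asarray([comm[v] for v in net.node_labels])
            cross = labels[:, None] != labels[None, :]
            Wc = np.where(cross, net.weights, 0.0)
            parts.append(
                pd.DataFrame(
                    {
                        "bridge_strength": np.abs(Wc).sum(axis=1),
                        "bridge_expected_influence": Wc.sum(axis=1),
                    },
                    index=list(net.node_labels),
                )
            )
        else:
            parts.append(bridge_metrics(net, communities)[bridged])
    return pd.concat(parts, axis=1)[list(indices)]


def _subtable(table: ResponseTable, idx: np.ndarray) -> ResponseTable:
    return ResponseTable(
        values=table.values.iloc[idx].reset_index(drop=True),
        scales=table.scales,
        demographics=None
        if table.demographics is None
        else table.demographics.iloc[idx].reset_index(drop=True),
        n_input=len(idx),
        n_dropped=0,
    )


@dataclass
class EdgeBootstrapResult:
    """Percentile CIs per node pair; ``summary`` covers every pair i < j
    (absent edges enter replicates as weight 0)."""

    summary: pd.DataFrame
    network: GGMNetwork
    B: int
    seed: int
    n_redraws: int = 0
    ci_level: float = 0.95
    replicates: np.ndarray | None = None

    def edges_only(self) -> pd.DataFrame:
        """Rows for the edges present in the original network."""
        return self.summary[self.summary["estimate"].abs() > 0].reset_index(drop=True)


def bootstrap_edges(
    table: ResponseTable,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    keep_replicates: bool = False,
    **estimator_kwargs,
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of edge weights.

    Replicates whose resample leaves an item with zero variance are
    redrawn (counted, capped at 10*B redraws).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    net = estimate_network(table, **estimator_kwargs)
    p = net.p
    iu = np.triu_indices(p, 1)
    n = table.n
    rng = np.random.default_rng(seed)

    reps = np.empty((B, iu[0].size))
    n_redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                bnet = estimate_network(_subtable(table, idx), **estimator_kwargs)
            except ZeroVarianceError:
                n_redraws += 1
                if n_redraws > 10 * B:
                    raise RuntimeError(
                        "too many degenerate bootstrap resamples"
                    ) from None
                continue
            break
        reps[b] = bnet.weights[iu]

    alpha = 100.0 * (1.0 - ci_level) / 2.0
    lo = np.percentile(reps, alpha, axis=0)
    hi = np.percentile(reps, 100.0 - alpha, axis=0)
    labels = net.node_labels
    summary = pd.DataFrame(
        {
            "node_a": [labels[i] for i in iu[0]],
            "node_b": [labels[j] for j in iu[1]],
            "estimate": net.weights[iu],
            "boot_mean": reps.mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    return EdgeBootstrapResult(
        summary=summary,
        network=net,
        B=B,
        seed=seed,
        n_redraws=n_redraws,
        ci_level=ci_level,
        replicates=reps if keep_replicates else None,
    )


@dataclass
class StabilityResult:
    """Case-dropping bootstrap correlations and CS coefficients.

    ``correlations`` is long-format: drop, replicate, index, r.
    """

    correlations: pd.DataFrame
    full_values: pd.DataFrame
    drop_grid: tuple[float, ...]
    B: int
    seed: int
    r_threshold: float = 0.7
    coverage: float = 0.95
    skipped: tuple[float, ...] = ()

    def cs(
        self, r_threshold: float | None = None, coverage: float | None = None
    ) -> dict[str, float]:
        """CS coefficient per index: the largest drop proportion at which
        corr >= r_threshold holds in >= coverage of replicates (0 if none)."""
        rt = self.r_threshold if r_threshold is None else r_threshold
        cov = self.coverage if coverage is None else coverage
        out: dict[str, float] = {}
        for index, grp in self.correlations.groupby("index"):
            ok = (
                grp.assign(pass_=grp["r"] >= rt)
                .groupby("drop")["pass_"]
                .mean()
            )
            passing = ok[ok >= cov]
            out[str(index)] = float(passing.index.max()) if len(passing) else 0.0
        return out

    def summary(self) -> pd.DataFrame:
        med = (
            self.correlations.groupby(["index", "drop"])["r"]
            .median()
            .rename("median_r")
            .reset_index()
        )
        cs = self.cs()
        med["cs"] = med["index"].map(cs)
        return med


def case_drop_bootstrap(
    table: ResponseTable,
    indices: Sequence[str] = ("strength",),
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
    r_threshold: float = 0.7,
    coverage: float = 0.95,
    communities: dict[str, str] | None = None,
    index_fn: Callable[[ResponseTable], pd.DataFrame] | None = None,
    **estimator_kwargs,
) -> StabilityResult:
    """Case-dropping bootstrap for centrality/bridge-index stability.

    For each drop proportion, B subsamples without replacement of the
    retained fraction are re-analysed; each subsample's node indices are
    Pearson-correlated (over nodes) with the full-sample values.
    ``index_fn`` may replace the default estimate-then-index computation
    (used for degenerate/diagnostic analyses).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    drop_grid = tuple(sorted(float(d) for d in drop_grid))
    if any(not 0.0 < d < 1.0 for d in drop_grid):
        raise ValueError("drop proportions must lie in (0, 1)")

    if index_fn is None:
        comm = communities
        if comm is None and "communities" in estimator_kwargs:
            comm = estimator_kwargs["communities"]

        def index_fn(tab: ResponseTable) -> pd.DataFrame:
            net = estimate_network(tab, **estimator_kwargs)
            return node_indices(net, indices, comm)

    full = index_fn(table)
    n = table.n
    p_nodes = full.shape[0]
    rng = np.random.default_rng(seed)

    rows = []
    skipped = []
    n_degenerate: dict[str, int] = {}
    for d in drop_grid:
        m = int(round(n * (1.0 - d)))
        if m < p_nodes + 1:
            warnings.warn(
                f"drop {d}: retained subsample ({m}) smaller than p+1; skipped"
            )
            skipped.append(d)
            continue
        redraws = 0
        for b in range(B):
            while True:
                idx = rng.choice(n, size=m, replace=False)
                try:
                    sub = index_fn(_subtable(table, idx))
                except ZeroVarianceError:
                    redraws += 1
                    if redraws > 10 * B:
                        raise RuntimeError(
                            "too many degenerate case-drop subsamples"
                        ) from None
                    continue
                break
            for col in full.columns:
                x = full[col].to_numpy(dtype=float)
                y = sub[col].to_numpy(dtype=float)
                if x.std() == 0 or y.std() == 0:
                    # e.g. an empty subsample network: all strengths zero
                    n_degenerate[col] = n_degenerate.get(col, 0) + 1
                    r = 0.0
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                rows.append((d, b, col, r))
    if n_degenerate:
        detail = ", ".join(f"{k}: {v}" for k, v in sorted(n_degenerate.items()))
        warnings.warn(
            f"zero-variance index values in some replicates (correlation set "
            f"to 0) — counts by index: {detail}"
        )

    correlations = pd.DataFrame(rows, columns=["drop", "replicate", "index", "r"])
    return StabilityResult(
        correlations=correlations,
        full_values=full,
        drop_grid=drop_grid,
        B=B,
        seed=seed,
        r_threshold=r_threshold,
        coverage=coverage,
        skipped=tuple(skipped),
    )
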