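"""Synthetic ordinal questionnaire data with a known latent network.

The generator realises the estimand of the whole pipeline: a sparse
Gaussian graphical model (GGM) over symptom nodes.  It builds a sparse
symmetric positive-definite precision matrix K with community structure
(an NSSI-function block plus singleton depressive and anxious nodes),
derives the implied partial correlations rho_ij = -K_ij / sqrt(K_ii K_jj),
and draws ordinal Likert responses by a Gaussian copula: latent
multivariate-normal vectors with covariance K^-1 (standardised) are cut at
per-node thresholds chosen to match target marginal category
probabilities.

Default marginals emulate a clinical adolescent NSSI cohort: 19 function
items on 1-5 anchors with item means between ~1.9 and ~3.9, and
total-score nodes for depression (0-27, mean ~18.6) and anxiety (0-21,
mean ~13.3).

Everything is driven by a single integer seed through one
``numpy.random.SeedSequence``; structure and sampling use separate child
streams so regenerating the truth never perturbs the draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scales import ANSSIAQ_FUNCTION, ResponseTable, ScaleDefinition

__all__ = [
    "TrueGGM",
    "SimConfig",
    "FUNCTION_ITEM_MARGINS",
    "TOTAL_NODE_MARGINS",
    "default_node_labels",
    "default_communities",
    "default_category_probabilities",
    "discretized_normal_probs",
    "partial_corr_from_precision",
    "make_true_network",
    "sample_likert",
]

# Reference marginal means/SDs for the 19 NSSI-function items (1-5 anchors),
# matching the cohort the generator emulates.
FUNCTION_ITEM_MARGINS: dict[str, tuple[float, float]] = {
    "F1": (3.274, 1.142),
    "F2": (3.206, 1.270),
    "F3": (2.767, 1.209),
    "F4": (3.890, 1.121),
    "F5": (3.308, 1.300),
    "F6": (2.904, 1.315),
    "F7": (3.507, 1.222),
    "F8": (2.144, 1.108),
    "F9": (1.911, 1.043),
    "F10": (3.048, 1.430),
    "F11": (2.322, 1.237),
    "F12": (3.220, 1.295),
    "F13": (2.027, 1.095),
    "F14": (3.404, 1.235),
    "F15": (2.329, 1.145),
    "F16": (3.815, 1.024),
    "F17": (3.315, 1.264),
    "F18": (2.363, 1.150),
    "F19": (2.959, 1.264),
}

# Total-score nodes: (mean, sd, min, max).
TOTAL_NODE_MARGINS: dict[str, tuple[float, float, int, int]] = {
    "PHQ9": (18.575, 6.175, 0, 27),
    "GAD7": (13.301, 5.043, 0, 21),
}


def default_node_labels() -> tuple[str, ...]:
    return tuple(FUNCTION_ITEM_MARGINS) + tuple(TOTAL_NODE_MARGINS)


def default_communities() -> dict[str, str]:
    comm = {f: "nssi_function" for f in FUNCTION_ITEM_MARGINS}
    comm["PHQ9"] = "depressive"
    comm["GAD7"] = "anxious"
    return comm


def discretized_normal_probs(
    values: np.ndarray, mean: float, sd: float, match_moments: bool = True
) -> np.ndarray:
    """Category probabilities on integer support ``values`` from a cut normal.

    Bins are [v - 0.5, v + 0.5) with open outer ends.  With
    ``match_moments`` the latent (mu, sigma) are solved so the *discrete*
    mean and SD hit the targets (the naive binning shifts both when mass
    piles against a support bound).
    """
    values = np.asarray(values, dtype=float)
    edges_inner = (values[:-1] + values[1:]) / 2.0

    def probs(mu: float, sigma: float) -> np.ndarray:
        cdf = stats.norm.cdf(edges_inner, loc=mu, scale=sigma)
        return np.diff(np.concatenate([[0.0], cdf, [1.0]]))

    def moments(p: np.ndarray) -> tuple[float, float]:
        m = float(p @ values)
        v = float(p @ (values - m) ** 2)
        return m, np.sqrt(max(v, 0.0))

    if match_moments:

        def residual(x: np.ndarray) -> list[float]:
            p = probs(x[0], np.exp(x[1]))
            m, s = moments(p)
            return [m - mean, s - sd]

        sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
        if sol.success:
            p = probs(sol.x[0], np.exp(sol.x[1]))
            return p / p.sum()
    p = probs(mean, sd)
    return p / p.sum()


def default_category_probabilities(
    node_labels: Sequence[str],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per node: (support values, category probabilities) for the defaults."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label in node_labels:
        if label in FUNCTION_ITEM_MARGINS:
            m, s = FUNCTION_ITEM_MARGINS[label]
            vals = np.arange(1, 6)
        elif label in TOTAL_NODE_MARGINS:
            m, s, lo, hi = TOTAL_NODE_MARGINS[label]
            vals = np.arange(lo, hi + 1)
        else:
            raise KeyError(
                f"no default marginal for node {label!r}; "
                "supply category_probabilities explicitly"
            )
        out[label] = (vals, discretized_normal_probs(vals, m, s))
    return out


@dataclass
class SimConfig:
    """Stated world of the simulation.

    sparsity is the expected fraction of nonzero off-diagonal precision
    entries; with the default 21-node set (210 pairs) the default yields
    ~30 edges.  Weight ranges are the magnitudes of the implied partial
    correlations for within- and between-community edges.
    """

    n: int = 412
    node_labels: tuple[str, ...] = field(default_factory=default_node_labels)
    communities: dict[str, str] = field(default_factory=default_communities)
    sparsity: float = 30.0 / 210.0
    between_sparsity: float | None = None
    within_community_weight: tuple[float, float] = (0.1, 0.4)
    between_community_weight: tuple[float, float] = (0.1, 0.4)
    p_negative: float = 0.1
    seed: int = 0
    category_probabilities: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must be in [0, 1]")
        missing = [v for v in self.node_labels if v not in self.communities]
        if missing:
            raise ValueError(f"nodes without community: {missing}")

    def resolved_category_probabilities(
        self,
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self.category_probabilities is not None:
            return {
                k: (np.asarray(v), np.asarray(p))
                for k, (v, p) in self.category_probabilities.items()
            }
        return default_category_probabilities(self.node_labels)


@dataclass
class TrueGGM:
    """Ground-truth network: precision matrix, implied partial correlations,
    community labels and copula discretization thresholds."""

    node_labels: tuple[str, ...]
    precision: np.ndarray
    partial_corr: np.ndarray
    communities: dict[str, str]
    thresholds: dict[str, np.ndarray]
    category_values: dict[str, np.ndarray]

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def edge_mask(self, tol: float = 1e-12) -> np.ndarray:
        """Boolean upper-triangle mask of true edges."""
        mask = np.abs(self.partial_corr) > tol
        mask[np.tril_indices(self.p)] = False
        return mask

    def n_edges(self, tol: float = 1e-12) -> int:
        return int(self.edge_mask(tol).sum())

    def strength(self) -> np.ndarray:
        return np.abs(self.partial_corr).sum(axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "node_labels": list(self.node_labels),
            "precision": self.precision.tolist(),
            "partial_corr": self.partial_corr.tolist(),
            "communities": self.communities,
            "thresholds": {k: v.tolist() for k, v in self.thresholds.items()},
            "category_values": {
                k: v.tolist() for k, v in self.category_values.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueGGM":
        d = json.loads(Path(path).read_text())
        return cls(
            node_labels=tuple(d["node_labels"]),
            precision=np.asarray(d["precision"]),
            partial_corr=np.asarray(d["partial_corr"]),
            communities=dict(d["communities"]),
            thresholds={k: np.asarray(v) for k, v in d["thresholds"].items()},
            category_values={
                k: np.asarray(v) for k, v in d["category_values"].items()
            },
        )


def partial_corr_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("K must have strictly positive diagonal")
    denom = np.sqrt(np.outer(d, d))
    rho = -K / denom
    np.fill_diagonal(rho, 0.0)
    return rho


def _thresholds_from_probs(probs: np.ndarray) -> np.ndarray:
    """Standard-normal cut points whose bins have the given probabilities."""
    cum = np.cumsum(probs)[:-1]
    cum = np.clip(cum, 1e-12, 1 - 1e-12)
    return stats.norm.ppf(cum)


def make_true_network(config: SimConfig, max_retries: int = 10) -> TrueGGM:
    """Build the ground-truth sparse precision matrix and copula thresholds.

    Edges are placed uniformly among within- and between-community pairs
    (counts set by the sparsity parameters), signed partial-correlation
    targets are drawn from the configured magnitude ranges, and the
    diagonal is inflated to max(1, 1.05 x absolute row sum) — strict
    diagonal dominance, hence positive definiteness.
    """
    labels = config.node_labels
    p = len(labels)
    comm = [config.communities[v] for v in labels]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])

    within_pairs = []
    between_pairs = []
    for i in range(p):
        for j in range(i + 1, p):
            (within_pairs if comm[i] == comm[j] else between_pairs).append((i, j))
    s_between = (
        config.sparsity if config.between_sparsity is None else config.between_sparsity
    )
    n_within = int(round(config.sparsity * len(within_pairs)))
    n_between = int(round(s_between * len(between_pairs)))

    for _ in range(max_retries):
        K = np.zeros((p, p))
        for pairs, n_pick, (wlo, whi) in (
            (within_pairs, n_within, config.within_community_weight),
            (between_pairs, n_between, config.between_community_weight),
        ):
            if not pairs or n_pick == 0:
                continue
            idx = rng.choice(len(pairs), size=min(n_pick, len(pairs)), replace=False)
            for k in idx:
                i, j = pairs[k]
                mag = rng.uniform(wlo, whi)
                sign = -1.0 if rng.uniform() < config.p_negative else 1.0
                # precision entry -rho gives partial correlation +rho
                K[i, j] = K[j, i] = -sign * mag
        rowsum = np.abs(K).sum(axis=1)
        np.fill_diagonal(K, np.maximum(1.0, 1.05 * rowsum))
        if np.linalg.eigvalsh(K)[0] > 0:
            break
    else:
        raise RuntimeError(
            "could not build a positive-definite precision matrix; "
            "reduce sparsity or edge weights"
        )

    catprobs = config.resolved_category_probabilities()
    thresholds = {}
    category_values = {}
    for label in labels:
        vals, probs = catprobs[label]
        thresholds[label] = _thresholds_from_probs(np.asarray(probs))
        category_values[label] = np.asarray(vals)

    return TrueGGM(
        node_labels=tuple(labels),
        precision=K,
        partial_corr=partial_corr_from_precision(K),
        communities=dict(config.communities),
        thresholds=thresholds,
        category_values=category_values,
    )


def _scales_for_nodes(truth: TrueGGM) -> tuple[ScaleDefinition, ...]:
    """Scale metadata for a simulated node set.

    The 19 function items, when all present with 1-5 support, are grouped
    under the ANSSIAQ function subscale; every other node (e.g. a
    total-score node) becomes its own single-item pseudo-scale spanning its
    category support.
    """
    scales: list[ScaleDefinition] = []
    f_items = set(ANSSIAQ_FUNCTION.item_ids)
    present_f = [v for v in truth.node_labels if v in f_items]
    grouped: set[str] = set()
    if len(present_f) == len(f_items) and all(
        truth.category_values[v].min() == 1 and truth.category_values[v].max() == 5
        for v in present_f
    ):
        scales.append(ANSSIAQ_FUNCTION)
        grouped = f_items
    for v in truth.node_labels:
        if v in grouped:
            continue
        vals = truth.category_values[v]
        scales.append(
            ScaleDefinition(f"{v}_node", (v,), int(vals.min()), int(vals.max()))
        )
    return tuple(scales)


def sample_likert(truth: TrueGGM, config: SimConfig) -> ResponseTable:
    """Draw n ordinal response vectors through the Gaussian copula.

    Latent vectors come from N(0, R) with R the correlation matrix implied
    by K^-1; each coordinate is mapped through its node's thresholds to the
    node's category values.  Fixed seed, fixed truth -> identical table.
    """
    if config.n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    Sigma = np.linalg.inv(truth.precision)
    d = np.sqrt(np.diag(Sigma))
    R = Sigma / np.outer(d, d)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((config.n, truth.p)) @ L.T

    data = {}
    for k, label in enumerate(truth.node_labels):
        idx = np.searchsorted(truth.thresholds[label], z[:, k])
        data[label] = truth.category_values[label][idx]
    values = pd.DataFrame(data, columns=list(truth.node_labels))
    return ResponseTable(
        values=values,
        scales=_scales_for_nodes(truth),
        demographics=None,
        n_input=config.n,
        n_dropped=0,
    )
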