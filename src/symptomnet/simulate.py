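"""Synthetic ordinal item-response data with a planted partial-correlation
network.

The generator builds a ground-truth Gaussian graphical model over two
item communities (7 anxiety + 10 depression items by default), with
positive-dominant within-community structure (a chain plus random extra
edges) and a small set of designated cross-community "bridge" edges.
Responses are drawn by the latent Gaussian copula route: multivariate
normal draws with the implied (standardized) covariance, discretized
per item at fixed thresholds into the ordinal categories {0,1,2,3}.
Thresholds default to right-skewed marginals matching the means
typically seen on these screening scales in community samples of older
adults (anxiety items ~0.15-0.35, depression items ~0.8-1.9 on the 0-3
scale).

A missingness injector turns complete data into a raw roster with an
exact number of records failing each screening stage, so the screening
cascade can be tested against known flow counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .association import ItemResponseMatrix
from .centrality import bridge_expected_influence
from .ggm import EDGE_EPS, NetworkModel, partial_correlations
from .screening import CESD_LABELS, GAD_LABELS, NODE_LABELS

#: Default planted bridge edges (anxiety node, depression node, partial r).
#: Four strong cross-community links dominate, mirroring the structure
#: reported for the anxiety-depression network in older adults living
#: alone: nervousness-sleep disturbance the strongest, then excessive
#: worry-effort, trouble relaxing-loneliness, irritability-feeling blue.
DEFAULT_BRIDGE_SPEC: tuple[tuple[str, str, float], ...] = (
    ("GAD1", "CESD10", 0.34),
    ("GAD3", "CESD4", 0.28),
    ("GAD4", "CESD8", 0.13),
    ("GAD6", "CESD3", 0.12),
)

#: Default target item means on the 0-3 scale (right-skewed marginals).
DEFAULT_ITEM_MEANS: dict[str, float] = {
    "GAD1": 0.34, "GAD2": 0.25, "GAD3": 0.29, "GAD4": 0.20,
    "GAD5": 0.17, "GAD6": 0.17, "GAD7": 0.15,
    "CESD1": 1.05, "CESD2": 1.47, "CESD3": 1.03, "CESD4": 1.63,
    "CESD5": 1.63, "CESD6": 0.89, "CESD7": 1.90, "CESD8": 1.41,
    "CESD9": 0.79, "CESD10": 1.47,
}


@dataclass
class GroundTruthNetwork:
    """Planted sparse precision matrix and the partial correlations it implies."""

    precision: np.ndarray
    partials: np.ndarray
    node_labels: list[str]
    communities: dict[str, str]
    bridge_edges: list[tuple[str, str, float]]

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def as_network_model(self) -> NetworkModel:
        return NetworkModel(
            weights=self.partials, node_labels=list(self.node_labels),
            community_of=dict(self.communities), lambda_used=0.0, gamma_used=0.0,
        )

    @property
    def latent_correlation(self) -> np.ndarray:
        """Standardized inverse of the precision: the copula's correlation."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)


@dataclass
class OrdinalThresholds:
    """Per-item increasing latent cut points defining categories {0,1,2,3}."""

    cuts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for lab, c in self.cuts.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (3,) or not np.all(np.diff(c) > 0):
                raise ValueError(f"thresholds for {lab} must be 3 increasing cuts")
            self.cuts[lab] = c

    def category_probabilities(self, label: str) -> np.ndarray:
        cdf = stats.norm.cdf(self.cuts[label])
        return np.diff(np.concatenate([[0.0], cdf, [1.0]]))


@dataclass
class SimulationConfig:
    n: int = 2000
    seed: int = 0
    missing_rate_demographic: float = 0.0
    missing_rate_items: float = 0.0
    stage_counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        for rate in (self.missing_rate_demographic, self.missing_rate_items):
            if not 0 <= rate <= 1:
                raise ValueError("missing rates must be in [0, 1]")


def _mean_to_cuts(target_mean: float) -> np.ndarray:
    """Latent cuts whose implied 0..3 category distribution has the target
    mean, assuming geometric-decay category probabilities p_k ~ r^k."""
    if not 0 < target_mean < 3:
        raise ValueError("target mean must be strictly inside (0, 3)")

    def mean_of(r: float) -> float:
        w = np.array([1.0, r, r * r, r ** 3])
        w = w / w.sum()
        return float(w @ np.arange(4))

    r = optimize.brentq(lambda x: mean_of(x) - target_mean, 1e-8, 1e8)
    w = np.array([1.0, r, r * r, r ** 3])
    w = w / w.sum()
    cum = np.cumsum(w)[:3]
    return stats.norm.ppf(cum)


def default_thresholds(
    item_means: dict[str, float] | None = None,
) -> OrdinalThresholds:
    means = item_means or DEFAULT_ITEM_MEANS
    return OrdinalThresholds({lab: _mean_to_cuts(m) for lab, m in means.items()})


def make_ground_truth(
    p_anx: int = 7,
    p_dep: int = 10,
    within_density: float = 0.15,
    bridge_spec: Sequence[tuple[str, str, float]] = DEFAULT_BRIDGE_SPEC,
    seed: int = 0,
    chain_weight_range: tuple[float, float] = (0.2, 0.32),
    extra_weight_range: tuple[float, float] = (0.08, 0.18),
    negative_fraction: float = 0.1,
) -> GroundTruthNetwork:
    """Plant a sparse, positive-dominant two-community GGM.

    Within each community the backbone is a chain with moderate positive
    partial correlations, plus random extra edges at ``within_density``
    (a fraction ``negative_fraction`` of which are negative); the
    requested bridge edges are added across communities. The precision
    matrix has unit diagonal, so the implied partial correlations equal
    the requested weights exactly; if the result is not positive
    definite the requested weights are infeasible and an error says so.
    """
    rng = np.random.default_rng(seed)
    if p_anx == 7 and p_dep == 10:
        labels = list(NODE_LABELS)
    else:
        labels = [f"A{i+1}" for i in range(p_anx)] + [f"D{i+1}" for i in range(p_dep)]
    communities = {
        lab: ("anxiety" if k < p_anx else "depression")
        for k, lab in enumerate(labels)
    }
    p = p_anx + p_dep
    idx = {lab: k for k, lab in enumerate(labels)}
    W = np.zeros((p, p))

    def put(i: int, j: int, w: float) -> None:
        W[i, j] = W[j, i] = w

    for block in (range(p_anx), range(p_anx, p)):
        block = list(block)
        for a, b in zip(block[:-1], block[1:]):
            put(a, b, rng.uniform(*chain_weight_range))
        extras = [
            (a, b)
            for ii, a in enumerate(block)
            for b in block[ii + 2:]
        ]
        for a, b in extras:
            if rng.random() < within_density:
                w = rng.uniform(*extra_weight_range)
                if rng.random() < negative_fraction:
                    w = -w
                put(a, b, w)

    for a, b, w in bridge_spec:
        ia, ib = idx[a], idx[b]
        if communities[a] == communities[b]:
            raise ValueError(f"bridge edge {a}-{b} does not cross communities")
        put(ia, ib, w)

    precision = np.eye(p) - W
    np.fill_diagonal(precision, 1.0)
    eigmin = float(np.linalg.eigvalsh(precision).min())
    if eigmin <= 1e-6:
        raise ValueError(
            "requested weights give a non-PD precision matrix "
            f"(min eigenvalue {eigmin:.4f}); reduce edge weights or density"
        )
    partials = partial_correlations(precision)
    for a, b, w in bridge_spec:
        got = partials[idx[a], idx[b]]
        if abs(got - w) > 0.02:
            raise AssertionError(
                f"implied partial for {a}-{b} is {got:.3f}, requested {w:.3f}"
            )
    return GroundTruthNetwork(
        precision=precision, partials=partials, node_labels=labels,
        communities=communities, bridge_edges=list(bridge_spec),
    )


def sample_ordinal(
    truth: GroundTruthNetwork,
    thresholds: OrdinalThresholds | None = None,
    n: int = 2000,
    seed: int = 0,
) -> ItemResponseMatrix:
    """Latent-Gaussian copula draw discretized to ordinal categories."""
    if thresholds is None:
        if truth.p == len(NODE_LABELS) and truth.node_labels == NODE_LABELS:
            thresholds = default_thresholds()
        else:
            thresholds = OrdinalThresholds({
                lab: stats.norm.ppf([0.25, 0.5, 0.75]) for lab in truth.node_labels
            })
    rng = np.random.default_rng(seed)
    corr = truth.latent_correlation
    latent = rng.multivariate_normal(
        np.zeros(truth.p), corr, size=n, method="cholesky"
    )
    values = np.zeros_like(latent)
    for k, lab in enumerate(truth.node_labels):
        values[:, k] = np.searchsorted(thresholds.cuts[lab], latent[:, k])
    return ItemResponseMatrix(
        values=values, node_labels=list(truth.node_labels),
        community_of=dict(truth.communities),
    )


def make_demographics(n: int, seed: int = 0) -> pd.DataFrame:
    """Ages, sex and residence resembling a community sample of older
    adults living alone (mean age ~84, ~38% male, mostly rural/town)."""
    rng = np.random.default_rng(seed)
    age = np.clip(np.round(rng.normal(84.27, 9.37, size=n)), 65, 117).astype(int)
    sex = rng.choice(["male", "female"], size=n, p=[0.3804, 0.6196])
    residence = rng.choice(
        ["city", "town", "rural"], size=n, p=[0.1838, 0.3431, 0.4731]
    )
    return pd.DataFrame({
        "id": [f"S{k+1:05d}" for k in range(n)],
        "age": age, "sex": sex, "residence": residence,
        "living": 2,
    })


def make_roster(
    data: ItemResponseMatrix,
    demographics: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete roster in the delimited format the screening module reads."""
    if demographics is None:
        demographics = make_demographics(data.n, seed=seed)
    if len(demographics) != data.n:
        raise ValueError("demographics row count must match data")
    roster = demographics.reset_index(drop=True).copy()
    for k, lab in enumerate(data.node_labels):
        roster[lab.lower()] = data.values[:, k].astype(int)
    return roster


def inject_missingness(
    roster: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Plant exactly ``config.stage_counts`` screening failures.

    Stage-1 records get a missing age/sex or more than a third of items
    blanked; stage-2 records lose one anxiety item (demographics and
    overall completeness intact); stage-3 records lose one depression
    item only. Placement is deterministic under the seed; remaining
    records stay complete.
    """
    counts = config.stage_counts or (0, 0, 0)
    if sum(counts) > len(roster):
        raise ValueError("requested stage counts exceed the roster size")
    rng = np.random.default_rng(config.seed)
    out = roster.copy()
    item_cols = [lab.lower() for lab in NODE_LABELS]
    gad_cols = [lab.lower() for lab in GAD_LABELS]
    cesd_cols = [lab.lower() for lab in CESD_LABELS]
    out[item_cols] = out[item_cols].astype(object)
    out["age"] = out["age"].astype(object)
    out["sex"] = out["sex"].astype(object)

    chosen = rng.choice(len(out), size=sum(counts), replace=False)
    s1 = chosen[: counts[0]]
    s2 = chosen[counts[0]: counts[0] + counts[1]]
    s3 = chosen[counts[0] + counts[1]:]
    for i in s1:
        if rng.random() < 0.5:
            out.loc[out.index[i], "age" if rng.random() < 0.5 else "sex"] = ""
        else:  # blank 7 of 17 items: strictly more than one third
            cols = rng.choice(item_cols, size=7, replace=False)
            out.loc[out.index[i], cols] = ""
    for i in s2:
        out.loc[out.index[i], rng.choice(gad_cols)] = ""
    for i in s3:
        out.loc[out.index[i], rng.choice(cesd_cols)] = ""
    return out


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    roster.to_csv(path, index=False)


def recovery_metrics(
    truth: GroundTruthNetwork,
    estimated: NetworkModel,
    weight_floor: float = 0.1,
) -> dict:
    """Edge-recovery report of an estimate against the planted network.

    TPR is reported both over all true edges and over the "strong" ones
    with |w| >= weight_floor; FPR over true non-edges; plus sign
    agreement on recovered true edges, Pearson correlation of weights
    over the union support, and whether the top-BEI node per community
    matches the planted dominant bridge carrier.
    """
    if truth.node_labels != estimated.node_labels:
        raise ValueError("truth and estimate must share the node set")
    iu = np.triu_indices(truth.p, 1)
    wt, we = truth.partials[iu], estimated.weights[iu]
    true_edge = np.abs(wt) > EDGE_EPS
    est_edge = np.abs(we) > EDGE_EPS
    strong = np.abs(wt) >= weight_floor

    def rate(num: np.ndarray, den: np.ndarray) -> float:
        return float(num.sum() / den.sum()) if den.sum() else float("nan")

    union = true_edge | est_edge
    if union.sum() >= 2 and wt[union].std() > 0 and we[union].std() > 0:
        wcorr = float(np.corrcoef(wt[union], we[union])[0, 1])
    else:
        wcorr = float("nan")

    truth_model = truth.as_network_model()
    bei_true = bridge_expected_influence(truth_model)
    bei_est = bridge_expected_influence(estimated)
    top_match = {}
    for comm in set(truth.communities.values()):
        members = [lab for lab in truth.node_labels
                   if truth.communities[lab] == comm]
        top_match[comm] = (
            bei_true[members].idxmax() == bei_est[members].idxmax()
        )
    both = true_edge & est_edge
    return {
        "tpr_all": rate(both, true_edge),
        "tpr_strong": rate(both & strong, strong),
        "fpr": rate(~true_edge & est_edge, ~true_edge),
        "sign_agreement": rate(both & (np.sign(wt) == np.sign(we)), both),
        "weight_correlation": wcorr,
        "top_bridge_match": top_match,
        "n_true_edges": int(true_edge.sum()),
        "n_estimated_edges": int(est_edge.sum()),
    }
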