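"""Bootstrap accuracy and stability of the estimated network.

Three procedures, all seeded and reproducible:

* nonparametric bootstrap of edge weights — resample rows with
  replacement, re-run the whole estimation (including penalty
  re-selection), and take percentile confidence intervals;
* case-dropping subset bootstrap — re-estimate centralities on
  progressively smaller row subsets and summarize with the
  correlation stability (CS) coefficient: the largest drop proportion
  at which the subset centralities still correlate >= 0.7 with the
  full-sample values in >= 95% of draws (CS < 0.25 is considered
  inadequate, > 0.50 robust);
* bootstrapped difference tests — an edge pair (or node pair) differs
  significantly when the percentile interval of the bootstrap
  differences excludes zero. No multiple-testing correction is
  applied; these are exploratory, per the protocol this mirrors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .association import ItemResponseMatrix
from .centrality import bridge_expected_influence, expected_influence
from .ggm import NetworkModel, SelectionConfig, select_network

logger = logging.getLogger(__name__)

Estimator = Callable[[ItemResponseMatrix], NetworkModel]


def make_estimator(config: SelectionConfig | None = None) -> Estimator:
    """Wrap select_network into a data -> model callable for the bootstrap."""
    def estimator(data: ItemResponseMatrix) -> NetworkModel:
        model, _ = select_network(data, config, return_path=False)
        return model
    return estimator


@dataclass
class BootstrapConfig:
    n_boot: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    drop_proportions: tuple[float, ...] = tuple(
        np.round(np.arange(0.10, 0.76, 0.05), 2)
    )
    cs_correlation: float = 0.7
    cs_probability: float = 0.95

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if list(self.drop_proportions) != sorted(self.drop_proportions) or not all(
            0 < d < 1 for d in self.drop_proportions
        ):
            raise ValueError("drop_proportions must be increasing and in (0,1)")


@dataclass
class EdgeCIResult:
    """Point estimates, percentile CIs and the raw bootstrap draws."""

    point: NetworkModel
    draws: np.ndarray  # (n_boot, p, p) weight matrices
    lower: np.ndarray
    upper: np.ndarray
    boot_mean: np.ndarray
    ci_level: float
    n_redrawn: int

    def edge_table(self) -> pd.DataFrame:
        labels = self.point.node_labels
        p = len(labels)
        iu = np.triu_indices(p, 1)
        return pd.DataFrame({
            "node_a": [labels[i] for i in iu[0]],
            "node_b": [labels[j] for j in iu[1]],
            "weight": self.point.weights[iu],
            "boot_mean": self.boot_mean[iu],
            "ci_lower": self.lower[iu],
            "ci_upper": self.upper[iu],
        })


@dataclass
class CSResult:
    """CS coefficient and the correlation curves behind it, per index."""

    cs: dict[str, float]
    curves: pd.DataFrame  # columns: index, drop, draw, correlation
    config: BootstrapConfig
    skipped_proportions: list[float] = field(default_factory=list)

    def interpretation(self) -> dict[str, str]:
        out = {}
        for index, value in self.cs.items():
            if value < 0.25:
                out[index] = "inadequate (CS < 0.25)"
            elif value <= 0.50:
                out[index] = "moderate (0.25 <= CS <= 0.50)"
            else:
                out[index] = "robust (CS > 0.50)"
        return out


def _resample(
    data: ItemResponseMatrix, rng: np.random.Generator
) -> tuple[ItemResponseMatrix, int]:
    """Row resample with replacement, redrawn if a column degenerates."""
    redraws = 0
    while True:
        rows = rng.integers(0, data.n, size=data.n)
        sub = data.values[rows]
        if (sub.var(axis=0) > 0).all():
            return data.subset(rows), redraws
        redraws += 1
        if redraws > 100:
            raise RuntimeError("could not draw a non-degenerate resample")


def bootstrap_edges(
    data: ItemResponseMatrix,
    estimator: Estimator,
    config: BootstrapConfig | None = None,
) -> EdgeCIResult:
    """Percentile bootstrap CIs for every edge weight.

    The estimator (penalty selection included) is re-run on each
    resample; resamples with a zero-variance column are redrawn and
    counted.
    """
    config = config or BootstrapConfig()
    rng = np.random.default_rng(config.seed)
    point = estimator(data)
    p = point.p
    draws = np.empty((config.n_boot, p, p))
    n_redrawn = 0
    for b in range(config.n_boot):
        sub, redraws = _resample(data, rng)
        n_redrawn += redraws
        draws[b] = estimator(sub).weights
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", n_redrawn)
    alpha = 1.0 - config.ci_level
    lower = np.quantile(draws, alpha / 2, axis=0)
    upper = np.quantile(draws, 1 - alpha / 2, axis=0)
    return EdgeCIResult(
        point=point, draws=draws, lower=lower, upper=upper,
        boot_mean=draws.mean(axis=0), ci_level=config.ci_level,
        n_redrawn=n_redrawn,
    )


def case_drop_bootstrap(
    data: ItemResponseMatrix,
    estimator: Estimator,
    config: BootstrapConfig | None = None,
    ei_variant: str = "absolute",
) -> CSResult:
    """Case-dropping subset bootstrap with CS coefficient for EI and BEI.

    For each drop proportion d, ``n_boot`` subsets of size round((1-d) n)
    are drawn without replacement and the subset centralities are
    Pearson-correlated with the full-sample ones (an undefined
    correlation — e.g. an empty subset network — counts as a failure).
    """
    config = config or BootstrapConfig()
    rng = np.random.default_rng(config.seed)
    full = estimator(data)
    full_ei = expected_influence(full, ei_variant).to_numpy()
    full_bei = bridge_expected_influence(full).to_numpy()
    rows = []
    skipped: list[float] = []
    for d in config.drop_proportions:
        m = int(round((1 - d) * data.n))
        if m < data.p + 1:
            logger.warning("drop proportion %.2f leaves %d rows < p+1; skipped", d, m)
            skipped.append(float(d))
            continue
        for b in range(config.n_boot):
            keep = rng.choice(data.n, size=m, replace=False)
            try:
                sub_model = estimator(data.subset(keep))
            except ValueError:
                rows.append({"index": "EI", "drop": d, "draw": b,
                             "correlation": np.nan})
                rows.append({"index": "BEI", "drop": d, "draw": b,
                             "correlation": np.nan})
                continue
            sub_ei = expected_influence(sub_model, ei_variant).to_numpy()
            sub_bei = bridge_expected_influence(sub_model).to_numpy()
            for name, fullv, subv in (
                ("EI", full_ei, sub_ei), ("BEI", full_bei, sub_bei)
            ):
                if fullv.std() > 0 and subv.std() > 0:
                    corr = float(np.corrcoef(fullv, subv)[0, 1])
                else:
                    corr = np.nan
                rows.append({"index": name, "drop": d, "draw": b,
                             "correlation": corr})
    curves = pd.DataFrame(rows, columns=["index", "drop", "draw", "correlation"])
    cs: dict[str, float] = {}
    for name in ("EI", "BEI"):
        cs[name] = 0.0
        sub = curves[curves["index"] == name]
        for d in config.drop_proportions:
            if float(d) in skipped or sub.empty:
                continue
            corr = sub.loc[sub["drop"] == d, "correlation"]
            ok = (corr >= config.cs_correlation).fillna(False)
            if ok.mean() >= config.cs_probability:
                cs[name] = max(cs[name], float(d))
    return CSResult(cs=cs, curves=curves, config=config,
                    skipped_proportions=skipped)


def _difference_matrix(
    draws: np.ndarray, labels: list[str], ci_level: float
) -> pd.DataFrame:
    """Pairwise percentile test: draws is (n_boot, k) for k quantities."""
    alpha = 1.0 - ci_level
    k = draws.shape[1]
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        diff = draws[:, [i]] - draws  # (n_boot, k)
        lo = np.quantile(diff, alpha / 2, axis=0)
        hi = np.quantile(diff, 1 - alpha / 2, axis=0)
        sig[i] = (lo > 0) | (hi < 0)
    sig = sig | sig.T
    np.fill_diagonal(sig, False)
    return pd.DataFrame(sig, index=labels, columns=labels)


def difference_test_edges(
    boot: EdgeCIResult, ci_level: float | None = None
) -> pd.DataFrame:
    """Bootstrapped difference test over all nonzero point-estimate edges."""
    level = ci_level if ci_level is not None else boot.ci_level
    labels_all = boot.point.node_labels
    p = len(labels_all)
    iu = np.triu_indices(p, 1)
    edge_labels = [f"{labels_all[i]}--{labels_all[j]}"
                   for i, j in zip(*iu)]
    edge_draws = boot.draws[:, iu[0], iu[1]]
    keep = np.abs(boot.point.weights[iu]) > 0
    return _difference_matrix(
        edge_draws[:, keep],
        [lab for lab, k in zip(edge_labels, keep) if k],
        level,
    )


def difference_test_centrality(
    boot: EdgeCIResult,
    index: str = "EI",
    ei_variant: str = "absolute",
    ci_level: float | None = None,
) -> pd.DataFrame:
    """Bootstrapped difference test for per-node EI or BEI values."""
    level = ci_level if ci_level is not None else boot.ci_level
    model = boot.point
    vals = np.empty((boot.draws.shape[0], model.p))
    for b in range(boot.draws.shape[0]):
        m = NetworkModel(boot.draws[b], model.node_labels,
                         model.community_of, model.lambda_used,
                         model.gamma_used)
        if index == "EI":
            vals[b] = expected_influence(m, ei_variant).to_numpy()
        elif index == "BEI":
            vals[b] = bridge_expected_influence(m).to_numpy()
        else:
            raise ValueError(f"unknown centrality index {index!r}")
    return _difference_matrix(vals, list(model.node_labels), level)
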