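"""Node centrality for symptom networks: expected influence and bridge
expected influence.

Expected influence (EI) sums a node's edge weights; the default here is
the absolute-value variant EI_i = sum_j |w_ij|, with the signed variant
exposed (the two coincide on all-positive networks). Bridge expected
influence (BEI) is the signed sum of a node's edges into the *other*
community, the quantity of interest when asking which symptoms carry
the anxiety-depression comorbidity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ggm import NetworkModel


def expected_influence(model: NetworkModel, variant: str = "absolute") -> pd.Series:
    """Per-node EI. variant 'absolute': sum of |w_ij|; 'signed': sum of w_ij."""
    if variant == "absolute":
        vals = np.abs(model.weights).sum(axis=1)
    elif variant == "signed":
        vals = model.weights.sum(axis=1)
    else:
        raise ValueError(f"unknown EI variant {variant!r}")
    return pd.Series(vals, index=model.node_labels, name=f"EI_{variant}")

def bridge_expected_influence(model: NetworkModel) -> pd.Series:
    """Per-node signed sum of edge weights into the other community."""
    communities = [model.community_of[lab] for lab in model.node_labels]
    if len(set(communities)) < 2:
        warnings.warn("single-community network: all BEI values are zero")
    comm = np.array(communities)
    cross = comm[:, None] != comm[None, :]
    vals = (model.weights * cross).sum(axis=1)
    return pd.Series(vals, index=model.node_labels, name="BEI")


def centrality_table(model: NetworkModel, ei_variant: str = "absolute") -> pd.DataFrame:
    """Raw EI and BEI per node plus ranks.

    EI is ranked over all nodes descending; BEI within each community
    descending. Ties break by node label so the ordering is
    deterministic. z-standardized columns are included as extras.
    """
    ei = expected_influence(model, ei_variant)
    bei = bridge_expected_influence(model)
    df = pd.DataFrame({
        "community": [model.community_of[lab] for lab in model.node_labels],
        "EI": ei,
        "BEI": bei,
    })
    df["ei_rank"] = pd.Series(
        range(1, len(df) + 1),
        index=sorted(df.index, key=lambda lab: (-df.loc[lab, "EI"], lab)),
    )
    bei_rank = {}
    for comm in df["community"].unique():
        members = df.index[df["community"] == comm]
        ordered = sorted(members, key=lambda lab: (-df.loc[lab, "BEI"], lab))
        bei_rank.update({lab: r for r, lab in enumerate(ordered, start=1)})
    df["bei_rank_within_community"] = pd.Series(bei_rank)
    for col in ("EI", "BEI"):
        sd = df[col].std(ddof=1)
        df[f"{col}_z"] = (df[col] - df[col].mean()) / sd if sd > 0 else 0.0
    return df


def rank_nodes(table: pd.DataFrame) -> pd.DataFrame:
    """Table sorted by EI rank (the report ordering)."""
    return table.sort_values("ei_rank")
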