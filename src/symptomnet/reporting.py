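"""Tabular reports: the descriptive/centrality summary table.

One row per symptom with columns Symptom, Abb, M, SD, EI, BEI, ordered
anxiety items first then depression items, rounded to two decimals in
the display version.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .screening import NODE_LABELS

#: long symptom names for the standard 17-item instrument pair
SYMPTOM_NAMES = {
    "GAD1": "Nervousness or anxiety",
    "GAD2": "Uncontrollable worry",
    "GAD3": "Worry too much",
    "GAD4": "Trouble relaxing",
    "GAD5": "Restlessness",
    "GAD6": "Easily annoyed/irritated",
    "GAD7": "Afraid something terrible might happen",
    "CESD1": "Feeling bothered",
    "CESD2": "Difficulty with concentrating",
    "CESD3": "Feeling blue/depressed",
    "CESD4": "Everything was an effort",
    "CESD5": "Hopelessness",
    "CESD6": "Felt fearful",
    "CESD7": "Lack of happiness",
    "CESD8": "Loneliness",
    "CESD9": "Inability to get going",
    "CESD10": "Sleep disturbances",
}


def make_table1(
    descriptives: pd.DataFrame,
    centrality: pd.DataFrame,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Combine per-item descriptives (M, SD) with centralities (EI, BEI).

    Both inputs must cover the same node set; the output row order is
    fixed (anxiety items then depression items) regardless of input
    order. ``decimals`` rounds the numeric columns for display.
    """
    missing = set(descriptives.index) ^ set(centrality.index)
    if missing:
        raise ValueError(
            f"descriptives and centrality node sets differ: {sorted(missing)}"
        )
    order = [lab for lab in NODE_LABELS if lab in descriptives.index]
    if not order:  # generic node labels: keep centrality's order
        order = list(centrality.index)
    table = pd.DataFrame({
        "Symptom": [SYMPTOM_NAMES.get(lab, lab) for lab in order],
        "Abb": order,
        "M": descriptives.loc[order, "M"].to_numpy(),
        "SD": descriptives.loc[order, "SD"].to_numpy(),
        "EI": centrality.loc[order, "EI"].to_numpy(),
        "BEI": centrality.loc[order, "BEI"].to_numpy(),
    })
    if decimals is not None:
        for col in ("M", "SD", "EI", "BEI"):
            table[col] = table[col].round(decimals)
    return table


def write_table1(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
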