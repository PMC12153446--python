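"""Cohort assembly for symptom-network analysis.

Builds the analytic sample from a raw survey roster: restricts to
respondents with the living-alone code, applies a staged exclusion
cascade (demographics / overall incompleteness, then missing anxiety
items, then missing depression items), scores the GAD-7 and CES-D-10
scales, and produces per-item descriptive statistics.

The staged order matters: a record is attributed to the *first* stage
that rejects it, so the stage counts are disjoint and sum (with the
retained count) to the input size.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_GAD = 7
N_CESD = 10
N_ITEMS = N_GAD + N_CESD

#: GAD-7 screening cutoff: total >= 5 flags anxiety symptoms.
GAD_CUTOFF = 5
#: CES-D-10 screening cutoff: total >= 10 flags depressive symptoms.
CESD_CUTOFF = 10

LIVING_ALONE_CODE = 2

GAD_LABELS = [f"GAD{i}" for i in range(1, N_GAD + 1)]
CESD_LABELS = [f"CESD{i}" for i in range(1, N_CESD + 1)]
NODE_LABELS = GAD_LABELS + CESD_LABELS

#: Raw-file tokens treated as missing, besides empty cells and
#: out-of-range numeric codes. Survey export dialects vary.
MISSING_SENTINELS = {"", "na", "n/a", "nan", ".", "-", "none", "null", "missing"}


class ColumnMapError(KeyError):
    """A required column is absent from the roster or the column map."""


@dataclass
class ParticipantRecord:
    """One respondent: demographics, living arrangement and 17 item responses.

    Item responses are floats so that ``nan`` can encode a missing answer;
    observed values are the ordinal codes 0..3.
    """

    id: str
    age: float  # years; nan if missing
    sex: str | None  # "male" / "female" / None
    residence: str | None  # "city" / "town" / "rural" / None
    living_arrangement: int | None  # 1 family, 2 alone, 3 institution
    gad_items: np.ndarray  # shape (7,)
    cesd_items: np.ndarray  # shape (10,)

    def __post_init__(self) -> None:
        self.gad_items = np.asarray(self.gad_items, dtype=float)
        self.cesd_items = np.asarray(self.cesd_items, dtype=float)
        if self.gad_items.shape != (N_GAD,):
            raise ValueError(f"gad_items must have length {N_GAD}")
        if self.cesd_items.shape != (N_CESD,):
            raise ValueError(f"cesd_items must have length {N_CESD}")
        for arr in (self.gad_items, self.cesd_items):
            observed = arr[~np.isnan(arr)]
            if observed.size and not np.isin(observed, [0, 1, 2, 3]).all():
                raise ValueError("item responses must be in {0,1,2,3} or missing")

    @property
    def all_items(self) -> np.ndarray:
        return np.concatenate([self.gad_items, self.cesd_items])

    @property
    def n_items_missing(self) -> int:
        return int(np.isnan(self.all_items).sum())


@dataclass
class ScreeningReport:
    """Stage-wise exclusion counts; stages are disjoint by construction."""

    n_initial: int
    n_excluded_demographic_or_incomplete: int
    n_excluded_missing_gad: int
    n_excluded_missing_cesd: int
    n_final: int
    excluded_ids_by_stage: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


@dataclass
class ScaleScores:
    cesd_total: int
    gad_total: int
    depressive_flag: bool
    anxiety_flag: bool


def _parse_item(token: object) -> float:
    """Map a raw cell to an ordinal code 0..3, or nan for any sentinel
    or out-of-range value."""
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return float("nan")
    text = str(token).strip().lower()
    if text in MISSING_SENTINELS:
        return float("nan")
    try:
        value = float(text)
    except ValueError:
        return float("nan")
    if value in (0.0, 1.0, 2.0, 3.0):
        return value
    return float("nan")


_SEX_CODES = {"male": "male", "m": "male", "1": "male",
              "female": "female", "f": "female", "2": "female"}
_RESIDENCE_CODES = {"city": "city", "1": "city",
                    "town": "town", "2": "town",
                    "rural": "rural", "3": "rural"}


def _parse_categorical(token: object, codes: Mapping[str, str]) -> str | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    text = str(token).strip().lower()
    if text.endswith(".0"):
        text = text[:-2]
    if text in MISSING_SENTINELS:
        return None
    return codes.get(text)


DEFAULT_COLUMN_MAP: dict[str, str] = {
    "id": "id", "age": "age", "sex": "sex",
    "residence": "residence", "living": "living",
    **{f"gad{i}": f"gad{i}" for i in range(1, N_GAD + 1)},
    **{f"cesd{i}": f"cesd{i}" for i in range(1, N_CESD + 1)},
}


def parse_roster(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[ParticipantRecord]:
    """Read a delimited roster (comma or tab, header row) into records.

    ``column_map`` maps the logical keys ``id, age, sex, residence,
    living, gad1..gad7, cesd1..cesd10`` to the file's column names.
    Unparseable or out-of-range item codes become missing (a warning is
    logged); a missing mandatory column raises :class:`ColumnMapError`.
    """
    column_map = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    for key in DEFAULT_COLUMN_MAP:
        if key not in column_map:
            raise ColumnMapError(f"column map lacks required key {key!r}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for key, col in column_map.items():
        if col not in df.columns:
            raise ColumnMapError(
                f"roster {path} lacks column {col!r} (mapped from {key!r})"
            )

    item_keys = [f"gad{i}" for i in range(1, N_GAD + 1)] + [
        f"cesd{i}" for i in range(1, N_CESD + 1)
    ]
    records: list[ParticipantRecord] = []
    n_bad_items = 0
    for _, row in df.iterrows():
        items = []
        for key in item_keys:
            raw = row[column_map[key]]
            val = _parse_item(raw)
            if math.isnan(val) and not (
                raw is None
                or (isinstance(raw, float) and math.isnan(raw))
                or str(raw).strip().lower() in MISSING_SENTINELS
            ):
                n_bad_items += 1
            items.append(val)
        age_raw = row[column_map["age"]]
        try:
            age = float(age_raw)
            if age < 0 or math.isnan(age):
                age = float("nan")
        except (TypeError, ValueError):
            age = float("nan")
        living_raw = _parse_categorical(
            row[column_map["living"]], {"1": "1", "2": "2", "3": "3"}
        )
        records.append(
            ParticipantRecord(
                id=str(row[column_map["id"]]),
                age=age,
                sex=_parse_categorical(row[column_map["sex"]], _SEX_CODES),
                residence=_parse_categorical(
                    row[column_map["residence"]], _RESIDENCE_CODES
                ),
                living_arrangement=int(living_raw) if living_raw else None,
                gad_items=np.array(items[:N_GAD]),
                cesd_items=np.array(items[N_GAD:]),
            )
        )
    if n_bad_items:
        logger.warning(
            "%d item codes were unparseable or out of range and set missing",
            n_bad_items,
        )
    return records


def apply_exclusions(
    records: Sequence[ParticipantRecord],
) -> tuple[list[ParticipantRecord], ScreeningReport]:
    """Staged exclusion cascade over living-alone respondents.

    Records whose living-arrangement code is not the living-alone code
    are dropped up front (recorded under ``not_alone``, outside the
    stage counts). Then, in order:

    1. missing age or sex, or more than one third of the 17 items missing;
    2. any missing GAD-7 item (among stage-1 survivors);
    3. any missing CES-D item (among stage-2 survivors).
    """
    alone = [r for r in records if r.living_arrangement == LIVING_ALONE_CODE]
    not_alone_ids = [
        r.id for r in records if r.living_arrangement != LIVING_ALONE_CODE
    ]

    stage1, stage2, stage3 = [], [], []
    retained: list[ParticipantRecord] = []
    for r in alone:
        if (
            math.isnan(r.age)
            or r.sex is None
            or r.n_items_missing > N_ITEMS / 3
        ):
            stage1.append(r.id)
        elif np.isnan(r.gad_items).any():
            stage2.append(r.id)
        elif np.isnan(r.cesd_items).any():
            stage3.append(r.id)
        else:
            retained.append(r)

    report = ScreeningReport(
        n_initial=len(alone),
        n_excluded_demographic_or_incomplete=len(stage1),
        n_excluded_missing_gad=len(stage2),
        n_excluded_missing_cesd=len(stage3),
        n_final=len(retained),
        excluded_ids_by_stage={
            "not_alone": not_alone_ids,
            "demographic_or_incomplete": stage1,
            "missing_gad": stage2,
            "missing_cesd": stage3,
        },
    )
    return retained, report


def score_scales(record: ParticipantRecord) -> ScaleScores:
    """Plain sum scores with the standard screening cutoffs.

    Requires a fully observed record (screening guarantees this).
    """
    if record.n_items_missing:
        raise ValueError(
            f"record {record.id} has missing items; screen before scoring"
        )
    gad_total = int(record.gad_items.sum())
    cesd_total = int(record.cesd_items.sum())
    return ScaleScores(
        cesd_total=cesd_total,
        gad_total=gad_total,
        depressive_flag=cesd_total >= CESD_CUTOFF,
        anxiety_flag=gad_total >= GAD_CUTOFF,
    )


def descriptives(retained: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Per-item mean and SD (n-1 denominator), indexed by node label."""
    if not retained:
        raise ValueError("descriptives requires a nonempty retained sample")
    items = np.array([r.all_items for r in retained])
    return pd.DataFrame(
        {"M": items.mean(axis=0), "SD": items.std(axis=0, ddof=1)},
        index=NODE_LABELS,
    )


def flag_prevalences(retained: Sequence[ParticipantRecord]) -> dict[str, float]:
    """Percentage of the retained sample above each screening cutoff."""
    if not retained:
        raise ValueError("prevalences require a nonempty retained sample")
    scores = [score_scales(r) for r in retained]
    n = len(scores)
    return {
        "depressive_pct": 100.0 * sum(s.depressive_flag for s in scores) / n,
        "anxiety_pct": 100.0 * sum(s.anxiety_flag for s in scores) / n,
    }


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Retained sample as a tidy table (one row per respondent)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id, "age": r.age, "sex": r.sex,
            "residence": r.residence, "living": r.living_arrangement,
        }
        row.update({lab.lower(): v for lab, v in zip(GAD_LABELS, r.gad_items)})
        row.update({lab.lower(): v for lab, v in zip(CESD_LABELS, r.cesd_items)})
        rows.append(row)
    return pd.DataFrame(rows)
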