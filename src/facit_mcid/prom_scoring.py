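"""Scoring for the patient-reported fatigue and well-being instruments.

Implements polarity-aware item recoding, prorating of partially answered
questionnaires, and range validation for the instruments used in the
fatigue analyses:

* FACIT-FS  -- 13 items scored 0-4, total 0-52, higher = less fatigue
* SF36-VT   -- 4 vitality items (9a, 9e, 9g, 9i) recoded onto 0-100 and
               averaged, higher = more vitality
* FACIT-EWB -- 6 emotional well-being items scored 0-4, total 0-24
* VAS       -- single 0-100 mm mark, higher = worse symptom

The scoring engine is instrument-agnostic: a :class:`QuestionnaireDefinition`
carries the item count, the number of ordered response levels, a per-item
polarity flag (``True`` means a higher raw response already indicates a
better state), an optional per-level recoding (e.g. the RAND 0/20/.../100
convention for the SF-36 vitality items) and the minimum answered fraction
required before a prorated score is reported.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoringError",
    "OutOfRangeError",
    "QuestionnaireDefinition",
    "ResponseSet",
    "ScaleScore",
    "score_scale",
    "validate_vas",
    "facit_fatigue_definition",
    "sf36_vitality_definition",
    "facit_ewb_definition",
    "load_definitions",
    "score_item_csv",
]


class ScoringError(ValueError):
    """Invalid questionnaire definition or response set."""


class OutOfRangeError(ScoringError):
    """A raw item response lies outside the admissible range."""


@dataclass(frozen=True)
class QuestionnaireDefinition:
    """Static description of one multi-item instrument.

    Parameters
    ----------
    name:
        Instrument label carried into every :class:`ScaleScore`.
    n_items:
        Number of items (>= 1).
    item_levels:
        Ordered response levels per item; raw responses are the integers
        ``0 .. item_levels - 1``.
    polarity:
        Per-item flag, ``True`` when a higher raw response means a better
        state.  Items with ``False`` are reverse-coded before aggregation
        so that higher always means better.
    aggregation:
        ``"sum"`` (FACIT-style totals, prorated by ``n_items/n_answered``)
        or ``"mean"`` (SF-36 subscale style, self-prorating).
    recode_map:
        Optional numeric value per *recoded* level (after the polarity
        flip), must be non-decreasing; ``None`` uses the level index.
    min_answered_fraction:
        Fraction of items that must be answered before any score is
        reported (FACIT convention: 0.5).
    """

    name: str
    n_items: int
    item_levels: int
    polarity: tuple[bool, ...]
    aggregation: str = "sum"
    recode_map: tuple[float, ...] | None = None
    min_answered_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ScoringError(f"{self.name}: n_items must be >= 1")
        if self.item_levels < 2:
            raise ScoringError(f"{self.name}: item_levels must be >= 2")
        if len(self.polarity) != self.n_items:
            raise ScoringError(
                f"{self.name}: polarity has {len(self.polarity)} entries "
                f"for {self.n_items} items"
            )
        if self.aggregation not in ("sum", "mean"):
            raise ScoringError(f"{self.name}: unknown aggregation {self.aggregation!r}")
        if self.recode_map is not None:
            if len(self.recode_map) != self.item_levels:
                raise ScoringError(f"{self.name}: recode_map length != item_levels")
            if any(b < a for a, b in zip(self.recode_map, self.recode_map[1:])):
                raise ScoringError(f"{self.name}: recode_map must be non-decreasing")
        if not 0.0 <= self.min_answered_fraction <= 1.0:
            raise ScoringError(f"{self.name}: min_answered_fraction outside [0, 1]")

    def item_value(self, item: int, raw: int) -> float:
        """Recoded value of one raw response, oriented so higher = better."""
        level = raw if self.polarity[item] else (self.item_levels - 1 - raw)
        if self.recode_map is not None:
            return float(self.recode_map[level])
        return float(level)

    @property
    def score_range(self) -> tuple[float, float]:
        """Attainable ``(min, max)`` of a complete, unprorated score."""
        values = self.recode_map if self.recode_map is not None else tuple(
            float(v) for v in range(self.item_levels)
        )
        lo, hi = min(values), max(values)
        if self.aggregation == "sum":
            return lo * self.n_items, hi * self.n_items
        return lo, hi


@dataclass(frozen=True)
class ResponseSet:
    """One respondent's raw item responses; ``None``/NaN marks missing."""

    patient_id: str
    item_values: tuple[float | None, ...]


@dataclass(frozen=True)
class ScaleScore:
    """A scored instrument for one respondent."""

    instrument: str
    value: float | None
    n_answered: int
    prorated: bool
    status: str = "ok"


def _is_missing(v: float | None) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def score_scale(definition: QuestionnaireDefinition, responses: ResponseSet) -> ScaleScore:
    """Score one response set against its questionnaire definition.

    Items are polarity-recoded so higher always means better, then summed
    (prorated by ``n_items / n_answered``) or averaged per the definition.
    If fewer than ``min_answered_fraction`` of items are answered the score
    is reported as missing with status ``"insufficient_items"``.

    Raises
    ------
    OutOfRangeError
        If any non-missing response is not an integer in
        ``[0, item_levels - 1]``; the message names the offending item.
    ScoringError
        If the response vector length does not match the definition or no
        item is answered at all.
    """
    items = responses.item_values
    if len(items) != definition.n_items:
        raise ScoringError(
            f"{definition.name}: expected {definition.n_items} responses, "
            f"got {len(items)}"
        )
    values: list[float] = []
    n_answered = 0
    for i, raw in enumerate(items):
        if _is_missing(raw):
            continue
        if float(raw) != int(raw) or not (0 <= int(raw) <= definition.item_levels - 1):
            raise OutOfRangeError(
                f"{definition.name}: item {i + 1} response {raw!r} outside "
                f"0..{definition.item_levels - 1}"
            )
        values.append(definition.item_value(i, int(raw)))
        n_answered += 1
    if n_answered == 0:
        raise ScoringError(f"{definition.name}: no item answered")
    frac = n_answered / definition.n_items
    prorated = n_answered < definition.n_items
    if frac < definition.min_answered_fraction:
        return ScaleScore(definition.name, None, n_answered, prorated,
                          status="insufficient_items")
    if definition.aggregation == "sum":
        value = sum(values) * definition.n_items / n_answered
    else:
        value = sum(values) / n_answered
    return ScaleScore(definition.name, value, n_answered, prorated)


def validate_vas(value: float, name: str = "VAS") -> ScaleScore:
    """Validate a 0-100 mm visual-analogue-scale mark.

    Values inside [0, 100] pass through unchanged; anything else raises
    :class:`OutOfRangeError`.
    """
    if _is_missing(value):
        return ScaleScore(name, None, 0, False, status="missing")
    if not 0.0 <= float(value) <= 100.0:
        raise OutOfRangeError(f"{name}: value {value!r} outside 0-100 mm")
    return ScaleScore(name, float(value), 1, False)


# ---------------------------------------------------------------------------
# Shipped instrument definitions
# ---------------------------------------------------------------------------

def facit_fatigue_definition() -> QuestionnaireDefinition:
    """13-item FACIT Fatigue Scale (0-52).

    Item order follows the standard form (HI7, HI12, An1-An4, An5, An6,
    An7, An8, An12, An14, An15).  All items are reverse-scored except the
    two positively worded ones -- "I have energy" (An5, position 7) and
    "I am able to do my usual activities" (An7, position 9).
    """
    polarity = [False] * 13
    polarity[6] = True   # An5
    polarity[8] = True   # An7
    return QuestionnaireDefinition(
        name="FACIT-FS", n_items=13, item_levels=5, polarity=tuple(polarity),
        aggregation="sum",
    )


def sf36_vitality_definition() -> QuestionnaireDefinition:
    """SF-36 Vitality subscale (items 9a, 9e, 9g, 9i), 0-100.

    Raw responses are the six ordered frequency levels 0 = "all of the
    time" .. 5 = "none of the time".  For the energy items (9a pep, 9e
    energy) frequent is good; for the exhaustion items (9g worn out,
    9i tired) frequent is bad.  Recoded levels map onto the RAND values
    0, 20, 40, 60, 80, 100 and answered items are averaged.
    """
    return QuestionnaireDefinition(
        name="SF36-VT", n_items=4, item_levels=6,
        polarity=(False, False, True, True),
        aggregation="mean",
        recode_map=(0.0, 20.0, 40.0, 60.0, 80.0, 100.0),
    )


def facit_ewb_definition() -> QuestionnaireDefinition:
    """FACIT Emotional Well-being subscale (6 items, 0-24).

    Only GE2 ("I am satisfied with how I am coping with my illness") is
    positively worded.
    """
    return QuestionnaireDefinition(
        name="FACIT-EWB", n_items=6, item_levels=5,
        polarity=(False, True, False, False, False, False),
        aggregation="sum",
    )


# ---------------------------------------------------------------------------
# External interfaces: TOML definitions, item-level CSV
# ---------------------------------------------------------------------------

def load_definitions(path: str | Path) -> dict[str, QuestionnaireDefinition]:
    """Read instrument definitions from a TOML file.

    Each top-level table defines one instrument::

        [facit_fs]
        n_items = 13
        item_levels = 5
        polarity = [false, false, ...]   # length n_items
        aggregation = "sum"
        # recode_map = [0, 20, 40, 60, 80, 100]
        # min_answered_fraction = 0.5
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out: dict[str, QuestionnaireDefinition] = {}
    for name, cfg in raw.items():
        out[name] = QuestionnaireDefinition(
            name=cfg.get("name", name),
            n_items=int(cfg["n_items"]),
            item_levels=int(cfg["item_levels"]),
            polarity=tuple(bool(p) for p in cfg["polarity"]),
            aggregation=cfg.get("aggregation", "sum"),
            recode_map=(tuple(float(v) for v in cfg["recode_map"])
                        if "recode_map" in cfg else None),
            min_answered_fraction=float(cfg.get("min_answered_fraction", 0.5)),
        )
    return out


def score_item_csv(path: str | Path,
                   definition: QuestionnaireDefinition,
                   id_column: str = "patient_id") -> pd.DataFrame:
    """Score an item-level CSV (columns ``item_1 .. item_k``, blanks missing).

    Returns a frame with one row per respondent: score value, number of
    answered items, prorated flag and status.
    """
    frame = pd.read_csv(path)
    cols = [f"item_{i + 1}" for i in range(definition.n_items)]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ScoringError(f"{definition.name}: CSV lacks columns {missing}")
    rows = []
    for _, rec in frame.iterrows():
        pid = str(rec[id_column]) if id_column in frame.columns else str(rec.name)
        values = tuple(None if pd.isna(rec[c]) else float(rec[c]) for c in cols)
        score = score_scale(definition, ResponseSet(pid, values))
        rows.append({
            id_column: pid,
            "instrument": score.instrument,
            "value": np.nan if score.value is None else score.value,
            "n_answered": score.n_answered,
            "prorated": score.prorated,
            "status": score.status,
        })
    return pd.DataFrame(rows)
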