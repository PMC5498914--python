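"""Clinical outcome metadata for caesarean (case) deliveries.

Each case record carries the umbilical-artery blood-gas panel measured at
delivery (pH, base deficit in extracellular fluid, pCO2, base excess) and
Apgar scores. The pH value drives a three-way grouping of caesarean
indications:

* ``acidosis``          — pH <= 7.20 (objective pathological outcome)
* ``deterioration``     — 7.20 < pH <= 7.25 (foetal deterioration)
* ``clinical_decision`` — pH > 7.25 (caesarean without pathological
  outcome-measure evidence)

The grouping is metadata only: the classification task downstream is
binary (case vs control) and does not use it as a label. The inclusive
7.25 boundary is deliberate — it is the only reading consistent with the
reference cohort, where pH 7.25 occurs twice and the deterioration band
counts four records.

A packaged fixture (``data/caesarean_outcomes.csv``) ships the 46-case
outcome panel of the CTU-UHB caesarean cohort.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .records import ValidationError

__all__ = [
    "OutcomeRecord",
    "CASE_GROUPS",
    "load_outcomes",
    "packaged_outcomes",
    "assign_case_group",
    "group_counts",
]

CASE_GROUPS = ("acidosis", "deterioration", "clinical_decision")

REQUIRED_COLUMNS = ["id", "age", "pH", "BDecf", "pCO2", "BE", "apgar1", "apgar5", "dev_type"]


@dataclass(frozen=True)
class OutcomeRecord:
    """One case's delivery outcome panel. Missing blood-gas fields are NaN."""

    id: int
    age: float
    pH: float
    BDecf: float
    pCO2: float
    BE: float
    apgar1: int
    apgar5: int
    dev_type: int

    def __post_init__(self) -> None:
        if not math.isnan(self.pH) and not (6.5 < self.pH < 7.8):
            raise ValidationError(f"record {self.id}: implausible pH {self.pH}")
        for name in ("apgar1", "apgar5"):
            v = getattr(self, name)
            if not (0 <= v <= 10):
                raise ValidationError(f"record {self.id}: {name}={v} outside [0, 10]")


def load_outcomes(path) -> list[OutcomeRecord]:
    """Load outcome records from a CSV with the columns
    ``id,age,pH,BDecf,pCO2,BE,apgar1,apgar5,dev_type`` (``NaN`` for missing)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty outcomes file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no outcome rows")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            OutcomeRecord(
                id=int(row.id),
                age=float(row.age),
                pH=float(row.pH),
                BDecf=float(row.BDecf),
                pCO2=float(row.pCO2),
                BE=float(row.BE),
                apgar1=int(row.apgar1),
                apgar5=int(row.apgar5),
                dev_type=int(row.dev_type),
            )
        )
    return records


def packaged_outcomes() -> list[OutcomeRecord]:
    """The packaged 46-row caesarean outcome fixture."""
    with resources.as_file(
        resources.files("ctglearn.data").joinpath("caesarean_outcomes.csv")
    ) as p:
        return load_outcomes(p)


def assign_case_group(rec: OutcomeRecord) -> str:
    """Map a case record to its pH band (see module docstring)."""
    if math.isnan(rec.pH):
        raise ValidationError(f"record {rec.id}: pH missing, cannot assign group")
    if rec.pH <= 7.20:
        return "acidosis"
    if rec.pH <= 7.25:
        return "deterioration"
    return "clinical_decision"


def group_counts(records: Iterable[OutcomeRecord]) -> dict[str, int]:
    """Counts per pH band; always contains all three group keys."""
    counts = Counter(assign_case_group(r) for r in records)
    return {g: counts.get(g, 0) for g in CASE_GROUPS}
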