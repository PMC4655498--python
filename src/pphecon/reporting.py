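"""Rendering of result tables (comparison, sensitivity, mix sweep).

Every reported integer or whole-dollar figure is round-half-away-from-zero of
an unrounded engine value that is retained alongside it in ``_raw`` columns,
so a written CSV can always be audited back to full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .analysis import ComparisonResult
from .cohort import round_half_away_from_zero
from .evidence import OUTCOMES, Outcome
from .sensitivity import SensitivityRow

__all__ = [
    "ResultTable",
    "comparison_table",
    "sensitivity_table",
    "write_csv",
    "read_csv",
    "to_text",
]

logger = logging.getLogger("pphecon")

ROUNDING_FOOTNOTE = (
    "Integers are round-half-away-from-zero of unrounded engine values; the "
    "CSV output retains those at full precision in audit columns."
)

_OUTCOME_LABELS = {
    Outcome.PPH: "PPH",
    Outcome.SEVERE_PPH: "Severe PPH",
    Outcome.ADDITIONAL_UTEROTONICS: "Additional uterotonics",
    Outcome.BLOOD_TRANSFUSION: "Blood transfusion",
    Outcome.SHIVERING: "Shivering",
    Outcome.FEVER: "Fever",
}


@dataclass(frozen=True)
class ResultTable:
    """An ordered result layout plus its audit-precision twin columns."""

    layout: str  # comparison | sensitivity | mix_sweep
    frame: pd.DataFrame
    footnote: str = ROUNDING_FOOTNOTE


def comparison_table(result: ComparisonResult) -> ResultTable:
    """Scenario-columns + increment layout for one evaluated comparison."""
    i_label = result.intervention.strategy.label()
    c_label = result.comparator.strategy.label()
    rows = []
    for outcome in OUTCOMES:
        i_raw = result.intervention.total(outcome)
        c_raw = result.comparator.total(outcome)
        inc_raw = result.increments.unrounded[outcome]
        rows.append(
            {
                "row": _OUTCOME_LABELS[outcome],
                "intervention": round_half_away_from_zero(i_raw),
                "comparator": round_half_away_from_zero(c_raw),
                "increment": round_half_away_from_zero(inc_raw),
                "intervention_raw": i_raw,
                "comparator_raw": c_raw,
                "increment_raw": inc_raw,
            }
        )
    cost_rows = (
        (
            "Drugs for prevention",
            result.intervention_costs.prophylaxis_drug_cost,
            result.comparator_costs.prophylaxis_drug_cost,
            result.incremental_cost.drug,
        ),
        (
            "Treatment of PPH",
            result.intervention_costs.pph_treatment_cost,
            result.comparator_costs.pph_treatment_cost,
            result.incremental_cost.treatment,
        ),
        (
            "Total cost",
            result.intervention_costs.total,
            result.comparator_costs.total,
            result.incremental_cost.total,
        ),
    )
    for label, i_raw, c_raw, inc_raw in cost_rows:
        rows.append(
            {
                "row": label,
                "intervention": round_half_away_from_zero(i_raw),
                "comparator": round_half_away_from_zero(c_raw),
                "increment": round_half_away_from_zero(inc_raw),
                "intervention_raw": i_raw,
                "comparator_raw": c_raw,
                "increment_raw": inc_raw,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["intervention_label"] = i_label
    frame.attrs["comparator_label"] = c_label
    logger.info(
        "comparison table: %s vs %s, source=%s, rr_bound=%s",
        i_label,
        c_label,
        result.config.pair.evidence_source,
        result.config.pair.rr_bound,
    )
    return ResultTable(layout="comparison", frame=frame)


def sensitivity_table(
    rows: Sequence[SensitivityRow], layout: str = "sensitivity"
) -> ResultTable:
    """One row per substitution (or mix), increments only, as in one-way
    sensitivity reports."""
    records = []
    for row in rows:
        record: dict[str, object] = {"analysis": row.label}
        for outcome in OUTCOMES:
            record[outcome.value] = row.increments[outcome]
        record["total_cost"] = row.incremental_cost_reported
        for outcome in OUTCOMES:
            record[f"{outcome.value}_raw"] = row.increments_unrounded[outcome]
        record["total_cost_raw"] = row.incremental_cost
        records.append(record)
    return ResultTable(layout=layout, frame=pd.DataFrame(records))


def write_csv(table: ResultTable, path: str) -> None:
    """Serialise to CSV (UTF-8, header row, full float precision)."""
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_csv(path: str) -> pd.DataFrame:
    # round_trip parsing so audit (_raw) columns come back bit-identical
    return pd.read_csv(path, float_precision="round_trip")


def to_text(table: ResultTable) -> str:
    """Human-readable rendering (reported columns only)."""
    visible = [c for c in table.frame.columns if not str(c).endswith("_raw")]
    body = table.frame[visible].to_string(index=False)
    return f"{body}\n\n{table.footnote}"
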