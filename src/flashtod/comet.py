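"""Comet-assay summaries and background-subtracted FLASH/CONV damage ratios.

The experimental sparing metric is

    damage_ratio = (test - control) / (conv - control)

on mean %Tail DNA, where ``control`` is the dataset's zero-dose background,
``conv`` the matched 0.1 Gy/s reference at the same oxygen level and dose,
and ``test`` a higher-dose-rate measurement.  A ratio of 1 means no sparing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DegenerateReferenceError, PairingError, ValidationError
from .grid import CONV_DOSE_RATE_GY_S, ROLE_CONTROL, ROLE_CONV, ROLE_TEST, Condition

#: Required columns of the delimited-text input schema, in canonical order.
SCHEMA_COLUMNS = (
    "dataset",
    "oxygen_percent",
    "dose_gy",
    "dose_rate_gy_s",
    "mean_tail_dna_percent",
    "n_comets",
)


@dataclass(frozen=True)
class CometRecord:
    """One per-condition comet-assay summary (mean %Tail DNA over n comets)."""

    condition: Condition
    mean_tail_dna: float
    n_comets: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.mean_tail_dna <= 100:
            raise ValidationError(
                f"mean_tail_dna must be in [0, 100], got {self.mean_tail_dna!r}"
            )
        if self.n_comets <= 0:
            raise ValidationError(f"n_comets must be > 0, got {self.n_comets!r}")


@dataclass(frozen=True)
class DamageRatio:
    """Background-subtracted relative damage of one test row vs its CONV pair."""

    condition: Condition
    damage_ratio: float
    control_tail: float
    conv_tail: float
    test_tail: float


def damage_ratio(
    test: CometRecord, conv: CometRecord, control: CometRecord
) -> DamageRatio:
    """Compute (test - control) / (conv - control) on mean %Tail DNA."""
    if control.condition.dose != 0:
        raise PairingError(
            f"control record must have dose 0, got {control.condition.dose}"
        )
    if conv.condition.dose_rate != CONV_DOSE_RATE_GY_S:
        raise PairingError(
            f"CONV record must be at {CONV_DOSE_RATE_GY_S} Gy/s, "
            f"got {conv.condition.dose_rate}"
        )
    if (test.condition.oxygen_percent, test.condition.dose) != (
        conv.condition.oxygen_percent,
        conv.condition.dose,
    ):
        raise PairingError(
            "test and CONV records must share oxygen and dose: "
            f"test {test.condition.physical_key} vs conv {conv.condition.physical_key}"
        )
    denom = conv.mean_tail_dna - control.mean_tail_dna
    if denom == 0:
        raise DegenerateReferenceError(
            "CONV and control %Tail DNA coincide; damage ratio undefined for "
            f"condition {test.condition.physical_key}"
        )
    value = (test.mean_tail_dna - control.mean_tail_dna) / denom
    return DamageRatio(
        condition=test.condition,
        damage_ratio=value,
        control_tail=control.mean_tail_dna,
        conv_tail=conv.mean_tail_dna,
        test_tail=test.mean_tail_dna,
    )


def _effective_control(controls: Sequence[CometRecord]) -> CometRecord:
    # Replicate zero-dose records collapse to one background level.
    mean = sum(r.mean_tail_dna for r in controls) / len(controls)
    first = controls[0]
    return CometRecord(
        condition=first.condition,
        mean_tail_dna=mean,
        n_comets=sum(r.n_comets for r in controls),
    )


def build_damage_table(records: Iterable[CometRecord]) -> list[DamageRatio]:
    """One damage ratio per irradiated row, paired within its dataset.

    Pairing key is (dataset, oxygen, dose); the control is the dataset's own
    zero-dose background (replicates averaged).  CONV rows are ratioed
    against themselves and so carry ratio 1 exactly; downstream filtering
    removes them before correlation.
    """
    records = list(records)
    by_dataset: dict[str, list[CometRecord]] = {}
    for rec in records:
        by_dataset.setdefault(rec.condition.dataset_label, []).append(rec)

    ratios: list[DamageRatio] = []
    orphans: list[tuple] = []
    for label, recs in by_dataset.items():
        controls = [r for r in recs if r.condition.role == ROLE_CONTROL]
        if not controls:
            orphans.extend(
                r.condition.key for r in recs if r.condition.role != ROLE_CONTROL
            )
            continue
        control = _effective_control(controls)
        conv_refs: dict[tuple, CometRecord] = {}
        for r in recs:
            if r.condition.role == ROLE_CONV:
                key = (r.condition.oxygen_percent, r.condition.dose)
                if key in conv_refs:
                    raise PairingError(
                        f"duplicate CONV reference in dataset {label!r} at "
                        f"oxygen/dose {key}"
                    )
                conv_refs[key] = r
        for r in recs:
            if r.condition.role == ROLE_CONTROL:
                continue
            conv = conv_refs.get((r.condition.oxygen_percent, r.condition.dose))
            if conv is None:
                orphans.append(r.condition.key)
                continue
            ratios.append(damage_ratio(r, conv, control))
    if orphans:
        raise PairingError(
            "records lacking a matched control/CONV reference: "
            + ", ".join(map(str, orphans))
        )
    return ratios


def filter_for_correlation(ratios: Iterable[DamageRatio]) -> list[DamageRatio]:
    """Retain only test rows: drop zero-dose controls and 0.1 Gy/s references."""
    return [r for r in ratios if r.condition.role == ROLE_TEST]


def records_to_frame(records: Iterable[CometRecord]) -> pd.DataFrame:
    rows = [
        {
            "dataset": r.condition.dataset_label,
            "oxygen_percent": r.condition.oxygen_percent,
            "dose_gy": r.condition.dose,
            "dose_rate_gy_s": r.condition.dose_rate,
            "mean_tail_dna_percent": r.mean_tail_dna,
            "n_comets": r.n_comets,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))


def write_comet_csv(records: Iterable[CometRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_comet_csv(path_or_buffer) -> list[CometRecord]:
    """Strictly parse the delimited comet schema; unknown columns are ignored
    for record construction but their presence is not an error (passthrough).
    """
    frame = pd.read_csv(path_or_buffer)
    missing = [c for c in SCHEMA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"comet input is missing required columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        numeric = {}
        for col in (
            "oxygen_percent",
            "dose_gy",
            "dose_rate_gy_s",
            "mean_tail_dna_percent",
            "n_comets",
        ):
            try:
                numeric[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"comet input row {i}, column {col!r}: "
                    f"cannot parse value {row[col]!r}"
                ) from exc
        try:
            condition = Condition(
                oxygen_percent=numeric["oxygen_percent"],
                dose=numeric["dose_gy"],
                dose_rate=numeric["dose_rate_gy_s"],
                dataset_label=str(row["dataset"]),
            )
            records.append(
                CometRecord(
                    condition=condition,
                    mean_tail_dna=numeric["mean_tail_dna_percent"],
                    n_comets=int(numeric["n_comets"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"comet input row {i}: {exc}") from exc
    return records
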