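"""Parameter grids and batch evaluation of the depletion + sparing pipeline.

Two designs are built in: the full factorial over the in-vitro study's value
lists (5 oxygen levels x 5 non-zero doses x 10 dose rates = 250 combinations,
255 with one zero-dose row per oxygen level) and the 36-measurement
one-factor-at-a-time design actually assayed (three datasets of 12).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .depletion import (
    Exposure,
    KineticParams,
    OxygenEnvironment,
    percent_to_mmhg,
    simulate_depletion,
)
from .errors import IntegrationError, ValidationError
from .oer import OERParams, tod_ratio

# Value lists of the reference in-vitro study.
TABLE1_OXYGEN_PERCENT = (0.25, 0.5, 1.0, 3.0, 21.0)
TABLE1_DOSES_GY = (5.0, 10.0, 20.0, 30.0, 40.0)
TABLE1_DOSE_RATES_GY_S = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 2000.0)

#: Study defaults while a single parameter is varied.
DEFAULT_OXYGEN_PERCENT = 0.5
DEFAULT_DOSE_GY = 20.0
FLASH_DOSE_RATE_GY_S = 2000.0
CONV_DOSE_RATE_GY_S = 0.1

#: Literature range of the radiolytic consumption rate, mol m^-3 Gy^-1.
G_SENSITIVITY_VALUES = (1e-4, 3e-4, 8e-4, 3e-3)

ROLE_CONTROL = "control"
ROLE_CONV = "CONV"
ROLE_TEST = "test"


def classify_role(dose: float, dose_rate: float) -> str:
    """Role of a condition: 0 Gy control, 0.1 Gy/s reference, or test row."""
    if dose == 0:
        return ROLE_CONTROL
    if dose_rate == CONV_DOSE_RATE_GY_S:
        return ROLE_CONV
    return ROLE_TEST


@dataclass(frozen=True)
class Condition:
    """One irradiation condition: oxygen fraction, dose, dose rate, dataset."""

    oxygen_percent: float
    dose: float
    dose_rate: float
    dataset_label: str = "factorial"

    def __post_init__(self) -> None:
        if self.oxygen_percent < 0:
            raise ValidationError("oxygen_percent must be >= 0")
        # Exposure validates dose/dose_rate domains.
        Exposure(self.dose, self.dose_rate)

    @property
    def role(self) -> str:
        return classify_role(self.dose, self.dose_rate)

    @property
    def key(self) -> tuple:
        """Join key: dataset + the three physical axes."""
        return (self.dataset_label, self.oxygen_percent, self.dose, self.dose_rate)

    @property
    def physical_key(self) -> tuple:
        return (self.oxygen_percent, self.dose, self.dose_rate)


@dataclass(frozen=True)
class TODTable:
    """Per-condition end oxygen and sparing ratio with full provenance."""

    frame: pd.DataFrame
    kinetic: KineticParams
    oer: OERParams
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def conditions(self) -> list[Condition]:
        return [
            Condition(
                oxygen_percent=row.oxygen_percent,
                dose=row.dose_gy,
                dose_rate=row.dose_rate_gy_s,
                dataset_label=row.dataset,
            )
            for row in self.frame.itertuples()
        ]

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _validate_axis(name: str, values: Sequence[float]) -> list[float]:
    values = list(values)
    if not values:
        raise ValidationError(f"{name} must be non-empty")
    if len(set(values)) != len(values):
        raise ValidationError(f"{name} contains duplicate values: {values}")
    return values


def full_factorial(
    oxygen_levels: Sequence[float] = TABLE1_OXYGEN_PERCENT,
    doses: Sequence[float] = TABLE1_DOSES_GY,
    dose_rates: Sequence[float] = TABLE1_DOSE_RATES_GY_S,
    include_zero_dose: bool = False,
) -> list[Condition]:
    """Cartesian product of the three axes, optionally with 0 Gy rows.

    With ``include_zero_dose`` one extra zero-dose condition is appended per
    oxygen level (at the lowest listed dose rate), matching the published
    count of 255 = 250 + 5.
    """
    oxygen_levels = _validate_axis("oxygen_levels", oxygen_levels)
    doses = _validate_axis("doses", doses)
    dose_rates = _validate_axis("dose_rates", dose_rates)

    conditions = []
    for oxy in sorted(oxygen_levels):
        all_doses = ([0.0] if include_zero_dose else []) + sorted(doses)
        for dose in all_doses:
            if dose == 0.0:
                conditions.append(Condition(oxy, 0.0, min(dose_rates), "factorial"))
                continue
            for rate in sorted(dose_rates):
                conditions.append(Condition(oxy, dose, rate, "factorial"))
    return conditions


def cooper_design() -> list[Condition]:
    """The 36-measurement one-factor-at-a-time design (three datasets of 12).

    Each dataset holds 2 zero-dose controls plus matched higher-dose-rate and
    0.1 Gy/s reference rows; non-varied parameters sit at the study defaults
    (0.5% O2, 20 Gy, 2000 Gy/s vs 0.1 Gy/s).  Controls carry the default
    oxygen level (0.5%) in every dataset.
    """
    conditions: list[Condition] = []

    # Dataset 1: oxygen varied at 20 Gy, FLASH vs CONV.
    label = "oxygen-varied"
    for _ in range(2):
        conditions.append(
            Condition(DEFAULT_OXYGEN_PERCENT, 0.0, CONV_DOSE_RATE_GY_S, label)
        )
    for rate in (CONV_DOSE_RATE_GY_S, FLASH_DOSE_RATE_GY_S):
        for oxy in TABLE1_OXYGEN_PERCENT:
            conditions.append(Condition(oxy, DEFAULT_DOSE_GY, rate, label))

    # Dataset 2: dose varied at 0.5% O2, FLASH vs CONV.
    label = "dose-varied"
    for _ in range(2):
        conditions.append(
            Condition(DEFAULT_OXYGEN_PERCENT, 0.0, CONV_DOSE_RATE_GY_S, label)
        )
    for rate in (CONV_DOSE_RATE_GY_S, FLASH_DOSE_RATE_GY_S):
        for dose in TABLE1_DOSES_GY:
            conditions.append(Condition(DEFAULT_OXYGEN_PERCENT, dose, rate, label))

    # Dataset 3: dose rate varied at 0.5% O2 and 20 Gy.
    label = "doserate-varied"
    for _ in range(2):
        conditions.append(
            Condition(DEFAULT_OXYGEN_PERCENT, 0.0, CONV_DOSE_RATE_GY_S, label)
        )
    for rate in TABLE1_DOSE_RATES_GY_S:
        conditions.append(
            Condition(DEFAULT_OXYGEN_PERCENT, DEFAULT_DOSE_GY, rate, label)
        )

    assert len(conditions) == 36
    return conditions


def run_grid(
    conditions: Iterable[Condition],
    kinetic: KineticParams = KineticParams(),
    oer_params: OERParams = OERParams(),
    *,
    method: str = "full",
    metadata: Mapping[str, object] | None = None,
) -> TODTable:
    """Simulate depletion and compute the sparing ratio for every condition.

    Physically identical conditions (repeated across datasets) are simulated
    once and shared.  Output row order follows input order; one row per
    input condition.
    """
    conditions = list(conditions)
    cache: dict[tuple, tuple[float, float, float]] = {}
    rows = []
    for cond in conditions:
        phys = cond.physical_key
        if phys not in cache:
            p0 = percent_to_mmhg(cond.oxygen_percent)
            env = OxygenEnvironment(initial_pO2=p0)
            exposure = Exposure(dose=cond.dose, dose_rate=cond.dose_rate)
            try:
                trace = simulate_depletion(env, exposure, kinetic, method=method)
            except IntegrationError as exc:
                raise IntegrationError(
                    f"condition {phys} (dataset {cond.dataset_label!r}): {exc}",
                    exc.time_reached,
                ) from exc
            result = tod_ratio(trace.end_pO2, p0, oer_params)
            cache[phys] = (p0, trace.end_pO2, result.tod_ratio)
        p0, end_pO2, ratio = cache[phys]
        rows.append(
            {
                "dataset": cond.dataset_label,
                "oxygen_percent": cond.oxygen_percent,
                "dose_gy": cond.dose,
                "dose_rate_gy_s": cond.dose_rate,
                "role": cond.role,
                "initial_pO2_mmHg": p0,
                "end_pO2_mmHg": end_pO2,
                "tod_ratio": ratio,
            }
        )
    meta = dict(metadata or {})
    meta.setdefault("kinetic", dataclasses.asdict(kinetic))
    meta.setdefault("oer", dataclasses.asdict(oer_params))
    meta.setdefault("solver_method", method)
    return TODTable(
        frame=pd.DataFrame(rows), kinetic=kinetic, oer=oer_params, metadata=meta
    )


def sensitivity_sweep(
    conditions: Iterable[Condition],
    g_values: Sequence[float] = G_SENSITIVITY_VALUES,
    oer_params: OERParams = OERParams(),
    kinetic_base: KineticParams = KineticParams(),
    *,
    method: str = "full",
) -> tuple[dict[float, TODTable], pd.DataFrame]:
    """Re-run the grid at each consumption rate g; summarize min sparing ratio."""
    conditions = list(conditions)
    if any(g < 0 for g in g_values):
        raise ValidationError("g_values must be non-negative")
    tables: dict[float, TODTable] = {}
    summary_rows = []
    for g in g_values:
        kinetic = dataclasses.replace(kinetic_base, g_consumption=g)
        table = run_grid(conditions, kinetic, oer_params, method=method)
        tables[g] = table
        summary_rows.append(
            {"g_mol_m3_gy": g, "min_tod_ratio": float(table.frame["tod_ratio"].min())}
        )
    return tables, pd.DataFrame(summary_rows)
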