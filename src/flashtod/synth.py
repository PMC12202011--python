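"""Synthetic comet-assay data with the statistical structure the pipeline
assumes: strand-break damage proportional to dose times the oxygen
enhancement ratio at the end-of-delivery oxygen tension, plus measurement
noise.  Stands in for the unpublished per-condition experimental means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .comet import CometRecord
from .depletion import (
    Exposure,
    KineticParams,
    OxygenEnvironment,
    percent_to_mmhg,
    simulate_depletion,
)
from .errors import ValidationError
from .grid import Condition, cooper_design
from .oer import OERParams, oer


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic damage model.

    ``mean_tail_dna = baseline + slope * dose * OER(end_pO2) + N(0, noise_sd)``
    for irradiated rows; controls receive baseline plus noise.  Values are
    clipped to the [0, 100] %Tail DNA range.
    """

    baseline_tail: float = 5.0
    damage_per_gy_per_oer: float = 0.4
    noise_sd: float = 1.0
    seed: int = 0
    design: tuple[Condition, ...] = field(
        default_factory=lambda: tuple(cooper_design())
    )
    n_comets: int = 50

    def __post_init__(self) -> None:
        if self.baseline_tail < 0:
            raise ValidationError("baseline_tail must be >= 0")
        if self.damage_per_gy_per_oer <= 0:
            raise ValidationError("damage_per_gy_per_oer must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def generate(
    config: SyntheticConfig,
    kinetic: KineticParams = KineticParams(),
    oer_params: OERParams = OERParams(),
    end_pO2_cache: dict[tuple, float] | None = None,
) -> list[CometRecord]:
    """Deterministic (seeded) synthetic records over the configured design.

    ``end_pO2_cache`` maps ``condition.physical_key`` to a precomputed
    end-of-delivery tension; missing entries are simulated and added, so a
    shared cache amortizes the ODE cost across repeated draws.
    """
    rng = np.random.default_rng(config.seed)
    end_cache = end_pO2_cache if end_pO2_cache is not None else {}
    records = []
    for cond in config.design:
        if cond.dose == 0:
            mean = config.baseline_tail
        else:
            phys = cond.physical_key
            if phys not in end_cache:
                p0 = percent_to_mmhg(cond.oxygen_percent)
                trace = simulate_depletion(
                    OxygenEnvironment(initial_pO2=p0),
                    Exposure(dose=cond.dose, dose_rate=cond.dose_rate),
                    kinetic,
                )
                end_cache[phys] = trace.end_pO2
            mean = (
                config.baseline_tail
                + config.damage_per_gy_per_oer
                * cond.dose
                * oer(end_cache[phys], oer_params)
            )
        noisy = mean + rng.normal(0.0, config.noise_sd)
        records.append(
            CometRecord(
                condition=cond,
                mean_tail_dna=float(np.clip(noisy, 0.0, 100.0)),
                n_comets=config.n_comets,
            )
        )
    return records
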