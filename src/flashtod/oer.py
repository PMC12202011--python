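"""Oxygen enhancement ratio curve and the transient-depletion sparing ratio.

The OER follows the classic hyperbolic oxygen dependence

    OER(p) = (oer_max * p + k_half) / (p + k_half)

rising from 1 under anoxia to ``oer_max`` at full oxygenation, with
half-maximal enhancement at ``p = k_half``.  The sparing metric compares the
OER at the end-of-delivery (depleted) oxygen tension with the OER at the
no-net-depletion reference tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class OERParams:
    """Parameters of the hyperbolic OER curve.

    Defaults are the standard Alper-Howard-Flanders values used throughout
    the oxygen-depletion modelling literature: maximum enhancement 3.0 and
    half-maximal tension 3.28 mmHg.
    """

    oer_max: float = 3.0
    k_half: float = 3.28

    def __post_init__(self) -> None:
        if not np.isfinite(self.oer_max) or self.oer_max <= 1:
            raise DomainError(f"oer_max must be > 1, got {self.oer_max!r}")
        if not np.isfinite(self.k_half) or self.k_half <= 0:
            raise DomainError(f"k_half must be > 0, got {self.k_half!r}")


@dataclass(frozen=True)
class TODRatioResult:
    """Sparing ratio between depleted and reference oxygenation states.

    ``tod_ratio = oer_end / oer_reference``; 1 means no change in
    radiosensitivity from depletion, smaller values mean more sparing.
    """

    tod_ratio: float
    end_pO2: float
    reference_pO2: float
    oer_end: float
    oer_reference: float


def oer(pO2, params: OERParams = OERParams()):
    """Evaluate the OER curve at an oxygen tension (mmHg; scalar or array)."""
    p = np.asarray(pO2, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0):
        raise DomainError(f"pO2 must be finite and >= 0, got {pO2!r}")
    value = (params.oer_max * p + params.k_half) / (p + params.k_half)
    return float(value) if np.isscalar(pO2) else value


def tod_ratio(
    end_pO2: float, reference_pO2: float, params: OERParams = OERParams()
) -> TODRatioResult:
    """Sparing ratio of the OER at the depleted level to the reference level."""
    oer_end = oer(end_pO2, params)
    oer_reference = oer(reference_pO2, params)
    return TODRatioResult(
        tod_ratio=oer_end / oer_reference,
        end_pO2=float(end_pO2),
        reference_pO2=float(reference_pO2),
        oer_end=oer_end,
        oer_reference=oer_reference,
    )
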