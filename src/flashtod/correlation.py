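"""Pairing of model sparing ratios with experimental damage ratios, and the
rank/linear correlation statistics linking them.

Spearman's rho is computed as Pearson's r on mid-ranks (average ranks for
ties); two-sided p-values for both statistics use the t transform

    t = s * sqrt((n - 2) / (1 - s^2)),   df = n - 2.

An exact permutation p-value for Spearman is available behind a flag for
small samples.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .comet import DamageRatio
from .errors import DegenerateCorrelationError, JoinError, ValidationError
from .grid import TODTable


@dataclass(frozen=True)
class PairedRatioTable:
    """Matched (model sparing ratio, experimental damage ratio) pairs."""

    frame: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def tod_ratios(self) -> np.ndarray:
        return self.frame["tod_ratio"].to_numpy()

    @property
    def damage_ratios(self) -> np.ndarray:
        return self.frame["damage_ratio"].to_numpy()

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class CorrelationResult:
    spearman_rho: float
    pearson_r: float
    p_spearman: float
    p_pearson: float
    n: int
    p_spearman_exact: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def pair_ratios(tod: TODTable, damage: list[DamageRatio]) -> PairedRatioTable:
    """Inner join of damage ratios onto the model table on condition keys.

    The key includes the dataset label because physically identical
    conditions recur across the one-factor-at-a-time datasets.  Every damage
    row must match exactly one model row; row count equals the damage count.
    """
    for d in damage:
        if d.condition.role != "test":
            raise ValidationError(
                f"paired table admits only test rows, got role "
                f"{d.condition.role!r} for {d.condition.key}"
            )
    keys = [d.condition.key for d in damage]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise JoinError(f"duplicated condition(s) in damage set: {dupes}")

    tod_index: dict[tuple, float] = {}
    for row in tod.frame.itertuples():
        if row.role != "test":
            continue  # control/CONV rows are never joined; replicates allowed there
        key = (row.dataset, row.oxygen_percent, row.dose_gy, row.dose_rate_gy_s)
        if key in tod_index:
            raise JoinError(f"duplicated condition in TOD table: {key}")
        tod_index[key] = row.tod_ratio

    rows = []
    for d in damage:
        key = d.condition.key
        if key not in tod_index:
            raise JoinError(f"damage condition not found in TOD table: {key}")
        rows.append(
            {
                "dataset": d.condition.dataset_label,
                "oxygen_percent": d.condition.oxygen_percent,
                "dose_gy": d.condition.dose,
                "dose_rate_gy_s": d.condition.dose_rate,
                "tod_ratio": tod_index[key],
                "damage_ratio": d.damage_ratio,
            }
        )
    columns = [
        "dataset",
        "oxygen_percent",
        "dose_gy",
        "dose_rate_gy_s",
        "tod_ratio",
        "damage_ratio",
    ]
    return PairedRatioTable(frame=pd.DataFrame(rows, columns=columns))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom)


def t_transform_pvalue(s: float, n: int) -> float:
    """Two-sided p-value of a correlation coefficient via the t transform."""
    if abs(s) >= 1.0:
        return float(np.finfo(float).tiny)
    t = abs(s) * np.sqrt((n - 2) / (1.0 - s * s))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return float(max(min(p, 1.0), np.finfo(float).tiny))


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    if n > 9:
        raise ValidationError(
            "exact permutation Spearman p supported only for n <= 9 "
            f"(full enumeration of n! permutations), got n = {n}"
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(_pearson(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_pearson(rx, np.array(perm))) >= observed - 1e-12:
            count += 1
    return count / total


def correlate(
    pairs: PairedRatioTable, *, exact_permutation: bool = False
) -> CorrelationResult:
    """Spearman and Pearson correlation of sparing vs damage ratios."""
    x = np.asarray(pairs.tod_ratios, dtype=float)
    y = np.asarray(pairs.damage_ratios, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError(f"correlation requires n >= 3, got n = {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateCorrelationError(
            "constant column: correlation is undefined (not silently 0)"
        )
    pearson_r = _pearson(x, y)
    spearman_rho = _pearson(stats.rankdata(x), stats.rankdata(y))
    result = CorrelationResult(
        spearman_rho=spearman_rho,
        pearson_r=pearson_r,
        p_spearman=t_transform_pvalue(spearman_rho, n),
        p_pearson=t_transform_pvalue(pearson_r, n),
        n=n,
        p_spearman_exact=(
            _exact_spearman_pvalue(x, y) if exact_permutation else None
        ),
    )
    return result
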