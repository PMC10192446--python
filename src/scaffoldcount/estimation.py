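"""Whole-scaffold cell number estimation from per-column counts.

Each column samples a known volume fraction of the scaffold, so its count
extrapolates to a per-column scaffold estimate

    N_hat_i = c_i * V_scaffold / v_col,

and the scaffold estimate is the mean of the nine N_hat_i.  The coefficient
of variation of the N_hat_i (sample SD / mean, n-1 convention) quantifies the
sampling noise of the design.  The scaffold volume itself is measured by
liquid displacement (Archimedes' principle) in a graduated cylinder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .counting import CountResult
from .errors import InvalidSpecError, ReadingError


@dataclass(frozen=True)
class ScaffoldEstimate:
    """Per-column extrapolated counts, their mean and CV."""

    per_column_estimates: np.ndarray
    estimate: float
    cv: float | None
    scaffold_volume_ul: float
    sampled_volume_ul: float

    def to_frame(self, scaffold_id: str | int = 0, method: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold_id": [scaffold_id],
                "method": [method],
                "estimate": [self.estimate],
                "cv": [np.nan if self.cv is None else self.cv],
                "scaffold_volume_ul": [self.scaffold_volume_ul],
                "sampled_volume_ul": [self.sampled_volume_ul],
            }
        )


@dataclass(frozen=True)
class VolumeMeasurement:
    """An Archimedes displacement reading.

    ``volume_ul`` is quantized to the 100-ul instrument resolution (0.1-ml
    graduations); ``raw_ul`` keeps the unrounded difference and
    ``relative_error`` propagates the +-0.05-ml reading uncertainty.
    """

    volume_ul: float
    raw_ul: float
    relative_error: float | None


def scaffold_estimate(
    counts: Sequence[CountResult | int],
    column_volume_ul: float,
    scaffold_volume_ul: float,
) -> ScaffoldEstimate:
    """Extrapolate per-column counts to the whole scaffold.

    Because all columns share one volume, the mean-of-columns form used here
    coincides with the pooled form sum(c) / (n * v_col) * V.
    """
    if scaffold_volume_ul <= 0 or column_volume_ul <= 0:
        raise InvalidSpecError("volumes must be positive")
    c = np.array(
        [x.count if isinstance(x, CountResult) else int(x) for x in counts],
        dtype=float,
    )
    if c.size == 0:
        raise InvalidSpecError("counts must be non-empty")
    if (c < 0).any():
        raise InvalidSpecError("counts must be >= 0")
    per_col = c * scaffold_volume_ul / column_volume_ul
    est = float(per_col.mean())
    if est > 0 and c.size >= 2:
        cv = float(per_col.std(ddof=1) / est)
    else:
        cv = None
    return ScaffoldEstimate(
        per_column_estimates=per_col,
        estimate=est,
        cv=cv,
        scaffold_volume_ul=scaffold_volume_ul,
        sampled_volume_ul=c.size * column_volume_ul,
    )


def pooled_estimate(
    counts: Sequence[CountResult | int],
    column_volume_ul: float,
    scaffold_volume_ul: float,
) -> float:
    """Pooled cross-check: sum of counts over total sampled volume, scaled."""
    c = np.array(
        [x.count if isinstance(x, CountResult) else int(x) for x in counts],
        dtype=float,
    )
    return float(c.sum() / (c.size * column_volume_ul) * scaffold_volume_ul)


def archimedes_volume(
    initial_reading_ml: float, final_reading_ml: float
) -> VolumeMeasurement:
    """Scaffold volume from cylinder readings before/after immersion."""
    if final_reading_ml < initial_reading_ml:
        raise ReadingError(
            "final reading below initial reading: negative displacement"
        )
    raw_ul = (final_reading_ml - initial_reading_ml) * 1000.0
    quantized = round(raw_ul / 100.0) * 100.0
    rel = (50.0 / quantized) if quantized > 0 else None
    return VolumeMeasurement(volume_ul=quantized, raw_ul=raw_ul, relative_error=rel)


def sampling_cv(
    estimates: Sequence[ScaffoldEstimate],
) -> tuple[list[float], float]:
    """Per-scaffold CVs and their mean across scaffolds.

    Scaffolds whose estimate is zero (CV undefined) are excluded with a
    warning.
    """
    cvs: list[float] = []
    for i, est in enumerate(estimates):
        if est.per_column_estimates.size < 2:
            raise InvalidSpecError("sampling_cv needs >= 2 columns per scaffold")
        if est.cv is None:
            warnings.warn(
                f"scaffold {i}: zero estimate, CV undefined; excluded",
                stacklevel=2,
            )
            continue
        cvs.append(est.cv)
    if not cvs:
        raise InvalidSpecError("no scaffold with a defined CV")
    return cvs, float(np.mean(cvs))
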