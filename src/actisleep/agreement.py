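"""Diary-versus-actigraphy agreement: Bland-Altman bias and correlations.

Differences are oriented diary minus derived, so a positive bias means
the diary over-reports relative to the device. Clock-time traits (onset,
wake time) are differenced on the circle, wrapping to +/- 12 h, before
the Bland-Altman statistics are formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementResult", "bland_altman", "trait_correlation"]


@dataclass
class AgreementResult:
    trait: str
    n_pairs: int
    bias: float  # mean(diary - derived)
    sd_diff: float
    loa_low: float  # bias - 1.96 * sd
    loa_high: float  # bias + 1.96 * sd
    pearson_r: float
    spearman_rho: float


def _paired(diary, derived) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(diary, dtype=float)
    b = np.asarray(derived, dtype=float)
    if a.shape != b.shape:
        raise ValueError("diary and derived values must be paired (same length)")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    return a[ok], b[ok]


def bland_altman(
    diary, derived, trait: str = "", circular_hours: bool = False
) -> AgreementResult:
    """Bland-Altman agreement between diary-reported and derived values.

    bias = mean(diary - derived); the 95% limits of agreement are
    bias +/- 1.96 * SD of the differences. With ``circular_hours`` the
    inputs are clock hours and each difference is wrapped into
    ``[-12, 12)`` first.
    """
    a, b = _paired(diary, derived)
    diff = a - b
    if circular_hours:
        diff = (diff + 12.0) % 24.0 - 12.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    r, rho = trait_correlation(a, b)
    return AgreementResult(
        trait=trait,
        n_pairs=len(diff),
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_r=r,
        spearman_rho=rho,
    )


def trait_correlation(diary, derived) -> tuple[float, float]:
    """Pearson r and Spearman rho over complete pairs."""
    a, b = _paired(diary, derived)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, _ = stats.pearsonr(a, b)
    rho, _ = stats.spearmanr(a, b)
    return float(r), float(rho)
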