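"""Per-feature differential statistics: Welch t, BH adjustment, DE calls.

All ORA-type enrichment methods and CAMERA consume these statistics.  The
sign convention for the mean difference is ``group 1 - group 0`` (case
minus reference), matching the simulation engine where mean signals are
added to the second group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset

__all__ = ["GeneLevelStats", "welch_stats", "bh_adjust", "de_flags", "z_scores"]

DEFAULT_FDR_CUTOFF = 0.05


@dataclass
class GeneLevelStats:
    """Per-feature Welch statistics with BH q-values and DE flags."""

    feature_ids: list[str]
    delta_e: np.ndarray  # signed mean difference, case - reference
    t_stat: np.ndarray
    df: np.ndarray  # Satterthwaite degrees of freedom
    p_value: np.ndarray
    q_value: np.ndarray | None = None
    is_de: np.ndarray | None = None
    z_score: np.ndarray | None = None
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF

    def __post_init__(self) -> None:
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    def feature_index(self, features) -> np.ndarray:
        return np.array([self._index[f] for f in features], dtype=int)

    @property
    def n_de(self) -> int:
        return int(np.sum(self.is_de)) if self.is_de is not None else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "delta_e": self.delta_e,
                "t": self.t_stat,
                "p": self.p_value,
                "q": self.q_value,
                "is_de": self.is_de,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def welch_stats(
    data: ExpressionDataset, fdr_cutoff: float = DEFAULT_FDR_CUTOFF
) -> GeneLevelStats:
    """Welch two-sample t-test per feature, with BH q-values and DE flags.

    Uses the Satterthwaite degrees-of-freedom approximation.  Features with
    zero variance in both groups and equal means get ``t=0, p=1``.  Each
    group needs at least two samples.
    """
    x = data.group_values(1)  # case
    y = data.group_values(0)  # reference
    n1, n0 = x.shape[1], y.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("welch_stats requires >= 2 samples per group")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    delta = mx - my
    se2 = vx / n1 + vy / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, delta / np.sqrt(se2), 0.0)
        num = se2**2
        den = (vx / n1) ** 2 / (n1 - 1) + (vy / n0) ** 2 / (n0 - 1)
        df = np.where(den > 0, num / den, n1 + n0 - 2)
    p = np.where(se2 > 0, 2.0 * sps.t.sf(np.abs(t), df), 1.0)
    # degenerate: both variances zero but means differ -> infinite evidence
    degenerate = (se2 == 0) & (delta != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(delta) * np.inf, t)
    p = np.where(degenerate, 0.0, p)
    out = GeneLevelStats(
        feature_ids=list(data.feature_ids),
        delta_e=delta,
        t_stat=t,
        df=df,
        p_value=p,
        fdr_cutoff=fdr_cutoff,
    )
    out.q_value = bh_adjust(out.p_value)
    out.is_de = de_flags(out, fdr_cutoff)
    out.z_score = z_scores(out)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_flags(stats: GeneLevelStats, cutoff: float = DEFAULT_FDR_CUTOFF) -> np.ndarray:
    """DE flag per feature: BH q-value at or below ``cutoff``."""
    if stats.q_value is None:
        raise ValueError("q-values not computed")
    return stats.q_value <= cutoff

def z_scores(stats: GeneLevelStats) -> np.ndarray:
    """Map Welch t statistics to normal-scale z via the quantile transform
    ``z = Phi^{-1}(F_t(t; df))``.  Sign-preserving and strictly increasing
    in t; infinite t maps to +/- 8 to keep downstream arithmetic finite.
    """
    t, df = stats.t_stat, stats.df
    z = np.empty_like(t, dtype=float)
    finite = np.isfinite(t)
    tt, dd = np.abs(t[finite]), df[finite]
    # work on the upper tail for numerical accuracy, then restore sign
    tail = sps.t.sf(tt, dd)
    zz = -sps.norm.ppf(np.clip(tail, 1e-300, 1.0))
    z[finite] = np.sign(t[finite]) * np.minimum(zz, 8.0)
    z[~finite] = np.sign(t[~finite]) * 8.0
    return z
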