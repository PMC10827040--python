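"""First-order decay-rate estimation from transcription-shutoff time courses.

Abundances are normalized to the shutoff start (t=0) within each replicate,
so the model is A(t) = exp(-k t) and the fit is least squares of
ln(abundance) against time *through the origin* (a free-intercept variant is
available). The pooled rate is the mean of per-replicate rates with its
standard error; half-life is ln2/k, flagged infinite for k at zero.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

LN2 = float(np.log(2.0))
_K_TOL = 1e-12


@dataclasses.dataclass
class DecaySeries:
    """One replicate time course, normalized so abundance(t=0) == 1."""

    ref_id: str
    condition: str
    replicate: int
    timepoints: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.timepoints.shape != self.abundances.shape:
            raise ValueError("timepoints and abundances differ in length")
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")
        if not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.timepoints[0] != 0.0:
            raise ValueError("t=0 must be present")
        if np.all(self.abundances == 0):
            raise ValueError("all-zero abundance series")
        if (self.abundances < 0).any():
            raise ValueError("abundances must be nonnegative")

    @classmethod
    def from_counts(cls, ref_id, condition, replicate, timepoints, counts) -> "DecaySeries":
        counts = np.asarray(counts, dtype=float)
        order = np.argsort(np.asarray(timepoints, dtype=float))
        t = np.asarray(timepoints, dtype=float)[order]
        c = counts[order]
        if c[0] <= 0:
            raise ValueError("t=0 abundance must be positive for normalization")
        return cls(ref_id, condition, int(replicate), t, c / c[0])


@dataclasses.dataclass
class DecayFit:
    """Pooled first-order decay fit across replicates."""

    k: float
    half_life: float
    r_squared: float
    se_k: float
    k_per_replicate: np.ndarray

    @property
    def n_replicates(self) -> int:
        return len(self.k_per_replicate)


class ExponentialDecay(BaseEstimator, RegressorMixin):
    """Least-squares exponential decay estimator, sklearn style.

    Fits ln(y) = -k*t (``through_origin=True``, the default, appropriate for
    t=0-normalized data) or ln(y) = c - k*t. Zeros in y are floored at
    ``epsilon`` with a warning. Fitted attributes: ``k_``, ``half_life_``,
    ``r_squared_``, ``intercept_``.
    """

    def __init__(self, through_origin: bool = True, epsilon: float = 1e-6,
                 clip_negative: bool = True):
        self.through_origin = through_origin
        self.epsilon = epsilon
        self.clip_negative = clip_negative

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y differ in length")
        if len(np.unique(t)) < 2:
            raise ValueError("need at least two distinct timepoints")
        if np.all(y == 0):
            raise ValueError("all-zero abundance series")
        if (y <= 0).any():
            warnings.warn(f"nonpositive abundances floored at epsilon={self.epsilon}")
            y = np.maximum(y, self.epsilon)
        logy = np.log(y)
        if self.through_origin:
            denom = float(np.sum(t * t))
            if denom == 0:
                raise ValueError("need a timepoint beyond t=0")
            slope = float(np.sum(t * logy)) / denom
            self.intercept_ = 0.0
        else:
            slope, intercept = np.polyfit(t, logy, 1)
            slope = float(slope)
            self.intercept_ = float(intercept)
        k = -slope
        if k < 0:
            if self.clip_negative:
                warnings.warn("fitted rate is negative (upward drift); clipped at 0")
                k = 0.0
        self.k_ = k
        self.half_life_ = np.inf if k <= _K_TOL else LN2 / k
        pred = self.intercept_ - self.k_ * t
        ss_res = float(np.sum((logy - pred) ** 2))
        center = 0.0 if self.through_origin else float(np.mean(logy))
        ss_tot = float(np.sum((logy - center) ** 2))
        self.r_squared_ = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return np.exp(self.intercept_ - self.k_ * t)


def fit_decay(
    series_replicates: Sequence[DecaySeries],
    *,
    through_origin: bool = True,
    epsilon: float = 1e-6,
) -> DecayFit:
    """Fit a pooled decay rate from replicate time courses.

    Per replicate, ln(abundance) is regressed on time through the origin
    (t=0 normalization makes the intercept zero by construction); the pooled
    rate is the replicate mean, se_k = SD/sqrt(n). r_squared pools all
    points against the pooled rate.
    """
    if len(series_replicates) == 0:
        raise ValueError("no replicates given")
    ks = []
    all_t, all_logy = [], []
    for s in series_replicates:
        est = ExponentialDecay(through_origin=through_origin, epsilon=epsilon)
        est.fit(s.timepoints, s.abundances)
        ks.append(est.k_)
        all_t.append(s.timepoints)
        all_logy.append(np.log(np.maximum(s.abundances, epsilon)))
    ks = np.asarray(ks, dtype=float)
    k = float(ks.mean())
    se_k = float(ks.std(ddof=1) / np.sqrt(len(ks))) if len(ks) > 1 else np.nan
    t = np.concatenate(all_t)
    logy = np.concatenate(all_logy)
    ss_res = float(np.sum((logy + k * t) ** 2))
    ss_tot = float(np.sum(logy**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DecayFit(
        k=k,
        half_life=np.inf if k <= _K_TOL else LN2 / k,
        r_squared=r2,
        se_k=se_k,
        k_per_replicate=ks,
    )


def compare_decay(fit_a: DecayFit, fit_b: DecayFit) -> tuple[float, float]:
    """Rate ratio k_B/k_A and a Welch two-sided p on replicate-level rates.

    Identical replicate rate sets (zero variance, equal means) return p=1 by
    convention. Requires >= 2 replicates per fit.
    """
    if fit_a.n_replicates < 2 or fit_b.n_replicates < 2:
        raise ValueError("compare_decay needs >= 2 replicates per condition")
    if fit_a.k <= _K_TOL:
        raise ValueError("reference rate is zero; ratio undefined")
    ratio = fit_b.k / fit_a.k
    a, b = fit_a.k_per_replicate, fit_b.k_per_replicate
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ratio, p


def series_from_table(counts: pd.DataFrame, *, condition: str = "") -> dict[str, list[DecaySeries]]:
    """Group a long-format (ref_id, replicate, time, count) table into series."""
    out: dict[str, list[DecaySeries]] = {}
    for (rid, rep), sub in counts.groupby(["ref_id", "replicate"]):
        out.setdefault(rid, []).append(
            DecaySeries.from_counts(rid, condition, rep, sub["time"].to_numpy(),
                                    sub["count"].to_numpy())
        )
    return out
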