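"""Clonal dynamics: diversity statistics, fate classification, overlap.

Longitudinal clone abundances are compared with two competing nonlinear
least-squares models — exponential growth ``a0·exp(k·t)`` for persister clones
and exponential decay ``a0·exp(−k·t)`` for sensitive clones.  Trajectories are
rescaled to [0, 1] by their own maximum before fitting so the residual
sum-of-squares threshold (RSS < 0.1) is scale-free.  Clones whose proportion
never exceeds a low-abundance cutoff, or that fit neither model, are labeled
low-abundance.

Diversity uses the Shannon index in nats, with Hutcheson's analytic variance
and two-sample t-test for comparing two samples' indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

FATE_LABELS = ("persister", "sensitive", "low_abundance")


@dataclass(frozen=True)
class TimepointMeta:
    """Sampling-time metadata used to normalize clone proportions."""

    label: str
    day: int
    tumor_volume: float  # mm^3
    activity_scalar: float = 1.0

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.tumor_volume <= 0:
            raise ValueError("tumor volume must be > 0")


@dataclass(frozen=True)
class DiversityResult:
    H: float  # nats
    variance: float  # Hutcheson variance of H
    n: int  # total count
    S: int  # number of observed categories


@dataclass(frozen=True)
class FitResult:
    a0: float
    k: float
    rss: float


@dataclass(frozen=True)
class FateCall:
    label: str
    rss_growth: float
    rss_decay: float
    fit_growth: FitResult
    fit_decay: FitResult


def shannon_index(counts: Sequence[float], base: float = math.e) -> DiversityResult:
    """Shannon diversity H = −Σ p·log p with Hutcheson's variance.

    The variance is ``(Σ p (ln p)² − H²)/n + (S−1)/(2n²)`` (natural-log scale;
    converted if another base is requested).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or np.any(arr < 0):
        raise ValueError("counts must be non-negative with at least one entry")
    n = arr.sum()
    if n <= 0:
        raise ValueError("at least one positive count required")
    p = arr[arr > 0] / n
    h_nats = float(-(p * np.log(p)).sum())
    s = int(p.size)
    var_nats = float(((p * np.log(p) ** 2).sum() - h_nats**2) / n + (s - 1) / (2 * n**2))
    scale = 1.0 / math.log(base)
    return DiversityResult(
        H=h_nats * scale, variance=var_nats * scale**2, n=int(round(n)), S=s
    )


def hutcheson_test(
    counts1: Sequence[float], counts2: Sequence[float]
) -> tuple[float, float, float]:
    """Two-tailed Hutcheson t-test comparing two Shannon indices.

    Returns ``(t, df, p)`` with Welch-style degrees of freedom
    ``(V1+V2)² / (V1²/n1 + V2²/n2)``.
    """
    d1 = shannon_index(counts1)
    d2 = shannon_index(counts2)
    v = d1.variance + d2.variance
    if v <= 0:
        raise ValueError("degenerate samples: zero pooled variance")
    t = (d1.H - d2.H) / math.sqrt(v)
    df = v**2 / (d1.variance**2 / d1.n + d2.variance**2 / d2.n)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, min(p, 1.0)


def normalize_abundance(p: float, meta: TimepointMeta) -> float:
    """Normalized abundance A = proportion × tumor volume × activity scalar."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    return p * meta.tumor_volume * meta.activity_scalar


def normalize_table(
    proportions: pd.DataFrame, meta: Sequence[TimepointMeta]
) -> pd.DataFrame:
    """Column-wise normalization of a clones × timepoints proportion table."""
    if proportions.shape[1] != len(meta):
        raise ValueError("one TimepointMeta per proportion column required")
    scale = np.array([m.tumor_volume * m.activity_scalar for m in meta])
    return proportions * scale


def _model(direction: str):
    sign = 1.0 if direction == "growth" else -1.0
    return lambda t, a0, k: a0 * np.exp(sign * k * t)


def fit_exponential(
    times: Sequence[float], values: Sequence[float], direction: str
) -> FitResult:
    """NLS fit of ``a0·exp(±k·t)`` with k ≥ 0; RSS on max-rescaled values.

    Initialization: a0 = first rescaled value, k = |slope| of a log-linear
    regression; k bounded to [0, 10] per day.  Non-convergence is reported as
    ``rss = inf`` (a failed fit), never raised.
    """
    if direction not in ("growth", "decay"):
        raise ValueError("direction must be 'growth' or 'decay'")
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("at least 3 timepoints required")
    ymax = y.max()
    if not np.isfinite(ymax) or ymax <= 0:
        return FitResult(0.0, 0.0, math.inf)
    y = y / ymax
    with np.errstate(divide="ignore"):
        logy = np.log(np.clip(y, 1e-12, None))
    slope = np.polyfit(t, logy, 1)[0] if t.size > 1 else 0.0
    p0 = (max(y[0], 1e-6), float(np.clip(abs(slope), 0.0, 10.0)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _model(direction),
                t,
                y,
                p0=p0,
                bounds=([0.0, 0.0], [np.inf, 10.0]),
                maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return FitResult(math.nan, math.nan, math.inf)
    resid = y - _model(direction)(t, *popt)
    return FitResult(float(popt[0]), float(popt[1]), float(resid @ resid))


def classify_fate(
    times: Sequence[float],
    abundances: Sequence[float],
    proportions: Sequence[float] | None = None,
    rss_threshold: float = 0.1,
    low_abundance_max: float = 1e-4,
) -> FateCall:
    """Label one clone persister / sensitive / low-abundance.

    ``abundances`` is the fitted series (normalized abundance when volume
    metadata is available, otherwise proportions).  A clone whose proportion
    never reaches ``low_abundance_max`` is low-abundance outright; otherwise
    the growth and decay fits compete: the label follows the model(s) with
    RSS below threshold, lower RSS winning when both qualify and exact ties
    (or neither qualifying) falling through to low-abundance.
    """
    props = abundances if proportions is None else proportions
    fg = fit_exponential(times, abundances, "growth")
    fd = fit_exponential(times, abundances, "decay")
    if float(np.max(props)) < low_abundance_max:
        label = "low_abundance"
    else:
        g_ok = fg.rss < rss_threshold
        d_ok = fd.rss < rss_threshold
        if g_ok and d_ok:
            if fg.rss < fd.rss:
                label = "persister"
            elif fd.rss < fg.rss:
                label = "sensitive"
            else:
                label = "low_abundance"
        elif g_ok:
            label = "persister"
        elif d_ok:
            label = "sensitive"
        else:
            label = "low_abundance"
    return FateCall(label, fg.rss, fd.rss, fg, fd)


def classify_trajectories(
    proportions: pd.DataFrame,
    meta: Sequence[TimepointMeta],
    rss_threshold: float = 0.1,
    low_abundance_max: float = 1e-4,
) -> pd.DataFrame:
    """Classify every clone in a clones × timepoints proportion table.

    Returns a DataFrame indexed by clone with columns
    label, rss_growth, rss_decay, k_growth, k_decay.
    """
    days = [m.day for m in meta]
    norm = normalize_table(proportions, meta)
    rows = {}
    for clone in proportions.index:
        call = classify_fate(
            days,
            norm.loc[clone].to_numpy(),
            proportions.loc[clone].to_numpy(),
            rss_threshold=rss_threshold,
            low_abundance_max=low_abundance_max,
        )
        rows[clone] = (
            call.label,
            call.rss_growth,
            call.rss_decay,
            call.fit_growth.k,
            call.fit_decay.k,
        )
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["label", "rss_growth", "rss_decay", "k_growth", "k_decay"],
    )


def overlap_fraction(set_pre: Iterable[str], set_post: Iterable[str]) -> dict:
    """Percentage of pre-treatment clones still detected post-treatment.

    ``100·|pre ∩ post| / |pre|`` — normalized by the first argument only.
    """
    pre = set(set_pre)
    post = set(set_post)
    if not pre:
        raise ValueError("pre-treatment set must be non-empty")
    shared = pre & post
    return {
        "n_pre": len(pre),
        "n_post": len(post),
        "n_shared": len(shared),
        "percent": 100.0 * len(shared) / len(pre),
    }


def shared_across(sets: Sequence[Iterable[str]]) -> set[str]:
    """Clones present in every one of several samples (k-way intersection)."""
    if not sets:
        raise ValueError("at least one set required")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out
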