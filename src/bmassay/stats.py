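"""Statistical battery: normality-gated t / permutation tests and BH-FDR.

Every comparison follows the same recipe: the Shapiro-Wilk test decides (at
alpha = 0.05) whether the sample is plausibly normal; normal samples get a
parametric paired or independent (pooled-variance) t-test, the rest get a
permutation t-test whose null is built by random sign-flips of the paired
differences or by label shuffles between groups.  Families of per-time-bin
comparisons are corrected with Benjamini-Hochberg step-up FDR; the
whole-period comparison is reported unadjusted, outside the bin family.

Missing values (a fish that never entered an ROI in a period) are deleted
pairwise before every test, so degrees of freedom vary between comparisons.

The Monte-Carlo permutation p-value uses the +1 correction,
``p = (1 + #{|T*| >= |T|}) / (1 + n_perm)``, so it is never exactly zero;
when the permutation group is small enough (all ``2^n`` sign patterns or all
label splits fit within ``n_perm``) the enumeration is exhaustive and the
p-value is exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, SampleSizeError
from .preference import PreferenceSummary

__all__ = [
    "StatResult",
    "t_test",
    "permutation_t",
    "shapiro_wilk",
    "bh_fdr",
    "gated_comparison",
    "analyze_experiment",
]

_TIE_EPS = 1e-12  # |T*| >= |T| comparisons are blurred by this to absorb float ties


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p: float
    method: str
    n_used: int
    df: Optional[float] = None
    p_adj: Optional[float] = None


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[np.isfinite(x)]


def _pair_clean(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def _t_one_sample(d: np.ndarray) -> tuple[float, float, float]:
    n = len(d)
    m = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 1.0, df
        return math.copysign(math.inf, m), 0.0, df
    t = m / (sd / math.sqrt(n))
    return t, 2.0 * float(sps.t.sf(abs(t), df)), df


def _t_independent(x: np.ndarray, y: np.ndarray, welch: bool = False) -> tuple[float, float, float]:
    n1, n2 = len(x), len(y)
    m1, m2 = float(np.mean(x)), float(np.mean(y))
    v1, v2 = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            return (0.0, 1.0, n1 + n2 - 2) if m1 == m2 else (math.copysign(math.inf, m1 - m2), 0.0, n1 + n2 - 2)
        t = (m1 - m2) / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0.0:
            return (0.0, 1.0, df) if m1 == m2 else (math.copysign(math.inf, m1 - m2), 0.0, df)
        t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, 2.0 * float(sps.t.sf(abs(t), df)), df


def t_test(a, b=None, paired: bool = False, welch: bool = False) -> StatResult:
    """Two-sided t-test; paired uses differences, independent pools variance.

    ``b=None`` with ``paired=True`` treats ``a`` as already-formed paired
    differences (tested against zero).  Zero variance with zero mean
    difference yields t = 0, p = 1.
    """
    if paired:
        if b is None:
            d = _clean(a)
        else:
            x, y = _pair_clean(a, b)
            d = x - y
        if len(d) < 2:
            raise SampleSizeError(f"need >= 2 pairs, got {len(d)}")
        t, p, df = _t_one_sample(d)
        return StatResult(statistic=t, p=p, df=df, method="paired-t", n_used=len(d))
    x, y = _clean(a), _clean(b)
    if len(x) < 2 or len(y) < 2:
        raise SampleSizeError("need >= 2 observations per group")
    t, p, df = _t_independent(x, y, welch=welch)
    method = "welch-t" if welch else "independent-t"
    return StatResult(statistic=t, p=p, df=df, method=method, n_used=len(x) + len(y))


def _perm_t_from_signs(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized paired t over sign-flip patterns (rows of ``signs``)."""
    n = len(d)
    means = signs @ d / n
    ss = float(np.sum(d * d))
    var = (ss - n * means**2) / (n - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / (sd / math.sqrt(n))
    t[sd == 0.0] = np.where(means[sd == 0.0] == 0.0, 0.0, np.inf)
    return t


def permutation_t(
    a,
    b=None,
    paired: bool = False,
    n_perm: int = 10_000,
    seed: int = 0,
    welch: bool = False,
) -> StatResult:
    """Permutation t-test (sign-flip null for paired, label-shuffle for independent).

    Exhaustive enumeration is used whenever the full permutation group fits
    within ``n_perm``; otherwise ``n_perm`` random draws with the +1
    corrected Monte-Carlo p-value.  Reproducible for a fixed ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if paired:
        if b is None:
            d = _clean(a)
        else:
            x, y = _pair_clean(a, b)
            d = x - y
        n = len(d)
        if n < 2:
            raise SampleSizeError(f"need >= 2 pairs, got {n}")
        t_obs, _, _ = _t_one_sample(d)
        exhaustive = 2**n <= n_perm
        if exhaustive:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        else:
            signs = rng.integers(0, 2, size=(n_perm, n)).astype(float) * 2.0 - 1.0
        t_null = _perm_t_from_signs(d, signs)
        n_used, method = n, "permutation-paired"
    else:
        x, y = _clean(a), _clean(b)
        n1, n2 = len(x), len(y)
        if n1 < 2 or n2 < 2:
            raise SampleSizeError("need >= 2 observations per group")
        t_obs, _, _ = _t_independent(x, y, welch=welch)
        pooled = np.concatenate([x, y])
        n = n1 + n2
        exhaustive = comb(n, n1) <= n_perm
        if exhaustive:
            t_null = np.array(
                [
                    _t_independent(pooled[list(idx)], np.delete(pooled, list(idx)), welch=welch)[0]
                    for idx in itertools.combinations(range(n), n1)
                ]
            )
        else:
            order = np.argsort(rng.random((n_perm, n)), axis=1)
            g1 = pooled[order[:, :n1]]
            g2 = pooled[order[:, n1:]]
            m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
            v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
            if welch:
                se2 = v1 / n1 + v2 / n2
            else:
                sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n - 2)
                se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_null = (m1 - m2) / np.sqrt(se2)
            t_null[se2 == 0.0] = np.where(m1[se2 == 0.0] == m2[se2 == 0.0], 0.0, np.inf)
        n_used, method = n, "permutation-independent"

    hits = int(np.sum(np.abs(t_null) >= abs(t_obs) - _TIE_EPS))
    if exhaustive:
        p = hits / len(t_null)
    else:
        p = (1 + hits) / (1 + len(t_null))
    return StatResult(statistic=t_obs, p=float(min(p, 1.0)), method=method, n_used=n_used)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (the gate for parametric vs permutation tests)."""
    x = _clean(x)
    n = len(x)
    if n < 3:
        raise SampleSizeError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {n}")
    if n > 5000:
        raise SampleSizeError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {n}")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    out = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def gated_comparison(
    a,
    b=None,
    paired: bool = False,
    alpha_gate: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    welch: bool = False,
) -> StatResult:
    """Normality-gated comparison: Shapiro-Wilk chooses t-test vs permutation.

    Paired data are gated on the differences; independent data on each group
    (either group non-normal routes to the permutation test).  Samples too
    small or too degenerate for Shapiro-Wilk fall back to the parametric test.
    """

    def _normal(x) -> bool:
        x = _clean(x)
        if len(x) < 3 or float(np.std(x)) == 0.0:
            return True
        return shapiro_wilk(x)[1] >= alpha_gate

    if paired:
        if b is None:
            d = _clean(a)
        else:
            x, y = _pair_clean(a, b)
            d = x - y
        use_t = _normal(d)
    else:
        use_t = _normal(a) and _normal(b)
    if use_t:
        return t_test(a, b, paired=paired, welch=welch)
    return permutation_t(a, b, paired=paired, n_perm=n_perm, seed=seed, welch=welch)


# ---------------------------------------------------------------------------
# experiment drivers


def _metric_matrix(
    summaries: Sequence[PreferenceSummary], roi: str, period: str, column: str
) -> np.ndarray:
    return np.array([s.value(roi, period, column) for s in summaries])


_METRICS = ("time_pct", "orient_pct", "rproj")
_BIN_PERIODS = ("bin1", "bin2", "bin3", "bin4")


def analyze_experiment(
    summaries: Sequence[PreferenceSummary],
    design: str = "within",
    groups: Sequence[str] | None = None,
    alpha_gate: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    welch: bool = False,
) -> pd.DataFrame:
    """Run the full comparison battery over a cohort of per-fish summaries.

    ``design="within"`` (dual-display): every fish sees both stimuli; the
    test-vs-baseline comparisons (Δ vs 0) are paired within fish for the
    whole test period and each 1-min bin, and ROI 1 vs ROI 2 Δs are compared
    paired.  ``design="between"`` (single-display): ``groups`` assigns each
    fish to a stimulus group; test-vs-baseline stays paired within each
    group's stimulus ROI (ROI 1), and the group contrast is an independent
    test of the two groups' ROI 1 Δs.

    FDR family: the four 1-min-bin comparisons within each metric x ROI (or
    metric x contrast), adjusted separately from the whole-period comparison.
    """
    if len(summaries) == 0:
        raise DesignError("no summaries")
    rows: list[dict] = []
    periods = ("test",) + _BIN_PERIODS
    seed_stream = itertools.count(seed)

    def _run(label_roi: str, comparison: str, getter) -> None:
        fam: list[dict] = []
        for period in periods:
            a, b, paired = getter(period)
            try:
                res = gated_comparison(
                    a, b, paired=paired, alpha_gate=alpha_gate,
                    n_perm=n_perm, seed=next(seed_stream), welch=welch,
                )
            except SampleSizeError:
                continue
            fam.append(
                {
                    "metric": metric,
                    "roi": label_roi,
                    "period": period,
                    "comparison": comparison,
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": res.df,
                    "n_used": res.n_used,
                    "p": res.p,
                    "p_adj": np.nan,
                }
            )
        bins = [r for r in fam if r["period"] != "test"]
        if bins:
            adj = bh_fdr([r["p"] for r in bins])
            for r, pa in zip(bins, adj):
                r["p_adj"] = pa
        rows.extend(fam)

    if design == "within":
        for metric in _METRICS:
            for roi in ("ROI 1", "ROI 2"):
                _run(
                    roi,
                    "test-vs-baseline",
                    lambda period, roi=roi, metric=metric: (
                        _metric_matrix(summaries, roi, period, f"d_{metric}"),
                        None,
                        True,
                    ),
                )
            _run(
                "ROI 1 vs ROI 2",
                "roi-contrast",
                lambda period, metric=metric: (
                    _metric_matrix(summaries, "ROI 1", period, f"d_{metric}"),
                    _metric_matrix(summaries, "ROI 2", period, f"d_{metric}"),
                    True,
                ),
            )
    elif design == "between":
        if groups is None:
            groups = [s.group for s in summaries]
        groups = np.asarray(groups)
        labels = [g for g in pd.unique(groups) if g is not None]
        if len(labels) != 2:
            raise DesignError(f"between design needs exactly 2 groups, got {labels}")
        split = {g: [s for s, gg in zip(summaries, groups) if gg == g] for g in labels}
        if min(len(v) for v in split.values()) < 3:
            raise DesignError("need >= 3 fish per group")
        for metric in _METRICS:
            for g in labels:
                _run(
                    f"ROI 1 ({g})",
                    "test-vs-baseline",
                    lambda period, g=g, metric=metric: (
                        _metric_matrix(split[g], "ROI 1", period, f"d_{metric}"),
                        None,
                        True,
                    ),
                )
            _run(
                f"ROI 1 ({labels[0]} vs {labels[1]})",
                "group-contrast",
                lambda period, metric=metric: (
                    _metric_matrix(split[labels[0]], "ROI 1", period, f"d_{metric}"),
                    _metric_matrix(split[labels[1]], "ROI 1", period, f"d_{metric}"),
                    False,
                ),
            )
    else:
        raise DesignError(f"unknown design {design!r}")
    return pd.DataFrame(rows)
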