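"""Trial statistics: descriptive summaries, ANOVA + LSD letters, correlations.

Implements the statistical layer of a genotype × treatment pot trial:

* per-trait descriptive statistics (min/max/mean/SE/CV) with CV banding
  (<15% low, 15–30% medium, >30% high);
* one-way fixed-effects ANOVA across genotypes with Fisher's least
  significant difference, LSD = t(1−α/2, df_E) · √(2·MSE/r), and a
  compact letter display in which two means share a letter exactly when
  their absolute difference is at most the LSD;
* the Pearson correlation matrix over genotype means with two-sided
  p-values from the t transform t = r√((n−2)/(1−r²)).

Significance stars follow the conventional fixed thresholds (0.05, 0.01,
0.001) with no multiple-testing correction by default; a Holm option is
available on the correlation long table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import TraitMeanMatrix

__all__ = [
    "TraitSummary",
    "AnovaLSD",
    "CorrelationMatrix",
    "describe_trait",
    "cv_band",
    "significance_code",
    "anova_lsd",
    "lsd_letters",
    "correlation_matrix",
    "correlation_long_table",
    "summarize_trial",
]

#: CV band cut points in percent (low < first ≤ medium ≤ second < high).
DEFAULT_CV_BANDS = (15.0, 30.0)


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    treatment: str
    n: int
    min: float
    max: float
    mean: float
    se: float
    cv_percent: float
    cv_band: str
    genotype_significance: str


@dataclass(frozen=True)
class AnovaLSD:
    """One-way ANOVA result with Fisher-LSD letter display."""

    F: float
    p: float
    lsd: float
    letters: dict[str, str]
    means: dict[str, float]
    mse: float
    df_error: int


@dataclass(frozen=True)
class CorrelationMatrix:
    traits: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def describe_trait(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(min, max, mean, SE, CV%) of a sample.

    SE and CV use the sample standard deviation (n−1 denominator);
    with fewer than two values both are NaN (undefined), while
    min/max/mean are still reported.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("describe_trait needs at least one value")
    mn, mx, mean = float(x.min()), float(x.max()), float(x.mean())
    if x.size < 2:
        return mn, mx, mean, float("nan"), float("nan")
    sd = float(x.std(ddof=1))
    se = sd / math.sqrt(x.size)
    cv = float("nan") if mean == 0 else 100.0 * sd / abs(mean)
    return mn, mx, mean, se, cv


def cv_band(
    cv_percent: float, bands: tuple[float, float] = DEFAULT_CV_BANDS
) -> str:
    """Band a coefficient of variation: <15% low, 15–30% medium, >30% high."""
    if not math.isfinite(cv_percent) or cv_percent < 0:
        raise ValueError("CV must be a non-negative finite percentage")
    lo, hi = bands
    if cv_percent < lo:
        return "low"
    if cv_percent <= hi:
        return "medium"
    return "high"


def significance_code(p: float) -> str:
    """Star-threshold code for a p-value: ns / p05 / p01 / p001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.001:
        return "p001"
    if p < 0.01:
        return "p01"
    if p < 0.05:
        return "p05"
    return "ns"


SIG_STARS = {"ns": "ns", "p05": "*", "p01": "**", "p001": "***"}


# ---------------------------------------------------------------------------
# One-way ANOVA with Fisher's LSD and compact letter display
# ---------------------------------------------------------------------------

def _harmonic_mean(ns: Sequence[int]) -> float:
    return len(ns) / sum(1.0 / n for n in ns)


def lsd_letters(means: Mapping[str, float], lsd: float) -> dict[str, str]:
    """Compact letter display for a threshold relation on group means.

    Two groups share a letter exactly when |mean_i − mean_j| ≤ LSD.  For
    a fixed-difference threshold the "not significantly different"
    relation on sorted means is an interval relation, so the maximal
    runs of within-LSD means are the maximal cliques; one letter per
    maximal run (a, b, c, … in descending-mean order) is the standard
    insert-and-absorb display.
    """
    order = sorted(means, key=lambda k: (-means[k], k))
    m = [means[k] for k in order]
    n = len(order)
    intervals: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and m[i] - m[j + 1] <= lsd:
            j += 1
        if not intervals or intervals[-1][1] < j:
            intervals.append((i, j))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {k: "" for k in order}
    for idx, (i, j) in enumerate(intervals):
        ch = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for k in range(i, j + 1):
            letters[order[k]] += ch
    return letters


def anova_lsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaLSD:
    """One-way fixed-effects ANOVA across lines with Fisher-LSD letters.

    Accepts balanced or unbalanced replicate counts; the LSD uses the
    harmonic-mean replicate number.  Degenerate cases: identical group
    means with zero residual variance yield an undefined F (NaN) and a
    single shared letter; distinct means with zero residual variance
    yield an infinite F and fully separated letters (LSD = 0).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two lines")
    data = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ValueError(f"line {k!r} needs at least two replicates")
    all_vals = np.concatenate(list(data.values()))
    grand = all_vals.mean()
    k = len(data)
    n_total = all_vals.size
    means = {g: float(v.mean()) for g, v in data.items()}
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_e = k - 1, n_total - k
    msb = ssb / df_b
    mse = ssw / df_e

    if mse == 0:
        if msb == 0:
            f_stat, p = float("nan"), float("nan")
        else:
            f_stat, p = float("inf"), 0.0
        lsd = 0.0
    else:
        f_stat = msb / mse
        p = float(sps.f.sf(f_stat, df_b, df_e))
        r_h = _harmonic_mean([v.size for v in data.values()])
        lsd = float(sps.t.ppf(1 - alpha / 2, df_e) * math.sqrt(2 * mse / r_h))

    return AnovaLSD(
        F=f_stat, p=p, lsd=lsd, letters=lsd_letters(means, lsd),
        means=means, mse=float(mse), df_error=df_e,
    )


# ---------------------------------------------------------------------------
# Correlations over genotype means
# ---------------------------------------------------------------------------

def correlation_matrix(
    means: TraitMeanMatrix | pd.DataFrame,
    traits: Sequence[str],
    treatment: str = "WS",
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over per-line trait means.

    ``means`` may be a :class:`TraitMeanMatrix` (restricted to one
    treatment, stress by default) or a ready lines × traits frame.
    p-values are two-sided from the exact t transform with n−2 degrees
    of freedom.  Zero-variance traits get NaN correlations (flagged by
    the NaN itself) rather than an arbitrary sign.
    """
    if isinstance(means, TraitMeanMatrix):
        frame = means.treatment_means(treatment, list(traits))
    else:
        frame = means.loc[:, list(traits)]
    frame = frame.dropna(axis=0, how="any")
    n = len(frame)
    if n < 3:
        raise ValueError("correlation needs at least 3 complete lines")
    x = frame.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[np.ix_(sd == 0, np.arange(len(traits)))] = np.nan
    r[np.ix_(np.arange(len(traits)), sd == 0)] = np.nan
    np.fill_diagonal(r, [1.0 if s > 0 else np.nan for s in sd])

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.isinf(t)] = 0.0
    np.fill_diagonal(p, np.nan)

    idx = pd.Index(list(traits))
    return CorrelationMatrix(
        traits=tuple(traits),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=n,
    )


def correlation_long_table(
    corr: CorrelationMatrix, holm: bool = False
) -> pd.DataFrame:
    """Long-form correlation table (trait_a, trait_b, r, p, stars).

    One row per unordered trait pair.  With ``holm=True`` p-values are
    Holm step-down adjusted before starring (off by default).
    """
    rows = []
    traits = corr.traits
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            rows.append((a, b, corr.r.loc[a, b], corr.p.loc[a, b]))
    df = pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p"])
    pvals = df["p"].to_numpy(dtype=float)
    if holm:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        pvals = adj
        df["p_adj"] = pvals
    df["stars"] = [
        SIG_STARS[significance_code(p)] if np.isfinite(p) else ""
        for p in pvals
    ]
    return df


# ---------------------------------------------------------------------------
# Whole-trial summary
# ---------------------------------------------------------------------------

def summarize_trial(
    obs: pd.DataFrame,
    alpha: float = 0.05,
    cv_bands: tuple[float, float] = DEFAULT_CV_BANDS,
) -> pd.DataFrame:
    """Descriptive-statistics table per (trait, treatment).

    Mirrors the layout of a trial summary table: min, max, mean, SE, CV%
    with its band, and the genotype-effect significance code from a
    one-way ANOVA across lines (``ns`` when the ANOVA is not estimable,
    e.g. a single replicate per line).
    """
    records = []
    for (trait, trt), sub in obs.groupby(["trait", "treatment"], sort=True):
        mn, mx, mean, se, cv = describe_trait(sub["value"].to_numpy())
        band = cv_band(cv, cv_bands) if math.isfinite(cv) else ""
        groups = {
            str(line): g["value"].to_numpy()
            for line, g in sub.groupby("line_id")
        }
        sig = "ns"
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            res = anova_lsd(groups, alpha)
            sig = significance_code(res.p) if math.isfinite(res.p) else "ns"
        records.append(
            TraitSummary(str(trait), str(trt), len(sub), mn, mx, mean, se,
                         cv, band, sig)
        )
    return pd.DataFrame([r.__dict__ for r in records])
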