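"""Cluster-aware inferential layer.

Observations are clustered: participants contribute up to two eyes and eyes
up to three visits, so eye- and scan-level measurements are not independent.
All interval estimates here therefore resample *clusters* (participants) with
replacement -- the cluster bootstrap -- rather than raw observations, and the
point estimands (means, mean differences, Pearson/Spearman correlations,
ICC, AUROC) are the ordinary full-sample statistics.  This replaces
mixed-model (random participant intercept) estimation with a resampling
scheme that respects the same dependence structure; the substitution is
recorded in every emitted result row via the ``method`` field.

Conventions: percentile bootstrap CIs (two-sided); bootstrap p-values by CI
inversion, p = 2 * min(P*(stat <= 0), P*(stat >= 0)); AUROC by the
Mann-Whitney rank formulation with ties scored 1/2; Spearman with midranks;
ICC is the two-way absolute-agreement single-measurement coefficient
ICC(A,1); DeLong's placement-value variance for correlated AUROC contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "paired_t",
    "pearson_clustered",
    "icc_agreement",
    "spearman_rho",
    "spearman_diff",
    "pearson_diff",
    "auroc",
    "delong_test",
    "group_means",
    "first_scan_filter",
    "cluster_bootstrap",
]


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined on the given sample."""


@dataclass
class StatResult:
    """One estimate with its uncertainty and clustering bookkeeping."""

    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float | None = None
    n_units: int = 0
    n_clusters: int = 0
    n_boot: int = 0
    method: str = ""
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_units": self.n_units,
            "n_clusters": self.n_clusters,
            "n_boot": self.n_boot,
            "method": self.method,
        }
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------

def _cluster_groups(cluster_id: np.ndarray) -> list[np.ndarray]:
    cluster_id = np.asarray(cluster_id)
    order = {}
    for i, c in enumerate(cluster_id):
        order.setdefault(c, []).append(i)
    return [np.asarray(v, int) for v in order.values()]


def cluster_bootstrap(
    stat_fn,
    n_obs: int,
    cluster_id: np.ndarray | None,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap draws of ``stat_fn(index_array)``, resampling whole clusters.

    ``stat_fn`` receives an integer index array into the observation vectors
    and returns a scalar (NaN to drop a degenerate replicate).  When
    ``cluster_id`` is None every observation is its own cluster, which reduces
    to ordinary case resampling.
    """
    if cluster_id is None:
        groups = [np.array([i]) for i in range(n_obs)]
    else:
        groups = _cluster_groups(cluster_id)
    m = len(groups)
    picks = rng.integers(0, m, size=(n_boot, m))
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([groups[j] for j in picks[b]])
        draws[b] = stat_fn(idx)
    return draws[np.isfinite(draws)]


def _percentile_ci(draws: np.ndarray, alpha: float) -> tuple[float, float]:
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _boot_p(draws: np.ndarray) -> float:
    """Two-sided bootstrap p for H0: statistic = 0, by CI inversion."""
    p = 2.0 * min(float(np.mean(draws <= 0.0)), float(np.mean(draws >= 0.0)))
    return min(1.0, max(p, 1.0 / (draws.size + 1)))


def _n_clusters(cluster_id, n_obs: int) -> int:
    return n_obs if cluster_id is None else len(set(np.asarray(cluster_id).tolist()))


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def paired_t(diffs: np.ndarray, alpha: float = 0.05) -> StatResult:
    """Classical paired-samples t test on per-unit differences."""
    d = np.asarray(diffs, float)
    if d.size < 2:
        raise DegenerateDataError("paired t requires n >= 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired t is undefined for zero-variance differences")
    mean = float(d.mean())
    se = sd / np.sqrt(d.size)
    tcrit = float(sps.t.ppf(1 - alpha / 2.0, d.size - 1))
    t_stat = mean / se
    p = float(2.0 * sps.t.sf(abs(t_stat), d.size - 1))
    return StatResult(
        estimate=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        p_value=p,
        n_units=int(d.size),
        n_clusters=int(d.size),
        method="PAIRED_T",
        extra={"t": float(t_stat), "df": int(d.size - 1)},
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0:
        return np.nan
    return float((xs * ys).sum() / denom)


def pearson_clustered(
    x,
    y,
    cluster_id=None,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> StatResult:
    """Pearson r with a percentile cluster-bootstrap CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("pearson requires paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("pearson is undefined for a constant vector")
    r = _pearson(x, y)
    rng = np.random.default_rng(seed)
    draws = cluster_bootstrap(
        lambda idx: _pearson(x[idx], y[idx]), x.size, cluster_id, n_boot, rng
    )
    lo, hi = _percentile_ci(draws, alpha)
    return StatResult(
        estimate=r,
        ci_low=lo,
        ci_high=hi,
        n_units=int(x.size),
        n_clusters=_n_clusters(cluster_id, x.size),
        n_boot=int(n_boot),
        method="PEARSON+CLUSTER_BOOT",
    )


def _icc_a1(x: np.ndarray, y: np.ndarray) -> float:
    """Two-way absolute-agreement single-measurement ICC(A,1)."""
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def icc_agreement(
    x,
    y,
    cluster_id=None,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> StatResult:
    """ICC(A,1) between two methods' measurements, cluster-bootstrap CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("ICC requires paired vectors with n >= 3")
    if np.ptp(np.stack([x, y])) == 0:
        raise DegenerateDataError("ICC is undefined for constant data")
    est = _icc_a1(x, y)
    if not np.isfinite(est):
        raise DegenerateDataError("ICC denominator is zero")
    rng = np.random.default_rng(seed)
    draws = cluster_bootstrap(
        lambda idx: _icc_a1(x[idx], y[idx]), x.size, cluster_id, n_boot, rng
    )
    lo, hi = _percentile_ci(draws, alpha)
    return StatResult(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        n_units=int(x.size),
        n_clusters=_n_clusters(cluster_id, x.size),
        n_boot=int(n_boot),
        method="ICC_A1+CLUSTER_BOOT",
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return _pearson(rx, ry)


def spearman_rho(x, y_ordinal) -> StatResult:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y_ordinal, float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("spearman requires paired vectors with n >= 3")
    if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
        raise DegenerateDataError("spearman is undefined for an all-tied vector")
    rho = _spearman(x, y)
    return StatResult(
        estimate=rho,
        n_units=int(x.size),
        n_clusters=int(x.size),
        method="SPEARMAN",
    )


def spearman_diff(
    xA,
    xB,
    y_ordinal,
    cluster_id=None,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> StatResult:
    """Difference of two methods' Spearman rho against the same ordinal outcome.

    CI and p come from the cluster bootstrap of the paired data (both methods
    resampled together, preserving their correlation).
    """
    xA = np.asarray(xA, float)
    xB = np.asarray(xB, float)
    y = np.asarray(y_ordinal, float)
    if not (xA.size == xB.size == y.size):
        raise DegenerateDataError("paired vectors must share length")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("all-tied ordinal outcome")
    est = _spearman(xA, y) - _spearman(xB, y)

    def stat(idx):
        yi = y[idx]
        if len(np.unique(yi)) < 2:
            return np.nan
        return _spearman(xA[idx], yi) - _spearman(xB[idx], yi)

    rng = np.random.default_rng(seed)
    draws = cluster_bootstrap(stat, y.size, cluster_id, n_boot, rng)
    lo, hi = _percentile_ci(draws, alpha)
    return StatResult(
        estimate=float(est),
        ci_low=lo,
        ci_high=hi,
        p_value=_boot_p(draws),
        n_units=int(y.size),
        n_clusters=_n_clusters(cluster_id, y.size),
        n_boot=int(n_boot),
        method="SPEARMAN_DIFF+CLUSTER_BOOT",
    )


def pearson_diff(
    xA,
    xB,
    y,
    cluster_id=None,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> StatResult:
    """Difference of two methods' Pearson r against the same outcome.

    Both methods are resampled together in the cluster bootstrap, preserving
    their within-unit correlation.
    """
    xA = np.asarray(xA, float)
    xB = np.asarray(xB, float)
    y = np.asarray(y, float)
    if not (xA.size == xB.size == y.size) or y.size < 3:
        raise DegenerateDataError("paired vectors with n >= 3 required")
    est = _pearson(xA, y) - _pearson(xB, y)

    def stat(idx):
        yi = y[idx]
        if np.ptp(yi) == 0:
            return np.nan
        return _pearson(xA[idx], yi) - _pearson(xB[idx], yi)

    rng = np.random.default_rng(seed)
    draws = cluster_bootstrap(stat, y.size, cluster_id, n_boot, rng)
    lo, hi = _percentile_ci(draws, alpha)
    return StatResult(
        estimate=float(est),
        ci_low=lo,
        ci_high=hi,
        p_value=_boot_p(draws),
        n_units=int(y.size),
        n_clusters=_n_clusters(cluster_id, y.size),
        n_boot=int(n_boot),
        method="PEARSON_DIFF+CLUSTER_BOOT",
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC with midrank tie handling (ties score 1/2)."""
    pos = labels.astype(bool)
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auroc(
    scores,
    binary_labels,
    cluster_id=None,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> StatResult:
    """AUROC (rank formulation) with a cluster-bootstrap CI."""
    scores = np.asarray(scores, float)
    labels = np.asarray(binary_labels).astype(bool)
    if scores.size != labels.size:
        raise DegenerateDataError("scores and labels must share length")
    est = _auroc(scores, labels)
    if not np.isfinite(est):
        raise DegenerateDataError("AUROC requires both classes present")
    rng = np.random.default_rng(seed)
    draws = cluster_bootstrap(
        lambda idx: _auroc(scores[idx], labels[idx]),
        scores.size,
        cluster_id,
        n_boot,
        rng,
    )
    lo, hi = _percentile_ci(draws, alpha)
    return StatResult(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        n_units=int(scores.size),
        n_clusters=_n_clusters(cluster_id, scores.size),
        n_boot=int(n_boot),
        method="AUROC+CLUSTER_BOOT",
    )


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    sp = scores[pos]
    sn = scores[~pos]
    # comparisons[i, j] = 1 if sp_i > sn_j, 0.5 if tie
    cmp = (sp[:, None] > sn[None, :]).astype(float) + 0.5 * (
        sp[:, None] == sn[None, :]
    )
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_test(scoresA, scoresB, binary_labels) -> StatResult:
    """DeLong's test for the difference of two correlated AUROCs.

    Scores must be paired on identical units.  Returns the AUROC difference
    (A minus B), its placement-variance CI and a two-sided z-test p.  If the
    two score vectors induce identical placements (e.g., A = B) the
    difference is 0 with p = 1.
    """
    sA = np.asarray(scoresA, float)
    sB = np.asarray(scoresB, float)
    labels = np.asarray(binary_labels).astype(bool)
    if not (sA.size == sB.size == labels.size):
        raise DegenerateDataError("paired scores must share length with labels")
    m = int(labels.sum())
    n = labels.size - m
    if m == 0 or n == 0:
        raise DegenerateDataError("DeLong requires both classes present")

    v10A, v01A = _placements(sA, labels)
    v10B, v01B = _placements(sB, labels)
    aucA = v10A.mean()
    aucB = v10B.mean()
    diff = float(aucA - aucB)

    d10 = v10A - v10B
    d01 = v01A - v01B
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(d01, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0:
        if diff == 0:
            return StatResult(
                estimate=0.0, ci_low=0.0, ci_high=0.0, p_value=1.0,
                n_units=int(labels.size), n_clusters=int(labels.size),
                method="DELONG", extra={"auroc_a": float(aucA), "auroc_b": float(aucB)},
            )
        raise DegenerateDataError("degenerate DeLong variance with nonzero difference")
    se = float(np.sqrt(var))
    z = diff / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return StatResult(
        estimate=diff,
        ci_low=diff - 1.959963984540054 * se,
        ci_high=diff + 1.959963984540054 * se,
        p_value=p,
        n_units=int(labels.size),
        n_clusters=int(labels.size),
        method="DELONG",
        extra={"auroc_a": float(aucA), "auroc_b": float(aucB), "z": float(z)},
    )


# ---------------------------------------------------------------------------
# group comparisons and cohort filtering
# ---------------------------------------------------------------------------

def group_means(
    values,
    severity_group,
    cluster_id,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    reference: str | None = None,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Group means and pairwise differences vs. a reference group.

    Differences carry percentile cluster-bootstrap CIs and CI-inversion
    p-values.  ``reference`` defaults to the first group in ``group_order``
    (or sorted order).
    """
    values = np.asarray(values, float)
    groups = np.asarray(severity_group)
    cluster_id = np.asarray(cluster_id)
    names = group_order or sorted(set(groups.tolist()))
    if len(names) < 2:
        raise DegenerateDataError("group_means requires >= 2 groups")
    for g in names:
        if not np.any(groups == g):
            raise DegenerateDataError(f"empty group {g!r}")
    if reference is None:
        reference = names[0]

    rng = np.random.default_rng(seed)
    rows = []
    for g in names:
        sel = groups == g
        rows.append(
            {
                "group": g,
                "n_scans": int(sel.sum()),
                "n_clusters": len(set(cluster_id[sel].tolist())),
                "mean": float(values[sel].mean()),
            }
        )
        if g == reference:
            rows[-1].update(diff_vs_ref=np.nan, ci_low=np.nan, ci_high=np.nan,
                            p_value=np.nan)
            continue

        pair = sel | (groups == reference)
        v = values[pair]
        gsub = groups[pair]
        csub = cluster_id[pair]
        est = float(v[gsub == g].mean() - v[gsub == reference].mean())

        def stat(idx, _g=g):
            gi = gsub[idx]
            a = gi == _g
            b = gi == reference
            if not a.any() or not b.any():
                return np.nan
            return v[idx][a].mean() - v[idx][b].mean()

        draws = cluster_bootstrap(stat, v.size, csub, n_boot, rng)
        lo, hi = _percentile_ci(draws, alpha)
        rows[-1].update(
            diff_vs_ref=est, ci_low=lo, ci_high=hi, p_value=_boot_p(draws)
        )
    out = pd.DataFrame(rows)
    out.attrs["reference"] = reference
    out.attrs["n_boot"] = n_boot
    out.attrs["inference"] = "percentile cluster bootstrap (participants resampled)"
    return out


def first_scan_filter(
    table: pd.DataFrame, ssi_cutoff: float = 55.0
) -> pd.DataFrame:
    """Keep each eye's first visit and drop scans with SSI below the cutoff.

    The SSI exclusion is applied first (a first visit failing quality is
    replaced by the earliest passing visit); the cutoff is inclusive, so
    SSI = 55.0 is retained.  Dropped-row counts are recorded in
    ``result.attrs``.
    """
    n0 = len(table)
    kept = table[table["ssi"] >= ssi_cutoff]
    n_ssi_dropped = n0 - len(kept)
    first = kept.loc[kept.groupby(["eye_id", "slab"])["visit_index"].idxmin()]
    out = first.sort_index().reset_index(drop=True)
    out.attrs["n_dropped_ssi"] = int(n_ssi_dropped)
    out.attrs["n_dropped_later_visits"] = int(len(kept) - len(out))
    out.attrs["ssi_cutoff"] = float(ssi_cutoff)
    return out
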