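"""Statistical comparison of MR-based and microCT-based BVTV.

The analysis surface mirrors a paired ex vivo validation study: normality
of each modality's BVTV values is checked with a one-sample
Kolmogorov-Smirnov test against a normal with estimated parameters
(Lilliefors convention, Monte-Carlo null); the modalities are compared with
a two-sided Wilcoxon rank-sum test (exact enumeration for small groups,
tie-corrected normal approximation otherwise); agreement is summarised by
Spearman's rank correlation with a 95% cluster-bootstrap confidence
interval that resamples whole specimens, respecting the dependence among
slices of the same specimen; and systematic bias is summarised by the
per-pair differences and the residuals of the least-squares line of MR on
microCT BVTV.

BVTV is stored as a fraction throughout and converted to percent only in
reports.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .registration import PairedMeasurement

__all__ = [
    "StatsReport",
    "ks_normality",
    "wilcoxon_ranksum",
    "spearman_with_cluster_bootstrap",
    "bias_and_residuals",
    "compile_report",
]


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov normality (Lilliefors convention)

def _lilliefors_statistic(sample: np.ndarray) -> float:
    x = np.sort(sample)
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max()
    d_minus = (cdf - (i - 1) / n).max()
    return float(max(d_plus, d_minus))


@lru_cache(maxsize=32)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic at size n."""
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((n_mc, n))
    samples.sort(axis=1)
    z = (samples - samples.mean(axis=1, keepdims=True)) / samples.std(
        axis=1, ddof=1, keepdims=True
    )
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def ks_normality(
    values: Sequence[float], n_mc: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """One-sample KS test of normality with estimated mean and SD.

    Because the normal parameters are estimated from the sample, the
    classical KS null is wrong; the p-value is computed against a seeded
    Monte-Carlo null of the same statistic (Lilliefors convention).
    Returns ``(statistic, p_value)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    d = _lilliefors_statistic(x)
    null = _lilliefors_null(x.size, n_mc, seed)
    p = (1 + int((null >= d).sum())) / (n_mc + 1)
    return d, float(p)


# ---------------------------------------------------------------------------
# Wilcoxon rank sum

EXACT_MAX_PER_GROUP = 10


def _ranksum_exact_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided p by full enumeration of rank assignments to group a."""
    n = ranks.size
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n_a)),
        dtype=np.intp,
    ).reshape(-1, n_a)
    sums = ranks[combos].sum(axis=1)
    total = sums.size
    eps = 1e-9
    p_le = (sums <= w_obs + eps).sum() / total
    p_ge = (sums >= w_obs - eps).sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_ranksum(
    a: Sequence[float], b: Sequence[float], exact: bool | None = None
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(rank_sum_a, p_value)``.

    With both groups of size <= 10 (or ``exact=True``) the p-value comes
    from full enumeration of all rank assignments, which handles ties by
    construction; otherwise a tie-corrected normal approximation with
    continuity correction is used.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n_a, n_b = x.size, y.size
    w = float(ranks[:n_a].sum())
    if exact is None:
        exact = max(n_a, n_b) <= EXACT_MAX_PER_GROUP
    if exact:
        return w, _ranksum_exact_p(ranks, n_a, w)
    n = n_a + n_b
    mean_w = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    diff = w - mean_w
    z = (diff - math.copysign(0.5, diff)) / math.sqrt(var_w) if diff != 0 else 0.0
    return w, float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Spearman with cluster bootstrap

def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


@dataclass(frozen=True)
class SpearmanBootstrap:
    r: float
    ci95: tuple[float, float]
    n_boot: int
    n_redraws: int
    seed: int


def spearman_with_cluster_bootstrap(
    pairs: Sequence[PairedMeasurement],
    n_boot: int = 1000,
    seed: int = 0,
    max_redraw_factor: int = 10,
) -> SpearmanBootstrap:
    """Spearman correlation with a specimen-level (cluster) bootstrap CI.

    The point estimate is the rank correlation over all pairs (average
    ranks on ties). The 95% CI is the percentile interval of the statistic
    over ``n_boot`` resamples that draw specimens with replacement and keep
    each drawn specimen's full slice block - the resampling unit that
    respects inter-specimen dependence. Resamples where either variable has
    zero rank variance are redrawn (counted; capped at
    ``max_redraw_factor * n_boot`` total draws).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs")
    specimens = sorted({p.specimen_id for p in pairs})
    if len(specimens) < 2:
        raise ValueError("cluster bootstrap undefined with a single specimen")
    x = np.array([p.bvtv_uct for p in pairs])
    y = np.array([p.bvtv_mr for p in pairs])
    spec_idx = {s: np.flatnonzero(np.array([p.specimen_id for p in pairs]) == s) for s in specimens}
    r_point = _spearman(x, y)
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_boot)
    n_spec = len(specimens)
    draws = redraws = 0
    filled = 0
    max_draws = max_redraw_factor * n_boot
    while filled < n_boot:
        if draws >= max_draws:
            raise RuntimeError(
                "cluster bootstrap exceeded redraw cap: data too degenerate"
            )
        draws += 1
        chosen = rng.integers(0, n_spec, size=n_spec)
        idx = np.concatenate([spec_idx[specimens[c]] for c in chosen])
        r = _spearman(x[idx], y[idx])
        if math.isnan(r):
            redraws += 1
            continue
        stats_out[filled] = r
        filled += 1
    lo, hi = np.percentile(stats_out, [2.5, 97.5])
    return SpearmanBootstrap(
        r=r_point,
        ci95=(float(lo), float(hi)),
        n_boot=n_boot,
        n_redraws=redraws,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bias and residuals

@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    min: float
    max: float

    @classmethod
    def of(cls, values: np.ndarray) -> "SummaryStats":
        v = np.asarray(values, dtype=float)
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(mean=float(v.mean()), sd=sd, min=float(v.min()), max=float(v.max()))


@dataclass(frozen=True)
class BiasResiduals:
    """Difference and linear-fit residual summaries (fractions, not percent)."""

    difference: SummaryStats
    residuals: SummaryStats
    slope: float
    intercept: float


def bias_and_residuals(pairs: Sequence[PairedMeasurement]) -> BiasResiduals:
    """Per-pair (microCT - MR) differences and OLS residuals of MR on microCT.

    The residual mean is zero by construction of the least-squares fit
    (asserted to machine precision); its SD and range quantify scatter
    about the calibration line.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    uct = np.array([p.bvtv_uct for p in pairs])
    mr = np.array([p.bvtv_mr for p in pairs])
    if np.ptp(uct) == 0:
        raise ValueError("constant microCT values: linear fit degenerate")
    slope, intercept = np.polyfit(uct, mr, 1)
    residuals = mr - (slope * uct + intercept)
    assert abs(residuals.mean()) < 1e-12, "OLS residual mean must vanish"
    return BiasResiduals(
        difference=SummaryStats.of(uct - mr),
        residuals=SummaryStats.of(residuals),
        slope=float(slope),
        intercept=float(intercept),
    )


# ---------------------------------------------------------------------------
# Report

@dataclass
class StatsReport:
    """The full comparison summary for one paired study.

    BVTV summaries are in percent (reporting convention); all underlying
    computation uses fractions.
    """

    n_pairs: int
    n_specimens: int
    ks_mr: tuple[float, float]
    ks_uct: tuple[float, float]
    wilcoxon_w: float
    wilcoxon_p: float
    mr_pct: SummaryStats
    uct_pct: SummaryStats
    spearman: SpearmanBootstrap
    bias: BiasResiduals
    n_boot: int
    seed: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        d = self.bias.difference
        r = self.bias.residuals
        lo, hi = self.spearman.ci95
        return "\n".join(
            [
                f"Paired BVTV comparison over {self.n_pairs} (specimen, slice) ROIs "
                f"from {self.n_specimens} specimens",
                f"  BVTV MR   : {self.mr_pct.mean:.1f} +/- {self.mr_pct.sd:.1f} %",
                f"  BVTV microCT: {self.uct_pct.mean:.1f} +/- {self.uct_pct.sd:.1f} %",
                f"  Wilcoxon rank-sum two-sided p = {self.wilcoxon_p:.3g}",
                f"  Spearman r = {self.spearman.r:.2f} "
                f"[{lo:.2f}-{hi:.2f}] (95% cluster-bootstrap CI, "
                f"{self.spearman.n_boot} iterations)",
                f"  Difference (microCT - MR): {100*d.mean:.1f} +/- {100*d.sd:.1f} % "
                f"[{100*d.min:.1f}-{100*d.max:.1f}]",
                f"  Residuals about fit line : {100*r.mean:.1f} +/- {100*r.sd:.1f} % "
                f"[{100*r.min:.1f}-{100*r.max:.1f}]",
            ]
        )


def compile_report(
    pairs: Sequence[PairedMeasurement],
    n_boot: int = 1000,
    seed: int = 0,
) -> StatsReport:
    """Run the full statistical comparison on a paired table."""
    mr = np.array([p.bvtv_mr for p in pairs])
    uct = np.array([p.bvtv_uct for p in pairs])
    specimens = {p.specimen_id for p in pairs}
    w, p_w = wilcoxon_ranksum(mr, uct, exact=False)
    boot = spearman_with_cluster_bootstrap(pairs, n_boot=n_boot, seed=seed)
    return StatsReport(
        n_pairs=len(pairs),
        n_specimens=len(specimens),
        ks_mr=ks_normality(mr, seed=seed),
        ks_uct=ks_normality(uct, seed=seed + 1),
        wilcoxon_w=w,
        wilcoxon_p=p_w,
        mr_pct=SummaryStats.of(100 * mr),
        uct_pct=SummaryStats.of(100 * uct),
        spearman=boot,
        bias=bias_and_residuals(pairs),
        n_boot=n_boot,
        seed=seed,
    )
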