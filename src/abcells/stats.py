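"""Autocorrelation-aware non-parametric comparison of metric time series.

Time-lapse metric series from different experimental conditions are
smoothed, cut into sliding windows, and compared with a Friedman test
in which each frame position is a block and each series a treatment.
Because adjacent frames are serially correlated, the classical test is
anti-conservative; two remedies are applied per window:

* a Bartlett effective-sample-size correction — the Friedman statistic
  is scaled by N_eff/N with N_eff = N(1−Q)/(1+Q) for lag-1
  autocorrelation Q (AR(1) approximation), and
* an exact permutation test that shuffles treatment labels within
  blocks.

Significant omnibus windows are followed by Conover pairwise
comparisons on within-block ranks with Holm family-wise control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SeriesPanel",
    "WindowTestResult",
    "BootstrapResult",
    "moving_average",
    "lag1_autocorrelation",
    "effective_sample_size",
    "friedman_statistic",
    "friedman_neff",
    "friedman_permutation",
    "conover_holm",
    "sliding_scan",
    "distribution_distance",
    "bootstrap_ci",
]

DEFAULT_MA_WINDOW = 15
DEFAULT_TEST_WINDOW = 15
DEFAULT_PERMUTATIONS = 1000
DEFAULT_BOOTSTRAP = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class SeriesPanel:
    """k aligned treatment series × T frames of one metric."""

    values: np.ndarray  # (k, T)
    series_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("panel must be (k >= 2, T)")
        if self.series_ids is None:
            self.series_ids = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "SeriesPanel":
        """Build from long format (series_id, frame, value)."""
        wide = df.pivot(index="series_id", columns="frame", values="value")
        return cls(wide.to_numpy(), series_ids=[str(s) for s in wide.index])

    def to_long(self) -> pd.DataFrame:
        k, T = self.values.shape
        return pd.DataFrame(
            {
                "series_id": np.repeat(self.series_ids, T),
                "frame": np.tile(np.arange(T), k),
                "value": self.values.ravel(),
            }
        )


@dataclass
class WindowTestResult:
    start: int
    end: int  # inclusive
    lag1_q_per_series: np.ndarray
    panel_q: float
    n_blocks: int
    n_eff: float
    friedman_stat: float
    df: int
    p_asymptotic: float  # NaN when the window is untestable (N_eff < 3)
    p_permutation: float
    posthoc: Optional[pd.DataFrame] = None  # Holm-adjusted pairwise p


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    lower: float
    upper: float
    n_resamples: int
    level: float
    seed: Optional[int]


# ----------------------------------------------------------------------
# building blocks


def moving_average(x: Sequence[float], w: int = DEFAULT_MA_WINDOW) -> np.ndarray:
    """Centered moving average; only full windows emitted (length T−w+1)."""
    x = np.asarray(x, dtype=float)
    if w < 1:
        raise ValueError("window must be >= 1")
    if w > x.size:
        raise ValueError(f"window {w} exceeds series length {x.size}")
    c = np.cumsum(np.concatenate([[0.0], x]))
    return (c[w:] - c[:-w]) / w


def lag1_autocorrelation(x: Sequence[float]) -> float:
    """Lag-1 serial correlation: Σ(x_t−x̄)(x_{t+1}−x̄) / Σ(x_t−x̄)²."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for lag-1 autocorrelation")
    d = x - x.mean()
    denom = (d**2).sum()
    if denom == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    return float((d[:-1] * d[1:]).sum() / denom)


def effective_sample_size(n: int, q: float) -> float:
    """Bartlett AR(1) effective sample size N_eff = N(1−Q)/(1+Q).

    Q is clamped to [0, 0.99]: negative autocorrelation would inflate
    N_eff above N (anti-conservative), so only positive dependence is
    corrected for.
    """
    if n < 2:
        raise ValueError("need N >= 2")
    q = min(max(q, 0.0), 0.99)
    return n * (1.0 - q) / (1.0 + q)


def _block_ranks(panel: np.ndarray) -> np.ndarray:
    """Within-block mid-ranks; panel is (k treatments, N blocks) -> (N, k)."""
    return np.apply_along_axis(_sstats.rankdata, 1, panel.T)


def friedman_statistic(panel: np.ndarray) -> tuple[float, np.ndarray]:
    """Classical Friedman chi-square with tie correction.

    ``panel`` is (k, N). Returns (statistic, block-rank matrix (N, k)).
    """
    k, n = panel.shape
    if k < 2:
        raise ValueError("need at least 2 treatments")
    ranks = _block_ranks(panel)
    rank_sums = ranks.sum(axis=0)
    stat = (12.0 / (n * k * (k + 1))) * (rank_sums**2).sum() - 3.0 * n * (k + 1)
    # tie correction (scipy-compatible)
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    c = 1.0 - ties / (k * (k**2 - 1) * n)
    if c > 0:
        stat /= c
    return float(stat), ranks


def friedman_neff(panel: np.ndarray) -> tuple[float, int, float, float]:
    """Bartlett-corrected Friedman test on one window.

    Per-series lag-1 autocorrelation is averaged (clamped to [0, 0.99])
    into a panel Q; the classical statistic is scaled by N_eff/N before
    the chi-square lookup, which reduces to the classical test at Q=0.
    Returns (corrected stat, df, p, N_eff); p is NaN when N_eff < 3.
    """
    panel = np.asarray(panel, dtype=float)
    k, n = panel.shape
    if k < 2:
        raise ValueError("need at least 2 treatments")
    if n < 3:
        raise ValueError("need at least 3 blocks")
    stat, _ = friedman_statistic(panel)
    qs = []
    for row in panel:
        try:
            qs.append(lag1_autocorrelation(row))
        except ValueError:  # constant series contributes no dependence info
            qs.append(0.0)
    panel_q = min(max(float(np.mean(qs)), 0.0), 0.99)
    n_eff = effective_sample_size(n, panel_q)
    corrected = stat * (n_eff / n)
    df = k - 1
    p = float(_sstats.chi2.sf(corrected, df)) if n_eff >= 3 else math.nan
    return corrected, df, p, n_eff


def friedman_permutation(
    panel: np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Within-block label-permutation p-value for the Friedman statistic.

    Uses the add-one estimator p = (1 + #{perm >= obs}) / (B + 1), so the
    attainable minimum is 1/(B+1) and p is never zero.
    """
    panel = np.asarray(panel, dtype=float)
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    k, n = panel.shape
    obs, ranks = friedman_statistic(panel)
    if rng is None:
        rng = np.random.default_rng(seed)
    # permuting labels within blocks == permuting the rank rows; vectorized
    # over all B permutations at once
    perm_idx = np.argsort(
        rng.random((n_permutations, n, k)), axis=2
    )  # (B, N, k) independent shuffles
    perm_ranks = np.take_along_axis(
        np.broadcast_to(ranks, (n_permutations, n, k)), perm_idx, axis=2
    )
    rank_sums = perm_ranks.sum(axis=1)  # (B, k)
    stats = (12.0 / (n * k * (k + 1))) * (rank_sums**2).sum(axis=1) - 3.0 * n * (
        k + 1
    )
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    c = 1.0 - ties / (k * (k**2 - 1) * n)
    if c > 0:
        stats = stats / c
    exceed = int((stats >= obs - 1e-12).sum())
    return (1 + exceed) / (n_permutations + 1)


def conover_holm(panel: np.ndarray, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Conover pairwise comparisons on within-block ranks, Holm-adjusted.

    Standard post hoc for a significant Friedman omnibus: the pairwise
    statistic |R_i − R_j| is referenced to a t distribution with
    (N−1)(k−1) degrees of freedom using the rank-variance estimate, and
    raw p-values get Holm step-down control. Returns a k×k DataFrame of
    adjusted p (NaN diagonal).
    """
    panel = np.asarray(panel, dtype=float)
    k, n = panel.shape
    ranks = _block_ranks(panel)
    rank_sums = ranks.sum(axis=0)
    a1 = (ranks**2).sum()
    c1 = n * k * (k + 1) ** 2 / 4.0
    t1_denom = a1 - c1
    if t1_denom <= 0:  # all blocks fully tied: nothing can differ
        adj = np.full((k, k), 1.0)
        np.fill_diagonal(adj, np.nan)
        return pd.DataFrame(adj)
    t1 = (k - 1) * ((rank_sums - n * (k + 1) / 2.0) ** 2).sum() / t1_denom
    dof = (n - 1) * (k - 1)
    scale = 2.0 * n * t1_denom * (1.0 - t1 / (n * (k - 1))) / dof
    scale = max(scale, 1e-300)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = []
    for i, j in pairs:
        t = abs(rank_sums[i] - rank_sums[j]) / math.sqrt(scale)
        raw.append(2.0 * float(_sstats.t.sf(t, dof)))
    adj_p = multipletests(raw, alpha=alpha, method="holm")[1]
    mat = np.full((k, k), np.nan)
    for (i, j), p in zip(pairs, adj_p):
        mat[i, j] = mat[j, i] = min(p, 1.0)
    return pd.DataFrame(mat)


# ----------------------------------------------------------------------
# sliding-window scan


def sliding_scan(
    panel: SeriesPanel,
    ma_w: int = DEFAULT_MA_WINDOW,
    window_w: int = DEFAULT_TEST_WINDOW,
    step: int = 1,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    alpha: float = DEFAULT_ALPHA,
    seed: Optional[int] = None,
) -> list[WindowTestResult]:
    """Smooth, slide, test: the full window-scan over a metric panel.

    Each series is smoothed with a centered moving average, then windows
    of ``window_w`` frames advance by ``step``; each window gets the
    Bartlett-corrected and permutation Friedman tests and, when the
    omnibus is significant at ``alpha``, Conover–Holm pairwise p-values.
    Window start/end indices refer to the smoothed series.
    """
    needed = ma_w + window_w - 1
    if panel.T < needed:
        raise ValueError(
            f"series length {panel.T} too short: need >= ma_w + window_w - 1 = {needed}"
        )
    smoothed = np.vstack([moving_average(row, ma_w) for row in panel.values])
    t_s = smoothed.shape[1]
    seeds = np.random.SeedSequence(seed).spawn((t_s - window_w) // step + 1)
    results: list[WindowTestResult] = []
    for w_idx, start in enumerate(range(0, t_s - window_w + 1, step)):
        window = smoothed[:, start : start + window_w]
        k, n = window.shape
        stat, df, p_asym, n_eff = friedman_neff(window)
        qs = []
        for row in window:
            try:
                qs.append(lag1_autocorrelation(row))
            except ValueError:
                qs.append(0.0)
        rng = np.random.default_rng(seeds[w_idx])
        p_perm = friedman_permutation(window, n_permutations, rng=rng)
        omnibus = p_asym if not math.isnan(p_asym) else p_perm
        posthoc = conover_holm(window, alpha) if omnibus < alpha else None
        results.append(
            WindowTestResult(
                start=start,
                end=start + window_w - 1,
                lag1_q_per_series=np.array(qs),
                panel_q=min(max(float(np.mean(qs)), 0.0), 0.99),
                n_blocks=n,
                n_eff=n_eff,
                friedman_stat=stat,
                df=df,
                p_asymptotic=p_asym,
                p_permutation=p_perm,
                posthoc=posthoc,
            )
        )
    return results


def scan_tables(
    results: Sequence[WindowTestResult], series_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten scan results into (window summary, pairwise significance)."""
    rows = []
    pair_rows = []
    for r in results:
        rows.append(
            {
                "start": r.start,
                "end": r.end,
                "panel_q": r.panel_q,
                "n_blocks": r.n_blocks,
                "n_eff": r.n_eff,
                "friedman_stat": r.friedman_stat,
                "df": r.df,
                "p_asymptotic": r.p_asymptotic,
                "p_permutation": r.p_permutation,
            }
        )
        if r.posthoc is not None:
            k = len(series_ids)
            for i in range(k):
                for j in range(i + 1, k):
                    pair_rows.append(
                        {
                            "start": r.start,
                            "end": r.end,
                            "pair": f"{series_ids[i]}|{series_ids[j]}",
                            "p_adjusted": r.posthoc.iloc[i, j],
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(
        pair_rows, columns=["start", "end", "pair", "p_adjusted"]
    )


# ----------------------------------------------------------------------
# distribution comparison


def distribution_distance(a, b, kind: str = "ks") -> float:
    """KS statistic or 1-D Wasserstein distance between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if kind == "ks":
        return float(_sstats.ks_2samp(a, b).statistic)
    if kind == "wasserstein":
        return float(_sstats.wasserstein_distance(a, b))
    raise ValueError(f"kind must be 'ks' or 'wasserstein', got {kind!r}")


def bootstrap_ci(
    values,
    n_resamples: int = DEFAULT_BOOTSTRAP,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> BootstrapResult:
    """Percentile bootstrap CI of the sample mean (seeded, reproducible)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if n_resamples < 1:
        raise ValueError("need at least 1 resample")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    est = float(values.mean())
    if level == 0.0:
        return BootstrapResult(est, est, est, n_resamples, level, seed)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(
        means, [100 * (1 - level) / 2.0, 100 * (1 + level) / 2.0]
    )
    return BootstrapResult(est, float(lo), float(hi), n_resamples, level, seed)
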