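"""Paired nonparametric inference: Wilcoxon signed-rank, Hodges-Lehmann,
percentile bootstrap CIs and the standardized effect size r = |Z|/sqrt(n).

The signed-rank test is implemented directly (not delegated) so that the exact
two-sided p-value can be validated against full 2^n sign enumeration: for
tie-free samples with n <= 25 the null distribution of W+ is built by dynamic
programming over the integer ranks; larger or tied samples use the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "WilcoxonResult",
    "PairedIndexTable",
    "PairedStatResult",
    "StatsConfig",
    "wilcoxon_signed_rank",
    "hodges_lehmann",
    "walsh_averages",
    "bootstrap_ci",
    "effect_size_r",
    "run_paired_analysis",
]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test outcome: W = min(W+, W-), two-sided p, normal deviate z."""

    W: float
    p: float
    z: float
    n: int
    method: Literal["exact", "approx"]


def _exact_two_sided_p(wplus: float, n: int) -> float:
    # null distribution of W+ over all 2^n sign assignments of ranks 1..n,
    # by subset-sum dynamic programming (counts are exact integers)
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=object)
    counts[0] = 1
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[:-r]
    total = 2**n
    w = int(round(wplus))
    p_le = int(sum(counts[: w + 1])) / total
    p_ge = int(sum(counts[w:])) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    zero_policy: Literal["wilcox", "pratt"] = "wilcox",
    mode: Literal["auto", "exact", "approx"] = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples x, y.

    ``zero_policy='wilcox'`` drops zero differences before ranking;
    ``'pratt'`` ranks them but drops their contribution to the rank sums.
    ``mode='auto'`` uses exact enumeration for tie-free samples with
    n <= 25 under the wilcox policy, else the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    d = x - y
    n_zero = int(np.count_nonzero(d == 0))
    if n_zero == d.size:
        raise ValueError("all paired differences are zero; test undefined")

    if zero_policy == "wilcox":
        d = d[d != 0]
        ranks = rankdata(np.abs(d))
        n_ranked = d.size
        zero_term_mu = 0.0
        zero_term_var = 0.0
    elif zero_policy == "pratt":
        ranks_all = rankdata(np.abs(d))
        keep = d != 0
        d, ranks = d[keep], ranks_all[keep]
        n_ranked = ranks_all.size
        zero_term_mu = n_zero * (n_zero + 1) / 4.0
        zero_term_var = n_zero * (n_zero + 1) * (2 * n_zero + 1) / 24.0
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    wplus = float(ranks[d > 0].sum())
    wminus = float(ranks[d < 0].sum())
    w = min(wplus, wminus)
    n = int(d.size)

    _, tie_counts = np.unique(ranks, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    mu = n_ranked * (n_ranked + 1) / 4.0 - zero_term_mu
    var = (
        n_ranked * (n_ranked + 1) * (2 * n_ranked + 1) / 24.0
        - zero_term_var
        - (tie_counts**3 - tie_counts).sum() / 48.0
    )
    if var > 0:
        dev = wplus - mu
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    else:
        z = 0.0

    exact_ok = not has_ties and zero_policy == "wilcox" and n <= EXACT_N_MAX
    if mode == "exact" and not exact_ok:
        raise ValueError("exact mode requires tie-free wilcox-policy samples with n <= 25")
    if mode == "exact" or (mode == "auto" and exact_ok):
        p = _exact_two_sided_p(wplus, n)
        method: Literal["exact", "approx"] = "exact"
    else:
        p = float(2.0 * norm.sf(abs(z)))
        method = "approx"
    return WilcoxonResult(W=w, p=min(p, 1.0), z=float(z), n=n, method=method)


def walsh_averages(diffs: Sequence[float]) -> np.ndarray:
    """All n(n+1)/2 pairwise means (d_i + d_j)/2, i <= j."""
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("need a non-empty 1-D sample")
    s = (d[:, None] + d[None, :]) / 2.0
    iu = np.triu_indices(d.size)
    return s[iu]


def hodges_lehmann(diffs: Sequence[float]) -> float:
    """Median of all Walsh averages of the paired differences."""
    return float(np.median(walsh_averages(diffs)))


def _hl_rows(samples: np.ndarray) -> np.ndarray:
    # vectorized Hodges-Lehmann over the rows of a (B, n) resample matrix
    b, n = samples.shape
    s = (samples[:, :, None] + samples[:, None, :]) / 2.0
    iu = np.triu_indices(n)
    return np.median(s[:, iu[0], iu[1]], axis=1)


def bootstrap_ci(
    diffs: Sequence[float],
    statistic: Callable[[np.ndarray], float] | None = None,
    B: int = 10000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a statistic of the differences.

    ``statistic=None`` means Hodges-Lehmann (computed vectorized).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("need a non-empty 1-D sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(B, d.size))
    resamples = d[idx]
    if statistic is None:
        stats = _hl_rows(resamples)
    else:
        stats = np.array([statistic(row) for row in resamples])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def effect_size_r(z: float, n: int) -> float:
    """Standardized effect size r = |Z| / sqrt(n), clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(min(abs(z) / np.sqrt(n), 1.0))


@dataclass
class PairedIndexTable:
    """Long-form table of per-subject region means: one row per (subject, index)."""

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "index", "cin_mean", "healthy_mean")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"paired table is missing columns: {missing}")

    @property
    def index_names(self) -> list[str]:
        return list(dict.fromkeys(self.frame["index"]))

    def differences(self, index_name: str) -> np.ndarray:
        """Paired differences (CIN - healthy) for one index, ordered by subject."""
        sub = self.frame[self.frame["index"] == index_name]
        if sub.empty:
            raise KeyError(f"no rows for index {index_name!r}")
        if sub["subject_id"].duplicated().any():
            raise ValueError(f"duplicate subjects for index {index_name!r}")
        return (sub["cin_mean"] - sub["healthy_mean"]).to_numpy(dtype=np.float64)


@dataclass
class StatsConfig:
    B: int = 10000
    level: float = 0.95
    seed: int = 0
    zero_policy: Literal["wilcox", "pratt"] = "wilcox"
    mode: Literal["auto", "exact", "approx"] = "auto"


@dataclass
class PairedStatResult:
    """Full inferential summary for one tissue index."""

    index_name: str
    n: int
    W: float | None = None
    p_value: float | None = None
    hl_estimate: float | None = None
    ci95: tuple[float, float] | None = None
    effect_size_r: float | None = None
    B: int = 0
    seed: int = 0
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "n": self.n,
            "W": self.W,
            "p_value": self.p_value,
            "hl_estimate": self.hl_estimate,
            "ci_low": None if self.ci95 is None else self.ci95[0],
            "ci_high": None if self.ci95 is None else self.ci95[1],
            "effect_size_r": self.effect_size_r,
            "bootstrap_B": self.B,
            "seed": self.seed,
            "error": self.error,
        }


def run_paired_analysis(
    table: PairedIndexTable, config: StatsConfig | None = None
) -> list[PairedStatResult]:
    """One signed-rank + Hodges-Lehmann + bootstrap summary per index.

    Differences are oriented as CIN - healthy.  No multiplicity adjustment is
    applied.  Indices whose differences are all zero are reported with an
    error marker instead of a test result.
    """
    config = config or StatsConfig()
    results: list[PairedStatResult] = []
    for i, name in enumerate(table.index_names):
        diffs = table.differences(name)
        res = PairedStatResult(index_name=name, n=diffs.size, B=config.B, seed=config.seed)
        if np.all(diffs == 0):
            res.error = "all paired differences are zero"
            results.append(res)
            continue
        wres = wilcoxon_signed_rank(
            diffs, np.zeros_like(diffs), zero_policy=config.zero_policy, mode=config.mode
        )
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        ci = bootstrap_ci(diffs, B=config.B, level=config.level, seed=rng)
        res.W = wres.W
        res.p_value = wres.p
        res.hl_estimate = hodges_lehmann(diffs)
        res.ci95 = ci
        res.effect_size_r = effect_size_r(wres.z, wres.n)
        results.append(res)
    return results
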