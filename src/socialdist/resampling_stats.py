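"""Pooled-null bootstrap difference-of-means test and related utilities.

The hypothesis test: given samples A (size n) and B (size m), the observed
statistic is the absolute difference of means, Δμ = |mean(A) − mean(B)|.
Under the null that A and B come from a common distribution, their values
are pooled; each bootstrap iteration draws two samples A*, B*, each of size
min(n, m), with replacement from the pool, and records
Δμ* = |mean(A*) − mean(B*)|.  The p-value is the fraction of n_boot
iterations with Δμ* ≥ Δμ (ties count toward the null; no small-sample +1
correction).  Significance is conventionally read at the 0.05 / 0.01 /
0.0001 tiers.  Bonferroni correction multiplies p by the number of
comparisons, capped at 1.

Also provided: Pearson correlation with an ordinary least-squares line
(for age/size analyses) and mean ± SEM group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Significance tiers used in reporting: p < 0.05, < 0.01, < 0.0001.
SIGNIFICANCE_TIERS = (0.05, 0.01, 0.0001)


@dataclass
class BootstrapTestResult:
    delta_mu_observed: float
    p_value: float
    n_boot: int
    n_A: int
    n_B: int
    seed: int
    null_sample: np.ndarray = field(repr=False)
    p_adjusted: float | None = None

    @property
    def significance_tier(self) -> float | None:
        """Smallest conventional tier the (adjusted, if any) p-value clears."""
        p = self.p_value if self.p_adjusted is None else self.p_adjusted
        cleared = [t for t in SIGNIFICANCE_TIERS if p < t]
        return min(cleared) if cleared else None

    def to_dict(self) -> dict:
        return {
            "delta_mu": self.delta_mu_observed,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "n_boot": self.n_boot,
            "n_A": self.n_A,
            "n_B": self.n_B,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float
    sem_defined: bool = True


def _validated_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"sample {name} needs at least 2 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def bootstrap_t_test(
    A, B, n_boot: int = 10_000, seed: int = 0, n_comparisons: int | None = None
) -> BootstrapTestResult:
    """Pooled-null bootstrap test for a difference in means.

    Deterministic under ``seed``; symmetric in (A, B) since both the
    statistic and the pooled resampling scheme are.  ``n_comparisons``
    additionally reports a Bonferroni-adjusted p-value.
    """
    a = _validated_sample(A, "A")
    b = _validated_sample(B, "B")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    delta = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    k = min(a.size, b.size)
    rng = np.random.default_rng(seed)
    # Vectorized resampling in chunks to bound memory at large n_boot.
    chunk = max(1, min(n_boot, 50_000_000 // (2 * k) or 1))
    exceed = 0
    null_parts = []
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, pool.size, size=(m, 2, k))
        means = pool[idx].mean(axis=2)  # (m, 2)
        d_star = np.abs(means[:, 0] - means[:, 1])
        exceed += int((d_star >= delta).sum())
        null_parts.append(d_star)
        done += m
    null_sample = np.concatenate(null_parts)
    p = exceed / n_boot
    p_adj = bonferroni(p, n_comparisons) if n_comparisons is not None else None
    return BootstrapTestResult(
        delta_mu_observed=float(delta),
        p_value=float(p),
        n_boot=n_boot,
        n_A=a.size,
        n_B=b.size,
        seed=seed,
        null_sample=null_sample,
        p_adjusted=p_adj,
    )


def bonferroni(p: float, n_comparisons: int) -> float:
    """min(1, p × n_comparisons)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p * n_comparisons)


def pearson_with_fit(x, y) -> tuple[float, float, float, float]:
    """Pearson r, two-sided p (t-distribution, n−2 df), OLS slope and intercept."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return float(r), float(p), float(fit.slope), float(fit.intercept)


def group_summary(values, label: str = "") -> GroupSummary:
    """Mean with SEM = sample sd (n−1 denominator) / sqrt(n).

    A single value has no sample sd; its SEM is reported as 0 with
    ``sem_defined=False``.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("group_summary requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if arr.size == 1:
        return GroupSummary(label, 1, float(arr[0]), 0.0, sem_defined=False)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return GroupSummary(label, int(arr.size), float(arr.mean()), sem)
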