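"""Group difference mapping and auxiliary nonparametric statistics.

Channelwise two-sample t-tests per biomarker, the binomial
multiple-comparison correction (a biomarker counts as significant only
when enough individual channels reach p < alpha), reduction of a cohort's
biomarker tensors to per-subject features (median over the significant
channels frozen on the training visit), permutation tests on the median,
BCa bootstrap confidence intervals and Barnard's exact test for 2x2
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import BiomarkerTensor
from .signal_core import InvalidArgumentError


# ---------------------------------------------------------------------------
# Difference map
# ---------------------------------------------------------------------------

@dataclass
class DifferenceMap:
    """Per-biomarker, per-channel p-values and the binomially corrected
    significance decision."""

    biomarker_names: list[str]
    channel_labels: list[str]
    p_values: np.ndarray          # (n_biomarkers, n_channels), NaN = untestable
    median_a: np.ndarray
    median_b: np.ndarray
    alpha: float = 0.05
    k_min: int = 3

    @property
    def significance_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p_values < self.alpha

    def significant_channels(self, biomarker: str) -> list[str]:
        i = self.biomarker_names.index(biomarker)
        return [c for c, s in zip(self.channel_labels, self.significance_mask[i])
                if s]

    @property
    def corrected_significant(self) -> np.ndarray:
        return self.significance_mask.sum(axis=1) >= self.k_min

    def binomial_tail_p(self) -> np.ndarray:
        """P(X >= observed count) under X ~ Binomial(n_valid_channels, alpha)."""
        counts = self.significance_mask.sum(axis=1)
        n_valid = np.sum(np.isfinite(self.p_values), axis=1)
        return np.array([
            binomial_channel_correction_tail(int(c), int(n), self.alpha)
            for c, n in zip(counts, n_valid)
        ])

    def selected_biomarkers(self) -> list[str]:
        return [n for n, s in zip(self.biomarker_names, self.corrected_significant)
                if s]


def channelwise_ttest(values_a: np.ndarray, values_b: np.ndarray,
                      equal_var: bool = True) -> float:
    """Two-sided Student's t-test p-value for one biomarker/channel cell.

    Classical equal-variance by default (Welch behind the flag). Returns
    NaN when either group has fewer than 2 non-missing values or both
    groups are constant.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else np.nan
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def binomial_channel_correction(p_values, alpha: float = 0.05,
                                k_min: int = 3) -> tuple[bool, float]:
    """Binomial multiple-comparison correction across channels.

    A biomarker is corrected-significant when at least ``k_min`` channels
    reach p < alpha. Also returns the exact binomial tail probability
    P(X >= count) for X ~ Binomial(n_valid, alpha) for transparency (for
    21 channels at alpha=0.05 the k>=3 rule's tail slightly exceeds 0.05).
    """
    p = np.asarray(p_values, dtype=float)
    valid = np.isfinite(p)
    if valid.sum() == 0:
        raise InvalidArgumentError("need at least one valid channel p-value")
    count = int(np.sum(p[valid] < alpha))
    return count >= k_min, binomial_channel_correction_tail(
        count, int(valid.sum()), alpha)


def binomial_channel_correction_tail(count: int, n: int, alpha: float) -> float:
    if n == 0:
        return np.nan
    return float(stats.binom.sf(count - 1, n, alpha)) if count > 0 else 1.0


def difference_map(tensors_a: list[BiomarkerTensor],
                   tensors_b: list[BiomarkerTensor],
                   alpha: float = 0.05, k_min: int = 3,
                   equal_var: bool = True) -> DifferenceMap:
    """Map all biomarker x channel group differences (a vs b)."""
    ref = tensors_a[0]
    names, channels = ref.biomarker_names, ref.channel_labels
    stack_a = np.stack([t.values for t in tensors_a])  # (subj, bio, ch)
    stack_b = np.stack([t.values for t in tensors_b])
    nb, nc = len(names), len(channels)
    p = np.full((nb, nc), np.nan)
    for i in range(nb):
        for j in range(nc):
            p[i, j] = channelwise_ttest(stack_a[:, i, j], stack_b[:, i, j],
                                        equal_var=equal_var)
    return DifferenceMap(
        biomarker_names=list(names), channel_labels=list(channels),
        p_values=p,
        median_a=np.nanmedian(stack_a, axis=0),
        median_b=np.nanmedian(stack_b, axis=0),
        alpha=alpha, k_min=k_min)


def reduce_to_features(tensors: list[BiomarkerTensor],
                       dmap: DifferenceMap) -> pd.DataFrame:
    """Subject x biomarker feature table.

    Each corrected-significant biomarker becomes one feature: the median of
    its values over the channels found significant on the training visit
    (the channel sets recorded in ``dmap`` are reused verbatim, so
    evaluation-visit data never influences them). Biomarkers with no
    significant channels are excluded.
    """
    selected = dmap.selected_biomarkers()
    rows = []
    for t in tensors:
        row = {"subject_id": t.subject_id, "group": t.group, "visit": t.visit}
        for name in selected:
            chans = dmap.significant_channels(name)
            idx = [t.channel_labels.index(c) for c in chans
                   if c in t.channel_labels]
            vals = t.values[t.biomarker_names.index(name), idx]
            vals = vals[np.isfinite(vals)]
            row[name] = float(np.median(vals)) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nonparametric statistics
# ---------------------------------------------------------------------------

def permutation_test_median(sample_a, sample_b, n_perm: int = 5000,
                            seed=None) -> float:
    """Two-sided permutation test on the difference of medians.

    p = (1 + #{|perm diff| >= |observed|}) / (1 + n_perm).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    observed = abs(np.median(a) - np.median(b))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(np.median(perm[:a.size]) - np.median(perm[a.size:])) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def bca_bootstrap_ci(sample, statistic=np.median, n_boot: int = 5000,
                     level: float = 0.95, seed=None) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval."""
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise InvalidArgumentError("sample size must be >= 8")
    if np.ptp(x) == 0:
        return float(x[0]), float(x[0])
    res = stats.bootstrap((x,), statistic, n_resamples=n_boot,
                          confidence_level=level, method="BCa",
                          vectorized=False,
                          rng=np.random.default_rng(seed))
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def barnard_exact_test(table) -> float:
    """Barnard's unconditional exact test for a 2x2 contingency table.

    Two-sided p-value maximized over the nuisance success probability.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InvalidArgumentError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise InvalidArgumentError("both margins must be positive")
    return float(stats.barnard_exact(t, alternative="two-sided").pvalue)
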