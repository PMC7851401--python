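"""Window-level likelihood model for joint deletion calling.

For one genomic window of width ``w`` the data of a sample ``S`` are the
insert-size deviations ``delta = i - mu_S`` of the read pairs overlapping
the window.  Deviations are scored against ``H_S``, the sample's null
insert-size histogram transformed to account for how many window placements
a pair of a given insert size can overlap.  Three genotype likelihoods
(0, 1 or 2 deletion alleles of length ``l``) are combined across samples by
allele-frequency-aware weights into a likelihood-ratio test of "no
deletion" against "a deletion of length ``l`` overlaps this window".

All products run in natural-log domain; the histogram is floored so that a
deviation outside the observed support never zeroes a product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from joindel.profile import InsertSizeHistogram

# chi^2(1 df) quantile at P = 0.01 one-tailed; precomputed, matching
# scipy.stats.chi2.ppf(0.99, 1)
CHI2_CUTOFF_P01 = 6.6348966010212145

LOG10 = math.log(10.0)


@dataclass
class WindowHistogram:
    """Relative likelihood ``H(delta)`` of observing a deviation in a window.

    ``probs[k]`` holds H for deviation ``offset + k``; deviations outside
    the support fall back to ``floor``.  The grid is integer: deviations are
    rounded to the nearest bp before lookup.
    """

    offset: int
    probs: np.ndarray
    floor: float
    log_probs: np.ndarray
    mean: float
    stddev: float
    read_group: int = 0

    def __getitem__(self, delta) -> np.ndarray:
        """H(delta) with floor outside the support (vectorised)."""
        idx = np.rint(np.asarray(delta, dtype=float)).astype(np.int64) - self.offset
        inside = (idx >= 0) & (idx < len(self.probs))
        out = np.full(idx.shape, self.floor)
        out[inside] = self.probs[idx[inside]]
        return out if out.ndim else float(out)

    def log(self, delta) -> np.ndarray:
        """log H(delta), floored."""
        idx = np.rint(np.asarray(delta, dtype=float)).astype(np.int64) - self.offset
        inside = (idx >= 0) & (idx < len(self.probs))
        out = np.full(idx.shape, math.log(self.floor))
        out[inside] = self.log_probs[idx[inside]]
        return out if out.ndim else float(out)


@dataclass
class GenotypeLikelihoods:
    """Per-sample relative genotype likelihoods, stored as natural logs."""

    log_l0: float
    log_l1: float
    log_l2: float
    sample_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.log_l0, self.log_l1, self.log_l2])

    def linear(self) -> np.ndarray:
        """Likelihoods rescaled so the largest is 1 (relative scale)."""
        a = self.as_array()
        return np.exp(a - a.max())


@dataclass
class GenotypeWeights:
    """Sample- and genotype-specific mixture weights; sums to 1."""

    a0: float
    a1: float
    a2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2])


def transform_histogram(
    hist: InsertSizeHistogram, window_size: int, floor: float = 1e-10
) -> WindowHistogram:
    """Turn a null insert-size histogram into a window-overlap likelihood.

    A pair with insert size ``i`` can overlap a window of width ``w`` placed
    at ``i + w - 1`` distinct start positions, so longer fragments are more
    likely to be observed in any given window.  Each deviation's mass is the
    null count at ``mu + delta`` times that placement factor, renormalised
    to sum to 1 and floored from below.
    """
    if hist.total <= 0:
        raise ValueError("cannot transform an empty histogram")
    if window_size < 1:
        raise ValueError("window size must be >= 1")
    mu = int(round(hist.mean))
    lo, hi = hist.support()
    offset = lo - mu
    probs = np.zeros(hi - lo + 1)
    for size, count in hist.counts.items():
        probs[size - lo] = count * max(size + window_size - 1, 1)
    probs /= probs.sum()
    probs = np.maximum(probs, floor)
    return WindowHistogram(
        offset=offset,
        probs=probs,
        floor=floor,
        log_probs=np.log(probs),
        mean=hist.mean,
        stddev=hist.stddev,
        read_group=hist.read_group,
    )


def genotype_likelihoods(
    deltas: Sequence[float],
    hist: WindowHistogram,
    length: float,
    eps: float = 0.0,
    sample_id: str = "",
) -> GenotypeLikelihoods:
    """Likelihoods of 0/1/2 deletion alleles given a sample's deviations.

    Non-carrier pairs follow the null distribution shifted by the
    sample-specific reference shift ``eps``; carrier pairs follow the null
    shifted by the deletion length; heterozygotes are an equal mixture.
    An empty deviation list gives the uninformative triple (1, 1, 1).
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        return GenotypeLikelihoods(0.0, 0.0, 0.0, sample_id)
    log_ref = hist.log(deltas - eps)
    log_del = hist.log(deltas - length)
    log_l0 = float(log_ref.sum())
    log_l2 = float(log_del.sum())
    m = np.maximum(log_ref, log_del)
    log_l1 = float((m + np.log(np.exp(log_ref - m) + np.exp(log_del - m)) - math.log(2.0)).sum())
    return GenotypeLikelihoods(log_l0, log_l1, log_l2, sample_id)


def genotype_frequency_priors(f: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-f)^2, 2f(1-f), f^2)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency {f} outside [0, 1]")
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f * f])


def genotype_weights(gl: GenotypeLikelihoods, f: float) -> GenotypeWeights:
    """Posterior-like mixing weights combining data likelihood and AF prior."""
    priors = genotype_frequency_priors(f)
    logs = gl.as_array()
    m = logs.max()
    if not np.isfinite(m):
        raise ValueError("genotype likelihoods must be finite")
    num = np.exp(logs - m) * priors
    total = num.sum()
    if total <= 0.0:
        raise ValueError("all genotype weights are zero")
    a = num / total
    return GenotypeWeights(float(a[0]), float(a[1]), float(a[2]))


@dataclass
class LikelihoodRatioResult:
    """Outcome of the joint likelihood-ratio test for one window."""

    log_lambda: float  # ln Lambda = ln L(no del) - ln L(del of length l)
    statistic: float  # -2 ln Lambda
    reject: bool

    @property
    def lambda_(self) -> float:
        # clamp to avoid overflow in the linear domain; the decision is
        # always taken on the log scale
        return math.exp(min(max(self.log_lambda, -700.0), 700.0))


def likelihood_ratio_test(
    states: Sequence[Tuple[GenotypeLikelihoods, GenotypeWeights]],
    pi: float = 1e-4,
    cutoff: float = CHI2_CUTOFF_P01,
) -> LikelihoodRatioResult:
    """Joint test of "no deletion" against "deletion of length l".

    The null model multiplies every sample's reference-genotype likelihood;
    the alternative multiplies each sample's weight-mixed three-genotype
    likelihood.  The null is rejected when ``-2 ln Lambda`` exceeds the
    chi-square(1) quantile for the configured P-value threshold.
    """
    if not states:
        raise ValueError("likelihood ratio test needs at least one sample")
    log_null = math.log1p(-pi)
    log_alt = math.log(pi)
    for gl, w in states:
        logs = gl.as_array()
        log_null += logs[0]
        m = logs.max()
        mix = float(np.dot(w.as_array(), np.exp(logs - m)))
        # a weight triple summing to 1 guarantees mix > 0 with floored hists
        log_alt += m + math.log(mix)
    log_lambda = log_null - log_alt
    stat = -2.0 * log_lambda
    return LikelihoodRatioResult(log_lambda, stat, stat >= cutoff)
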