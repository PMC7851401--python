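"""Iterative per-window estimation of deletion length and allele frequency.

Each candidate window is examined once per initial deletion length.  An
iteration alternates: genotype likelihoods for the current length, mixture
weights for the current allele frequency, an allele-frequency update from
the weights, per-pair probabilities that a deviation stems from the shifted
(deletion) distribution, and a length update as the probability-weighted
mean deviation.  Iteration stops when both parameters converge, the
iteration limit is reached, the length falls below the minimum detectable
length (no-call) or the state starts to oscillate (the best-scoring state
seen is kept).

The module exposes the individual update rules for testing and a
vectorised :func:`iterate_window` used by the genome sweep, which evaluates
all samples' read pairs in flat numpy arrays against a stacked histogram
matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from joindel.config import RunConfig
from joindel.likelihood import (
    GenotypeLikelihoods,
    GenotypeWeights,
    LikelihoodRatioResult,
    WindowHistogram,
    genotype_frequency_priors,
    likelihood_ratio_test,
)

LOG2 = math.log(2.0)


@dataclass
class IterationConfig:
    """Termination controls for the per-window iteration."""

    max_iterations: int = 15
    len_tol_bp: float = 2.0
    af_tol: float = 1e-3
    min_del_length: float = 30.0

    @classmethod
    def from_run_config(cls, cfg: RunConfig, min_del_length: float) -> "IterationConfig":
        return cls(
            max_iterations=cfg.max_iterations,
            len_tol_bp=cfg.len_tol_bp,
            af_tol=cfg.af_tol,
            min_del_length=cfg.min_del_length or min_del_length,
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_lengths(
    deltas_per_sample: Sequence[np.ndarray],
    sigma_pooled: float,
    min_del_length: float,
    cluster_tol: Optional[float] = None,
) -> List[float]:
    """Initial deletion lengths from greedy clustering of per-sample Q3s.

    Samples with similar third quartiles of their deviation lists are
    clustered greedily (descending Q3 order, deterministic); each cluster
    contributes its median Q3 as one initial length.  Clusters below the
    minimum detectable length are dropped, so a window with only null-like
    deviations yields an empty list and is skipped.
    """
    tol = cluster_tol if cluster_tol is not None else max(sigma_pooled, 40.0)
    q3s = sorted(
        (float(np.percentile(d, 75)) for d in deltas_per_sample if len(d) > 0),
        reverse=True,
    )
    if not q3s:
        return []
    inits: List[float] = []
    i = 0
    while i < len(q3s):
        seed = q3s[i]
        j = i
        while j < len(q3s) and seed - q3s[j] <= tol:
            j += 1
        cluster = q3s[i:j]
        length = float(np.median(cluster))
        if length >= min_del_length:
            inits.append(length)
        i = j
    return inits


def initialize_allele_frequency(
    deltas_per_sample: Sequence[np.ndarray],
    sigmas: Sequence[float],
    n_samples: int,
    support_sd_mult: float = 3.0,
) -> float:
    """Fraction of deletion-supporting pairs among all pairs in the window.

    A pair supports a deletion when its deviation exceeds
    ``support_sd_mult`` null standard deviations of its sample.  The result
    is clamped away from 0 and 1 by half an allele count so that the
    genotype-frequency priors stay informative.
    """
    total = 0
    supporting = 0
    for deltas, sigma in zip(deltas_per_sample, sigmas):
        total += len(deltas)
        supporting += int(np.count_nonzero(np.asarray(deltas) > support_sd_mult * sigma))
    if total == 0:
        raise ValueError("no read pairs overlap the window")
    f = supporting / total
    lo = 1.0 / (2.0 * n_samples)
    return float(min(max(f, lo), 1.0 - lo))


# ---------------------------------------------------------------------------
# update rules
# ---------------------------------------------------------------------------


def update_allele_frequency(weights: Sequence[GenotypeWeights]) -> float:
    """New allele frequency: mean expected allele count over 2N alleles."""
    n = len(weights)
    if n == 0:
        raise ValueError("no samples")
    return float(sum(w.a1 + 2.0 * w.a2 for w in weights) / (2.0 * n))


def shift_probability(
    deltas,
    length: float,
    eps: float,
    weights: GenotypeWeights,
    hist: WindowHistogram,
) -> np.ndarray:
    """Probability that each deviation stems from the length-shifted null.

    ``P = a1 * H(d-l) / (H(d-eps) + H(d-l)) + a2``; a homozygous-carrier
    weight of 1 forces P = 1, a pure-reference weight forces P = 0.
    """
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    h_ref = np.asarray(hist[deltas - eps], dtype=float)
    h_del = np.asarray(hist[deltas - length], dtype=float)
    return weights.a1 * h_del / (h_ref + h_del) + weights.a2


def update_length(
    contributions: Sequence[Tuple[np.ndarray, np.ndarray]]
) -> float:
    """New deletion length: probability-weighted mean of all deviations."""
    num = 0.0
    den = 0.0
    for deltas, probs in contributions:
        deltas = np.asarray(deltas, dtype=float)
        probs = np.asarray(probs, dtype=float)
        num += float(np.dot(deltas, probs))
        den += float(probs.sum())
    if den <= 0.0:
        raise ValueError("no deletion-supporting probability mass")
    return num / den


def estimate_start_position(
    supporting_fwd_read_ends: Sequence[int], fallback: int
) -> int:
    """Deletion start from the rightmost forward-read end of supporting pairs.

    ``supporting_fwd_read_ends`` holds the rightmost aligned (clip-extended,
    0-based closed) positions of forward reads whose deviation supports the
    deletion; the start is one past the largest of them.  Without supporting
    pairs the window start is used.
    """
    ends = list(supporting_fwd_read_ends)
    if not ends:
        return fallback
    return int(max(ends)) + 1


# ---------------------------------------------------------------------------
# vectorised window state
# ---------------------------------------------------------------------------


class CohortHistograms:
    """Stacked log window-histograms of all (sample, read group) rows.

    Rows share one integer deviation grid ``[offset, offset + span)``;
    lookups outside the grid return the log floor.  Built once per contig
    and reused by every window.
    """

    def __init__(self, hists: Sequence[WindowHistogram]):
        self.offset = min(h.offset for h in hists)
        hi = max(h.offset + len(h.probs) for h in hists)
        self.span = hi - self.offset
        self.log_floor = math.log(min(h.floor for h in hists))
        self.log_mat = np.full((len(hists), self.span), self.log_floor)
        for row, h in enumerate(hists):
            a = h.offset - self.offset
            self.log_mat[row, a : a + len(h.probs)] = h.log_probs
        self.sigmas = np.array([h.stddev for h in hists])

    def log(self, rows: np.ndarray, deltas: np.ndarray) -> np.ndarray:
        idx = np.rint(deltas).astype(np.int64) - self.offset
        inside = (idx >= 0) & (idx < self.span)
        out = np.full(deltas.shape, self.log_floor)
        out[inside] = self.log_mat[rows[inside], idx[inside]]
        return out


@dataclass
class WindowObservations:
    """All read-pair deviations of one window, flattened across samples."""

    deltas: np.ndarray  # float, concatenated over samples
    sample_idx: np.ndarray  # int, parallel to deltas
    row_idx: np.ndarray  # int, (sample, read-group) row in the histogram matrix
    n_samples: int
    hists: CohortHistograms
    eps: np.ndarray  # per-row reference shift
    fwd_read_ends: Optional[np.ndarray] = None  # parallel to deltas

    @classmethod
    def from_samples(
        cls,
        deltas_per_sample: Sequence[Sequence[float]],
        hists: Sequence[WindowHistogram],
        eps: Optional[Sequence[float]] = None,
        fwd_read_ends: Optional[Sequence[Sequence[int]]] = None,
    ) -> "WindowObservations":
        """One read group per sample; row i belongs to sample i."""
        n = len(deltas_per_sample)
        deltas = np.concatenate([np.asarray(d, dtype=float) for d in deltas_per_sample]) \
            if n else np.empty(0)
        sidx = np.concatenate(
            [np.full(len(d), i, dtype=np.int64) for i, d in enumerate(deltas_per_sample)]
        ) if n else np.empty(0, dtype=np.int64)
        ends = None
        if fwd_read_ends is not None:
            ends = np.concatenate([np.asarray(e, dtype=np.int64) for e in fwd_read_ends])
        return cls(
            deltas=deltas,
            sample_idx=sidx,
            row_idx=sidx.copy(),
            n_samples=n,
            hists=CohortHistograms(hists),
            eps=np.asarray(eps if eps is not None else np.zeros(n), dtype=float),
            fwd_read_ends=ends,
        )

    def deltas_of_sample(self, i: int) -> np.ndarray:
        return self.deltas[self.sample_idx == i]


@dataclass
class WindowFit:
    """Converged (or aborted) estimation state of one window."""

    length: float
    freq: float
    log_gl: np.ndarray  # (n_samples, 3) natural-log genotype likelihoods
    weights: np.ndarray  # (n_samples, 3)
    lrt: Optional[LikelihoodRatioResult]
    converged: bool
    n_iterations: int
    no_call: bool = False
    reason: str = ""

    def genotype_likelihood_list(self) -> List[GenotypeLikelihoods]:
        return [GenotypeLikelihoods(*row) for row in self.log_gl]

    def weight_list(self) -> List[GenotypeWeights]:
        return [GenotypeWeights(*row) for row in self.weights]


def _likelihood_pass(
    obs: WindowObservations, length: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample log genotype likelihoods and the per-pair log lookups."""
    log_ref = obs.hists.log(obs.row_idx, obs.deltas - obs.eps[obs.row_idx])
    log_del = obs.hists.log(obs.row_idx, obs.deltas - length)
    m = np.maximum(log_ref, log_del)
    log_mix = m + np.log(np.exp(log_ref - m) + np.exp(log_del - m)) - LOG2
    n = obs.n_samples
    log_gl = np.column_stack(
        [
            np.bincount(obs.sample_idx, weights=log_ref, minlength=n),
            np.bincount(obs.sample_idx, weights=log_mix, minlength=n),
            np.bincount(obs.sample_idx, weights=log_del, minlength=n),
        ]
    )
    return log_gl, log_ref, log_del


def _weights_pass(log_gl: np.ndarray, f: float) -> np.ndarray:
    priors = genotype_frequency_priors(f)
    m = log_gl.max(axis=1, keepdims=True)
    num = np.exp(log_gl - m) * priors
    return num / num.sum(axis=1, keepdims=True)


def _lrt_pass(
    log_gl: np.ndarray, weights: np.ndarray, pi: float, cutoff: float
) -> LikelihoodRatioResult:
    m = log_gl.max(axis=1, keepdims=True)
    mix = (weights * np.exp(log_gl - m)).sum(axis=1)
    log_alt = math.log(pi) + float((m[:, 0] + np.log(mix)).sum())
    log_null = math.log1p(-pi) + float(log_gl[:, 0].sum())
    log_lambda = log_null - log_alt
    stat = -2.0 * log_lambda
    return LikelihoodRatioResult(log_lambda, stat, stat >= cutoff)


def iterate_window(
    obs: WindowObservations,
    init_length: float,
    init_freq: float,
    iter_cfg: IterationConfig,
    pi: float = 1e-4,
    cutoff: float = 6.6348966010212145,
) -> WindowFit:
    """Run the length/frequency iteration to convergence for one window.

    Returns a no-call fit when the estimated length collapses below the
    minimum detectable length or no probability mass supports a deletion.
    When the state oscillates, the iteration stops and the state with the
    strongest likelihood-ratio statistic seen so far is kept.
    """
    length, freq = float(init_length), float(init_freq)
    seen = set()
    best: Optional[Tuple[float, float, float]] = None  # (stat, length, freq)
    converged = False
    iterations = 0
    for iterations in range(1, iter_cfg.max_iterations + 1):
        log_gl, log_ref, log_del = _likelihood_pass(obs, length)
        weights = _weights_pass(log_gl, freq)
        freq_new = float((weights[:, 1] + 2.0 * weights[:, 2]).sum() / (2.0 * obs.n_samples))
        # P that each pair's deviation stems from the length-shifted null;
        # pairs at the histogram floor under both models (e.g. a second,
        # differently sized deletion in another sample) are uninformative
        # for this length and excluded from the update
        ratio = 1.0 / (1.0 + np.exp(log_ref - log_del))
        informative = (log_ref > obs.hists.log_floor) | (log_del > obs.hists.log_floor)
        probs = (
            weights[obs.sample_idx, 1] * ratio + weights[obs.sample_idx, 2]
        ) * informative
        den = float(probs.sum())
        if den <= 0.0:
            return WindowFit(length, freq, log_gl, weights, None, False, iterations,
                             no_call=True, reason="no supporting probability mass")
        length_new = float(np.dot(obs.deltas, probs) / den)
        lrt = _lrt_pass(log_gl, weights, pi, cutoff)
        if best is None or lrt.statistic > best[0]:
            best = (lrt.statistic, length, freq)
        delta_l = abs(length_new - length)
        delta_f = abs(freq_new - freq)
        length, freq = length_new, freq_new
        if length < iter_cfg.min_del_length:
            return WindowFit(length, freq, log_gl, weights, None, False, iterations,
                             no_call=True, reason="length below minimum detectable")
        if delta_l <= iter_cfg.len_tol_bp and delta_f <= iter_cfg.af_tol:
            converged = True
            break
        state = (round(length, 1), round(freq, 4))
        if state in seen:  # oscillation: keep the best-scoring state
            length, freq = best[1], best[2]
            break
        seen.add(state)

    log_gl, log_ref, log_del = _likelihood_pass(obs, length)
    weights = _weights_pass(log_gl, freq)
    lrt = _lrt_pass(log_gl, weights, pi, cutoff)
    return WindowFit(length, freq, log_gl, weights, lrt, converged, iterations)


def supporting_pair_mask(obs: WindowObservations, fit: WindowFit) -> np.ndarray:
    """Pairs whose deviation supports the fitted deletion (P >= 0.5).

    Genotype weights are ignored here: support reflects the deviation
    itself, so that carrier pairs can anchor the start position even when a
    sample's weight is spread over genotypes.
    """
    log_ref = obs.hists.log(obs.row_idx, obs.deltas - obs.eps[obs.row_idx])
    log_del = obs.hists.log(obs.row_idx, obs.deltas - fit.length)
    # deviations outside both supports tie at the floor; only those near the
    # fitted length (not far null tails) count as support there
    return (log_del > log_ref) | ((log_del == log_ref) & (obs.deltas > fit.length / 2.0))
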