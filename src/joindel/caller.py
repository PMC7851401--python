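"""Joint calling sweep: from per-sample profiles to deletion calls.

The sweep visits each contig once.  Per sample it computes insert-size
deviations against the sample's null mean, pre-screens the window grid for
positions where at least one sample shows a minimum number of
deletion-supporting pairs, and runs the iterative estimation plus the
likelihood-ratio test only on those candidate windows.  Significant windows
become merge candidates; merging and genotype assembly produce the final
calls.  Each profile is read exactly once per region, so adding the N+1st
sample to a cohort only requires its own profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from joindel.config import RunConfig, parse_region
from joindel.estimate import (
    CohortHistograms,
    IterationConfig,
    WindowObservations,
    estimate_start_position,
    initialize_allele_frequency,
    initialize_lengths,
    iterate_window,
    supporting_pair_mask,
)
from joindel.likelihood import transform_histogram
from joindel.merge import CandidateWindow, merge_candidates
from joindel.profile import SampleProfile
from joindel.vcfout import DeletionCall

logger = logging.getLogger(__name__)

try:  # scipy is a hard dependency, but the cutoff has a closed fallback
    from scipy.stats import chi2 as _chi2
except ImportError:  # pragma: no cover
    _chi2 = None


def chi2_cutoff(alpha: float) -> float:
    """One-tailed chi-square(1 df) rejection boundary for P threshold alpha."""
    if alpha == 0.01 or _chi2 is None:
        return 6.6348966010212145
    return float(_chi2.ppf(1.0 - alpha, 1))


def check_sequence_dictionaries(profiles: Sequence[SampleProfile]) -> List[Tuple[str, int]]:
    """All profiles must agree on the reference; returns the shared dictionary."""
    ref = profiles[0].sequence_dictionary
    for p in profiles[1:]:
        if p.sequence_dictionary != ref:
            ours = {c for c, _ in ref}
            theirs = {c for c, _ in p.sequence_dictionary}
            diff = ours.symmetric_difference(theirs) or ours
            raise ValueError(
                f"sequence dictionary of {p.sample_id!r} does not match "
                f"{profiles[0].sample_id!r}; differing contigs: {sorted(diff)}"
            )
    return ref


@dataclass
class _ContigData:
    """Per-sample arrays of one contig, ready for the window sweep."""

    starts: List[np.ndarray]  # fwd_start per sample
    ends: List[np.ndarray]  # fragment footprint end = start + insert
    deltas: List[np.ndarray]  # insert - round(mu of the pair's read group)
    rows: List[np.ndarray]  # histogram-matrix row per pair
    max_insert: int


def _prepare_contig(
    profiles: Sequence[SampleProfile],
    contig_id: int,
    row_of: Dict[Tuple[int, int], int],
    mu_row: np.ndarray,
) -> _ContigData:
    starts, ends, deltas, rows = [], [], [], []
    max_insert = 1
    for s, prof in enumerate(profiles):
        arr = prof.records_by_contig.get(contig_id)
        if arr is None or len(arr["start"]) == 0:
            empty = np.empty(0, dtype=np.int64)
            starts.append(empty)
            ends.append(empty)
            deltas.append(np.empty(0))
            rows.append(empty)
            continue
        row = np.array([row_of[(s, int(g))] for g in arr["rg"]], dtype=np.int64)
        ins = arr["insert"].astype(np.int64)
        starts.append(arr["start"].astype(np.int64))
        ends.append(arr["start"].astype(np.int64) + ins)
        deltas.append(ins - mu_row[row])
        rows.append(row)
        max_insert = max(max_insert, int(ins.max()))
    return _ContigData(starts, ends, deltas, rows, max_insert)


def _candidate_windows(
    data: _ContigData,
    sigmas_row: np.ndarray,
    contig_length: int,
    window_size: int,
    support_sd_mult: float,
    min_support: int,
) -> np.ndarray:
    """Window indices where some sample has >= min_support supporting pairs.

    A supporting pair deviates by more than ``support_sd_mult`` null
    standard deviations; its fragment footprint marks every window it
    overlaps.  The scan is a difference-array sweep per sample.
    """
    n_windows = contig_length // window_size + 1
    hit = np.zeros(n_windows, dtype=bool)
    for s in range(len(data.starts)):
        if len(data.starts[s]) == 0:
            continue
        thresh = support_sd_mult * sigmas_row[data.rows[s]]
        sel = data.deltas[s] > thresh
        if not sel.any():
            continue
        lo = data.starts[s][sel] // window_size
        hi = np.minimum(data.ends[s][sel] // window_size + 1, n_windows)
        diff = np.zeros(n_windows + 1, dtype=np.int32)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        hit |= np.cumsum(diff[:-1]) >= min_support
    return np.flatnonzero(hit)


def call_deletions(
    profiles: Sequence[SampleProfile],
    config: Optional[RunConfig] = None,
) -> Tuple[List[DeletionCall], List[str], List[Tuple[str, int]]]:
    """Jointly detect and genotype deletions across all profiles.

    Returns the merged calls, the sample order and the shared sequence
    dictionary.  Restricting to ``config.region`` limits the window sweep
    to one contig or sub-interval.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    config = config or RunConfig()
    seqdict = check_sequence_dictionaries(profiles)
    sample_ids = [p.sample_id for p in profiles]

    region = parse_region(config.region) if config.region else None
    w = config.window_size
    cutoff = chi2_cutoff(config.chi2_alpha)

    # one histogram row per (sample, read group)
    row_of: Dict[Tuple[int, int], int] = {}
    window_hists = []
    row_sample = []
    for s, prof in enumerate(profiles):
        for rg in sorted(prof.histograms):
            row_of[(s, rg)] = len(window_hists)
            window_hists.append(
                transform_histogram(prof.histograms[rg], w, floor=config.hist_floor)
            )
            row_sample.append(s)
    cohort_hists = CohortHistograms(window_hists)
    mu_row = np.array([int(round(h.mean)) for h in window_hists], dtype=np.int64)
    sigmas_row = cohort_hists.sigmas
    sigma_pooled = float(np.median(sigmas_row))
    min_len = config.min_del_length or float(
        np.median(
            [
                prof.histograms[rg].abs_deviation_percentile(95.0)
                for prof in profiles
                for rg in prof.histograms
            ]
        )
    )
    iter_cfg = IterationConfig.from_run_config(config, min_len)
    read_lens = [p.read_len for p in profiles]
    n_samples = len(profiles)

    all_calls: List[DeletionCall] = []
    for contig_id, (contig, contig_length) in enumerate(seqdict):
        if region and contig != region[0]:
            continue
        data = _prepare_contig(profiles, contig_id, row_of, mu_row)
        if all(len(s) == 0 for s in data.starts):
            continue
        windows = _candidate_windows(
            data,
            sigmas_row,
            contig_length,
            w,
            config.support_sd_mult,
            config.min_candidate_support,
        )
        if region and region[1] is not None:
            lo, hi = region[1] // w, (region[2] // w if region[2] else windows.max() + 1)
            windows = windows[(windows >= lo) & (windows <= hi)]
        logger.info(
            "contig %s: %d candidate windows of %d", contig, len(windows),
            contig_length // w + 1,
        )
        candidates = _sweep_contig(
            contig, windows, data, cohort_hists, sigmas_row, row_sample,
            read_lens, n_samples, sigma_pooled, iter_cfg, config, cutoff,
        )
        all_calls.extend(
            merge_candidates(
                candidates,
                start_tol=config.merge_start_tol,
                len_tol_frac=config.merge_len_tol_frac,
                window_size=w,
                min_genotype_pairs=config.min_genotype_pairs,
                coverage_mult=config.coverage_mult,
                inner_margin=float(np.median(read_lens)) + w,
            )
        )
    contig_order = {name: i for i, (name, _) in enumerate(seqdict)}
    all_calls.sort(key=lambda c: (contig_order[c.contig], c.start))
    return all_calls, sample_ids, seqdict


def _sweep_contig(
    contig: str,
    windows: np.ndarray,
    data: _ContigData,
    cohort_hists: CohortHistograms,
    sigmas_row: np.ndarray,
    row_sample: Sequence[int],
    read_lens: Sequence[int],
    n_samples: int,
    sigma_pooled: float,
    iter_cfg: IterationConfig,
    config: RunConfig,
    cutoff: float,
) -> List[CandidateWindow]:
    w = config.window_size
    eps = np.zeros(len(sigmas_row))
    candidates: List[CandidateWindow] = []
    for widx in windows:
        p = int(widx) * w
        win_end = p + w
        deltas_list: List[np.ndarray] = []
        rows_list: List[np.ndarray] = []
        sidx_list: List[np.ndarray] = []
        fwd_end_list: List[np.ndarray] = []
        sigma_list: List[float] = []
        for s in range(n_samples):
            st = data.starts[s]
            hi = int(np.searchsorted(st, win_end, side="left"))
            lo = int(np.searchsorted(st, p - data.max_insert, side="left"))
            sel = data.ends[s][lo:hi] > p
            d = data.deltas[s][lo:hi][sel]
            deltas_list.append(d)
            rows_list.append(data.rows[s][lo:hi][sel])
            sidx_list.append(np.full(len(d), s, dtype=np.int64))
            fwd_end_list.append(st[lo:hi][sel] + read_lens[s] - 1)
            sigma_list.append(float(sigmas_row[data.rows[s][lo]]) if hi > lo else sigma_pooled)

        inits = initialize_lengths(deltas_list, sigma_pooled, iter_cfg.min_del_length)
        if not inits:
            continue
        try:
            f0 = initialize_allele_frequency(
                deltas_list, sigma_list, n_samples, config.support_sd_mult
            )
        except ValueError:
            continue

        obs = WindowObservations(
            deltas=np.concatenate(deltas_list) if deltas_list else np.empty(0),
            sample_idx=np.concatenate(sidx_list),
            row_idx=np.concatenate(rows_list),
            n_samples=n_samples,
            hists=cohort_hists,
            eps=eps,
        )
        if config.local_recenter:
            obs = _recenter(obs, sigmas_row)
        fwd_ends = np.concatenate(fwd_end_list)
        pair_counts = np.bincount(obs.sample_idx, minlength=n_samples).astype(float)

        for l0 in inits:
            fit = iterate_window(obs, l0, f0, iter_cfg, config.prior_pi, cutoff)
            if fit.no_call or fit.lrt is None or not fit.lrt.reject:
                continue
            mask = supporting_pair_mask(obs, fit)
            start = estimate_start_position(fwd_ends[mask], fallback=p)
            # the window itself must intersect the deletion it predicts;
            # flank windows (overlapped only by the spanning fragments'
            # footprints) see partial support and misplace the start
            if not (p + w > start and p < start + fit.length):
                continue
            log_gl = fit.log_gl - fit.log_gl.max(axis=1, keepdims=True)
            candidates.append(
                CandidateWindow(
                    contig=contig,
                    start=start,
                    length=fit.length,
                    log_lambda=fit.lrt.log_lambda,
                    log_gl=log_gl,
                    pair_counts=pair_counts,
                    window_start=p,
                )
            )
    return candidates


def _recenter(obs: WindowObservations, sigmas_row: np.ndarray) -> WindowObservations:
    """Estimate per-sample reference shifts from null-like deviations.

    The shift is the median deviation of pairs within 3 sigma of zero,
    capped at one standard deviation, approximating local biases such as
    GC content.
    """
    eps = obs.eps.copy()
    for row in np.unique(obs.row_idx):
        d = obs.deltas[obs.row_idx == row]
        near = d[np.abs(d) < 3.0 * sigmas_row[row]]
        if len(near):
            eps[row] = float(
                np.clip(np.median(near), -sigmas_row[row], sigmas_row[row])
            )
    return WindowObservations(
        obs.deltas, obs.sample_idx, obs.row_idx, obs.n_samples, obs.hists, eps,
        obs.fwd_read_ends,
    )
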