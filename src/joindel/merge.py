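"""Combining consecutive significant windows into non-redundant calls.

A deletion typically rejects the null hypothesis in many consecutive
windows (and possibly for several length initialisations).  Candidate
windows are sorted by predicted start, length and likelihood ratio, then a
single left-to-right pass groups windows whose starts and lengths are
similar enough; each group is emitted as one call with the median start and
length and per-sample genotype likelihoods averaged over the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from joindel.vcfout import DeletionCall, assemble_call


@dataclass
class CandidateWindow:
    """One window/length pair whose null hypothesis was rejected."""

    contig: str
    start: int  # predicted deletion start (0-based)
    length: float
    log_lambda: float  # ln of the likelihood ratio; smaller = stronger
    log_gl: np.ndarray  # (n_samples, 3) normalised natural-log likelihoods
    pair_counts: np.ndarray  # (n_samples,)
    window_start: int = 0


def sort_candidates(windows: Sequence[CandidateWindow]) -> List[CandidateWindow]:
    """Stable sort by ascending (start, length, likelihood ratio)."""
    return sorted(windows, key=lambda w: (w.start, w.length, w.log_lambda))


def _similar(a: CandidateWindow, b: CandidateWindow,
             start_tol: Optional[float], len_tol_frac: float,
             window_size: int) -> bool:
    tol = start_tol if start_tol is not None else max(a.length / 2.0, 3.0 * window_size)
    if abs(b.start - a.start) > tol:
        return False
    rel = abs(a.length - b.length) / max(a.length, b.length)
    return rel <= len_tol_frac


def merge_candidates(
    windows: Sequence[CandidateWindow],
    start_tol: Optional[float] = None,
    len_tol_frac: float = 0.25,
    window_size: int = 30,
    min_genotype_pairs: int = 3,
    coverage_mult: float = 4.0,
    inner_margin: float = 0.0,
) -> List[DeletionCall]:
    """Left-to-right grouping of sorted candidates, iterated to fixation.

    The default start tolerance is ``max(length/2, 3 * window_size)`` of the
    group's seed.  The grouping pass runs on group representatives (median
    start and length) and repeats until no two groups can be combined, so
    that no two emitted calls satisfy the merge criteria with each other
    even when medians drift away from the original seeds.  Every input
    window ends up in exactly one call.
    """

    def _median_rep(group: List[CandidateWindow]) -> Tuple[int, float]:
        return (
            int(round(float(np.median([w.start for w in group])))),
            float(np.median([w.length for w in group])),
        )

    groups: List[List[CandidateWindow]] = [[w] for w in sort_candidates(windows)]
    while True:
        reps = [_median_rep(g) for g in groups]
        order = sorted(range(len(groups)), key=lambda i: reps[i])
        used = [False] * len(groups)
        next_groups: List[List[CandidateWindow]] = []
        changed = False
        for a, i in enumerate(order):
            if used[a]:
                continue
            used[a] = True
            combined = list(groups[i])
            seed_start, seed_len = reps[i]
            tol = start_tol if start_tol is not None else max(
                seed_len / 2.0, 3.0 * window_size
            )
            for b in range(a + 1, len(order)):
                if used[b]:
                    continue
                cand_start, cand_len = reps[order[b]]
                if cand_start - seed_start > tol:
                    break
                if (
                    abs(cand_start - seed_start) <= tol
                    and abs(seed_len - cand_len) / max(seed_len, cand_len)
                    <= len_tol_frac
                ):
                    combined.extend(groups[order[b]])
                    used[b] = True
                    changed = True
            next_groups.append(combined)
        groups = next_groups
        if not changed:
            break

    calls: List[DeletionCall] = []
    for group in groups:
        # genotypes come from the windows inside the called span: windows in
        # the flanks also reject (spanning fragments overlap them) but mix
        # reference pairs into carrier samples and would bias genotypes.
        # The estimated start can also overrun the true one by up to a read
        # length (forward reads crossing the breakpoint), so the tail of the
        # span is excluded via inner_margin.
        med_start = float(np.median([w.start for w in group]))
        med_len = float(np.median([w.length for w in group]))
        inner = [
            w
            for w in group
            if med_start <= w.window_start < med_start + med_len - inner_margin
        ] or group
        calls.append(
            assemble_call(
                contig=group[0].contig,
                starts=[w.start for w in group],
                lengths=[w.length for w in group],
                log_gl_stack=np.stack([w.log_gl for w in inner]),
                pair_counts=np.stack([w.pair_counts for w in inner]),
                min_pairs=min_genotype_pairs,
                coverage_mult=coverage_mult,
            )
        )
    calls.sort(key=lambda c: (c.contig, c.start))
    return calls
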