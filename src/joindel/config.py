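"""Run-time configuration shared across the profiling and calling steps.

Every tunable of the pipeline lives here with its documented default so that
the command line, the library API and the test-suite all agree on one source
of truth.  Values are grouped roughly by pipeline stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

logger = logging.getLogger("joindel")


@dataclass
class RunConfig:
    """All configuration keys of the pipeline with their defaults.

    Profiling
    ---------
    min_mapq:
        Minimum mapping quality for a read pair to enter a profile.
    max_insert_sd_mult:
        Cap on inserts entering the null histogram, expressed as
        ``mean + k * stddev``; bounds the histogram support.  Stored records
        may exceed it by up to ``max_del_length`` so that pairs spanning
        long deletions are retained.
    max_del_length:
        Largest deletion length the caller targets; bounds the stored
        insert sizes and the candidate-window search.
    max_sample_pairs:
        Maximum number of read pairs sampled per read group when estimating
        the null insert-size distribution.
    min_sample_pairs:
        Hard lower bound of sampled pairs below which the null distribution
        is considered unreliable.

    Calling
    -------
    window_size:
        Width in bp of the sliding genomic window.
    prior_pi:
        Prior probability of a window overlapping a deletion.
    chi2_alpha:
        One-tailed P-value threshold of the likelihood-ratio test.
    hist_floor:
        Probability assigned to insert-size deviations outside the observed
        histogram support.
    support_sd_mult:
        A read pair supports a deletion when its deviation exceeds this many
        null standard deviations.
    min_candidate_support:
        Minimum number of supporting pairs from a single sample for a window
        to be examined at all (cheap pre-screen).
    max_iterations / len_tol_bp / af_tol:
        Termination controls of the iterative length/frequency estimation.
    min_del_length:
        Minimum detectable deletion length in bp; ``None`` derives it from
        the null distribution (95th percentile of the absolute deviation).
    local_recenter:
        If true, re-estimate the per-sample reference shift from the window
        data instead of assuming 0.

    Merging / output
    ----------------
    merge_start_tol:
        Maximum start-position difference for two candidate windows to be
        combined; ``None`` means ``max(length/2, 3*window_size)``.
    merge_len_tol_frac:
        Maximum relative length difference for combination.
    min_genotype_pairs / coverage_mult:
        A sample is not genotyped at a locus with fewer pairs than
        ``min_genotype_pairs`` or more than ``coverage_mult`` times the
        cohort median pair count.
    """

    # profiling
    min_mapq: int = 30
    max_insert_sd_mult: float = 50.0
    max_sample_pairs: int = 100_000
    min_sample_pairs: int = 1000
    max_del_length: int = 10_000

    # likelihood / window model
    window_size: int = 30
    prior_pi: float = 1e-4
    chi2_alpha: float = 0.01
    hist_floor: float = 1e-10

    # iterative estimation
    support_sd_mult: float = 3.0
    min_candidate_support: int = 3
    max_iterations: int = 15
    len_tol_bp: float = 2.0
    af_tol: float = 1e-3
    min_del_length: Optional[float] = None
    local_recenter: bool = False

    # merging
    merge_start_tol: Optional[float] = None
    merge_len_tol_frac: float = 0.25

    # genotype reporting
    min_genotype_pairs: int = 3
    coverage_mult: float = 4.0

    # general
    seed: int = 0
    region: Optional[str] = None
    log_level: str = "INFO"

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def echo(self) -> None:
        """Log the effective configuration (one line per key)."""
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def parse_region(region: str) -> Tuple[str, Optional[int], Optional[int]]:
    """Parse a ``contig[:start-end]`` region string (1-based, inclusive).

    Returns ``(contig, start0, end0)`` with 0-based half-open coordinates,
    or ``(contig, None, None)`` when only a contig is given.
    """
    if ":" not in region:
        return region, None, None
    contig, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    start = int(start_s.replace(",", ""))
    end = int(end_s.replace(",", "")) if end_s else None
    if start < 1 or (end is not None and end < start):
        raise ValueError(f"invalid region {region!r}")
    return contig, start - 1, end
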