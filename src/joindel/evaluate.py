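"""Call-set scoring and population/trio quality control.

Benchmarking matches calls against a truth set one-to-one at 50% reciprocal
overlap.  Population QC removes sites out of Hardy-Weinberg equilibrium
with an exact test; trio QC computes the Mendelian inheritance error rate,
the transmission rate of deletion alleles from heterozygous parents (50%
expected) and screens for de novo candidates.  A genotype-matrix export
supports downstream population-structure analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln

from joindel.vcfout import MISSING_GT, DeletionCall

Interval = Tuple[str, int, int]


# ---------------------------------------------------------------------------
# interval matching
# ---------------------------------------------------------------------------


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """min of the two mutual overlap fractions of half-open intervals."""
    if a[0] != b[0]:
        return 0.0
    inter = min(a[2], b[2]) - max(a[1], b[1])
    if inter <= 0:
        return 0.0
    return min(inter / (a[2] - a[1]), inter / (b[2] - b[1]))


@dataclass
class MatchResult:
    """One-to-one assignment of calls to truth variants."""

    matches: Dict[int, int]  # truth index -> call index
    n_truth: int
    n_calls: int

    @property
    def recall(self) -> float:
        return len(self.matches) / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return len(self.matches) / self.n_calls if self.n_calls else float("nan")

    @property
    def f1(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if (r + p) > 0 else 0.0


def _as_interval(x) -> Interval:
    if isinstance(x, tuple):
        return x
    return x.interval()


def match_callsets(
    calls: Sequence, truth: Sequence, threshold: float = 0.5
) -> MatchResult:
    """Greedy best-overlap one-to-one matching of calls to truth variants.

    Candidate pairs at or above the reciprocal-overlap threshold are
    assigned in descending overlap order; every truth variant and every
    call participates in at most one match.
    """
    call_iv = [_as_interval(c) for c in calls]
    truth_iv = [_as_interval(t) for t in truth]
    pairs = []
    # prune with a sort on start positions: a pair can only overlap if the
    # intervals intersect at all
    order = sorted(range(len(call_iv)), key=lambda j: (call_iv[j][0], call_iv[j][1]))
    starts_by_contig: Dict[str, List[Tuple[int, int, int]]] = {}
    for j in order:
        c = call_iv[j]
        starts_by_contig.setdefault(c[0], []).append((c[1], c[2], j))
    for i, t in enumerate(truth_iv):
        for s, e, j in starts_by_contig.get(t[0], []):
            if s >= t[2]:
                break
            if e <= t[1]:
                continue
            ro = reciprocal_overlap(t, (t[0], s, e))
            if ro >= threshold:
                pairs.append((ro, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    matched_truth: Set[int] = set()
    matched_call: Set[int] = set()
    matches: Dict[int, int] = {}
    for ro, i, j in pairs:
        if i in matched_truth or j in matched_call:
            continue
        matches[i] = j
        matched_truth.add(i)
        matched_call.add(j)
    return MatchResult(matches, len(truth_iv), len(call_iv))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def parse_bed(path: str) -> List[Interval]:
    """Read a BED file of 0-based half-open intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line {line!r}")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line {line!r}") from exc
    return intervals


def _overlaps_any(iv: Interval, regions: Sequence[Interval]) -> bool:
    return any(
        r[0] == iv[0] and min(iv[2], r[2]) > max(iv[1], r[1]) for r in regions
    )


def _contained_in_any(iv: Interval, regions: Sequence[Interval]) -> bool:
    return any(r[0] == iv[0] and r[1] <= iv[1] and iv[2] <= r[2] for r in regions)


def filter_calls(
    calls: Sequence[DeletionCall],
    size_range: Tuple[int, int] = (500, 10_000),
    exclude_regions: Optional[Sequence[Interval]] = None,
    include_regions: Optional[Sequence[Interval]] = None,
    gq_min: int = 0,
) -> List[DeletionCall]:
    """Size, region and genotype-quality filtering of a call set.

    Calls outside the size range, with *any* overlap of an exclude region,
    or not fully contained in the include regions (when given) are removed.
    Genotypes below ``gq_min`` are masked to missing; calls left without
    any called genotype are dropped.
    """
    out = []
    for call in calls:
        if not (size_range[0] <= call.length <= size_range[1]):
            continue
        iv = call.interval()
        if exclude_regions and _overlaps_any(iv, exclude_regions):
            continue
        if include_regions is not None and not _contained_in_any(iv, include_regions):
            continue
        if gq_min > 0:
            masked = []
            for sc in call.samples:
                if sc.gt != MISSING_GT and sc.gq < gq_min:
                    sc = type(sc)(sc.pl, MISSING_GT, sc.gq, genotyped=False)
                masked.append(sc)
            if not any(sc.gt != MISSING_GT for sc in masked):
                continue
            call = DeletionCall(
                call.contig, call.start, call.length, masked, call.af, call.n_windows
            )
        out.append(call)
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg P value conditional on the allele counts.

    Sums the probabilities of all heterozygote configurations no more
    likely than the observed one (two-sided, without mid-P correction).
    Monomorphic sites return 1.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    if n == 0 or n_alt == 0 or n_ref == 0:
        return 1.0
    rare = min(n_alt, n_ref)

    def log_prob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(h + 1)
            - gammaln(hom_common + 1)
            + gammaln(n_alt + 1)
            + gammaln(n_ref + 1)
            - gammaln(2 * n + 1)
            + h * math.log(2.0)
        )

    hs = np.arange(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(int(h)) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[list(hs).index(n_het)] if n_het in hs else 0.0
    # numerical slack so configurations equal to the observed one count
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(
    counts: Tuple[int, int, int], alpha: float = 0.01
) -> bool:
    """True (keep) when the site is consistent with Hardy-Weinberg."""
    return hwe_exact_pvalue(*counts) >= alpha


# ---------------------------------------------------------------------------
# trio statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrioGenotypes:
    """Genotypes of one trio at one deletion site."""

    site_id: str
    trio_id: str
    father: str
    mother: str
    child: str
    gq_father: int = 99
    gq_mother: int = 99
    gq_child: int = 99

    @property
    def ignored(self) -> bool:
        """Missing genotypes, or all three 0/0, carry no information."""
        gts = (self.father, self.mother, self.child)
        if MISSING_GT in gts:
            return True
        return all(g == "0/0" for g in gts)


_ALLELES = {"0/0": (0,), "0/1": (0, 1), "1/1": (1,)}


def mendelian_consistent(father: str, mother: str, child: str) -> bool:
    """Whether the child genotype is possible under biparental transmission."""
    child_count = child.count("1")
    possible = {
        a + b for a in _ALLELES[father] for b in _ALLELES[mother]
    }
    return child_count in possible


def mendelian_error_rate(
    trios: Sequence[TrioGenotypes],
) -> Tuple[float, Dict[str, int]]:
    """Mendelian inheritance error rate over all informative trio-sites.

    Returns the error fraction ``errors / (errors + consistent)`` and the
    number of consistent sites per trio; ignored trio-sites (missing
    genotypes or all-reference) do not count.
    """
    errors = 0
    consistent = 0
    per_trio: Dict[str, int] = {}
    for t in trios:
        if t.ignored:
            continue
        if mendelian_consistent(t.father, t.mother, t.child):
            consistent += 1
            per_trio[t.trio_id] = per_trio.get(t.trio_id, 0) + 1
        else:
            errors += 1
            per_trio.setdefault(t.trio_id, per_trio.get(t.trio_id, 0))
    total = errors + consistent
    rate = errors / total if total else float("nan")
    return rate, per_trio


def _carries_deletion(gt: str) -> bool:
    return gt in ("0/1", "1/1")


def transmission_rate(
    trios: Sequence[TrioGenotypes], mode: str = "unique_single_parent"
) -> Optional[float]:
    """Percentage of deletion alleles transmitted from heterozygous parents.

    ``unique_single_parent`` restricts to sites whose deletion allele is
    observed in exactly one trio, with one parent heterozygous and the
    other homozygous reference; the allele is transmitted when the child is
    heterozygous.  ``single_parent`` applies the same parental
    configuration without the uniqueness constraint.  Returns ``None`` when
    no site qualifies.
    """
    if mode not in ("unique_single_parent", "single_parent"):
        raise ValueError(f"unknown transmission mode {mode!r}")
    by_site: Dict[str, List[TrioGenotypes]] = {}
    for t in trios:
        if t.ignored:
            continue
        by_site.setdefault(t.site_id, []).append(t)
    transmitted = 0
    considered = 0
    for site, site_trios in by_site.items():
        carrier_trios = [
            t
            for t in site_trios
            if any(_carries_deletion(g) for g in (t.father, t.mother, t.child))
        ]
        if mode == "unique_single_parent" and len(carrier_trios) != 1:
            continue
        for t in carrier_trios:
            parents = sorted((t.father, t.mother))
            if parents != ["0/0", "0/1"]:
                continue
            if t.child == "0/0":
                considered += 1
            elif t.child == "0/1":
                considered += 1
                transmitted += 1
            # a 1/1 child is a Mendelian error here, not a transmission
    if considered == 0:
        return None
    return 100.0 * transmitted / considered


def de_novo_candidates(
    trios: Sequence[TrioGenotypes], gq_min: int = 50
) -> List[TrioGenotypes]:
    """Sites where a confidently genotyped child carries an allele absent
    from both confidently genotyped parents."""
    out = []
    for t in trios:
        if t.ignored:
            continue
        if t.father == "0/0" and t.mother == "0/0" and _carries_deletion(t.child):
            if min(t.gq_father, t.gq_mother, t.gq_child) >= gq_min:
                out.append(t)
    return out


def expected_de_novo(
    verified_events: int, reference_trios: int, n_trios: int
) -> float:
    """Expected de novo deletion count scaled from a reference trio study."""
    if reference_trios <= 0 or n_trios < 0 or verified_events < 0:
        raise ValueError("inputs must be positive")
    return round(verified_events / reference_trios * n_trios, 2)


# ---------------------------------------------------------------------------
# cohort export
# ---------------------------------------------------------------------------


def genotype_matrix(
    calls: Sequence[DeletionCall], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Samples x sites matrix of deletion allele counts.

    Entries are 0/1/2 allele counts with ``NaN`` for missing genotypes;
    monomorphic (uninformative) columns are dropped.  Linkage pruning and
    principal-component analysis are left to downstream tooling.
    """
    count = {"0/0": 0.0, "0/1": 1.0, "1/1": 2.0, MISSING_GT: np.nan}
    cols = {}
    for call in calls:
        site = f"{call.contig}:{call.start + 1}:{call.length}"
        cols[site] = [count[sc.gt] for sc in call.samples]
    df = pd.DataFrame(cols, index=list(sample_ids))
    keep = [
        c
        for c in df.columns
        if df[c].dropna().nunique() > 1
    ]
    return df[keep]


def trio_table_from_calls(
    calls: Sequence[DeletionCall],
    sample_ids: Sequence[str],
    pedigree: Sequence[Tuple[str, str, str]],
) -> List[TrioGenotypes]:
    """Build the trio genotype table for a call set.

    ``pedigree`` rows are (child, father, mother) sample ids.
    """
    index = {sid: k for k, sid in enumerate(sample_ids)}
    table = []
    for call in calls:
        site = f"{call.contig}:{call.start + 1}:{call.length}"
        for t, (child, father, mother) in enumerate(pedigree):
            fa, mo, ch = (call.samples[index[s]] for s in (father, mother, child))
            table.append(
                TrioGenotypes(
                    site_id=site,
                    trio_id=f"trio{t}",
                    father=fa.gt,
                    mother=mo.gt,
                    child=ch.gt,
                    gq_father=fa.gq,
                    gq_mother=mo.gq,
                    gq_child=ch.gq,
                )
            )
    return table


def parse_pedigree(path: str) -> List[Tuple[str, str, str]]:
    """Read a pedigree file with one ``child father mother`` triple per line."""
    ped = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'child father mother'")
            ped.append((parts[0], parts[1], parts[2]))
    return ped
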