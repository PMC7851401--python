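"""Synthetic cohort simulator: deletions, genotypes and read pairs.

The generator mirrors a standard population-cohort simulation design at
three levels.  A deletion set draws lengths uniformly from 100-10,000 bp
and allele frequencies uniformly from (0, 1), placing deletions on one
contig at least 1 kb apart.  Haplotypes carry each deletion independently
with its allele frequency and are paired into diploid samples, so a
1000-sample cohort carries on average n/3 heterozygous and n/3 homozygous
deletions per individual.  Read pairs are generated at the fragment level:
fragments are placed uniformly on each haplotype with a normal insert-size
distribution; a fragment spanning a deletion acquires an apparent insert
inflated by the deletion length, and homozygously deleted sequence yields
no fragments at all.  Sequence-level details (base calls, errors, GC bias)
are not simulated; the caller consumes only positions and insert sizes.

All entry points are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from joindel.config import RunConfig
from joindel.profile import (
    InsertSizeHistogram,
    ReadPairRecord,
    SampleProfile,
    default_sampling_regions,
    estimate_null_distribution,
)
from joindel.vcfout import DeletionCall, SampleCall, write_vcf

DEFAULT_CONTIG = "chr21"
DEFAULT_CONTIG_LENGTH = 46_709_983  # a chromosome-21-sized contig


@dataclass(frozen=True)
class TrueDeletion:
    """A simulated deletion with its population allele frequency."""

    contig: str
    start: int  # 0-based
    length: int
    af: float

    @property
    def end(self) -> int:
        return self.start + self.length

    def interval(self) -> Tuple[str, int, int]:
        return (self.contig, self.start, self.end)


@dataclass
class SimCohort:
    """Diploid samples assembled from independently sampled haplotypes."""

    sample_ids: List[str]
    haplotypes: np.ndarray  # (2 * n_samples, n_deletions) bool
    genotypes: np.ndarray  # (n_samples, n_deletions) int8 in {0, 1, 2}
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def mean_het_hom(self) -> Tuple[float, float]:
        """Mean heterozygous and homozygous deletion count per individual."""
        het = float((self.genotypes == 1).sum(axis=1).mean())
        hom = float((self.genotypes == 2).sum(axis=1).mean())
        return het, hom


def simulate_deletion_set(
    n: int,
    contig_length: int = DEFAULT_CONTIG_LENGTH,
    len_range: Tuple[int, int] = (100, 10_000),
    min_gap: int = 1000,
    seed: int = 0,
    contig: str = DEFAULT_CONTIG,
    af_range: Tuple[float, float] = (0.0, 1.0),
) -> List[TrueDeletion]:
    """Draw ``n`` non-overlapping deletions with uniform lengths and AFs.

    Positions are uniform subject to a minimum pairwise gap, realised by
    distributing the leftover sequence uniformly between the ordered
    deletions (a draw of ordered uniform spacings); raises ``ValueError``
    when the contig cannot accommodate the request.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    lengths = rng.integers(len_range[0], len_range[1] + 1, size=n)
    afs = rng.uniform(af_range[0], af_range[1], size=n)
    free = contig_length - int(lengths.sum()) - (n - 1) * min_gap
    if free < 0:
        raise ValueError(
            f"cannot place {n} deletions of total length {int(lengths.sum())} "
            f"with gap {min_gap} on a {contig_length} bp contig; reduce n"
        )
    slack = np.sort(rng.uniform(0.0, free, size=n)).astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths[:-1] + min_gap)])
    starts = slack + offsets
    return [
        TrueDeletion(contig, int(s), int(l), float(a))
        for s, l, a in zip(starts, lengths, afs)
    ]


def simulate_genotypes(
    deletions: Sequence[TrueDeletion], n_samples: int, seed: int = 0
) -> SimCohort:
    """Sample 2N haplotypes by allele frequency and pair them into diploids."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    afs = np.array([d.af for d in deletions])
    haplotypes = rng.random((2 * n_samples, len(deletions))) < afs
    genotypes = (haplotypes[0::2].astype(np.int8) + haplotypes[1::2].astype(np.int8))
    width = max(3, len(str(n_samples - 1)))
    sample_ids = [f"S{i:0{width}d}" for i in range(n_samples)]
    return SimCohort(sample_ids, haplotypes, genotypes, seed)


def simulate_trios(
    deletions: Sequence[TrueDeletion], n_trios: int, seed: int = 0
) -> Tuple[SimCohort, List[Tuple[str, str, str]]]:
    """Simulate trios under Mendelian transmission.

    Parent haplotypes are drawn by allele frequency; each child inherits
    one uniformly chosen haplotype from each parent.  Returns the cohort
    (samples ordered father, mother, child per trio) and a pedigree of
    (child, father, mother) sample-id triples.
    """
    rng = np.random.default_rng(seed)
    afs = np.array([d.af for d in deletions])
    m = len(deletions)
    hap_rows = []
    sample_ids: List[str] = []
    pedigree: List[Tuple[str, str, str]] = []
    for t in range(n_trios):
        fa = rng.random((2, m)) < afs
        mo = rng.random((2, m)) < afs
        child = np.stack([fa[rng.integers(0, 2)], mo[rng.integers(0, 2)]])
        hap_rows.extend([fa[0], fa[1], mo[0], mo[1], child[0], child[1]])
        f_id, m_id, c_id = f"T{t:03d}F", f"T{t:03d}M", f"T{t:03d}C"
        sample_ids.extend([f_id, m_id, c_id])
        pedigree.append((c_id, f_id, m_id))
    haplotypes = np.array(hap_rows)
    genotypes = haplotypes[0::2].astype(np.int8) + haplotypes[1::2].astype(np.int8)
    return SimCohort(sample_ids, haplotypes, genotypes, seed), pedigree


# ---------------------------------------------------------------------------
# read-pair level simulation
# ---------------------------------------------------------------------------


def _haplotype_read_pairs(
    carried: np.ndarray,
    del_starts: np.ndarray,
    del_lengths: np.ndarray,
    contig_length: int,
    coverage_per_hap: float,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fragments of one haplotype mapped back to reference coordinates.

    Returns (forward-read start, apparent insert size), both on the
    reference.  A fragment whose interior contains an excision breakpoint
    spans the deletion and gains its length; sequence removed on both
    haplotypes contributes no fragments, which is the read-depth signal.
    """
    starts = del_starts[carried]
    lengths = del_lengths[carried]
    cum = np.concatenate([[0], np.cumsum(lengths)])
    # breakpoint positions in haplotype coordinates
    breakpoints = starts - cum[:-1]
    hap_len = contig_length - int(lengths.sum())
    n_frags = int(round(coverage_per_hap * hap_len / (2.0 * read_len)))
    inserts = np.rint(rng.normal(insert_mean, insert_sd, size=n_frags)).astype(np.int64)
    inserts = np.maximum(inserts, 2 * read_len)
    x = (rng.random(n_frags) * (hap_len - inserts)).astype(np.int64)
    idx_start = np.searchsorted(breakpoints, x, side="right")
    idx_end = np.searchsorted(breakpoints, x + inserts, side="left")
    ref_start = x + cum[idx_start]
    apparent = inserts + (cum[idx_end] - cum[idx_start])
    order = np.argsort(ref_start, kind="stable")
    return ref_start[order], apparent[order]


def simulate_read_pairs(
    deletions: Sequence[TrueDeletion],
    cohort: SimCohort,
    contig_length: int = DEFAULT_CONTIG_LENGTH,
    coverage: float = 30.0,
    read_len: int = 150,
    insert_mean: float = 450.0,
    insert_sd: float = 15.0,
    seed: int = 0,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-sample (fwd_start, insert_size) arrays for one contig.

    ``coverage`` is the total diploid coverage; each haplotype contributes
    half.  Deterministic given ``seed``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_mean <= 2 * read_len:
        raise ValueError("insert mean must exceed twice the read length")
    rng = np.random.default_rng(seed)
    del_starts = np.array([d.start for d in deletions], dtype=np.int64)
    del_lengths = np.array([d.length for d in deletions], dtype=np.int64)
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for i, sid in enumerate(cohort.sample_ids):
        chunks = []
        for hap_row in (2 * i, 2 * i + 1):
            chunks.append(
                _haplotype_read_pairs(
                    cohort.haplotypes[hap_row],
                    del_starts,
                    del_lengths,
                    contig_length,
                    coverage / 2.0,
                    read_len,
                    insert_mean,
                    insert_sd,
                    rng,
                )
            )
        starts = np.concatenate([c[0] for c in chunks])
        inserts = np.concatenate([c[1] for c in chunks])
        order = np.argsort(starts, kind="stable")
        out[sid] = (starts[order], inserts[order])
    return out


def simulate_profiles(
    deletions: Sequence[TrueDeletion],
    cohort: SimCohort,
    contig: str = DEFAULT_CONTIG,
    contig_length: int = DEFAULT_CONTIG_LENGTH,
    coverage: float = 30.0,
    read_len: int = 150,
    insert_mean: float = 450.0,
    insert_sd: float = 15.0,
    seed: int = 0,
    config: Optional[RunConfig] = None,
) -> List[SampleProfile]:
    """Simulate read pairs and reduce them to one profile per sample.

    The null insert-size distribution of each profile is estimated from the
    simulated pairs with the same estimator used for real alignments.
    """
    config = config or RunConfig()
    seqdict = [(contig, contig_length)]
    pairs = simulate_read_pairs(
        deletions, cohort, contig_length, coverage, read_len, insert_mean, insert_sd, seed
    )
    profiles = []
    regions = default_sampling_regions(seqdict)
    for sid in cohort.sample_ids:
        starts, inserts = pairs[sid]
        records = (
            ReadPairRecord(0, int(s), int(v)) for s, v in zip(starts, inserts)
        )
        hists = estimate_null_distribution(
            records,
            regions,
            seqdict,
            max_pairs=config.max_sample_pairs,
            min_pairs=min(config.min_sample_pairs, max(1, len(starts) // 10)),
        )
        prof = SampleProfile(
            sample_id=sid,
            sequence_dictionary=seqdict,
            histograms=hists,
            read_len=read_len,
        )
        cap = (
            hists[0].mean
            + config.max_insert_sd_mult * hists[0].stddev
            + config.max_del_length
        )
        keep = inserts <= cap
        prof.add_records(0, starts[keep], inserts[keep])
        profiles.append(prof)
    return profiles


# ---------------------------------------------------------------------------
# truth output and SAM emission
# ---------------------------------------------------------------------------


def write_truth(
    deletions: Sequence[TrueDeletion],
    cohort: SimCohort,
    vcf_path: str,
    bed_path: Optional[str] = None,
    sequence_dictionary: Optional[Sequence[Tuple[str, int]]] = None,
) -> None:
    """Write the simulated truth as a genotyped VCF and a BED of intervals."""
    seqdict = list(sequence_dictionary) if sequence_dictionary else [
        (DEFAULT_CONTIG, DEFAULT_CONTIG_LENGTH)
    ]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    calls = []
    order = np.argsort([d.start for d in deletions], kind="stable")
    for j in order:
        d = deletions[j]
        gts = cohort.genotypes[:, j]
        samples = [SampleCall((0, 0, 0), gt_str[int(g)], 99) for g in gts]
        called = 2 * len(gts)
        af = float(gts.sum()) / called if called else 0.0
        calls.append(
            DeletionCall(
                contig=d.contig, start=d.start, length=d.length, samples=samples, af=af
            )
        )
    write_vcf(calls, cohort.sample_ids, seqdict, vcf_path)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for j in order:
                d = deletions[j]
                fh.write(f"{d.contig}\t{d.start}\t{d.end}\n")


def write_sam(
    sample_id: str,
    starts: np.ndarray,
    inserts: np.ndarray,
    contig: str,
    contig_length: int,
    read_len: int,
    path: str,
) -> None:
    """Render simulated read pairs as a minimal coordinate-sorted SAM file.

    Reads are written as ungapped matches with fixed base qualities; the
    file exercises the alignment-ingestion path of the profiler, not a
    sequence-level simulation.
    """
    recs = []
    seq = "A" * read_len
    qual = "I" * read_len
    for k, (s, ins) in enumerate(zip(starts, inserts)):
        s, ins = int(s), int(ins)
        name = f"{sample_id}.{k}"
        rev_pos = s + ins - read_len
        recs.append((s, f"{name}\t99\t{contig}\t{s + 1}\t60\t{read_len}M\t=\t{rev_pos + 1}\t{ins}\t{seq}\t{qual}\tRG:Z:rg0"))
        recs.append((rev_pos, f"{name}\t147\t{contig}\t{rev_pos + 1}\t60\t{read_len}M\t=\t{s + 1}\t{-ins}\t{seq}\t{qual}\tRG:Z:rg0"))
    recs.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{contig_length}\n")
        fh.write(f"@RG\tID:rg0\tSM:{sample_id}\n")
        for _, line in recs:
            fh.write(line + "\n")
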