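"""Genotype reporting and VCF emission.

Per-sample genotype likelihoods of the windows combined into one call are
averaged in natural-log space, PHRED-scaled and normalised so the best
genotype has likelihood 0.  The genotype is the most likely one (ties give
a missing genotype) and the genotype quality is the gap between the two
smallest PHRED values.  Calls are written as symbolic ``<DEL>`` records in
VCF 4.2 with END/SVLEN/SVTYPE/AF info and GT:PL:GQ per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

LOG10 = math.log(10.0)

GT_STRINGS = ("0/0", "0/1", "1/1")
MISSING_GT = "./."


@dataclass
class SampleCall:
    """Genotype of one sample at one deletion."""

    pl: Tuple[int, int, int]
    gt: str
    gq: int
    genotyped: bool = True


@dataclass
class DeletionCall:
    """One merged deletion with per-sample genotypes.

    ``start`` is 0-based (the first deleted base); the VCF writer converts
    to 1-based POS.
    """

    contig: str
    start: int
    length: int
    samples: List[SampleCall]
    af: float = 0.0
    n_windows: int = 1

    @property
    def end(self) -> int:
        return self.start + self.length

    def interval(self) -> Tuple[str, int, int]:
        return (self.contig, self.start, self.start + self.length)


def phred_and_genotype(
    mean_log_likelihoods: Sequence[float],
) -> Tuple[Tuple[int, int, int], str, int]:
    """PHRED-scale a natural-log likelihood triple and call the genotype.

    Returns ``(PL, GT, GQ)`` with ``min(PL) == 0``; a tie for the best
    genotype yields the missing genotype ``./.``.
    """
    logs = np.asarray(mean_log_likelihoods, dtype=float)
    if not np.all(np.isfinite(logs)):
        raise ValueError("genotype likelihoods must be finite")
    pl = np.rint(-10.0 * (logs - logs.max()) / LOG10).astype(int)
    pl -= pl.min()
    order = np.sort(pl)
    gq = int(order[1] - order[0])
    best = np.flatnonzero(pl == 0)
    gt = GT_STRINGS[int(best[0])] if len(best) == 1 else MISSING_GT
    return (int(pl[0]), int(pl[1]), int(pl[2])), gt, gq


def genotype_skip_rule(
    pair_count: float,
    cohort_median_pairs: float,
    min_pairs: int = 3,
    coverage_mult: float = 4.0,
) -> bool:
    """True when the sample has enough (but not excessive) data to genotype.

    Samples with fewer than ``min_pairs`` read pairs at the locus, or more
    than ``coverage_mult`` times the cohort median (suggesting a collapsed
    repeat or CNV), are reported as ``./.``.
    """
    if pair_count < min_pairs:
        return False
    if cohort_median_pairs > 0 and pair_count > coverage_mult * cohort_median_pairs:
        return False
    return True


def assemble_call(
    contig: str,
    starts: Sequence[float],
    lengths: Sequence[float],
    log_gl_stack: np.ndarray,
    pair_counts: np.ndarray,
    min_pairs: int = 3,
    coverage_mult: float = 4.0,
) -> DeletionCall:
    """Combine the windows of one merge group into a deletion call.

    ``log_gl_stack`` is (n_windows, n_samples, 3) of natural-log genotype
    likelihoods (normalised per sample and window); ``pair_counts`` is
    (n_windows, n_samples).  Start and length are medians over the group,
    genotype likelihoods are means in log space.
    """
    start = int(round(float(np.median(starts))))
    length = int(round(float(np.median(lengths))))
    mean_log = log_gl_stack.mean(axis=0)  # (n_samples, 3)
    counts = np.median(pair_counts, axis=0)
    cohort_median = float(np.median(counts))
    samples: List[SampleCall] = []
    alt = 0
    called = 0
    for s in range(mean_log.shape[0]):
        pl, gt, gq = phred_and_genotype(mean_log[s])
        if not genotype_skip_rule(counts[s], cohort_median, min_pairs, coverage_mult):
            samples.append(SampleCall(pl, MISSING_GT, gq, genotyped=False))
            continue
        samples.append(SampleCall(pl, gt, gq))
        if gt != MISSING_GT:
            called += 2
            alt += gt.count("1")
    af = alt / called if called else 0.0
    return DeletionCall(
        contig=contig,
        start=start,
        length=length,
        samples=samples,
        af=af,
        n_windows=len(starts),
    )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def _build_header(
    sample_ids: Sequence[str], sequence_dictionary: Sequence[Tuple[str, int]]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in sequence_dictionary:
        header.contigs.add(name, length=length)
    header.add_meta("ALT", items=[("ID", "DEL"), ("Description", "Deletion")])
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant (negative for deletions)")
    header.info.add("AF", "A", "Float", "Deletion allele frequency among genotyped samples")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PL", "G", "Integer", "PHRED-scaled genotype likelihoods")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for sid in sample_ids:
        header.add_sample(sid)
    return header


_GT_TUPLES = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1), MISSING_GT: (None, None)}


def write_vcf(
    calls: Sequence[DeletionCall],
    sample_ids: Sequence[str],
    sequence_dictionary: Sequence[Tuple[str, int]],
    path: str,
) -> None:
    """Write calls as a multi-sample VCF 4.2 file (plain text).

    Calls must be sorted by (contig order in the dictionary, start); POS is
    the 1-based position of the first deleted base and END = POS + length.
    """
    order = {name: i for i, (name, _) in enumerate(sequence_dictionary)}
    keys = [(order[c.contig], c.start) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (contig, start) before writing")
    header = _build_header(sample_ids, sequence_dictionary)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for call in calls:
            rec = vf.new_record(
                contig=call.contig,
                start=call.start,
                stop=call.start + call.length + 1,
                alleles=("N", "<DEL>"),
                filter="PASS",
            )
            rec.info["SVTYPE"] = "DEL"
            rec.info["SVLEN"] = -call.length
            rec.info["AF"] = (call.af,)
            for sid, sc in zip(sample_ids, call.samples):
                rec.samples[sid]["GT"] = _GT_TUPLES[sc.gt]
                rec.samples[sid]["PL"] = list(sc.pl)
                rec.samples[sid]["GQ"] = sc.gq
            vf.write(rec)


def read_vcf(path: str) -> Tuple[List[DeletionCall], List[str]]:
    """Read a deletion VCF written by :func:`write_vcf` (or truth files)."""
    calls: List[DeletionCall] = []
    with pysam.VariantFile(path) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            length = abs(int(svlen)) if svlen is not None else rec.rlen
            samples = []
            for sid in sample_ids:
                data = rec.samples[sid]
                gt = data.get("GT")
                if gt is None or any(a is None for a in gt):
                    gt_str = MISSING_GT
                else:
                    gt_str = GT_STRINGS[sum(gt)]
                pl = data.get("PL") or (0, 0, 0)
                gq = data.get("GQ")
                samples.append(
                    SampleCall(
                        tuple(int(p) for p in pl),
                        gt_str,
                        int(gq) if gq is not None else 0,
                        genotyped=gt_str != MISSING_GT,
                    )
                )
            af = rec.info.get("AF", (0.0,))
            af = float(af[0] if isinstance(af, tuple) else af)
            calls.append(
                DeletionCall(
                    contig=rec.contig,
                    start=rec.start,
                    length=length,
                    samples=samples,
                    af=af,
                )
            )
    return calls, sample_ids
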