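"""Per-sample read-pair profiles.

A profile reduces one sample's coordinate-sorted alignment file to the data
the joint caller needs: for every confidently aligned read pair the leftmost
position of the forward read and the clip-extended insert size, plus one
null insert-size histogram per read group and a positional index.  Profiles
are stored in the ``.jdp`` binary format documented in :func:`write_profile`
and are typically 1-3% of the size of the alignments they summarise.

Coordinates are 0-based half-open throughout this package; only the VCF
writer converts to 1-based positions.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from joindel.config import RunConfig

logger = logging.getLogger(__name__)

MAGIC = b"JDPF"
MAGIC_TAIL = b"JDPX"
FORMAT_VERSION = 1
BUCKET_SHIFT = 16  # index granularity: one block per 2^16 bp


@dataclass(frozen=True)
class ReadPairRecord:
    """One confidently aligned read pair.

    ``fwd_start`` is the 0-based leftmost alignment position of the forward
    read; ``insert_size`` is the clip-extended distance to the rightmost
    aligned position of the reverse mate (half-open, so a 300 bp fragment
    gives 300).
    """

    contig_id: int
    fwd_start: int
    insert_size: int
    read_group: int = 0


class InsertSizeHistogram:
    """Null distribution of insert sizes for one read group.

    Parameters
    ----------
    counts:
        Mapping from insert size (bp) to the number of sampled pairs.
    read_group:
        Integer read-group id this histogram belongs to.
    """

    def __init__(self, counts: Dict[int, int], read_group: int = 0):
        if any(c < 0 for c in counts.values()):
            raise ValueError("histogram counts must be non-negative")
        self.counts: Dict[int, int] = {int(k): int(v) for k, v in counts.items() if v > 0}
        self.read_group = read_group

    @classmethod
    def from_insert_sizes(cls, inserts: Iterable[int], read_group: int = 0) -> "InsertSizeHistogram":
        values, counts = np.unique(np.asarray(list(inserts), dtype=np.int64), return_counts=True)
        return cls(dict(zip(values.tolist(), counts.tolist())), read_group)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def mean(self) -> float:
        n = self.total
        if n == 0:
            raise ValueError("empty histogram has no mean")
        return sum(k * v for k, v in self.counts.items()) / n

    @property
    def stddev(self) -> float:
        n = self.total
        mu = self.mean
        var = sum(v * (k - mu) ** 2 for k, v in self.counts.items()) / n
        return float(np.sqrt(var))

    def support(self) -> Tuple[int, int]:
        """Smallest and largest insert size with non-zero count."""
        keys = self.counts.keys()
        return min(keys), max(keys)

    def abs_deviation_percentile(self, q: float) -> float:
        """q-th percentile of |insert - mean| under the null distribution."""
        mu = self.mean
        # weighted percentile over the histogram
        sizes = np.array(sorted(self.counts), dtype=float)
        absdev = np.abs(sizes - mu)
        order = np.argsort(absdev)
        absdev = absdev[order]
        weights = np.array([self.counts[int(s)] for s in sizes[order]], dtype=float)
        cum = np.cumsum(weights) / weights.sum()
        idx = int(np.searchsorted(cum, q / 100.0))
        return float(absdev[min(idx, len(absdev) - 1)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, InsertSizeHistogram)
            and self.counts == other.counts
            and self.read_group == other.read_group
        )

    def __repr__(self) -> str:
        return (
            f"InsertSizeHistogram(rg={self.read_group}, n={self.total}, "
            f"mean={self.mean:.1f}, sd={self.stddev:.1f})"
        )


@dataclass
class SampleProfile:
    """Compact, indexed insert-size profile of one sample.

    Records are stored per contig as parallel numpy arrays sorted by
    ``fwd_start``; :meth:`seek` yields every record at or after a genomic
    position, which is the access pattern of the window sweep.
    """

    sample_id: str
    sequence_dictionary: List[Tuple[str, int]]
    histograms: Dict[int, InsertSizeHistogram]
    read_len: int = 150
    # contig_id -> dict with "start" (int64), "insert" (int32), "rg" (int16)
    records_by_contig: Dict[int, Dict[str, np.ndarray]] = field(default_factory=dict)

    def contig_id(self, name: str) -> int:
        for i, (n, _) in enumerate(self.sequence_dictionary):
            if n == name:
                return i
        raise KeyError(f"contig {name!r} not in sequence dictionary")

    def add_records(self, contig_id: int, starts, inserts, rgs=None) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        inserts = np.asarray(inserts, dtype=np.int32)
        if rgs is None:
            rgs = np.zeros(len(starts), dtype=np.int16)
        rgs = np.asarray(rgs, dtype=np.int16)
        order = np.argsort(starts, kind="stable")
        self.records_by_contig[int(contig_id)] = {
            "start": starts[order],
            "insert": inserts[order],
            "rg": rgs[order],
        }

    @property
    def n_records(self) -> int:
        return sum(len(v["start"]) for v in self.records_by_contig.values())

    def records(self) -> Iterator[ReadPairRecord]:
        """All records in (contig_id, fwd_start) order."""
        for cid in sorted(self.records_by_contig):
            arr = self.records_by_contig[cid]
            for s, i, g in zip(arr["start"], arr["insert"], arr["rg"]):
                yield ReadPairRecord(cid, int(s), int(i), int(g))

    def seek(self, contig: str, pos: int) -> Iterator[ReadPairRecord]:
        """Yield every record on ``contig`` with ``fwd_start >= pos``."""
        cid = self.contig_id(contig)
        arr = self.records_by_contig.get(cid)
        if arr is None:
            return
        lo = int(np.searchsorted(arr["start"], pos, side="left"))
        for s, i, g in zip(arr["start"][lo:], arr["insert"][lo:], arr["rg"][lo:]):
            yield ReadPairRecord(cid, int(s), int(i), int(g))

    def equals(self, other: "SampleProfile") -> bool:
        if (
            self.sample_id != other.sample_id
            or self.sequence_dictionary != other.sequence_dictionary
            or self.read_len != other.read_len
            or self.histograms != other.histograms
            or set(self.records_by_contig) != set(other.records_by_contig)
        ):
            return False
        for cid, arr in self.records_by_contig.items():
            brr = other.records_by_contig[cid]
            for key in ("start", "insert", "rg"):
                if not np.array_equal(arr[key], brr[key]):
                    return False
        return True


# ---------------------------------------------------------------------------
# alignment-record level operations
# ---------------------------------------------------------------------------


def _left_clip(aln: pysam.AlignedSegment) -> int:
    cig = aln.cigartuples
    if cig and cig[0][0] in (4, 5):  # soft / hard clip
        return cig[0][1]
    return 0


def _right_clip(aln: pysam.AlignedSegment) -> int:
    cig = aln.cigartuples
    if cig and cig[-1][0] in (4, 5):
        return cig[-1][1]
    return 0


def compute_insert_size(
    fwd_aln: pysam.AlignedSegment, rev_aln: pysam.AlignedSegment
) -> Optional[int]:
    """Clip-extended insert size of a forward/reverse pair.

    Distance from the leftmost alignment position of the forward read
    (extended by its left clip) to the rightmost alignment position of the
    reverse read (extended by its right clip), half-open.  Returns ``None``
    for pairs on different contigs, in inverted orientation, or with a
    non-positive result; such pairs are filtered, not errors.
    """
    if fwd_aln.is_reverse or not rev_aln.is_reverse:
        return None
    if fwd_aln.reference_id != rev_aln.reference_id:
        return None
    left = fwd_aln.reference_start - _left_clip(fwd_aln)
    right = rev_aln.reference_end + _right_clip(rev_aln)
    insert = right - left
    if insert < 1 or fwd_aln.reference_start > rev_aln.reference_end:
        return None
    return insert


def passes_quality_filters(
    aln: pysam.AlignedSegment,
    config: RunConfig,
    max_insert: Optional[int] = None,
) -> bool:
    """Confident-pair criteria applied to a single alignment record.

    Both mates mapped on the same contig in FR orientation, primary,
    non-duplicate, non-QC-fail, mapping quality at or above the configured
    threshold, and (when ``max_insert`` is known) a template length within
    the cap that bounds the histogram support.
    """
    try:
        if not aln.is_paired or aln.is_unmapped or aln.mate_is_unmapped:
            return False
        if aln.is_secondary or aln.is_supplementary or aln.is_duplicate or aln.is_qcfail:
            return False
        if aln.reference_id != aln.next_reference_id:
            return False
        if aln.is_reverse == aln.mate_is_reverse:
            return False
        # FR orientation: forward mate must not start right of the reverse mate
        if aln.is_reverse:
            if aln.next_reference_start > aln.reference_start:
                return False
        else:
            if aln.reference_start > aln.next_reference_start:
                return False
        if aln.mapping_quality < config.min_mapq:
            return False
        if max_insert is not None and abs(aln.template_length) > max_insert:
            return False
    except (ValueError, AttributeError) as exc:  # unparseable record
        logger.warning("skipping unparseable alignment record: %s", exc)
        return False
    return True


# ---------------------------------------------------------------------------
# null distribution estimation
# ---------------------------------------------------------------------------


def default_sampling_regions(
    sequence_dictionary: Sequence[Tuple[str, int]], fraction: float = 0.6
) -> List[Tuple[str, int, int]]:
    """Middle ``fraction`` of every contig, as 0-based half-open intervals.

    Used when no sampling BED is supplied; the central portion of a contig
    avoids telomeric/assembly-edge artefacts in typical references.
    """
    regions = []
    for name, length in sequence_dictionary:
        margin = int(length * (1.0 - fraction) / 2.0)
        if length - 2 * margin >= 1:
            regions.append((name, margin, length - margin))
    return regions


def estimate_null_distribution(
    pairs: Iterable[ReadPairRecord],
    sampling_regions: Sequence[Tuple[str, int, int]],
    sequence_dictionary: Sequence[Tuple[str, int]],
    max_pairs: int = 100_000,
    min_pairs: int = 1000,
    trim_sd_mult: float = 8.0,
) -> Dict[int, InsertSizeHistogram]:
    """Estimate one null insert-size histogram per read group.

    Pairs whose forward read starts inside a sampling region contribute, up
    to ``max_pairs`` per read group.  Inserts further than ``trim_sd_mult``
    robust standard deviations (1.4826 * MAD) from the median are trimmed
    before the histogram is built, so that pairs spanning deletions inside
    the sampling regions cannot inflate the null distribution.  Raises
    ``ValueError`` when fewer than ``min_pairs`` pairs are available for a
    read group.
    """
    if not sampling_regions:
        raise ValueError("no sampling regions supplied")
    name_to_id = {name: i for i, (name, _) in enumerate(sequence_dictionary)}
    region_ids = set()
    by_contig: Dict[int, List[Tuple[int, int]]] = {}
    for name, start, end in sampling_regions:
        if name not in name_to_id:
            raise ValueError(f"sampling region contig {name!r} not in sequence dictionary")
        by_contig.setdefault(name_to_id[name], []).append((start, end))
        region_ids.add(name_to_id[name])

    inserts: Dict[int, List[int]] = {}
    for rec in pairs:
        ivals = by_contig.get(rec.contig_id)
        if not ivals:
            continue
        if not any(s <= rec.fwd_start < e for s, e in ivals):
            continue
        bucket = inserts.setdefault(rec.read_group, [])
        if len(bucket) < max_pairs:
            bucket.append(rec.insert_size)

    if not inserts:
        raise ValueError("insufficient data for null distribution: no pairs in sampling regions")
    hists = {}
    for rg, vals in inserts.items():
        if len(vals) < min_pairs:
            raise ValueError(
                f"insufficient data for null distribution: read group {rg} has "
                f"{len(vals)} pairs (< {min_pairs})"
            )
        arr = np.asarray(vals, dtype=np.int64)
        med = np.median(arr)
        scale = max(1.4826 * np.median(np.abs(arr - med)), 1.0)
        keep = np.abs(arr - med) <= trim_sd_mult * scale
        hists[rg] = InsertSizeHistogram.from_insert_sizes(arr[keep], read_group=rg)
    return hists


# ---------------------------------------------------------------------------
# profile construction from SAM/BAM
# ---------------------------------------------------------------------------


def profile_from_alignments(
    path: str,
    config: Optional[RunConfig] = None,
    sampling_regions: Optional[Sequence[Tuple[str, int, int]]] = None,
    sample_id: Optional[str] = None,
    region: Optional[Tuple[str, Optional[int], Optional[int]]] = None,
) -> SampleProfile:
    """Build a :class:`SampleProfile` from a coordinate-sorted SAM/BAM file.

    Pairs are matched by query name; the insert size is computed from the
    two mates' clip-extended alignment spans.  After the null distribution
    is estimated, records with insert size above
    ``mean + max_insert_sd_mult * stddev`` of their read group are removed.
    """
    config = config or RunConfig()
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        seqdict = [(name, af.get_reference_length(name)) for name in af.references]
        rg_names = [rg.get("ID", str(i)) for i, rg in enumerate(af.header.to_dict().get("RG", []))]
        rg_ids = {name: i for i, name in enumerate(rg_names)}

        pending: Dict[str, Tuple[bool, int, int]] = {}
        starts: Dict[int, List[int]] = {}
        inserts: Dict[int, List[int]] = {}
        rgs: Dict[int, List[int]] = {}
        read_len = 0
        last_pos: Dict[int, int] = {}

        iterator = af.fetch(*_fetch_args(region)) if (region and af.has_index()) else af
        for aln in iterator:
            if not passes_quality_filters(aln, config):
                continue
            if aln.reference_start < last_pos.get(aln.reference_id, 0):
                raise ValueError(f"input {path!r} is not coordinate-sorted")
            last_pos[aln.reference_id] = aln.reference_start
            read_len = max(read_len, aln.query_length or aln.infer_read_length() or 0)
            key = aln.query_name
            if key in pending:
                other = pending.pop(key)
                fwd, rev = (aln, other) if other.is_reverse else (other, aln)
                size = compute_insert_size(fwd, rev)
                if size is None:
                    continue
                rg = rg_ids.get(_rg_tag(fwd), 0)
                cid = fwd.reference_id
                starts.setdefault(cid, []).append(fwd.reference_start)
                inserts.setdefault(cid, []).append(size)
                rgs.setdefault(cid, []).append(rg)
            else:
                pending[key] = aln

    if sampling_regions is None:
        sampling_regions = default_sampling_regions(seqdict)

    all_records = (
        ReadPairRecord(cid, s, i, g)
        for cid in sorted(starts)
        for s, i, g in zip(starts[cid], inserts[cid], rgs[cid])
    )
    hists = estimate_null_distribution(
        all_records,
        sampling_regions,
        seqdict,
        max_pairs=config.max_sample_pairs,
        min_pairs=config.min_sample_pairs,
    )

    # stored records may exceed the histogram cap by a full deletion length
    caps = {
        rg: h.mean + config.max_insert_sd_mult * h.stddev + config.max_del_length
        for rg, h in hists.items()
    }
    profile = SampleProfile(
        sample_id=sample_id or _infer_sample_id(path),
        sequence_dictionary=seqdict,
        histograms=hists,
        read_len=read_len or 150,
    )
    for cid in sorted(starts):
        s = np.asarray(starts[cid], dtype=np.int64)
        i = np.asarray(inserts[cid], dtype=np.int64)
        g = np.asarray(rgs[cid], dtype=np.int64)
        keep = i <= np.array([caps.get(int(x), np.inf) for x in g])
        if region is not None and region[1] is not None:
            name = seqdict[cid][0]
            if name == region[0]:
                keep &= (s >= region[1]) & (s < (region[2] if region[2] is not None else np.inf))
            else:
                keep &= False
        profile.add_records(cid, s[keep], i[keep], g[keep])
    return profile


def _fetch_args(region):
    contig, start, end = region
    return (contig, start, end)


def _rg_tag(aln: pysam.AlignedSegment) -> str:
    try:
        return aln.get_tag("RG")
    except KeyError:
        return ""


def _infer_sample_id(path: str) -> str:
    import os

    base = os.path.basename(path)
    for suffix in (".bam", ".sam", ".cram"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return base


# ---------------------------------------------------------------------------
# binary profile format (.jdp)
# ---------------------------------------------------------------------------
#
# Layout (all integers little-endian, fixed width):
#   magic "JDPF", u16 version
#   u16 len + utf-8 sample id
#   u32 read length
#   u32 n_contigs; per contig: u16 len + utf-8 name, u64 length
#   u16 n_read_groups; per read group:
#       u16 rg id, f64 mean, f64 stddev, u32 n_bins,
#       bins as n * (u32 insert size, u64 count)
#   record blocks, one per (contig, 2^16 bp bucket) with >=1 record:
#       u32 contig id, u32 bucket, u32 n_records,
#       n * u32 zig-zag delta-encoded fwd_start (first delta vs bucket base),
#       n * u32 insert size, n * u16 read group
#   index: u64 n_entries; per entry u32 contig, u32 bucket, u64 file offset,
#       u32 n_records; then u64 index offset and magic "JDPX"


def _zigzag_encode(deltas: np.ndarray) -> np.ndarray:
    d = deltas.astype(np.int64)
    return ((d << 1) ^ (d >> 63)).astype(np.uint32)


def _zigzag_decode(enc: np.ndarray) -> np.ndarray:
    u = enc.astype(np.uint64)
    return ((u >> np.uint64(1)).astype(np.int64)) ^ -(u & np.uint64(1)).astype(np.int64)


def write_profile(profile: SampleProfile, path: str) -> None:
    """Serialise a profile to the ``.jdp`` binary format (see module notes)."""
    index: List[Tuple[int, int, int, int]] = []
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<H", FORMAT_VERSION))
        sid = profile.sample_id.encode()
        fh.write(struct.pack("<H", len(sid)) + sid)
        fh.write(struct.pack("<I", profile.read_len))
        fh.write(struct.pack("<I", len(profile.sequence_dictionary)))
        for name, length in profile.sequence_dictionary:
            nm = name.encode()
            fh.write(struct.pack("<H", len(nm)) + nm)
            fh.write(struct.pack("<Q", length))
        fh.write(struct.pack("<H", len(profile.histograms)))
        for rg in sorted(profile.histograms):
            hist = profile.histograms[rg]
            fh.write(struct.pack("<Hdd I", rg, hist.mean, hist.stddev, len(hist.counts)))
            for size in sorted(hist.counts):
                fh.write(struct.pack("<IQ", size, hist.counts[size]))
        for cid in sorted(profile.records_by_contig):
            arr = profile.records_by_contig[cid]
            starts = arr["start"]
            buckets = (starts >> BUCKET_SHIFT).astype(np.int64)
            for bucket in np.unique(buckets):
                sel = buckets == bucket
                bs = starts[sel]
                offset = fh.tell()
                index.append((int(cid), int(bucket), offset, int(sel.sum())))
                fh.write(struct.pack("<III", cid, int(bucket), int(sel.sum())))
                base = int(bucket) << BUCKET_SHIFT
                deltas = np.diff(bs, prepend=base)
                fh.write(_zigzag_encode(deltas).tobytes())
                fh.write(arr["insert"][sel].astype("<u4").tobytes())
                fh.write(arr["rg"][sel].astype("<u2").tobytes())
        index_offset = fh.tell()
        fh.write(struct.pack("<Q", len(index)))
        for cid, bucket, offset, n in index:
            fh.write(struct.pack("<IIQI", cid, bucket, offset, n))
        fh.write(struct.pack("<Q", index_offset))
        fh.write(MAGIC_TAIL)


def read_profile(path: str) -> SampleProfile:
    """Read a ``.jdp`` profile; lossless inverse of :func:`write_profile`."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 18 or data[:4] != MAGIC:
        raise ValueError(f"{path!r} is not a profile file (bad magic)")
    if data[-4:] != MAGIC_TAIL:
        raise ValueError(f"profile {path!r} is truncated (missing tail magic)")
    (version,) = struct.unpack_from("<H", data, 4)
    if version != FORMAT_VERSION:
        raise ValueError(
            f"profile version mismatch: expected {FORMAT_VERSION}, found {version}"
        )
    off = 6
    (slen,) = struct.unpack_from("<H", data, off)
    off += 2
    sample_id = data[off : off + slen].decode()
    off += slen
    (read_len,) = struct.unpack_from("<I", data, off)
    off += 4
    (n_contigs,) = struct.unpack_from("<I", data, off)
    off += 4
    seqdict = []
    for _ in range(n_contigs):
        (nlen,) = struct.unpack_from("<H", data, off)
        off += 2
        name = data[off : off + nlen].decode()
        off += nlen
        (length,) = struct.unpack_from("<Q", data, off)
        off += 8
        seqdict.append((name, length))
    (n_rg,) = struct.unpack_from("<H", data, off)
    off += 2
    hists = {}
    for _ in range(n_rg):
        rg, mean, stddev, nbins = struct.unpack_from("<Hdd I", data, off)
        off += struct.calcsize("<Hdd I")
        counts = {}
        for _ in range(nbins):
            size, count = struct.unpack_from("<IQ", data, off)
            off += 12
            counts[size] = count
        hists[rg] = InsertSizeHistogram(counts, read_group=rg)

    (index_offset,) = struct.unpack_from("<Q", data, len(data) - 12)
    (n_entries,) = struct.unpack_from("<Q", data, index_offset)
    entries = []
    pos = index_offset + 8
    for _ in range(n_entries):
        cid, bucket, boff, n = struct.unpack_from("<IIQI", data, pos)
        pos += struct.calcsize("<IIQI")
        entries.append((cid, bucket, boff, n))

    per_contig: Dict[int, List[Tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for cid, bucket, boff, n in entries:
        cid2, bucket2, n2 = struct.unpack_from("<III", data, boff)
        if (cid2, bucket2, n2) != (cid, bucket, n):
            raise ValueError(f"profile {path!r} is corrupt: block/index mismatch")
        p = boff + 12
        enc = np.frombuffer(data, dtype="<u4", count=n, offset=p)
        p += 4 * n
        ins = np.frombuffer(data, dtype="<u4", count=n, offset=p)
        p += 4 * n
        rg = np.frombuffer(data, dtype="<u2", count=n, offset=p)
        base = bucket << BUCKET_SHIFT
        starts = base + np.cumsum(_zigzag_decode(enc))
        per_contig.setdefault(cid, []).append((starts, ins, rg))

    profile = SampleProfile(
        sample_id=sample_id,
        sequence_dictionary=seqdict,
        histograms=hists,
        read_len=read_len,
    )
    for cid, chunks in per_contig.items():
        starts = np.concatenate([c[0] for c in chunks])
        ins = np.concatenate([c[1] for c in chunks]).astype(np.int32)
        rg = np.concatenate([c[2] for c in chunks]).astype(np.int16)
        profile.add_records(cid, starts, ins, rg)
    return profile
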