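"""Toy ungapped read mapper, the study's read filters, duplicate removal and
compartment statistics.

The mapper is a deterministic seed-and-extend scheme: every exact k-mer seed
hit (default k=13) is extended ungapped in both directions, a candidate is
accepted when its mismatch count is at most ceil(max_mismatch_frac * L), and
a read is placed with MQ 37 only when a single candidate attains the best
score (ties -> MQ 0).  This is deliberately not an emulation of a
production short-read aligner; it exists
so the pipeline's MQ >= 30 gate, the length-cutoff exploration and the
spurious-alignment simulation are exactly reproducible in-repo.

Coordinates are 0-based half-open internally; SAM I/O converts to 1-based.
Reverse-strand reads are stored as sequenced; comparisons against the
reference use the reverse-complemented reference slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from ._util import decode, decode_flat, encode, flatten, gather_segments, segment_ids
from .simulate import DECOY, MITO, NUCLEAR, ReadSet, ReferenceSet

MAPQ_UNIQUE = 37


@dataclass
class AlignedRead:
    """One placed read; interval length equals read length (ungapped)."""

    read_id: str
    chromosome: str
    start: int          # 0-based inclusive
    end: int            # exclusive
    strand: str         # '+' or '-'
    mapq: int           # 0 or 37
    sequence: str       # as sequenced (5'->3' of the read)
    qualities: str
    n_mismatch: int


@dataclass(frozen=True)
class ReadFilter:
    min_length: int = 25
    min_mapq: int = 30
    min_baseq: int = 30

    def __post_init__(self):
        if min(self.min_length, self.min_mapq, self.min_baseq) < 0:
            raise ValueError("filter thresholds must be >= 0")


class Alignments:
    """Columnar alignment container (struct of arrays).

    All pipeline operations work on this container natively; ``records()``
    and ``from_records()`` bridge to per-read :class:`AlignedRead` objects
    for hand-built fixtures.
    """

    def __init__(self, ids, chrom_ids, starts, strands, mapq, flat, offsets,
                 chrom_names, n_mismatch=None, qualities=None):
        self.ids = list(ids)
        self.chrom_ids = np.asarray(chrom_ids, dtype=np.int32)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=np.int8)  # 0:'+', 1:'-'
        self.mapq = np.asarray(mapq, dtype=np.int16)
        self.flat = np.asarray(flat, dtype=np.uint8)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = self.offsets[1:] - self.offsets[:-1]
        self.ends = self.starts + self.lengths
        self.chrom_names = list(chrom_names)
        self.n_mismatch = (np.full(len(self.ids), -1, dtype=np.int32)
                           if n_mismatch is None else np.asarray(n_mismatch, dtype=np.int32))
        # per-read quality strings; None means constant Q37
        self.qualities = qualities

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, i: int) -> str:
        return decode(self.flat[self.offsets[i]:self.offsets[i + 1]])

    def quality(self, i: int) -> str:
        if self.qualities is None:
            return "F" * int(self.lengths[i])
        return self.qualities[i]

    def baseq(self, i: int) -> np.ndarray:
        if self.qualities is None:
            return np.full(int(self.lengths[i]), 37, dtype=np.int16)
        return np.frombuffer(self.qualities[i].encode(), dtype=np.uint8).astype(np.int16) - 33

    def subset(self, indices) -> "Alignments":
        idx = np.asarray(indices, dtype=np.int64)
        flat, offsets = gather_segments(self.flat, self.offsets, idx)
        quals = None if self.qualities is None else [self.qualities[i] for i in idx]
        return Alignments([self.ids[i] for i in idx], self.chrom_ids[idx], self.starts[idx],
                          self.strands[idx], self.mapq[idx], flat, offsets, self.chrom_names,
                          self.n_mismatch[idx], quals)

    def records(self) -> list[AlignedRead]:
        seqs = decode_flat(self.flat, self.offsets)
        return [
            AlignedRead(self.ids[i], self.chrom_names[self.chrom_ids[i]], int(self.starts[i]),
                        int(self.ends[i]), "-" if self.strands[i] else "+", int(self.mapq[i]),
                        seqs[i], self.quality(i), int(self.n_mismatch[i]))
            for i in range(len(self))
        ]

    @classmethod
    def from_records(cls, records: list[AlignedRead], chrom_names: list[str] | None = None) -> "Alignments":
        if chrom_names is None:
            chrom_names = sorted({r.chromosome for r in records})
        lookup = {nm: i for i, nm in enumerate(chrom_names)}
        flat, offsets, _ = flatten([r.sequence for r in records])
        quals = [r.qualities for r in records]
        if all(set(q) <= {"F"} for q in quals):
            quals = None
        return cls([r.read_id for r in records], [lookup[r.chromosome] for r in records],
                   [r.start for r in records], [1 if r.strand == "-" else 0 for r in records],
                   [r.mapq for r in records], flat, offsets, chrom_names,
                   [r.n_mismatch for r in records], quals)


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(window codes base-4, validity mask) for all k-windows of a code array
    that may contain sentinel values >= 4."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(np.minimum(c, 3), k)
    vals = win @ powers
    bad = np.cumsum(np.concatenate([[0], (codes >= 4).astype(np.int64)]))
    valid = (bad[k:] - bad[:-k]) == 0
    return vals, valid


class _TargetIndex:
    """Concatenated target genome with a sorted k-mer index."""

    def __init__(self, ref: ReferenceSet, k: int, compartments: tuple[str, ...]):
        names = [n for n in ref.names if ref.compartments[n] in compartments]
        if not names:
            raise ValueError("empty reference for requested target compartments")
        self.k = k
        self.names = names
        parts, chrom_id_parts, offsets = [], [], []
        pos = 0
        sep = np.full(k, 4, dtype=np.uint8)
        for i, nm in enumerate(names):
            codes = ref.codes(nm)
            offsets.append(pos)
            parts.append(codes)
            chrom_id_parts.append(np.full(codes.size, i, dtype=np.int32))
            pos += codes.size
            if i < len(names) - 1:
                parts.append(sep)
                chrom_id_parts.append(np.full(k, -1, dtype=np.int32))
                pos += k
        self.genome = np.concatenate(parts)
        self.chrom_id = np.concatenate(chrom_id_parts)
        self.chrom_offset = np.array(offsets, dtype=np.int64)
        vals, valid = _window_codes(self.genome, k)
        self.positions = np.flatnonzero(valid).astype(np.int64)
        codes = vals[self.positions]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = self.positions[order]


def map_reads(reads, ref: ReferenceSet, max_mismatch_frac: float = 0.06,
              seed_k: int = 13,
              target_compartments: tuple[str, ...] = (NUCLEAR, MITO),
              chunk_reads: int = 200_000) -> Alignments:
    """Map a ReadSet (or list of (id, seq)) against the target compartments.

    Returns placed reads only: unique best-score candidates get MQ 37,
    ambiguous best scores MQ 0 (placed at the lowest-coordinate candidate);
    reads without an acceptable candidate are dropped.  Deterministic.
    """
    if not isinstance(reads, ReadSet):
        ids = [r[0] for r in reads]
        reads = ReadSet.from_sequences([r[1] for r in reads], ids=ids)
    index = _TargetIndex(ref, seed_k, target_compartments)

    chunks = []
    n = len(reads)
    for lo in range(0, n, chunk_reads):
        hi = min(n, lo + chunk_reads)
        res = _map_chunk(reads, lo, hi, index, seed_k, max_mismatch_frac)
        if res is not None:
            chunks.append(res)

    if not chunks:
        return Alignments([], [], [], [], [], np.empty(0, np.uint8),
                          np.zeros(1, np.int64), index.names)
    ridx = np.concatenate([c[0] for c in chunks])
    chrom = np.concatenate([c[1] for c in chunks])
    start = np.concatenate([c[2] for c in chunks])
    strand = np.concatenate([c[3] for c in chunks])
    mapq = np.concatenate([c[4] for c in chunks])
    mism = np.concatenate([c[5] for c in chunks])
    flat, offsets = gather_segments(reads.flat, reads.offsets, ridx)
    ids = [reads.ids[i] for i in ridx]
    return Alignments(ids, chrom, start, strand, mapq, flat, offsets, index.names, mism)


def _map_chunk(reads: ReadSet, lo: int, hi: int, index: _TargetIndex, k: int,
               maxmm: float):
    off0 = int(reads.offsets[lo])
    flat = reads.flat[off0:int(reads.offsets[hi])]
    offsets = reads.offsets[lo:hi + 1] - off0
    lengths = offsets[1:] - offsets[:-1]

    ids_pos = segment_ids(offsets)
    within = np.arange(flat.size, dtype=np.int64) - offsets[ids_pos]
    rc_flat = _revcomp_flat(flat, offsets, ids_pos, within, lengths)

    cand_read, cand_start, cand_strand = [], [], []
    for strand, arr in ((0, flat), (1, rc_flat)):
        vals, _ = _window_codes(arr, k)
        if vals.size == 0:
            continue
        wid = ids_pos[:vals.size]
        woff = within[:vals.size]
        ok = woff <= lengths[wid] - k
        qvals, qid, qoff = vals[ok], wid[ok], woff[ok]
        left = np.searchsorted(index.sorted_codes, qvals, side="left")
        right = np.searchsorted(index.sorted_codes, qvals, side="right")
        counts = right - left
        hit_q = np.flatnonzero(counts)
        if hit_q.size == 0:
            continue
        reps = counts[hit_q]
        flat_hits = _gather_ranges(index.sorted_pos, left[hit_q], right[hit_q])
        rq = np.repeat(hit_q, reps)
        starts = flat_hits - qoff[rq]
        cand_read.append(qid[rq])
        cand_start.append(starts)
        cand_strand.append(np.full(starts.size, strand, dtype=np.int8))

    if not cand_read:
        return None
    cr = np.concatenate(cand_read)
    cs = np.concatenate(cand_start)
    cstrand = np.concatenate(cand_strand).astype(np.int64)

    # dedupe candidates, keep in-bounds single-chromosome placements
    key = (cr * 2 + cstrand) * (index.genome.size + 1) + (cs + 1)
    _, uniq_idx = np.unique(key, return_index=True)
    cr, cs, cstrand = cr[uniq_idx], cs[uniq_idx], cstrand[uniq_idx]
    L = lengths[cr]
    inb = (cs >= 0) & (cs + L <= index.genome.size)
    cr, cs, cstrand, L = cr[inb], cs[inb], cstrand[inb], L[inb]
    same = (index.chrom_id[cs] >= 0) & (index.chrom_id[cs + L - 1] == index.chrom_id[cs])
    cr, cs, cstrand, L = cr[same], cs[same], cstrand[same], L[same]
    if cr.size == 0:
        return None

    # verify candidates (count mismatches) per length group
    mism = np.empty(cr.size, dtype=np.int32)
    for length in np.unique(L):
        sel = np.flatnonzero(L == length)
        span = np.arange(length)
        refmat = index.genome[cs[sel][:, None] + span]
        read_off = offsets[cr[sel]]
        minus = cstrand[sel].astype(bool)
        src = np.empty((sel.size, length), dtype=np.uint8)
        if (~minus).any():
            src[~minus] = flat[read_off[~minus][:, None] + span]
        if minus.any():
            src[minus] = rc_flat[read_off[minus][:, None] + span]
        mism[sel] = (refmat != src).sum(axis=1).astype(np.int32)

    allowed = np.ceil(maxmm * L).astype(np.int32)
    ok = mism <= allowed
    cr, cs, cstrand, mism = cr[ok], cs[ok], cstrand[ok], mism[ok]
    if cr.size == 0:
        return None

    # per read: best score wins; ties -> MQ 0 at lowest (mism, strand, start)
    order = np.lexsort((cs, cstrand, mism, cr))
    cr, cs, cstrand, mism = cr[order], cs[order], cstrand[order], mism[order]
    first = np.concatenate([[True], cr[1:] != cr[:-1]])
    first_idx = np.flatnonzero(first)
    best_mism = mism[first_idx]
    group_of = np.cumsum(first) - 1
    n_best = np.zeros(first_idx.size, dtype=np.int64)
    np.add.at(n_best, group_of, (mism == best_mism[group_of]).astype(np.int64))
    mapq = np.where(n_best == 1, MAPQ_UNIQUE, 0).astype(np.int16)

    chrom = index.chrom_id[cs[first_idx]]
    local = cs[first_idx] - index.chrom_offset[chrom]
    return (cr[first_idx] + lo, chrom, local, cstrand[first_idx].astype(np.int8),
            mapq, mism[first_idx])


def _gather_ranges(arr: np.ndarray, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    counts = right - left
    total = int(counts.sum())
    out = np.empty(total, dtype=arr.dtype)
    idx = np.repeat(left + counts - np.cumsum(counts), counts) + np.arange(total)
    # idx reconstructs concatenated ranges: left_i + (position within range)
    np.take(arr, idx, out=out)
    return out


def _revcomp_flat(flat, offsets, ids_pos, within, lengths) -> np.ndarray:
    idx = offsets[ids_pos] + (lengths[ids_pos] - 1 - within)
    return (3 - flat[idx]).astype(np.uint8)


def mapping_acceptance_probability(lengths, degradation=None, gc: float = 0.41,
                                   max_mismatch_frac: float = 0.06,
                                   eps: float = 0.001) -> np.ndarray:
    """P(read of each length passes the mapper's mismatch cap), Poisson model.

    A read is accepted when its mismatch count against the true locus is at
    most ceil(max_mismatch_frac * L).  Mismatches arise from deamination
    (for damaged molecules, via the degradation curve at reference-C
    positions, C fraction gc/2) and from flat sequencing error; their count
    is approximated as Poisson with the summed per-position rates.  With
    ``degradation=None`` the error-only (contaminant) process is used.
    Ambiguous-placement losses are not modelled (negligible and common to
    both components).
    """
    from scipy.stats import poisson

    lengths = np.atleast_1d(np.asarray(lengths, dtype=np.int64))
    p_c = gc / 2.0
    out = np.empty(lengths.size)
    for j, L in enumerate(lengths):
        L = int(L)
        if degradation is not None:
            i = np.arange(1, L + 1, dtype=float)
            d = degradation.rate(i, float(L))
            e = degradation.eps
            # reference-C position: observed non-C w.p. 1-(1-d)(1-e)-d*e/3
            m_c = 1.0 - (1.0 - d) * (1.0 - e) - d * e / 3.0
            lam = float(p_c * m_c.sum() + (1.0 - p_c) * e * L)
        else:
            lam = eps * L
        allowed = int(np.ceil(max_mismatch_frac * L))
        out[j] = poisson.cdf(allowed, lam)
    return out


def alignments_from_truth(reads: ReadSet, truth: pd.DataFrame, ref: ReferenceSet,
                          sources: tuple[str, ...] | None = None) -> Alignments:
    """Place simulated reads at their true coordinates (MQ 37), optionally
    restricted to the given truth sources.  Used to study profiling and
    estimation behaviour independent of mapper noise."""
    t = truth
    keep = np.ones(len(t), dtype=bool)
    if sources is not None:
        keep &= t["source"].isin(sources).to_numpy()
    keep &= t["compartment"].isin([NUCLEAR, MITO]).to_numpy()
    idx = np.flatnonzero(keep)
    sub = reads.subset(idx)
    chrom_names = [n for n in ref.names if ref.compartments[n] != DECOY]
    lookup = {nm: i for i, nm in enumerate(chrom_names)}
    chrom_ids = np.array([lookup[c] for c in t["chromosome"].to_numpy()[idx]], dtype=np.int32)
    strands = (t["strand"].to_numpy()[idx] == "-").astype(np.int8)
    return Alignments(sub.ids, chrom_ids, t["start"].to_numpy()[idx], strands,
                      np.full(idx.size, MAPQ_UNIQUE), sub.flat, sub.offsets, chrom_names)


# ---------------------------------------------------------------------------
# Filters, dedup, compartment stats
# ---------------------------------------------------------------------------

def filter_reads(alignments: Alignments, f: ReadFilter) -> Alignments:
    """Keep reads with length >= min_length and MQ >= min_mapq; order kept."""
    keep = (alignments.lengths >= f.min_length) & (alignments.mapq >= f.min_mapq)
    return alignments.subset(np.flatnonzero(keep))


def dedup(alignments: Alignments) -> Alignments:
    """Among reads sharing (chromosome, start, end, strand) keep the first."""
    if len(alignments) == 0:
        return alignments
    key = pd.DataFrame({
        "c": alignments.chrom_ids, "s": alignments.starts,
        "e": alignments.ends, "st": alignments.strands,
    })
    keep = ~key.duplicated(keep="first").to_numpy()
    return alignments.subset(np.flatnonzero(keep))


@dataclass(frozen=True)
class CompartmentStats:
    n_mito: int
    n_nuclear: int
    mt_nuc_ratio: float
    undefined: bool  # True when no nuclear reads


def compartment_stats(alignments: Alignments, ref: ReferenceSet) -> CompartmentStats:
    """Coverage-normalised mt/nuc read ratio:
    (n_mito / mito length) / (n_nuclear / nuclear length)."""
    comp_of = np.array([0 if ref.compartments[nm] == NUCLEAR else 1 if ref.compartments[nm] == MITO else 2
                        for nm in alignments.chrom_names])
    comp = comp_of[alignments.chrom_ids]
    n_nuc = int((comp == 0).sum())
    n_mito = int((comp == 1).sum())
    if n_nuc == 0:
        return CompartmentStats(n_mito, 0, float("nan"), True)
    if n_mito == 0:
        return CompartmentStats(0, n_nuc, 0.0, False)
    ratio = (n_mito / ref.compartment_length(MITO)) / (n_nuc / ref.compartment_length(NUCLEAR))
    return CompartmentStats(n_mito, n_nuc, float(ratio), False)


# ---------------------------------------------------------------------------
# SAM I/O (plain text; FLAG bits 4/16, ungapped CIGAR)
# ---------------------------------------------------------------------------

def write_sam(alignments: Alignments, ref: ReferenceSet, path) -> None:
    header = pysam.AlignmentHeader.from_references(
        list(alignments.chrom_names), [ref.length(nm) for nm in alignments.chrom_names])
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i in range(len(alignments)):
            a = pysam.AlignedSegment(header)
            a.query_name = alignments.ids[i]
            minus = bool(alignments.strands[i])
            a.flag = 16 if minus else 0
            a.reference_id = int(alignments.chrom_ids[i])
            a.reference_start = int(alignments.starts[i])
            a.mapping_quality = int(alignments.mapq[i])
            L = int(alignments.lengths[i])
            a.cigarstring = f"{L}M"
            seq = alignments.sequence(i)
            qual = alignments.quality(i)
            if minus:  # SAM stores reference-orientation sequence
                seq = decode(3 - encode(seq)[::-1])
                qual = qual[::-1]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual)
            fh.write(a)


def read_sam(path, ref: ReferenceSet | None = None) -> tuple[Alignments, int]:
    """Read a SAM file into an Alignments container.

    Soft-clips are trimmed; reads with any other non-M CIGAR operation are
    skipped and counted (second return value), as the container is ungapped.
    """
    skipped = 0
    recs: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        chrom_names = list(fh.references)
        for a in fh:
            if a.is_unmapped:
                continue
            cig = a.cigartuples or []
            core = [(op, ln) for op, ln in cig if op != 4]  # drop soft clips
            if any(op != 0 for op, _ in core):
                skipped += 1
                continue
            seq = a.query_alignment_sequence
            qual = a.query_alignment_qualities
            qual_str = "".join(chr(q + 33) for q in qual) if qual is not None else "F" * len(seq)
            if a.is_reverse:  # back to as-sequenced orientation
                seq = decode(3 - encode(seq)[::-1])
                qual_str = qual_str[::-1]
            recs.append(AlignedRead(a.query_name, a.reference_name, a.reference_start,
                                    a.reference_start + len(seq), "-" if a.is_reverse else "+",
                                    a.mapping_quality, seq, qual_str,
                                    int(a.get_tag("NM")) if a.has_tag("NM") else -1))
    if not recs:
        empty = Alignments([], [], [], [], [], np.empty(0, np.uint8),
                           np.zeros(1, np.int64), chrom_names)
        return empty, skipped
    return Alignments.from_records(recs, chrom_names=chrom_names), skipped
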