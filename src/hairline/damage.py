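"""Position-specific substitution spectra and read-length statistics.

For every aligned read the reference slice is oriented to the read (minus
strand reads compare against the reverse-complemented reference), then
reference-C positions are tallied from the 5' end and from the 3' end:
C opportunities and observed C->T events, position by position.  The G->A
channel is tallied the same way; for a single-stranded library it stays at
the sequencing-error floor, which is itself a diagnostic of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import Alignments
from .simulate import MITO, NUCLEAR, ReferenceSet
from ._util import segment_ids


@dataclass
class DamageProfile:
    """Per-position substitution tallies from both read ends.

    ``rate[i] = count[i] / opportunities[i]`` (0 where no opportunities).
    Reads shorter than 2P contribute positions to both end tallies; the
    number of such reads is reported in ``n_overlap_reads``.
    """

    positions: int
    ct5_opportunities: np.ndarray
    ct5_count: np.ndarray
    ct3_opportunities: np.ndarray
    ct3_count: np.ndarray
    ga5_opportunities: np.ndarray
    ga5_count: np.ndarray
    ga3_opportunities: np.ndarray
    ga3_count: np.ndarray
    n_reads: int
    n_overlap_reads: int = 0
    empty: bool = False

    @staticmethod
    def _rate(count, opp):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(opp > 0, count / np.maximum(opp, 1), 0.0)
        return r

    @property
    def ct5_rate(self) -> np.ndarray:
        return self._rate(self.ct5_count, self.ct5_opportunities)

    @property
    def ct3_rate(self) -> np.ndarray:
        return self._rate(self.ct3_count, self.ct3_opportunities)

    @property
    def ga5_rate(self) -> np.ndarray:
        return self._rate(self.ga5_count, self.ga5_opportunities)

    @property
    def ga3_rate(self) -> np.ndarray:
        return self._rate(self.ga3_count, self.ga3_opportunities)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(5' table, 3' table) with columns position/opportunities/count/rate."""
        p = np.arange(1, self.positions + 1)
        five = pd.DataFrame({"position": p, "opportunities": self.ct5_opportunities,
                             "count": self.ct5_count, "rate": self.ct5_rate,
                             "ga_opportunities": self.ga5_opportunities,
                             "ga_count": self.ga5_count, "ga_rate": self.ga5_rate})
        three = pd.DataFrame({"position": p, "opportunities": self.ct3_opportunities,
                              "count": self.ct3_count, "rate": self.ct3_rate,
                              "ga_opportunities": self.ga3_opportunities,
                              "ga_count": self.ga3_count, "ga_rate": self.ga3_rate})
        return five, three


def _oriented_reference_flat(alignments: Alignments, ref: ReferenceSet) -> np.ndarray:
    """Reference slice per read, oriented 5'->3' of the read, flattened to
    match ``alignments.flat``."""
    name_to_codes = {i: ref.codes(nm) for i, nm in enumerate(alignments.chrom_names)}
    genome_parts = []
    chrom_global_off = {}
    pos = 0
    for i in range(len(alignments.chrom_names)):
        chrom_global_off[i] = pos
        genome_parts.append(name_to_codes[i])
        pos += name_to_codes[i].size
    genome = np.concatenate(genome_parts) if genome_parts else np.empty(0, np.uint8)

    offsets = alignments.offsets
    ids = segment_ids(offsets)
    within = np.arange(int(offsets[-1]), dtype=np.int64) - offsets[ids]
    goff = np.array([chrom_global_off[c] for c in alignments.chrom_ids], dtype=np.int64)
    abs_start = goff + alignments.starts
    minus = alignments.strands.astype(bool)[ids]
    lengths = alignments.lengths[ids]
    pos_idx = np.where(minus, abs_start[ids] + lengths - 1 - within, abs_start[ids] + within)
    out = genome[pos_idx]
    return np.where(minus, 3 - out, out).astype(np.uint8)


def substitution_profile(alignments: Alignments, ref: ReferenceSet, positions: int = 25) -> DamageProfile:
    """Tally C->T and G->A rates for the first ``positions`` bases from each
    read end (read orientation, reference-defined opportunities)."""
    if positions < 1:
        raise ValueError("positions must be >= 1")
    P = positions
    n = len(alignments)
    zeros = lambda: np.zeros(P, dtype=np.int64)  # noqa: E731
    if n == 0:
        return DamageProfile(P, zeros(), zeros(), zeros(), zeros(),
                             zeros(), zeros(), zeros(), zeros(), 0, empty=True)
    for i, nm in enumerate(alignments.chrom_names):
        if nm not in ref:
            raise KeyError(f"alignment chromosome {nm!r} not in reference")
    ends_ok = alignments.ends <= np.array([ref.length(nm) for nm in alignments.chrom_names])[alignments.chrom_ids]
    if not ends_ok.all() or (alignments.starts < 0).any():
        raise ValueError("alignment interval outside reference bounds")

    refflat = _oriented_reference_flat(alignments, ref)
    readflat = alignments.flat
    offsets = alignments.offsets
    ids = segment_ids(offsets)
    within = np.arange(int(offsets[-1]), dtype=np.int64) - offsets[ids]
    lengths = alignments.lengths[ids]
    from3 = lengths - 1 - within

    def tally(ref_base, read_base):
        is_opp = refflat == ref_base
        is_hit = is_opp & (readflat == read_base)
        m5 = within < P
        m3 = from3 < P
        opp5 = np.bincount(within[is_opp & m5], minlength=P)
        hit5 = np.bincount(within[is_hit & m5], minlength=P)
        opp3 = np.bincount(from3[is_opp & m3], minlength=P)
        hit3 = np.bincount(from3[is_hit & m3], minlength=P)
        return opp5, hit5, opp3, hit3

    ct = tally(1, 3)  # C -> T
    ga = tally(2, 0)  # G -> A
    n_overlap = int((alignments.lengths < 2 * P).sum())
    return DamageProfile(P, ct[0], ct[1], ct[2], ct[3], ga[0], ga[1], ga[2], ga[3],
                         n_reads=n, n_overlap_reads=n_overlap)


@dataclass
class LengthStats:
    histogram: pd.Series   # index: length, value: count
    median: int            # lower middle order statistic for even n
    mean: float
    n: int


def length_stats(alignments: Alignments) -> LengthStats:
    if len(alignments) == 0:
        raise ValueError("length_stats of empty alignment set")
    lengths = np.sort(alignments.lengths)
    median = int(lengths[(lengths.size - 1) // 2])
    vals, counts = np.unique(lengths, return_counts=True)
    hist = pd.Series(counts, index=vals, name="count")
    return LengthStats(hist, median, float(lengths.mean()), int(lengths.size))


@dataclass
class CompartmentComparison:
    nuclear: DamageProfile
    mito: DamageProfile
    rate_difference: pd.DataFrame  # per position, nuclear minus mito, both ends
    median_length: dict[str, int | None]


def compare_compartments(alignments: Alignments, ref: ReferenceSet,
                         positions: int = 25) -> CompartmentComparison:
    """Damage profiles and length medians per compartment on identical
    settings.  A compartment without reads yields an explicitly flagged
    empty profile rather than silent zeros."""
    comp_of = np.array([0 if ref.compartments[nm] == NUCLEAR
                        else 1 if ref.compartments[nm] == MITO else 2
                        for nm in alignments.chrom_names])
    comp = comp_of[alignments.chrom_ids] if len(alignments) else np.empty(0, dtype=int)
    profiles = {}
    medians: dict[str, int | None] = {}
    for code, name in ((0, NUCLEAR), (1, MITO)):
        sub = alignments.subset(np.flatnonzero(comp == code))
        profiles[name] = substitution_profile(sub, ref, positions)
        medians[name] = length_stats(sub).median if len(sub) else None
    nuc, mito = profiles[NUCLEAR], profiles[MITO]
    diff = pd.DataFrame({
        "position": np.arange(1, positions + 1),
        "ct5_nuclear": nuc.ct5_rate, "ct5_mito": mito.ct5_rate,
        "ct5_diff": nuc.ct5_rate - mito.ct5_rate,
        "ct3_nuclear": nuc.ct3_rate, "ct3_mito": mito.ct3_rate,
        "ct3_diff": nuc.ct3_rate - mito.ct3_rate,
    })
    return CompartmentComparison(nuc, mito, diff, medians)
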