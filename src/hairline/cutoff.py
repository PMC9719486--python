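"""Read-length cutoff exploration: spurious-alignment simulation, per-cutoff
pipeline statistics, and the dual-threshold safe-cutoff rule.

Ultra-short reads trade mapping specificity against yield: lowering the
length cutoff admits more authentic molecules but also more spurious
placements of non-target (environmental) fragments, while raising it
enriches long modern contaminants.  ``cutoff_report`` tabulates both sides
per candidate cutoff; ``choose_cutoff`` returns the smallest cutoff whose
contamination upper bound and spurious-alignment fraction both clear their
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import align as al
from .align import Alignments, ReadFilter
from .contam import ContaminationModel, estimate_contamination
from .damage import length_stats, substitution_profile
from .simulate import DECOY, MITO, NUCLEAR, ReadSet, ReferenceSet


@dataclass(frozen=True)
class MapperParams:
    max_mismatch_frac: float = 0.06
    seed_k: int = 13


def spurious_rate(ref: ReferenceSet, source: str, length: int, n_sims: int,
                  mapper: MapperParams = MapperParams(), seed: int = 0,
                  min_mapq: int = 30) -> tuple[float, float]:
    """Fraction of non-target reads of exactly ``length`` bp that map to the
    target compartments at MQ >= min_mapq, with its binomial SE.

    source 'random-gc' draws i.i.d. reads matching the target's GC;
    source 'decoy' slices reads from the decoy chromosomes.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    if length < mapper.seed_k:
        raise ValueError(f"length {length} below mapper seed k={mapper.seed_k}")
    rng = np.random.default_rng(seed)
    if source == "random-gc":
        gc = ref.gc_fraction([n for n in ref.names if ref.compartments[n] != DECOY])
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes = rng.choice(4, size=(n_sims, length), p=p).astype(np.uint8)
        flat = codes.reshape(-1)
        offsets = np.arange(n_sims + 1, dtype=np.int64) * length
        reads = ReadSet([f"s{i}" for i in range(n_sims)], flat, offsets)
    elif source == "decoy":
        names = ref.chromosomes_of(DECOY)
        if not names:
            raise ValueError("decoy source requested but reference has no decoy compartment")
        lens = np.array([ref.length(n) for n in names], dtype=float)
        pick = rng.choice(len(names), size=n_sims, p=lens / lens.sum())
        seqs = []
        for i in range(n_sims):
            nm = names[pick[i]]
            start = rng.integers(0, ref.length(nm) - length + 1)
            codes = ref.codes(nm)[start:start + length]
            if rng.random() < 0.5:
                codes = (3 - codes)[::-1]
            seqs.append(codes)
        flat = np.concatenate(seqs)
        offsets = np.arange(n_sims + 1, dtype=np.int64) * length
        reads = ReadSet([f"s{i}" for i in range(n_sims)], flat.astype(np.uint8), offsets)
    else:
        raise ValueError(f"unknown source {source!r}")
    aln = al.map_reads(reads, ref, max_mismatch_frac=mapper.max_mismatch_frac,
                       seed_k=mapper.seed_k, target_compartments=(NUCLEAR, MITO))
    n_pass = int((aln.mapq >= min_mapq).sum())
    frac = n_pass / n_sims
    se = float(np.sqrt(frac * (1.0 - frac) / n_sims))
    return frac, se


@dataclass
class CutoffReport:
    table: pd.DataFrame  # one row per cutoff

    def row(self, cutoff: int) -> pd.Series:
        hit = self.table[self.table["cutoff"] == cutoff]
        if hit.empty:
            raise KeyError(f"no row for cutoff {cutoff}")
        return hit.iloc[0]


def cutoff_report(alignments: Alignments, ref: ReferenceSet, cutoffs: list[int],
                  contam_model: ContaminationModel,
                  spurious_source: str = "random-gc", spurious_n: int = 2000,
                  mapper: MapperParams = MapperParams(), min_mapq: int = 30,
                  seed: int = 0) -> CutoffReport:
    """Per-cutoff: filter (length >= cutoff, MQ), dedup, read count, median
    length, 5' position-1 damage, contamination MLE, spurious fraction.

    A stage failure annotates its row; other rows are still produced.
    """
    cutoffs = sorted(cutoffs)
    rows = []
    for ci, cutoff in enumerate(cutoffs):
        row: dict = {"cutoff": cutoff, "error": ""}
        try:
            sub = al.filter_reads(alignments, ReadFilter(min_length=cutoff, min_mapq=min_mapq))
            sub = al.dedup(sub)
            row["n_mapped"] = len(sub)
            if len(sub):
                row["median_length"] = length_stats(sub).median
                prof = substitution_profile(sub, ref, positions=1)
                row["damage_5p1"] = float(prof.ct5_rate[0])
            else:
                row["median_length"] = np.nan
                row["damage_5p1"] = np.nan
            try:
                est = estimate_contamination(sub, ref, contam_model)
                row["rho"], row["rho_se"] = est.rho, est.se
                row["rho_boundary"] = est.boundary
            except ValueError as exc:
                row["rho"] = row["rho_se"] = np.nan
                row["rho_boundary"] = False
                row["error"] = f"contamination: {exc}"
            sp, sp_se = spurious_rate(ref, spurious_source, cutoff, spurious_n,
                                      mapper=mapper, seed=seed + ci, min_mapq=min_mapq)
            row["spurious"], row["spurious_se"] = sp, sp_se
        except Exception as exc:  # annotate, keep the other rows
            row.setdefault("n_mapped", np.nan)
            row["error"] = str(exc)
        rows.append(row)
    return CutoffReport(table=pd.DataFrame(rows))


def choose_cutoff(report: CutoffReport, max_contamination: float = 0.05,
                  max_spurious: float = 0.10) -> int | None:
    """Smallest cutoff with rho + 2*SE <= max_contamination and spurious
    fraction <= max_spurious; None when no row qualifies."""
    if report.table.empty:
        raise ValueError("empty cutoff report")
    t = report.table.sort_values("cutoff")
    for _, row in t.iterrows():
        rho, se, sp = row.get("rho"), row.get("rho_se"), row.get("spurious")
        if any(pd.isna(v) for v in (rho, se, sp)):
            continue
        if rho + 2.0 * se <= max_contamination and sp <= max_spurious:
            return int(row["cutoff"])
    return None
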