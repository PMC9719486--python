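"""Pseudo-haploid genotype calling at panel SNPs and EIGENSTRAT I/O.

Genotype codes follow the EIGENSTRAT convention: the number of copies of
the reference allele (0/1/2), 9 for missing.  Haploid calls are stored as
homozygous diploid codes (0 or 2) for panel compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Alignments
from .simulate import ReferenceSet
from ._util import segment_ids

MISSING = 9


@dataclass
class GenotypePanel:
    """Biallelic SNP panel: SNP table, individuals x SNPs genotype matrix
    (ref-allele copies, 9 missing), individual table with populations."""

    snp: pd.DataFrame          # id, chromosome, position, ref, alt
    genotypes: np.ndarray      # (n_individuals, n_snps) int8
    individuals: pd.DataFrame  # id, sex, population

    def __post_init__(self):
        n_ind, n_snp = self.genotypes.shape
        if n_snp != len(self.snp) or n_ind != len(self.individuals):
            raise ValueError("genotype matrix dimensions inconsistent with tables")
        vals = np.unique(self.genotypes)
        if not np.isin(vals, [0, 1, 2, MISSING]).all():
            raise ValueError("genotype codes must be in {0,1,2,9}")
        same = self.snp["ref"].to_numpy() == self.snp["alt"].to_numpy()
        if same.any():
            raise ValueError("ref and alt alleles must differ")

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def population_indices(self) -> dict[str, np.ndarray]:
        pops = self.individuals["population"].to_numpy()
        return {p: np.flatnonzero(pops == p) for p in pd.unique(pops)}


# ---------------------------------------------------------------------------
# Pileup and pseudo-haploid calling
# ---------------------------------------------------------------------------

def pileup_at_snps(alignments: Alignments, ref: ReferenceSet, panel: GenotypePanel,
                   min_baseq: int = 30, min_mapq: int = 30) -> pd.DataFrame:
    """Per-SNP base counts (A/C/G/T columns, reference orientation) from
    reads passing the MQ gate, bases passing the BQ gate.

    SNPs outside the reference are flagged in the ``skipped`` column and get
    zero counts.
    """
    n_snp = panel.n_snps
    counts = np.zeros((n_snp, 4), dtype=np.int64)
    skipped = np.zeros(n_snp, dtype=bool)

    chrom_lookup = {nm: i for i, nm in enumerate(alignments.chrom_names)}
    snp_chrom_raw = panel.snp["chromosome"].astype(str).to_numpy()
    snp_pos = panel.snp["position"].to_numpy(dtype=np.int64)

    for j in range(n_snp):
        nm = snp_chrom_raw[j]
        if nm not in chrom_lookup or not (nm in ref and 0 <= snp_pos[j] < ref.length(nm)):
            skipped[j] = True

    keep = alignments.mapq >= min_mapq
    aln = alignments.subset(np.flatnonzero(keep))
    if len(aln):
        ids = segment_ids(aln.offsets)
        order = np.argsort(aln.starts, kind="stable")
        by_chrom: dict[int, np.ndarray] = {}
        for ci in np.unique(aln.chrom_ids):
            by_chrom[ci] = np.flatnonzero(aln.chrom_ids == ci)
        baseq_const = aln.qualities is None
        for j in range(n_snp):
            if skipped[j]:
                continue
            ci = chrom_lookup.get(snp_chrom_raw[j])
            if ci is None or ci not in by_chrom:
                continue
            cand = by_chrom[ci]
            pos = snp_pos[j]
            over = cand[(aln.starts[cand] <= pos) & (aln.ends[cand] > pos)]
            for i in over:
                L = int(aln.lengths[i])
                if aln.strands[i]:  # minus: read stored as sequenced
                    read_idx = int(aln.ends[i]) - 1 - pos
                    base = 3 - aln.flat[aln.offsets[i] + read_idx]
                else:
                    read_idx = pos - int(aln.starts[i])
                    base = aln.flat[aln.offsets[i] + read_idx]
                q = 37 if baseq_const else int(aln.baseq(i)[read_idx])
                if q >= min_baseq:
                    counts[j, int(base)] += 1
    out = pd.DataFrame(counts, columns=list("ACGT"))
    out.insert(0, "snp_id", panel.snp["id"].to_numpy())
    out["skipped"] = skipped
    return out


@dataclass
class PseudoHaploidCalls:
    """Per SNP: called allele ('ref'/'alt'/missing None) + allelic depth."""

    snp_id: pd.Series
    call: np.ndarray          # int8: 2 ref-hom, 0 alt-hom, 9 missing
    depth: np.ndarray         # count of passing allelic bases

    def genotypes(self) -> np.ndarray:
        return self.call.copy()

    def to_frame(self) -> pd.DataFrame:
        label = np.where(self.call == 2, "ref", np.where(self.call == 0, "alt", "missing"))
        return pd.DataFrame({"snp_id": self.snp_id, "call": label, "depth": self.depth,
                             "genotype": self.call})


def pseudo_haploid_call(pileup: pd.DataFrame, panel: GenotypePanel, seed: int) -> PseudoHaploidCalls:
    """One uniformly random passing allelic base per SNP; bases matching
    neither panel allele are discarded before sampling."""
    rng = np.random.default_rng(seed)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ref_i = panel.snp["ref"].map(base_idx).to_numpy()
    alt_i = panel.snp["alt"].map(base_idx).to_numpy()
    count_mat = pileup[list("ACGT")].to_numpy()
    n = len(panel.snp)
    n_ref = count_mat[np.arange(n), ref_i]
    n_alt = count_mat[np.arange(n), alt_i]
    total = n_ref + n_alt
    call = np.full(n, MISSING, dtype=np.int8)
    has = total > 0
    pick_ref = rng.random(n) < np.divide(n_ref, np.maximum(total, 1))
    call[has & pick_ref] = 2
    call[has & ~pick_ref] = 0
    return PseudoHaploidCalls(snp_id=pileup["snp_id"], call=call, depth=total)


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

def write_eigenstrat(panel: GenotypePanel, prefix) -> None:
    prefix = Path(prefix)
    geno = panel.genotypes
    with open(Path(str(prefix) + ".geno"), "w") as fh:
        # one line per SNP, one digit per individual
        for j in range(panel.n_snps):
            fh.write("".join(str(int(v)) for v in geno[:, j]) + "\n")
    snp = panel.snp
    with open(Path(str(prefix) + ".snp"), "w") as fh:
        for _, row in snp.iterrows():
            fh.write(f"{row['id']}\t{row['chromosome']}\t0.0\t{row['position']}\t{row['ref']}\t{row['alt']}\n")
    with open(Path(str(prefix) + ".ind"), "w") as fh:
        for _, row in panel.individuals.iterrows():
            fh.write(f"{row['id']}\t{row.get('sex', 'U')}\t{row['population']}\n")


def read_eigenstrat(prefix) -> GenotypePanel:
    prefix = Path(prefix)
    snp_rows = []
    with open(Path(str(prefix) + ".snp")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f".snp line {ln}: expected 6 columns, got {len(parts)}")
            snp_rows.append((parts[0], parts[1], int(parts[3]), parts[4], parts[5]))
    snp = pd.DataFrame(snp_rows, columns=["id", "chromosome", "position", "ref", "alt"])
    try:
        snp["chromosome"] = snp["chromosome"].astype(int)
    except ValueError:
        pass
    ind_rows = []
    with open(Path(str(prefix) + ".ind")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f".ind line {ln}: expected 3 columns, got {len(parts)}")
            ind_rows.append(parts)
    ind = pd.DataFrame(ind_rows, columns=["id", "sex", "population"])
    n_ind = len(ind)
    geno_cols = []
    with open(Path(str(prefix) + ".geno")) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if len(line) != n_ind:
                raise ValueError(f".geno line {ln}: expected {n_ind} genotypes, got {len(line)}")
            if not set(line) <= set("0129"):
                bad = sorted(set(line) - set("0129"))[0]
                raise ValueError(f".geno line {ln}: unknown genotype code {bad!r}")
            geno_cols.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if len(geno_cols) != len(snp):
        raise ValueError(f".geno has {len(geno_cols)} lines but .snp has {len(snp)}")
    geno = np.array(geno_cols, dtype=np.int8).T if geno_cols else np.empty((n_ind, 0), np.int8)
    return GenotypePanel(snp=snp, genotypes=geno, individuals=ind)
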