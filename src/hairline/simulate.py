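"""Generative model of a degraded single-stranded-library aDNA sequencing run.

The simulator produces everything the downstream pipeline consumes, with
per-read truth: a synthetic reference split into nuclear / mitochondrial /
environmental-decoy compartments, fragment lengths from a mixture model
tuned to the ultra-short hair regime (post-25 bp-filter median of 25 bp),
position-dependent C->T deamination with a 5' terminal excess, a high
interior plateau and 3' suppression, undamaged longer modern-contaminant
molecules, capture bias against short/damaged molecules, and a
Balding-Nichols multi-population genotype panel with a cladal pair of
pseudo-haploid ancient samples.

Damage model
------------
A cytosine at 1-based position ``i`` of an ``L``-long molecule deaminates
(reads as T) with probability

    d(i, L) = (a5 * exp(-lam5 * (i - 1)) + c) * (1 - b3 * exp(-mu3 * (L - i)))

i.e. a decaying 5' terminal excess ``a5`` on top of an interior plateau
``c``, multiplied by a suppression factor that pulls the 3'-most bases down
to ``c * (1 - b3)``.  Defaults give d(1,.) ~ 0.15, d(10,.) ~ 0.10 and a
last-base rate of ~0.01.  Because the library protocol converts each strand
independently, all deamination appears as C->T in read orientation; there
is no complementary G->A channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import decode, decode_flat, encode, flatten, gather_segments, segment_ids

NUCLEAR, MITO, DECOY = "nuclear", "mito", "decoy"
_COMPARTMENTS = (NUCLEAR, MITO, DECOY)


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

class ReferenceSet:
    """Ordered named chromosomes with compartment labels.

    Sequences are restricted to ACGT.  Encoded (uint8) copies are cached for
    the vectorised consumers.
    """

    def __init__(self, chromosomes: dict[str, str], compartments: dict[str, str]):
        if not chromosomes:
            raise ValueError("empty reference")
        if set(chromosomes) != set(compartments):
            raise ValueError("compartment labels must cover exactly the chromosome names")
        for name, seq in chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if compartments[name] not in _COMPARTMENTS:
                raise ValueError(f"unknown compartment {compartments[name]!r}")
        mito = [n for n, c in compartments.items() if c == MITO]
        if len(mito) > 1:
            raise ValueError("at most one mito chromosome is supported")
        self.names: list[str] = list(chromosomes)
        self.compartments = dict(compartments)
        self._codes: dict[str, np.ndarray] = {n: encode(s) for n, s in chromosomes.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._codes

    def sequence(self, name: str) -> str:
        return decode(self._codes[name])

    def codes(self, name: str) -> np.ndarray:
        return self._codes[name]

    def length(self, name: str) -> int:
        return int(self._codes[name].size)

    def chromosomes_of(self, compartment: str) -> list[str]:
        return [n for n in self.names if self.compartments[n] == compartment]

    def compartment_length(self, compartment: str) -> int:
        return sum(self.length(n) for n in self.chromosomes_of(compartment))

    def gc_fraction(self, names: list[str] | None = None) -> float:
        names = names or self.names
        gc = tot = 0
        for n in names:
            c = self._codes[n]
            gc += int(((c == 1) | (c == 2)).sum())
            tot += c.size
        return gc / tot

    # -- FASTA round trip ---------------------------------------------------
    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(n)), id=n, description=f"compartment={self.compartments[n]}")
            for n in self.names
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        chroms: dict[str, str] = {}
        comps: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            chroms[rec.id] = str(rec.seq).upper()
            comp = NUCLEAR
            for tok in rec.description.split():
                if tok.startswith("compartment="):
                    comp = tok.split("=", 1)[1]
            if comp == NUCLEAR and rec.id.upper() in ("MT", "CHRM", "MITO"):
                comp = MITO
            comps[rec.id] = comp
        return cls(chroms, comps)


def make_reference(spec: list[tuple[str, int, str, float]], seed: int) -> ReferenceSet:
    """Draw i.i.d. bases per chromosome: (name, length, compartment, GC)."""
    if not spec:
        raise ValueError("empty reference spec")
    names = [s[0] for s in spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    rng = np.random.default_rng(seed)
    chroms: dict[str, str] = {}
    comps: dict[str, str] = {}
    for name, length, compartment, gc in spec:
        if length < 200:
            raise ValueError(f"chromosome {name!r}: length must be >= 200")
        if not 0.0 < gc < 1.0:
            raise ValueError(f"chromosome {name!r}: GC must be in (0,1)")
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes = rng.choice(4, size=length, p=p).astype(np.uint8)
        chroms[name] = decode(codes)
        comps[name] = compartment
    return ReferenceSet(chroms, comps)


def default_reference(seed: int = 0, nuclear_bp: int = 2_000_000, mito_bp: int = 16_000,
                      decoy_bp: int = 1_000_000, gc: float = 0.41) -> ReferenceSet:
    """Toy human-like target (two nuclear chromosomes + MT) plus an
    environmental decoy source of the same base composition."""
    half = nuclear_bp // 2
    return make_reference(
        [("nuc1", half, NUCLEAR, gc), ("nuc2", nuclear_bp - half, NUCLEAR, gc),
         ("MT", mito_bp, MITO, gc), ("decoy1", decoy_bp, DECOY, gc)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fragment lengths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentLengthModel:
    """Mixture of point-mass / shifted-exponential / lognormal components.

    Sampled lengths are rounded to integers and clamped to ``hard_min``.
    ``truncate_min`` conditions the whole mixture on length >= truncate_min
    (rejection sampling), used by scenarios defined on post-filter molecules.
    """

    components: tuple[tuple[float, str, tuple[float, ...]], ...]
    hard_min: int = 10
    truncate_min: int | None = None

    def __post_init__(self):
        w = np.array([c[0] for c in self.components], dtype=float)
        if len(w) == 0 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be >= 0 and sum to 1")
        if self.hard_min < 10:
            raise ValueError("hard minimum length must be >= 10")
        for _, kind, _ in self.components:
            if kind not in ("point", "shifted_exponential", "lognormal"):
                raise ValueError(f"unknown component family {kind!r}")

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def point(length: float) -> tuple:
        return (1.0, "point", (float(length),))

    @staticmethod
    def shifted_exponential(shift: float, scale: float, weight: float = 1.0) -> tuple:
        return (weight, "shifted_exponential", (float(shift), float(scale)))

    @staticmethod
    def lognormal(mean_log: float, sd_log: float, weight: float = 1.0) -> tuple:
        return (weight, "lognormal", (float(mean_log), float(sd_log)))

    # -- sampling ------------------------------------------------------------
    def _sample_raw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        w = np.array([c[0] for c in self.components])
        comp = rng.choice(len(w), size=n, p=w / w.sum())
        out = np.empty(n, dtype=float)
        for idx, (_, kind, pars) in enumerate(self.components):
            m = comp == idx
            k = int(m.sum())
            if k == 0:
                continue
            if kind == "point":
                out[m] = pars[0]
            elif kind == "shifted_exponential":
                out[m] = pars[0] + rng.exponential(pars[1], size=k)
            else:
                out[m] = rng.lognormal(pars[0], pars[1], size=k)
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n <= 0:
            raise ValueError("n must be > 0")
        raw = np.rint(self._sample_raw(n, rng)).astype(np.int64)
        raw = np.maximum(raw, self.hard_min)
        if self.truncate_min is not None:
            t = self.truncate_min
            bad = raw < t
            while bad.any():
                raw[bad] = np.maximum(
                    np.rint(self._sample_raw(int(bad.sum()), rng)).astype(np.int64),
                    self.hard_min,
                )
                bad = raw < t
        return raw

    # -- closed forms ---------------------------------------------------------
    def survival(self, min_len: int) -> float:
        """P(sampled integer length >= min_len), exact under the rounding and
        clamping conventions (for min_len > hard_min)."""
        def mix_sf(x: float) -> float:
            s = 0.0
            for w, kind, pars in self.components:
                if kind == "point":
                    s += w * (1.0 if pars[0] >= x else 0.0)
                elif kind == "shifted_exponential":
                    s += w * float(stats.expon.sf(x, loc=pars[0], scale=pars[1]))
                else:
                    s += w * float(stats.lognorm.sf(x, s=pars[1], scale=math.exp(pars[0])))
            return s

        x = min_len - 0.5
        if self.truncate_min is not None:
            base = mix_sf(self.truncate_min - 0.5)
            return mix_sf(max(x, self.truncate_min - 0.5)) / base
        if min_len <= self.hard_min:
            return 1.0
        return mix_sf(x)


def hair_fragment_model() -> FragmentLengthModel:
    """Default endogenous hair model: an ultra-short bulk, a steep
    just-over-the-cutoff component, and a thin long tail carrying the
    interior-damage signal.  Median after the >=25 bp filter is 25 bp."""
    return FragmentLengthModel(
        components=(
            FragmentLengthModel.shifted_exponential(14.0, 3.0, weight=0.50),
            FragmentLengthModel.shifted_exponential(24.0, 1.0, weight=0.45),
            FragmentLengthModel.lognormal(math.log(42.0), 0.35, weight=0.05),
        ),
        hard_min=10,
    )


def contaminant_fragment_model() -> FragmentLengthModel:
    """Modern contaminant molecules: long, lognormal(ln 60, 0.40)."""
    return FragmentLengthModel(
        components=(FragmentLengthModel.lognormal(math.log(60.0), 0.40),),
        hard_min=10,
    )


def sample_fragment_lengths(model: FragmentLengthModel, n: int, seed: int) -> np.ndarray:
    return model.sample(n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegradationParams:
    """Parametric single-stranded damage curve plus flat sequencing error."""

    a5: float = 0.05     # 5' terminal excess deamination probability
    lam5: float = 0.5    # 5' decay rate per bp
    c: float = 0.10      # interior plateau deamination probability
    b3: float = 0.90     # 3' suppression depth in [0, 1]
    mu3: float = 1.0     # 3' suppression decay per bp
    eps: float = 0.001   # per-base sequencing error probability

    def __post_init__(self):
        for name in ("a5", "c", "b3", "eps"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.lam5 < 0 or self.mu3 < 0:
            raise ValueError("decay rates must be >= 0")
        if self.a5 + self.c > 1.0:
            raise ValueError("a5 + c must be <= 1 so that d(i,L) stays a probability")

    def rate(self, i, L):
        """d(i, L) for 1-based position(s) i of molecule length(s) L."""
        i = np.asarray(i, dtype=float)
        L = np.asarray(L, dtype=float)
        five = self.a5 * np.exp(-self.lam5 * (i - 1.0)) + self.c
        three = 1.0 - self.b3 * np.exp(-self.mu3 * (L - i))
        return five * three


def _degrade_flat(flat: np.ndarray, offsets: np.ndarray, params: DegradationParams,
                  rng: np.random.Generator, ids: np.ndarray | None = None,
                  within: np.ndarray | None = None) -> np.ndarray:
    """Deaminate then error-inject a flat batch in place; returns per-read
    deamination event counts (sequencing errors excluded)."""
    n_reads = len(offsets) - 1
    if flat.size == 0:
        return np.zeros(n_reads, dtype=np.int64)
    if ids is None:
        ids = segment_ids(offsets)
    if within is None:
        within = np.arange(flat.size, dtype=np.int64) - offsets[ids]
    # damage probabilities are only needed at cytosines
    idx_c = np.flatnonzero(flat == 1)
    ids_c = ids[idx_c]
    d = params.rate(within[idx_c] + 1, (offsets[1:] - offsets[:-1])[ids_c])
    hit = idx_c[rng.random(idx_c.size) < d]
    flat[hit] = 3  # C -> T
    events = np.bincount(ids[hit], minlength=n_reads)
    if params.eps > 0:
        err = np.flatnonzero(rng.random(flat.size) < params.eps)
        if err.size:
            flat[err] = (flat[err] + rng.integers(1, 4, size=err.size).astype(np.uint8)) % 4
    return events


def apply_degradation(molecule: str, params: DegradationParams, seed: int) -> tuple[str, int]:
    """Degrade one molecule (5'->3' as sequenced): each C at position i
    becomes T with probability d(i, L); then every base flips to a uniformly
    chosen different base with probability eps.  No G->A channel exists."""
    if len(molecule) < 1:
        raise ValueError("molecule must have length >= 1")
    flat = encode(molecule)
    offsets = np.array([0, flat.size], dtype=np.int64)
    events = _degrade_flat(flat, offsets, params, np.random.default_rng(seed))
    return decode(flat), int(events[0])


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

class ReadSet:
    """Columnar FASTQ-like read container (ids, 2-bit-codeable sequences,
    constant Q37 base qualities)."""

    def __init__(self, ids: list[str], flat: np.ndarray, offsets: np.ndarray):
        self.ids = ids
        self.flat = flat
        self.offsets = offsets
        self.lengths = offsets[1:] - offsets[:-1]

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, i: int) -> str:
        return decode(self.flat[self.offsets[i]:self.offsets[i + 1]])

    def sequences(self) -> list[str]:
        return decode_flat(self.flat, self.offsets)

    def subset(self, indices) -> "ReadSet":
        indices = np.asarray(indices, dtype=np.int64)
        flat, offsets = gather_segments(self.flat, self.offsets, indices)
        return ReadSet([self.ids[i] for i in indices], flat, offsets)

    @classmethod
    def from_sequences(cls, seqs: list[str], ids: list[str] | None = None) -> "ReadSet":
        flat, offsets, _ = flatten(seqs)
        ids = ids if ids is not None else [f"r{i:08d}" for i in range(len(seqs))]
        return cls(ids, flat, offsets)

    def to_fastq(self, path) -> None:
        seqs = self.sequences()
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, seqs):
                fh.write(f"@{rid}\n{seq}\n+\n{'F' * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fastq"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls.from_sequences(seqs, ids=ids)


@dataclass(frozen=True)
class LibrarySimConfig:
    """One sequencing-run scenario.

    ``endogenous_fraction`` is the probability a raw read is an endogenous
    (target-organism) molecule; ``contaminant_fraction`` is the contaminant
    share among human-mapping molecules (endogenous + contaminant); the
    remainder of the run is environmental (decoy-derived) reads.
    """

    n_reads: int
    endogenous_fraction: float
    contaminant_fraction: float = 0.0
    mito_share: float = 0.0
    endo_length_model: FragmentLengthModel = field(default_factory=hair_fragment_model)
    cont_length_model: FragmentLengthModel = field(default_factory=contaminant_fragment_model)
    env_length_model: FragmentLengthModel | None = None
    degradation: DegradationParams = field(default_factory=DegradationParams)
    cont_error: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        for name in ("endogenous_fraction", "contaminant_fraction", "mito_share", "cont_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.source_probabilities()[2] < -1e-12:
            raise ValueError("endogenous + contaminant fractions exceed 1")

    def source_probabilities(self) -> tuple[float, float, float]:
        """(P(endogenous), P(contaminant), P(environmental)) per raw read."""
        p_endo = self.endogenous_fraction
        rho = self.contaminant_fraction
        p_cont = 0.0 if rho == 0 else p_endo * rho / (1.0 - rho) if rho < 1 else 1.0 - p_endo
        if rho == 1:
            p_endo = 0.0
            p_cont = 1.0
        return p_endo, p_cont, max(0.0, 1.0 - p_endo - p_cont)


SOURCE_ENDO, SOURCE_CONT, SOURCE_ENV = "endogenous", "contaminant", "environmental"


def simulate_library(ref: ReferenceSet, config: LibrarySimConfig) -> tuple[ReadSet, pd.DataFrame]:
    """Emit reads 5'->3' as sequenced plus a complete truth table.

    Molecules are sampled uniformly from their compartment (chromosome chosen
    proportional to length), strand uniform; minus-strand molecules are the
    reverse complement of the reference slice.  Damage is applied to the
    molecule strand (read orientation), so all deamination is C->T as read.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    p_endo, p_cont, p_env = config.source_probabilities()

    u = rng.random(n)
    source = np.full(n, 2, dtype=np.int8)  # 0 endo, 1 cont, 2 env
    source[u < p_endo] = 0
    source[(u >= p_endo) & (u < p_endo + p_cont)] = 1

    needed = {0: NUCLEAR, 2: DECOY}
    for code, comp in needed.items():
        if (source == code).any() and not ref.chromosomes_of(comp):
            raise ValueError(f"reference lacks required compartment {comp!r}")

    # compartment: endogenous reads may be mitochondrial; others nuclear/decoy
    compartment = np.where(source == 2, 2, 0).astype(np.int8)  # 0 nuc, 1 mito, 2 decoy
    endo_mask = source == 0
    if config.mito_share > 0 and endo_mask.any():
        if not ref.chromosomes_of(MITO):
            raise ValueError("mito share > 0 but reference has no mito chromosome")
        mito = endo_mask & (rng.random(n) < config.mito_share)
        compartment[mito] = 1

    # lengths per source
    lengths = np.empty(n, dtype=np.int64)
    env_model = config.env_length_model or config.endo_length_model
    for code, model in ((0, config.endo_length_model), (1, config.cont_length_model), (2, env_model)):
        m = source == code
        if m.any():
            lengths[m] = model.sample(int(m.sum()), rng)

    # chromosome and start per compartment
    chrom_names = list(ref.names)
    chrom_index = {nm: i for i, nm in enumerate(chrom_names)}
    chrom_of = np.empty(n, dtype=np.int32)
    start = np.empty(n, dtype=np.int64)
    for comp_code, comp in ((0, NUCLEAR), (1, MITO), (2, DECOY)):
        m = compartment == comp_code
        if not m.any():
            continue
        names = ref.chromosomes_of(comp)
        lens = np.array([ref.length(nm) for nm in names], dtype=float)
        pick = rng.choice(len(names), size=int(m.sum()), p=lens / lens.sum())
        clens = np.array([ref.length(nm) for nm in names], dtype=np.int64)[pick]
        lm = lengths[m]
        if (lm > clens).any():
            bad = int(np.argmax(lm > clens))
            raise ValueError(
                f"requested fragment of {int(lm[bad])} bp exceeds chromosome "
                f"{names[int(pick[bad])]!r} ({int(clens[bad])} bp)"
            )
        chrom_of[m] = np.array([chrom_index[names[i]] for i in range(len(names))])[pick]
        start[m] = np.floor(rng.random(int(m.sum())) * (clens - lm + 1)).astype(np.int64)

    strand_minus = rng.random(n) < 0.5

    # gather molecule sequences (oriented 5'->3' as sequenced) in one pass
    genome = np.concatenate([ref.codes(nm) for nm in chrom_names])
    goff = np.zeros(len(chrom_names), dtype=np.int64)
    np.cumsum([ref.length(nm) for nm in chrom_names[:-1]], out=goff[1:])
    abs_start = goff[chrom_of] + start
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    ids_pos = segment_ids(offsets)
    total = int(offsets[-1])
    within = np.arange(total, dtype=np.int64)
    within -= offsets[ids_pos]
    pos = abs_start[ids_pos]
    minus_rep = strand_minus[ids_pos]
    pos[minus_rep] += (lengths[ids_pos] - 1 - within)[minus_rep]
    pos[~minus_rep] += within[~minus_rep]
    flat = genome[pos]
    np.subtract(3, flat, out=flat, where=minus_rep)

    # degrade endogenous molecules; error-inject the rest
    n_deam = np.zeros(n, dtype=np.int64)
    endo_pos = endo_mask[ids_pos]
    if endo_mask.any():
        endo_idx = np.flatnonzero(endo_mask)
        sub_lengths = lengths[endo_idx]
        sub_off = np.zeros(endo_idx.size + 1, dtype=np.int64)
        np.cumsum(sub_lengths, out=sub_off[1:])
        sub_flat = flat[endo_pos].copy()
        ev = _degrade_flat(sub_flat, sub_off, config.degradation, rng)
        flat[endo_pos] = sub_flat
        n_deam[endo_idx] = ev
    for code, eps in ((1, config.cont_error), (2, config.degradation.eps)):
        m = source == code
        if not m.any() or eps <= 0:
            continue
        sel = np.flatnonzero(m[ids_pos])
        err = sel[rng.random(sel.size) < eps]
        if err.size:
            flat[err] = (flat[err] + rng.integers(1, 4, size=err.size).astype(np.uint8)) % 4

    ids = [f"r{i:08d}" for i in range(n)]
    reads = ReadSet(ids, flat, offsets)
    comp_names = np.array([NUCLEAR, MITO, DECOY])
    src_names = np.array([SOURCE_ENDO, SOURCE_CONT, SOURCE_ENV])
    truth = pd.DataFrame(
        {
            "read_id": ids,
            "source": pd.Categorical.from_codes(source, categories=list(src_names)),
            "compartment": pd.Categorical.from_codes(compartment, categories=list(comp_names)),
            "chromosome": pd.Categorical.from_codes(chrom_of, categories=chrom_names),
            "start": start,
            "end": start + lengths,
            "strand": pd.Categorical.from_codes(strand_minus.astype(np.int8), categories=["+", "-"]),
            "length": lengths,
            "n_deamination": n_deam,
        }
    )
    return reads, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Capture bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaptureBias:
    """Retention probability logistic(slope*(L-midpoint)) * exp(-penalty*n_deam)."""

    length_midpoint: float = 30.0
    length_slope: float = 0.15
    damage_penalty: float = 0.5

    def retention_probability(self, length, n_deamination):
        z = self.length_slope * (np.asarray(length, dtype=float) - self.length_midpoint)
        p = 1.0 / (1.0 + np.exp(-z))
        p = p * np.exp(-self.damage_penalty * np.asarray(n_deamination, dtype=float))
        return np.clip(p, 0.0, 1.0)


def simulate_capture(reads, truth: pd.DataFrame, bias: CaptureBias, seed: int) -> list[str]:
    """Independent Bernoulli retention per read; returns retained read ids."""
    ids = list(reads.ids) if isinstance(reads, ReadSet) else list(reads)
    t = truth.set_index("read_id")
    missing = [r for r in ids if r not in t.index]
    if missing:
        raise KeyError(f"truth row missing for read {missing[0]!r}")
    sub = t.loc[ids]
    p = bias.retention_probability(sub["length"].to_numpy(), sub["n_deamination"].to_numpy())
    keep = np.random.default_rng(seed).random(len(ids)) < p
    return [r for r, k in zip(ids, keep) if k]


# ---------------------------------------------------------------------------
# Genotype panel simulation (Balding–Nichols)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSimConfig:
    n_snps: int = 5000
    n_populations: int = 4
    drift: tuple[float, ...] | float = 0.05       # per-population F in (0,1)
    samples_per_population: int = 10
    n_chromosomes: int = 22
    outgroup_divergence: float = 0.1
    ancient_missingness: float = 0.5
    ancient_sources: tuple[int, int] = (0, 0)     # population index per ancient sample
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        fs = self.drifts()
        if any(not 0.0 < f < 1.0 for f in fs):
            raise ValueError("drift F must be in (0,1)")
        if max(self.ancient_sources) >= self.n_populations:
            raise ValueError("ancient source population out of range")

    def drifts(self) -> list[float]:
        if isinstance(self.drift, (int, float)):
            return [float(self.drift)] * self.n_populations
        if len(self.drift) != self.n_populations:
            raise ValueError("drift tuple length must equal n_populations")
        return [float(f) for f in self.drift]


@dataclass
class PanelSim:
    """Simulated panel plus truth: population allele frequencies and the two
    pseudo-haploid ancient samples (genotype codes 0/2/9, ref-allele copies)."""

    panel: "object"                   # genotype.GenotypePanel (moderns + outgroup)
    ancient_genotypes: np.ndarray     # (2, n_snps) int8 in {0, 2, 9}
    ancient_ids: tuple[str, str]
    source_populations: tuple[str, str]
    true_frequencies: pd.DataFrame    # populations x SNPs, ref-allele frequency


def simulate_panel(config: PanelSimConfig) -> PanelSim:
    """Star-shaped Balding–Nichols panel with an outgroup and two
    pseudo-haploid ancient samples drawn from designated source populations."""
    from . import genotype as gt

    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    fs = config.drifts()

    anc = rng.uniform(0.05, 0.95, size=n)  # ancestral ref-allele frequency
    pop_names = [f"Pop{k}" for k in range(config.n_populations)]
    freqs = np.empty((config.n_populations, n))
    for k, f in enumerate(fs):
        a = anc * (1 - f) / f
        b = (1 - anc) * (1 - f) / f
        freqs[k] = rng.beta(a, b)

    s = config.samples_per_population
    geno_rows = []
    ind_ids, ind_pops = [], []
    for k, name in enumerate(pop_names):
        g = rng.binomial(2, freqs[k], size=(s, n)).astype(np.int8)
        geno_rows.append(g)
        ind_ids += [f"{name}_{j}" for j in range(s)]
        ind_pops += [name] * s

    # outgroup: fixed at the ancestral (reference) allele, flipped to the
    # alternate at the divergence rate
    flip = rng.random(n) < config.outgroup_divergence
    og = np.where(flip, 0, 2).astype(np.int8)
    geno_rows.append(np.tile(og, (2, 1)))
    ind_ids += ["Outgroup_0", "Outgroup_1"]
    ind_pops += ["Outgroup", "Outgroup"]
    geno = np.vstack(geno_rows)

    # SNP table: chromosome labels 1..n_chromosomes round-robin
    chrom = (np.arange(n) % config.n_chromosomes) + 1
    order = np.argsort(chrom, kind="stable")
    chrom = chrom[order]
    geno = geno[:, order]
    freqs = freqs[:, order]
    pos = np.concatenate([np.arange(1, int((chrom == c).sum()) + 1) * 1000
                          for c in range(1, config.n_chromosomes + 1)])
    ref_allele = np.array(list("ACGT"))[rng.integers(0, 4, size=n)]
    alt_shift = rng.integers(1, 4, size=n)
    base_idx = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in ref_allele])
    alt_allele = np.array(list("ACGT"))[(base_idx + alt_shift) % 4]
    snp = pd.DataFrame({
        "id": [f"rs{j}" for j in range(n)],
        "chromosome": chrom.astype(int),
        "position": pos.astype(int),
        "ref": ref_allele,
        "alt": alt_allele,
    })
    ind = pd.DataFrame({"id": ind_ids, "sex": "U", "population": ind_pops})
    panel = gt.GenotypePanel(snp=snp, genotypes=geno, individuals=ind)

    # ancient pseudo-haploid samples: one allele drawn per site from the
    # source population's frequency, homozygous-coded, i.i.d. missingness
    anc_geno = np.empty((2, n), dtype=np.int8)
    src_names = []
    for a_i, k in enumerate(config.ancient_sources):
        hap = rng.binomial(1, freqs[k], size=n)
        g = (2 * hap).astype(np.int8)
        miss = rng.random(n) < config.ancient_missingness
        g[miss] = 9
        anc_geno[a_i] = g
        src_names.append(pop_names[k])
    true_freqs = pd.DataFrame(freqs, index=pop_names, columns=snp["id"])
    return PanelSim(
        panel=panel,
        ancient_genotypes=anc_geno,
        ancient_ids=("Ancient_0", "Ancient_1"),
        source_populations=(src_names[0], src_names[1]),
        true_frequencies=true_freqs,
    )


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

#: mito share solved so the coverage-normalised mt/nuc ratio is ~200 on the
#: 2 Mb + 16 kb toy genome: share/(1-share) * (2e6/16e3) = 200 -> share ~ 0.615
MTNUC_MITO_SHARE = 200.0 / (200.0 + 2_000_000 / 16_000)

SCENARIO_CUTOFF = {"hair_25bp": 25, "hair_30bp": 30, "hair_mtnuc": 25, "shotgun": 25}
#: contaminant share among molecules passing the scenario's own length cutoff
SCENARIO_CONTAM_AT_CUTOFF = {"hair_25bp": 0.001, "hair_30bp": 0.473,
                             "hair_mtnuc": 0.001, "shotgun": 0.001}


def _effective_yield(model: FragmentLengthModel, cutoff: int,
                     degradation: DegradationParams | None,
                     gc: float, max_mismatch_frac: float, eps: float,
                     max_len: int = 400) -> float:
    """P(molecule >= cutoff AND accepted by the mapper's mismatch cap)."""
    from .align import mapping_acceptance_probability

    lengths = np.arange(cutoff, max_len + 1)
    pmf = np.array([model.survival(int(L)) - model.survival(int(L) + 1) for L in lengths])
    acc = mapping_acceptance_probability(lengths, degradation=degradation, gc=gc,
                                         max_mismatch_frac=max_mismatch_frac, eps=eps)
    return float(np.sum(pmf * acc))


def _prefilter_contaminant_fraction(share_at_cutoff: float, cutoff: int,
                                    endo_model: FragmentLengthModel,
                                    cont_model: FragmentLengthModel,
                                    degradation: DegradationParams | None = None,
                                    gc: float = 0.41,
                                    max_mismatch_frac: float = 0.06,
                                    cont_error: float = 0.001) -> float:
    """Invert the pipeline's enrichment of long undamaged contaminants.

    The scenario quotes the contaminant share among ALIGNED fragments
    passing the length cutoff (the quantity contamination is measured on);
    the raw-molecule share is solved from each component's effective yield:
    length survival times mapper acceptance (damaged molecules fail the
    mismatch cap more often).
    """
    s = share_at_cutoff
    if degradation is None:
        qe = endo_model.survival(cutoff)
        qc = cont_model.survival(cutoff)
    else:
        qe = _effective_yield(endo_model, cutoff, degradation, gc, max_mismatch_frac,
                              degradation.eps)
        qc = _effective_yield(cont_model, cutoff, None, gc, max_mismatch_frac, cont_error)
    return s * qe / (s * qe + (1.0 - s) * qc)


def scenario_config(name: str, n_reads: int | None = None, seed: int = 0) -> LibrarySimConfig:
    """Named study regimes.

    hair_25bp / hair_30bp mirror the two length-cutoff rows of the deep-shotgun
    run (0.1% and 47.3% contamination at their respective cutoffs);
    hair_mtnuc adds the mt/nuc ~ 200 mitochondrial share; shotgun is the raw
    sequencing regime with 0.231% endogenous mappable content.
    """
    endo = hair_fragment_model()
    cont = contaminant_fragment_model()
    if name in ("hair_25bp", "hair_30bp", "hair_mtnuc"):
        cutoff = SCENARIO_CUTOFF[name]
        rho0 = _prefilter_contaminant_fraction(
            SCENARIO_CONTAM_AT_CUTOFF[name], cutoff, endo, cont,
            degradation=DegradationParams())
        mito = MTNUC_MITO_SHARE if name == "hair_mtnuc" else 0.02
        env = 0.0 if name == "hair_mtnuc" else 0.02
        human = 1.0 - env
        return LibrarySimConfig(
            n_reads=n_reads or 200_000,
            endogenous_fraction=human * (1.0 - rho0),
            contaminant_fraction=rho0,
            mito_share=mito,
            endo_length_model=endo,
            cont_length_model=cont,
            seed=seed,
        )
    if name == "shotgun":
        rho0 = _prefilter_contaminant_fraction(0.001, 25, endo, cont)
        return LibrarySimConfig(
            n_reads=n_reads or 1_000_000,
            endogenous_fraction=0.00231,
            contaminant_fraction=rho0,
            mito_share=MTNUC_MITO_SHARE,
            endo_length_model=replace(endo, truncate_min=25),
            cont_length_model=cont,
            env_length_model=endo,
            seed=seed,
        )
    raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIO_CUTOFF)}")


def expected_filter_pass(config: LibrarySimConfig, cutoff: int) -> float:
    """Expected fraction of raw reads that are human-derived AND >= cutoff
    (environmental reads never survive mapping)."""
    p_endo, p_cont, _ = config.source_probabilities()
    return (p_endo * config.endo_length_model.survival(cutoff)
            + p_cont * config.cont_length_model.survival(cutoff))
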