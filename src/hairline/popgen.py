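"""f-statistics and PCA projection with weighted block-jackknife errors.

Outgroup-f3(A, B; O) = mean over usable SNPs of (a - o)(b - o), the shared
drift of A and B relative to the outgroup O; no heterozygosity normalisation
or finite-sample bias correction is applied (outgroup mode).
f4(A, B; C, D) = mean of (a - b)(c - d); it is zero in expectation when
(A, B) form a clade with respect to (C, D), and departures are judged by the
conventional |Z| > 3 rule.

Standard errors come from the weighted block jackknife over chromosomes
(blocks of unequal SNP counts m_k, n = sum m_k, g blocks):

    h_k   = n / m_k
    tau_k = h_k * theta_hat - (h_k - 1) * theta_hat_{-k}
    theta_J = g * theta_hat - sum_k (1 - m_k / n) * theta_hat_{-k}
    SE^2  = (1/g) * sum_k (tau_k - theta_J)^2 / (h_k - 1)

PCA: modern individuals are standardised per SNP by mean mu_j and scale
sqrt(p_j (1 - p_j)) with p_j = mu_j / 2, missing entries set to 0 after
centering, and decomposed by SVD.  Low-coverage samples are placed by least
squares on their non-missing SNPs (lsq projection); their uncertainty is a
take-one-chromosome-out jackknife that refits the projection, never the
basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypePanel


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_freqs(panel: GenotypePanel, populations: list[str] | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(frequencies, has_data): per-population per-SNP reference-allele
    frequency (NaN where a population has no data) and a boolean mask."""
    groups = panel.population_indices()
    populations = populations or list(groups)
    rows, masks = [], []
    for p in populations:
        idx = groups.get(p)
        if idx is None or idx.size == 0:
            raise ValueError(f"population {p!r} is empty or absent")
        g = panel.genotypes[idx].astype(float)
        g[g == MISSING] = np.nan
        cnt = np.sum(~np.isnan(g), axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(g, axis=0) / (2.0 * cnt)
        freq[cnt == 0] = np.nan
        rows.append(freq)
        masks.append(cnt > 0)
    freqs = pd.DataFrame(rows, index=populations, columns=panel.snp["id"])
    has = pd.DataFrame(masks, index=populations, columns=panel.snp["id"])
    return freqs, has


def haploid_freqs(genotypes: np.ndarray) -> np.ndarray:
    """Frequency vector for one pseudo-haploid sample (codes 0/2/9)."""
    f = genotypes.astype(float) / 2.0
    f[genotypes == MISSING] = np.nan
    return f


# ---------------------------------------------------------------------------
# Weighted block jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeResult:
    estimate: float
    se: float
    n: int
    n_blocks: int
    block_estimates: np.ndarray  # leave-one-out estimates per block
    block_sizes: np.ndarray


def weighted_jackknife(theta_hat: float, theta_minus: np.ndarray,
                       block_sizes: np.ndarray) -> tuple[float, float]:
    """(bias-corrected estimate theta_J, SE) from leave-block-out estimates."""
    m = np.asarray(block_sizes, dtype=float)
    g = m.size
    if g < 2:
        raise ValueError("need at least 2 blocks for a jackknife")
    if (m < 1).any():
        raise ValueError("block sizes must be >= 1")
    n = m.sum()
    h = n / m
    tau = h * theta_hat - (h - 1.0) * theta_minus
    theta_j = g * theta_hat - float(np.sum((1.0 - m / n) * theta_minus))
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    return theta_j, float(np.sqrt(var))


def block_jackknife(contributions: np.ndarray, block_labels: np.ndarray) -> JackknifeResult:
    """Jackknife of a mean over per-SNP contributions grouped into blocks."""
    x = np.asarray(contributions, dtype=float)
    labels = np.asarray(block_labels)
    if x.size != labels.size:
        raise ValueError("contributions and block labels differ in length")
    if not np.isfinite(x).all():
        raise ValueError("non-finite contributions")
    uniq, inv = np.unique(labels, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise ValueError("need at least 2 blocks")
    n = x.size
    total = x.sum()
    block_sum = np.bincount(inv, weights=x, minlength=g)
    m = np.bincount(inv, minlength=g).astype(float)
    theta_hat = total / n
    theta_minus = (total - block_sum) / (n - m)
    _, se = weighted_jackknife(theta_hat, theta_minus, m)
    return JackknifeResult(estimate=float(theta_hat), se=se, n=n, n_blocks=g,
                           block_estimates=theta_minus, block_sizes=m.astype(int))


# ---------------------------------------------------------------------------
# f statistics
# ---------------------------------------------------------------------------

@dataclass
class FStatResult:
    value: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    block_estimates: np.ndarray = field(repr=False)


def _fstat(contrib: np.ndarray, usable: np.ndarray, blocks: np.ndarray,
           min_snps: int) -> FStatResult:
    idx = np.flatnonzero(usable)
    if idx.size < min_snps:
        raise ValueError(f"only {idx.size} usable SNPs (< {min_snps} required)")
    jk = block_jackknife(contrib[idx], blocks[idx])
    z = jk.estimate / jk.se if jk.se > 0 else 0.0 if jk.estimate == 0 else np.inf * np.sign(jk.estimate)
    return FStatResult(value=jk.estimate, se=jk.se, z=float(z), n_snps=jk.n,
                       n_blocks=jk.n_blocks, block_estimates=jk.block_estimates)


def f3_outgroup(a: np.ndarray, b: np.ndarray, o: np.ndarray, block_labels: np.ndarray,
                min_snps: int = 1000) -> FStatResult:
    """Outgroup-f3: mean (a-o)(b-o) over SNPs where all three are non-missing.

    The default 1000-SNP floor mirrors reporting practice for sparse ancient
    samples; pass a smaller ``min_snps`` explicitly for unit-scale data.
    """
    a, b, o = (np.asarray(x, dtype=float) for x in (a, b, o))
    usable = ~(np.isnan(a) | np.isnan(b) | np.isnan(o))
    contrib = np.where(usable, (a - o) * (b - o), 0.0)
    return _fstat(contrib, usable, np.asarray(block_labels), min_snps)


def f4_stat(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
            block_labels: np.ndarray, min_snps: int = 1) -> FStatResult:
    """f4(A,B;C,D) = mean (a-b)(c-d); |Z| > 3 is the significance convention."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    usable = ~(np.isnan(a) | np.isnan(b) | np.isnan(c) | np.isnan(d))
    contrib = np.where(usable, (a - b) * (c - d), 0.0)
    return _fstat(contrib, usable, np.asarray(block_labels), min_snps)


# ---------------------------------------------------------------------------
# PCA fit and least-squares projection
# ---------------------------------------------------------------------------

@dataclass
class PCABasis:
    loadings: np.ndarray      # (n_kept_snps, n_pcs) SNP loadings, orthonormal
    eigenvalues: np.ndarray
    scores: pd.DataFrame      # individual scores (rows: individual ids)
    mean: np.ndarray          # per kept SNP
    scale: np.ndarray         # per kept SNP
    kept: np.ndarray          # indices of kept SNPs in the fitting panel
    snp_ids: np.ndarray
    dropped_monomorphic: int = 0


def pca_fit(panel: GenotypePanel, populations: list[str] | None = None,
            n_pcs: int | None = None) -> PCABasis:
    """SVD of the standardised modern genotype matrix.

    Missing entries are mean-imputed (0 after centering); monomorphic SNPs
    are dropped; each PC's sign is fixed so its largest-|loading| entry is
    positive.
    """
    if populations is not None:
        groups = panel.population_indices()
        idx = np.concatenate([groups[p] for p in populations])
    else:
        idx = np.arange(panel.genotypes.shape[0])
    ids = panel.individuals["id"].to_numpy()[idx]
    g = panel.genotypes[idx].astype(float)
    if g.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    p = mu / 2.0
    scale = np.sqrt(p * (1.0 - p))
    kept = np.flatnonzero((scale > 0) & np.isfinite(scale) & (np.nanvar(g, axis=0) > 0))
    dropped = g.shape[1] - kept.size
    x = (g[:, kept] - mu[kept]) / scale[kept]
    x[np.isnan(x)] = 0.0
    max_pcs = min(x.shape) - 1 if min(x.shape) > 1 else 1
    k = max_pcs if n_pcs is None else n_pcs
    if k > min(x.shape):
        raise ValueError(f"requested {k} PCs from a {x.shape} matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| entry of each PC is positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = pd.DataFrame(u * s, index=ids, columns=[f"PC{i+1}" for i in range(k)])
    eig = s ** 2 / max(x.shape[0] - 1, 1)
    return PCABasis(loadings=vt.T, eigenvalues=eig, scores=scores, mean=mu[kept],
                    scale=scale[kept], kept=kept,
                    snp_ids=panel.snp["id"].to_numpy()[kept], dropped_monomorphic=dropped)


@dataclass
class PCAProjection:
    coordinates: np.ndarray
    se: np.ndarray | None
    n_snps: int
    n_pcs: int


def _project(values: np.ndarray, basis: PCABasis, n_pcs: int,
             use: np.ndarray) -> np.ndarray:
    v = basis.loadings[use, :n_pcs]
    x = (values[use] - basis.mean[use]) / basis.scale[use]
    if np.linalg.matrix_rank(v) < n_pcs:
        raise ValueError("restricted loadings are rank deficient")
    coef, *_ = np.linalg.lstsq(v, x, rcond=None)
    return coef


def pca_project(calls: np.ndarray, basis: PCABasis, n_pcs: int = 2) -> PCAProjection:
    """Least-squares placement of a (possibly sparse, haploid-coded 0/2)
    sample into a fixed PC basis using its non-missing SNPs."""
    calls = np.asarray(calls)
    vals = calls[basis.kept].astype(float)
    use = calls[basis.kept] != MISSING
    if int(use.sum()) < n_pcs:
        raise ValueError(f"sample has {int(use.sum())} usable SNPs < {n_pcs} PCs")
    coef = _project(vals, basis, n_pcs, np.flatnonzero(use))
    return PCAProjection(coordinates=coef, se=None, n_snps=int(use.sum()), n_pcs=n_pcs)


def pca_jackknife(calls: np.ndarray, basis: PCABasis, chromosomes: np.ndarray,
                  n_pcs: int = 2) -> PCAProjection:
    """Take-one-chromosome-out jackknife of the projected coordinates.

    The PC basis stays fixed; only the least-squares projection is refit on
    the sample's remaining non-missing SNPs, and the leave-out coordinates
    feed the weighted jackknife with block sizes m_k = the sample's
    non-missing SNP count on chromosome k.
    """
    calls = np.asarray(calls)
    chroms = np.asarray(chromosomes)[basis.kept]
    vals = calls[basis.kept].astype(float)
    nonmiss = calls[basis.kept] != MISSING
    labels = np.unique(chroms[nonmiss])
    if labels.size < 2:
        raise ValueError("sample's informative SNPs span fewer than 2 chromosomes")
    full = _project(vals, basis, n_pcs, np.flatnonzero(nonmiss))
    minus = np.empty((labels.size, n_pcs))
    sizes = np.empty(labels.size, dtype=int)
    for bi, c in enumerate(labels):
        use = nonmiss & (chroms != c)
        minus[bi] = _project(vals, basis, n_pcs, np.flatnonzero(use))
        sizes[bi] = int((nonmiss & (chroms == c)).sum())
    se = np.empty(n_pcs)
    for pc in range(n_pcs):
        _, se[pc] = weighted_jackknife(full[pc], minus[:, pc], sizes)
    return PCAProjection(coordinates=full, se=se, n_snps=int(nonmiss.sum()), n_pcs=n_pcs)
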