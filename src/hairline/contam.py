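"""Deamination-conditioned contamination estimation.

Each aligned read is scored under two per-read likelihood components: an
endogenous component in which a reference-C at read position i of an L-long
read is observed as T with probability d(i,L) (the damage curve) plus
sequencing error, and a contaminant component with the same error model but
no deamination (d = 0).  The contaminant fraction rho maximises

    L(rho) = sum_r log[ rho * exp(ll_cont_r) + (1 - rho) * exp(ll_endo_r) ]

which is concave in rho.  This is an independent-sites mixture: the hidden
single-/double-stranded state machinery of full-likelihood tools is
deliberately not reproduced, which is adequate here because the simulator's
damage process is itself independent across sites.

Only reference-C positions enter the likelihoods: all other positions
contribute identical factors to both components and cancel in the mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .align import AlignedRead, Alignments
from .damage import DamageProfile, substitution_profile
from .simulate import DegradationParams, ReferenceSet
from .damage import _oriented_reference_flat
from ._util import segment_ids


class EmpiricalDamage:
    """Damage curve looked up from an observed profile.

    Position i (1-based from 5') uses the smoothed 5' rate while i <= P and
    i is closer to the 5' end; positions within P of the 3' end use the
    smoothed 3' rate; the interior falls back to the mean rate over 5'
    positions 10..P (the plateau).
    """

    def __init__(self, profile: DamageProfile, smooth: int = 3):
        if smooth < 1 or smooth % 2 == 0:
            raise ValueError("smooth must be an odd window size >= 1")
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        self.rate5 = np.convolve(np.pad(profile.ct5_rate, pad, mode="edge"), kernel, "valid")
        self.rate3 = np.convolve(np.pad(profile.ct3_rate, pad, mode="edge"), kernel, "valid")
        self.P = profile.positions
        lo = min(9, self.P - 1)
        self.plateau = float(self.rate5[lo:].mean())

    def rate(self, i, L):
        i = np.asarray(i, dtype=np.int64)
        L = np.asarray(L, dtype=np.int64)
        j = L - i + 1  # 1-based from the 3' end
        out = np.full(np.broadcast_shapes(i.shape, L.shape), self.plateau, dtype=float)
        i, L, j = np.broadcast_to(i, out.shape), np.broadcast_to(L, out.shape), np.broadcast_to(j, out.shape)
        use3 = j <= self.P
        use5 = (i <= self.P) & (i <= j)
        out[use3] = self.rate3[np.minimum(j[use3], self.P) - 1]
        out[use5] = self.rate5[i[use5] - 1]
        return out


@dataclass
class ContaminationModel:
    """Damage curve (parametric or empirical) plus the flat error prob; the
    contaminant component uses the same error with d identically zero.

    When the two fragment-length models are supplied, each component's
    likelihood additionally includes the probability of the read's length
    under that component.  Endogenous and contaminant molecules have very
    different length distributions, and a substitution-only mixture then
    over-weights the long (information-rich, contaminant-heavy) reads, so
    the length terms are required for the estimate to recover the
    count-weighted contaminant share; without them the estimate is the
    information-weighted share (documented limitation for real data, where
    the generative length models are unknown).
    """

    damage: DegradationParams | EmpiricalDamage
    eps: float = 0.001
    endo_length_model: "object | None" = None   # FragmentLengthModel
    cont_length_model: "object | None" = None
    #: when set (with the length models), components are conditioned on the
    #: mapper's mismatch-cap acceptance: damaged molecules fail it more often,
    #: so reads that survived mapping are a biased draw from each component
    max_mismatch_frac: float | None = None
    gc: float = 0.41

    def __post_init__(self):
        if not 0.0 <= self.eps < 1.0:
            raise ValueError("eps must be in [0,1)")
        if (self.endo_length_model is None) != (self.cont_length_model is None):
            raise ValueError("supply both length models or neither")
        if self.max_mismatch_frac is not None and self.endo_length_model is None:
            raise ValueError("mapping conditioning requires the length models")

    def rate(self, i, L):
        return np.clip(self.damage.rate(i, L), 0.0, 1.0)

    @property
    def has_length_models(self) -> bool:
        return self.endo_length_model is not None

    def length_logpmf(self, lengths: np.ndarray, component: str,
                      min_length: int | None = None) -> np.ndarray:
        """log P(length | component, survived the pipeline).

        The length filter truncates both components; with
        ``max_mismatch_frac`` set the normaliser is the component's full
        yield (length survival times mapper acceptance), which is the
        correct conditional density for reads observed after mapping.
        """
        model = self.endo_length_model if component == "endo" else self.cont_length_model
        out = np.zeros(lengths.size)
        if min_length is None:
            log_norm = 0.0
        elif self.max_mismatch_frac is not None:
            from .simulate import _effective_yield
            deg = self.damage if component == "endo" else None
            if deg is not None and not isinstance(deg, DegradationParams):
                deg = None  # empirical curves: fall back to error-only acceptance
            q = _effective_yield(model, int(min_length), deg, self.gc,
                                 self.max_mismatch_frac, self.eps)
            log_norm = np.log(max(q, 1e-300))
        else:
            log_norm = np.log(max(model.survival(int(min_length)), 1e-300))
        for L in np.unique(lengths):
            pmf = model.survival(int(L)) - model.survival(int(L) + 1)
            out[lengths == L] = np.log(max(pmf, 1e-300)) - log_norm
        return out


def model_from_alignments(alignments: Alignments, ref: ReferenceSet, positions: int = 25,
                          smooth: int = 3, eps: float = 0.001) -> ContaminationModel:
    """Self-calibrated model: empirical damage profile of the same library."""
    return ContaminationModel(EmpiricalDamage(substitution_profile(alignments, ref, positions),
                                              smooth=smooth), eps=eps)


def _component_logliks(alignments: Alignments, ref: ReferenceSet,
                       model: ContaminationModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ll_endo, ll_cont, informative) per read, over reference-C positions."""
    refflat = _oriented_reference_flat(alignments, ref)
    readflat = alignments.flat
    offsets = alignments.offsets
    ids = segment_ids(offsets)
    within = np.arange(int(offsets[-1]), dtype=np.int64) - offsets[ids]
    lengths = alignments.lengths[ids]

    is_c = refflat == 1
    d = np.zeros(refflat.size)
    d[is_c] = model.rate(within[is_c] + 1, lengths[is_c])
    eps = model.eps

    def loglik(dvec):
        p_t = dvec + (1.0 - dvec) * eps / 3.0
        p_c = (1.0 - dvec) * (1.0 - eps) + dvec * eps / 3.0
        p_other = np.maximum((1.0 - p_t - p_c) / 2.0, 1e-300)
        obs = readflat
        p = np.where(obs == 3, p_t, np.where(obs == 1, p_c, p_other))
        contrib = np.zeros(refflat.size)
        contrib[is_c] = np.log(np.maximum(p[is_c], 1e-300))
        n_reads = len(alignments)
        return np.bincount(ids[is_c], weights=contrib[is_c], minlength=n_reads)

    ll_endo = loglik(d)
    ll_cont = loglik(np.zeros_like(d))
    if model.has_length_models:
        L = alignments.lengths
        min_length = int(L.min()) if L.size else None
        ll_endo = ll_endo + model.length_logpmf(L, "endo", min_length)
        ll_cont = ll_cont + model.length_logpmf(L, "cont", min_length)
    informative = np.bincount(ids[is_c], minlength=len(alignments)) > 0
    if model.has_length_models:
        informative = np.ones(len(alignments), dtype=bool)
    return ll_endo, ll_cont, informative


def read_loglik(read: AlignedRead, ref: ReferenceSet, model: ContaminationModel,
                component: str) -> float:
    """Log-likelihood of one read under 'endo' or 'cont'."""
    if component not in ("endo", "cont"):
        raise ValueError("component must be 'endo' or 'cont'")
    aln = Alignments.from_records([read], chrom_names=list(ref.names))
    ll_endo, ll_cont, _ = _component_logliks(aln, ref, model)
    return float(ll_endo[0] if component == "endo" else ll_cont[0])


@dataclass
class ContaminationEstimate:
    rho: float
    se: float
    loglik: float
    n_reads: int
    boundary: bool

    def as_dict(self) -> dict:
        return {"rho": self.rho, "se": self.se, "loglik": self.loglik,
                "n": self.n_reads, "boundary": self.boundary}


def _mixture_loglik_terms(ll_endo, ll_cont):
    """Stable per-read pieces: returns a function L(rho) and derivatives."""
    llr = ll_cont - ll_endo

    def total(rho):
        if rho <= 0.0:
            return float(ll_endo.sum())
        if rho >= 1.0:
            return float(ll_cont.sum())
        return float(np.logaddexp(np.log(rho) + ll_cont, np.log1p(-rho) + ll_endo).sum())

    def dtotal(rho):
        # sum (r-1)/(rho r + 1 - rho) with r = exp(llr), computed stably
        pos = llr > 0
        out = np.empty_like(llr)
        r = np.exp(llr[~pos])
        out[~pos] = (r - 1.0) / (rho * r + (1.0 - rho))
        rinv = np.exp(-llr[pos])
        out[pos] = (1.0 - rinv) / (rho + (1.0 - rho) * rinv)
        return float(out.sum())

    def d2total(rho):
        pos = llr > 0
        out = np.empty_like(llr)
        r = np.exp(llr[~pos])
        out[~pos] = ((r - 1.0) / (rho * r + (1.0 - rho))) ** 2
        rinv = np.exp(-llr[pos])
        out[pos] = ((1.0 - rinv) / (rho + (1.0 - rho) * rinv)) ** 2
        return -float(out.sum())

    return total, dtotal, d2total


def estimate_contamination(alignments: Alignments, ref: ReferenceSet,
                           model: ContaminationModel, method: str = "mle",
                           min_reads: int = 100) -> ContaminationEstimate:
    """MLE of the contaminant fraction with Fisher-information SE.

    Near a boundary (rho within 1e-4 of 0 or 1) the boundary flag is set and
    a one-sided profile-likelihood SE (0.5 log-lik drop) is reported instead.
    """
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    ll_endo, ll_cont, informative = _component_logliks(alignments, ref, model)
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError("all reads are uninformative (no reference-C positions)")
    if n_inf < min_reads:
        raise ValueError(f"need >= {min_reads} informative reads, got {n_inf}")
    ll_endo, ll_cont = ll_endo[informative], ll_cont[informative]

    total, dtotal, d2total = _mixture_loglik_terms(ll_endo, ll_cont)

    # golden-section/Brent bracketing, then Newton polish
    res = minimize_scalar(lambda r: -total(r), bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(np.clip(res.x, 0.0, 1.0))
    for _ in range(10):
        d1, d2 = dtotal(rho), d2total(rho)
        if d2 >= 0:
            break
        step = d1 / d2
        new = float(np.clip(rho - step, 0.0, 1.0))
        if abs(new - rho) < 1e-10:
            rho = new
            break
        rho = new
    # boundary snap: if the likelihood is decreasing at 0 (increasing at 1)
    if dtotal(1e-12) <= 0:
        rho = 0.0
    elif dtotal(1.0 - 1e-12) >= 0:
        rho = 1.0

    boundary = rho < 1e-4 or rho > 1.0 - 1e-4
    ll_max = total(rho)
    if not boundary:
        info = -d2total(rho)
        se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    else:
        # one-sided profile SE: rho shift giving a 0.5 log-likelihood drop
        from scipy.optimize import brentq
        direction = 1.0 if rho < 0.5 else -1.0
        lo, hi = (rho, 1.0) if direction > 0 else (0.0, rho)
        f = lambda r: total(r) - (ll_max - 0.5)  # noqa: E731
        try:
            edge = hi if direction > 0 else lo
            if f(edge) > 0:
                se = float(abs(edge - rho))
            else:
                se = float(abs(brentq(f, min(rho + 1e-12, 1.0), hi) - rho)) if direction > 0 \
                    else float(abs(brentq(f, lo, max(rho - 1e-12, 0.0)) - rho))
        except ValueError:
            se = float("nan")
    return ContaminationEstimate(rho=float(rho), se=se, loglik=float(ll_max),
                                 n_reads=n_inf, boundary=bool(boundary))
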