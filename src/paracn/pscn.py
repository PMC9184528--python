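"""Paralog-specific copy number (ParalogCN) via PSVs and an EM algorithm.

For a repeat with reference copy number c_r, a sample with AggregateCN c_s
has a ParalogCN tuple: a length-(c_r/2) non-negative integer vector summing
to c_s (one entry per repeat copy, copy order fixed across samples).  PSV
reference alleles are not necessarily fixed in the population, so the
frequency f_vk of the reference allele of PSV v on copy k is estimated
jointly with the hidden per-sample tuples by EM over samples whose
AggregateCN equals c_r.  PSVs with min_k f_vk >= 0.95 are *reliable* copy
markers; only those are used to genotype individual samples (one E-step
with f frozen).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

RELIABLE_MIN_F = 0.95
MIN_REF_SAMPLES = 50
MAX_REF_CN = 8
MAX_TUPLES = 500
MIN_RELIABLE_PSVS = 3
SEQ_ERROR = 0.01        # per-read probability of an off-model ("other") allele
BASEQ_THRESHOLD = 20    # min base quality when counting reads at a PSV
EM_TOL = 1e-3
EM_MAX_ITER = 100
N_RESTARTS = 2  # per-PSV grid restarts in the M-step handle multimodality
F_INIT = 0.9
EVEN_SPLIT_PRIOR = 0.5  # genotyping prior weight on the even tuple at c_s=c_r
QUALITY_CAP = 100.0

SKIP_REF_CN = "ref_cn>8"
SKIP_TUPLES = "tuples>500"
SKIP_FEW_PSVS = "too_few_reliable_psvs"
SKIP_FEW_SAMPLES = "too_few_ref_samples"


def n_tuples(c_r: int, c_s: int) -> int:
    """Closed-form tuple count C(c_s + c_r/2 - 1, c_r/2 - 1)."""
    k = c_r // 2
    return math.comb(c_s + k - 1, k - 1)


def enumerate_tuples(c_r: int, c_s: int) -> list[tuple[int, ...]]:
    """All ParalogCN tuples for reference CN c_r and AggregateCN c_s, in
    lexicographic order."""
    if c_r % 2 != 0:
        raise ValueError("reference copy number must be even")
    if c_r < 2:
        raise ValueError("reference copy number must be >= 2")
    if c_s < 0:
        raise ValueError("AggregateCN must be non-negative")
    k = c_r // 2
    out = []
    # compositions of c_s into k parts via bar placement
    for bars in combinations_with_replacement(range(c_s + 1), k - 1):
        cuts = (0,) + bars + (c_s,)
        out.append(tuple(cuts[i + 1] - cuts[i] for i in range(k)))
    return sorted(out)


def allele_prob(
    t, f_row, alleles: list[str] | None = None, *, eps: float = SEQ_ERROR
) -> np.ndarray:
    """Probability that a read at this PSV shows each distinct allele.

    ``t`` is the ParalogCN tuple, ``f_row`` the PSV's reference-allele
    frequency per copy.  A chromosome of copy k carries copy k's reference
    allele with probability f_k; otherwise it carries one of the *other*
    copies' alleles, uniformly over the distinct alternatives (alleles shared
    between copies pool their mass).  A sequencing-error mass ``eps`` goes to
    a trailing "other" bin.  Returns a vector over the distinct allele
    strings of the PSV plus "other"; sums to 1.
    """
    t = np.asarray(t, dtype=float)
    f_row = np.asarray(f_row, dtype=float)
    c_s = t.sum()
    if c_s <= 0:
        raise ValueError("allele probabilities undefined at AggregateCN 0")
    k = len(t)
    if alleles is None:
        alleles = [str(i) for i in range(k)]  # distinct by construction
    distinct: list[str] = []
    for a in alleles:
        if a not in distinct:
            distinct.append(a)
    aidx = {a: i for i, a in enumerate(distinct)}
    probs = np.zeros(len(distinct) + 1)
    for j in range(k):
        own = aidx[alleles[j]]
        probs[own] += t[j] * f_row[j] / c_s
        alts = [a for a in distinct if a != alleles[j]]
        if alts:
            share = t[j] * (1.0 - f_row[j]) / c_s / len(alts)
            for a in alts:
                probs[aidx[a]] += share
        else:
            probs[own] += t[j] * (1.0 - f_row[j]) / c_s
    probs *= 1.0 - eps
    probs[-1] = eps
    return probs


@dataclass
class PsvSet:
    """Alleles of each PSV per copy, defining the count columns.

    ``counts`` arrays elsewhere have one column per distinct allele of the
    PSV (order of first appearance over copies) plus a final "other" column.
    """

    alleles: list[list[str]]  # per PSV, one allele string per copy

    def __post_init__(self):
        kk = {len(a) for a in self.alleles}
        if len(kk) > 1:
            raise ValueError("all PSVs must cover the same copies")

    @property
    def n_psvs(self) -> int:
        return len(self.alleles)

    @property
    def n_copies(self) -> int:
        return len(self.alleles[0]) if self.alleles else 0

    @classmethod
    def biallelic(cls, n_psvs: int) -> "PsvSet":
        return cls([["A", "B"]] * n_psvs)


@dataclass
class FMatrix:
    """PSV reference-allele frequencies f[v][k] with per-PSV support."""

    f: np.ndarray                 # (V, K) in [0, 1]
    support: np.ndarray           # effective samples per PSV

    def reliable(self, min_f: float = RELIABLE_MIN_F) -> np.ndarray:
        return classify_reliable(self.f, min_f=min_f)


def classify_reliable(f: np.ndarray, *, min_f: float = RELIABLE_MIN_F):
    """A PSV is reliable iff its f values are all close to 1
    (min over copies >= 0.95)."""
    f = np.asarray(f)
    return f.min(axis=-1) >= min_f


@dataclass
class ParalogCnCall:
    sample: str
    tuple: tuple[int, ...] | None
    posterior: float = 0.0
    copy_qualities: list[float] = field(default_factory=list)
    skip_reason: str | None = None


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


class _CarriageModel:
    """Carriage-marginalized read likelihood over PSVs and tuples.

    A sample's chromosomes are fixed draws: each of the t_k chromosomes of
    copy k carries copy k's reference allele with probability f_vk,
    otherwise one of the other distinct alleles (uniformly).  Reads then
    sample chromosomes.  Marginalizing the carriage configuration g (the
    number of reference-carrying chromosomes per copy) keeps the
    between-sample overdispersion that identifies f: a polymorphic PSV
    (f ~ 0.5) produces spread allele ratios across samples where a fixed
    PSV (f = 1) produces tight ones — their read-level *marginals* can
    coincide exactly on reference-tuple cohorts.  Exact for distinct-allele
    PSVs; for shared alleles the non-carrier allele choice stays collapsed.

    Only the binomial carriage weights depend on f, so per (PSV, tuple) the
    allele probabilities and their projection onto the observed counts are
    precomputed once.
    """

    def __init__(self, counts, psvs: PsvSet, tuples, eps: float):
        self.tuples = [np.asarray(t, dtype=int) for t in tuples]
        self.S = counts[0].shape[0]
        self.T = len(tuples)
        self.V = psvs.n_psvs
        # per (v, ti): grid (G, K), log-binomial-coefficients (G,),
        # count projection (S, G) = counts_v @ log p(alleles | g).T
        self.grid: list[list[np.ndarray]] = []
        self.logcomb: list[list[np.ndarray]] = []
        self.proj: list[list[np.ndarray]] = []
        for v in range(self.V):
            alleles = psvs.alleles[v]
            distinct: list[str] = []
            for a in alleles:
                if a not in distinct:
                    distinct.append(a)
            aidx = {a: i for i, a in enumerate(distinct)}
            A = len(distinct)
            gv, cv_, pv = [], [], []
            for t in self.tuples:
                c_s = int(t.sum())
                if c_s == 0:
                    gv.append(None)
                    cv_.append(None)
                    pv.append(None)
                    continue
                axes = [np.arange(tk + 1) for tk in t]
                mesh = np.meshgrid(*axes, indexing="ij")
                grid = np.stack([m.ravel() for m in mesh], axis=1)  # (G, K)
                G = grid.shape[0]
                logcomb = np.zeros(G)
                probs = np.zeros((G, A + 1))
                for j, tk in enumerate(t):
                    logcomb += np.log(
                        [math.comb(tk, int(g)) for g in grid[:, j]]
                    )
                    probs[:, aidx[alleles[j]]] += grid[:, j] / c_s
                    non = (tk - grid[:, j]) / c_s
                    alts = [a for a in distinct if a != alleles[j]]
                    if alts:
                        for a in alts:
                            probs[:, aidx[a]] += non / len(alts)
                    else:
                        probs[:, aidx[alleles[j]]] += non
                probs *= 1.0 - eps
                probs[:, A] = eps
                logp = np.log(np.maximum(probs, 1e-300))
                gv.append(grid)
                cv_.append(logcomb)
                pv.append(counts[v] @ logp.T)  # (S, G)
            self.grid.append(gv)
            self.logcomb.append(cv_)
            self.proj.append(pv)

    def _logw(self, v: int, ti: int, f_row: np.ndarray) -> np.ndarray:
        grid = self.grid[v][ti]
        t = self.tuples[ti]
        f = np.clip(np.asarray(f_row, dtype=float), 1e-12, 1 - 1e-12)
        return (
            self.logcomb[v][ti]
            + grid @ np.log(f)
            + (t[None, :] - grid) @ np.log1p(-f)
        )

    def loglik_psv(self, v: int, f_row) -> np.ndarray:
        """(S, T) log-likelihood contribution of one PSV."""
        out = np.zeros((self.S, self.T))
        for ti in range(self.T):
            if self.grid[v][ti] is None:
                continue
            logw = self._logw(v, ti, f_row)
            out[:, ti] = logsumexp(self.proj[v][ti] + logw[None, :], axis=1)
        return out

    def loglik(self, f: np.ndarray) -> np.ndarray:
        """(S, T) joint log-likelihood over all PSVs (independence)."""
        ll = np.zeros((self.S, self.T))
        for v in range(self.V):
            ll += self.loglik_psv(v, f[v])
        return ll


def _loglik_matrix(counts, psvs: PsvSet, tuples, f, eps: float) -> np.ndarray:
    """(S, T) log-likelihood of each sample's counts under each tuple,
    carriage configurations marginalized (multinomial coefficients omitted;
    constant in both t and f)."""
    return _CarriageModel(counts, psvs, tuples, eps).loglik(np.asarray(f))


def em_fit(
    counts,
    psvs: PsvSet,
    c_r: int,
    *,
    min_samples: int = MIN_REF_SAMPLES,
    eps: float = SEQ_ERROR,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    n_restarts: int = N_RESTARTS,
    seed: int = 0,
):
    """Joint EM for the f matrix and hidden ParalogCN tuples.

    Runs on samples whose AggregateCN equals c_r (the caller pre-filters);
    tuple prior is uniform.  E-step: posterior over tuples per sample.
    M-step: coordinate ascent, each f_vk maximized by bounded 1-D search on
    the expected complete-data log-likelihood.  Multiple seeded restarts
    break the copy-label symmetry; the best observed-data likelihood wins.

    Returns (FMatrix, posteriors (S, T), tuples, loglik_trace).
    """
    S = counts[0].shape[0]
    if S < min_samples:
        raise ValueError(
            f"{SKIP_FEW_SAMPLES}: {S} reference-CN samples < {min_samples}"
        )
    if c_r > MAX_REF_CN:
        raise ValueError(f"{SKIP_REF_CN}: reference CN {c_r}")
    tuples = enumerate_tuples(c_r, c_r)
    if len(tuples) > MAX_TUPLES:
        raise ValueError(f"{SKIP_TUPLES}: {len(tuples)} tuples")
    V, K = psvs.n_psvs, psvs.n_copies

    rng = np.random.default_rng(seed)
    inits = [np.full((V, K), F_INIT)]
    for _ in range(n_restarts):
        inits.append(rng.uniform(0.5, 1.0, size=(V, K)))

    model = _CarriageModel(counts, psvs, tuples, eps)
    best = None
    for f0 in inits:
        f = f0.copy()
        trace: list[float] = []
        post = None
        for _ in range(max_iter):
            ll = model.loglik(f)
            obs = float(logsumexp(ll - np.log(len(tuples)), axis=1).sum())
            if trace and obs < trace[-1] - 1e-6:
                logger.warning("EM log-likelihood decreased: %.6f -> %.6f",
                               trace[-1], obs)
            post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
            if trace and abs(obs - trace[-1]) < tol:
                trace.append(obs)
                break
            trace.append(obs)
            f = _m_step(model, f, post)
        if best is None or trace[-1] > best[3][-1]:
            best = (f, post, tuples, trace)
    f, post, tuples, trace = best
    support = np.full(V, float(S))
    return FMatrix(f, support), post, tuples, trace


_F_GRID = (0.5, 0.75, 0.9, 0.97, 1.0)


def _m_step(model: _CarriageModel, f, post) -> np.ndarray:
    """M-step over the rows of f (PSVs decouple given the posterior).

    Each PSV row is restarted from the best of its current value and a
    small grid of candidate rows — the expected complete-data likelihood is
    multimodal in f (a polymorphic and a fixed PSV can trap each other's
    basin) and the grid escapes such per-PSV local optima — then refined by
    bounded 1-D coordinate ascent.  Never decreases the Q-function.
    """
    from itertools import product as _product

    V, K = f.shape
    new_f = f.copy()
    for v in range(V):
        def q_of(row) -> float:
            return float((post * model.loglik_psv(v, row)).sum())

        best_row = new_f[v].copy()
        best_q = q_of(best_row)
        for cand in _product(_F_GRID, repeat=K):
            qc = q_of(np.asarray(cand, dtype=float))
            if qc > best_q:
                best_q, best_row = qc, np.asarray(cand, dtype=float)
        new_f[v] = best_row
        for k in range(K):
            def neg_q(x: float, v=v, k=k) -> float:
                row = new_f[v].copy()
                row[k] = x
                return -q_of(row)

            res = optimize.minimize_scalar(
                neg_q, bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun > best_q:
                new_f[v, k] = float(res.x)
                best_q = -res.fun
    return new_f


def count_psv_alleles(
    alignments, psvs, *, baseq: int = BASEQ_THRESHOLD
) -> tuple[PsvSet, list[np.ndarray]]:
    """Allele-specific read counts at PSV sites from one sample's alignments.

    For every PSV, reads overlapping each copy's position contribute the
    base they carry there (base quality >= ``baseq``); bases matching a
    copy-specific allele are tallied in that allele's column, anything else
    in the trailing "other" column.  Only substitution PSVs on forward-
    oriented copies are counted (indel PSVs are skipped with a log note).

    Returns (PsvSet, counts) with counts[v] a length-(A_v + 1) vector.
    """
    kept = [p for p in psvs if not p.is_indel
            and all(c.strand == "+" for c in p.copies)]
    skipped = len(psvs) - len(kept)
    if skipped:
        logger.info("skipping %d indel or reverse-strand PSV(s)", skipped)
    psv_set = PsvSet([p.alleles for p in kept])
    counts: list[np.ndarray] = []
    for psv in kept:
        distinct: list[str] = []
        for a in psv.alleles:
            if a not in distinct:
                distinct.append(a)
        vec = np.zeros(len(distinct) + 1, dtype=int)
        span = len(psv.alleles[0])
        for copy_iv in psv.copies:
            for read in alignments.fetch(
                copy_iv.contig, copy_iv.start, copy_iv.start + span
            ):
                if read.is_secondary or read.is_supplementary or read.is_unmapped:
                    continue
                pairs = {
                    rpos: qpos
                    for qpos, rpos in read.get_aligned_pairs(matches_only=True)
                }
                qpos = pairs.get(copy_iv.start)
                if qpos is None:
                    continue
                if read.query_qualities is not None and \
                        read.query_qualities[qpos] < baseq:
                    continue
                base = read.query_sequence[qpos : qpos + span]
                if base in distinct:
                    vec[distinct.index(base)] += 1
                else:
                    vec[len(distinct)] += 1
        counts.append(vec)
    return psv_set, counts


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------


def genotype_sample(
    sample_counts,
    c_s: int,
    c_r: int,
    fmat: FMatrix,
    psvs: PsvSet,
    *,
    sample: str = "sample",
    min_reliable: int = MIN_RELIABLE_PSVS,
    eps: float = SEQ_ERROR,
    even_split_prior: float = EVEN_SPLIT_PRIOR,
) -> ParalogCnCall:
    """ParalogCN call for one sample from reliable PSVs only.

    ``sample_counts``: list over PSVs of length-(A_v+1) count vectors.  The
    E-step of the EM runs with f frozen; per-copy qualities are Phred scores
    of the marginal posterior that copy k has its called value.
    """
    if c_r > MAX_REF_CN:
        return ParalogCnCall(sample, None, skip_reason=SKIP_REF_CN)
    tuples = enumerate_tuples(c_r, c_s)
    if n_tuples(c_r, c_r) > MAX_TUPLES:
        return ParalogCnCall(sample, None, skip_reason=SKIP_TUPLES)
    if c_s == 0:
        t0 = tuples[0]
        return ParalogCnCall(sample, t0, 1.0, [QUALITY_CAP] * len(t0))

    rel = fmat.reliable()
    idx = [v for v in range(psvs.n_psvs) if rel[v]]
    idx = [v for v in idx if np.asarray(sample_counts[v]).sum() > 0]
    if len(idx) < min_reliable:
        return ParalogCnCall(sample, None, skip_reason=SKIP_FEW_PSVS)

    sub_counts = [np.asarray(sample_counts[v])[None, :] for v in idx]
    sub_psvs = PsvSet([psvs.alleles[v] for v in idx])
    ll = _loglik_matrix(sub_counts, sub_psvs, tuples, fmat.f[idx], eps)[0]

    log_prior = np.full(len(tuples), -np.inf)
    if c_s == c_r:
        even = tuples.index(tuple([2] * (c_r // 2)))
        rest = np.log((1 - even_split_prior) / max(len(tuples) - 1, 1))
        log_prior[:] = rest
        log_prior[even] = np.log(even_split_prior)
    else:
        log_prior[:] = -np.log(len(tuples))
    lp = ll + log_prior
    lp -= logsumexp(lp)
    post = np.exp(lp)

    best = int(np.argmax(post))
    t_best = tuples[best]
    K = c_r // 2
    quals = []
    for k in range(K):
        marg = sum(post[i] for i, t in enumerate(tuples) if t[k] == t_best[k])
        err = max(1.0 - marg, 10 ** (-QUALITY_CAP / 10.0))
        quals.append(min(-10.0 * np.log10(err), QUALITY_CAP))
    return ParalogCnCall(sample, t_best, float(post[best]), quals)
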