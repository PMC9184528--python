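"""Mendelian trio concordance for paralog-specific copy number calls.

Diploid ParalogCN tuples are modelled as the sum of two independent haploid
tuples drawn from an unknown single-chromosome population distribution
(random mating).  That distribution is recovered from a cohort's diploid
calls by EM deconvolution, and the probability that a child's call is
reachable by transmitting one haploid tuple from each parent is computed by
summing over parental decompositions weighted by the haploid frequencies
(Bayes-conditioned on each parent's diploid call).  A trio is discordant
when this probability falls below 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

logger = logging.getLogger(__name__)

DISCORDANT_THRESHOLD = 0.01
MIN_CALLS = 20
QUALITY_THRESHOLD = 20.0
EM_TOL = 1e-8
EM_MAX_ITER = 500

Tuple = tuple[int, ...]


@dataclass
class HaploidFreqs:
    """Population distribution over single-chromosome ParalogCN tuples."""

    probs: dict[Tuple, float]
    loglik_trace: list[float]

    def support(self) -> list[Tuple]:
        return sorted(self.probs)

    def p(self, h: Tuple) -> float:
        return self.probs.get(h, 0.0)


@dataclass
class TrioVerdict:
    probability: float
    concordant: bool
    child_quality: float = np.inf
    mother_quality: float = np.inf
    father_quality: float = np.inf


def _decompositions(d: Tuple) -> list[tuple[Tuple, Tuple]]:
    """All ordered pairs (h1, h2) of haploid tuples with h1 + h2 == d."""
    ranges = [range(x + 1) for x in d]
    out = []
    for h1 in product(*ranges):
        h2 = tuple(a - b for a, b in zip(d, h1))
        out.append((h1, h2))
    return out


def fit_haploid_freqs(
    diploid_calls: list[Tuple],
    *,
    min_calls: int = MIN_CALLS,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaploidFreqs:
    """EM deconvolution of haploid tuple frequencies from diploid calls.

    The support is every haploid tuple occurring in a decomposition of an
    observed diploid tuple.  The observed-data log-likelihood is monotone
    non-decreasing; exact ties between equal-likelihood decompositions
    resolve deterministically because tuples are iterated in sorted order.
    """
    if len(diploid_calls) < min_calls:
        raise ValueError(
            f"need >= {min_calls} high-quality diploid calls, got "
            f"{len(diploid_calls)}"
        )
    obs: dict[Tuple, int] = {}
    for d in diploid_calls:
        obs[tuple(d)] = obs.get(tuple(d), 0) + 1
    decomp = {d: _decompositions(d) for d in sorted(obs)}
    support = sorted({h for pairs in decomp.values() for h, _ in pairs})
    hidx = {h: i for i, h in enumerate(support)}
    H = len(support)
    # a uniform start is a stationary saddle of the EM (fully symmetric
    # responsibilities reproduce it); initialize peaked at half the mean
    # diploid call, the random-mating center of mass
    center = np.mean([list(d) for d in diploid_calls], axis=0) / 2.0
    q = np.array(
        [np.exp(-float(np.sum((np.array(h) - center) ** 2))) for h in support]
    )
    q /= q.sum()
    n_total = sum(obs.values())

    trace: list[float] = []
    for _ in range(max_iter):
        loglik = 0.0
        expected = np.zeros(H)
        for d, count in sorted(obs.items()):
            pairs = decomp[d]
            w = np.array([q[hidx[h1]] * q[hidx[h2]] for h1, h2 in pairs])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
                tot = 1.0
                loglik += count * -700.0  # impossible observation under q
            else:
                loglik += count * float(np.log(tot))
            w /= w.sum()
            for (h1, h2), wi in zip(pairs, w):
                expected[hidx[h1]] += count * wi
                expected[hidx[h2]] += count * wi
        if trace and loglik < trace[-1] - 1e-9:
            logger.warning("deconvolution log-likelihood decreased")
        if trace and abs(loglik - trace[-1]) < tol:
            trace.append(loglik)
            break
        trace.append(loglik)
        q = expected / (2.0 * n_total)
        q = np.maximum(q, 0)
        q /= q.sum()
    probs = {h: float(q[hidx[h]]) for h in support if q[hidx[h]] > 1e-12}
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    return HaploidFreqs(probs, trace)


def _parent_decomp_weights(
    parent: Tuple, freqs: HaploidFreqs
) -> list[tuple[Tuple, Tuple, float]]:
    """Ordered decompositions of a parent's diploid call with posterior
    weights q(h1)q(h2) normalized over all decompositions of that call."""
    pairs = _decompositions(tuple(parent))
    w = np.array([freqs.p(h1) * freqs.p(h2) for h1, h2 in pairs])
    tot = w.sum()
    if tot <= 0:
        # parent call unexplainable under the population model; fall back to
        # a uniform decomposition so the trio check remains defined
        w = np.full(len(pairs), 1.0 / len(pairs))
    else:
        w /= tot
    return [(h1, h2, float(wi)) for (h1, h2), wi in zip(pairs, w)]


def trio_probability(
    child: Tuple,
    mother: Tuple,
    father: Tuple,
    freqs: HaploidFreqs,
    *,
    threshold: float = DISCORDANT_THRESHOLD,
) -> TrioVerdict:
    """Probability that the child's diploid tuple arises from one transmitted
    haploid tuple per parent, marginalizing parental decompositions."""
    child = tuple(child)
    if not (len(child) == len(mother) == len(father)):
        raise ValueError("calls are from different loci (tuple lengths differ)")
    p = 0.0
    for mh1, mh2, wm in _parent_decomp_weights(tuple(mother), freqs):
        for fh1, fh2, wf in _parent_decomp_weights(tuple(father), freqs):
            hit = 0.0
            for hm in (mh1, mh2):
                for hf in (fh1, fh2):
                    if tuple(a + b for a, b in zip(hm, hf)) == child:
                        hit += 0.25
            p += wm * wf * hit
    return TrioVerdict(p, p >= threshold)
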