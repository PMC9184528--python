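"""Multi-sample HMM for aggregate copy number (AggregateCN) profiles.

Hidden states are candidate AggregateCN values c; observations are pooled
window read counts o_w^(s).  Emissions are Negative Binomial with the
background size parameter scaled by c/2 and a per-window scale factor m_w
shared by all samples, b_w^(s)(c) = NB(o_w^(s); n_w^(s) * c/2 * m_w, p_w^(s)).
Transitions between adjacent windows use two jump parameters per boundary,
a_up and a_down in [0, 1/10]: a jump from state i to j>i has probability
a_up^(j-i), to k<i probability a_down^(i-k); diagonals absorb the rest.

Fitting iterates: per-sample Forward-Backward -> joint maximum-likelihood
update of m_w -> Baum-Welch-style pooled update of transitions and the
initial distribution, until the total log-likelihood converges.  Viterbi
decoding then yields per-sample profiles with Phred segment qualities.
The fitted parameters can be frozen and reused to decode single samples.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

A_INIT = 1e-5            # first-iteration jump parameter
A_MIN, A_MAX = 1e-6, 0.1  # clamp for fitted jump parameters
M_MIN, M_MAX = 0.1, 10.0  # window scale factor bounds
PI_FLOOR_FACTOR = 10      # per-state floor 1 / (PI_FLOOR_FACTOR * S)
CONVERGENCE_TOL = 0.01
MAX_ITERATIONS = 30
QUALITY_CAP = 100.0
STATE_MARGIN = 6          # states capped at ref_cn + STATE_MARGIN

# copy number 0 still sees occasional mismapped reads: mixture of a point
# mass at zero and a geometric tail with mean 1
ZERO_CN_DELTA = 0.99
_LOG_DELTA = np.log(ZERO_CN_DELTA)
_LOG_TAIL = np.log(1.0 - ZERO_CN_DELTA)


@dataclass(frozen=True)
class HmmStateSpace:
    copy_numbers: tuple[int, ...]
    ref_cn: int

    def __post_init__(self):
        cn = self.copy_numbers
        if not cn or any(b - a != 1 for a, b in zip(cn, cn[1:])):
            raise ValueError("states must be a contiguous increasing range")
        if self.ref_cn not in cn:
            raise ValueError("state space must contain the reference CN")

    @property
    def K(self) -> int:
        return len(self.copy_numbers)

    def index(self, cn: int) -> int:
        return self.copy_numbers.index(cn)


@dataclass
class HmmParams:
    states: HmmStateSpace
    pi: np.ndarray       # (K,)
    a_up: np.ndarray     # (W-1,)
    a_down: np.ndarray   # (W-1,)
    m: np.ndarray        # (W,)
    window_hash: str = ""
    converged: bool = True

    def to_json(self) -> dict:
        return {
            "copy_numbers": list(self.states.copy_numbers),
            "ref_cn": self.states.ref_cn,
            "pi": self.pi.tolist(),
            "a_up": self.a_up.tolist(),
            "a_down": self.a_down.tolist(),
            "m": self.m.tolist(),
            "window_hash": self.window_hash,
            "converged": self.converged,
        }

    @classmethod
    def from_json(cls, d: dict) -> "HmmParams":
        if not d:
            raise ValueError("empty HMM parameter record")
        return cls(
            HmmStateSpace(tuple(d["copy_numbers"]), d["ref_cn"]),
            np.asarray(d["pi"], dtype=float),
            np.asarray(d["a_up"], dtype=float),
            np.asarray(d["a_down"], dtype=float),
            np.asarray(d["m"], dtype=float),
            window_hash=d.get("window_hash", ""),
            converged=d.get("converged", True),
        )


@dataclass
class CnSegment:
    start_window: int
    end_window: int  # inclusive
    agg_cn: int
    quality: float


@dataclass
class CnProfile:
    sample: str
    segments: list[CnSegment]
    gamma: np.ndarray | None = None  # (W, K) posteriors, optionally retained

    def path(self) -> list[int]:
        out = []
        for seg in self.segments:
            out.extend([seg.agg_cn] * (seg.end_window - seg.start_window + 1))
        return out


def window_layout_hash(windows) -> str:
    key = ";".join(
        f"{r.contig}:{r.start}-{r.end}" for r in windows.itertuples()
    )
    return hashlib.sha256(key.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Model building blocks
# ---------------------------------------------------------------------------


def select_states(
    ref_cn: int, counts: np.ndarray, nb_means: np.ndarray
) -> HmmStateSpace:
    """Candidate AggregateCN range from observed normalized depth.

    Each sample's trimmed-mean normalized depth 2*o/e rounds to a copy
    number estimate; the state set is the contiguous range covering all
    estimates +-1, always containing ref_cn, clipped to [0, ref_cn + 6].
    """
    norm = 2.0 * counts / np.maximum(nb_means, 1e-9)
    est = []
    for row in norm:
        est.append(int(round(float(stats.trim_mean(row, 0.2)))))
    lo = min(min(est) - 1, ref_cn)
    hi = max(max(est) + 1, ref_cn)
    lo = max(lo, 0)
    hi = min(hi, ref_cn + STATE_MARGIN)
    return HmmStateSpace(tuple(range(lo, hi + 1)), ref_cn)


def log_emission(
    o: np.ndarray, n: np.ndarray, p: np.ndarray, c: int, m: np.ndarray
) -> np.ndarray:
    """log b(o; c) per window for one sample (arrays over windows)."""
    o = np.asarray(o)
    if np.any(o < 0):
        raise ValueError("negative read counts")
    if c == 0:
        tail = _LOG_TAIL + (o + 1) * np.log(0.5)  # geometric, mean 1
        return np.where(o == 0, np.logaddexp(_LOG_DELTA, tail), tail)
    return stats.nbinom.logpmf(o, n * (c / 2.0) * m, p)


def log_emission_matrix(
    o: np.ndarray, n: np.ndarray, p: np.ndarray, states: HmmStateSpace,
    m: np.ndarray,
) -> np.ndarray:
    """(W, K) log-emission matrix for one sample."""
    cols = [log_emission(o, n, p, c, m) for c in states.copy_numbers]
    logb = np.stack(cols, axis=1)
    dead = np.where(~np.isfinite(logsumexp(logb, axis=1)))[0]
    if dead.size:
        raise ValueError(f"all-zero emission row at window {int(dead[0])}")
    return logb


def transition_matrix(a_up: float, a_down: float, K: int) -> np.ndarray:
    """K x K stochastic matrix from the two geometric jump parameters."""
    if not (0 <= a_up <= A_MAX and 0 <= a_down <= A_MAX):
        raise ValueError("jump parameters must lie in [0, 0.1]")
    A = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if j > i:
                A[i, j] = a_up ** (j - i)
            elif j < i:
                A[i, j] = a_down ** (i - j)
    diag = 1.0 - A.sum(axis=1)
    if np.any(diag < 0):
        logger.warning("transition diagonal went negative; renormalizing rows")
        np.fill_diagonal(A, 0.0)
        A /= A.sum(axis=1, keepdims=True)
    else:
        np.fill_diagonal(A, diag)
    return A


def _log_transitions(params: HmmParams) -> np.ndarray:
    K = params.states.K
    out = np.empty((len(params.a_up), K, K))
    with np.errstate(divide="ignore"):
        for w, (u, d) in enumerate(zip(params.a_up, params.a_down)):
            out[w] = np.log(transition_matrix(u, d, K))
    return out


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def _lse(a: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Minimal log-sum-exp (scipy's carries too much call overhead for the
    per-window recursions)."""
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


def forward_backward(
    logb: np.ndarray, log_pi: np.ndarray, log_trans: np.ndarray
):
    """Log-space Forward-Backward.

    Returns (gamma (W,K), xi (W-1,K,K), log-likelihood); gamma rows and xi
    slices are normalized probabilities.
    """
    W, K = logb.shape
    alpha = np.empty((W, K))
    beta = np.empty((W, K))
    alpha[0] = log_pi + logb[0]
    for w in range(1, W):
        alpha[w] = logb[w] + _lse(alpha[w - 1][:, None] + log_trans[w - 1], 0)
    beta[-1] = 0.0
    for w in range(W - 2, -1, -1):
        beta[w] = _lse(log_trans[w] + (logb[w + 1] + beta[w + 1])[None, :], 1)
    loglik = float(logsumexp(alpha[-1]))
    if not np.isfinite(loglik):
        raise ValueError("non-finite likelihood in forward pass")
    gamma = np.exp(alpha + beta - loglik)
    gamma /= gamma.sum(axis=1, keepdims=True)
    # xi computed for all boundaries at once
    if W > 1:
        lx = (
            alpha[:-1, :, None]
            + log_trans
            + (logb[1:] + beta[1:])[:, None, :]
        )
        lx -= lx.max(axis=(1, 2), keepdims=True)
        xi = np.exp(lx)
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = np.empty((0, K, K))
    return gamma, xi, loglik


def viterbi(logb: np.ndarray, log_pi: np.ndarray, log_trans: np.ndarray):
    """Most probable state path (window state indices)."""
    W, K = logb.shape
    delta = log_pi + logb[0]
    back = np.zeros((W, K), dtype=int)
    for w in range(1, W):
        scores = delta[:, None] + log_trans[w - 1]
        back[w] = np.argmax(scores, axis=0)
        delta = scores[back[w], np.arange(K)] + logb[w]
    path = np.empty(W, dtype=int)
    path[-1] = int(np.argmax(delta))
    for w in range(W - 1, 0, -1):
        path[w - 1] = back[w, path[w]]
    return path, float(np.max(delta))


# ---------------------------------------------------------------------------
# Parameter updates
# ---------------------------------------------------------------------------


def update_scale(
    gammas: np.ndarray, counts: np.ndarray, nb_n: np.ndarray, nb_p: np.ndarray,
    states: HmmStateSpace, m: np.ndarray,
) -> np.ndarray:
    """Window scale factors maximizing the gamma-weighted NB log-likelihood.

    gammas: (S, W, K); counts, nb_n, nb_p: (S, W).  Each window solves a
    bounded 1-D problem; windows with zero depth in every sample keep their
    current value (the c=0 term does not depend on m).
    """
    S, W, K = gammas.shape
    cns = np.asarray(states.copy_numbers, dtype=float)
    new_m = m.copy()
    for w in range(W):
        if counts[:, w].sum() == 0:
            continue
        g = gammas[:, w, :]          # (S, K)
        o = counts[:, w][:, None]    # (S, 1)
        n0 = nb_n[:, w][:, None]
        p0 = nb_p[:, w][:, None]
        pos = cns > 0
        cpos = cns[pos][None, :]

        def neg_q(mv: float) -> float:
            lp = stats.nbinom.logpmf(o, n0 * (cpos / 2.0) * mv, p0)
            return -float((g[:, pos] * lp).sum())

        res = optimize.minimize_scalar(
            neg_q, bounds=(M_MIN, M_MAX), method="bounded",
            options={"xatol": 1e-4},
        )
        new_m[w] = float(res.x)
    return new_m


def _fit_jump_params(xi_sum: np.ndarray) -> tuple[float, float]:
    """ML fit of (a_up, a_down) for one boundary from pooled expected
    transition counts (K x K), using the geometric jump parametrization."""
    K = xi_sum.shape[0]
    iu, ju = np.triu_indices(K, k=1)
    il, jl = np.tril_indices(K, k=-1)

    def neg_ll(x: np.ndarray) -> float:
        up, down = x
        with np.errstate(divide="ignore"):
            A = transition_matrix(up, down, K)
            logA = np.log(np.maximum(A, 1e-300))
        return -float((xi_sum * logA).sum())

    res = optimize.minimize(
        neg_ll,
        x0=np.array([1e-3, 1e-3]),
        bounds=[(A_MIN, A_MAX)] * 2,
        method="L-BFGS-B",
    )
    up, down = res.x
    return float(np.clip(up, A_MIN, A_MAX)), float(np.clip(down, A_MIN, A_MAX))


def update_transitions_initial(
    gammas: np.ndarray, xis: np.ndarray, states: HmmStateSpace
):
    """Pooled Baum-Welch-style update of pi and per-boundary jump parameters.

    Shared events concentrate expected jump counts at the boundaries where
    they occur, raising a_up/a_down there; pi comes from pooled first-window
    posteriors with a per-state floor of 1/(10*S).
    """
    S = gammas.shape[0]
    pi = gammas[:, 0, :].sum(axis=0) / S
    pi = np.maximum(pi, 1.0 / (PI_FLOOR_FACTOR * S))
    pi /= pi.sum()

    Wm1 = xis.shape[1]
    a_up = np.empty(Wm1)
    a_down = np.empty(Wm1)
    for w in range(Wm1):
        a_up[w], a_down[w] = _fit_jump_params(xis[:, w].sum(axis=0))
    return pi, a_up, a_down


def refine_shared_boundaries(
    counts: np.ndarray, nb_n: np.ndarray, nb_p: np.ndarray,
    states: HmmStateSpace, params: HmmParams, *, margin: int = 8,
    min_members: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Sharpen transition spikes at boundaries of events shared by samples.

    Copy-number events present in several samples carry pooled breakpoint
    information that per-sample decoding cannot use: each sample's own
    boundary estimate wanders by a few windows at typical depth, while the
    cohort log-likelihood summed over carriers localizes the shared
    breakpoint almost exactly.  This step decodes all samples with the
    current parameters, clusters overlapping same-CN events, maximizes the
    pooled log-likelihood ratio over a shared (start, end) within ``margin``
    windows of the observed boundaries, and raises a_up/a_down to the
    ceiling at the consensus boundaries (elsewhere parameters keep their
    fitted values).  Deterministic; clusters smaller than ``min_members``
    carry too little pooled information and are left untouched.
    """
    S, W = counts.shape
    ref = states.ref_cn
    log_pi = np.log(params.pi)
    log_trans = _log_transitions(params)
    logbs = [
        log_emission_matrix(counts[s], nb_n[s], nb_p[s], states, params.m)
        for s in range(S)
    ]
    events: list[tuple[int, int, int, int]] = []  # (cn, start, end, sample)
    for s in range(S):
        path, _ = viterbi(logbs[s], log_pi, log_trans)
        w = 0
        while w < W:
            w2 = w
            while w2 + 1 < W and path[w2 + 1] == path[w]:
                w2 += 1
            cn = states.copy_numbers[path[w]]
            if cn != ref:
                events.append((cn, w, w2, s))
            w = w2 + 1
    a_up = params.a_up.copy()
    a_down = params.a_down.copy()
    # greedy overlap clustering per CN value
    events.sort()
    used = [False] * len(events)
    spikes: list[tuple[str, int]] = []            # (direction, boundary)
    suppress: list[tuple[int, int]] = []          # boundary ranges to reset
    for i, (cn, st, en, s) in enumerate(events):
        if used[i]:
            continue
        members = [(st, en, s)]
        used[i] = True
        lo, hi = st, en
        for j in range(i + 1, len(events)):
            cn2, st2, en2, s2 = events[j]
            if used[j] or cn2 != cn:
                continue
            if st2 <= hi and lo <= en2:
                members.append((st2, en2, s2))
                used[j] = True
                lo, hi = min(lo, st2), max(hi, en2)
        if len(members) < min_members:
            continue
        ki = states.index(cn)
        kr = states.index(ref)
        a_lo = max(0, min(m[0] for m in members) - margin)
        a_hi = min(W - 1, max(m[0] for m in members) + margin)
        b_lo = max(0, min(m[1] for m in members) - margin)
        b_hi = min(W - 1, max(m[1] for m in members) + margin)
        # pooled LLR of "event spans [a, b]" over member samples
        diff = np.zeros(W)
        for _, _, s2 in members:
            diff += logbs[s2][:, ki] - logbs[s2][:, kr]
        cum = np.concatenate([[0.0], np.cumsum(diff)])
        best, best_ab = -np.inf, None
        for a in range(a_lo, a_hi + 1):
            for b in range(max(b_lo, a), b_hi + 1):
                score = cum[b + 1] - cum[a]
                if score > best:
                    best, best_ab = score, (a, b)
        a, b = best_ab
        enter_up = cn > ref
        suppress += [(a_lo, a_hi), (b_lo, b_hi)]
        if a > 0:
            spikes.append(("up" if enter_up else "down", a - 1))
        if b < W - 1:
            spikes.append(("down" if enter_up else "up", b))
    # smear from shared events elevated nearby boundaries; reset them to the
    # background level first so the consensus spikes have contrast
    bg_up = float(np.median(a_up))
    bg_down = float(np.median(a_down))
    for lo2, hi2 in suppress:
        for w in range(max(lo2 - 1, 0), min(hi2 + 1, W - 1)):
            a_up[w] = min(a_up[w], bg_up)
            a_down[w] = min(a_down[w], bg_down)
    for direction, w in spikes:
        if direction == "up":
            a_up[w] = A_MAX
        else:
            a_down[w] = A_MAX
    return a_up, a_down


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def initial_params(
    states: HmmStateSpace, n_samples: int, n_windows: int
) -> HmmParams:
    K = states.K
    S = max(n_samples, K + 1)  # keep pi a valid distribution for tiny cohorts
    pi = np.full(K, 1.0 / S)
    pi[states.index(states.ref_cn)] = 1.0 - (K - 1) / S
    pi /= pi.sum()
    return HmmParams(
        states,
        pi,
        np.full(max(n_windows - 1, 0), A_INIT),
        np.full(max(n_windows - 1, 0), A_INIT),
        np.ones(n_windows),
    )


def _decode(
    o, n, p, params: HmmParams, sample: str, keep_gamma: bool = False
) -> CnProfile:
    logb = log_emission_matrix(o, n, p, params.states, params.m)
    log_pi = np.log(params.pi)
    log_trans = _log_transitions(params)
    path, _ = viterbi(logb, log_pi, log_trans)
    gamma, _, _ = forward_backward(logb, log_pi, log_trans)
    segments = []
    w = 0
    W = len(path)
    while w < W:
        w2 = w
        while w2 + 1 < W and path[w2 + 1] == path[w]:
            w2 += 1
        post = gamma[w : w2 + 1, path[w]]
        err = max(1.0 - float(post.min()), 10 ** (-QUALITY_CAP / 10.0))
        qual = min(-10.0 * np.log10(err), QUALITY_CAP)
        segments.append(
            CnSegment(w, w2, params.states.copy_numbers[path[w]], qual)
        )
        w = w2 + 1
    return CnProfile(sample, segments, gamma if keep_gamma else None)


def run_multi_sample(
    counts: np.ndarray,
    nb_n: np.ndarray,
    nb_p: np.ndarray,
    ref_cn: int,
    samples: list[str] | None = None,
    *,
    states: HmmStateSpace | None = None,
    tol: float = CONVERGENCE_TOL,
    max_iter: int = MAX_ITERATIONS,
    window_hash: str = "",
):
    """Joint fit over a cohort; returns (profiles, fitted HmmParams).

    counts, nb_n, nb_p: (S, W) pooled depth and per-sample background NB
    parameters for each window's GC.  The total log-likelihood is monitored
    every iteration; decreases beyond numerical noise are logged (updates
    are clamped, so exact monotonicity is not guaranteed).
    """
    counts = np.asarray(counts)
    S, W = counts.shape
    if samples is None:
        samples = [f"sample{i}" for i in range(S)]
    with np.errstate(divide="ignore", invalid="ignore"):
        nb_means = nb_n * (1 - nb_p) / nb_p
    if states is None:
        states = select_states(ref_cn, counts, nb_means)
    K = states.K
    params = initial_params(states, S, W)
    params.window_hash = window_hash

    prev_ll = -np.inf
    loglik_trace: list[float] = []
    for iteration in range(max_iter):
        log_pi = np.log(params.pi)
        log_trans = _log_transitions(params)
        gammas = np.empty((S, W, K))
        xis = np.empty((S, max(W - 1, 0), K, K))
        total_ll = 0.0
        for s in range(S):
            logb = log_emission_matrix(
                counts[s], nb_n[s], nb_p[s], states, params.m
            )
            gammas[s], xis[s], ll = forward_backward(logb, log_pi, log_trans)
            total_ll += ll
        loglik_trace.append(total_ll)
        if total_ll < prev_ll - 1e-6:
            logger.warning(
                "log-likelihood decreased at iteration %d (%.6f -> %.6f); "
                "parameter clamps are active",
                iteration, prev_ll, total_ll,
            )
        if abs(total_ll - prev_ll) < tol:
            params.converged = True
            break
        prev_ll = total_ll
        params.m = update_scale(gammas, counts, nb_n, nb_p, states, params.m)
        if W > 1:
            params.pi, params.a_up, params.a_down = update_transitions_initial(
                gammas, xis, states
            )
    else:
        params.converged = False
        logger.warning("HMM did not converge in %d iterations", max_iter)

    if W > 1 and K > 1:
        params.a_up, params.a_down = refine_shared_boundaries(
            counts, nb_n, nb_p, states, params
        )
    profiles = [
        _decode(counts[s], nb_n[s], nb_p[s], params, samples[s], keep_gamma=True)
        for s in range(S)
    ]
    return profiles, params, loglik_trace


def run_single_sample(
    counts: np.ndarray, nb_n: np.ndarray, nb_p: np.ndarray,
    params: HmmParams, sample: str = "sample", *, window_hash: str = "",
) -> CnProfile:
    """Decode one sample with frozen parameters (no updates)."""
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.shape[0] != params.m.shape[0]:
        raise ValueError("window layout does not match the frozen parameters")
    if window_hash and params.window_hash and window_hash != params.window_hash:
        raise ValueError("window layout hash mismatch")
    return _decode(counts, nb_n, nb_p, params, sample, keep_gamma=True)
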