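"""Two-state HMM segmentation of binned GRO-seq signal into transcript units.

The model has a non-transcribed state N and a transcribed state T.  Per-bin
read counts are emitted from a zero-inflated gamma in each state: a point
mass at zero (most bins carry no reads at typical depth) and a gamma density
for positive counts.  The gamma shape of the non-transcribed state and the
negative log transition probability out of the transcribed state are the two
knobs fixed by configuration (defaults 5 and 200; 5 and 10 for the
alpha-amanitin preset, which must resolve much shorter non-Pol II units);
the remaining emission parameters are fitted to each dataset by
expectation-maximization.  Decoding is Viterbi in log space with ties broken
toward N, so a signal-free genome yields zero transcripts deterministically.

States are indexed N=0, T=1 throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import special
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from .intervals import GenomicInterval
from .tracks import WindowedTrack

N_STATE, T_STATE = 0, 1
_STATE_NAMES = ("N", "T")

NEG_INF = float("-inf")


@dataclass
class HMMParams:
    """Parameters of the two-state zero-inflated-gamma HMM.

    ``neg_log_trans_*`` hold the negative natural log of the corresponding
    transition probability, i.e. P(T->N) = exp(-neg_log_trans_t_to_n).
    ``neg_log_trans_n_to_t`` defaults to the T->N value when unset.
    Emission fields left at ``None`` are estimated by :func:`fit_emissions`.
    """

    shape_n: float = 5.0
    neg_log_trans_t_to_n: float = 200.0
    neg_log_trans_n_to_t: Optional[float] = None
    scale_n: Optional[float] = None
    shape_t: Optional[float] = None
    scale_t: Optional[float] = None
    zero_mass_n: Optional[float] = None
    zero_mass_t: Optional[float] = None
    initial_state_logprobs: Tuple[float, float] = (math.log(0.5), math.log(0.5))

    def __post_init__(self) -> None:
        if self.shape_n is not None and self.shape_n <= 0:
            raise ValueError("shape_n must be positive")
        for attr in ("scale_n", "shape_t", "scale_t"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{attr} must be positive")
        for attr in ("zero_mass_n", "zero_mass_t"):
            v = getattr(self, attr)
            if v is not None and not (0 <= v < 1):
                raise ValueError(f"{attr} must lie in [0, 1)")
        if self.neg_log_trans_t_to_n <= 0:
            raise ValueError("neg_log_trans_t_to_n must be positive")
        if self.neg_log_trans_n_to_t is not None and self.neg_log_trans_n_to_t <= 0:
            raise ValueError("neg_log_trans_n_to_t must be positive")

    @classmethod
    def amanitin_preset(cls, **kwargs) -> "HMMParams":
        """Preset for alpha-amanitin data: shape 5, negative-log transition 10.

        The softer exit penalty lets the model call the much shorter
        (typically < 400 nt) Pol I/III units.
        """
        kwargs.setdefault("shape_n", 5.0)
        kwargs.setdefault("neg_log_trans_t_to_n", 10.0)
        return cls(**kwargs)

    @property
    def emissions_set(self) -> bool:
        return None not in (
            self.scale_n, self.shape_t, self.scale_t, self.zero_mass_n, self.zero_mass_t
        )

    def log_transition_matrix(self) -> np.ndarray:
        """2x2 log transition matrix, rows = from-state (N, T), rows sum to 1."""
        b = self.neg_log_trans_t_to_n
        a = self.neg_log_trans_n_to_t if self.neg_log_trans_n_to_t is not None else b
        # log(1 - e^-x) via log1p for tiny e^-x
        return np.array(
            [
                [math.log1p(-math.exp(-a)), -a],
                [-b, math.log1p(-math.exp(-b))],
            ]
        )


def emission_loglik(count: float, state: str, params: HMMParams) -> float:
    """Log emission density of one bin count under state ``"N"`` or ``"T"``.

    Zero counts draw the state's point mass; positive counts the
    complementary gamma density.  A zero count under zero mass 0 returns
    -inf (impossible observation).
    """
    if count < 0:
        raise ValueError("bin counts must be non-negative")
    if state not in _STATE_NAMES:
        raise ValueError(f"unknown state {state!r}")
    if state == "N":
        shape, scale, zm = params.shape_n, params.scale_n, params.zero_mass_n
    else:
        shape, scale, zm = params.shape_t, params.scale_t, params.zero_mass_t
    if shape is None or scale is None or zm is None:
        raise ValueError("emission parameters are unset; fit or supply them")
    if count == 0:
        return math.log(zm) if zm > 0 else NEG_INF
    return math.log1p(-zm) + gamma_dist.logpdf(count, shape, scale=scale)


def _emission_matrix(obs: np.ndarray, params: HMMParams) -> np.ndarray:
    """(n, 2) matrix of per-bin log emissions, vectorized."""
    obs = np.asarray(obs, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations must be finite")
    if np.any(obs < 0):
        raise ValueError("bin counts must be non-negative")
    out = np.empty((obs.size, 2))
    zero = obs == 0
    for s, (shape, scale, zm) in enumerate(
        (
            (params.shape_n, params.scale_n, params.zero_mass_n),
            (params.shape_t, params.scale_t, params.zero_mass_t),
        )
    ):
        if shape is None or scale is None or zm is None:
            raise ValueError("emission parameters are unset; fit or supply them")
        out[zero, s] = math.log(zm) if zm > 0 else NEG_INF
        pos = obs[~zero]
        out[~zero, s] = math.log1p(-zm) + (
            (shape - 1) * np.log(pos) - pos / scale
            - shape * math.log(scale) - special.gammaln(shape)
        )
    return out


def viterbi(observations: Sequence[float], params: HMMParams) -> np.ndarray:
    """Maximum-joint-probability state path over the observations.

    Log-space dynamic programming; at every tie the lower-indexed state (N)
    wins, both for predecessors and for the final state.
    """
    emis = _emission_matrix(np.asarray(observations, dtype=float), params)
    log_trans = params.log_transition_matrix()
    init = np.asarray(params.initial_state_logprobs, dtype=float)
    return _viterbi_kernel(emis, log_trans, init)


def _viterbi_core(emis: np.ndarray, log_trans: np.ndarray, init: np.ndarray) -> np.ndarray:
    n = emis.shape[0]
    delta = np.empty((n, 2))
    back = np.zeros((n, 2), dtype=np.int8)
    delta[0, 0] = init[0] + emis[0, 0]
    delta[0, 1] = init[1] + emis[0, 1]
    for i in range(1, n):
        for s in range(2):
            from_n = delta[i - 1, 0] + log_trans[0, s]
            from_t = delta[i - 1, 1] + log_trans[1, s]
            if from_t > from_n:  # strict: ties keep N
                delta[i, s] = from_t + emis[i, s]
                back[i, s] = 1
            else:
                delta[i, s] = from_n + emis[i, s]
    path = np.empty(n, dtype=np.int8)
    path[n - 1] = 1 if delta[n - 1, 1] > delta[n - 1, 0] else 0
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def _fb_core(p_emis: np.ndarray, trans: np.ndarray, p_init: np.ndarray):
    """Scaled forward-backward on linear-space (per-bin shifted) emissions."""
    n = p_emis.shape[0]
    alpha = np.empty((n, 2))
    c = np.empty(n)
    a0 = p_init[0] * p_emis[0, 0]
    a1 = p_init[1] * p_emis[0, 1]
    c[0] = a0 + a1
    alpha[0, 0] = a0 / c[0]
    alpha[0, 1] = a1 / c[0]
    for i in range(1, n):
        a0 = (alpha[i - 1, 0] * trans[0, 0] + alpha[i - 1, 1] * trans[1, 0]) * p_emis[i, 0]
        a1 = (alpha[i - 1, 0] * trans[0, 1] + alpha[i - 1, 1] * trans[1, 1]) * p_emis[i, 1]
        c[i] = a0 + a1
        if c[i] <= 0:
            return alpha, c, False
        alpha[i, 0] = a0 / c[i]
        alpha[i, 1] = a1 / c[i]
    gamma = np.empty((n, 2))
    b0 = 1.0
    b1 = 1.0
    gamma[n - 1, 0] = alpha[n - 1, 0]
    gamma[n - 1, 1] = alpha[n - 1, 1]
    for i in range(n - 2, -1, -1):
        e0 = p_emis[i + 1, 0] * b0
        e1 = p_emis[i + 1, 1] * b1
        b0 = (trans[0, 0] * e0 + trans[0, 1] * e1) / c[i + 1]
        b1 = (trans[1, 0] * e0 + trans[1, 1] * e1) / c[i + 1]
        g0 = alpha[i, 0] * b0
        g1 = alpha[i, 1] * b1
        tot = g0 + g1
        gamma[i, 0] = g0 / tot
        gamma[i, 1] = g1 / tot
    return gamma, c, True


try:  # JIT the two hot kernels; the pure-numpy code path is the fallback
    from numba import njit as _njit

    _viterbi_kernel = _njit(cache=False)(_viterbi_core)
    _fb_kernel = _njit(cache=False)(_fb_core)
except ImportError:  # pragma: no cover
    _viterbi_kernel = _viterbi_core
    _fb_kernel = _fb_core


def brute_force_decode(observations: Sequence[float], params: HMMParams) -> np.ndarray:
    """Exhaustive decoding oracle: score all 2^n paths, return the argmax.

    Scores are accumulated left to right exactly as the Viterbi recursion
    does, and ties are resolved the same way (preference for N propagating
    from the sequence end), so the two functions agree bit for bit.  Only
    for n <= 16.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size > 16:
        raise ValueError("brute-force decoding is limited to 16 bins")
    emis = _emission_matrix(obs, params)
    log_trans = params.log_transition_matrix()
    init = params.initial_state_logprobs
    best_path: Optional[Tuple[int, ...]] = None
    best_score = NEG_INF
    best_key: Optional[Tuple[int, ...]] = None
    for path in itertools.product((0, 1), repeat=obs.size):
        score = init[path[0]] + emis[0, path[0]]
        for i in range(1, obs.size):
            score = score + log_trans[path[i - 1], path[i]] + emis[i, path[i]]
        # tie-break: prefer N from the end of the sequence inward, matching
        # Viterbi's backtracking preference
        key = tuple(reversed(path))
        if score > best_score or (score == best_score and key < best_key):
            best_score, best_path, best_key = score, path, key
    return np.array(best_path, dtype=np.int8)


# ---------------------------------------------------------------------------
# EM fitting


def _weighted_gamma_fit(x: np.ndarray, w: np.ndarray, shape: Optional[float]) -> Tuple[float, float]:
    """Weighted gamma MLE on positive observations.

    With ``shape`` given, only the scale is estimated (mean / shape).  With
    ``shape`` None, the shape solves the weighted profile likelihood
    equation log(k) - digamma(k) = log(mean) - mean(log x).
    """
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("no weight on positive observations")
    mean = float(np.dot(w, x) / wsum)
    if shape is not None:
        return shape, mean / shape
    s = math.log(mean) - float(np.dot(w, np.log(x)) / wsum)
    if s <= 0:  # numerically degenerate (all x equal): fall back to huge shape
        return 1e3, mean / 1e3
    # Minka's closed-form initialisation, then a bracketed root solve
    k0 = (3 - s + math.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    f = lambda k: math.log(k) - special.digamma(k) - s
    lo, hi = k0 / 10, k0 * 10
    while f(lo) < 0:
        lo /= 10
    while f(hi) > 0:
        hi *= 10
    k = brentq(f, lo, hi, xtol=1e-10)
    return k, mean / k


_ZM_FLOOR = 1e-6  # keep zero emissions possible in both states


def moment_init(observations: np.ndarray, params: HMMParams) -> HMMParams:
    """Method-of-moments initialization for EM.

    Bins are split at the median of the *positive* bin values (GRO-seq
    tracks are mostly zero, so the overall median is degenerate): bins at or
    below it initialize the non-transcribed state, bins above it the
    transcribed state.
    """
    obs = np.asarray(observations, dtype=float)
    pos = obs[obs > 0]
    if pos.size == 0:
        raise ValueError("cannot initialize emissions on an all-zero track")
    thresh = float(np.median(pos))
    lo, hi = obs[obs <= thresh], obs[obs > thresh]
    if hi.size == 0:  # constant positive values: split zeros vs positives
        lo, hi = obs[obs == 0], pos
    zm_n = max(_ZM_FLOOR, min(1 - _ZM_FLOOR, np.mean(lo == 0)))
    zm_t = max(_ZM_FLOOR, min(1 - _ZM_FLOOR, np.mean(hi == 0)))
    lo_pos = lo[lo > 0]
    scale_n = (float(lo_pos.mean()) if lo_pos.size else thresh) / params.shape_n
    hi_mean, hi_var = float(hi.mean()), float(hi.var())
    if hi_var <= 0:
        shape_t, scale_t = 10.0, hi_mean / 10.0
    else:
        shape_t = max(0.1, hi_mean**2 / hi_var)
        scale_t = hi_mean / shape_t
    return replace(
        params,
        scale_n=scale_n,
        shape_t=shape_t,
        scale_t=scale_t,
        zero_mass_n=float(zm_n),
        zero_mass_t=float(zm_t),
    )


def _forward_backward(emis: np.ndarray, log_trans: np.ndarray, init: np.ndarray):
    """Scaled forward-backward.  Returns (posteriors, log-likelihood).

    Emissions are shifted per bin before exponentiation so that the better
    state has probability 1, which keeps the scaled recursion away from
    underflow even when one state assigns astronomically small density.
    """
    shift = emis.max(axis=1)
    shift[~np.isfinite(shift)] = 0.0
    p_emis = np.exp(emis - shift[:, None])
    trans = np.exp(log_trans)
    gamma, c, ok = _fb_kernel(p_emis, trans, np.exp(np.asarray(init)))
    if not ok:
        raise FloatingPointError("forward pass underflow: impossible observation")
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, loglik


def fit_emissions(
    track: WindowedTrack | np.ndarray,
    params: Optional[HMMParams] = None,
    max_iter: int = 30,
    tol: float = 1e-4,
    return_history: bool = False,
):
    """Estimate the free emission parameters by expectation-maximization.

    ``shape_n`` and both transition parameters stay fixed at their
    configured values; the two scales, the transcribed-state shape and both
    zero masses are re-estimated from forward-backward posteriors.  The
    observed-data log-likelihood is non-decreasing across iterations (up to
    ``tol``); fitting stops at ``max_iter`` or when the relative improvement
    drops below ``tol``.  ``max_iter = 0`` returns the initialization
    unchanged.  With ``return_history`` the per-iteration log-likelihoods
    are returned alongside the parameters.
    """
    obs = track.values if isinstance(track, WindowedTrack) else np.asarray(track, float)
    if params is None:
        params = HMMParams()
    if not np.any(obs > 0):
        raise ValueError("cannot fit emissions on an all-zero track")
    cur = params if params.emissions_set else moment_init(obs, params)
    history: List[float] = []
    if max_iter == 0:
        return (cur, history) if return_history else cur
    log_trans = cur.log_transition_matrix()
    init = np.asarray(cur.initial_state_logprobs)
    pos_mask = obs > 0
    pos = obs[pos_mask]
    prev_ll = NEG_INF
    for _ in range(max_iter):
        gamma, ll = _forward_backward(_emission_matrix(obs, cur), log_trans, init)
        history.append(ll)
        w_n, w_t = gamma[:, 0], gamma[:, 1]
        zm_n = float(np.clip(w_n[~pos_mask].sum() / max(w_n.sum(), 1e-300), _ZM_FLOOR, 1 - _ZM_FLOOR))
        zm_t = float(np.clip(w_t[~pos_mask].sum() / max(w_t.sum(), 1e-300), _ZM_FLOOR, 1 - _ZM_FLOOR))
        _, scale_n = _weighted_gamma_fit(pos, w_n[pos_mask], cur.shape_n)
        shape_t, scale_t = _weighted_gamma_fit(pos, w_t[pos_mask], None)
        cur = replace(
            cur,
            scale_n=scale_n, shape_t=shape_t, scale_t=scale_t,
            zero_mass_n=zm_n, zero_mass_t=zm_t,
        )
        if prev_ll != NEG_INF and ll - prev_ll < tol * abs(prev_ll):
            break
        prev_ll = ll
    return (cur, history) if return_history else cur


# ---------------------------------------------------------------------------
# transcript units


@dataclass
class TranscriptUnit:
    """A maximal transcribed-state run, as a bin-aligned genomic interval."""

    interval: GenomicInterval
    mean_signal: float
    id: str

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    def __len__(self) -> int:
        return len(self.interval)


def call_transcripts(
    track: WindowedTrack,
    params: HMMParams,
    min_length: int = 0,
) -> List[TranscriptUnit]:
    """Segment one track and emit transcript units.

    Maximal runs of the transcribed state become intervals (bin index times
    bin width); runs shorter than ``min_length`` bp are dropped.  No gap
    merging is performed.  Unit ids are ``{chrom}_{strand}_{serial}``.
    """
    path = viterbi(track.values, params)
    return units_from_path(path, track, min_length)


def units_from_path(
    path: np.ndarray, track: WindowedTrack, min_length: int = 0
) -> List[TranscriptUnit]:
    units: List[TranscriptUnit] = []
    bw = track.bin_width
    in_run = False
    run_start = 0
    serial = 0
    strand_tag = "plus" if track.strand == "+" else "minus"
    for i, s in enumerate(np.append(path, N_STATE)):  # sentinel closes final run
        if s == T_STATE and not in_run:
            in_run, run_start = True, i
        elif s != T_STATE and in_run:
            in_run = False
            start, end = run_start * bw, i * bw
            if end - start >= max(min_length, 1):
                serial += 1
                iv = GenomicInterval(
                    track.chrom, start, end, track.strand,
                    name=f"{track.chrom}_{strand_tag}_{serial}",
                )
                units.append(
                    TranscriptUnit(iv, float(track.values[run_start:i].mean()), iv.name)
                )
    return units


def call_transcripts_genome(
    tracks: Iterable[WindowedTrack],
    params: Optional[HMMParams] = None,
    min_length: int = 0,
    fit: bool = True,
    max_iter: int = 30,
    tol: float = 1e-4,
) -> Tuple[List[TranscriptUnit], HMMParams]:
    """Fit one emission model genome-wide, then call units on every track.

    E-step sufficient statistics are accumulated across tracks so that a
    single parameter set describes the whole dataset, mirroring genome-wide
    calling.  Returns the units from all tracks plus the fitted parameters.
    """
    tracks = list(tracks)
    if params is None:
        params = HMMParams()
    if fit and not params.emissions_set:
        pooled = np.concatenate([t.values for t in tracks])
        params = fit_emissions(pooled, params, max_iter=max_iter, tol=tol)
    elif not params.emissions_set:
        raise ValueError("emission parameters unset and fitting disabled")
    units: List[TranscriptUnit] = []
    for track in tracks:
        units.extend(call_transcripts(track, params, min_length=min_length))
    return units, params


def merge_unit_sets(unit_sets: Sequence[Sequence[TranscriptUnit]]) -> List[TranscriptUnit]:
    """Union-merge units called in different conditions (same strand overlap).

    Overlapping same-strand units from different calls collapse to their
    spanning interval; a transcript expressed in at least one condition
    survives the merge.
    """
    by_key: Dict[Tuple[str, str], List[TranscriptUnit]] = {}
    for units in unit_sets:
        for u in units:
            by_key.setdefault((u.chrom, u.strand), []).append(u)
    merged: List[TranscriptUnit] = []
    for (chrom, strand), units in sorted(by_key.items()):
        units.sort(key=lambda u: u.start)
        cur_s, cur_e, sigs = units[0].start, units[0].end, [units[0].mean_signal]
        serial = 0
        strand_tag = "plus" if strand == "+" else "minus"

        def emit(s, e, sigs):
            nonlocal serial
            serial += 1
            name = f"{chrom}_{strand_tag}_m{serial}"
            merged.append(
                TranscriptUnit(GenomicInterval(chrom, s, e, strand, name),
                               float(np.mean(sigs)), name)
            )

        for u in units[1:]:
            if u.start < cur_e:
                cur_e = max(cur_e, u.end)
                sigs.append(u.mean_signal)
            else:
                emit(cur_s, cur_e, sigs)
                cur_s, cur_e, sigs = u.start, u.end, [u.mean_signal]
        emit(cur_s, cur_e, sigs)
    return merged
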