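"""Numba hot loops for the reputation, binary-baseline, and recovery dynamics.

All kernels draw from numba's in-njit ``np.random`` (MT19937, seeded per
call), so a given seed reproduces a run bit-for-bit.  The quantitative and
binary kernels consume the random stream in an identical order, which lets
tests couple the two engines on a shared stream.

Third-party observation/misperception is sampled by counts rather than one
uniform per observer: per round the number of non-observers is
Binomial(N-2, 1-q) and, among observers, the number of misperceivers is
Binomial(n_obs, eps); the corresponding index sets are then drawn uniformly
(Floyd's subset sampling, rejection for the misperceivers).  This is
distributionally identical to independent per-observer draws — each third
party independently skips w.p. 1-q, updates with the flipped action w.p.
q*eps, and with the true action otherwise — at a fraction of the RNG cost.
The recipient always observes (misperceiving w.p. eps); the donor perceives
their own action without error.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_rounds_quant", "run_rounds_binary", "run_recovery"]

# mark codes for third parties
_OBS, _SKIP, _FLIP = 0, 1, 2


@njit(cache=True, inline="always")
def _draw_pair(N):
    d = np.random.randint(0, N)
    r0 = np.random.randint(0, N - 1)
    r = r0 + 1 if r0 >= d else r0
    return d, r


@njit(cache=True)
def _binomial_cdf_table(n_max, p):
    """cdf[n, k] = P(Binomial(n, p) <= k), for all n in 0..n_max."""
    cdf = np.ones((n_max + 1, n_max + 1))
    for n in range(n_max + 1):
        if p <= 0.0:
            continue
        if p >= 1.0:
            for k in range(n):
                cdf[n, k] = 0.0
            continue
        pmf = (1.0 - p) ** n
        acc = pmf
        cdf[n, 0] = acc
        for k in range(n):
            pmf *= (n - k) / (k + 1.0) * p / (1.0 - p)
            acc += pmf
            cdf[n, k + 1] = acc if acc < 1.0 else 1.0
        cdf[n, n] = 1.0
    return cdf


@njit(cache=True, inline="always")
def _draw_count(cdf_row, n):
    """Inverse-CDF Binomial draw from one uniform."""
    u = np.random.random()
    k = 0
    while k < n and u > cdf_row[k]:
        k += 1
    return k


@njit(cache=True, inline="always")
def _sample_marks(mark, m, q, eps, skip_cdf, flip_cdf):
    """Fill mark[0:m] with SKIP/FLIP/OBS codes for the third parties."""
    n_skip = 0
    if q < 1.0:
        n_skip = _draw_count(skip_cdf[m], m)
        for j in range(m - n_skip, m):
            t = np.random.randint(0, j + 1)
            if mark[t] != _OBS:
                t = j
            mark[t] = _SKIP
    n_obs = m - n_skip
    if eps > 0.0 and n_obs > 0:
        n_flip = _draw_count(flip_cdf[n_obs], n_obs)
        cnt = 0
        while cnt < n_flip:
            t = np.random.randint(0, m)
            if mark[t] == _OBS:
                mark[t] = _FLIP
                cnt += 1


@njit(cache=True, inline="always")
def _refresh_intent(intend_cur, intend_sum, intend_last, labmat, act, norm_idx,
                    i, j, t, burn_in):
    """Lazy update of the time-weighted intended-action accumulator (i -> j)."""
    new_int = act[norm_idx[i], labmat[i, i], labmat[i, j]]
    if new_int != intend_cur[i, j]:
        if t >= burn_in:
            tau = t - burn_in
            intend_sum[i, j] += intend_cur[i, j] * (tau - intend_last[i, j])
            intend_last[i, j] = tau
        intend_cur[i, j] = new_int


@njit(cache=True)
def run_rounds_quant(scores, norm_idx, assess, act, V, A, S, tie_good,
                     eps, q, donor_self_update, recipient_error,
                     T, burn_in, seed,
                     coop_cnt, pair_cnt, labsum, intend_sum, snap_every, snaps):
    """Simulate T donation-game rounds on an integer-score image matrix.

    Mutates ``scores`` and accumulates cooperation counts, ordered-pair
    counts, post-round judgment sums, and time-weighted intended-action sums
    (rounds >= burn_in) in place.  The intended action act(J_ii, J_ij) is
    the donor's move as a deterministic function of the current labels;
    because the (donor, recipient) draw is independent of the state, its
    time average is an unbiased, much lower-variance estimator of the
    pairwise cooperation rate than the empirical per-pair frequency.
    """
    np.random.seed(seed)
    N = scores.shape[0]
    m = N - 2
    labmat = np.empty((N, N), dtype=np.int64)
    for i in range(N):
        for j in range(N):
            if tie_good:
                labmat[i, j] = 1 if scores[i, j] >= S else 0
            else:
                labmat[i, j] = 1 if scores[i, j] > S else 0
    intend_cur = np.empty((N, N), dtype=np.int64)
    for i in range(N):
        for j in range(N):
            intend_cur[i, j] = act[norm_idx[i], labmat[i, i], labmat[i, j]]
    intend_sum_last = np.zeros((N, N), dtype=np.int64)
    last = np.zeros((N, N), dtype=np.int64)
    mark = np.zeros(max(m, 1), dtype=np.int8)
    skip_cdf = _binomial_cdf_table(max(m, 1), 1.0 - q)
    flip_cdf = _binomial_cdf_table(max(m, 1), eps)
    n_snap = 0
    for t in range(T):
        d, r = _draw_pair(N)
        action = act[norm_idx[d], labmat[d, d], labmat[d, r]]
        if t >= burn_in:
            pair_cnt[d, r] += 1
            coop_cnt[d, r] += action
        _sample_marks(mark, m, q, eps, skip_cdf, flip_cdf)
        r_flip = recipient_error and eps > 0.0 and np.random.random() < eps
        rank = 0
        for i in range(N):
            if i == d:
                if not donor_self_update:
                    continue
                perceived = action
            elif i == r:
                perceived = 1 - action if r_flip else action
            else:
                mk = mark[rank]
                mark[rank] = _OBS
                rank += 1
                if mk == _SKIP:
                    continue
                perceived = 1 - action if mk == _FLIP else action
            delta = assess[norm_idx[i], labmat[i, d], labmat[i, r], perceived]
            s_new = scores[i, d] + delta
            if s_new > A:
                s_new = A
            elif s_new < V:
                s_new = V
            if s_new != scores[i, d]:
                scores[i, d] = s_new
                if tie_good:
                    new_lab = 1 if s_new >= S else 0
                else:
                    new_lab = 1 if s_new > S else 0
                if new_lab != labmat[i, d]:
                    if t >= burn_in:
                        tau = t - burn_in
                        labsum[i, d] += labmat[i, d] * (tau - last[i, d])
                        last[i, d] = tau
                    labmat[i, d] = new_lab
                    if i == d:
                        # the donor's self-image changed: every intended
                        # action of player i may change
                        for j in range(N):
                            _refresh_intent(intend_cur, intend_sum, intend_sum_last,
                                            labmat, act, norm_idx, i, j, t, burn_in)
                    else:
                        _refresh_intent(intend_cur, intend_sum, intend_sum_last,
                                        labmat, act, norm_idx, i, d, t, burn_in)
        if snap_every > 0 and (t + 1) % snap_every == 0 and n_snap < snaps.shape[0]:
            snaps[n_snap] = scores
            n_snap += 1
    T_acc = T - burn_in
    for i in range(N):
        for j in range(N):
            labsum[i, j] += labmat[i, j] * (T_acc - last[i, j])
            intend_sum[i, j] += intend_cur[i, j] * (T_acc - intend_sum_last[i, j])


@njit(cache=True)
def run_rounds_binary(labels, norm_idx, assess, act,
                      eps, q, donor_self_update, recipient_error,
                      T, burn_in, seed,
                      coop_cnt, pair_cnt, labsum, intend_sum, snap_every, snaps):
    """Direct binary-reputation baseline: reputations are G/B labels.

    A positive assessment *sets* the donor's label to good, a negative one
    to bad (no scores, no clamping).  Random-stream layout matches
    :func:`run_rounds_quant` exactly.
    """
    np.random.seed(seed)
    N = labels.shape[0]
    m = N - 2
    intend_cur = np.empty((N, N), dtype=np.int64)
    for i in range(N):
        for j in range(N):
            intend_cur[i, j] = act[norm_idx[i], labels[i, i], labels[i, j]]
    intend_sum_last = np.zeros((N, N), dtype=np.int64)
    last = np.zeros((N, N), dtype=np.int64)
    mark = np.zeros(max(m, 1), dtype=np.int8)
    skip_cdf = _binomial_cdf_table(max(m, 1), 1.0 - q)
    flip_cdf = _binomial_cdf_table(max(m, 1), eps)
    n_snap = 0
    for t in range(T):
        d, r = _draw_pair(N)
        action = act[norm_idx[d], labels[d, d], labels[d, r]]
        if t >= burn_in:
            pair_cnt[d, r] += 1
            coop_cnt[d, r] += action
        _sample_marks(mark, m, q, eps, skip_cdf, flip_cdf)
        r_flip = recipient_error and eps > 0.0 and np.random.random() < eps
        rank = 0
        for i in range(N):
            if i == d:
                if not donor_self_update:
                    continue
                perceived = action
            elif i == r:
                perceived = 1 - action if r_flip else action
            else:
                mk = mark[rank]
                mark[rank] = _OBS
                rank += 1
                if mk == _SKIP:
                    continue
                perceived = 1 - action if mk == _FLIP else action
            new_lab = 1 if assess[norm_idx[i], labels[i, d], labels[i, r], perceived] > 0 else 0
            if new_lab != labels[i, d]:
                if t >= burn_in:
                    tau = t - burn_in
                    labsum[i, d] += labels[i, d] * (tau - last[i, d])
                    last[i, d] = tau
                labels[i, d] = new_lab
                if i == d:
                    for j in range(N):
                        _refresh_intent(intend_cur, intend_sum, intend_sum_last,
                                        labels, act, norm_idx, i, j, t, burn_in)
                else:
                    _refresh_intent(intend_cur, intend_sum, intend_sum_last,
                                    labels, act, norm_idx, i, d, t, burn_in)
        if snap_every > 0 and (t + 1) % snap_every == 0 and n_snap < snaps.shape[0]:
            snaps[n_snap] = labels
            n_snap += 1
    T_acc = T - burn_in
    for i in range(N):
        for j in range(N):
            labsum[i, j] += labels[i, j] * (T_acc - last[i, j])
            intend_sum[i, j] += intend_cur[i, j] * (T_acc - intend_sum_last[i, j])


@njit(cache=True)
def run_recovery(scores, norm_idx, assess, act, V, A, S, tie_good,
                 max_rounds, seed):
    """Perfect-information dynamics (eps=0, q=1) until unanimous good judgments.

    Returns ``(recovered, rounds, defections)``; ``rounds`` is the number of
    interaction rounds until no player judges any player bad (0 if already
    unanimous), capped at ``max_rounds``.
    """
    np.random.seed(seed)
    N = scores.shape[0]
    labmat = np.empty((N, N), dtype=np.int64)
    n_bad = 0
    for i in range(N):
        for j in range(N):
            if tie_good:
                labmat[i, j] = 1 if scores[i, j] >= S else 0
            else:
                labmat[i, j] = 1 if scores[i, j] > S else 0
            if labmat[i, j] == 0:
                n_bad += 1
    defections = 0
    t = 0
    while n_bad > 0 and t < max_rounds:
        d, r = _draw_pair(N)
        action = act[norm_idx[d], labmat[d, d], labmat[d, r]]
        if action == 0:
            defections += 1
        for i in range(N):
            delta = assess[norm_idx[i], labmat[i, d], labmat[i, r], action]
            s_new = scores[i, d] + delta
            if s_new > A:
                s_new = A
            elif s_new < V:
                s_new = V
            if s_new != scores[i, d]:
                scores[i, d] = s_new
                if tie_good:
                    new_lab = 1 if s_new >= S else 0
                else:
                    new_lab = 1 if s_new > S else 0
                if new_lab != labmat[i, d]:
                    n_bad += 1 if new_lab == 0 else -1
                    labmat[i, d] = new_lab
        t += 1
    recovered = n_bad == 0
    return recovered, t, defections
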