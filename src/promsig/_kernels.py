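"""Numba kernels for message passing on the promoter-signature lattice.

The hidden state space per position is {b0, b1, bx, matrix-run states}.
Because matrix runs are deterministic once entered, the forward/backward
recursions collapse to two log-mass tracks per sequence:

* ``A0[i]`` – log relative mass of paths that emitted positions < i with no
  completed site yet (b0 territory),
* ``A1[i]`` – log relative mass with at least one completed site (b1).

"Relative" means divided by the background likelihood of the emitted prefix,
so a background step contributes only its transition factor and a site block
starting at i contributes q * exp(logW[i, strand]) where logW is the
log-likelihood-ratio of the site's emissions versus background.

Positions where no site fits (too close to the 3' end, or overlapping masked
fill / ambiguous bases) give the background transition probability one; this
is the structural rule that sites must complete inside the sequence.

Transition probabilities into a site are indexed by p, the distance in bp
from the TSS (3' end) to the site's TSS-proximal end: for a site starting at
string index i in a sequence of length L, p = L - w - i.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _logaddexp(a, b):
    # beyond 40 nats the smaller term is below double resolution
    if a >= b:
        if b == NEG_INF or a - b > 40.0:
            return a
        return a + np.log1p(np.exp(b - a))
    if a == NEG_INF or b - a > 40.0:
        return b
    return b + np.log1p(np.exp(a - b))


@njit(cache=True)
def forward_batch(lengths, logW, log_qf, log_qr, log_stay, w, monosite):
    """log relative likelihood of (N, C=1 | R=1) for each sequence.

    lengths : (n,) int64
    logW    : (n, Lmax, 2) site log likelihood ratios; -inf where invalid
    log_qf, log_qr, log_stay : (Pmax+1,) transition log-probabilities by p
    Returns (n,) log M1 with P(N, C=1 | R=1) = BG(N) * exp(M1).
    """
    n = lengths.shape[0]
    out = np.empty(n)
    for j in range(n):
        L = lengths[j]
        A0 = np.full(L + 1, NEG_INF)
        A1 = np.full(L + 1, NEG_INF)
        A0[0] = 0.0
        for i in range(L):
            valid = i <= L - w and logW[j, i, 0] > NEG_INF
            if valid:
                p = L - w - i
                st = log_stay[p]
                qfW = log_qf[p] + logW[j, i, 0]
                qrW = log_qr[p] + logW[j, i, 1]
                site = _logaddexp(qfW, qrW)
                src = A0[i] if monosite else _logaddexp(A0[i], A1[i])
                if src > NEG_INF and site > NEG_INF:
                    A1[i + w] = _logaddexp(A1[i + w], src + site)
            else:
                st = 0.0
            A0[i + 1] = A0[i] + st  # background extension is b0's only edge
            if A1[i] > NEG_INF:
                st1 = st if not monosite else 0.0
                A1[i + 1] = _logaddexp(A1[i + 1], A1[i] + st1)
        out[j] = A1[L]
    return out


@njit(cache=True)
def forward_backward_batch(lengths, logW, log_qf, log_qr, log_stay, w,
                           monosite):
    """Site-start posteriors conditional on R=1, C=1.

    Returns (logM1, post) where post[j, i, s] = P(site starts at i on strand
    s | N_j, R=1, C=1).
    """
    n, Lmax, _ = logW.shape
    post = np.zeros((n, Lmax, 2))
    logM1 = np.empty(n)
    for j in range(n):
        L = lengths[j]
        A0 = np.full(L + 1, NEG_INF)
        A1 = np.full(L + 1, NEG_INF)
        A0[0] = 0.0
        for i in range(L):
            valid = i <= L - w and logW[j, i, 0] > NEG_INF
            if valid:
                p = L - w - i
                st = log_stay[p]
                qfW = log_qf[p] + logW[j, i, 0]
                qrW = log_qr[p] + logW[j, i, 1]
                site = _logaddexp(qfW, qrW)
                src = A0[i] if monosite else _logaddexp(A0[i], A1[i])
                if src > NEG_INF and site > NEG_INF:
                    A1[i + w] = _logaddexp(A1[i + w], src + site)
            else:
                st = 0.0
            A0[i + 1] = A0[i] + st
            if A1[i] > NEG_INF:
                st1 = st if not monosite else 0.0
                A1[i + 1] = _logaddexp(A1[i + 1], A1[i] + st1)
        logM1[j] = A1[L]
        if A1[L] == NEG_INF:
            continue
        # backward: B1[i] = mass to finish from b1 territory entering i,
        #           B0[i] = mass to finish (>=1 site still required) from b0.
        B0 = np.full(L + 1, NEG_INF)
        B1 = np.full(L + 1, NEG_INF)
        B1[L] = 0.0
        B0[L] = NEG_INF
        for i in range(L - 1, -1, -1):
            valid = i <= L - w and logW[j, i, 0] > NEG_INF
            if valid:
                p = L - w - i
                st = log_stay[p]
                qfW = log_qf[p] + logW[j, i, 0]
                qrW = log_qr[p] + logW[j, i, 1]
                site_mass = _logaddexp(qfW, qrW)
                if monosite:
                    # after the single site only unit-probability background
                    B0[i] = _logaddexp(st + B0[i + 1], site_mass)
                    B1[i] = B1[i + 1]
                else:
                    B0[i] = _logaddexp(st + B0[i + 1], site_mass + B1[i + w])
                    B1[i] = _logaddexp(st + B1[i + 1], site_mass + B1[i + w])
            else:
                B0[i] = B0[i + 1]
                B1[i] = B1[i + 1] if not monosite else B1[i + 1]
        for i in range(L - w + 1):
            if logW[j, i, 0] == NEG_INF:
                continue
            p = L - w - i
            for s in range(2):
                lq = log_qf[p] if s == 0 else log_qr[p]
                if lq == NEG_INF:
                    continue
                lw = logW[j, i, s]
                if monosite:
                    lp = A0[i] + lq + lw - A1[L]
                else:
                    src = _logaddexp(A0[i], A1[i])
                    lp = src + lq + lw + B1[i + w] - A1[L]
                if lp > NEG_INF:
                    post[j, i, s] = np.exp(lp)
    return logM1, post


@njit(cache=True)
def consistency_mass(L, log_qf, log_qr, log_stay, w, monosite):
    """log P(C=1 | R=1) for an unmasked sequence of length L.

    Same recursion as forward_batch with all emission ratios marginalised
    out (they sum to one over bases).
    """
    A0 = np.full(L + 1, NEG_INF)
    A1 = np.full(L + 1, NEG_INF)
    A0[0] = 0.0
    for i in range(L):
        if i <= L - w:
            p = L - w - i
            st = log_stay[p]
            site = _logaddexp(log_qf[p], log_qr[p])
            if A0[i] > NEG_INF and site > NEG_INF:
                A1[i + w] = _logaddexp(A1[i + w], A0[i] + site)
            if not monosite and A1[i] > NEG_INF and site > NEG_INF:
                A1[i + w] = _logaddexp(A1[i + w], A1[i] + site)
        else:
            st = 0.0
        if A0[i] > NEG_INF:
            A0[i + 1] = _logaddexp(A0[i + 1], A0[i] + st)
        if A1[i] > NEG_INF:
            st1 = st if not monosite else 0.0
            A1[i + 1] = _logaddexp(A1[i + 1], A1[i] + st1)
    return A1[L]


@njit(cache=True)
def scramble_kernel(seqs, lengths, tracks, w, seg_lo, seg_hi, threshold,
                    iterations, max_attempts, fwd_tab, rev_tab, seed):
    """Iterative segment-swap scrambler.

    seqs    : (m, Lmax) int8 codes, padded with 4 beyond each length
    tracks  : (m, Lmax) float64, max-over-strands log2 score of the site
              starting at each position (-inf where no site fits); updated
              in place after every swap
    fwd_tab, rev_tab : (w, 5) per-position score lookup tables
    Returns number of iterations skipped for want of a legal segment pair.
    """
    np.random.seed(seed)
    m = seqs.shape[0]
    skipped = 0
    for _ in range(iterations):
        found = False
        a = -1
        astart = 0
        seglen = 0
        for _try in range(max_attempts):
            a = np.random.randint(0, m)
            La = lengths[a]
            seglen = np.random.randint(seg_lo, seg_hi + 1)
            if seglen >= La:
                continue
            astart = np.random.randint(0, La - seglen + 1)
            if _borders_clear(tracks, a, astart, seglen, w, threshold,
                              lengths):
                found = True
                break
        if not found:
            skipped += 1
            continue
        found = False
        b = -1
        bstart = 0
        for _try in range(max_attempts):
            b = np.random.randint(0, m)
            if b == a:
                continue
            Lb = lengths[b]
            if seglen >= Lb:
                continue
            bstart = np.random.randint(0, Lb - seglen + 1)
            if _borders_clear(tracks, b, bstart, seglen, w, threshold,
                              lengths):
                found = True
                break
        if not found:
            skipped += 1
            continue
        for k in range(seglen):
            tmp = seqs[a, astart + k]
            seqs[a, astart + k] = seqs[b, bstart + k]
            seqs[b, bstart + k] = tmp
        _rescan(seqs, tracks, a, astart, seglen, w, fwd_tab, rev_tab, lengths)
        _rescan(seqs, tracks, b, bstart, seglen, w, fwd_tab, rev_tab, lengths)
    return skipped


@njit(cache=True)
def _borders_clear(tracks, j, start, seglen, w, threshold, lengths):
    L = lengths[j]
    lo = start - w + 1
    if lo < 0:
        lo = 0
    for i in range(lo, start):
        if tracks[j, i] >= threshold:
            return False
    end = start + seglen
    lo = end - w + 1
    if lo < 0:
        lo = 0
    hi = end
    if hi > L - w + 1:
        hi = L - w + 1
    for i in range(lo, hi):
        if i < end - w + 1:
            continue
        if tracks[j, i] >= threshold:
            return False
    return True


@njit(cache=True)
def _rescan(seqs, tracks, j, start, seglen, w, fwd_tab, rev_tab, lengths):
    L = lengths[j]
    lo = start - w + 1
    if lo < 0:
        lo = 0
    hi = start + seglen
    if hi > L - w + 1:
        hi = L - w + 1
    for i in range(lo, hi):
        sf = 0.0
        sr = 0.0
        for k in range(w):
            c = seqs[j, i + k]
            sf += fwd_tab[k, c]
            sr += rev_tab[k, c]
        tracks[j, i] = sf if sf > sr else sr
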