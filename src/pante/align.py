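"""Built-in pairwise aligner: exact k-mer seeding, collinear chaining, and
banded local alignment with affine gaps.

The aligner is deliberately simple: flank-extended TE copies from one
species are either near-identical end to end (same locus) or share only
their TE interior (same family, different locus), so exact k-mer anchors
are dense wherever homology exists. Anchors are chained by longest
increasing subsequence and the chain's diagonal range (plus a pad) defines
the band of a local Gotoh alignment whose traceback yields the fragment
span, score and identity.

Scoring defaults: match +2, mismatch -3, gap open -5, gap extend -2
(a gap of length L costs open + L*extend).
"""

from __future__ import annotations

from bisect import bisect_left, insort

import numpy as np
from numba import njit

__all__ = ["encode", "revcomp", "kmer_index", "collect_anchors", "chain_anchors",
           "banded_local_align", "align_pair"]

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T to 0..3 (anything else, e.g. N, to 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Map each exact k-mer (without N) to its start positions."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def collect_anchors(query: str, target_index: dict[str, list[int]], k: int) -> list[tuple[int, int]]:
    """(query_pos, target_pos) pairs of exact shared k-mers."""
    anchors = []
    for i in range(len(query) - k + 1):
        hits = target_index.get(query[i : i + k])
        if hits:
            for j in hits:
                anchors.append((i, j))
    return anchors


def chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest collinear chain: anchors strictly increasing in both
    coordinates (longest increasing subsequence on target positions)."""
    if not anchors:
        return []
    # sort by query; within a query position, descending target so the LIS
    # never takes two anchors with the same query coordinate
    anchors = sorted(anchors, key=lambda a: (a[0], -a[1]))
    tails: list[int] = []          # tails[h] = smallest chain-end t for length h+1
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for idx, (_q, t) in enumerate(anchors):
        pos = bisect_left(tails, t)
        parent[idx] = tails_idx[pos - 1] if pos > 0 else -1
        if pos == len(tails):
            tails.append(t)
            tails_idx.append(idx)
        else:
            tails[pos] = t
            tails_idx[pos] = idx
    chain = []
    idx = tails_idx[-1]
    while idx != -1:
        chain.append(anchors[idx])
        idx = parent[idx]
    chain.reverse()
    return chain


@njit(cache=True)
def _banded_gotoh(q, t, d_lo, d_hi, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Banded local affine alignment (Gotoh) with traceback.

    Band restricts the diagonal d = j - i to [d_lo, d_hi]. Returns
    (score, q_start, q_end, t_start, t_end, n_match, n_columns),
    ends half-open. All-zero result when no positive-score cell exists.
    """
    n, m = q.shape[0], t.shape[0]
    w = d_hi - d_lo + 1
    NEG = -10**9
    H = np.full((n + 1, w), 0, dtype=np.int64)
    E = np.full((n + 1, w), NEG, dtype=np.int64)
    F = np.full((n + 1, w), NEG, dtype=np.int64)
    TH = np.zeros((n + 1, w), dtype=np.uint8)  # 0 stop, 1 diag, 2 from F, 3 from E
    TE = np.zeros((n + 1, w), dtype=np.uint8)  # 0 open, 1 extend
    TF = np.zeros((n + 1, w), dtype=np.uint8)
    best = 0
    bi = -1
    bb = -1
    for i in range(1, n + 1):
        j_min = i - 1 + d_lo
        j_max = i - 1 + d_hi
        if j_min < 1:
            j_min = 1
        if j_max > m:
            j_max = m
        for j in range(j_min, j_max + 1):
            b = j - i - d_lo  # band offset for (i, j): diagonal j - i
            # E: gap in query (consume target, move left)
            e = NEG
            te = 0
            if b - 1 >= 0:
                open_e = H[i, b - 1] + gap_open + gap_extend
                ext_e = E[i, b - 1] + gap_extend
                if ext_e > open_e:
                    e = ext_e
                    te = 1
                else:
                    e = open_e
            # F: gap in target (consume query, move up); (i-1, j) has offset b+1
            f = NEG
            tf = 0
            if b + 1 < w:
                open_f = H[i - 1, b + 1] + gap_open + gap_extend
                ext_f = F[i - 1, b + 1] + gap_extend
                if ext_f > open_f:
                    f = ext_f
                    tf = 1
                else:
                    f = open_f
            # diagonal: (i-1, j-1) has offset b
            qa = q[i - 1]
            ta = t[j - 1]
            sub = match if (qa == ta and qa < 4) else mismatch
            diag = H[i - 1, b] + sub
            h = 0
            th = 0
            if diag > h:
                h = diag
                th = 1
            if f > h:
                h = f
                th = 2
            if e > h:
                h = e
                th = 3
            H[i, b] = h
            E[i, b] = e
            F[i, b] = f
            TH[i, b] = th
            TE[i, b] = te
            TF[i, b] = tf
            if h > best:
                best = h
                bi = i
                bb = b
    if bi < 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback from best H cell
    i = bi
    b = bb
    state = 0  # 0 = H, 1 = E, 2 = F
    n_match = 0
    n_cols = 0
    q_end = bi
    t_end = bi + b + d_lo
    while True:
        j = i + b + d_lo
        if state == 0:
            th = TH[i, b]
            if th == 0:
                break
            if th == 1:
                n_cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    n_match += 1
                i -= 1
            elif th == 2:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: consumed t[j-1]
            n_cols += 1
            ext = TE[i, b]
            b -= 1
            if ext == 0:
                state = 0
        else:  # F: consumed q[i-1]
            n_cols += 1
            ext = TF[i, b]
            i -= 1
            b += 1
            if ext == 0:
                state = 0
    q_start = i
    t_start = i + b + d_lo
    return best, q_start, q_end, t_start, t_end, n_match, n_cols


def banded_local_align(
    query: str,
    target: str,
    d_lo: int,
    d_hi: int,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
):
    """Run the banded local alignment; see :func:`_banded_gotoh`.

    Returns a dict with score, half-open query/target spans, and identity
    over aligned columns (percent), or None when no alignment scores > 0.
    """
    q = encode(query)
    t = encode(target)
    d_lo = max(d_lo, -(len(query)) + 1)
    d_hi = min(d_hi, len(target) - 1)
    if d_lo > d_hi:
        return None
    score, qs, qe, ts, te, n_match, n_cols = _banded_gotoh(
        q, t, d_lo, d_hi, match, mismatch, gap_open, gap_extend
    )
    if score <= 0 or qe <= qs:
        return None
    return {
        "score": int(score),
        "q_start": int(qs),
        "q_end": int(qe),
        "t_start": int(ts),
        "t_end": int(te),
        "identity_pct": 100.0 * n_match / n_cols if n_cols else 0.0,
    }


def align_pair(
    query: str,
    target: str,
    k: int = 15,
    min_anchors: int = 4,
    band_pad: int = 24,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
    target_index: dict[str, list[int]] | None = None,
):
    """Seed-chain-align one query/target pair on the forward strand.

    Returns the :func:`banded_local_align` result dict or None when fewer
    than ``min_anchors`` collinear anchors exist.
    """
    if target_index is None:
        target_index = kmer_index(target, k)
    anchors = collect_anchors(query, target_index, k)
    chain = chain_anchors(anchors)
    if len(chain) < min_anchors:
        return None
    diags = [t - q for q, t in chain]
    return banded_local_align(
        query, target, min(diags) - band_pad, max(diags) + band_pad,
        match, mismatch, gap_open, gap_extend,
    )
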