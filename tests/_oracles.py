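"""Independent brute-force oracles used by the test suite.

These recompute expected results by the most literal method available —
per-base arrays, exhaustive enumeration, naive agglomeration — and are
deliberately written without reusing the package's data structures or
algorithms beyond plain inputs.
"""
from __future__ import annotations

import math
from fractions import Fraction
from itertools import product

import numpy as np


def perbase_profile(calls, length: int, fill) -> np.ndarray:
    """Per-base total copy numbers for one sample on one chromosome.

    ``calls`` is a list of (start, end, total_cn); uncovered bases get
    ``fill`` (kept exact by scaling to the fill's denominator).
    """
    f = Fraction(fill)
    scale = f.denominator
    arr = np.full(length, f.numerator, dtype=np.int64)
    covered = np.zeros(length, dtype=bool)
    for s, e, cn in calls:
        arr[s:e] = cn * scale
        covered[s:e] = True
    return arr, scale, covered


def round_half_away_fraction(num: int, den: int) -> int:
    if num >= 0:
        return (2 * num + den) // (2 * den)
    return -((-2 * num + den) // (2 * den))


def window_mean_perbase(calls, length: int, fill, start: int, end: int) -> int:
    """Rounded per-base mean copy number over [start, end)."""
    arr, scale, _ = perbase_profile(calls, length, fill)
    total = int(arr[start:end].sum())
    return round_half_away_fraction(total, scale * (end - start))


def brute_force_tiling(length: int, L: int, centromere=None):
    """Literal application of the tiling rule: tile from 0, subtract the
    centromere, then repeatedly merge any piece of length < L/2 into its
    upstream (else downstream) neighbour on the same arm."""
    tiles = [[s, min(s + L, length)] for s in range(0, length, L)]
    arms = [(0, length)]
    if centromere is not None:
        cs, ce = centromere
        arms = [a for a in [(0, cs), (ce, length)] if a[1] > a[0]]
    out = []
    for a0, a1 in arms:
        pieces = []
        for s, e in tiles:
            s2, e2 = max(s, a0), min(e, a1)
            if e2 > s2:
                pieces.append([s2, e2])
        changed = True
        while changed and len(pieces) > 1:
            changed = False
            for k, (s, e) in enumerate(pieces):
                if 2 * (e - s) < L:
                    if k > 0:
                        pieces[k - 1][1] = e
                    else:
                        pieces[1][0] = s
                    del pieces[k]
                    changed = True
                    break
        out.extend((s, e) for s, e in pieces)
    return out


def ward_d_agglomerate(X: np.ndarray):
    """Naive ward.D agglomeration over rows of X.

    Returns a list of (leafset_a, leafset_b, height) with the same
    deterministic tie rule as the implementation (smallest (min id,
    max id) cluster-id pair), tracked with plain dicts.
    """
    n = X.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = math.sqrt(float(((X[i] - X[j]) ** 2).sum()))
    merges = []
    next_id = n
    for _ in range(n - 1):
        dmin = min(dist.values())
        tol = 1e-12 * (1.0 + abs(dmin))
        cand = [k for k, v in dist.items() if v <= dmin + tol]
        a, b = min(cand)
        h = dist[(a, b)]
        merges.append((clusters[a], clusters[b], h))
        na, nb = len(clusters[a]), len(clusters[b])
        new = next_id
        next_id += 1
        newdist = {}
        for c in list(clusters):
            if c in (a, b):
                continue
            nc = len(clusters[c])
            dac = dist[tuple(sorted((a, c)))]
            dbc = dist[tuple(sorted((b, c)))]
            newdist[c] = ((na + nc) * dac + (nb + nc) * dbc - nc * h) / (
                na + nb + nc
            )
        clusters[new] = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        dist = {
            k: v for k, v in dist.items() if a not in k and b not in k
        }
        for c, v in newdist.items():
            dist[tuple(sorted((c, new)))] = v
    return merges


def fisher_enumerate(table) -> Fraction:
    """Exact two-sided p by enumeration over all r x 2 tables with the
    observed margins (probability-ordering convention)."""
    t = [[int(x) for x in row] for row in table]
    rows = [sum(r) for r in t]
    c1 = sum(r[0] for r in t)
    if min(rows) == 0 or c1 == 0 or sum(r[1] for r in t) == 0:
        return Fraction(1)
    w_obs = 1
    for r, row in zip(rows, t):
        w_obs *= math.comb(r, row[0])
    total = 0
    hits = 0
    ranges = [range(0, r + 1) for r in rows]
    for alloc in product(*ranges):
        if sum(alloc) != c1:
            continue
        w = 1
        for r, a in zip(rows, alloc):
            w *= math.comb(r, a)
        total += w
        if w <= w_obs:
            hits += w
    return Fraction(hits, total)
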