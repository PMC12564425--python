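"""Independent brute-force oracles for the tolerance algebra and the U test.

Everything here is a quadratic all-pairs scan (or an exhaustive enumeration)
kept deliberately separate from the package's windowed-search implementation.
"""

from __future__ import annotations

from itertools import combinations

import math

import numpy as np

from micard.io import Ion, IonMatrix, MatchTolerance


def match_matrix(a: IonMatrix, b: IonMatrix, tol: MatchTolerance) -> np.ndarray:
    """Full (len(a), len(b)) boolean all-pairs match table."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)), dtype=bool)
    dtr = np.abs(a.t_r[:, None] - b.t_r[None, :])
    dmz = np.abs(a.mz[:, None] - b.mz[None, :])
    return (dtr <= tol.dt_r) & (dmz <= tol.dmz)


def has_match_bf(a: IonMatrix, b: IonMatrix, tol: MatchTolerance) -> np.ndarray:
    return match_matrix(a, b, tol).any(axis=1)


def pairs_bf(a: IonMatrix, b: IonMatrix, tol: MatchTolerance):
    m = match_matrix(a, b, tol)
    return tuple(sorted((int(i), int(j)) for i, j in zip(*np.nonzero(m))))


def subtract_bf(sample: IonMatrix, other: IonMatrix, tol: MatchTolerance) -> IonMatrix:
    keep = ~has_match_bf(sample, other, tol)
    return sample.with_ions(ion for ion, k in zip(sample.ions, keep) if k)


def filter_rt_bf(m: IonMatrix, lo: float, hi: float) -> IonMatrix:
    return m.with_ions(i for i in m.ions if lo <= i.t_r <= hi)


def top_n_bf(m: IonMatrix, n: int) -> IonMatrix:
    ranked = sorted(m.ions, key=lambda i: (-i.intensity, i.mz, i.t_r))
    return m.with_ions(ranked[:n])


def best_partner_bf(ion: Ion, batch: IonMatrix, tol: MatchTolerance) -> int | None:
    best, best_key = None, None
    for j, cand in enumerate(batch.ions):
        if abs(cand.t_r - ion.t_r) > tol.dt_r or abs(cand.mz - ion.mz) > tol.dmz:
            continue
        key = (abs(cand.mz - ion.mz), abs(cand.t_r - ion.t_r), -cand.intensity)
        if best_key is None or key < best_key:
            best, best_key = j, key
    return best


def common_ions_bf(batches, tol: MatchTolerance, ref_idx: int = 0) -> IonMatrix:
    ref = batches[ref_idx]
    others = [b for k, b in enumerate(batches) if k != ref_idx]
    # precomputed all-pairs tables keep the oracle quadratic but usable at n=2000
    tables = [match_matrix(ref, b, tol) for b in others]
    consensus = []
    for i, ion in enumerate(ref.ions):
        partners = [ion]
        for b, tab in zip(others, tables):
            cand = np.nonzero(tab[i])[0]
            if cand.size == 0:
                partners = []
                break
            best_j = min(
                (int(j) for j in cand),
                key=lambda j: (
                    abs(b.ions[j].mz - ion.mz),
                    abs(b.ions[j].t_r - ion.t_r),
                    -b.ions[j].intensity,
                ),
            )
            partners.append(b.ions[best_j])
        if partners:
            n = len(partners)
            consensus.append(
                Ion(
                    math.fsum(p.t_r for p in partners) / n,
                    math.fsum(p.mz for p in partners) / n,
                    math.fsum(p.intensity for p in partners) / n,
                )
            )
    return ref.with_ions(consensus)


def _midrank_u(values: np.ndarray, labels: np.ndarray) -> float:
    """min(U_a, U_b) from midranks, for one labeling."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n_a = int(labels.sum())
    n_b = len(values) - n_a
    r_a = ranks[labels].sum()
    u_a = r_a - n_a * (n_a + 1) / 2
    return min(u_a, n_a * n_b - u_a)


def mw_exact(group_a, group_b):
    """Exhaustive-permutation U and two-sided p for small groups.

    Two-sided p = fraction of labelings whose min-U is <= the observed min-U
    (equivalently whose |U - n_a n_b / 2| is at least as extreme).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    n_a = len(a)
    obs_labels = np.zeros(n, dtype=bool)
    obs_labels[:n_a] = True
    u_obs = _midrank_u(pooled, obs_labels)
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        labels = np.zeros(n, dtype=bool)
        labels[list(idx)] = True
        total += 1
        if _midrank_u(pooled, labels) <= u_obs + 1e-12:
            count += 1
    return u_obs, count / total
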