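"""Tolerance-based set algebra on ion matrices.

Two ions "match" when both |Δt_R| ≤ dt_r and |Δm/z| ≤ dmz.  The relation is
symmetric and reflexive but NOT transitive, so no operation here assumes
transitivity; the multi-batch intersection is explicitly anchored on a
reference batch.

All matching goes through an m/z-sorted window search (``searchsorted`` on
the target's m/z axis, then a retention-time check on the candidates), which
is exactly equivalent to — and is tested against — a quadratic all-pairs scan.
All operations are pure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, ShortfallWarning
from .io import Ion, IonMatrix, MatchTolerance

__all__ = [
    "RtWindow",
    "MatchReport",
    "ions_match",
    "has_match",
    "match_report",
    "filter_rt_window",
    "subtract_blank",
    "common_ions",
    "difference_set",
    "rank_by_intensity",
    "top_n_by_intensity",
]


@dataclass(frozen=True, slots=True)
class RtWindow:
    """Closed retention-time interval [lo, hi] in minutes; defaults 1.00–33.00."""

    lo: float = 1.00
    hi: float = 33.00

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"RtWindow requires lo < hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class MatchReport:
    """Audit record of a matching pass.

    ``pairs`` holds (query index, partner index) for every within-tolerance
    pair found; ``n_matched`` counts query ions with at least one partner.
    """

    n_query: int
    n_matched: int
    pairs: tuple[tuple[int, int], ...]


def ions_match(a: Ion, b: Ion, tol: MatchTolerance = MatchTolerance()) -> bool:
    """True iff |Δt_R| ≤ dt_r and |Δm/z| ≤ dmz.  Intensity plays no role."""
    return abs(a.t_r - b.t_r) <= tol.dt_r and abs(a.mz - b.mz) <= tol.dmz


def _window_bounds(target: IonMatrix, query_mz: np.ndarray, dmz: float):
    """searchsorted bounds of the m/z window for each query, plus sorted views."""
    order = target._mz_order
    mz_sorted = target.mz[order]
    lo = np.searchsorted(mz_sorted, query_mz - dmz, side="left")
    hi = np.searchsorted(mz_sorted, query_mz + dmz, side="right")
    return order, mz_sorted, lo, hi


def has_match(query: IonMatrix, target: IonMatrix, tol: MatchTolerance) -> np.ndarray:
    """Boolean array: for each query ion, does it match ≥1 target ion?"""
    nq = len(query)
    out = np.zeros(nq, dtype=bool)
    if nq == 0 or len(target) == 0:
        return out
    order, _, lo, hi = _window_bounds(target, query.mz, tol.dmz)
    tr_sorted = target.t_r[order]
    q_tr = query.t_r
    for i in range(nq):
        if lo[i] < hi[i]:
            out[i] = bool(
                np.any(np.abs(tr_sorted[lo[i]:hi[i]] - q_tr[i]) <= tol.dt_r)
            )
    return out


def match_report(query: IonMatrix, target: IonMatrix, tol: MatchTolerance) -> MatchReport:
    """Full audit of query-vs-target matching (all within-tolerance pairs)."""
    pairs: list[tuple[int, int]] = []
    nq = len(query)
    if nq and len(target):
        order, _, lo, hi = _window_bounds(target, query.mz, tol.dmz)
        tr_sorted = target.t_r[order]
        for i in range(nq):
            if lo[i] < hi[i]:
                hits = np.nonzero(
                    np.abs(tr_sorted[lo[i]:hi[i]] - query.ions[i].t_r) <= tol.dt_r
                )[0]
                for h in hits:
                    pairs.append((i, int(order[lo[i] + h])))
    n_matched = len({i for i, _ in pairs})
    return MatchReport(n_query=nq, n_matched=n_matched, pairs=tuple(sorted(pairs)))


def filter_rt_window(m: IonMatrix, w: RtWindow = RtWindow()) -> IonMatrix:
    """Keep exactly the ions with lo ≤ t_R ≤ hi (closed interval)."""
    return m.with_ions(i for i in m.ions if w.lo <= i.t_r <= w.hi)


def subtract_blank(sample: IonMatrix, blank: IonMatrix, tol: MatchTolerance) -> IonMatrix:
    """Remove sample ions matching any blank (solvent background) ion."""
    if len(sample) == 0 or len(blank) == 0:
        return sample
    keep = ~has_match(sample, blank, tol)
    return sample.with_ions(ion for ion, k in zip(sample.ions, keep) if k)


def difference_set(own: IonMatrix, other: IonMatrix, tol: MatchTolerance) -> IonMatrix:
    """Ions of `own` with no within-tolerance counterpart in `other`.

    This is the cross-species screen: a feature present (within tolerance) in
    both species' common-ion matrices is non-proprietary and is excluded.
    """
    if len(own) == 0 or len(other) == 0:
        return own
    keep = ~has_match(own, other, tol)
    return own.with_ions(ion for ion, k in zip(own.ions, keep) if k)


def best_partner(ion: Ion, batch: IonMatrix, tol: MatchTolerance) -> int | None:
    """Index of the best within-tolerance partner for `ion` in `batch`.

    Best = smallest |Δm/z|, then smallest |Δt_R|, then highest intensity
    (mass accuracy is the more reliable axis).  None when nothing matches.
    """
    if len(batch) == 0:
        return None
    order = batch._mz_order
    mz_sorted = batch.mz[order]
    lo = int(np.searchsorted(mz_sorted, ion.mz - tol.dmz, side="left"))
    hi = int(np.searchsorted(mz_sorted, ion.mz + tol.dmz, side="right"))
    best_idx: int | None = None
    best_key: tuple[float, float, float] | None = None
    for j in range(lo, hi):
        idx = int(order[j])
        cand = batch.ions[idx]
        if abs(cand.t_r - ion.t_r) > tol.dt_r:
            continue
        key = (abs(cand.mz - ion.mz), abs(cand.t_r - ion.t_r), -cand.intensity)
        if best_key is None or key < best_key:
            best_key, best_idx = key, idx
    return best_idx


def common_ions(
    batches: Sequence[IonMatrix],
    tol: MatchTolerance,
    reference: int | str = 0,
) -> IonMatrix:
    """Consensus ions present (within tolerance) in every batch.

    Because the match relation is not transitive, "common to all batches" is
    anchored on a reference batch (by position or batch_id): each reference
    ion that finds ≥1 partner in every other batch yields one consensus ion
    whose t_R, m/z, and intensity are the plain arithmetic means over the
    reference ion and one best partner per other batch.  Batch order beyond
    the reference does not affect the result.
    """
    if len(batches) == 0:
        raise InputError("common_ions requires at least one batch")
    if isinstance(reference, str):
        ids = [b.batch_id for b in batches]
        if reference not in ids:
            raise InputError(f"reference batch {reference!r} not among {ids!r}")
        ref_idx = ids.index(reference)
    else:
        ref_idx = int(reference)
        if not 0 <= ref_idx < len(batches):
            raise InputError(f"reference index {ref_idx} out of range")
    ref = batches[ref_idx]
    others = [b for k, b in enumerate(batches) if k != ref_idx]
    consensus: list[Ion] = []
    for ion in ref.ions:
        partners = [ion]
        for b in others:
            j = best_partner(ion, b, tol)
            if j is None:
                partners = []
                break
            partners.append(b.ions[j])
        if partners:
            n = len(partners)
            # fsum: exactly rounded, so the consensus is invariant to batch order
            consensus.append(
                Ion(
                    math.fsum(p.t_r for p in partners) / n,
                    math.fsum(p.mz for p in partners) / n,
                    math.fsum(p.intensity for p in partners) / n,
                )
            )
    return IonMatrix(
        ions=tuple(consensus),
        sample_id=f"common[{ref.material or ref.sample_id}]",
        batch_id="consensus",
        material=ref.material,
        role="reference",
    )


def rank_by_intensity(m: IonMatrix) -> tuple[Ion, ...]:
    """Ions ordered intensity-descending; ties by ascending m/z then t_R."""
    return tuple(sorted(m.ions, key=lambda i: (-i.intensity, i.mz, i.t_r)))


def top_n_by_intensity(m: IonMatrix, n: int) -> IonMatrix:
    """The n highest-intensity ions (deterministic tie-break; see rank_by_intensity).

    Returns all ions with a :class:`ShortfallWarning` when fewer than n exist.
    """
    if n < 1:
        raise InputError(f"top_n_by_intensity requires n >= 1, got {n}")
    ranked = rank_by_intensity(m)
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} ions available for top-{n} selection",
            ShortfallWarning,
            stacklevel=2,
        )
    return m.with_ions(ranked[:n])
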