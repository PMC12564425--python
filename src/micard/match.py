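"""Contrast-credibility scoring, threshold calibration, and classification.

The matching score of a test sample against a card is its *contrast
credibility*:

    CC = 100 × (number of matched ions) / (number of ions in the card)

where "matched ions" counts TEST-sample ions having at least one
within-tolerance partner among card ions.  Counting test ions (not card
ions) is what lets CC exceed 100% when feature detection splits a peak into
two nearby features — observed in practice as scores of 101–102%.

The adulteration-detection threshold is NOT a constant of the method: it is
re-derived per analysis from positive adulterated controls prepared at the
adulteration limit, like an accompanying standard curve in quantitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, InputError
from .io import MIC, IonMatrix, Ion, MatchTolerance
from .ops import MatchReport, has_match, match_report

__all__ = [
    "CCResult",
    "ThresholdCalibration",
    "Classification",
    "contrast_credibility",
    "calibrate_threshold",
    "classify",
    "extract_marker_ion",
    "round_half_up",
]

ADULTERATED = "adulterated"
NOT_DETECTED = "not-detected"


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact half-up ties (25.8→26, 24.5→25)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CCResult:
    """Contrast credibility of one sample against one card.

    ``cc_raw`` is the unrounded percentage used for threshold comparison;
    ``cc_percent`` is the integer percent reported in tables.
    """

    sample_id: str
    mic_material: str
    n_matched: int
    mic_size: int
    cc_raw: float

    @property
    def cc_percent(self) -> int:
        return round_half_up(self.cc_raw)

    def __str__(self) -> str:
        return (
            f"{self.sample_id}: {self.n_matched}/{self.mic_size} ions matched "
            f"vs {self.mic_material} card → CC = {self.cc_percent}%"
        )


@dataclass(frozen=True)
class ThresholdCalibration:
    """Detection threshold derived from replicate positive-control CCs."""

    replicate_ccs: tuple[float, ...]
    mean_cc: float
    threshold: int
    cc_min: float
    cc_max: float


@dataclass(frozen=True)
class Classification:
    decision: str
    cc_raw: float
    threshold: int

    def __str__(self) -> str:
        return f"CC {self.cc_raw:.1f}% vs threshold {self.threshold}% → {self.decision}"


def contrast_credibility(
    test: IonMatrix,
    mic: MIC,
    tol: MatchTolerance | None = None,
) -> CCResult:
    """Score a test sample against a card.

    Tolerance defaults to the one the card was built with.  Deterministic and
    invariant under permutation of either ion list and under any positive
    rescaling of intensities (matching ignores intensity).
    """
    if len(mic) == 0:
        raise EmptyInputError(f"MIC for {mic.material!r} holds no ions")
    tol = tol if tol is not None else mic.tolerance
    n_matched = int(has_match(test, mic.as_matrix(), tol).sum())
    return CCResult(
        sample_id=test.sample_id,
        mic_material=mic.material,
        n_matched=n_matched,
        mic_size=len(mic),
        cc_raw=100.0 * n_matched / len(mic),
    )


def calibrate_threshold(replicate_ccs: Sequence[float]) -> ThresholdCalibration:
    """Average replicate positive-control CCs into an integer threshold.

    Requires ≥2 replicates — a single adulterated control cannot set a
    threshold.  The threshold is the half-up-rounded mean.
    """
    ccs = tuple(float(c) for c in replicate_ccs)
    if len(ccs) < 2:
        raise InputError(
            f"threshold calibration needs >= 2 positive-control CCs, got {len(ccs)}"
        )
    mean_cc = float(np.mean(ccs))
    return ThresholdCalibration(
        replicate_ccs=ccs,
        mean_cc=mean_cc,
        threshold=round_half_up(mean_cc),
        cc_min=min(ccs),
        cc_max=max(ccs),
    )


def classify(cc: CCResult | float, threshold: int) -> Classification:
    """Adulterated iff raw CC ≥ threshold.

    The calibration controls ARE adulterated, so their mean must itself
    classify as adulterated — hence ≥, not >.
    """
    cc_raw = cc.cc_raw if isinstance(cc, CCResult) else float(cc)
    decision = ADULTERATED if cc_raw >= threshold else NOT_DETECTED
    return Classification(decision=decision, cc_raw=cc_raw, threshold=int(threshold))


def extract_marker_ion(
    m: IonMatrix,
    t_r: float,
    mz: float,
    tol: MatchTolerance = MatchTolerance(),
) -> MatchReport:
    """Targeted query: all ions of `m` within tolerance of (t_r, mz).

    Used for orthogonal verification against a known species-exclusive
    marker (e.g. the [M+HCOO]⁻ adduct of pseudo-ginsenoside F11 near
    13.71 min / 845.49 m/z).  Hits are ordered by |Δm/z| then |Δt_R|.
    """
    probe = IonMatrix(ions=(Ion(t_r, mz, 0.0),), sample_id="marker-query")
    rep = match_report(probe, m, tol)
    hits = sorted(
        (j for _, j in rep.pairs),
        key=lambda j: (abs(m.ions[j].mz - mz), abs(m.ions[j].t_r - t_r)),
    )
    return MatchReport(
        n_query=1,
        n_matched=rep.n_matched,
        pairs=tuple((0, j) for j in hits),
    )
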