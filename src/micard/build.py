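"""MIC construction: the full screening pipeline for a pair of materials.

Per material the pipeline is fixed:

    retention-time window  →  blank subtraction (each batch)  →
    multi-batch intersection (common ions)  →
    difference set against the other material's common ions  →
    top-N by intensity

Windowing comes first because it shrinks every later step and belongs to
data transformation; the ±tolerance intersection is anchored on a reference
batch (first listed by default) because the match relation is not transitive.
The defining property of the output — no card ion of one material matches any
common ion of the other — is asserted after every build.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import BuildError, InputError
from .io import MIC, IonMatrix, MatchTolerance
from .ops import (
    RtWindow,
    common_ions,
    difference_set,
    filter_rt_window,
    has_match,
    rank_by_intensity,
    subtract_blank,
    top_n_by_intensity,
)

__all__ = ["MicBuildConfig", "build_common_matrix", "build_mic_pair"]


@dataclass(frozen=True)
class MicBuildConfig:
    """Knobs of the MIC pipeline.

    ``reference_batch`` selects the intersection anchor: None → first listed,
    otherwise the batch_id to anchor on.  ``built_at`` is an optional
    provenance stamp copied into both cards (kept out by default so artifacts
    are byte-deterministic).
    """

    tolerance: MatchTolerance = field(default_factory=MatchTolerance)
    rt_window: RtWindow = field(default_factory=RtWindow)
    n_top: int = 100
    reference_batch: str | None = None
    built_at: str | None = None

    def __post_init__(self) -> None:
        if self.n_top < 1:
            raise ValueError(f"n_top must be >= 1, got {self.n_top}")


def _as_blanks(
    blank: IonMatrix | Sequence[IonMatrix] | None, n: int
) -> list[IonMatrix | None]:
    if blank is None:
        return [None] * n
    if isinstance(blank, IonMatrix):
        return [blank] * n
    blanks = list(blank)
    if len(blanks) != n:
        raise InputError(f"{len(blanks)} blanks given for {n} batches")
    return blanks


def build_common_matrix(
    batches: Sequence[IonMatrix],
    blank: IonMatrix | Sequence[IonMatrix] | None,
    cfg: MicBuildConfig,
) -> IonMatrix:
    """Window + blank-subtract each batch, then intersect across batches."""
    if len(batches) == 0:
        raise InputError("at least one batch is required")
    cleaned = []
    for b, bl in zip(batches, _as_blanks(blank, len(batches))):
        b = filter_rt_window(b, cfg.rt_window)
        if bl is not None:
            b = subtract_blank(b, bl, cfg.tolerance)
        cleaned.append(b)
    # a named anchor only binds the material that actually contains that batch
    reference: int | str = 0
    if cfg.reference_batch is not None and any(
        b.batch_id == cfg.reference_batch for b in cleaned
    ):
        reference = cfg.reference_batch
    return common_ions(cleaned, cfg.tolerance, reference=reference)


def _material_label(batches: Sequence[IonMatrix], fallback: str) -> str:
    labels = {b.material for b in batches if b.material}
    if len(labels) == 1:
        return labels.pop()
    return fallback


def build_mic_pair(
    batches_a: Sequence[IonMatrix],
    batches_b: Sequence[IonMatrix],
    blank: IonMatrix | Sequence[IonMatrix] | None = None,
    cfg: MicBuildConfig = MicBuildConfig(),
) -> tuple[MIC, MIC]:
    """Build the two matrix identity cards for a pair of materials.

    Raises :class:`BuildError` naming the material whose specific-ion set is
    empty; a card smaller than ``n_top`` is a warning, not an error.
    """
    if len(batches_a) == 0 or len(batches_b) == 0:
        raise InputError("each material needs at least one batch")
    common_a = build_common_matrix(batches_a, blank, cfg)
    common_b = build_common_matrix(batches_b, blank, cfg)

    mics = []
    for own, other, own_batches, fallback in (
        (common_a, common_b, batches_a, "A"),
        (common_b, common_a, batches_b, "B"),
    ):
        label = _material_label(own_batches, fallback)
        specific = difference_set(own, other, cfg.tolerance)
        if len(specific) == 0:
            raise BuildError(
                f"material {label!r}: no specific ions survive the cross-material "
                "difference — the two materials are indistinguishable at this tolerance"
            )
        top = top_n_by_intensity(specific, cfg.n_top)
        mic = MIC(
            ions=rank_by_intensity(top),
            material=label,
            n_requested=cfg.n_top,
            tolerance=cfg.tolerance,
            source_batches=tuple(b.batch_id for b in own_batches),
            built_at=cfg.built_at,
        )
        # defining property of specificity: card ions match nothing across species
        if has_match(mic.as_matrix(), other, cfg.tolerance).any():
            raise BuildError(
                f"internal consistency failure: a {label!r} card ion matches the "
                "other material's common-ion matrix"
            )
        mics.append(mic)
    return mics[0], mics[1]
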