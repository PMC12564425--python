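"""Synthetic two-species peak-list generator.

Emulates the statistical structure the card-matching method assumes: two
botanically close materials whose runs share most features, while each
species owns a set of species-specific ions; batch-to-batch jitter in
retention time and m/z; multiplicative intensity noise; occasional ion
dropout; and linear mixing of two pure materials at a stated proportion with
a detection floor (low-proportion adulterant ions fall below the floor, which
is what produces the dose–response of the matching score).

What it deliberately does NOT emulate: raw spectra, isotope patterns,
adducts, chromatographic drift that varies along the gradient, or
intensity-dependent dropout — the unit of simulation is the
post-feature-detection ion.

All randomness flows from explicit seeds; batch-level streams are derived by
hashing (seed, batch_id), so any batch can be regenerated in isolation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .io import Ion, IonMatrix, MatchTolerance
from .ops import RtWindow, best_partner

__all__ = [
    "SpeciesTemplate",
    "JitterModel",
    "make_template_pair",
    "sample_batch",
    "generate_batches",
    "mix_samples",
    "DEFAULT_MZ_RANGE",
    "DEFAULT_INTENSITY_RANGE",
    "DEFAULT_DETECTION_FLOOR",
]

DEFAULT_MZ_RANGE = (100.0, 1200.0)  # Da; typical QTOF full-scan range
DEFAULT_INTENSITY_RANGE = (1e3, 1e6)  # a.u.; ~3 decades of dynamic range
#: Default detection floor for mixtures, in the same arbitrary units as the
#: default intensity range.  Chosen (see methods note) so that with the
#: canonical templates a 5% adulterant scores in the ~20–35% CC band against
#: the adulterant's card while a pure adulterant still scores near 100%.
DEFAULT_DETECTION_FLOOR = 2e4


@dataclass(frozen=True)
class SpeciesTemplate:
    """Ground-truth ion sets for one species: shared + species-specific."""

    name: str
    shared_ions: tuple[Ion, ...]
    specific_ions: tuple[Ion, ...]

    @property
    def all_ions(self) -> tuple[Ion, ...]:
        return self.shared_ions + self.specific_ions

    def to_matrix(self) -> IonMatrix:
        return IonMatrix(
            ions=self.all_ions,
            sample_id=f"template-{self.name}",
            material=self.name,
            role="reference",
        )


@dataclass(frozen=True)
class JitterModel:
    """Batch-to-batch measurement noise.

    sigma_tr/sigma_mz are Gaussian jitter SDs (minutes / daltons), both well
    inside the default matching tolerances; intensity_cv is the coefficient of
    variation of log-normal intensity noise; dropout_rate is the per-batch
    probability that an ion goes undetected.
    """

    sigma_tr: float = 0.03
    sigma_mz: float = 0.002
    intensity_cv: float = 0.3
    dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_tr", "sigma_mz", "intensity_cv", "dropout_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"JitterModel.{name} must be non-negative")
        if self.dropout_rate >= 1:
            raise ValueError("dropout_rate must be < 1")


def _separated(tr, mz, trs, mzs, min_dtr, min_dmz) -> bool:
    """No existing ion lies within BOTH separation radii of the candidate."""
    if len(trs) == 0:
        return True
    clash = (np.abs(trs - tr) <= min_dtr) & (np.abs(mzs - mz) <= min_dmz)
    return not bool(clash.any())


def make_template_pair(
    n_shared: int,
    n_specific: int,
    rt_window: RtWindow = RtWindow(),
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
    seed: int = 0,
    intensity_range: tuple[float, float] = DEFAULT_INTENSITY_RANGE,
    tolerance: MatchTolerance = MatchTolerance(),
    names: tuple[str, str] = ("A", "B"),
    separation_factor: float = 2.0,
) -> tuple[SpeciesTemplate, SpeciesTemplate]:
    """Ground-truth templates for two species sharing ``n_shared`` ions.

    Ion positions are uniform over the retention window and m/z range with
    log-uniform intensities.  Rejection sampling enforces pairwise separation
    greater than ``separation_factor`` × tolerance between ALL template ions
    (shared and specific, within and across species), which guarantees the
    planted specificity invariant — no specific ion of one species matches
    any ion of the other — with enough margin that default jitter cannot
    create cross-species matches in practice.
    """
    if n_shared < 0 or n_specific < 0:
        raise GenerationError("n_shared and n_specific must be >= 0")
    if not (mz_range[0] > 0 and mz_range[1] > mz_range[0]):
        raise GenerationError(f"invalid mz_range {mz_range}")
    rng = np.random.default_rng(seed)
    total = n_shared + 2 * n_specific
    min_dtr = separation_factor * tolerance.dt_r
    min_dmz = separation_factor * tolerance.dmz
    log_lo, log_hi = math.log10(intensity_range[0]), math.log10(intensity_range[1])

    trs = np.empty(total)
    mzs = np.empty(total)
    placed = 0
    attempts = 0
    max_attempts = max(1000, 200 * total)
    while placed < total:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {total} ions with separation "
                f"(>{min_dtr} min, >{min_dmz} Da) after {max_attempts} draws; "
                "widen the retention window or m/z range, or lower the count"
            )
        tr = rng.uniform(rt_window.lo, rt_window.hi)
        mz = rng.uniform(mz_range[0], mz_range[1])
        if _separated(tr, mz, trs[:placed], mzs[:placed], min_dtr, min_dmz):
            trs[placed], mzs[placed] = tr, mz
            placed += 1
    intens = 10.0 ** rng.uniform(log_lo, log_hi, size=total)

    ions = [Ion(float(t), float(m), float(i)) for t, m, i in zip(trs, mzs, intens)]
    shared = tuple(ions[:n_shared])
    spec_a = tuple(ions[n_shared : n_shared + n_specific])
    spec_b = tuple(ions[n_shared + n_specific :])
    return (
        SpeciesTemplate(name=names[0], shared_ions=shared, specific_ions=spec_a),
        SpeciesTemplate(name=names[1], shared_ions=shared, specific_ions=spec_b),
    )


def _batch_rng(seed: int, batch_id: str) -> np.random.Generator:
    # independent, reproducible stream per (seed, batch_id)
    return np.random.default_rng([seed, zlib.crc32(batch_id.encode("utf-8"))])


def sample_batch(t: SpeciesTemplate, jm: JitterModel, batch_id: str) -> IonMatrix:
    """One simulated run of a pure material: dropout + jitter + intensity noise."""
    rng = _batch_rng(jm.seed, batch_id)
    template = t.all_ions
    n = len(template)
    keep = rng.random(n) >= jm.dropout_rate
    d_tr = rng.normal(0.0, jm.sigma_tr, n) if jm.sigma_tr > 0 else np.zeros(n)
    d_mz = rng.normal(0.0, jm.sigma_mz, n) if jm.sigma_mz > 0 else np.zeros(n)
    if jm.intensity_cv > 0:
        sigma_log = math.sqrt(math.log1p(jm.intensity_cv**2))
        factor = np.exp(rng.normal(-0.5 * sigma_log**2, sigma_log, n))
    else:
        factor = np.ones(n)
    ions = []
    for k, ion in enumerate(template):
        if not keep[k]:
            continue
        ions.append(
            Ion(
                max(0.0, ion.t_r + float(d_tr[k])),
                max(1e-9, ion.mz + float(d_mz[k])),
                ion.intensity * float(factor[k]),
            )
        )
    return IonMatrix(
        ions=tuple(ions),
        sample_id=f"{t.name}-{batch_id}",
        batch_id=batch_id,
        material=t.name,
        role="sample",
    )


def generate_batches(
    t: SpeciesTemplate, jm: JitterModel, n_batches: int, prefix: str | None = None
) -> list[IonMatrix]:
    """n independent batches named ``{prefix}{01..n}``."""
    prefix = prefix if prefix is not None else t.name
    return [
        sample_batch(t, jm, f"{prefix}{k + 1:02d}") for k in range(n_batches)
    ]


def mix_samples(
    a: IonMatrix,
    b: IonMatrix,
    proportion_b: float,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
    tol: MatchTolerance = MatchTolerance(),
) -> IonMatrix:
    """Linear in-silico blend of two pure-material runs.

    Ions matching across the two runs merge into one feature whose
    coordinates and intensity are proportion-weighted means
    ((1−p)·a + p·b, so p=0 reproduces `a` exactly and p=1 reproduces `b`);
    unshared ions carry scaled intensity (1−p)·I_a or p·I_b.  Ions whose
    blended intensity is zero or below ``detection_floor`` are dropped — the
    floor is what makes a low-proportion adulterant only partially
    detectable, reproducing the CC dose response.
    """
    p = float(proportion_b)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion_b must be in [0, 1], got {p}")
    if detection_floor < 0:
        raise ValueError("detection_floor must be >= 0")
    q = 1.0 - p
    ions: list[Ion] = []
    matched_b: set[int] = set()
    for ion in a.ions:
        j = best_partner(ion, b, tol)
        if j is None:
            ions.append(Ion(ion.t_r, ion.mz, q * ion.intensity))
        else:
            matched_b.add(j)
            other = b.ions[j]
            ions.append(
                Ion(
                    q * ion.t_r + p * other.t_r,
                    q * ion.mz + p * other.mz,
                    q * ion.intensity + p * other.intensity,
                )
            )
    for j, ion in enumerate(b.ions):
        if j not in matched_b:
            ions.append(Ion(ion.t_r, ion.mz, p * ion.intensity))
    kept = [i for i in ions if i.intensity > 0 and i.intensity >= detection_floor]
    return IonMatrix(
        ions=tuple(kept),
        sample_id=f"mix({a.sample_id}+{b.sample_id})@{p:g}",
        material="mixture",
        role="sample",
    )
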