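"""Peak-list and MIC artifact I/O, plus the core domain types.

The unit of data is the *ion*: one ``[t_R, m/z, I]`` triplet produced by
feature detection on an LC-MS run.  A sample's ions form an :class:`IonMatrix`;
the species fingerprint distilled from many batches is a :class:`MIC`
("matrix identity card"): the top-N species-specific ions by intensity.

Peak lists are delimited text as exported by feature-detection software; the
column mapping is configuration (:class:`PeaklistDialect`), never hard-coded.
MIC artifacts are stored as a self-describing tab-separated text file with a
small ``#`` header block — human-inspectable and diff-able.  Floats are
written with ``repr`` so every round trip is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    InputError,
    MicardWarning,
    RejectedRowsWarning,
)

__all__ = [
    "Ion",
    "IonMatrix",
    "MatchTolerance",
    "MIC",
    "PeaklistDialect",
    "read_peaklist",
    "write_peaklist",
    "read_mic",
    "write_mic",
]

_ROLES = ("sample", "blank", "reference")


@dataclass(frozen=True, slots=True)
class Ion:
    """One detected feature: retention time (min), m/z (Da), intensity (a.u.)."""

    t_r: float
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        for name in ("t_r", "mz", "intensity"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"Ion.{name} must be finite, got {v!r}")
        if self.t_r < 0:
            raise ValueError(f"Ion.t_r must be >= 0, got {self.t_r}")
        if self.mz <= 0:
            raise ValueError(f"Ion.mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"Ion.intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True, slots=True)
class MatchTolerance:
    """The (ΔtR, Δm/z) window under which two ions count as the same feature.

    Both tolerances are absolute: minutes for ``dt_r``, daltons for ``dmz``
    (not ppm).  The defaults (0.20 min, 0.01 Da) are the method's entire
    cross-run alignment model.
    """

    dt_r: float = 0.20
    dmz: float = 0.01

    def __post_init__(self) -> None:
        if not (self.dt_r > 0 and math.isfinite(self.dt_r)):
            raise ValueError(f"dt_r must be > 0, got {self.dt_r}")
        if not (self.dmz > 0 and math.isfinite(self.dmz)):
            raise ValueError(f"dmz must be > 0, got {self.dmz}")


def _normalize_ions(ions: Iterable[Ion]) -> tuple[Ion, ...]:
    """Deduplicate on exact (t_r, mz), keeping max intensity; sort by (t_r, mz)."""
    best: dict[tuple[float, float], Ion] = {}
    for ion in ions:
        key = (ion.t_r, ion.mz)
        prev = best.get(key)
        if prev is None or ion.intensity > prev.intensity:
            best[key] = ion
    return tuple(sorted(best.values(), key=lambda i: (i.t_r, i.mz)))


@dataclass(frozen=True)
class IonMatrix:
    """Ordered ion collection for one sample run, with its metadata.

    Ions are stored sorted by (t_r, mz) ascending and deduplicated on exact
    coordinates (keeping the higher intensity — feature detection occasionally
    splits a peak into identical rows).
    """

    ions: tuple[Ion, ...]
    sample_id: str = ""
    batch_id: str = ""
    material: str = ""
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        object.__setattr__(self, "ions", _normalize_ions(self.ions))

    def __len__(self) -> int:
        return len(self.ions)

    @cached_property
    def t_r(self) -> np.ndarray:
        return np.array([i.t_r for i in self.ions], dtype=float)

    @cached_property
    def mz(self) -> np.ndarray:
        return np.array([i.mz for i in self.ions], dtype=float)

    @cached_property
    def intensity(self) -> np.ndarray:
        return np.array([i.intensity for i in self.ions], dtype=float)

    @cached_property
    def _mz_order(self) -> np.ndarray:
        # index permutation sorting ions by m/z; used by windowed matching
        return np.argsort(self.mz, kind="stable")

    def with_ions(self, ions: Iterable[Ion]) -> "IonMatrix":
        """A copy carrying the same metadata but a new ion set."""
        return replace(self, ions=tuple(ions))

    @classmethod
    def from_arrays(
        cls,
        t_r: Sequence[float],
        mz: Sequence[float],
        intensity: Sequence[float],
        **meta: str,
    ) -> "IonMatrix":
        ions = tuple(Ion(float(t), float(m), float(i)) for t, m, i in zip(t_r, mz, intensity))
        return cls(ions=ions, **meta)


@dataclass(frozen=True)
class MIC:
    """A matrix identity card: a species' top-N specific ions plus provenance.

    Ions are stored intensity-descending (the selection order).  ``n_requested``
    is the target card size (100 by convention); the stored ion count may fall
    short when too few specific ions survive screening.
    """

    ions: tuple[Ion, ...]
    material: str
    n_requested: int = 100
    tolerance: MatchTolerance = field(default_factory=MatchTolerance)
    source_batches: tuple[str, ...] = ()
    built_at: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ions", tuple(self.ions))
        object.__setattr__(self, "source_batches", tuple(self.source_batches))
        if self.n_requested < 1:
            raise ValueError(f"n_requested must be >= 1, got {self.n_requested}")
        if len(self.ions) > self.n_requested:
            raise ValueError(
                f"MIC holds {len(self.ions)} ions but n_requested={self.n_requested}"
            )
        inten = [i.intensity for i in self.ions]
        if any(a < b for a, b in zip(inten, inten[1:])):
            raise ValueError("MIC ions must be sorted intensity-descending")

    def __len__(self) -> int:
        return len(self.ions)

    def as_matrix(self) -> IonMatrix:
        """The card's ions as an IonMatrix (role='reference')."""
        return IonMatrix(
            ions=self.ions,
            sample_id=f"MIC-{self.material}",
            material=self.material,
            role="reference",
        )


# ---------------------------------------------------------------------------
# Peak-list I/O


@dataclass(frozen=True)
class PeaklistDialect:
    """Column mapping + delimiter for peak-list files.

    ``delimiter=None`` autodetects comma vs tab.  The default header names are
    a convention for feature-detection exports, not a standard — remap freely.
    """

    t_r_column: str = "Retention time (min)"
    mz_column: str = "m/z"
    intensity_column: str = "Abundance"
    delimiter: str | None = None


DEFAULT_DIALECT = PeaklistDialect()


def read_peaklist(
    path: str | Path,
    dialect: PeaklistDialect = DEFAULT_DIALECT,
    *,
    sample_id: str | None = None,
    batch_id: str = "",
    material: str = "",
    role: str = "sample",
) -> IonMatrix:
    """Read one delimited peak list into an :class:`IonMatrix`.

    Rows with non-numeric, non-finite, or invariant-violating values
    (negative t_R, non-positive m/z, negative intensity) are dropped; a
    :class:`RejectedRowsWarning` reports how many.  Exact-duplicate
    coordinates collapse to the max-intensity row.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"peak list not found: {path}")
    sep = dialect.delimiter
    try:
        # dtype=str + Python float(): exact round trips (repr-written values
        # re-read bit-identically, which fast CSV float parsers do not promise)
        if sep is None:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        else:
            df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"peak list has no data: {path}") from None
    for col in (dialect.t_r_column, dialect.mz_column, dialect.intensity_column):
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing column {col!r} (found {list(df.columns)!r})"
            )
    cols = [dialect.t_r_column, dialect.mz_column, dialect.intensity_column]

    def _exact_floats(series: pd.Series) -> np.ndarray:
        out = np.empty(len(series))
        for k, v in enumerate(series):
            try:
                out[k] = float(v)
            except (TypeError, ValueError):
                out[k] = np.nan
        return out

    vals = np.column_stack([_exact_floats(df[c]) for c in cols])
    finite = np.isfinite(vals).all(axis=1)
    with np.errstate(invalid="ignore"):
        valid = finite & (vals[:, 0] >= 0) & (vals[:, 1] > 0) & (vals[:, 2] >= 0)
    n_rejected = int((~valid).sum())
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} of {len(df)} rows "
            "(non-numeric, non-finite, or out-of-range values)",
            RejectedRowsWarning,
            stacklevel=2,
        )
    vals = vals[valid]
    if len(vals) == 0:
        raise EmptyInputError(f"{path}: zero valid rows")
    return IonMatrix.from_arrays(
        vals[:, 0],
        vals[:, 1],
        vals[:, 2],
        sample_id=sample_id if sample_id is not None else path.stem,
        batch_id=batch_id,
        material=material,
        role=role,
    )


def write_peaklist(
    m: IonMatrix,
    path: str | Path,
    dialect: PeaklistDialect = DEFAULT_DIALECT,
) -> None:
    """Write an IonMatrix as a delimited peak list (full float precision)."""
    sep = dialect.delimiter or ","
    lines = [sep.join((dialect.t_r_column, dialect.mz_column, dialect.intensity_column))]
    for ion in m.ions:
        lines.append(sep.join((repr(ion.t_r), repr(ion.mz), repr(ion.intensity))))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MIC artifact I/O

_MIC_MAGIC = "# micard matrix identity card v1"


def write_mic(mic: MIC, path: str | Path) -> None:
    """Write a MIC artifact; deterministic byte-for-byte for equal inputs."""
    lines = [
        _MIC_MAGIC,
        f"# material: {mic.material}",
        f"# n_requested: {mic.n_requested}",
        f"# dt_r: {repr(mic.tolerance.dt_r)}",
        f"# dmz: {repr(mic.tolerance.dmz)}",
        f"# source_batches: {','.join(mic.source_batches) or '-'}",
        f"# built_at: {mic.built_at if mic.built_at is not None else '-'}",
        "t_r\tmz\tintensity",
    ]
    for ion in mic.ions:
        lines.append(f"{ion.t_r!r}\t{ion.mz!r}\t{ion.intensity!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header_line(line: str, key: str, path: Path) -> str:
    prefix = f"# {key}:"
    if not line.startswith(prefix):
        raise FormatError(f"{path}: expected header field {key!r}, got {line!r}")
    return line[len(prefix):].strip()


def read_mic(path: str | Path) -> MIC:
    """Read a MIC artifact written by :func:`write_mic` (exact round trip)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"MIC file not found: {path}")
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _MIC_MAGIC:
        raise FormatError(f"{path}: not a micard MIC file (bad magic line)")
    if len(lines) < 8:
        raise FormatError(f"{path}: truncated header")
    material = _parse_header_line(lines[1], "material", path)
    try:
        n_requested = int(_parse_header_line(lines[2], "n_requested", path))
    except ValueError as e:
        raise FormatError(f"{path}: n_requested is not an integer") from e
    try:
        dt_r = float(_parse_header_line(lines[3], "dt_r", path))
        dmz = float(_parse_header_line(lines[4], "dmz", path))
    except ValueError as e:
        raise FormatError(f"{path}: tolerance fields must be numeric") from e
    batches_raw = _parse_header_line(lines[5], "source_batches", path)
    source_batches = () if batches_raw == "-" else tuple(batches_raw.split(","))
    built_raw = _parse_header_line(lines[6], "built_at", path)
    built_at = None if built_raw == "-" else built_raw
    if lines[7] != "t_r\tmz\tintensity":
        raise FormatError(f"{path}: expected column header line, got {lines[7]!r}")
    ions = []
    for ln in lines[8:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: malformed ion row {ln!r}")
        try:
            ions.append(Ion(float(parts[0]), float(parts[1]), float(parts[2])))
        except ValueError as e:
            raise FormatError(f"{path}: bad ion row {ln!r}: {e}") from e
    if not ions:
        warnings.warn(f"{path}: MIC has no ions", MicardWarning, stacklevel=2)
    return MIC(
        ions=tuple(ions),
        material=material,
        n_requested=n_requested,
        tolerance=MatchTolerance(dt_r=dt_r, dmz=dmz),
        source_batches=source_batches,
        built_at=built_at,
    )
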