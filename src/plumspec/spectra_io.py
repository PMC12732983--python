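"""Spectra containers and I/O.

Raw Vis/NIR reflectance scans are converted to absorbance against dark and
white references, replicate scans per fruit are averaged, and the noisy
short-wavelength end of the grid is truncated before modeling.  Spectra
travel as wide CSV tables (``sample_id, cultivar, <wavelength>, ...``) and
reference enzyme activities as two-column CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "RawScan",
    "ReferenceTable",
    "compute_absorbance",
    "average_replicates",
    "truncate_wavelengths",
    "read_spectra_table",
    "write_spectra_table",
    "read_reference_table",
    "write_reference_table",
]

# Default analysis window: the 350-510 nm region is dropped because of poor
# detector signal-to-noise at the blue end of a silicon CCD array.
DEFAULT_TRUNCATION_NM = (510.0, 1100.0)


@dataclass
class SpectraSet:
    """Sample-by-wavelength absorbance matrix with metadata.

    Attributes
    ----------
    wavelengths_nm : (p,) float array, strictly increasing.  Sub-nm spacing
        is allowed; nothing assumes an integer grid.
    absorbance : (n, p) float array of unitless absorbance values.
    sample_ids : list of n unique labels.
    cultivar : optional list of n cultivar labels.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    cultivar: list[str] | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelengths_nm must be one-dimensional")
        if self.absorbance.shape[1] != self.wavelengths_nm.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but "
                f"{self.wavelengths_nm.size} wavelengths were given"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("one sample_id per spectrum row is required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.cultivar is not None and len(self.cultivar) != len(self.sample_ids):
            raise ValueError("cultivar labels must match sample count")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must all be finite")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size


@dataclass
class RawScan:
    """One raw reflectance scan with its dark and white reference frames.

    All three intensity vectors share one wavelength grid (detector counts,
    arbitrary units).  The white reference must exceed the dark frame at
    every wavelength for the reflectance ratio to be defined.
    """

    wavelengths_nm: np.ndarray
    sample_intensity: np.ndarray
    dark_intensity: np.ndarray
    white_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.sample_intensity = np.asarray(self.sample_intensity, dtype=float)
        self.dark_intensity = np.asarray(self.dark_intensity, dtype=float)
        self.white_intensity = np.asarray(self.white_intensity, dtype=float)
        shapes = {
            v.shape
            for v in (
                self.wavelengths_nm,
                self.sample_intensity,
                self.dark_intensity,
                self.white_intensity,
            )
        }
        if len(shapes) != 1:
            raise ValueError("all scan vectors must share one wavelength grid")
        if np.any(self.white_intensity <= self.dark_intensity):
            bad = self.wavelengths_nm[self.white_intensity <= self.dark_intensity]
            raise ValueError(
                f"white reference not above dark frame at {bad[0]:g} nm"
            )


@dataclass
class ReferenceTable:
    """Per-sample PPO activity (absorbance change per minute per gram)."""

    sample_ids: list[str]
    ppo_activity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.ppo_activity = np.asarray(self.ppo_activity, dtype=float)
        if len(self.sample_ids) != self.ppo_activity.size:
            raise ValueError("one activity value per sample_id is required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if np.any(self.ppo_activity < 0):
            raise ValueError("PPO activities must be non-negative")

    @property
    def n(self) -> int:
        return self.ppo_activity.size

    def aligned_to(self, spectra: SpectraSet) -> np.ndarray:
        """Activity vector reordered to match ``spectra.sample_ids``."""
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [sid for sid in spectra.sample_ids if sid not in index]
        if missing:
            raise KeyError(f"reference table lacks samples: {missing[:5]}")
        return self.ppo_activity[[index[sid] for sid in spectra.sample_ids]]


def compute_absorbance(scan: RawScan) -> np.ndarray:
    """Convert a raw scan to absorbance, ``A = -log10((S-D)/(W-D))``.

    The standard diffuse-reflectance convention: the sample signal is
    dark-corrected, ratioed against the dark-corrected white reference, and
    the relative reflectance is converted to absorbance.  ``A = 0`` where
    the sample equals the white reference.

    Raises
    ------
    ValueError
        If the sample signal does not exceed the dark frame at some
        wavelength (reflectance would be non-positive); the offending
        wavelength is named.
    """
    s, d, w = scan.sample_intensity, scan.dark_intensity, scan.white_intensity
    reflectance = (s - d) / (w - d)
    if np.any(reflectance <= 0):
        bad = scan.wavelengths_nm[reflectance <= 0]
        raise ValueError(
            f"signal at or below dark level at {bad[0]:g} nm: "
            "reflectance undefined"
        )
    return -np.log10(reflectance)


def average_replicates(
    scans: list[np.ndarray],
    group_map: list[list[int]] | dict[str, list[int]],
    wavelengths_nm: np.ndarray,
    sample_ids: list[str] | None = None,
    cultivar: list[str] | None = None,
) -> SpectraSet:
    """Average replicate absorbance vectors into one spectrum per sample.

    ``group_map`` lists, per output sample, the indices into ``scans`` of
    its replicates (four probe positions per fruit in the reference
    protocol).  Groups are supplied explicitly, never inferred from id
    patterns.  The unweighted arithmetic mean is used.
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if isinstance(group_map, dict):
        ids = list(group_map.keys())
        groups = list(group_map.values())
    else:
        groups = list(group_map)
        ids = sample_ids if sample_ids is not None else [
            f"sample_{i:03d}" for i in range(len(groups))
        ]
    rows = []
    for gi, members in enumerate(groups):
        if len(members) == 0:
            raise ValueError(f"replicate group {ids[gi]!r} is empty")
        block = []
        for m in members:
            vec = np.asarray(scans[m], dtype=float)
            if vec.shape != wavelengths_nm.shape:
                raise ValueError(
                    f"scan {m} has {vec.size} points, grid has "
                    f"{wavelengths_nm.size}: mismatched grids"
                )
            block.append(vec)
        rows.append(np.mean(block, axis=0))
    return SpectraSet(wavelengths_nm, np.vstack(rows), ids, cultivar)


def truncate_wavelengths(
    s: SpectraSet,
    low_nm: float = DEFAULT_TRUNCATION_NM[0],
    high_nm: float = DEFAULT_TRUNCATION_NM[1],
) -> SpectraSet:
    """Keep wavelengths within the closed interval ``[low_nm, high_nm]``."""
    if not low_nm < high_nm:
        raise ValueError("low_nm must be below high_nm")
    keep = (s.wavelengths_nm >= low_nm) & (s.wavelengths_nm <= high_nm)
    if not np.any(keep):
        raise ValueError(
            f"no wavelengths remain in [{low_nm:g}, {high_nm:g}] nm"
        )
    return SpectraSet(
        s.wavelengths_nm[keep],
        s.absorbance[:, keep],
        list(s.sample_ids),
        list(s.cultivar) if s.cultivar is not None else None,
    )


# ---------------------------------------------------------------------------
# CSV round-trip.  Wide table: sample_id, cultivar, then one column per
# wavelength (label = decimal nm, "." decimal separator, UTF-8).


def write_spectra_table(s: SpectraSet, path) -> None:
    df = pd.DataFrame(
        s.absorbance, columns=[f"{w:.12g}" for w in s.wavelengths_nm]
    )
    df.insert(0, "cultivar", s.cultivar if s.cultivar is not None else "")
    df.insert(0, "sample_id", s.sample_ids)
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectra_table(path) -> SpectraSet:
    df = pd.read_csv(path, dtype={"sample_id": str, "cultivar": str})
    if list(df.columns[:2]) != ["sample_id", "cultivar"]:
        raise ValueError(
            "spectra table must start with 'sample_id','cultivar' columns"
        )
    try:
        wavelengths = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength label in header: {exc}")
    if wavelengths.size == 0:
        raise ValueError("spectra table has no wavelength columns")
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength header not strictly increasing")
    ids = df["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in spectra table")
    matrix = df.iloc[:, 2:].to_numpy()
    if not np.issubdtype(matrix.dtype, np.number):
        for ri in range(matrix.shape[0]):
            for ci in range(matrix.shape[1]):
                try:
                    float(matrix[ri, ci])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {ri}, column "
                        f"{df.columns[2 + ci]!r}"
                    )
        matrix = matrix.astype(float)
    cultivar = df["cultivar"].tolist()
    if all(pd.isna(c) or c == "" for c in cultivar):
        cultivar = None
    return SpectraSet(wavelengths, matrix.astype(float), ids, cultivar)


def write_reference_table(ref: ReferenceTable, path) -> None:
    pd.DataFrame(
        {"sample_id": ref.sample_ids, "ppo_activity": ref.ppo_activity}
    ).to_csv(path, index=False, float_format="%.12g")


def read_reference_table(path) -> ReferenceTable:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if list(df.columns) != ["sample_id", "ppo_activity"]:
        raise ValueError(
            "reference table must have columns 'sample_id','ppo_activity'"
        )
    return ReferenceTable(
        df["sample_id"].tolist(), df["ppo_activity"].to_numpy(dtype=float)
    )
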