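"""Reading, validation and classification of cave water-column observations.

The data model follows how anchialine groundwater studies are organised in
practice: discrete water samples (one row per syringe/bottle, carrying a
conservative tracer plus concentrations and δ¹³C values of the carbon
species), and continuous multi-parameter sonde casts (depth, salinity,
dissolved oxygen, temperature).  A density-stratified karst aquifer hosts
three vertically stacked water masses — meteoric freshwater (MFW), meteoric
brackish water (MBW) and saline groundwater (SGW) — separated by thin
haloclines; the helpers here convert chloride to salinity, locate those
haloclines in sonde profiles, and assign water-mass labels from salinity.

Units: depth in metres below the water table (positive downward), salinity
in psu, chloride in mM (or mg l⁻¹ via a reader flag), CH₄ in nM, DOC and
POC in µM, DIC and SO₄²⁻ in mM, δ¹³C in ‰ vs VPDB.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as _dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("karstmix")

__all__ = [
    "ValidationError",
    "WaterSample",
    "SondeProfile",
    "HaloclineInterval",
    "ReaderConfig",
    "ReadResult",
    "WaterMassThresholds",
    "chloride_to_salinity",
    "salinity_to_chloride",
    "read_sample_table",
    "detect_haloclines",
    "classify_water_mass",
    "WATER_MASSES",
]

#: molar mass of chloride, g mol⁻¹ (mM → mg l⁻¹)
CHLORIDE_MOLAR_MASS = 35.453
#: empirical chloride-to-salinity factor, psu per (mg l⁻¹ Cl⁻)
CHLORIDE_TO_SALINITY = 0.0018066

#: plausibility band for δ¹³C values, ‰ vs VPDB
DELTA_BAND = (-110.0, 10.0)

WATER_MASSES = ("MFW", "MBW", "SGW", "POOL", "SEA", "UNASSIGNED")


class ValidationError(ValueError):
    """Raised when an input value or table violates a domain invariant."""


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def chloride_to_salinity(chloride_mm):
    """Convert chloride concentration (mM) to salinity (psu).

    Chloride is first converted to mg l⁻¹ with the 35.453 g mol⁻¹ molar
    mass, then scaled by the empirical factor 0.0018066 psu per mg l⁻¹.
    Accepts scalars or arrays.
    """
    chloride_mm = np.asarray(chloride_mm, dtype=float)
    if np.any(chloride_mm < 0):
        raise ValidationError("chloride concentration must be non-negative")
    out = chloride_mm * CHLORIDE_MOLAR_MASS * CHLORIDE_TO_SALINITY
    return float(out) if out.ndim == 0 else out


def salinity_to_chloride(salinity_psu):
    """Inverse of :func:`chloride_to_salinity` (psu → mM chloride)."""
    salinity_psu = np.asarray(salinity_psu, dtype=float)
    if np.any(salinity_psu < 0):
        raise ValidationError("salinity must be non-negative")
    out = salinity_psu / (CHLORIDE_MOLAR_MASS * CHLORIDE_TO_SALINITY)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# water samples
# ---------------------------------------------------------------------------

_CONCENTRATION_FIELDS = ("ch4", "doc", "dic", "poc", "so4")
_DELTA_FIELDS = ("d13c_ch4", "d13c_doc", "d13c_dic", "d13c_poc")


@dataclass
class WaterSample:
    """One geochemical observation of the water column.

    When both chloride and salinity are supplied, chloride is authoritative
    (salinity is a derived quantity in this framework); the supplied
    salinity is cross-checked against the chloride-derived value and a
    warning is logged when they disagree by more than ``cross_check_tol``
    relative.
    """

    sample_id: str = ""
    event: str = ""
    depth: Optional[float] = None           # m below water table
    salinity: Optional[float] = None        # psu
    chloride: Optional[float] = None        # mM
    ch4: Optional[float] = None             # nM
    doc: Optional[float] = None             # µM
    dic: Optional[float] = None             # mM
    poc: Optional[float] = None             # µM
    so4: Optional[float] = None             # mM
    d13c_ch4: Optional[float] = None        # ‰ VPDB
    d13c_doc: Optional[float] = None
    d13c_dic: Optional[float] = None
    d13c_poc: Optional[float] = None
    water_mass: str = "UNASSIGNED"
    cross_check_tol: float = 0.05

    def __post_init__(self):
        if self.salinity is None and self.chloride is None:
            raise ValidationError(
                f"sample {self.sample_id!r}: needs salinity or chloride"
            )
        if self.chloride is not None:
            if self.chloride < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative chloride"
                )
            derived = chloride_to_salinity(self.chloride)
            if self.salinity is not None and self.salinity > 0:
                rel = abs(self.salinity - derived) / max(self.salinity, 1e-12)
                if rel > self.cross_check_tol:
                    logger.warning(
                        "sample %s: salinity column %.3f psu disagrees with "
                        "chloride-derived %.3f psu (>%.0f%%); using chloride",
                        self.sample_id, self.salinity, derived,
                        100 * self.cross_check_tol,
                    )
            self.salinity = derived
        if self.salinity is not None and self.salinity < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative salinity")
        for name in _CONCENTRATION_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative {name} concentration"
                )
        lo, hi = DELTA_BAND
        for name in _DELTA_FIELDS:
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name}={v}‰ outside sanity "
                    f"band [{lo}, {hi}]"
                )
        if self.water_mass not in WATER_MASSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown water mass "
                f"{self.water_mass!r}"
            )


DEFAULT_COLUMN_MAP = {
    "sample_id": "sample_id",
    "event": "event",
    "depth": "depth",
    "salinity": "salinity",
    "chloride": "chloride",
    "ch4": "ch4",
    "doc": "doc",
    "dic": "dic",
    "poc": "poc",
    "so4": "so4",
    "d13c_ch4": "d13c_ch4",
    "d13c_doc": "d13c_doc",
    "d13c_dic": "d13c_dic",
    "d13c_poc": "d13c_poc",
    "water_mass": "water_mass",
}


@dataclass
class ReaderConfig:
    """How to read a delimited sample table.

    ``column_map`` maps :class:`WaterSample` field names to column headers
    in the file; absent entries/columns yield absent fields (never zero).
    ``chloride_unit`` is ``"mM"`` (default) or ``"mg/L"``.
    """

    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    delimiter: Optional[str] = None     # None → sniff (csv/tsv)
    chloride_unit: str = "mM"
    cross_check_tol: float = 0.05

    def __post_init__(self):
        if self.chloride_unit not in ("mM", "mg/L"):
            raise ValidationError(
                f"chloride_unit must be 'mM' or 'mg/L', got "
                f"{self.chloride_unit!r}"
            )


@dataclass
class RowError:
    line: int           # 1-based line in the file (header is line 1)
    message: str


@dataclass
class ReadResult:
    """Validated samples plus a row-level error report (nothing is silently
    dropped: every rejected row appears in ``errors`` with its line number)."""

    samples: list
    errors: list

    def samples_frame(self) -> pd.DataFrame:
        """Echo the validated samples as a DataFrame."""
        return pd.DataFrame([vars(s) for s in self.samples]).drop(
            columns=["cross_check_tol"], errors="ignore"
        )

    def errors_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(e) for e in self.errors], columns=["line", "message"]
        )


_NUMERIC_FIELDS = (
    ("depth",) + ("salinity", "chloride") + _CONCENTRATION_FIELDS + _DELTA_FIELDS
)


def read_sample_table(path, config: Optional[ReaderConfig] = None) -> ReadResult:
    """Read a delimited water-sample table into validated samples.

    Rows violating invariants (negative concentrations, δ values outside the
    sanity band, missing tracer, unparseable numerics) are collected into
    the error report with their 1-based file line numbers.  If the salinity
    column is absent the tracer is derived from chloride.
    """
    config = config or ReaderConfig()
    if config.delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=config.delimiter, dtype=str)
    cmap = config.column_map
    have = {f: c for f, c in cmap.items() if c in df.columns}
    if "salinity" not in have and "chloride" not in have:
        raise ValidationError(
            "sample table has neither a salinity nor a chloride column "
            f"(mapped names: {cmap.get('salinity')!r}, {cmap.get('chloride')!r})"
        )

    samples, errors = [], []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header occupies line 1
        kwargs = {"cross_check_tol": config.cross_check_tol}
        bad = None
        for fld, col in have.items():
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            raw = str(raw).strip()
            if raw == "" or raw.lower() in ("na", "nan", "nd", "-", "–"):
                continue
            if fld in _NUMERIC_FIELDS:
                try:
                    val = float(raw)
                except ValueError:
                    bad = f"column {col!r}: unparseable numeric {raw!r}"
                    break
                if fld == "chloride" and config.chloride_unit == "mg/L":
                    val = val / CHLORIDE_MOLAR_MASS   # mg/l → mM
                kwargs[fld] = val
            else:
                kwargs[fld] = raw
        if bad is not None:
            errors.append(RowError(line, bad))
            continue
        if "sample_id" not in kwargs:
            kwargs["sample_id"] = f"row{line}"
        try:
            samples.append(WaterSample(**kwargs))
        except ValidationError as exc:
            errors.append(RowError(line, str(exc)))
    return ReadResult(samples=samples, errors=errors)


# ---------------------------------------------------------------------------
# sonde profiles and halocline detection
# ---------------------------------------------------------------------------

@dataclass
class SondeProfile:
    """A vertical multi-parameter cast through the stratified water column.

    Depth must be strictly increasing.  Salinity must be non-decreasing to
    within ``mono_tol`` (a density-stratified column cannot sustain a
    salinity inversion beyond instrument noise).
    """

    depth: np.ndarray                  # m, strictly increasing
    salinity: np.ndarray               # psu
    dissolved_oxygen: Optional[np.ndarray] = None   # µM
    temperature: Optional[np.ndarray] = None        # °C
    mono_tol: float = 0.1              # psu, permitted inversion amplitude

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.salinity = np.asarray(self.salinity, dtype=float)
        if self.depth.ndim != 1 or self.depth.shape != self.salinity.shape:
            raise ValidationError("depth and salinity must be equal-length 1-D")
        if np.any(np.diff(self.depth) <= 0):
            raise ValidationError("profile depth must be strictly increasing")
        if np.any(np.diff(self.salinity) < -self.mono_tol):
            raise ValidationError(
                "salinity decreases with depth beyond tolerance "
                f"({self.mono_tol} psu): not a stratified column"
            )
        for name in ("dissolved_oxygen", "temperature"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.depth.shape:
                    raise ValidationError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self):
        return self.depth.size

    @property
    def span(self) -> float:
        return float(self.depth[-1] - self.depth[0])

    def to_frame(self) -> pd.DataFrame:
        data = {"depth": self.depth, "salinity": self.salinity}
        if self.dissolved_oxygen is not None:
            data["dissolved_oxygen"] = self.dissolved_oxygen
        if self.temperature is not None:
            data["temperature"] = self.temperature
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "SondeProfile":
        return cls(
            depth=df["depth"].to_numpy(),
            salinity=df["salinity"].to_numpy(),
            dissolved_oxygen=(
                df["dissolved_oxygen"].to_numpy()
                if "dissolved_oxygen" in df else None
            ),
            temperature=(
                df["temperature"].to_numpy() if "temperature" in df else None
            ),
            **kwargs,
        )


@dataclass
class HaloclineInterval:
    """A thin depth interval of sharp salinity change.

    ``salinity_above`` is the salinity at the shallow edge, ``salinity_below``
    at the deep edge.  Up to two intervals are labelled H1 (shallow) and H2
    (deep); further intervals carry ``label=None``.
    """

    top_depth: float
    bottom_depth: float
    salinity_above: float
    salinity_below: float
    label: Optional[str] = None

    def __post_init__(self):
        if not self.bottom_depth > self.top_depth:
            raise ValidationError("halocline must have positive thickness")

    @property
    def thickness(self) -> float:
        return self.bottom_depth - self.top_depth

    @property
    def salinity_step(self) -> float:
        return self.salinity_below - self.salinity_above

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top_depth + self.bottom_depth)


def detect_haloclines(
    profile: SondeProfile,
    gradient_threshold: float = 1.0,
    merge_gap: float = 0.3,
    max_labeled: int = 2,
) -> list:
    """Locate haloclines as maximal runs of steep salinity gradient.

    A depth interval between consecutive sonde records belongs to a
    halocline when |Δsalinity/Δdepth| ≥ ``gradient_threshold`` (psu m⁻¹).
    Contiguous steep intervals are merged, as are runs separated by less
    than ``merge_gap`` metres.  The ``max_labeled`` intervals with the
    largest total salinity step are labelled H1, H2, … in top-down depth
    order; any extras are returned unlabelled.

    Returns an empty list when no interval exceeds the threshold.
    """
    if len(profile) < 3 or profile.span <= 1.0:
        raise ValidationError(
            "profile too short for halocline detection "
            "(need ≥ 3 records spanning > 1 m)"
        )
    d, s = profile.depth, profile.salinity
    grad = np.diff(s) / np.diff(d)
    steep = np.abs(grad) >= gradient_threshold

    # maximal runs of steep intervals
    runs = []
    i = 0
    n = steep.size
    while i < n:
        if steep[i]:
            j = i
            while j + 1 < n and steep[j + 1]:
                j += 1
            runs.append([i, j])          # interval indices [i, j] inclusive
            i = j + 1
        else:
            i += 1
    # merge runs separated by a small depth gap
    merged = []
    for run in runs:
        if merged and d[run[0]] - d[merged[-1][1] + 1] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    intervals = [
        HaloclineInterval(
            top_depth=float(d[i0]),
            bottom_depth=float(d[j0 + 1]),
            salinity_above=float(s[i0]),
            salinity_below=float(s[j0 + 1]),
        )
        for i0, j0 in merged
    ]
    # label the strongest steps H1..Hk in top-down order
    by_strength = sorted(
        intervals, key=lambda h: abs(h.salinity_step), reverse=True
    )[:max_labeled]
    labeled = sorted(by_strength, key=lambda h: h.top_depth)
    for rank, h in enumerate(labeled, start=1):
        h.label = f"H{rank}"
    return intervals


# ---------------------------------------------------------------------------
# water-mass classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterMassThresholds:
    """Salinity cutoffs bracketing the observed water-mass ranges.

    MFW: s ≤ mfw_max; MBW: mfw_max < s ≤ mbw_max; SGW: s > sgw_min;
    the (mbw_max, sgw_min] band is the mixing interface → UNASSIGNED.
    POOL and SEA can only be assigned from metadata, never from salinity.
    """

    mfw_max: float = 1.0
    mbw_max: float = 10.0
    sgw_min: float = 30.0

    def __post_init__(self):
        if not (0 < self.mfw_max < self.mbw_max <= self.sgw_min):
            raise ValidationError("thresholds must satisfy 0 < mfw_max < mbw_max <= sgw_min")


def classify_water_mass(
    salinity: float, thresholds: Optional[WaterMassThresholds] = None
) -> str:
    """Assign a water-mass label from salinity alone (total on s ≥ 0)."""
    if salinity < 0:
        raise ValidationError("salinity must be non-negative")
    t = thresholds or WaterMassThresholds()
    if salinity <= t.mfw_max:
        return "MFW"
    if salinity <= t.mbw_max:
        return "MBW"
    if salinity > t.sgw_min:
        return "SGW"
    return "UNASSIGNED"
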