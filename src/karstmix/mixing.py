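"""Conservative mixing analysis for reactive solutes in a salinity gradient.

In an estuarine mixing zone, a solute that undergoes no reaction is a linear
function of the conservative tracer (chloride, or equivalently salinity):

    C_MIX = f·C_MFW + (1 − f)·C_SGW,     f = (T_SGW − T_MIX)/(T_SGW − T_MFW)

where f is the fraction of the fresh end member in the mixture and T is the
tracer.  The isotope ratio of the conservative mixture is the
concentration-weighted blend of the end-member δ values:

    δ_MIX = [f·C_MFW·δ_MFW + (1 − f)·C_SGW·δ_SGW] / C_MIX

An ensemble of mixing lines over repeat sampling events spans a mixing
field (envelope); measured concentrations falling below it indicate in situ
consumption, above it production.  The net fraction of a constituent
removed between the fresh end member and the intermediate (brackish) water
mass is

    % consumed = (C_MIX − C_MBW)/C_MFW × 100

evaluated with C_MIX at the brackish tracer value.  Because salinity here is
a fixed linear rescaling of chloride, mixing fractions computed from either
tracer are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .samples_io import ValidationError, WaterSample

__all__ = [
    "FractionResult",
    "EndMemberPair",
    "MixingEnvelope",
    "ConsumptionResult",
    "PartitionResult",
    "mixing_fraction",
    "conservative_concentration",
    "conservative_delta",
    "build_mixing_envelope",
    "classify_deviation",
    "classify_sample_deviation",
    "percent_consumed",
    "organic_carbon_partition",
    "CONSTITUENTS",
    "CONSTITUENT_FIELDS",
]

CONSTITUENTS = ("CH4", "DOC", "DIC", "SO4")

#: WaterSample attribute holding each constituent's concentration / δ¹³C
CONSTITUENT_FIELDS = {
    "CH4": ("ch4", "d13c_ch4"),
    "DOC": ("doc", "d13c_doc"),
    "DIC": ("dic", "d13c_dic"),
    "SO4": ("so4", None),
    "POC": ("poc", "d13c_poc"),
}


class FractionResult(NamedTuple):
    """Fresh-water mixing fraction with an out-of-bracket flag.

    ``value`` is not clamped: samples whose tracer falls outside the
    end-member bracket yield f outside [0, 1] and ``out_of_bracket=True``.
    """

    value: float
    out_of_bracket: bool


def mixing_fraction(tracer_mix, tracer_mfw, tracer_sgw) -> FractionResult:
    """Fraction of the fresh end member in a mixture, from the tracer.

    f = (T_SGW − T_MIX) / (T_SGW − T_MFW).  The tracer may be chloride or
    salinity as long as all three values share the unit.
    """
    if not tracer_sgw > tracer_mfw:
        raise ValidationError(
            "degenerate end members: tracer_sgw must exceed tracer_mfw "
            f"(got {tracer_sgw} <= {tracer_mfw})"
        )
    f = (tracer_sgw - tracer_mix) / (tracer_sgw - tracer_mfw)
    return FractionResult(float(f), not (0.0 <= f <= 1.0))


def conservative_concentration(
    f_mfw, c_mfw, c_sgw, *, allow_extrapolation: bool = False
):
    """Expected concentration under pure physical mixing (linear blend)."""
    f = np.asarray(f_mfw, dtype=float)
    if not allow_extrapolation and np.any((f < 0) | (f > 1)):
        raise ValidationError(
            "mixing fraction outside [0, 1]; pass allow_extrapolation=True "
            "to evaluate the mixing line beyond the end-member bracket"
        )
    out = f * c_mfw + (1.0 - f) * c_sgw
    return float(out) if out.ndim == 0 else out


def conservative_delta(
    f_mfw, c_mfw, d_mfw, c_sgw, d_sgw, *, allow_extrapolation: bool = False
):
    """Expected δ value under pure mixing (concentration-weighted blend)."""
    if c_mfw == 0 and c_sgw == 0:
        raise ValidationError("δ of a mixture of two zero-concentration pools is undefined")
    f = np.asarray(f_mfw, dtype=float)
    if not allow_extrapolation and np.any((f < 0) | (f > 1)):
        raise ValidationError("mixing fraction outside [0, 1]")
    c_mix = f * c_mfw + (1.0 - f) * c_sgw
    if np.any(c_mix <= 0):
        if not allow_extrapolation:
            raise ValidationError(
                "conservative concentration is non-positive; δ undefined"
            )
        # beyond the end-member bracket the mixing line can cross zero
        # concentration, where δ has no meaning: mark those points NaN
        c_mix = np.where(c_mix > 0, c_mix, np.nan)
    with np.errstate(invalid="ignore"):
        out = (f * c_mfw * d_mfw + (1.0 - f) * c_sgw * d_sgw) / c_mix
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# end members and envelopes
# ---------------------------------------------------------------------------

@dataclass
class EndMemberPair:
    """Fresh (MFW) and saline (SGW) end members for one constituent.

    One pair defines one conservative mixing line; several pairs (two per
    sampling event, built from the lowest and the highest end-member
    concentrations) define the mixing field.  δ values are optional (the
    sulfate model is concentration-only).
    """

    constituent: str
    tracer_mfw: float           # psu (or mM chloride, consistently)
    tracer_sgw: float
    c_mfw: float
    c_sgw: float
    d_mfw: Optional[float] = None
    d_sgw: Optional[float] = None
    event: str = ""

    def __post_init__(self):
        if not self.tracer_sgw > self.tracer_mfw:
            raise ValidationError(
                f"{self.constituent} end members: tracer_sgw must exceed tracer_mfw"
            )
        if self.c_mfw < 0 or self.c_sgw < 0:
            raise ValidationError(
                f"{self.constituent} end members: concentrations must be ≥ 0"
            )

    @property
    def has_delta(self) -> bool:
        return self.d_mfw is not None and self.d_sgw is not None

    def fraction_at(self, tracer) -> np.ndarray:
        t = np.asarray(tracer, dtype=float)
        return (self.tracer_sgw - t) / (self.tracer_sgw - self.tracer_mfw)

    def concentration_line(self, tracer) -> np.ndarray:
        """Evaluate this pair's mixing line at tracer values (extrapolates)."""
        return conservative_concentration(
            self.fraction_at(tracer), self.c_mfw, self.c_sgw,
            allow_extrapolation=True,
        )

    def delta_line(self, tracer) -> np.ndarray:
        if not self.has_delta:
            raise ValidationError(
                f"{self.constituent} end members carry no δ values"
            )
        return conservative_delta(
            self.fraction_at(tracer), self.c_mfw, self.d_mfw,
            self.c_sgw, self.d_sgw, allow_extrapolation=True,
        )


@dataclass
class MixingEnvelope:
    """Pointwise bounds over an ensemble of conservative mixing lines.

    ``lower_line``/``upper_line`` are the minimum/maximum expected
    concentration at each tracer grid point across all event mixing lines
    (the general mixing field); ``lower_delta``/``upper_delta`` are the
    analogous bounds on the conservative δ value when end members carry δ.
    """

    constituent: str
    tracer_grid: np.ndarray
    lower_line: np.ndarray
    upper_line: np.ndarray
    lower_delta: Optional[np.ndarray] = None
    upper_delta: Optional[np.ndarray] = None

    def __post_init__(self):
        self.tracer_grid = np.asarray(self.tracer_grid, dtype=float)
        self.lower_line = np.asarray(self.lower_line, dtype=float)
        self.upper_line = np.asarray(self.upper_line, dtype=float)
        if np.any(self.lower_line > self.upper_line + 1e-12):
            raise ValidationError("envelope lower line exceeds upper line")

    @property
    def span(self):
        return float(self.tracer_grid[0]), float(self.tracer_grid[-1])

    def _check_span(self, tracer):
        lo, hi = self.span
        if np.any((np.asarray(tracer) < lo) | (np.asarray(tracer) > hi)):
            raise ValidationError(
                f"tracer outside envelope span [{lo:g}, {hi:g}]"
            )

    def concentration_bounds_at(self, tracer):
        """(lower, upper) expected concentration, linearly interpolated."""
        self._check_span(tracer)
        lo = np.interp(tracer, self.tracer_grid, self.lower_line)
        hi = np.interp(tracer, self.tracer_grid, self.upper_line)
        return lo, hi

    def delta_bounds_at(self, tracer):
        if self.lower_delta is None:
            raise ValidationError("envelope carries no δ lines")
        self._check_span(tracer)
        lo = np.interp(tracer, self.tracer_grid, self.lower_delta)
        hi = np.interp(tracer, self.tracer_grid, self.upper_delta)
        return lo, hi

    def to_frame(self):
        import pandas as pd

        data = {
            "tracer": self.tracer_grid,
            "lower": self.lower_line,
            "upper": self.upper_line,
        }
        if self.lower_delta is not None:
            data["lower_delta"] = self.lower_delta
            data["upper_delta"] = self.upper_delta
        return pd.DataFrame(data)


def build_mixing_envelope(
    pairs: Sequence[EndMemberPair],
    tracer_grid: Optional[np.ndarray] = None,
    n_grid: int = 200,
) -> MixingEnvelope:
    """Build the mixing field spanned by an ensemble of end-member pairs.

    Each pair contributes one mixing line; the envelope is the pointwise
    minimum and maximum over all lines on a common tracer grid.  The grid
    (linear in tracer — mixing is linear in tracer, so a linear grid is the
    natural discretisation) spans the lowest fresh to the highest saline
    end-member tracer by default.  With a single pair the envelope collapses
    to that pair's line.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("need at least one end-member pair")
    constituent = pairs[0].constituent
    if any(p.constituent != constituent for p in pairs):
        raise ValidationError("all end-member pairs must share a constituent")
    if tracer_grid is None:
        t0 = min(p.tracer_mfw for p in pairs)
        t1 = max(p.tracer_sgw for p in pairs)
        tracer_grid = np.linspace(t0, t1, n_grid)
    tracer_grid = np.asarray(tracer_grid, dtype=float)

    lines = np.vstack([p.concentration_line(tracer_grid) for p in pairs])
    lower, upper = lines.min(axis=0), lines.max(axis=0)
    lower_delta = upper_delta = None
    if all(p.has_delta for p in pairs):
        dlines = np.vstack([p.delta_line(tracer_grid) for p in pairs])
        with np.errstate(all="ignore"):
            lower_delta = np.nanmin(dlines, axis=0)
            upper_delta = np.nanmax(dlines, axis=0)
    return MixingEnvelope(
        constituent=constituent,
        tracer_grid=tracer_grid,
        lower_line=lower,
        upper_line=upper,
        lower_delta=lower_delta,
        upper_delta=upper_delta,
    )


def classify_deviation(
    tracer: float,
    concentration: float,
    envelope: MixingEnvelope,
    sigma: float = 0.0,
    k: float = 1.0,
) -> str:
    """Classify a measurement against the conservative mixing field.

    Above the upper bound → ``"production"``; below the lower bound →
    ``"consumption"``; otherwise ``"conservative"``.  A measurement within
    ``k·sigma`` of a bound (sigma = replicate analytical error) is treated
    as conservative, since plotted symbols carry that uncertainty.
    """
    lo, hi = envelope.concentration_bounds_at(tracer)
    # numeric slack so a sample exactly on an envelope line is conservative
    # despite grid interpolation round-off
    eps = 1e-9 * max(abs(concentration), abs(hi), abs(lo), 1.0)
    pad = k * sigma + eps
    if concentration > hi + pad:
        return "production"
    if concentration < lo - pad:
        return "consumption"
    return "conservative"


def classify_sample_deviation(
    sample: WaterSample,
    envelope: MixingEnvelope,
    constituent: str,
    sigma: float = 0.0,
    k: float = 1.0,
) -> str:
    """:func:`classify_deviation` addressed by sample and constituent name."""
    conc_field, _ = CONSTITUENT_FIELDS[constituent]
    value = getattr(sample, conc_field)
    if value is None:
        raise ValidationError(
            f"sample {sample.sample_id!r} has no {constituent} measurement"
        )
    return classify_deviation(sample.salinity, value, envelope, sigma=sigma, k=k)


# ---------------------------------------------------------------------------
# consumption statistic and organic-carbon partition
# ---------------------------------------------------------------------------

@dataclass
class ConsumptionResult:
    """Net removal of a constituent between mixing prediction and observation.

    ``percent_consumed`` = (C_MIX − C_MBW)/C_MFW × 100 where C_MIX is the
    conservative expectation at the brackish-water tracer value and C_MBW
    the observed brackish concentration.  Negative values indicate net
    production and are flagged, not clipped.
    """

    constituent: str
    event: str
    c_mix: float
    c_mbw: float
    c_mfw: float
    percent_consumed: float
    absolute_reduction: float
    net_production: bool

    def to_dict(self) -> dict:
        return {
            "constituent": self.constituent,
            "event": self.event,
            "c_mix": self.c_mix,
            "c_mbw": self.c_mbw,
            "c_mfw": self.c_mfw,
            "percent_consumed": self.percent_consumed,
            "percent_consumed_rounded": round(self.percent_consumed),
            "absolute_reduction": self.absolute_reduction,
            "net_production": self.net_production,
        }


def percent_consumed(
    c_mix: float,
    c_mbw: float,
    c_mfw: float,
    constituent: str = "",
    event: str = "pooled",
) -> ConsumptionResult:
    """Percent of a constituent consumed in the brackish layer.

    Normalises the shortfall (C_MIX − C_MBW) by the fresh end-member
    concentration C_MFW, expressing removal as a fraction of the source
    inventory.
    """
    if not c_mfw > 0:
        raise ValidationError("c_mfw must be positive")
    reduction = c_mix - c_mbw
    pct = reduction / c_mfw * 100.0
    return ConsumptionResult(
        constituent=constituent,
        event=event,
        c_mix=float(c_mix),
        c_mbw=float(c_mbw),
        c_mfw=float(c_mfw),
        percent_consumed=float(pct),
        absolute_reduction=float(reduction),
        net_production=pct < 0,
    )


class PartitionResult(NamedTuple):
    ratio: float                   # DOC / POC
    poc_percent_of_doc: float      # %


def organic_carbon_partition(doc: float, poc: float) -> PartitionResult:
    """Partition of the organic carbon pool between dissolved and particulate.

    Returns the DOC:POC ratio and POC expressed as a percentage of DOC.
    Both inputs must share units (µM).
    """
    if not poc > 0:
        raise ValidationError("poc must be positive")
    if doc < 0:
        raise ValidationError("doc must be non-negative")
    return PartitionResult(ratio=doc / poc, poc_percent_of_doc=poc / doc * 100.0)
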