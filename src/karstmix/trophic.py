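"""Two-source stable-isotope mixing for consumer diets.

A filter-feeding consumer whose carbon comes from two isotopically distinct
pools — methanotroph biomass carrying the δ¹³C of microbial methane, and
heterotroph biomass carrying the δ¹³C of soil-derived organic matter —
has a bulk tissue value that is a linear blend of the two sources:

    % methane carbon = (δ_consumer − δ_OM) / (δ_methane − δ_OM) × 100

No trophic fractionation correction is applied; the model deliberately
ignores the (small) ¹³C fractionation by the intermediary bacteria, so the
fraction is a conservative first-order dietary estimate.  Specimens outside
the source bracket yield raw fractions outside [0, 100]; by default these
are clamped with the raw value retained.

When both δ¹³C and δD are measured, the spread of specimens along the
two-source mixing line lets one extrapolate to the δD of the methane source
itself (a Keeling-style source-signature regression): fit δD against δ¹³C
and evaluate at the methane δ¹³C end member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .samples_io import ValidationError

__all__ = [
    "SourceEndMembers",
    "ConsumerSpecimen",
    "MethaneFraction",
    "PopulationSummary",
    "SourceDeltaEstimate",
    "methane_fraction",
    "summarize_population",
    "estimate_source_dD",
    "read_consumer_table",
]

#: plausibility bands for consumer bulk isotope values (‰)
D13C_BAND = (-70.0, 0.0)
DD_BAND = (-450.0, 0.0)


@dataclass(frozen=True)
class SourceEndMembers:
    """δ¹³C end members of the two dietary carbon sources.

    Defaults are the fresh-water averages for microbial methane
    (−66.3 ± 0.7 ‰) and soil-derived organic matter, represented by
    fresh-water DOC (−28.0 ± 0.1 ‰).
    """

    d13c_methane: float = -66.3
    d13c_om: float = -28.0
    d13c_methane_se: float = 0.7
    d13c_om_se: float = 0.1

    def __post_init__(self):
        if self.d13c_methane == self.d13c_om:
            raise ValidationError("source end members must differ")


@dataclass
class ConsumerSpecimen:
    """Bulk isotope measurement of one consumer (shrimp or insect)."""

    specimen_id: str
    d13c: float                       # ‰ VPDB
    dD: Optional[float] = None        # ‰ V-SMOW
    taxon: str = ""
    site: str = ""
    water_mass: str = "UNASSIGNED"
    methane_fraction: Optional[float] = None   # %, filled by analysis

    def __post_init__(self):
        lo, hi = D13C_BAND
        if not (lo <= self.d13c <= hi):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: δ¹³C={self.d13c}‰ outside "
                f"sanity band [{lo}, {hi}]"
            )
        if self.dD is not None:
            lo, hi = DD_BAND
            if not (lo <= self.dD <= hi):
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: δD={self.dD}‰ outside "
                    f"sanity band [{lo}, {hi}]"
                )


class MethaneFraction(NamedTuple):
    """Methane-carbon contribution (%): clamped value, raw value, flag."""

    percent: float
    raw_percent: float
    clamped: bool


def methane_fraction(
    d13c_consumer: float,
    sources: Optional[SourceEndMembers] = None,
    clamp: bool = True,
) -> MethaneFraction:
    """Methane-carbon contribution to a consumer's biomass, in percent.

    Linear two-source solution; with ``clamp`` (default) the reported value
    is restricted to [0, 100] while the raw solution is always retained.
    """
    sources = sources or SourceEndMembers()
    raw = (
        (d13c_consumer - sources.d13c_om)
        / (sources.d13c_methane - sources.d13c_om)
        * 100.0
    )
    if clamp:
        value = min(max(raw, 0.0), 100.0)
    else:
        value = raw
    return MethaneFraction(percent=value, raw_percent=raw, clamped=value != raw)


@dataclass
class PopulationSummary:
    min_percent: float
    max_percent: float
    mean_percent: float
    n: int

    def to_dict(self) -> dict:
        return {
            "min_percent": self.min_percent,
            "max_percent": self.max_percent,
            "mean_percent": self.mean_percent,
            "mean_percent_rounded": round(self.mean_percent),
            "n": self.n,
        }


def summarize_population(
    specimens: Sequence[ConsumerSpecimen],
    sources: Optional[SourceEndMembers] = None,
    clamp: bool = True,
    exclude_taxa: Sequence[str] = ("insect",),
) -> PopulationSummary:
    """Min/max/mean methane-carbon contribution over a consumer population.

    Fractions are computed per specimen (clamped by default, consistent
    with reporting a dietary range that starts at 0) and summarised over
    the specimens remaining after the taxon filter.  ``exclude_taxa`` is a
    list of case-insensitive substrings matched against each specimen's
    taxon (default drops surface insects, which calibrate the OM end of the
    diagram rather than the cave population).
    """
    kept = [
        s for s in specimens
        if not any(pat.lower() in s.taxon.lower() for pat in exclude_taxa if pat)
    ]
    if not kept:
        raise ValidationError("no specimens left after taxon filter")
    values = []
    for s in kept:
        frac = methane_fraction(s.d13c, sources, clamp=clamp)
        s.methane_fraction = frac.percent
        values.append(frac.percent)
    arr = np.asarray(values)
    return PopulationSummary(
        min_percent=float(arr.min()),
        max_percent=float(arr.max()),
        mean_percent=float(arr.mean()),
        n=arr.size,
    )


# ---------------------------------------------------------------------------
# δD source-signature extrapolation
# ---------------------------------------------------------------------------

@dataclass
class SourceDeltaEstimate:
    """Result of extrapolating the (δ¹³C, δD) consumer trend to a source."""

    estimate: float            # δD at d13c_source, ‰
    slope: float
    intercept: float
    ci_low: float              # bootstrap percentile interval on estimate
    ci_high: float
    method: str                # "ols" or "rma"
    n: int
    extrapolated: bool         # d13c_source outside the specimen range

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "n": self.n,
            "extrapolated": self.extrapolated,
        }


def _fit_line(x: np.ndarray, y: np.ndarray, method: str):
    if method == "ols":
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return float(res.params[1]), float(res.params[0])
    if method == "rma":
        # reduced major axis: slope magnitude sd(y)/sd(x), sign of r
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        r = np.corrcoef(x, y)[0, 1]
        slope = np.sign(r if r != 0 else 1.0) * sy / sx
        return float(slope), float(y.mean() - slope * x.mean())
    raise ValidationError(f"unknown regression method {method!r}")


def estimate_source_dD(
    specimens: Sequence[ConsumerSpecimen],
    d13c_source: float = -66.3,
    method: str = "ols",
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> SourceDeltaEstimate:
    """Estimate a source's δD by regressing consumer δD on δ¹³C.

    Fits a line through (δ¹³C, δD) of all specimens that carry both
    isotopes and evaluates it at ``d13c_source`` (the methane end member by
    default).  ``method`` is ordinary least squares (``"ols"``, default) or
    reduced major axis (``"rma"``, appropriate when both axes carry error).
    The confidence band is a bootstrap percentile interval over specimen
    resamples.
    """
    pairs = [(s.d13c, s.dD) for s in specimens if s.dD is not None]
    if len(pairs) < 3:
        raise ValidationError("need ≥ 3 specimens with both δ¹³C and δD")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValidationError("zero δ¹³C variance: source extrapolation undefined")

    slope, intercept = _fit_line(x, y, method)
    estimate = slope * d13c_source + intercept

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:
            continue
        sb, ib = _fit_line(xb, yb, method)
        boot.append(sb * d13c_source + ib)
    if boot:
        lo, hi = np.percentile(boot, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    else:
        lo = hi = estimate
    return SourceDeltaEstimate(
        estimate=float(estimate),
        slope=slope,
        intercept=intercept,
        ci_low=float(lo),
        ci_high=float(hi),
        method=method,
        n=x.size,
        extrapolated=not (x.min() < d13c_source < x.max()),
    )


def read_consumer_table(path, **read_csv_kwargs):
    """Read a consumer isotope CSV into specimens plus a row-error report.

    Expected columns: ``specimen_id``, ``d13c``; optional ``dD``, ``taxon``,
    ``site``, ``water_mass``.  Invalid rows are reported with 1-based file
    line numbers, not silently dropped.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    if "d13c" not in df.columns:
        raise ValidationError("consumer table needs a 'd13c' column")
    specimens, errors = [], []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            dD = row.get("dD")
            specimens.append(
                ConsumerSpecimen(
                    specimen_id=str(row.get("specimen_id", f"row{line}")),
                    d13c=float(row["d13c"]),
                    dD=None if dD is None or pd.isna(dD) else float(dD),
                    taxon=str(row.get("taxon", "") or ""),
                    site=str(row.get("site", "") or ""),
                    water_mass=str(row.get("water_mass", "UNASSIGNED") or "UNASSIGNED"),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append((line, str(exc)))
    return specimens, errors
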