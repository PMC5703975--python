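"""Synthetic data with known ground truth for every analysis stage.

The generator emulates the study system: a three-layer density-stratified
karst aquifer (fresh ≈ 0.26 psu, brackish ≈ 1.81 psu, saline ≈ 32.87 psu)
in which methane and DOC enter with the fresh water, mix conservatively
with the saline end member, and are partially consumed within the brackish
layer.  Residual methane is ¹³C-enriched following a closed-system
Rayleigh approximation, δ_res ≈ δ_mix + ε·ln(1 − r), with an enrichment
factor ε in the range typical of aerobic methanotrophy.  Consumer (shrimp)
isotope values are linear two-source blends of a methane and a soil-OM end
member in both δ¹³C and δD; that shared-fraction linearisation is the same
simplification the downstream source-signature extrapolation relies on.

Every generated table is accompanied by a machine-readable ground-truth
"sidecar" holding the scenario parameters and the expected value of each
downstream estimate, so that parameter-recovery tests can be scored
without reference to anything outside the generated files.

All randomness flows through one ``numpy`` generator seeded from the
scenario config: identical seed and config give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .samples_io import SondeProfile, ValidationError
from .mixing import (
    EndMemberPair,
    conservative_concentration,
    conservative_delta,
    mixing_fraction,
)

__all__ = [
    "WATER_MASS_STATS",
    "ScenarioConfig",
    "SondeConfig",
    "TrophicSources",
    "default_end_members",
    "removal_for_target_percent",
    "generate_water_column",
    "generate_sonde_profile",
    "generate_shrimp",
]

#: Water-mass summary statistics used as scenario defaults:
#: ``(mean, standard error, n)`` per variable and water mass.  The noise
#: model converts the standard errors back to per-sample standard
#: deviations via sd = se·√n.
WATER_MASS_STATS: Dict[str, Dict[str, tuple]] = {
    "MFW": {
        "salinity": (0.26, 0.03, 8),
        "so4": (0.3, 0.1, 7),
        "ch4": (6466.0, 659.0, 8),
        "d13c_ch4": (-66.3, 0.7, 7),
        "doc": (661.0, 132.0, 3),
        "d13c_doc": (-28.0, 0.1, 3),
        "dic": (4.4, 0.2, 6),
        "d13c_dic": (-16.4, 1.0, 7),
        "poc": (10.9, 3.8, 3),
        "d13c_poc": (-28.5, 0.5, 3),
    },
    "MBW": {
        "salinity": (1.81, 0.04, 29),
        "so4": (1.6, 0.1, 27),
        "ch4": (157.0, 16.0, 28),
        "d13c_ch4": (-52.7, 1.9, 25),
        "doc": (131.0, 16.0, 16),
        "d13c_doc": (-28.3, 0.2, 16),
        "dic": (7.1, 0.2, 24),
        "d13c_dic": (-11.1, 0.7, 25),
        "poc": (5.0, 2.3, 3),
        "d13c_poc": (-27.6, 0.7, 3),
    },
    "SGW": {
        "salinity": (32.87, 0.94, 13),
        "so4": (26.4, 1.0, 11),
        "ch4": (110.0, 17.0, 12),
        "d13c_ch4": (-56.3, 1.5, 11),
        "doc": (41.0, 20.0, 3),
        "d13c_doc": (-26.6, 0.4, 3),
        "dic": (2.4, 0.2, 10),
        "d13c_dic": (-6.3, 1.0, 11),
        "poc": (3.0, 0.9, 3),
        "d13c_poc": (-27.1, 1.0, 3),
    },
}

_CONSTITUENT_VARS = {
    "CH4": ("ch4", "d13c_ch4"),
    "DOC": ("doc", "d13c_doc"),
    "DIC": ("dic", "d13c_dic"),
    "SO4": ("so4", None),
}


def _stat(wm: str, var: str) -> tuple:
    return WATER_MASS_STATS[wm][var]


def _sd(wm: str, var: str) -> float:
    mean, se, n = _stat(wm, var)
    return se * math.sqrt(n)


def default_end_members() -> Dict[str, EndMemberPair]:
    """Scenario-default end members (fresh / saline water-mass means)."""
    t_mfw = _stat("MFW", "salinity")[0]
    t_sgw = _stat("SGW", "salinity")[0]
    pairs = {}
    for const, (cvar, dvar) in _CONSTITUENT_VARS.items():
        pairs[const] = EndMemberPair(
            constituent=const,
            tracer_mfw=t_mfw,
            tracer_sgw=t_sgw,
            c_mfw=_stat("MFW", cvar)[0],
            c_sgw=_stat("SGW", cvar)[0],
            d_mfw=_stat("MFW", dvar)[0] if dvar else None,
            d_sgw=_stat("SGW", dvar)[0] if dvar else None,
            event="scenario",
        )
    return pairs


def _default_removal() -> Dict[str, float]:
    """Removal fractions reproducing the observed brackish-water means.

    ``r`` is the fraction of the conservative expectation removed within
    the brackish layer: C_MBW = (1 − r)·C_MIX.  Defaults pin the expected
    brackish concentrations of CH₄ and DOC at their observed water-mass
    means; DIC and SO₄ mix conservatively.
    """
    pairs = default_end_members()
    t_mbw = _stat("MBW", "salinity")[0]
    removal = {}
    for const in ("CH4", "DOC"):
        p = pairs[const]
        f = mixing_fraction(t_mbw, p.tracer_mfw, p.tracer_sgw).value
        c_mix = conservative_concentration(f, p.c_mfw, p.c_sgw)
        observed = _stat("MBW", _CONSTITUENT_VARS[const][0])[0]
        removal[const] = 1.0 - observed / c_mix
    removal["DIC"] = 0.0
    removal["SO4"] = 0.0
    return removal


def removal_for_target_percent(
    target_percent: float, pair: EndMemberPair, tracer_mbw: float
) -> float:
    """Removal fraction r such that the expected consumption statistic
    (C_MIX − C_MBW)/C_MFW × 100 equals ``target_percent`` at zero noise."""
    f = mixing_fraction(tracer_mbw, pair.tracer_mfw, pair.tracer_sgw).value
    c_mix = conservative_concentration(f, pair.c_mfw, pair.c_sgw)
    r = target_percent / 100.0 * pair.c_mfw / c_mix
    if not 0.0 <= r <= 1.0:
        raise ValidationError(
            f"target {target_percent}% requires removal fraction {r:.3f} "
            "outside [0, 1]"
        )
    return r


@dataclass
class ScenarioConfig:
    """Ground-truth scenario for the stratified water column.

    Defaults reproduce the study conditions: water-mass tracer values
    0.26/1.81/32.87 psu, end members at the fresh/saline water-mass means,
    removal fractions pinning the expected brackish CH₄ and DOC at their
    observed means, Rayleigh enrichment ε = −15 ‰ for residual methane,
    per-variable noise at the water-mass standard deviations (standard
    error × √n), and the study's per-water-mass sample counts.
    ``noise_scale`` rescales all noise at once (0 → deterministic values).
    """

    tracer_mfw: float = 0.26
    tracer_mbw: float = 1.81
    tracer_sgw: float = 32.87
    end_members: Dict[str, EndMemberPair] = field(default_factory=default_end_members)
    removal: Dict[str, float] = field(default_factory=_default_removal)
    rayleigh_epsilon: float = -15.0        # ‰, enrichment factor for CH4
    noise_scale: float = 1.0
    n_samples: Dict[str, int] = field(
        default_factory=lambda: {"MFW": 8, "MBW": 29, "SGW": 13}
    )
    event: str = "S1"
    seed: int = 0

    def __post_init__(self):
        for const, r in self.removal.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(
                    f"removal fraction for {const} must be in [0, 1], got {r}"
                )
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be ≥ 0")
        if not self.tracer_mfw < self.tracer_mbw < self.tracer_sgw:
            raise ValidationError("tracer values must be ordered MFW < MBW < SGW")
        for wm, n in self.n_samples.items():
            if n < 1:
                raise ValidationError(f"n_samples[{wm!r}] must be ≥ 1")


_NOMINAL_DEPTH = {"MFW": 3.0, "MBW": 12.0, "SGW": 22.0}


def generate_water_column(config: Optional[ScenarioConfig] = None):
    """Generate a water-sample table plus its ground-truth sidecar.

    For each sample the tracer is drawn around its water-mass value, the
    conservative concentration and δ¹³C follow from the end members, the
    brackish layer loses the configured fraction r of each constituent
    (with Rayleigh ¹³C-enrichment of the residual methane), and Gaussian
    measurement noise is added.  Mixing fractions are clamped to [0, 1] for
    generation: samples drawn beyond the end-member bracket take on
    end-member composition rather than extrapolated values.  Concentrations
    are truncated at zero after noise (rarely triggered at default noise).

    Returns ``(table, truth)``: a DataFrame with one row per sample and a
    dict recording the scenario plus the expected value of every
    downstream estimate (expected consumption percentages evaluated at the
    mean tracer values).
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    tracers = {
        "MFW": config.tracer_mfw,
        "MBW": config.tracer_mbw,
        "SGW": config.tracer_sgw,
    }

    rows = []
    k = 0
    for wm in ("MFW", "MBW", "SGW"):
        t_mean = tracers[wm]
        t_sd = _sd(wm, "salinity") * config.noise_scale
        for _ in range(config.n_samples[wm]):
            k += 1
            s = max(float(rng.normal(t_mean, t_sd)), 0.0) if t_sd else t_mean
            f = mixing_fraction(s, config.tracer_mfw, config.tracer_sgw).value
            f = min(max(f, 0.0), 1.0)
            row = {
                "sample_id": f"syn{k:03d}",
                "event": config.event,
                "water_mass": wm,
                "depth": _NOMINAL_DEPTH[wm],
                "salinity": s,
            }
            for const, pair in config.end_members.items():
                cvar, dvar = _CONSTITUENT_VARS[const]
                c = conservative_concentration(f, pair.c_mfw, pair.c_sgw)
                d = (
                    conservative_delta(f, pair.c_mfw, pair.d_mfw, pair.c_sgw, pair.d_sgw)
                    if pair.has_delta
                    else None
                )
                if wm == "MBW":
                    r = config.removal.get(const, 0.0)
                    if r > 0:
                        c = c * (1.0 - r)
                        if const == "CH4" and d is not None:
                            d = d + config.rayleigh_epsilon * math.log(1.0 - r)
                c_sd = _sd(wm, cvar) * config.noise_scale
                row[cvar] = max(float(c + rng.normal(0.0, c_sd)), 0.0) if c_sd else float(c)
                if d is not None and dvar is not None:
                    d_sd = _sd(wm, dvar) * config.noise_scale
                    row[dvar] = float(d + rng.normal(0.0, d_sd)) if d_sd else float(d)
            # POC is observational (not part of the mixing model): draw
            # around the water-mass mean for the organic-carbon partition.
            poc_mean = _stat(wm, "poc")[0]
            poc_sd = _sd(wm, "poc") * config.noise_scale
            row["poc"] = max(float(poc_mean + rng.normal(0.0, poc_sd)), 0.0) if poc_sd else poc_mean
            rows.append(row)

    table = pd.DataFrame(rows)
    truth = _water_column_truth(config)
    return table, truth


def _water_column_truth(config: ScenarioConfig) -> dict:
    f_mbw = mixing_fraction(
        config.tracer_mbw, config.tracer_mfw, config.tracer_sgw
    ).value
    expected = {}
    for const, pair in config.end_members.items():
        c_mix = conservative_concentration(f_mbw, pair.c_mfw, pair.c_sgw)
        r = config.removal.get(const, 0.0)
        c_mbw = c_mix * (1.0 - r)
        expected[const] = {
            "c_mix": c_mix,
            "c_mbw": c_mbw,
            "percent_consumed": (c_mix - c_mbw) / pair.c_mfw * 100.0,
            "removal_fraction": r,
        }
    return {
        "kind": "water_column",
        "seed": config.seed,
        "event": config.event,
        "tracers": {
            "MFW": config.tracer_mfw,
            "MBW": config.tracer_mbw,
            "SGW": config.tracer_sgw,
        },
        "f_mfw_at_mbw": f_mbw,
        "rayleigh_epsilon": config.rayleigh_epsilon,
        "noise_scale": config.noise_scale,
        "n_samples": dict(config.n_samples),
        "end_members": {
            const: {
                "tracer_mfw": p.tracer_mfw,
                "tracer_sgw": p.tracer_sgw,
                "c_mfw": p.c_mfw,
                "c_sgw": p.c_sgw,
                "d_mfw": p.d_mfw,
                "d_sgw": p.d_sgw,
            }
            for const, p in config.end_members.items()
        },
        "expected": expected,
    }


# ---------------------------------------------------------------------------
# sonde profiles
# ---------------------------------------------------------------------------

@dataclass
class SondeConfig:
    """Three-layer salinity structure with thin, smoothed haloclines.

    Salinity is piecewise constant with linear ramps of the given
    thicknesses centred at ``step_depths``.  Dissolved oxygen mimics the
    two observed regimes: ``"invariant"`` (constant within the brackish
    layer) or ``"gradient"`` (anoxic at the shallow halocline, rising
    toward the deep one).
    """

    max_depth: float = 25.0                 # m
    resolution: float = 0.05                # m between records
    step_depths: Sequence[float] = (7.0, 20.0)
    layer_salinities: Sequence[float] = (0.5, 2.2, 35.0)
    step_thickness: Sequence[float] = (0.4, 0.4)   # m
    do_regime: str = "invariant"            # or "gradient"
    do_levels: Sequence[float] = (5.0, 25.0, 50.0)  # µM per layer
    temperature: float = 25.4               # °C, near-isothermal column
    noise_sd: float = 0.0                   # psu, optional sensor noise
    seed: int = 0

    def __post_init__(self):
        if len(self.layer_salinities) != len(self.step_depths) + 1:
            raise ValidationError("need one more layer salinity than step depth")
        if len(self.step_thickness) != len(self.step_depths):
            raise ValidationError("need one thickness per step")
        for z, w in zip(self.step_depths, self.step_thickness):
            if not (0 < z - w / 2 and z + w / 2 < self.max_depth):
                raise ValidationError(
                    f"step at {z} m (thickness {w} m) outside profile span"
                )
        if self.do_regime not in ("invariant", "gradient"):
            raise ValidationError("do_regime must be 'invariant' or 'gradient'")


def _ramp(z, z0, w):
    """0→1 linear ramp of width w centred at z0."""
    return np.clip((z - (z0 - w / 2)) / w, 0.0, 1.0)


def generate_sonde_profile(config: Optional[SondeConfig] = None):
    """Generate a sonde cast plus its ground-truth sidecar."""
    config = config or SondeConfig()
    z = np.arange(0.0, config.max_depth + config.resolution / 2, config.resolution)
    sal = np.full_like(z, float(config.layer_salinities[0]))
    for (z0, w, s_lo, s_hi) in zip(
        config.step_depths,
        config.step_thickness,
        config.layer_salinities[:-1],
        config.layer_salinities[1:],
    ):
        sal = sal + (s_hi - s_lo) * _ramp(z, z0, w)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        sal = np.maximum(sal + rng.normal(0.0, config.noise_sd, sal.size), 0.0)

    do = np.full_like(z, float(config.do_levels[0]))
    if len(config.step_depths) == 2:
        z1, z2 = config.step_depths
        w1, w2 = config.step_thickness
        in_mbw = (z > z1) & (z <= z2)
        if config.do_regime == "invariant":
            do[in_mbw] = config.do_levels[1]
        else:
            # anoxic at the shallow halocline, rising linearly toward H2
            frac = (z[in_mbw] - z1) / (z2 - z1)
            do[in_mbw] = frac * config.do_levels[1] * 2.0
        do[z > z2] = config.do_levels[2]
    temp = np.full_like(z, config.temperature)

    profile = SondeProfile(
        depth=z, salinity=sal, dissolved_oxygen=do, temperature=temp
    )
    truth = {
        "kind": "sonde_profile",
        "seed": config.seed,
        "step_depths": list(config.step_depths),
        "step_thickness": list(config.step_thickness),
        "layer_salinities": list(config.layer_salinities),
        "resolution": config.resolution,
        "do_regime": config.do_regime,
    }
    return profile, truth


# ---------------------------------------------------------------------------
# consumers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrophicSources:
    """Dietary source signatures in both isotope systems.

    δ¹³C defaults are the fresh-water methane and DOC averages; δD of the
    methane source defaults to −390 ‰ (microbial, acetoclastic methane)
    and of the soil-OM source to −96 ‰ (upper end of the insect/soil
    range).
    """

    d13c_methane: float = -66.3
    d13c_om: float = -28.0
    dD_methane: float = -390.0
    dD_om: float = -96.0


def generate_shrimp(
    n: int = 29,
    fractions: Optional[Sequence[float]] = None,
    fraction_range: tuple = (0.0, 0.55),
    sources: Optional[TrophicSources] = None,
    noise_d13c: float = 0.04,
    noise_dD: float = 1.9,
    seed: int = 0,
    taxon: str = "Typhlatya sp.",
):
    """Generate a consumer isotope table plus its ground-truth sidecar.

    Each specimen takes a true methane-carbon fraction (given explicitly or
    drawn uniformly from ``fraction_range``); its δ¹³C and δD are linear
    blends of the source signatures by that same fraction (the generator's
    documented linearisation of hydrogen-pool mixing), plus Gaussian
    analytical noise (defaults: 0.04 ‰ for δ¹³C, 1.9 ‰ for δD).
    """
    sources = sources or TrophicSources()
    rng = np.random.default_rng(seed)
    if fractions is None:
        lo, hi = fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("fraction_range must satisfy 0 ≤ lo ≤ hi ≤ 1")
        fr = rng.uniform(lo, hi, n)
    else:
        fr = np.asarray(fractions, dtype=float)
        if fr.size != n:
            raise ValidationError("len(fractions) must equal n")
        if np.any((fr < 0) | (fr > 1)):
            raise ValidationError("true fractions must lie in [0, 1]")

    d13c = fr * sources.d13c_methane + (1 - fr) * sources.d13c_om
    dD = fr * sources.dD_methane + (1 - fr) * sources.dD_om
    if noise_d13c > 0:
        d13c = d13c + rng.normal(0.0, noise_d13c, n)
    if noise_dD > 0:
        dD = dD + rng.normal(0.0, noise_dD, n)

    table = pd.DataFrame(
        {
            "specimen_id": [f"shr{i + 1:03d}" for i in range(n)],
            "taxon": taxon,
            "site": "synthetic-cave",
            "water_mass": "MBW",
            "d13c": d13c,
            "dD": dD,
        }
    )
    truth = {
        "kind": "consumers",
        "seed": seed,
        "n": n,
        "true_fractions": [float(v) for v in fr],
        "expected_mean_percent": float(fr.mean() * 100.0),
        "sources": {
            "d13c_methane": sources.d13c_methane,
            "d13c_om": sources.d13c_om,
            "dD_methane": sources.dD_methane,
            "dD_om": sources.dD_om,
        },
        "noise_d13c": noise_d13c,
        "noise_dD": noise_dD,
    }
    return table, truth
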