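"""End-to-end orchestration: read → classify → mix → consume → trophic.

The pipeline assembles the standalone operations into the study's report:
per-event end members and mixing envelopes, deviation classification of
brackish-water samples, pooled and per-event consumption statistics for
each constituent, the DIC excess and DOC:POC partition, and the trophic
summary with the optional δD source extrapolation.  Every number in the
report is the output of a standalone operation on the same inputs — the
pipeline adds bookkeeping and provenance, never arithmetic.

Two averaging modes are provided for the consumption statistic: pooled
(water-mass means across all events, one statistic per constituent) and
per-event (the statistic evaluated within each sampling event, then
averaged).  With a single event they coincide.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .samples_io import (
    ValidationError,
    WaterSample,
    classify_water_mass,
)
from .mixing import (
    CONSTITUENT_FIELDS,
    EndMemberPair,
    MixingEnvelope,
    build_mixing_envelope,
    classify_deviation,
    mixing_fraction,
    conservative_concentration,
    organic_carbon_partition,
    percent_consumed,
)
from .trophic import (
    ConsumerSpecimen,
    SourceEndMembers,
    estimate_source_dD,
    methane_fraction,
    summarize_population,
)

logger = logging.getLogger("karstmix")

__all__ = [
    "MixingAnalysis",
    "run_mixing_analysis",
    "run_trophic_analysis",
    "report_json",
]

#: default 1σ analytical/replicate error per constituent (brackish-water
#: standard errors), used to pad the envelope in deviation classification
DEFAULT_SIGMA = {"CH4": 16.0, "DOC": 16.0, "DIC": 0.2, "SO4": 0.1}

DEFAULT_CONSTITUENTS = ("CH4", "DOC", "DIC", "SO4")


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        df = pd.DataFrame([vars(s) for s in samples]).drop(
            columns=["cross_check_tol"], errors="ignore"
        )
    if "salinity" not in df.columns:
        raise ValidationError("sample table needs a salinity column")
    if "event" not in df.columns:
        df["event"] = "all"
    if "water_mass" not in df.columns or df["water_mass"].isna().all():
        df["water_mass"] = [classify_water_mass(s) for s in df["salinity"]]
    return df


def _mass_values(df: pd.DataFrame, wm: str, col: str) -> pd.Series:
    sub = df[df["water_mass"] == wm]
    if col not in sub.columns:
        return pd.Series(dtype=float)
    return pd.to_numeric(sub[col], errors="coerce").dropna()


def _config_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(params: dict, inputs: Optional[dict] = None) -> dict:
    prov = {"config_hash": _config_hash(params), "parameters": params}
    if inputs:
        prov["input_checksums"] = inputs
    return prov


@dataclass
class MixingAnalysis:
    """Geochemical half of the analysis report."""

    report: dict
    envelopes: Dict[str, MixingEnvelope]
    classifications: pd.DataFrame


def run_mixing_analysis(
    samples,
    constituents: Sequence[str] = DEFAULT_CONSTITUENTS,
    sigma: Optional[Dict[str, float]] = None,
    k: float = 1.0,
    n_grid: int = 200,
    input_checksums: Optional[dict] = None,
) -> MixingAnalysis:
    """Run the conservative-mixing analysis over a sample table.

    ``samples`` is a DataFrame (generator output or a reader echo) or a
    list of :class:`~karstmix.samples_io.WaterSample`.  For each requested
    constituent the per-event end members follow the min/min–max/max rule
    (lowest fresh with lowest saline concentration, highest with highest),
    the envelope is the pointwise field over all event lines, brackish
    samples are classified against it, and the consumption statistic is
    evaluated pooled and per event.  A constituent missing a water mass is
    skipped with a warning, never a crash.
    """
    t0 = time.perf_counter()
    df = _as_frame(samples)
    sigma = dict(DEFAULT_SIGMA, **(sigma or {}))
    events = sorted(df["event"].astype(str).unique())

    report: dict = {"constituents": {}, "events": events}
    envelopes: Dict[str, MixingEnvelope] = {}
    class_rows = []

    for const in constituents:
        conc_col, delta_col = CONSTITUENT_FIELDS[const]
        pairs = []
        for ev in events:
            sub = df[df["event"].astype(str) == ev]
            mfw = _mass_values(sub, "MFW", conc_col)
            sgw = _mass_values(sub, "SGW", conc_col)
            if mfw.empty or sgw.empty:
                logger.warning(
                    "%s event %s: missing MFW or SGW samples; event skipped",
                    const, ev,
                )
                continue
            t_mfw = _mass_values(sub, "MFW", "salinity").mean()
            t_sgw = _mass_values(sub, "SGW", "salinity").mean()
            d_mfw = d_sgw = None
            if delta_col is not None:
                dm = _mass_values(sub, "MFW", delta_col)
                ds = _mass_values(sub, "SGW", delta_col)
                if not dm.empty and not ds.empty:
                    d_mfw, d_sgw = float(dm.mean()), float(ds.mean())
            for lo_hi in ("low", "high"):
                pick = min if lo_hi == "low" else max
                pairs.append(
                    EndMemberPair(
                        constituent=const,
                        tracer_mfw=float(t_mfw),
                        tracer_sgw=float(t_sgw),
                        c_mfw=float(pick(mfw)),
                        c_sgw=float(pick(sgw)),
                        d_mfw=d_mfw,
                        d_sgw=d_sgw,
                        event=f"{ev}:{lo_hi}",
                    )
                )
        if not pairs:
            logger.warning("%s: no usable events; constituent skipped", const)
            report["constituents"][const] = {"skipped": "missing water mass"}
            continue

        envelope = build_mixing_envelope(pairs, n_grid=n_grid)
        envelopes[const] = envelope

        # deviation classification of brackish samples
        counts = {"production": 0, "consumption": 0, "conservative": 0}
        mbw_rows = df[df["water_mass"] == "MBW"]
        lo_span, hi_span = envelope.span
        for _, row in mbw_rows.iterrows():
            val = pd.to_numeric(pd.Series([row.get(conc_col)]), errors="coerce").iloc[0]
            if pd.isna(val) or not (lo_span <= row["salinity"] <= hi_span):
                continue
            label = classify_deviation(
                float(row["salinity"]), float(val), envelope,
                sigma=sigma.get(const, 0.0), k=k,
            )
            counts[label] += 1
            class_rows.append(
                {
                    "sample_id": row.get("sample_id", ""),
                    "event": row["event"],
                    "constituent": const,
                    "salinity": float(row["salinity"]),
                    "value": float(val),
                    "classification": label,
                }
            )

        # pooled consumption statistic (water-mass means over all events)
        entry: dict = {"classification_counts": counts}
        mfw_all = _mass_values(df, "MFW", conc_col)
        sgw_all = _mass_values(df, "SGW", conc_col)
        mbw_all = _mass_values(df, "MBW", conc_col)
        if not mbw_all.empty:
            t_mfw = _mass_values(df, "MFW", "salinity").mean()
            t_sgw = _mass_values(df, "SGW", "salinity").mean()
            t_mbw = _mass_values(df, "MBW", "salinity").mean()
            frac = mixing_fraction(t_mbw, t_mfw, t_sgw)
            if frac.out_of_bracket:
                logger.warning(
                    "%s: pooled brackish tracer outside end-member bracket", const
                )
            c_mix = conservative_concentration(
                frac.value, mfw_all.mean(), sgw_all.mean(),
                allow_extrapolation=True,
            )
            pooled = percent_consumed(
                c_mix, mbw_all.mean(), mfw_all.mean(),
                constituent=const, event="pooled",
            )
            entry["pooled"] = pooled.to_dict()
            entry["pooled"]["f_mfw"] = frac.value

            # per-event statistics, then averaged
            per_event = []
            for ev in events:
                sub = df[df["event"].astype(str) == ev]
                e_mfw = _mass_values(sub, "MFW", conc_col)
                e_sgw = _mass_values(sub, "SGW", conc_col)
                e_mbw = _mass_values(sub, "MBW", conc_col)
                if e_mfw.empty or e_sgw.empty or e_mbw.empty:
                    continue
                et_mfw = _mass_values(sub, "MFW", "salinity").mean()
                et_sgw = _mass_values(sub, "SGW", "salinity").mean()
                et_mbw = _mass_values(sub, "MBW", "salinity").mean()
                ef = mixing_fraction(et_mbw, et_mfw, et_sgw)
                ec_mix = conservative_concentration(
                    ef.value, e_mfw.mean(), e_sgw.mean(),
                    allow_extrapolation=True,
                )
                per_event.append(
                    percent_consumed(
                        ec_mix, e_mbw.mean(), e_mfw.mean(),
                        constituent=const, event=ev,
                    )
                )
            if per_event:
                entry["per_event"] = [r.to_dict() for r in per_event]
                entry["per_event_mean"] = {
                    "percent_consumed": float(
                        np.mean([r.percent_consumed for r in per_event])
                    ),
                    "absolute_reduction": float(
                        np.mean([r.absolute_reduction for r in per_event])
                    ),
                    "n_events": len(per_event),
                }
        report["constituents"][const] = entry

    # DIC excess above the mixing field (reported, source unattributed)
    if "DIC" in envelopes:
        mbw_dic = _mass_values(df, "MBW", "dic")
        t_mbw = _mass_values(df, "MBW", "salinity").mean()
        lo_span, hi_span = envelopes["DIC"].span
        if not mbw_dic.empty and lo_span <= t_mbw <= hi_span:
            _, upper = envelopes["DIC"].concentration_bounds_at(float(t_mbw))
            report["dic_excess"] = {
                "mean_mbw_dic": float(mbw_dic.mean()),
                "envelope_upper_at_mbw": float(upper),
                "excess": float(mbw_dic.mean() - upper),
            }

    # organic-carbon partition in the fresh end member
    mfw_doc = _mass_values(df, "MFW", "doc")
    mfw_poc = _mass_values(df, "MFW", "poc")
    if not mfw_doc.empty and not mfw_poc.empty and mfw_poc.mean() > 0:
        part = organic_carbon_partition(mfw_doc.mean(), mfw_poc.mean())
        report["organic_carbon_partition"] = {
            "doc_mfw": float(mfw_doc.mean()),
            "poc_mfw": float(mfw_poc.mean()),
            "ratio": part.ratio,
            "poc_percent_of_doc": part.poc_percent_of_doc,
        }

    report["provenance"] = _provenance(
        {
            "constituents": list(constituents),
            "sigma": sigma,
            "k": k,
            "n_grid": n_grid,
            "n_samples": int(len(df)),
        },
        inputs=input_checksums,
    )
    logger.info(
        "mixing analysis: %d samples, %d events, %.3f s",
        len(df), len(events), time.perf_counter() - t0,
    )
    classifications = pd.DataFrame(
        class_rows,
        columns=["sample_id", "event", "constituent", "salinity", "value",
                 "classification"],
    )
    return MixingAnalysis(
        report=report, envelopes=envelopes, classifications=classifications
    )


def run_trophic_analysis(
    consumers,
    sources: Optional[SourceEndMembers] = None,
    clamp: bool = True,
    exclude_taxa: Sequence[str] = ("insect",),
    d13c_source: Optional[float] = None,
    regression: str = "ols",
    n_boot: int = 1000,
    seed: int = 0,
    input_checksums: Optional[dict] = None,
) -> dict:
    """Run the trophic mixing analysis over a consumer table.

    ``consumers`` is a DataFrame (columns ``specimen_id``, ``d13c``,
    optional ``dD``/``taxon``/``site``/``water_mass``) or a list of
    :class:`~karstmix.trophic.ConsumerSpecimen`.  Returns the trophic half
    of the analysis report: per-specimen methane-carbon fractions, the
    population summary, and — when ≥ 3 specimens carry δD — the δD
    source-signature extrapolation.
    """
    t0 = time.perf_counter()
    sources = sources or SourceEndMembers()
    if isinstance(consumers, pd.DataFrame):
        specimens = [
            ConsumerSpecimen(
                specimen_id=str(row.get("specimen_id", f"row{i}")),
                d13c=float(row["d13c"]),
                dD=None if pd.isna(row.get("dD")) else float(row.get("dD")),
                taxon=str(row.get("taxon", "") or ""),
                site=str(row.get("site", "") or ""),
                water_mass=str(row.get("water_mass", "UNASSIGNED") or "UNASSIGNED"),
            )
            for i, (_, row) in enumerate(consumers.iterrows())
        ]
    else:
        specimens = list(consumers)
    if not specimens:
        raise ValidationError("empty consumer table")

    summary = summarize_population(
        specimens, sources, clamp=clamp, exclude_taxa=exclude_taxa
    )
    kept = [s for s in specimens if s.methane_fraction is not None]
    per_specimen = []
    for s in kept:
        frac = methane_fraction(s.d13c, sources, clamp=clamp)
        per_specimen.append(
            {
                "specimen_id": s.specimen_id,
                "taxon": s.taxon,
                "d13c": s.d13c,
                "dD": s.dD,
                "percent": frac.percent,
                "raw_percent": frac.raw_percent,
                "clamped": frac.clamped,
            }
        )

    report = {
        "sources": {
            "d13c_methane": sources.d13c_methane,
            "d13c_om": sources.d13c_om,
        },
        "per_specimen": per_specimen,
        "summary": summary.to_dict(),
    }
    with_dd = [s for s in kept if s.dD is not None]
    if len(with_dd) >= 3:
        est = estimate_source_dD(
            with_dd,
            d13c_source=(
                sources.d13c_methane if d13c_source is None else d13c_source
            ),
            method=regression,
            n_boot=n_boot,
            seed=seed,
        )
        report["dD_source_estimate"] = est.to_dict()

    report["provenance"] = _provenance(
        {
            "clamp": clamp,
            "exclude_taxa": list(exclude_taxa),
            "regression": regression,
            "n_boot": n_boot,
            "seed": seed,
            "sources": report["sources"],
            "n_specimens": len(specimens),
        },
        inputs=input_checksums,
    )
    logger.info(
        "trophic analysis: %d specimens, %.3f s",
        len(specimens), time.perf_counter() - t0,
    )
    return report


def report_json(report: dict) -> str:
    """Serialise a report deterministically (sorted keys, fixed layout)."""
    return json.dumps(report, sort_keys=True, indent=2, default=float)
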