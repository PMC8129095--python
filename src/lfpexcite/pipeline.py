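"""Cohort-level orchestration: traces -> per-slice summaries -> statistics.

Ties the spectral and event stages together into the long-format summary
table the classification and ANOVA stages consume (one row per slice x
concentration).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .events import DetectorConfig, detect_events, rate_per_minute
from .excitability import classify_cohort, mixed_anova, proportion_table
from .spectral import AREA_BAND, GAMMA_BAND, final_minute, trace_metrics
from .synthetic import GroundTruth, LfpTrace

__all__ = ["summarize_cohort", "cohort_statistics"]


def summarize_cohort(traces: Iterable[LfpTrace | tuple[LfpTrace, GroundTruth]],
                     detector_config: DetectorConfig | None = None,
                     band: tuple[float, float] = GAMMA_BAND,
                     area_band: tuple[float, float] = AREA_BAND,
                     snr_min: float = 5.0) -> pd.DataFrame:
    """Per slice x concentration metrics: event counts/rates + spectral metrics.

    Accepts bare traces or (trace, ground_truth) pairs (truth is ignored
    here; it is only for downstream recovery checks).  Event detection runs
    on every trace; spectral metrics carry the clear-gamma flag so group
    statistics can exclude gated-out rows per concentration.
    """
    rows = []
    for item in traces:
        trace = item[0] if isinstance(item, tuple) else item
        segment = final_minute(trace)
        events = detect_events(segment, detector_config)
        metrics = trace_metrics(trace, band=band, area_band=area_band,
                                snr_min=snr_min)
        counts = events.counts()
        rows.append({
            "slice_id": trace.slice_id, "mouse_id": trace.mouse_id,
            "genotype": trace.genotype, "ka_nm": trace.ka_nm,
            "spike_count": counts["spike"], "iid_count": counts["iid"],
            "spike_rate": rate_per_minute(events, "spike"),
            "iid_rate": rate_per_minute(events, "iid"),
            "peak_frequency": metrics.peak_frequency,
            "peak_amplitude": metrics.peak_amplitude,
            "area_power": metrics.area_power,
            "clear_gamma": metrics.clear_gamma,
        })
    return pd.DataFrame(rows)


def cohort_statistics(summary: pd.DataFrame, wt_label: str = "WT") -> dict:
    """Study-style statistics for a cohort summary.

    Returns slice classifications, class proportions, rank-transform mixed
    ANOVAs on spike and IID rates (all concentrations above baseline), and a
    log10 mixed ANOVA on area power restricted to rows passing the
    clear-gamma gate.
    """
    active = summary[summary["ka_nm"] > 0]
    classified = classify_cohort(active, wt_label=wt_label)
    proportions = proportion_table(classified)
    anova_spikes = mixed_anova(active, dv="spike_rate", transform="rank")
    anova_iids = mixed_anova(active, dv="iid_rate", transform="rank")
    spectral_rows = active[active["clear_gamma"] & (active["area_power"] > 0)]
    anova_area = mixed_anova(spectral_rows, dv="area_power", transform="log10")
    return {
        "classified": classified,
        "proportions": proportions,
        "anova_spike_rate": anova_spikes,
        "anova_iid_rate": anova_iids,
        "anova_area_power": anova_area,
    }
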