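"""End-to-end study analysis: raw tables in, trade-off records out."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .binding import FitConfig, fit_isotherm, read_titrations, summarize_affinity
from .kabat import VhVariant
from .melt import MeltConfig, estimate_tm, read_melts, summarize_tm
from .tradeoff import TradeoffRecord, build_tradeoff_table

__all__ = ["affinity_summaries", "stability_summaries", "analyze_study"]


def affinity_summaries(
    titrations: pd.DataFrame, config: FitConfig | None = None
) -> dict[str, "AffinitySummary"]:
    """Fit every replicate titration and summarize K_A per variant."""
    by_variant: dict[str, list] = {}
    for ds in read_titrations(titrations):
        by_variant.setdefault(ds.variant, []).append(fit_isotherm(ds, config))
    return {v: summarize_affinity(fits, v) for v, fits in by_variant.items()}


def stability_summaries(
    melts: pd.DataFrame, config: MeltConfig | None = None
) -> dict[str, "TmEstimate"]:
    """Estimate T_m* from the first heating of every replicate melt and
    summarize per variant (second scans, if present, feed only reversibility
    and are ignored here)."""
    by_variant: dict[str, list] = {}
    for (variant, _rep), scans in read_melts(melts).items():
        first = scans[min(scans)]
        by_variant.setdefault(variant, []).append(estimate_tm(first, config))
    return {v: summarize_tm(ests, v) for v, ests in by_variant.items()}


def analyze_study(
    titrations: pd.DataFrame,
    melts: pd.DataFrame,
    lineage: Mapping[str, VhVariant],
    fit_config: FitConfig | None = None,
    melt_config: MeltConfig | None = None,
    t_variant: str = "equal-variance",
) -> list[TradeoffRecord]:
    """Run the full pipeline on raw titration and melt tables."""
    affinity = affinity_summaries(titrations, fit_config)
    stability = stability_summaries(melts, melt_config)
    return build_tradeoff_table(affinity, stability, lineage, t_variant)
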