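"""Per-mutation affinity/stability trade-off classification.

Each mutation acquired during affinity maturation is probed by a reversion
construct: the evolved context variant with that one residue mutated back
to wild type.  Comparing replicate K_A values (variant vs reversion) and
replicate T_m* values with a two-tailed two-sample t-test yields, per
mutation, a signed affinity effect and a signed stability effect with
significance stars, which together place the mutation in one of the
trade-off quadrants (e.g. affinity-enhancing but destabilizing).
Significance thresholds are p < 0.05 (*) and p < 0.01 (**); effects with
p >= 0.05 are classified neutral.  When a variant's affinity is too low to
measure, the comparison is marked not-computable (the dagger convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binding import AffinitySummary
from .kabat import Mutation, VhVariant
from .melt import TmEstimate

__all__ = [
    "TTestResult",
    "TradeoffRecord",
    "AffinityClass",
    "StabilityClass",
    "students_t_test",
    "reversion_effect",
    "build_tradeoff_table",
    "records_to_frame",
]

NOT_COMPUTABLE = "not-computable"


class AffinityClass(str, Enum):
    ENHANCING = "enhancing"
    NEUTRAL = "neutral"
    REDUCING = "reducing"
    NOT_COMPUTABLE = NOT_COMPUTABLE


class StabilityClass(str, Enum):
    STABILIZING = "stabilizing"
    NEUTRAL = "neutral"
    DESTABILIZING = "destabilizing"
    NOT_COMPUTABLE = NOT_COMPUTABLE


@dataclass(frozen=True)
class TTestResult:
    """Two-tailed two-sample t-test with significance stars."""

    t_statistic: float
    df: float
    p_two_tailed: float
    stars: str  # "", "*" or "**"
    computable: bool = True

    @staticmethod
    def not_computable() -> "TTestResult":
        return TTestResult(float("nan"), float("nan"), float("nan"), "", False)


def _stars(p: float) -> str:
    # strict inequalities: p exactly 0.05 gets no star
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def students_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variant: str = "equal-variance",
) -> TTestResult:
    """Two-tailed two-sample t-test (classical equal-variance or Welch).

    The t statistic is computed explicitly so degenerate spreads are handled
    deterministically: zero pooled variance gives p = 1 for equal means and
    p = 0 otherwise.  Samples with fewer than two values yield a
    not-computable result rather than an exception.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return TTestResult.not_computable()
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variant == "equal-variance":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
    elif variant == "welch":
        se2a, se2b = va / na, vb / nb
        se = math.sqrt(se2a + se2b)
        if se > 0:
            df = (se2a + se2b) ** 2 / (
                se2a**2 / (na - 1) + se2b**2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    else:
        raise ValueError(f"unknown t-test variant: {variant!r}")
    if se == 0:
        if diff == 0:
            return TTestResult(0.0, float(df), 1.0, "")
        t = math.inf if diff > 0 else -math.inf
        return TTestResult(t, float(df), 0.0, "**")
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, _stars(p))


@dataclass(frozen=True)
class TradeoffRecord:
    """Paired affinity/stability effect of one mutation in one context."""

    mutation: Mutation
    context_variant: str
    delta_ka: float = float("nan")
    sd_delta_ka: float = float("nan")
    p_ka: float = float("nan")
    stars_ka: str = ""
    affinity_class: AffinityClass = AffinityClass.NOT_COMPUTABLE
    delta_tm: float = float("nan")
    sd_delta_tm: float = float("nan")
    p_tm: float = float("nan")
    stars_tm: str = ""
    stability_class: StabilityClass = StabilityClass.NOT_COMPUTABLE

    @property
    def label(self) -> str:
        """Evolved residue + Kabat position, the figure-style name (e.g. K98)."""
        return f"{self.mutation.to_aa}{self.mutation.position}"


def _classify(delta: float, p: float, kind) -> "AffinityClass | StabilityClass":
    if p >= 0.05 or delta == 0:
        return kind.NEUTRAL
    if kind is AffinityClass:
        return kind.ENHANCING if delta > 0 else kind.REDUCING
    return kind.STABILIZING if delta > 0 else kind.DESTABILIZING


def reversion_effect(
    parent_summary: "AffinitySummary | TmEstimate",
    reverted_summary: "AffinitySummary | TmEstimate",
    mutation: Mutation,
    t_variant: str = "equal-variance",
) -> TradeoffRecord:
    """One trade-off axis from a (context, reversion-construct) summary pair.

    ``mutation`` is the forward mutation being probed; deltas are
    context-variant minus reverted, so a positive delta means the mutation
    contributes positively to that property.
    """
    is_affinity = isinstance(parent_summary, AffinitySummary)
    if is_affinity != isinstance(reverted_summary, AffinitySummary):
        raise ValueError("summaries must be of the same kind")
    kwargs: dict = {}
    if is_affinity:
        if not (parent_summary.measurable and reverted_summary.measurable):
            return TradeoffRecord(mutation=mutation, context_variant=parent_summary.variant)
        tt = students_t_test(
            parent_summary.replicate_kas, reverted_summary.replicate_kas, t_variant
        )
        delta = parent_summary.mean_ka - reverted_summary.mean_ka
        sd = math.hypot(parent_summary.sd_ka, reverted_summary.sd_ka)
        kwargs.update(
            delta_ka=delta,
            sd_delta_ka=sd,
            p_ka=tt.p_two_tailed,
            stars_ka=tt.stars,
            affinity_class=(
                _classify(delta, tt.p_two_tailed, AffinityClass)
                if tt.computable
                else AffinityClass.NOT_COMPUTABLE
            ),
        )
        context = parent_summary.variant
    else:
        tt = students_t_test(
            parent_summary.replicate_tms, reverted_summary.replicate_tms, t_variant
        )
        delta = parent_summary.tm_app - reverted_summary.tm_app
        sd = math.hypot(parent_summary.sd, reverted_summary.sd)
        kwargs.update(
            delta_tm=delta,
            sd_delta_tm=sd,
            p_tm=tt.p_two_tailed,
            stars_tm=tt.stars,
            stability_class=(
                _classify(delta, tt.p_two_tailed, StabilityClass)
                if tt.computable
                else StabilityClass.NOT_COMPUTABLE
            ),
        )
        context = parent_summary.variant
    return TradeoffRecord(mutation=mutation, context_variant=context, **kwargs)


def _merge(aff: TradeoffRecord | None, stab: TradeoffRecord | None) -> TradeoffRecord:
    base = aff or stab
    assert base is not None
    kwargs = dict(mutation=base.mutation, context_variant=base.context_variant)
    if aff is not None:
        kwargs.update(
            delta_ka=aff.delta_ka, sd_delta_ka=aff.sd_delta_ka, p_ka=aff.p_ka,
            stars_ka=aff.stars_ka, affinity_class=aff.affinity_class,
        )
    if stab is not None:
        kwargs.update(
            delta_tm=stab.delta_tm, sd_delta_tm=stab.sd_delta_tm, p_tm=stab.p_tm,
            stars_tm=stab.stars_tm, stability_class=stab.stability_class,
        )
    return TradeoffRecord(**kwargs)


def build_tradeoff_table(
    affinity: Mapping[str, AffinitySummary],
    stability: Mapping[str, TmEstimate],
    lineage: Mapping[str, VhVariant],
    t_variant: str = "equal-variance",
) -> list[TradeoffRecord]:
    """Assemble one TradeoffRecord per single-reversion construct in the lineage.

    A reversion construct is any variant whose single mutation-from-parent is
    the reverse of a mutation its parent context carries relative to the
    wild type; the record is keyed by the forward mutation and the context.
    Records are ordered by context then Kabat position.
    """
    records: dict[tuple[str, str], dict[str, TradeoffRecord]] = {}
    for v in lineage.values():
        if v.parent is None or len(v.mutations_from_parent) != 1:
            continue
        reversion = v.mutations_from_parent[0]
        forward = reversion.reverse()
        context = v.parent
        key = (context, str(forward.position))
        slot = records.setdefault(key, {"mutation": forward, "context": context})
        if context in affinity and v.name in affinity:
            if "aff" in slot:
                raise ValueError(f"duplicate affinity summary for {v.name}")
            slot["aff"] = reversion_effect(
                affinity[context], affinity[v.name], forward, t_variant
            )
        if context in stability and v.name in stability:
            if "stab" in slot:
                raise ValueError(f"duplicate stability summary for {v.name}")
            slot["stab"] = reversion_effect(
                stability[context], stability[v.name], forward, t_variant
            )
    out = []
    for key in sorted(
        records,
        key=lambda k: (k[0], records[k]["mutation"].position._key()),
    ):
        slot = records[key]
        if "aff" in slot or "stab" in slot:
            out.append(_merge(slot.get("aff"), slot.get("stab")))
    return out


def records_to_frame(records: Sequence[TradeoffRecord]) -> pd.DataFrame:
    """Flat table (CSV-ready) of the trade-off quadrant data."""
    return pd.DataFrame(
        [
            {
                "context": r.context_variant,
                "mutation": str(r.mutation),
                "label": r.label,
                "delta_ka_per_M": r.delta_ka,
                "sd_delta_ka": r.sd_delta_ka,
                "p_ka": r.p_ka,
                "stars_ka": r.stars_ka,
                "affinity_class": r.affinity_class.value,
                "delta_tm_C": r.delta_tm,
                "sd_delta_tm": r.sd_delta_tm,
                "p_tm": r.p_tm,
                "stars_tm": r.stars_tm,
                "stability_class": r.stability_class.value,
            }
            for r in records
        ]
    )
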