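"""Dinucleotide substrate-preference analysis of deaminase editors.

Cytosine sites are pooled across a sgRNA panel by protospacer position; a
position class enters the analysis if at least one of its sites reaches a
normalized C->T frequency of 0.8.  The retained sites are grouped by the
base immediately 5' (NC: AC/CC/GC/TC) or 3' (CN: CA/CC/CG/CT) of the edited
cytosine and group differences are tested by classical fixed-effects
one-way ANOVA (p < 0.05 significant).  Orderings are printed in the
conventional "TC/AC>CC>GC" style, with "/" joining contexts whose means
tie within a tolerance and "N.S." marking non-significant panels.

Values entering the ANOVA are normalized frequencies, which makes sites
comparable across sgRNAs of different absolute activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from cbekit.coords import TargetSite, context_at
from cbekit.windows import FreqMap

__all__ = [
    "SiteObservation",
    "PreferenceResult",
    "AnovaUndefinedError",
    "select_sites",
    "group_by_context",
    "one_way_anova",
    "preference_ordering",
    "analyze_preference",
]

UPSTREAM_CONTEXTS = ("AC", "CC", "GC", "TC")
DOWNSTREAM_CONTEXTS = ("CA", "CC", "CG", "CT")


class AnovaUndefinedError(ValueError):
    """Raised when the ANOVA preconditions (>=2 groups, within-group df >= 1) fail."""


@dataclass(frozen=True)
class SiteObservation:
    """One cytosine site retained for preference analysis."""

    sgrna_id: str
    cp: int
    upstream_di: str
    downstream_di: str
    value: float  # normalized C->T frequency


@dataclass
class PreferenceResult:
    """ANOVA outcome and ranking for one editor in one direction (NC or CN)."""

    editor_id: str
    direction: str  # "NC" or "CN"
    groups: Dict[str, List[float]]
    F: Optional[float]
    p: Optional[float]
    ordering: str
    significant: bool
    flags: List[str] = field(default_factory=list)


def select_sites(
    panel: Sequence[Tuple[TargetSite, FreqMap]], min_norm: float = 0.8
) -> List[SiteObservation]:
    """Pick all C sites at position classes showing high-efficiency editing.

    ``panel`` pairs each sgRNA's :class:`~cbekit.coords.TargetSite` with its
    normalized C->T frequency map.  A protospacer position qualifies when at
    least one site there (across the panel) has a normalized frequency of at
    least ``min_norm``; every site at qualifying positions is returned with
    its dinucleotide contexts.
    """
    by_cp: Dict[int, List[SiteObservation]] = {}
    for site, norm in panel:
        if norm is None:
            continue
        for cp, v in norm.items():
            if v is None:
                continue
            ctx = context_at(site, cp)
            by_cp.setdefault(cp, []).append(
                SiteObservation(site.site_id, cp, ctx.upstream_di, ctx.downstream_di, v)
            )
    selected: List[SiteObservation] = []
    for cp, obs in sorted(by_cp.items()):
        if any(o.value >= min_norm for o in obs):
            selected.extend(obs)
    return selected


def group_by_context(
    sites: Sequence[SiteObservation], direction: str = "NC"
) -> Dict[str, List[float]]:
    """Partition site values by upstream (NC) or downstream (CN) dinucleotide.

    All four contexts appear in the result; empty ones carry an empty list
    (n = 0) and are excluded from the ANOVA by the caller.
    """
    if direction == "NC":
        contexts, attr = UPSTREAM_CONTEXTS, "upstream_di"
    elif direction == "CN":
        contexts, attr = DOWNSTREAM_CONTEXTS, "downstream_di"
    else:
        raise ValueError(f"direction must be 'NC' or 'CN', got {direction!r}")
    groups: Dict[str, List[float]] = {c: [] for c in contexts}
    for o in sites:
        groups[getattr(o, attr)].append(o.value)
    return groups


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    F = (SSB/(k-1)) / (SSW/(N-k)) with p from the F(k-1, N-k) distribution.
    When the within-group sum of squares is zero with unequal means, F is
    infinite and p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    if k < 2 or n_total - k < 1:
        raise AnovaUndefinedError(
            f"ANOVA needs >= 2 non-empty groups and within-group df >= 1 "
            f"(got k={k}, N={n_total})"
        )
    means = [g.mean() for g in groups]
    ssw = sum(float(((g - m) ** 2).sum()) for g, m in zip(groups, means))
    if ssw == 0.0:
        if max(means) == min(means):
            return 0.0, 1.0
        return math.inf, 0.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def preference_ordering(
    groups: Dict[str, List[float]],
    p_value: Optional[float],
    tie_tol: float = 0.05,
    alpha: float = 0.05,
) -> str:
    """Rank contexts by mean value, tying within ``tie_tol``.

    Produces strings like ``"TC/AC>CC>GC"``; returns ``"N.S."`` when the
    ANOVA p-value is missing or not below ``alpha``.
    """
    if p_value is None or p_value >= alpha:
        return "N.S."
    means = [(c, float(np.mean(v))) for c, v in groups.items() if v]
    means.sort(key=lambda t: (-t[1], t[0]))
    tiers: List[List[str]] = []
    tier_head: Optional[float] = None
    for c, m in means:
        if tier_head is not None and tier_head - m < tie_tol:
            tiers[-1].append(c)
        else:
            tiers.append([c])
            tier_head = m
    return ">".join("/".join(t) for t in tiers)


def analyze_preference(
    editor_id: str,
    panel: Sequence[Tuple[TargetSite, FreqMap]],
    min_norm: float = 0.8,
    tie_tol: float = 0.05,
    alpha: float = 0.05,
) -> Dict[str, PreferenceResult]:
    """Run the full preference analysis in both directions for one editor.

    Returns ``{"NC": ..., "CN": ...}``.  Degenerate panels (no qualifying
    sites, or too few groups/values for the ANOVA) yield flagged results
    with ``F`` and ``p`` set to ``None``.
    """
    sites = select_sites(panel, min_norm=min_norm)
    out: Dict[str, PreferenceResult] = {}
    for direction in ("NC", "CN"):
        groups = group_by_context(sites, direction)
        flags: List[str] = []
        if not sites:
            flags.append("no site reached the normalized-frequency cutoff")
        F: Optional[float] = None
        p: Optional[float] = None
        try:
            F, p = one_way_anova(list(groups.values()))
        except AnovaUndefinedError as exc:
            flags.append(str(exc))
        if F is not None and math.isinf(F):
            flags.append("zero within-group variance with unequal means")
        ordering = preference_ordering(groups, p, tie_tol=tie_tol, alpha=alpha)
        out[direction] = PreferenceResult(
            editor_id=editor_id,
            direction=direction,
            groups=groups,
            F=F,
            p=p,
            ordering=ordering,
            significant=(p is not None and p < alpha),
            flags=flags,
        )
    return out
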