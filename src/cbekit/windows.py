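"""Editing-window statistics and editor classification.

For each sgRNA the C->T frequency profile is normalized so its best-edited
cytosine equals 1; the comprehensive editing window (CEW) of an editor is
the set of protospacer positions whose mean normalized efficiency across a
sgRNA panel strictly exceeds 0.6.  The per-sgRNA editing scope is the set
of C positions edited at >= 40% raw frequency.  Editors are labeled by
where their CEW sits on the protospacer:

* FSCBE -- forward-shifted, editing the PAM-distal low-numbered region,
  like the classic position 4-8 window;
* BSCBE -- backward-shifted, window starting at position >= 7;
* BRCBE -- broad-range, spanning both regions.

The decision thresholds are configurable; the defaults reproduce the
grouping of known editors by their published windows (e.g. 1-8 forward,
9-13 backward, 1-14 broad).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

__all__ = [
    "WindowResult",
    "ClassifierConfig",
    "normalize_sgrna",
    "editing_scope",
    "comprehensive_window",
    "classify_editor",
    "analyze_editor",
]

FreqMap = Dict[int, Optional[float]]


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the window-location decision rule."""

    broad_span: int = 12  # CEW spanning this many positions => broad
    broad_lo: int = 2  # ... or reaching both cp <= broad_lo
    broad_hi: int = 9  # ... and cp >= broad_hi
    backward_min_start: int = 7  # otherwise, CEW starting here => backward


@dataclass
class WindowResult:
    """Window analysis of one editor across a sgRNA panel."""

    editor_id: str
    normalized: Dict[str, FreqMap]  # per sgRNA
    scope: Dict[str, Set[int]]  # per sgRNA, >= 40% raw rule
    mean_norm: Dict[int, float]  # per cp, across sgRNAs with a C there
    cew: Set[int]
    class_label: str
    no_editing_sgrnas: List[str] = field(default_factory=list)

    @property
    def cew_span(self) -> Optional[Tuple[int, int]]:
        return (min(self.cew), max(self.cew)) if self.cew else None


def normalize_sgrna(freqs: FreqMap, min_signal: float = 0.0) -> Optional[FreqMap]:
    """Scale a sgRNA's C->T frequencies so the highest-edited C equals 1.

    Missing positions stay missing.  Returns ``None`` (the "no editing"
    flag) when every frequency is missing or the maximum does not exceed
    ``min_signal``; such sgRNAs are excluded from CEW averaging.
    """
    values = [v for v in freqs.values() if v is not None]
    if not values:
        return None
    peak = max(values)
    if peak <= min_signal or peak == 0.0:
        return None
    return {cp: (None if v is None else v / peak) for cp, v in freqs.items()}


def editing_scope(freqs: FreqMap, threshold: float = 0.40) -> Set[int]:
    """C positions with raw editing frequency at or above ``threshold`` (>= 40%)."""
    return {cp for cp, v in freqs.items() if v is not None and v >= threshold}


def comprehensive_window(
    normalized_maps: Iterable[Optional[FreqMap]], threshold: float = 0.6
) -> Tuple[Set[int], Dict[int, float]]:
    """Mean normalized efficiency per position and the CEW (mean > ``threshold``).

    Each position's mean runs only over sgRNAs that actually carry a
    cytosine (a non-missing value) there; positions covered by no sgRNA are
    absent from the output rather than zero.  CEW membership is strict.
    """
    sums: Dict[int, float] = {}
    ns: Dict[int, int] = {}
    for norm in normalized_maps:
        if norm is None:
            continue
        for cp, v in norm.items():
            if v is None:
                continue
            sums[cp] = sums.get(cp, 0.0) + v
            ns[cp] = ns.get(cp, 0) + 1
    means = {cp: sums[cp] / ns[cp] for cp in sums}
    cew = {cp for cp, m in means.items() if m > threshold}
    return cew, means


def classify_editor(cew: Set[int], config: ClassifierConfig = ClassifierConfig()) -> str:
    """Label an editor by its CEW location: FSCBE, BSCBE, BRCBE or inactive."""
    if not cew:
        return "inactive"
    a, b = min(cew), max(cew)
    if (b - a + 1) >= config.broad_span or (a <= config.broad_lo and b >= config.broad_hi):
        return "BRCBE"
    if a >= config.backward_min_start:
        return "BSCBE"
    return "FSCBE"


def analyze_editor(
    editor_id: str,
    raw_freqs: Dict[str, FreqMap],
    scope_threshold: float = 0.40,
    cew_threshold: float = 0.6,
    min_signal: float = 0.0,
    classifier: ClassifierConfig = ClassifierConfig(),
) -> WindowResult:
    """Full window analysis for one editor given per-sgRNA raw C->T frequencies."""
    normalized: Dict[str, FreqMap] = {}
    no_editing: List[str] = []
    for sg, freqs in raw_freqs.items():
        norm = normalize_sgrna(freqs, min_signal=min_signal)
        if norm is None:
            no_editing.append(sg)
        else:
            normalized[sg] = norm
    scope = {sg: editing_scope(freqs, scope_threshold) for sg, freqs in raw_freqs.items()}
    cew, means = comprehensive_window(normalized.values(), cew_threshold)
    label = classify_editor(cew, classifier)
    return WindowResult(
        editor_id=editor_id,
        normalized=normalized,
        scope=scope,
        mean_norm=means,
        cew=cew,
        class_label=label,
        no_editing_sgrnas=no_editing,
    )
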