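"""On/off-target specificity scoring.

Specificity of an editor at a locus pair is computed from the single best-
edited cytosine on each side: with onC^h and offC^h the highest C->T
conversion frequencies in the on-target and off-target quantification
windows,

    specificity = (onC^h - offC^h) / onC^h.

Two categorical outcomes replace the number: ``"no-activity"`` when the
on-target shows no obvious activity (onC^h below a configurable floor,
default 5%), and ``"N.Sp."`` (no specificity) when the off-target is edited
more strongly than the on-target (the raw, negative value is still
recorded).  Each off-target is scored in its own protospacer coordinate
window; when one on-target has several off-targets, per-pair scores are
primary and the minimum is reported as the worst-case summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from cbekit.quantify import ConversionTable

__all__ = [
    "SpecificityResult",
    "highest_conversion",
    "specificity_score",
    "specificity_panel",
]


@dataclass
class SpecificityResult:
    """Specificity of one editor for one (on-target, off-target) pair."""

    editor_id: str
    on_site_id: str
    off_site_id: str
    on_ch: Optional[float]
    off_ch: Optional[float]
    value: Optional[float]
    label: str  # "numeric", "N.Sp." or "no-activity"


def highest_conversion(
    table: ConversionTable, min_depth: int = 1
) -> Optional[Tuple[float, int]]:
    """Highest C->T frequency over covered reference-C window positions.

    Returns ``(frequency, cp)``, taking the smallest cp on ties; ``None``
    when no reference cytosine has sufficient depth (no measurable
    activity).
    """
    freqs = table.c_to_t_frequencies(min_depth=min_depth)
    best: Optional[Tuple[float, int]] = None
    for cp in sorted(freqs):
        v = freqs[cp]
        if v is None:
            continue
        if best is None or v > best[0]:
            best = (v, cp)
    return best


def specificity_score(
    editor_id: str,
    on_site_id: str,
    off_site_id: str,
    on_ch: Optional[float],
    off_ch: Optional[float],
    min_activity: float = 0.05,
) -> SpecificityResult:
    """Apply the (onC^h - offC^h)/onC^h rule with its categorical escapes."""
    if on_ch is None or on_ch < min_activity:
        return SpecificityResult(
            editor_id, on_site_id, off_site_id, on_ch, off_ch, None, "no-activity"
        )
    if off_ch is None:
        off_ch = 0.0  # an uncovered off-target shows no activity
    value = (on_ch - off_ch) / on_ch
    label = "N.Sp." if off_ch > on_ch else "numeric"
    return SpecificityResult(editor_id, on_site_id, off_site_id, on_ch, off_ch, value, label)


def specificity_panel(
    editor_id: str,
    on_tables: Dict[str, ConversionTable],
    off_tables: Dict[str, ConversionTable],
    pairs: Sequence[Tuple[str, str]],
    min_activity: float = 0.05,
    min_depth: int = 1,
) -> Tuple[List[SpecificityResult], Dict[str, SpecificityResult]]:
    """Score every (on-target, off-target) pair and summarize per on-target.

    ``pairs`` lists ``(on_site_id, off_site_id)``; every id must resolve to
    a table.  Returns the per-pair results plus, for each on-target, the
    worst (minimum-specificity) result across its off-target panel.
    """
    results: List[SpecificityResult] = []
    for on_id, off_id in pairs:
        if on_id not in on_tables:
            raise KeyError(f"on-target {on_id} has no conversion table")
        if off_id not in off_tables:
            raise KeyError(f"off-target {off_id} has no conversion table")
        on_best = highest_conversion(on_tables[on_id], min_depth)
        off_best = highest_conversion(off_tables[off_id], min_depth)
        results.append(
            specificity_score(
                editor_id,
                on_id,
                off_id,
                on_best[0] if on_best else None,
                off_best[0] if off_best else None,
                min_activity,
            )
        )
    worst: Dict[str, SpecificityResult] = {}
    for r in results:
        cur = worst.get(r.on_site_id)
        if cur is None or _worse(r, cur):
            worst[r.on_site_id] = r
    return results, worst


def _worse(a: SpecificityResult, b: SpecificityResult) -> bool:
    """Order results by badness: no-activity first, then lower specificity."""
    rank = {"no-activity": 0, "N.Sp.": 1, "numeric": 2}
    if rank[a.label] != rank[b.label]:
        return rank[a.label] < rank[b.label]
    if a.value is None or b.value is None:
        return False
    return a.value < b.value
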