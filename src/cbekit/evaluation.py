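"""Seeded end-to-end validation studies on synthetic data.

Each function runs the full simulate -> quantify -> analyze path under a
named study condition and reports a summary statistic with known expected
behavior: recovery of the closed-form expected conversion frequency,
recovery of a designed comprehensive editing window, classification
accuracy for the window archetypes, substrate-preference detection for a
GC-averse editor, type-I error of the preference ANOVA under a null with
no context effect, and recovery of a designed specificity value.

These studies double as the package's acceptance checks; problem sizes
(reads per sample, sgRNAs per panel, replicate counts) are the defaults a
desk-scale validation uses and are arguments everywhere.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cbekit.coords import TargetSite, protospacer_base, quantification_window
from cbekit.preference import analyze_preference
from cbekit.quantify import ConversionTable, quantify_reads
from cbekit.simulate import (
    EditorProfile,
    make_profile_library,
    make_sgrna_panel,
    make_synthetic_site,
    simulate_reads,
)
from cbekit.specificity import highest_conversion, specificity_score
from cbekit.windows import analyze_editor, normalize_sgrna

__all__ = [
    "simulate_and_quantify",
    "binomial_frequency_maps",
    "frequency_recovery_max_z",
    "cew_recovery_rate",
    "classification_accuracy",
    "preference_recovery_rate",
    "anova_null_type_i_rate",
    "specificity_recovery",
]

# panel with two+ cytosines per even protospacer position and balanced
# upstream contexts; used by the preference studies
_PREF_COVER = tuple(range(2, 15, 2))


def _seed(base: int, *idx: int) -> int:
    h = base
    for i in idx:
        h = (h * 1000003 + i + 1) % 2**31
    return h


def simulate_and_quantify(
    site: TargetSite, profile: EditorProfile, n_reads: int, seed: int
) -> Tuple[ConversionTable, Dict[int, float]]:
    """One sample through the read-level pipeline; returns (table, truth map)."""
    batch, truth = simulate_reads(site, profile, n_reads, seed)
    table = quantify_reads(batch, site).tables["default"]
    return table, truth.expected


def frequency_recovery_max_z(
    seed: int, n_reads: int = 20000, profiles: Optional[Sequence[EditorProfile]] = None
) -> float:
    """Worst |z| between observed and expected T frequency over all Cs and archetypes.

    z is in binomial standard deviations at the observed depth; under a
    correct pipeline it stays within ~4 for every reference cytosine.
    """
    profiles = list(profiles) if profiles is not None else make_profile_library()
    # a site carrying Cs in all four upstream contexts, in and out of the windows
    site = make_synthetic_site(
        "recovery", _seed(seed, 1), {2: "A", 4: "C", 6: "G", 8: "T", 10: "A", 12: "G", 14: "T"}
    )
    worst = 0.0
    for p_i, profile in enumerate(profiles):
        table, expected = simulate_and_quantify(site, profile, n_reads, _seed(seed, 2, p_i))
        freqs = table.c_to_t_frequencies()
        for cp, exp in expected.items():
            obs = freqs[cp]
            depth = int(table.depth[table.cps.index(cp)])
            sd = max(np.sqrt(exp * (1 - exp) / depth), 1.0 / depth)
            worst = max(worst, abs(obs - exp) / sd)
    return worst


def cew_recovery_rate(
    seed: int,
    n_seeds: int = 20,
    n_sgrnas: int = 9,
    n_reads: int = 10000,
    target_window: Tuple[int, int] = (4, 8),
) -> float:
    """Fraction of seeded runs whose CEW equals the designed window exactly.

    The simulated editor edits positions ``target_window`` at 0.6 and every
    other window cytosine at 0.05, over a panel of ``n_sgrnas`` sgRNAs.
    """
    lo, hi = target_window
    hits = 0
    for r in range(n_seeds):
        # every guide targets at least one C inside the designed window, as
        # a real editing panel would; normalization is per guide
        panel = make_sgrna_panel(
            n_sgrnas, _seed(seed, 3, r), anchors=tuple(range(lo, hi + 1))
        )
        p_edit = {}
        for cp in quantification_window(panel[0]):
            p_edit[cp] = 0.6 if lo <= cp <= hi else 0.05
        profile = EditorProfile("cew_probe", p_edit)
        raw = {}
        for s_i, site in enumerate(panel):
            table, _ = simulate_and_quantify(site, profile, n_reads, _seed(seed, 4, r, s_i))
            raw[site.site_id] = table.c_to_t_frequencies()
        res = analyze_editor("cew_probe", raw)
        hits += res.cew == set(range(lo, hi + 1))
    return hits / n_seeds


def classification_accuracy(
    seed: int, n_runs: int = 100, n_sgrnas: int = 4, n_reads: int = 10000
) -> Dict[str, float]:
    """Per-archetype fraction of runs recovering the designed editor class."""
    expected = {"forward": "FSCBE", "backward": "BSCBE", "broad": "BRCBE"}
    profiles = [p for p in make_profile_library() if p.editor_id in expected]
    hits = {p.editor_id: 0 for p in profiles}
    for r in range(n_runs):
        panel = make_sgrna_panel(n_sgrnas, _seed(seed, 5, r))
        for p_i, profile in enumerate(profiles):
            raw = {}
            for s_i, site in enumerate(panel):
                table, _ = simulate_and_quantify(
                    site, profile, n_reads, _seed(seed, 6, r, p_i, s_i)
                )
                raw[site.site_id] = table.c_to_t_frequencies()
            res = analyze_editor(profile.editor_id, raw)
            hits[profile.editor_id] += res.class_label == expected[profile.editor_id]
    return {e: h / n_runs for e, h in hits.items()}


def preference_recovery_rate(
    seed: int, n_runs: int = 100, n_sgrnas: int = 6, n_reads: int = 10000
) -> float:
    """Fraction of runs where the GC-averse editor shows significant NC
    preference (p < 0.05) with GC ranked last."""
    profile = next(p for p in make_profile_library() if p.editor_id == "gc_averse")
    hits = 0
    for r in range(n_runs):
        panel = make_sgrna_panel(
            n_sgrnas, _seed(seed, 7, r), cover=_PREF_COVER, per_position=3
        )
        pairs = []
        for s_i, site in enumerate(panel):
            table, _ = simulate_and_quantify(site, profile, n_reads, _seed(seed, 8, r, s_i))
            norm = normalize_sgrna(table.c_to_t_frequencies())
            if norm is not None:
                pairs.append((site, norm))
        res = analyze_preference(profile.editor_id, pairs)["NC"]
        gc_last = res.ordering.split(">")[-1] == "GC" if res.significant else False
        hits += res.significant and gc_last
    return hits / n_runs


def binomial_frequency_maps(
    panel: Sequence[TargetSite], p_true: float, depth: int, seed: int
) -> List[Dict[int, float]]:
    """Frequency-level sampler: binomial conversion counts at every reference C.

    Draws ``Binomial(depth, p_true)/depth`` independently per cytosine --
    the sampling distribution the read-level pipeline produces at a fixed
    placed depth -- without materializing reads.  Used for replicate-heavy
    calibration studies such as the ANOVA null.
    """
    rng = np.random.default_rng(seed)
    maps = []
    for site in panel:
        freqs: Dict[int, float] = {}
        for cp in quantification_window(site):
            if protospacer_base(site, cp) == "C":
                freqs[cp] = rng.binomial(depth, p_true) / depth
        maps.append(freqs)
    return maps


def anova_null_type_i_rate(
    seed: int,
    n_replicates: int = 1000,
    n_sgrnas: int = 6,
    depth: int = 10000,
    p_true: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the NC-preference ANOVA when no context effect exists.

    Every cytosine edits at the same probability regardless of context, so
    a nominal-level test should flag ~``alpha`` of replicates.  Sampling is
    frequency-level (see :func:`binomial_frequency_maps`); the panel is
    fixed across replicates.
    """
    panel = make_sgrna_panel(n_sgrnas, _seed(seed, 9), cover=_PREF_COVER, per_position=3)
    false_hits = 0
    for r in range(n_replicates):
        maps = binomial_frequency_maps(panel, p_true, depth, _seed(seed, 10, r))
        pairs = []
        for site, freqs in zip(panel, maps):
            norm = normalize_sgrna(freqs)
            if norm is not None:
                pairs.append((site, norm))
        res = analyze_preference("null", pairs)["NC"]
        false_hits += res.significant
    return false_hits / n_replicates


def specificity_recovery(
    seed: int, n_reads: int = 20000, q_on: float = 0.5, q_off: float = 0.1
) -> Dict[str, float]:
    """Recover a designed specificity from a simulated on/off-target pair.

    Both loci carry one edited cytosine (no sequencing error), so the true
    specificity is (q_on - q_off)/q_on.
    """
    on_site = make_synthetic_site("on", _seed(seed, 11), {6: "A"})
    off_site = make_synthetic_site("off", _seed(seed, 12), {6: "T"})
    on_prof = EditorProfile("probe", {6: q_on}, seq_error=0.0)
    off_prof = EditorProfile("probe", {6: q_off}, seq_error=0.0)
    on_tbl, _ = simulate_and_quantify(on_site, on_prof, n_reads, _seed(seed, 13))
    off_tbl, _ = simulate_and_quantify(off_site, off_prof, n_reads, _seed(seed, 14))
    on_ch = highest_conversion(on_tbl)[0]
    off_ch = highest_conversion(off_tbl)[0]
    result = specificity_score("probe", "on", "off", on_ch, off_ch)
    return {
        "on_ch": on_ch,
        "off_ch": off_ch,
        "specificity": result.value,
        "true_specificity": (q_on - q_off) / q_on,
    }
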