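"""Synthetic amplicon-read generator with known editing ground truth.

Emulates the statistical structure of targeted amplicon sequencing of base-
edited loci: independent per-read, per-position C->T conversion whose
probability depends on protospacer position and on the dinucleotide context
of the cytosine, followed by uniform substitution sequencing error, Phred
qualities, and optional sample barcodes.  Every run records the exact
expected T frequency at each reference cytosine, so downstream quantification
can be validated against a closed form rather than against itself.

Modeling choices: conversion events are independent across positions within
a read (no processivity/co-editing), sequencing error is substitution-only
and uniform (no indels), and context modulation acts through the upstream
dinucleotide by default with an optional downstream map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, NamedTuple, Optional, Tuple

import numpy as np

from cbekit.coords import (
    NotACytosineError,
    TargetSite,
    context_at,
    cp_to_amplicon_index,
    protospacer_base,
    quantification_window,
    revcomp,
)

__all__ = [
    "EditorProfile",
    "SimTruth",
    "FastqRead",
    "ReadBatch",
    "effective_edit_probability",
    "expected_t_frequency",
    "simulate_reads",
    "make_profile_library",
    "make_synthetic_site",
    "make_sgrna_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# ASCII code -> base index (A=0 C=1 G=2 T=3), 255 for anything else
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _COMP[_x] = _y


class FastqRead(NamedTuple):
    """A single FASTQ record (Phred+33 quality string)."""

    id: str
    seq: str
    qual: str


@dataclass
class ReadBatch:
    """Dense in-memory container for equal-length reads.

    ``seq`` and ``qual`` are ``(n_reads, read_len)`` uint8 arrays of ASCII
    codes; this is the fast interchange format between the simulator and the
    quantifier.  Iteration yields :class:`FastqRead` records.
    """

    seq: np.ndarray
    qual: np.ndarray
    id_prefix: str = "read"

    def __post_init__(self) -> None:
        if self.seq.shape != self.qual.shape:
            raise ValueError("seq and qual arrays must have identical shapes")

    def __len__(self) -> int:
        return self.seq.shape[0]

    @property
    def read_len(self) -> int:
        return self.seq.shape[1]

    def __iter__(self) -> Iterator[FastqRead]:
        for i in range(len(self)):
            yield FastqRead(
                f"{self.id_prefix}:{i}",
                self.seq[i].tobytes().decode(),
                self.qual[i].tobytes().decode(),
            )

    def to_fastq(self, handle) -> None:
        """Write standard 4-line FASTQ records to a text handle."""
        for rec in self:
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")

    @classmethod
    def from_records(cls, records: List[FastqRead], id_prefix: str = "read") -> "ReadBatch":
        if not records:
            return cls(np.zeros((0, 0), np.uint8), np.zeros((0, 0), np.uint8), id_prefix)
        lens = {len(r.seq) for r in records}
        if len(lens) != 1:
            raise ValueError("ReadBatch requires equal-length reads")
        seq = np.frombuffer("".join(r.seq for r in records).encode(), np.uint8)
        qual = np.frombuffer("".join(r.qual for r in records).encode(), np.uint8)
        n = len(records)
        return cls(seq.reshape(n, -1).copy(), qual.reshape(n, -1).copy(), id_prefix)


@dataclass
class EditorProfile:
    """Generative model of a base editor for simulation.

    ``p_edit`` maps protospacer positions to per-read deamination
    probabilities (absent positions edit at 0).  ``context_mult`` scales the
    probability by the upstream dinucleotide (NC) of each cytosine;
    ``downstream_mult`` optionally does the same for the downstream (CN)
    dinucleotide and defaults to no effect.  Products exceeding 1 are
    clipped, and clip events are counted in the run's :class:`SimTruth`.
    """

    editor_id: str
    p_edit: Dict[int, float]
    context_mult: Dict[str, float] = field(
        default_factory=lambda: {"AC": 1.0, "CC": 1.0, "GC": 1.0, "TC": 1.0}
    )
    downstream_mult: Dict[str, float] = field(
        default_factory=lambda: {"CA": 1.0, "CC": 1.0, "CG": 1.0, "CT": 1.0}
    )
    seq_error: float = 0.001
    base_quality: int = 37
    low_q_tail_len: int = 0
    low_q_score: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.seq_error < 0.25:
            raise ValueError("seq_error must lie in [0, 0.25)")
        for cp, p in self.p_edit.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_edit[{cp}]={p} outside [0, 1]")
        for m in (*self.context_mult.values(), *self.downstream_mult.values()):
            if m < 0:
                raise ValueError("context multipliers must be >= 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated sample: expected T frequency per C."""

    site_id: str
    n_reads: int
    seed: int
    expected: Dict[int, float]
    clipped_positions: int = 0


def effective_edit_probability(
    profile: EditorProfile, site: TargetSite, cp: int
) -> Tuple[float, bool]:
    """Per-read C->T probability at ``cp`` after context modulation.

    Returns ``(q, clipped)`` where ``q = min(1, p_edit * NC_mult * CN_mult)``.
    Raises :class:`NotACytosineError` off reference cytosines.
    """
    ctx = context_at(site, cp)  # raises if not a C
    raw = (
        profile.p_edit.get(cp, 0.0)
        * profile.context_mult.get(ctx.upstream_di, 1.0)
        * profile.downstream_mult.get(ctx.downstream_di, 1.0)
    )
    return min(1.0, raw), raw > 1.0


def expected_t_frequency(profile: EditorProfile, site: TargetSite, cp: int) -> float:
    """Exact expected fraction of reads showing T at a reference cytosine.

    With edit probability ``q`` and uniform substitution error ``e``, a read
    shows T when the base was edited and not mis-read (``q(1-e)``) or
    unedited but mis-read to T (``(1-q)e/3``).
    """
    q, _ = effective_edit_probability(profile, site, cp)
    e = profile.seq_error
    return q * (1.0 - e) + (1.0 - q) * (e / 3.0)


def simulate_reads(
    site: TargetSite,
    profile: EditorProfile,
    n_reads: int,
    seed: int,
    barcode: str = "",
    flank5: int = 20,
    flank3: int = 0,
) -> Tuple[ReadBatch, SimTruth]:
    """Simulate amplicon reads spanning the quantification window.

    Reads cover the window plus ``flank5``/``flank3`` extra reference bases
    (the 5' flank gives the placement seed an edit-free anchor).  Per read
    and reference cytosine, C->T conversion fires independently with the
    context-modulated probability; every base (barcode included) is then
    substituted uniformly to one of the other three bases with probability
    ``seq_error``.  Deterministic for a fixed seed.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    window = quantification_window(site)
    idxs = [cp_to_amplicon_index(site, cp) for cp in window]
    lo, hi = min(idxs), max(idxs) + 1
    lo -= flank5
    hi += flank3
    if lo < 0 or hi > len(site.amplicon_seq):
        raise ValueError(
            f"site {site.site_id}: amplicon too short for flanks ({flank5}, {flank3})"
        )
    ref = np.frombuffer(site.amplicon_seq[lo:hi].encode(), np.uint8)
    seq = np.tile(ref, (n_reads, 1))

    expected: Dict[int, float] = {}
    clipped = 0
    for cp, idx in zip(window, idxs):
        if protospacer_base(site, cp) != "C":
            continue
        q, was_clipped = effective_edit_probability(profile, site, cp)
        clipped += int(was_clipped)
        expected[cp] = expected_t_frequency(profile, site, cp)
        if q > 0 and n_reads > 0:
            col = idx - lo
            # C->T on the protospacer strand is G->A on the forward strand
            # of a minus-strand site.
            product = ord("T") if site.strand == "+" else ord("A")
            hit = rng.random(n_reads) < q
            seq[hit, col] = product

    if barcode:
        bc = np.frombuffer(barcode.encode(), np.uint8)
        seq = np.concatenate([np.tile(bc, (n_reads, 1)), seq], axis=1)

    e = profile.seq_error
    if e > 0 and n_reads > 0:
        err = rng.random(seq.shape) < e
        shift = rng.integers(1, 4, size=int(err.sum()))
        codes = _CODE[seq[err]]
        seq[err] = _BASES[(codes + shift) % 4]

    qual = np.full(seq.shape, 33 + profile.base_quality, np.uint8)
    if profile.low_q_tail_len > 0:
        qual[:, seq.shape[1] - profile.low_q_tail_len :] = 33 + profile.low_q_score

    batch = ReadBatch(seq, qual, id_prefix=f"{profile.editor_id}:{site.site_id}")
    truth = SimTruth(site.site_id, n_reads, seed, expected, clipped)
    return batch, truth


# ---------------------------------------------------------------------------
# built-in archetypes and designed synthetic loci


def make_profile_library() -> List[EditorProfile]:
    """Built-in editor archetypes spanning the observed window classes.

    ``forward`` edits protospacer positions 1-8 (the classic 5' window),
    ``backward`` 9-13, ``broad`` 1-14, and ``gc_averse`` edits 2-12 with a
    strongly down-weighted GC context -- mirroring the window shapes and
    context biases reported for natural deaminase editors.
    """
    flat = {"AC": 1.0, "CC": 1.0, "GC": 1.0, "TC": 1.0}
    return [
        EditorProfile("forward", {cp: 0.6 for cp in range(1, 9)}, dict(flat)),
        EditorProfile("backward", {cp: 0.6 for cp in range(9, 14)}, dict(flat)),
        EditorProfile("broad", {cp: 0.5 for cp in range(1, 15)}, dict(flat)),
        EditorProfile(
            "gc_averse",
            {cp: 0.7 for cp in range(2, 13)},
            {"AC": 1.0, "CC": 0.7, "GC": 0.1, "TC": 1.0},
        ),
    ]


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    letters = np.frombuffer(alphabet.encode(), np.uint8)
    return rng.choice(letters, size=n).tobytes().decode()


def make_synthetic_site(
    site_id: str,
    seed: int,
    c_positions: Optional[Dict[int, str]] = None,
    strand: str = "+",
    pad: int = 25,
) -> TargetSite:
    """Construct a synthetic target site with cytosines at chosen positions.

    ``c_positions`` maps protospacer positions (1..20) to the desired
    upstream base of the C placed there; all other protospacer bases are
    drawn from A/G/T so cytosine placement is fully controlled.  The PAM is
    AGG and flanks are random with a C-free 5' anchor for read placement.
    """
    rng = np.random.default_rng(seed)
    c_positions = c_positions or {}
    proto = list(_random_seq(rng, 20, "AGT"))
    for cp, up in sorted(c_positions.items()):
        if not 1 <= cp <= 20:
            raise ValueError(f"c_positions key {cp} outside protospacer 1..20")
        proto[cp - 1] = "C"
        if cp >= 2 and proto[cp - 2] != "C":
            proto[cp - 2] = up
    upstream = _random_seq(rng, 10 + pad)
    downstream = _random_seq(rng, 10 + pad)
    amplicon = upstream + "".join(proto) + "AGG" + downstream
    if strand == "-":
        start = len(amplicon) - 1 - len(upstream)
        return TargetSite(site_id, revcomp(amplicon), start, "-")
    return TargetSite(site_id, amplicon, len(upstream), "+")


def make_sgrna_panel(
    n_sgrnas: int,
    seed: int,
    cover: Tuple[int, ...] = tuple(range(1, 15)),
    per_position: int = 1,
    context_cycle: Tuple[str, ...] = ("A", "C", "G", "T"),
    anchors: Tuple[int, ...] = (),
    id_prefix: str = "sg",
) -> List[TargetSite]:
    """Design a panel of synthetic sgRNA target sites with guaranteed C coverage.

    Every position in ``cover`` receives a cytosine in ``per_position``
    distinct panel members (round-robin), with upstream context bases cycled
    through ``context_cycle`` so contexts are balanced across the panel.
    When ``anchors`` is given, every sgRNA additionally carries a cytosine
    at one anchor position (round-robin over the anchors) -- a panel of
    guides that all target at least one cytosine inside a region of
    interest, as real editing panels do.  Within one sgRNA no two designed
    Cs are adjacent as long as the positions assigned to it are at least 2
    apart (always true for ``per_position == 1`` and ``n_sgrnas >= 2``; use
    even-spaced ``cover`` for larger ``per_position``); incidental
    adjacency only shifts the realized upstream context, which is always
    re-read from the final sequence.
    """
    if n_sgrnas < 1:
        raise ValueError("n_sgrnas must be >= 1")
    if per_position > n_sgrnas:
        raise ValueError("per_position cannot exceed n_sgrnas")
    plans: List[Dict[int, str]] = [dict() for _ in range(n_sgrnas)]
    k = 0
    for j, cp in enumerate(sorted(cover)):
        for r in range(per_position):
            plans[(j + r) % n_sgrnas][cp] = context_cycle[k % len(context_cycle)]
            k += 1
    for i, plan in enumerate(plans):
        if anchors and not any(cp in plan for cp in anchors):
            plan[anchors[i % len(anchors)]] = context_cycle[k % len(context_cycle)]
            k += 1
    return [
        make_synthetic_site(f"{id_prefix}{i + 1}", (seed * 1000 + i) % 2**31, plan)
        for i, plan in enumerate(plans)
    ]
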