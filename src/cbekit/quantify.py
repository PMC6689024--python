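"""From FASTQ reads to per-position base-conversion frequency tables.

The stages mirror a standard amplicon-editing workflow: demultiplex by exact
barcode prefix, trim low-quality 3' tails (Phred < 15 by default), place
each read on the amplicon by an exact 20-mer seed match on either strand,
reject placements with too many mismatches, and tabulate observed bases at
every quantification-window position on the protospacer strand.  The
conversion frequency at a position is simply

    frequency = base conversion reads / total reads

i.e. count(to_base) / depth.  Positions with zero depth are reported as
missing, never as 0%.

Only substitutions are tabulated; reads that would require indels to place
(or that run off the amplicon) are discarded and counted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from cbekit.coords import (
    TargetSite,
    WindowBoundsError,
    cp_to_amplicon_index,
    protospacer_base,
    quantification_window,
    revcomp,
)
from cbekit.simulate import FastqRead, ReadBatch, _CODE, _COMP

__all__ = [
    "ConversionTable",
    "QuantifyResult",
    "Placement",
    "AmbiguousSeedError",
    "NOT_APPLICABLE",
    "demultiplex",
    "quality_trim",
    "place_read",
    "tabulate",
    "conversion_frequency",
    "quantify_reads",
]

_BASE_ORDER = "ACGT"
_PHRED_OFFSET = 33


class _NotApplicable:
    """Typed marker for a frequency query at a position with a different reference base."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_APPLICABLE"


NOT_APPLICABLE = _NotApplicable()


class AmbiguousSeedError(ValueError):
    """Raised when a read's placement seed matches the amplicon more than once."""


@dataclass(frozen=True)
class Placement:
    """Accepted read placement: forward-strand offset and original orientation."""

    offset: int
    strand: str  # '+' read as given, '-' read was reverse-complemented
    mismatches: int


@dataclass
class ConversionTable:
    """Per-position observed base counts for one sample x target site.

    ``counts[i]`` holds A/C/G/T counts (protospacer strand) at window
    position ``cps[i]``; ``ref_bases[i]`` is the protospacer-strand
    reference base there.
    """

    site_id: str
    sample_id: str
    cps: List[int]
    ref_bases: List[str]
    counts: np.ndarray  # (n_positions, 4) int64, columns A,C,G,T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.cps), 4):
            raise ValueError("counts must be (n_positions, 4)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def _pos(self, cp: int) -> int:
        try:
            return self.cps.index(cp)
        except ValueError:
            raise WindowBoundsError(f"cp={cp} outside quantification window") from None

    def frequency(self, cp: int, from_base: str, to_base: str):
        """count(to_base)/depth at ``cp``; ``None`` if depth is 0;
        :data:`NOT_APPLICABLE` if the reference base differs from ``from_base``."""
        i = self._pos(cp)
        if self.ref_bases[i] != from_base:
            return NOT_APPLICABLE
        d = int(self.counts[i].sum())
        if d == 0:
            return None
        return float(self.counts[i, _BASE_ORDER.index(to_base)]) / d

    def c_to_t_frequencies(self, min_depth: int = 1) -> Dict[int, Optional[float]]:
        """C->T frequency at every reference-C window position (None when
        depth < ``min_depth``)."""
        out: Dict[int, Optional[float]] = {}
        for i, cp in enumerate(self.cps):
            if self.ref_bases[i] != "C":
                continue
            d = int(self.counts[i].sum())
            out[cp] = float(self.counts[i, 3]) / d if d >= max(min_depth, 1) else None
        return out


def conversion_frequency(table: ConversionTable, cp: int, from_base: str, to_base: str):
    """Functional alias for :meth:`ConversionTable.frequency`."""
    return table.frequency(cp, from_base, to_base)


@dataclass
class QuantifyResult:
    """Per-sample conversion tables plus read accounting for one run."""

    tables: Dict[str, ConversionTable]
    assigned: Dict[str, int]  # reads demultiplexed into each sample
    placed: Dict[str, int] = field(default_factory=dict)  # reads tabulated
    unassigned: int = 0
    discarded_short: int = 0
    unplaced: int = 0
    ambiguous: int = 0
    rejected_mismatch: int = 0


# ---------------------------------------------------------------------------
# per-read operations


def demultiplex(
    reads: Iterable[FastqRead], barcode_map: Dict[str, str]
) -> Tuple[Dict[str, List[FastqRead]], int]:
    """Assign reads to samples by exact barcode prefix match, stripping the barcode.

    An empty ``barcode_map`` passes everything through under sample
    ``"default"``.  Returns (per-sample reads, unassigned count).
    """
    _check_barcodes(barcode_map)
    if not barcode_map:
        return {"default": list(reads)}, 0
    bc_len = len(next(iter(barcode_map)))
    out: Dict[str, List[FastqRead]] = {s: [] for s in barcode_map.values()}
    unassigned = 0
    for read in reads:
        sample = barcode_map.get(read.seq[:bc_len])
        if sample is None:
            unassigned += 1
        else:
            out[sample].append(FastqRead(read.id, read.seq[bc_len:], read.qual[bc_len:]))
    return out, unassigned


def _check_barcodes(barcode_map: Dict[str, str]) -> None:
    if not barcode_map:
        return
    lens = {len(b) for b in barcode_map}
    if len(lens) != 1:
        raise ValueError("barcodes must all have the same length")
    if len(set(barcode_map)) != len(barcode_map):  # dict keys are unique by construction
        raise ValueError("duplicate barcodes")


def quality_trim(read: FastqRead, q_min: int = 15) -> FastqRead:
    """Trim the read's 3' tail of bases with Phred quality below ``q_min``."""
    if len(read.seq) != len(read.qual):
        raise ValueError(f"read {read.id}: sequence/quality length mismatch")
    keep = len(read.seq)
    while keep > 0 and ord(read.qual[keep - 1]) - _PHRED_OFFSET < q_min:
        keep -= 1
    return FastqRead(read.id, read.seq[:keep], read.qual[:keep])


def place_read(
    read: Union[FastqRead, str],
    site: TargetSite,
    seed_len: int = 20,
    max_mm: float = 0.2,
) -> Optional[Placement]:
    """Place a read on the amplicon (either strand) by exact seed match.

    The first ``seed_len`` bases of the read (or of its reverse complement,
    for reverse-strand placements) must match the amplicon exactly; the
    full-length alignment is then accepted if its mismatch fraction is at
    most ``max_mm``.  Returns ``None`` for unplaced or rejected reads and
    raises :class:`AmbiguousSeedError` when the seed matches more than once.
    """
    seq = read if isinstance(read, str) else read.seq
    if len(seq) < seed_len:
        return None
    amp = site.amplicon_seq
    seed = seq[:seed_len]
    candidates: List[Tuple[str, str, int]] = []  # (strand, reference, offset on it)
    for strand, ref in (("+", amp), ("-", revcomp(amp))):
        start = 0
        while True:
            i = ref.find(seed, start)
            if i < 0:
                break
            candidates.append((strand, ref, i))
            start = i + 1
    if len(candidates) > 1:
        raise AmbiguousSeedError(f"seed matches amplicon {len(candidates)} times")
    if not candidates:
        return None
    strand, ref, off = candidates[0]
    if off + len(seq) > len(ref):
        return None  # would run off the amplicon
    mm = sum(a != b for a, b in zip(seq, ref[off : off + len(seq)]))
    if mm > max_mm * len(seq):
        return None
    fwd_off = off if strand == "+" else len(amp) - off - len(seq)
    return Placement(fwd_off, strand, mm)


def tabulate(
    placed: Sequence[Tuple[int, str]], site: TargetSite, sample_id: str = "default"
) -> ConversionTable:
    """Count observed bases at window positions from placed, forward-oriented reads.

    ``placed`` holds ``(offset, sequence)`` pairs in amplicon forward
    orientation.  Counts are re-oriented to the protospacer strand for
    minus-strand sites.
    """
    window = quantification_window(site)
    idxs = np.array([cp_to_amplicon_index(site, cp) for cp in window])
    counts = np.zeros((len(window), 4), dtype=np.int64)
    for offset, seq in placed:
        arr = _CODE[np.frombuffer(seq.encode(), np.uint8)]
        inside = (idxs >= offset) & (idxs < offset + len(seq))
        codes = arr[idxs[inside] - offset]
        ok = codes < 4
        rows = np.nonzero(inside)[0][ok]
        counts[rows, codes[ok]] += 1
    return _finalize_table(counts, site, sample_id, window)


def _finalize_table(
    fwd_counts: np.ndarray, site: TargetSite, sample_id: str, window: List[int]
) -> ConversionTable:
    # counts were accumulated on the amplicon forward strand; complement the
    # base axis for minus-strand sites so everything reads protospacer-strand
    counts = fwd_counts[:, ::-1] if site.strand == "-" else fwd_counts
    refs = [protospacer_base(site, cp) for cp in window]
    return ConversionTable(site.site_id, sample_id, list(window), refs, counts.copy())


# ---------------------------------------------------------------------------
# batch engine


def _seed_index(site: TargetSite, seed_len: int) -> Dict[bytes, Optional[Tuple[str, int]]]:
    """Exact-match lookup: seed k-mer -> unique (strand, offset) or None if ambiguous."""
    index: Dict[bytes, Optional[Tuple[str, int]]] = {}
    for strand, seq in (("+", site.amplicon_seq), ("-", revcomp(site.amplicon_seq))):
        b = seq.encode()
        for i in range(len(b) - seed_len + 1):
            k = b[i : i + seed_len]
            index[k] = None if k in index else (strand, i)
    return index


def _quantify_batch(
    batch: ReadBatch,
    site: TargetSite,
    barcode_map: Dict[str, str],
    q_min: int,
    seed_len: int,
    max_mm: float,
) -> QuantifyResult:
    """Vectorized demultiplex -> trim -> place -> tabulate over a ReadBatch."""
    _check_barcodes(barcode_map)
    n, L = batch.seq.shape
    window = quantification_window(site)
    idxs = np.array([cp_to_amplicon_index(site, cp) for cp in window])
    amp_b = site.amplicon_seq.encode()
    rc_b = revcomp(site.amplicon_seq).encode()
    seed_idx = _seed_index(site, seed_len)

    if barcode_map:
        bc_len = len(next(iter(barcode_map)))
        sample_of = np.full(n, -1, dtype=np.int64)
        samples = list(dict.fromkeys(barcode_map.values()))
        for bc, s in barcode_map.items():
            arr = np.frombuffer(bc.encode(), np.uint8)
            sample_of[(batch.seq[:, :bc_len] == arr).all(axis=1)] = samples.index(s)
        seq = batch.seq[:, bc_len:]
        qual = batch.qual[:, bc_len:]
    else:
        samples = ["default"]
        sample_of = np.zeros(n, dtype=np.int64)
        seq, qual = batch.seq, batch.qual
    unassigned = int((sample_of < 0).sum())

    # 3' trim: keep the longest prefix ending in a base with q >= q_min
    good = qual - _PHRED_OFFSET >= q_min
    rev_good = good[:, ::-1]
    any_good = rev_good.any(axis=1)
    keep_len = np.where(any_good, seq.shape[1] - rev_good.argmax(axis=1), 0)

    result = QuantifyResult(
        tables={},
        assigned={s: int((sample_of == i).sum()) for i, s in enumerate(samples)},
        placed={s: 0 for s in samples},
        unassigned=unassigned,
    )
    counts = {s: np.zeros((len(window), 4), dtype=np.int64) for s in samples}

    too_short = keep_len < seed_len
    result.discarded_short = int((too_short & (sample_of >= 0)).sum())
    active = (~too_short) & (sample_of >= 0)

    # group reads by (placement, keep_len) and score/tabulate per group
    seed_bytes = seq[:, :seed_len].tobytes()
    groups: Dict[Tuple[str, int, int], List[int]] = defaultdict(list)
    for i in np.nonzero(active)[0]:
        k = seed_bytes[i * seed_len : (i + 1) * seed_len]
        hit = seed_idx.get(k, "absent")
        if hit == "absent":
            result.unplaced += 1
        elif hit is None:
            result.ambiguous += 1
        else:
            strand, off = hit
            groups[(strand, off, int(keep_len[i]))].append(i)

    for (strand, off, klen), rows in groups.items():
        ref_b = amp_b if strand == "+" else rc_b
        if off + klen > len(ref_b):
            result.unplaced += len(rows)
            continue
        sub = seq[rows, :klen]
        ref = np.frombuffer(ref_b[off : off + klen], np.uint8)
        mm = (sub != ref).sum(axis=1)
        ok = mm <= max_mm * klen
        result.rejected_mismatch += int((~ok).sum())
        rows_arr = np.asarray(rows)[ok]
        if rows_arr.size == 0:
            continue
        sub = seq[rows_arr, :klen]
        if strand == "-":
            # re-orient to the amplicon forward strand
            sub = _COMP[sub[:, ::-1]]
            fwd_off = len(amp_b) - off - klen
        else:
            fwd_off = off
        inside = (idxs >= fwd_off) & (idxs < fwd_off + klen)
        cols = idxs[inside] - fwd_off
        codes = _CODE[sub[:, cols]]
        pos_rows = np.nonzero(inside)[0]
        for s_i, s in enumerate(samples):
            sel = sample_of[rows_arr] == s_i
            if not sel.any():
                continue
            result.placed[s] += int(sel.sum())
            block = codes[sel]
            for j, prow in enumerate(pos_rows):
                bc = np.bincount(block[:, j], minlength=5)[:4]
                counts[s][prow] += bc

    for s in samples:
        result.tables[s] = _finalize_table(counts[s], site, s, window)
    return result


def quantify_reads(
    reads: Union[ReadBatch, Iterable[FastqRead]],
    site: TargetSite,
    barcode_map: Optional[Dict[str, str]] = None,
    q_min: int = 15,
    seed_len: int = 20,
    max_mm: float = 0.2,
) -> QuantifyResult:
    """Run the full quantification stage for one target site.

    Accepts a :class:`ReadBatch` (vectorized fast path) or any iterable of
    :class:`FastqRead`; both paths implement the same pipeline and yield
    identical tables.
    """
    barcode_map = barcode_map or {}
    if isinstance(reads, ReadBatch):
        return _quantify_batch(reads, site, barcode_map, q_min, seed_len, max_mm)

    per_sample, unassigned = demultiplex(reads, barcode_map)
    result = QuantifyResult(
        tables={},
        assigned={s: len(r) for s, r in per_sample.items()},
        placed={s: 0 for s in per_sample},
        unassigned=unassigned,
    )
    for sample, sample_reads in per_sample.items():
        placed: List[Tuple[int, str]] = []
        for read in sample_reads:
            trimmed = quality_trim(read, q_min)
            if len(trimmed.seq) < seed_len:
                result.discarded_short += 1
                continue
            try:
                p = place_read(trimmed, site, seed_len=seed_len, max_mm=max_mm)
            except AmbiguousSeedError:
                result.ambiguous += 1
                continue
            if p is None:
                # distinguish seedless from mismatch-rejected for accounting
                seedless = _no_seed_hit(trimmed.seq, site, seed_len)
                if seedless:
                    result.unplaced += 1
                else:
                    result.rejected_mismatch += 1
                continue
            oriented = trimmed.seq if p.strand == "+" else revcomp(trimmed.seq)
            placed.append((p.offset, oriented))
            result.placed[sample] += 1
        result.tables[sample] = tabulate(placed, site, sample)
    return result


def _no_seed_hit(seq: str, site: TargetSite, seed_len: int) -> bool:
    amp = site.amplicon_seq
    return amp.find(seq[:seed_len]) < 0 and amp.find(revcomp(seq)[:seed_len]) < 0
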