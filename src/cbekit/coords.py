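"""Protospacer coordinate system and the amplicon quantification window.

Positions are counted on the protospacer strand: 1..20 run 5'->3' along the
protospacer, the PAM occupies 21..23 (for the canonical 20-nt spacer /
3-nt NGG PAM), positions 3' of the PAM continue 24, 25, ... and positions
5' of the protospacer are -1, -2, ... with -1 immediately adjacent to 1.
There is no position 0.

Base conversion is quantified over a fixed window running from 30 nt
upstream of the PAM's 5' end (i.e. the 20-nt protospacer plus 10 further
upstream bases) through 10 nt downstream of the PAM's 3' end -- 43
positions in the canonical geometry.

All conversion calls are made on the protospacer strand: a C->T event on a
minus-strand protospacer appears as G->A on the amplicon forward strand and
is re-oriented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TargetSite",
    "SequenceContext",
    "InvalidPositionError",
    "WindowBoundsError",
    "NotACytosineError",
    "quantification_window",
    "cp_to_amplicon_index",
    "amplicon_index_to_cp",
    "context_at",
    "protospacer_base",
    "load_fasta",
    "load_sites",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Bases upstream of the PAM included in the window (covers the protospacer
# plus extra 5' context) and bases downstream of the PAM.
WINDOW_UPSTREAM_OF_PAM = 30
WINDOW_DOWNSTREAM_OF_PAM = 10


class InvalidPositionError(ValueError):
    """Raised for protospacer position 0, which does not exist."""


class WindowBoundsError(ValueError):
    """Raised when a window position falls outside the amplicon."""


class NotACytosineError(ValueError):
    """Raised when a context query targets a non-C protospacer base."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceContext:
    """Dinucleotide context of an edited cytosine, read on the protospacer strand.

    ``upstream_di`` is the 5' neighbour followed by the C ("NC");
    ``downstream_di`` is the C followed by its 3' neighbour ("CN").
    """

    upstream_di: str
    downstream_di: str

    def __post_init__(self) -> None:
        if len(self.upstream_di) != 2 or self.upstream_di[1] != "C":
            raise ValueError(f"upstream_di must be 'NC', got {self.upstream_di!r}")
        if len(self.downstream_di) != 2 or self.downstream_di[0] != "C":
            raise ValueError(f"downstream_di must be 'CN', got {self.downstream_di!r}")


@dataclass(frozen=True)
class TargetSite:
    """An amplicon reference with an annotated protospacer and PAM.

    Parameters
    ----------
    site_id
        Identifier for the target locus.
    amplicon_seq
        Uppercase ACGT amplicon reference (forward strand).
    protospacer_start
        0-based index of protospacer position 1 on the amplicon forward
        strand.  For a minus-strand protospacer this is the index of the
        forward-strand base that pairs with protospacer position 1.
    strand
        ``"+"`` if the protospacer reads 5'->3' along the amplicon forward
        strand, ``"-"`` otherwise.
    pam_len, protospacer_len
        PAM and protospacer lengths (3 and 20 for SpCas9).
    """

    site_id: str
    amplicon_seq: str
    protospacer_start: int
    strand: str = "+"
    pam_len: int = 3
    protospacer_len: int = 20

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pam_len < 1 or self.protospacer_len < 1:
            raise ValueError("pam_len and protospacer_len must be >= 1")
        bad = set(self.amplicon_seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"amplicon_seq contains non-ACGT characters {sorted(bad)}; "
                "ambiguity codes are not accepted in references"
            )
        # Every window position must fall on the amplicon.
        for cp in quantification_window(self, validate=False):
            idx = cp_to_amplicon_index(self, cp, validate=False)
            if not 0 <= idx < len(self.amplicon_seq):
                raise WindowBoundsError(
                    f"site {self.site_id}: window position cp={cp} maps to "
                    f"amplicon index {idx}, outside [0, {len(self.amplicon_seq)})"
                )

    @property
    def window(self) -> List[int]:
        return quantification_window(self)

    def window_amplicon_span(self) -> Tuple[int, int]:
        """Half-open forward-strand amplicon interval covered by the window."""
        idxs = [cp_to_amplicon_index(self, cp) for cp in quantification_window(self)]
        return min(idxs), max(idxs) + 1


def quantification_window(site: TargetSite, validate: bool = True) -> List[int]:
    """Ordered protospacer positions of the quantification window.

    Runs from ``WINDOW_UPSTREAM_OF_PAM`` nt 5' of the PAM through
    ``WINDOW_DOWNSTREAM_OF_PAM`` nt 3' of it, in 5'->3' protospacer order;
    length is always ``30 + pam_len + 10``.  For the canonical geometry this
    is cp -10..-1, 1..33 (43 positions).
    """
    n_upstream_of_protospacer = WINDOW_UPSTREAM_OF_PAM - site.protospacer_len
    first = -n_upstream_of_protospacer if n_upstream_of_protospacer > 0 else 1
    last = site.protospacer_len + site.pam_len + WINDOW_DOWNSTREAM_OF_PAM
    cps = [cp for cp in range(first, last + 1) if cp != 0]
    if n_upstream_of_protospacer <= 0:
        # Protospacers of 30+ nt fill the upstream span entirely.
        cps = [cp for cp in cps if cp > site.protospacer_len - WINDOW_UPSTREAM_OF_PAM]
    if validate:
        for cp in cps:
            idx = cp_to_amplicon_index(site, cp, validate=False)
            if not 0 <= idx < len(site.amplicon_seq):
                raise WindowBoundsError(
                    f"window position cp={cp} outside amplicon for site {site.site_id}"
                )
    return cps


def cp_to_amplicon_index(site: TargetSite, cp: int, validate: bool = True) -> int:
    """Map a protospacer position to a 0-based forward-strand amplicon index.

    On the plus strand cp=1 maps to ``protospacer_start`` and consecutive
    positions (skipping the nonexistent 0) map to consecutive indices; on
    the minus strand the mapping is mirrored.
    """
    if cp == 0:
        raise InvalidPositionError("protospacer position 0 does not exist")
    step = cp - 1 if cp > 0 else cp  # collapse the missing 0
    idx = site.protospacer_start + step if site.strand == "+" else site.protospacer_start - step
    if validate and not 0 <= idx < len(site.amplicon_seq):
        raise WindowBoundsError(
            f"cp={cp} maps to amplicon index {idx}, outside site {site.site_id}"
        )
    return idx


def amplicon_index_to_cp(site: TargetSite, idx: int) -> int:
    """Inverse of :func:`cp_to_amplicon_index`."""
    if not 0 <= idx < len(site.amplicon_seq):
        raise WindowBoundsError(f"amplicon index {idx} outside site {site.site_id}")
    step = idx - site.protospacer_start if site.strand == "+" else site.protospacer_start - idx
    return step + 1 if step >= 0 else step


def protospacer_base(site: TargetSite, cp: int) -> str:
    """Protospacer-strand base at a position (complemented for minus-strand sites)."""
    base = site.amplicon_seq[cp_to_amplicon_index(site, cp)]
    return base if site.strand == "+" else base.translate(_COMPLEMENT)


def context_at(site: TargetSite, cp: int) -> SequenceContext:
    """Dinucleotide contexts (NC and CN) of the cytosine at ``cp``.

    Both dinucleotides are read on the protospacer strand; for minus-strand
    sites they are reverse-complemented from the amplicon forward strand.
    Raises :class:`NotACytosineError` if the protospacer-strand base is not C.
    """
    base = protospacer_base(site, cp)
    if base != "C":
        raise NotACytosineError(
            f"protospacer-strand base at cp={cp} of site {site.site_id} is {base}, not C"
        )
    idx = cp_to_amplicon_index(site, cp)
    if site.strand == "+":
        if idx == 0 or idx + 1 >= len(site.amplicon_seq):
            raise WindowBoundsError(f"context at cp={cp} runs off the amplicon")
        up = site.amplicon_seq[idx - 1]
        down = site.amplicon_seq[idx + 1]
    else:
        if idx + 1 >= len(site.amplicon_seq) or idx == 0:
            raise WindowBoundsError(f"context at cp={cp} runs off the amplicon")
        up = site.amplicon_seq[idx + 1].translate(_COMPLEMENT)
        down = site.amplicon_seq[idx - 1].translate(_COMPLEMENT)
    return SequenceContext(upstream_di=up + "C", downstream_di="C" + down)


# ---------------------------------------------------------------------------
# reference I/O


def load_fasta(path: str | Path) -> Dict[str, str]:
    """Read a (possibly line-wrapped) multi-record FASTA into {id: sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _pam_matches(observed: str, pam: str) -> bool:
    return len(observed) == len(pam) and all(
        p == "N" or p == o for p, o in zip(pam, observed)
    )


def load_sites(sites_tsv: str | Path, fasta_path: str | Path) -> List[TargetSite]:
    """Build :class:`TargetSite` objects from a site annotation TSV + FASTA.

    The TSV has columns ``site_id, fasta_id, protospacer_seq, pam_seq,
    strand``; the protospacer is located in the referenced FASTA record by
    exact match (an error if it occurs zero or more than one time) and the
    annotated PAM (IUPAC N allowed) is checked in place.
    """
    import pandas as pd

    refs = load_fasta(fasta_path)
    df = pd.read_csv(sites_tsv, sep="\t", dtype=str)
    required = {"site_id", "fasta_id", "protospacer_seq", "pam_seq", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table {sites_tsv} lacks columns {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        if row.fasta_id not in refs:
            raise ValueError(f"site {row.site_id}: FASTA record {row.fasta_id} not found")
        amp = refs[row.fasta_id]
        proto = row.protospacer_seq.upper()
        strand = row.strand
        query = proto if strand == "+" else revcomp(proto)
        hits = _find_all(amp, query)
        if len(hits) != 1:
            raise ValueError(
                f"site {row.site_id}: protospacer matches amplicon "
                f"{len(hits)} times (need exactly 1)"
            )
        m = hits[0]
        if strand == "+":
            start = m
            pam_obs = amp[m + len(proto) : m + len(proto) + len(row.pam_seq)]
        else:
            start = m + len(proto) - 1
            pam_obs = revcomp(amp[m - len(row.pam_seq) : m])
        if not _pam_matches(pam_obs, row.pam_seq.upper()):
            raise ValueError(
                f"site {row.site_id}: PAM mismatch (annotated {row.pam_seq}, "
                f"found {pam_obs})"
            )
        sites.append(
            TargetSite(
                site_id=row.site_id,
                amplicon_seq=amp,
                protospacer_start=start,
                strand=strand,
                pam_len=len(row.pam_seq),
                protospacer_len=len(proto),
            )
        )
    return sites


def _find_all(haystack: str, needle: str) -> List[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1
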