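"""Direct-repeat (RARE) motif scanning over aligned promoter pairs.

Retinoic-acid response elements are direct repeats (DR) of the hexameric
nuclear-receptor half-site PuG(G/T)TCA (IUPAC ``RGKTCA``), classically with
1, 2 or 5 intervening bases (DR1/DR2/DR5, the spacings preferred by
RAR/RXR heterodimers).  This module finds half-sites and direct repeats on
either strand of an upstream promoter region, optionally restricts hits to
cross-species conserved blocks of a pairwise alignment, and reports each
hit's offset relative to the region's 3′ anchor (TSS or ATG).

Coordinate convention: offsets are 1-based distances upstream of the
anchor, reported negative, measured to the hit's 5′-most base *on the plus
strand of the promoter sequence* (−1 is the base immediately before the
anchor).  A minus-strand repeat is a repeat on the reverse complement,
reported at the plus-strand position of its window start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotifParams",
    "PromoterPair",
    "MotifHit",
    "ConservedBlock",
    "ScanReport",
    "reverse_complement",
    "find_half_sites",
    "find_direct_repeats",
    "align_promoters",
    "conserved_blocks",
    "scan_promoter_pair",
    "read_promoter_pair",
    "write_promoter_pair",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN-", "TGCAYRMKVBHDSWN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifParams:
    """Half-site consensus and repeat geometry.

    ``half_site_consensus`` is an IUPAC-degenerate string (an ``N`` in the
    *sequence* never matches any consensus letter).  Other RARE families
    can be reached by changing the consensus, the spacer set or the
    per-half-site mismatch budget rather than by special cases.
    """

    half_site_consensus: str = "RGKTCA"
    spacers: frozenset[int] = frozenset({1, 2, 5})
    max_mismatches_per_half_site: int = 0
    strands: str = "both"  # "forward" or "both"

    def __post_init__(self) -> None:
        if len(self.half_site_consensus) < 4:
            raise ValueError("consensus must be at least 4 bases")
        bad = set(self.half_site_consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid consensus characters: {sorted(bad)}")
        if any(s < 0 for s in self.spacers):
            raise ValueError("spacers must be non-negative")
        if self.strands not in ("forward", "both"):
            raise ValueError("strands must be 'forward' or 'both'")
        object.__setattr__(self, "spacers", frozenset(self.spacers))

    @property
    def width(self) -> int:
        return len(self.half_site_consensus)


@dataclass
class PromoterPair:
    """Upstream regions of two orthologous promoters, optionally aligned.

    Sequences run 5′→3′ and end at the anchor (default TSS), so the last
    base is at offset −1.  ``aligned_a``/``aligned_b`` are equal-length
    gapped versions (``-`` gaps) whose ungapped content must equal
    ``seq_a``/``seq_b``.
    """

    species_a: str
    species_b: str
    seq_a: str
    seq_b: str
    aligned_a: str | None = None
    aligned_b: str | None = None
    anchor: str = "TSS"
    region_length: int | None = None

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{name} contains invalid characters: {sorted(bad)}")
        if (self.aligned_a is None) != (self.aligned_b is None):
            raise ValueError("provide both aligned sequences or neither")
        if self.aligned_a is not None:
            self.aligned_a = self.aligned_a.upper()
            self.aligned_b = self.aligned_b.upper()
            if len(self.aligned_a) != len(self.aligned_b):
                raise ValueError("aligned sequences must have equal length")
            if self.aligned_a.replace("-", "") != self.seq_a:
                raise ValueError("aligned_a does not match seq_a")
            if self.aligned_b.replace("-", "") != self.seq_b:
                raise ValueError("aligned_b does not match seq_b")
        if self.region_length is None:
            self.region_length = max(len(self.seq_a), len(self.seq_b))

    @property
    def aligned(self) -> bool:
        return self.aligned_a is not None


@dataclass
class MotifHit:
    """One direct repeat.

    ``offset`` follows the module's coordinate convention; ``half_site_1``
    and ``half_site_2`` are the observed hexamers in repeat order on the
    hit's strand.  ``conserved``/``aligned_partner_offset`` are filled by
    :func:`scan_promoter_pair`.
    """

    species: str
    offset: int
    strand: str
    half_site_1: str
    half_site_2: str
    spacer: int
    dr_class: str
    mismatches: int = 0
    conserved: bool | None = None
    aligned_partner_offset: int | None = None

    @property
    def footprint(self) -> int:
        return len(self.half_site_1) + self.spacer + len(self.half_site_2)


@dataclass(frozen=True)
class ConservedBlock:
    """Maximal run of alignment columns covered by qualifying windows."""

    start_col: int  # 1-based, inclusive
    end_col: int  # 1-based, inclusive
    length: int
    identity: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return arr


def _mismatch_profile(seq: str, consensus: str) -> np.ndarray:
    """mismatches[i] = number of consensus positions violated by the
    window starting at i (length len(seq) − width + 1)."""
    w = len(consensus)
    n = len(seq)
    if n < w:
        return np.zeros(0, dtype=int)
    arr = _encode(seq)
    mism = np.zeros(n - w + 1, dtype=int)
    for j, c in enumerate(consensus.upper()):
        allowed = np.frombuffer("".join(sorted(IUPAC[c])).encode(), dtype=np.uint8)
        window = arr[j : j + n - w + 1]
        mism += (~np.isin(window, allowed)).astype(int)
    return mism


def _check_alphabet(seq: str) -> None:
    bad = [i + 1 for i, ch in enumerate(seq.upper()) if ch not in "ACGTN"]
    if bad:
        shown = bad[:10]
        raise ValueError(f"invalid characters at positions {shown}" + (" ..." if len(bad) > 10 else ""))


def find_half_sites(seq: str, params: MotifParams | None = None) -> list[tuple[int, str, str, int]]:
    """All half-site matches as (position, strand, observed, mismatches).

    Positions are 1-based on the plus strand of ``seq``; a minus-strand
    entry means the reverse complement of the window matches the
    consensus, and ``observed`` is the hexamer as read on the minus
    strand.
    """
    params = params or MotifParams()
    _check_alphabet(seq)
    seq = seq.upper()
    w = params.width
    hits = []
    plus = _mismatch_profile(seq, params.half_site_consensus)
    for i in np.nonzero(plus <= params.max_mismatches_per_half_site)[0]:
        hits.append((int(i) + 1, "+", seq[i : i + w], int(plus[i])))
    if params.strands == "both":
        rc = reverse_complement(seq)
        minus = _mismatch_profile(rc, params.half_site_consensus)
        n = len(seq)
        for j in np.nonzero(minus <= params.max_mismatches_per_half_site)[0]:
            i = n - int(j) - w  # plus-strand start of the window
            hits.append((i + 1, "-", rc[j : j + w], int(minus[j])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _repeats_one_strand(
    seq: str, params: MotifParams
) -> list[tuple[int, str, str, int, int]]:
    """(start0, half1, half2, spacer, mismatches) on the given sequence's
    own plus strand."""
    w = params.width
    mism = _mismatch_profile(seq, params.half_site_consensus)
    ok = mism <= params.max_mismatches_per_half_site
    out = []
    for spacer in sorted(params.spacers):
        step = w + spacer
        if len(ok) <= step:
            continue
        first = ok[: len(ok) - step]
        second = ok[step:]
        for i in np.nonzero(first & second)[0]:
            i = int(i)
            out.append(
                (
                    i,
                    seq[i : i + w],
                    seq[i + step : i + step + w],
                    spacer,
                    int(mism[i] + mism[i + step]),
                )
            )
    return out


def find_direct_repeats(
    seq: str,
    params: MotifParams | None = None,
    species: str = "",
    region_length: int | None = None,
) -> list[MotifHit]:
    """Direct repeats of the half-site with spacer in ``params.spacers``.

    Every qualifying ordered pair of same-strand half-sites yields one
    hit (chained repeats are not de-duplicated).  Minus-strand geometry is
    evaluated on the reverse complement and mapped back to plus-strand
    window starts.  Offsets are relative to the anchor at the 3′ end of
    ``seq`` (override ``region_length`` if the sequence was truncated).
    """
    params = params or MotifParams()
    _check_alphabet(seq)
    seq = seq.upper()
    L = region_length if region_length is not None else len(seq)
    w = params.width
    hits: list[MotifHit] = []
    for start0, h1, h2, spacer, mm in _repeats_one_strand(seq, params):
        hits.append(
            MotifHit(
                species=species,
                offset=start0 - L,
                strand="+",
                half_site_1=h1,
                half_site_2=h2,
                spacer=spacer,
                dr_class=f"DR{spacer}",
                mismatches=mm,
            )
        )
    if params.strands == "both":
        rc = reverse_complement(seq)
        n = len(seq)
        for j, h1, h2, spacer, mm in _repeats_one_strand(rc, params):
            width = 2 * w + spacer
            start0 = n - j - width
            hits.append(
                MotifHit(
                    species=species,
                    offset=start0 - L,
                    strand="-",
                    half_site_1=h1,
                    half_site_2=h2,
                    spacer=spacer,
                    dr_class=f"DR{spacer}",
                    mismatches=mm,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand, h.spacer))
    return hits


def align_promoters(
    pair: PromoterPair,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PromoterPair:
    """Global pairwise alignment with affine gap penalties.

    A gap of length k costs ``gap_open + (k−1)·gap_extend``.  Uses the
    highest-scoring alignment; among co-optimal alignments the aligner's
    canonical first traceback is taken, which is deterministic.
    """
    from Bio import Align

    if not pair.seq_a or not pair.seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(pair.seq_a, pair.seq_b)[0]
    return replace(pair, aligned_a=str(alignment[0]), aligned_b=str(alignment[1]))


def conserved_blocks(
    pair: PromoterPair,
    window: int = 100,
    min_identity: float = 0.7,
) -> list[ConservedBlock]:
    """Sliding-window identity over alignment columns, merged into blocks.

    A column counts as identical only if both sequences carry the same
    unambiguous base there (gaps and N mismatch).  Every length-``window``
    window with identity ≥ ``min_identity`` marks its columns; maximal runs
    of marked columns become blocks, whose identity is recomputed over the
    merged span.
    """
    if not pair.aligned:
        raise ValueError("pair has no alignment")
    a, b = pair.aligned_a, pair.aligned_b
    ncol = len(a)
    if window > ncol:
        raise ValueError(f"window {window} exceeds alignment length {ncol}")
    ea, eb = _encode(a), _encode(b)
    ident = (ea == eb) & np.isin(ea, _encode("ACGT"))
    csum = np.concatenate([[0], np.cumsum(ident)])
    win_id = (csum[window:] - csum[:-window]) / window  # identity of window starting at i
    good = win_id >= min_identity
    covered = np.zeros(ncol, dtype=bool)
    for i in np.nonzero(good)[0]:
        covered[i : i + window] = True
    blocks: list[ConservedBlock] = []
    i = 0
    while i < ncol:
        if covered[i]:
            j = i
            while j + 1 < ncol and covered[j + 1]:
                j += 1
            span_id = float(ident[i : j + 1].mean())
            blocks.append(
                ConservedBlock(start_col=i + 1, end_col=j + 1, length=j - i + 1, identity=span_id)
            )
            i = j + 1
        else:
            i += 1
    return blocks


def _column_of_position(aligned: str) -> np.ndarray:
    """col_of[p] = 0-based alignment column of ungapped position p."""
    arr = _encode(aligned)
    return np.nonzero(arr != ord("-"))[0]


def _ungapped_before(aligned: str) -> np.ndarray:
    """n[c] = number of non-gap characters strictly before column c."""
    arr = _encode(aligned)
    return np.concatenate([[0], np.cumsum(arr != ord("-"))])[:-1]


@dataclass
class ScanReport:
    """Everything one promoter-pair scan produced."""

    pair: PromoterPair
    params: MotifParams
    window: int
    min_identity: float
    hits_a: list[MotifHit] = field(default_factory=list)
    hits_b: list[MotifHit] = field(default_factory=list)
    blocks: list[ConservedBlock] = field(default_factory=list)

    @property
    def hits(self) -> list[MotifHit]:
        return self.hits_a + self.hits_b

    def conserved_hits(self) -> list[MotifHit]:
        return [h for h in self.hits if h.conserved]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": h.species,
                "offset": h.offset,
                "strand": h.strand,
                "half_site_1": h.half_site_1,
                "half_site_2": h.half_site_2,
                "spacer": h.spacer,
                "dr_class": h.dr_class,
                "mismatches": h.mismatches,
                "conserved": h.conserved,
                "partner_offset": h.aligned_partner_offset,
            }
            for h in self.hits
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "species", "offset", "strand", "half_site_1", "half_site_2",
                "spacer", "dr_class", "mismatches", "conserved", "partner_offset",
            ],
        )

    def to_bed(self) -> pd.DataFrame:
        """Hits as BED-style intervals in promoter-local plus-strand
        coordinates (0-based half-open)."""
        rows = []
        for h in self.hits:
            length = len(self.pair.seq_a if h.species == self.pair.species_a else self.pair.seq_b)
            start = length + h.offset
            rows.append(
                {
                    "chrom": h.species,
                    "start": start,
                    "end": start + h.footprint,
                    "name": f"{h.dr_class}{h.strand}",
                    "score": 0,
                    "strand": h.strand,
                }
            )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def _annotate_conservation(
    hits: list[MotifHit],
    aligned_self: str,
    aligned_other: str,
    seq_len_self: int,
    seq_len_other: int,
    blocks: list[ConservedBlock],
) -> None:
    col_of = _column_of_position(aligned_self)
    before_other = _ungapped_before(aligned_other)
    for h in hits:
        start = seq_len_self + h.offset
        cols = col_of[start : start + h.footprint]
        h.conserved = False
        h.aligned_partner_offset = None
        for blk in blocks:
            if cols[0] >= blk.start_col - 1 and cols[-1] <= blk.end_col - 1:
                h.conserved = True
                partner_start = int(before_other[cols[0]])
                h.aligned_partner_offset = partner_start - seq_len_other
                break


def scan_promoter_pair(
    pair: PromoterPair,
    params: MotifParams | None = None,
    window: int = 100,
    min_identity: float = 0.7,
) -> ScanReport:
    """Scan both species, call conserved blocks, annotate conserved hits.

    Hits are found on the ungapped sequences; a hit is *conserved* when
    every alignment column of its footprint lies inside one conserved
    block, in which case the partner offset gives where the aligned
    columns fall in the other species' ungapped coordinates.  The pair is
    aligned first if no alignment is attached.
    """
    params = params or MotifParams()
    if not pair.aligned:
        pair = align_promoters(pair)
    hits_a = find_direct_repeats(pair.seq_a, params, species=pair.species_a)
    hits_b = find_direct_repeats(pair.seq_b, params, species=pair.species_b)
    blocks = conserved_blocks(pair, window=window, min_identity=min_identity)
    _annotate_conservation(
        hits_a, pair.aligned_a, pair.aligned_b, len(pair.seq_a), len(pair.seq_b), blocks
    )
    _annotate_conservation(
        hits_b, pair.aligned_b, pair.aligned_a, len(pair.seq_b), len(pair.seq_a), blocks
    )
    return ScanReport(
        pair=pair,
        params=params,
        window=window,
        min_identity=min_identity,
        hits_a=hits_a,
        hits_b=hits_b,
        blocks=blocks,
    )


def read_promoter_pair(source, species: tuple[str, str] | None = None) -> PromoterPair:
    """Two-record FASTA: plain sequences, or a gapped pair (``-`` gaps)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(source, "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 FASTA records, got {len(records)}")
    names = species or (records[0].id, records[1].id)
    raw = [str(r.seq).upper() for r in records]
    if "-" in raw[0] or "-" in raw[1]:
        return PromoterPair(
            species_a=names[0],
            species_b=names[1],
            seq_a=raw[0].replace("-", ""),
            seq_b=raw[1].replace("-", ""),
            aligned_a=raw[0],
            aligned_b=raw[1],
        )
    return PromoterPair(species_a=names[0], species_b=names[1], seq_a=raw[0], seq_b=raw[1])


def write_promoter_pair(pair: PromoterPair, sink, aligned: bool = True) -> None:
    seqs = (
        (pair.aligned_a, pair.aligned_b) if aligned and pair.aligned else (pair.seq_a, pair.seq_b)
    )
    close = False
    if isinstance(sink, str):
        sink = open(sink, "wt", encoding="utf-8")
        close = True
    try:
        for name, seq in zip((pair.species_a, pair.species_b), seqs):
            sink.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                sink.write(seq[i : i + 70] + "\n")
    finally:
        if close:
            sink.close()
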