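"""Reading and writing spot-level two-colour array files and design tables.

The on-disk dialect is a tab-delimited table with a single header row carrying
(at least) the six columns produced by GenePix-style image analysis:

    ID, F635 Median, B635 Median, F532 Median, B532 Median, Flags

``F``/``B`` are per-spot foreground/background fluorescence medians for the
635 nm (red) and 532 nm (green) channels.  Lines preceding the header that
belong to an Axon Text File preamble (``ATF`` magic, quoted key/value lines,
or numeric count lines) are tolerated and ignored; the full ATF spec is not
implemented.  Unknown columns are carried through unmodified.

A design table maps slides to biological comparisons and records the dye
orientation of each slide so that a forward/swapped pair can be combined
downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, TextIO

import pandas as pd

__all__ = [
    "SpotRecord",
    "SlideAssay",
    "DesignTable",
    "GprFormatError",
    "DesignError",
    "REQUIRED_COLUMNS",
    "read_gpr",
    "write_gpr",
    "read_design",
    "write_design",
]

#: qc_status values a spot can carry after filtering.
QC_RETAINED = "retained"
QC_EXCLUDED_FLAG = "excluded_flag"
QC_EXCLUDED_SATURATED = "excluded_saturated"
QC_EXCLUDED_SB = "excluded_sb"

REQUIRED_COLUMNS = (
    "ID",
    "F635 Median",
    "B635 Median",
    "F532 Median",
    "B532 Median",
    "Flags",
)

_INTENSITY_COLUMNS = REQUIRED_COLUMNS[1:5]

#: internal (DataFrame) column names, in canonical file order
_CANONICAL = {
    "ID": "gene_id",
    "F635 Median": "f635_median",
    "B635 Median": "b635_median",
    "F532 Median": "f532_median",
    "B532 Median": "b532_median",
    "Flags": "flag",
}
_CANONICAL_INV = {v: k for k, v in _CANONICAL.items()}


class GprFormatError(ValueError):
    """Malformed spot file: missing column, non-numeric intensity, ..."""


class DesignError(ValueError):
    """Inconsistent experiment design (orientations, missing slides, ...)."""


@dataclass(frozen=True)
class SpotRecord:
    """A single printed spot: two-channel fluorescence medians plus QC state."""

    spot_id: str
    gene_id: str
    f635_median: int
    b635_median: int
    f532_median: int
    b532_median: int
    flag: int = 0
    qc_status: str = QC_RETAINED


@dataclass
class SlideAssay:
    """One hybridised slide: ordered spots plus dye orientation.

    ``orientation`` states which biological condition was labelled with the
    635 nm dye: ``"forward"`` means the comparison's numerator (treated)
    condition is in the 635 channel, ``"swapped"`` means it is in the 532
    channel.  ``spots`` is a DataFrame with columns ``spot_id, gene_id,
    f635_median, b635_median, f532_median, b532_median, flag, qc_status`` in
    file order; use :meth:`records` for dataclass views.
    """

    slide_id: str
    orientation: str
    spots: pd.DataFrame
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "swapped"):
            raise ValueError(f"orientation must be forward/swapped, got {self.orientation!r}")
        if len(self.spots) == 0:
            raise ValueError(f"slide {self.slide_id!r} has no spots")
        if "qc_status" not in self.spots.columns:
            self.spots = self.spots.assign(qc_status=QC_RETAINED)
        if "spot_id" not in self.spots.columns:
            self.spots = self.spots.assign(
                spot_id=[f"s{i + 1}" for i in range(len(self.spots))]
            )

    @classmethod
    def from_records(
        cls,
        slide_id: str,
        orientation: str,
        records: Iterable[SpotRecord],
        channel_meta: Mapping | None = None,
    ) -> "SlideAssay":
        df = pd.DataFrame([r.__dict__ for r in records])
        return cls(slide_id, orientation, df, dict(channel_meta or {}))

    def records(self) -> Iterator[SpotRecord]:
        cols = list(SpotRecord.__dataclass_fields__)
        for row in self.spots[cols].itertuples(index=False):
            yield SpotRecord(*row)

    def retained(self) -> pd.DataFrame:
        return self.spots[self.spots["qc_status"] == QC_RETAINED]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SlideAssay):
            return NotImplemented
        return (
            self.slide_id == other.slide_id
            and self.orientation == other.orientation
            and self.spots.reset_index(drop=True).equals(other.spots.reset_index(drop=True))
        )


@dataclass
class DesignTable:
    """Slide-to-comparison map.

    ``comparisons``: (name, condition_numerator, condition_denominator).
    ``replicate_pairs``: (forward_slide_id, swapped_slide_id, comparison_name).
    """

    comparisons: list[tuple[str, str, str]]
    replicate_pairs: list[tuple[str, str, str]]

    def validate(self, slides: Mapping[str, SlideAssay] | None = None) -> None:
        names = {c[0] for c in self.comparisons}
        seen: set[str] = set()
        for fwd, swp, comp in self.replicate_pairs:
            if comp not in names:
                raise DesignError(f"pair ({fwd}, {swp}) references unknown comparison {comp!r}")
            if fwd == swp:
                raise DesignError(f"pair uses slide {fwd!r} twice")
            for sid in (fwd, swp):
                if sid in seen:
                    raise DesignError(f"slide {sid!r} appears in more than one pair")
                seen.add(sid)
            if slides is not None:
                for sid, want in ((fwd, "forward"), (swp, "swapped")):
                    if sid not in slides:
                        raise DesignError(f"design references missing slide {sid!r}")
                    got = slides[sid].orientation
                    if got != want:
                        raise DesignError(
                            f"slide {sid!r} has orientation {got!r}, design expects {want!r}"
                        )

    def pairs_for(self, comparison: str) -> list[tuple[str, str]]:
        return [(f, s) for f, s, c in self.replicate_pairs if c == comparison]


def _is_preamble(line: str) -> bool:
    # the header row itself is recognised before this is consulted, so any
    # leading quoted metadata line, ATF magic or "ncols nrows" count line can
    # simply be skipped
    s = line.strip()
    if not s or s.upper().startswith("ATF") or s.startswith('"'):
        return True
    return all(tok.isdigit() for tok in s.split())


def read_gpr(source: TextIO | str) -> SlideAssay:
    """Parse a spot table into a :class:`SlideAssay`.

    ``source`` is a text stream or a path.  The slide id defaults to the
    stream/file name stem and the orientation to ``"forward"``; both are
    normally overridden by the design table, which is the authority on dye
    orientation.  Raises :class:`GprFormatError` if a required column is
    missing or an intensity is non-numeric (reported with its line number).
    """
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as fh:
            slide = read_gpr(fh)
        stem = source.rsplit("/", 1)[-1]
        slide.slide_id = stem.rsplit(".", 1)[0]
        return slide

    lines = source.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        fields = [f.strip().strip('"') for f in line.split("\t")]
        if "ID" in fields and "F635 Median" in fields:
            header_idx = i
            break
        if not _is_preamble(line):
            break
    if header_idx is None:
        raise GprFormatError("no header row with required columns found")

    header = [f.strip().strip('"') for f in lines[header_idx].split("\t")]
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise GprFormatError(f"missing required column {col!r}")

    body = "\n".join(lines[header_idx:])
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().strip('"') for c in df.columns]

    for col in _INTENSITY_COLUMNS + ("Flags",):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(bad.idxmax())
            # +2: header line itself, and 1-based numbering
            raise GprFormatError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at line {header_idx + row + 2}"
            )
        df[col] = converted.astype(int)

    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS and c != "Spot ID"]
    meta = {c: df[c].tolist() for c in extra}

    spots = pd.DataFrame(
        {
            "spot_id": df["Spot ID"].tolist()
            if "Spot ID" in df.columns
            else [f"s{i + 1}" for i in range(len(df))],
            "gene_id": df["ID"].tolist(),
            "f635_median": df["F635 Median"].to_numpy(),
            "b635_median": df["B635 Median"].to_numpy(),
            "f532_median": df["F532 Median"].to_numpy(),
            "b532_median": df["B532 Median"].to_numpy(),
            "flag": df["Flags"].to_numpy(),
            "qc_status": QC_RETAINED,
        }
    )
    name = getattr(source, "name", "slide")
    slide_id = str(name).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return SlideAssay(slide_id=slide_id, orientation="forward", spots=spots, channel_meta=meta)


def write_gpr(slide: SlideAssay, sink: TextIO | str) -> None:
    """Write a slide in the canonical dialect (header + one row per spot).

    Pass-through columns from ``channel_meta`` are appended after the six
    required columns so that write∘read round-trips.
    """
    if isinstance(sink, str):
        with open(sink, "wt", encoding="utf-8") as fh:
            write_gpr(slide, fh)
        return
    if len(slide.spots) == 0:
        raise ValueError("refusing to write a slide with no spots")
    out = pd.DataFrame({"Spot ID": slide.spots["spot_id"]})
    for internal, public in (
        ("gene_id", "ID"),
        ("f635_median", "F635 Median"),
        ("b635_median", "B635 Median"),
        ("f532_median", "F532 Median"),
        ("b532_median", "B532 Median"),
        ("flag", "Flags"),
    ):
        out[public] = slide.spots[internal].to_numpy()
    for col, values in slide.channel_meta.items():
        out[col] = values
    out.to_csv(sink, sep="\t", index=False, lineterminator="\n")


def read_design(source: TextIO | str) -> DesignTable:
    """Parse a design table.

    Two tab-delimited sections are accepted in one file: rows with
    ``record=comparison`` (name, numerator, denominator) and rows with
    ``record=pair`` (forward slide, swapped slide, comparison).  Header row::

        record	a	b	c
    """
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_design(fh)
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in ("record", "a", "b", "c"):
        if col not in df.columns:
            raise DesignError(f"design table missing column {col!r}")
    comparisons = [
        (r.a, r.b, r.c) for r in df[df["record"] == "comparison"].itertuples()
    ]
    pairs = [(r.a, r.b, r.c) for r in df[df["record"] == "pair"].itertuples()]
    table = DesignTable(comparisons=comparisons, replicate_pairs=pairs)
    table.validate()
    return table


def write_design(design: DesignTable, sink: TextIO | str) -> None:
    if isinstance(sink, str):
        with open(sink, "wt", encoding="utf-8") as fh:
            write_design(design, fh)
        return
    rows = [("comparison",) + c for c in design.comparisons]
    rows += [("pair",) + p for p in design.replicate_pairs]
    pd.DataFrame(rows, columns=["record", "a", "b", "c"]).to_csv(
        sink, sep="\t", index=False, lineterminator="\n"
    )
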