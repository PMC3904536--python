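"""Core data types for synteny blocks and coordinate arithmetic.

Coordinates follow the UCSC MAF convention: 0-based starts, ``size`` counts
residues (non-gap characters), and minus-strand starts are relative to the
reverse-complemented source sequence.  All internal interval math is 0-based
half-open on the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

GAP = "-"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Sentinel quality score stored at gap positions (scores are gap-expanded:
#: one slot per text column, so column slicing is uniform).
GAP_SCORE = -1


class MafError(Exception):
    """Base error for malformed alignment data or coordinate misuse."""


@dataclass
class MafSequence:
    """One aligned row of a synteny block.

    Parameters
    ----------
    species, chromosome:
        Text labels; the MAF ``src`` field is ``species.chromosome``.
    start:
        0-based start, relative to the strand (per the MAF standard).
    size:
        Number of non-gap characters in ``text``.
    strand:
        ``'+'`` or ``'-'``.
    src_size:
        Full length of the source sequence.
    text:
        Gapped sequence over ``{A,C,G,T,N,a,c,g,t,n,-}``.
    scores:
        Optional per-column quality scores, gap-expanded (``-1`` at gaps).
    """

    species: str
    chromosome: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str
    scores: list[int] | None = None

    @property
    def src(self) -> str:
        return f"{self.species}.{self.chromosome}" if self.chromosome else self.species

    @property
    def end(self) -> int:
        """Strand-relative exclusive end (``start + size``)."""
        return self.start + self.size

    def ungapped_length(self) -> int:
        return len(self.text) - self.text.count(GAP)

    def validate(self) -> None:
        """Check the MafSequence invariants, raising :class:`MafError`."""
        if self.strand not in "+-":
            raise MafError(f"invalid strand {self.strand!r} for {self.src}")
        if self.start < 0 or self.size < 0:
            raise MafError(f"negative coordinates for {self.src}")
        if self.ungapped_length() != self.size:
            raise MafError(
                f"size={self.size} does not match non-gap character count "
                f"{self.ungapped_length()} for {self.src}"
            )
        if self.start + self.size > self.src_size:
            raise MafError(
                f"start+size={self.start + self.size} exceeds src_size="
                f"{self.src_size} for {self.src}"
            )
        if self.scores is not None and len(self.scores) != len(self.text):
            raise MafError(
                f"scores length {len(self.scores)} != text length "
                f"{len(self.text)} for {self.src}"
            )

    def copy(self) -> "MafSequence":
        return MafSequence(
            self.species,
            self.chromosome,
            self.start,
            self.size,
            self.strand,
            self.src_size,
            self.text,
            None if self.scores is None else list(self.scores),
        )

    def reverse_complement(self) -> "MafSequence":
        """Return the row as seen on the opposite strand."""
        return MafSequence(
            self.species,
            self.chromosome,
            self.src_size - self.start - self.size,
            self.size,
            "-" if self.strand == "+" else "+",
            self.src_size,
            self.text.translate(_COMPLEMENT)[::-1],
            None if self.scores is None else list(reversed(self.scores)),
        )


@dataclass
class MafBlock:
    """One synteny block: rows of identical gapped length, an optional MAF
    ``a score=`` value and an optional attached phylogeny."""

    sequences: list[MafSequence] = field(default_factory=list)
    score: float | None = None
    tree: object | None = None
    #: free-form annotations set by filters (e.g. source feature id)
    annotations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return block_length(self)

    @property
    def species(self) -> list[str]:
        return [s.species for s in self.sequences]

    def find(self, species: str) -> list[MafSequence]:
        return [s for s in self.sequences if s.species == species]

    def find_one(self, species: str) -> MafSequence | None:
        """Return the row for *species* if it occurs exactly once, else None
        (raising on duplicates is left to callers that require uniqueness)."""
        rows = self.find(species)
        return rows[0] if len(rows) == 1 else None

    def columns(self) -> Iterator[tuple[str, ...]]:
        """Iterate over alignment columns as tuples of characters."""
        return zip(*(s.text for s in self.sequences))

    def validate(self) -> None:
        lengths = {len(s.text) for s in self.sequences}
        if len(lengths) > 1:
            raise MafError(f"unequal row lengths in block: {sorted(lengths)}")
        for s in self.sequences:
            s.validate()

    def copy(self) -> "MafBlock":
        return MafBlock(
            [s.copy() for s in self.sequences],
            self.score,
            self.tree,
            dict(self.annotations),
        )


@dataclass(frozen=True)
class Feature:
    """A strand-aware genomic interval (0-based half-open internally)."""

    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    kind: str = ""
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise MafError(
                f"invalid feature interval [{self.start}, {self.end}) for "
                f"{self.species}.{self.chromosome}"
            )


class FeatureSet:
    """Features indexed by (species, chromosome)."""

    def __init__(self, features: Iterable[Feature] = ()) -> None:
        self._by_key: dict[tuple[str, str], list[Feature]] = {}
        for f in features:
            self.add(f)

    def add(self, feature: Feature) -> None:
        self._by_key.setdefault((feature.species, feature.chromosome), []).append(
            feature
        )

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_key.values())

    def __iter__(self) -> Iterator[Feature]:
        for key in sorted(self._by_key):
            yield from sorted(self._by_key[key], key=lambda f: (f.start, f.end))

    def overlapping(
        self, species: str, chromosome: str, start: int, end: int
    ) -> list[Feature]:
        """Features overlapping [start, end) on the forward strand, sorted."""
        hits = [
            f
            for f in self._by_key.get((species, chromosome), ())
            if f.start < end and f.end > start
        ]
        hits.sort(key=lambda f: (f.start, f.end))
        return hits


def block_length(block: MafBlock) -> int:
    """Gapped column count of *block* (0 for an empty block)."""
    if not block.sequences:
        return 0
    return len(block.sequences[0].text)


def column_to_coordinate(seq: MafSequence, column: int) -> int | None:
    """Strand-relative source position of the residue at *column*.

    Returns ``None`` when the column is a gap in this row.  Positions
    increase left to right by one per non-gap character, starting at
    ``seq.start``.
    """
    if column < 0 or column >= len(seq.text):
        raise IndexError(
            f"column {column} out of range for text of length {len(seq.text)}"
        )
    if seq.text[column] == GAP:
        return None
    return seq.start + (len(seq.text[:column]) - seq.text.count(GAP, 0, column))


def coordinate_map(seq: MafSequence) -> list[int | None]:
    """Per-column strand-relative positions (``None`` at gaps)."""
    out: list[int | None] = []
    pos = seq.start
    for ch in seq.text:
        if ch == GAP:
            out.append(None)
        else:
            out.append(pos)
            pos += 1
    return out


def subblock(block: MafBlock, col_from: int, col_to: int) -> MafBlock:
    """New block containing columns ``[col_from, col_to)``.

    Each row's ``start`` advances past the residues left of the slice and its
    ``size`` is recounted.  The block score (and any attached tree) is
    dropped: neither is meaningful for a fragment.
    """
    length = block_length(block)
    if not (0 <= col_from < col_to <= length):
        raise IndexError(
            f"invalid column slice [{col_from}, {col_to}) for block of "
            f"length {length}"
        )
    rows = []
    for s in block.sequences:
        skipped = (col_from) - s.text.count(GAP, 0, col_from)
        text = s.text[col_from:col_to]
        size = len(text) - text.count(GAP)
        scores = None if s.scores is None else s.scores[col_from:col_to]
        rows.append(
            MafSequence(
                s.species,
                s.chromosome,
                s.start + skipped,
                size,
                s.strand,
                s.src_size,
                text,
                scores,
            )
        )
    return MafBlock(rows, None, None, dict(block.annotations))


def to_plus_strand_interval(seq: MafSequence) -> tuple[str, int, int]:
    """0-based half-open interval of *seq* on the forward strand."""
    if seq.strand == "+":
        return seq.chromosome, seq.start, seq.start + seq.size
    return (
        seq.chromosome,
        seq.src_size - seq.start - seq.size,
        seq.src_size - seq.start,
    )
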