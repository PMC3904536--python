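"""Per-block statistics streamed to a CSV table keyed by block coordinates.

A "complete" site has no gap and no unresolved character over the rows
under consideration (the ingroup only, for group statistics).  Coordinates
in the CSV are 1-based inclusive, matching exported alignment headers.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable, Iterator, Sequence

from .model import GAP, MafBlock, MafError, to_plus_strand_interval

logger = logging.getLogger("mafstream")

_UNAMBIGUOUS = frozenset("ACGT")


def _residues(column: Sequence[str]) -> list[str]:
    """Case-folded unambiguous residues of a column (gaps and N dropped)."""
    return [c.upper() for c in column if c.upper() in _UNAMBIGUOUS]


def _is_complete(column: Sequence[str]) -> bool:
    return all(c.upper() in _UNAMBIGUOUS for c in column)


def block_counts(block: MafBlock) -> dict[str, int]:
    """Character counts over all rows (case-folded; '-' keyed as 'gap').

    Counts sum to rows x length.
    """
    counts: Counter = Counter()
    for s in block.sequences:
        counts.update(s.text.upper())
    out = {k: 0 for k in ("A", "C", "G", "T", "N", "gap")}
    for ch, n in counts.items():
        key = "gap" if ch == GAP else ch
        out[key] = out.get(key, 0) + n
    return out


def site_statistics(block: MafBlock) -> tuple[int, int, int]:
    """(gap-free sites, complete sites, parsimony-informative sites).

    A parsimony-informative column has >= 2 distinct residues each present
    >= 2 times; gaps and N are not counted as states, but a column
    containing them can still qualify.
    """
    gap_free = complete = informative = 0
    for column in block.columns():
        if GAP not in column:
            gap_free += 1
            if _is_complete(column):
                complete += 1
        counts = Counter(_residues(column))
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative += 1
    return gap_free, complete, informative


def pairwise_divergence(block: MafBlock, sp1: str, sp2: str) -> float | None:
    """Percent mismatches over columns where both rows hold unambiguous
    residues; None when no site is comparable."""
    a = block.find_one(sp1)
    b = block.find_one(sp2)
    if a is None or b is None:
        raise MafError(
            f"pairwise divergence requires exactly one row each for "
            f"{sp1!r} and {sp2!r}"
        )
    sites = mismatches = 0
    for x, y in zip(a.text.upper(), b.text.upper()):
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS:
            sites += 1
            if x != y:
                mismatches += 1
    return 100.0 * mismatches / sites if sites else None


def polymorphism_statistics(
    block: MafBlock, group1: Sequence[str], group2: Sequence[str]
) -> dict[str, int]:
    """McDonald-Kreitman-style per-column classification of two groups.

    Over columns complete in both groups: P1/P2 = polymorphic within that
    group only, PS = polymorphic in both, FD = fixed difference with both
    groups monomorphic.  F1/F2 are the complementary fixed views (fixed in
    that group, polymorphic in the other), i.e. F1 == P2 and F2 == P1.
    {P1, P2, PS, FD} are mutually exclusive and cover every variable
    complete column.
    """
    if set(group1) & set(group2):
        raise MafError("polymorphism groups must be disjoint")
    rows1 = [s for s in block.sequences if s.species in set(group1)]
    rows2 = [s for s in block.sequences if s.species in set(group2)]
    if not rows1 or not rows2:
        raise MafError("both groups need at least one row present in the block")
    out = {"P1": 0, "P2": 0, "F1": 0, "F2": 0, "FD": 0, "PS": 0}
    for col1, col2 in zip(
        zip(*(s.text for s in rows1)), zip(*(s.text for s in rows2))
    ):
        if not (_is_complete(col1) and _is_complete(col2)):
            continue
        s1 = {c.upper() for c in col1}
        s2 = {c.upper() for c in col2}
        poly1, poly2 = len(s1) > 1, len(s2) > 1
        if poly1 and poly2:
            out["PS"] += 1
        elif poly1:
            out["P1"] += 1
            out["F2"] += 1
        elif poly2:
            out["P2"] += 1
            out["F1"] += 1
        elif s1 != s2:
            out["FD"] += 1
    return out


def watterson_a(n: int) -> float:
    """Harmonic number a_n = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def diversity_statistics(
    block: MafBlock, group: Sequence[str], per_site: bool = False
) -> tuple[int, float]:
    """(S, Watterson's theta) for the rows of *group*.

    S counts complete columns with >= 2 distinct residues; theta = S / a_n
    with a_n = sum 1/i for i in 1..n-1 (per block).  With *per_site*, theta
    is further divided by the number of complete columns.
    """
    rows = [s for s in block.sequences if s.species in set(group)]
    n = len(rows)
    if n < 2:
        raise MafError(f"diversity statistics need >= 2 usable rows, got {n}")
    s_count = complete = 0
    for column in zip(*(r.text for r in rows)):
        if not _is_complete(column):
            continue
        complete += 1
        if len({c.upper() for c in column}) > 1:
            s_count += 1
    theta = s_count / watterson_a(n)
    if per_site:
        theta = theta / complete if complete else math.nan
    return s_count, theta


class SiteFrequencySpectrum:
    """Unfolded site-frequency spectrum polarized by an outgroup.

    ``bins[k]`` counts polarizable biallelic columns whose derived-allele
    ingroup count falls in ``[edges[k], edges[k+1])`` (the last bin is
    closed).  ``unpolarizable`` counts biallelic columns whose outgroup
    allele matches neither ingroup allele, and multi-allelic columns;
    ``ignored`` counts monomorphic complete columns.
    """

    def __init__(self, edges: Sequence[float]):
        if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
            raise MafError("SFS bin edges must be strictly increasing, >= 2 values")
        self.edges = list(edges)
        self.bins = [0] * (len(edges) - 1)
        self.unpolarizable = 0
        self.ignored = 0

    def add(self, derived_count: int) -> None:
        if derived_count < self.edges[0] or derived_count > self.edges[-1]:
            self.unpolarizable += 1
            return
        for k in range(len(self.bins)):
            if derived_count < self.edges[k + 1] or k == len(self.bins) - 1:
                self.bins[k] += 1
                return

    def total(self) -> int:
        return sum(self.bins)


def site_frequency_spectrum(
    block: MafBlock,
    ingroup: Sequence[str],
    outgroup: str,
    edges: Sequence[float] | None = None,
) -> SiteFrequencySpectrum:
    """Tally derived-allele counts over complete biallelic ingroup columns.

    The derived allele of a column is the ingroup allele not carried by the
    outgroup; columns where the outgroup carries a third allele (or the
    ingroup is multi-allelic) are unpolarizable, and monomorphic columns
    are ignored.
    """
    rows = [s for s in block.sequences if s.species in set(ingroup)]
    out_row = block.find_one(outgroup)
    if out_row is None:
        raise MafError(f"outgroup {outgroup!r} must be present exactly once")
    if len(rows) < 2:
        raise MafError("SFS needs >= 2 ingroup rows")
    n = len(rows)
    sfs = SiteFrequencySpectrum(list(range(1, n + 1)) if edges is None else edges)
    for column in zip(*(r.text for r in rows), out_row.text):
        if not _is_complete(column):
            continue
        in_col = [c.upper() for c in column[:-1]]
        out_allele = column[-1].upper()
        alleles = sorted(set(in_col))
        if len(alleles) == 1:
            sfs.ignored += 1
            continue
        if len(alleles) > 2 or out_allele not in alleles:
            sfs.unpolarizable += 1
            continue
        derived = alleles[0] if alleles[1] == out_allele else alleles[1]
        sfs.add(in_col.count(derived))
    return sfs


def count_clusters(block: MafBlock, threshold: float) -> int:
    """Number of haplotype groups after cutting every tree branch longer
    than *threshold* (components containing at least one leaf)."""
    if block.tree is None:
        raise MafError("count_clusters requires a previously computed tree")

    def walk(node) -> tuple[int, bool]:
        # returns (clusters fully split off below, node still connected to a leaf)
        if node.is_leaf:
            return 0, True
        clusters = 0
        connected = False
        for child in node.children:
            below, child_conn = walk(child)
            clusters += below
            cut = child.length is not None and child.length > threshold
            if child_conn:
                if cut:
                    clusters += 1
                else:
                    connected = True
        return clusters, connected

    clusters, root_connected = walk(block.tree)
    return clusters + (1 if root_connected else 0)


def sequence_length(block: MafBlock, species: str) -> int:
    """Total non-gap characters of *species* in the block (0 if absent)."""
    return sum(s.size for s in block.find(species))


def block_size(block: MafBlock) -> int:
    return len(block.sequences)


def aln_score(block: MafBlock) -> float | None:
    return block.score


# ---------------------------------------------------------------------------
# the SequenceStatistics streaming filter


def _reference_interval(block: MafBlock, ref_species: str | None):
    seq = None
    if ref_species is not None:
        rows = block.find(ref_species)
        seq = rows[0] if rows else None
    if seq is None and block.sequences:
        seq = block.sequences[0]
    if seq is None:
        return "NA", "NA", "NA"
    chrom, start, end = to_plus_strand_interval(seq)
    return chrom, start + 1, end  # 1-based inclusive


class StatisticSpec:
    """One requested statistic: a name and its keyword arguments."""

    def __init__(self, name: str, **kwargs):
        if name not in STATISTICS:
            raise MafError(f"unknown statistic {name!r}")
        self.name = name
        self.kwargs = kwargs

    def headers(self, block: MafBlock | None = None) -> list[str]:
        return STATISTICS[self.name][0](self.kwargs)

    def compute(self, block: MafBlock) -> list:
        return STATISTICS[self.name][1](block, self.kwargs)


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


# registry: name -> (headers(kwargs) -> [str], compute(block, kwargs) -> [values])
STATISTICS = {
    "BlockLength": (lambda kw: ["BlockLength"], lambda b, kw: [len(b)]),
    "BlockSize": (lambda kw: ["BlockSize"], lambda b, kw: [block_size(b)]),
    "AlnScore": (lambda kw: ["AlnScore"], lambda b, kw: [aln_score(b)]),
    "SequenceLength": (
        lambda kw: [f"SequenceLength.{kw['species']}"],
        lambda b, kw: [sequence_length(b, kw["species"])],
    ),
    "BlockCounts": (
        lambda kw: ["Count.A", "Count.C", "Count.G", "Count.T", "Count.N", "Count.gap"],
        lambda b, kw: [block_counts(b)[k] for k in ("A", "C", "G", "T", "N", "gap")],
    ),
    "SiteStatistics": (
        lambda kw: ["Sites.NoGap", "Sites.Complete", "Sites.ParsimonyInformative"],
        lambda b, kw: list(site_statistics(b)),
    ),
    "PairwiseDivergence": (
        lambda kw: [f"Div.{kw['species1']}-{kw['species2']}"],
        lambda b, kw: [pairwise_divergence(b, kw["species1"], kw["species2"])],
    ),
    "PolymorphismStatistics": (
        lambda kw: ["P1", "P2", "F1", "F2", "FD", "PS"],
        lambda b, kw: [
            polymorphism_statistics(b, kw["group1"], kw["group2"])[k]
            for k in ("P1", "P2", "F1", "F2", "FD", "PS")
        ],
    ),
    "DiversityStatistics": (
        lambda kw: ["S", "ThetaW"],
        lambda b, kw: list(
            diversity_statistics(b, kw["group"], kw.get("per_site", False))
        ),
    ),
    "SiteFrequencySpectrum": (
        lambda kw: [f"SFS.{i}" for i in range(1, len(kw["ingroup"]))]
        + ["SFS.unpolarizable", "SFS.ignored"],
        lambda b, kw: (
            lambda sfs: sfs.bins + [sfs.unpolarizable, sfs.ignored]
        )(site_frequency_spectrum(b, kw["ingroup"], kw["outgroup"])),
    ),
    "CountClusters": (
        lambda kw: [f"Clusters.{kw['threshold']:g}"],
        lambda b, kw: [count_clusters(b, kw["threshold"])],
    ),
}


def sequence_statistics(
    blocks: Iterable[MafBlock],
    statistics: Sequence[StatisticSpec],
    path,
    ref_species: str | None = None,
) -> Iterator[MafBlock]:
    """Streaming filter: compute *statistics* per block, append a CSV row
    keyed by the reference row's forward-strand coordinates, and forward
    the block unmodified."""
    from .io import open_output

    with open_output(path, "auto") as fh:
        header = ["Block", "Chr", "Start", "Stop"]
        for spec in statistics:
            header.extend(spec.headers())
        fh.write(",".join(header) + "\n")
        for ordinal, block in enumerate(blocks):
            chrom, start, stop = _reference_interval(block, ref_species)
            row = [str(ordinal), str(chrom), str(start), str(stop)]
            for spec in statistics:
                row.extend(_fmt(v) for v in spec.compute(block))
            fh.write(",".join(row) + "\n")
            yield block
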