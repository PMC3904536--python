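"""The streaming filter chain.

Every operation here consumes a lazy iterable of blocks and yields one, so
filters compose into single-pass, bounded-memory pipelines.  Thresholds are
inclusive "keep if compliant".
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable, Iterator, Sequence

from .model import (
    GAP,
    FeatureSet,
    MafBlock,
    MafError,
    MafSequence,
    block_length,
    coordinate_map,
    subblock,
    to_plus_strand_interval,
)

logger = logging.getLogger("mafstream")

Blocks = Iterable[MafBlock]

_UNAMBIGUOUS = frozenset("ACGT")


# ---------------------------------------------------------------------------
# data extraction


def subset(
    blocks: Blocks,
    species: Sequence[str],
    strict: bool = False,
    keep_others: bool = False,
    remove_duplicates: bool = False,
    keep_first_duplicate: bool = False,
) -> Iterator[MafBlock]:
    """Keep the rows of the listed species.

    With *strict*, blocks missing any listed species are discarded; with
    *remove_duplicates*, blocks where a listed species occurs more than
    once are discarded (or deduplicated to the first row when
    *keep_first_duplicate* is set).  Blocks left without rows are dropped.
    """
    if not species:
        raise MafError("subset requires a non-empty species list")
    wanted = list(species)
    wanted_set = set(wanted)
    for block in blocks:
        present = Counter(s.species for s in block.sequences)
        if strict and any(present[sp] == 0 for sp in wanted):
            continue
        dupes = [sp for sp in wanted if present[sp] > 1]
        if dupes and remove_duplicates and not keep_first_duplicate:
            continue
        rows = []
        seen: set[str] = set()
        for s in block.sequences:
            if s.species in wanted_set:
                if s.species in dupes and keep_first_duplicate and s.species in seen:
                    continue
                seen.add(s.species)
                rows.append(s)
            elif keep_others:
                rows.append(s)
        if rows:
            yield MafBlock(rows, block.score, block.tree, dict(block.annotations))


def _merge_two(
    prev: MafBlock, nxt: MafBlock, species: Sequence[str], max_dist: int
) -> MafBlock | None:
    """Merge two consecutive blocks if syntenic for every listed species."""
    gaps: dict[str, int] = {}
    for sp in species:
        a, b = prev.find(sp), nxt.find(sp)
        if len(a) != 1 or len(b) != 1:
            return None
        pa, pb = a[0], b[0]
        if pa.chromosome != pb.chromosome or pa.strand != pb.strand:
            return None
        dist = pb.start - (pa.start + pa.size)
        if dist < 0 or dist > max_dist:
            return None
        gaps[sp] = dist

    len_prev, len_next = block_length(prev), block_length(nxt)
    listed = set(species)
    # rows present exactly once on both sides chain when their own gap fits
    chained: dict[str, int] = dict(gaps)
    for sp in sorted({s.species for s in prev.sequences} & {s.species for s in nxt.sequences}):
        if sp in listed:
            continue
        a, b = prev.find(sp), nxt.find(sp)
        if len(a) != 1 or len(b) != 1:
            continue
        pa, pb = a[0], b[0]
        if pa.chromosome != pb.chromosome or pa.strand != pb.strand:
            continue
        dist = pb.start - (pa.start + pa.size)
        if 0 <= dist <= max_dist:
            chained[sp] = dist

    fill = max(chained.values(), default=0)
    rows: list[MafSequence] = []
    used_next: set[int] = set()

    def pad_scores(scores, n_fill, n_dash, other_scores, other_len):
        if scores is None and other_scores is None:
            return None
        left = scores if scores is not None else [-1] * len_prev
        right = other_scores if other_scores is not None else [-1] * other_len
        return left + [0] * n_fill + [-1] * n_dash + right

    for s in prev.sequences:
        sp = s.species
        if sp in chained:
            other = nxt.find(sp)[0]
            used_next.add(id(other))
            g = chained[sp]
            text = s.text + "N" * g + "-" * (fill - g) + other.text
            rows.append(
                MafSequence(
                    sp,
                    s.chromosome,
                    s.start,
                    s.size + g + other.size,
                    s.strand,
                    s.src_size,
                    text,
                    pad_scores(s.scores, g, fill - g, other.scores, len_next),
                )
            )
        else:
            scores = None if s.scores is None else s.scores + [-1] * (fill + len_next)
            rows.append(
                MafSequence(
                    sp,
                    s.chromosome,
                    s.start,
                    s.size,
                    s.strand,
                    s.src_size,
                    s.text + "-" * (fill + len_next),
                    scores,
                )
            )
    for s in nxt.sequences:
        if id(s) in used_next:
            continue
        scores = None if s.scores is None else [-1] * (len_prev + fill) + s.scores
        rows.append(
            MafSequence(
                s.species,
                s.chromosome,
                s.start,
                s.size,
                s.strand,
                s.src_size,
                "-" * (len_prev + fill) + s.text,
                scores,
            )
        )
    return MafBlock(rows)


def merge(
    blocks: Blocks, species: Sequence[str], max_dist: int = 0
) -> Iterator[MafBlock]:
    """Greedily merge consecutive syntenic blocks.

    Two consecutive blocks merge when every listed species occurs exactly
    once in both with equal chromosome and strand, and the inter-block
    distance lies in [0, max_dist].  The gap is filled with 'N' in chained
    rows and '-' elsewhere (unknown sequence, not deletion).
    """
    current: MafBlock | None = None
    for block in blocks:
        if current is None:
            current = block
            continue
        merged = _merge_two(current, block, species, max_dist)
        if merged is not None:
            current = merged
        else:
            yield current
            current = block
    if current is not None:
        yield current


def concatenate(blocks: Blocks, min_length: int) -> Iterator[MafBlock]:
    """Append consecutive blocks species-wise until *min_length* columns.

    Blocks are appended as long as they share an identical species
    multiset; a change of species set flushes the accumulator.
    Concatenated rows keep the first block's coordinates with size
    recounted, and the result is flagged ``coordinates_valid=False``.
    """

    pending: list[MafBlock] = []
    pending_len = 0

    def flush() -> MafBlock | None:
        nonlocal pending, pending_len
        if not pending:
            return None
        if len(pending) == 1:
            out = pending[0]
        else:
            first = pending[0]
            rows = []
            for idx, base in enumerate(first.sequences):
                text = "".join(b.sequences[idx].text for b in pending)
                scores = None
                if all(b.sequences[idx].scores is not None for b in pending):
                    scores = [v for b in pending for v in b.sequences[idx].scores]
                rows.append(
                    MafSequence(
                        base.species,
                        base.chromosome,
                        base.start,
                        len(text) - text.count(GAP),
                        base.strand,
                        base.src_size,
                        text,
                        scores,
                    )
                )
            out = MafBlock(rows, annotations={"coordinates_valid": False})
        pending = []
        pending_len = 0
        return out

    signature = None
    for block in blocks:
        sig = tuple(sorted(s.species for s in block.sequences))
        if pending and sig != signature:
            flushed = flush()
            if flushed is not None:
                yield flushed
        if not pending:
            signature = sig
        # align row order to the first pending block by species occurrence
        if pending:
            order: dict[str, list[MafSequence]] = {}
            for s in block.sequences:
                order.setdefault(s.species, []).append(s)
            reordered = [
                order[s.species].pop(0) for s in pending[0].sequences
            ]
            block = MafBlock(reordered, block.score, block.tree, dict(block.annotations))
        pending.append(block)
        pending_len += block_length(block)
        if pending_len >= min_length:
            flushed = flush()
            if flushed is not None:
                yield flushed
    flushed = flush()
    if flushed is not None:
        yield flushed


def remove_full_gap_columns(
    blocks: Blocks, species: Sequence[str]
) -> Iterator[MafBlock]:
    """Delete every column where ALL listed (ingroup) species have a gap.

    Ingroup coordinates stay exact (only their gaps are removed); residues
    of other rows falling in deleted columns are discarded, making those
    rows' coordinates approximate.
    """
    ingroup = set(species)
    for block in blocks:
        focal = [s for s in block.sequences if s.species in ingroup]
        if not focal:
            yield block
            continue
        keep = [
            i
            for i in range(block_length(block))
            if any(s.text[i] != GAP for s in focal)
        ]
        if len(keep) == block_length(block):
            yield block
            continue
        if not keep:
            continue
        rows = []
        for s in block.sequences:
            text = "".join(s.text[i] for i in keep)
            scores = None if s.scores is None else [s.scores[i] for i in keep]
            rows.append(
                MafSequence(
                    s.species,
                    s.chromosome,
                    s.start,
                    len(text) - text.count(GAP),
                    s.strand,
                    s.src_size,
                    text,
                    scores,
                )
            )
        yield MafBlock(rows, block.score, None, dict(block.annotations))


# ---------------------------------------------------------------------------
# feature-based filters


def _feature_column_ranges(
    ref: MafSequence, features, clip: bool = True
) -> list[tuple[int, int, object]]:
    """Map forward-strand feature intervals to column ranges of the block."""
    chrom, fwd_start, fwd_end = to_plus_strand_interval(ref)
    positions = coordinate_map(ref)  # strand-relative
    if ref.strand == "+":
        fwd = positions
    else:
        fwd = [None if p is None else ref.src_size - 1 - p for p in positions]
    ranges = []
    for feature in features:
        lo = max(feature.start, fwd_start) if clip else feature.start
        hi = min(feature.end, fwd_end) if clip else feature.end
        cols = [i for i, p in enumerate(fwd) if p is not None and lo <= p < hi]
        if cols:
            ranges.append((min(cols), max(cols) + 1, feature))
    return ranges


def _merge_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ranges:
        return []
    ranges = sorted(ranges)
    out = [list(ranges[0])]
    for lo, hi in ranges[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [tuple(r) for r in out]


def _complement_ranges(length: int, ranges: list[tuple[int, int]]):
    pos = 0
    for lo, hi in ranges:
        if lo > pos:
            yield pos, lo
        pos = max(pos, hi)
    if pos < length:
        yield pos, length


def feature_filter(
    blocks: Blocks, features: FeatureSet, reference_species: str
) -> Iterator[MafBlock]:
    """Excise regions overlapping *features* on the reference row, splitting
    each block into the surviving fragments."""
    for block in blocks:
        rows = block.find(reference_species)
        if not rows:
            logger.warning(
                "reference species %r absent; block passes unfiltered",
                reference_species,
            )
            yield block
            continue
        ref = rows[0]
        chrom, start, end = to_plus_strand_interval(ref)
        hits = features.overlapping(ref.species, chrom, start, end)
        if not hits:
            yield block
            continue
        excised = _merge_ranges(
            [(lo, hi) for lo, hi, _ in _feature_column_ranges(ref, hits)]
        )
        for lo, hi in _complement_ranges(block_length(block), excised):
            yield subblock(block, lo, hi)


def _reverse_complement_block(block: MafBlock) -> MafBlock:
    return MafBlock(
        [s.reverse_complement() for s in block.sequences],
        None,
        None,
        dict(block.annotations),
    )


def extract_features(
    blocks: Blocks,
    features: FeatureSet,
    reference_species: str,
    complete_only: bool = False,
) -> Iterator[MafBlock]:
    """Emit one block per (block x overlapping feature) intersection.

    The feature id is carried as a block annotation.  Minus-strand features
    yield reverse-complemented blocks, so the emitted alignment reads in
    the feature's 5'->3' orientation.  With *complete_only*, features not
    fully contained in the reference interval are skipped.
    """
    for block in blocks:
        rows = block.find(reference_species)
        if not rows:
            logger.warning(
                "reference species %r absent; block yields no features",
                reference_species,
            )
            continue
        ref = rows[0]
        chrom, start, end = to_plus_strand_interval(ref)
        hits = features.overlapping(ref.species, chrom, start, end)
        for lo, hi, feature in _feature_column_ranges(ref, hits):
            if complete_only and not (feature.start >= start and feature.end <= end):
                continue
            piece = subblock(block, lo, hi)
            piece.annotations["feature_id"] = feature.id
            if feature.strand == "-":
                piece = _reverse_complement_block(piece)
            yield piece


def select_chromosome(
    blocks: Blocks, reference_species: str, chromosome: str
) -> Iterator[MafBlock]:
    """Keep blocks whose reference row's chromosome matches exactly."""
    for block in blocks:
        rows = block.find(reference_species)
        if rows and rows[0].chromosome == chromosome:
            yield block


def min_block_length(blocks: Blocks, min_columns: int) -> Iterator[MafBlock]:
    return (b for b in blocks if block_length(b) >= min_columns)


def min_block_size(blocks: Blocks, min_sequences: int) -> Iterator[MafBlock]:
    return (b for b in blocks if len(b.sequences) >= min_sequences)


# ---------------------------------------------------------------------------
# windowing


def window_split(
    blocks: Blocks, window_size: int, alignment: str = "center"
) -> Iterator[MafBlock]:
    """Partition blocks into consecutive windows of *window_size* columns.

    Remainder columns are dropped at the right (``left``), split evenly on
    both sides (``center``), dropped at the left (``right``); ``adjust``
    instead balances window sizes so nothing is dropped.  Blocks shorter
    than the window yield nothing (or themselves, with ``adjust``).
    """
    if window_size < 1:
        raise MafError("window_size must be >= 1")
    if alignment not in ("left", "center", "right", "adjust"):
        raise MafError(f"unknown window alignment {alignment!r}")
    for block in blocks:
        length = block_length(block)
        if alignment == "adjust":
            if length == 0:
                continue
            if length <= window_size:
                yield block
                continue
            n = math.ceil(length / window_size)
            base, extra = divmod(length, n)
            pos = 0
            for k in range(n):
                size = base + (1 if k < extra else 0)
                yield subblock(block, pos, pos + size)
                pos += size
            continue
        n = length // window_size
        if n == 0:
            continue
        rem = length - n * window_size
        offset = {"left": 0, "center": rem // 2, "right": rem}[alignment]
        for k in range(n):
            lo = offset + k * window_size
            yield subblock(block, lo, lo + window_size)


# ---------------------------------------------------------------------------
# sliding-window cleaning

PREDICATES = ("gap_count", "gap_events", "entropy", "mask_count", "quality_mean")


def _count_gap_runs(text: str) -> int:
    runs = 0
    in_gap = False
    for ch in text:
        if ch == GAP:
            if not in_gap:
                runs += 1
            in_gap = True
        else:
            in_gap = False
    return runs


def column_entropy(column: Sequence[str]) -> float:
    """Shannon entropy (bits) of the {A,C,G,T} frequencies of a column,
    gaps and N excluded; 0*log(0) = 0."""
    residues = [c.upper() for c in column if c.upper() in _UNAMBIGUOUS]
    if not residues:
        return 0.0
    total = len(residues)
    h = 0.0
    for count in Counter(residues).values():
        p = count / total
        h -= p * math.log2(p)
    return h


def _window_fails(
    block: MafBlock,
    focal: list[MafSequence],
    lo: int,
    hi: int,
    predicate: str,
    params: dict,
) -> bool:
    if predicate == "gap_count":
        gaps = sum(s.text.count(GAP, lo, hi) for s in focal)
        return gaps > params["max_gap"]
    if predicate == "gap_events":
        events = sum(_count_gap_runs(s.text[lo:hi]) for s in focal)
        return events > params["max_events"]
    if predicate == "entropy":
        bad = 0
        for i in range(lo, hi):
            if column_entropy([s.text[i] for s in focal]) > params["entropy_threshold"]:
                bad += 1
        return bad > params["max_columns"]
    if predicate == "mask_count":
        masked = sum(1 for s in focal for ch in s.text[lo:hi] if ch.islower())
        return masked > params["max_masked"]
    if predicate == "quality_mean":
        values = [
            v for s in focal for v in s.scores[lo:hi] if v >= 0
        ]
        if not values:
            return False
        return sum(values) / len(values) < params["min_quality"]
    raise MafError(f"unknown window predicate {predicate!r}")


def _failing_ranges(
    block: MafBlock,
    focal: list[MafSequence],
    window_size: int,
    step: int,
    predicate: str,
    params: dict,
) -> list[tuple[int, int]]:
    length = block_length(block)
    ranges = []
    lo = 0
    while lo + window_size <= length:
        if _window_fails(block, focal, lo, lo + window_size, predicate, params):
            ranges.append((lo, lo + window_size))
        lo += step
    return _merge_ranges(ranges)


def sliding_window_clean(
    blocks: Blocks,
    window_size: int,
    step: int,
    predicate: str,
    focal_species: Sequence[str] | None = None,
    action: str = "remove",
    **params,
) -> Iterator[MafBlock]:
    """Slide a window of *window_size* columns by *step* and excise (or
    mask with 'N') the union of failing windows.

    Predicates (a window FAILS when):

    - ``gap_count``: total gaps across focal rows > ``max_gap``
    - ``gap_events``: distinct gap openings across focal rows > ``max_events``
    - ``entropy``: columns with entropy > ``entropy_threshold`` number more
      than ``max_columns``
    - ``mask_count``: lowercase (soft-masked) characters > ``max_masked``
    - ``quality_mean``: mean quality score < ``min_quality`` (blocks
      without scores pass with a warning)

    With ``action="remove"``, excision is iterated until no window inside
    any emitted fragment fails, so the output is sound regardless of step.
    """
    if step < 1 or window_size < 1:
        raise MafError("window_size and step must be >= 1")
    if step > window_size:
        raise MafError("step must not exceed window_size")
    if predicate not in PREDICATES:
        raise MafError(f"unknown window predicate {predicate!r}")
    if action not in ("remove", "mask"):
        raise MafError(f"unknown action {action!r}")

    for block in blocks:
        if focal_species is None:
            focal = list(block.sequences)
        else:
            focal = [s for s in block.sequences if s.species in set(focal_species)]
        if predicate == "quality_mean" and any(s.scores is None for s in focal):
            logger.warning("block lacks quality scores; passes quality filter")
            yield block
            continue
        if not focal:
            yield block
            continue

        if action == "mask":
            ranges = _failing_ranges(
                block, focal, window_size, step, predicate, params
            )
            if not ranges:
                yield block
                continue
            rows = []
            for s in block.sequences:
                chars = list(s.text)
                for lo, hi in ranges:
                    for i in range(lo, hi):
                        if chars[i] != GAP:
                            chars[i] = "N"
                text = "".join(chars)
                rows.append(
                    MafSequence(
                        s.species,
                        s.chromosome,
                        s.start,
                        s.size,
                        s.strand,
                        s.src_size,
                        text,
                        None if s.scores is None else list(s.scores),
                    )
                )
            yield MafBlock(rows, block.score, None, dict(block.annotations))
            continue

        # remove: iterate excision to a fixed point so no surviving window fails
        queue = [block]
        while queue:
            current = queue.pop(0)
            if focal_species is None:
                cur_focal = list(current.sequences)
            else:
                cur_focal = [
                    s for s in current.sequences if s.species in set(focal_species)
                ]
            ranges = _failing_ranges(
                current, cur_focal, window_size, step, predicate, params
            )
            if not ranges:
                yield current
                continue
            fragments = [
                subblock(current, lo, hi)
                for lo, hi in _complement_ranges(block_length(current), ranges)
            ]
            queue = fragments + queue


# ---------------------------------------------------------------------------
# phylogenetic stream filters


def distance_estimation(blocks: Blocks, method: str = "kimura") -> Iterator[MafBlock]:
    """Attach a pairwise distance matrix to each block (annotation
    ``"distance_matrix"``)."""
    from .phylo import distance_matrix

    for block in blocks:
        block.annotations["distance_matrix"] = distance_matrix(block, method)
        yield block


def distance_based_phylogeny(blocks: Blocks, method: str = "bionj") -> Iterator[MafBlock]:
    """Build a tree from each block's attached distance matrix."""
    from .phylo import build_tree

    for block in blocks:
        matrix = block.annotations.get("distance_matrix")
        if matrix is None:
            raise MafError(
                "distance_based_phylogeny requires a prior distance_estimation step"
            )
        block.tree = build_tree(matrix, method)
        yield block


def new_outgroup(blocks: Blocks, outgroup: str) -> Iterator[MafBlock]:
    """Reroot each block's tree on the given outgroup species."""
    from .phylo import reroot_with_outgroup

    for block in blocks:
        if block.tree is not None:
            block.tree = reroot_with_outgroup(block.tree, outgroup)
        yield block


def drop_species_filter(blocks: Blocks, species: str) -> Iterator[MafBlock]:
    """Prune a species' leaf from each block's tree."""
    from .phylo import drop_species

    for block in blocks:
        if block.tree is not None:
            block.tree = drop_species(block.tree, species)
        yield block
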