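"""Readers and writers for on-disk formats, with transparent compression.

Supported formats: MAF (UCSC), Fasta, Clustal, Phylip (strict and relaxed),
GFF3, BED, Newick and VCF 4.x.  Every reader and writer accepts a
compression kind in ``{none, zip, gzip, bzip2}`` (or ``auto`` to detect it
from the filename extension).
"""

from __future__ import annotations

import bz2
import gzip
import io as _stdio
import logging
import os
import re
import zipfile
from contextlib import contextmanager
from typing import IO, Iterable, Iterator

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GAP,
    Feature,
    FeatureSet,
    MafBlock,
    MafError,
    MafSequence,
    coordinate_map,
    to_plus_strand_interval,
)

logger = logging.getLogger("mafstream")

COMPRESSION_KINDS = ("none", "zip", "gzip", "bzip2")

_EXTENSIONS = {".gz": "gzip", ".bz2": "bzip2", ".zip": "zip"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(MafError):
    """Raised on malformed input, carrying the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# compression plumbing


def detect_compression(path: str | os.PathLike) -> str:
    return _EXTENSIONS.get(os.path.splitext(str(path))[1], "none")


def _check_kind(compression: str) -> str:
    if compression not in COMPRESSION_KINDS + ("auto",):
        raise ValueError(
            f"unknown compression {compression!r}; expected one of "
            f"{COMPRESSION_KINDS + ('auto',)}"
        )
    return compression


@contextmanager
def open_input(path: str | os.PathLike, compression: str = "auto") -> Iterator[IO[str]]:
    """Open *path* for text reading, decompressing per *compression*."""
    kind = _check_kind(compression)
    if kind == "auto":
        kind = detect_compression(path)
    if kind == "none":
        with open(path, "rt", encoding="utf-8") as fh:
            yield fh
    elif kind == "gzip":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            yield fh
    elif kind == "bzip2":
        with bz2.open(path, "rt", encoding="utf-8") as fh:
            yield fh
    else:  # zip: read the first archive member
        with zipfile.ZipFile(path) as zf:
            names = zf.namelist()
            if not names:
                raise ParseError(f"zip archive {path} has no members")
            with zf.open(names[0]) as raw:
                yield _stdio.TextIOWrapper(raw, encoding="utf-8")


@contextmanager
def open_output(
    path: str | os.PathLike, compression: str = "auto"
) -> Iterator[IO[str]]:
    """Open *path* for text writing, compressing per *compression*.

    Writing ``zip`` produces a single-member archive whose member name is
    the target basename without the ``.zip`` extension.
    """
    kind = _check_kind(compression)
    if kind == "auto":
        kind = detect_compression(path)
    if kind == "none":
        with open(path, "wt", encoding="utf-8") as fh:
            yield fh
    elif kind == "gzip":
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            yield fh
    elif kind == "bzip2":
        with bz2.open(path, "wt", encoding="utf-8") as fh:
            yield fh
    else:
        member = os.path.basename(str(path))
        if member.endswith(".zip"):
            member = member[:-4] or "data"
        buf = _stdio.StringIO()
        yield buf
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr(member, buf.getvalue())


# ---------------------------------------------------------------------------
# MAF


def split_src(src: str) -> tuple[str, str]:
    """Split a MAF ``src`` field into (species, chromosome) on the FIRST dot.

    A src with no dot yields species == chromosome == src (degenerate
    single-genome files).
    """
    if "." in src:
        species, chromosome = src.split(".", 1)
        return species, chromosome
    return src, src


def _decode_quality(qual: str, text: str, lineno: int) -> list[int]:
    if len(qual) != len(text):
        raise ParseError(
            f"'q' line value length {len(qual)} does not match alignment "
            f"text length {len(text)}",
            lineno,
        )
    scores: list[int] = []
    for i, (q, t) in enumerate(zip(qual, text)):
        if t == GAP:
            if q not in "-.":
                raise ParseError(
                    f"'q' line carries score {q!r} at gap column {i}", lineno
                )
            scores.append(-1)
        elif q in "-.":
            raise ParseError(f"'q' line has gap mark at residue column {i}", lineno)
        elif q.isdigit():
            scores.append(int(q))
        elif q in "Ff":
            scores.append(99)
        else:
            raise ParseError(f"invalid quality character {q!r}", lineno)
    return scores


def _encode_quality(scores: list[int], src: str) -> str:
    chars = []
    for v in scores:
        if v == -1:
            chars.append("-")
        elif 0 <= v <= 9:
            chars.append(str(v))
        elif v == 99:
            chars.append("F")
        else:
            raise MafError(
                f"quality score {v} for {src} cannot be encoded as a MAF 'q' "
                "character (allowed: -1, 0-9, 99)"
            )
    return "".join(chars)


def _parse_s_line(fields: list[str], lineno: int) -> MafSequence:
    if len(fields) != 7:
        raise ParseError(
            f"'s' line has {len(fields)} fields, expected 7", lineno
        )
    _, src, start, size, strand, src_size, text = fields
    try:
        start_i, size_i, src_size_i = int(start), int(size), int(src_size)
    except ValueError:
        raise ParseError(f"non-numeric coordinates in 's' line: {fields[2:6]}", lineno)
    if strand not in "+-":
        raise ParseError(f"invalid strand {strand!r}", lineno)
    species, chromosome = split_src(src)
    seq = MafSequence(species, chromosome, start_i, size_i, strand, src_size_i, text)
    if seq.ungapped_length() != size_i:
        raise ParseError(
            f"declared size {size_i} does not match {seq.ungapped_length()} "
            f"non-gap characters for {src}",
            lineno,
        )
    if start_i + size_i > src_size_i:
        raise ParseError(
            f"start+size exceeds srcSize for {src}", lineno
        )
    return seq


def read_maf(
    path: str | os.PathLike, compression: str = "auto"
) -> Iterator[MafBlock]:
    """Lazily iterate over the blocks of a MAF file.

    Blocks are yielded in file order, one at a time; the underlying stream
    is consumed block by block.  ``s`` lines become :class:`MafSequence`
    rows (``src`` split on the first dot), ``q`` lines attach quality scores
    to the preceding ``s`` line, and a blank line ends a block.
    """
    with open_input(path, compression) as fh:
        block: MafBlock | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            if not stripped:
                if block is not None and block.sequences:
                    yield block
                block = None
                continue
            fields = stripped.split()
            tag = fields[0]
            if tag == "a":
                if block is not None and block.sequences:
                    yield block
                score = None
                for f in fields[1:]:
                    if f.startswith("score="):
                        try:
                            score = float(f[6:])
                        except ValueError:
                            raise ParseError(f"non-numeric score {f[6:]!r}", lineno)
                block = MafBlock(score=score)
            elif tag == "s":
                if block is None:
                    block = MafBlock()
                block.sequences.append(_parse_s_line(fields, lineno))
            elif tag == "q":
                if block is None or not block.sequences:
                    raise ParseError("'q' line without a preceding 's' line", lineno)
                if len(fields) != 3:
                    raise ParseError(
                        f"'q' line has {len(fields)} fields, expected 3", lineno
                    )
                target = block.sequences[-1]
                block.sequences[-1].scores = _decode_quality(
                    fields[2], target.text, lineno
                )
            elif tag in ("i", "e"):
                continue  # synteny context lines: out of scope, skipped
            else:
                raise ParseError(f"unrecognized MAF line type {tag!r}", lineno)
        if block is not None and block.sequences:
            yield block


def format_block(block: MafBlock) -> str:
    """Serialize one block to MAF text (``a``/``s``/``q`` lines + blank)."""
    out = []
    if block.score is not None:
        out.append(f"a score={block.score:g}")
    else:
        out.append("a")
    if block.sequences:
        w_src = max(len(s.src) for s in block.sequences)
        w_start = max(len(str(s.start)) for s in block.sequences)
        w_size = max(len(str(s.size)) for s in block.sequences)
        w_ssize = max(len(str(s.src_size)) for s in block.sequences)
        for s in block.sequences:
            out.append(
                f"s {s.src:<{w_src}} {s.start:>{w_start}} {s.size:>{w_size}} "
                f"{s.strand} {s.src_size:>{w_ssize}} {s.text}"
            )
            if s.scores is not None:
                pad = w_start + w_size + w_ssize + 5
                out.append(
                    f"q {s.src:<{w_src}} {'':<{pad}}{_encode_quality(s.scores, s.src)}"
                )
    out.append("")
    return "\n".join(out) + "\n"


def write_maf(
    blocks: Iterable[MafBlock],
    path: str | os.PathLike,
    compression: str = "auto",
) -> int:
    """Write *blocks* to a MAF file; returns the number of blocks written."""
    n = 0
    with open_output(path, compression) as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write(format_block(block))
            n += 1
    return n


# ---------------------------------------------------------------------------
# Fasta import


def read_fasta_as_blocks(
    path: str | os.PathLike,
    compression: str = "auto",
    species: str | None = None,
) -> Iterator[MafBlock]:
    """Import a whole-genome Fasta file as single-sequence synteny blocks.

    Sequences must be comprehensive (every record is a complete contig
    starting at position 1), so each record becomes one block with start 0,
    forward strand and ``src_size`` equal to the record length.  Record ids
    are interpreted as ``species.chromosome``; pass *species* to treat the
    whole id as the chromosome of a fixed species instead.
    """
    with open_input(path, compression) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if species is None:
                sp, chrom = split_src(record.id)
            else:
                sp, chrom = species, record.id
            text = str(record.seq)
            n = len(text)
            yield MafBlock(
                [MafSequence(sp, chrom, 0, n, "+", n, text)]
            )


# ---------------------------------------------------------------------------
# features (GFF3 / BED)


def read_features(
    path: str | os.PathLike,
    format: str = "gff3",
    compression: str = "auto",
    species: str | None = None,
    kinds: set[str] | None = None,
) -> FeatureSet:
    """Load a GFF3 (1-based inclusive) or BED (0-based half-open) file into
    a :class:`FeatureSet` with unified 0-based half-open coordinates.

    The seqid column is interpreted as ``species.chromosome`` unless a fixed
    *species* is given.  *kinds* optionally restricts GFF3 records by type.
    """
    fmt = format.lower()
    if fmt not in ("gff3", "gff", "bed"):
        raise ValueError(f"unsupported feature format {format!r}")
    features = FeatureSet()
    with open_input(path, compression) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if fmt in ("gff3", "gff"):
                if len(fields) < 8:
                    raise ParseError(
                        f"GFF3 line has {len(fields)} fields, expected >= 8", lineno
                    )
                seqid, _source, kind, start, end, _score, strand, _frame = fields[:8]
                if kinds is not None and kind not in kinds:
                    continue
                try:
                    s, e = int(start) - 1, int(end)
                except ValueError:
                    raise ParseError("non-numeric GFF3 coordinates", lineno)
                attrs = fields[8] if len(fields) > 8 else ""
                m = re.search(r"(?:^|;)(?:ID|Name)=([^;]+)", attrs)
                fid = m.group(1) if m else f"{kind}:{lineno}"
            else:
                if len(fields) < 3:
                    raise ParseError(
                        f"BED line has {len(fields)} fields, expected >= 3", lineno
                    )
                seqid, start, end = fields[:3]
                try:
                    s, e = int(start), int(end)
                except ValueError:
                    raise ParseError("non-numeric BED coordinates", lineno)
                fid = fields[3] if len(fields) > 3 else f"bed:{lineno}"
                strand = fields[5] if len(fields) > 5 else "."
                kind = "region"
            if e <= s or s < 0:
                raise ParseError(f"invalid interval [{s}, {e})", lineno)
            if species is None:
                sp, chrom = split_src(seqid)
            else:
                sp, chrom = species, seqid
            features.add(Feature(sp, chrom, s, e, strand or ".", kind, fid))
    return features


# ---------------------------------------------------------------------------
# alignment export with coordinate-bearing headers


def ensembl_name(seq: MafSequence) -> str:
    """Coordinate-bearing sequence name
    ``species.chromosome/first-last(strand)`` with 1-based inclusive
    forward-strand positions."""
    chrom, start, end = to_plus_strand_interval(seq)
    return f"{seq.species}.{chrom}/{start + 1}-{end}({seq.strand})"


_NAME_RE = re.compile(r"^(?P<src>.+)/(?P<first>\d+)-(?P<last>\d+)\((?P<strand>[+-])\)$")


def parse_ensembl_name(name: str) -> dict:
    """Invert :func:`ensembl_name`: returns species, chromosome, 0-based
    half-open forward-strand start/end, and strand."""
    m = _NAME_RE.match(name)
    if m is None:
        raise MafError(f"cannot parse coordinate header {name!r}")
    species, chromosome = split_src(m.group("src"))
    return {
        "species": species,
        "chromosome": chromosome,
        "start": int(m.group("first")) - 1,
        "end": int(m.group("last")),
        "strand": m.group("strand"),
    }


ALIGNMENT_FORMATS = ("fasta", "clustal", "phylip", "phylip-relaxed")


def write_alignment(block: MafBlock, handle_or_path, format: str = "fasta") -> None:
    """Write one block as a multiple alignment with Ensembl-style headers."""
    fmt = format.lower()
    if fmt not in ALIGNMENT_FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}")
    records = [
        SeqRecord(Seq(s.text), id=ensembl_name(s), description="")
        for s in block.sequences
    ]
    if fmt == "phylip":
        too_long = [r.id for r in records if len(r.id) > 10]
        if too_long:
            raise MafError(
                f"strict phylip limits names to 10 characters ({too_long[0]!r} "
                "overflows); use format 'phylip-relaxed'"
            )
    msa = MultipleSeqAlignment(records)
    if hasattr(handle_or_path, "write"):
        AlignIO.write(msa, handle_or_path, fmt)
    else:
        with open(handle_or_path, "at", encoding="utf-8") as fh:
            AlignIO.write(msa, fh, fmt)


# ---------------------------------------------------------------------------
# trees


def write_trees(blocks: Iterable[MafBlock], path, compression: str = "auto") -> int:
    """One Newick line per block with a tree, in stream order.

    Blocks lacking a tree are skipped with a logged warning.  Returns the
    number of trees written.
    """
    from .phylo import to_newick

    n = 0
    with open_output(path, compression) as fh:
        for i, block in enumerate(blocks):
            if block.tree is None:
                logger.warning("block %d has no attached tree; skipped", i)
                continue
            fh.write(to_newick(block.tree) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# VCF export

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mafstream
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count among non-reference sequences">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Number of called alleles among non-reference sequences">
"""

_UNAMBIGUOUS = frozenset("ACGT")


def vcf_header(sample_names: list[str] | None) -> str:
    """VCF 4.x header lines, including the #CHROM line."""
    out = _VCF_HEADER
    columns = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if sample_names is not None:
        out += '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n'
        columns += "\tFORMAT\t" + "\t".join(sample_names)
    return out + columns + "\n"


def vcf_lines_for_block(
    block: MafBlock, reference: str, sample_names: list[str] | None = None
) -> list[str]:
    """Formatted VCF record lines (no newline) for one block's SNPs."""
    lines = []
    for chrom, pos, ref_c, alts, an, ac, gts in _vcf_records_for_block(
        block, reference, sample_names
    ):
        info = f"AC={','.join(map(str, ac))};AN={an}"
        row = [chrom, str(pos), ".", ref_c, ",".join(alts), ".", ".", info]
        if gts is not None:
            row.append("GT")
            row.extend(gts)
        lines.append("\t".join(row))
    return lines


def _vcf_records_for_block(
    block: MafBlock, reference: str, sample_names: list[str] | None
) -> list[tuple]:
    ref_rows = block.find(reference)
    if len(ref_rows) > 1:
        raise MafError(f"reference species {reference!r} duplicated in block")
    if not ref_rows:
        logger.warning("reference species %r absent from block; skipped", reference)
        return []
    ref = ref_rows[0]
    others = [s for s in block.sequences if s is not ref]
    flip = ref.strand == "-"
    positions = coordinate_map(ref)
    records = []
    for col, pos in enumerate(positions):
        if pos is None:
            continue
        ref_char = ref.text[col].upper()
        if ref_char not in _UNAMBIGUOUS:
            continue
        calls = []  # (species, residue or None) per non-reference row
        alts: list[str] = []
        for s in others:
            ch = s.text[col].upper()
            if ch not in _UNAMBIGUOUS:
                calls.append((s.species, None))
                continue
            if flip:
                ch = ch.translate(_COMPLEMENT)
            calls.append((s.species, ch))
            if ch != (ref_char.translate(_COMPLEMENT) if flip else ref_char):
                if ch not in alts:
                    alts.append(ch)
        if not alts:
            continue
        out_ref = ref_char.translate(_COMPLEMENT) if flip else ref_char
        fwd = ref.src_size - 1 - pos if flip else pos
        alleles = [out_ref] + alts
        an = sum(1 for _, c in calls if c is not None)
        ac = [sum(1 for _, c in calls if c == a) for a in alts]
        gts = None
        if sample_names is not None:
            by_species: dict[str, str] = {}
            for sp, c in calls:
                if sp not in by_species:
                    by_species[sp] = "." if c is None else str(alleles.index(c))
            gts = [by_species.get(name, ".") for name in sample_names]
        records.append((ref.chromosome, fwd + 1, out_ref, alts, an, ac, gts))
    records.sort(key=lambda r: r[1])
    return records


def write_vcf(
    blocks: Iterable[MafBlock],
    reference: str,
    path,
    genotypes: bool | list[str] = False,
    compression: str = "auto",
) -> int:
    """Call SNPs against *reference* and write them as VCF 4.x records.

    For every column where the reference row holds an unambiguous residue
    and at least one other row differs with an unambiguous residue, one
    record is emitted.  Coordinates are 1-based forward-strand positions;
    residues from minus-strand reference rows are complemented.  With
    *genotypes* (a species list, or ``True`` to take the non-reference
    species of the first block), one haploid GT column is written per
    sample.  Returns the number of records written.
    """
    n = 0
    blocks = iter(blocks)
    first: MafBlock | None = next(blocks, None)
    sample_names: list[str] | None = None
    if genotypes:
        if isinstance(genotypes, (list, tuple)):
            sample_names = list(genotypes)
        elif first is not None:
            seen = []
            for s in first.sequences:
                if s.species != reference and s.species not in seen:
                    seen.append(s.species)
            sample_names = seen
        else:
            sample_names = []
    with open_output(path, compression) as fh:
        fh.write(vcf_header(sample_names))

        def emit(block: MafBlock) -> int:
            lines = vcf_lines_for_block(block, reference, sample_names)
            for line in lines:
                fh.write(line + "\n")
            return len(lines)

        if first is not None:
            n += emit(first)
        for block in blocks:
            n += emit(block)
    return n
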