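"""Shared fixtures: hand-written blocks, random block generators, and an
instrumented source for laziness checks."""

from __future__ import annotations

import random

import pytest

from mafstream.model import MafBlock, MafSequence

TWO_BLOCK_MAF = """\
##maf version=1
a score=23262.0
s hg18.chr7    27578828 38 + 158545518 AAA-GGGAATGTTAACCAAATGA---ATTGTCTCTTACGGTG
s panTro1.chr6 28741140 38 + 161576975 AAA-GGGAATGTTAACCAAATGA---ATTGTCTCTTACGGTG
s baboon.chr1    116834 38 +   4622798 AAA-GGGAATGTTAACCAAATGA---GTTGTCTCTTATGGTG
q baboon.chr1                          999-9999999999999999999---9999999999998789

a score=5062.0
s hg18.chr7    27699739 6 + 158545518 TAAAGA
s panTro1.chr6 28862317 6 + 161576975 TAAAGA
s baboon.chr1    241163 6 +   4622798 TAAAGA

"""


def make_block(rows, score=None):
    """rows: list of (species, chromosome, start, strand, src_size, text)."""
    seqs = []
    for species, chromosome, start, strand, src_size, text in rows:
        size = len(text) - text.count("-")
        seqs.append(MafSequence(species, chromosome, start, size, strand, src_size, text))
    return MafBlock(seqs, score=score)


def simple_block(texts, species=None, start=0, chrom="chr1", src_size=10_000):
    """Gap-aware block from raw texts with auto-derived coordinates."""
    species = species or [f"sp{i}" for i in range(len(texts))]
    return make_block(
        [(sp, chrom, start, "+", src_size, text) for sp, text in zip(species, texts)]
    )


def random_block(rng: random.Random, n_rows=4, n_cols=30, gap_rate=0.1, n_rate=0.05):
    texts = []
    for _ in range(n_rows):
        chars = []
        for _ in range(n_cols):
            r = rng.random()
            if r < gap_rate:
                chars.append("-")
            elif r < gap_rate + n_rate:
                chars.append("N")
            else:
                chars.append(rng.choice("ACGT"))
        texts.append("".join(chars))
    return simple_block(texts)


class CountingSource:
    """Wraps a block iterable and counts how many blocks were pulled."""

    def __init__(self, blocks):
        self._iter = iter(blocks)
        self.consumed = 0

    def __iter__(self):
        return self

    def __next__(self):
        block = next(self._iter)
        self.consumed += 1
        return block


@pytest.fixture
def two_block_maf(tmp_path):
    path = tmp_path / "two.maf"
    path.write_text(TWO_BLOCK_MAF)
    return path


@pytest.fixture
def rng():
    return random.Random(42)
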