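"""Synthetic-data generation: K80 sequence simulation on a tree, synteny
fixtures with known coordinate ground truth, and topology mixtures.

All generators are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

import argparse
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .model import GAP, MafBlock, MafSequence
from .phylo import TreeNode, parse_newick

_ALPHABET = np.array(list("ACGT"))
_TRANSITION_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T


def k80_rate_matrix(kappa: float) -> np.ndarray:
    """K80 rate matrix (order ACGT), scaled to one expected substitution
    per unit branch length."""
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = kappa if _TRANSITION_PARTNER[i] == j else 1.0
    np.fill_diagonal(q, -q.sum(axis=1))
    # every state leaves at rate kappa + 2, so this scales the mean rate to 1
    return q / (kappa + 2.0)


def k80_transition_matrix(kappa: float, t: float) -> np.ndarray:
    """Exact transition probabilities P(t) = expm(Q t)."""
    return expm(k80_rate_matrix(kappa) * t)


@dataclass
class SimSpec:
    """Parameters for simulating one alignment block under K80."""

    tree: TreeNode | str
    kappa: float = 2.0
    length: int = 1000
    seed: int = 0
    gap_rate: float = 0.0
    mask_rate: float = 0.0
    with_quality: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.tree, str):
            self.tree = parse_newick(self.tree)
        if not (0.0 <= self.gap_rate <= 1.0 and 0.0 <= self.mask_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")


def _evolve(
    parent_states: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    child = np.empty_like(parent_states)
    for state in range(4):
        idx = np.nonzero(parent_states == state)[0]
        if idx.size:
            child[idx] = rng.choice(4, size=idx.size, p=p[state])
    return child


def simulate_k80_block(spec: SimSpec) -> MafBlock:
    """Evolve a uniform-random root sequence down the tree under K80.

    Each leaf becomes one row with a distinct ``species.chr1`` source,
    start 0 and forward strand.  Gaps, soft-masking and quality scores are
    injected post hoc at the given rates.
    """
    rng = np.random.default_rng(spec.seed)
    root_states = rng.integers(0, 4, size=spec.length)
    leaf_states: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, states: np.ndarray) -> None:
        for child in node.children:
            t = child.length or 0.0
            child_states = (
                states.copy()
                if t == 0.0
                else _evolve(states, k80_transition_matrix(spec.kappa, t), rng)
            )
            if child.is_leaf:
                leaf_states[child.label] = child_states
            else:
                walk(child, child_states)

    tree: TreeNode = spec.tree  # type: ignore[assignment]
    if tree.is_leaf:
        leaf_states[tree.label] = root_states
    else:
        walk(tree, root_states)

    rows = []
    for label in tree.leaf_names():
        chars = _ALPHABET[leaf_states[label]].copy()
        if spec.mask_rate > 0:
            masked = rng.random(spec.length) < spec.mask_rate
            chars = np.where(masked, np.char.lower(chars), chars)
        if spec.gap_rate > 0:
            gapped = rng.random(spec.length) < spec.gap_rate
            chars = np.where(gapped, GAP, chars)
        text = "".join(chars)
        size = len(text) - text.count(GAP)
        scores = None
        if spec.with_quality:
            scores = [
                -1 if ch == GAP else int(rng.integers(0, 10)) for ch in text
            ]
        rows.append(MafSequence(label, "chr1", 0, size, "+", size, text, scores))
    return MafBlock(rows)


# ---------------------------------------------------------------------------
# synteny fixtures


@dataclass
class SyntenyFixture:
    """A generated MAF file plus its ground-truth inventory."""

    maf_text: str
    gff3_text: str
    species: list[str]
    block_length: int
    gaps: list[int]  # inter-block distances, len n_blocks - 1
    feature_blocks: list[int]
    blocks: list[MafBlock] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.gaps) + 1

    def expected_after_merge(self, max_dist: int) -> int:
        """Number of blocks left after merging boundaries with gap <= max_dist."""
        return 1 + sum(1 for g in self.gaps if g > max_dist)


def make_synteny_fixture(
    n_blocks: int,
    species: tuple[str, ...] = ("alpha", "beta", "gamma"),
    block_length: int = 50,
    gaps: list[int] | None = None,
    feature_blocks: list[int] | None = None,
    seed: int = 0,
) -> SyntenyFixture:
    """Emit *n_blocks* gap-free blocks with programmed contiguity.

    ``gaps[i]`` is the genomic distance between block i and block i+1 (for
    every species); 0 means directly mergeable.  ``feature_blocks`` lists
    block indices each fully covered by one GFF3 feature on the first
    species, at known offsets.
    """
    rng = np.random.default_rng(seed)
    if gaps is None:
        gaps = [0] * (n_blocks - 1)
    if len(gaps) != n_blocks - 1:
        raise ValueError(f"need {n_blocks - 1} inter-block gaps, got {len(gaps)}")
    feature_blocks = list(feature_blocks or [])

    total_span = n_blocks * block_length + sum(gaps)
    starts = []
    pos = 0
    for i in range(n_blocks):
        starts.append(pos)
        pos += block_length
        if i < n_blocks - 1:
            pos += gaps[i]

    blocks = []
    for i in range(n_blocks):
        rows = []
        for sp in species:
            text = "".join(_ALPHABET[rng.integers(0, 4, size=block_length)])
            rows.append(
                MafSequence(
                    sp, "chr1", starts[i], block_length, "+", total_span, text
                )
            )
        blocks.append(MafBlock(rows, score=float(i)))

    from .io import format_block

    maf_lines = ["##maf version=1\n"]
    maf_lines.extend(format_block(b) for b in blocks)

    gff_lines = ["##gff-version 3"]
    for k, idx in enumerate(feature_blocks):
        lo, hi = starts[idx], starts[idx] + block_length
        gff_lines.append(
            f"{species[0]}.chr1\tfixture\texon\t{lo + 1}\t{hi}\t.\t+\t.\tID=feat{k}"
        )

    return SyntenyFixture(
        "".join(maf_lines),
        "\n".join(gff_lines) + "\n",
        list(species),
        block_length,
        list(gaps),
        feature_blocks,
        blocks,
    )


# ---------------------------------------------------------------------------
# topology mixtures


def _apportion(n: int, proportions: list[float]) -> list[int]:
    """Largest-remainder rounding of n * proportions (sums to n exactly)."""
    raw = [p * n for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_topology_mixture(
    n_trees: int,
    proportions: tuple[float, float, float],
    labels: tuple[str, str, str, str],
    seed: int = 0,
) -> list[str]:
    """Newick quartet trees with the three triplet resolutions in exact
    given counts, shuffled by seed.

    ``labels = (a, b, c, outgroup)``; ``proportions`` order is the cherry
    (a,b), then (a,c), then (b,c).
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    a, b, c, out = labels
    shapes = [
        f"((({a}:1,{b}:1):1,{c}:2):1,{out}:3);",
        f"((({a}:1,{c}:1):1,{b}:2):1,{out}:3);",
        f"((({b}:1,{c}:1):1,{a}:2):1,{out}:3);",
    ]
    counts = _apportion(n_trees, list(proportions))
    trees = [shape for shape, k in zip(shapes, counts) for _ in range(k)]
    rng = np.random.default_rng(seed)
    rng.shuffle(trees)
    return trees


# ---------------------------------------------------------------------------
# demo-data CLI


def fixtures_main(argv: list[str] | None = None) -> int:
    """Entry point of ``mafstream-fixtures``: write demo MAF/GFF3 files."""
    parser = argparse.ArgumentParser(
        prog="mafstream-fixtures",
        description="Generate synthetic MAF (and GFF3) demo data.",
    )
    parser.add_argument("--blocks", type=int, default=10)
    parser.add_argument("--block-length", type=int, default=100)
    parser.add_argument("--species", default="alpha,beta,gamma")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", required=True, help="output MAF path")
    parser.add_argument("--gff", help="optional output GFF3 path")
    args = parser.parse_args(argv)

    fixture = make_synteny_fixture(
        args.blocks,
        tuple(args.species.split(",")),
        args.block_length,
        feature_blocks=[args.blocks // 2] if args.gff else [],
        seed=args.seed,
    )
    with open(args.out, "wt", encoding="utf-8") as fh:
        fh.write(fixture.maf_text)
    if args.gff:
        with open(args.gff, "wt", encoding="utf-8") as fh:
            fh.write(fixture.gff3_text)
    print(f"wrote {fixture.n_blocks} blocks to {args.out}")
    return 0
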