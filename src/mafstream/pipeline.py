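"""The option-file pipeline language and its execution engine.

Option files are UTF-8 text with ``key=value`` lines, ``#`` comments and
backslash continuation.  The ``maf.filter`` key holds a comma-separated
list of filter invocations ``Name(arg=value, arg=(list, of, items), ...)``;
values are parsed as int, real, flag (yes/no), string or parenthesized
list, and list items may themselves be nested calls (used by
SequenceStatistics).  Command-line arguments override file entries.

Grammar (informal)::

    file        := line*
    line        := key "=" value | comment | blank
    value       := scalar | call-list
    call-list   := call ("," call)*
    call        := NAME "(" [arg ("," arg)*] ")"
    arg         := key "=" (scalar | list | call)
    list        := "(" item ("," item)* ")"
    item        := scalar | call
    scalar      := INT | REAL | "yes" | "no" | STRING
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

from . import filters as _filters
from . import io as _io
from . import statistics as _statistics
from .model import MafBlock, MafError

logger = logging.getLogger("mafstream")


class OptionError(MafError):
    """Syntax or type error in an option file."""


# ---------------------------------------------------------------------------
# parsing


@dataclass
class FilterCall:
    name: str
    args: dict = field(default_factory=dict)

    def __repr__(self) -> str:
        return f"{self.name}({self.args})"


@dataclass
class PipelineSpec:
    input_file: str
    input_format: str = "maf"
    input_compression: str = "auto"
    input_species: str | None = None
    filters: list[FilterCall] = field(default_factory=list)
    options: dict = field(default_factory=dict)


def _parse_scalar(token: str):
    token = token.strip()
    if token.lower() in ("yes", "true"):
        return True
    if token.lower() in ("no", "false"):
        return False
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        pass
    return token


class _Tokenizer:
    """Cursor over a filter-list string, tracking column for errors."""

    def __init__(self, text: str, line: int):
        self.text = text
        self.pos = 0
        self.line = line

    def error(self, message: str) -> OptionError:
        return OptionError(f"line {self.line}, column {self.pos + 1}: {message}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def take_until(self, stops: str) -> str:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in stops:
            self.pos += 1
        return self.text[start : self.pos]

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}, found {self.peek()!r}")
        self.pos += 1


def _parse_value(tok: _Tokenizer):
    """scalar | list | nested call"""
    tok.skip_ws()
    if tok.peek() == "(":
        tok.expect("(")
        items = []
        tok.skip_ws()
        if tok.peek() == ")":
            tok.expect(")")
            return items
        while True:
            items.append(_parse_value(tok))
            tok.skip_ws()
            if tok.peek() == ",":
                tok.expect(",")
                continue
            tok.expect(")")
            return items
    word = tok.take_until("(),=").strip()
    tok.skip_ws()
    if tok.peek() == "(":
        return _parse_call_body(tok, word)
    if tok.peek() == "=":
        raise tok.error(f"unexpected '=' after {word!r}")
    return _parse_scalar(word)


def _parse_call_body(tok: _Tokenizer, name: str) -> FilterCall:
    name = name.strip()
    if not name:
        raise tok.error("missing filter name before '('")
    tok.expect("(")
    args: dict = {}
    tok.skip_ws()
    if tok.peek() == ")":
        tok.expect(")")
        return FilterCall(name, args)
    while True:
        tok.skip_ws()
        key = tok.take_until("=(),").strip()
        tok.skip_ws()
        if tok.peek() == "=":
            tok.expect("=")
            args[key] = _parse_value(tok)
        elif tok.peek() == "(":
            # bare nested call used as a positional item is not allowed here
            raise tok.error(f"argument {key!r} is missing '=value'")
        else:
            raise tok.error(f"argument {key!r} is missing '=value'")
        tok.skip_ws()
        if tok.peek() == ",":
            tok.expect(",")
            continue
        tok.expect(")")
        return FilterCall(name, args)


def parse_filter_list(text: str, line: int = 0) -> list[FilterCall]:
    tok = _Tokenizer(text, line)
    calls = []
    while True:
        tok.skip_ws()
        if not tok.peek():
            break
        name = tok.take_until("(,")
        tok.skip_ws()
        if tok.peek() != "(":
            raise tok.error(f"filter {name.strip()!r} is missing its argument list")
        calls.append(_parse_call_body(tok, name))
        tok.skip_ws()
        if tok.peek() == ",":
            tok.expect(",")
    return calls


_KNOWN_KEYS = {
    "input.file",
    "input.format",
    "input.compression",
    "input.species",
    "maf.filter",
}


def parse_options(text: str, overrides: dict | None = None) -> PipelineSpec:
    """Parse option text into a validated :class:`PipelineSpec`.

    *overrides* (e.g. from the command line) replace file entries key by
    key before validation.
    """
    raw: dict[str, tuple[str, int]] = {}
    pending = ""
    pending_line = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if "#" in line:
            line = line[: line.index("#")]
        if pending:
            line = pending + line
            lineno = pending_line
            pending = ""
        line = line.rstrip()
        if line.endswith("\\"):
            pending = line[:-1]
            pending_line = lineno
            continue
        if not line.strip():
            continue
        if "=" not in line:
            raise OptionError(f"line {lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        key = key.strip()
        if key == "maf.filter" and key in raw:
            raw[key] = (raw[key][0] + "," + value.strip(), raw[key][1])
        else:
            raw[key] = (value.strip(), lineno)
    if pending:
        raise OptionError(f"line {pending_line}: dangling continuation")

    for key, value in (overrides or {}).items():
        raw[key] = (value, 0)

    for key, (_value, lineno) in raw.items():
        if key not in _KNOWN_KEYS:
            logger.warning("line %d: unknown option %r ignored", lineno, key)

    if "input.file" not in raw:
        raise OptionError("missing required option 'input.file'")
    input_file = raw["input.file"][0]
    input_format = raw.get("input.format", ("maf", 0))[0].lower()
    if input_format not in ("maf", "fasta"):
        raise OptionError(f"unsupported input.format {input_format!r}")
    compression = raw.get("input.compression", ("auto", 0))[0].lower()
    species = raw.get("input.species", (None, 0))[0]

    calls: list[FilterCall] = []
    if "maf.filter" in raw:
        value, lineno = raw["maf.filter"]
        calls = parse_filter_list(value, lineno)
    spec = PipelineSpec(
        input_file,
        input_format,
        compression,
        species,
        calls,
        {k: v for k, (v, _) in raw.items()},
    )
    validate_spec(spec)
    return spec


def render_options(spec: PipelineSpec) -> str:
    """Serialize a spec back to option-file text (parse(render(s)) == s)."""

    def render_value(v) -> str:
        if isinstance(v, bool):
            return "yes" if v else "no"
        if isinstance(v, list):
            return "(" + ", ".join(render_value(x) for x in v) + ")"
        if isinstance(v, FilterCall):
            return render_call(v)
        return str(v)

    def render_call(call: FilterCall) -> str:
        args = ", ".join(f"{k}={render_value(v)}" for k, v in call.args.items())
        return f"{call.name}({args})"

    lines = [
        f"input.file={spec.input_file}",
        f"input.format={spec.input_format.capitalize()}",
        f"input.compression={spec.input_compression}",
    ]
    if spec.input_species:
        lines.append(f"input.species={spec.input_species}")
    if spec.filters:
        lines.append("maf.filter=" + ", ".join(render_call(c) for c in spec.filters))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# filter registry and validation

# argument types: int, float, bool, str, list (of strings), calls (list of
# plain names or nested calls)
_SIGNATURES: dict[str, dict[str, tuple[str, bool]]] = {
    "Subset": {
        "species": ("list", True),
        "strict": ("bool", False),
        "keep": ("bool", False),
        "remove_duplicates": ("bool", False),
    },
    "Merge": {"species": ("list", True), "dist_max": ("int", False)},
    "Concatenate": {"minimum_size": ("int", True)},
    "XFullGap": {"species": ("list", True)},
    "FeatureFilter": {
        "file": ("str", True),
        "format": ("str", False),
        "ref_species": ("str", True),
        "feature_species": ("str", False),
    },
    "ExtractFeature": {
        "file": ("str", True),
        "format": ("str", False),
        "ref_species": ("str", True),
        "feature_species": ("str", False),
        "complete": ("bool", False),
    },
    "SelectChr": {"ref_species": ("str", True), "chromosome": ("str", True)},
    "MinBlockLength": {"min_length": ("int", True)},
    "MinBlockSize": {"min_size": ("int", True)},
    "AlnFilter": {
        "window.size": ("int", True),
        "window.step": ("int", True),
        "max.gap": ("int", True),
        "species": ("list", False),
        "action": ("str", False),
    },
    "AlnFilter2": {
        "window.size": ("int", True),
        "window.step": ("int", True),
        "max.ev": ("int", True),
        "species": ("list", False),
        "action": ("str", False),
    },
    "EntropyFilter": {
        "window.size": ("int", True),
        "window.step": ("int", True),
        "max.ent": ("float", True),
        "max.pos": ("int", True),
        "species": ("list", False),
        "action": ("str", False),
    },
    "MaskFilter": {
        "window.size": ("int", True),
        "window.step": ("int", True),
        "max.masked": ("int", True),
        "species": ("list", False),
        "action": ("str", False),
    },
    "QualityFilter": {
        "window.size": ("int", True),
        "window.step": ("int", True),
        "min.qual": ("float", True),
        "species": ("list", False),
        "action": ("str", False),
    },
    "WindowSplit": {"window.size": ("int", True), "align": ("str", False)},
    "SequenceStatistics": {
        "statistics": ("calls", True),
        "ref_species": ("str", False),
        "file": ("str", True),
    },
    "DistanceEstimation": {"method": ("str", False)},
    "DistanceBasedPhylogeny": {"method": ("str", False)},
    "NewOutgroup": {"outgroup": ("str", True)},
    "DropSpecies": {"species": ("str", True)},
    "Output": {"file": ("str", True), "compression": ("str", False)},
    "OutputAlignments": {"file": ("str", True), "format": ("str", False)},
    "OutputTrees": {"file": ("str", True)},
    "VcfOutput": {
        "file": ("str", True),
        "reference": ("str", True),
        "genotypes": ("list", False),
    },
}


def list_filters() -> dict[str, dict[str, tuple[str, bool]]]:
    """Registered filter names and their typed signatures."""
    return dict(_SIGNATURES)


def _check_type(value, kind: str) -> bool:
    if kind == "int":
        return isinstance(value, int) and not isinstance(value, bool)
    if kind == "float":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if kind == "bool":
        return isinstance(value, bool)
    if kind == "str":
        return isinstance(value, str)
    if kind == "list":
        return isinstance(value, list) and all(
            not isinstance(v, FilterCall) for v in value
        )
    if kind == "calls":
        return isinstance(value, list)
    return False


def validate_spec(spec: PipelineSpec) -> None:
    for call in spec.filters:
        if call.name not in _SIGNATURES:
            raise OptionError(
                f"unknown filter {call.name!r}; see --list-filters for the registry"
            )
        signature = _SIGNATURES[call.name]
        for arg, value in call.args.items():
            if arg not in signature:
                raise OptionError(
                    f"{call.name}: unknown argument {arg!r} "
                    f"(expected one of {sorted(signature)})"
                )
            kind, _required = signature[arg]
            if not _check_type(value, kind):
                raise OptionError(
                    f"{call.name}: argument {arg!r} should be of type {kind}, "
                    f"got {value!r}"
                )
        for arg, (kind, required) in signature.items():
            if required and arg not in call.args:
                raise OptionError(f"{call.name}: missing required argument {arg!r}")


# ---------------------------------------------------------------------------
# pipeline assembly and execution


def _as_str_list(value) -> list[str]:
    return [str(v) for v in value]


def _statistic_specs(items: list) -> list[_statistics.StatisticSpec]:
    specs = []
    for item in items:
        if isinstance(item, FilterCall):
            kwargs = {}
            for key, val in item.args.items():
                if isinstance(val, list):
                    kwargs[key] = _as_str_list(val)
                else:
                    kwargs[key] = val
            # option-language argument names -> python keyword names
            renames = {"species1": "species1", "species2": "species2"}
            kwargs = {renames.get(k, k): v for k, v in kwargs.items()}
            specs.append(_statistics.StatisticSpec(item.name, **kwargs))
        else:
            specs.append(_statistics.StatisticSpec(str(item)))
    return specs


class _Counter:
    """Counts blocks flowing out of one chain stage."""

    def __init__(self, name: str):
        self.name = name
        self.count = 0

    def wrap(self, blocks: Iterable[MafBlock]) -> Iterator[MafBlock]:
        for block in blocks:
            self.count += 1
            yield block


def _build_stage(call: FilterCall, spec: PipelineSpec) -> Callable:
    """Return a function blocks -> blocks for one filter invocation."""
    a = call.args
    name = call.name
    if name == "Subset":
        return lambda blocks: _filters.subset(
            blocks,
            _as_str_list(a["species"]),
            strict=a.get("strict", False),
            keep_others=a.get("keep", False),
            remove_duplicates=a.get("remove_duplicates", True),
        )
    if name == "Merge":
        return lambda blocks: _filters.merge(
            blocks, _as_str_list(a["species"]), max_dist=a.get("dist_max", 0)
        )
    if name == "Concatenate":
        return lambda blocks: _filters.concatenate(blocks, a["minimum_size"])
    if name == "XFullGap":
        return lambda blocks: _filters.remove_full_gap_columns(
            blocks, _as_str_list(a["species"])
        )
    if name in ("FeatureFilter", "ExtractFeature"):
        features = _io.read_features(
            a["file"],
            a.get("format", "gff3"),
            species=a.get("feature_species"),
        )
        if name == "FeatureFilter":
            return lambda blocks: _filters.feature_filter(
                blocks, features, a["ref_species"]
            )
        return lambda blocks: _filters.extract_features(
            blocks, features, a["ref_species"], complete_only=a.get("complete", False)
        )
    if name == "SelectChr":
        return lambda blocks: _filters.select_chromosome(
            blocks, a["ref_species"], a["chromosome"]
        )
    if name == "MinBlockLength":
        return lambda blocks: _filters.min_block_length(blocks, a["min_length"])
    if name == "MinBlockSize":
        return lambda blocks: _filters.min_block_size(blocks, a["min_size"])
    if name in ("AlnFilter", "AlnFilter2", "EntropyFilter", "MaskFilter", "QualityFilter"):
        predicate, params = {
            "AlnFilter": ("gap_count", {"max_gap": a.get("max.gap")}),
            "AlnFilter2": ("gap_events", {"max_events": a.get("max.ev")}),
            "EntropyFilter": (
                "entropy",
                {
                    "entropy_threshold": a.get("max.ent"),
                    "max_columns": a.get("max.pos"),
                },
            ),
            "MaskFilter": ("mask_count", {"max_masked": a.get("max.masked")}),
            "QualityFilter": ("quality_mean", {"min_quality": a.get("min.qual")}),
        }[name]
        focal = _as_str_list(a["species"]) if "species" in a else None
        return lambda blocks: _filters.sliding_window_clean(
            blocks,
            a["window.size"],
            a["window.step"],
            predicate,
            focal_species=focal,
            action=a.get("action", "remove"),
            **params,
        )
    if name == "WindowSplit":
        return lambda blocks: _filters.window_split(
            blocks, a["window.size"], alignment=a.get("align", "center")
        )
    if name == "SequenceStatistics":
        stat_specs = _statistic_specs(a["statistics"])
        return lambda blocks: _statistics.sequence_statistics(
            blocks, stat_specs, a["file"], ref_species=a.get("ref_species")
        )
    if name == "DistanceEstimation":
        return lambda blocks: _filters.distance_estimation(
            blocks, a.get("method", "kimura")
        )
    if name == "DistanceBasedPhylogeny":
        return lambda blocks: _filters.distance_based_phylogeny(
            blocks, a.get("method", "bionj")
        )
    if name == "NewOutgroup":
        return lambda blocks: _filters.new_outgroup(blocks, a["outgroup"])
    if name == "DropSpecies":
        return lambda blocks: _filters.drop_species_filter(blocks, a["species"])
    if name == "Output":

        def maf_sink(blocks):
            with _io.open_output(a["file"], a.get("compression", "auto")) as fh:
                fh.write("##maf version=1\n")
                for block in blocks:
                    fh.write(_io.format_block(block))
                    yield block

        return maf_sink
    if name == "OutputAlignments":

        def aln_sink(blocks):
            fmt = a.get("format", "fasta").lower()
            with open(a["file"], "wt", encoding="utf-8") as fh:
                for block in blocks:
                    _io.write_alignment(block, fh, fmt)
                    yield block

        return aln_sink
    if name == "OutputTrees":

        def tree_sink(blocks):
            from .phylo import to_newick

            with _io.open_output(a["file"], "auto") as fh:
                for i, block in enumerate(blocks):
                    if block.tree is None:
                        logger.warning("block %d has no attached tree; skipped", i)
                    else:
                        fh.write(to_newick(block.tree) + "\n")
                    yield block

        return tree_sink
    if name == "VcfOutput":

        def vcf_sink(blocks):
            samples = _as_str_list(a["genotypes"]) if "genotypes" in a else None
            with _io.open_output(a["file"], "auto") as fh:
                fh.write(_io.vcf_header(samples))
                for block in blocks:
                    for line in _io.vcf_lines_for_block(block, a["reference"], samples):
                        fh.write(line + "\n")
                    yield block

        return vcf_sink
    raise OptionError(f"unknown filter {name!r}")  # pragma: no cover


@dataclass
class PipelineSummary:
    blocks_read: int
    emitted: dict[str, int]
    wall_time: float


def run_pipeline(spec: PipelineSpec) -> PipelineSummary:
    """Compose source -> filter1 -> ... -> filterN lazily and drain it."""
    t0 = time.perf_counter()
    if spec.input_format == "maf":
        source: Iterable[MafBlock] = _io.read_maf(
            spec.input_file, spec.input_compression
        )
    else:
        source = _io.read_fasta_as_blocks(
            spec.input_file, spec.input_compression, species=spec.input_species
        )
    read_counter = _Counter("input")
    chain: Iterable[MafBlock] = read_counter.wrap(source)
    counters: list[_Counter] = []
    for index, call in enumerate(spec.filters):
        stage = _build_stage(call, spec)
        counter = _Counter(f"{index + 1}:{call.name}")
        chain = counter.wrap(stage(chain))
        counters.append(counter)

    ordinal = 0
    try:
        for ordinal, _block in enumerate(chain, start=1):
            pass
    except MafError as exc:
        raise MafError(
            f"pipeline aborted at output block {ordinal + 1}: {exc}"
        ) from exc
    emitted = {c.name: c.count for c in counters}
    for counter in counters:
        logger.info("%s emitted %d blocks", counter.name, counter.count)
    return PipelineSummary(read_counter.count, emitted, time.perf_counter() - t0)
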