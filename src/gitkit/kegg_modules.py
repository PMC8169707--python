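"""KEGG-style module definitions: parsing and per-sample completeness.

A module definition is a boolean/step expression over KO accessions in the
public KEGG convention: whitespace separates consecutive steps (an ordered
AND), a comma separates alternatives (OR), ``+`` joins the subunits of a
complex (AND), a ``-`` prefix marks an optional component that never counts
toward or against completeness, parentheses group, and a bare ``--`` (a gap
in the definition) is an always-satisfied step.  Given the set of KOs
detected in a sample, every module is classified as *complete* (all steps
satisfied), *not detected* (no non-optional KO of the module present), or
*incomplete* otherwise — the three colors of the completeness heatmap.
"""

from __future__ import annotations

import html
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .errors import GitkitError
from .git_format import GeneRecord

KO_PATTERN = re.compile(r"^K\d{5}$")

COMPLETE = "complete"
INCOMPLETE = "incomplete"
NOT_DETECTED = "not_detected"


class ModuleParseError(GitkitError):
    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"position {position}: {message}")


# ---------------------------------------------------------------- expression tree

@dataclass(frozen=True)
class Leaf:
    ko: str


@dataclass(frozen=True)
class Always:
    """A ``--`` gap: satisfied by definition."""


@dataclass(frozen=True)
class OptionalPart:
    child: object


@dataclass(frozen=True)
class StepSequence:
    children: tuple


@dataclass(frozen=True)
class Alternative:
    children: tuple


@dataclass(frozen=True)
class Complex:
    children: tuple


_IDENT_RE = re.compile(r"[A-Za-z0-9_.]+")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _error(self, message: str):
        raise ModuleParseError(message, self.pos)

    def _peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _skip_ws(self) -> None:
        while self._peek() == " ":
            self.pos += 1

    def parse_steps(self, closing: str = "") -> tuple:
        steps = []
        self._skip_ws()
        while True:
            char = self._peek()
            if char == "" or char == closing:
                break
            steps.append(self.parse_alternative())
            self._skip_ws()
        if not steps:
            self._error("empty step")
        return tuple(steps)

    def parse_alternative(self):
        chains = [self.parse_chain()]
        while self._peek() == ",":
            self.pos += 1
            chains.append(self.parse_chain())
        return chains[0] if len(chains) == 1 else Alternative(tuple(chains))

    def parse_chain(self):
        units = [self._parse_opt_unit()]
        while self._peek() in ("+", "-"):
            op = self.text[self.pos]
            self.pos += 1
            if op == "+":
                units.append(self.parse_unit())
            else:
                if self._peek() == "-":  # embedded gap, e.g. "K1--K2"
                    self.pos += 1
                    units.append(Always())
                    if self._peek() not in ("", " ", ")", ",", "+", "-"):
                        units.append(self.parse_unit())
                else:
                    units.append(OptionalPart(self.parse_unit()))
        return units[0] if len(units) == 1 else Complex(tuple(units))

    def _parse_opt_unit(self):
        if self._peek() == "-":
            self.pos += 1
            if self._peek() == "-":
                self.pos += 1
                return Always()
            if self._peek() in ("", " ", ")", ","):
                return Always()
            return OptionalPart(self.parse_unit())
        return self.parse_unit()

    def parse_unit(self):
        char = self._peek()
        if char == "(":
            self.pos += 1
            steps = self.parse_steps(closing=")")
            if self._peek() != ")":
                self._error("unbalanced parenthesis")
            self.pos += 1
            return steps[0] if len(steps) == 1 else StepSequence(steps)
        match = _IDENT_RE.match(self.text, self.pos)
        if not match:
            self._error(f"expected a KO accession, found {char!r}" if char else "unexpected end")
        token = match.group(0)
        if not KO_PATTERN.match(token):
            self._error(f"{token!r} is not a KO accession")
        self.pos = match.end()
        return Leaf(token)


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    root: StepSequence

    @property
    def n_steps(self) -> int:
        return len(self.root.children)

    def leaves(self) -> set[str]:
        return _leaves(self.root, include_optional=True)

    def non_optional_leaves(self) -> set[str]:
        return _leaves(self.root, include_optional=False)


def _leaves(node, include_optional: bool) -> set[str]:
    if isinstance(node, Leaf):
        return {node.ko}
    if isinstance(node, Always):
        return set()
    if isinstance(node, OptionalPart):
        return _leaves(node.child, include_optional) if include_optional else set()
    result: set[str] = set()
    for child in node.children:
        result |= _leaves(child, include_optional)
    return result


def parse_module_definition(module_id: str, text: str) -> ModuleDefinition:
    """Parse a definition string; positions in errors are 0-based offsets."""
    parser = _Parser(text.strip())
    steps = parser.parse_steps()
    if parser.pos != len(parser.text):
        parser._error(f"unexpected {parser.text[parser.pos]!r}")
    definition = ModuleDefinition(module_id, StepSequence(steps))
    if not definition.non_optional_leaves():
        raise ModuleParseError("module has no non-optional KO", 0)
    return definition


# precedence levels for canonical re-serialization
_P_SEQ, _P_ALT, _P_CHAIN, _P_ATOM = 0, 1, 2, 3


def serialize_expression(node, need: int = _P_SEQ) -> str:
    if isinstance(node, Leaf):
        text, level = node.ko, _P_ATOM
    elif isinstance(node, Always):
        text, level = "--", _P_ATOM
    elif isinstance(node, OptionalPart):
        text, level = "-" + serialize_expression(node.child, _P_ATOM), _P_CHAIN
    elif isinstance(node, Complex):
        parts = []
        for index, child in enumerate(node.children):
            if isinstance(child, OptionalPart):
                parts.append("-" + serialize_expression(child.child, _P_ATOM))
            elif isinstance(child, Always):
                parts.append("-" + "-")
            else:
                parts.append(("+" if index else "") + serialize_expression(child, _P_ATOM))
        text, level = "".join(parts), _P_CHAIN
    elif isinstance(node, Alternative):
        text = ",".join(serialize_expression(c, _P_CHAIN) for c in node.children)
        level = _P_ALT
    elif isinstance(node, StepSequence):
        text = " ".join(serialize_expression(c, _P_ALT) for c in node.children)
        level = _P_SEQ
    else:  # pragma: no cover
        raise TypeError(f"unknown node {node!r}")
    if level < need:
        return "(" + text + ")"
    return text


def serialize_module(definition: ModuleDefinition) -> str:
    return serialize_expression(definition.root)


# ---------------------------------------------------------------- evaluation

@dataclass(frozen=True)
class ModuleStatus:
    status: str
    steps_satisfied: int
    steps_total: int


def _evaluate(node, ko_set: frozenset | set) -> bool:
    if isinstance(node, Leaf):
        return node.ko in ko_set
    if isinstance(node, (Always, OptionalPart)):
        return True
    if isinstance(node, Alternative):
        return any(_evaluate(child, ko_set) for child in node.children)
    # StepSequence and Complex are both conjunctions
    return all(_evaluate(child, ko_set) for child in node.children)


def evaluate_module(definition: ModuleDefinition, ko_set: Iterable[str]) -> ModuleStatus:
    """Classify one module against one sample's detected KO set."""
    ko_set = set(ko_set)
    steps = definition.root.children
    satisfied = sum(1 for step in steps if _evaluate(step, ko_set))
    total = len(steps)
    if satisfied == total:
        status = COMPLETE
    elif satisfied == 0 and not (definition.non_optional_leaves() & ko_set):
        status = NOT_DETECTED
    else:
        status = INCOMPLETE
    return ModuleStatus(status, satisfied, total)


def ko_set_from_records(records: Iterable[GeneRecord],
                        restrict_to_filter: str | None = None) -> set[str]:
    """KOs observed in a GIT, optionally only from genes carrying a filter token."""
    kos = set()
    for record in records:
        if restrict_to_filter is not None and restrict_to_filter not in record.filters:
            continue
        if record.ko_id:
            kos.add(record.ko_id)
    return kos


@dataclass
class ModuleMatrix:
    samples: list[str]
    module_ids: list[str]
    cells: dict[tuple[str, str], ModuleStatus]

    def status_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.cells[(s, m)].status for m in self.module_ids] for s in self.samples],
            index=self.samples,
            columns=self.module_ids,
        )

    def to_tsv(self) -> str:
        lines = ["\t".join(["#sample"] + self.module_ids)]
        for sample in self.samples:
            row = [sample]
            for module_id in self.module_ids:
                cell = self.cells[(sample, module_id)]
                row.append(f"{cell.status}:{cell.steps_satisfied}/{cell.steps_total}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def module_matrix(sample_kos: Mapping[str, Iterable[str]] | None,
                  modules: Sequence[ModuleDefinition],
                  *,
                  records_by_sample: Mapping[str, Iterable[GeneRecord]] | None = None,
                  restrict_to_filter: str | None = None) -> ModuleMatrix:
    """Evaluate every module against every sample's KO set.

    KO sets are given directly via ``sample_kos`` or rebuilt from GIT
    records; with ``restrict_to_filter`` only genes carrying that filter
    token (e.g. ``F.AntiBiotic.Resistance``) contribute KOs.  The
    restriction changes KO sets only, never module definitions.
    """
    if records_by_sample is not None:
        sample_kos = {
            sample: ko_set_from_records(records, restrict_to_filter)
            for sample, records in records_by_sample.items()
        }
    if sample_kos is None:
        raise GitkitError("module_matrix needs sample_kos or records_by_sample")
    samples = list(sample_kos)
    cells = {}
    for sample in samples:
        kos = set(sample_kos[sample])
        for module in modules:
            cells[(sample, module.module_id)] = evaluate_module(module, kos)
    return ModuleMatrix(samples, [m.module_id for m in modules], cells)


_STATUS_COLOR = {COMPLETE: "#c62828", INCOMPLETE: "#9e9e9e", NOT_DETECTED: "#ffffff"}


def render_module_heatmap(matrix: ModuleMatrix, title: str = "Module completeness") -> str:
    """Self-contained HTML heatmap: modules as rows, samples as columns.

    Cells are red/grey/white for complete/incomplete/not detected and carry
    the module id plus satisfied/total step counts as hover metadata.
    """
    rows = []
    header = "".join(f"<th>{html.escape(s)}</th>" for s in matrix.samples)
    rows.append(f"<tr><th>module</th>{header}</tr>")
    for module_id in matrix.module_ids:
        cells = []
        for sample in matrix.samples:
            status = matrix.cells[(sample, module_id)]
            tooltip = (f"{module_id} / {sample}: {status.status} "
                       f"({status.steps_satisfied}/{status.steps_total} steps)")
            cells.append(
                f'<td class="cell" data-module="{html.escape(module_id)}" '
                f'data-sample="{html.escape(sample)}" '
                f'data-steps="{status.steps_satisfied}/{status.steps_total}" '
                f'title="{html.escape(tooltip)}" '
                f'style="background:{_STATUS_COLOR[status.status]}"></td>'
            )
        rows.append(f"<tr><th>{html.escape(module_id)}</th>{''.join(cells)}</tr>")
    table = "\n".join(rows)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{html.escape(title)}</title>"
        "<style>table{border-collapse:collapse}td.cell{width:18px;height:18px;"
        "border:1px solid #ddd}th{font:12px sans-serif;padding:2px 6px;text-align:left}"
        "</style></head><body>"
        f"<h1>{html.escape(title)}</h1>\n<table>\n{table}\n</table>"
        "</body></html>\n"
    )


def read_module_definitions(source: str | TextIO | Iterable[str]) -> list[ModuleDefinition]:
    """Two-column TSV: module_id, definition text."""
    import io as _io

    if isinstance(source, str):
        source = _io.StringIO(source)
    modules = []
    for raw in source:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        module_id, _, text = line.partition("\t")
        if not text:
            raise GitkitError(f"module row without a definition: {line!r}")
        modules.append(parse_module_definition(module_id, text))
    return modules


def write_module_definitions(modules: Sequence[ModuleDefinition]) -> str:
    return "".join(f"{m.module_id}\t{serialize_module(m)}\n" for m in modules)
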