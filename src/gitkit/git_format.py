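"""Gene Information Table (GIT) format: one tab-separated row per gene.

A GIT integrates, for every gene of a sample or gene catalog, its taxonomic
assignment, functional identifiers (KO, EC, GO, InterPro, COG, eggNOG), the
provenance and homology statistics of the evidence behind them, and free-form
"filter" tokens marking genes of interest (e.g. ``F.AntiBiotic.Resistance``).
The file is plain UTF-8 text: one ``#``-prefixed header line naming the 16
canonical columns, then one row per gene.  Multi-valued cells use ``||`` as
the list separator.  The filters field sits at column 14.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, TextIO

from .errors import MalformedRowError, RecordValidationError

#: Canonical column order.  Filters is column 14 (1-based).
COLUMNS = (
    "gene_id",
    "sample_id",
    "gene_name",
    "go_ids",
    "ec_ids",
    "interpro_ids",
    "taxon_id",
    "ko_id",
    "cog_id",
    "eggnog_id",
    "weight",
    "source",
    "evalue",
    "filters",
    "percent_identity",
    "percent_coverage",
)

FILTERS_COLUMN = 14  # 1-based position of the filters field

LIST_SEP = "||"

_LIST_FIELDS = ("go_ids", "ec_ids", "interpro_ids", "filters")

# Tokens may not contain whitespace, tabs, or the list separator.
_TOKEN_RE = re.compile(r"^[^\s|]+$")


@dataclass
class GeneRecord:
    """Integrated annotation of a single gene — one GIT row.

    ``taxon_id`` 0 means taxonomically unassigned.  ``evalue``,
    ``percent_identity`` and ``percent_coverage`` are ``None`` when no
    homology evidence backs the record; ``weight`` defaults to one gene copy.
    """

    gene_id: str
    sample_id: str = ""
    gene_name: str = ""
    go_ids: list[str] = field(default_factory=list)
    ec_ids: list[str] = field(default_factory=list)
    interpro_ids: list[str] = field(default_factory=list)
    taxon_id: int = 0
    ko_id: str = ""
    cog_id: str = ""
    eggnog_id: str = ""
    weight: float = 1.0
    source: str = "none"
    evalue: float | None = None
    filters: list[str] = field(default_factory=list)
    percent_identity: float | None = None
    percent_coverage: float | None = None

    def copy(self) -> "GeneRecord":
        return replace(
            self,
            go_ids=list(self.go_ids),
            ec_ids=list(self.ec_ids),
            interpro_ids=list(self.interpro_ids),
            filters=list(self.filters),
        )


def _fmt_num(x: float | None) -> str:
    if x is None:
        return ""
    return format(float(x), ".12g")


def _parse_float(text: str, name: str, line_number: int) -> float | None:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise MalformedRowError(f"non-numeric {name}: {text!r}", line_number) from None


def _split_list(cell: str) -> list[str]:
    return cell.split(LIST_SEP) if cell else []


def _record_from_fields(fields: list[str], line_number: int) -> GeneRecord:
    if len(fields) != len(COLUMNS):
        raise MalformedRowError(
            f"expected {len(COLUMNS)} tab-separated fields, got {len(fields)}",
            line_number,
        )
    taxon_cell = fields[6]
    if taxon_cell == "":
        taxon_id = 0
    else:
        try:
            taxon_id = int(taxon_cell)
        except ValueError:
            raise MalformedRowError(
                f"non-integer taxon_id: {taxon_cell!r}", line_number
            ) from None
    weight = _parse_float(fields[10], "weight", line_number)
    return GeneRecord(
        gene_id=fields[0],
        sample_id=fields[1],
        gene_name=fields[2],
        go_ids=_split_list(fields[3]),
        ec_ids=_split_list(fields[4]),
        interpro_ids=_split_list(fields[5]),
        taxon_id=taxon_id,
        ko_id=fields[7],
        cog_id=fields[8],
        eggnog_id=fields[9],
        weight=1.0 if weight is None else weight,
        source=fields[11],
        evalue=_parse_float(fields[12], "evalue", line_number),
        filters=_split_list(fields[13]),
        percent_identity=_parse_float(fields[14], "percent_identity", line_number),
        percent_coverage=_parse_float(fields[15], "percent_coverage", line_number),
    )


def _iter_lines(source: str | TextIO | Iterable[str]) -> Iterator[str]:
    if isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


def read_git(source: str | TextIO | Iterable[str]) -> list[GeneRecord]:
    """Parse a GIT from a text block, open file, or iterable of lines.

    Leading ``#`` lines are treated as header/comment and skipped.
    """
    records = []
    for line_number, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            continue
        records.append(_record_from_fields(line.split("\t"), line_number))
    return records


def read_git_file(path) -> list[GeneRecord]:
    with open(path, encoding="utf-8") as handle:
        return read_git(handle)


def record_to_line(record: GeneRecord) -> str:
    cells = (
        record.gene_id,
        record.sample_id,
        record.gene_name,
        LIST_SEP.join(record.go_ids),
        LIST_SEP.join(record.ec_ids),
        LIST_SEP.join(record.interpro_ids),
        str(int(record.taxon_id)),
        record.ko_id,
        record.cog_id,
        record.eggnog_id,
        _fmt_num(record.weight),
        record.source,
        _fmt_num(record.evalue),
        LIST_SEP.join(record.filters),
        _fmt_num(record.percent_identity),
        _fmt_num(record.percent_coverage),
    )
    return "\t".join(cells)


def write_git(records: Iterable[GeneRecord], stream: TextIO | None = None) -> str:
    """Serialize records in canonical column order, input order preserved.

    Raises :class:`RecordValidationError` if any record violates the GIT
    invariants (see :func:`validate_git`).
    """
    records = list(records)
    report = validate_git(records)
    if not report.ok:
        raise RecordValidationError(
            "records violate GIT invariants: " + "; ".join(f.message for f in report.findings[:5])
        )
    out = stream if stream is not None else io.StringIO()
    out.write("#" + "\t".join(COLUMNS) + "\n")
    for record in records:
        out.write(record_to_line(record) + "\n")
    if stream is None:
        return out.getvalue()
    return ""


def write_git_file(records: Iterable[GeneRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        write_git(records, handle)


@dataclass
class Finding:
    kind: str  # "duplicate", "range", "token", "empty_id"
    record_index: int
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding]

    @property
    def ok(self) -> bool:
        return not self.findings


def _check_tokens(values: Iterable[str], what: str, index: int, findings: list[Finding]):
    seen = set()
    for value in values:
        if not _TOKEN_RE.match(value):
            findings.append(
                Finding("token", index, f"record {index}: malformed {what} token {value!r}")
            )
        if value in seen:
            findings.append(
                Finding("token", index, f"record {index}: duplicate {what} token {value!r}")
            )
        seen.add(value)


def validate_git(records: Iterable[GeneRecord]) -> ValidationReport:
    """Report-only validation: duplicates, numeric ranges, token syntax."""
    findings: list[Finding] = []
    seen_keys: dict[tuple[str, str], int] = {}
    for index, record in enumerate(records):
        if not record.gene_id:
            findings.append(Finding("empty_id", index, f"record {index}: empty gene_id"))
        key = (record.gene_id, record.sample_id)
        if key in seen_keys:
            findings.append(
                Finding(
                    "duplicate",
                    index,
                    f"record {index}: duplicate (gene_id, sample_id) {key!r} "
                    f"(first at {seen_keys[key]})",
                )
            )
        else:
            seen_keys[key] = index
        if record.taxon_id < 0:
            findings.append(Finding("range", index, f"record {index}: negative taxon_id"))
        if record.weight is not None and record.weight < 0:
            findings.append(Finding("range", index, f"record {index}: negative weight"))
        if record.evalue is not None and record.evalue < 0:
            findings.append(Finding("range", index, f"record {index}: negative evalue"))
        for name in ("percent_identity", "percent_coverage"):
            value = getattr(record, name)
            if value is not None and not (0.0 <= value <= 100.0):
                findings.append(
                    Finding("range", index, f"record {index}: {name} {value} outside [0,100]")
                )
        for name in _LIST_FIELDS:
            _check_tokens(getattr(record, name), name, index, findings)
    return ValidationReport(findings)
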