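"""File formats: protein FASTA, annotation TSV, ortholog alignments, results.

All text is UTF-8 with tab separators and ``\\n`` line endings.  Writers are
byte-stable: identical inputs produce identical files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

from .rules import AMBIGUITY_AA, CANONICAL_AA, ProcessingOutcome

if TYPE_CHECKING:  # pragma: no cover
    from .screen import ScreenSummary

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "AnnotationRow",
    "OrthologAlignment",
    "COMPARTMENTS",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "write_annotation_table",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_results",
    "read_outcomes_table",
]

_VALID_LETTERS = frozenset(CANONICAL_AA) | AMBIGUITY_AA

#: Controlled vocabulary for mitochondrial subcompartment labels.
COMPARTMENTS: tuple[str, ...] = ("matrix", "IMS", "IMM", "OMM", "membrane", "unknown")

_COMPARTMENT_LOOKUP = {c.lower(): c for c in COMPARTMENTS}

_TRUE_STRINGS = {"1", "true", "yes"}
_FALSE_STRINGS = {"0", "false", "no"}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, free-text description, amino-acid sequence.

    Sequences are upper-cased on construction and may contain the 20
    canonical letters plus the ambiguity letters X, B, Z, U, J, O.  Residue
    numbering is 1-based with the initiator at position 1.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        for pos, letter in enumerate(seq, start=1):
            if letter not in _VALID_LETTERS:
                raise ValueError(
                    f"record {self.id!r}: illegal character {letter!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRow:
    """Annotation for one accession: compartment, MTS flag, pathway labels."""

    id: str
    compartment: str = "unknown"
    has_n_terminal_mts: bool = False
    symbol: str = ""
    pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("annotation row id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment {self.compartment!r} not in vocabulary {COMPARTMENTS}"
            )


@dataclass(frozen=True)
class OrthologAlignment:
    """A pre-computed multiple alignment of orthologs of one protein family.

    ``rows`` holds ``(species_label, aligned_sequence)`` pairs; the gap
    character is ``-``.  All rows have equal width, there are at least two
    rows, and no column is all-gap (readers trim such columns on ingest).
    """

    name: str
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"alignment {self.name!r}: need at least 2 rows")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) != 1:
            raise ValueError(f"alignment {self.name!r}: rows have unequal widths {sorted(widths)}")
        ncol = widths.pop()
        if ncol == 0:
            raise ValueError(f"alignment {self.name!r}: zero columns")
        rows = tuple((label, seq.upper()) for label, seq in self.rows)
        for col in range(ncol):
            if all(seq[col] == "-" for _, seq in rows):
                raise ValueError(f"alignment {self.name!r}: column {col + 1} is all-gap")
        object.__setattr__(self, "rows", rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def ungapped_sequences(self) -> list[str]:
        return [seq.replace("-", "") for _, seq in self.rows]


def read_fasta(path: str | os.PathLike[str]) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records, order preserved.

    Wrapped lines are concatenated and sequences upper-cased.  A single
    trailing ``*`` (stop) is stripped; interior ``*`` or other illegal
    characters raise with the offending position.  Duplicate ids and empty
    files raise.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Sequence[ProteinRecord], path: str | os.PathLike[str], width: int = 60
) -> None:
    """Write records as FASTA with fixed line wrapping (byte-stable)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for start in range(0, rec.length, width):
                fh.write(rec.sequence[start : start + width] + "\n")


def _parse_bool(value: object, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValueError(f"column {column!r}: cannot parse boolean from {value!r}")


def read_annotation_table(path: str | os.PathLike[str]) -> list[AnnotationRow]:
    """Read a proteome annotation TSV (MitoCarta-style) into rows.

    Required columns: ``id``, ``compartment``, ``has_n_terminal_mts``;
    optional: ``symbol``, ``pathways`` (semicolon-separated labels).
    Compartment values outside the vocabulary map to ``unknown`` with a
    logged warning; the boolean column accepts 0/1/true/false/yes/no in any
    case.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "compartment", "has_n_terminal_mts"):
        if col not in df.columns:
            raise ValueError(f"annotation table {path} missing required column {col!r}")
    rows: list[AnnotationRow] = []
    for rec in df.itertuples(index=False):
        compartment = _COMPARTMENT_LOOKUP.get(str(rec.compartment).strip().lower())
        if compartment is None:
            logger.warning(
                "annotation %s: compartment %r not in vocabulary, using 'unknown'",
                rec.id,
                rec.compartment,
            )
            compartment = "unknown"
        pathways: frozenset[str] = frozenset()
        if "pathways" in df.columns:
            raw = str(getattr(rec, "pathways", "")).strip()
            if raw:
                pathways = frozenset(p.strip() for p in raw.split(";") if p.strip())
        rows.append(
            AnnotationRow(
                id=str(rec.id),
                compartment=compartment,
                has_n_terminal_mts=_parse_bool(rec.has_n_terminal_mts, "has_n_terminal_mts"),
                symbol=str(getattr(rec, "symbol", "")),
                pathways=pathways,
            )
        )
    return rows


def write_annotation_table(
    rows: Sequence[AnnotationRow], path: str | os.PathLike[str]
) -> None:
    """Write annotation rows as the TSV understood by :func:`read_annotation_table`."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "symbol": [r.symbol for r in rows],
            "compartment": [r.compartment for r in rows],
            "has_n_terminal_mts": [int(r.has_n_terminal_mts) for r in rows],
            "pathways": [";".join(sorted(r.pathways)) for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _trim_all_gap_columns(rows: list[tuple[str, str]]) -> list[tuple[str, str]]:
    if not rows:
        return rows
    ncol = len(rows[0][1])
    keep = [c for c in range(ncol) if any(seq[c] != "-" for _, seq in rows)]
    return [(label, "".join(seq[c] for c in keep)) for label, seq in rows]


def read_alignment_fasta(
    path: str | os.PathLike[str], name: str | None = None
) -> OrthologAlignment:
    """Read an aligned FASTA into an :class:`OrthologAlignment`.

    All-gap columns are trimmed on ingest so downstream profile math never
    sees an empty column.
    """
    path = Path(path)
    alignment = AlignIO.read(str(path), "fasta")
    rows = [(rec.id, str(rec.seq).upper()) for rec in alignment]
    rows = _trim_all_gap_columns(rows)
    return OrthologAlignment(name=name or path.stem, rows=tuple(rows))


def write_alignment_fasta(
    alignment: OrthologAlignment, path: str | os.PathLike[str]
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for label, seq in alignment.rows:
            fh.write(f">{label}\n{seq}\n")


_OUTCOME_COLUMNS = (
    "id",
    "pattern",
    "route",
    "released",
    "neo_residue",
    "neo_prefix",
    "degron",
)


def outcomes_to_frame(outcomes: Sequence[ProcessingOutcome]) -> pd.DataFrame:
    """Tabulate per-protein outcomes (one row per protein)."""
    return pd.DataFrame(
        {
            "id": [o.id for o in outcomes],
            "pattern": [o.pattern for o in outcomes],
            "route": [o.route for o in outcomes],
            "released": ["+".join(o.released) for o in outcomes],
            "neo_residue": [o.neo_residue or "" for o in outcomes],
            "neo_prefix": [o.neo_prefix or "" for o in outcomes],
            "degron": [o.degron.branch if o.degron else "" for o in outcomes],
        },
        columns=list(_OUTCOME_COLUMNS),
    )


def write_results(
    outcomes: Sequence[ProcessingOutcome],
    summary: "ScreenSummary | None",
    out_dir: str | os.PathLike[str],
) -> dict[str, Path]:
    """Write the per-protein outcome TSV and the JSON screen summary.

    Returns the paths written.  Both files are byte-stable for identical
    inputs.  Raises on an empty outcome list or an unwritable directory.
    """
    if not outcomes:
        raise ValueError("cannot write results for an empty outcome list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tsv_path = out_dir / "outcomes.tsv"
    outcomes_to_frame(outcomes).to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    paths["outcomes"] = tsv_path
    if summary is not None:
        json_path = out_dir / "summary.json"
        with open(json_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["summary"] = json_path
    return paths


def read_outcomes_table(path: str | os.PathLike[str]) -> pd.DataFrame:
    """Read back the per-protein outcome TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"outcome table {path} missing columns {missing}")
    return df
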