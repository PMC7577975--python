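"""Readers and writers for every external representation the pipeline touches.

Conventions at the package boundary:

* sequences are RNA (``A/C/G/U``) after normalization — DNA input is accepted
  and transcribed (``T``→``U``), mixed case is accepted and uppercased;
* all coordinates in files are 1-based and inclusive (miRBase style);
* records that violate an invariant are *quarantined* with a reason, never
  silently dropped: ``records_in == records_valid + records_quarantined``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("mirduplex")

RNA_ALPHABET = frozenset("ACGU")
ARMS = ("5p", "3p")
DIRECTIONS = ("base_to_loop", "loop_to_base", "unknown")

ANNOTATION_COLUMNS = (
    "id",
    "species",
    "group",
    "mirna_start",
    "mirna_end",
    "arm",
    "direction",
)

MIRNA_LENGTH_RANGE = (19, 25)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or record."""


@dataclasses.dataclass(frozen=True)
class QuarantineItem:
    """A record set aside with an auditable reason."""

    record_id: str
    reason: str
    detail: str = ""


@dataclasses.dataclass
class PrecursorRecord:
    """One annotated precursor: sequence, mature-miRNA interval, arm, direction.

    ``mirna_start``/``mirna_end`` are 1-based inclusive positions on the
    precursor sequence.  ``structure``, when present, is a dot-bracket string
    of the same length as the sequence.
    """

    id: str
    species: str
    group: str
    sequence: str
    mirna_start: int
    mirna_end: int
    arm: str
    direction: str = "unknown"
    structure: str | None = None

    @property
    def mirna_interval(self) -> tuple[int, int]:
        return (self.mirna_start, self.mirna_end)

    @property
    def mirna_length(self) -> int:
        return self.mirna_end - self.mirna_start + 1

    def validation_problems(self) -> list[str]:
        """Invariant violations, empty when the record is valid."""
        problems: list[str] = []
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            problems.append(
                "non_rna_alphabet: %s" % ",".join(sorted(bad)))
        if not (1 <= self.mirna_start <= self.mirna_end <= len(self.sequence)):
            problems.append("coordinate_out_of_range")
        else:
            lo, hi = MIRNA_LENGTH_RANGE
            if not (lo <= self.mirna_length <= hi):
                problems.append("mirna_length_out_of_range")
        if self.arm not in ARMS:
            problems.append("bad_arm")
        if self.direction not in DIRECTIONS:
            problems.append("bad_direction")
        if self.structure is not None and len(self.structure) != len(self.sequence):
            problems.append("structure_length_mismatch")
        return problems


@dataclasses.dataclass(frozen=True)
class NucleotideComposition:
    """Mononucleotide counts and frequencies over a stated position set."""

    counts: Mapping[str, int]
    total: int

    @property
    def frequencies(self) -> dict[str, float]:
        if self.total == 0:
            return {nt: 0.0 for nt in "ACGU"}
        return {nt: self.counts.get(nt, 0) / self.total for nt in "ACGU"}

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "NucleotideComposition":
        counts = {nt: 0 for nt in "ACGU"}
        for seq in sequences:
            for nt in seq:
                if nt in counts:
                    counts[nt] += 1
        return cls(counts=counts, total=sum(counts.values()))


def normalize_sequence(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased and transcribed (T→U); IDs are the first
    whitespace-delimited header token.  Non-ACGU characters are kept so that
    downstream validation can quarantine the record rather than drop it here.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>' before sequence data")
            break
        else:
            log.warning("%s: empty FASTA file", path)
            return []
    out = [(rec.id, normalize_sequence(str(rec.seq)))
           for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        log.warning("%s: empty FASTA file", path)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

def read_annotation_table(
    path: str | Path,
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
) -> tuple[list[PrecursorRecord], list[QuarantineItem]]:
    """Join a TSV annotation table to FASTA sequences by ``id``.

    Columns: id, species, group, mirna_start, mirna_end, arm, direction
    (direction may be blank → ``unknown``).  Rows whose id has no sequence are
    a hard error listing the orphans; rows that violate record invariants are
    quarantined with a reason.
    """
    if not isinstance(sequences, Mapping):
        sequences = dict(sequences)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS[:6]) - set(table.columns)
    if missing_cols:
        raise ParseError(
            f"{path}: missing annotation columns: {sorted(missing_cols)}")
    if "direction" not in table.columns:
        table["direction"] = ""

    orphans = [rid for rid in table["id"] if rid not in sequences]
    if orphans:
        raise ParseError(
            f"{path}: annotation rows with no matching sequence: {sorted(set(orphans))}")

    records: list[PrecursorRecord] = []
    quarantined: list[QuarantineItem] = []
    for row in table.itertuples(index=False):
        direction = row.direction.strip() or "unknown"
        try:
            start, end = int(row.mirna_start), int(row.mirna_end)
        except ValueError:
            quarantined.append(QuarantineItem(row.id, "bad_coordinates",
                                              f"{row.mirna_start}..{row.mirna_end}"))
            continue
        rec = PrecursorRecord(
            id=row.id, species=row.species, group=row.group,
            sequence=sequences[row.id], mirna_start=start, mirna_end=end,
            arm=row.arm, direction=direction)
        problems = rec.validation_problems()
        if problems:
            quarantined.append(QuarantineItem(rec.id, problems[0],
                                              "; ".join(problems)))
            log.info("quarantined %s: %s", rec.id, problems[0])
        else:
            records.append(rec)
    log.info("annotation %s: %d valid, %d quarantined",
             path, len(records), len(quarantined))
    return records, quarantined


def write_annotation_table(records: Iterable[PrecursorRecord],
                           path: str | Path) -> None:
    rows = [
        {
            "id": r.id, "species": r.species, "group": r.group,
            "mirna_start": r.mirna_start, "mirna_end": r.mirna_end,
            "arm": r.arm,
            "direction": "" if r.direction == "unknown" else r.direction,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dot-bracket structure files
# ---------------------------------------------------------------------------

_STRUCT_RE = re.compile(r"^[().]+$")
_SEQ_RE = re.compile(r"^[A-Za-z]+$")


def read_dotbracket_file(path: str | Path) -> dict[str, str]:
    """Vienna-style file: ``>id`` then an optional sequence line, then one
    dot-bracket line.  Returns ``{id: dotbracket}``."""
    structures: dict[str, str] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
            elif _STRUCT_RE.match(line.split()[0]):
                if current is None:
                    raise ParseError(
                        f"{path}: line {lineno}: structure before any header")
                structures[current] = line.split()[0]
            elif _SEQ_RE.match(line):
                continue  # sequence line, structure follows
            else:
                raise ParseError(f"{path}: line {lineno}: unrecognized line")
    return structures


def write_dotbracket_file(
    entries: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write ``(id, sequence, dotbracket)`` triples in Vienna layout."""
    with open(path, "w") as fh:
        for rid, seq, db in entries:
            fh.write(f">{rid}\n{seq}\n{db}\n")


# ---------------------------------------------------------------------------
# Frequency reports
# ---------------------------------------------------------------------------

def write_frequency_report(matrix, path: str | Path, format: str = "tsv",
                           metadata: dict | None = None) -> None:
    """Serialize a :class:`~mirduplex.pair_stats.PairFrequencyMatrix`.

    TSV: positions as columns, classes as rows, percentages to 2 decimals.
    JSON: full precision plus a metadata block (n precursors per position,
    mode, config hash) — the bit-exact round-trip format.
    """
    pct = matrix.percentages
    colsums = pct.sum(axis=0)
    if not ((colsums - 100.0).abs() < 0.01).all():
        raise ValueError("frequency matrix columns must sum to 100 +/- 0.01")
    path = Path(path)
    if format == "tsv":
        pct.round(2).to_csv(path, sep="\t", float_format="%.2f",
                            index_label="class")
    elif format == "json":
        payload = {
            "metadata": {
                "mode": matrix.mode,
                "n_per_position": {str(c): int(n)
                                   for c, n in matrix.n_per_position.items()},
                **(metadata or {}),
            },
            "positions": [str(c) for c in pct.columns],
            "classes": list(pct.index),
            "counts": {str(c): [int(v) for v in matrix.counts[c]]
                       for c in matrix.counts.columns},
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown report format: {format}")


def read_frequency_report(path: str | Path, format: str = "tsv"):
    """Inverse of :func:`write_frequency_report` (same format)."""
    from .pair_stats import PairFrequencyMatrix  # local import, no cycle at import time

    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col="class")
        frame.columns = [_coerce_coord(c) for c in frame.columns]
        return frame
    if format == "json":
        payload = json.loads(path.read_text())
        coords = [_coerce_coord(c) for c in payload["positions"]]
        counts = pd.DataFrame(
            {c: payload["counts"][str(c)] for c in coords},
            index=payload["classes"])
        n = pd.Series({_coerce_coord(k): v for k, v in
                       payload["metadata"]["n_per_position"].items()})
        return PairFrequencyMatrix(counts=counts, n_per_position=n,
                                   mode=payload["metadata"]["mode"])
    raise ValueError(f"unknown report format: {format}")


def _coerce_coord(c):
    try:
        return int(c)
    except (TypeError, ValueError):
        return c


# ---------------------------------------------------------------------------
# miRBase-style converter
# ---------------------------------------------------------------------------

def convert_mirbase(
    hairpins: Sequence[tuple[str, str]],
    matures: Sequence[tuple[str, str]],
    group: str = "human",
    species: str = "",
) -> tuple[list[PrecursorRecord], list[QuarantineItem]]:
    """Map miRBase-style hairpin + mature FASTA pairs to annotated records.

    Matures are matched to hairpins by substring search; the mature id must
    share the hairpin id as a case-insensitive prefix (``hsa-mir-21`` ↔
    ``hsa-miR-21-5p``).  A hairpin with no matching mature, or a mature whose
    sequence is absent or ambiguous in the hairpin, is quarantined.
    """
    records: list[PrecursorRecord] = []
    quarantined: list[QuarantineItem] = []
    mat_by_prefix: dict[str, list[tuple[str, str]]] = {}
    for mid, mseq in matures:
        key = re.sub(r"-(5p|3p)$", "", mid.lower())
        mat_by_prefix.setdefault(key, []).append((mid, normalize_sequence(mseq)))

    for hid, hseq in hairpins:
        hseq = normalize_sequence(hseq)
        candidates = mat_by_prefix.get(hid.lower(), [])
        if not candidates:
            quarantined.append(QuarantineItem(hid, "no_mature_match"))
            continue
        matched = False
        for mid, mseq in candidates:
            hits = [m.start() for m in re.finditer(
                f"(?={re.escape(mseq)})", hseq)]
            if len(hits) == 0:
                quarantined.append(QuarantineItem(
                    hid, "mature_not_in_hairpin", mid))
                continue
            if len(hits) > 1:
                quarantined.append(QuarantineItem(
                    hid, "ambiguous_mature_match", mid))
                continue
            start = hits[0] + 1
            end = start + len(mseq) - 1
            mid_l = mid.lower()
            if mid_l.endswith("-5p"):
                arm = "5p"
            elif mid_l.endswith("-3p"):
                arm = "3p"
            else:
                arm = "5p" if (start + end) / 2 <= len(hseq) / 2 else "3p"
            rec = PrecursorRecord(
                id=f"{hid}|{mid}", species=species or hid.split("-")[0],
                group=group, sequence=hseq, mirna_start=start,
                mirna_end=end, arm=arm, direction="unknown")
            problems = rec.validation_problems()
            if problems:
                quarantined.append(
                    QuarantineItem(rec.id, problems[0], "; ".join(problems)))
            else:
                records.append(rec)
                matched = True
        if not matched and not candidates:
            quarantined.append(QuarantineItem(hid, "no_mature_match"))
    return records, quarantined


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for provenance blocks."""
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
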