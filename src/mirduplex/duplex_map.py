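"""Register the two arms of an imperfect foldback into a positional alignment.

This is the analytical core of the package.  Given a precursor's structure
and its mature-miRNA interval it

1. infers the miRNA* from the Dicer-family signature — the miRNA/miRNA*
   duplex carries a 2-nt 3' overhang at both ends, so the star's 5' end is
   the partner of (miRNA 3' end − 2) and its 3' end is the partner of the
   miRNA 5' end plus 2;
2. walks the two arms in register (5' arm ascending, 3' arm descending) from
   the basal boundary of the duplex, emitting one row per aligned position:
   a *paired* row when the pair table links the two positions, a *mismatch*
   row when two unpaired nucleotides face each other, and a *bulge* row (one
   side gapped) when a nucleotide's counterpart is consumed by a pair further
   along; and
3. assigns cleavage-site coordinates: coordinate 1 is the basal-most position
   of the miRNA/miRNA* duplex, coordinates increase toward the terminal loop,
   negative coordinates run below the duplex toward the precursor base, and
   coordinate 0 does not exist.  The two Dicer-like cuts sit at coordinates
   {−1, 1, 2, 3} (basal) and {L, L+1, L+2, L+3} for an L-nt miRNA (21 →
   {21, 22, 23, 24}).  For base-to-loop precursors the basal cut is the
   *first* cleavage site; for loop-to-base precursors the site labels swap
   while the coordinates stay fixed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from .io_formats import PrecursorRecord, QuarantineItem
from .structure import SecondaryStructure, parse_dotbracket

GAP = "-"

#: default window: 15 coordinates below the duplex, 41 at/above (56 total)
DEFAULT_WINDOW_BELOW = 15
DEFAULT_WINDOW_ABOVE = 41

#: how far (nt) infer_star may slide off an unpaired anchor
ANCHOR_SEARCH = 3


class RegistrationError(ValueError):
    """A record whose duplex cannot be registered; carries a quarantine reason."""

    def __init__(self, reason: str, detail: str = ""):
        super().__init__(f"{reason}: {detail}" if detail else reason)
        self.reason = reason
        self.detail = detail


@dataclasses.dataclass(frozen=True)
class PositionPair:
    """One row of the registered alignment, in cleavage-site coordinates."""

    coord: int | None
    nt5: str
    nt3: str
    paired: bool
    src5: int | None
    src3: int | None

    @property
    def is_bulge(self) -> bool:
        return self.nt5 == GAP or self.nt3 == GAP

    def triple(self) -> tuple[int | None, int | None, bool]:
        return (self.src5, self.src3, self.paired)


@dataclasses.dataclass(frozen=True)
class StarInference:
    start: int
    end: int
    clipped: bool = False
    interpolated: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclasses.dataclass
class DuplexAlignment:
    """Ordered position-pairs for one precursor, anchored on the duplex base."""

    record_id: str
    rows: list[PositionPair]
    arm: str
    direction: str
    mirna_interval: tuple[int, int]
    star_interval: tuple[int, int]
    duplex_span: tuple[int, int] | None = None
    first_site: tuple[int, ...] = ()
    second_site: tuple[int, ...] = ()
    flags: frozenset[str] = frozenset()

    def coords(self) -> list[int]:
        return [r.coord for r in self.rows if r.coord is not None]

    def row_at(self, coord: int) -> PositionPair | None:
        for r in self.rows:
            if r.coord == coord:
                return r
        return None

    def nt5_string(self) -> str:
        return "".join(r.nt5 for r in self.rows if r.nt5 != GAP)

    def nt3_string(self) -> str:
        """3'-arm nucleotides in row order (3'→5' on the precursor)."""
        return "".join(r.nt3 for r in self.rows if r.nt3 != GAP)

    def triples(self) -> set[tuple[int | None, int | None, bool]]:
        return {r.triple() for r in self.rows}


# ---------------------------------------------------------------------------
# miRNA* inference
# ---------------------------------------------------------------------------

def _resolve_anchor(structure: SecondaryStructure, pos: int,
                    toward: int) -> tuple[int, int] | None:
    """Nearest paired position within ``ANCHOR_SEARCH`` nt of ``pos``.

    Returns ``(position, offset)`` with ``offset = position - pos``; ties in
    distance are broken toward the duplex interior (sign of ``toward``).
    """
    n = len(structure)
    for dist in range(ANCHOR_SEARCH + 1):
        for sign in ((toward, -toward) if toward else (1, -1)):
            cand = pos + sign * dist
            if 1 <= cand <= n and structure.is_paired(cand):
                return cand, cand - pos
            if dist == 0:
                break
    return None


def infer_star(structure: SecondaryStructure,
               mirna_interval: tuple[int, int]) -> StarInference:
    """Infer the miRNA* interval from the 2-nt 3'-overhang rule.

    star 5' end = partner(miRNA_end − 2); star 3' end = partner(miRNA_start)
    + 2.  When an anchor position is unpaired the nearest paired position
    within ±3 nt is used and the offset compensated.  The returned interval
    is clipped to the sequence bounds with ``clipped=True`` when that occurs.
    Raises :class:`RegistrationError` (``star_uninferrable``) when no paired
    anchor exists within range on either end.
    """
    start, end = mirna_interval
    n = len(structure)
    interpolated = False

    hit = _resolve_anchor(structure, end - 2, toward=-1)
    if hit is None:
        raise RegistrationError("star_uninferrable",
                                f"no paired anchor within +/-{ANCHOR_SEARCH} of {end - 2}")
    a, off_a = hit
    interpolated |= off_a != 0
    star_a = structure.partner(a) + off_a  # == partner(end-2) by local register

    hit = _resolve_anchor(structure, start, toward=+1)
    if hit is None:
        raise RegistrationError("star_uninferrable",
                                f"no paired anchor within +/-{ANCHOR_SEARCH} of {start}")
    b, off_b = hit
    interpolated |= off_b != 0
    star_b = structure.partner(b) + off_b + 2  # == partner(start) + 2

    lo, hi = sorted((star_a, star_b))
    clipped = lo < 1 or hi > n
    lo, hi = max(lo, 1), min(hi, n)
    if lo > hi:
        raise RegistrationError("star_uninferrable", "inferred interval empty")
    return StarInference(start=lo, end=hi, clipped=clipped,
                         interpolated=interpolated)


# ---------------------------------------------------------------------------
# Arm registration
# ---------------------------------------------------------------------------

def _has_pair_inside(structure: SecondaryStructure, i: int, j: int) -> bool:
    """True when some pair lies entirely within [i, j] (not yet at the loop)."""
    for k in range(i, j + 1):
        p = structure.partner(k)
        if p is not None and i <= p <= j:
            return True
    return False


def register_arms(
    sequence: str,
    structure: SecondaryStructure,
    mirna_interval: tuple[int, int],
    star_interval: tuple[int, int],
    direction: str = "base_to_loop",
    max_below: int = DEFAULT_WINDOW_BELOW + 5,
    max_above: int = DEFAULT_WINDOW_ABOVE + 5,
) -> DuplexAlignment:
    """Two-pointer registration of the two arms, anchored at the duplex base.

    The upward walk (toward the loop) starts at the basal duplex boundary and
    stops at the terminal loop; the downward walk mirrors it toward the
    precursor base.  Short precursors simply yield short alignments (flagged
    ``short_window``); coordinates are assigned afterwards by
    :func:`assign_cleavage_coords`.
    """
    n = len(sequence)
    m_start, m_end = mirna_interval
    s_start, s_end = star_interval
    arm = "5p" if m_start < s_start else "3p"
    flags: set[str] = set()

    # basal anchor columns: the positions facing each other at the duplex base
    if arm == "5p":
        i0 = m_start
        p = structure.partner(m_start)
        j0 = p if (p is not None and p > m_end) else s_end - 2
    else:
        j0 = m_end
        p = structure.partner(m_end)
        i0 = p if (p is not None and p < m_start) else s_start - 2
    j0 = min(max(j0, 1), n)
    i0 = min(max(i0, 1), n)

    def nt(pos: int) -> str:
        return sequence[pos - 1]

    def row(i, j, paired):
        return PositionPair(
            coord=None,
            nt5=nt(i) if i is not None else GAP,
            nt3=nt(j) if j is not None else GAP,
            paired=paired, src5=i, src3=j)

    # --- upward walk (toward the terminal loop) ---
    up: list[PositionPair] = []
    i, j = i0, j0
    while i <= n and j >= 1 and i < j and len(up) < max_above:
        if not _has_pair_inside(structure, i, j):
            break  # terminal loop reached
        pi, pj = structure.partner(i), structure.partner(j)
        if pi == j:
            up.append(row(i, j, True)); i += 1; j -= 1
        elif pi is not None and i < pi < j:
            up.append(row(None, j, False)); j -= 1      # 3'-side bulge
        elif pj is not None and i < pj < j:
            up.append(row(i, None, False)); i += 1      # 5'-side bulge
        else:
            up.append(row(i, j, False)); i += 1; j -= 1  # mismatch
    if len(up) < (m_end - m_start + 1):
        flags.add("short_window")

    # --- downward walk (toward the precursor base) ---
    down: list[PositionPair] = []
    i, j = i0 - 1, j0 + 1
    while i >= 1 and j <= n and len(down) < max_below:
        pi, pj = structure.partner(i), structure.partner(j)
        if pi == j:
            down.append(row(i, j, True)); i -= 1; j += 1
        elif pi is not None and pi > j:
            down.append(row(None, j, False)); j += 1    # 3'-side bulge
        elif pj is not None and pj < i:
            down.append(row(i, None, False)); i -= 1    # 5'-side bulge
        else:
            down.append(row(i, j, False)); i -= 1; j += 1
    if i >= 1 or j <= n:
        pass  # precursor continues beyond the walk bound; window crops anyway
    else:
        flags.add("reached_precursor_end")

    rows = list(reversed(down)) + up
    return DuplexAlignment(
        record_id="", rows=rows, arm=arm, direction=direction,
        mirna_interval=mirna_interval, star_interval=star_interval,
        flags=frozenset(flags))


def assign_cleavage_coords(
    alignment: DuplexAlignment,
    direction: str | None = None,
    mirna_length: int | None = None,
    window_below: int = DEFAULT_WINDOW_BELOW,
    window_above: int = DEFAULT_WINDOW_ABOVE,
) -> DuplexAlignment:
    """Fix coordinate 1 at the basal end of the miRNA/miRNA* duplex and crop
    to the analysis window.

    The anchor row is the one holding the miRNA's basal terminus on its own
    arm (5'-arm miRNA: its 5' end; 3'-arm miRNA: its 3' end).  Rows above get
    2, 3, …; rows below −1, −2, … (no coordinate 0).  Unknown direction is
    treated as base-to-loop with a ``direction_assumed`` flag.
    """
    direction = direction or alignment.direction or "unknown"
    flags = set(alignment.flags)
    if direction not in ("base_to_loop", "loop_to_base"):
        direction = "base_to_loop"
        flags.add("direction_assumed")
    m_start, m_end = alignment.mirna_interval
    L = mirna_length or (m_end - m_start + 1)

    anchor_idx = None
    for k, r in enumerate(alignment.rows):
        if alignment.arm == "5p" and r.src5 == m_start:
            anchor_idx = k
            break
        if alignment.arm == "3p" and r.src3 == m_end:
            anchor_idx = k
            break
    if anchor_idx is None:
        raise RegistrationError("anchor_not_registered",
                                "miRNA basal terminus missing from the walk")

    rows: list[PositionPair] = []
    for k, r in enumerate(alignment.rows):
        offset = k - anchor_idx
        coord = offset + 1 if offset >= 0 else offset
        if -window_below <= coord <= window_above:
            rows.append(dataclasses.replace(r, coord=coord))
    if len(rows) < window_below + window_above:
        flags.add("short_window")

    basal = (-1, 1, 2, 3)
    apical = (L, L + 1, L + 2, L + 3)
    first, second = ((basal, apical) if direction == "base_to_loop"
                     else (apical, basal))
    return dataclasses.replace(
        alignment, rows=rows, direction=direction,
        duplex_span=(1, L), first_site=first, second_site=second,
        flags=frozenset(flags))


def align_record(
    record: PrecursorRecord,
    structure: SecondaryStructure | None = None,
    window_below: int = DEFAULT_WINDOW_BELOW,
    window_above: int = DEFAULT_WINDOW_ABOVE,
) -> DuplexAlignment:
    """Full per-record pipeline: star inference → registration → coordinates."""
    if structure is None:
        if record.structure is None:
            raise ValueError(f"{record.id}: record has no structure")
        structure = parse_dotbracket(record.structure)
    star = infer_star(structure, record.mirna_interval)
    aln = register_arms(record.sequence, structure, record.mirna_interval,
                        star.interval, direction=record.direction,
                        max_below=window_below + 5,
                        max_above=window_above + 5)
    aln.record_id = record.id
    flags = set(aln.flags)
    if star.clipped:
        flags.add("star_clipped")
    if star.interpolated:
        flags.add("star_interpolated")
    aln.flags = frozenset(flags)
    return assign_cleavage_coords(aln, direction=record.direction,
                                  window_below=window_below,
                                  window_above=window_above)


def cleavage_site_coords(mirna_length: int = 21) -> dict[str, tuple[int, ...]]:
    """Basal and apical cut coordinates for an L-nt miRNA."""
    return {"basal": (-1, 1, 2, 3),
            "apical": tuple(range(mirna_length, mirna_length + 4))}


def dump_alignment(alignment: DuplexAlignment) -> str:
    """TSV dump with columns coord, nt5, nt3, paired, src5, src3."""
    lines = ["coord\tnt5\tnt3\tpaired\tsrc5\tsrc3"]
    for r in alignment.rows:
        lines.append("\t".join(str(x) if x is not None else ""
                               for x in (r.coord, r.nt5, r.nt3,
                                         int(r.paired), r.src5, r.src3)))
    return "\n".join(lines) + "\n"
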