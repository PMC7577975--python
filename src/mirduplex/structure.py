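"""Secondary structures: dot-bracket parsing and MFE folding.

A precursor's structure either arrives precomputed (Vienna dot-bracket) or is
obtained from a scriptable minimum-free-energy engine (ViennaRNA's ``RNA``
bindings) at default parameters.  Only the engine's single MFE structure is
used; no suboptimal ensemble, and whatever the engine's defaults produce
(lonely pairs, dangling ends) is accepted unmodified.
"""

from __future__ import annotations

import dataclasses

from .io_formats import PrecursorRecord, QuarantineItem


class StructureError(ValueError):
    """Unbalanced or otherwise invalid dot-bracket input."""


class FoldingEngineError(RuntimeError):
    """The configured folding engine is unavailable or failed."""


@dataclasses.dataclass(frozen=True)
class SecondaryStructure:
    """A dot-bracket string with its derived pair table.

    ``pairs`` maps 1-based position → 1-based partner for every paired
    position and is an involution: ``pairs[pairs[i]] == i``.
    """

    dotbracket: str
    pairs: dict[int, int]
    mfe: float | None = None

    def __len__(self) -> int:
        return len(self.dotbracket)

    def partner(self, i: int) -> int | None:
        return self.pairs.get(i)

    def is_paired(self, i: int) -> bool:
        return i in self.pairs

    def render(self) -> str:
        return self.dotbracket


def parse_dotbracket(s: str, mfe: float | None = None) -> SecondaryStructure:
    """Stack-based bracket matching; errors carry the 1-based position of the
    first violation (an unmatched ``)`` or the first unclosed ``(``)."""
    bad = set(s) - set("().")
    if bad:
        raise StructureError(
            f"invalid dot-bracket characters: {sorted(bad)}")
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for pos, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {pos}")
            opener = stack.pop()
            pairs[opener] = pos
            pairs[pos] = opener
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[0]}")
    return SecondaryStructure(dotbracket=s, pairs=pairs, mfe=mfe)


_FOLD_CACHE: dict[tuple, SecondaryStructure] = {}


def engine_version(engine: str = "viennarna") -> str:
    if engine != "viennarna":
        raise FoldingEngineError(f"unknown folding engine: {engine}")
    try:
        import RNA
    except ImportError:
        return "unavailable"
    return f"ViennaRNA {RNA.__version__}"


def fold_sequence(sequence: str,
                  engine_config: dict | None = None) -> SecondaryStructure:
    """MFE structure of ``sequence`` from the configured engine.

    Deterministic for a fixed engine and parameters; results are cached on
    ``(sequence, engine, params)``.  A missing engine raises an actionable
    error pointing at the precomputed dot-bracket alternative.
    """
    cfg = dict(engine_config or {})
    engine = cfg.pop("engine", "viennarna")
    key = (sequence, engine, tuple(sorted(cfg.items())))
    if key in _FOLD_CACHE:
        return _FOLD_CACHE[key]
    if engine != "viennarna":
        raise FoldingEngineError(f"unknown folding engine: {engine}")
    try:
        import RNA
    except ImportError as exc:
        raise FoldingEngineError(
            "ViennaRNA Python bindings are not installed; either install the "
            "'fold' extra or supply precomputed dot-bracket structures"
        ) from exc
    db, mfe = RNA.fold(sequence)
    result = parse_dotbracket(db, mfe=mfe)
    _FOLD_CACHE[key] = result
    return result


def validate_structure(
    record: PrecursorRecord,
    structure: SecondaryStructure | None = None,
    terminal_slack: int = 2,
) -> QuarantineItem | None:
    """Check that the miRNA interval lies on a single arm of the foldback.

    Partners of miRNA positions, where paired, must fall outside the interval
    — except permitted terminal overlaps, where both partners sit within
    ``terminal_slack`` nt of the interval's ends (a closing pair right at the
    duplex boundary).  A violating record is quarantined with reason
    ``mirna_spans_loop``; an entirely unpaired interval with
    ``mirna_unstructured``.  Returns ``None`` when the record passes.
    """
    if structure is None:
        if record.structure is None:
            raise ValueError(f"{record.id}: no structure to validate")
        structure = parse_dotbracket(record.structure)
    start, end = record.mirna_interval
    paired_any = False
    for i in range(start, end + 1):
        j = structure.partner(i)
        if j is None:
            continue
        paired_any = True
        if start <= j <= end:
            near_edge = (
                min(i, j) - start < terminal_slack
                and end - max(i, j) < terminal_slack
            )
            if not near_edge:
                return QuarantineItem(record.id, "mirna_spans_loop",
                                      f"positions {i} and {j} pair inside the miRNA")
    if not paired_any:
        return QuarantineItem(record.id, "mirna_unstructured",
                              "every miRNA position is unpaired")
    return None
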