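"""Screen a (natural or artificial) precursor against empirical sequence rules.

The rules encode which pair identities support efficient Dicer-like
processing in plants.  C-C mismatches consistently impair biogenesis and are
depleted from natural precursors, so they fail anywhere in the window; G-G
fails at the cleavage-site coordinates and warns elsewhere; mismatch
identities outside {A-C, C-U, U-U} at a cleavage site warn (A-A/A-G/G-A-type
variants retain only a small fraction of mature miRNA); an unpaired
coordinate 1, 3 or L+2 warns, since those positions are mostly paired in
natural precursors.  A C-C inside the miRNA/miRNA* duplex additionally
carries an info note: such duplexes can yield length/sequence variants
(isomiRs) rather than a single product.

Severities map effect sizes to actions: >10-fold loss of mature miRNA →
fail; ~2-fold or context-dependent → warn; qualitative → info.  Coordinate
−1 pairing is never penalized (it is unpaired in ~40% of natural
precursors).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

from .duplex_map import DuplexAlignment
from .pair_stats import classify_pair

ALLOWED_MISMATCHES = ("A-C", "C-U", "U-U")

SEVERITY_ORDER = {"info": 0, "warn": 1, "fail": 2}


@dataclasses.dataclass(frozen=True)
class Rule:
    rule_id: str
    severity: str
    citation: str
    enabled: bool = True


DEFAULT_RULESET: tuple[Rule, ...] = (
    Rule("R1", "fail",
         "C-C mismatches consistently impair plant miRNA biogenesis and are "
         "depleted from natural precursors"),
    Rule("R2", "fail",
         "G-G mismatches at a cleavage site strongly reduce mature miRNA "
         "accumulation"),
    Rule("R3", "warn",
         "G-G mismatches are rare in natural precursors even outside the "
         "cleavage sites"),
    Rule("R4", "warn",
         "cleavage-site mismatches outside A-C/C-U/U-U retain only ~10% "
         "mature miRNA accumulation"),
    Rule("R5", "warn",
         "coordinates 1, 3 and L+2 are mostly paired in natural precursors"),
    Rule("R6", "info",
         "a C-C mismatch inside the miRNA/miRNA* duplex can trigger isomiR "
         "production"),
)


@dataclasses.dataclass(frozen=True)
class Finding:
    rule_id: str
    coord: int
    observed: str
    severity: str
    citation: str


@dataclasses.dataclass
class DesignReport:
    record_id: str
    findings: list[Finding]

    @property
    def verdict(self) -> str:
        worst = max((SEVERITY_ORDER[f.severity] for f in self.findings),
                    default=0)
        if worst >= SEVERITY_ORDER["fail"]:
            return "fail"
        if worst >= SEVERITY_ORDER["warn"]:
            return "warn"
        return "pass"

    def to_json(self) -> str:
        return json.dumps({
            "record_id": self.record_id,
            "verdict": self.verdict,
            "findings": [dataclasses.asdict(f) for f in self.findings],
        }, indent=1)

    def to_text(self) -> str:
        lines = [f"{self.record_id}: {self.verdict.upper()}"]
        for f in sorted(self.findings,
                        key=lambda f: (-SEVERITY_ORDER[f.severity], f.coord)):
            lines.append(f"  [{f.severity}] {f.rule_id} at coord {f.coord}: "
                         f"{f.observed} — {f.citation}")
        if not self.findings:
            lines.append("  no findings")
        return "\n".join(lines)


def amirna_check(
    alignment: DuplexAlignment,
    ruleset: Sequence[Rule] = DEFAULT_RULESET,
) -> DesignReport:
    """Evaluate one registered precursor against the rule set.

    Requires an alignment with assigned cleavage-site coordinates (run the
    registration pipeline first); raises otherwise.
    """
    if alignment.duplex_span is None or not alignment.first_site:
        raise ValueError(
            f"{alignment.record_id}: alignment has no cleavage-site "
            "coordinates; run register_arms/assign_cleavage_coords first")
    rules = {r.rule_id: r for r in ruleset if r.enabled}
    L = alignment.duplex_span[1]
    site_coords = set(alignment.first_site) | set(alignment.second_site)
    findings: list[Finding] = []

    def add(rule_id: str, coord: int, observed: str) -> None:
        rule = rules.get(rule_id)
        if rule:
            findings.append(Finding(rule_id, coord, observed,
                                    rule.severity, rule.citation))

    for row in alignment.rows:
        if row.coord is None:
            continue
        pc = classify_pair(row, alignment.record_id)
        coord = row.coord
        at_site = coord in site_coords
        if pc.kind == "MISMATCH":
            ident = pc.identity_symmetric
            if ident == "C-C":
                add("R1", coord, "C-C mismatch")
                if 1 <= coord <= L:
                    add("R6", coord, "C-C mismatch inside the duplex")
            elif ident == "G-G":
                add("R2" if at_site else "R3", coord, "G-G mismatch")
            elif at_site and ident not in ALLOWED_MISMATCHES:
                add("R4", coord, f"{ident} mismatch")
        if coord in (1, 3, L + 2) and pc.kind in ("MISMATCH", "BULGE"):
            add("R5", coord, f"unpaired ({pc.identity_symmetric})")
    return DesignReport(record_id=alignment.record_id, findings=findings)
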