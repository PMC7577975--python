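"""Shared fixtures: hand-built hairpins and small synthetic surveys."""

from __future__ import annotations

import pytest

from mirduplex.io_formats import PrecursorRecord
from mirduplex.synthetic_data import SyntheticSpec, generate_records


def make_hairpin(pattern: list[str], loop: str = "AAAA",
                 flank5: str = "", flank3: str = ""):
    """Build a hairpin from a base-to-loop row pattern.

    Pattern symbols: ``P`` (G-C pair), ``M`` (A-A mismatch), ``B5``
    (5'-arm bulged A), ``B3`` (3'-arm bulged A).  Returns
    ``(sequence, dotbracket, arm5_interval, arm3_interval)`` with 1-based
    inclusive arm intervals.
    """
    nt_map = {"P": ("G", "C"), "M": ("A", "A"),
              "B5": ("A", ""), "B3": ("", "A")}
    seq5, seq3, db5, db3 = [], [], [], []
    for sym in pattern:
        a, b = nt_map[sym]
        if a:
            seq5.append(a)
            db5.append("(" if sym == "P" else ".")
        if b:
            seq3.append(b)
            db3.append(")" if sym == "P" else ".")
    arm5 = "".join(seq5)
    arm3 = "".join(reversed(seq3))
    dot5 = "".join(db5)
    dot3 = "".join(reversed(db3))
    sequence = flank5 + arm5 + loop + arm3 + flank3
    dotbracket = ("." * len(flank5) + dot5 + "." * len(loop)
                  + dot3 + "." * len(flank3))
    a5 = (len(flank5) + 1, len(flank5) + len(arm5))
    a3 = (len(flank5) + len(arm5) + len(loop) + 1,
          len(flank5) + len(arm5) + len(loop) + len(arm3))
    return sequence, dotbracket, a5, a3


@pytest.fixture
def perfect_hairpin():
    """50-nt hairpin: i pairs with 51-i for i <= 23, loop at 24-27."""
    sequence = "G" * 23 + "AAAA" + "C" * 23
    dotbracket = "(" * 23 + "...." + ")" * 23
    return sequence, dotbracket


@pytest.fixture
def planted_survey():
    """Small deterministic synthetic survey with default study conditions."""
    spec = SyntheticSpec(n_records=60, seed=11)
    records, truths = generate_records(spec)
    return spec, records, truths


def record_from(sequence, dotbracket, mirna, arm="5p",
                direction="base_to_loop", rid="rec1"):
    return PrecursorRecord(
        id=rid, species="test", group="test", sequence=sequence,
        mirna_start=mirna[0], mirna_end=mirna[1], arm=arm,
        direction=direction, structure=dotbracket)
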