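"""Synthetic precursors with planted, per-position ground truth.

Each generated record is a hairpin assembled row by row in cleavage-site
coordinates: an unstructured A-rich basal flank, a lower stem (the 15–17 bp
double-stranded segment typical of base-to-loop precursors; 16 rows by
default), the miRNA/miRNA* duplex region, an upper-stem extension, and a
terminal loop.  Every row's pair class is drawn from a per-coordinate
probability vector, so the planted class map, dot-bracket structure, miRNA
and star intervals are all known exactly and the whole pipeline can be
exercised without any external data.

The default per-coordinate distributions emulate the positional biases of
natural plant precursors: roughly 65% of positions paired overall with the
G-U wobble rare relative to A-U/G-C; a strongly paired coordinate 1 with
G-C at 59%; coordinate −1 unpaired in ~40% of records with A-C the
preferred mismatch (25%); coordinates 3 and L+2 mostly paired; C-C and G-G
mismatches absent from the cleavage-site coordinates and rare elsewhere,
with U-U the most common mismatch.  The outermost lower-stem row and the
topmost upper row are clamped to Watson–Crick closing pairs so that every
planted coordinate stays inside the registrable stem.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io_formats
from .io_formats import PrecursorRecord

PAIRED_CLASSES = ("G-C", "A-U", "G-U")
MISMATCH_CLASSES = ("A-A", "A-C", "A-G", "C-C", "C-U", "G-G", "U-U")
BULGE_CLASSES = ("bulge5", "bulge3")
ALL_CLASSES = PAIRED_CLASSES + MISMATCH_CLASSES + BULGE_CLASSES

#: off-site default: ~65% paired, wobble rare, U-U the top mismatch
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "G-C": 0.30, "A-U": 0.29, "G-U": 0.08,
    "U-U": 0.09, "A-C": 0.08, "C-U": 0.06, "A-A": 0.05, "A-G": 0.04,
    "C-C": 0.005, "G-G": 0.005,
}

#: lower stem: a predominantly double-stranded segment
LOWER_STEM_PROBS: dict[str, float] = {
    "G-C": 0.48, "A-U": 0.34, "G-U": 0.08,
    "U-U": 0.03, "A-C": 0.03, "C-U": 0.02, "A-A": 0.01, "A-G": 0.01,
}

#: cleavage-site coordinates: C-C/G-G absent; coord 1 G-C-dominated and
#: >=90% paired; coord -1 ~40% unpaired with A-C preferred; 3 and L+2 mostly
#: paired.  Keys are resolved against (basal coords, L = miRNA length).
SITE_PROBS: dict[str, dict[str, float]] = {
    "coord_1": {"G-C": 0.59, "A-U": 0.22, "G-U": 0.09,
                "A-C": 0.04, "C-U": 0.03, "U-U": 0.03},
    "coord_-1": {"G-C": 0.25, "A-U": 0.25, "G-U": 0.10,
                 "A-C": 0.25, "U-U": 0.06, "C-U": 0.05,
                 "A-A": 0.02, "A-G": 0.02},
    "mostly_paired": {"G-C": 0.40, "A-U": 0.35, "G-U": 0.10,
                      "A-C": 0.06, "U-U": 0.05, "C-U": 0.04},
    "site_default": {"G-C": 0.30, "A-U": 0.29, "G-U": 0.08,
                     "U-U": 0.095, "A-C": 0.085, "C-U": 0.065,
                     "A-A": 0.05, "A-G": 0.035},
}

_COMPLEMENT = {"G-C": ("G", "C"), "A-U": ("A", "U"), "G-U": ("G", "U")}


class SpecError(ValueError):
    """An unsatisfiable or inconsistent synthetic specification."""


@dataclasses.dataclass
class SyntheticSpec:
    """Study conditions for one synthetic survey."""

    n_records: int = 100
    mirna_length: int = 21
    lower_stem_length: int = 16
    loop_length: int = 8
    upper_length: int = 8
    flank_length: int = 8
    #: explicit per-coordinate class probabilities; unlisted coordinates fall
    #: back to the positional defaults above
    class_probs: Mapping[int, Mapping[str, float]] = dataclasses.field(
        default_factory=dict)
    direction_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"base_to_loop": 0.5, "loop_to_base": 0.5})
    arm: str = "5p"
    seed: int = 0
    group: str = "synthetic"
    species: str = "synthetic"

    def validate(self) -> None:
        if self.n_records < 0 or self.mirna_length <= 0 \
                or self.lower_stem_length <= 0 or self.upper_length < 0:
            raise SpecError("lengths must be positive")
        if self.loop_length < 3:
            raise SpecError("loop_length must be >= 3")
        if self.arm not in ("5p", "3p"):
            raise SpecError(f"bad arm: {self.arm}")
        for coord, probs in self.class_probs.items():
            self._check_vector(coord, probs)
        if not np.isclose(sum(self.direction_mix.values()), 1.0, atol=1e-9):
            raise SpecError("direction mix must sum to 1")

    @staticmethod
    def _check_vector(coord, probs) -> None:
        unknown = set(probs) - set(ALL_CLASSES)
        if unknown:
            raise SpecError(
                f"coord {coord}: unknown or unsatisfiable classes {sorted(unknown)} "
                f"(pair classes are {ALL_CLASSES})")
        if not np.isclose(sum(probs.values()), 1.0, atol=1e-9):
            raise SpecError(f"coord {coord}: probabilities must sum to 1")

    # -- resolved per-coordinate distributions (the planted truth) --
    def coordinates(self) -> list[int]:
        lower = list(range(-self.lower_stem_length, 0))
        upper = list(range(1, self.mirna_length + self.upper_length + 1))
        return lower + upper

    def probs_for(self, coord: int) -> dict[str, float]:
        coords = self.coordinates()
        if coord == coords[0] or coord == coords[-1]:
            # clamp the stem ends to WC closing pairs (keeps the registration
            # window closed; see methods note)
            return {"G-C": 0.6, "A-U": 0.4}
        if coord in self.class_probs:
            return dict(self.class_probs[coord])
        L = self.mirna_length
        if coord == 1:
            return dict(SITE_PROBS["coord_1"])
        if coord == -1:
            return dict(SITE_PROBS["coord_-1"])
        if coord in (3, L + 2):
            return dict(SITE_PROBS["mostly_paired"])
        if coord in (2, L, L + 1, L + 3):
            return dict(SITE_PROBS["site_default"])
        if coord < 0:
            return dict(LOWER_STEM_PROBS)
        return dict(DEFAULT_CLASS_PROBS)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth planted into one record."""

    record_id: str
    dotbracket: str
    mirna_interval: tuple[int, int]
    star_interval: tuple[int, int]
    arm: str
    direction: str
    class_map: dict[int, str]  # coord -> planted class label ("bulge" pooled)

    def to_json_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "dotbracket": self.dotbracket,
            "mirna_interval": list(self.mirna_interval),
            "star_interval": list(self.star_interval),
            "arm": self.arm,
            "direction": self.direction,
            "class_map": {str(k): v for k, v in self.class_map.items()},
        }


def _sample_nts(rng: np.random.Generator, label: str) -> tuple[str, str]:
    """Nucleotides (nt5, nt3) realizing a class label, orientation random."""
    if label in _COMPLEMENT:
        a, b = _COMPLEMENT[label]
    elif label in MISMATCH_CLASSES:
        a, b = label.split("-")
    elif label == "bulge5":
        return str(rng.choice(list("ACGU"))), ""
    elif label == "bulge3":
        return "", str(rng.choice(list("ACGU")))
    else:
        raise SpecError(f"cannot realize class {label}")
    if a != b and rng.random() < 0.5:
        a, b = b, a
    return a, b


def _sample_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACU"), size=length,
                              p=[0.8, 0.1, 0.1]))


def generate_precursor(
    spec: SyntheticSpec, seed: int,
) -> tuple[PrecursorRecord, SyntheticTruth]:
    """One record plus its planted truth; byte-deterministic per (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    coords = spec.coordinates()

    planted: dict[int, str] = {}
    rows: list[tuple[int, str, str]] = []  # (coord, nt5, nt3)
    for coord in coords:
        probs = spec.probs_for(coord)
        labels = sorted(probs)
        label = str(rng.choice(labels, p=[probs[k] for k in labels]))
        nt5, nt3 = _sample_nts(rng, label)
        planted[coord] = "bulge" if label.startswith("bulge") else label
        rows.append((coord, nt5, nt3))

    flank5 = _sample_flank(rng, spec.flank_length)
    flank3 = _sample_flank(rng, spec.flank_length)
    loop = "A" * spec.loop_length

    # assemble sequence and per-row source positions
    src5: dict[int, int] = {}
    src3: dict[int, int] = {}
    pos = len(flank5)
    seq5 = []
    for coord, nt5, _ in rows:
        if nt5:
            pos += 1
            src5[coord] = pos
            seq5.append(nt5)
    pos += len(loop)
    seq3 = []
    for coord, _, nt3 in reversed(rows):
        if nt3:
            pos += 1
            src3[coord] = pos
            seq3.append(nt3)
    sequence = flank5 + "".join(seq5) + loop + "".join(seq3) + flank3

    db = ["."] * len(sequence)
    for coord, nt5, nt3 in rows:
        if nt5 and nt3 and planted[coord] in PAIRED_CLASSES:
            db[src5[coord] - 1] = "("
            db[src3[coord] - 1] = ")"
    dotbracket = "".join(db)

    L = spec.mirna_length
    duplex_coords = [c for c in coords if 1 <= c <= L]
    star_coords = [c for c in coords if -2 <= c <= L - 2 and c != 0]
    if spec.arm == "5p":
        m5 = [src5[c] for c in duplex_coords if c in src5]
        s3 = [src3[c] for c in star_coords if c in src3]
        mirna = (min(m5), max(m5))
        star = (min(s3), max(s3))
    else:
        m3 = [src3[c] for c in duplex_coords if c in src3]
        s5 = [src5[c] for c in star_coords if c in src5]
        mirna = (min(m3), max(m3))
        star = (min(s5), max(s5))

    directions = sorted(spec.direction_mix)
    direction = str(rng.choice(
        directions, p=[spec.direction_mix[d] for d in directions]))

    rid = f"syn-{seed:08d}"
    record = PrecursorRecord(
        id=rid, species=spec.species, group=spec.group, sequence=sequence,
        mirna_start=mirna[0], mirna_end=mirna[1], arm=spec.arm,
        direction=direction, structure=dotbracket)
    truth = SyntheticTruth(
        record_id=rid, dotbracket=dotbracket, mirna_interval=mirna,
        star_interval=star, arm=spec.arm, direction=direction,
        class_map=planted)
    return record, truth


def generate_records(
    spec: SyntheticSpec,
) -> tuple[list[PrecursorRecord], list[SyntheticTruth]]:
    """All records for a spec; per-record seeds derive from ``spec.seed`` by
    counter through a splittable seed sequence."""
    spec.validate()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_records)
    records, truths = [], []
    for k, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        rec, truth = generate_precursor(spec, seed)
        rec.id = f"syn-{spec.seed}-{k:05d}"
        truth.record_id = rec.id
        records.append(rec)
        truths.append(truth)
    return records, truths


def generate_survey(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a full survey bundle: FASTA, annotation TSV, dot-bracket file and
    truth JSON.  Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truths = generate_records(spec)
    paths = {
        "fasta": outdir / "precursors.fasta",
        "annotation": outdir / "annotation.tsv",
        "dotbracket": outdir / "structures.db",
        "truth": outdir / "truth.json",
    }
    io_formats.write_fasta([(r.id, r.sequence) for r in records],
                           paths["fasta"])
    io_formats.write_annotation_table(records, paths["annotation"])
    io_formats.write_dotbracket_file(
        [(r.id, r.sequence, r.structure) for r in records],
        paths["dotbracket"])
    payload = {
        "spec": {
            "n_records": spec.n_records, "mirna_length": spec.mirna_length,
            "lower_stem_length": spec.lower_stem_length,
            "loop_length": spec.loop_length, "upper_length": spec.upper_length,
            "arm": spec.arm, "seed": spec.seed,
        },
        "records": [t.to_json_dict() for t in truths],
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
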