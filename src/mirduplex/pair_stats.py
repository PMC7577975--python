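"""Classify position-pairs and aggregate positional frequency matrices.

Pair classes follow the field's usage: Watson–Crick (A-U, G-C), the G-U
wobble, mismatches (two opposed unpaired nucleotides) and bulges (a
nucleotide with no counterpart).  Symmetric identities pool the two strand
orientations (A-C/C-A → "A-C"); ordered identities keep nt5-nt3.  Bulged
nucleotides are never counted as mismatches — the mismatch identity tables
stay pure two-nucleotide classes — but fold into "unpaired" for the
paired/unpaired dichotomy by default.

Overall shares are pooled across positions and precursors (not averaged per
precursor); a per-precursor averaging mode is available.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .duplex_map import GAP, DuplexAlignment, PositionPair
from .io_formats import NucleotideComposition

log = logging.getLogger("mirduplex")

WC_ORDERED = ("A-U", "U-A", "G-C", "C-G")
WOBBLE_ORDERED = ("G-U", "U-G")

#: canonical symmetric labels, matching the conventional figure labels
SYMMETRIC_LABEL = {
    frozenset("AU"): "A-U",
    frozenset("GC"): "G-C",
    frozenset("GU"): "G-U",
    frozenset("AC"): "A-C",
    frozenset("AG"): "A-G",
    frozenset("CU"): "C-U",
    frozenset("A"): "A-A",
    frozenset("C"): "C-C",
    frozenset("G"): "G-G",
    frozenset("U"): "U-U",
}

SYMMETRIC_CLASSES = ("A-U", "G-C", "G-U",
                     "A-A", "A-C", "A-G", "C-C", "C-U", "G-G", "U-U")
ORDERED_CLASSES = tuple(f"{a}-{b}" for a in "ACGU" for b in "ACGU")
KIND_CLASSES = ("WC", "WOBBLE", "MISMATCH", "BULGE")
BULGE = "bulge"


class IntegrityError(RuntimeError):
    """The structure engine reported a paired non-canonical combination."""


@dataclasses.dataclass(frozen=True)
class PairClass:
    kind: str                 # WC | WOBBLE | MISMATCH | BULGE
    identity_ordered: str     # "G-C", ... or "bulge"
    identity_symmetric: str   # canonical symmetric label or "bulge"


def classify_pair(pp: PositionPair, record_id: str = "") -> PairClass:
    """Deterministic class lookup for one alignment row."""
    if pp.nt5 == GAP or pp.nt3 == GAP:
        return PairClass("BULGE", BULGE, BULGE)
    ordered = f"{pp.nt5}-{pp.nt3}"
    symmetric = SYMMETRIC_LABEL[frozenset((pp.nt5, pp.nt3))]
    if pp.paired:
        if ordered in WC_ORDERED:
            return PairClass("WC", ordered, symmetric)
        if ordered in WOBBLE_ORDERED:
            return PairClass("WOBBLE", ordered, symmetric)
        raise IntegrityError(
            f"record {record_id or '?'}: engine reports paired {ordered}, "
            "which is not a canonical pair")
    return PairClass("MISMATCH", ordered, symmetric)


def symmetric_identity(nt5: str, nt3: str) -> str:
    return SYMMETRIC_LABEL[frozenset((nt5, nt3))]


# ---------------------------------------------------------------------------
# Frequency matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PairFrequencyMatrix:
    """Positions × pair-class table held as raw counts.

    ``counts`` has classes as the index and coordinates as columns;
    percentages are derived on demand so that rounding happens only at
    serialization.  Every percentage column sums to 100 (over its class set)
    whenever the column has any observations.
    """

    counts: pd.DataFrame
    n_per_position: pd.Series
    mode: str  # "kind" | "symmetric" | "ordered"

    @property
    def percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = self.counts.div(totals, axis=1) * 100.0
        return pct.fillna(0.0) if (totals == 0).any() else pct

    @property
    def positions(self) -> list:
        return list(self.counts.columns)

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    def value(self, cls: str, coord) -> float:
        return float(self.percentages.loc[cls, coord])

    def __eq__(self, other) -> bool:
        if not isinstance(other, PairFrequencyMatrix):
            return NotImplemented
        return (self.mode == other.mode
                and self.counts.equals(other.counts)
                and self.n_per_position.astype(int).equals(
                    other.n_per_position.astype(int)))


def _class_of(pp: PositionPair, mode: str, record_id: str = "") -> str:
    pc = classify_pair(pp, record_id)
    if mode == "kind":
        return pc.kind
    if mode == "symmetric":
        return pc.identity_symmetric
    if mode == "ordered":
        return pc.identity_ordered
    raise ValueError(f"unknown identity mode: {mode}")


def _class_universe(mode: str, include_bulge: bool) -> list[str]:
    base = {"kind": [k for k in KIND_CLASSES if k != "BULGE"],
            "symmetric": list(SYMMETRIC_CLASSES),
            "ordered": list(ORDERED_CLASSES)}[mode]
    if include_bulge:
        base = base + (["BULGE"] if mode == "kind" else [BULGE])
    return base


def _window_rows(aln: DuplexAlignment,
                 window: Sequence[int] | None) -> Iterable[PositionPair]:
    for r in aln.rows:
        if r.coord is None:
            continue
        if window is not None and r.coord not in window:
            continue
        yield r


def overall_composition(
    alignments: Sequence[DuplexAlignment],
    window: Sequence[int] | None = None,
    mode: str = "kind",
    include_bulge: bool = True,
    pooling: str = "pooled",
) -> PairFrequencyMatrix:
    """Overall class shares across all window positions, as a single pooled
    column ``"all"`` (pie-chart style).  ``pooling="per_precursor"`` averages
    each precursor's own shares instead of pooling positions."""
    if not alignments:
        raise ValueError("no alignments")
    classes = _class_universe(mode, include_bulge)
    if pooling == "pooled":
        counts = dict.fromkeys(classes, 0)
        n_records = 0
        for aln in alignments:
            contributed = False
            for r in _window_rows(aln, window):
                c = _class_of(r, mode, aln.record_id)
                if c in counts:
                    counts[c] += 1
                    contributed = True
            n_records += contributed
        total = sum(counts.values())
        if total == 0:
            raise ValueError("empty window: no positions to pool")
        frame = pd.DataFrame({"all": pd.Series(counts)[classes]})
        return PairFrequencyMatrix(
            counts=frame, n_per_position=pd.Series({"all": n_records}),
            mode=mode)
    if pooling == "per_precursor":
        shares = []
        for aln in alignments:
            c = dict.fromkeys(classes, 0)
            for r in _window_rows(aln, window):
                k = _class_of(r, mode, aln.record_id)
                if k in c:
                    c[k] += 1
            tot = sum(c.values())
            if tot:
                shares.append({k: v / tot for k, v in c.items()})
        if not shares:
            raise ValueError("empty window: no positions to pool")
        mean = pd.DataFrame(shares).mean()
        # rescale to pseudo-counts so the container stays count-based
        scale = 10_000
        frame = pd.DataFrame({"all": (mean[classes] * scale).round().astype(int)})
        return PairFrequencyMatrix(
            counts=frame, n_per_position=pd.Series({"all": len(shares)}),
            mode=mode)
    raise ValueError(f"unknown pooling mode: {pooling}")


def site_composition(
    alignments: Sequence[DuplexAlignment],
    coord_set: Sequence[int],
    mode: str = "symmetric",
    include_bulge: bool = True,
) -> PairFrequencyMatrix:
    """Per-coordinate class percentages over ``coord_set``.

    A record lacking a coordinate (short precursor) is excluded from that
    column's denominator.
    """
    coords = list(coord_set)
    classes = _class_universe(mode, include_bulge)
    counts = pd.DataFrame(0, index=classes, columns=coords, dtype=int)
    n = pd.Series(0, index=coords, dtype=int)
    for aln in alignments:
        for r in _window_rows(aln, coords):
            c = _class_of(r, mode, aln.record_id)
            if c in counts.index:
                counts.loc[c, r.coord] += 1
                n[r.coord] += 1
    return PairFrequencyMatrix(counts=counts, n_per_position=n, mode=mode)


def paired_unpaired_shares(matrix: PairFrequencyMatrix,
                           fold_bulges: bool = True) -> pd.DataFrame:
    """Paired (WC+wobble) vs unpaired percentage per column; bulges count as
    unpaired by default (``fold_bulges=False`` drops them instead)."""
    paired_classes = {"WC", "WOBBLE", "A-U", "G-C", "G-U"} | set(
        WC_ORDERED) | set(WOBBLE_ORDERED)
    counts = matrix.counts
    if matrix.mode != "kind":
        # symmetric/ordered: G-U label is wobble, other doubles are mismatches
        paired_classes = {"A-U", "G-C", "G-U", "U-A", "C-G", "U-G"}
    paired = counts.loc[[c for c in counts.index if c in paired_classes]].sum()
    bulges = counts.loc[[c for c in counts.index
                         if c in ("BULGE", BULGE)]].sum()
    unpaired = counts.sum() - paired - (0 if fold_bulges else bulges)
    total = paired + unpaired
    with np.errstate(invalid="ignore", divide="ignore"):
        out = pd.DataFrame({"paired": paired / total * 100.0,
                            "unpaired": unpaired / total * 100.0})
    return out.fillna(0.0)


def count_mismatch_positions(
    alignments: Sequence[DuplexAlignment],
    window: Sequence[int] | None = None,
) -> tuple[int, int]:
    """(number of mismatch-class positions, number of contributing precursors)."""
    n_positions = 0
    n_precursors = 0
    for aln in alignments:
        here = sum(1 for r in _window_rows(aln, window)
                   if classify_pair(r, aln.record_id).kind == "MISMATCH")
        n_positions += here
        n_precursors += here > 0
    return n_positions, n_precursors


def conservation_count(
    alignments: Sequence[DuplexAlignment],
    coord: int,
    identity: str,
    mode: str = "symmetric",
) -> tuple[int, int]:
    """How many precursors carry ``identity`` at ``coord`` (n_with, n_total);
    the denominator counts precursors that have the coordinate at all."""
    n_with = n_total = 0
    for aln in alignments:
        r = aln.row_at(coord)
        if r is None:
            continue
        n_total += 1
        if _class_of(r, mode, aln.record_id) == identity:
            n_with += 1
    return n_with, n_total


# ---------------------------------------------------------------------------
# Mononucleotide null
# ---------------------------------------------------------------------------

INF_SENTINEL = float("inf")


@dataclasses.dataclass
class NullComparison:
    """Independence-null expectations and, when observed data is supplied,
    per-class enrichment and per-position goodness of fit."""

    expected_ordered: pd.Series      # percentages, 16 ordered pairs
    expected_symmetric: pd.Series    # percentages, 10 symmetric classes
    enrichment: pd.DataFrame | None = None   # log2(obs/exp) per class, position
    chisquare: pd.DataFrame | None = None    # statistic, dof, pvalue per position


def expected_pair_frequencies(
    composition: NucleotideComposition | Mapping[str, float],
    observed: PairFrequencyMatrix | None = None,
) -> NullComparison:
    """Expected pair shares if the two sides were independent draws from the
    mononucleotide composition: ordered pair (x, y) gets p(x)·p(y); symmetric
    classes sum their ordered members.

    With ``observed`` (an identity-mode matrix), also returns per-class
    log2(observed/expected) enrichment — ``+inf`` sentinel where expected is
    zero but observed is not, excluded from the chi-square with a warning —
    and a chi-square goodness-of-fit statistic per position.
    """
    p = (composition.frequencies if isinstance(composition, NucleotideComposition)
         else dict(composition))
    total = sum(p.get(nt, 0.0) for nt in "ACGU")
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"composition frequencies must sum to 1, got {total}")

    ordered = pd.Series(
        {f"{a}-{b}": p.get(a, 0.0) * p.get(b, 0.0) * 100.0
         for a in "ACGU" for b in "ACGU"})
    symmetric = pd.Series(0.0, index=list(SYMMETRIC_CLASSES))
    for pair, val in ordered.items():
        symmetric[SYMMETRIC_LABEL[frozenset(pair.split("-"))]] += val

    result = NullComparison(expected_ordered=ordered,
                            expected_symmetric=symmetric)
    if observed is None:
        return result
    if observed.mode not in ("ordered", "symmetric"):
        raise ValueError("null comparison needs an identity-mode matrix")
    expected = ordered if observed.mode == "ordered" else symmetric

    obs_pct = observed.percentages
    classes = [c for c in obs_pct.index if c in expected.index]
    exp = expected[classes] / expected[classes].sum() * 100.0  # drop bulge mass
    enr = pd.DataFrame(index=classes, columns=obs_pct.columns, dtype=float)
    chis = []
    for col in obs_pct.columns:
        obs_counts = observed.counts.loc[classes, col].astype(float)
        n = obs_counts.sum()
        usable = exp > 0
        dropped = (~usable) & (obs_counts > 0)
        if dropped.any():
            warnings.warn(
                f"position {col}: classes {list(obs_counts.index[dropped])} "
                "observed with zero expectation; excluded from chi-square")
        o = obs_pct.loc[classes, col].astype(float).to_numpy()
        e = exp.to_numpy()
        vals = np.zeros(len(o))
        with np.errstate(divide="ignore", invalid="ignore"):
            pos = (o > 0) & (e > 0)
            vals[pos] = np.log2(o[pos] / e[pos])
        vals[(o > 0) & (e == 0)] = INF_SENTINEL
        vals[(o == 0) & (e > 0)] = -INF_SENTINEL
        enr[col] = vals
        n_usable = obs_counts[usable].sum()
        if n_usable > 0 and usable.sum() > 1:
            # conditional fit over the usable classes only
            f_exp = (exp[usable] / exp[usable].sum() * n_usable).to_numpy()
            stat, pval = stats.chisquare(obs_counts[usable].to_numpy(), f_exp)
            chis.append({"position": col, "statistic": stat,
                         "dof": int(usable.sum()) - 1, "pvalue": pval,
                         "n": int(n_usable)})
    result.enrichment = enr
    result.chisquare = pd.DataFrame(chis)
    return result


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_groups(matrix_a: PairFrequencyMatrix,
                   matrix_b: PairFrequencyMatrix,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Cell-wise percentage-point differences (A − B) with two-proportion
    z-test p-values, Benjamini–Hochberg adjusted across all cells."""
    if (matrix_a.mode != matrix_b.mode
            or list(matrix_a.counts.index) != list(matrix_b.counts.index)
            or list(matrix_a.counts.columns) != list(matrix_b.counts.columns)):
        raise ValueError("matrices have different class/coordinate layouts")
    rows = []
    tot_a = matrix_a.counts.sum(axis=0)
    tot_b = matrix_b.counts.sum(axis=0)
    pa, pb = matrix_a.percentages, matrix_b.percentages
    for col in matrix_a.counts.columns:
        na, nb = int(tot_a[col]), int(tot_b[col])
        for cls in matrix_a.counts.index:
            ca = int(matrix_a.counts.loc[cls, col])
            cb = int(matrix_b.counts.loc[cls, col])
            diff = float(pa.loc[cls, col] - pb.loc[cls, col])
            if na and nb and 0 < ca + cb < na + nb:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, pval = proportions_ztest([ca, cb], [na, nb])
            else:
                pval = np.nan
            rows.append({"class": cls, "position": col, "diff_pp": diff,
                         "count_a": ca, "count_b": cb,
                         "n_a": na, "n_b": nb, "pvalue": pval})
    table = pd.DataFrame(rows)
    mask = table["pvalue"].notna()
    table["qvalue"] = np.nan
    if mask.any():
        table.loc[mask, "qvalue"] = multipletests(
            table.loc[mask, "pvalue"], method="fdr_bh")[1]
    table["significant"] = table["qvalue"] < alpha
    return table
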