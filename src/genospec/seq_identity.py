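"""Marker-gene sequence statistics: identity matrices, Kimura two-parameter
distances, alignment summaries, MLSA concatenation, and identity screens.

Two identity conventions are supported through ``gap_policy``:
``gaps-are-differences`` (the "number of differences" convention in which an
indel column counts as a mismatch — used for the MLSA screen) and
``exclude-pairwise`` (gapped columns dropped per pair, as distance programs
usually do). The K2P distance always excludes sites with a gap or N in
either sequence.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _seqcodes as sc
from .io_formats import AlignmentBlock, LabeledMatrix, SequenceRecord

__all__ = [
    "K2PEstimate",
    "AlignmentStats",
    "MlsaScreenResult",
    "SaturationError",
    "MLSA_CONCATENATION_ORDER",
    "MLSA_SAME_SPECIES_MIN",
    "MLSA_DIFFERENT_SPECIES_MAX",
    "GENUS_BOUNDARY",
    "GENUS_BOUNDARY_TOLERANCE",
    "pairwise_identity",
    "k2p_distance",
    "alignment_stats",
    "concatenate_loci",
    "mlsa_species_screen",
    "genus_boundary_screen",
]

#: Housekeeping genes in the fixed order used to build the MLSA alignment.
MLSA_CONCATENATION_ORDER = ("clpA", "atpD", "gyrB", "rpoH",
                            "secF", "dnaJ", "rpoD", "rpoS")

#: MLSA identity screen: above the first bound two strains belong to the
#: same genomic species, below the second they do not; in between lies a
#: grey zone. Derived from comparing MLSA identities with whole-genome
#: species assignments in the Thioalkalivibrio dataset.
MLSA_SAME_SPECIES_MIN = 98.13
MLSA_DIFFERENT_SPECIES_MAX = 97.77

#: Proposed minimal 16S rRNA identity separating two genera, with its
#: tolerance band (94.8 +/- 0.25).
GENUS_BOUNDARY = 94.8
GENUS_BOUNDARY_TOLERANCE = 0.25


class SaturationError(ValueError):
    """Raised when divergence is too high for the K2P correction."""


@dataclass
class K2PEstimate:
    """Kimura two-parameter distance between one pair of aligned sequences.

    P and Q are the observed transition and transversion proportions over
    the ``n_sites`` comparable (ungapped, unambiguous) site pairs.
    """

    P: float
    Q: float
    d: float
    n_sites: int


@dataclass
class AlignmentStats:
    """Summary statistics of one alignment (marker gene or MLSA)."""

    length: int
    pct_polymorphic: float
    mean_gc: float
    min_d: float
    max_d: float
    mean_d: float
    n_saturated_pairs: int = 0


@dataclass
class MlsaScreenResult:
    verdict: str  # same-species | different-species | grey-zone
    identity: float


def _block_array(block: AlignmentBlock) -> np.ndarray:
    return np.vstack([sc.encode(r.seq) for r in block.records])


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------

def pairwise_identity(block: AlignmentBlock,
                      gap_policy: str = "gaps-are-differences"
                      ) -> LabeledMatrix:
    """Percent-identity matrix over all sequence pairs of an alignment.

    identity(i,j) = 100 * matches / compared columns. Columns that are gaps
    in *all* sequences are dropped up front; columns with an N in either
    member of a pair are excluded from that pair's comparison. Under
    ``gaps-are-differences`` a column gapped in one sequence of the pair is
    compared (and counts as a mismatch); under ``exclude-pairwise`` it is
    dropped for that pair.
    """
    if gap_policy not in ("gaps-are-differences", "exclude-pairwise"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    arr = _block_array(block)
    all_gap = np.all(arr == sc.GAP, axis=0)
    arr = arr[:, ~all_gap]
    n = arr.shape[0]
    vals = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        a, b = arr[i], arr[j]
        usable = (a != sc.N) & (b != sc.N)
        if gap_policy == "exclude-pairwise":
            usable &= (a != sc.GAP) & (b != sc.GAP)
        else:
            usable &= ~((a == sc.GAP) & (b == sc.GAP))
        n_cmp = int(usable.sum())
        if n_cmp == 0:
            raise ValueError(
                f"no comparable columns between {block.ids[i]!r} and "
                f"{block.ids[j]!r}"
            )
        matches = int(np.sum((a == b) & usable & (a < 4)))
        vals[i, j] = vals[j, i] = 100.0 * matches / n_cmp
    kind = "16S-identity" if block.locus == "16S" else "MLSA-identity"
    return LabeledMatrix(block.ids, vals, kind)


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------

def k2p_distance(seq_a: str | SequenceRecord,
                 seq_b: str | SequenceRecord) -> K2PEstimate:
    """Kimura two-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    Sites with a gap or N in either sequence are excluded. Raises
    :class:`SaturationError` when the log argument is non-positive
    (divergence too high for the correction) and ``ValueError`` when no
    comparable sites remain.
    """
    a = sc.encode(seq_a.seq if isinstance(seq_a, SequenceRecord) else seq_a)
    b = sc.encode(seq_b.seq if isinstance(seq_b, SequenceRecord) else seq_b)
    if a.size != b.size:
        raise ValueError("K2P requires equal-length aligned sequences")
    usable = (a < 4) & (b < 4)
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    au, bu = a[usable], b[usable]
    diff = au != bu
    ti = int(np.sum(sc.is_transition(au, bu)))
    tv = int(diff.sum()) - ti
    P, Q = ti / n, tv / n
    x = 1.0 - 2.0 * P - Q
    y = 1.0 - 2.0 * Q
    if x <= 0 or y <= 0:
        raise SaturationError(
            f"saturated divergence (P={P:.3f}, Q={Q:.3f}); K2P undefined"
        )
    d = -0.5 * math.log(x * math.sqrt(y))
    return K2PEstimate(P=P, Q=Q, d=d, n_sites=n)


def k2p_distance_matrix(block: AlignmentBlock) -> LabeledMatrix:
    """All-pairs K2P distances; saturated pairs become NaN with a warning."""
    n = len(block.records)
    vals = np.zeros((n, n))
    n_sat = 0
    for i, j in itertools.combinations(range(n), 2):
        try:
            vals[i, j] = vals[j, i] = k2p_distance(
                block.records[i], block.records[j]).d
        except SaturationError:
            vals[i, j] = vals[j, i] = np.nan
            n_sat += 1
    if n_sat:
        warnings.warn(f"{n_sat} saturated pair(s) reported as missing")
    return LabeledMatrix(block.ids, vals, "distance")


# ---------------------------------------------------------------------------
# Alignment summary
# ---------------------------------------------------------------------------

def alignment_stats(block: AlignmentBlock) -> AlignmentStats:
    """Length, polymorphic-site percentage, mean G+C, and the min/max/mean
    pairwise K2P distance of an alignment.

    A column is polymorphic when it shows >=2 distinct states among
    {A,C,G,T}; gaps and Ns are not states. Saturated pairs are skipped and
    counted in ``n_saturated_pairs``.
    """
    arr = _block_array(block)
    length = arr.shape[1]
    poly = 0
    for col in range(length):
        states = np.unique(arr[arr[:, col] < 4, col])
        if states.size >= 2:
            poly += 1
    acgt = arr < 4
    gc_per_seq = (np.sum((arr == sc.C) | (arr == sc.G), axis=1)
                  / np.maximum(acgt.sum(axis=1), 1))
    ds = []
    n_sat = 0
    for i, j in itertools.combinations(range(arr.shape[0]), 2):
        try:
            ds.append(k2p_distance(block.records[i], block.records[j]).d)
        except SaturationError:
            n_sat += 1
    if n_sat:
        warnings.warn(f"{n_sat} saturated pair(s) excluded from distance stats")
    if not ds:
        raise ValueError("all pairs saturated; no distances available")
    return AlignmentStats(
        length=length,
        pct_polymorphic=100.0 * poly / length,
        mean_gc=100.0 * float(np.mean(gc_per_seq)),
        min_d=float(np.min(ds)),
        max_d=float(np.max(ds)),
        mean_d=float(np.mean(ds)),
        n_saturated_pairs=n_sat,
    )


# ---------------------------------------------------------------------------
# MLSA
# ---------------------------------------------------------------------------

def concatenate_loci(blocks: list[AlignmentBlock]) -> AlignmentBlock:
    """Concatenate the eight housekeeping loci into the MLSA alignment.

    Columns are joined in the fixed order clpA, atpD, gyrB, rpoH, secF,
    dnaJ, rpoD, rpoS regardless of the order in which blocks are supplied.
    Every locus must cover exactly the same strain set.
    """
    by_locus = {b.locus: b for b in blocks}
    if len(by_locus) != len(blocks):
        raise ValueError("duplicate locus in concatenation input")
    present = [l for l in MLSA_CONCATENATION_ORDER if l in by_locus]
    extra = set(by_locus) - set(MLSA_CONCATENATION_ORDER)
    if extra:
        raise ValueError(f"loci not part of the MLSA set: {sorted(extra)}")
    if not present:
        raise ValueError("no MLSA loci supplied")
    ref_ids = by_locus[present[0]].ids
    ref_set = set(ref_ids)
    for locus in present:
        missing = ref_set.symmetric_difference(by_locus[locus].ids)
        if missing:
            raise ValueError(
                f"strain set mismatch at locus {locus}: {sorted(missing)}"
            )
    ordered_ids = sorted(ref_ids)
    seqs = {sid: [] for sid in ordered_ids}
    for locus in present:
        block = by_locus[locus]
        rec_by_id = {r.id: r for r in block.records}
        for sid in ordered_ids:
            seqs[sid].append(rec_by_id[sid].seq)
    records = [SequenceRecord(sid, "".join(parts))
               for sid, parts in seqs.items()]
    return AlignmentBlock(records, "MLSA")


def mlsa_species_screen(identity: float) -> MlsaScreenResult:
    """Classify an MLSA identity value against the species screen bounds."""
    if not 0 <= identity <= 100:
        raise ValueError("identity must be a percentage in [0, 100]")
    if identity > MLSA_SAME_SPECIES_MIN:
        verdict = "same-species"
    elif identity < MLSA_DIFFERENT_SPECIES_MAX:
        verdict = "different-species"
    else:
        verdict = "grey-zone"
    return MlsaScreenResult(verdict=verdict, identity=identity)


def genus_boundary_screen(identity_matrix: LabeledMatrix,
                          group_a: set[str], group_b: set[str]) -> dict:
    """Assess whether two strain groups fall on opposite sides of the
    proposed 16S genus boundary (94.8% +/- 0.25).

    Returns the min/max/mean inter-group identity and a verdict:
    'separate-genera-supported' when every inter-group identity lies below
    the boundary minus its tolerance, 'within-band' when any value falls
    inside the tolerance band, else 'same-genus-supported'.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    idx = identity_matrix.index
    vals = [identity_matrix.values[idx[a], idx[b]]
            for a in sorted(group_a) for b in sorted(group_b)]
    vals = np.asarray(vals)
    lo = GENUS_BOUNDARY - GENUS_BOUNDARY_TOLERANCE
    hi = GENUS_BOUNDARY + GENUS_BOUNDARY_TOLERANCE
    if np.max(vals) < lo:
        verdict = "separate-genera-supported"
    elif np.any((vals >= lo) & (vals <= hi)):
        verdict = "within-band"
    else:
        verdict = "same-genus-supported"
    return {
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
        "mean": float(np.mean(vals)),
        "verdict": verdict,
    }
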