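"""Type-radius species affiliation and threshold-linkage clustering.

The delineation procedure has three steps:

1. **Type-radius affiliation** — every strain within a similarity radius of
   a described type strain (e.g. 70% dDDH, 96% ANI) is attributed to that
   species; strains inside two or more radii are recorded as ambiguities.
2. **De-novo clustering** — strains affiliated to no described type are
   clustered by threshold linkage: strains are "linked" when their pairwise
   distance is <= T, and two clusters merge when the fraction of linked
   inter-cluster pairs is at least the linkage fraction F (F = 0 is single
   linkage, F = 1 complete linkage; F = 0.5 is the recommended default).
3. **Ambiguity scan** — one putative type strain (PT) is chosen per novel
   cluster and the affiliation scan is repeated over described + putative
   types; strains falling into >= 2 radii are counted as ambiguous.

Subspecies are delineated by re-running the threshold-linkage clustering
within each species cluster at a tighter cutoff (79 on the dDDH scale).

The merge order of the fraction-linkage procedure is made fully
deterministic: among admissible merges the pair with maximal link fraction
wins, ties broken by minimal mean inter-cluster distance, then by the
lexicographically smallest label pair, so identical inputs give bit-
identical partitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_distance import similarity_to_distance
from .io_formats import LabeledMatrix, StrainRecord

__all__ = [
    "ClusteringParams",
    "RadiusSpec",
    "SpeciesPartition",
    "SubspeciesPartition",
    "type_radius_affiliate",
    "fraction_linkage_cluster",
    "delineate_species",
    "delineate_subspecies",
    "threshold_sweep",
]

_EPS = 1e-12


@dataclass
class ClusteringParams:
    """Threshold T (on the distance scale) and linkage fraction F.

    Use :meth:`from_similarity` to state the threshold on the scale it is
    usually published on (dDDH %, ANI %, or a TETRA correlation).
    """

    T: float
    F: float = 0.5
    scale: str = "distance"

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("distance threshold T must be >= 0")
        if not 0 <= self.F <= 1:
            raise ValueError("linkage fraction F must lie in [0, 1]")

    @classmethod
    def from_similarity(cls, threshold: float, kind: str,
                        F: float = 0.5) -> "ClusteringParams":
        if kind == "TETRA":
            return cls(T=1.0 - threshold, F=F, scale=kind)
        return cls(T=similarity_to_distance(threshold), F=F, scale=kind)


@dataclass
class RadiusSpec:
    """A species radius around a type strain, stated as a similarity
    threshold on the matrix's own scale, with optional CI variants."""

    center: str
    threshold: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        for v in (self.lower, self.upper):
            if v is None:
                continue
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.threshold <= self.upper):
                raise ValueError("radius CIs must bracket the nominal threshold")


@dataclass
class SpeciesPartition:
    """Result of the full species delineation."""

    clusters: list[set[str]]
    affiliation: dict[str, set[str]]       # strain -> type ids whose radius holds it
    novel: list[bool]                      # per cluster: no described type inside
    putative_types: dict[int, str]         # novel cluster index -> PT strain
    ambiguities: list[tuple[str, tuple[str, ...]]]

    def cluster_of(self, strain: str) -> int:
        for i, c in enumerate(self.clusters):
            if strain in c:
                return i
        raise KeyError(strain)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_novel(self) -> int:
        return sum(self.novel)

    @property
    def n_ambiguous_strains(self) -> int:
        return len({s for s, _ in self.ambiguities})

    def labels_dict(self) -> dict[str, int]:
        return {s: i for i, c in enumerate(self.clusters) for s in c}

    def validate(self, strains: Sequence[str]) -> "SpeciesPartition":
        seen: set[str] = set()
        for c in self.clusters:
            if c & seen:
                raise ValueError("clusters overlap")
            seen |= c
        if seen != set(strains):
            raise ValueError("clusters do not cover the strain set")
        return self


@dataclass
class SubspeciesPartition:
    """Per-species sub-clusters at the subspecies cutoff.

    Singleton sub-clusters are recorded but excluded from
    ``nontrivial_count`` (a lone strain is a trivial subspecies).
    """

    by_species: dict[int, list[set[str]]]

    @property
    def nontrivial_count(self) -> int:
        return sum(1 for subs in self.by_species.values()
                   for s in subs if len(s) >= 2)

    def all_subclusters(self) -> list[set[str]]:
        return [s for subs in self.by_species.values() for s in subs]


# ---------------------------------------------------------------------------
# Step 1: type-radius affiliation
# ---------------------------------------------------------------------------

def type_radius_affiliate(matrix: LabeledMatrix, types: Sequence[RadiusSpec],
                          which: str = "nominal"
                          ) -> tuple[dict[str, set[str]],
                                     list[tuple[str, tuple[str, ...]]]]:
    """Affiliate every strain to the type strains whose radius contains it.

    A strain s is inside the radius of type t when similarity(s, t) >=
    threshold. Returns the affiliation map and the ambiguity list (strains
    inside >= 2 radii, with the conflicting type ids). ``which`` selects the
    nominal threshold or its 'lower'/'upper' CI variant.
    """
    if matrix.kind == "distance":
        raise ValueError("affiliation needs a similarity-kind matrix")
    idx = matrix.index
    for spec in types:
        if spec.center not in idx:
            raise KeyError(f"type strain {spec.center!r} not in matrix")
    affiliation: dict[str, set[str]] = {}
    for s in matrix.labels:
        hits = set()
        for spec in types:
            thr = {"nominal": spec.threshold,
                   "lower": spec.lower if spec.lower is not None else spec.threshold,
                   "upper": spec.upper if spec.upper is not None else spec.threshold,
                   }[which]
            if matrix.values[idx[s], idx[spec.center]] >= thr - _EPS:
                hits.add(spec.center)
        affiliation[s] = hits
    ambiguities = [(s, tuple(sorted(h)))
                   for s, h in sorted(affiliation.items()) if len(h) >= 2]
    return affiliation, ambiguities


# ---------------------------------------------------------------------------
# Step 2: threshold-linkage clustering with linkage fraction F
# ---------------------------------------------------------------------------

def fraction_linkage_cluster(dist: LabeledMatrix,
                             params: ClusteringParams) -> list[set[str]]:
    """Agglomerative threshold-linkage clustering.

    Pairs with distance <= T are links. Starting from singletons, a merge of
    clusters A and B is admissible when the inter-cluster link fraction
    f(A,B) = links(A,B)/(|A||B|) satisfies f >= F and f > 0 (so F = 0
    reduces to single linkage: at least one link suffices). The admissible
    merge with maximal f is performed, ties broken by minimal mean
    inter-cluster distance, then by smallest lexicographic label pair;
    clustering stops when no admissible merge remains.
    """
    if dist.kind != "distance":
        raise ValueError("fraction_linkage_cluster needs a distance matrix")
    if np.nanmax(np.abs(dist.values - dist.values.T)) > 1e-9:
        raise ValueError("distance matrix must be symmetric")
    labels = dist.labels
    d = dist.values
    link = d <= params.T + _EPS
    clusters: list[list[int]] = [[i] for i in range(len(labels))]

    def stats(a: list[int], b: list[int]) -> tuple[float, float]:
        sub = link[np.ix_(a, b)]
        f = float(sub.mean())
        md = float(d[np.ix_(a, b)].mean())
        return f, md

    while True:
        best = None
        for ia, ib in itertools.combinations(range(len(clusters)), 2):
            f, md = stats(clusters[ia], clusters[ib])
            if f <= 0 or f + _EPS < params.F:
                continue
            pair = tuple(sorted((min(labels[i] for i in clusters[ia]),
                                 min(labels[i] for i in clusters[ib]))))
            key = (-f, md, pair)
            if best is None or key < best[0]:
                best = (key, ia, ib)
        if best is None:
            break
        _, ia, ib = best
        clusters[ia] = clusters[ia] + clusters[ib]
        del clusters[ib]
    return [set(labels[i] for i in c) for c in clusters]


# ---------------------------------------------------------------------------
# Steps 1-3 combined
# ---------------------------------------------------------------------------

def _pt_candidates(matrix: LabeledMatrix, cluster: set[str],
                   all_strains: set[str], threshold: float) -> list[str]:
    """Members whose radius captures the whole cluster and nothing else."""
    idx = matrix.index
    good = []
    for s in sorted(cluster):
        inside = {t for t in all_strains
                  if matrix.values[idx[t], idx[s]] >= threshold - _EPS}
        if inside == cluster:
            good.append(s)
    return good


def _medoid(matrix: LabeledMatrix, cluster: set[str]) -> str:
    """Strain with maximal within-cluster minimum similarity, lowest label
    on ties."""
    idx = matrix.index
    best, best_key = None, None
    for s in sorted(cluster):
        others = [matrix.values[idx[s], idx[o]] for o in cluster if o != s]
        key = min(others) if others else matrix.scale
        if best_key is None or key > best_key + _EPS:
            best, best_key = s, key
    return best


def delineate_species(matrix: LabeledMatrix, metadata: Sequence[StrainRecord],
                      params: ClusteringParams,
                      radius_threshold: float | None = None,
                      ci: tuple[float, float] | None = None,
                      which: str = "nominal") -> SpeciesPartition:
    """Full species delineation on a similarity matrix.

    ``radius_threshold`` (on the matrix scale) defaults to the similarity
    equivalent of params.T. Described type strains are taken from the
    metadata; strains unaffiliated to any described type are clustered de
    novo with ``fraction_linkage_cluster``; one putative type (PT) is chosen
    per novel cluster and a final affiliation scan over all (described +
    putative) types yields the reported ambiguities.
    """
    strains = list(matrix.labels)
    meta = {m.id: m for m in metadata}
    missing = [s for s in strains if s not in meta]
    if missing:
        raise ValueError(f"strains missing from metadata: {missing}")
    described = [m.id for m in metadata if m.is_type and m.id in set(strains)]
    if radius_threshold is None:
        if matrix.kind == "TETRA":
            radius_threshold = 1.0 - params.T
        else:
            radius_threshold = 100.0 * (1.0 - params.T)
    if not described and not strains:
        raise ValueError("no type strains and no strains to cluster")

    lo, hi = (ci if ci is not None else (None, None))
    specs = [RadiusSpec(t, radius_threshold, lo, hi) for t in described]

    # step 1: affiliation to described types
    affiliation, _ = type_radius_affiliate(matrix, specs, which=which) \
        if specs else ({s: set() for s in strains}, [])
    unaffiliated = [s for s in strains if not affiliation[s]]

    # step 2: de-novo clustering of the unaffiliated strains
    novel_clusters: list[set[str]] = []
    if unaffiliated:
        sub = matrix.subset(unaffiliated).to_distance()
        novel_clusters = fraction_linkage_cluster(sub, params)

    # assemble clusters around described types; ambiguous strains go to the
    # most similar of their conflicting types
    idx = matrix.index
    type_clusters: dict[str, set[str]] = {t: {t} for t in described}
    for s in strains:
        hits = affiliation[s]
        if not hits or s in described:
            continue
        if len(hits) == 1:
            type_clusters[next(iter(hits))].add(s)
        else:
            best = max(sorted(hits),
                       key=lambda t: matrix.values[idx[s], idx[t]])
            type_clusters[best].add(s)

    clusters: list[set[str]] = [type_clusters[t] for t in described]
    novel_flags = [False] * len(described)
    putative: dict[int, str] = {}
    all_strains = set(strains)
    for c in novel_clusters:
        cands = _pt_candidates(matrix, c, all_strains, radius_threshold)
        pt = cands[0] if len(cands) == 1 else (
            _medoid(matrix.subset(sorted(c)), c) if not cands else
            _medoid(matrix.subset(cands), set(cands)))
        putative[len(clusters)] = pt
        clusters.append(set(c))
        novel_flags.append(True)

    # step 3: ambiguity scan over described + putative types
    pt_specs = specs + [RadiusSpec(pt, radius_threshold, lo, hi)
                        for pt in putative.values()]
    final_affiliation, ambiguities = type_radius_affiliate(
        matrix, pt_specs, which=which) if pt_specs else ({}, [])

    part = SpeciesPartition(
        clusters=clusters,
        affiliation=final_affiliation,
        novel=novel_flags,
        putative_types=putative,
        ambiguities=ambiguities,
    )
    return part.validate(strains)


def delineate_subspecies(matrix: LabeledMatrix, species: SpeciesPartition,
                         cutoff: float = 79.0, F: float = 0.5
                         ) -> SubspeciesPartition:
    """Subspecies delineation within each multi-member species cluster.

    ``cutoff`` is a similarity on the matrix's own scale (79 on the dDDH
    scale by default); within each cluster the threshold-linkage clustering
    is re-run at the corresponding distance.
    """
    idx = set(matrix.labels)
    by_species: dict[int, list[set[str]]] = {}
    params = ClusteringParams.from_similarity(cutoff, matrix.kind, F=F)
    for ci, cluster in enumerate(species.clusters):
        missing = cluster - idx
        if missing:
            raise ValueError(f"strains missing from matrix: {sorted(missing)}")
        if len(cluster) == 1:
            by_species[ci] = [set(cluster)]
            continue
        sub = matrix.subset(sorted(cluster)).to_distance()
        by_species[ci] = fraction_linkage_cluster(sub, params)
    return SubspeciesPartition(by_species)


def threshold_sweep(matrix: LabeledMatrix, metadata: Sequence[StrainRecord],
                    thresholds: Sequence[float], F: float = 0.5,
                    reference: SpeciesPartition | None = None) -> list[dict]:
    """Run the delineation at several radius thresholds and tabulate
    cluster counts, ambiguity counts and (optionally) agreement with a
    reference partition."""
    if not thresholds:
        raise ValueError("at least one threshold required")
    from .pipeline import compare_partitions  # late import to avoid cycle
    rows = []
    for thr in thresholds:
        params = ClusteringParams.from_similarity(thr, matrix.kind, F=F)
        part = delineate_species(matrix, metadata, params,
                                 radius_threshold=thr)
        row = {
            "threshold": thr,
            "n_clusters": part.n_clusters,
            "n_novel": part.n_novel,
            "n_ambiguous_strains": part.n_ambiguous_strains,
        }
        if reference is not None:
            cmp = compare_partitions(part, reference)
            row["exact_match"] = cmp["exact_match"]
            row["adjusted_rand"] = cmp["adjusted_rand"]
        rows.append(row)
    return rows
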