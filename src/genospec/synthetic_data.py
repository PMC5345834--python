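"""Synthetic genomes and marker-gene alignments with a planted taxonomy.

The generator plants a three-level hierarchy (species > subspecies > strain)
and evolves sequences down it under a Kimura two-parameter substitution
process, so that pairwise divergences land in controlled bands:

* within-subspecies pairs  ~ ``band_within_subspecies``   (default 0.005 subst/site)
* within-species pairs     ~ ``band_within_species``      (default 0.03)
* between-species pairs    ~ ``band_between_species``     (default 0.10, plus the
  within-species contribution)
* a genus-level band       ~ ``band_between_genus``       (default 0.25) is available
  for outgroup material.

The defaults are chosen so that fragment ANI of within-species pairs lands
above the 96% species boundary and between-species pairs land below 94%,
straddling the conventional thresholds. No indels are simulated by default
(identity statistics downstream treat gaps as differences, and an indel-free
chromosome keeps the ANI expectation analytic); genomes are emitted as
multiple contigs by cutting the chromosome at random breakpoints.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _seqcodes as sc
from .io_formats import SequenceRecord, StrainRecord

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "Genome",
    "LOCUS_LENGTHS",
    "LOCUS_RATE_MULTIPLIERS",
    "DEFAULT_REGIONS",
    "mutate_sequence",
    "random_genome",
    "simulate_species_complex",
    "simulate_marker_alignments",
]

#: Default aligned lengths (bp) for the marker loci: the 16S rRNA gene and
#: the eight housekeeping genes used for MLSA.
LOCUS_LENGTHS = {
    "16S": 1360,
    "atpD": 1380,
    "clpA": 2299,
    "dnaJ": 1162,
    "gyrB": 2457,
    "rpoD": 1960,
    "rpoH": 897,
    "rpoS": 1156,
    "secF": 972,
}

#: Per-locus substitution-rate multipliers relative to the genomic band.
#: 16S evolves far slower than the housekeeping genes (observed mean 16S
#: distance is roughly 0.15x of the MLSA mean in this genus).
LOCUS_RATE_MULTIPLIERS = {
    "16S": 0.15,
    "atpD": 0.6,
    "clpA": 0.9,
    "dnaJ": 1.0,
    "gyrB": 1.3,
    "rpoD": 0.6,
    "rpoH": 1.2,
    "rpoS": 1.3,
    "secF": 1.3,
}

#: Isolation regions used for strain metadata (soda-lake areas plus an
#: engineered source), cycled over species as "home" regions.
DEFAULT_REGIONS = (
    "Kulunda Steppe",
    "Kenya",
    "Wadi Natrun",
    "Mongolia",
    "Buriatia",
    "California",
    "Transbaikal",
    "bioreactor",
)


@dataclass
class SimulationConfig:
    """Parameters of the planted species complex.

    ``cluster_sizes`` gives the number of strains per species (1..12 each,
    mirroring realistically small genomic-species groups).
    ``subspecies_per_cluster`` optionally fixes the number of planted
    subspecies per species; by default clusters with >=4 strains receive two
    subspecies and smaller clusters one.
    """

    cluster_sizes: Sequence[int] = (4, 3, 2, 1)
    genome_length: int = 200_000
    n_contigs: int = 5
    gc_target: float = 0.62
    band_within_subspecies: float = 0.005
    band_within_species: float = 0.03
    band_between_species: float = 0.10
    band_between_genus: float = 0.25
    ti_tv_ratio: float = 2.0
    seed: int = 0
    subspecies_per_cluster: Sequence[int] | None = None
    n_described: int | None = None  # species carrying a described type strain
    migrant_fraction: float = 0.2   # strains isolated away from the home region
    allow_large_clusters: bool = False

    @property
    def n_species(self) -> int:
        return len(self.cluster_sizes)

    def validate(self) -> "SimulationConfig":
        if not self.cluster_sizes:
            raise ValueError("cluster_sizes must be non-empty")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("every cluster needs at least one strain")
        if not self.allow_large_clusters and any(s > 12 for s in self.cluster_sizes):
            raise ValueError("cluster sizes above 12 require allow_large_clusters")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be at least 1 kb")
        bands = (self.band_within_subspecies, self.band_within_species,
                 self.band_between_species, self.band_between_genus)
        if not all(b1 < b2 for b1, b2 in zip(bands, bands[1:])):
            raise ValueError("divergence bands must be strictly increasing")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be a fraction in (0,1)")
        return self


@dataclass
class Genome:
    """A strain's genome as a list of contigs."""

    id: str
    contigs: list[SequenceRecord]

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def sequence(self) -> str:
        return "".join(c.seq for c in self.contigs)


@dataclass
class PlantedTruth:
    """Ground-truth membership and divergence plan emitted by the simulator."""

    species_of: dict[str, int]
    subspecies_of: dict[str, int]
    type_strains: dict[int, str]          # described species index -> type id
    divergence_plan: dict[tuple[str, str], float]
    bands: dict[str, float]
    seed: int

    def species_partition(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for strain, sp in self.species_of.items():
            out.setdefault(sp, set()).add(strain)
        return [out[k] for k in sorted(out)]

    def subspecies_partition(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for strain, ss in self.subspecies_of.items():
            out.setdefault(ss, set()).add(strain)
        return [out[k] for k in sorted(out)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species_of": self.species_of,
            "subspecies_of": self.subspecies_of,
            "type_strains": {str(k): v for k, v in self.type_strains.items()},
            "divergence_plan": {f"{a}|{b}": v
                                for (a, b), v in self.divergence_plan.items()},
            "bands": self.bands,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            species_of=d["species_of"],
            subspecies_of=d["subspecies_of"],
            type_strains={int(k): v for k, v in d["type_strains"].items()},
            divergence_plan={tuple(k.split("|")): v
                             for k, v in d["divergence_plan"].items()},
            bands=d["bands"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# Elementary evolution steps
# ---------------------------------------------------------------------------

def random_genome(length: int, gc: float, rng: np.random.Generator,
                  signature_concentration: float = 1.0) -> np.ndarray:
    """Random chromosome (code array) with an oligonucleotide signature.

    The sequence is drawn from an order-3 Markov chain whose per-context
    transition probabilities are Dirichlet-sampled around the target base
    composition. This gives every simulated genome genuine fourth-order
    compositional structure — the signal tetranucleotide z-scores measure.
    A homogeneous i.i.d. sequence (``signature_concentration <= 0``) carries
    no such signal, and signature correlations between related genomes would
    be meaninglessly noisy. Lower concentrations mean stronger, more
    genome-specific word-usage bias; the realised G+C lands near ``gc`` but
    is not exact.
    """
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if signature_concentration <= 0:
        return rng.choice(4, size=length, p=base).astype(np.uint8)
    tables = rng.dirichlet(signature_concentration * 4 * base, size=64)
    cum = np.cumsum(tables, axis=1).tolist()
    u = rng.random(length).tolist()
    first = rng.choice(4, size=3, p=base).tolist()
    seq = list(first)
    ctx = first[0] * 16 + first[1] * 4 + first[2]
    for i in range(3, length):
        c = cum[ctx]
        x = u[i]
        b = 0 if x < c[0] else 1 if x < c[1] else 2 if x < c[2] else 3
        seq.append(b)
        ctx = (ctx % 16) * 4 + b
    return np.array(seq[:length], dtype=np.uint8)


def _mutate_codes(codes: np.ndarray, rate: float, ti_tv_ratio: float,
                  rng: np.random.Generator) -> np.ndarray:
    """K2P point substitution on a code array: each site changes with
    probability ``rate``; changed sites are transitions with probability
    R/(R+1) and each transversion with probability 1/(2(R+1))."""
    if not 0 <= rate < 0.75:
        raise ValueError(f"substitution rate {rate} outside [0, 0.75)")
    out = codes.copy()
    if rate == 0:
        return out
    hit = np.nonzero(rng.random(codes.size) < rate)[0]
    if hit.size == 0:
        return out
    r = ti_tv_ratio
    u = rng.random(hit.size)
    old = out[hit]
    new = old.copy()
    ti = u < r / (r + 1)
    # transition: A<->G, C<->T == XOR with 2 in this code table
    new[ti] = old[ti] ^ 2
    tv = ~ti
    # transversion: flip bit 0, and half the time also bit 1
    tv1 = tv & (u < (2 * r + 1) / (2 * (r + 1)))
    tv2 = tv & ~tv1
    new[tv1] = old[tv1] ^ 1
    new[tv2] = old[tv2] ^ 3
    out[hit] = new
    return out


def mutate_sequence(seq: str, rate: float, ti_tv_ratio: float = 2.0,
                    seed: int | np.random.Generator = 0) -> str:
    """Apply K2P point substitutions to a nucleotide string.

    The expected fraction of changed sites equals ``rate`` and the expected
    transition:transversion count ratio equals ``ti_tv_ratio``. Length is
    preserved; no indels are introduced.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    codes = sc.encode(seq)
    if np.any(codes >= 4):
        raise ValueError("mutate_sequence expects an ungapped A/C/G/T sequence")
    return sc.decode(_mutate_codes(codes, rate, ti_tv_ratio, rng))


# ---------------------------------------------------------------------------
# The species complex
# ---------------------------------------------------------------------------

def _cut_contigs(codes: np.ndarray, n_contigs: int, strain: str,
                 rng: np.random.Generator) -> list[SequenceRecord]:
    n = min(n_contigs, codes.size)
    if n <= 1:
        return [SequenceRecord(f"{strain}_c1", sc.decode(codes))]
    cuts = np.sort(rng.choice(np.arange(1, codes.size), size=n - 1, replace=False))
    pieces = np.split(codes, cuts)
    return [SequenceRecord(f"{strain}_c{i + 1}", sc.decode(p))
            for i, p in enumerate(pieces)]


def simulate_species_complex(config: SimulationConfig
                             ) -> tuple[list[Genome], PlantedTruth,
                                        list[StrainRecord]]:
    """Simulate genomes for a planted species/subspecies hierarchy.

    One ancestral chromosome per species is evolved from a common root so
    that between-species *pairwise* divergence is ~``band_between_species``;
    strains then diverge from their (sub)species ancestors so that pairwise
    within-species divergence is ~``band_within_species`` and
    within-subspecies divergence ~``band_within_subspecies``. Each edge
    therefore carries half the corresponding band. Fully reproducible for a
    fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    root = random_genome(config.genome_length, config.gc_target, rng)

    sizes = list(config.cluster_sizes)
    n_sp = len(sizes)
    if config.subspecies_per_cluster is not None:
        n_sub = list(config.subspecies_per_cluster)
        if len(n_sub) != n_sp:
            raise ValueError("subspecies_per_cluster must match cluster_sizes")
    else:
        n_sub = [2 if s >= 4 else 1 for s in sizes]
    n_described = (math.ceil(n_sp / 2) if config.n_described is None
                   else min(config.n_described, n_sp))

    half = lambda b: b / 2.0
    genomes: list[Genome] = []
    species_of: dict[str, int] = {}
    subspecies_of: dict[str, int] = {}
    type_strains: dict[int, str] = {}
    metadata: list[StrainRecord] = []
    sub_counter = 0

    for si, size in enumerate(sizes, start=1):
        anc = _mutate_codes(root, half(config.band_between_species),
                            config.ti_tv_ratio, rng)
        # A species without planted subspecies structure has every strain in
        # its own (trivial) subspecies: strains then sit at the full
        # within-species band from one another, and the subspecies cut
        # correctly recovers singletons.
        raw = n_sub[si - 1]
        k_sub = size if raw <= 1 else min(raw, size)
        sub_ancs = []
        for _ in range(k_sub):
            sub_ancs.append(_mutate_codes(
                anc,
                half(config.band_within_species - config.band_within_subspecies),
                config.ti_tv_ratio, rng))
        home = DEFAULT_REGIONS[(si - 1) % len(DEFAULT_REGIONS)]
        for k in range(size):
            strain = f"T{si:02d}-{k + 1:02d}"
            sub_idx = k % k_sub
            codes = _mutate_codes(sub_ancs[sub_idx],
                                  half(config.band_within_subspecies),
                                  config.ti_tv_ratio, rng)
            genomes.append(Genome(strain, _cut_contigs(
                codes, config.n_contigs, strain, rng)))
            species_of[strain] = si
            subspecies_of[strain] = sub_counter + sub_idx + 1
            described = si <= n_described and k == 0
            if described:
                type_strains[si] = strain
            region = home
            if size > 1 and rng.random() < config.migrant_fraction:
                others = [r for r in DEFAULT_REGIONS if r != home]
                region = others[rng.integers(len(others))]
            metadata.append(StrainRecord(
                id=strain, is_type=described,
                species_name=f"sp{si}" if described else "",
                region=region))
        sub_counter += k_sub

    bands = {
        "within_subspecies": config.band_within_subspecies,
        "within_species": config.band_within_species,
        "between_species": config.band_between_species,
        "between_genus": config.band_between_genus,
        "ti_tv_ratio": config.ti_tv_ratio,
    }
    plan: dict[tuple[str, str], float] = {}
    strains = [g.id for g in genomes]
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            if species_of[a] != species_of[b]:
                d = config.band_between_species
            elif subspecies_of[a] != subspecies_of[b]:
                d = config.band_within_species
            else:
                d = config.band_within_subspecies
            plan[(a, b)] = d

    truth = PlantedTruth(species_of, subspecies_of, type_strains, plan,
                         bands, config.seed)
    return genomes, truth, metadata


def simulate_marker_alignments(truth: PlantedTruth,
                               loci: Sequence[tuple[str, int]] | None = None,
                               seed: int = 0,
                               rate_multipliers: dict[str, float] | None = None,
                               gc_target: float = 0.62,
                               ti_tv_ratio: float | None = None,
                               ) -> list["AlignmentBlock"]:
    """Evolve gap-free aligned marker loci on the planted hierarchy.

    Each locus gets its own root sequence and a per-locus rate multiplier
    applied to the genomic divergence bands; the 16S multiplier is far below
    the housekeeping multipliers, so 16S distances come out much smaller
    than MLSA distances on the same strains.
    """
    from .io_formats import AlignmentBlock  # local import avoids a cycle

    if loci is None:
        loci = list(LOCUS_LENGTHS.items())
    if not loci:
        raise ValueError("loci list must be non-empty")
    mult = dict(LOCUS_RATE_MULTIPLIERS)
    if rate_multipliers:
        mult.update(rate_multipliers)
    titv = truth.bands.get("ti_tv_ratio", 2.0) if ti_tv_ratio is None else ti_tv_ratio

    strains = sorted(truth.species_of)
    species = sorted(set(truth.species_of.values()))
    subs_by_species: dict[int, list[int]] = {}
    for s in strains:
        subs_by_species.setdefault(truth.species_of[s], [])
        ss = truth.subspecies_of[s]
        if ss not in subs_by_species[truth.species_of[s]]:
            subs_by_species[truth.species_of[s]].append(ss)

    b_sub = truth.bands["within_subspecies"]
    b_sp = truth.bands["within_species"]
    b_between = truth.bands["between_species"]

    blocks: list[AlignmentBlock] = []
    for locus, length in loci:
        if locus not in LOCUS_LENGTHS:
            raise ValueError(f"unknown locus {locus!r}; known: "
                             f"{sorted(LOCUS_LENGTHS)}")
        if length <= 0:
            raise ValueError(f"locus {locus}: length must be positive")
        m = mult.get(locus, 1.0)
        rng = np.random.default_rng([seed, zlib.crc32(locus.encode()) % (2**31)])
        root = random_genome(length, gc_target, rng)
        recs = []
        anc_cache: dict[int, np.ndarray] = {}
        sub_cache: dict[int, np.ndarray] = {}
        for sp in species:
            anc_cache[sp] = _mutate_codes(root, m * b_between / 2, titv, rng)
            for ss in subs_by_species[sp]:
                sub_cache[ss] = _mutate_codes(
                    anc_cache[sp], m * (b_sp - b_sub) / 2, titv, rng)
        for s in strains:
            codes = _mutate_codes(sub_cache[truth.subspecies_of[s]],
                                  m * b_sub / 2, titv, rng)
            recs.append(SequenceRecord(s, sc.decode(codes)))
        blocks.append(AlignmentBlock(recs, locus))
    return blocks
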