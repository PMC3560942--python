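"""Synthetic inbred-strain crosses with incompletely penetrant binary phenotypes
and pooled low-coverage sequencing.

This module stands in for the mouse colony and the sequencer.  It simulates

* two fully homozygous parental strains (``A`` and ``B``) that differ at a
  configurable set of informative markers,
* meiosis with recombination under the Haldane model (crossover counts are
  Poisson with mean ``length_cM / 100`` per chromosome, positions uniform in
  genetic distance, no interference),
* F1, F2 (F1 intercross) and F1 x parent backcross cohorts,
* a binary phenotype whose penetrance depends on the genotype at one
  designated trait locus and on the scoring age, plus an optional
  genotype-independent background rate, and
* low-coverage pooled sequencing as Poisson-depth allele draws with a base
  error rate at known strain-distinguishing variant sites.

Genotypes are coded 0 (A/A), 1 (A/B), 2 (B/B) with -9 for missing; strain A is
the first-listed parent.  At variant sites the reference allele is the
strain-B allele and the alternate allele is the strain-A allele (the reference
genome is strain-B-like).

Randomness flows from a single master seed through named substreams
(:func:`substream`) so that every stage is independently reproducible.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import stats

# ---------------------------------------------------------------------------
# Codes and seeding
# ---------------------------------------------------------------------------

GENO_MISSING = -9

AFFECTED = 1
UNAFFECTED = 0
UNSCORED = -9

PHENOTYPE_LABELS = {AFFECTED: "affected", UNAFFECTED: "unaffected", UNSCORED: "unscored"}
PHENOTYPE_CODES = {v: k for k, v in PHENOTYPE_LABELS.items()}


def substream(master_seed: int, name: str) -> Generator:
    """Return a named, reproducible random substream of a master seed.

    The substream is keyed by a CRC32 of ``name`` so that stages ("cross",
    "phenotype", "pool_a", ...) draw from independent streams that are stable
    across runs and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return default_rng(SeedSequence(master_seed, spawn_key=(key,)))


def _as_rng(rng: Generator | int | None) -> Generator:
    if isinstance(rng, Generator):
        return rng
    return default_rng(rng)


# ---------------------------------------------------------------------------
# Genetic map and markers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.length_cM <= 0:
            raise ValueError(f"chromosome {self.name}: lengths must be positive")


class GeneticMap:
    """Physical (bp) and genetic (cM) coordinates for a set of chromosomes.

    ``anchors`` maps chromosome name to a list of (bp, cM) anchor points,
    strictly increasing in both coordinates; bp<->cM conversion is
    piecewise-linear interpolation between anchors.  By default each
    chromosome gets the two trivial anchors (0, 0) and
    (length_bp, length_cM), i.e. a uniform recombination rate.
    """

    def __init__(
        self,
        chromosomes: Sequence[Chromosome],
        anchors: dict[str, Sequence[tuple[int, float]]] | None = None,
    ) -> None:
        if not chromosomes:
            raise ValueError("a genetic map needs at least one chromosome")
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.chromosomes: list[Chromosome] = list(chromosomes)
        self._index = {c.name: c for c in self.chromosomes}
        self._anchors: dict[str, np.ndarray] = {}
        anchors = anchors or {}
        for c in self.chromosomes:
            pts = anchors.get(c.name, [(0, 0.0), (c.length_bp, c.length_cM)])
            arr = np.asarray(pts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"chromosome {c.name}: need >=2 (bp, cM) anchor points")
            if not (np.all(np.diff(arr[:, 0]) > 0) and np.all(np.diff(arr[:, 1]) > 0)):
                raise ValueError(f"chromosome {c.name}: anchors must strictly increase in bp and cM")
            if arr[0, 0] > 0 or arr[-1, 0] < c.length_bp:
                raise ValueError(f"chromosome {c.name}: anchors must span [0, length_bp]")
            self._anchors[c.name] = arr

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> Chromosome:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} is not in the map") from None

    def chrom_rank(self, name: str) -> int:
        return self.names.index(name)

    def lengths_bp(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    def bp_to_cm(self, chrom: str, pos_bp: float | np.ndarray) -> float | np.ndarray:
        c = self.chrom(chrom)
        pos = np.asarray(pos_bp, dtype=float)
        if np.any(pos < 0) or np.any(pos > c.length_bp):
            raise ValueError(f"position outside chromosome {chrom} (0..{c.length_bp} bp)")
        a = self._anchors[chrom]
        out = np.interp(pos, a[:, 0], a[:, 1])
        return float(out) if np.isscalar(pos_bp) or np.ndim(pos_bp) == 0 else out

    def cm_to_bp(self, chrom: str, pos_cm: float | np.ndarray) -> float | np.ndarray:
        c = self.chrom(chrom)
        pos = np.asarray(pos_cm, dtype=float)
        if np.any(pos < 0) or np.any(pos > c.length_cM):
            raise ValueError(f"position outside chromosome {chrom} (0..{c.length_cM} cM)")
        a = self._anchors[chrom]
        out = np.interp(pos, a[:, 1], a[:, 0])
        return float(out) if np.isscalar(pos_cm) or np.ndim(pos_cm) == 0 else out


@dataclass(frozen=True)
class Marker:
    """A biallelic informative marker (SNP or microsatellite treated as biallelic)."""

    id: str
    chrom: str
    pos_bp: int
    pos_cM: float
    kind: str = "snp"  # {"snp", "microsatellite"}
    alleles: tuple[str, str] = ("A", "B")  # (strain-A allele, strain-B allele)

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.id}: pos_bp must be >= 1")
        if self.pos_cM < 0:
            raise ValueError(f"marker {self.id}: pos_cM must be >= 0")
        if self.kind not in ("snp", "microsatellite"):
            raise ValueError(f"marker {self.id}: unknown kind {self.kind!r}")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"marker {self.id}: alleles must differ for an informative marker")


def validate_markers(markers: Sequence[Marker], gmap: GeneticMap) -> None:
    """Check marker ids are unique and every marker lies within its chromosome."""
    ids = [m.id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValueError("marker ids are not unique")
    for m in markers:
        c = gmap.chrom(m.chrom)  # KeyError -> marker outside map
        if m.pos_bp > c.length_bp:
            raise ValueError(f"marker {m.id} at {m.pos_bp} bp exceeds {m.chrom} ({c.length_bp} bp)")
        if m.pos_cM > c.length_cM:
            raise ValueError(f"marker {m.id} at {m.pos_cM} cM exceeds {m.chrom} ({c.length_cM} cM)")


def _markers_by_chrom(markers: Sequence[Marker]) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Group marker indices by chromosome, preserving input order.

    Returns a list of (chrom, index_array, pos_cM_array).
    """
    groups: dict[str, list[int]] = {}
    for i, m in enumerate(markers):
        groups.setdefault(m.chrom, []).append(i)
    return [
        (chrom, np.asarray(idx, dtype=int), np.asarray([markers[i].pos_cM for i in idx], dtype=float))
        for chrom, idx in groups.items()
    ]


# ---------------------------------------------------------------------------
# Default genome: 19 mouse-like autosomes
# ---------------------------------------------------------------------------

# Approximate mouse autosome sizes (Mb) and genetic lengths (cM); the simulator
# only needs a realistic order of magnitude, not exact map positions.
_MOUSE_AUTOSOMES: list[tuple[str, int, float]] = [
    ("chr1", 197_000_000, 98.0), ("chr2", 182_000_000, 103.0), ("chr3", 160_000_000, 82.0),
    ("chr4", 156_000_000, 88.0), ("chr5", 152_000_000, 90.0), ("chr6", 150_000_000, 79.0),
    ("chr7", 152_000_000, 89.0), ("chr8", 131_000_000, 76.0), ("chr9", 124_000_000, 75.0),
    ("chr10", 130_000_000, 77.0), ("chr11", 122_000_000, 88.0), ("chr12", 121_000_000, 64.0),
    ("chr13", 120_000_000, 67.0), ("chr14", 125_000_000, 66.0), ("chr15", 103_000_000, 59.0),
    ("chr16", 98_000_000, 57.0), ("chr17", 95_000_000, 61.0), ("chr18", 91_000_000, 58.0),
    ("chr19", 61_000_000, 56.0),
]


def default_mouse_map() -> GeneticMap:
    """A 19-autosome mouse-like genetic map with uniform recombination."""
    return GeneticMap([Chromosome(n, bp, cm) for n, bp, cm in _MOUSE_AUTOSOMES])


def default_marker_set(gmap: GeneticMap, n_markers: int = 874) -> list[Marker]:
    """Spread ``n_markers`` informative SNPs across the genome.

    Markers are allocated to chromosomes proportionally to genetic length and
    placed evenly in cM, mimicking a genotyping array designed for uniform
    genetic coverage.
    """
    cm_lengths = np.array([c.length_cM for c in gmap.chromosomes])
    alloc = np.maximum(1, np.round(n_markers * cm_lengths / cm_lengths.sum()).astype(int))
    # fix rounding so the total is exact
    while alloc.sum() > n_markers:
        alloc[int(np.argmax(alloc))] -= 1
    while alloc.sum() < n_markers:
        alloc[int(np.argmin(alloc))] += 1
    markers: list[Marker] = []
    for c, k in zip(gmap.chromosomes, alloc):
        cms = np.round(np.linspace(0.5, c.length_cM - 0.5, k), 6)
        for j, cm in enumerate(cms):
            bp = int(round(gmap.cm_to_bp(c.name, cm)))
            markers.append(
                Marker(id=f"m{c.name[3:]:>02s}_{j:04d}", chrom=c.name, pos_bp=max(1, bp),
                       pos_cM=float(cm), kind="snp", alleles=("A", "B"))
            )
    return markers


# ---------------------------------------------------------------------------
# Cross designs, individuals, cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossDesign:
    type: str  # {"F1", "F2", "BC"}
    parent_strains: tuple[str, str] = ("A", "B")
    recurrent_parent: str | None = None  # BC only
    n_offspring: int = 0

    def __post_init__(self) -> None:
        if self.type not in ("F1", "F2", "BC"):
            raise ValueError(f"unknown cross type {self.type!r}")
        if (self.type == "BC") != (self.recurrent_parent is not None):
            raise ValueError("recurrent_parent must be given iff type is BC")
        if self.recurrent_parent is not None and self.recurrent_parent not in self.parent_strains:
            raise ValueError("recurrent_parent must be one of the parent strains")


@dataclass
class Individual:
    id: str
    hap1: np.ndarray  # parental-strain origin per marker: 0 = A, 1 = B
    hap2: np.ndarray
    phenotype: int = UNSCORED
    scoring_age: str | None = None

    def genotype(self) -> np.ndarray:
        return (self.hap1 + self.hap2).astype(np.int8)


@dataclass
class Cohort:
    """A set of individuals from one cross design.

    ``hap1``/``hap2`` are (n, m) int8 arrays of parental-strain origin
    (0 = strain A, 1 = strain B).  ``genotypes_`` is only set for cohorts
    loaded from files, where phase is unknown and missing values occur.
    """

    markers: list[Marker]
    ids: list[str]
    hap1: np.ndarray | None = None
    hap2: np.ndarray | None = None
    genotypes_: np.ndarray | None = None
    phenotype: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int8))
    scoring_age: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.phenotype.size == 0:
            self.phenotype = np.full(n, UNSCORED, dtype=np.int8)
        if not self.scoring_age:
            self.scoring_age = [None] * n
        if self.hap1 is None and self.genotypes_ is None:
            raise ValueError("a cohort needs haplotypes or a genotype matrix")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def genotypes(self) -> np.ndarray:
        """Genotype codes (n, m): 0 = A/A, 1 = A/B, 2 = B/B, -9 = missing."""
        if self.genotypes_ is not None:
            return self.genotypes_
        return (self.hap1 + self.hap2).astype(np.int8)

    def marker_index(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m.id == marker_id:
                return i
        raise KeyError(f"marker {marker_id!r} not in cohort")

    def individual(self, i: int) -> Individual:
        if self.hap1 is None:
            raise ValueError("cohort has no phased haplotypes")
        return Individual(self.ids[i], self.hap1[i], self.hap2[i],
                          int(self.phenotype[i]), self.scoring_age[i])

    def subset(self, idx: np.ndarray | Sequence[int]) -> "Cohort":
        idx = np.asarray(idx, dtype=int)
        return Cohort(
            markers=self.markers,
            ids=[self.ids[i] for i in idx],
            hap1=None if self.hap1 is None else self.hap1[idx],
            hap2=None if self.hap2 is None else self.hap2[idx],
            genotypes_=None if self.genotypes_ is None else self.genotypes_[idx],
            phenotype=self.phenotype[idx].copy(),
            scoring_age=[self.scoring_age[i] for i in idx],
        )

    def affected_only(self) -> "Cohort":
        return self.subset(np.flatnonzero(self.phenotype == AFFECTED))


# ---------------------------------------------------------------------------
# Meiosis (Haldane model) and crosses
# ---------------------------------------------------------------------------


def _meiosis_origins(n: int, length_cM: float, marker_cM: np.ndarray, rng: Generator) -> np.ndarray:
    """Parental-haplotype origin (0/1) at each marker for ``n`` gametes of one
    chromosome.

    Crossover counts are Poisson(length_cM/100), positions uniform in cM, no
    interference; the origin at a marker is the starting haplotype flipped once
    per crossover to its left.
    """
    k = rng.poisson(length_cM / 100.0, size=n)
    start = rng.integers(0, 2, size=n, dtype=np.int8)
    kmax = int(k.max(initial=0))
    if kmax == 0:
        return np.repeat(start[:, None], len(marker_cM), axis=1)
    x = rng.uniform(0.0, length_cM, size=(n, kmax))
    x[np.arange(kmax)[None, :] >= k[:, None]] = np.inf  # pad unused draws
    below = (x[:, None, :] < marker_cM[None, :, None]).sum(axis=2)
    return ((start[:, None] + below) % 2).astype(np.int8)


def simulate_gametes(parent: Individual, gmap: GeneticMap, markers: Sequence[Marker],
                     rng: Generator | int | None = None) -> np.ndarray:
    """One recombinant gamete (strain-origin vector over ``markers``) of ``parent``."""
    rng = _as_rng(rng)
    validate_markers(markers, gmap)
    gamete = np.empty(len(markers), dtype=np.int8)
    for chrom, idx, cms in _markers_by_chrom(markers):
        origin = _meiosis_origins(1, gmap.chrom(chrom).length_cM, cms, rng)[0]
        gamete[idx] = np.where(origin == 0, parent.hap1[idx], parent.hap2[idx])
    return gamete


def _f1_gamete_batch(n: int, gmap: GeneticMap, markers: Sequence[Marker], rng: Generator) -> np.ndarray:
    """(n, m) strain-origin matrix of gametes from an F1 of two inbreds.

    An F1 of inbred strains carries one pure-A and one pure-B haplotype, so a
    gamete's allele at a marker equals the meiotic origin directly.
    """
    out = np.empty((n, len(markers)), dtype=np.int8)
    for chrom, idx, cms in _markers_by_chrom(markers):
        out[:, idx] = _meiosis_origins(n, gmap.chrom(chrom).length_cM, cms, rng)
    return out


def simulate_cross(design: CrossDesign, gmap: GeneticMap, markers: Sequence[Marker],
                   rng: Generator | int | None = None) -> Cohort:
    """Simulate a cohort of offspring from two fully homozygous parents.

    F1 offspring get one gamete from each inbred parent (heterozygous
    everywhere); F2 offspring get two independent F1 gametes; backcross
    offspring get one F1 gamete and one gamete from the recurrent inbred
    parent.
    """
    rng = _as_rng(rng)
    validate_markers(markers, gmap)
    n = design.n_offspring
    if n <= 0:
        raise ValueError("n_offspring must be positive")
    m = len(markers)
    if design.type == "F1":
        hap1 = np.zeros((n, m), dtype=np.int8)
        hap2 = np.ones((n, m), dtype=np.int8)
    elif design.type == "F2":
        hap1 = _f1_gamete_batch(n, gmap, markers, rng)
        hap2 = _f1_gamete_batch(n, gmap, markers, rng)
    else:  # BC
        hap1 = _f1_gamete_batch(n, gmap, markers, rng)
        code = 0 if design.recurrent_parent == design.parent_strains[0] else 1
        hap2 = np.full((n, m), code, dtype=np.int8)
    ids = [f"{design.type}_{i:05d}" for i in range(n)]
    return Cohort(markers=list(markers), ids=ids, hap1=hap1, hap2=hap2)


def simulate_unlinked_f2_genotypes(n: int, m: int, rng: Generator | int | None = None) -> np.ndarray:
    """(n, m) F2 genotype codes at mutually unlinked markers.

    At an unlinked marker each F2 genotype is the sum of two independent
    Bernoulli(1/2) gametes, giving the 1:2:1 law with no correlation between
    markers — the exact null of an affected-only scan with no trait locus.
    """
    rng = _as_rng(rng)
    a = rng.integers(0, 2, size=(n, m), dtype=np.int8)
    b = rng.integers(0, 2, size=(n, m), dtype=np.int8)
    return a + b


# ---------------------------------------------------------------------------
# Penetrance
# ---------------------------------------------------------------------------


@dataclass
class PenetranceModel:
    """Age-dependent incomplete penetrance at a single trait locus.

    ``penetrance`` maps scoring age (e.g. "P21", "P35") to (p0, p1, p2) =
    P(affected | genotype A/A, A/B, B/B at the trait locus).  An individual is
    affected with probability 1 - (1 - p_g)(1 - background_rate): the trait
    channel and a genotype-independent background channel act independently.
    """

    trait_locus: str
    penetrance: dict[str, tuple[float, float, float]]
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        for age, ps in self.penetrance.items():
            if len(ps) != 3 or any(not (0.0 <= p <= 1.0) for p in ps):
                raise ValueError(f"penetrance at {age}: need three probabilities in [0, 1]")
        if not (0.0 <= self.background_rate <= 1.0):
            raise ValueError("background_rate must lie in [0, 1]")


def apply_penetrance(cohort: Cohort, model: PenetranceModel, scoring_age: str,
                     rng: Generator | int | None = None) -> Cohort:
    """Assign affected/unaffected phenotypes to a cohort at a given scoring age."""
    rng = _as_rng(rng)
    if scoring_age not in model.penetrance:
        raise KeyError(f"scoring age {scoring_age!r} absent from penetrance model")
    ti = cohort.marker_index(model.trait_locus)
    g = cohort.genotypes()[:, ti]
    if np.any(g == GENO_MISSING):
        raise ValueError("trait locus must be genotyped in every individual")
    p_g = np.asarray(model.penetrance[scoring_age], dtype=float)[g]
    prob = 1.0 - (1.0 - p_g) * (1.0 - model.background_rate)
    affected = rng.uniform(size=len(cohort)) < prob
    out = replace(cohort)
    out.phenotype = np.where(affected, AFFECTED, UNAFFECTED).astype(np.int8)
    out.scoring_age = [scoring_age] * len(cohort)
    return out


# ---------------------------------------------------------------------------
# Variant sites and pooled sequencing
# ---------------------------------------------------------------------------


@dataclass
class VariantSite:
    """A candidate strain-distinguishing SNP.

    ``ref_allele`` is the strain-B allele (the reference genome is
    strain-B-like) and ``alt_allele`` the strain-A allele.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    status: str = "candidate"  # {"known", "imputed", "candidate"}
    in_repeat: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site {self.chrom}:{self.pos}: pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"site {self.chrom}:{self.pos}: ref and alt must differ")


@dataclass(frozen=True)
class PileupSummary:
    """Per-site pooled read counts for pools A (strain-A-like) and B, with
    caller-style site and mapping qualities."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    a_ref: int
    a_alt: int
    b_ref: int
    b_alt: int
    site_quality: float
    mapping_quality: float

    @property
    def depth_a(self) -> int:
        return self.a_ref + self.a_alt

    @property
    def depth_b(self) -> int:
        return self.b_ref + self.b_alt


@dataclass
class PoolSpec:
    """A DNA pool: either named cohort members or a whole parental strain.

    Sequencing is modelled as Poisson(``mean_depth``) reads per site; each
    read samples a uniformly chosen pool member's uniformly chosen allele and
    is miscalled to the other allele with probability ``base_error_rate``.
    """

    members: Sequence[int] | None = None
    strain: str | None = None  # "A" or "B" for a parental pool
    mean_depth: float = 2.5
    base_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if (self.members is None or len(self.members) == 0) and self.strain is None:
            raise ValueError("pool is empty: give member indices or a strain label")
        if self.strain is not None and self.strain not in ("A", "B"):
            raise ValueError("strain pool must be 'A' or 'B'")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0.0 <= self.base_error_rate < 1.0):
            raise ValueError("base_error_rate must lie in [0, 1)")


def sites_from_markers(markers: Sequence[Marker], status: str = "known") -> list[VariantSite]:
    """Variant sites co-located with markers: alt = strain-A allele, ref = strain-B."""
    return [
        VariantSite(chrom=m.chrom, pos=m.pos_bp, ref_allele=m.alleles[1],
                    alt_allele=m.alleles[0], status=status)
        for m in markers
    ]


def pool_alt_frequency(pool: PoolSpec, sites: Sequence[VariantSite],
                       cohort: Cohort | None = None) -> np.ndarray:
    """True alternate-allele (strain-A allele) frequency of the pool at each site."""
    if pool.strain is not None:
        f = 1.0 if pool.strain == "A" else 0.0
        return np.full(len(sites), f)
    if cohort is None:
        raise ValueError("a member pool needs the cohort its members come from")
    pos_index = {(m.chrom, m.pos_bp): i for i, m in enumerate(cohort.markers)}
    try:
        cols = [pos_index[(s.chrom, s.pos)] for s in sites]
    except KeyError as e:
        raise ValueError(f"site {e.args[0]} has no matching cohort marker") from None
    g = cohort.genotypes()[np.asarray(pool.members, dtype=int)][:, cols]
    if np.any(g == GENO_MISSING):
        raise ValueError("pool members must be genotyped at every site")
    # genotype code counts strain-B alleles; alt dosage is 2 - code
    return (2.0 - g.mean(axis=0)) / 2.0


def simulate_pool_counts(alt_freq: np.ndarray, mean_depth: float, base_error_rate: float,
                         rng: Generator) -> tuple[np.ndarray, np.ndarray]:
    """(ref_reads, alt_reads) per site for a pool with given alt-allele frequencies.

    Each read independently samples a pool chromosome, so the alt count at a
    site of depth d is Binomial(d, f(1-e) + (1-f)e) exactly; depths are
    Poisson(mean_depth).
    """
    alt_freq = np.asarray(alt_freq, dtype=float)
    depth = rng.poisson(mean_depth, size=alt_freq.shape)
    p_alt = alt_freq * (1.0 - base_error_rate) + (1.0 - alt_freq) * base_error_rate
    alt = rng.binomial(depth, p_alt)
    return depth - alt, alt


def simulate_pool_reads(pool: PoolSpec, sites: Sequence[VariantSite],
                        cohort: Cohort | None = None,
                        rng: Generator | int | None = None) -> pd.DataFrame:
    """Per-site read counts for one pool: columns chrom, pos, ref_reads, alt_reads."""
    rng = _as_rng(rng)
    f = pool_alt_frequency(pool, sites, cohort)
    ref, alt = simulate_pool_counts(f, pool.mean_depth, pool.base_error_rate, rng)
    return pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref_reads": ref,
        "alt_reads": alt,
    })


def _truncated_normal(mean: float, sd: float, size: int, rng: Generator) -> np.ndarray:
    a = (0.0 - mean) / sd  # truncate at 0: qualities are non-negative
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_pileups(sites: Sequence[VariantSite], pool_a: PoolSpec, pool_b: PoolSpec,
                     cohort_a: Cohort | None = None, cohort_b: Cohort | None = None,
                     rng: Generator | int | None = None,
                     qual_mean: float = 60.0, qual_sd: float = 15.0,
                     mq_mean: float = 55.0, mq_sd: float = 8.0) -> pd.DataFrame:
    """Two-pool pileup table at variant sites.

    Columns: chrom, pos, ref, alt, a_ref, a_alt, b_ref, b_alt, qual, mq.
    Site and mapping qualities are drawn from normal distributions truncated
    at 0 whose defaults sit above typical hard-filter thresholds, emulating
    well-behaved caller annotations.
    """
    rng = _as_rng(rng)
    fa = pool_alt_frequency(pool_a, sites, cohort_a)
    fb = pool_alt_frequency(pool_b, sites, cohort_b)
    a_ref, a_alt = simulate_pool_counts(fa, pool_a.mean_depth, pool_a.base_error_rate, rng)
    b_ref, b_alt = simulate_pool_counts(fb, pool_b.mean_depth, pool_b.base_error_rate, rng)
    n = len(sites)
    return pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref": [s.ref_allele for s in sites],
        "alt": [s.alt_allele for s in sites],
        "a_ref": a_ref, "a_alt": a_alt,
        "b_ref": b_ref, "b_alt": b_alt,
        "qual": np.round(_truncated_normal(qual_mean, qual_sd, n, rng), 2),
        "mq": np.round(_truncated_normal(mq_mean, mq_sd, n, rng), 2),
    })
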