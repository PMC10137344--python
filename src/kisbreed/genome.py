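"""Genome, founder-population and quantitative-trait simulation.

This module provides the forward-in-time simulation primitives that the
breeding-program layer is built on: a marker map with genetic positions, a
diploid phased population container, Mendelian inheritance with Haldane
(no-interference) recombination, quantitative-trait architectures calibrated
to unit genetic variance in the founder population, true breeding values,
total genotypic values (with optional dominance and additive-by-additive
epistasis) and phenotypes.

Conventions
-----------
* Alleles are coded 0/1; a genotype dosage is the number of copies of the
  "1" allele, so dosages live in {0, 1, 2}.
* Genetic positions are in Morgans along each chromosome.
* Recombination follows the Haldane model: the probability that an odd
  number of crossovers falls between two adjacent markers a distance ``d``
  Morgans apart is ``(1 - exp(-2 d)) / 2``, independently across disjoint
  intervals.  Gametes are simulated directly at marker resolution from those
  interval switch probabilities, which is distributionally equivalent to
  simulating Poisson-distributed crossover positions without interference.
* Sex is coded with the module constants ``MALE`` (0) and ``FEMALE`` (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    CalibrationError,
    ConfigurationError,
    DataShapeError,
)

__all__ = [
    "MALE",
    "FEMALE",
    "GenomeMap",
    "Population",
    "TraitArchitecture",
    "make_genome",
    "simulate_founders",
    "assign_trait",
    "add_nonadditive",
    "meiosis",
    "produce_offspring",
    "true_breeding_value",
    "genotypic_value",
    "phenotype",
    "concat_populations",
]

MALE = 0
FEMALE = 1


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeMap:
    """Marker map: chromosome assignment, genetic positions, founder freqs.

    Attributes
    ----------
    n_chromosomes, markers_per_chromosome : int
        Grid dimensions; all chromosomes carry the same number of markers.
    chromosome_length : float
        Length of each chromosome in Morgans.
    positions : (n_markers,) float array
        Position of each marker in Morgans *within its chromosome*,
        strictly increasing per chromosome.
    chrom : (n_markers,) int array
        0-based chromosome index per marker.
    founder_freqs : (n_markers,) float array
        Frequency of the "1" allele among founder gametes.
    """

    n_chromosomes: int
    markers_per_chromosome: int
    chromosome_length: float
    positions: np.ndarray
    chrom: np.ndarray
    founder_freqs: np.ndarray
    # Per-marker haplotype-switch probability used by the gamete sampler:
    # 0.5 at each chromosome start (independent restart), Haldane's map
    # function of the adjacent-marker distance elsewhere.
    switch_probs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        n = self.n_chromosomes * self.markers_per_chromosome
        if len(self.positions) != n or len(self.chrom) != n or len(self.founder_freqs) != n:
            raise ConfigurationError(
                f"genome arrays must have length {n} "
                f"(= n_chromosomes x markers_per_chromosome)"
            )
        if np.any((self.founder_freqs < 0) | (self.founder_freqs > 1)):
            raise ConfigurationError("founder allele frequencies must lie in [0, 1]")
        for c in range(self.n_chromosomes):
            pos = self.positions[self.chrom == c]
            if len(pos) > 1 and np.any(np.diff(pos) <= 0):
                raise ConfigurationError(
                    f"marker positions must be strictly increasing on chromosome {c}"
                )
        if self.switch_probs is None:
            sw = np.empty(n)
            sw[0] = 0.5
            d = np.diff(self.positions)
            same = np.diff(self.chrom) == 0
            sw[1:] = np.where(same, 0.5 * (1.0 - np.exp(-2.0 * d)), 0.5)
            object.__setattr__(self, "switch_probs", sw)

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def marker_ids(self) -> list[str]:
        """Canonical marker identifiers, ``chr{c}_{i}`` (both 1-based)."""
        return [
            f"chr{c + 1}_{i + 1}"
            for c in range(self.n_chromosomes)
            for i in range(self.markers_per_chromosome)
        ]

    def marker_index(self, marker_id: str) -> int:
        """Inverse of :meth:`marker_ids` for a single identifier."""
        try:
            c_part, i_part = marker_id.split("_")
            c = int(c_part.removeprefix("chr")) - 1
            i = int(i_part) - 1
        except (ValueError, AttributeError) as exc:
            raise DataShapeError(f"unrecognised marker id {marker_id!r}") from exc
        if not (0 <= c < self.n_chromosomes and 0 <= i < self.markers_per_chromosome):
            raise DataShapeError(f"marker id {marker_id!r} outside genome")
        return c * self.markers_per_chromosome + i


def make_genome(
    n_chromosomes: int = 10,
    chromosome_length: float = 1.0,
    markers_per_chromosome: int = 500,
    freq_sampler=(0.05, 0.95),
    seed=None,
) -> GenomeMap:
    """Build a genome with equally spaced markers and sampled founder freqs.

    Parameters
    ----------
    freq_sampler
        Either a fixed float frequency, a ``(low, high)`` tuple for i.i.d.
        Uniform(low, high) draws, or a callable ``f(rng, size) -> array``.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ConfigurationError("chromosome and marker counts must be >= 1")
    if chromosome_length < 0:
        raise ConfigurationError("chromosome length must be >= 0")
    rng = _as_rng(seed)
    m = n_chromosomes * markers_per_chromosome
    within = (
        np.arange(markers_per_chromosome, dtype=float)
        / markers_per_chromosome
        * chromosome_length
    )
    if chromosome_length == 0:
        # degenerate: stack markers at distinct epsilon-free positions is
        # impossible; keep a strictly increasing index-based pseudo-position
        within = np.arange(markers_per_chromosome, dtype=float) * 0.0
        if markers_per_chromosome > 1:
            raise ConfigurationError(
                "zero-length chromosomes admit a single marker only"
            )
    positions = np.tile(within, n_chromosomes)
    chrom = np.repeat(np.arange(n_chromosomes), markers_per_chromosome)
    if callable(freq_sampler):
        freqs = np.asarray(freq_sampler(rng, m), dtype=float)
    elif np.isscalar(freq_sampler):
        freqs = np.full(m, float(freq_sampler))
    else:
        low, high = freq_sampler
        freqs = rng.uniform(low, high, size=m)
    return GenomeMap(
        n_chromosomes=n_chromosomes,
        markers_per_chromosome=markers_per_chromosome,
        chromosome_length=chromosome_length,
        positions=positions,
        chrom=chrom,
        founder_freqs=freqs,
    )


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """A cohort of diploid, phased individuals.

    ``haplotypes`` has shape ``(n, 2, n_markers)`` with entries in {0, 1};
    ``sire``/``dam`` are parent ids (-1 for founders).  ``phenotype`` holds
    the breeding-objective phenotype when one has been generated.
    """

    ids: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    haplotypes: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    phenotype: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.ids)
        if self.haplotypes.shape[:2] != (n, 2):
            raise DataShapeError("haplotypes must have shape (n, 2, n_markers)")
        for name in ("sex", "generation", "sire", "dam"):
            if len(getattr(self, name)) != n:
                raise DataShapeError(f"{name} must have length n={n}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """Genotype dosage matrix Z = hap1 + hap2, entries in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1, dtype=np.int16)

    def subset(self, index) -> "Population":
        index = np.asarray(index)
        return Population(
            ids=self.ids[index],
            sex=self.sex[index],
            generation=self.generation[index],
            haplotypes=self.haplotypes[index],
            sire=self.sire[index],
            dam=self.dam[index],
            phenotype=None if self.phenotype is None else self.phenotype[index],
        )

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)


def concat_populations(pops: list[Population]) -> Population:
    """Stack cohorts (e.g. to form a training set) preserving order."""
    if not pops:
        raise ConfigurationError("cannot concatenate zero populations")
    phen = None
    if all(p.phenotype is not None for p in pops):
        phen = np.concatenate([p.phenotype for p in pops])
    return Population(
        ids=np.concatenate([p.ids for p in pops]),
        sex=np.concatenate([p.sex for p in pops]),
        generation=np.concatenate([p.generation for p in pops]),
        haplotypes=np.concatenate([p.haplotypes for p in pops]),
        sire=np.concatenate([p.sire for p in pops]),
        dam=np.concatenate([p.dam for p in pops]),
        phenotype=phen,
    )


def simulate_founders(
    genome: GenomeMap,
    n: int,
    seed=None,
    generation_label: str = "hist0",
    id_start: int = 0,
) -> Population:
    """Draw ``n`` founders (half male, half female) in linkage equilibrium.

    Each haplotype allele is an independent Bernoulli draw at the marker's
    founder frequency, i.e. the base population is unstructured and in
    Hardy-Weinberg/linkage equilibrium.
    """
    if n <= 0 or n % 2:
        raise ConfigurationError("founder count must be positive and even")
    rng = _as_rng(seed)
    haps = (
        rng.random((n, 2, genome.n_markers)) < genome.founder_freqs
    ).astype(np.uint8)
    sex = np.empty(n, dtype=np.int8)
    sex[: n // 2] = MALE
    sex[n // 2:] = FEMALE
    return Population(
        ids=np.arange(id_start, id_start + n, dtype=np.int64),
        sex=sex,
        generation=np.full(n, generation_label, dtype=object),
        haplotypes=haps,
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Trait architectures
# ---------------------------------------------------------------------------


@dataclass
class TraitArchitecture:
    """QTL positions and effects for one quantitative trait.

    ``additive``/``dominance`` are raw sampled effects; ``scale`` is the
    single multiplicative calibration factor that brings the genetic
    variance across the calibration (founder) population to exactly 1.
    Epistatic pairs are stored as parallel arrays of marker indices and an
    additive-by-additive interaction effect on centred dosages.
    """

    trait_id: str
    qtl_indices: np.ndarray
    additive: np.ndarray
    dominance: np.ndarray
    epi_a: np.ndarray
    epi_b: np.ndarray
    epi_effect: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise ConfigurationError("QTL indices must be distinct")
        qtl = set(self.qtl_indices.tolist())
        for a, b in zip(self.epi_a, self.epi_b):
            if a not in qtl or b not in qtl:
                raise ConfigurationError("epistatic pairs must reference QTL indices")
        pairs = {tuple(sorted(p)) for p in zip(self.epi_a.tolist(), self.epi_b.tolist())}
        if len(pairs) != len(self.epi_a):
            raise ConfigurationError("epistatic pairs must not repeat")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)

    @property
    def scaled_additive(self) -> np.ndarray:
        return self.additive * self.scale


def _default_effect_sampler(rng, size):
    return rng.standard_normal(size)


def _calibration_sd(raw: np.ndarray) -> float:
    """Sample sd of raw genetic values, rejecting (numerically) zero variance."""
    sd = float(np.std(raw, ddof=1))
    # relative guard: constant vectors can carry ~1e-16 float summation noise
    if not np.isfinite(sd) or sd <= 1e-10 * max(1.0, float(np.abs(raw).mean())):
        raise CalibrationError(
            "founder genetic variance is zero (all QTLs monomorphic?); "
            "cannot calibrate trait variance"
        )
    return sd


def assign_trait(
    genome: GenomeMap,
    n_qtl: int,
    founders: Population,
    effect_sampler=None,
    exclude_indices=(),
    seed=None,
    trait_id: str = "trait",
) -> TraitArchitecture:
    """Sample an additive QTL architecture calibrated to unit variance.

    QTL marker indices are drawn without replacement avoiding
    ``exclude_indices`` (so two traits can be given disjoint QTL sets);
    raw additive effects come from ``effect_sampler`` (standard normal by
    default).  The calibration factor is 1 over the sample standard
    deviation of the raw true breeding values across ``founders``, so the
    founder-population TBV variance is exactly 1 by construction.
    """
    rng = _as_rng(seed)
    available = np.setdiff1d(np.arange(genome.n_markers), np.asarray(list(exclude_indices), dtype=int))
    if n_qtl > len(available):
        raise ConfigurationError(
            f"requested {n_qtl} QTLs but only {len(available)} markers available"
        )
    sampler = effect_sampler or _default_effect_sampler
    qtl = np.sort(rng.choice(available, size=n_qtl, replace=False))
    a = np.asarray(sampler(rng, n_qtl), dtype=float)
    arch = TraitArchitecture(
        trait_id=trait_id,
        qtl_indices=qtl,
        additive=a,
        dominance=np.zeros(n_qtl),
        epi_a=np.array([], dtype=int),
        epi_b=np.array([], dtype=int),
        epi_effect=np.array([]),
        scale=1.0,
    )
    raw = true_breeding_value(founders.dosages(), arch)
    return replace(arch, scale=1.0 / _calibration_sd(raw))


def add_nonadditive(
    arch: TraitArchitecture,
    proportion: float,
    mode: str,
    founders: Population,
    effect_sampler=None,
    seed=None,
) -> TraitArchitecture:
    """Give a fraction of the QTLs dominance and/or epistatic effects.

    ``mode`` is ``"dominance"``, ``"epistasis"`` or ``"both"``.  With
    proportion ``p`` and ``n`` additive QTLs, dominance mode assigns
    dominance deviations to ``round(p*n)`` randomly chosen QTLs; epistasis
    mode creates ``round(p*n)`` disjoint additive-by-additive pairs among
    randomly chosen QTLs.  The total genotypic-value variance is then
    recalibrated to 1 on the founder population, so the additive share of
    the (unit) genetic variance shrinks as ``p`` grows.
    """
    if proportion == 0:
        return arch
    if not (0 < proportion <= 1):
        raise ConfigurationError("non-additive proportion must lie in (0, 1]")
    if mode not in ("dominance", "epistasis", "both"):
        raise ConfigurationError(f"unknown non-additive mode {mode!r}")
    rng = _as_rng(seed)
    sampler = effect_sampler or _default_effect_sampler
    n = arch.n_qtl
    k = int(round(proportion * n))
    dominance = arch.dominance.copy()
    epi_a, epi_b, epi_eff = arch.epi_a, arch.epi_b, arch.epi_effect
    if mode in ("dominance", "both"):
        chosen = rng.choice(n, size=k, replace=False)
        dominance = dominance.copy()
        dominance[chosen] = sampler(rng, k)
    if mode in ("epistasis", "both"):
        if 2 * k > n:
            raise ConfigurationError(
                f"cannot form {k} disjoint epistatic pairs from {n} QTLs"
            )
        members = rng.choice(arch.qtl_indices, size=2 * k, replace=False)
        epi_a = members[:k]
        epi_b = members[k:]
        epi_eff = np.asarray(sampler(rng, k), dtype=float)
    out = TraitArchitecture(
        trait_id=arch.trait_id,
        qtl_indices=arch.qtl_indices,
        additive=arch.additive,
        dominance=dominance,
        epi_a=epi_a,
        epi_b=epi_b,
        epi_effect=epi_eff,
        scale=1.0,
    )
    raw = genotypic_value(founders.dosages(), out)
    return replace(out, scale=1.0 / _calibration_sd(raw))


# ---------------------------------------------------------------------------
# Inheritance
# ---------------------------------------------------------------------------


def _sample_sources(genome: GenomeMap, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Sample (n_gametes, n_markers) haplotype-of-origin indicators.

    The first marker of each chromosome switches with probability 1/2,
    which both picks the starting haplotype uniformly and makes
    chromosomes segregate independently.
    """
    switches = rng.random((n_gametes, genome.n_markers)) < genome.switch_probs
    return np.cumsum(switches, axis=1, dtype=np.int64) % 2


def meiosis(parent_haplotypes: np.ndarray, genome: GenomeMap, seed=None) -> np.ndarray:
    """Produce one gamete from a parent's two phased haplotypes."""
    haps = np.asarray(parent_haplotypes)
    if haps.shape != (2, genome.n_markers):
        raise DataShapeError(
            f"parent haplotypes must have shape (2, {genome.n_markers})"
        )
    rng = _as_rng(seed)
    src = _sample_sources(genome, 1, rng)[0]
    return haps[src, np.arange(genome.n_markers)]


def produce_offspring(
    sires: Population,
    dams: Population,
    n_offspring: int,
    genome: GenomeMap,
    generation_label: str,
    seed=None,
    id_start: int | None = None,
    strict: bool = True,
) -> Population:
    """Mate selected sires and dams into a balanced offspring cohort.

    Dams are partitioned at random among sires (equally when counts divide;
    with ``strict=False`` the remainder is spread as evenly as possible) and
    each dam contributes ``n_offspring / n_dams`` offspring (again, the
    remainder is spread when not divisible and ``strict=False``).  Offspring
    sexes are exactly half male, half female, assigned at random.
    """
    n_s, n_d = sires.n, dams.n
    if n_s < 1 or n_d < 1 or n_offspring < 1:
        raise ConfigurationError("need at least one sire, one dam and one offspring")
    if n_offspring % 2:
        raise ConfigurationError("offspring count must be even for a 1:1 sex ratio")
    if strict and (n_offspring % n_d or n_d % n_s):
        raise ConfigurationError(
            f"balanced mating needs n_offspring divisible by n_dams and "
            f"n_dams by n_sires (got {n_offspring}/{n_d}/{n_s}); "
            f"pass strict=False for near-balanced allocation"
        )
    rng = _as_rng(seed)

    # dams -> sires, as evenly as possible, at random
    sire_of_dam = np.repeat(np.arange(n_s), -(-n_d // n_s))[:n_d]
    rng.shuffle(sire_of_dam)
    # offspring -> dams, as evenly as possible
    base, extra = divmod(n_offspring, n_d)
    per_dam = np.full(n_d, base)
    if extra:
        per_dam[rng.choice(n_d, size=extra, replace=False)] += 1
    dam_of_off = np.repeat(np.arange(n_d), per_dam)
    sire_of_off = sire_of_dam[dam_of_off]

    pat = _sample_sources(genome, n_offspring, rng)
    mat = _sample_sources(genome, n_offspring, rng)
    cols = np.arange(genome.n_markers)
    hap_p = sires.haplotypes[sire_of_off][np.arange(n_offspring)[:, None], pat, cols]
    hap_m = dams.haplotypes[dam_of_off][np.arange(n_offspring)[:, None], mat, cols]
    haps = np.stack([hap_p, hap_m], axis=1).astype(np.uint8)

    sex = np.empty(n_offspring, dtype=np.int8)
    sex[: n_offspring // 2] = MALE
    sex[n_offspring // 2:] = FEMALE
    rng.shuffle(sex)

    if id_start is None:
        id_start = int(max(sires.ids.max(), dams.ids.max())) + 1
    return Population(
        ids=np.arange(id_start, id_start + n_offspring, dtype=np.int64),
        sex=sex,
        generation=np.full(n_offspring, generation_label, dtype=object),
        haplotypes=haps,
        sire=sires.ids[sire_of_off],
        dam=dams.ids[dam_of_off],
    )


# ---------------------------------------------------------------------------
# Genetic values and phenotypes
# ---------------------------------------------------------------------------


def _arch_list(arch) -> list[TraitArchitecture]:
    return list(arch) if isinstance(arch, (list, tuple)) else [arch]


def true_breeding_value(Z: np.ndarray, arch) -> np.ndarray:
    """Additive true breeding value, summed over traits if a list is given.

    TBV_i = sum_j Z_ij * a_j * scale, with Z the 0/1/2 dosage matrix.
    """
    Z = np.asarray(Z)
    tbv = np.zeros(Z.shape[0])
    for a in _arch_list(arch):
        if a.n_qtl and a.qtl_indices.max() >= Z.shape[1]:
            raise DataShapeError("genotype matrix does not cover all QTL columns")
        tbv += Z[:, a.qtl_indices] @ a.scaled_additive
    return tbv


def genotypic_value(Z: np.ndarray, arch) -> np.ndarray:
    """Total genotypic value: additive + dominance + pairwise epistasis.

    Dominance contributes ``d_j`` at heterozygous QTLs; an epistatic pair
    (j, k) contributes ``e_jk * (Z_j - 1) * (Z_k - 1)`` (product of centred
    dosages).  Reduces to the TBV when all non-additive effects are zero.
    """
    Z = np.asarray(Z)
    g = np.zeros(Z.shape[0])
    for a in _arch_list(arch):
        if a.n_qtl and a.qtl_indices.max() >= Z.shape[1]:
            raise DataShapeError("genotype matrix does not cover all QTL columns")
        Zq = Z[:, a.qtl_indices]
        part = Zq @ a.additive
        if np.any(a.dominance):
            part = part + (Zq == 1) @ a.dominance
        if len(a.epi_effect):
            w = Z - 1
            part = part + (w[:, a.epi_a] * w[:, a.epi_b]) @ a.epi_effect
        g += a.scale * part
    return g


def phenotype(
    genetic_values: np.ndarray,
    h2: float,
    seed=None,
    var_g: float | None = None,
) -> np.ndarray:
    """Add Gaussian environmental noise for a target heritability.

    ``y = g + e`` with ``e ~ N(0, var_g * (1 - h2) / h2)``.  ``var_g``
    defaults to the sample variance of ``genetic_values``; the breeding
    program passes the founder-calibrated variance instead so the residual
    variance stays constant across generations under selection.
    """
    if not (0 < h2 <= 1):
        raise ConfigurationError("heritability must lie in (0, 1]")
    g = np.asarray(genetic_values, dtype=float)
    if h2 == 1:
        return g.copy()
    vg = float(np.var(g, ddof=1)) if var_g is None else float(var_g)
    ve = vg * (1.0 - h2) / h2
    rng = _as_rng(seed)
    return g + rng.normal(0.0, np.sqrt(ve), size=len(g))
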