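"""The breeding-program design: historical phase, hybridization, reproduction.

The simulated program mirrors a two-breed improvement scheme for small
populations:

1. **Historical phase** — a founder population (default 200, sexes equal) is
   split into two purebred lines A and B.  Line A is selected for trait 1 and
   line B for trait 2, each for 10 generations by genotype similarity to its
   own trait's ideal individual (5 sires x 20 dams -> 200 offspring per
   generation).
2. **Hybridization** — F1 = 5 line-A sires x 20 line-B dams; F2 = 5 line-B
   generation-10 males x 20 F1 females.  From here on the breeding objective
   combines both traits and parents are chosen by the selection method under
   test (kinship index, GBLUP, BayesB, true breeding value, or the
   negative-control score).
3. **Purebred reproduction** — five further generations G1..G5, each time
   truncation-selecting 5 males and 20 females from the current cohort.

Every cohort records the mean true breeding value (combined, additive, using
the true QTL effects) of its selected males and females, plus the
whole-cohort mean.  All randomness flows from one master seed through named
substreams keyed by replicate and generation — never by method — so the
methods compared within a replicate share founders, trait architectures,
historical selection and mating randomness (common random numbers).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .exceptions import ConfigurationError
from .genome import (
    GenomeMap,
    Population,
    TraitArchitecture,
    add_nonadditive,
    assign_trait,
    concat_populations,
    genotypic_value,
    make_genome,
    phenotype,
    produce_offspring,
    simulate_founders,
    true_breeding_value,
)
from .prediction import bayesb_ebv, gblup_ebv, grm_vanraden
from .rng import child_seed, substream
from .selection import (
    IdealIndividual,
    build_ideal,
    false_negative_ideal,
    false_positive_ideal,
    kis_score,
    negative_control_ideal,
    select_parents,
)

__all__ = [
    "METHODS",
    "BreedingConfig",
    "BaseState",
    "Trajectory",
    "build_base_state",
    "run_historical_phase",
    "run_hybridization",
    "run_purebred_reproduction",
    "run_scenario",
]

METHODS = ("KIS", "GBLUP", "BayesB", "TBV", "negative_control")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreedingConfig:
    """Complete scenario configuration with the base-design defaults."""

    # genome
    n_chromosomes: int = 10
    chromosome_length: float = 1.0
    markers_per_chromosome: int = 500
    freq_low: float = 0.05
    freq_high: float = 0.95
    # population design
    founder_n: int = 200
    n_sires: int = 5
    n_dams: int = 20
    offspring_per_generation: int = 200
    historical_generations: int = 10
    reproduction_generations: int = 5
    # traits
    qtl_count_1: int = 100
    qtl_count_2: int = 500
    h2: float = 0.5
    # selection method and robustness settings
    method: str = "KIS"
    weighting: str = "equal"
    false_negative_rate: float = 0.0
    false_positive_rate: float = 0.0
    nonadditive_proportion: float = 0.0
    nonadditive_mode: str = "both"
    negative_control_loci: int = 600
    # genomic prediction
    training_window: int = 3
    gblup_ridge: float = 0.01
    bayesb_pi: float = 0.95
    bayesb_iterations: int = 2000
    bayesb_burn_in: int = 500
    # bookkeeping
    scenario_id: str = "base"
    master_seed: int = 1

    def __post_init__(self):
        for name in (
            "n_chromosomes",
            "markers_per_chromosome",
            "founder_n",
            "n_sires",
            "n_dams",
            "offspring_per_generation",
            "qtl_count_1",
            "qtl_count_2",
            "training_window",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.historical_generations < 0 or self.reproduction_generations < 0:
            raise ConfigurationError("generation counts must be >= 0")
        if self.founder_n % 4:
            raise ConfigurationError(
                "founder_n must be divisible by 4 (two lines, two sexes)"
            )
        if self.offspring_per_generation % 2:
            raise ConfigurationError("offspring_per_generation must be even")
        if not (0 < self.h2 <= 1):
            raise ConfigurationError("h2 must lie in (0, 1]")
        if self.method not in METHODS:
            raise ConfigurationError(f"method must be one of {METHODS}")
        if self.weighting not in ("equal", "effect"):
            raise ConfigurationError("weighting must be 'equal' or 'effect'")
        for name in ("false_negative_rate", "false_positive_rate"):
            if not (0 <= getattr(self, name) < 1):
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if not (0 <= self.nonadditive_proportion <= 1):
            raise ConfigurationError("nonadditive_proportion must lie in [0, 1]")
        if self.nonadditive_mode not in ("dominance", "epistasis", "both"):
            raise ConfigurationError("invalid nonadditive_mode")
        pool = min(self.founder_n // 4, self.offspring_per_generation // 2)
        if self.n_sires > pool or self.n_dams > pool:
            raise ConfigurationError(
                f"cannot select {self.n_sires} sires / {self.n_dams} dams from a "
                f"per-sex candidate pool of {pool}"
            )
        total_markers = self.n_chromosomes * self.markers_per_chromosome
        if self.qtl_count_1 + self.qtl_count_2 > total_markers:
            raise ConfigurationError("QTL counts exceed the marker count")
        if self.bayesb_iterations <= self.bayesb_burn_in:
            raise ConfigurationError("bayesb_iterations must exceed bayesb_burn_in")

    def with_(self, **kwargs) -> "BreedingConfig":
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def base_state_key(self) -> tuple:
        """Fields that determine the shared pre-cross simulation state."""
        names = [
            f.name
            for f in fields(self)
            if f.name
            not in (
                "method",
                "weighting",
                "false_negative_rate",
                "false_positive_rate",
                "negative_control_loci",
                "training_window",
                "gblup_ridge",
                "bayesb_pi",
                "bayesb_iterations",
                "bayesb_burn_in",
                "scenario_id",
            )
        ]
        return tuple(getattr(self, n) for n in names)


# ---------------------------------------------------------------------------
# Base state: genome, traits, historical phase
# ---------------------------------------------------------------------------


@dataclass
class BaseState:
    """Everything the compared methods share within one replicate."""

    config: BreedingConfig
    replicate: int
    genome: GenomeMap
    traits: list[TraitArchitecture]
    A_hist: list[Population]
    B_hist: list[Population]
    next_id: int
    founder_checksum: int

    @property
    def popA(self) -> Population:
        return self.A_hist[-1]

    @property
    def popB(self) -> Population:
        return self.B_hist[-1]


def _total_genetic_value(pop: Population, traits) -> np.ndarray:
    return genotypic_value(pop.dosages(), traits)


def _phenotype_cohort(pop: Population, traits, config, rng) -> None:
    # residual variance anchored at the founder-calibrated genetic variance
    # (1 per trait) so selection does not shrink the noise level
    g = _total_genetic_value(pop, traits)
    pop.phenotype = phenotype(g, config.h2, seed=rng, var_g=float(len(traits)))


def build_base_state(
    config: BreedingConfig,
    replicate: int = 0,
    genome: GenomeMap | None = None,
    traits: list[TraitArchitecture] | None = None,
) -> BaseState:
    """Found the population, calibrate the traits, run the historical phase."""
    ms = config.master_seed
    if genome is None:
        genome = make_genome(
            config.n_chromosomes,
            config.chromosome_length,
            config.markers_per_chromosome,
            (config.freq_low, config.freq_high),
            seed=substream(ms, "genome", replicate),
        )
    founders = simulate_founders(
        genome, config.founder_n, seed=substream(ms, "founders", replicate)
    )
    checksum = zlib.crc32(founders.haplotypes.tobytes())
    if traits is None:
        t1 = assign_trait(
            genome,
            config.qtl_count_1,
            founders,
            seed=substream(ms, "trait", replicate, 1),
            trait_id="trait1",
        )
        t2 = assign_trait(
            genome,
            config.qtl_count_2,
            founders,
            exclude_indices=t1.qtl_indices,
            seed=substream(ms, "trait", replicate, 2),
            trait_id="trait2",
        )
        traits = [t1, t2]
        if config.nonadditive_proportion > 0:
            traits = [
                add_nonadditive(
                    t,
                    config.nonadditive_proportion,
                    config.nonadditive_mode,
                    founders,
                    seed=substream(ms, "nonadd", replicate, i),
                )
                for i, t in enumerate(traits)
            ]

    # split founders into lines A and B, balanced by sex, at random
    rng = substream(ms, "split", replicate)
    males = founders.males()
    females = founders.females()
    rng.shuffle(males)
    rng.shuffle(females)
    half_m, half_f = len(males) // 2, len(females) // 2
    idx_a = np.concatenate([males[:half_m], females[:half_f]])
    idx_b = np.concatenate([males[half_m:], females[half_f:]])

    next_id = itertools.count(config.founder_n)
    lineages = {}
    for name, idx, trait in (("A", idx_a, traits[0]), ("B", idx_b, traits[1])):
        pop0 = founders.subset(np.sort(idx))
        _phenotype_cohort(pop0, traits, config, substream(ms, "pheno", replicate, name, 0))
        ideal = build_ideal(trait, "equal")
        hist = [pop0]
        cur = pop0
        for g in range(1, config.historical_generations + 1):
            scores = kis_score(cur.dosages(), ideal)
            dec = select_parents(
                scores,
                cur.sex,
                config.n_sires,
                config.n_dams,
                seed=substream(ms, "hist_sel", replicate, name, g),
            )
            start = next(next_id)
            cur = produce_offspring(
                cur.subset(dec.sire_index),
                cur.subset(dec.dam_index),
                config.offspring_per_generation,
                genome,
                f"hist{g}",
                seed=substream(ms, "hist_mate", replicate, name, g),
                id_start=start,
                strict=False,
            )
            next_id = itertools.count(start + config.offspring_per_generation)
            _phenotype_cohort(cur, traits, config, substream(ms, "pheno", replicate, name, g))
            hist.append(cur)
        lineages[name] = hist

    return BaseState(
        config=config,
        replicate=replicate,
        genome=genome,
        traits=traits,
        A_hist=lineages["A"],
        B_hist=lineages["B"],
        next_id=next(next_id),
        founder_checksum=int(checksum),
    )


def run_historical_phase(
    config: BreedingConfig,
    genome: GenomeMap | None = None,
    traits: list[TraitArchitecture] | None = None,
    seed: int | None = None,
) -> tuple[Population, Population]:
    """Convenience wrapper returning the two generation-10 purebred lines."""
    if seed is not None:
        config = config.with_(master_seed=seed)
    state = build_base_state(config, genome=genome, traits=traits)
    return state.popA, state.popB


# ---------------------------------------------------------------------------
# Method scoring context
# ---------------------------------------------------------------------------


class _ScoreContext:
    """Scores cohorts under one selection method within one replicate.

    For the genomic-prediction methods, training uses the phenotypes of the
    last ``training_window`` cohorts on the running timeline plus the
    candidates themselves.
    """

    def __init__(self, config, method, replicate, genome, traits, ideal, timeline):
        if method not in METHODS:
            raise ConfigurationError(f"unknown method {method!r}")
        self.config = config
        self.method = method
        self.replicate = replicate
        self.genome = genome
        self.traits = traits
        self.ideal = ideal
        self.timeline = list(timeline)

    def push(self, pop: Population) -> None:
        self.timeline.append(pop)

    def scores(self, pops: list[Population], stage: str) -> np.ndarray:
        """Concatenated candidate scores for the cohorts in ``pops``."""
        Z = np.concatenate([p.dosages() for p in pops])
        if self.method in ("KIS", "negative_control"):
            return kis_score(Z, self.ideal)
        if self.method == "TBV":
            return true_breeding_value(Z, self.traits)
        return self._ebv_scores(pops, stage)

    def _ebv_scores(self, pops, stage):
        # Candidates are scored as unphenotyped juveniles: their own records
        # are masked and their EBVs flow through genomic relationships to the
        # phenotyped cohorts of the training window.
        cfg = self.config
        window = self.timeline[-cfg.training_window:]
        train = list(window) + [p for p in pops if not any(p is q for q in window)]
        full = concat_populations(train)
        if full.phenotype is None:
            raise ConfigurationError(
                "genomic-prediction methods need phenotyped training cohorts"
            )
        Z = full.dosages()
        y = full.phenotype.copy()
        candidate_ids = np.concatenate([p.ids for p in pops])
        y[np.isin(full.ids, candidate_ids)] = np.nan
        if not np.isfinite(y).any():
            raise ConfigurationError(
                "no phenotyped training individuals besides the candidates"
            )
        if self.method == "GBLUP":
            grm = grm_vanraden(Z)
            ebv = gblup_ebv(y, grm, cfg.h2, ridge=cfg.gblup_ridge)
        else:
            ebv, _ = bayesb_ebv(
                y,
                Z,
                pi=cfg.bayesb_pi,
                n_iter=cfg.bayesb_iterations,
                n_burn=cfg.bayesb_burn_in,
                seed=child_seed(cfg.master_seed, "bayesb", self.replicate, stage),
                h2=cfg.h2,
            )
        pos = {int(i): k for k, i in enumerate(full.ids)}
        out = []
        for p in pops:
            out.append(ebv[[pos[int(i)] for i in p.ids]])
        return np.concatenate(out)


def build_method_ideal(
    config: BreedingConfig,
    method: str,
    genome: GenomeMap,
    traits,
    replicate: int = 0,
) -> IdealIndividual | None:
    """The (possibly perturbed) ideal the method scores against, if any."""
    ms = config.master_seed
    if method == "negative_control":
        return negative_control_ideal(
            genome,
            traits,
            config.negative_control_loci,
            seed=substream(ms, "nc", replicate),
        )
    if method != "KIS":
        return None
    ideal = build_ideal(traits, config.weighting)
    if config.false_negative_rate > 0:
        ideal = false_negative_ideal(
            ideal, [config.false_negative_rate], seed=substream(ms, "fn", replicate)
        )[0]
    if config.false_positive_rate > 0:
        ideal = false_positive_ideal(
            ideal,
            config.false_positive_rate,
            genome,
            seed=substream(ms, "fp", replicate),
        )
    return ideal


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Ordered per-generation records plus the cohorts they describe."""

    method: str
    records: list[dict] = field(default_factory=list)
    populations: dict[str, Population] = field(default_factory=dict)

    def labels(self) -> list[str]:
        seen = list(dict.fromkeys(r["generation"] for r in self.records))
        return seen


def _record_cohort(ctx, traj, pop, scores, label, rng, extra):
    cfg = ctx.config
    dec = select_parents(scores, pop.sex, cfg.n_sires, cfg.n_dams, seed=rng)
    tbv = true_breeding_value(pop.dosages(), ctx.traits)
    gen_mean = float(tbv.mean())
    for sex_name, index in (("male", dec.sire_index), ("female", dec.dam_index)):
        traj.records.append(
            {
                "generation": label,
                "method": ctx.method,
                "sex": sex_name,
                "mean_TBV": float(tbv[index].mean()),
                "generation_mean_TBV": gen_mean,
                **extra,
            }
        )
    traj.populations[label] = pop
    return dec


def _next_cohort(ctx, sires, dams, label, id_start, rng_mate, rng_pheno):
    cfg = ctx.config
    pop = produce_offspring(
        sires,
        dams,
        cfg.offspring_per_generation,
        ctx.genome,
        label,
        seed=rng_mate,
        id_start=id_start,
        strict=False,
    )
    _phenotype_cohort(pop, ctx.traits, cfg, rng_pheno)
    ctx.push(pop)
    return pop


def run_hybridization(
    popA: Population,
    popB: Population,
    config: BreedingConfig,
    method_tag: str,
    seed: int | None = None,
    *,
    genome: GenomeMap,
    traits,
    replicate: int = 0,
    timeline: list[Population] | None = None,
    ideal: IdealIndividual | None = None,
    next_id: int | None = None,
) -> Trajectory:
    """Cross line A sires with line B dams (F1), then B males with F1 females (F2).

    Sires and dams for each cross are chosen by ``method_tag`` against the
    combined two-trait objective; the F1 and F2 cohorts are each scored and
    truncation-selected for the trajectory records.
    """
    ms = config.master_seed if seed is None else seed
    config = config.with_(master_seed=ms)
    if timeline is None:
        timeline = [popA, popB]
    if ideal is None:
        ideal = build_method_ideal(config, method_tag, genome, traits, replicate)
    ctx = _ScoreContext(config, method_tag, replicate, genome, traits, ideal, timeline)
    traj = Trajectory(method=method_tag)
    extra = {"replicate": replicate, "scenario_id": config.scenario_id}
    if next_id is None:
        next_id = int(max(popA.ids.max(), popB.ids.max())) + 1

    # F1: sires from line A males, dams from line B females
    sc = ctx.scores([popA, popB], "F1p")
    scA, scB = sc[: popA.n], sc[popA.n:]
    rng_sel = substream(ms, "sel", replicate, "F1p")
    decA = select_parents(scA, popA.sex, config.n_sires, 0, seed=rng_sel)
    decB = select_parents(scB, popB.sex, 0, config.n_dams, seed=rng_sel)
    f1 = _next_cohort(
        ctx,
        popA.subset(decA.sire_index),
        popB.subset(decB.dam_index),
        "F1",
        next_id,
        substream(ms, "mate", replicate, "F1"),
        substream(ms, "pheno_x", replicate, "F1"),
    )
    next_id += f1.n

    # score line-B males and the F1 cohort together: records F1, parents of F2
    sc = ctx.scores([popB, f1], "F1")
    scB, scF1 = sc[: popB.n], sc[popB.n:]
    dec_f1 = _record_cohort(
        ctx, traj, f1, scF1, "F1", substream(ms, "sel", replicate, "F1"), extra
    )
    decB = select_parents(
        scB, popB.sex, config.n_sires, 0, seed=substream(ms, "sel", replicate, "F2p")
    )
    f2 = _next_cohort(
        ctx,
        popB.subset(decB.sire_index),
        f1.subset(dec_f1.dam_index),
        "F2",
        next_id,
        substream(ms, "mate", replicate, "F2"),
        substream(ms, "pheno_x", replicate, "F2"),
    )
    sc_f2 = ctx.scores([f2], "F2")
    _record_cohort(ctx, traj, f2, sc_f2, "F2", substream(ms, "sel", replicate, "F2"), extra)
    traj.populations["F1"] = f1
    traj.populations["F2"] = f2
    return traj


def run_purebred_reproduction(
    f2: Population,
    config: BreedingConfig,
    method_tag: str,
    seed: int | None = None,
    *,
    genome: GenomeMap,
    traits,
    replicate: int = 0,
    timeline: list[Population] | None = None,
    ideal: IdealIndividual | None = None,
) -> Trajectory:
    """Run G1..Gk purebred generations under ``method_tag`` selection."""
    ms = config.master_seed if seed is None else seed
    config = config.with_(master_seed=ms)
    if timeline is None:
        timeline = [f2]
    if ideal is None:
        ideal = build_method_ideal(config, method_tag, genome, traits, replicate)
    ctx = _ScoreContext(config, method_tag, replicate, genome, traits, ideal, timeline)
    traj = Trajectory(method=method_tag)
    extra = {"replicate": replicate, "scenario_id": config.scenario_id}

    cur = f2
    cur_label = "F2"
    sc = ctx.scores([cur], cur_label)
    dec = select_parents(
        sc, cur.sex, config.n_sires, config.n_dams,
        seed=substream(ms, "sel", replicate, cur_label),
    )
    next_id = int(cur.ids.max()) + 1
    for g in range(1, config.reproduction_generations + 1):
        label = f"G{g}"
        cur = _next_cohort(
            ctx,
            cur.subset(dec.sire_index),
            cur.subset(dec.dam_index),
            label,
            next_id,
            substream(ms, "mate", replicate, label),
            substream(ms, "pheno_x", replicate, label),
        )
        next_id += cur.n
        sc = ctx.scores([cur], label)
        dec = _record_cohort(
            ctx, traj, cur, sc, label, substream(ms, "sel", replicate, label), extra
        )
    return traj


def run_from_cross(state: BaseState, config: BreedingConfig, method: str) -> Trajectory:
    """Hybridization followed by purebred reproduction on a shared base state."""
    cfg = config
    w = cfg.training_window
    timeline = state.A_hist[-w:] + state.B_hist[-w:]
    ideal = build_method_ideal(cfg, method, state.genome, state.traits, state.replicate)
    hyb = run_hybridization(
        state.popA,
        state.popB,
        cfg,
        method,
        genome=state.genome,
        traits=state.traits,
        replicate=state.replicate,
        timeline=timeline,
        ideal=ideal,
        next_id=state.next_id,
    )
    rep = run_purebred_reproduction(
        hyb.populations["F2"],
        cfg,
        method,
        genome=state.genome,
        traits=state.traits,
        replicate=state.replicate,
        timeline=timeline + [hyb.populations["F1"], hyb.populations["F2"]],
        ideal=ideal,
    )
    traj = Trajectory(method=method)
    traj.records = hyb.records + rep.records
    traj.populations = {**hyb.populations, **rep.populations}
    for r in traj.records:
        r["founder_checksum"] = state.founder_checksum
    return traj


def run_scenario(
    config: BreedingConfig,
    replicate: int = 0,
    state: BaseState | None = None,
    method: str | None = None,
) -> Trajectory:
    """One full replicate: historical phase, hybridization, reproduction."""
    if state is None:
        state = build_base_state(config, replicate)
    return run_from_cross(state, config, method or config.method)
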