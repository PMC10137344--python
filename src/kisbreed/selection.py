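"""Ideal individuals and kinship-index (genotype-similarity) selection.

The kinship-index selection criterion ranks candidates by how similar their
genotypes are to a virtual *ideal individual*: a genotype homozygous for the
beneficial allele at every locus tied to the breeding objective.  At each
ideal locus a candidate contributes 0, 1 or 2 — the number of beneficial
allele copies it carries — multiplied by the locus weight; the kinship index
(KI) is the sum over loci.  Candidates are then truncation-selected within
sex.

Besides the exact ideal derived from a simulated trait architecture, this
module builds the perturbed ideals used to probe robustness: ideals with a
fraction of true loci deleted (false negatives), ideals with spurious loci
adjacent to true QTLs added (pseudo-positives), and a negative-control ideal
made entirely of loci with no effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DataShapeError, GenerationError
from .genome import FEMALE, MALE, GenomeMap, TraitArchitecture, _arch_list, _as_rng

__all__ = [
    "IdealIndividual",
    "SelectionDecision",
    "build_ideal",
    "kis_score",
    "false_negative_ideal",
    "false_positive_ideal",
    "negative_control_ideal",
    "select_parents",
]


@dataclass
class IdealIndividual:
    """Scored loci, beneficial allele and weight per locus.

    ``subsystem`` tags each locus with the trait (or trait category) it came
    from so that per-subsystem similarity scores can be reported and
    re-weighted.
    """

    loci: np.ndarray
    beneficial: np.ndarray
    weights: np.ndarray
    subsystem: np.ndarray

    def __post_init__(self):
        self.loci = np.asarray(self.loci, dtype=int)
        self.beneficial = np.asarray(self.beneficial, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.subsystem = np.asarray(self.subsystem, dtype=object)
        if len(np.unique(self.loci)) != len(self.loci):
            raise ConfigurationError("ideal-individual loci must be distinct")
        if np.any((self.beneficial != 0) & (self.beneficial != 1)):
            raise ConfigurationError("beneficial alleles must be 0 or 1")
        if np.any(self.weights < 0):
            raise ConfigurationError("locus weights must be non-negative")
        for arr in (self.beneficial, self.weights, self.subsystem):
            if len(arr) != len(self.loci):
                raise DataShapeError("per-locus arrays must match loci length")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def max_score(self) -> float:
        """The score of the ideal genotype itself: 2 x sum of weights."""
        return 2.0 * float(self.weights.sum())

    def subset(self, index) -> "IdealIndividual":
        index = np.asarray(index)
        return IdealIndividual(
            loci=self.loci[index],
            beneficial=self.beneficial[index],
            weights=self.weights[index],
            subsystem=self.subsystem[index],
        )


def build_ideal(arch, weighting: str = "equal") -> IdealIndividual:
    """Derive the ideal individual from one or more trait architectures.

    The beneficial allele at a QTL is the allele whose dosage increase
    raises the TBV ("1" for a positive additive effect, "0" for a negative
    one); zero-effect loci are dropped.  Weights are 1 under ``equal``
    weighting and |scaled additive effect| under ``effect`` weighting.
    Multiple traits concatenate, tagged by trait id as the subsystem.
    """
    if weighting not in ("equal", "effect"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    archs = _arch_list(arch)
    if not archs or all(a.n_qtl == 0 for a in archs):
        raise ConfigurationError("cannot build an ideal from an empty architecture")
    loci, beneficial, weights, subsystem = [], [], [], []
    for a in archs:
        keep = a.additive != 0
        loci.append(a.qtl_indices[keep])
        beneficial.append((a.additive[keep] > 0).astype(int))
        if weighting == "equal":
            weights.append(np.ones(keep.sum()))
        else:
            weights.append(np.abs(a.scaled_additive[keep]))
        subsystem.append(np.full(keep.sum(), a.trait_id, dtype=object))
    return IdealIndividual(
        loci=np.concatenate(loci),
        beneficial=np.concatenate(beneficial),
        weights=np.concatenate(weights),
        subsystem=np.concatenate(subsystem),
    )


def kis_score(
    Z: np.ndarray,
    ideal: IdealIndividual,
    subsystem_weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Kinship index of each candidate row of the dosage matrix ``Z``.

    Per locus the contribution is ``weight x (beneficial-allele copies)``
    where the copy count is 0, 1 or 2; the score is the sum over loci.
    Optional ``subsystem_weights`` rescale whole trait subsystems when
    synthesising the comprehensive index from several traits.
    """
    Z = np.asarray(Z)
    if Z.ndim != 2:
        raise DataShapeError("Z must be a 2-D individuals x markers matrix")
    if ideal.n_loci and ideal.loci.max() >= Z.shape[1]:
        raise DataShapeError("genotype matrix does not cover all ideal loci")
    copies = Z[:, ideal.loci].astype(float)
    flip = ideal.beneficial == 0
    copies[:, flip] = 2.0 - copies[:, flip]
    w = ideal.weights
    if subsystem_weights is not None:
        w = w * np.array([subsystem_weights.get(s, 1.0) for s in ideal.subsystem])
    return copies @ w


def subsystem_scores(Z: np.ndarray, ideal: IdealIndividual) -> dict[str, np.ndarray]:
    """Per-subsystem (per-trait) similarity scores for each candidate."""
    out = {}
    for label in dict.fromkeys(ideal.subsystem.tolist()):
        out[str(label)] = kis_score(Z, ideal.subset(ideal.subsystem == label))
    return out


def false_negative_ideal(
    ideal: IdealIndividual, rates, seed=None
) -> list[IdealIndividual]:
    """Delete a fraction of the ideal's loci, nested across rates.

    For each rate ``r`` (ascending, in [0, 1)), ``round(r * L)`` loci are
    dropped uniformly at random; the loci missing at a lower rate are a
    subset of those missing at any higher rate, so the perturbations form a
    nested family driven by one random permutation.
    """
    rates = list(rates)
    if any(not (0 <= r < 1) for r in rates):
        raise ConfigurationError("false-negative rates must lie in [0, 1)")
    if sorted(rates) != rates:
        raise ConfigurationError("false-negative rates must be sorted ascending")
    rng = _as_rng(seed)
    order = rng.permutation(ideal.n_loci)
    out = []
    for r in rates:
        k = int(round(r * ideal.n_loci))
        keep = np.sort(order[k:])
        out.append(ideal.subset(keep))
    return out


def false_positive_ideal(
    ideal: IdealIndividual, rate: float, genome: GenomeMap, seed=None
) -> IdealIndividual:
    """Add spurious loci adjacent to randomly chosen true loci.

    ``round(rate * L)`` pseudo-positive loci are added, each the nearest
    marker (preferring index+1, then index-1, then farther neighbours on
    the same chromosome) to a randomly chosen true locus that is not
    already part of the ideal.  Added loci get Bernoulli(1/2) beneficial
    alleles, unit weight and the subsystem tag ``"pseudo"``.
    """
    if not (0 <= rate < 1):
        raise ConfigurationError("pseudo-positive rate must lie in [0, 1)")
    k = int(round(rate * ideal.n_loci))
    if k == 0:
        return ideal
    rng = _as_rng(seed)
    taken = set(ideal.loci.tolist())
    anchors = rng.choice(ideal.loci, size=k, replace=False)
    added = []
    for anchor in anchors:
        c = genome.chrom[anchor]
        found = None
        for step in range(1, genome.markers_per_chromosome):
            for cand in (anchor + step, anchor - step):
                if 0 <= cand < genome.n_markers and genome.chrom[cand] == c and cand not in taken:
                    found = cand
                    break
            if found is not None:
                break
        if found is None:
            raise GenerationError(
                f"no free marker adjacent to locus {anchor} on chromosome {c}"
            )
        taken.add(found)
        added.append(found)
    added = np.array(added, dtype=int)
    return IdealIndividual(
        loci=np.concatenate([ideal.loci, added]),
        beneficial=np.concatenate([ideal.beneficial, rng.integers(0, 2, size=k)]),
        weights=np.concatenate([ideal.weights, np.ones(k)]),
        subsystem=np.concatenate([ideal.subsystem, np.full(k, "pseudo", dtype=object)]),
    )


def negative_control_ideal(
    genome: GenomeMap, arch, n_loci: int = 600, seed=None
) -> IdealIndividual:
    """An ideal built from loci carrying no effect, with random alleles.

    Sampled from markers outside every QTL set of ``arch``; used as the
    negative control: selecting on similarity to it should produce no
    genetic gain.
    """
    rng = _as_rng(seed)
    qtl = np.concatenate([a.qtl_indices for a in _arch_list(arch)])
    free = np.setdiff1d(np.arange(genome.n_markers), qtl)
    if n_loci > len(free):
        raise GenerationError(
            f"need {n_loci} non-QTL markers but only {len(free)} exist"
        )
    loci = np.sort(rng.choice(free, size=n_loci, replace=False))
    return IdealIndividual(
        loci=loci,
        beneficial=rng.integers(0, 2, size=n_loci),
        weights=np.ones(n_loci),
        subsystem=np.full(n_loci, "control", dtype=object),
    )


@dataclass
class SelectionDecision:
    """Result of truncation selection within sex."""

    scores: np.ndarray
    sire_index: np.ndarray
    dam_index: np.ndarray
    selected_sires: np.ndarray
    selected_dams: np.ndarray
    method_tag: str = ""


def select_parents(
    scores: np.ndarray,
    sexes: np.ndarray,
    n_sires: int,
    n_dams: int,
    seed=None,
    ids: np.ndarray | None = None,
    method_tag: str = "",
) -> SelectionDecision:
    """Truncation-select the top males and females by score.

    Ties are broken by a seeded uniform draw (not by id order), so repeated
    calls with the same seed reproduce the same choice among tied
    candidates.
    """
    scores = np.asarray(scores, dtype=float)
    sexes = np.asarray(sexes)
    if ids is None:
        ids = np.arange(len(scores))
    rng = _as_rng(seed)
    tie = rng.random(len(scores))

    def top(sex, k):
        idx = np.flatnonzero(sexes == sex)
        if len(idx) < k:
            raise ConfigurationError(
                f"need {k} candidates of sex {sex} but only {len(idx)} available"
            )
        order = idx[np.lexsort((tie[idx], -scores[idx]))]
        return order[:k]

    sire_index = top(MALE, n_sires)
    dam_index = top(FEMALE, n_dams)
    return SelectionDecision(
        scores=scores,
        sire_index=sire_index,
        dam_index=dam_index,
        selected_sires=np.asarray(ids)[sire_index],
        selected_dams=np.asarray(ids)[dam_index],
        method_tag=method_tag,
    )
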