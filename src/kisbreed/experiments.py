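"""Replicate runner and statistics for the simulation experiments.

Provides the replicated feasibility comparison (kinship-index selection vs
GBLUP, BayesB, true-breeding-value selection and the negative control), the
six robustness scenario families, one-way ANOVA with Tukey HSD post-hoc
comparisons summarised as a compact letter display, and coefficients of
variation across replicates.

Replicates use common random numbers: within a replicate every compared
method (and, where the design allows, every scenario level) shares the same
genome, trait architectures, founders and historical phase, so method
contrasts are paired.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .program import METHODS, BaseState, BreedingConfig, build_base_state, run_from_cross

__all__ = [
    "run_replicates",
    "feasibility_experiment",
    "robustness_suite",
    "anova_letters",
    "coefficient_of_variation",
    "FOUNDATION_SCALES",
    "SELECTION_PROPORTIONS",
    "QTL_GRADIENTS",
]

# Scenario-family gradients for the robustness suite.  The foundation-scale
# gradient spans 100..2000 founders; 50 is not representable under the
# balanced two-line split (25 animals per line cannot supply 20 dams).
FOUNDATION_SCALES = (2000, 1000, 500, 200, 100)
SELECTION_PROPORTIONS = ((3, 10), (5, 20), (10, 30), (15, 40), (20, 50))
QTL_GRADIENTS = ((100, 500), (100, 350), (150, 400), (200, 500))
PERTURBATION_RATES = (0.0, 0.1, 0.2, 0.3)
NONADDITIVE_PROPORTIONS = (0.1, 0.2, 0.3)


def _rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    cols = [
        "replicate",
        "scenario_id",
        "method",
        "generation",
        "sex",
        "mean_TBV",
        "generation_mean_TBV",
        "founder_checksum",
    ]
    return df[cols]


def run_replicates(
    config: BreedingConfig,
    n_reps: int,
    master_seed: int | None = None,
    methods: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Run ``n_reps`` replicates of one scenario, tidily tabulated.

    If several ``methods`` are given they share each replicate's base state
    (common random numbers).  Returns one row per (replicate, scenario,
    method, generation, sex) with the mean TBV of the selected parents and
    of the whole cohort.
    """
    if n_reps < 1:
        raise ConfigurationError("need at least one replicate")
    if master_seed is not None:
        config = config.with_(master_seed=master_seed)
    methods = methods or (config.method,)
    rows = []
    for rep in range(n_reps):
        state = build_base_state(config, rep)
        for method in methods:
            traj = run_from_cross(state, config, method)
            rows.extend(traj.records)
    return _rows_to_frame(rows)


def run_scenario_family(
    variants: list[BreedingConfig],
    n_reps: int,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Run several scenario variants, sharing base states where possible.

    Variants that differ only in post-cross settings (ideal perturbations,
    weighting, method) reuse the same simulated base population within each
    replicate.
    """
    rows = []
    for rep in range(n_reps):
        cache: dict[tuple, BaseState] = {}
        for cfg in variants:
            if master_seed is not None:
                cfg = cfg.with_(master_seed=master_seed)
            key = cfg.base_state_key()
            if key not in cache:
                cache[key] = build_base_state(cfg, rep)
            traj = run_from_cross(cache[key], cfg, cfg.method)
            rows.extend(traj.records)
    return _rows_to_frame(rows)


def feasibility_experiment(
    config: BreedingConfig,
    n_reps: int = 10,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """All selection methods plus the negative control, common random numbers."""
    return run_replicates(config, n_reps, master_seed, methods=METHODS)


def robustness_suite(
    base_config: BreedingConfig,
    n_reps: int = 10,
    master_seed: int | None = None,
    families: tuple[str, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the six robustness scenario families for the kinship-index method.

    Families: ``false_negative`` (deletion rates x equal/effect weighting),
    ``pseudo_positive`` (spurious-locus rates), ``qtl_gradient`` (trait QTL
    counts), ``foundation_scale`` (founder numbers), ``selection_proportion``
    (sires/dams kept) and ``nonadditive`` (dominance/epistasis proportions).
    """
    base = base_config.with_(method="KIS")
    builders = {
        "false_negative": lambda: [
            base.with_(
                false_negative_rate=r,
                weighting=w,
                scenario_id=f"fn_{int(r * 100)}_{w}",
            )
            for w in ("equal", "effect")
            for r in PERTURBATION_RATES
        ],
        "pseudo_positive": lambda: [
            base.with_(false_positive_rate=r, scenario_id=f"fp_{int(r * 100)}")
            for r in PERTURBATION_RATES
        ],
        "qtl_gradient": lambda: [
            base.with_(qtl_count_1=q1, qtl_count_2=q2, scenario_id=f"qtl_{q1}_{q2}")
            for q1, q2 in QTL_GRADIENTS
        ],
        "foundation_scale": lambda: [
            base.with_(
                founder_n=n,
                offspring_per_generation=n,
                scenario_id=f"popsize_{n}",
            )
            for n in FOUNDATION_SCALES
        ],
        "selection_proportion": lambda: [
            base.with_(n_sires=s, n_dams=d, scenario_id=f"SI_{s}_{d}")
            for s, d in SELECTION_PROPORTIONS
        ],
        "nonadditive": lambda: [
            base.with_(
                nonadditive_proportion=p,
                nonadditive_mode=m,
                scenario_id=f"nonadd_{m}_{int(p * 100)}",
            )
            for m in ("dominance", "epistasis", "both")
            for p in NONADDITIVE_PROPORTIONS
        ],
    }
    families = families or tuple(builders)
    out = {}
    for fam in families:
        if fam not in builders:
            raise ConfigurationError(f"unknown robustness family {fam!r}")
        out[fam] = run_scenario_family(builders[fam](), n_reps, master_seed)
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def _compact_letters(groups: list, separated: set[frozenset]) -> dict:
    """Insert-and-absorb compact letter display.

    ``separated`` holds the pairs declared significantly different.  Any two
    groups NOT in ``separated`` share at least one letter; any pair in it
    shares none.
    """
    columns: list[set] = [set(groups)]
    for pair in separated:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb columns that became subsets of others
        columns = [
            c
            for i, c in enumerate(columns)
            if c and not any(c < d or (c == d and i > j) for j, d in enumerate(columns))
        ]
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    # letter columns ordered by the best (highest-mean) group they contain
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in groups:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def anova_letters(
    result: pd.DataFrame,
    grouping: str = "method",
    alpha: float = 0.05,
    value: str = "mean_TBV",
    sex: str | None = None,
) -> pd.DataFrame:
    """Per-generation one-way ANOVA with Tukey HSD compact letter display.

    Rows of ``result`` are replicate records; ``grouping`` names the column
    whose levels are compared (``method`` or ``scenario_id``).  When ``sex``
    is None the male and female records of a replicate are averaged first.
    Returns a table with one row per (generation, group): the across-
    replicate mean, the ANOVA F/p for that generation, and the letter
    assignment (groups sharing a letter are not significantly different at
    ``alpha``).
    """
    df = result.copy()
    if sex is not None:
        df = df[df["sex"] == sex]
    per_rep = (
        df.groupby(["generation", grouping, "replicate"])[value].mean().reset_index()
    )
    out_rows = []
    for gen, sub in per_rep.groupby("generation", sort=False):
        groups = (
            sub.groupby(grouping)[value]
            .mean()
            .sort_values(ascending=False)
            .index.tolist()
        )
        samples = [sub.loc[sub[grouping] == g, value].to_numpy() for g in groups]
        if len(groups) < 2 or min(len(s) for s in samples) < 2:
            raise ConfigurationError(
                "ANOVA needs >= 2 groups with >= 2 replicates each"
            )
        separated: set[frozenset] = set()
        if all(np.ptp(s) == 0 for s in samples):
            # degenerate: no within-group variance; compare means exactly
            fstat, pval = np.nan, np.nan
            for a, b in itertools.combinations(range(len(groups)), 2):
                if samples[a][0] != samples[b][0]:
                    separated.add(frozenset((groups[a], groups[b])))
        else:
            fstat, pval = stats.f_oneway(*samples)
            res = stats.tukey_hsd(*samples)
            for a, b in itertools.combinations(range(len(groups)), 2):
                if res.pvalue[a, b] < alpha:
                    separated.add(frozenset((groups[a], groups[b])))
        letters = _compact_letters(groups, separated)
        for g, s in zip(groups, samples):
            out_rows.append(
                {
                    "generation": gen,
                    grouping: g,
                    "mean": float(np.mean(s)),
                    "letters": letters[g],
                    "F": float(fstat) if np.isfinite(fstat) else np.nan,
                    "p": float(pval) if np.isfinite(pval) else np.nan,
                }
            )
    return pd.DataFrame(out_rows)


def coefficient_of_variation(
    result: pd.DataFrame,
    value: str = "mean_TBV",
    by: tuple[str, str] = ("method", "generation"),
    sex: str | None = None,
) -> pd.DataFrame:
    """Across-replicate CV (sample sd / mean) per method per generation."""
    df = result.copy()
    if sex is not None:
        df = df[df["sex"] == sex]
    per_rep = df.groupby([*by, "replicate"])[value].mean().reset_index()
    if per_rep.groupby(list(by))["replicate"].count().min() < 2:
        raise ConfigurationError("CV needs >= 2 replicates")

    def _cv(x):
        m = x.mean()
        if m == 0:
            return np.nan  # undefined CV flagged as NaN
        return x.std(ddof=1) / m

    out = per_rep.groupby(list(by))[value].agg(mean="mean", sd=lambda x: x.std(ddof=1))
    out["cv"] = per_rep.groupby(list(by))[value].apply(_cv)
    return out.reset_index()
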