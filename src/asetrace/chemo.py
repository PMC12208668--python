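"""Chemotaxis-plate index, inclusion rules and condition-level statistics.

Each end-point assay plate yields counts A (worms at the attractant spot)
and C (worms at the control spot); the plate's chemotaxis index is
(A - C) / (A + C), in [-1, 1]. Plates are analysed per condition
(genotype x salt) with a fixed-effects two-way ANOVA and Dunnett
many-to-one comparisons against a reference genotype within each salt.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PlateRecord",
    "AssayResult",
    "chemotaxis_index",
    "apply_inclusion",
    "summarize_conditions",
    "dunnett_adjusted_pvalues",
    "dunnett_critical_value",
    "two_way_anova_dunnett",
    "MIN_SCORED_WORMS",
]

# A plate counts toward the assay only if at least this many worms
# reached the scoring arenas.
MIN_SCORED_WORMS = 10


def chemotaxis_index(A: int, C: int) -> float:
    """Chemotaxis index (A - C) / (A + C); undefined when A + C = 0."""
    if A < 0 or C < 0:
        raise ValueError("counts must be non-negative")
    if A + C == 0:
        raise ValueError("index undefined: no worms reached the scoring arenas")
    return float(Fraction(A - C, A + C))


@dataclass(frozen=True)
class PlateRecord:
    """One assay plate: counts, loading, and its condition key."""

    plate_id: str
    genotype: str
    salt: str
    A: int
    C: int
    n_loaded: int = 200
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.A < 0 or self.C < 0 or self.n_loaded < 0:
            raise ValueError("counts must be non-negative")
        if self.A + self.C > self.n_loaded:
            raise ValueError("scored worms exceed the number loaded")

    @property
    def n_scored(self) -> int:
        return self.A + self.C

    @property
    def included(self) -> bool:
        return self.n_scored >= MIN_SCORED_WORMS

    @property
    def index(self) -> float:
        return chemotaxis_index(self.A, self.C)


def apply_inclusion(
    plates: Sequence[PlateRecord],
    manual_exclusions: Optional[Iterable[str]] = None,
) -> Tuple[List[PlateRecord], List[Tuple[PlateRecord, str]]]:
    """Split plates into included and excluded-with-reason.

    Plates with fewer than 10 scored worms are excluded with reason
    "participation". Plates whose id appears in ``manual_exclusions``
    are excluded with reason "manual" — a deliberate, logged, user-
    supplied list (mirroring a documented scoring-error exclusion);
    outliers are never auto-detected.
    """
    manual = set(manual_exclusions or ())
    included: List[PlateRecord] = []
    excluded: List[Tuple[PlateRecord, str]] = []
    for p in plates:
        if p.plate_id in manual:
            excluded.append((p, "manual"))
        elif not p.included:
            excluded.append((p, "participation"))
        else:
            included.append(p)
    return included, excluded


def _plates_frame(plates: Sequence[PlateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plate_id": [p.plate_id for p in plates],
            "genotype": [p.genotype for p in plates],
            "salt": [p.salt for p in plates],
            "A": [p.A for p in plates],
            "C": [p.C for p in plates],
            "index": [p.index for p in plates],
        }
    )


def summarize_conditions(
    plates: Sequence[PlateRecord],
    grouping: Sequence[str] = ("genotype", "salt"),
) -> pd.DataFrame:
    """Per-condition mean index, SEM (s / sqrt(n)) and plate count.

    SEM is NaN for single-plate conditions (flagged, not imputed).
    """
    if not plates:
        raise ValueError("no plates to summarize")
    df = _plates_frame(plates)
    out = (
        df.groupby(list(grouping), sort=True)["index"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    return out


def dunnett_adjusted_pvalues(
    t_obs: np.ndarray,
    corr: np.ndarray,
    df_resid: int,
    n_sim: int = 20_000,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided Dunnett-adjusted p-values by Monte-Carlo integration.

    Samples the joint null distribution of the many-to-one t statistics
    (a multivariate t with the comparisons' correlation matrix and the
    ANOVA residual df) and returns, for each observed statistic, the
    probability that the family maximum |T| exceeds it.
    """
    from scipy.stats import multivariate_t

    t_obs = np.atleast_1d(np.asarray(t_obs, dtype=float))
    draws = multivariate_t.rvs(
        shape=corr, df=df_resid, size=n_sim, random_state=np.random.default_rng(seed)
    )
    draws = np.atleast_2d(draws)
    if draws.shape[0] != n_sim:  # single-comparison case comes back 1-D
        draws = draws.reshape(n_sim, -1)
    max_abs = np.abs(draws).max(axis=1)
    return np.array([(max_abs >= abs(t)).mean() for t in t_obs])


def dunnett_critical_value(
    n_arms: Sequence[int],
    n_control: int,
    df_resid: int,
    alpha: float = 0.05,
    n_sim: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided critical |t| controlling the FWER at ``alpha`` for
    many-to-one comparisons of the given arm sizes against one control."""
    from scipy.stats import multivariate_t

    corr = _dunnett_corr(np.asarray(n_arms, float), float(n_control))
    draws = multivariate_t.rvs(
        shape=corr, df=df_resid, size=n_sim, random_state=np.random.default_rng(seed)
    )
    draws = np.atleast_2d(draws)
    if draws.shape[0] != n_sim:
        draws = draws.reshape(n_sim, -1)
    max_abs = np.abs(draws).max(axis=1)
    return float(np.quantile(max_abs, 1.0 - alpha))


def _dunnett_corr(n_arms: np.ndarray, n_control: float) -> np.ndarray:
    """Correlation of many-to-one t statistics sharing one control group."""
    k = len(n_arms)
    var = 1.0 / n_arms + 1.0 / n_control
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = 1.0 if i == j else (1.0 / n_control) / np.sqrt(var[i] * var[j])
    return corr


@dataclass
class AssayResult:
    """Condition summaries, ANOVA table and Dunnett comparisons."""

    summary: pd.DataFrame  # genotype, salt, mean, sem, n
    anova: pd.DataFrame  # statsmodels anova_lm table
    comparisons: pd.DataFrame  # salt, genotype, estimate, t, p_adj, significant
    excluded: List[Tuple[PlateRecord, str]]


def two_way_anova_dunnett(
    plates: Sequence[PlateRecord],
    reference_level: str = "wildtype",
    alpha: float = 0.05,
    interaction: bool = True,
    manual_exclusions: Optional[Iterable[str]] = None,
    n_sim: int = 20_000,
    seed: int = 0,
) -> AssayResult:
    """Two-way fixed-effects ANOVA on plate indices with Dunnett post hoc.

    Factors are genotype and salt (interaction included by default).
    Within each salt, every genotype is compared against
    ``reference_level`` with many-to-one t statistics pooled on the
    ANOVA residual mean square; the family-wise adjustment uses the
    seeded Monte-Carlo multivariate-t evaluation.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    included, excluded = apply_inclusion(plates, manual_exclusions)
    if not included:
        raise ValueError("no plates pass the inclusion filter")
    df = _plates_frame(included)

    genotypes = sorted(df["genotype"].unique())
    salts = sorted(df["salt"].unique())
    if reference_level not in genotypes:
        raise ValueError(f"reference level {reference_level!r} absent from the data")
    if len(genotypes) < 2 or len(salts) < 2:
        raise ValueError("two-way ANOVA needs at least 2 levels per factor")
    for g in genotypes:
        for s in salts:
            if ((df["genotype"] == g) & (df["salt"] == s)).sum() == 0:
                raise ValueError(f"singular design: empty cell (genotype={g}, salt={s})")

    formula = "ci ~ C(genotype) * C(salt)" if interaction else "ci ~ C(genotype) + C(salt)"
    # restrict to model columns: the plate frame's "C" count column would
    # shadow the categorical operator in the formula
    model_df = df[["genotype", "salt"]].assign(ci=df["index"].to_numpy())
    fit = smf.ols(formula, data=model_df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    mse = float(fit.mse_resid)
    df_resid = int(fit.df_resid)
    if np.ptp(model_df["ci"].to_numpy()) == 0.0:
        # all indices identical: every sum of squares is 0 and the F
        # ratios are 0/0 float dust; report the no-evidence limit
        anova.loc[anova["F"].notna(), "PR(>F)"] = 1.0
        anova.loc[anova["F"].notna(), "F"] = 0.0
        mse = 0.0

    rows = []
    others = [g for g in genotypes if g != reference_level]
    for s_i, s in enumerate(salts):
        sub = df[df["salt"] == s]
        ref = sub[sub["genotype"] == reference_level]["index"]
        n0, m0 = len(ref), float(ref.mean())
        t_stats, estimates, n_arms = [], [], []
        for g in others:
            grp = sub[sub["genotype"] == g]["index"]
            est = float(grp.mean()) - m0
            # all-equal data gives mse = 0; define t = 0 there (no evidence)
            se = np.sqrt(mse * (1.0 / len(grp) + 1.0 / n0))
            t_stats.append(est / se if se > 0 else 0.0)
            estimates.append(est)
            n_arms.append(len(grp))
        if mse > 0:
            corr = _dunnett_corr(np.asarray(n_arms, float), float(n0))
            p_adj = dunnett_adjusted_pvalues(
                np.asarray(t_stats), corr, df_resid, n_sim=n_sim, seed=seed + s_i
            )
        else:
            p_adj = np.ones(len(others))
        for g, est, t, p in zip(others, estimates, t_stats, p_adj):
            rows.append(
                {
                    "salt": s,
                    "genotype": g,
                    "reference": reference_level,
                    "estimate": est,
                    "t": t,
                    "p_adj": float(p),
                    "significant": bool(p < alpha),
                }
            )

    return AssayResult(
        summary=summarize_conditions(included),
        anova=anova,
        comparisons=pd.DataFrame(rows),
        excluded=excluded,
    )
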