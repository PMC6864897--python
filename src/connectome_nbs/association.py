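"""Follow-up association tests on sub-network connectivity scores.

Three analyses: (1) genotype x sex interaction on per-subject mean
sub-network connectivity; (2) re-tests of the group effect in sex-matched or
single-sex subsamples; (3) partial Pearson correlations between sub-network
connectivity and behavioral scores (ERQ reappraisal/suppression, SRRS)
controlling for age, sex and acquisition site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .datatypes import CohortDesign, ConnectivityMatrix
from .nbs import NBSComponent
from .netchar import subnetwork_mean_connectivity

__all__ = [
    "AssociationResult",
    "interaction_test",
    "sex_matched_retest",
    "partial_correlation",
]


@dataclass
class AssociationResult:
    """One association test's outcome with the exact n and covariates
    used."""

    name: str
    statistic: float
    stat_name: str  # "F" or "t"
    p: float
    n: int
    covariates: tuple[str, ...]
    r: float | None = None  # partial correlation where applicable
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r is not None and not -1 <= self.r <= 1:
            raise ValueError("correlation must lie in [-1, 1]")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")


def _merge_scores(scores: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    merged = design.table.merge(scores[["subject_id", "score"]],
                                on="subject_id", how="inner")
    if len(merged) != len(scores):
        raise ValueError("scores contain subjects absent from the design")
    return merged


def interaction_test(
    scores: pd.DataFrame, design: CohortDesign
) -> AssociationResult:
    """Genotype x sex interaction on mean sub-network connectivity.

    Fits ``score ~ group + sex + group:sex + age + site`` by OLS and reports
    the F (= t^2, 1 df) and p of the interaction term. Requires every
    group x sex cell to be populated.
    """
    df = _merge_scores(scores, design)
    cells = df.groupby(["group", "sex"]).size()
    expected = [(g, s) for g in df["group"].unique()
                for s in df["sex"].unique()]
    empty = [c for c in expected if c not in cells.index]
    if empty:
        raise ValueError(f"empty group x sex cell(s): {empty}")
    model = smf.ols(
        "score ~ C(group) * C(sex) + age + C(site)", data=df).fit()
    term = [t for t in model.params.index if ":" in t]
    if len(term) != 1:
        raise RuntimeError(f"expected one interaction term, got {term}")
    t_val = float(model.tvalues[term[0]])
    return AssociationResult(
        name="group_x_sex_interaction",
        statistic=t_val**2, stat_name="F",
        p=float(model.pvalues[term[0]]),
        n=len(df), covariates=("age", "site"),
        extra={"term": term[0]},
    )


def _matched_subsample(
    df: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomly down-sample so both groups share the same male fraction.

    The group with the higher male fraction has males dropped (and likewise
    for females in the other group) until the male:female ratios match the
    more balanced group as closely as integer counts allow.
    """
    parts = []
    fracs = df.groupby("group")["sex"].apply(lambda s: (s == "M").mean())
    target = fracs.min()
    for grp, sub in df.groupby("group"):
        males = sub[sub["sex"] == "M"]
        females = sub[sub["sex"] == "F"]
        if len(females) == 0 or len(males) == 0:
            parts.append(sub)
            continue
        # keep n_m males so that n_m / (n_m + n_f) ~= target
        n_m = min(len(males),
                  int(round(target / (1 - target) * len(females))))
        keep = rng.choice(males.index.to_numpy(), size=n_m, replace=False)
        parts.append(pd.concat([males.loc[np.sort(keep)], females]))
    return pd.concat(parts).sort_index()


def sex_matched_retest(
    matrices: list[ConnectivityMatrix],
    design: CohortDesign,
    component: NBSComponent,
    strategy: str = "matched-subsample",
    seed: int = 0,
    min_per_group: int = 10,
) -> AssociationResult:
    """Re-test the group effect on mean component connectivity in a
    sex-restricted subsample.

    ``strategy`` is one of ``matched-subsample`` (seeded random
    down-sampling to equal male fractions across groups), ``male-only`` or
    ``female-only``. The subsample is analysed by OLS with the remaining
    covariates; sex is dropped as a covariate in single-sex strata.
    """
    strategies = ("matched-subsample", "male-only", "female-only")
    if strategy not in strategies:
        raise ValueError(f"strategy must be one of {strategies}")
    scores = subnetwork_mean_connectivity(matrices, component)
    df = _merge_scores(scores, design)
    rng = np.random.default_rng(seed)
    if strategy == "male-only":
        sub = df[df["sex"] == "M"]
    elif strategy == "female-only":
        sub = df[df["sex"] == "F"]
    else:
        sub = _matched_subsample(df, rng)
    counts = sub.groupby("group").size()
    if len(counts) < 2 or counts.min() < min_per_group:
        raise ValueError(
            f"subsample too small for strategy {strategy!r}: "
            f"{counts.to_dict()} (need >= {min_per_group} per group)")
    sex_term = " + C(sex)" if sub["sex"].nunique() > 1 else ""
    covs = ("age", "site") + (("sex",) if sex_term else ())
    model = smf.ols(f"score ~ C(group) + age + C(site){sex_term}",
                    data=sub).fit()
    term = [t for t in model.params.index if t.startswith("C(group)")]
    t_val = float(model.tvalues[term[0]])
    return AssociationResult(
        name=f"group_effect_{strategy}",
        statistic=t_val, stat_name="t",
        p=float(model.pvalues[term[0]]),
        n=len(sub), covariates=covs,
        extra={"strategy": strategy, "seed": seed,
               "group_coefficient": float(model.params[term[0]])},
    )


def partial_correlation(
    scores: pd.DataFrame,
    behavioral: str,
    design: CohortDesign,
    covariates: tuple[str, ...] = ("age", "sex", "site"),
) -> AssociationResult:
    """Partial Pearson correlation between sub-network connectivity and a
    behavioral score, controlling for covariates.

    Both variables are residualized on [intercept | covariates] (factors
    dummy-coded); r is the Pearson correlation of the residuals and p comes
    from the t transform with ``df = n - 2 - k`` where k counts all
    residualized regressor columns. Missing behavioral values are dropped
    listwise.
    """
    df = _merge_scores(scores, design)
    if behavioral not in df.columns:
        raise ValueError(f"behavioral column {behavioral!r} not in design")
    complete = df.dropna(subset=[behavioral, "score"]).reset_index(drop=True)
    n = len(complete)
    sub_design = CohortDesign(complete[design.table.columns])
    z, cov_names = sub_design.covariate_matrix(covariates)
    k = z.shape[1]
    if n < k + 5:
        raise ValueError(
            f"only {n} complete cases for {k} covariates (need >= {k + 5})")
    x = np.hstack([np.ones((n, 1)), z])
    y1 = complete["score"].to_numpy(float)
    y2 = complete[behavioral].to_numpy(float)
    beta1, *_ = np.linalg.lstsq(x, y1, rcond=None)
    beta2, *_ = np.linalg.lstsq(x, y2, rcond=None)
    r1, r2 = y1 - x @ beta1, y2 - x @ beta2
    r = float(np.corrcoef(r1, r2)[0, 1])
    dof = n - 2 - k
    t_val = r * np.sqrt(dof / max(1e-300, 1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t_val), dof))
    return AssociationResult(
        name=f"partial_corr_{behavioral}",
        statistic=float(t_val), stat_name="t",
        p=min(max(p, np.finfo(float).tiny), 1.0),
        n=n, covariates=tuple(cov_names), r=r,
        extra={"df": int(dof), "behavioral": behavioral,
               "n_dropped": int(len(df) - n)},
    )
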