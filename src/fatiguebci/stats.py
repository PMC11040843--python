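"""Session-level statistics: reliability, repeated-measures correlation,
linear mixed models, and questionnaire composite binning.

The study design is a three-session crossover (motor-imagery BCI, P300 BCI,
video control) with pre/post measurements of two primary outcomes —
self-reported fatigue on a 0-10 visual analog scale (VASF) and resting-state
alpha band power.  This module provides:

* absolute reliability from test-retest pairs — the standard error of
  measurement SEM = SD(differences)/sqrt(2) and the minimum detectable
  change MDC95 = 1.96 * sqrt(2) * SEM;
* the repeated-measures correlation (common within-participant association,
  estimated by analysis of covariance with participant as a factor and a
  shared slope);
* the mixed-model contract — REML linear mixed models with participant
  random intercepts, omnibus F tests per fixed term, estimated marginal
  means per cell, AIC, and Holm-corrected post-hoc contrasts;
* the composite bins used as factors in secondary models (motivation,
  workload, discomfort, age-group median split).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ReliabilityResult",
    "RmcorrResult",
    "LmmResult",
    "sem_from_pairs",
    "mdc_from_sem",
    "rmcorr",
    "fit_lmm",
    "composite_bins",
    "assign_age_groups",
    "holm_adjust",
]


# ---------------------------------------------------------------------------
# reliability


@dataclass
class ReliabilityResult:
    """Absolute reliability of an outcome, in the outcome's units."""

    sem: float
    mdc95: float

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM cannot be negative")
        if self.mdc95 < self.sem - 1e-12:
            raise ValueError("MDC95 cannot be smaller than the SEM")


def mdc_from_sem(sem: float, level: float = 0.95) -> float:
    """Minimum detectable change at the given confidence level.

    MDC = z * sqrt(2) * SEM, with z the two-sided normal quantile
    (1.96 at 95%)."""
    z = spstats.norm.ppf(0.5 + level / 2)
    return float(z * math.sqrt(2.0) * sem)


def sem_from_pairs(test, retest) -> ReliabilityResult:
    """SEM and MDC95 from test-retest pairs (difference-score method).

    SEM = SD(test - retest) / sqrt(2); MDC95 = 1.96 * sqrt(2) * SEM.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape:
        raise ValueError(
            f"test and retest must have equal length (got {test.shape} vs {retest.shape})"
        )
    if test.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = test - retest
    sem = float(np.std(diffs, ddof=1) / math.sqrt(2.0))
    return ReliabilityResult(sem=sem, mdc95=mdc_from_sem(sem, 0.95))


# ---------------------------------------------------------------------------
# repeated-measures correlation


@dataclass
class RmcorrResult:
    """Common within-participant correlation."""

    r: float
    dof: int
    p: float
    n_participants: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")


def rmcorr(records: pd.DataFrame, x: str, y: str,
           participant: str = "participant") -> RmcorrResult:
    """Repeated-measures correlation via the analysis-of-covariance formulation.

    Fits a common slope of ``y`` on ``x`` with participant as a factor
    (per-participant intercepts).  Writing x̃, ỹ for the within-participant
    centered variables, r = sign(Σx̃ỹ) * sqrt(SS_reg / (SS_reg + SS_err))
    with SS_reg = (Σx̃ỹ)²/Σx̃²; dof = N_obs - N_participants - 1.

    Participants with fewer than two complete (x, y) pairs are dropped with
    a logged warning; if none remain the call is invalid.
    """
    df = records[[participant, x, y]].dropna()
    counts = df.groupby(participant).size()
    keep = counts[counts >= 2].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.warning(
            "rmcorr: dropping %d participant(s) with < 2 observations: %s",
            len(dropped), dropped,
        )
    df = df[df[participant].isin(keep)]
    k = df[participant].nunique()
    n = len(df)
    if k < 2 or n - k - 1 < 1:
        raise ValueError("rmcorr needs >= 2 participants with >= 2 observations each")
    xc = df[x] - df.groupby(participant)[x].transform("mean")
    yc = df[y] - df.groupby(participant)[y].transform("mean")
    sxy = float((xc * yc).sum())
    sxx = float((xc**2).sum())
    syy = float((yc**2).sum())
    if sxx == 0 or syy == 0:
        raise ValueError("rmcorr is undefined: no within-participant variance")
    ss_reg = sxy**2 / sxx
    ss_err = syy - ss_reg
    r = math.copysign(math.sqrt(ss_reg / (ss_reg + ss_err)), sxy)
    dof = n - k - 1
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(dof / (1.0 - r**2))
        p = float(2 * spstats.t.sf(abs(t), dof))
    return RmcorrResult(r=r, dof=dof, p=p, n_participants=k)


# ---------------------------------------------------------------------------
# linear mixed models


@dataclass
class LmmResult:
    """REML mixed-model fit with participant random intercepts.

    ``fixed_effects`` maps each fixed term to its omnibus test
    (``estimate`` is the term's coefficient for 1-df terms, NaN otherwise);
    ``emm`` maps factor-level cells (tuples) to estimated marginal means
    with 95% CIs; ``posthoc`` holds Holm-corrected pairwise cell contrasts.
    """

    fixed_effects: dict
    coefficients: dict
    emm: dict
    posthoc: pd.DataFrame
    aic: float
    n_obs: int
    n_groups: int

    def _term_entry(self, term: str) -> dict:
        if term in self.fixed_effects:
            return self.fixed_effects[term]
        matches = [
            k for k in self.fixed_effects
            if term in k and k.count(":") == term.count(":")
        ]
        if len(matches) != 1:
            raise KeyError(
                f"term {term!r} matches {matches or 'nothing'} among "
                f"{list(self.fixed_effects)}"
            )
        return self.fixed_effects[matches[0]]

    def term_f(self, term: str) -> float:
        return self._term_entry(term)["F"]

    def term_p(self, term: str) -> float:
        return self._term_entry(term)["p"]

    def coef(self, substring: str) -> float:
        """The single fixed-effect coefficient whose name contains ``substring``."""
        matches = [k for k in self.coefficients if substring in k]
        if len(matches) != 1:
            raise KeyError(f"{substring!r} matches {matches or 'nothing'}")
        return self.coefficients[matches[0]]


def _term_names(design_info) -> list[str]:
    return [t for t in design_info.term_names if t != "Intercept"]


def fit_lmm(
    records: pd.DataFrame,
    outcome: str,
    fixed_terms: tuple[str, ...] = ("session", "time"),
    interaction: bool = True,
    groups: str = "participant",
    emm_factors: tuple[str, ...] | None = None,
) -> LmmResult:
    """Fit ``outcome ~ fixed_terms`` with participant random intercepts (REML).

    Categorical terms are wrapped in ``C()``; ``interaction=True`` adds all
    pairwise interactions of the listed terms (the study's primary models
    use ``session * time``).  Rows with missing outcome or terms are
    omitted (no imputation).  Omnibus F statistics per term are Wald tests
    on the term's coefficients with a residual-style denominator dof
    (N_obs - rank(X) - N_groups + 1); estimated marginal means are
    model predictions per factor cell averaged over the reference grid of
    the remaining terms; pairwise cell contrasts are Holm-corrected.
    """
    cols = [groups, outcome, *fixed_terms]
    df = records[cols].dropna().copy()
    if df[groups].nunique() < 2:
        raise ValueError("need >= 2 participants")
    wrapped = []
    for t in fixed_terms:
        if pd.api.types.is_numeric_dtype(df[t]):
            wrapped.append(t)
        elif set(df[t].unique()) == {"pre", "post"}:
            # anchor pre/post factors at 'pre' so the coefficient is the
            # pre-to-post shift
            wrapped.append(f"C({t}, Treatment('pre'))")
        else:
            wrapped.append(f"C({t})")
    rhs = " * ".join(wrapped) if interaction and len(wrapped) > 1 else " + ".join(wrapped)
    formula = f"{outcome} ~ {rhs}"
    model = smf.mixedlm(formula, df, groups=df[groups])
    res = None
    last_err = None
    for method in ("lbfgs", "cg", "powell"):
        try:
            res = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError as err:
            last_err = err
    if res is None:
        raise ValueError(
            f"singular design for terms {fixed_terms}: {last_err}"
        ) from None

    design_info = model.data.design_info
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    n_obs = len(df)
    n_groups = df[groups].nunique()
    ddf = max(n_obs - rank - n_groups + 1, 1)

    k_fe = len(res.fe_params)
    cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]
    fe = np.asarray(res.fe_params)
    coef_names = list(design_info.column_names)

    fixed_effects = {}
    for term in _term_names(design_info):
        sl = design_info.term_name_slices[term]
        idx = list(range(sl.start, sl.stop))
        L = np.zeros((len(idx), len(coef_names)))
        for r_, c_ in enumerate(idx):
            L[r_, c_] = 1.0
        est = fe[idx]
        V = cov_fe[np.ix_(idx, idx)]
        chi2 = float(est @ np.linalg.solve(V, est))
        q = len(idx)
        F = chi2 / q
        p = float(spstats.f.sf(F, q, ddf))
        fixed_effects[term] = {
            "estimate": float(est[0]) if q == 1 else float("nan"),
            "F": F,
            "df_num": q,
            "df_den": ddf,
            "p": p,
        }

    coefficients = dict(zip(coef_names, map(float, fe)))

    # --- estimated marginal means over factor cells
    if emm_factors is None:
        emm_factors = tuple(
            t for t in fixed_terms if not pd.api.types.is_numeric_dtype(df[t])
        )
    emm: dict = {}
    rows_for_cells: list[tuple[tuple, np.ndarray]] = []
    if emm_factors:
        from patsy import build_design_matrices

        levels = {t: sorted(df[t].unique()) for t in emm_factors}
        others = [t for t in fixed_terms if t not in emm_factors]
        other_levels = {t: sorted(df[t].unique()) for t in others}
        for cell in itertools.product(*(levels[t] for t in emm_factors)):
            grid = {t: v for t, v in zip(emm_factors, cell)}
            rows = []
            combos = (
                itertools.product(*(other_levels[t] for t in others))
                if others else [()]
            )
            for combo in combos:
                point = dict(grid)
                point.update({t: v for t, v in zip(others, combo)})
                (row,) = build_design_matrices(
                    [design_info], {k: [v] for k, v in point.items()}
                )
                rows.append(np.asarray(row)[0])
            xrow = np.mean(rows, axis=0)
            mean = float(xrow @ fe)
            se = float(np.sqrt(xrow @ cov_fe @ xrow))
            z = spstats.norm.ppf(0.975)
            emm[cell] = {
                "mean": mean,
                "se": se,
                "ci_low": mean - z * se,
                "ci_high": mean + z * se,
            }
            rows_for_cells.append((cell, xrow))

    # --- Holm-corrected pairwise contrasts between cells
    contrasts = []
    for (c1, x1), (c2, x2) in itertools.combinations(rows_for_cells, 2):
        d = x1 - x2
        est = float(d @ fe)
        se = float(np.sqrt(d @ cov_fe @ d))
        if se == 0:
            continue
        t = est / se
        praw = float(2 * spstats.t.sf(abs(t), ddf))
        contrasts.append({"cell_a": c1, "cell_b": c2, "estimate": est,
                          "se": se, "t": t, "p_raw": praw})
    posthoc = pd.DataFrame(contrasts)
    if len(posthoc):
        posthoc["p_holm"] = holm_adjust(posthoc["p_raw"].to_numpy())

    llf = float(res.llf)
    n_params = k_fe + 1 + 1  # fixed effects + random-intercept variance + residual
    aic = -2 * llf + 2 * n_params
    return LmmResult(
        fixed_effects=fixed_effects,
        coefficients=coefficients,
        emm=emm,
        posthoc=posthoc,
        aic=aic,
        n_obs=n_obs,
        n_groups=n_groups,
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (weakly larger than raw, monotone)."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="holm")[1]


# ---------------------------------------------------------------------------
# composite bins


MOTIVATION_RANGE = (0.0, 50.0)
WORKLOAD_RANGE = (0.0, 100.0)
PAIN_RANGE = (0, 5)
WORKLOAD_BINS = ("0-24", "25-49", "50-74", "75-100")


def _check_range(name: str, values: pd.Series, lo: float, hi: float) -> None:
    bad = values[(values < lo) | (values > hi)]
    if len(bad):
        raise ValueError(
            f"{name} out of legal range [{lo}, {hi}]: {bad.tolist()[:5]}"
        )


def composite_bins(records: pd.DataFrame) -> pd.DataFrame:
    """Bin questionnaire composites into the study's categorical groups.

    * motivation (0-50 scale): lower (26-35) vs higher (36-45) group —
      scores below the observed 26-45 range fall in *lower*, above in
      *higher* (threshold at 36);
    * workload (0-100 scale, performance item already excluded from the
      total): ordinal quartile bins 0-24 / 25-49 / 50-74 / 75-100;
    * pain (0-5): low-to-no discomfort (0-2) vs higher discomfort (3-5).

    Returns a copy with ``motivation_group``, ``workload_group`` and
    ``pain_group`` columns added.
    """
    df = records.copy()
    _check_range("motivation_total", df["motivation_total"], *MOTIVATION_RANGE)
    _check_range("workload_total", df["workload_total"], *WORKLOAD_RANGE)
    _check_range("pain", df["pain"], *PAIN_RANGE)
    df["motivation_group"] = np.where(df["motivation_total"] >= 36, "higher", "lower")
    df["workload_group"] = pd.cut(
        df["workload_total"],
        bins=[-0.001, 24.999, 49.999, 74.999, 100.0],
        labels=WORKLOAD_BINS,
    ).astype(str)
    df["pain_group"] = np.where(df["pain"] >= 3, "higher", "low/no")
    return df


def assign_age_groups(records: pd.DataFrame, age_col: str = "age",
                      participant: str = "participant") -> pd.DataFrame:
    """Median split of the cohort into younger/older halves by date of birth
    (equivalently, by age at enrollment)."""
    df = records.copy()
    per_part = df.drop_duplicates(participant).set_index(participant)[age_col]
    median = per_part.median()
    group = {p: ("younger" if a < median else "older") for p, a in per_part.items()}
    df["age_group"] = df[participant].map(group)
    return df
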