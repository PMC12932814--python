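"""Statistical evaluation of the three sensitivity tests.

The evaluation follows a fixed recipe per variable: a 4-way fixed-effects
ANOVA with main effects and first-level (two-way) interactions, pairwise
Fisher LSD comparisons only when the preceding F-test is significant
(protected LSD), and Cohen's d for the two-level contrast of interest.
The significance threshold is p < 0.01 throughout.

The stage is organised as a model/results pair: :class:`SensitivityAnova`
is built from a feature table joined to the experimental design, and its
:meth:`~SensitivityAnova.fit` returns a :class:`SensitivityResults` object
carrying per-variable F/p, effect sizes, interaction flags and LSD tables,
with a ``summary()`` table per sensitivity test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .design import DesignTable, SENSITIVITY_TESTS, sensitivity_subset
from .synthesis import VARIABLES

ALPHA = 0.01

#: interaction-flag letters used in the summary tables
FACTOR_LETTERS = {"day": "d", "batch": "b", "blending": "p",
                  "host_tree": "h", "subspecies": "s"}


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary pieces


def cohens_d(group_a, group_b) -> float:
    """Standardised mean difference (mean_a - mean_b) / pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise StatsError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def effect_size_label(d: float) -> str:
    """Conventional magnitude labels: small 0.2, medium 0.5, large 0.8."""
    m = abs(d)
    if m >= 0.8:
        return "large"
    if m >= 0.5:
        return "medium"
    if m >= 0.2:
        return "small"
    return "negligible"


def significance_stars(p: float) -> str:
    """* p<0.01, ** p<0.001, *** p<0.0001."""
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationFilterReport:
    correlation: pd.DataFrame
    kept: tuple
    dropped: dict  # variable -> offending partner
    threshold: float = 0.7

    def __post_init__(self):
        sub = self.correlation.loc[list(self.kept), list(self.kept)].to_numpy()
        off = sub[~np.eye(len(self.kept), dtype=bool)]
        if len(off) and np.nanmax(np.abs(off)) > self.threshold + 1e-12:
            raise StatsError("kept set still contains an offending pair")


def correlation_filter(features: pd.DataFrame, candidates: "list[str] | None" = None,
                       threshold: float = 0.7) -> CorrelationFilterReport:
    """Greedy Pearson-correlation pruning of the candidate variable pool.

    While any kept pair exceeds |r| > threshold, the member of the
    highest-|r| pair with the larger mean |r| to all other kept variables
    is dropped.  Constant columns (undefined correlation) are dropped with
    a warning before filtering.
    """
    if candidates is None:
        candidates = [c for c in features.columns if c != "plate_id"
                      and pd.api.types.is_numeric_dtype(features[c])]
    missing = [c for c in candidates if c not in features.columns]
    if missing:
        raise StatsError(f"candidate variables not in table: {missing}")
    if len(features) < 3:
        raise StatsError("need at least 3 observations")

    dropped = {}
    kept = list(candidates)
    for c in list(kept):
        if features[c].nunique() <= 1:
            warnings.warn(f"constant column {c!r} dropped (correlation undefined)",
                          stacklevel=2)
            kept.remove(c)
            dropped[c] = "<constant>"
    corr = features[kept].corr(method="pearson")

    def offending():
        best = None
        for a, b in itertools.combinations(kept, 2):
            r = abs(corr.loc[a, b])
            if r > threshold and (best is None or r > best[0]):
                best = (r, a, b)
        return best

    while True:
        off = offending()
        if off is None:
            break
        _, a, b = off
        def mean_abs(v):
            others = [u for u in kept if u != v]
            return corr.loc[v, others].abs().mean() if others else 0.0
        victim, partner = (a, b) if mean_abs(a) >= mean_abs(b) else (b, a)
        kept.remove(victim)
        dropped[victim] = partner

    full_corr = features[[c for c in candidates if c in corr.columns]].corr()
    return CorrelationFilterReport(correlation=full_corr, kept=tuple(kept),
                                   dropped=dropped, threshold=threshold)


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    df: float
    sum_sq: float
    mean_sq: float
    F: float
    p: float


def _check_aliasing(data: pd.DataFrame, factors: list) -> None:
    for f in factors:
        if data[f].nunique() < 2:
            raise StatsError(f"factor {f!r} has fewer than 2 levels")
    for a, b in itertools.combinations(factors, 2):
        na, nb = data[a].nunique(), data[b].nunique()
        if na == nb and (data.groupby(a)[b].nunique() == 1).all():
            raise StatsError(
                f"factors {a!r} and {b!r} are aliased; exclude one before fitting"
            )


def fit_anova(data: pd.DataFrame, response: str, factors: list,
              typ: int = 2) -> list:
    """Fixed-effects factorial ANOVA: main effects + two-way interactions.

    Sum-to-zero factor coding; Type-II sums of squares by default (equal
    to Type I on balanced layouts, appropriate for the unbalanced pooled
    contrasts).  A zero-residual fit reports F as +inf with p = 0 for
    effects carrying positive sum of squares.
    """
    if response not in data.columns:
        raise StatsError(f"response {response!r} not in data")
    _check_aliasing(data, factors)
    terms = [f"C({f}, Sum)" for f in factors]
    inters = [f"{a}:{b}" for a, b in itertools.combinations(terms, 2)]
    formula = f"Q('{response}') ~ " + " + ".join(terms + inters)
    model = smf.ols(formula, data=data).fit()
    if model.df_resid < 1:
        raise StatsError("residual degrees of freedom < 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=typ)

    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = float(table.loc["Residual", "df"])
    total_ss = float(table["sum_sq"].sum())
    degenerate = resid_ss <= 1e-12 * max(total_ss, 1.0)

    def clean_name(term: str) -> str:
        return (term.replace(", Sum)", ")").replace("C(", "")
                .replace(")", "").replace(":", ":"))

    effects = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        ss, df = float(row["sum_sq"]), float(row["df"])
        if degenerate:
            F = math.inf if ss > 1e-12 * max(total_ss, 1.0) else 0.0
            p = 0.0 if math.isinf(F) else 1.0
        else:
            F, p = float(row["F"]), float(row["PR(>F)"])
        effects.append(AnovaEffect(name=clean_name(term), df=df, sum_sq=ss,
                                   mean_sq=ss / df, F=F, p=p))
    effects.append(AnovaEffect(name="Residual", df=resid_df, sum_sq=resid_ss,
                               mean_sq=resid_ss / resid_df if resid_df else math.nan,
                               F=math.nan, p=math.nan))
    return effects


def protected_lsd(data: pd.DataFrame, anova: list, response: str, factor: str,
                  alpha: float = ALPHA) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons, gated by the F-test (protection).

    Returns an empty table when the factor's F-test p >= alpha; otherwise
    every level pair is compared by t = (mean_i - mean_j) /
    sqrt(MSE * (1/n_i + 1/n_j)) on the residual degrees of freedom.
    """
    effect = next((e for e in anova if e.name == factor), None)
    if effect is None:
        raise StatsError(f"factor {factor!r} absent from the fitted model")
    resid = next(e for e in anova if e.name == "Residual")
    cols = ["level_a", "level_b", "mean_diff", "t", "p"]
    if not (effect.p < alpha):
        return pd.DataFrame(columns=cols)
    mse, dof = resid.mean_sq, resid.df
    groups = data.groupby(factor)[response]
    means, ns = groups.mean(), groups.size()
    rows = []
    for a, b in itertools.combinations(sorted(means.index, key=str), 2):
        diff = means[a] - means[b]
        se = math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        t = diff / se if se > 0 else math.inf * np.sign(diff)
        p = 2.0 * sps.t.sf(abs(t), dof) if math.isfinite(t) else 0.0
        rows.append({"level_a": a, "level_b": b, "mean_diff": diff,
                     "t": t, "p": p})
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# model / results


class SensitivityAnova:
    """One sensitivity test on a feature table joined to the design.

    Parameters
    ----------
    features : DataFrame with ``plate_id`` and the analysis variables.
    design : DesignTable of the full Verum run.
    test_id : one of ``subspecies``, ``deciduous``, ``blending``.
    alpha : significance threshold (default 0.01).
    """

    def __init__(self, features: pd.DataFrame, design: DesignTable,
                 test_id: str, alpha: float = ALPHA,
                 variables: "tuple | None" = None):
        if test_id not in SENSITIVITY_TESTS:
            raise StatsError(f"unknown sensitivity test {test_id!r}")
        subset, spec = sensitivity_subset(design, test_id)
        data = subset.frame.merge(features, on="plate_id", how="inner")
        if len(data) != len(subset):
            raise StatsError("feature table does not cover the design subset")
        self.data = data
        self.test_id = test_id
        self.alpha = alpha
        self.factor_of_interest = spec["factor_of_interest"]
        # nuisance factors with a single level in the data (e.g. day in a
        # one-day run) cannot enter the model; drop them with a warning
        factors = []
        for f in spec["factors"]:
            if data[f].nunique() < 2:
                if f == self.factor_of_interest:
                    raise StatsError(
                        f"factor of interest {f!r} has fewer than 2 levels")
                warnings.warn(f"dropping single-level factor {f!r} from the "
                              f"{test_id} model", stacklevel=2)
            else:
                factors.append(f)
        self.factors = factors
        self.contrast = spec["contrast"]
        self.variables = tuple(variables) if variables is not None else tuple(
            v for v in VARIABLES if v in features.columns)
        if not self.variables:
            raise StatsError("no analysis variables present in the feature table")

    @classmethod
    def from_dataframes(cls, features: pd.DataFrame, design: pd.DataFrame,
                        test_id: str, **kw) -> "SensitivityAnova":
        return cls(features, DesignTable(design), test_id, **kw)

    def fit(self) -> "SensitivityResults":
        foi = self.factor_of_interest
        level_a, level_b = self.contrast
        per_variable = {}
        for var in self.variables:
            anova = fit_anova(self.data, var, self.factors)
            by = {e.name: e for e in anova}
            main = by[foi]
            # interaction flags: first-level interactions involving the
            # factor of interest, encoded by the partner factor's letter
            flags = ""
            for other in self.factors:
                if other == foi:
                    continue
                inter = by.get(f"{other}:{foi}") or by.get(f"{foi}:{other}")
                if inter is not None and inter.p < self.alpha:
                    flags += FACTOR_LETTERS[other]
            a_vals = self.data.loc[self.data[foi] == level_a, var]
            b_vals = self.data.loc[self.data[foi] == level_b, var]
            d = cohens_d(a_vals, b_vals)
            lsd = protected_lsd(self.data, anova, var, foi, self.alpha)
            drill = None
            if "d" in flags:
                drill = self._per_day_contrast(var)
            per_variable[var] = VariableResult(
                variable=var, anova=tuple(anova), p=main.p, F=main.F,
                effect_size=d, interactions=flags, lsd=lsd, per_day=drill,
            )
        return SensitivityResults(model=self, per_variable=per_variable)

    def _per_day_contrast(self, var: str) -> pd.DataFrame:
        """Pairwise contrast of interest within each experimental day;
        run when a day interaction is flagged."""
        foi = self.factor_of_interest
        level_a, level_b = self.contrast
        rows = []
        for day, grp in self.data.groupby("day"):
            a = grp.loc[grp[foi] == level_a, var]
            b = grp.loc[grp[foi] == level_b, var]
            t, p = sps.ttest_ind(a, b, equal_var=True)
            rows.append({"day": day, "mean_diff": a.mean() - b.mean(),
                         "t": float(t), "p": float(p),
                         "significant": bool(p < self.alpha)})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariableResult:
    variable: str
    anova: tuple
    p: float
    F: float
    effect_size: float
    interactions: str
    lsd: pd.DataFrame
    per_day: "pd.DataFrame | None" = None


@dataclass(frozen=True)
class SensitivityResults:
    """Fitted per-variable results of one sensitivity test."""

    model: SensitivityAnova
    per_variable: dict = field(default_factory=dict)

    def __getitem__(self, var: str) -> VariableResult:
        return self.per_variable[var]

    @property
    def effect_sizes(self) -> dict:
        return {v: r.effect_size for v, r in self.per_variable.items()}

    def summary(self) -> pd.DataFrame:
        """Per-test summary table: variable, p, stars, |d|, interactions."""
        rows = []
        for var, r in self.per_variable.items():
            rows.append({
                "variable": var,
                "p": r.p,
                "stars": significance_stars(r.p),
                "effect_size": abs(r.effect_size),
                "effect_label": effect_size_label(r.effect_size),
                "interactions": r.interactions or "-",
            })
        return pd.DataFrame(rows)

    def lsd_tables(self) -> pd.DataFrame:
        frames = []
        for var, r in self.per_variable.items():
            if len(r.lsd):
                t = r.lsd.copy()
                t.insert(0, "variable", var)
                frames.append(t)
        if not frames:
            return pd.DataFrame(
                columns=["variable", "level_a", "level_b", "mean_diff", "t", "p"])
        return pd.concat(frames, ignore_index=True)

    def plot_effects(self, ax=None):
        """Bar chart of |d| per variable, annotated with significance."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        summ = self.summary()
        ax.bar(summ["variable"], summ["effect_size"], color="steelblue")
        for x, (d, stars) in enumerate(zip(summ["effect_size"], summ["stars"])):
            ax.text(x, d, stars, ha="center", va="bottom")
        ax.set_ylabel("|Cohen's d|")
        ax.set_title(f"sensitivity test: {self.model.test_id}")
        ax.tick_params(axis="x", rotation=45)
        return ax


def run_sensitivity_test(features: pd.DataFrame, design: DesignTable,
                         test_id: str, alpha: float = ALPHA,
                         variables: "tuple | None" = None) -> SensitivityResults:
    """Functional wrapper: build the model and fit it."""
    return SensitivityAnova(features, design, test_id, alpha=alpha,
                            variables=variables).fit()


def recover_effect_size(design: DesignTable, test_id: str, variable: str,
                        true_d: float, n_reps: int = 200,
                        seed: int = 0) -> dict:
    """Effect-size recovery simulation at the design's group sizes.

    Generates direct-mode synthetic data with the given standardised
    difference on ``variable`` for the test's contrast (unit residual SD),
    runs the evaluation stage, and collects the recovered Cohen's d over
    ``n_reps`` independently seeded replicates.  Returns the replicate
    mean, its standard error and the replicate values.
    """
    from .synthesis import EffectSpec, generate_feature_table

    contrast_name = {"subspecies": "subspecies", "deciduous": "deciduous",
                     "blending": "blending"}[test_id]
    spec = EffectSpec(effects={variable: {contrast_name: true_d}},
                      residual_sigma=1.0, seed=seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) & 0x7FFFFFFF
    ds = []
    for rep_seed in child_seeds:
        features = generate_feature_table(design, spec, seed=int(rep_seed))
        results = run_sensitivity_test(features, design, test_id,
                                       variables=(variable,))
        ds.append(results[variable].effect_size)
    ds = np.asarray(ds)
    return {"mean_d": float(ds.mean()),
            "se": float(ds.std(ddof=1) / math.sqrt(n_reps)),
            "replicates": ds}
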