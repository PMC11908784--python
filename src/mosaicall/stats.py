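"""Cohort-level inference on mutational burden.

Group comparisons (Mann-Whitney / Kruskal-Wallis + Dunn), rank and
product-moment correlation, carrier logistic regression, linear
mixed-effects burden modeling with likelihood-ratio model comparison, and
hypergeometric gene-set enrichment against a panel background.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .calling import bh_adjust

__all__ = [
    "TestResult",
    "LogisticResult",
    "MixedModelResult",
    "SeparationError",
    "UndefinedCorrelationError",
    "compare_groups",
    "correlate",
    "carrier_logistic",
    "burden_mixed_model",
    "enrich_pathways",
]


class SeparationError(ValueError):
    """Logistic fit with complete (quasi-)separation."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested against a constant vector."""


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p: float
    group_sizes: tuple[int, ...]
    effect_direction: int  # sign of (first group median - second), 0 for ties/omnibus
    groups: tuple[str, str] | None = None


@dataclass(frozen=True)
class LogisticResult:
    terms: tuple[str, ...]
    coef: dict[str, float]
    odds_ratio: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    n: int


@dataclass(frozen=True)
class MixedModelResult:
    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    random_intercept_var: float
    residual_var: float
    loglik: float
    conditional_r2: float
    lrt: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    n_samples: int = 0
    n_donors: int = 0


def _as_groups(values_by_group) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[str(name)] = arr
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def compare_groups(values_by_group, method: str = "mann_whitney") -> list[TestResult]:
    """Two-group Mann-Whitney (exact when combined n <= 20 and tie-free) or
    Kruskal-Wallis omnibus plus BH-adjusted Dunn pairwise comparisons."""
    groups = _as_groups(values_by_group)
    names = list(groups)
    if method == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        x, y = groups[names[0]], groups[names[1]]
        combined = np.concatenate([x, y])
        tie_free = len(np.unique(combined)) == combined.size
        how = "exact" if (combined.size <= 20 and tie_free) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=how)
        direction = int(np.sign(np.median(x) - np.median(y)))
        return [
            TestResult(
                f"mann_whitney_{how}", float(res.statistic), float(res.pvalue),
                (x.size, y.size), direction, (names[0], names[1]),
            )
        ]
    if method == "kruskal_dunn":
        arrays = [groups[n] for n in names]
        kw = sps.kruskal(*arrays)
        results = [
            TestResult("kruskal_wallis", float(kw.statistic), float(kw.pvalue),
                       tuple(a.size for a in arrays), 0)
        ]
        results.extend(_dunn_pairwise(groups))
        return results
    raise ValueError(f"unknown method {method!r}")


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """Dunn's z-tests on pooled ranks with tie correction, BH-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_rank, sizes, i = {}, {}, 0
    for n in names:
        k = groups[n].size
        mean_rank[n] = ranks[i : i + k].mean()
        sizes[n] = k
        i += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    raw = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = max(2.0 * sps.norm.sf(abs(z)), 1e-300)
        raw.append((a, b, z, p))
    qs = bh_adjust([p for *_, p in raw]) if raw else []
    return [
        TestResult("dunn", float(z), float(q), (sizes[a], sizes[b]),
                   int(np.sign(z)), (a, b))
        for (a, b, z, _), q in zip(raw, qs)
    ]


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def carrier_logistic(
    cohort: pd.DataFrame,
    *,
    outcome: str = "status",
    carrier: str = "carrier",
    covariates: tuple[str, ...] = ("age", "sex"),
) -> LogisticResult:
    """Logistic regression of disease status on carrier state plus covariates.

    Binary columns may be coded 0/1, booleans, case/control or F/M strings.
    Raises :class:`SeparationError` instead of returning a degenerate fit.
    """
    df = cohort.reset_index(drop=True)
    y = _binarize(df[outcome], positive={"case", "ad", "1", "true", "yes"})
    X = pd.DataFrame({carrier: _binarize(df[carrier], positive={"1", "true", "yes"})})
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            X[cov] = _binarize(col, positive={"m", "male", "1", "true", "yes"})
        else:
            X[cov] = col.astype(float)
    X = sm.add_constant(X, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", False) or np.any(np.abs(fit.params) > 25):
        raise SeparationError(
            "logistic fit did not converge to a finite solution "
            "(likely complete separation; consider a penalized fit)"
        )
    conf = fit.conf_int(alpha=0.05)
    terms = tuple(t for t in X.columns if t != "const")
    return LogisticResult(
        terms=terms,
        coef={t: float(fit.params[t]) for t in X.columns},
        odds_ratio={t: float(np.exp(fit.params[t])) for t in terms},
        ci_low={t: float(np.exp(conf.loc[t, 0])) for t in terms},
        ci_high={t: float(np.exp(conf.loc[t, 1])) for t in terms},
        p={t: float(fit.pvalues[t]) for t in terms},
        n=int(len(df)),
    )


def _binarize(col: pd.Series, positive: set[str]) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy().astype(float)
    if col.dtype == object or str(col.dtype) == "category":
        vals = col.astype(str).str.strip().str.lower()
        uniq = set(vals.unique())
        if not (uniq & positive) and len(uniq) == 2:
            # fall back to lexicographic coding for unrecognized label pairs
            positive = {sorted(uniq)[1]}
        return vals.isin(positive).to_numpy().astype(float)
    return col.to_numpy().astype(float)


def burden_mixed_model(
    samples: pd.DataFrame,
    *,
    burden: str = "burden",
    disease: str = "status",
    age: str = "age",
    donor: str = "donor_id",
) -> MixedModelResult:
    """ML fit of burden ~ disease + age with a donor random intercept.

    Each fixed effect is additionally tested by a likelihood-ratio
    comparison against the nested model dropping that term (chi2, df=1).
    Conditional R^2 is (fixed-effect variance + intercept variance) over
    total variance.
    """
    df = samples.copy()
    if df[donor].nunique() < 2:
        raise ValueError("random intercept unidentifiable with a single donor")
    df["_y"] = df[burden].astype(float)
    df["_disease"] = _binarize(df[disease], positive={"case", "ad", "1", "true", "yes"})
    df["_age"] = df[age].astype(float)
    df["_donor"] = df[donor].astype(str)

    full = _fit_mixed("_y ~ _disease + _age", df)
    reduced = {
        "disease": _fit_mixed("_y ~ _age", df),
        "age": _fit_mixed("_y ~ _disease", df),
    }
    lrt = {}
    for term, red in reduced.items():
        stat = max(0.0, 2.0 * (full.llf - red.llf))
        lrt[term] = (float(stat), 1, float(sps.chi2.sf(stat, df=1)))

    fixed = {"intercept": float(full.params["Intercept"]),
             "disease": float(full.params["_disease"]),
             "age": float(full.params["_age"])}
    se = {"intercept": float(full.bse["Intercept"]),
          "disease": float(full.bse["_disease"]),
          "age": float(full.bse["_age"])}
    var_re = float(np.asarray(full.cov_re)[0, 0])
    var_res = float(full.scale)
    fitted_fixed = (
        fixed["intercept"] + fixed["disease"] * df["_disease"] + fixed["age"] * df["_age"]
    )
    var_f = float(np.var(fitted_fixed))
    total = var_f + var_re + var_res
    r2c = (var_f + var_re) / total if total > 0 else 0.0
    return MixedModelResult(
        fixed_effects=fixed,
        fixed_se=se,
        random_intercept_var=var_re,
        residual_var=var_res,
        loglik=float(full.llf),
        conditional_r2=float(r2c),
        lrt=lrt,
        n_samples=int(len(df)),
        n_donors=int(df["_donor"].nunique()),
    )


def _fit_mixed(formula: str, df: pd.DataFrame):
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["_donor"])
        fit = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=False, method=method, maxiter=1000)
                break
            except np.linalg.LinAlgError:
                continue
        if fit is None:
            raise RuntimeError("mixed-model fit failed with every optimizer")
        fit.llf, fit.bse, fit.params  # force lazy evaluation inside the guard
        return fit


def enrich_pathways(
    hit_genes,
    catalog,
    background,
    *,
    p_max: float = 0.05,
    min_count: int = 3,
    min_factor: float = 1.5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of hits against a fixed background.

    Gene sets are intersected with the background before testing; hits
    outside the background are dropped with a warning.  A set is flagged
    ``reported`` when p < 0.05, overlap >= 3 and enrichment factor > 1.5.
    """
    bg = {str(g).upper() for g in background}
    if not bg:
        raise ValueError("background gene list is empty")
    hits = {str(g).upper() for g in hit_genes}
    outside = hits - bg
    if outside:
        warnings.warn(f"{len(outside)} hit genes outside the background were dropped")
        hits &= bg

    n_bg = len(bg)
    n_hits = len(hits)
    rows = []
    for name, members in catalog.sets.items():
        in_bg = members & bg
        k = len(in_bg & hits)
        big_k = len(in_bg)
        expected = n_hits * big_k / n_bg
        factor = k / expected if expected > 0 else np.nan
        p = float(sps.hypergeom.sf(k - 1, n_bg, big_k, n_hits))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size_in_background": big_k,
                "n_hits": n_hits,
                "n_background": n_bg,
                "expected": expected,
                "enrichment_factor": factor,
                "p": min(max(p, 1e-300), 1.0),
                "reported": bool(p < p_max and k >= min_count and
                                 (factor is not np.nan and factor > min_factor)),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
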