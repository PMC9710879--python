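"""Mendelian segregation tests, litter-adjusted growth model, qPCR ratios.

The chi-square goodness-of-fit follows the convention needed for survival
models that zero out categories: a category with expected count 0 must have
observed count 0 (otherwise the model is contradicted outright), is dropped,
and degrees of freedom count only the remaining categories minus one.

The growth model is ordinary least squares of embryo weight on genotype and
litter as fixed effects; adjusted genotype means marginalize litters with
equal weight, and the growth-rescue percentage compares the double
heterozygote's recovery against the single mutant's deficit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from generescue.constants import GENOTYPES


@dataclass(frozen=True)
class GofResult:
    chi_square: float
    df: int
    p_value: float
    dropped_categories: tuple[str, ...]


def gof_chisq(
    observed: Sequence[float],
    expected: Sequence[float],
    categories: Sequence[str] | None = None,
) -> GofResult:
    """Chi-square goodness of fit with the zero-expected-category convention.

    statistic = sum (O - E)^2 / E over categories with E > 0;
    df = (categories with E > 0) - 1. E = 0 with O > 0 raises: the survival
    model under test forbids that category entirely.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if (obs < 0).any() or (exp < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    if not np.isclose(exp.sum(), total, rtol=1e-2):
        raise ValueError(
            f"expected counts sum to {exp.sum():g}, observed to {total:g}; "
            "the expected model must be scaled to the observed total"
        )
    labels = (
        [str(c) for c in categories]
        if categories is not None
        else [f"category{i + 1}" for i in range(len(obs))]
    )
    zero = exp == 0
    if (obs[zero] > 0).any():
        bad = [labels[i] for i in np.flatnonzero(zero & (obs > 0))]
        raise ValueError(
            f"category(ies) {bad} observed despite expected count 0: "
            "the survival model is contradicted"
        )
    keep = ~zero
    df = int(keep.sum()) - 1
    if df <= 0:
        raise ValueError("need at least 2 categories with positive expectation")
    chi2 = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    return GofResult(
        chi_square=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        dropped_categories=tuple(labels[i] for i in np.flatnonzero(zero)),
    )


def mendelian_expected(
    n_total: float,
    proportions: Sequence[float],
    survival: Sequence[float],
) -> np.ndarray:
    """Expected counts: Mendelian proportions filtered by a survival model.

    expected = n_total * (proportions * survival) renormalized to sum to
    n_total; a category the survival model kills gets expected 0 and the
    survivors share the total in their Mendelian ratio.
    """
    props = np.asarray(proportions, dtype=float)
    surv = np.asarray(survival, dtype=float)
    if props.shape != surv.shape:
        raise ValueError("proportions and survival must have equal length")
    if not np.isclose(props.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1")
    if (surv < 0).any() or (surv > 1).any():
        raise ValueError("survival probabilities must lie in [0, 1]")
    weighted = props * surv
    if weighted.sum() <= 0:
        raise ValueError("survival model kills every category")
    return n_total * weighted / weighted.sum()


@dataclass(frozen=True)
class GrowthFit:
    """Litter-adjusted growth model summary.

    ``adjusted_means`` marginalizes litter effects with equal weight per
    litter; ``contrasts`` holds the genotype effects vs WT and the
    double-vs-single comparison with t-based p-values.
    """

    adjusted_means: dict[str, float]
    contrasts: pd.DataFrame
    n: int
    r_squared: float

    def conf_int(self, contrast: str, level: float = 0.95) -> tuple[float, float]:
        row = self.contrasts.loc[contrast]
        half = stats.t.ppf(0.5 + level / 2.0, row["df"]) * row["se"]
        return (row["estimate"] - half, row["estimate"] + half)

    @property
    def rescue_percent_growth(self) -> float:
        return rescue_percent(
            self.adjusted_means["WT"],
            self.adjusted_means["NipblHet"],
            self.adjusted_means["Double"],
        )


def growth_fit(records: pd.DataFrame) -> GrowthFit:
    """OLS of weight on genotype and litter (both fixed effects).

    ``records`` needs columns genotype, litter, weight_g. The litter term is
    included whenever more than one litter is present; a design where
    genotype is perfectly confounded with litter raises.
    """
    req = {"genotype", "litter", "weight_g"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"weight records missing column(s) {sorted(missing)}")
    unknown = set(records["genotype"]) - set(GENOTYPES)
    if unknown:
        raise ValueError(
            f"unknown genotype labels {sorted(unknown)}; allowed: {GENOTYPES}"
        )
    genos = [g for g in GENOTYPES if g in set(records["genotype"])]
    if len(genos) < 2:
        raise ValueError("need at least 2 genotypes")
    litters = sorted(set(records["litter"]))
    formula = "weight_g ~ C(genotype, Treatment('WT'))"
    if len(litters) > 1:
        formula += " + C(litter)"
    model = smf.ols(formula, data=records)
    n_params = model.exog.shape[1]
    if np.linalg.matrix_rank(model.exog) < n_params:
        raise ValueError(
            "singular design: genotype is confounded with litter (some "
            "genotype occurs in only one litter pattern)"
        )
    fit = model.fit()

    def geno_term(g: str) -> str:
        return f"C(genotype, Treatment('WT'))[T.{g}]"

    litter_effects = [0.0] + [
        fit.params[f"C(litter)[T.{lit}]"] for lit in litters[1:]
    ]
    litter_mean = float(np.mean(litter_effects))
    adjusted = {}
    for g in genos:
        coef = 0.0 if g == "WT" else float(fit.params[geno_term(g)])
        adjusted[g] = float(fit.params["Intercept"]) + coef + litter_mean

    rows = {}
    for g in genos:
        if g == "WT":
            continue
        term = geno_term(g)
        rows[f"{g}_vs_WT"] = {
            "estimate": float(fit.params[term]),
            "se": float(fit.bse[term]),
            "p_value": float(fit.pvalues[term]),
            "df": float(fit.df_resid),
        }
    if "Double" in genos and "NipblHet" in genos:
        tt = fit.t_test(f"{geno_term('Double')} - {geno_term('NipblHet')}")
        rows["Double_vs_NipblHet"] = {
            "estimate": float(tt.effect[0]),
            "se": float(tt.sd[0][0]),
            "p_value": float(tt.pvalue),
            "df": float(fit.df_resid),
        }
    return GrowthFit(
        adjusted_means=adjusted,
        contrasts=pd.DataFrame(rows).T,
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )


def percent_change(reference: float, comparison: float) -> tuple[float, str]:
    """Signed percent change vs a positive reference, with a direction word."""
    if reference <= 0:
        raise ValueError("reference mean must be positive")
    pct = 100.0 * (comparison - reference) / reference
    direction = "increase" if pct > 0 else ("decrease" if pct < 0 else "unchanged")
    return pct, direction


def rescue_percent(mu_wt: float, mu_single: float, mu_double: float) -> float:
    """Fraction of the single-mutant deficit recovered by the double mutant.

    100 x (mu_double - mu_single) / (mu_wt - mu_single): 0 means the double
    mutant matches the single mutant, 100 means it matches wild type.
    """
    if mu_wt == mu_single:
        raise ValueError("no deficit to rescue: wild-type and single-mutant "
                         "means are equal")
    return 100.0 * (mu_double - mu_single) / (mu_wt - mu_single)


def relative_expression(
    target: Sequence[float],
    reference: Sequence[float],
    groups: Sequence[str],
    baseline_group: str = "WT",
) -> pd.Series:
    """qPCR-style double normalization: target/reference, then over baseline.

    r_j = (target_j / reference_j) / mean over baseline samples of the same
    ratio, so the baseline group averages exactly 1.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reference, dtype=float)
    g = np.asarray([str(x) for x in groups])
    if t.shape != r.shape or t.shape != g.shape:
        raise ValueError("target, reference and groups must have equal length")
    if (r <= 0).any():
        raise ValueError("reference values must be positive")
    base = g == baseline_group
    if not base.any():
        raise ValueError(f"baseline group {baseline_group!r} has no samples")
    ratio = t / r
    return pd.Series(ratio / ratio[base].mean(), index=g, name="relative_expression")
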