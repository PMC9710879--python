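"""Effect-ratio rescue regression, DEG overlap and enrichment.

The core statistic: for every gene, log2 effect ratios against wild type are
computed from genotype-averaged normalized counts,

    e_X = log2((mean_X + pc) / (mean_WT + pc)),

and the double-heterozygote ratio e_D is regressed on a single-heterozygote
ratio (e_N or e_W) over a DEG set. A slope of 1 means the double mutant
reproduces the single mutant's dysregulation (no rescue); a slope of 0 means
expression returns to wild-type levels (complete rescue); rescue percent is
(1 - slope) x 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from generescue.constants import GENOTYPES
from generescue.diffexpr import bh_adjust

#: effect-ratio column per genotype axis
AXIS_COLUMNS = {"N": "e_N", "W": "e_W", "D": "e_D"}
_AXIS_GENOTYPE = {"N": "NipblHet", "W": "WaplHet", "D": "Double"}


def genotype_means(
    norm_counts: pd.DataFrame,
    samples: pd.DataFrame,
    required: Sequence[str] = GENOTYPES,
) -> pd.DataFrame:
    """Average normalized counts across replicates within each genotype."""
    present = set(samples["genotype"])
    missing = [g for g in required if g not in present]
    if missing:
        raise ValueError(f"genotype(s) with no samples: {missing}")
    cols = {}
    for g in required:
        ids = samples.index[samples["genotype"] == g]
        cols[g] = norm_counts[ids].mean(axis=1)
    return pd.DataFrame(cols)


def effect_ratios(
    profile: pd.DataFrame,
    genes: Iterable[str] | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """log2 mutant/WT ratios of genotype means, WT as common denominator.

    The pseudocount is added symmetrically to numerator and denominator so a
    gene with zero counts everywhere gets an effect ratio of exactly 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if genes is not None:
        missing = [g for g in genes if g not in profile.index]
        if missing:
            raise KeyError(f"genes absent from profile: {missing[:5]}")
        profile = profile.loc[list(genes)]
    denom = profile["WT"] + pseudocount
    out = {}
    for axis, col in AXIS_COLUMNS.items():
        out[col] = np.log2((profile[_AXIS_GENOTYPE[axis]] + pseudocount) / denom)
    return pd.DataFrame(out, index=profile.index)


@dataclass(frozen=True)
class RescueFit:
    """OLS summary of e_D on a single-heterozygote axis over a gene set."""

    label: str
    axis: str
    n_genes: int
    slope: float
    intercept: float
    r_squared: float

    @property
    def rescue_percent(self) -> float:
        return 100.0 * (1.0 - self.slope)


def fit_rescue(
    effects: pd.DataFrame,
    gene_set: Iterable[str],
    axis: str = "N",
    label: str = "",
) -> RescueFit:
    """Regress double-het effect ratios on a single-het axis (with intercept).

    The intercept is reported rather than suppressed so a global shift of the
    double-mutant transcriptome is visible instead of folded into the slope.
    """
    if axis not in ("N", "W"):
        raise ValueError("axis must be 'N' or 'W'")
    genes = [g for g in gene_set]
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to fit the rescue regression")
    sub = effects.loc[genes]
    x = sub[AXIS_COLUMNS[axis]].to_numpy(dtype=float)
    y = sub["e_D"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor effect ratios have zero variance")
    fit = stats.linregress(x, y)
    return RescueFit(
        label=label or f"{len(genes)} genes",
        axis=axis,
        n_genes=len(genes),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


@dataclass(frozen=True)
class RtmControl:
    """Regression-to-the-mean control: primary fit vs fit on the union set.

    Selecting genes for being extreme in a single mutant biases the naive
    slope downward; refitting after adding the double-mutant DEG set should
    leave the slope essentially unchanged if the rescue is real.
    """

    primary: RescueFit
    union: RescueFit

    @property
    def slope_difference(self) -> float:
        return self.union.slope - self.primary.slope


def rtm_control(
    effects: pd.DataFrame,
    primary_deg_set: Iterable[str],
    double_deg_set: Iterable[str],
    axis: str = "N",
) -> RtmControl:
    """Refit the rescue regression on primary-DEGs union double-DEGs."""
    primary = list(primary_deg_set)
    double = list(double_deg_set)
    if not primary or not double:
        raise ValueError("both DEG sets must be non-empty")
    union = sorted(set(primary) | set(double))
    primary_fit = fit_rescue(effects, primary, axis, label="primary DEGs")
    union_fit = fit_rescue(effects, union, axis, label="primary + double DEGs")
    return RtmControl(primary=primary_fit, union=union_fit)


@dataclass(frozen=True)
class OverlapResult:
    """Concordance of two DEG sets over a common tested-gene universe."""

    n_universe: int
    n_a: int
    n_a_up: int
    n_a_down: int
    n_b: int
    n_b_up: int
    n_b_down: int
    n_shared: int
    n_same_direction: int
    n_opposite_direction: int
    chi_square: float
    p_value: float
    correlation: float


def overlap_analysis(
    de_a: pd.DataFrame, de_b: pd.DataFrame, effects: pd.DataFrame | None = None,
    axes: tuple[str, str] = ("N", "W"),
) -> OverlapResult:
    """DEG overlap between two contrasts with a 2x2 chi-square of proportions.

    The chi-square (Pearson, no continuity correction) tests independence of
    DEG membership in the two contrasts over the shared tested universe.
    Direction concordance uses the sign of each table's log2FC. If an
    effect-ratio table is supplied, the Pearson correlation of the two
    single-mutant effect ratios over shared DEGs is reported.
    """
    universe = de_a.index.intersection(de_b.index)
    if len(universe) == 0:
        raise ValueError("the two DE tables have disjoint gene universes")
    a = de_a.loc[universe]
    b = de_b.loc[universe]
    in_a = a["isDEG"].to_numpy(dtype=bool)
    in_b = b["isDEG"].to_numpy(dtype=bool)
    shared = in_a & in_b
    same = shared & (
        np.sign(a["log2FC"].to_numpy()) == np.sign(b["log2FC"].to_numpy())
    )
    table = np.array(
        [
            [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
            [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = 0.0, 1.0  # a zero margin leaves no independence to test
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)

    correlation = float("nan")
    if effects is not None and shared.sum() >= 2:
        sub = effects.loc[universe[shared]]
        correlation = float(
            np.corrcoef(sub[AXIS_COLUMNS[axes[0]]], sub[AXIS_COLUMNS[axes[1]]])[0, 1]
        )

    def _counts(tab: pd.DataFrame) -> tuple[int, int, int]:
        deg = tab[tab["isDEG"]]
        up = int((deg["log2FC"] > 0).sum())
        return len(deg), up, len(deg) - up

    n_a, n_a_up, n_a_down = _counts(a)
    n_b, n_b_up, n_b_down = _counts(b)
    return OverlapResult(
        n_universe=len(universe),
        n_a=n_a, n_a_up=n_a_up, n_a_down=n_a_down,
        n_b=n_b, n_b_up=n_b_up, n_b_down=n_b_down,
        n_shared=int(shared.sum()),
        n_same_direction=int(same.sum()),
        n_opposite_direction=int(shared.sum() - same.sum()),
        chi_square=float(chi2),
        p_value=float(p),
        correlation=correlation,
    )


def enrichment(
    hit_genes: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of hits in each gene set.

    Each set is first intersected with the universe; p = P(overlap >= observed)
    under sampling len(hits) genes without replacement. BH adjustment across
    sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    hits = set(hit_genes)
    stray = hits - uni
    if stray:
        raise ValueError(f"hit genes outside the universe: {sorted(stray)[:5]}")
    rows = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        k = len(in_uni & hits)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(in_uni), len(hits)))
        rows.append({"gene_set": name, "set_size": len(in_uni),
                     "overlap": k, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("gene_set")
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["padj"] = []
    return out


def report_gene_panel(
    de_tables: Mapping[str, pd.DataFrame],
    panel_genes: Sequence[str],
    rescue_class: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene panel report: fold change and adjusted p per contrast.

    Genes absent from a contrast's tested universe get NaNs and
    ``in_universe`` False; absent genes are flagged, never fatal.
    """
    rows = []
    for gene in panel_genes:
        row: dict[str, object] = {"gene": gene}
        present = False
        for contrast, table in de_tables.items():
            if gene in table.index:
                present = True
                row[f"log2FC_{contrast}"] = float(table.at[gene, "log2FC"])
                row[f"padj_{contrast}"] = float(table.at[gene, "padj"])
                row[f"direction_{contrast}"] = (
                    "up" if table.at[gene, "log2FC"] > 0 else "down"
                )
            else:
                row[f"log2FC_{contrast}"] = float("nan")
                row[f"padj_{contrast}"] = float("nan")
                row[f"direction_{contrast}"] = ""
        row["in_universe"] = present
        if rescue_class is not None:
            row["rescue_class"] = (
                str(rescue_class.get(gene, "unclassified")) if present else ""
            )
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["gene", "in_universe"]).set_index("gene")
    return pd.DataFrame(rows).set_index("gene")
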