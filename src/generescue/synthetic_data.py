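"""Seeded generators for counts, embryo weights and cross outcomes.

The count generator emulates a bulk RNA-seq experiment on E17.5 mouse brain
with four genotype groups (wild type, two single heterozygotes, the double
heterozygote). Per-gene counts are negative binomial around a baseline mean
modulated by log2 genotype effects; a latent shared effect makes the two
single-mutant effect vectors correlated, and the double-mutant effect is a
damped copy of the Nipbl-het effect whose damping coefficient (``rescue_r``)
is the ground truth the rescue regression downstream should recover.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from generescue.constants import DEFAULT_GROUP_SIZES, GENOTYPES


class ConfigError(ValueError):
    """Raised when a simulation config field fails validation."""


def _require(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ConfigError(f"invalid field {fieldname!r}: {message}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic count experiment.

    Defaults mirror the study conditions: 21 samples (5 WT, 7 Wapl-het,
    3 Nipbl-het, 6 double-het), a quarter of genes dysregulated with mostly
    sub-twofold effects (sigma_u = 0.35 on the log2 scale), single-mutant
    effects correlated at 0.82, and a double-mutant damping coefficient of
    0.58 (slope of the rescue regression; 42% rescue).
    """

    n_genes: int = 5000
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    pi_dys: float = 0.25
    sigma_u: float = 0.35
    effect_cor: float = 0.82
    rescue_r: float = 0.58
    sigma_resid_effect: float = 0.10
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    disp_a0: float = 0.01
    disp_a1: float = 2.0
    sf_low: float = 0.7
    sf_high: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        _require(int(self.n_genes) >= 1, "n_genes", "must be a positive integer")
        unknown = set(self.group_sizes) - set(GENOTYPES)
        _require(not unknown, "group_sizes", f"unknown genotypes {sorted(unknown)}")
        _require(set(self.group_sizes) == set(GENOTYPES), "group_sizes",
                 f"all four genotypes {GENOTYPES} must be present")
        for g, n in self.group_sizes.items():
            _require(int(n) >= 1, "group_sizes", f"group {g!r} needs >= 1 sample")
        _require(0.0 <= self.pi_dys <= 1.0, "pi_dys", "must lie in [0, 1]")
        _require(self.sigma_u >= 0.0, "sigma_u", "must be >= 0")
        _require(0.0 <= self.effect_cor <= 1.0, "effect_cor", "must lie in [0, 1]")
        _require(0.0 <= self.rescue_r <= 1.0, "rescue_r", "must lie in [0, 1]")
        _require(self.sigma_resid_effect >= 0.0, "sigma_resid_effect", "must be >= 0")
        _require(self.baseline_log2_sd >= 0.0, "baseline_log2_sd", "must be >= 0")
        _require(self.disp_a0 >= 0.0, "disp_a0", "must be >= 0")
        _require(self.disp_a1 >= 0.0, "disp_a1", "must be >= 0")
        _require(0.0 < self.sf_low <= self.sf_high, "sf_low",
                 "need 0 < sf_low <= sf_high")


def _wapl_noise_sd(config: SimConfig) -> float:
    """SD of the Wapl-axis effect noise that realizes ``effect_cor``.

    With delta_N = u + eps_N and delta_W = u + eps_W (u ~ N(0, sigma_u^2)),
    corr(delta_N, delta_W) = sigma_u^2 / sqrt((sigma_u^2 + s_N^2)(sigma_u^2 + s_W^2)),
    solved here for s_W.
    """
    a = config.sigma_u**2
    if a == 0.0:
        return config.sigma_resid_effect
    rho = config.effect_cor
    if rho == 0.0:
        raise ConfigError(
            "invalid field 'effect_cor': 0 is unreachable with a shared latent "
            "effect; use pi_dys = 0 for fully null data"
        )
    var_n = a + config.sigma_resid_effect**2
    var_w = a**2 / (rho**2 * var_n)
    if var_w < a:
        raise ConfigError(
            "invalid field 'effect_cor': "
            f"{rho} is unattainable with sigma_u={config.sigma_u} and "
            f"sigma_resid_effect={config.sigma_resid_effect} "
            f"(maximum reachable correlation is {a / math.sqrt(a * var_n):.4f})"
        )
    return math.sqrt(var_w - a)


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a count matrix with known per-gene genotype effects.

    Returns
    -------
    counts : DataFrame (genes x samples, non-negative integers)
    samples : DataFrame indexed by sample id with columns ``genotype``,
        ``sex`` (all "F": the study sequenced female embryos), ``litter``
        (empty; litters are not modeled for counts) and the drawn
        ``size_factor``.
    effects : DataFrame indexed by gene with the simulation ground truth:
        ``dysregulated``, ``delta_N``, ``delta_W``, ``delta_D`` (log2 effects
        vs WT), ``baseline_mean`` and ``dispersion``.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = int(config.n_genes)
    genes = np.array([f"gene{i + 1:05d}" for i in range(n_genes)])

    sample_ids: list[str] = []
    genotype_of: list[str] = []
    for g in GENOTYPES:
        for i in range(int(config.group_sizes[g])):
            sample_ids.append(f"{g}_{i + 1}")
            genotype_of.append(g)
    n_samples = len(sample_ids)

    log2_mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    mu = np.exp2(log2_mu)
    dispersion = config.disp_a0 + config.disp_a1 / mu

    dys = rng.random(n_genes) < config.pi_dys
    delta_n = np.zeros(n_genes)
    delta_w = np.zeros(n_genes)
    delta_d = np.zeros(n_genes)
    n_dys = int(dys.sum())
    if n_dys:
        s_w = _wapl_noise_sd(config)
        u = rng.normal(0.0, config.sigma_u, n_dys)
        delta_n[dys] = u + rng.normal(0.0, config.sigma_resid_effect, n_dys)
        delta_w[dys] = u + rng.normal(0.0, s_w, n_dys)
        delta_d[dys] = config.rescue_r * delta_n[dys] + rng.normal(
            0.0, config.sigma_resid_effect, n_dys
        )

    size_factor = rng.uniform(config.sf_low, config.sf_high, n_samples)

    delta_by_genotype = {
        "WT": np.zeros(n_genes),
        "WaplHet": delta_w,
        "NipblHet": delta_n,
        "Double": delta_d,
    }
    mean = np.empty((n_genes, n_samples))
    for j, g in enumerate(genotype_of):
        mean[:, j] = size_factor[j] * mu * np.exp2(delta_by_genotype[g])

    # NB with variance mu + alpha*mu^2: shape r = 1/alpha, success prob r/(r+mu)
    r = 1.0 / dispersion[:, None]
    counts = rng.negative_binomial(r, r / (r + mean))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=sample_ids)
    samples_df = pd.DataFrame(
        {
            "genotype": genotype_of,
            "sex": "F",
            "litter": "",
            "size_factor": size_factor,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    effects_df = pd.DataFrame(
        {
            "dysregulated": dys,
            "delta_N": delta_n,
            "delta_W": delta_w,
            "delta_D": delta_d,
            "baseline_mean": mu,
            "dispersion": dispersion,
        },
        index=pd.Index(genes, name="gene"),
    )
    return counts_df, samples_df, effects_df


def expected_profile(effects: pd.DataFrame) -> pd.DataFrame:
    """Noiseless genotype-mean profile implied by the simulation ground truth.

    Per gene: baseline_mean scaled by 2^delta for each genotype (WT delta is
    0). This is the profile the count data estimate; running the effect-ratio
    regression on it recovers the configured rescue coefficient free of
    counting noise, separating method correctness from sampling attenuation.
    """
    return pd.DataFrame(
        {
            "WT": effects["baseline_mean"],
            "WaplHet": effects["baseline_mean"] * np.exp2(effects["delta_W"]),
            "NipblHet": effects["baseline_mean"] * np.exp2(effects["delta_N"]),
            "Double": effects["baseline_mean"] * np.exp2(effects["delta_D"]),
        },
        index=effects.index,
    )


@dataclass(frozen=True)
class WeightSimConfig:
    """Parameters of the embryo-weight generator.

    Genotype effects are on the gram scale relative to the wild-type mean
    (0.936 g at E17.5); litters contribute a shared random offset, so the
    downstream growth model must adjust for litter to recover the genotype
    contrasts.
    """

    n_litters: int = 15
    litter_size_range: tuple[int, int] = (4, 8)
    genotype_probabilities: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.25 for g in GENOTYPES}
    )
    mu_wt: float = 0.936
    beta_nipbl: float = -0.321
    beta_wapl: float = -0.042
    beta_double: float = -0.246
    sigma_litter: float = 0.05
    sigma_resid: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        _require(int(self.n_litters) >= 1, "n_litters", "must be >= 1")
        lo, hi = self.litter_size_range
        _require(1 <= int(lo) <= int(hi), "litter_size_range",
                 "need 1 <= low <= high")
        _require(set(self.genotype_probabilities) == set(GENOTYPES),
                 "genotype_probabilities", f"must cover {GENOTYPES}")
        probs = np.array([self.genotype_probabilities[g] for g in GENOTYPES])
        _require(np.all(probs >= 0), "genotype_probabilities",
                 "probabilities must be >= 0")
        _require(abs(probs.sum() - 1.0) < 1e-8, "genotype_probabilities",
                 "probabilities must sum to 1")
        _require(self.mu_wt > 0, "mu_wt", "must be > 0")
        _require(self.sigma_litter >= 0, "sigma_litter", "must be >= 0")
        _require(self.sigma_resid >= 0, "sigma_resid", "must be >= 0")


def simulate_weights(config: WeightSimConfig) -> pd.DataFrame:
    """Draw an embryo-weight table (embryo, litter, genotype, weight_g).

    weight = mu_wt + genotype effect + litter effect + residual noise.
    Genotypes within a litter are drawn independently from
    ``genotype_probabilities``, so genotype is not confounded with litter by
    construction.
    """
    rng = np.random.default_rng(config.seed)
    beta = {
        "WT": 0.0,
        "WaplHet": config.beta_wapl,
        "NipblHet": config.beta_nipbl,
        "Double": config.beta_double,
    }
    probs = np.array([config.genotype_probabilities[g] for g in GENOTYPES])
    probs = probs / probs.sum()
    lo, hi = config.litter_size_range

    rows = []
    embryo = 0
    for li in range(int(config.n_litters)):
        litter_id = f"L{li + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        litter_eff = rng.normal(0.0, config.sigma_litter)
        genos = rng.choice(GENOTYPES, size=size, p=probs)
        resid = rng.normal(0.0, config.sigma_resid, size)
        for k in range(size):
            embryo += 1
            g = str(genos[k])
            rows.append(
                {
                    "embryo": f"E{embryo:03d}",
                    "litter": litter_id,
                    "genotype": g,
                    "weight_g": config.mu_wt + beta[g] + litter_eff + resid[k],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CrossConfig:
    """A mating cross: Mendelian category proportions filtered by survival."""

    categories: Sequence[str]
    mendelian_proportions: Sequence[float]
    survival_probabilities: Sequence[float]
    n_offspring: int
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.categories)
        _require(k >= 1, "categories", "need at least one category")
        _require(len(set(self.categories)) == k, "categories", "labels must be unique")
        _require(len(self.mendelian_proportions) == k, "mendelian_proportions",
                 "length must match categories")
        _require(len(self.survival_probabilities) == k, "survival_probabilities",
                 "length must match categories")
        props = np.asarray(self.mendelian_proportions, dtype=float)
        _require(np.all(props >= 0), "mendelian_proportions", "must be >= 0")
        _require(abs(props.sum() - 1.0) < 1e-6, "mendelian_proportions",
                 "must sum to 1")
        surv = np.asarray(self.survival_probabilities, dtype=float)
        _require(np.all((surv >= 0) & (surv <= 1)), "survival_probabilities",
                 "must lie in [0, 1]")
        _require(float((props * surv).sum()) > 0, "survival_probabilities",
                 "at least one category must have positive survival")
        _require(int(self.n_offspring) >= 1, "n_offspring", "must be >= 1")


def simulate_cross(config: CrossConfig) -> pd.DataFrame:
    """Multinomial draw of surviving offspring counts per genotype category."""
    rng = np.random.default_rng(config.seed)
    props = np.asarray(config.mendelian_proportions, dtype=float)
    surv = np.asarray(config.survival_probabilities, dtype=float)
    p = props * surv
    p = p / p.sum()
    observed = rng.multinomial(int(config.n_offspring), p)
    return pd.DataFrame(
        {"category": list(config.categories), "observed": observed.astype(int)}
    )
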