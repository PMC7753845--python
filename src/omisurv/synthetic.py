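"""Synthetic multi-omics survival cohorts with known two-group structure.

Emulates a paired RNA-seq / miRNA-seq / promoter-methylation cohort in which
a single latent grouping drives (a) a mean shift in a planted subset of
features in every block and (b) a proportional-hazards difference in overall
survival.  Because the same latent group is shared across blocks, integrated
analyses have more signal to find than any single block — the premise the
downstream pipeline is built to exploit.

Counts (RNA, miRNA) follow a negative-binomial model with log-normal
baseline means; promoter methylation follows Beta distributions on [0, 1].
Survival is exponential (constant hazard) with the group-2 hazard scaled by
``hazard_ratio``, and independent exponential censoring whose rate is solved
numerically so the expected censored fraction equals ``censoring_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ClinicalTable, OmicsMatrix

# Fixed distributional constants (see docs/methods.md for rationale).
_NB_DISPERSION = 10.0          # NB size parameter r; variance = mu + mu^2/r
_LOG_MEAN_RNA = (3.0, 1.0)     # log10 baseline mean ~ Normal(loc, scale)
_LOG_MEAN_MIRNA = (2.5, 1.0)
_BETA_CONCENTRATION = 30.0     # a + b of the methylation Beta distributions
_BETA_SHIFT_PER_EFFECT = 0.1   # beta-mean shift per unit effect_size


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Attributes
    ----------
    n_samples : int
        Cohort size.
    group_proportion : float
        Fraction of samples assigned to group 2 (the shifted / higher-hazard
        group when ``hazard_ratio`` > 1).
    n_features : dict
        Features per block, keys ``rna``, ``mirna``, ``methylation``.
    n_informative : dict
        Planted differential features per block (subset of ``n_features``).
    effect_size : float
        Log-fold mean shift (natural log) applied to informative count
        features in group 2; methylation informative features are shifted by
        ``effect_size / 10`` on the beta-mean scale.  Shift direction
        alternates (up/down) across informative features.
    hazard_ratio : float
        Group-2 vs group-1 hazard ratio.
    baseline_hazard : float
        Group-1 event rate, events per year.
    censoring_rate : float
        Expected fraction of samples right-censored.
    missing_rate : float
        Fraction of entries in every block set missing at random.
    seed : int
        RNG seed; fixed seed gives bitwise-identical cohorts.
    """

    n_samples: int = 300
    group_proportion: float = 0.5
    n_features: dict = field(default_factory=lambda: {"rna": 500, "mirna": 100, "methylation": 500})
    n_informative: dict = field(default_factory=lambda: {"rna": 50, "mirna": 10, "methylation": 50})
    effect_size: float = 1.0
    hazard_ratio: float = 2.0
    baseline_hazard: float = 0.2
    censoring_rate: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("group_proportion", "censoring_rate", "missing_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a finite fraction in [0, 1], got {v}")
        if self.missing_rate >= 1.0:
            raise ValueError(f"missing_rate must be < 1, got {self.missing_rate}")
        if not np.isfinite(self.hazard_ratio) or self.hazard_ratio <= 0:
            raise ValueError(f"hazard_ratio must be finite and > 0, got {self.hazard_ratio}")
        if not np.isfinite(self.baseline_hazard) or self.baseline_hazard <= 0:
            raise ValueError(f"baseline_hazard must be finite and > 0, got {self.baseline_hazard}")
        if not np.isfinite(self.effect_size):
            raise ValueError(f"effect_size must be finite, got {self.effect_size}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        for block in ("rna", "mirna", "methylation"):
            nf = self.n_features[block]
            ni = self.n_informative[block]
            if nf < 1:
                raise ValueError(f"n_features[{block!r}] must be >= 1, got {nf}")
            if ni < 0 or ni > nf:
                raise ValueError(
                    f"n_informative[{block!r}] must be in [0, n_features], got {ni}"
                )


@dataclass
class GroundTruth:
    """The planted structure: true group per sample, informative feature IDs."""

    true_group: pd.Series                 # sample -> 1 or 2
    informative: dict[str, list[str]]     # block -> feature IDs

    def __post_init__(self) -> None:
        groups = set(self.true_group.unique())
        if not groups <= {1, 2}:
            raise ValueError("true_group labels must take values in {1, 2}")

    def to_tsv(self, path: str | Path) -> None:
        self.true_group.rename("true_group").to_frame().to_csv(
            path, sep="\t", index_label="sample_id"
        )


def _censoring_rate_solve(
    lam1: float, lam2: float, pi2: float, target: float
) -> float:
    """Exponential censoring rate c with P(C < T) == target.

    For exponential event time with rate lam and independent exponential
    censoring with rate c, P(censored) = c / (lam + c); the cohort-level
    probability is the mixture over the two groups.
    """
    if target <= 0:
        return 0.0

    def f(c: float) -> float:
        return (1 - pi2) * c / (lam1 + c) + pi2 * c / (lam2 + c) - target

    hi = 10.0 * max(lam1, lam2)
    while f(hi) < 0:
        hi *= 10.0
    return float(optimize.brentq(f, 1e-12, hi))


def _sample_counts(
    rng: np.random.Generator,
    n_samples: int,
    n_features: int,
    n_informative: int,
    effect_size: float,
    group: np.ndarray,
    log_mean: tuple[float, float],
    prefix: str,
) -> tuple[pd.DataFrame, list[str]]:
    base_mean = 10.0 ** rng.normal(log_mean[0], log_mean[1], size=n_features)
    base_mean = np.clip(base_mean, 1.0, None)
    # log-fold shift in group 2 for informative features, alternating sign
    shift = np.zeros(n_features)
    sign = np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    shift[:n_informative] = effect_size * sign
    mu = base_mean[None, :] * np.exp(shift[None, :] * (group[:, None] - 1))
    # NB(mean mu, size r) via Gamma-Poisson mixture
    r = _NB_DISPERSION
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(float)
    feats = [f"{prefix}{i:04d}" for i in range(n_features)]
    return pd.DataFrame(counts, columns=feats), feats[:n_informative]


def _sample_methylation(
    rng: np.random.Generator,
    n_samples: int,
    n_features: int,
    n_informative: int,
    effect_size: float,
    group: np.ndarray,
) -> tuple[pd.DataFrame, list[str]]:
    base_mean = rng.uniform(0.2, 0.8, size=n_features)
    delta = np.zeros(n_features)
    sign = np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    delta[:n_informative] = _BETA_SHIFT_PER_EFFECT * effect_size * sign
    mean = base_mean[None, :] + delta[None, :] * (group[:, None] - 1)
    mean = np.clip(mean, 0.02, 0.98)
    kappa = _BETA_CONCENTRATION
    beta = rng.beta(mean * kappa, (1.0 - mean) * kappa)
    feats = [f"meth{i:04d}" for i in range(n_features)]
    return pd.DataFrame(beta, columns=feats), feats[:n_informative]


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[dict[str, OmicsMatrix], ClinicalTable, GroundTruth]:
    """Draw one cohort: three omics blocks, a clinical table, ground truth.

    Returns
    -------
    blocks : dict mapping ``rna`` / ``mirna`` / ``methylation`` to OmicsMatrix
    clinical : ClinicalTable with columns os_time, os_event
    truth : GroundTruth with the planted group and informative feature IDs
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    keys = ("group", "rna", "mirna", "methylation", "survival", "missing")
    rngs = dict(zip(keys, (np.random.default_rng(s) for s in ss.spawn(len(keys)))))

    n = cfg.n_samples
    n2 = int(round(cfg.group_proportion * n))
    group = np.ones(n, dtype=int)
    group[:n2] = 2
    rngs["group"].shuffle(group)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    rna_df, rna_inf = _sample_counts(
        rngs["rna"], n, cfg.n_features["rna"], cfg.n_informative["rna"],
        cfg.effect_size, group, _LOG_MEAN_RNA, "gene",
    )
    mirna_df, mirna_inf = _sample_counts(
        rngs["mirna"], n, cfg.n_features["mirna"], cfg.n_informative["mirna"],
        cfg.effect_size, group, _LOG_MEAN_MIRNA, "mir",
    )
    meth_df, meth_inf = _sample_methylation(
        rngs["methylation"], n, cfg.n_features["methylation"],
        cfg.n_informative["methylation"], cfg.effect_size, group,
    )
    for df in (rna_df, mirna_df, meth_df):
        df.index = pd.Index(sample_ids, name="sample_id")

    # exponential survival: hazard = baseline * HR^(group-1)
    lam1 = cfg.baseline_hazard
    lam2 = cfg.baseline_hazard * cfg.hazard_ratio
    lam = np.where(group == 2, lam2, lam1)
    rng_s = rngs["survival"]
    event_time = rng_s.exponential(1.0 / lam)
    c_rate = _censoring_rate_solve(lam1, lam2, cfg.group_proportion, cfg.censoring_rate)
    if c_rate > 0:
        censor_time = rng_s.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {"os_time": os_time, "os_event": os_event},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    blocks = {
        "rna": OmicsMatrix(rna_df, "rna"),
        "mirna": OmicsMatrix(mirna_df, "mirna"),
        "methylation": OmicsMatrix(meth_df, "methylation"),
    }
    if cfg.missing_rate > 0:
        miss_seeds = rngs["missing"].integers(0, 2**31 - 1, size=3)
        for s, key in zip(miss_seeds, ("rna", "mirna", "methylation")):
            blocks[key] = inject_missingness(blocks[key], cfg.missing_rate, int(s))

    truth = GroundTruth(
        true_group=pd.Series(group, index=pd.Index(sample_ids, name="sample_id")),
        informative={"rna": rna_inf, "mirna": mirna_inf, "methylation": meth_inf},
    )
    return blocks, clinical, truth


def inject_missingness(block: OmicsMatrix, rate: float, seed: int) -> OmicsMatrix:
    """Mask a uniformly random fraction ``rate`` of entries as missing."""
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return OmicsMatrix(block.values.copy(), block.omic)
    rng = np.random.default_rng(seed)
    mask = rng.random(block.values.shape) < rate
    arr = block.values.to_numpy(dtype=float, copy=True)
    arr[mask] = np.nan
    values = pd.DataFrame(arr, index=block.values.index, columns=block.values.columns)
    return OmicsMatrix(values, block.omic)
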