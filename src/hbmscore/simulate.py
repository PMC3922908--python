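"""Synthetic Likert-item responses under the second-order HBM latent model.

The generator is parameterized directly in the standardized metric: the
second-order factor, every first-order factor and every continuous item
variable have population variance 1 (at cohort mean-shift 0, mean 0 too),
so published standardized coefficients can be used verbatim as generating
values.  Disturbance variances are derived from that constraint rather
than supplied.

Two cohorts are produced: a pre-intervention cohort with the second-order
factor centred at 0 and a post-intervention cohort shifted upward by
``delta`` latent standard deviations, mimicking a health-education effect
on underlying health belief.  Responses are either the continuous latent
item variables or their discretization onto the 1-5 Likert scale via four
ascending thresholds.  Missingness, when requested, is MCAR per cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import (
    DEFAULT_SPEC,
    ITEM_COLUMNS,
    REFERENCE_BETA,
    REFERENCE_GAMMA,
    REFERENCE_TOTAL_EFFECTS,
    HBMModelSpec,
)


class ConfigurationError(ValueError):
    """Raised when generator parameters violate the standardized-metric model."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Standardized generating parameters for the synthetic study.

    Parameters
    ----------
    gamma
        Second-order standardized coefficients, one per first-order factor
        in spec order (HB -> SUS, SER, BEN, BAR, CTA); each in (-1, 1).
    beta
        Standardized coefficients of the structural paths among first-order
        factors (one per path in the spec; BAR -> CTA by default).
    loadings
        Standardized loading of each of the 22 items on its assigned factor,
        each in (-1, 1).
    delta
        Mean shift of the second-order factor for the post cohort, in latent
        standard-deviation units.
    n_pre, n_post
        Cohort sizes.
    thresholds
        Four strictly ascending cut-points on the latent response scale;
        category = 1 + number of thresholds below the latent value.
    response_scale
        ``"ordinal"`` (1-5 integer scores) or ``"continuous"``.
    missing_rate
        Per-cell MCAR missingness probability in [0, 1); applied by
        :func:`generate_study` when positive.
    seed
        Master seed; all randomness derives from it.
    """

    gamma: tuple[float, ...] = REFERENCE_GAMMA
    beta: tuple[float, ...] = (REFERENCE_BETA,)
    loadings: tuple[float, ...] = ()
    delta: float = 0.3
    n_pre: int = 843
    n_post: int = 1269
    thresholds: tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)
    response_scale: str = "ordinal"
    missing_rate: float = 0.0
    seed: int = 0
    spec: HBMModelSpec = field(default_factory=lambda: DEFAULT_SPEC)

    def __post_init__(self) -> None:
        if not self.loadings:
            object.__setattr__(self, "loadings", reference_loadings())
        gamma = np.asarray(self.gamma, dtype=float)
        lam = np.asarray(self.loadings, dtype=float)
        if gamma.shape != (self.spec.n_factors,):
            raise ConfigurationError("gamma must have one entry per factor")
        if lam.shape != (self.spec.n_items,):
            raise ConfigurationError("loadings must have one entry per item")
        if len(self.beta) != len(self.spec.structural_paths):
            raise ConfigurationError("beta must have one entry per structural path")
        bad = np.flatnonzero(1.0 - lam**2 <= 0.0)
        if bad.size:
            raise ConfigurationError(
                f"loading for item {bad[0] + 1} implies nonpositive residual variance "
                f"(lambda={lam[bad[0]]:.4g})"
            )
        psi = disturbance_variances(self)
        for k, v in enumerate(psi):
            if v <= 0.0:
                raise ConfigurationError(
                    f"implied disturbance variance of factor {self.spec.factors[k]} "
                    f"is nonpositive ({v:.4g}); reduce gamma/beta magnitudes"
                )
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.ndim != 1 or thr.size < 1 or np.any(np.diff(thr) <= 0):
            raise ConfigurationError("thresholds must be strictly increasing")
        if self.response_scale not in ("ordinal", "continuous"):
            raise ConfigurationError("response_scale must be 'ordinal' or 'continuous'")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.n_pre <= 0 or self.n_post <= 0:
            raise ConfigurationError("cohort sizes must be positive")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("spec")
        for key in ("gamma", "beta", "loadings", "thresholds"):
            d[key] = [float(v) for v in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("gamma", "beta", "loadings", "thresholds"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def reference_loadings() -> tuple[float, ...]:
    """Standardized loadings implied by the reference total effects.

    Each item's loading is its total effect divided by the total effect of
    health belief on its factor (gamma, plus the mediated BAR -> CTA route
    for CTA items).  Loadings are capped at 0.99 in magnitude so every
    implied residual variance stays positive; only item 22, whose published
    rounded total effect marginally exceeds the implied factor-level total
    effect, is affected.
    """
    spec = DEFAULT_SPEC
    gamma = np.asarray(REFERENCE_GAMMA)
    te_factor = gamma.copy()
    k_bar, k_cta = spec.factor_index("BAR"), spec.factor_index("CTA")
    te_factor[k_cta] = gamma[k_cta] + REFERENCE_BETA * gamma[k_bar]
    lam = np.asarray(REFERENCE_TOTAL_EFFECTS) / te_factor[spec.item_factor_indices]
    lam = np.clip(lam, -0.99, 0.99)
    return tuple(float(v) for v in lam)


def reference_config(**overrides) -> GeneratorConfig:
    """Generator configuration encoding the reference standardized solution."""
    base: dict = dict(
        gamma=REFERENCE_GAMMA,
        beta=(REFERENCE_BETA,),
        loadings=reference_loadings(),
    )
    base.update(overrides)
    return GeneratorConfig(**base)


# -- latent algebra --------------------------------------------------------


def _reduced_form(config: GeneratorConfig) -> np.ndarray:
    """A = (I - B)^-1 for the structural matrix among first-order factors."""
    B = config.spec.structural_matrix(np.asarray(config.beta, dtype=float))
    return np.linalg.inv(np.eye(config.spec.n_factors) - B)


def disturbance_variances(config: GeneratorConfig) -> np.ndarray:
    """First-order disturbance variances making every factor variance 1.

    With F = A (gamma * HB + zeta) and Var(HB) = 1, the variance of factor k
    is (a_k' gamma)^2 + sum_j a_kj^2 psi_j.  Solving in topological order
    (a_kk = 1 for an acyclic structure) yields psi_k.
    """
    gamma = np.asarray(config.gamma, dtype=float)
    A = _reduced_form(config)
    n = gamma.size
    psi = np.zeros(n)
    # topological order: process factors by number of ancestors (off-diagonal
    # support of A row); for the default single-path model this is spec order
    order = np.argsort([np.count_nonzero(A[k]) for k in range(n)], kind="stable")
    for k in order:
        systematic = float(A[k] @ gamma) ** 2
        carried = float(np.sum(A[k] ** 2 * psi)) - psi[k] * A[k, k] ** 2
        psi[k] = 1.0 - systematic - carried
    return psi


def population_item_covariance(config: GeneratorConfig) -> np.ndarray:
    """Population covariance of the continuous item variables (a correlation
    matrix in the standardized metric)."""
    spec = config.spec
    gamma = np.asarray(config.gamma, dtype=float)
    lam = np.asarray(config.loadings, dtype=float)
    A = _reduced_form(config)
    psi = disturbance_variances(config)
    phi = A @ (np.outer(gamma, gamma) + np.diag(psi)) @ A.T
    idx = spec.item_factor_indices
    sigma = (lam[:, None] * lam[None, :]) * phi[np.ix_(idx, idx)]
    np.fill_diagonal(sigma, 1.0)
    return sigma


# -- generation ------------------------------------------------------------


def generate_cohort(
    config: GeneratorConfig,
    cohort_label: str,
    n: int,
    mean_shift: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one cohort of item responses from the latent model.

    HB ~ Normal(mean_shift, 1); first-order factors follow the second-order
    and structural equations with disturbances scaled for unit variance;
    item i is ``loadings[i] * F_k(i)`` plus Normal residual of variance
    ``1 - loadings[i]**2``.  Ordinal mode discretizes through the config
    thresholds onto 1..5.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = config.spec
    gamma = np.asarray(config.gamma, dtype=float)
    lam = np.asarray(config.loadings, dtype=float)
    A = _reduced_form(config)
    psi = disturbance_variances(config)

    hb = rng.normal(mean_shift, 1.0, size=n)
    zeta = rng.normal(0.0, np.sqrt(psi), size=(n, spec.n_factors))
    factors = (hb[:, None] * gamma + zeta) @ A.T
    eps = rng.normal(0.0, np.sqrt(1.0 - lam**2), size=(n, spec.n_items))
    y = factors[:, spec.item_factor_indices] * lam + eps

    meta = pd.DataFrame(
        {
            "respondent_id": [f"{cohort_label}_{i + 1:05d}" for i in range(n)],
            "cohort": cohort_label,
            "age": rng.integers(15, 19, size=n),
            "gender": np.where(rng.random(n) < 0.5, "male", "female"),
        }
    )
    cols = [f"item_{i:02d}" for i in range(1, spec.n_items + 1)]
    if config.response_scale == "ordinal":
        scores = np.digitize(y, np.asarray(config.thresholds, dtype=float)) + 1
        items = pd.DataFrame(scores, columns=cols).astype("Int64")
    else:
        items = pd.DataFrame(y, columns=cols)
    return pd.concat([meta, items], axis=1)


def generate_study(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate independent pre (shift 0) and post (shift delta) cohorts.

    MCAR missingness at ``config.missing_rate`` is injected into both
    cohorts when the rate is positive.  All randomness flows from
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4)
    pre = generate_cohort(
        config, "pre", config.n_pre, 0.0, np.random.default_rng(seeds[0])
    )
    post = generate_cohort(
        config, "post", config.n_post, config.delta, np.random.default_rng(seeds[1])
    )
    if config.missing_rate > 0.0:
        pre = inject_missing(pre, config.missing_rate, rng=np.random.default_rng(seeds[2]))
        post = inject_missing(post, config.missing_rate, rng=np.random.default_rng(seeds[3]))
    return pre, post


def inject_missing(
    table: pd.DataFrame,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Set each item cell missing independently with probability ``rate``.

    Metadata columns are untouched.  Returns a new table.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError("missing rate must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = table.copy()
    if rate == 0.0:
        return out
    items = [c for c in out.columns if c in ITEM_COLUMNS]
    mask = rng.random((len(out), len(items))) < rate
    block = out[items]
    if any(pd.api.types.is_integer_dtype(dt) and str(dt) != "Int64" for dt in block.dtypes):
        # promote plain integers to nullable so scores survive masking
        block = block.astype("Int64")
    block = block.mask(pd.DataFrame(mask, index=out.index, columns=items))
    out[items] = block
    return out
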