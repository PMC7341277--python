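"""Beta priors on leak/link probabilities and Monte-Carlo risk summaries.

The leak probability (clinical signs with every modeled risk factor
absent) and the link probabilities (signs produced by one factor alone)
are not known exactly; a degree of belief about each is expressed as a
Beta distribution, the conjugate family for probabilities. This module
elicits Beta shapes from the summaries practitioners actually state
(mean + sd, or mean + concentration), draws from them reproducibly, and
propagates the uncertainty through the noisy-OR risk formula to give the
mean and spread of the disease risk for any combination of active
factors.

Seven packaged prior groups span weak to strong beliefs about the
non-genetic factors (diet, exercise, age; shared mean 10/30/50%) and the
genetic factor (homozygous-mutant genotype; mean 10/50/90%), with the
leak mean fixed at 1% throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .exceptions import InfeasibleMomentsError, ValidationError

__all__ = [
    "BetaSpec",
    "PriorGroup",
    "beta_from_moments",
    "beta_from_mean_concentration",
    "sample",
    "summarize_risk",
    "risk_table",
    "table1_groups",
    "DEFAULT_CONCENTRATION",
    "DEFAULT_LEAK_MEAN",
]

#: Default Beta concentration nu = alpha + beta used when only a mean is
#: stated. nu = 9 at mean 10% gives sd 9.49%, the right order of
#: uncertainty for weakly-informed link probabilities.
DEFAULT_CONCENTRATION = 9.0

#: Default mean of the leak (background) probability: 1%.
DEFAULT_LEAK_MEAN = 0.01


@dataclass(frozen=True)
class BetaSpec:
    """Shape parameters of a Beta prior on a probability."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValidationError("Beta shape parameters must be finite")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError(
                f"Beta shape parameters must be positive, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )

    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def var(self) -> float:
        nu = self.alpha + self.beta
        return self.alpha * self.beta / (nu * nu * (nu + 1.0))

    def sd(self) -> float:
        return math.sqrt(self.var())

    def concentration(self) -> float:
        return self.alpha + self.beta


#: A prior is either a proper Beta or a point mass (degenerate, sd = 0).
PriorLike = Union[BetaSpec, float]


def prior_mean(prior: PriorLike) -> float:
    """Mean of a BetaSpec or a point-mass float."""
    if isinstance(prior, BetaSpec):
        return prior.mean()
    p = float(prior)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"point-mass probability {p} outside [0, 1]")
    return p


@dataclass(frozen=True)
class PriorGroup:
    """One column of prior settings: leak, shared non-genetic link, genetic link.

    ``link_ng`` is shared by the three non-genetic factors (diet,
    exercise, age). Fields may be point-mass floats for degenerate
    (no-uncertainty) settings.
    """

    label: str
    leak: PriorLike
    link_ng: PriorLike
    link_g: PriorLike

    def __post_init__(self) -> None:
        for name in ("leak", "link_ng", "link_g"):
            prior_mean(getattr(self, name))  # validates range

    def means(self) -> tuple[float, float, float]:
        return (
            prior_mean(self.leak),
            prior_mean(self.link_ng),
            prior_mean(self.link_g),
        )


def beta_from_moments(mean: float, sd: float) -> BetaSpec:
    """Beta spec with exactly the given mean and standard deviation.

    Solves the moment equations: with concentration
    ``nu = mean*(1-mean)/sd**2 - 1``, set ``alpha = mean*nu`` and
    ``beta = (1-mean)*nu``. Raises :class:`InfeasibleMomentsError` when
    ``sd**2 >= mean*(1-mean)`` (no Beta distribution is that dispersed).
    """
    if not (math.isfinite(mean) and math.isfinite(sd)):
        raise ValidationError("mean and sd must be finite")
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"mean must lie strictly in (0, 1), got {mean}")
    if sd <= 0.0:
        raise ValidationError(f"sd must be positive, got {sd}")
    limit = mean * (1.0 - mean)
    if sd * sd >= limit:
        raise InfeasibleMomentsError(
            f"infeasible moments: sd^2 = {sd * sd:.6g} must be below "
            f"mean*(1-mean) = {limit:.6g}"
        )
    nu = limit / (sd * sd) - 1.0
    return BetaSpec(alpha=mean * nu, beta=(1.0 - mean) * nu)


def beta_from_mean_concentration(mean: float, nu: float = DEFAULT_CONCENTRATION) -> BetaSpec:
    """Beta spec from a mean and a concentration ``nu = alpha + beta``."""
    if not (math.isfinite(mean) and math.isfinite(nu)):
        raise ValidationError("mean and nu must be finite")
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"mean must lie strictly in (0, 1), got {mean}")
    if nu <= 0.0:
        raise ValidationError(f"concentration nu must be positive, got {nu}")
    return BetaSpec(alpha=mean * nu, beta=(1.0 - mean) * nu)


def sample(spec: PriorLike, n: int, seed) -> np.ndarray:
    """Draw ``n`` values from a prior, reproducibly.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    Generator. Point-mass priors return a constant vector.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(spec, BetaSpec):
        return rng.beta(spec.alpha, spec.beta, size=n)
    return np.full(n, prior_mean(spec))


def table1_groups(nu: float = DEFAULT_CONCENTRATION) -> dict[int, PriorGroup]:
    """The seven packaged prior groups.

    Non-genetic link means cycle through 10/30% (50% in group 7); genetic
    link means through 10/50/90% (50% in group 7); leak mean is 1%
    everywhere. All priors use the same concentration ``nu``.
    """
    ng_means = {1: 0.10, 2: 0.30, 3: 0.10, 4: 0.30, 5: 0.10, 6: 0.30, 7: 0.50}
    g_means = {1: 0.10, 2: 0.10, 3: 0.50, 4: 0.50, 5: 0.90, 6: 0.90, 7: 0.50}
    return {
        k: PriorGroup(
            label=f"group {k}",
            leak=beta_from_mean_concentration(DEFAULT_LEAK_MEAN, nu),
            link_ng=beta_from_mean_concentration(ng_means[k], nu),
            link_g=beta_from_mean_concentration(g_means[k], nu),
        )
        for k in range(1, 8)
    }


def _spawn(seed, n_children: int) -> list[np.random.Generator]:
    """Split one root seed into independent child generators.

    Each sampled quantity gets its own child stream, so adding a new
    query never perturbs the draws of an existing one.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_children)]


def summarize_risk(
    group: PriorGroup,
    n_ng_active: int,
    g_active: bool,
    n_draws: int = 10_000,
    seed=0,
    draw_mode: str = "independent",
) -> tuple[float, float]:
    """Monte-Carlo mean and sd of the noisy-OR risk under a prior group.

    Per draw, sample the leak ``l`` and the link probability of every
    active cause, then evaluate ``1 - (1-l) * prod(1 - p_i)``. In
    ``independent`` mode each active non-genetic cause is a separate
    mechanism with its own draw; in ``shared_ng`` one non-genetic draw is
    reused for all active non-genetic causes within a realization.

    Draws are common across calls with the same seed: the k active
    non-genetic causes use the first k columns of one fixed draw matrix,
    so risk summaries are monotone in ``n_ng_active`` draw by draw.
    """
    if n_draws < 2:
        raise ValidationError(f"n_draws must be >= 2, got {n_draws}")
    if not 0 <= n_ng_active <= 3:
        raise ValidationError(f"n_ng_active must be in 0..3, got {n_ng_active}")
    if draw_mode not in ("independent", "shared_ng"):
        raise ValidationError(f"unknown draw_mode {draw_mode!r}")

    rng_leak, rng_ng, rng_g = _spawn(seed, 3)
    leak = sample(group.leak, n_draws, rng_leak)
    survive = 1.0 - leak  # probability that no mechanism fires
    if n_ng_active:
        if draw_mode == "independent":
            ng = np.column_stack(
                [sample(group.link_ng, n_draws, rng_ng) for _ in range(3)]
            )
        else:
            ng = np.repeat(sample(group.link_ng, n_draws, rng_ng)[:, None], 3, axis=1)
        survive = survive * np.prod(1.0 - ng[:, :n_ng_active], axis=1)
    if g_active:
        survive = survive * (1.0 - sample(group.link_g, n_draws, rng_g))
    risk = 1.0 - survive
    return float(risk.mean()), float(risk.std(ddof=1))


#: Row labels of the packaged risk summary table, in reporting order.
RISK_TABLE_ROWS = ("NG1", "NG2", "NG3", "G", "NG1+G", "NG2+G", "NG3+G")


def risk_table(
    group: PriorGroup,
    n_draws: int = 10_000,
    seed=0,
    draw_mode: str = "independent",
):
    """Risk summary for one prior group, as a DataFrame in percent.

    Rows: one, two or three non-genetic factors active (NG1..NG3), the
    genetic factor alone (G), and combinations (NGk+G). Columns:
    ``mean_pct`` and ``sd_pct``.
    """
    import pandas as pd

    rows = {}
    for label in RISK_TABLE_ROWS:
        g_active = label.endswith("+G") or label == "G"
        n_ng = int(label[2]) if label.startswith("NG") else 0
        mean, sd = summarize_risk(group, n_ng, g_active, n_draws, seed, draw_mode)
        rows[label] = (100.0 * mean, 100.0 * sd)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["mean_pct", "sd_pct"])
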