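"""Pooling mined effects into zero-centered Normal priors on the log-HR scale.

Each screened study contributes a log hazard ratio b_i and its standard error
SE(b_i), the latter recovered from the reported confidence interval,

    SE(b_i) = (log HR_u - log HR_l) / (2 z*),   z* = Q(1 - alpha/2),

with Q the standard-Normal quantile function.  Because the sign of b_i is an
artifact of arm coding, each study enters sign-symmetrized (+b_i and -b_i),
which forces the pooled mean to 0.  The prior standard deviation is the
pooled standard deviation of the merged per-study samples under an assumed
common per-study size n (default 200):

    sigma_p = sqrt( ((n-1) * sum SE_i^2 + n * sum b_i^2) / (N n - 1) ).

Large-SE studies widen the prior rather than being down-weighted — this is a
deliberate departure from inverse-variance meta-analytic weighting, whose
pooled interval would shrink indefinitely with corpus size.  A sensitivity
analysis redraws the per-study sizes uniformly to probe the constant-n
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StudyEffect",
    "Corpus",
    "PriorSpec",
    "SensitivityResult",
    "se_from_ci",
    "pooled_mu",
    "pooled_sigma",
    "pooled_sigma_varying",
    "sensitivity_sigma",
    "prior_from_corpus",
]


@dataclass(frozen=True)
class StudyEffect:
    """One study's log hazard ratio and its standard error."""

    b: float
    se: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.b):
            raise ValueError("b must be finite")
        if self.se < 0 or not np.isfinite(self.se):
            raise ValueError("se must be finite and >= 0")


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of study effects for one subfield."""

    subfield: str
    effects: tuple[StudyEffect, ...]

    @property
    def n_studies(self) -> int:
        return len(self.effects)

    @property
    def b(self) -> np.ndarray:
        return np.array([e.b for e in self.effects])

    @property
    def se(self) -> np.ndarray:
        return np.array([e.se for e in self.effects])

    @classmethod
    def from_arrays(
        cls, b: Sequence[float], se: Sequence[float], subfield: str = ""
    ) -> "Corpus":
        b = np.asarray(b, dtype=float)
        se = np.asarray(se, dtype=float)
        if b.shape != se.shape:
            raise ValueError("b and se must have the same length")
        return cls(subfield, tuple(StudyEffect(float(x), float(s)) for x, s in zip(b, se)))


@dataclass(frozen=True)
class PriorSpec:
    """A Normal prior on the Cox log hazard ratio, optionally truncated at 0.

    ``truncation='positive'`` keeps the half-line beta > 0 (renormalized),
    ``'negative'`` the half-line beta < 0, ``'none'`` the whole line.
    """

    mu: float
    sigma: float
    family: str = "normal"
    truncation: str = "none"

    def __post_init__(self) -> None:
        if self.sigma <= 0 or not np.isfinite(self.sigma):
            raise ValueError("sigma must be positive and finite")
        if self.family != "normal":
            raise ValueError("only the Normal family is supported")
        if self.truncation not in ("none", "positive", "negative"):
            raise ValueError("truncation must be none/positive/negative")

    def truncate(self, truncation: str) -> "PriorSpec":
        return PriorSpec(self.mu, self.sigma, self.family, truncation)

    def support(self) -> tuple[float, float]:
        if self.truncation == "positive":
            return (0.0, np.inf)
        if self.truncation == "negative":
            return (-np.inf, 0.0)
        return (-np.inf, np.inf)

    def logpdf(self, beta):
        """Log density, with the truncated half renormalized."""
        beta = np.asarray(beta, dtype=float)
        out = stats.norm.logpdf(beta, self.mu, self.sigma)
        if self.truncation == "positive":
            out = np.where(
                beta >= 0.0,
                out - stats.norm.logsf(0.0, self.mu, self.sigma),
                -np.inf,
            )
        elif self.truncation == "negative":
            out = np.where(
                beta <= 0.0,
                out - stats.norm.logcdf(0.0, self.mu, self.sigma),
                -np.inf,
            )
        return out if out.ndim else float(out)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Seeded draws, truncation by reflection (valid for mu = 0) or rejection."""
        draws = rng.normal(self.mu, self.sigma, size=size)
        if self.truncation == "none":
            return draws
        if self.mu == 0.0:
            draws = np.abs(draws)
            return draws if self.truncation == "positive" else -draws
        keep_pos = self.truncation == "positive"
        out = draws[(draws > 0) if keep_pos else (draws < 0)]
        while out.size < size:
            extra = rng.normal(self.mu, self.sigma, size=size)
            extra = extra[(extra > 0) if keep_pos else (extra < 0)]
            out = np.concatenate([out, extra])
        return out[:size]


@dataclass(frozen=True)
class SensitivityResult:
    """Monte-Carlo distribution of sigma_p under redrawn per-study sizes."""

    sigmas: np.ndarray
    reps: int
    n_low: int
    n_high: int
    seed: int

    def summary(self) -> dict[str, float]:
        q1, med, q3 = np.percentile(self.sigmas, [25, 50, 75])
        return {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "iqr": float(q3 - q1),
            "min": float(self.sigmas.min()),
            "max": float(self.sigmas.max()),
        }


def se_from_ci(hr_lower: float, hr_upper: float, level: float) -> float:
    """Standard error of the log hazard ratio from a reported CI.

    ``level`` is the confidence level in percent (e.g. 95).  Uses
    SE = (log HR_u - log HR_l) / (2 z*) with z* = Q(1 - alpha/2).
    """
    if not 0.0 < level < 100.0:
        raise ValueError(f"confidence level must lie in (0, 100), got {level}")
    if hr_lower <= 0.0 or hr_upper <= 0.0:
        raise ValueError("interval bounds must be strictly positive")
    if hr_lower > hr_upper:
        raise ValueError("hr_lower must not exceed hr_upper")
    z = stats.norm.ppf(0.5 + level / 200.0)
    return float((np.log(hr_upper) - np.log(hr_lower)) / (2.0 * z))


def _require_nonempty(corpus: Corpus) -> None:
    if corpus.n_studies < 1:
        raise ValueError("corpus must contain at least one study")


def pooled_mu(corpus: Corpus) -> float:
    """Pooled prior mean: identically 0 under sign symmetrization.

    Each study enters as both +b_i and -b_i because the sign of the log HR
    depends on arbitrary arm coding, so the pooled mean cancels exactly.
    """
    _require_nonempty(corpus)
    return 0.0


def pooled_sigma(corpus: Corpus, n: int = 200) -> float:
    """Pooled prior standard deviation at a constant assumed per-study size n."""
    _require_nonempty(corpus)
    if n < 2:
        raise ValueError("assumed per-study size n must be >= 2")
    b2 = np.sum(corpus.b**2)
    se2 = np.sum(corpus.se**2)
    N = corpus.n_studies
    return float(np.sqrt(((n - 1) * se2 + n * b2) / (N * n - 1)))


def pooled_sigma_varying(corpus: Corpus, sizes: Sequence[int]) -> float:
    """Pooled prior SD with per-study sizes n_i; equals :func:`pooled_sigma`
    when all n_i coincide."""
    _require_nonempty(corpus)
    sizes = np.asarray(sizes)
    if sizes.shape != (corpus.n_studies,):
        raise ValueError("sizes must have one entry per study")
    if np.any(sizes < 2):
        raise ValueError("every per-study size must be >= 2")
    num = np.sum((sizes - 1) * corpus.se**2) + np.sum(sizes * corpus.b**2)
    return float(np.sqrt(num / (np.sum(sizes) - 1)))


def sensitivity_sigma(
    corpus: Corpus,
    reps: int = 100_000,
    n_low: int = 10,
    n_high: int = 10_000,
    seed: int = 0,
) -> SensitivityResult:
    """Distribution of sigma_p when per-study sizes are redrawn uniformly.

    Each repetition draws n_i independently from the discrete uniform on
    [n_low, n_high] (sizes are counts) and recomputes the pooled SD.
    Deterministic given ``seed``.
    """
    _require_nonempty(corpus)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 2 <= n_low <= n_high:
        raise ValueError("need 2 <= n_low <= n_high")
    rng = np.random.default_rng(seed)
    b2 = corpus.b**2
    se2 = corpus.se**2
    sizes = rng.integers(n_low, n_high + 1, size=(reps, corpus.n_studies))
    num = (sizes - 1) @ se2 + sizes @ b2
    sigmas = np.sqrt(num / (sizes.sum(axis=1) - 1))
    return SensitivityResult(sigmas=sigmas, reps=reps, n_low=n_low, n_high=n_high, seed=seed)


def prior_from_corpus(corpus: Corpus, n: int = 200) -> PriorSpec:
    """Zero-centered Normal prior pooled from a corpus.

    Raises for degenerate corpora (all b and SE zero): a Normal prior needs a
    strictly positive scale.
    """
    sigma = pooled_sigma(corpus, n=n)
    if sigma <= 0.0:
        raise ValueError(
            f"degenerate corpus for {corpus.subfield!r}: pooled sigma is 0"
        )
    return PriorSpec(mu=pooled_mu(corpus), sigma=sigma)
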