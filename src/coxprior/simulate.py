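"""Synthetic inputs for every pipeline stage.

Three generators, all deterministic under a seed:

* :func:`gen_abstracts` — templated abstracts that embed a known hazard-ratio
  tuple rendered in one of the reporting variants the miner accepts, plus
  decoy sentences (HR-with-p-value, "heart rate (HR)") that must never be
  extracted.  A ground-truth ledger records the printed numbers, so mining
  can be validated by exact round-trip.
* :func:`gen_effect_corpus` — study corpora of (log HR, SE) pairs whose
  population moments are set directly, a statistical stand-in for mined
  subfield corpora.
* :func:`gen_survival` — two-arm exponential survival data under the
  proportional-hazards model with independent exponential censoring and/or an
  administrative cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cox import SurvivalDataset
from .mining import ExtractedEffect, screen_effect
from .pooling import Corpus, se_from_ci

__all__ = [
    "AbstractTemplateConfig",
    "EffectCorpusConfig",
    "TrialConfig",
    "default_journal_lists",
    "gen_abstracts",
    "gen_effect_corpus",
    "gen_survival",
]


@dataclass(frozen=True)
class AbstractTemplateConfig:
    """Study conditions for the abstract generator.

    ``p_complete`` is the probability an abstract carries one full HR+CI
    tuple (default 0.6, matching the observed ~60% extraction success rate on
    real corpora); ``p_decoy`` the probability of an added decoy sentence.
    ``level_mix`` puts most mass on 95% intervals, the dominant convention.
    """

    n_articles: int = 100
    p_complete: float = 0.6
    p_decoy: float = 0.3
    format_mix: Optional[dict[int, float]] = None
    level_mix: dict[float, float] = field(
        default_factory=lambda: {95.0: 0.9, 90.0: 0.05, 99.0: 0.05}
    )
    seed: int = 0
    journals: tuple[str, ...] = (
        "Journal of Synthetic Oncology",
        "Annals of Synthetic Cardiology",
        "Synthetic Gastroenterology, The",
        "Heart & Vessel Letters",
        "PAIN SIMULANS",
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_complete <= 1.0 or not 0.0 <= self.p_decoy <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_articles < 0:
            raise ValueError("n_articles must be >= 0")


@dataclass(frozen=True)
class EffectCorpusConfig:
    """Study conditions for synthetic effect corpora.

    True log hazard ratios are folded-Normal magnitudes with random sign,
    b_i = s_i |z_i| tau (heavy mass near zero, occasional large effects);
    standard errors follow SE_i = c / sqrt(n_i) with n_i uniform on
    ``size_range``, linking per-study precision to sample size.  Defaults are
    calibrated so E[b^2] = tau^2 ~ 0.87 and E[SE^2] ~ 0.1, the typical
    magnitudes of mined biomedical corpora.
    """

    N: int = 1000
    tau: float = 0.933
    size_range: tuple[int, int] = (30, 3000)
    baseline_se_const: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.tau < 0 or self.baseline_se_const < 0:
            raise ValueError("tau and baseline_se_const must be >= 0")
        if not 2 <= self.size_range[0] <= self.size_range[1]:
            raise ValueError("need 2 <= n_low <= n_high")


@dataclass(frozen=True)
class TrialConfig:
    """Two-arm exponential trial under proportional hazards.

    Event times are exponential with rate ``baseline_rate * exp(true_beta)``
    in the treated arm; censoring is independent exponential with
    ``censor_rate`` (0 disables) and/or an administrative ``cutoff``.
    """

    n_per_arm: int = 500
    true_beta: float = 0.7
    baseline_rate: float = 0.1
    censor_rate: float = 0.02
    cutoff: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.baseline_rate <= 0 or self.censor_rate < 0:
            raise ValueError("rates must be positive (censor_rate may be 0)")


# Reporting variants: head token, separator, interval template.
_HEADS = (
    "HR",
    "H.R.",
    "hazard ratio",
    "hazards ratio",
    "hazard ratios",
    "hazard ratio (HR)",
    "hazards ratio [HR]",
)
_SEPS = ("=", " = ", ":", " : ")
_CI_TEMPLATES = (
    "({level}% CI: {lower}-{upper})",
    "({level}% CI {lower} to {upper})",
    "({level}% CI, {lower}-{upper})",
    "(CI {level}%: {lower}, {upper})",
    "; {level}% confidence interval: {lower}–{upper}",
)
_FILLERS = (
    "We enrolled patients in a multicenter cohort.",
    "Outcomes were assessed by blinded adjudicators.",
    "Median follow-up was 4.2 years.",
    "Baseline characteristics were balanced between groups.",
)
_DECOYS = (
    "Mean heart rate (HR) was 72 bpm at baseline.",
    "The treatment effect was significant (HR = 1.8, p = 0.02).",
    "A Cox model gave hazard ratio = 2.3, p = 0.01 for the endpoint.",
)


def default_journal_lists() -> pd.DataFrame:
    """Subfield/journal table for the synthetic journal pool.

    One journal is shared between two subfields to exercise multi-allocation.
    """
    rows = [
        ("synthetic oncology", "Journal of Synthetic Oncology"),
        ("synthetic oncology", "Synthetic Gastroenterology, The"),
        ("synthetic cardiology", "Annals of Synthetic Cardiology"),
        ("synthetic cardiology", "Heart & Vessel Letters"),
        ("synthetic cardiology", "PAIN SIMULANS"),
        ("synthetic anesthesiology", "PAIN SIMULANS"),
    ]
    return pd.DataFrame(rows, columns=["subfield", "journal"])


def _format_level(level: float) -> str:
    return f"{level:g}"


def _render_tuple(rng: np.random.Generator, level: float) -> tuple[str, dict]:
    """Draw a true effect, round it for printing, and render one sentence.

    Rounds at 1-2 decimals (redrawing/refining until the printed tuple passes
    screening, so every embedded tuple survives the validity checks by
    construction) and returns the sentence plus the ledger entry with both
    true and printed values.
    """
    for _ in range(1000):
        b_true = float(rng.choice([-1.0, 1.0]) * np.abs(rng.standard_normal()) * 0.9)
        n_i = int(rng.integers(30, 3001))
        se_true = 4.0 / np.sqrt(n_i)
        zstar = float(stats.norm.ppf(0.5 + level / 200.0))
        hr, lower, upper = (
            np.exp(b_true),
            np.exp(b_true - zstar * se_true),
            np.exp(b_true + zstar * se_true),
        )
        for d in (int(rng.integers(1, 3)), 2, 3, 4):
            printed = ExtractedEffect(
                hr=round(hr, d),
                level=level,
                hr_lower=round(lower, d),
                hr_upper=round(upper, d),
                decimals_hr=d,
                decimals_lower=d,
                decimals_upper=d,
            )
            if (
                screen_effect(printed).passed
                and printed.hr_lower < printed.hr_upper
            ):
                head = _HEADS[rng.integers(len(_HEADS))]
                sep = _SEPS[rng.integers(len(_SEPS))]
                tmpl = _CI_TEMPLATES[rng.integers(len(_CI_TEMPLATES))]
                fmt = f"{{:.{d}f}}"
                ci = tmpl.format(
                    level=_format_level(level),
                    lower=fmt.format(printed.hr_lower),
                    upper=fmt.format(printed.hr_upper),
                )
                sentence = (
                    f"The primary endpoint favored treatment, "
                    f"{head}{sep}{fmt.format(printed.hr)} {ci}."
                )
                ledger = {
                    "hr": printed.hr,
                    "level": level,
                    "hr_lower": printed.hr_lower,
                    "hr_upper": printed.hr_upper,
                    "decimals": d,
                    "b_true": b_true,
                    "se_true": se_true,
                    "b_printed": float(np.log(printed.hr)),
                    "se_printed": se_from_ci(printed.hr_lower, printed.hr_upper, level),
                }
                return sentence, ledger
    raise RuntimeError("could not render a screen-passing tuple")  # pragma: no cover


def gen_abstracts(cfg: AbstractTemplateConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate templated abstracts and their ground-truth ledger.

    Returns ``(articles, ledger)``: articles has columns
    ``article_id, journal, abstract``; the ledger one row per article with
    ``has_tuple, has_decoy`` flags and, for complete articles, the printed
    tuple and the underlying true (b, SE).
    """
    rng = np.random.default_rng(cfg.seed)
    levels = np.array(sorted(cfg.level_mix))
    weights = np.array([cfg.level_mix[l] for l in levels], dtype=float)
    weights = weights / weights.sum()

    articles = []
    ledger_rows = []
    for i in range(cfg.n_articles):
        article_id = f"A{i:05d}"
        journal = cfg.journals[rng.integers(len(cfg.journals))]
        complete = rng.random() < cfg.p_complete
        decoy = rng.random() < cfg.p_decoy
        sentences = [_FILLERS[rng.integers(len(_FILLERS))]]
        row: dict = {"article_id": article_id, "has_tuple": complete, "has_decoy": decoy}
        if decoy:
            sentences.append(_DECOYS[rng.integers(len(_DECOYS))])
        if complete:
            level = float(rng.choice(levels, p=weights))
            sentence, ledger = _render_tuple(rng, level)
            sentences.append(sentence)
            row.update(ledger)
        sentences.append(_FILLERS[rng.integers(len(_FILLERS))])
        articles.append(
            {"article_id": article_id, "journal": journal, "abstract": " ".join(sentences)}
        )
        ledger_rows.append(row)
    return pd.DataFrame(articles), pd.DataFrame(ledger_rows)


def gen_effect_corpus(cfg: EffectCorpusConfig) -> Corpus:
    """Synthetic corpus of (b, SE) study effects; see
    :class:`EffectCorpusConfig` for the generative model."""
    rng = np.random.default_rng(cfg.seed)
    signs = rng.choice([-1.0, 1.0], size=cfg.N)
    b = signs * np.abs(rng.standard_normal(cfg.N)) * cfg.tau
    sizes = rng.integers(cfg.size_range[0], cfg.size_range[1] + 1, size=cfg.N)
    se = cfg.baseline_se_const / np.sqrt(sizes)
    return Corpus.from_arrays(b, se, subfield="synthetic")


def gen_survival(cfg: TrialConfig) -> SurvivalDataset:
    """Two-arm exponential survival data under the proportional-hazards model."""
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_arm
    arm = np.repeat([0, 1], cfg.n_per_arm)
    rate = cfg.baseline_rate * np.exp(cfg.true_beta * arm)
    event_time = rng.exponential(1.0 / rate)
    time = event_time
    event = np.ones(n, dtype=int)
    if cfg.censor_rate > 0:
        censor_time = rng.exponential(1.0 / cfg.censor_rate, size=n)
        event = (event_time <= censor_time).astype(int)
        time = np.minimum(event_time, censor_time)
    if cfg.cutoff is not None:
        event = np.where(time <= cfg.cutoff, event, 0)
        time = np.minimum(time, cfg.cutoff)
    order = rng.permutation(n)
    return SurvivalDataset(time=time, event=event, arm=arm, entry_order=order)
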