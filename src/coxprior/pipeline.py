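"""End-to-end pipeline: mine -> screen -> pool, with optional sensitivity and
sequential Bayes-factor stages, plus run accounting.

The manifest mirrors the corpus bookkeeping table of the mining stage:
per subfield, the number of article allocations, the number with a successful
extraction, and the number surviving the validity screen (considered <=
matched <= allocated by construction).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as cio
from .cox import sequential_bf
from .mining import (
    ArticleRecord,
    allocate_subfields,
    build_subfield_index,
    extract_first_effect,
    screen_effect,
)
from .pooling import prior_from_corpus, sensitivity_sigma

logger = logging.getLogger("coxprior")

__all__ = ["PipelineConfig", "RunManifest", "mine_articles", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run."""

    articles_path: str
    journals_path: str
    out_dir: str
    n_assumed: int = 200
    keep_failed: bool = False
    sensitivity_reps: int = 0
    sensitivity_range: tuple[int, int] = (10, 10_000)
    survival_path: Optional[str] = None
    bf_subfield: Optional[str] = None
    bf_side: str = "positive"
    thresholds: tuple[float, float] = (1 / 20, 20.0)
    step: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        # identifies the analysis (inputs + parameters), not the output location
        items = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.md5(repr(sorted(items.items())).encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    """Per-subfield allocated/matched/considered counts plus run metadata."""

    counts: dict[str, dict[str, int]]
    config_hash: str
    seed: int
    started_at: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def validate(self) -> None:
        for subfield, c in self.counts.items():
            if not c["considered"] <= c["matched"] <= c["allocated"]:
                raise AssertionError(
                    f"count ordering violated for {subfield!r}: {c}"
                )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"subfield": sf, **c} for sf, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["subfield", "allocated", "matched", "considered"])


def mine_articles(
    articles: pd.DataFrame, journal_lists: pd.DataFrame, keep_failed: bool = False
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Allocate, extract, and screen every article; return the effects table
    and per-subfield counts.

    An article allocated to several subfields contributes its effect to each
    of them.  With ``keep_failed`` the table also carries screened-out rows
    (flagged by ``passed`` and ``reason_codes``).
    """
    index = build_subfield_index(journal_lists)
    counts: dict[str, dict[str, int]] = {
        sf: {"allocated": 0, "matched": 0, "considered": 0} for sf in index
    }
    rows = []
    for rec in articles.itertuples(index=False):
        record = ArticleRecord(str(rec.article_id), str(rec.journal), str(rec.abstract))
        subfields = allocate_subfields(record, index)
        if not subfields:
            continue
        effect = extract_first_effect(record.abstract)
        report = screen_effect(effect) if effect is not None else None
        for sf in sorted(subfields):
            counts[sf]["allocated"] += 1
            if effect is None:
                continue
            counts[sf]["matched"] += 1
            if report.passed:
                counts[sf]["considered"] += 1
            if report.passed or keep_failed:
                rows.append(
                    {
                        "article_id": record.article_id,
                        "subfield": sf,
                        "hr": effect.hr,
                        "level": effect.level,
                        "hr_lower": effect.hr_lower,
                        "hr_upper": effect.hr_upper,
                        "decimals_hr": effect.decimals_hr,
                        "decimals_lower": effect.decimals_lower,
                        "decimals_upper": effect.decimals_upper,
                        "passed": report.passed,
                        "reason_codes": ";".join(report.reason_codes),
                    }
                )
    columns = [
        "article_id", "subfield", "hr", "level", "hr_lower", "hr_upper",
        "decimals_hr", "decimals_lower", "decimals_upper", "passed", "reason_codes",
    ]
    effects = pd.DataFrame(rows, columns=columns)
    for sf in sorted(counts):
        c = counts[sf]
        logger.info(
            "%s: allocated=%d matched=%d considered=%d",
            sf, c["allocated"], c["matched"], c["considered"],
        )
    return effects, counts


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute mine -> screen -> pool (-> sensitivity -> sequential BF).

    Writes ``effects.csv``, ``priors.txt``, ``manifest.csv`` and, when
    requested, ``sensitivity.csv`` and ``trajectory.csv`` under ``out_dir``.
    Artifacts embed the config hash and seed in a header comment; re-running
    with the same inputs and seed reproduces them byte for byte.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={cfg.config_hash()} seed={cfg.seed}"

    try:
        articles = cio.read_articles(cfg.articles_path)
        journal_lists = cio.read_journal_lists(cfg.journals_path)
    except Exception as err:  # noqa: BLE001 - stage context for the operator
        raise RuntimeError(f"stage=read inputs failed: {err}") from err

    effects, counts = mine_articles(articles, journal_lists, keep_failed=cfg.keep_failed)
    manifest = RunManifest(counts=counts, config_hash=cfg.config_hash(), seed=cfg.seed)
    manifest.validate()
    cio.write_effects(effects, out_dir / "effects.csv", comment=stamp)
    cio._write_csv(manifest.to_dataframe(), out_dir / "manifest.csv", comment=stamp)

    total_matched = sum(c["matched"] for c in counts.values())
    total_considered = sum(c["considered"] for c in counts.values())
    if total_matched > 0 and total_considered == 0:
        raise RuntimeError(
            "stage=pool failed: every record was screened out (N=0 in all subfields)"
        )
    if total_considered == 0:
        logger.warning("no screened effects: no prior emitted")
        (out_dir / "priors.txt").write_text(
            f"# {stamp}\n# no screened effects\n", encoding="utf-8"
        )
        return manifest
    corpora = cio.effects_to_corpora(effects)

    prior_lines = [f"# {stamp}"]
    priors = {}
    for subfield, corpus in sorted(corpora.items()):
        prior = prior_from_corpus(corpus, n=cfg.n_assumed)
        priors[subfield] = prior
        prior_lines += [
            f"subfield: {subfield}",
            f"family: {prior.family}",
            f"mu: {prior.mu!r}",
            f"sigma: {prior.sigma!r}",
            f"truncation: {prior.truncation}",
            f"n_assumed: {cfg.n_assumed}",
            f"n_studies: {corpus.n_studies}",
            "",
        ]
        logger.info("prior[%s]: N(0, %.3f) from N=%d", subfield, prior.sigma, corpus.n_studies)
    (out_dir / "priors.txt").write_text("\n".join(prior_lines), encoding="utf-8")

    if cfg.sensitivity_reps > 0:
        frames = []
        for subfield, corpus in sorted(corpora.items()):
            res = sensitivity_sigma(
                corpus,
                reps=cfg.sensitivity_reps,
                n_low=cfg.sensitivity_range[0],
                n_high=cfg.sensitivity_range[1],
                seed=cfg.seed,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "subfield": subfield,
                        "rep": range(res.reps),
                        "sigma": res.sigmas,
                    }
                )
            )
        cio._write_csv(pd.concat(frames, ignore_index=True), out_dir / "sensitivity.csv", comment=stamp)

    if cfg.survival_path is not None:
        subfield = cfg.bf_subfield or (sorted(priors)[0] if priors else None)
        if subfield is None or subfield not in priors:
            raise RuntimeError(f"stage=bf failed: no prior for subfield {subfield!r}")
        data = cio.read_survival(cfg.survival_path)
        trajectory = sequential_bf(
            data,
            priors[subfield],
            side=cfg.bf_side,
            thresholds=cfg.thresholds,
            step=cfg.step,
            order_seed=None if data.entry_order is not None else cfg.seed,
        )
        cio.write_trajectory(trajectory, out_dir / "trajectory.csv", extra_comment=stamp)
    return manifest
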