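"""CSV and plain-text readers/writers for the pipeline surfaces.

All tabular artifacts are UTF-8 CSV with a header row and "." decimals;
prior specifications are plain-text ``key: value`` files.  Writers accept an
optional header comment (config hash, seed) emitted as ``#``-prefixed lines,
which every reader skips.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .cox import SurvivalDataset
from .pooling import Corpus, PriorSpec, se_from_ci

import numpy as np

__all__ = [
    "read_articles",
    "read_journal_lists",
    "write_effects",
    "read_effects",
    "effects_to_corpora",
    "write_prior_spec",
    "read_prior_spec",
    "read_survival",
    "write_survival",
    "write_trajectory",
]

PathLike = Union[str, Path]


def _write_csv(df: pd.DataFrame, path: PathLike, comment: Optional[str] = None) -> None:
    buf = _io.StringIO()
    if comment:
        for line in comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _read_csv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", encoding="utf-8", **kwargs)


def read_articles(path: PathLike) -> pd.DataFrame:
    """Article table: columns article_id, journal, abstract."""
    df = _read_csv(path, dtype={"article_id": str, "journal": str, "abstract": str})
    missing = {"article_id", "journal", "abstract"} - set(df.columns)
    if missing:
        raise ValueError(f"articles file missing columns: {sorted(missing)}")
    df["abstract"] = df["abstract"].fillna("")
    return df


def read_journal_lists(path: PathLike) -> pd.DataFrame:
    """Journal lists: columns subfield, journal."""
    df = _read_csv(path, dtype=str)
    missing = {"subfield", "journal"} - set(df.columns)
    if missing:
        raise ValueError(f"journal list file missing columns: {sorted(missing)}")
    return df


def write_effects(df: pd.DataFrame, path: PathLike, comment: Optional[str] = None) -> None:
    _write_csv(df, path, comment)


def read_effects(path: PathLike) -> pd.DataFrame:
    return _read_csv(path)


def effects_to_corpora(effects: pd.DataFrame) -> dict[str, Corpus]:
    """Per-subfield corpora from an effects table.

    Accepts either pre-converted columns ``subfield, b, se`` or the raw miner
    output (``subfield, hr, level, hr_lower, hr_upper, passed``), which is
    log-transformed and converted via the CI-to-SE rule; failed rows are
    dropped.
    """
    if {"b", "se"} <= set(effects.columns):
        work = effects[["subfield", "b", "se"]].copy()
    else:
        required = {"subfield", "hr", "level", "hr_lower", "hr_upper"}
        missing = required - set(effects.columns)
        if missing:
            raise ValueError(f"effects table missing columns: {sorted(missing)}")
        work = effects
        if "passed" in work.columns:
            work = work[work["passed"].astype(bool)]
        work = work.assign(
            b=np.log(work["hr"].astype(float)),
            se=[
                se_from_ci(lo, up, lv)
                for lo, up, lv in zip(work["hr_lower"], work["hr_upper"], work["level"])
            ],
        )[["subfield", "b", "se"]]
    corpora = {}
    for subfield, grp in work.groupby("subfield", sort=True):
        corpora[str(subfield)] = Corpus.from_arrays(
            grp["b"].to_numpy(), grp["se"].to_numpy(), subfield=str(subfield)
        )
    return corpora


def write_prior_spec(
    prior: PriorSpec,
    path: PathLike,
    subfield: str = "",
    n_assumed: Optional[int] = None,
    n_studies: Optional[int] = None,
) -> None:
    lines = [
        f"subfield: {subfield}",
        f"family: {prior.family}",
        f"mu: {prior.mu!r}",
        f"sigma: {prior.sigma!r}",
        f"truncation: {prior.truncation}",
    ]
    if n_assumed is not None:
        lines.append(f"n_assumed: {n_assumed}")
    if n_studies is not None:
        lines.append(f"n_studies: {n_studies}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_prior_spec(path: PathLike) -> PriorSpec:
    fields: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    return PriorSpec(
        mu=float(fields["mu"]),
        sigma=float(fields["sigma"]),
        family=fields.get("family", "normal"),
        truncation=fields.get("truncation", "none"),
    )


def read_survival(path: PathLike) -> SurvivalDataset:
    """Survival CSV: columns time, event, arm, optional entry_order."""
    df = _read_csv(path)
    missing = {"time", "event", "arm"} - set(df.columns)
    if missing:
        raise ValueError(f"survival file missing columns: {sorted(missing)}")
    return SurvivalDataset.from_dataframe(df)


def write_survival(data: SurvivalDataset, path: PathLike, comment: Optional[str] = None) -> None:
    _write_csv(data.to_dataframe(), path, comment)


def write_trajectory(trajectory, path: PathLike, extra_comment: Optional[str] = None) -> None:
    """Trajectory CSV with the prior echoed in a header comment."""
    p = trajectory.prior
    comment = (
        f"prior: family={p.family} mu={p.mu!r} sigma={p.sigma!r} "
        f"truncation={p.truncation} side={trajectory.side} "
        f"thresholds=({trajectory.thresholds[0]!r}, {trajectory.thresholds[1]!r})"
    )
    if extra_comment:
        comment += "\n" + extra_comment
    _write_csv(trajectory.to_dataframe(), path, comment)
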