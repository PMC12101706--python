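"""Bundled summaries of the nine biomedical literature corpora behind the
package's default priors.

For each subfield the table records the corpus bookkeeping (journals matched /
listed; articles allocated, with a successful extraction, and surviving the
validity screen) together with the per-study means of b^2 and SE(b)^2 on the
log hazard-ratio scale.  Because the pooled-SD estimator depends on the
corpus only through N, sum(b^2) and sum(SE^2), these summaries determine each
subfield's default prior exactly: a surrogate corpus with constant
b = sqrt(mean b^2) and SE = sqrt(mean SE^2) has the same sums as the full
corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pooling import Corpus, PriorSpec, pooled_sigma, prior_from_corpus

__all__ = ["SubfieldSummary", "SUBFIELD_SUMMARIES", "surrogate_corpus", "default_prior"]


@dataclass(frozen=True)
class SubfieldSummary:
    """Corpus bookkeeping and second moments for one subfield."""

    journals_matched: int
    journals_listed: int
    allocated: int
    matched: int
    considered: int
    mean_b2: float
    mean_se2: float


SUBFIELD_SUMMARIES: dict[str, SubfieldSummary] = {
    "anesthesiology and pain medicine": SubfieldSummary(44, 132, 360, 215, 211, 0.804, 0.089),
    "cardiology and cardiovascular medicine": SubfieldSummary(230, 366, 10_718, 6_555, 6_504, 0.824, 0.099),
    "gastroenterology": SubfieldSummary(88, 157, 2_088, 1_311, 1_300, 1.027, 0.137),
    "hematology": SubfieldSummary(66, 134, 1_601, 857, 849, 1.029, 0.123),
    "immunology and allergy": SubfieldSummary(82, 214, 1_360, 839, 833, 0.937, 0.110),
    "neurology": SubfieldSummary(178, 387, 2_840, 1_651, 1_640, 0.978, 0.115),
    "oncology": SubfieldSummary(239, 373, 13_163, 7_741, 7_684, 0.830, 0.107),
    "psychiatry and mental health": SubfieldSummary(159, 560, 1_750, 1_038, 1_029, 0.768, 0.070),
    "pulmonary and respiratory medicine": SubfieldSummary(84, 146, 2_551, 1_561, 1_548, 0.886, 0.112),
}


def surrogate_corpus(
    n_studies: int, mean_b2: float, mean_se2: float, subfield: str = ""
) -> Corpus:
    """Constant-effect corpus with the same (N, sum b^2, sum SE^2) as a corpus
    having the given per-study second moments."""
    b = np.full(n_studies, np.sqrt(mean_b2))
    se = np.full(n_studies, np.sqrt(mean_se2))
    return Corpus.from_arrays(b, se, subfield=subfield)


def default_prior(subfield: str, n: int = 200) -> PriorSpec:
    """The package's default pooled prior for a subfield (case-insensitive)."""
    key = subfield.strip().lower()
    if key not in SUBFIELD_SUMMARIES:
        raise KeyError(
            f"unknown subfield {subfield!r}; choose from {sorted(SUBFIELD_SUMMARIES)}"
        )
    s = SUBFIELD_SUMMARIES[key]
    return prior_from_corpus(
        surrogate_corpus(s.considered, s.mean_b2, s.mean_se2, subfield=key), n=n
    )
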