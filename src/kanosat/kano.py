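"""Kano classification of topics from paired regression evidence.

Following the two-factor view of satisfaction, a topic's character is read
off six discrimination indicators computed from the satisfaction (PD) and
dissatisfaction (ND) Tobit fits and from its review sentiment counts:

    PS = 1  iff the topic's satisfaction coefficient is significant,
    NS = 1  iff its dissatisfaction coefficient is significant,
    CD = 1  iff the Wald asymmetry test between the two is significant,
    NT = 1  iff satisfied reviews (rating >= threshold) outnumber
            dissatisfied ones within the topic,
    sign_pd, sign_nd: the signs of the two coefficients.

The category rule table, evaluated top-down:

    attractive   PS=1, NS=1, CD=1, NT=1, sign_pd=+1
    basic        PS=1, NS=1, CD=1, NT=0, sign_nd=+1
    expected     PS=1, NS=1, CD=0
    reverse      PS=1, sign_pd=−1, NS=0
    indifferent  PS=0, NS=0
    unclassified otherwise (reported, never coerced)

Attractive factors raise satisfaction when present but their absence is
tolerated; basic (must-be) factors are taken for granted and drive
dissatisfaction when they fail — the asymmetry the Wald test certifies.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .tobit import TobitFit, wald_asymmetry, wald_from_summary

__all__ = [
    "TopicEvidence",
    "KanoIndicators",
    "KanoReport",
    "CATEGORIES",
    "compute_indicators",
    "classify",
    "classify_all",
    "evidence_from_fits",
    "load_worked_example",
]

CATEGORIES = ("attractive", "basic", "expected", "indifferent", "reverse", "unclassified")

#: "satisfied" review: rating at or above this many stars
DEFAULT_SATISFACTION_THRESHOLD = 4


@dataclass(frozen=True)
class TopicEvidence:
    """Everything the rule engine needs to know about one topic.

    ``n_satisfied`` / ``n_dissatisfied`` are the topic's review counts at
    and below the satisfaction threshold (membership by best topic).  When
    only the direction of the comparison is known — as with published
    summary tables that omit the raw counts — set ``more_satisfied``
    instead and leave the counts None.
    """

    label: str
    beta_pd: float
    se_pd: float
    p_pd: float
    beta_nd: float
    se_nd: float
    p_nd: float
    wald_p: float
    n_satisfied: int | None = None
    n_dissatisfied: int | None = None
    more_satisfied: bool | None = None

    def __post_init__(self):
        for name in ("p_pd", "p_nd", "wald_p"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        counts = self.n_satisfied is not None and self.n_dissatisfied is not None
        if counts and (self.n_satisfied < 0 or self.n_dissatisfied < 0):
            raise ValueError("review counts must be non-negative")
        if not counts and self.more_satisfied is None:
            raise ValueError(
                f"topic {self.label!r}: provide satisfied/dissatisfied counts "
                "or the more_satisfied direction"
            )

    @property
    def nt(self) -> bool:
        if self.n_satisfied is not None and self.n_dissatisfied is not None:
            return self.n_satisfied > self.n_dissatisfied  # strict: ties give NT=0
        return bool(self.more_satisfied)


@dataclass(frozen=True)
class KanoIndicators:
    ps: int
    ns: int
    cd: int
    nt: int
    sign_pd: int
    sign_nd: int


def _sign(x: float) -> int:
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


def compute_indicators(evidence: TopicEvidence, alpha: float = 0.05) -> KanoIndicators:
    """The six discrimination indicators at significance level ``alpha``."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return KanoIndicators(
        ps=int(evidence.p_pd < alpha),
        ns=int(evidence.p_nd < alpha),
        cd=int(evidence.wald_p < alpha),
        nt=int(evidence.nt),
        sign_pd=_sign(evidence.beta_pd),
        sign_nd=_sign(evidence.beta_nd),
    )


def classify(ind: KanoIndicators) -> str:
    """Map an indicator vector to its Kano category (rule table, top-down)."""
    if ind.ps and ind.ns and ind.cd and ind.nt and ind.sign_pd == 1:
        return "attractive"
    if ind.ps and ind.ns and ind.cd and not ind.nt and ind.sign_nd == 1:
        return "basic"
    if ind.ps and ind.ns and not ind.cd:
        return "expected"
    if ind.ps and ind.sign_pd == -1 and not ind.ns:
        return "reverse"
    if not ind.ps and not ind.ns:
        return "indifferent"
    return "unclassified"


@dataclass
class KanoReport:
    categories: dict[str, str]  # topic label -> category
    indicators: dict[str, KanoIndicators]
    counts: dict[str, int]  # category -> number of topics
    quadrant: dict[str, tuple[float, float]]  # label -> (|beta_nd|, |beta_pd|)


def classify_all(evidence: Sequence[TopicEvidence], alpha: float = 0.05) -> KanoReport:
    """Classify every topic; also emits (|beta_nd|, |beta_pd|) plot coordinates."""
    labels = [e.label for e in evidence]
    if len(set(labels)) != len(labels):
        raise ValueError("topic labels must be unique")
    categories: dict[str, str] = {}
    indicators: dict[str, KanoIndicators] = {}
    quadrant: dict[str, tuple[float, float]] = {}
    for e in evidence:
        ind = compute_indicators(e, alpha)
        indicators[e.label] = ind
        categories[e.label] = classify(ind)
        quadrant[e.label] = (abs(e.beta_nd), abs(e.beta_pd))
    counts = {c: 0 for c in CATEGORIES}
    for c in categories.values():
        counts[c] += 1
    counts = {c: n for c, n in counts.items() if n}
    return KanoReport(categories=categories, indicators=indicators, counts=counts,
                      quadrant=quadrant)


def evidence_from_fits(
    fit_pd: TobitFit,
    fit_nd: TobitFit,
    n_satisfied: Sequence[int],
    n_dissatisfied: Sequence[int],
    labels: Sequence[str] | None = None,
    mode: str = "difference",
) -> list[TopicEvidence]:
    """Assemble per-topic evidence from the two Tobit fits and review counts."""
    k = len(fit_pd.beta)
    if labels is None:
        labels = fit_pd.names
    if not (len(labels) == k == len(fit_nd.beta) == len(n_satisfied) == len(n_dissatisfied)):
        raise ValueError("fits, labels and counts must agree on the number of topics")
    out = []
    for j in range(k):
        wald = wald_asymmetry(fit_pd, fit_nd, j, mode=mode)
        out.append(
            TopicEvidence(
                label=str(labels[j]),
                beta_pd=float(fit_pd.beta[j]),
                se_pd=float(fit_pd.se[j]),
                p_pd=float(fit_pd.p[j]),
                beta_nd=float(fit_nd.beta[j]),
                se_nd=float(fit_nd.se[j]),
                p_nd=float(fit_nd.p[j]),
                wald_p=wald.p,
                n_satisfied=int(n_satisfied[j]),
                n_dissatisfied=int(n_dissatisfied[j]),
            )
        )
    return out


def load_worked_example() -> list[TopicEvidence]:
    """The shipped worked example: published coefficient estimates for the
    12 review themes of a large pregnancy-management app study.

    The table carries each theme's satisfaction and dissatisfaction
    coefficients with standard errors and p-values, plus the direction of
    its satisfied-vs-dissatisfied review comparison; the Wald asymmetry
    p-value is recomputed here from the summary statistics rather than
    stored.
    """
    raw = resources.files("kanosat.data").joinpath("pregnancy_app_themes.csv").read_text("utf-8")
    out = []
    for rec in csv.DictReader(raw.splitlines()):
        wald = wald_from_summary(
            float(rec["beta_pd"]), float(rec["se_pd"]),
            float(rec["beta_nd"]), float(rec["se_nd"]),
        )
        out.append(
            TopicEvidence(
                label=rec["theme"],
                beta_pd=float(rec["beta_pd"]),
                se_pd=float(rec["se_pd"]),
                p_pd=float(rec["p_pd"]),
                beta_nd=float(rec["beta_nd"]),
                se_nd=float(rec["se_nd"]),
                p_nd=float(rec["p_nd"]),
                wald_p=wald.p,
                more_satisfied=rec["more_satisfied"].strip().lower() == "true",
            )
        )
    return out
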