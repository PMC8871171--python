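"""Info-exposure spillover validation: topic tagging, exposure, elasticity.

A user is *exposed* to a message if they posted it themselves or perceive
it from a followee.  The spillover hypothesis is that the topics a user
has been exposed to change the likelihood that they go on to retweet
preventive-measure (PM) messages — masks, lockdowns, social distancing.
The framework here quantifies that:

1. tag messages with topics via keyword lexicons;
2. compute each user's exposure profile over the analysis period;
3. partition users into exposed/unexposed (or exclusive topic-pair)
   groups with a designated control group;
4. compare per-group *adoption likelihood*
   ``alpha(V_i) = |V_i ∩ PM-adopters| / |V_i|`` against the control via
   the *spillover elasticity*  ``epsilon = (alpha_i - alpha_c) / alpha_c``.

A positive elasticity means exposure to the topic raises PM adoption.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph_data import Cascade, MessageStore, SocialGraph

logger = logging.getLogger("spillcast")

__all__ = [
    "DEFAULT_LEXICON",
    "REFERENCE_SINGLE_TOPIC_VALIDATION",
    "TopicLexicon",
    "ExposureProfile",
    "GroupSet",
    "UndefinedStatisticError",
    "classify_topics",
    "compute_exposure",
    "single_topic_groups",
    "composition_groups",
    "adoption_likelihood",
    "elasticity",
    "pm_adopters",
    "spillover_report",
]

#: Default keyword lexicon: the preventive-measure list plus six analysis
#: topics (three pandemic-related: unemployment, panic buying, school
#: closures; three general: stop-Asian-hate, black-lives-matter,
#: loneliness), with multilingual variants as used in Greater-Region
#: (FR/DE/EN) Twitter studies of the first COVID-19 wave.
DEFAULT_LEXICON: dict[str, list[str]] = {
    "PM": [
        "stayathome", "mask", "masque", "maske", "wash hand", "social distancing",
        "socialdistancing", "staysafe", "lockdown",
    ],
    "U": [
        "job", "jobsearch", "unemployment", "employment", "career", "resume",
        "recruitment", "recession", "economy", "economic", "emploi", "stelle",
        "employ", "arbeitslos", "chômeurs",
    ],
    "PB": [
        "panicbuying", "panicshopping", "panicbuyers", "toiletpaper",
        "handsanitizer", "coronashopping",
    ],
    "SC": [
        "schoolclos", "closenypublicschool", "closenycschools", "suny", "cuny",
        "homeschool", "noschool", "shutdownschools",
    ],
    "SAH": [
        "stopasianhate", "stopaapihate", "stopasianhatecrimes", "asian", "aapi",
        "asianlivesmatter", "asiansareguman", "antiasianhate",
    ],
    "BLM": [
        "blacklifematters", "blacklivesmatter", "atlantaprotest", "blm",
        "changethesystem", "justiceforgeorgefloyd",
    ],
    "L": [
        "lonely", "loneliness", "alone", "solitaire", "solitude", "seul",
        "einsam", "einsamkeit", "allein",
    ],
}

#: The six non-PM analysis topics in canonical order.
ANALYSIS_TOPICS: tuple[str, ...] = ("U", "PB", "SC", "SAH", "BLM", "L")

#: Published single-topic validation summary from the Greater-Region
#: first-wave Twitter corpus this framework was developed on: per topic,
#: the exposed/unexposed group sizes, their PM adoption likelihoods and
#: the printed elasticity.  Bundled for worked examples and cross-checks;
#: the printed elasticities were computed from unrounded likelihoods, so
#: recomputing them from the 2-decimal alphas can differ in the last digit.
REFERENCE_SINGLE_TOPIC_VALIDATION: pd.DataFrame = pd.DataFrame(
    [
        ("U", 4238, 0.67, 17101, 0.25, 1.69),
        ("PB", 6119, 0.39, 15220, 0.31, 0.25),
        ("SC", 6460, 0.61, 14879, 0.21, 1.87),
        ("SAH", 6740, 0.72, 14599, 0.28, 1.53),
        ("BLM", 9041, 0.48, 12298, 0.41, 0.16),
        ("L", 5343, 0.79, 15996, 0.30, 1.63),
    ],
    columns=["topic", "n_exposed", "alpha_exposed", "n_unexposed", "alpha_unexposed", "elasticity"],
)


class UndefinedStatisticError(ValueError):
    """A group statistic (likelihood or elasticity) has no defined value."""


# ---------------------------------------------------------------------------
# Lexicon & topic tagging
# ---------------------------------------------------------------------------


@dataclass
class TopicLexicon:
    """Topic name → lowercase keyword list."""

    topics: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_LEXICON.items()})

    def __post_init__(self):
        for name, kws in self.topics.items():
            if not kws:
                raise ValueError(f"topic {name!r}: empty keyword list")
            lowered = [k.lower() for k in kws]
            if len(set(lowered)) != len(lowered):
                raise ValueError(f"topic {name!r}: duplicate keywords")
            self.topics[name] = lowered

    def __contains__(self, topic: str) -> bool:
        return topic in self.topics

    def names(self) -> list[str]:
        return list(self.topics)

    def keywords(self, topic: str) -> list[str]:
        return self.topics[topic]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TopicLexicon":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(topics={str(k): [str(w) for w in v] for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.topics, fh, allow_unicode=True, sort_keys=False)


def classify_topics(text: str, lexicon: TopicLexicon | None = None) -> set[str]:
    """Topics whose keywords occur in the case-folded text.

    Matching is case-insensitive substring matching with ``#`` stripped
    first, so hashtag-concatenated keywords ("stayathome") match both the
    plain word and the hashtag form.
    """
    lexicon = lexicon or TopicLexicon()
    folded = text.lower().replace("#", "")
    return {name for name, kws in lexicon.topics.items() if any(k in folded for k in kws)}


# ---------------------------------------------------------------------------
# Exposure
# ---------------------------------------------------------------------------


@dataclass
class ExposureProfile:
    """user id → set of topics the user was exposed to."""

    topics_by_user: dict[str, set[str]]

    def exposure(self, user: str) -> set[str]:
        return self.topics_by_user.get(user, set())

    @property
    def universe(self) -> set[str]:
        return set(self.topics_by_user)


def compute_exposure(
    graph: SocialGraph,
    store: MessageStore,
    lexicon: TopicLexicon | None = None,
    mutual_only: bool = False,
) -> ExposureProfile:
    """Exposure over the whole analysis period.

    User v is exposed to topic T iff v authored or retweeted a T-message,
    or some followee of v did (``mutual_only=True`` restricts the second
    clause to mutual followers).  Authors missing from the graph are
    warned about and contribute self-exposure only.
    """
    lexicon = lexicon or TopicLexicon()
    authored: dict[str, set[str]] = {v: set() for v in graph.nodes}
    missing: set[str] = set()
    for m in store:
        topics = classify_topics(m.text, lexicon)
        if not topics:
            continue
        if m.author not in authored:
            missing.add(m.author)
            authored[m.author] = set()
        authored[m.author] |= topics
    if missing:
        logger.warning(
            "compute_exposure: %d author(s) not in graph; counted for self-exposure only",
            len(missing),
        )

    profile: dict[str, set[str]] = {}
    for v in graph.nodes:
        exposed = set(authored.get(v, ()))
        sources = graph.mutual_neighbors(v) if mutual_only else graph.followees(v)
        for u in sources:
            exposed |= authored.get(u, set())
        profile[v] = exposed
    for v in missing:  # off-graph authors keep self-exposure
        profile[v] = set(authored[v])
    return ExposureProfile(topics_by_user=profile)


# ---------------------------------------------------------------------------
# Group construction
# ---------------------------------------------------------------------------


@dataclass
class GroupSet:
    """Named user groups with a designated control group.

    ``likelihoods`` and ``elasticities`` are filled by
    :func:`spillover_report` (or manually); groups whose statistics are
    undefined (empty group, zero control likelihood) are left out.
    """

    groups: dict[str, set[str]]
    control: str
    likelihoods: dict[str, float] = field(default_factory=dict)
    elasticities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} not among groups")

    def __getitem__(self, name: str) -> set[str]:
        return self.groups[name]

    def names(self) -> list[str]:
        return list(self.groups)


def single_topic_groups(profile: ExposureProfile, topic: str) -> GroupSet:
    """Partition the universe into exposed / unexposed for one topic.

    The unexposed group is the control.  The two groups always partition
    the universe, mirroring constant row sums across topics in the
    reference validation table.
    """
    exposed = {v for v, ts in profile.topics_by_user.items() if topic in ts}
    unexposed = profile.universe - exposed
    if not exposed:
        logger.warning("single_topic_groups(%r): exposed group is empty; statistics undefined", topic)
    return GroupSet(groups={"exposed": exposed, "unexposed": unexposed}, control="unexposed")


def composition_groups(profile: ExposureProfile, topics: list[str]) -> GroupSet:
    """Exclusive-exposure groups for topic pairs and singles, plus control.

    For k topics: one group per unordered pair (users exposed to exactly
    that pair among the listed topics), one per single topic (exclusive
    exposure), and a control of users exposed to none — k(k-1)/2 + k + 1
    groups, pairwise disjoint by construction.  Exposure to topics outside
    ``topics`` is ignored.
    """
    if len(topics) < 2:
        raise ValueError("composition_groups needs at least 2 topics")
    if len(set(topics)) != len(topics):
        raise ValueError("topics must be distinct")
    tset = set(topics)
    groups: dict[str, set[str]] = {}
    for a, b in itertools.combinations(topics, 2):
        groups[f"{a}+{b}"] = set()
    for t in topics:
        groups[t] = set()
    groups["control"] = set()
    for v, exposed in profile.topics_by_user.items():
        hit = exposed & tset
        if len(hit) == 0:
            groups["control"].add(v)
        elif len(hit) == 1:
            groups[next(iter(hit))].add(v)
        elif len(hit) == 2:
            a, b = sorted(hit, key=topics.index)
            groups[f"{a}+{b}"].add(v)
        # users exposed to 3+ listed topics fall outside every group
    return GroupSet(groups=groups, control="control")


# ---------------------------------------------------------------------------
# Adoption likelihood & elasticity
# ---------------------------------------------------------------------------


def pm_adopters(cascades: list[Cascade], pm_roots: set[str]) -> set[str]:
    """Users who ever participated in a preventive-measure cascade.

    Participation means appearing in the adopter list (root author
    included) of any cascade whose root message is PM-classified.
    """
    out: set[str] = set()
    for c in cascades:
        if c.root_message in pm_roots:
            out.update(c.users())
    return out


def adoption_likelihood(group: set[str], adopters: set[str]) -> float:
    """alpha = |group ∩ adopters| / |group|, the PM adoption rate of a group."""
    if not group:
        raise UndefinedStatisticError("adoption likelihood of an empty group is undefined")
    return len(group & adopters) / len(group)


def elasticity(alpha_i: float, alpha_c: float) -> float:
    """Spillover elasticity epsilon = (alpha_i - alpha_c) / alpha_c.

    Bounded below by -1 (a group can at worst adopt nothing); positive
    values mean the group's common exposure raises PM adoption relative
    to the control.
    """
    if alpha_c <= 0:
        raise UndefinedStatisticError("elasticity undefined for zero control likelihood")
    return (alpha_i - alpha_c) / alpha_c


def _bootstrap_ci(
    group: set[str], adopters: set[str], alpha_c: float, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    flags = np.array([u in adopters for u in sorted(group)], dtype=float)
    idx = rng.integers(0, len(flags), size=(n_boot, len(flags)))
    alphas = flags[idx].mean(axis=1)
    eps = (alphas - alpha_c) / alpha_c
    lo, hi = np.quantile(eps, [0.025, 0.975])
    return float(lo), float(hi)


def spillover_report(
    profile: ExposureProfile,
    cascades: list[Cascade],
    pm_roots: set[str],
    topics: tuple[str, ...] = ANALYSIS_TOPICS,
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-topic validation table: one row per topic.

    Columns mirror the reference validation layout (topic, group sizes,
    adoption likelihoods, elasticity), optionally with a nonparametric
    bootstrap CI over users of the exposed group (``n_boot > 0``).
    """
    adopters = pm_adopters(cascades, pm_roots)
    rng = np.random.default_rng(seed)
    rows = []
    for topic in topics:
        gs = single_topic_groups(profile, topic)
        exposed, unexposed = gs["exposed"], gs["unexposed"]
        row: dict = {"topic": topic, "n_exposed": len(exposed), "n_unexposed": len(unexposed)}
        try:
            a_e = adoption_likelihood(exposed, adopters)
            a_u = adoption_likelihood(unexposed, adopters)
            eps = elasticity(a_e, a_u)
            row.update(alpha_exposed=a_e, alpha_unexposed=a_u, elasticity=eps)
            if n_boot > 0:
                lo, hi = _bootstrap_ci(exposed, adopters, a_u, n_boot, rng)
                row.update(elasticity_lo=lo, elasticity_hi=hi)
        except UndefinedStatisticError:
            row.update(alpha_exposed=np.nan, alpha_unexposed=np.nan, elasticity=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
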