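"""Modified-Delphi consensus analysis for model-conceptualization surveys.

An expert panel rates candidate model items (health states/events and
patient attributes) on a 0–5 Likert scale, with an explicit "Don't Know"
option. High agreement is defined a priori:

* **inclusion** — at least 80% of informative respondents rate the item 4
  or higher;
* **exclusion** — at least 80% rate it 2 or lower;
* **non-consensus** — anything else; the item is carried forward and
  re-rated in the next round, alongside newly proposed items.

"Informative respondents" excludes Don't Know answers: both the agreement
fractions and the panel average are computed over respondents who gave a
numeric rating.  Threshold comparisons use exact rational arithmetic so a
panel of 10 with 8 high ratings sits exactly at the 0.80 boundary and is
included; panel averages are displayed half-up rounded to two decimals.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ItemRatingDistribution",
    "ConsensusCriteria",
    "ItemClassification",
    "RoundSummary",
    "panel_average",
    "classify_item",
    "summarize_round",
    "build_next_round",
    "cumulative_inclusions",
    "load_ratings",
    "packaged_ratings",
    "packaged_printed_summary",
    "packaged_data_sha256",
]

RATING_SCALE = range(6)  # 0..5 Likert points

ITEM_KINDS = ("health_state_event", "patient_attribute")

CATEGORIES = ("inclusion", "exclusion", "non_consensus")


class NoInformativeRatingsError(ValueError):
    """Every respondent answered Don't Know; summary statistics are undefined."""


@dataclass(frozen=True)
class ItemRatingDistribution:
    """Aggregate rating counts for one survey item in one round."""

    item_id: str
    item_label: str
    item_kind: str
    round_index: int
    counts: tuple[int, int, int, int, int, int]
    dont_know_count: int
    n_respondents: int

    def __post_init__(self) -> None:
        if self.item_kind not in ITEM_KINDS:
            raise ValueError(f"unknown item_kind {self.item_kind!r}")
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != 6 or any(c < 0 for c in counts):
            raise ValueError("counts must be 6 non-negative integers (ratings 0..5)")
        object.__setattr__(self, "counts", counts)
        if self.dont_know_count < 0:
            raise ValueError("dont_know_count must be non-negative")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be positive")
        if sum(counts) + self.dont_know_count != self.n_respondents:
            raise ValueError(
                f"{self.item_id} round {self.round_index}: counts "
                f"{sum(counts)} + dont_know {self.dont_know_count} "
                f"!= n_respondents {self.n_respondents}"
            )

    @property
    def informative_n(self) -> int:
        """Respondents who gave a numeric rating (Don't Know excluded)."""
        return self.n_respondents - self.dont_know_count


@dataclass(frozen=True)
class ConsensusCriteria:
    """A-priori high-agreement rule for classifying rated items."""

    agreement_fraction: float = 0.80
    inclusion_min_rating: int = 4
    exclusion_max_rating: int = 2
    max_rounds: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.agreement_fraction <= 1):
            raise ValueError("agreement_fraction must be in (0, 1]")
        if self.exclusion_max_rating >= self.inclusion_min_rating:
            raise ValueError("exclusion_max_rating must be < inclusion_min_rating")

    @property
    def agreement_exact(self) -> Fraction:
        # via str() so 0.80 becomes exactly 4/5, not the binary float
        return Fraction(str(self.agreement_fraction))


@dataclass(frozen=True)
class ItemClassification:
    category: str
    informative_n: int
    fraction_high: Fraction
    fraction_low: Fraction
    panel_average: float


@dataclass
class RoundSummary:
    """Per-round classification results and carry-forward bookkeeping."""

    round_index: int
    classifications: dict[str, ItemClassification]
    category_counts: dict[str, int] = field(init=False)
    carried_forward_item_ids: list[str] = field(init=False)
    retired_item_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        tally = Counter(c.category for c in self.classifications.values())
        self.category_counts = {cat: tally.get(cat, 0) for cat in CATEGORIES}
        self.carried_forward_item_ids = [
            i for i, c in self.classifications.items() if c.category == "non_consensus"
        ]
        self.retired_item_ids = [
            i for i, c in self.classifications.items() if c.category != "non_consensus"
        ]

    def inclusion_item_ids(self) -> list[str]:
        return [i for i, c in self.classifications.items() if c.category == "inclusion"]


def _round_half_up(value: Fraction, decimals: int = 2) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    dec = (Decimal(value.numerator) / Decimal(value.denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(dec)


def panel_average(dist: ItemRatingDistribution) -> float:
    """Mean rating over informative respondents, half-up rounded to 2 dp."""
    if dist.informative_n == 0:
        raise NoInformativeRatingsError(
            f"{dist.item_id}: no informative ratings (all Don't Know)"
        )
    total = sum(r * c for r, c in zip(RATING_SCALE, dist.counts))
    return _round_half_up(Fraction(total, dist.informative_n))


def classify_item(
    dist: ItemRatingDistribution, criteria: ConsensusCriteria | None = None
) -> ItemClassification:
    """Apply the high-agreement rule to one item's rating distribution."""
    criteria = criteria or ConsensusCriteria()
    n = dist.informative_n
    if n == 0:
        raise NoInformativeRatingsError(
            f"{dist.item_id}: no informative ratings (all Don't Know)"
        )
    high = sum(dist.counts[criteria.inclusion_min_rating :])
    low = sum(dist.counts[: criteria.exclusion_max_rating + 1])
    fraction_high = Fraction(high, n)
    fraction_low = Fraction(low, n)
    threshold = criteria.agreement_exact
    if fraction_high >= threshold:
        category = "inclusion"
    elif fraction_low >= threshold:
        category = "exclusion"
    else:
        category = "non_consensus"
    return ItemClassification(
        category=category,
        informative_n=n,
        fraction_high=fraction_high,
        fraction_low=fraction_low,
        panel_average=panel_average(dist),
    )


def summarize_round(
    dists: Sequence[ItemRatingDistribution],
    criteria: ConsensusCriteria | None = None,
) -> RoundSummary:
    """Classify every item rated in one round.

    All distributions must share a round index and panel size; duplicate
    item ids are rejected (an item is rated at most once per round).
    """
    criteria = criteria or ConsensusCriteria()
    if not dists:
        return RoundSummary(round_index=0, classifications={})
    rounds = {d.round_index for d in dists}
    if len(rounds) != 1:
        raise ValueError(f"mixed round indices in one summary: {sorted(rounds)}")
    panel_sizes = {d.n_respondents for d in dists}
    if len(panel_sizes) != 1:
        raise ValueError(f"mixed panel sizes in one round: {sorted(panel_sizes)}")
    seen = Counter(d.item_id for d in dists)
    duplicates = sorted(i for i, k in seen.items() if k > 1)
    if duplicates:
        raise ValueError(f"duplicate item_ids in round: {duplicates}")
    return RoundSummary(
        round_index=rounds.pop(),
        classifications={d.item_id: classify_item(d, criteria) for d in dists},
    )


def build_next_round(summary: RoundSummary, new_items: Iterable[str] = ()) -> list[str]:
    """Item ids to be rated in the next round.

    Non-consensus items are carried forward and re-rated together with newly
    proposed items; included/excluded items are retired from rating.  An
    empty result means the stopping criterion is met.
    """
    new_items = list(new_items)
    existing = set(summary.classifications)
    clashes = sorted(set(new_items) & existing)
    if clashes:
        raise ValueError(f"new items duplicate existing ids: {clashes}")
    if len(set(new_items)) != len(new_items):
        raise ValueError("new_items contains duplicates")
    return list(summary.carried_forward_item_ids) + new_items


def cumulative_inclusions(summaries: Sequence[RoundSummary]) -> set[str]:
    """Union of included item ids across survey rounds."""
    if not summaries:
        raise ValueError("at least one round summary required")
    included: set[str] = set()
    for summary in summaries:
        included.update(summary.inclusion_item_ids())
    return included


# ---------------------------------------------------------------------------
# Fixture I/O

_RATINGS_COLUMNS = [
    "item_id", "item_label", "item_kind", "round",
    "count_0", "count_1", "count_2", "count_3", "count_4", "count_5",
    "dont_know", "n_respondents",
]


def load_ratings(path: str | Path | pd.DataFrame) -> list[ItemRatingDistribution]:
    """Read rating distributions from CSV (or a pre-loaded frame)."""
    frame = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    missing = [c for c in _RATINGS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    dists = []
    for row in frame.itertuples(index=False):
        dists.append(
            ItemRatingDistribution(
                item_id=row.item_id,
                item_label=row.item_label,
                item_kind=row.item_kind,
                round_index=int(getattr(row, "round")),
                counts=tuple(int(getattr(row, f"count_{r}")) for r in RATING_SCALE),
                dont_know_count=int(row.dont_know),
                n_respondents=int(row.n_respondents),
            )
        )
    return dists


def _data_path(name: str):
    return resources.files("fallsim.data").joinpath(name)


def packaged_ratings(
    item_kind: str | None = None, round_index: int | None = None
) -> list[ItemRatingDistribution]:
    """The bundled survey rating tables, optionally filtered."""
    with resources.as_file(_data_path("delphi_ratings.csv")) as path:
        dists = load_ratings(path)
    if item_kind is not None:
        dists = [d for d in dists if d.item_kind == item_kind]
    if round_index is not None:
        dists = [d for d in dists if d.round_index == round_index]
    return dists


def packaged_printed_summary() -> pd.DataFrame:
    """Published per-item panel averages and classification blocks."""
    with resources.as_file(_data_path("delphi_printed_summary.csv")) as path:
        return pd.read_csv(path)


def packaged_data_sha256() -> dict[str, str]:
    """Checksums of the bundled transcriptions, to guard against drift."""
    digests = {}
    for name in ("delphi_ratings.csv", "delphi_printed_summary.csv"):
        with resources.as_file(_data_path(name)) as path:
            digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return digests
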