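"""Ordinal scaling of heterogeneous interaction-strength measurements.

Literature sources report interaction strength in incommensurable native
metrics (frequency of occurrence, relative biomass, caloric fraction, prey
counts, ...). The scaling procedure makes them comparable in three steps:

1. **Standardize** within each study-consumer pair so the consumer's
   interactions sum to 100%. This removes the metric's native scale but
   requires a uniform metric within the pair.
2. **Bin** each standardized share onto an ordinal log2 scale:
   0 = absence (0%), 1 = marginal (0-5%], 2 = auxiliary (5-20%],
   4 = primary (20-67%], 8 = keystone (> 67%, an interaction roughly twice
   as strong as any other the consumer has).
3. **Average** the per-study scores for each consumer-resource-layer-season
   and round to one decimal, so links supported by several studies can take
   intermediate values.

Links known only from anecdotal case reports (no quantitative study for that
season) receive a fixed minimal averaged score of 0.1, and summer strengths
can be copied to winter for an explicit, curator-supplied list of links where
the interaction plausibly persists year-round but was never measured in
winter.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .records import InteractionRecord, Season, classify_season

logger = logging.getLogger(__name__)

#: Upper edges of the marginal / auxiliary / primary bins, in percent.
#: Shares above the last edge are keystone.
DEFAULT_BIN_EDGES: tuple[float, float, float] = (5.0, 20.0, 67.0)

#: The ordinal scores, in bin order (absence, then the log2 progression).
ORDINAL_SCORES: tuple[int, ...] = (0, 1, 2, 4, 8)

DEFAULT_CASE_FLOOR = 0.1

PROVENANCE_MEASURED = "measured"
PROVENANCE_CASE_ONLY = "case_only"
PROVENANCE_EXTRAPOLATED = "extrapolated"


@dataclass(frozen=True)
class StandardizedShare:
    """One record's share of its study-consumer total, in percent."""

    study_id: str
    consumer: str
    resource: str
    layer: str
    season: Season
    share: float


@dataclass(frozen=True)
class ScaledLink:
    """A consumer-resource-layer-season link with its averaged ordinal strength.

    ``strength`` lies in [0, 8] and carries one decimal; ``provenance``
    records whether it was measured, floored from case reports only, or
    extrapolated from the summer estimate.
    """

    consumer: str
    resource: str
    layer: str
    season: Season
    strength: float
    n_studies: int
    provenance: str

    @property
    def key(self) -> tuple[str, str, str, Season]:
        return (self.consumer, self.resource, self.layer, self.season)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (so 0.25 -> 0.3 at one decimal)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def scale_share(
    share: float, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> int:
    """Map a standardized share (percent) to its ordinal score.

    Bins are upper-inclusive: 0 -> 0, (0, 5] -> 1, (5, 20] -> 2,
    (20, 67] -> 4, (67, 100] -> 8 with the default edges.
    """
    if not 0.0 <= share <= 100.0:
        raise ValueError(f"share {share!r} outside [0, 100]")
    e1, e2, e3 = bin_edges
    if not 0 < e1 < e2 < e3 < 100:
        raise ValueError(f"bin edges {bin_edges!r} must be strictly increasing in (0, 100)")
    if share == 0:
        return 0
    if share <= e1:
        return 1
    if share <= e2:
        return 2
    if share <= e3:
        return 4
    return 8


def standardize_shares(
    records: Sequence[InteractionRecord],
) -> list[StandardizedShare]:
    """Standardize one study-consumer group of quantitative records to 100%.

    All records must belong to the same study and consumer, be quantitative,
    and share one metric_type (metrics are incommensurable, so a mixed group
    is an error). Raises ``ValueError`` on all-zero raw values.
    """
    if not records:
        raise ValueError("empty study-consumer group")
    keys = {(r.study_id, r.consumer) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span several study-consumer pairs: {sorted(keys)}")
    if any(not r.is_quantitative or r.raw_value is None for r in records):
        raise ValueError("standardization applies to quantitative records only")
    metrics = {r.metric_type for r in records}
    if len(metrics) > 1:
        (study_id, consumer), = keys
        raise ValueError(
            f"mixed metric_type {sorted(metrics)} within study {study_id!r} "
            f"consumer {consumer!r}: metrics are incommensurable"
        )
    total = sum(r.raw_value for r in records)
    if total <= 0:
        raise ValueError("all-zero raw values: shares are undefined")
    return [
        StandardizedShare(
            study_id=r.study_id,
            consumer=r.consumer,
            resource=r.resource,
            layer=r.layer,
            season=r.season,
            share=100.0 * r.raw_value / total,
        )
        for r in records
    ]


def average_scores(
    scores: Sequence[float], *, decimals: int = 1
) -> float:
    """Unweighted arithmetic mean of per-study scores, rounded half up."""
    if not scores:
        raise ValueError("no scores to average")
    return round_half_up(sum(scores) / len(scores), decimals)


LinkKey = tuple[str, str, str, Season]


def _measured_links(
    quantitative: Sequence[InteractionRecord],
    *,
    bin_edges: Sequence[float],
    decimals: int,
) -> list[ScaledLink]:
    # standardize within each study-consumer pair
    groups: dict[tuple[str, str], list[InteractionRecord]] = defaultdict(list)
    for rec in quantitative:
        groups[(rec.study_id, rec.consumer)].append(rec)

    # one score per study per (consumer, resource, layer); a study listing
    # the same link twice contributes its summed share once
    per_study_scores: dict[LinkKey, dict[str, float]] = defaultdict(dict)
    for (study_id, consumer), group in sorted(groups.items()):
        shares = standardize_shares(group)
        summed: dict[tuple[str, str, Season], float] = defaultdict(float)
        for s in shares:
            summed[(s.resource, s.layer, s.season)] += s.share
        for (resource, layer, season), share in summed.items():
            if season is Season.UNCLASSIFIED:
                logger.warning(
                    "study %s consumer %s: study months fit neither season "
                    "block; excluded from seasonal averaging",
                    study_id, consumer,
                )
                continue
            key = (consumer, resource, layer, season)
            per_study_scores[key][study_id] = scale_share(
                min(share, 100.0), bin_edges
            )

    links = []
    for key in sorted(per_study_scores, key=lambda k: (k[0], k[1], k[2], k[3].value)):
        scores = list(per_study_scores[key].values())
        links.append(
            ScaledLink(
                consumer=key[0],
                resource=key[1],
                layer=key[2],
                season=key[3],
                strength=average_scores(scores, decimals=decimals),
                n_studies=len(scores),
                provenance=PROVENANCE_MEASURED,
            )
        )
    return links


def apply_case_study_floor(
    measured: Sequence[ScaledLink],
    case_records: Sequence[InteractionRecord],
    *,
    case_floor: float = DEFAULT_CASE_FLOOR,
) -> list[ScaledLink]:
    """Complement measured links with case-report-only links at a fixed floor.

    A link-season documented only by anecdotal case reports receives the
    constant minimal averaged score (0.1 by default), however many reports
    exist. Case records whose study months classify to a season floor only
    that season; records with no or unclassifiable months are treated as
    season-agnostic and floor every season lacking quantitative data.
    When any quantitative study covers the link-season, the case reports are
    ignored (they add existence evidence the measurement already provides).
    """
    measured_keys = {ln.key for ln in measured}
    counts: dict[LinkKey, int] = defaultdict(int)
    for rec in case_records:
        if rec.study_type != "case_study":
            raise ValueError(f"record from study {rec.study_id!r} is not a case study")
        season = rec.season
        seasons = (
            [season] if season is not Season.UNCLASSIFIED
            else [Season.SUMMER, Season.WINTER]
        )
        for s in seasons:
            key = (rec.consumer, rec.resource, rec.layer, s)
            if key not in measured_keys:
                counts[key] += 1
    floored = [
        ScaledLink(
            consumer=c, resource=r, layer=l, season=s,
            strength=case_floor, n_studies=n,
            provenance=PROVENANCE_CASE_ONLY,
        )
        for (c, r, l, s), n in sorted(
            counts.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3].value)
        )
    ]
    return list(measured) + floored


def extrapolate_winter(
    links: Sequence[ScaledLink],
    extrapolate_links: Iterable[tuple[str, str, str] | Sequence[str] | Mapping[str, str]],
) -> list[ScaledLink]:
    """Copy summer strengths to winter for an explicit list of links.

    Extrapolation is opt-in per (consumer, resource, layer) triple: the
    summer link must exist and no measured winter link may be present
    (raises ``ValueError`` rather than overwrite a measurement). An existing
    case-only winter floor is replaced, since the summer measurement is
    strictly more informative than the anecdotal constant.
    """
    triples: list[tuple[str, str, str]] = []
    for item in extrapolate_links:
        if isinstance(item, Mapping):
            triples.append((item["consumer"], item["resource"], item["layer"]))
        else:
            c, r, l = item
            triples.append((c, r, l))

    by_key = {ln.key: ln for ln in links}
    out = list(links)
    for consumer, resource, layer in triples:
        summer = by_key.get((consumer, resource, layer, Season.SUMMER))
        if summer is None:
            logger.warning(
                "extrapolation requested for %s<-%s [%s] but no summer link exists",
                consumer, resource, layer,
            )
            continue
        winter_key = (consumer, resource, layer, Season.WINTER)
        existing = by_key.get(winter_key)
        if existing is not None:
            if existing.provenance == PROVENANCE_MEASURED:
                raise ValueError(
                    f"measured winter strength already present for "
                    f"{consumer}<-{resource} [{layer}]; refusing to overwrite"
                )
            out.remove(existing)
        winter = ScaledLink(
            consumer=consumer, resource=resource, layer=layer,
            season=Season.WINTER, strength=summer.strength,
            n_studies=0, provenance=PROVENANCE_EXTRAPOLATED,
        )
        by_key[winter_key] = winter
        out.append(winter)
    return out


def scale_records(
    records: Sequence[InteractionRecord],
    *,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    case_floor: float = DEFAULT_CASE_FLOOR,
    rounding_decimals: int = 1,
    extrapolate_links: Iterable = (),
) -> list[ScaledLink]:
    """Full scaling pipeline: standardize, bin, average per season, floor
    case-only links, then apply the configured winter extrapolations."""
    quantitative = [r for r in records if r.is_quantitative]
    cases = [r for r in records if r.study_type == "case_study"]
    links = _measured_links(
        quantitative, bin_edges=bin_edges, decimals=rounding_decimals
    )
    links = apply_case_study_floor(links, cases, case_floor=case_floor)
    links = extrapolate_winter(links, extrapolate_links)
    links.sort(key=lambda ln: (ln.consumer, ln.resource, ln.layer, ln.season.value))
    return links


def links_to_frame(links: Sequence[ScaledLink]):
    import pandas as pd

    return pd.DataFrame(
        [{
            "consumer": ln.consumer,
            "resource": ln.resource,
            "layer": ln.layer,
            "season": ln.season.value,
            "strength": f"{ln.strength:.1f}",
            "n_studies": ln.n_studies,
            "provenance": ln.provenance,
        } for ln in links],
        columns=["consumer", "resource", "layer", "season",
                 "strength", "n_studies", "provenance"],
    )


def write_links(links: Sequence[ScaledLink], path) -> None:
    links_to_frame(links).to_csv(path, index=False)


def read_links(path) -> list[ScaledLink]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        ScaledLink(
            consumer=row["consumer"],
            resource=row["resource"],
            layer=row["layer"],
            season=Season(row["season"]),
            strength=float(row["strength"]),
            n_studies=int(row["n_studies"]),
            provenance=row["provenance"],
        )
        for _, row in df.iterrows()
    ]
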