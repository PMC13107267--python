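"""Shared fixtures: worked-example tables, a mini metaweb, and an
independent brute-force reference for the scaling pipeline."""

from __future__ import annotations

from fractions import Fraction

import pytest

from metawebkit.records import InteractionRecord, Season, classify_season
from metawebkit.scaling import ScaledLink
from metawebkit.synth import (
    SynthConfig,
    generate_records,
    knowledge_example,
    mini_metaweb,
)


@pytest.fixture
def knowledge_fixture():
    return knowledge_example()


@pytest.fixture
def mini_web():
    return mini_metaweb()


@pytest.fixture
def synth_small():
    cfg = SynthConfig(seed=11, n_nodes=15, n_studies=60)
    return generate_records(cfg)


def brute_force_scale(records, *, case_floor=0.1):
    """Per-row reference for the scaling pipeline.

    Recomputes every link with plain dict-and-loop arithmetic and exact
    Fraction averaging (half-away-from-zero at one decimal), independently
    of the implementation under test.
    """
    def bin_score(share):
        if share == 0:
            return 0
        if share <= 5:
            return 1
        if share <= 20:
            return 2
        if share <= 67:
            return 4
        return 8

    groups = {}
    for r in records:
        if r.study_type == "quantitative":
            groups.setdefault((r.study_id, r.consumer), []).append(r)

    per_link_scores = {}
    for (study_id, consumer), grp in groups.items():
        total = Fraction(0)
        for r in grp:
            total += Fraction(str(r.raw_value))
        assert total > 0
        shares = {}
        for r in grp:
            season = classify_season(r.study_months)
            if season is Season.UNCLASSIFIED:
                continue
            key = (r.resource, r.layer, season)
            shares[key] = shares.get(key, Fraction(0)) + \
                100 * Fraction(str(r.raw_value)) / total
        for (resource, layer, season), share in shares.items():
            link = (consumer, resource, layer, season)
            per_link_scores.setdefault(link, {})[study_id] = bin_score(
                min(share, Fraction(100))
            )

    links = {}
    for link, scores in per_link_scores.items():
        mean10 = Fraction(10 * sum(scores.values()), len(scores))
        rounded = (mean10 + Fraction(1, 2)).__floor__()  # half away from zero (scores >= 0)
        links[link] = ScaledLink(
            consumer=link[0], resource=link[1], layer=link[2], season=link[3],
            strength=rounded / 10, n_studies=len(scores), provenance="measured",
        )

    for r in records:
        if r.study_type != "case_study":
            continue
        season = r.season
        seasons = [season] if season is not Season.UNCLASSIFIED else [
            Season.SUMMER, Season.WINTER
        ]
        for s in seasons:
            link = (r.consumer, r.resource, r.layer, s)
            if link not in links:
                links[link] = ScaledLink(
                    consumer=r.consumer, resource=r.resource, layer=r.layer,
                    season=s, strength=case_floor, n_studies=1,
                    provenance="case_only",
                )
            elif links[link].provenance == "case_only":
                old = links[link]
                links[link] = ScaledLink(
                    consumer=old.consumer, resource=old.resource,
                    layer=old.layer, season=old.season, strength=old.strength,
                    n_studies=old.n_studies + 1, provenance="case_only",
                )
    return links


@pytest.fixture
def oracle():
    return brute_force_scale
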