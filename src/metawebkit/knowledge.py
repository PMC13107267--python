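"""Node-level knowledge scores and literature-accumulation curves.

Literature-derived networks inherit the biases of the literature: flagship
taxa are studied intensively while most nodes are known from a handful of
anecdotes. The knowledge score makes that bias explicit. Every
(publication, species) pair contributes 1 if the publication measured the
interaction strength for that species, or 0.25 if it was a case study that
only established an interaction's existence. Per-node sums are then divided
by the node's species count ("weighted knowledge"), so an aggregate node of
many little-studied species scores lower than a single well-studied species.

Example: a 3-species node covered by one strength study of species A (1),
one of species A and B (2), and one case study of species C (0.25) has
knowledge sum 3.25 and weighted knowledge 3.25 / 3 = 1.08.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .records import InteractionRecord, NodeInfo, drop_excluded_reviews

MEASURED_CONTRIBUTION = 1.0
CASE_CONTRIBUTION = 0.25


def pair_contributions(
    records: Sequence[InteractionRecord],
) -> dict[tuple[str, str, str], float]:
    """Contribution of every (study, consumer node, species) pair.

    A pair contributes 1 if any of its records is quantitative, else 0.25:
    a publication that both measures a species and mentions it anecdotally
    counts once, as measured. A blank species means the study resolved the
    node as a whole, which still forms one pair.
    """
    measured: set[tuple[str, str, str]] = set()
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        key = (rec.study_id, rec.consumer, rec.species)
        seen.add(key)
        if rec.is_quantitative:
            measured.add(key)
    return {
        key: MEASURED_CONTRIBUTION if key in measured else CASE_CONTRIBUTION
        for key in seen
    }


def knowledge_score(
    records: Sequence[InteractionRecord],
    nodes: Mapping[str, NodeInfo],
) -> pd.DataFrame:
    """Per-node knowledge sums and species-count-weighted scores.

    Records from excluded reviews are removed first. Returns a DataFrame
    with one row per node (zero rows included): node_id, knowledge_sum,
    n_species, weighted (= knowledge_sum / n_species, full precision; format
    to two decimals for display).
    """
    for node in nodes.values():
        if node.n_species < 1:
            raise ValueError(f"node {node.node_id!r} has n_species < 1")
    usable = drop_excluded_reviews(records)
    sums: dict[str, float] = defaultdict(float)
    for (study, consumer, _species), contrib in pair_contributions(usable).items():
        sums[consumer] += contrib
    rows = []
    for node_id in sorted(nodes):
        node = nodes[node_id]
        total = sums.get(node_id, 0.0)
        rows.append({
            "node_id": node_id,
            "knowledge_sum": total,
            "n_species": node.n_species,
            "weighted": total / node.n_species,
        })
    return pd.DataFrame(rows, columns=["node_id", "knowledge_sum", "n_species", "weighted"])


def accumulation_curve(records: Sequence[InteractionRecord]) -> pd.Series:
    """Cumulative count of distinct studies by publication year.

    Returns a Series indexed by year (years with at least one new study),
    monotone non-decreasing. Empty input yields an empty curve.
    """
    first_year: dict[str, int] = {}
    for rec in records:
        year = first_year.get(rec.study_id)
        if year is None or rec.pub_year < year:
            first_year[rec.study_id] = rec.pub_year
    if not first_year:
        return pd.Series(dtype=int, name="cumulative_studies")
    per_year = pd.Series(list(first_year.values())).value_counts().sort_index()
    curve = per_year.cumsum()
    curve.name = "cumulative_studies"
    curve.index.name = "year"
    return curve


def write_knowledge(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["knowledge_sum"] = out["knowledge_sum"].map(lambda v: f"{v:.2f}")
    out["weighted"] = out["weighted"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)
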