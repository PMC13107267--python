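"""Literature-record data model, CSV input/output, and season classification.

The unit of evidence is one literature observation of a consumer-resource
link: a study measured the interaction's strength in some native metric
(frequency of occurrence, relative biomass, caloric fraction, ...) or merely
reported that the interaction exists (a case study). Records reference nodes
-- species or groups of ecologically similar species -- described in a
separate node table with guild, realm (marine / terrestrial / coastal),
species count and a flagship flag.

Each study is assigned to a season from the calendar months it covered:
winter is November-March, summer is May-September, and a study is classified
to the block that holds a strict majority of its covered months. April and
October belong to neither block, so studies dominated by them (or tied
between blocks) stay unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Interaction-layer codes: predation, scavenging, herbivory, pollination,
#: kleptoparasitism, coprophagy, detritus flow.
LAYERS = ("Pr", "Sc", "He", "Po", "Kl", "Co", "De")

LAYER_NAMES = {
    "Pr": "predation",
    "Sc": "scavenging",
    "He": "herbivory",
    "Po": "pollination",
    "Kl": "kleptoparasitism",
    "Co": "coprophagy",
    "De": "detritus",
}

REALMS = ("marine", "terrestrial", "coastal")
STUDY_TYPES = ("quantitative", "case_study")

WINTER_MONTHS = frozenset({11, 12, 1, 2, 3})
SUMMER_MONTHS = frozenset({5, 6, 7, 8, 9})

_MONTH_ABBR = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)
_MONTH_LOOKUP = {abbr.lower(): i + 1 for i, abbr in enumerate(_MONTH_ABBR)}
_MONTH_LOOKUP.update({str(i): i for i in range(1, 13)})

RECORD_COLUMNS = (
    "study_id", "pub_year", "consumer", "resource", "layer", "metric_type",
    "raw_value", "study_months", "study_type", "excluded_review",
)
#: Optional extra column: the focal taxon within the consumer node that the
#: study addressed. Blank means the study is resolved only to the node.
OPTIONAL_RECORD_COLUMNS = ("species",)

NODE_COLUMNS = ("node_id", "label", "guild", "realm", "n_species", "flagship")


class Season(str, Enum):
    SUMMER = "summer"
    WINTER = "winter"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ValidationError(ValueError):
    """Raised when a record or node table violates the schema.

    ``problems`` lists every offending row with its file line number.
    """

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n"
            + "\n".join(self.problems)
        )


@dataclass(frozen=True)
class NodeInfo:
    """One network node: a species or a group of ecologically similar species."""

    node_id: str
    label: str
    guild: str
    realm: str
    n_species: int
    flagship: bool = False


@dataclass(frozen=True)
class InteractionRecord:
    """One literature observation of a consumer-resource interaction."""

    study_id: str
    pub_year: int
    consumer: str
    resource: str
    layer: str
    metric_type: str
    raw_value: float | None
    study_months: frozenset[int]
    study_type: str
    excluded_review: bool = False
    species: str = ""

    @property
    def season(self) -> Season:
        if not self.study_months:
            return Season.UNCLASSIFIED
        return classify_season(self.study_months)

    @property
    def is_quantitative(self) -> bool:
        return self.study_type == "quantitative"


def classify_season(study_months: Iterable[int]) -> Season:
    """Classify a set of covered calendar months into a season.

    The block (winter = Nov-Mar, summer = May-Sep) holding a strict majority
    of the covered months wins; April and October count toward neither block.
    Ties and month sets dominated by neither block are ``UNCLASSIFIED``.

    Raises ``ValueError`` for an empty set or out-of-range months.
    """
    months = set(study_months)
    if not months:
        raise ValueError("cannot classify an empty month set")
    bad = sorted(m for m in months if not (isinstance(m, int) and 1 <= m <= 12))
    if bad:
        raise ValueError(f"months out of range 1-12: {bad}")
    n = len(months)
    winter = len(months & WINTER_MONTHS)
    summer = len(months & SUMMER_MONTHS)
    if summer * 2 > n:
        return Season.SUMMER
    if winter * 2 > n:
        return Season.WINTER
    return Season.UNCLASSIFIED


def parse_months(cell: str) -> frozenset[int]:
    """Parse a month-set cell: 3-letter English abbreviations or integers
    1-12, separated by ``;``, ``|`` or whitespace. Empty cell -> empty set."""
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    tokens = cell.replace("|", ";").replace(",", ";").split(";")
    months: set[int] = set()
    for tok in tokens:
        for sub in tok.split():
            key = sub.strip().lower()
            if not key:
                continue
            if key not in _MONTH_LOOKUP:
                raise ValueError(f"unrecognized month token {sub!r}")
            months.add(_MONTH_LOOKUP[key])
    return frozenset(months)


def format_months(months: Iterable[int]) -> str:
    return ";".join(_MONTH_ABBR[m - 1] for m in sorted(set(months)))


def _parse_bool(cell: str, *, default: bool = False) -> bool:
    cell = (cell or "").strip().lower()
    if cell in ("", "na", "nan"):
        return default
    if cell in ("true", "t", "yes", "y", "1"):
        return True
    if cell in ("false", "f", "no", "n", "0"):
        return False
    raise ValueError(f"unrecognized boolean {cell!r}")


def read_nodes(path: str | Path) -> dict[str, NodeInfo]:
    """Read and validate a node table; returns a node_id -> NodeInfo mapping."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"{path}: missing node columns {missing}"])
    problems: list[str] = []
    nodes: dict[str, NodeInfo] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        node_id = row["node_id"].strip()
        if not node_id:
            problems.append(f"{path}:{line}: empty node_id")
            continue
        if node_id in nodes:
            problems.append(f"{path}:{line}: duplicate node_id {node_id!r}")
            continue
        realm = row["realm"].strip().lower()
        if realm not in REALMS:
            problems.append(
                f"{path}:{line}: realm {row['realm']!r} not in {REALMS}"
            )
            continue
        try:
            n_species = int(row["n_species"])
            if n_species < 1:
                raise ValueError
        except ValueError:
            problems.append(
                f"{path}:{line}: n_species {row['n_species']!r} "
                "must be an integer >= 1"
            )
            continue
        try:
            flagship = _parse_bool(row["flagship"])
        except ValueError as exc:
            problems.append(f"{path}:{line}: {exc}")
            continue
        nodes[node_id] = NodeInfo(
            node_id=node_id,
            label=row["label"].strip(),
            guild=row["guild"].strip(),
            realm=realm,
            n_species=n_species,
            flagship=flagship,
        )
    if problems:
        raise ValidationError(problems)
    return nodes


def _parse_record_row(row: Mapping[str, str], line: int, source: str,
                      problems: list[str]) -> InteractionRecord | None:
    def fail(msg: str) -> None:
        problems.append(f"{source}:{line}: {msg}")

    study_id = row["study_id"].strip()
    if not study_id:
        fail("empty study_id")
        return None
    try:
        pub_year = int(row["pub_year"])
    except ValueError:
        fail(f"pub_year {row['pub_year']!r} is not an integer")
        return None
    layer = row["layer"].strip()
    if layer not in LAYERS:
        fail(f"unknown layer code {layer!r} (expected one of {LAYERS})")
        return None
    study_type = row["study_type"].strip()
    if study_type not in STUDY_TYPES:
        fail(f"study_type {study_type!r} not in {STUDY_TYPES}")
        return None
    raw_cell = row["raw_value"].strip()
    raw_value: float | None
    if raw_cell in ("", "na", "NA", "nan", "NaN"):
        raw_value = None
    else:
        try:
            raw_value = float(raw_cell)
        except ValueError:
            fail(f"raw_value {raw_cell!r} is not a number")
            return None
        if raw_value < 0:
            fail(f"negative raw_value {raw_value}")
            return None
    try:
        months = parse_months(row["study_months"])
    except ValueError as exc:
        fail(str(exc))
        return None
    if study_type == "quantitative":
        if raw_value is None:
            fail("quantitative record with missing raw_value")
            return None
        if not months:
            fail("quantitative record with empty study_months")
            return None
    try:
        excluded = _parse_bool(row["excluded_review"])
    except ValueError as exc:
        fail(str(exc))
        return None
    return InteractionRecord(
        study_id=study_id,
        pub_year=pub_year,
        consumer=row["consumer"].strip(),
        resource=row["resource"].strip(),
        layer=layer,
        metric_type=row["metric_type"].strip(),
        raw_value=raw_value,
        study_months=months,
        study_type=study_type,
        excluded_review=excluded,
        species=row.get("species", "").strip(),
    )


def read_records(
    path: str | Path,
    node_table: str | Path | Mapping[str, NodeInfo],
    *,
    allow_self_loops: bool = False,
) -> tuple[list[InteractionRecord], dict[str, NodeInfo]]:
    """Read and validate the record table against a node table.

    Every consumer/resource must resolve to a node_id; malformed rows are
    reported with their file line numbers in a single ``ValidationError``.
    """
    if isinstance(node_table, (str, Path)):
        nodes = read_nodes(node_table)
    else:
        nodes = dict(node_table)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"{path}: missing record columns {missing}"])
    problems: list[str] = []
    records: list[InteractionRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2
        rec = _parse_record_row(row, line, str(path), problems)
        if rec is None:
            continue
        for endpoint in (rec.consumer, rec.resource):
            if endpoint not in nodes:
                problems.append(
                    f"{path}:{line}: node {endpoint!r} absent from node table"
                )
                rec = None
                break
        if rec is None:
            continue
        if rec.consumer == rec.resource and not allow_self_loops:
            problems.append(
                f"{path}:{line}: self-loop on {rec.consumer!r} "
                "(pass allow_self_loops=True to accept cannibalism links)"
            )
            continue
        records.append(rec)
    if problems:
        raise ValidationError(problems)
    return records, nodes


def validate_records(
    records: Sequence[InteractionRecord], nodes: Mapping[str, NodeInfo],
    *, allow_self_loops: bool = False,
) -> None:
    """Re-validate in-memory records against a node table."""
    problems = []
    for i, rec in enumerate(records):
        for endpoint in (rec.consumer, rec.resource):
            if endpoint not in nodes:
                problems.append(f"record {i}: unknown node {endpoint!r}")
        if rec.consumer == rec.resource and not allow_self_loops:
            problems.append(f"record {i}: self-loop on {rec.consumer!r}")
        if rec.layer not in LAYERS:
            problems.append(f"record {i}: unknown layer {rec.layer!r}")
        if rec.raw_value is not None and rec.raw_value < 0:
            problems.append(f"record {i}: negative raw_value")
        if rec.is_quantitative and not rec.study_months:
            problems.append(f"record {i}: quantitative without study_months")
    if problems:
        raise ValidationError(problems)


def records_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({
            "study_id": rec.study_id,
            "pub_year": rec.pub_year,
            "consumer": rec.consumer,
            "resource": rec.resource,
            "layer": rec.layer,
            "metric_type": rec.metric_type,
            "raw_value": "" if rec.raw_value is None else repr(rec.raw_value),
            "study_months": format_months(rec.study_months),
            "study_type": rec.study_type,
            "excluded_review": str(rec.excluded_review).lower(),
            "species": rec.species,
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS + OPTIONAL_RECORD_COLUMNS)


def nodes_to_frame(nodes: Mapping[str, NodeInfo]) -> pd.DataFrame:
    rows = [{
        "node_id": n.node_id,
        "label": n.label,
        "guild": n.guild,
        "realm": n.realm,
        "n_species": n.n_species,
        "flagship": str(n.flagship).lower(),
    } for n in nodes.values()]
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def write_records(records: Sequence[InteractionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_nodes(nodes: Mapping[str, NodeInfo], path: str | Path) -> None:
    nodes_to_frame(nodes).to_csv(path, index=False)


def drop_excluded_reviews(
    records: Sequence[InteractionRecord],
) -> list[InteractionRecord]:
    """Remove records stemming from reviews flagged as excluded.

    Review articles re-report primary observations; counting them would
    double-weight the underlying studies, so flagged reviews are set aside
    before any scoring or scaling.
    """
    kept = [r for r in records if not r.excluded_review]
    dropped = len(records) - len(kept)
    if dropped:
        logger.warning("dropped %d record(s) from excluded reviews", dropped)
    return kept
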