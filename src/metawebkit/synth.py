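"""Seeded synthetic literature-record generator and worked-example fixtures.

The generator emulates the statistical structure of a literature corpus on
Arctic species interactions so the whole pipeline runs without external
data:

* each consumer has a latent "true" diet: Dirichlet-distributed shares over
  a handful of resource nodes, each pair carrying a fixed interaction layer;
* studies sample consumers unevenly -- flagship taxa (bears, foxes,
  reindeer, geese) are oversampled by a configurable multiplier;
* seasonal coverage is summer-heavy: only a small fraction of studies are
  winter studies, mirroring the scarcity of winter fieldwork;
* studies report in heterogeneous metrics that differ only by scale
  (percent, per-mille, sample counts), which the standardization step must
  neutralize;
* a fraction of studies are anecdotal case reports that establish a link
  without measuring it, and a small fraction are review articles flagged
  for exclusion.

Measurement noise resamples each study's observed shares around the true
diet with a Dirichlet concentration; at zero noise every study observes the
true shares exactly, so recovered ordinal classes must match the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (
    InteractionRecord,
    LAYERS,
    NodeInfo,
    Season,
    SUMMER_MONTHS,
    WINTER_MONTHS,
    write_nodes,
    write_records,
)
from .scaling import ScaledLink, scale_share, scale_records

DEFAULT_LAYER_WEIGHTS = {
    "Pr": 0.40, "Sc": 0.15, "He": 0.20, "Po": 0.10,
    "Kl": 0.05, "Co": 0.05, "De": 0.05,
}

_GUILDS = (
    "apex predator", "mesopredator", "herbivore", "seabird", "shorebird",
    "waterfowl", "arthropod", "plant", "pinniped", "scavenger",
)

# (metric label, scale factor applied to the observed shares)
_METRICS = (
    ("frequency_of_occurrence_pct", 100.0),
    ("relative_biomass_permille", 1000.0),
    ("prey_item_count", 357.0),
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic literature corpus (seed-deterministic)."""

    seed: int = 0
    n_nodes: int = 30
    n_studies: int = 120
    flagship_fraction: float = 0.15
    flagship_oversampling: float = 4.0
    winter_study_fraction: float = 0.15
    case_study_fraction: float = 0.25
    excluded_review_fraction: float = 0.02
    layer_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_WEIGHTS)
    )
    true_diet_concentration: float = 1.0
    #: 0 = every study observes the true diet exactly; larger values lower
    #: the Dirichlet concentration (alpha = true_shares * 100 / noise).
    measurement_noise: float = 0.5
    resources_per_consumer: tuple[int, int] = (3, 8)
    year_range: tuple[int, int] = (1900, 2025)

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_studies < 1:
            raise ValueError("need at least 1 study")
        for name in ("flagship_fraction", "winter_study_fraction",
                     "case_study_fraction", "excluded_review_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.flagship_oversampling < 1.0:
            raise ValueError("flagship_oversampling must be >= 1")
        if self.measurement_noise < 0:
            raise ValueError("measurement_noise must be >= 0")
        if self.true_diet_concentration <= 0:
            raise ValueError("true_diet_concentration must be > 0")
        total = sum(self.layer_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"layer_weights sum to {total}, expected 1")
        unknown = set(self.layer_weights) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layers in layer_weights: {sorted(unknown)}")


def _make_nodes(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, NodeInfo]:
    realms = rng.choice(
        ["terrestrial", "marine", "coastal"], size=cfg.n_nodes, p=[0.5, 0.35, 0.15]
    )
    flagship = rng.random(cfg.n_nodes) < cfg.flagship_fraction
    if cfg.flagship_fraction > 0 and not flagship.any():
        flagship[0] = True  # keep the oversampling contrast observable
    nodes = {}
    for i in range(cfg.n_nodes):
        node_id = f"n{i:03d}"
        nodes[node_id] = NodeInfo(
            node_id=node_id,
            label=f"Taxon {i:03d}",
            guild=str(rng.choice(_GUILDS)),
            realm=str(realms[i]),
            n_species=1 + int(rng.poisson(3.0)),
            flagship=bool(flagship[i]),
        )
    return nodes


def _true_web(
    cfg: SynthConfig, rng: np.random.Generator, node_ids: Sequence[str]
) -> pd.DataFrame:
    """Latent diets: per consumer a Dirichlet share over resources, each
    consumer-resource pair carrying one fixed layer."""
    layer_names = sorted(cfg.layer_weights)
    layer_p = np.array([cfg.layer_weights[l] for l in layer_names])
    lo, hi = cfg.resources_per_consumer
    rows = []
    for consumer in node_ids:
        others = [n for n in node_ids if n != consumer]
        k = int(rng.integers(lo, min(hi, len(others)) + 1))
        resources = list(rng.choice(others, size=k, replace=False))
        shares = rng.dirichlet(np.full(k, cfg.true_diet_concentration))
        layers = rng.choice(layer_names, size=k, p=layer_p)
        for resource, share, layer in zip(resources, shares, layers):
            rows.append({
                "consumer": consumer,
                "resource": resource,
                "layer": str(layer),
                "true_share": float(share),
                "true_score": scale_share(100.0 * float(share)),
            })
    return pd.DataFrame(rows)


def _sample_months(
    rng: np.random.Generator, season: Season
) -> frozenset[int]:
    block = sorted(SUMMER_MONTHS) if season is Season.SUMMER else [11, 12, 1, 2, 3]
    length = int(rng.integers(1, 4))
    start = int(rng.integers(0, len(block) - length + 1))
    return frozenset(block[start:start + length])


def generate_records(
    config: SynthConfig,
) -> tuple[list[InteractionRecord], dict[str, NodeInfo], pd.DataFrame]:
    """Generate a synthetic record table, node table, and the latent truth.

    The truth DataFrame (consumer, resource, layer, true_share, true_score)
    supports parameter-recovery checks; it is not part of the emitted CSVs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nodes = _make_nodes(config, rng)
    node_ids = sorted(nodes)
    truth = _true_web(config, rng, node_ids)
    diets = {
        consumer: grp.reset_index(drop=True)
        for consumer, grp in truth.groupby("consumer", sort=True)
    }

    weights = np.array([
        config.flagship_oversampling if nodes[n].flagship else 1.0
        for n in node_ids
    ])
    weights = weights / weights.sum()

    y0, y1 = config.year_range
    records: list[InteractionRecord] = []
    for i in range(config.n_studies):
        study_id = f"S{i + 1:04d}"
        # literature accumulates slowly, then accelerates
        pub_year = y0 + int((y1 - y0) * rng.beta(3.0, 1.2))
        consumer = str(rng.choice(node_ids, p=weights))
        diet = diets[consumer]
        season = (
            Season.WINTER if rng.random() < config.winter_study_fraction
            else Season.SUMMER
        )
        months = _sample_months(rng, season)
        excluded = bool(rng.random() < config.excluded_review_fraction)
        if rng.random() < config.case_study_fraction:
            # anecdotal report of a single (usually prominent) link
            j = int(rng.choice(len(diet), p=diet["true_share"].to_numpy()))
            row = diet.iloc[j]
            records.append(InteractionRecord(
                study_id=study_id,
                pub_year=pub_year,
                consumer=consumer,
                resource=row["resource"],
                layer=row["layer"],
                metric_type="anecdote",
                raw_value=None,
                study_months=months if rng.random() < 0.8 else frozenset(),
                study_type="case_study",
                excluded_review=excluded,
            ))
            continue
        true_shares = diet["true_share"].to_numpy()
        if config.measurement_noise == 0:
            observed = true_shares
        else:
            alpha = true_shares * (100.0 / config.measurement_noise)
            observed = rng.dirichlet(np.clip(alpha, 1e-3, None))
        metric, scale = _METRICS[int(rng.integers(len(_METRICS)))]
        for j in range(len(diet)):
            records.append(InteractionRecord(
                study_id=study_id,
                pub_year=pub_year,
                consumer=consumer,
                resource=diet.iloc[j]["resource"],
                layer=diet.iloc[j]["layer"],
                metric_type=metric,
                raw_value=float(observed[j] * scale),
                study_months=months,
                study_type="quantitative",
                excluded_review=excluded,
            ))
    return records, nodes, truth


def write_synthetic(config: SynthConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write records.csv and nodes.csv for a config; byte-deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, nodes, _ = generate_records(config)
    records_path = out / "records.csv"
    nodes_path = out / "nodes.csv"
    write_records(records, records_path)
    write_nodes(nodes, nodes_path)
    return records_path, nodes_path


_CLASSES = (0, 1, 2, 4, 8)


def _nearest_class(strength: float) -> int:
    return min(_CLASSES, key=lambda c: (abs(strength - c), c))


def ordinal_recovery(
    records: Sequence[InteractionRecord], truth: pd.DataFrame
) -> float:
    """Fraction of measured links whose averaged strength maps back to the
    true ordinal class (nearest of {0,1,2,4,8}, ties to the lower class)."""
    links = scale_records([r for r in records if not r.excluded_review])
    true_score = {
        (row.consumer, row.resource, row.layer): row.true_score
        for row in truth.itertuples()
    }
    measured = [ln for ln in links if ln.provenance == "measured"]
    if not measured:
        raise ValueError("no measured links to evaluate")
    hits = sum(
        1 for ln in measured
        if _nearest_class(ln.strength)
        == true_score[(ln.consumer, ln.resource, ln.layer)]
    )
    return hits / len(measured)


# ---------------------------------------------------------------------------
# hand-built worked-example fixtures


def knowledge_example() -> tuple[list[InteractionRecord], dict[str, NodeInfo]]:
    """The 3-species worked example for knowledge scoring.

    One node aggregates three species; paper P1 measures interaction
    strength for species A, P2 for species A and B, and P3 is a case study
    of species C. Expected: knowledge sum 3.25, weighted 3.25/3 ~ 1.08.
    """
    nodes = {
        "auks": NodeInfo("auks", "Auks", "seabird", "coastal", n_species=3),
        "polar_cod": NodeInfo("polar_cod", "Polar cod", "fish", "marine", n_species=1),
    }
    summer = frozenset({6, 7, 8})

    def rec(study, species, quantitative, raw=50.0):
        return InteractionRecord(
            study_id=study, pub_year=2000, consumer="auks",
            resource="polar_cod", layer="Pr",
            metric_type="frequency_of_occurrence_pct" if quantitative else "anecdote",
            raw_value=raw if quantitative else None,
            study_months=summer,
            study_type="quantitative" if quantitative else "case_study",
            species=species,
        )

    records = [
        rec("P1", "sp_A", True),
        rec("P2", "sp_A", True),
        rec("P2", "sp_B", True),
        rec("P3", "sp_C", False),
    ]
    return records, nodes


def share_bin_examples() -> list[tuple[float, int]]:
    """Standardized shares covering every ordinal bin and its boundaries,
    paired with their expected scores."""
    return [
        (0.0, 0), (3.0, 1), (5.0, 1), (10.0, 2),
        (20.0, 2), (50.0, 4), (67.0, 4), (80.0, 8),
    ]


def mini_metaweb() -> tuple[list[ScaledLink], dict[str, NodeInfo]]:
    """A small Arctic-flavoured metaweb: marine, coastal and terrestrial
    nodes, all five resolvable layers with >= 3 measured links each, plus a
    single-link coprophagy layer for sparse-layer exclusion tests."""
    def node(nid, label, guild, realm, n_species=1, flagship=False):
        return NodeInfo(nid, label, guild, realm, n_species, flagship)

    node_list = [
        node("seal", "Ringed seal", "pinniped", "marine", 2),
        node("fish", "Forage fish", "fish", "marine", 5),
        node("polar_bear", "Polar bear", "apex predator", "coastal", 1, True),
        node("arctic_fox", "Arctic fox", "mesopredator", "terrestrial", 1, True),
        node("reindeer", "Svalbard reindeer", "herbivore", "terrestrial", 1, True),
        node("goose", "Geese", "waterfowl", "terrestrial", 3),
        node("gull", "Glaucous gull", "seabird", "coastal", 1),
        node("skua", "Skuas", "seabird", "coastal", 2),
        node("seabirds", "Cliff-nesting seabirds", "seabird", "coastal", 6),
        node("plants", "Vascular plants", "plant", "terrestrial", 60),
        node("moss", "Mosses", "plant", "terrestrial", 30),
        node("forbs", "Flowering forbs", "plant", "terrestrial", 20),
        node("flies", "Muscid flies", "arthropod", "terrestrial", 15),
        node("hoverflies", "Hoverflies", "arthropod", "terrestrial", 5),
    ]
    nodes = {n.node_id: n for n in node_list}

    def link(consumer, resource, layer, strength, season=Season.SUMMER,
             provenance="measured", n_studies=1):
        return ScaledLink(consumer, resource, layer, season,
                          strength, n_studies, provenance)

    links = [
        # predation
        link("polar_bear", "seal", "Pr", 8.0, n_studies=3),
        link("polar_bear", "reindeer", "Pr", 1.0),
        link("gull", "fish", "Pr", 4.0),
        link("seabirds", "fish", "Pr", 8.0, n_studies=2),
        link("arctic_fox", "goose", "Pr", 4.0, n_studies=2),
        # scavenging
        link("arctic_fox", "reindeer", "Sc", 4.0, n_studies=2),
        link("gull", "seal", "Sc", 2.0),
        link("arctic_fox", "seal", "Sc", 2.0),
        # herbivory
        link("reindeer", "plants", "He", 8.0, n_studies=4),
        link("reindeer", "moss", "He", 2.0),
        link("goose", "plants", "He", 8.0, n_studies=2),
        # pollination (plant -> pollinator energy via nectar and pollen)
        link("flies", "forbs", "Po", 4.0),
        link("hoverflies", "forbs", "Po", 4.0),
        link("flies", "plants", "Po", 2.0),
        # kleptoparasitism (victim as resource)
        link("arctic_fox", "polar_bear", "Kl", 2.0),
        link("gull", "arctic_fox", "Kl", 1.0),
        link("skua", "gull", "Kl", 2.0),
        # coprophagy: a single anecdote-backed measured link (too sparse)
        link("reindeer", "goose", "Co", 1.0),
    ]
    return links, nodes
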