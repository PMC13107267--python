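"""Metaweb assembly, sparse-layer exclusion, subwebs, crossover profiles,
summaries and export round-trips."""

from __future__ import annotations

import pytest

from metawebkit.network import (
    build_metaweb,
    crossover_summary,
    exclude_sparse_layers,
    extract_subweb,
    network_summary,
    read_edge_csv,
    read_graphml,
    write_edge_csv,
    write_graphml,
)
from metawebkit.records import NodeInfo, Season
from metawebkit.scaling import ScaledLink


def link(consumer, resource, layer="Pr", season=Season.SUMMER, strength=4.0,
         n_studies=1, provenance="measured"):
    return ScaledLink(consumer, resource, layer, season, strength,
                      n_studies, provenance)


class TestBuild:
    def test_five_link_fixture(self, mini_web):
        links, nodes = mini_web
        five = links[:5]
        mw = build_metaweb(five, nodes)
        assert mw.n_edges == 5
        assert mw.included_layers == {ln.layer for ln in five}
        # edges run resource -> consumer (energy flow)
        assert mw.graph.has_edge("seal", "polar_bear")

    def test_empty_link_set_is_valid(self, mini_web):
        _, nodes = mini_web
        mw = build_metaweb([], nodes)
        assert mw.n_edges == 0
        assert mw.included_layers == frozenset()

    def test_duplicate_link_key_rejected(self, mini_web):
        _, nodes = mini_web
        dup = [link("polar_bear", "seal"), link("polar_bear", "seal")]
        with pytest.raises(ValueError, match="duplicate"):
            build_metaweb(dup, nodes)

    def test_missing_endpoint_rejected(self, mini_web):
        _, nodes = mini_web
        with pytest.raises(ValueError, match="absent"):
            build_metaweb([link("polar_bear", "narwhal")], nodes)

    def test_zero_strength_links_are_not_edges(self, mini_web):
        _, nodes = mini_web
        mw = build_metaweb([link("polar_bear", "seal", strength=0.0)], nodes)
        assert mw.n_edges == 0

    def test_season_filter(self, mini_web):
        _, nodes = mini_web
        links = [link("polar_bear", "seal", season=Season.SUMMER),
                 link("polar_bear", "seal", season=Season.WINTER, strength=8.0)]
        assert build_metaweb(links, nodes, season="summer").n_edges == 1
        assert build_metaweb(links, nodes, season="both").n_edges == 2


class TestSparseLayers:
    def test_single_link_layer_dropped(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        reduced, report = exclude_sparse_layers(mw, min_links=3)
        assert "Co" not in reduced.included_layers
        assert report["Co"] == {"measured_links": 1, "dropped": True}
        assert report["Pr"]["dropped"] is False

    def test_min_links_one_keeps_every_supported_layer(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        reduced, _ = exclude_sparse_layers(mw, min_links=1)
        assert reduced.included_layers == mw.included_layers
        assert reduced.n_edges == mw.n_edges

    def test_case_only_links_do_not_support_a_layer(self, mini_web):
        _, nodes = mini_web
        links = [link("arctic_fox", "goose", layer="De",
                      provenance="case_only", strength=0.1)
                 for _ in range(1)]
        links += [link("reindeer", "plants", layer="He")] * 0
        links += [link("reindeer", "plants", layer="He"),
                  link("goose", "plants", layer="He"),
                  link("reindeer", "moss", layer="He")]
        mw = build_metaweb(links, nodes)
        reduced, report = exclude_sparse_layers(mw, min_links=1)
        assert "De" not in reduced.included_layers
        assert report["De"]["measured_links"] == 0

    def test_exclusion_never_adds_edges(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        for k in (1, 3, 10):
            reduced, _ = exclude_sparse_layers(mw, min_links=k)
            assert reduced.n_edges <= mw.n_edges


class TestSubwebs:
    def test_plant_pollinator_subweb(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        sub = extract_subweb(mw, consumers={"flies", "hoverflies"},
                             resources={"forbs", "plants", "dryas"} & set(nodes),
                             layers={"Po"})
        assert sub.included_layers == {"Po"}
        assert sub.n_edges == 3
        assert all(d["layer"] == "Po" for _, _, d in sub.graph.edges(data=True))

    def test_empty_consumer_set_gives_empty_subweb(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        sub = extract_subweb(mw, consumers=set(), resources={"seal"}, layers={"Pr"})
        assert sub.n_edges == 0

    def test_unknown_node_id_rejected(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        with pytest.raises(ValueError, match="unknown node"):
            extract_subweb(mw, consumers={"yeti"}, resources=set(), layers={"Pr"})

    def test_subweb_is_monotone_and_commutes_with_exclusion(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        consumers = {"arctic_fox", "gull", "polar_bear"}
        resources = {"seal", "reindeer", "goose"}
        layers = {"Pr", "Sc"}
        sub = extract_subweb(mw, consumers, resources, layers)
        assert sub.n_edges <= mw.n_edges
        a, _ = exclude_sparse_layers(
            extract_subweb(mw, consumers, resources, layers), min_links=2)
        b = extract_subweb(
            exclude_sparse_layers(mw, min_links=2)[0],
            consumers, resources, layers)
        assert {tuple(sorted(e)) for e in a.graph.edges(keys=True)} == \
               {tuple(sorted(e)) for e in b.graph.edges(keys=True)}


class TestCrossover:
    def test_even_marine_terrestrial_split(self, mini_web):
        _, nodes = mini_web
        links = [link("arctic_fox", "seal", strength=4.0),
                 link("arctic_fox", "goose", strength=4.0)]
        profile = crossover_summary(build_metaweb(links, nodes), "arctic_fox")
        assert profile.realm_split == pytest.approx(
            {"marine": 0.5, "terrestrial": 0.5})

    def test_all_marine_resources(self, mini_web):
        _, nodes = mini_web
        links = [link("polar_bear", "seal"), link("polar_bear", "fish")]
        profile = crossover_summary(build_metaweb(links, nodes), "polar_bear")
        assert profile.realm_split == {"marine": 1.0}

    def test_consumer_without_incoming_energy_is_flagged(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        profile = crossover_summary(mw, "moss")
        assert profile.total_strength == 0
        assert profile.realm_split is None

    def test_realm_fractions_sum_to_one(self, mini_web):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        for consumer in nodes:
            profile = crossover_summary(mw, consumer)
            if profile.realm_split is not None:
                assert sum(profile.realm_split.values()) == pytest.approx(
                    1.0, abs=1e-9)


class TestSummaryAndExports:
    def test_per_layer_counts(self, mini_web):
        _, nodes = mini_web
        links = [link("polar_bear", "seal"), link("gull", "fish"),
                 link("arctic_fox", "goose"),
                 link("reindeer", "plants", layer="He"),
                 link("goose", "plants", layer="He")]
        summary = network_summary(build_metaweb(links, nodes))
        counts = dict(zip(summary["layer"], summary["n_links"]))
        assert counts == {"Pr": 3, "He": 2}
        assert (summary["strength_min"] >= 0).all()
        assert (summary["strength_max"] <= 8).all()

    def test_summer_superset_has_no_smaller_counts(self, mini_web):
        links, nodes = mini_web
        winter_links = [link("arctic_fox", "reindeer", layer="Sc",
                             season=Season.WINTER)]
        mw_both = build_metaweb(links + winter_links, nodes)
        summer = network_summary(build_metaweb(links, nodes, season="summer"))
        both = network_summary(mw_both)
        assert summer["n_links"].sum() <= both["n_links"].sum()

    def test_edge_csv_round_trip(self, mini_web, tmp_path):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        path = tmp_path / "edges.csv"
        write_edge_csv(mw, path)
        back = read_edge_csv(path, nodes)
        assert back.links() == mw.links()

    def test_graphml_round_trip(self, mini_web, tmp_path):
        links, nodes = mini_web
        mw = build_metaweb(links, nodes)
        path = tmp_path / "web.graphml"
        write_graphml(mw, path)
        back = read_graphml(path)
        assert back.links() == mw.links()
        assert back.included_layers == mw.included_layers
        for node in nodes.values():
            assert back.node_info(node.node_id) == node
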