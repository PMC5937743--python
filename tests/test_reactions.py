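"""Reaction grammar, metabolite lists, and GML round trips."""

import logging

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacore.gmlio import read_gml, write_gml
from metacore.reactions import (
    InvalidMetaboliteError,
    Reaction,
    ReactionParseError,
    normalize_name,
    parse_reaction,
    read_metabolite_list,
    read_reaction_file,
    write_reaction_file,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("  ATP ", "ATP"),
        ("coenzyme  A", "coenzyme A"),
        ("NAD+", "NAD+"),
        ("\tL-glutamate\n", "L-glutamate"),
        ("a  b   c", "a b c"),
    ],
)
def test_normalize_name(raw, expected):
    assert normalize_name(raw) == expected


def test_normalize_name_rejects_empty():
    with pytest.raises(InvalidMetaboliteError):
        normalize_name("   ")


def test_normalize_name_case_fold_is_opt_in():
    assert normalize_name("ATP") != normalize_name("atp")
    assert normalize_name("ATP", case_fold=True) == normalize_name(
        "atp", case_fold=True
    )


@given(st.text(min_size=1).filter(lambda s: s.strip()))
@settings(max_examples=50, derandomize=True)
def test_normalize_name_idempotent(raw):
    once = normalize_name(raw)
    assert normalize_name(once) == once
    assert once == once.strip()


@pytest.mark.parametrize(
    "line,subs,prods",
    [
        ("R1: ATP + H2O -> ADP + phosphate", {"ATP", "H2O"}, {"ADP", "phosphate"}),
        ("R2: 2 pyruvate <=> 2 L-lactate", {"pyruvate"}, {"L-lactate"}),
        # reverse arrow swaps sides to the forward sense
        ("R4: ADP <- ATP", {"ATP"}, {"ADP"}),
        ("R5: A = B", {"A"}, {"B"}),
        # internal '+' survives because ' + ' is the separator
        ("R6: NAD+ + H+ -> NADH", {"NAD+", "H+"}, {"NADH"}),
        # duplicated metabolite on one side is deduplicated
        ("R7: A + A -> B", {"A"}, {"B"}),
        # a bare integer term is a name, not a coefficient
        ("R8: 2 -> B", {"2"}, {"B"}),
    ],
)
def test_parse_reaction(line, subs, prods):
    rxn = parse_reaction(line)
    assert rxn.substrates == frozenset(subs)
    assert rxn.products == frozenset(prods)


@pytest.mark.parametrize(
    "line",
    [
        "R3: A + B",          # no arrow
        "R: -> B",            # empty left side
        "R: A -> ",           # empty right side
        " : A -> B",          # empty id
        "no separator A -> B",
        "R: A -> B -> C",     # two arrows
    ],
)
def test_parse_reaction_errors(line):
    with pytest.raises(ReactionParseError):
        parse_reaction(line)


def test_read_reaction_file(tmp_path):
    p = tmp_path / "rxn.txt"
    p.write_text(
        "# a comment\n"
        "R1: ATP + H2O -> ADP + phosphate\n"
        "\n"
        "R2: glucose -> pyruvate\n"
        "R3: pyruvate <- PEP\n"
    )
    rxns = read_reaction_file(p)
    assert [r.id for r in rxns] == ["R1", "R2", "R3"]
    assert rxns[2].substrates == frozenset({"PEP"})


def test_read_reaction_file_duplicate_id(tmp_path):
    p = tmp_path / "rxn.txt"
    p.write_text("R1: A -> B\nR1: C -> D\n")
    with pytest.raises(ReactionParseError, match="R1"):
        read_reaction_file(p)


def test_read_reaction_file_aggregates_errors_with_line_numbers(tmp_path):
    p = tmp_path / "rxn.txt"
    p.write_text("R1: A -> B\nbad line one\nR2: C -> D\nanother bad\n")
    with pytest.raises(ReactionParseError) as exc:
        read_reaction_file(p)
    assert "line 2" in str(exc.value) and "line 4" in str(exc.value)


def test_read_reaction_file_empty(tmp_path):
    p = tmp_path / "empty.txt"
    p.write_text("")
    assert read_reaction_file(p) == []


def test_reaction_file_round_trip(tmp_path):
    rxns = [
        Reaction("R1", frozenset({"ATP", "H2O"}), frozenset({"ADP", "phosphate"})),
        Reaction("R2", frozenset({"NAD+"}), frozenset({"NADH", "H+"})),
    ]
    p = tmp_path / "out.txt"
    write_reaction_file(rxns, p)
    assert read_reaction_file(p) == rxns


def test_read_metabolite_list(tmp_path):
    p = tmp_path / "list.txt"
    p.write_text(" ATP \nADP\nATP\n\n# note\n")
    ml = read_metabolite_list(p, "common")
    assert ml.label == "common"
    assert ml.members == {"ATP", "ADP"}
    assert len(ml) == 2 and "ATP" in ml


def test_read_metabolite_list_empty(tmp_path):
    p = tmp_path / "list.txt"
    p.write_text("")
    assert read_metabolite_list(p, "x").members == set()


def test_gml_round_trip(tmp_path):
    G = nx.path_graph(4)
    G = nx.relabel_nodes(G, {i: f"M{i}" for i in range(4)})
    G.add_node("isolated")
    path = tmp_path / "net.gml"
    write_gml(G, path)
    H = read_gml(path, species="sp")
    assert set(H.nodes) == set(G.nodes)
    assert {frozenset(e) for e in H.edges} == {frozenset(e) for e in G.edges}
    assert H.graph["species"] == "sp"


def test_gml_species_defaults_to_stem(tmp_path):
    write_gml(nx.path_graph(3), tmp_path / "arabidopsis.gml")
    assert read_gml(tmp_path / "arabidopsis.gml").graph["species"] == "arabidopsis"


def test_gml_drops_self_loop_with_warning(tmp_path, caplog):
    path = tmp_path / "loop.gml"
    path.write_text(
        "graph [\n  node [ id 0 label \"A\" ]\n  node [ id 1 label \"B\" ]\n"
        "  edge [ source 0 target 1 ]\n  edge [ source 0 target 0 ]\n]\n"
    )
    with caplog.at_level(logging.WARNING):
        G = read_gml(path)
    assert set(G.edges) == {("A", "B")}
    assert "self-loop" in caplog.text


def test_gml_collapses_duplicate_edges(tmp_path, caplog):
    path = tmp_path / "dup.gml"
    path.write_text(
        "graph [\n  node [ id 0 label \"A\" ]\n  node [ id 1 label \"B\" ]\n"
        "  edge [ source 0 target 1 ]\n  edge [ source 0 target 1 ]\n]\n"
    )
    with caplog.at_level(logging.WARNING):
        G = read_gml(path)
    assert G.number_of_edges() == 1
    assert "duplicate" in caplog.text


def test_gml_node_without_label_is_an_error(tmp_path):
    path = tmp_path / "bad.gml"
    path.write_text("graph [\n  node [ id 0 ]\n]\n")
    with pytest.raises(nx.NetworkXError):
        read_gml(path)
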