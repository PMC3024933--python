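"""Model readers/writers and pathway reports."""

import json
from fractions import Fraction

import pytest

import spabbats as sp
from spabbats import model_io
from conftest import make_network, prepare

MINIMAL_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="mini">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="B" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R1" reversible="{rev}">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="{coeff}" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


class TestSbml:
    def test_minimal_irreversible_reaction(self, tmp_path):
        path = tmp_path / "m.xml"
        path.write_text(MINIMAL_SBML.format(rev="false", coeff="1"))
        net = sp.read_sbml(path)
        assert net.metabolite_ids == ("A", "B")
        [rxn] = net.reactions
        assert dict(rxn.stoichiometry) == {"A": Fraction(-1), "B": Fraction(1)}
        assert rxn.reversible is False

    def test_reversible_flag_honored(self, tmp_path):
        path = tmp_path / "m.xml"
        path.write_text(MINIMAL_SBML.format(rev="true", coeff="1"))
        assert sp.read_sbml(path).reactions[0].reversible is True

    def test_fractional_stoichiometry_is_exact(self, tmp_path):
        path = tmp_path / "m.xml"
        path.write_text(MINIMAL_SBML.format(rev="false", coeff="0.5"))
        net = sp.read_sbml(path)
        assert net.reactions[0].stoichiometry["A"] == Fraction(-1, 2)
        integerized = sp.integerize(net.reactions[0])
        assert dict(integerized.stoichiometry) == {"A": Fraction(-1), "B": Fraction(2)}

    def test_malformed_sbml_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml><model></sbml>")
        with pytest.raises(sp.ModelIOError):
            sp.read_sbml(path)

    def test_sbml_and_native_fixture_files_agree(self):
        """The packaged SBML and TSV encodings of the glutamate network load
        to identical stoichiometry, reversibility and id sets."""
        from_sbml = sp.read_sbml(str(sp.fixture_path("glutamate.xml")))
        from_tsv = sp.read_native(str(sp.fixture_path("glutamate.tsv")))
        assert from_sbml.reaction_ids == from_tsv.reaction_ids
        assert set(from_sbml.metabolite_ids) == set(from_tsv.metabolite_ids)
        for a, b in zip(from_sbml.reactions, from_tsv.reactions):
            assert dict(a.stoichiometry) == dict(b.stoichiometry)
            assert a.reversible == b.reversible


class TestNative:
    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_round_trip(self, tmp_path, fmt):
        net = make_network(
            {"R1": {"a": "-0.5", "b": "1.5"}, "R2": {"b": -1, "c": "2/3"}},
            reversible={"R2"},
        )
        path = tmp_path / f"net.{fmt}"
        sp.write_native(net, path)
        back = sp.read_native(path)
        assert back.reaction_ids == net.reaction_ids
        for a, b in zip(back.reactions, net.reactions):
            assert dict(a.stoichiometry) == dict(b.stoichiometry)
            assert a.reversible == b.reversible
        # byte-identical on the second cycle (canonical form)
        path2 = tmp_path / f"net2.{fmt}"
        sp.write_native(back, path2)
        assert path.read_text() == path2.read_text()

    def test_decimal_coefficient_survives_as_decimal(self, tmp_path):
        net = make_network({"R1": {"a": "-1.5", "b": 1}})
        path = tmp_path / "net.tsv"
        sp.write_native(net, path)
        assert "a:-1.5" in path.read_text()

    def test_empty_model_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("\n")
        with pytest.raises(sp.ModelIOError):
            sp.read_native(path)

    def test_parse_errors_carry_line_numbers(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("R1\tirr\ta:-1,b:1\nR2\tirr\tbroken\n")
        with pytest.raises(sp.ModelIOError, match=":2"):
            sp.read_native(path)

    @pytest.mark.parametrize(
        "frac, text",
        [(Fraction(3), "3"), (Fraction(-3, 2), "-1.5"), (Fraction(1, 8), "0.125"),
         (Fraction(2, 3), "2/3"), (Fraction(-29, 4), "-7.25")],
    )
    def test_coefficient_serialization(self, frac, text):
        assert model_io.coeff_to_str(frac) == text
        assert sp.Reaction(id="r", stoichiometry={"m": text}).stoichiometry["m"] == frac


class TestReports:
    @pytest.fixture
    def fixture_result(self, glutamate):
        _, dnet, part = glutamate
        return sp.enumerate_pathways(dnet, part, max_pathways=10)

    def test_empty_result_report(self):
        net = make_network({"R1": {"o": -1, "g": 1}})
        dnet, part = prepare(net, {"g"}, {"o"})
        result = sp.enumerate_pathways(dnet, part)
        payload = json.loads(model_io.render_report(result, "json"))
        assert payload["n_pathways"] == 0
        assert payload["terminated_by"] == "exhausted"

    def test_fixture_report_has_four_ranked_blocks(self, fixture_result):
        payload = json.loads(model_io.render_report(fixture_result, "json"))
        assert [rec["rank"] for rec in payload["pathways"]] == [1, 2, 3, 4]
        assert [rec["length"] for rec in payload["pathways"]] == [2, 2, 2, 4]
        for rec in payload["pathways"]:  # net production excludes basis species
            assert "glutamate" not in rec["net_production"]
            assert rec["net_production"]["oxoglutarate"] >= 1

    def test_json_report_round_trips(self, fixture_result, tmp_path):
        path = tmp_path / "report.json"
        sp.write_report(fixture_result, path, fmt="json")
        back = model_io.result_from_dict(json.loads(path.read_text()),
                                         partition=fixture_result.partition)
        assert back.terminated_by == fixture_result.terminated_by
        assert [p.active_set for p in back.pathways] == [
            p.active_set for p in fixture_result.pathways
        ]
        assert [dict(p.magnitudes) for p in back.pathways] == [
            dict(p.magnitudes) for p in fixture_result.pathways
        ]

    def test_reports_are_reproducible_bytes(self, fixture_result):
        for fmt in ("json", "tsv", "text"):
            assert model_io.render_report(fixture_result, fmt) == model_io.render_report(
                fixture_result, fmt
            )

    def test_text_report_mirrors_pathway_presentation(self, fixture_result):
        text = model_io.render_report(fixture_result, "text")
        assert "pathway 1 (2 reactions)" in text
        assert "pathway 4 (4 reactions)" in text
        assert "ANSB" in text
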