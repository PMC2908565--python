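"""Model parsing, I/O round-trips, GPR logic and network statistics."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import methyloflux as mf
from methyloflux.model import (
    EquationParseError,
    GPRParseError,
    Metabolite,
    ModelError,
    Reaction,
    gpr_genes,
)


class TestParseEquation:
    @pytest.mark.parametrize(
        "text, expected, reversible",
        [
            (
                "1 mthl[c] + 1 o2[c] -> 1 fald[c] + 1 h2o2[c]",
                {"mthl[c]": -1, "o2[c]": -1, "fald[c]": 1, "h2o2[c]": 1},
                False,
            ),
            ("a[c] <=> a[m]", {"a[c]": -1, "a[m]": 1}, True),
            (
                "2 h[c] + x[c] -> x[e] + 2 h[e]",
                {"h[c]": -2, "x[c]": -1, "x[e]": 1, "h[e]": 2},
                False,
            ),
            # net-summing of a species on both sides
            ("2 a[c] + b[c] -> a[c] + c[c]", {"a[c]": -1, "b[c]": -1, "c[c]": 1},
             False),
            # empty side: drain pseudo-reaction
            ("glc[e] ->", {"glc[e]": -1}, False),
            # fractional coefficient
            ("1/2 o2[c] -> w[c]", {"o2[c]": -0.5, "w[c]": 1}, False),
        ],
    )
    def test_grammar(self, text, expected, reversible):
        stoich, rev = mf.parse_equation(text)
        assert stoich == pytest.approx(expected)
        assert rev is reversible

    @pytest.mark.parametrize(
        "bad",
        [
            "a[c] -> b[q]",  # unknown compartment tag
            "a[c] b[c] -> c[c]",  # missing '+'
            "a[c] = b[c]",  # no arrow
            "a[c] -> a[c]",  # everything cancels
            "-> ",  # empty both sides
        ],
    )
    def test_malformed(self, bad):
        with pytest.raises(EquationParseError):
            mf.parse_equation(bad)


class TestGPR:
    @pytest.mark.parametrize(
        "gpr, deleted, expected",
        [
            ("(g1 and g2) or g3", {"g1"}, True),
            ("g1 and g2", {"g2"}, False),
            ("", {"anything"}, True),
            ("g1 or g2", {"g1", "g2"}, False),
        ],
    )
    def test_examples(self, gpr, deleted, expected):
        assert mf.evaluate_gpr(gpr, deleted) is expected

    def test_malformed(self):
        with pytest.raises(GPRParseError):
            mf.evaluate_gpr("g1 and (g2 or", set())

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_truth_table(self, data):
        """Random AND/OR trees of depth <= 4 agree with brute-force eval."""
        genes = ["g0", "g1", "g2", "g3"]

        def tree(depth):
            if depth == 0 or data.draw(st.booleans()):
                return data.draw(st.sampled_from(genes))
            op = data.draw(st.sampled_from(["and", "or"]))
            return (op, tree(depth - 1), tree(depth - 1))

        def render(node):
            if isinstance(node, str):
                return node
            op, a, b = node
            return f"({render(a)} {op} {render(b)})"

        def brute(node, present):
            if isinstance(node, str):
                return present[node]
            op, a, b = node
            fa, fb = brute(a, present), brute(b, present)
            return (fa and fb) if op == "and" else (fa or fb)

        t = tree(4)
        text = render(t)
        for bits in itertools.product([True, False], repeat=len(genes)):
            present = dict(zip(genes, bits))
            deleted = {g for g, keep in present.items() if not keep}
            assert mf.evaluate_gpr(text, deleted) == brute(t, present)

    def test_gene_extraction(self):
        assert gpr_genes("(g1 and g2) or (g3 and g1)") == {"g1", "g2", "g3"}


class TestIO:
    def test_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "toy.tsv"
        mf.write_model(toy_model, path)
        back = mf.load_model(path)
        assert set(back.reactions) == set(toy_model.reactions)
        for rid, rxn in toy_model.reactions.items():
            rx2 = back.reactions[rid]
            assert rx2.stoichiometry == pytest.approx(rxn.stoichiometry)
            assert rx2.reversible == rxn.reversible
            assert rx2.lower_bound == rxn.lower_bound
            assert rx2.upper_bound == rxn.upper_bound
            assert gpr_genes(rx2.gpr) == gpr_genes(rxn.gpr)

    def test_duplicate_id_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "id\tname\tequation\tgpr\tsubsystem\tlb\tub\n"
            "R1\t\ta[c] -> b[c]\t\t\t\t\n"
            "R1\t\tb[c] -> a[c]\t\t\t\t\n"
            "EX_biomass\tbiomass drain\tb[c] -> \t\t\t\t\n"
        )
        with pytest.raises(ModelError, match="R1"):
            mf.load_model(path)

    def test_missing_column_error(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("id\tname\nR1\tx\n")
        with pytest.raises(ModelError, match="equation"):
            mf.load_model(path)

    def test_sbml_read(self, tmp_path):
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="mini">
    <listOfParameters>
      <parameter id="lb0" value="0" constant="true"/>
      <parameter id="lbm" value="-1000" constant="true"/>
      <parameter id="ub" value="1000" constant="true"/>
    </listOfParameters>
    <listOfSpecies>
      <species id="M_a_e" compartment="e"/>
      <species id="M_a_c" compartment="c"/>
      <species id="M_b_c" compartment="c"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R_EX_a" reversible="true"
                fbc:lowerFluxBound="lbm" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_a_e" stoichiometry="1"/>
        </listOfReactants>
      </reaction>
      <reaction id="R_T" reversible="false"
                fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_a_e" stoichiometry="1"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_a_c" stoichiometry="1"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:or>
            <fbc:geneProductRef fbc:geneProduct="G_g1"/>
            <fbc:geneProductRef fbc:geneProduct="G_g2"/>
          </fbc:or>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="R_BIOMASS" reversible="false"
                fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_a_c" stoichiometry="2"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_b_c" stoichiometry="1"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
        path = tmp_path / "mini.xml"
        path.write_text(sbml)
        model = mf.load_model(path, format="sbml")
        assert set(model.reactions) == {"EX_a", "T", "BIOMASS"}
        assert model.reactions["T"].stoichiometry == {"a[e]": -1, "a[c]": 1}
        assert model.genes == {"g1", "g2"}
        assert model.objective_id == "BIOMASS"


class TestStats:
    def test_toy_counts(self, toy_model):
        st_ = mf.model_stats(toy_model)
        assert st_.n_internal + st_.n_exchange == st_.n_reactions
        assert st_.n_intra_compartment + st_.n_inter_compartment == st_.n_internal
        assert sum(st_.metabolites_per_compartment.values()) == st_.n_metabolites
        assert sum(st_.reactions_per_subsystem.values()) == st_.n_reactions
        assert st_.n_exchange == len(toy_model.exchanges())
        assert st_.n_unique_metabolites <= st_.n_metabolites
        assert st_.n_genes == len(toy_model.genes)

    def test_constructed_counts(self, chain_model):
        st_ = mf.model_stats(chain_model)
        assert st_.n_reactions == 4
        assert st_.n_exchange == 1
        assert st_.n_metabolites == 3
        assert st_.n_unique_metabolites == 2  # a[e]/a[c] share a base id
        assert st_.n_inter_compartment == 1  # the transport step


class TestDecompartmentalize:
    def test_transport_removed_and_duplicates_collapsed(self):
        mets = [
            Metabolite("pyr[c]"),
            Metabolite("pyr[m]"),
            Metabolite("a[c]"),
            Metabolite("a[x]"),
            Metabolite("b[c]"),
            Metabolite("b[x]"),
        ]
        rxns = [
            Reaction("T", {"pyr[c]": -1.0, "pyr[m]": 1.0}, True),
            Reaction("E_c", {"a[c]": -1.0, "b[c]": 1.0}, False),
            Reaction("E_x", {"a[x]": -1.0, "b[x]": 1.0}, False),
            Reaction("BIOMASS", {"b[c]": -1.0, "pyr[c]": -1.0}, False),
        ]
        model = mf.MetabolicModel(mets, rxns, "BIOMASS")
        flat = mf.decompartmentalize(model)
        assert "T" not in flat.reactions  # pure transport dropped
        # cytosolic/peroxisomal enzyme duplicates collapse to one
        assert len([r for r in flat.reactions if r.startswith("E_")]) == 1
        assert mf.model_stats(flat).n_unique_metabolites == 3

    def test_idempotent(self, toy_model):
        once = mf.decompartmentalize(toy_model)
        twice = mf.decompartmentalize(once)
        assert set(once.reactions) == set(twice.reactions)
        assert {m for m in once.metabolites} == {m for m in twice.metabolites}


class TestInvariants:
    def test_exchange_must_be_extracellular(self):
        with pytest.raises(ModelError, match="exchange"):
            mf.MetabolicModel(
                [Metabolite("a[c]")],
                [Reaction("EX_a", {"a[c]": -1.0}, False),
                 Reaction("B", {"a[c]": -1.0}, False)],
                "B",
            )

    def test_orphan_metabolite_reference(self):
        with pytest.raises(ModelError, match="unknown metabolite"):
            mf.MetabolicModel(
                [Metabolite("a[c]")],
                [Reaction("R", {"a[c]": -1.0, "ghost[c]": 1.0}, False)],
                "R",
            )

    def test_formula_carbon_consistency(self):
        met = Metabolite("glc[c]", formula="C6H12O6")
        assert met.n_carbon == 6
        with pytest.raises(ModelError):
            Metabolite("glc[c]", formula="C6H12O6", n_carbon=5)
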