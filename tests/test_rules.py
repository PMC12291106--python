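"""Rule schema, SMARTS predicates, matrix compilation and agreement."""

import json

import numpy as np
import pytest
from rdkit import Chem

from rulefinder.dataset import Dataset, ModifierRecord
from rulefinder.presets import (
    AMINE_SMARTS,
    BROMOMETHYL_SMARTS,
    NITRO_SMARTS,
    REFERENCE_MODIFIERS,
    final_benzoate_rule,
)
from rulefinder.rules import (
    Clause,
    FeatureMatrix,
    PredicateSpec,
    RuleMatrixFeaturizer,
    RuleSet,
    RuleSpec,
    build_feature_matrix,
    check_matrix,
    compile_rule,
    load_ruleset,
    match_predicate,
    matrix_agreement,
    save_ruleset,
)
from rulefinder.synthetic import default_candidate_rules

from conftest import make_records


AMINO = "Nc1ccc(C(=O)O)cc1"
METHYL = "Cc1ccc(C(=O)O)cc1"


# --- independent brute-force oracle: explicit match enumeration + recursion ---

def oracle_predicate(pred: PredicateSpec, mol) -> bool:
    if pred.kind in ("smarts", "count_ge"):
        q = Chem.MolFromSmarts(pred.smarts)
        n = len(mol.GetSubstructMatches(q, uniquify=True))
        return n >= (pred.threshold if pred.kind == "count_ge" else 1)
    child_values = [oracle_predicate(c, mol) for c in pred.children]
    if pred.kind == "and":
        return all(child_values)
    if pred.kind == "or":
        return any(child_values)
    return not child_values[0]


def oracle_rule(rule: RuleSpec, smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if rule.scope is not None and not oracle_predicate(rule.scope, mol):
        return 0
    for clause in rule.clauses:
        if oracle_predicate(clause.predicate, mol):
            return clause.direction
    return 0


class TestPredicates:
    @pytest.mark.parametrize(
        "pattern,smiles,expected",
        [
            (AMINE_SMARTS, AMINO, True),
            ("[NX3](=O)=O", METHYL, False),
            (AMINE_SMARTS, METHYL, False),
            (BROMOMETHYL_SMARTS, "BrCc1ccc(C(=O)O)cc1", True),
        ],
    )
    def test_smarts_leaf(self, pattern, smiles, expected):
        assert match_predicate(pattern, smiles) is expected

    def test_hypervalent_nitro_smarts_matches_charged_nitro(self):
        # the charge-separated RDKit normal form must satisfy the
        # hypervalent-depiction query
        assert match_predicate(NITRO_SMARTS, "O=[N+]([O-])c1ccc(C(=O)O)cc1")

    def test_boolean_composition(self):
        pred = PredicateSpec.and_(
            PredicateSpec.smarts_("c1ccccc1"),
            PredicateSpec.not_(PredicateSpec.smarts_("[OX2H]")),
        )
        assert match_predicate(pred, "c1ccccc1O") is False
        assert match_predicate(pred, "c1ccccc1C") is True

    def test_count_ge_uses_deduplicated_matches(self):
        two_oh = PredicateSpec.count_ge_("[OX2H]", 2)
        assert match_predicate(two_oh, "OCCO") is True
        assert match_predicate(two_oh, "OCC") is False

    def test_invalid_smarts_rejected_at_schema(self):
        with pytest.raises(ValueError, match="SMARTS"):
            PredicateSpec.smarts_("[[[")

    def test_invalid_smiles_raises(self):
        with pytest.raises(ValueError, match="SMILES"):
            match_predicate("C", "C1CC")

    def test_not_requires_single_child(self):
        with pytest.raises(ValueError):
            PredicateSpec(kind="not", children=[])


class TestCompileRule:
    @pytest.mark.parametrize("name", list(REFERENCE_MODIFIERS))
    def test_final_rule_on_reference_benzoates(self, name):
        smiles, expected = REFERENCE_MODIFIERS[name]
        assert compile_rule(final_benzoate_rule())(smiles) == expected

    def test_out_of_scope_molecule_scores_zero(self):
        assert compile_rule(final_benzoate_rule())("CC(=O)O") == 0

    def test_first_matching_clause_wins(self):
        overlapping = RuleSpec(
            rule_id="r",
            clauses=[
                Clause(predicate=PredicateSpec.smarts_("c1ccccc1"), direction=1),
                Clause(predicate=PredicateSpec.smarts_("c1ccccc1"), direction=-1),
            ],
        )
        assert compile_rule(overlapping)("c1ccccc1") == 1

    def test_permuting_non_overlapping_clauses_is_neutral(self):
        a = Clause(predicate=PredicateSpec.smarts_("[OX2H]"), direction=1)
        b = Clause(predicate=PredicateSpec.smarts_("[NX3;H2]"), direction=-1)
        fwd = compile_rule(RuleSpec(rule_id="r", clauses=[a, b]))
        rev = compile_rule(RuleSpec(rule_id="r", clauses=[b, a]))
        for smi in ("OCC", "NCC", "CCC"):
            assert fwd(smi) == rev(smi)


class TestFeatureMatrix:
    def _dataset(self):
        smiles = [AMINO, METHYL, "CC(=O)O"]
        return make_records([10, 20, 30], smiles=smiles)

    def test_empty_ruleset_gives_n_by_zero(self):
        fm = build_feature_matrix(RuleSet(rules=[]), self._dataset())
        assert fm.shape == (3, 0)

    def test_final_rule_column(self):
        fm = build_feature_matrix(RuleSet(rules=[final_benzoate_rule()]), self._dataset())
        np.testing.assert_array_equal(fm.values[:, 0], [1, -1, 0])

    def test_duplicate_smiles_give_identical_rows(self):
        ds = make_records([1, 2], smiles=[AMINO, AMINO])
        fm = build_feature_matrix(default_candidate_rules(), ds)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_build_is_deterministic(self, library_molecules):
        ds = make_records(range(len(library_molecules)), smiles=library_molecules)
        rs = default_candidate_rules()
        a = build_feature_matrix(rs, ds)
        b = build_feature_matrix(rs, ds)
        np.testing.assert_array_equal(a.values, b.values)

    def test_entries_are_ternary(self, library_molecules):
        ds = make_records(range(len(library_molecules)), smiles=library_molecules)
        fm = build_feature_matrix(default_candidate_rules(), ds)
        assert set(np.unique(fm.values)) <= {-1, 0, 1}

    def test_interpreter_agrees_with_bruteforce_oracle(self, library_molecules):
        """Cell-for-cell oracle equivalence on 36 molecules x 9 rules."""
        ds = make_records(range(len(library_molecules)), smiles=library_molecules)
        rs = default_candidate_rules()
        fm = build_feature_matrix(rs, ds)
        expected = np.array(
            [[oracle_rule(rule, smi) for rule in rs.rules] for smi in library_molecules]
        )
        np.testing.assert_array_equal(fm.values, expected)

    def test_compilation_error_names_rule(self):
        rule = RuleSpec.model_construct(
            rule_id="bad",
            text="",
            clauses=[Clause.model_construct(predicate=PredicateSpec.model_construct(kind="smarts", smarts="[[", children=[], threshold=1), direction=1)],
            scope=None,
        )
        with pytest.raises(Exception, match="bad"):
            build_feature_matrix(RuleSet.model_construct(rules=[rule]), self._dataset())


class TestCheckMatrix:
    def _fm(self, cols):
        vals = np.array(cols).T
        return FeatureMatrix(vals, tuple(f"s{i}" for i in range(vals.shape[0])), tuple(f"r{j}" for j in range(vals.shape[1])))

    def test_zero_column_flagged(self):
        diags = check_matrix(self._fm([[0, 0, 0, 0]]))
        assert len(diags) == 1 and "zero-coverage" in diags[0]

    def test_single_support_flagged(self):
        diags = check_matrix(self._fm([[1, 0, 0, 0]]))
        assert any("coverage<2" in d for d in diags)

    def test_constant_column_flagged(self):
        diags = check_matrix(self._fm([[1, 1, 1, 1]]))
        assert any("constant" in d for d in diags)

    def test_well_covered_matrix_clean(self):
        diags = check_matrix(self._fm([[1, -1, 1, 0], [0, 1, -1, -1]]))
        assert diags == []


class TestMatrixAgreement:
    def _random_pair(self, seed):
        rng = np.random.default_rng(seed)
        shape = (36, 10)
        ids = (tuple(f"s{i}" for i in range(36)), tuple(f"r{j}" for j in range(10)))
        a = FeatureMatrix(rng.integers(-1, 2, size=shape), *ids)
        b = FeatureMatrix(rng.integers(-1, 2, size=shape), *ids)
        return a, b

    def test_identity_is_one(self):
        a, _ = self._random_pair(0)
        assert matrix_agreement(a, a) == 1.0

    def test_single_cell_difference(self):
        ids = (tuple("abcde"), ("r1", "r2"))
        vals = np.zeros((5, 2), dtype=int)
        a = FeatureMatrix(vals, *ids)
        changed = vals.copy()
        changed[0, 0] = 1
        b = FeatureMatrix(changed, *ids)
        assert matrix_agreement(a, b) == pytest.approx(0.9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_cell_count_oracle_and_symmetry(self, seed):
        a, b = self._random_pair(seed)
        count = sum(
            int(a.values[i, j] == b.values[i, j]) for i in range(36) for j in range(10)
        )
        assert matrix_agreement(a, b) == pytest.approx(count / 360)
        assert matrix_agreement(a, b) == matrix_agreement(b, a)

    def test_shape_mismatch_raises(self):
        a, _ = self._random_pair(0)
        small = FeatureMatrix(np.zeros((2, 2), dtype=int), ("x", "y"), ("r1", "r2"))
        with pytest.raises(ValueError):
            matrix_agreement(a, small)


class TestSerialization:
    def test_ruleset_json_round_trip(self, tmp_path):
        rs = default_candidate_rules()
        path = tmp_path / "rules.json"
        save_ruleset(rs, path)
        loaded = load_ruleset(path)
        assert loaded.model_dump() == rs.model_dump()

    def test_matrix_csv_round_trip(self, tmp_path, library_molecules):
        ds = make_records(range(5), smiles=library_molecules[:5])
        fm = build_feature_matrix(default_candidate_rules(), ds)
        path = tmp_path / "m.csv"
        fm.to_csv(path)
        loaded = FeatureMatrix.from_csv(path)
        np.testing.assert_array_equal(loaded.values, fm.values)
        assert loaded.col_ids == fm.col_ids


def test_rule_matrix_featurizer_sklearn_pipeline(library_molecules):
    from sklearn.pipeline import make_pipeline

    feat = RuleMatrixFeaturizer(default_candidate_rules()).fit()
    X = feat.transform(library_molecules[:10])
    assert X.shape == (10, 9)
    assert list(feat.get_feature_names_out())[0] == "R2"
    pipe = make_pipeline(RuleMatrixFeaturizer(default_candidate_rules()))
    np.testing.assert_array_equal(pipe.fit_transform(library_molecules[:10]), X)
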