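"""Declarative substructure rules and their compilation to ternary features.

A *rule* is a human-readable structure-activity statement ("para-substituted
benzoic acids with electron-withdrawing, metal-coordinating groups yield
high; electron-donating or noncoordinating groups yield low") made
executable as an ordered list of *clauses*: each clause pairs a SMARTS-based
substructure predicate with a predicted direction, +1 (high activity) or -1
(low activity). Evaluating a rule on a molecule yields

* ``+1`` - the rule applies and predicts high,
* ``-1`` - the rule applies and predicts low,
* ``0``  - the rule is irrelevant to the molecule (no clause matches, or an
  optional *scope* gate fails).

Clause order defines precedence: the first matching clause wins, mirroring
the if/elif structure of generated rule-to-matrix code. Rules compiled over
a dataset give an n_samples x n_rules integer feature matrix with entries
in {-1, 0, 1}.

SMARTS matching notes
---------------------
RDKit sanitization rewrites hypervalent nitro groups ``N(=O)=O`` to the
charge-separated form ``[N+](=O)[O-]``, so SMARTS written against the
hypervalent depiction (a common convention in other toolkits and in
generated code) would silently never match. The matcher here therefore also
tests a hypervalent-nitro variant of the molecule, making both conventions
equivalent. Substructure matches are deduplicated (``uniquify``) for the
``count_ge`` predicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import Dataset

__all__ = [
    "PredicateSpec",
    "Clause",
    "RuleSpec",
    "RuleSet",
    "FeatureMatrix",
    "RuleCompilationError",
    "compile_predicate",
    "match_predicate",
    "compile_rule",
    "build_feature_matrix",
    "check_matrix",
    "matrix_agreement",
    "RuleMatrixFeaturizer",
    "load_ruleset",
    "save_ruleset",
]


class RuleCompilationError(ValueError):
    """A SMARTS pattern in a rule failed to compile."""


# --------------------------------------------------------------------------
# declarative schema
# --------------------------------------------------------------------------

PredicateKind = Literal["smarts", "and", "or", "not", "count_ge"]


class PredicateSpec(BaseModel):
    """A substructure predicate: a SMARTS leaf or a Boolean combinator.

    ``kind="smarts"`` matches a SMARTS pattern; ``and``/``or``/``not``
    combine child predicates; ``count_ge`` is true iff the (deduplicated)
    number of matches of its single child's SMARTS is >= ``threshold``.
    """

    kind: PredicateKind
    smarts: str | None = None
    children: list["PredicateSpec"] = Field(default_factory=list)
    threshold: int = 1

    @model_validator(mode="after")
    def _check_arity(self) -> "PredicateSpec":
        if self.kind == "smarts":
            if not self.smarts:
                raise ValueError("smarts predicate requires a pattern")
            if Chem.MolFromSmarts(self.smarts) is None:
                raise ValueError(f"invalid SMARTS: {self.smarts!r}")
        elif self.kind == "not":
            if len(self.children) != 1:
                raise ValueError("'not' takes exactly one child")
        elif self.kind in ("and", "or"):
            if len(self.children) < 1:
                raise ValueError(f"{self.kind!r} takes at least one child")
        elif self.kind == "count_ge":
            if self.smarts is None or Chem.MolFromSmarts(self.smarts) is None:
                raise ValueError(f"count_ge requires a valid SMARTS, got {self.smarts!r}")
            if self.threshold < 1:
                raise ValueError("count_ge threshold must be >= 1")
        return self

    @classmethod
    def smarts_(cls, pattern: str) -> "PredicateSpec":
        return cls(kind="smarts", smarts=pattern)

    @classmethod
    def and_(cls, *children: "PredicateSpec") -> "PredicateSpec":
        return cls(kind="and", children=list(children))

    @classmethod
    def or_(cls, *children: "PredicateSpec") -> "PredicateSpec":
        return cls(kind="or", children=list(children))

    @classmethod
    def not_(cls, child: "PredicateSpec") -> "PredicateSpec":
        return cls(kind="not", children=[child])

    @classmethod
    def count_ge_(cls, pattern: str, threshold: int) -> "PredicateSpec":
        return cls(kind="count_ge", smarts=pattern, threshold=threshold)


class Clause(BaseModel):
    """One (predicate, direction) pair of a rule; direction is +1 or -1."""

    predicate: PredicateSpec
    direction: int

    @field_validator("direction")
    @classmethod
    def _dir(cls, v: int) -> int:
        if v not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        return v


class RuleSpec(BaseModel):
    """A named rule: free text plus ordered executable clauses.

    ``scope`` is an optional applicability gate; molecules outside the scope
    always evaluate to 0 regardless of the clauses.
    """

    rule_id: str
    text: str = ""
    clauses: list[Clause] = Field(min_length=1)
    scope: PredicateSpec | None = None


class RuleSet(BaseModel):
    """Ordered collection of rules with unique ids."""

    rules: list[RuleSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_ids(self) -> "RuleSet":
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("rule_ids must be unique")
        return self

    def rule_ids(self) -> list[str]:
        return [r.rule_id for r in self.rules]

    def __len__(self) -> int:
        return len(self.rules)

    def validate_size(self, max_rules: int = 15) -> None:
        if not 1 <= len(self.rules) <= max_rules:
            raise ValueError(f"rule set must contain 1..{max_rules} rules, has {len(self.rules)}")


def load_ruleset(path: str | Path) -> RuleSet:
    """Load a rule set from a JSON file (``{"rules": [...]}``)."""
    with open(path, encoding="utf-8") as fh:
        return RuleSet.model_validate(json.load(fh))


def save_ruleset(rs: RuleSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rs.model_dump(exclude_none=True), fh, indent=2)


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------

_NITRO_CHARGED = Chem.MolFromSmarts("[N+X3](=O)[O-X1]")


def _hypervalent_nitro_copy(mol: Chem.Mol) -> Chem.Mol | None:
    """Copy of *mol* with charge-separated nitro rewritten as N(=O)=O.

    Returns None when the molecule contains no nitro group.
    """
    matches = mol.GetSubstructMatches(_NITRO_CHARGED)
    if not matches:
        return None
    rw = Chem.RWMol(mol)
    for n_idx, _o_dbl, o_sgl in matches:
        n = rw.GetAtomWithIdx(n_idx)
        o = rw.GetAtomWithIdx(o_sgl)
        n.SetFormalCharge(0)
        o.SetFormalCharge(0)
        n.SetNoImplicit(True)
        rw.GetBondBetweenAtoms(n_idx, o_sgl).SetBondType(Chem.BondType.DOUBLE)
    out = rw.GetMol()
    out.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(out)
    return out


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    return mol


def _match_views(mol: Chem.Mol) -> list[Chem.Mol]:
    alt = _hypervalent_nitro_copy(mol)
    return [mol] if alt is None else [mol, alt]


def compile_predicate(pred: PredicateSpec) -> Callable[[Chem.Mol], bool]:
    """Compile a predicate into a pure ``Mol -> bool`` function."""
    if pred.kind == "smarts":
        query = Chem.MolFromSmarts(pred.smarts)
        if query is None:  # pragma: no cover - schema already validates
            raise RuleCompilationError(f"invalid SMARTS: {pred.smarts!r}")
        return lambda mol: any(v.HasSubstructMatch(query) for v in _match_views(mol))
    if pred.kind == "count_ge":
        query = Chem.MolFromSmarts(pred.smarts)
        if query is None:  # pragma: no cover
            raise RuleCompilationError(f"invalid SMARTS: {pred.smarts!r}")
        thr = pred.threshold
        return lambda mol: max(
            len(v.GetSubstructMatches(query, uniquify=True)) for v in _match_views(mol)
        ) >= thr
    children = [compile_predicate(c) for c in pred.children]
    if pred.kind == "and":
        return lambda mol: all(c(mol) for c in children)
    if pred.kind == "or":
        return lambda mol: any(c(mol) for c in children)
    if pred.kind == "not":
        child = children[0]
        return lambda mol: not child(mol)
    raise RuleCompilationError(f"unknown predicate kind: {pred.kind!r}")  # pragma: no cover


def match_predicate(pred: PredicateSpec | str, smiles: str) -> bool:
    """Evaluate a predicate (or bare SMARTS string) on a SMILES string."""
    if isinstance(pred, str):
        pred = PredicateSpec.smarts_(pred)
    return compile_predicate(pred)(mol_from_smiles(smiles))


def compile_rule(spec: RuleSpec) -> Callable[[str], int]:
    """Compile a rule into a pure, deterministic ``SMILES -> {-1, 0, 1}``.

    The first clause (in authored order) whose predicate matches decides the
    output; if no clause matches, or the scope gate fails, the output is 0.
    """
    scope_fn = compile_predicate(spec.scope) if spec.scope is not None else None
    clause_fns = [(compile_predicate(c.predicate), c.direction) for c in spec.clauses]

    def evaluate(smiles: str) -> int:
        mol = mol_from_smiles(smiles)
        if scope_fn is not None and not scope_fn(mol):
            return 0
        for fn, direction in clause_fns:
            if fn(mol):
                return direction
        return 0

    return evaluate


# --------------------------------------------------------------------------
# feature matrix
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureMatrix:
    """n_samples x n_rules integer matrix with entries in {-1, 0, 1}."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=int)
        if vals.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if vals.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {vals.shape} inconsistent with {len(self.row_ids)} row ids "
                f"and {len(self.col_ids)} col ids"
            )
        if vals.size and not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("feature matrix entries must be in {-1, 0, 1}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        object.__setattr__(self, "col_ids", tuple(self.col_ids))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, rule_id: str) -> np.ndarray:
        return self.values[:, self.col_ids.index(rule_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.col_ids))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=int), tuple(map(str, df.index)), tuple(map(str, df.columns)))


def build_feature_matrix(rs: RuleSet, ds: Dataset) -> FeatureMatrix:
    """Evaluate every rule on every molecule: the deterministic "code mode".

    Entry (i, j) is rule j evaluated on molecule i. Compilation errors are
    re-raised with the offending rule id attached.
    """
    evaluators = []
    for rule in rs.rules:
        try:
            evaluators.append(compile_rule(rule))
        except (ValueError, RuleCompilationError) as exc:
            raise RuleCompilationError(f"rule {rule.rule_id!r}: {exc}") from exc
    values = np.zeros((ds.n, len(rs.rules)), dtype=int)
    for i, rec in enumerate(ds.records):
        for j, ev in enumerate(evaluators):
            values[i, j] = ev(rec.smiles)
    return FeatureMatrix(values, tuple(ds.ids), tuple(rs.rule_ids()))


def check_matrix(fm: FeatureMatrix, rs: RuleSet | None = None) -> list[str]:
    """Structural diagnostics on a rule matrix.

    Flags all-zero columns ("zero-coverage"), columns with fewer than two
    nonzero entries ("coverage<2", the reviewer's minimum-support
    criterion), and nonzero constant columns ("constant").
    """
    if rs is not None and tuple(rs.rule_ids()) != fm.col_ids:
        raise ValueError("rule set and matrix column ids disagree")
    diags: list[str] = []
    for j, rid in enumerate(fm.col_ids):
        col = fm.values[:, j]
        nnz = int(np.count_nonzero(col))
        if nnz == 0:
            diags.append(f"zero-coverage: rule {rid!r} never applies")
            continue
        if nnz < 2:
            diags.append(f"coverage<2: rule {rid!r} applies to only {nnz} sample")
        if col.size > 1 and len(set(col.tolist())) == 1:
            diags.append(f"constant: rule {rid!r} assigns {int(col[0]):+d} to every sample")
    return diags


def matrix_agreement(generated: FeatureMatrix, reference: FeatureMatrix) -> float:
    """Fraction of cells where two matrices over the same ids agree."""
    if generated.shape != reference.shape:
        raise ValueError(f"shape mismatch: {generated.shape} vs {reference.shape}")
    if generated.row_ids != reference.row_ids or generated.col_ids != reference.col_ids:
        raise ValueError("row/column ids mismatch")
    if generated.values.size == 0:
        raise ValueError("cannot compute agreement of empty matrices")
    return float(np.mean(generated.values == reference.values))


class RuleMatrixFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn transformer mapping SMILES sequences to a ternary rule matrix.

    Parameters
    ----------
    ruleset : RuleSet
        The rules to compile. ``fit`` compiles them (validating all SMARTS);
        ``transform`` accepts a sequence of SMILES and returns an
        ``(n, n_rules)`` integer array. ``get_feature_names_out`` exposes the
        rule ids.
    """

    def __init__(self, ruleset: RuleSet | None = None):
        self.ruleset = ruleset

    def fit(self, X=None, y=None):
        if self.ruleset is None:
            raise ValueError("ruleset must be provided")
        self.evaluators_ = []
        for rule in self.ruleset.rules:
            try:
                self.evaluators_.append(compile_rule(rule))
            except (ValueError, RuleCompilationError) as exc:
                raise RuleCompilationError(f"rule {rule.rule_id!r}: {exc}") from exc
        self.feature_names_out_ = np.asarray(self.ruleset.rule_ids(), dtype=object)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "evaluators_"):
            raise ValueError("RuleMatrixFeaturizer is not fitted")
        out = np.zeros((len(X), len(self.evaluators_)), dtype=int)
        for i, smi in enumerate(X):
            for j, ev in enumerate(self.evaluators_):
                out[i, j] = ev(smi)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return self.feature_names_out_
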