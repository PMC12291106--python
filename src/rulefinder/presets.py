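"""Canonical rule encodings and reference molecules for the benzoate study.

The refined outcome of the iterative rule search is a single statement:
*para-substituted benzoic acids with electron-withdrawing, metal-coordinating
groups yield high; electron-donating or noncoordinating groups yield low.*
This module encodes that rule declaratively, together with the SMARTS used
to recognize the coordinating groups (primary/secondary amine, nitro,
bromomethyl) and a panel of reference modifiers with known classifications.
"""

from __future__ import annotations

import json

from .rules import Clause, PredicateSpec, RuleSet, RuleSpec

__all__ = [
    "AMINE_SMARTS",
    "NITRO_SMARTS",
    "BROMOMETHYL_SMARTS",
    "PARA_BENZOIC_SCOPE_SMARTS",
    "final_benzoate_rule",
    "REFERENCE_MODIFIERS",
    "benzoate_rule_versions",
    "refinement_replay_messages",
]

#: Primary or secondary amine.
AMINE_SMARTS = "[NX3;H2,H1]"
#: Nitro group, hypervalent depiction (the matcher also accepts the
#: charge-separated RDKit normal form).
NITRO_SMARTS = "[NX3](=O)=O"
#: Bromomethyl group (aliphatic carbon bearing Br).
BROMOMETHYL_SMARTS = "CBr"

#: Benzoic acid carrying a heavy-atom substituent para (1,4 on a six-membered
#: aromatic carbocycle) to the carboxyl group.
PARA_BENZOIC_SCOPE_SMARTS = "[!#1]c1ccc(cc1)[CX3](=O)[OX2H1,OX1-]"

_PARA = "c1ccc(cc1)[CX3](=O)[OX2H1,OX1-]"


def final_benzoate_rule(rule_id: str = "R2") -> RuleSpec:
    """The refined para-benzoate rule as an executable RuleSpec.

    Scope: para-substituted benzoic acids (other molecules score 0).
    Clause 1 (+1): the para substituent is a coordinating / electron-
    withdrawing group - primary or secondary amine, nitro, or bromomethyl.
    Clause 2 (-1): any other para substituent (electron-donating or
    noncoordinating). First-match precedence makes clause 2 the fallback.
    """
    coordinating = PredicateSpec.or_(
        PredicateSpec.smarts_(f"[NX3;H2,H1]{_PARA}"),
        PredicateSpec.smarts_(f"[$([NX3](=O)=O),$([NX3+](=O)[O-])]{_PARA}"),
        PredicateSpec.smarts_(f"[CX4;!$(C(=O))]([Br]){_PARA}"),
    )
    return RuleSpec(
        rule_id=rule_id,
        text=(
            "para-substituted benzoic acids with electron-withdrawing, "
            "metal-coordinating groups yield high; electron-donating or "
            "noncoordinating groups yield low"
        ),
        scope=PredicateSpec.smarts_(PARA_BENZOIC_SCOPE_SMARTS),
        clauses=[
            Clause(predicate=coordinating, direction=1),
            Clause(predicate=PredicateSpec.smarts_(PARA_BENZOIC_SCOPE_SMARTS), direction=-1),
        ],
    )


def _ewg_only_clauses() -> list[Clause]:
    ewg = PredicateSpec.or_(
        PredicateSpec.smarts_(f"[$([NX3](=O)=O),$([NX3+](=O)[O-])]{_PARA}"),
        PredicateSpec.smarts_(f"[CX4;!$(C(=O))]([Br]){_PARA}"),
    )
    return [
        Clause(predicate=ewg, direction=1),
        Clause(predicate=PredicateSpec.smarts_(PARA_BENZOIC_SCOPE_SMARTS), direction=-1),
    ]


def benzoate_rule_versions() -> list[RuleSpec]:
    """Successive wordings of the benzoate rule along its refinement path.

    Version 1 credits para electron-withdrawing groups only; version 2 adds
    the electron-donating/bulky low-yield wording; version 3 pivots to
    metal coordination (bringing the amine into the high-yield clause);
    version 4 is the final combined statement.
    """
    scope = PredicateSpec.smarts_(PARA_BENZOIC_SCOPE_SMARTS)
    final = final_benzoate_rule()
    return [
        RuleSpec(
            rule_id="R2",
            text="para-substituted benzoic acids with electron-withdrawing groups yield high",
            scope=scope,
            clauses=_ewg_only_clauses(),
        ),
        RuleSpec(
            rule_id="R2",
            text=(
                "para-substituted benzoic acids with electron-withdrawing groups yield "
                "high; electron-donating or bulky groups yield low"
            ),
            scope=scope,
            clauses=_ewg_only_clauses(),
        ),
        RuleSpec(
            rule_id="R2",
            text=(
                "para-substituted benzoic acids with metal-coordinating groups yield "
                "high; noncoordinating groups yield low"
            ),
            scope=scope,
            clauses=final.clauses,
        ),
        final,
    ]


def refinement_replay_messages() -> list[dict]:
    """Scripted backend transcript replaying the benzoate rule refinement.

    Five rounds: the generator walks through the four rule versions and
    then re-emits the final version unchanged, at which point the manager
    accepts. Suitable for :class:`rulefinder.loop.ScriptedBackend`; the
    replay is fully deterministic and offline.
    """

    def block(payload: dict, prose: str) -> str:
        return f"{prose}\n```json\n{json.dumps(payload)}\n```"

    versions = benzoate_rule_versions()
    rounds = versions + [versions[-1]]
    comments = [
        "Rule 2 is clear and in line with the data.",
        "Inconsistency: the amino group is electron-donating yet appears among high-yield examples.",
        "Updated Rule 2 approved; coordination focus resolves the amino contradiction.",
        "Final Rule 2 approved.",
        "No further concerns.",
    ]
    advice = [
        "Seek broader coverage or merge with similar rules.",
        "Shift focus from EWG/EDG to metal coordination; combine steric and electronic effects.",
        "Merge with the conjugation rule for metal-coordination.",
        "Revised over three times with limited improvement; pass to the next stage.",
        "Limited further gains; accept the current rule.",
    ]
    ml_comments = [
        "Rule trends consistent; watch coverage.",
        "Underestimation for coordinating substituents persists.",
        "Improved consistency after the coordination pivot.",
        "Clarify electron-withdrawing groups and non-para substitution effects.",
        "No inconsistencies remaining.",
    ]
    messages: list[dict] = []
    for i, (rule, note) in enumerate(zip(rounds, ["initial proposal", "added EDG/bulky wording",
                                                  "pivot to metal coordination", "combined final rule",
                                                  "rule unchanged"])):
        ruleset = RuleSet(rules=[rule]).model_dump(exclude_none=True)
        messages.append({"role": "rule_generator", "content": block(ruleset, f"Round {i}: {note}.")})
        messages.append({"role": "rule_commenter", "content": block({"comments": [comments[i]]}, "Review:")})
        messages.append({"role": "rule_advisor", "content": block({"advice": advice[i]}, "Guidance:")})
        messages.append({"role": "ml_commenter", "content": block({"comments": [ml_comments[i]]}, "Analysis:")})
        decision = {"decision": "stop", "reason": "manager acceptance"} if i == len(rounds) - 1 else {
            "decision": "continue", "reason": "further refinement requested"}
        messages.append({"role": "project_manager", "content": block(decision, "Decision:")})
    return messages


#: Reference para-substituted benzoic acids with their expected rule output.
REFERENCE_MODIFIERS: dict[str, tuple[str, int]] = {
    "4-aminobenzoic acid": ("Nc1ccc(C(=O)O)cc1", +1),
    "4-nitrobenzoic acid": ("O=[N+]([O-])c1ccc(C(=O)O)cc1", +1),
    "4-(bromomethyl)benzoic acid": ("BrCc1ccc(C(=O)O)cc1", +1),
    "4-methylbenzoic acid": ("Cc1ccc(C(=O)O)cc1", -1),
    "4-formylbenzoic acid": ("O=Cc1ccc(C(=O)O)cc1", -1),
    "4-sulfanylbenzoic acid": ("Sc1ccc(C(=O)O)cc1", -1),
}
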