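"""Iterative multi-role rule-refinement loop with pluggable chat backends.

The refinement protocol assigns ten roles to the search for a good rule
set. Five are conversational (they produce free text with one embedded JSON
payload): the *rule generator* proposes or revises rules, the *rule
commenter* reviews them against clarity/coverage/balance criteria, the
*rule advisor* digests the comments into revision guidance, the *ML
commenter* interprets validation results, and the *project manager* decides
whether to continue. The other five are computational and run locally in
"code mode": matrix generation (declarative rules compiled by
:mod:`rulefinder.rules`), matrix checking, association metrics, and the
tree-ensemble cross-validation of :mod:`rulefinder.evaluation`.

A backend is anything with ``respond(role, prompt) -> str``. The
:class:`ScriptedBackend` replays a recorded transcript (JSONL, one message
per line) verbatim, which makes the whole loop deterministic and offline;
an HTTP chat-completion backend is provided for live runs but is never
exercised by the test suite.

The generator and commenter see only the current round; the advisor and
manager see the full history. One retry is allowed per protocol violation
(unparseable or empty payload), with the error echoed back; a second
failure marks the round as failed without advancing the state.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Protocol, Sequence

from pydantic import BaseModel

from .dataset import Dataset, binarize_by_median, labels_to_int
from .evaluation import EvalReport, ModelSpec, kfold_cv
from .metrics import RuleMetricsRow, metrics_report
from .rules import FeatureMatrix, RuleSet, build_feature_matrix, check_matrix

__all__ = [
    "CHAT_ROLES",
    "ROLE_MEMORY_SCOPE",
    "AgentMessage",
    "LoopConfig",
    "LoopState",
    "ProtocolViolation",
    "ChatBackend",
    "ScriptedBackend",
    "HttpChatBackend",
    "extract_json_payload",
    "guideline_check",
    "stopping_rule",
    "run_round",
    "run_loop",
    "save_transcript",
    "load_transcript",
]

#: Conversational roles, in the order they speak within one round.
CHAT_ROLES = ("rule_generator", "rule_commenter", "rule_advisor", "ml_commenter", "project_manager")

#: What each role is allowed to remember.
ROLE_MEMORY_SCOPE = {
    "rule_generator": "current_round",
    "rule_commenter": "current_round",
    "rule_advisor": "full_history",
    "matrix_generator": "current_round",
    "matrix_checker": "current_round",
    "metric_calculator": "current_round",
    "metric_commenter": "current_round",
    "ml_calculator": "current_round",
    "ml_commenter": "current_round",
    "project_manager": "full_history",
}


class ProtocolViolation(RuntimeError):
    """A backend response could not be parsed into its expected payload."""


class AgentMessage(BaseModel):
    """One request or response in the loop transcript."""

    role: str
    iteration: int
    direction: Literal["request", "response"]
    content: str
    payload: dict | None = None


class ChatBackend(Protocol):
    def respond(self, role: str, prompt: str) -> str: ...


class ScriptedBackend:
    """Replays recorded responses in order, keyed by role.

    ``messages`` is a sequence of ``{"role": ..., "content": ...}`` dicts
    (or a JSONL file of the same). Each ``respond`` call consumes the next
    message, which must belong to the requested role; a mismatch or an
    exhausted script raises with the expected role named.
    """

    def __init__(self, messages: Sequence[dict] | str | Path):
        if isinstance(messages, (str, Path)):
            messages = load_transcript(messages)
        self._messages = [dict(m) for m in messages]
        self._pos = 0

    def respond(self, role: str, prompt: str) -> str:
        if self._pos >= len(self._messages):
            raise ProtocolViolation(f"script exhausted; no response left for role {role!r}")
        msg = self._messages[self._pos]
        if msg.get("role") != role:
            raise ProtocolViolation(
                f"script out of order: expected a {msg.get('role')!r} response next, "
                f"but role {role!r} was asked"
            )
        self._pos += 1
        return str(msg.get("content", ""))

    @property
    def exhausted(self) -> bool:
        return self._pos >= len(self._messages)


class HttpChatBackend:
    """Minimal chat-completion client (stdlib urllib); not used in tests.

    Sends role-tagged messages to an OpenAI-style ``/chat/completions``
    endpoint. Temperature and model name are configuration values.
    """

    def __init__(self, url: str, model: str, api_key: str = "", temperature: float = 0.2, timeout: float = 120.0):
        self.url = url
        self.model = model
        self.api_key = api_key
        self.temperature = temperature
        self.timeout = timeout

    def respond(self, role: str, prompt: str) -> str:  # pragma: no cover - network
        import urllib.request

        body = json.dumps(
            {
                "model": self.model,
                "temperature": self.temperature,
                "messages": [
                    {"role": "system", "content": f"You are the {role.replace('_', ' ')}."},
                    {"role": "user", "content": prompt},
                ],
            }
        ).encode()
        req = urllib.request.Request(
            self.url,
            data=body,
            headers={"Content-Type": "application/json", "Authorization": f"Bearer {self.api_key}"},
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            data = json.loads(resp.read())
        return data["choices"][0]["message"]["content"]


_FENCE_RE = re.compile(r"```(?:json)?\s*(\{.*?\})\s*```", re.DOTALL)


def extract_json_payload(content: str) -> dict:
    """Extract exactly one JSON object embedded in a prose response.

    Accepts a fenced ```json block (preferred), a bare JSON body, or a
    single balanced top-level ``{...}`` region. Multiple fenced blocks or no
    parseable object raise :class:`ProtocolViolation`.
    """
    fenced = _FENCE_RE.findall(content)
    if len(fenced) > 1:
        raise ProtocolViolation("response contains more than one JSON block")
    if len(fenced) == 1:
        try:
            return json.loads(fenced[0])
        except json.JSONDecodeError as exc:
            raise ProtocolViolation(f"fenced JSON block does not parse: {exc}") from exc
    try:
        obj = json.loads(content)
        if isinstance(obj, dict):
            return obj
        raise ProtocolViolation("top-level JSON payload must be an object")
    except json.JSONDecodeError:
        pass
    start = content.find("{")
    while start != -1:
        depth = 0
        for i in range(start, len(content)):
            if content[i] == "{":
                depth += 1
            elif content[i] == "}":
                depth -= 1
                if depth == 0:
                    try:
                        obj = json.loads(content[start : i + 1])
                        if isinstance(obj, dict):
                            return obj
                    except json.JSONDecodeError:
                        break
                    break
        start = content.find("{", start + 1)
    raise ProtocolViolation("no JSON object found in response")


@dataclass
class LoopConfig:
    """Knobs of the refinement loop."""

    epsilon: float = 0.01  # minimum accuracy gain that counts as improvement
    revision_threshold: int = 3  # stop once a rule is revised more than this
    max_iterations: int = 10
    max_rules: int = 15
    min_rules: int = 5
    kfold_k: int = 5
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    seed: int = 0


@dataclass
class LoopState:
    """Full history of a refinement run."""

    iteration: int = 0
    ruleset_versions: list[RuleSet] = field(default_factory=list)
    transcripts: list[AgentMessage] = field(default_factory=list)
    matrices: list[FeatureMatrix] = field(default_factory=list)
    metric_reports: list[list[RuleMetricsRow]] = field(default_factory=list)
    ml_reports: list[EvalReport] = field(default_factory=list)
    accuracy_history: list[float] = field(default_factory=list)
    revision_counts: dict[str, int] = field(default_factory=dict)
    manager_decisions: list[dict] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)
    stopped: bool = False
    stop_reason: str = ""

    @property
    def current_ruleset(self) -> RuleSet | None:
        return self.ruleset_versions[-1] if self.ruleset_versions else None


def guideline_check(rs: RuleSet, fm: FeatureMatrix, min_rules: int = 5, max_rules: int = 15,
                    require_balance: bool = False) -> list[str]:
    """Reviewer-style diagnostics on a rule set and its matrix.

    Flags rule counts outside [min_rules, max_rules], rules supported by
    fewer than two samples, and (when direction balance was requested)
    rules whose nonzero entries are all one sign.
    """
    diags: list[str] = []
    if not min_rules <= len(rs) <= max_rules:
        bound = "below" if len(rs) < min_rules else "above"
        diags.append(f"rule count {len(rs)} is {bound} the {min_rules}..{max_rules} guideline")
    for rid in fm.col_ids:
        col = fm.column(rid)
        nnz = int((col != 0).sum())
        if nnz < 2:
            diags.append(f"coverage: rule {rid!r} is supported by {nnz} sample(s), need >= 2")
        elif require_balance and not ((col == 1).any() and (col == -1).any()):
            diags.append(f"balance: rule {rid!r} predicts a single direction")
    return diags


def stopping_rule(state: LoopState, config: LoopConfig = LoopConfig()) -> tuple[str, str]:
    """Decide ``("continue", "")`` or ``("stop", reason)``.

    Stops when the manager signalled acceptance, when some rule has been
    revised more than ``revision_threshold`` times with less than
    ``epsilon`` accuracy improvement in the last round, or at the
    iteration cap.
    """
    if state.manager_decisions and state.manager_decisions[-1].get("decision") == "stop":
        return "stop", state.manager_decisions[-1].get("reason", "manager acceptance")
    if state.revision_counts and max(state.revision_counts.values()) > config.revision_threshold:
        if len(state.accuracy_history) >= 2:
            delta = state.accuracy_history[-1] - state.accuracy_history[-2]
        else:
            delta = 0.0
        if delta < config.epsilon:
            return "stop", "revision threshold"
    if state.iteration >= config.max_iterations:
        return "stop", "max iterations"
    return "continue", ""


def _ask(
    backend: ChatBackend,
    state: LoopState,
    role: str,
    prompt: str,
    iteration: int,
    expect_payload: bool,
) -> dict | None:
    """One request/response exchange with one retry on protocol violation."""
    state.transcripts.append(AgentMessage(role=role, iteration=iteration, direction="request", content=prompt))
    for attempt in range(2):
        content = backend.respond(role, prompt)
        payload = None
        err = None
        if expect_payload:
            try:
                payload = extract_json_payload(content)
            except ProtocolViolation as exc:
                err = str(exc)
        state.transcripts.append(
            AgentMessage(role=role, iteration=iteration, direction="response", content=content, payload=payload)
        )
        if err is None:
            return payload
        state.violations.append(f"iteration {iteration}, {role}: {err}")
        if attempt == 0:
            prompt = f"Your previous response was invalid ({err}). Reply again with exactly one JSON object."
            state.transcripts.append(
                AgentMessage(role=role, iteration=iteration, direction="request", content=prompt)
            )
    raise ProtocolViolation(f"{role} failed to produce a valid payload after retry")


def _count_revisions(previous: RuleSet | None, current: RuleSet, counts: dict[str, int]) -> None:
    prev = {r.rule_id: r for r in previous.rules} if previous is not None else {}
    for rule in current.rules:
        old = prev.get(rule.rule_id)
        if old is None:
            counts.setdefault(rule.rule_id, 0)
        elif old.model_dump() != rule.model_dump():
            counts[rule.rule_id] = counts.get(rule.rule_id, 0) + 1


def run_round(state: LoopState, backend: ChatBackend, ds: Dataset, config: LoopConfig = LoopConfig()) -> LoopState:
    """Execute one refinement cycle in place and return the state.

    generate/revise -> comment -> advise -> compile matrix -> check ->
    metrics -> CV evaluation -> ML comment -> manager decision. A round
    whose generator payload cannot be parsed (after one retry) or is empty
    leaves the ruleset history unchanged and records the failure.
    """
    if state.stopped:
        raise ValueError("loop already stopped")
    if any(lab is None for lab in ds.labels):
        ds = binarize_by_median(ds)
    it = state.iteration

    snapshot = {
        "ruleset_versions": len(state.ruleset_versions),
        "matrices": len(state.matrices),
        "metric_reports": len(state.metric_reports),
        "ml_reports": len(state.ml_reports),
        "accuracy_history": len(state.accuracy_history),
        "manager_decisions": len(state.manager_decisions),
        "revision_counts": dict(state.revision_counts),
    }
    try:
        return _run_round_inner(state, backend, ds, config, it)
    except ProtocolViolation as exc:
        # roll back artifacts of the failed round; transcripts keep the record
        state.violations.append(f"iteration {it}: round failed: {exc}")
        state.ruleset_versions = state.ruleset_versions[: snapshot["ruleset_versions"]]
        state.matrices = state.matrices[: snapshot["matrices"]]
        state.metric_reports = state.metric_reports[: snapshot["metric_reports"]]
        state.ml_reports = state.ml_reports[: snapshot["ml_reports"]]
        state.accuracy_history = state.accuracy_history[: snapshot["accuracy_history"]]
        state.manager_decisions = state.manager_decisions[: snapshot["manager_decisions"]]
        state.revision_counts = snapshot["revision_counts"]
        return state


def _run_round_inner(
    state: LoopState, backend: ChatBackend, ds: Dataset, config: LoopConfig, it: int
) -> LoopState:
    payload = _ask(backend, state, "rule_generator", "Propose or revise the rule set.", it, True)
    try:
        ruleset = RuleSet.model_validate(payload)
    except ValueError as exc:
        raise ProtocolViolation(f"rule generator payload is not a valid rule set: {exc}") from exc
    if len(ruleset) == 0:
        raise ProtocolViolation("rule generator returned an empty rule set")

    _count_revisions(state.current_ruleset, ruleset, state.revision_counts)
    state.ruleset_versions.append(ruleset)

    _ask(backend, state, "rule_commenter", "Review the proposed rules.", it, True)
    _ask(backend, state, "rule_advisor", "Advise on the next revision.", it, True)

    fm = build_feature_matrix(ruleset, ds)
    state.matrices.append(fm)
    diags = check_matrix(fm) + guideline_check(fm=fm, rs=ruleset, min_rules=config.min_rules, max_rules=config.max_rules)
    state.transcripts.append(
        AgentMessage(
            role="matrix_checker",
            iteration=it,
            direction="response",
            content="matrix diagnostics",
            payload={"diagnostics": diags},
        )
    )

    y = labels_to_int(ds.labels)
    rows = metrics_report(fm, y)
    state.metric_reports.append(rows)
    state.transcripts.append(
        AgentMessage(
            role="metric_calculator",
            iteration=it,
            direction="response",
            content="association metrics",
            payload={
                "rules": [
                    {
                        "rule_id": r.rule_id,
                        "support": r.support,
                        "confidence": r.confidence,
                        "lift": r.lift,
                        "leverage": r.leverage,
                    }
                    for r in rows
                ]
            },
        )
    )

    k = min(config.kfold_k, int(min((y == 0).sum(), (y == 1).sum())))
    report = kfold_cv(fm.values, y, config.model_spec, seed=config.seed, k=max(2, k))
    state.ml_reports.append(report)
    state.accuracy_history.append(report.accuracy_mean)
    state.transcripts.append(
        AgentMessage(
            role="ml_calculator",
            iteration=it,
            direction="response",
            content="cross-validation report",
            payload={"accuracy_mean": report.accuracy_mean, "accuracy_sd": report.accuracy_sd},
        )
    )

    _ask(backend, state, "ml_commenter", "Interpret the validation results.", it, True)
    decision = _ask(backend, state, "project_manager", "Continue refining or stop?", it, True)
    state.manager_decisions.append(decision or {})

    state.iteration = it + 1
    verdict, reason = stopping_rule(state, config)
    if verdict == "stop":
        state.stopped = True
        state.stop_reason = reason
    return state


def run_loop(ds: Dataset, backend: ChatBackend, config: LoopConfig = LoopConfig()) -> LoopState:
    """Run rounds until the stopping rule fires; returns the final state."""
    state = LoopState()
    while not state.stopped:
        before = state.iteration
        run_round(state, backend, ds, config)
        if state.iteration == before:  # failed round: avoid spinning forever
            state.stopped = True
            state.stop_reason = "protocol failure"
    return state


def save_transcript(messages: Sequence[AgentMessage], path: str | Path) -> None:
    """Write a transcript as JSONL, one message per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in messages:
            fh.write(m.model_dump_json() + "\n")


def load_transcript(path: str | Path) -> list[dict]:
    """Read a JSONL transcript into plain dicts."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
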