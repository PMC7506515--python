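"""Rule-based keyword matching over clinical-note text.

The matcher implements a deliberately constrained search semantics that
works well for infection surveillance in copy-paste-heavy clinical prose:

* a rule is an ordered sequence of word groups, each group a set of
  accepted spelling variants ("staph" / "staphylococcus");
* word order is preserved, and at most ``max_gap_tokens`` tokens may
  intervene between consecutive matched words (default 1, i.e. words are
  adjacent or separated by a single token);
* matching is case-insensitive on whitespace/punctuation tokens; there is
  no stemming, edit distance, or negation handling;
* a rule only fires on notes whose title passes its title filter and whose
  date falls inside its day window relative to the index procedure.

Finding an ordered subsequence under a bounded-gap constraint is done with
a backward reachability sweep over token positions (a greedy left-to-right
scan is not sound: committing to the earliest candidate for one word group
can strand a later group outside its gap window).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from importlib import resources
from typing import Literal, Mapping, Sequence

import re
import yaml

from ciedwatch.emr import ClinicalNote, MicrobiologyRecord, day_offset

Polarity = Literal["post_infection", "pre_history", "organism"]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; punctuation acts as a token boundary."""
    return _TOKEN_RE.findall(text.lower())


class RuleConfigError(ValueError):
    """A rule definition failed validation; the message names the rule."""


@dataclass(frozen=True)
class KeywordRule:
    """A declarative text-matching rule.

    ``words`` is an ordered tuple of variant groups; each group is a
    frozenset of lowercase spellings, any one of which matches.
    ``note_titles`` is either the string ``"any"`` or a tuple of
    case-insensitive substring patterns, at least one of which must occur
    in the note title.  ``window_days`` is an inclusive day interval
    relative to the index procedure (day 0).
    """

    rule_id: str
    words: tuple[frozenset[str], ...]
    max_gap_tokens: int = 1
    note_titles: tuple[str, ...] | str = "any"
    window_days: tuple[int, int] = (3, 90)
    polarity: Polarity = "post_infection"

    def __post_init__(self):
        if not self.words:
            raise RuleConfigError(f"rule {self.rule_id!r}: empty word sequence")
        for g in self.words:
            if not g:
                raise RuleConfigError(f"rule {self.rule_id!r}: empty word group")
        if self.max_gap_tokens < 0:
            raise RuleConfigError(f"rule {self.rule_id!r}: negative max_gap_tokens")
        lo, hi = self.window_days
        if lo > hi:
            raise RuleConfigError(
                f"rule {self.rule_id!r}: window_days lower bound exceeds upper")


@dataclass(frozen=True)
class MatchResult:
    rule_id: str
    note_id: str
    matched_span: tuple[int, int]  # inclusive token-index interval
    matched_text: str


def find_spans(tokens: Sequence[str], words: Sequence[frozenset[str]],
               max_gap: int) -> list[tuple[int, int]]:
    """All start positions from which the word groups can be matched in
    order with at most ``max_gap`` intervening tokens between consecutive
    matched words; one (start, end) span per viable start.

    Backward sweep: ``ok[j][i]`` is true when token ``i`` belongs to group
    ``j`` and the remaining groups can be completed from some position in
    ``(i, i + 1 + max_gap]``.
    """
    n, k = len(tokens), len(words)
    if n == 0 or k == 0:
        return []
    ok = [[False] * n for _ in range(k)]
    for j in range(k - 1, -1, -1):
        group = words[j]
        for i in range(n - 1, -1, -1):
            if tokens[i] not in group:
                continue
            if j == k - 1:
                ok[j][i] = True
            else:
                hi = min(n, i + 2 + max_gap)
                ok[j][i] = any(ok[j + 1][i2] for i2 in range(i + 1, hi))
    spans: list[tuple[int, int]] = []
    for start in range(n):
        if not ok[0][start]:
            continue
        # reconstruct one witness chain (earliest viable next position)
        pos = start
        for j in range(1, k):
            hi = min(n, pos + 2 + max_gap)
            pos = next(i2 for i2 in range(pos + 1, hi) if ok[j][i2])
        spans.append((start, pos))
    return spans


def match_rule(note: ClinicalNote, rule: KeywordRule,
               procedure_date: date) -> list[MatchResult]:
    """Apply one rule to one note relative to an index procedure date.

    Out-of-window or title-filtered notes yield an empty list, never an
    error: absence of a match is the ordinary outcome.
    """
    lo, hi = rule.window_days
    if not (lo <= day_offset(note.note_date, procedure_date) <= hi):
        return []
    if rule.note_titles != "any":
        title = note.note_title.lower()
        if not any(pat.lower() in title for pat in rule.note_titles):
            return []
    tokens = tokenize(note.text)
    spans = find_spans(tokens, rule.words, rule.max_gap_tokens)
    return [
        MatchResult(rule_id=rule.rule_id, note_id=note.note_id,
                    matched_span=span,
                    matched_text=" ".join(tokens[span[0]:span[1] + 1]))
        for span in spans
    ]


@dataclass(frozen=True)
class OrganismRule:
    """Variant-aware word-sequence rule applied to microbiology result text."""

    name: str
    words: tuple[frozenset[str], ...]
    max_gap_tokens: int = 1


@dataclass(frozen=True)
class Ruleset:
    """Compiled, validated set of note rules plus organism rules.

    Evaluation over a note stream is a pure function of the notes and the
    procedure date; the ruleset itself carries no mutable state.
    """

    rules: tuple[KeywordRule, ...]
    organisms: Mapping[str, OrganismRule]

    def by_polarity(self, polarity: Polarity) -> tuple[KeywordRule, ...]:
        return tuple(r for r in self.rules if r.polarity == polarity)

    def match_notes(self, notes: Sequence[ClinicalNote], procedure_date: date,
                    polarity: Polarity) -> list[MatchResult]:
        out: list[MatchResult] = []
        for rule in self.by_polarity(polarity):
            for note in notes:
                out.extend(match_rule(note, rule, procedure_date))
        return out


_RULE_FIELDS = {"id", "words", "max_gap_tokens", "note_titles",
                "window_days", "polarity"}


def _parse_words(raw, rule_id: str) -> tuple[frozenset[str], ...]:
    if not isinstance(raw, list) or not raw:
        raise RuleConfigError(f"rule {rule_id!r}: 'words' must be a non-empty list")
    groups = []
    for g in raw:
        if isinstance(g, str):
            g = [g]
        if not isinstance(g, list) or not g:
            raise RuleConfigError(f"rule {rule_id!r}: empty word group")
        groups.append(frozenset(str(w).lower() for w in g))
    return tuple(groups)


def compile_ruleset(config: Mapping) -> Ruleset:
    """Compile a rule-definition mapping (parsed YAML/JSON) into a Ruleset.

    Raises :class:`RuleConfigError` naming the offending rule on unknown
    fields, empty word groups, or duplicate ids.
    """
    rules: list[KeywordRule] = []
    seen: set[str] = set()
    for raw in config.get("rules", []):
        rule_id = str(raw.get("id", "<missing id>"))
        unknown = set(raw) - _RULE_FIELDS
        if unknown:
            raise RuleConfigError(
                f"rule {rule_id!r}: unknown field(s) {sorted(unknown)}")
        if "id" not in raw:
            raise RuleConfigError("rule definition missing 'id'")
        if rule_id in seen:
            raise RuleConfigError(f"duplicate rule id {rule_id!r}")
        seen.add(rule_id)
        titles = raw.get("note_titles", "any")
        if titles != "any":
            titles = tuple(str(t) for t in titles)
        window = tuple(raw.get("window_days", (3, 90)))
        if len(window) != 2:
            raise RuleConfigError(
                f"rule {rule_id!r}: window_days must be [lo, hi]")
        polarity = raw.get("polarity", "post_infection")
        if polarity not in ("post_infection", "pre_history", "organism"):
            raise RuleConfigError(
                f"rule {rule_id!r}: unknown polarity {polarity!r}")
        rules.append(KeywordRule(
            rule_id=rule_id,
            words=_parse_words(raw["words"], rule_id),
            max_gap_tokens=int(raw.get("max_gap_tokens", 1)),
            note_titles=titles,
            window_days=(int(window[0]), int(window[1])),
            polarity=polarity,
        ))

    organisms: dict[str, OrganismRule] = {}
    for name, raw in config.get("organisms", {}).items():
        organisms[name] = OrganismRule(
            name=name,
            words=_parse_words(raw["words"], name),
            max_gap_tokens=int(raw.get("max_gap_tokens", 1)),
        )
    return Ruleset(rules=tuple(rules), organisms=organisms)


def load_ruleset(path) -> Ruleset:
    with open(path, encoding="utf-8") as fh:
        return compile_ruleset(yaml.safe_load(fh))


def default_ruleset() -> Ruleset:
    """The packaged default ruleset (editable stand-in; replace per site)."""
    text = resources.files("ciedwatch.data").joinpath("rules.yaml").read_text()
    return compile_ruleset(yaml.safe_load(text))


def scan_result_text(micro: MicrobiologyRecord,
                     organism_rules: Mapping[str, OrganismRule]) -> dict[str, bool]:
    """Organism flags from variant-aware matching of a result's free text.

    Returns one boolean per organism rule (e.g. ``s_aureus``,
    ``coag_neg_staph``); empty result text yields all-false.
    """
    tokens = tokenize(micro.result_text)
    return {
        name: bool(find_spans(tokens, rule.words, rule.max_gap_tokens))
        for name, rule in organism_rules.items()
    }
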