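"""Functional classification of candidate proteins into four categories.

Surviving candidates are binned into exactly one of four classes —
metabolic/acidification regulators, immune modulators, oncogenic drivers, or
the metastasis-associated/unknown fallback — by matching a user-supplied
annotation table (protein → functional terms drawn from GO, KEGG and
curated functional descriptions) against per-category trigger-term rules.

Matching is deliberately term-set based rather than free-text mining:
a trigger term matches when it occurs as a case-insensitive substring of any
annotation term.  When several categories match, the rule with the lowest
precedence number wins; proteins with no annotation or no match fall into
the metastasis/unknown class.  The shipped default rule file
(``data/category_rules.yaml``) is an explicit, editable stand-in for
curation criteria that are otherwise subjective.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import yaml

from .identifiers import ProteinID
from .setalgebra import ProteinSet


class Category(str, Enum):
    METABOLIC_ACIDIFICATION = "metabolic_acidification"
    IMMUNE_MODULATION = "immune_modulation"
    ONCOGENIC_DRIVER = "oncogenic_driver"
    METASTASIS_UNKNOWN = "metastasis_unknown"


class DuplicatePrecedenceError(ValueError):
    """Two category rules share a precedence value."""


class IncompleteRulesError(ValueError):
    """The rule set does not cover all four categories."""


@dataclass(frozen=True)
class CategoryRule:
    """Trigger terms for one category; lower precedence wins ties.

    The fallback category needs no trigger terms: it absorbs everything
    unmatched.
    """

    category: Category
    terms: frozenset[str]
    precedence: int

    def matches(self, annotation_terms: frozenset[str]) -> frozenset[str]:
        """Trigger terms found (as substrings) among the annotation terms."""
        hits = set()
        for trigger in self.terms:
            for term in annotation_terms:
                if trigger in term:
                    hits.add(trigger)
                    break
        return frozenset(hits)


@dataclass(frozen=True)
class CategoryAssignment:
    protein: ProteinID
    category: Category
    matched_terms: frozenset[str]
    precedence: int | None  # None for the unmatched fallback


@dataclass
class ClassificationResult:
    assignments: list[CategoryAssignment]

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(a.category.value for a in self.assignments)
        return {cat.value: c.get(cat.value, 0) for cat in Category}

    def to_tsv(self) -> str:
        lines = ["protein\tcategory\tmatched_terms\tprecedence"]
        for a in sorted(self.assignments, key=lambda a: a.protein.value):
            lines.append(
                "\t".join(
                    [
                        a.protein.value,
                        a.category.value,
                        ";".join(sorted(a.matched_terms)),
                        "" if a.precedence is None else str(a.precedence),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def normalize_terms(terms: Iterable[str]) -> frozenset[str]:
    """Lower-case, strip and deduplicate annotation/trigger terms."""
    return frozenset(t.strip().lower() for t in terms if t.strip())


def validate_rules(rules: Iterable[CategoryRule]) -> list[CategoryRule]:
    rules = list(rules)
    precedences = [r.precedence for r in rules]
    if len(set(precedences)) != len(precedences):
        dupes = sorted({p for p in precedences if precedences.count(p) > 1})
        raise DuplicatePrecedenceError(f"duplicate rule precedences: {dupes}")
    covered = {r.category for r in rules}
    missing = set(Category) - covered
    if missing:
        raise IncompleteRulesError(
            f"rules missing categories: {sorted(c.value for c in missing)}"
        )
    return sorted(rules, key=lambda r: r.precedence)


def classify(
    candidates: ProteinSet,
    annotations: Mapping[ProteinID, frozenset[str]],
    rules: Iterable[CategoryRule],
) -> ClassificationResult:
    """Assign every candidate to exactly one functional category.

    The per-category counts of the result always sum to ``len(candidates)``
    (partition property) and the outcome is independent of iteration order:
    candidates are processed in sorted order and ties between matching
    categories are broken by rule precedence alone.
    """
    ordered_rules = validate_rules(rules)
    assignments: list[CategoryAssignment] = []
    for pid in sorted(candidates.members):
        terms = normalize_terms(annotations.get(pid, frozenset()))
        assignment = None
        for rule in ordered_rules:
            if not rule.terms:
                continue
            hits = rule.matches(terms)
            if hits:
                assignment = CategoryAssignment(
                    protein=pid,
                    category=rule.category,
                    matched_terms=hits,
                    precedence=rule.precedence,
                )
                break
        if assignment is None:
            assignment = CategoryAssignment(
                protein=pid,
                category=Category.METASTASIS_UNKNOWN,
                matched_terms=frozenset(),
                precedence=None,
            )
        assignments.append(assignment)
    return ClassificationResult(assignments=assignments)


def rules_from_yaml(path: str | Path) -> list[CategoryRule]:
    """Load category rules from a YAML file.

    Expected structure::

        rules:
          - category: immune_modulation
            precedence: 1
            terms: [antigen, cytokine, ...]
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _rules_from_doc(doc, source=str(path))


def default_rules() -> list[CategoryRule]:
    """The shipped default trigger-term rule set."""
    text = resources.files("sfdkit").joinpath("data/category_rules.yaml").read_text()
    return _rules_from_doc(yaml.safe_load(text), source="<default rules>")


def _rules_from_doc(doc: dict, source: str) -> list[CategoryRule]:
    try:
        raw_rules = doc["rules"]
    except (TypeError, KeyError):
        raise ValueError(f"rule file {source}: top-level 'rules' list required")
    rules = [
        CategoryRule(
            category=Category(r["category"]),
            terms=normalize_terms(r.get("terms", [])),
            precedence=int(r["precedence"]),
        )
        for r in raw_rules
    ]
    return validate_rules(rules)
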