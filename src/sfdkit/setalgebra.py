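"""Provenance-tracked protein-set algebra: the deconvolution cascade itself.

Scaffold-free functional deconvolution (SFD) treats a disease EV proteome as
a plain presence/absence set and refines it by two moves only:

* **subtract** a healthy/contaminant reference (remove constitutive EV
  scaffold proteins and co-isolated serum proteins), and
* **intersect** a function-specific reference (keep only proteins with a
  documented role: metastasis, surface accessibility, immunosuppression, ...),
  optionally repeated for sub-functions.

Because each step discards candidates irreversibly, every
:class:`ProteinSet` carries a provenance chain and :func:`run_cascade` emits
a :class:`FunnelReport` recording, per step, not just the retained/removed
counts but *which* members were removed — the audit trail needed to explain
why a known marker (the CSPG4 situation: present in both disease and healthy
vesicles) fell out of the final list.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum

from .identifiers import Namespace, ProteinID

logger = logging.getLogger(__name__)


class NamespaceMismatchError(ValueError):
    """Set operation attempted across different identifier namespaces."""


class UnresolvableReferenceError(KeyError):
    """A cascade step names a reference set that was never loaded."""


@dataclass(frozen=True)
class ProvenanceRecord:
    """One operation applied to a :class:`ProteinSet`."""

    op: str
    reference: str
    before: int
    after: int


@dataclass(frozen=True)
class ProteinSet:
    """A labeled, deduplicated set of protein identifiers in one namespace.

    The provenance chain is append-only; ``after`` of the last record always
    equals the current cardinality.
    """

    label: str
    members: frozenset[ProteinID]
    provenance: tuple[ProvenanceRecord, ...] = ()

    @classmethod
    def from_ids(cls, label: str, ids: Iterable[ProteinID]) -> "ProteinSet":
        members = frozenset(ids)
        namespaces = {m.namespace for m in members}
        if len(namespaces) > 1:
            raise NamespaceMismatchError(
                f"set {label!r} mixes namespaces: "
                f"{sorted(n.value for n in namespaces)}"
            )
        return cls(label=label, members=members)

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str]) -> "ProteinSet":
        """Convenience constructor for gene-symbol sets (upper-cased)."""
        return cls.from_ids(
            label,
            (ProteinID(Namespace.GENE_SYMBOL, s.strip().upper()) for s in symbols),
        )

    @property
    def namespace(self) -> Namespace | None:
        for m in self.members:
            return m.namespace
        return None

    def values(self) -> list[str]:
        """Sorted member values, for deterministic output."""
        return sorted(m.value for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, pid: ProteinID) -> bool:
        return pid in self.members

    def _check_namespace(self, other: "ProteinSet") -> None:
        a, b = self.namespace, other.namespace
        if a is not None and b is not None and a is not b:
            raise NamespaceMismatchError(
                f"cannot combine {self.label!r} ({a.value}) with "
                f"{other.label!r} ({b.value})"
            )

    def _derive(self, op: str, reference: str, members: frozenset[ProteinID]) -> "ProteinSet":
        record = ProvenanceRecord(op=op, reference=reference, before=len(self.members), after=len(members))
        if not members:
            logger.warning(
                "set %r is empty after %s against %r", self.label, op, reference
            )
        return ProteinSet(
            label=self.label, members=members, provenance=self.provenance + (record,)
        )


def subtract(x: ProteinSet, ref: ProteinSet) -> ProteinSet:
    """Remove from ``x`` every protein present in ``ref`` (scaffold removal)."""
    x._check_namespace(ref)
    return x._derive("subtract", ref.label, x.members - ref.members)


def intersect(x: ProteinSet, ref: ProteinSet) -> ProteinSet:
    """Keep only proteins of ``x`` present in ``ref`` (function filter)."""
    x._check_namespace(ref)
    return x._derive("intersect", ref.label, x.members & ref.members)


def iterate_subfunction(x: ProteinSet, ref: ProteinSet) -> ProteinSet:
    """Intersect with a sub-function reference (iterated refinement).

    Set-theoretically identical to :func:`intersect`; the provenance record
    is tagged ``subfunction`` so funnel reports distinguish the refinement
    passes from the first function filter.
    """
    x._check_namespace(ref)
    return x._derive("subfunction", ref.label, x.members & ref.members)


class StepKind(str, Enum):
    SUBTRACT = "subtract"
    INTERSECT = "intersect"
    SUBFUNCTION = "subfunction"


@dataclass(frozen=True)
class CascadeStep:
    """One configured step: an operation kind plus a reference-set label."""

    kind: StepKind
    reference: str


@dataclass
class FunnelStepReport:
    kind: str
    reference: str
    retained: int
    removed: int
    removed_members: list[str]


@dataclass
class FunnelReport:
    """Per-step accounting of a cascade: the printable funnel.

    Invariant (checked in :func:`run_cascade`): at every step
    ``retained + removed`` equals the previous step's retained count, and the
    final member list has exactly the last retained count.
    """

    input_label: str
    input_size: int
    steps: list[FunnelStepReport]
    final_members: list[str]
    final_set: ProteinSet

    @property
    def counts(self) -> list[int]:
        """The funnel as a list of sizes: input, then retained after each step."""
        return [self.input_size] + [s.retained for s in self.steps]

    def to_dict(self) -> dict:
        return {
            "input": {"label": self.input_label, "size": self.input_size},
            "steps": [
                {
                    "kind": s.kind,
                    "reference": s.reference,
                    "retained": s.retained,
                    "removed": s.removed,
                    "removed_members": s.removed_members,
                }
                for s in self.steps
            ],
            "final": {"size": len(self.final_members), "members": self.final_members},
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        """Human-readable per-step table (one row per step)."""
        lines = ["step\tkind\treference\tretained\tremoved"]
        lines.append(f"0\tinput\t{self.input_label}\t{self.input_size}\t0")
        for i, s in enumerate(self.steps, start=1):
            lines.append(f"{i}\t{s.kind}\t{s.reference}\t{s.retained}\t{s.removed}")
        return "\n".join(lines) + "\n"


def run_cascade(
    x: ProteinSet,
    steps: Sequence[CascadeStep],
    references: Mapping[str, ProteinSet],
) -> FunnelReport:
    """Apply an ordered sequence of subtract/intersect steps to ``x``.

    Raises
    ------
    UnresolvableReferenceError
        If a step references a label absent from ``references`` (raised
        before any work is done, naming the label).
    """
    for step in steps:
        if step.reference not in references:
            raise UnresolvableReferenceError(
                f"cascade step references unknown set {step.reference!r}; "
                f"loaded references: {sorted(references)}"
            )

    current = x
    step_reports: list[FunnelStepReport] = []
    for step in steps:
        ref = references[step.reference]
        before = current.members
        if step.kind is StepKind.SUBTRACT:
            current = subtract(current, ref)
        elif step.kind is StepKind.INTERSECT:
            current = intersect(current, ref)
        else:
            current = iterate_subfunction(current, ref)
        removed = before - current.members
        assert len(current) + len(removed) == len(before)  # conservation
        step_reports.append(
            FunnelStepReport(
                kind=step.kind.value,
                reference=step.reference,
                retained=len(current),
                removed=len(removed),
                removed_members=sorted(m.value for m in removed),
            )
        )
    return FunnelReport(
        input_label=x.label,
        input_size=len(x),
        steps=step_reports,
        final_members=current.values(),
        final_set=current,
    )
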