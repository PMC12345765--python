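"""Protein identifier canonicalization and namespace translation.

Mass-spectrometry search engines report UniProt accessions (``P04637``,
possibly with an isoform suffix ``-2``) while gene-level resources — cancer
metastasis databases, surfaceome atlases, expression cohorts — key on HGNC
gene symbols.  Presence/absence set algebra is only meaningful once both
sides speak the same dialect, so every identifier entering the pipeline is
canonicalized into one of two namespaces and, where a mapping table is
supplied, translated accession → symbol.

No remote lookups are performed: translation is driven entirely by a
user-supplied two-column TSV, keeping runs reproducible.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path


class Namespace(str, Enum):
    """Identifier namespaces the pipeline understands."""

    UNIPROT_ACCESSION = "uniprot_accession"
    GENE_SYMBOL = "gene_symbol"


class InvalidIdentifierError(ValueError):
    """Raised for empty or whitespace-only identifier input."""


class MixedNamespaceError(ValueError):
    """Raised when a single collection mixes identifier namespaces."""


_ISOFORM_SUFFIX = re.compile(r"-\d+$")


@dataclass(frozen=True, order=True)
class ProteinID:
    """A canonical protein identifier.

    Instances are immutable and hashable so they can live in sets.  Use
    :func:`canonicalize` rather than the constructor for raw input.
    """

    namespace: Namespace
    value: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def canonicalize(raw: str, namespace: Namespace) -> ProteinID:
    """Normalize a raw identifier string into a canonical :class:`ProteinID`.

    Gene symbols are upper-cased; UniProt accessions are upper-cased and any
    isoform suffix (``-<digits>``) is stripped, since the pipeline is not
    isoform-aware.  Surrounding whitespace is removed.

    Raises
    ------
    InvalidIdentifierError
        If ``raw`` is empty after trimming.
    """
    namespace = Namespace(namespace)
    value = raw.strip()
    if not value:
        raise InvalidIdentifierError(
            f"empty identifier (raw input {raw!r}) in namespace {namespace.value}"
        )
    value = value.upper()
    if namespace is Namespace.UNIPROT_ACCESSION:
        value = _ISOFORM_SUFFIX.sub("", value)
    return ProteinID(namespace=namespace, value=value)


@dataclass
class IdMapping:
    """Many-to-one accession → gene-symbol map.

    ``pairs`` values are stored canonical; lookups canonicalize their key, so
    ``P04637-2`` finds the entry for ``P04637``.
    """

    pairs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, str]) -> "IdMapping":
        canon = {}
        for acc, sym in pairs.items():
            a = canonicalize(acc, Namespace.UNIPROT_ACCESSION)
            s = canonicalize(sym, Namespace.GENE_SYMBOL)
            canon[a.value] = s.value
        return cls(pairs=canon)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMapping":
        """Read a 2-column (accession, symbol) TSV; header required,
        ``#`` comment lines ignored."""
        pairs: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            header_seen = False
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    header_seen = True  # first non-comment line is the header
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(
                        f"mapping file {path}: expected 2 tab-separated columns, "
                        f"got {line!r}"
                    )
                acc = canonicalize(fields[0], Namespace.UNIPROT_ACCESSION)
                sym = canonicalize(fields[1], Namespace.GENE_SYMBOL)
                pairs[acc.value] = sym.value
        if not header_seen:
            raise ValueError(f"mapping file {path} is empty (header required)")
        return cls(pairs=pairs)

    def lookup(self, pid: ProteinID) -> ProteinID | None:
        if pid.namespace is not Namespace.UNIPROT_ACCESSION:
            raise ValueError("IdMapping maps UniProt accessions to gene symbols")
        sym = self.pairs.get(pid.value)
        if sym is None:
            return None
        return ProteinID(Namespace.GENE_SYMBOL, sym)


@dataclass
class TranslationResult:
    """Outcome of :func:`translate`.

    ``collapsed`` counts inputs lost to many-to-one mapping: the number of
    mapped inputs minus the number of distinct translated identifiers.
    Unmapped identifiers are retained here rather than silently dropped so
    downstream funnel accounting stays honest.
    """

    translated: frozenset[ProteinID]
    unmapped: frozenset[ProteinID]
    collapsed: int
    target: Namespace


def translate(
    ids: Iterable[ProteinID],
    mapping: IdMapping,
    target: Namespace = Namespace.GENE_SYMBOL,
) -> TranslationResult:
    """Translate a single-namespace identifier collection into ``target``.

    Every input identifier lands in exactly one of ``translated`` or
    ``unmapped``.  Identifiers already in the target namespace pass through
    unchanged.  Duplicate outputs from a many-to-one map collapse to one set
    member; the collapse count is recorded.

    Raises
    ------
    MixedNamespaceError
        If the inputs do not all share one namespace.
    """
    target = Namespace(target)
    ids = list(ids)
    namespaces = {i.namespace for i in ids}
    if len(namespaces) > 1:
        raise MixedNamespaceError(
            f"input mixes namespaces: {sorted(n.value for n in namespaces)}"
        )
    if not ids:
        return TranslationResult(frozenset(), frozenset(), 0, target)
    source = next(iter(namespaces))
    if source is target:
        return TranslationResult(frozenset(ids), frozenset(), 0, target)
    if target is not Namespace.GENE_SYMBOL:
        raise ValueError("only accession → gene_symbol translation is supported")

    translated: list[ProteinID] = []
    unmapped: list[ProteinID] = []
    for pid in ids:
        sym = mapping.lookup(pid)
        if sym is None:
            unmapped.append(pid)
        else:
            translated.append(sym)
    distinct = frozenset(translated)
    return TranslationResult(
        translated=distinct,
        unmapped=frozenset(unmapped),
        collapsed=len(translated) - len(distinct),
        target=target,
    )
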