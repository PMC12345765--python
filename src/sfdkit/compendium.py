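"""Healthy-EV reference compendium construction.

The scaffold reference subtracted by the cascade is itself assembled from
many healthy source proteomes — vesicles from serum, fibroblasts,
cerebrospinal fluid, breast milk, aqueous humor and other normal sample
types, or from several healthy donors of a matched cell type.  This module
merges those per-source presence lists into one reference set.

Default semantics are the union (a protein seen in *any* healthy source is
scaffold), the conservative reading that maximizes background removal; a
``min_sources`` presence threshold is exposed for stricter definitions
(e.g. "seen in at least 3 of 24 sample types").
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass

from .identifiers import ProteinID
from .setalgebra import ProteinSet, ProvenanceRecord


@dataclass(frozen=True)
class SourceList:
    """One healthy source proteome: a name, a sample-type tag and its set."""

    name: str
    sample_type: str
    proteins: ProteinSet


class EmptyCompendiumError(ValueError):
    """Raised when building a reference from zero sources."""


def build_reference(
    sources: Iterable[SourceList],
    min_sources: int = 1,
    label: str = "healthy_ev_reference",
) -> ProteinSet:
    """Merge healthy source lists into a scaffold reference set.

    A protein enters the reference when it appears in at least
    ``min_sources`` distinct source lists; ``min_sources=1`` (default) is the
    plain union.  Per-source sizes are recorded in the provenance chain so
    the compendium's composition is auditable.

    Raises
    ------
    EmptyCompendiumError
        If ``sources`` is empty.
    ValueError
        If ``min_sources`` is < 1 or exceeds the number of sources, or if
        source names collide.
    """
    sources = list(sources)
    if not sources:
        raise EmptyCompendiumError("cannot build a reference from zero sources")
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate source names in compendium: {dupes}")
    if not 1 <= min_sources <= len(sources):
        raise ValueError(
            f"min_sources must be in [1, {len(sources)}], got {min_sources}"
        )

    counts: Counter[ProteinID] = Counter()
    for src in sources:
        counts.update(src.proteins.members)
    members = frozenset(pid for pid, c in counts.items() if c >= min_sources)

    provenance = tuple(
        ProvenanceRecord(
            op="compendium_source",
            reference=f"{src.name} ({src.sample_type})",
            before=len(src.proteins),
            after=len(src.proteins),
        )
        for src in sources
    ) + (
        ProvenanceRecord(
            op=f"compendium_merge(min_sources={min_sources})",
            reference=f"{len(sources)} sources",
            before=sum(len(s.proteins) for s in sources),
            after=len(members),
        ),
    )
    result = ProteinSet(label=label, members=members, provenance=provenance)
    # trip the mixed-namespace guard if sources disagree
    ProteinSet.from_ids(label, members)
    return result
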