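"""Reconciliation of the metadata and tree-derived taxon candidates.

The final study-level taxon follows three rules: (a) when both methods
propose the same name the result is highly reliable; (b) when they differ —
or only the metadata method produced a name — the metadata candidate wins,
because tree tip labels are often abbreviated; when only the tree method
produced a name it is kept at lower confidence; (c) when neither method
yields a credible name the study is marked undetermined and reserved for
manual review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .taxonomy import TaxonomyIndex
from .textmine import CandidateName


class Confidence(str, Enum):
    """Stratum of the final assignment, mirroring the validation strata."""

    BOTH_AGREE = "both_agree"
    METADATA_ONLY = "metadata_only"
    TREE_ONLY = "tree_only"
    UNDETERMINED = "undetermined"


@dataclass
class AssignmentResult:
    final_name: str | None
    final_rank: str | None
    confidence: Confidence
    name1: CandidateName | None = None
    name2: CandidateName | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def cand(c: CandidateName | None) -> dict | None:
            if c is None:
                return None
            return {
                "name": c.name,
                "rank": c.rank,
                "method": c.method,
                "frequency": c.frequency,
                "ambiguous": c.ambiguous,
            }

        return {
            "final_name": self.final_name,
            "final_rank": self.final_rank,
            "confidence": self.confidence.value,
            "name1": cand(self.name1),
            "name2": cand(self.name2),
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssignmentResult":
        def cand(c: dict | None, method: str) -> CandidateName | None:
            if c is None:
                return None
            return CandidateName(
                name=c["name"],
                rank=c["rank"],
                method=c.get("method", method),
                frequency=c.get("frequency", 1),
                ambiguous=c.get("ambiguous", False),
            )

        return cls(
            final_name=d.get("final_name"),
            final_rank=d.get("final_rank"),
            confidence=Confidence(d.get("confidence", "undetermined")),
            name1=cand(d.get("name1"), "metadata"),
            name2=cand(d.get("name2"), "tree"),
            notes=list(d.get("notes", [])),
        )


def _consistent_lineage(
    name1: CandidateName, name2: CandidateName, index: TaxonomyIndex
) -> bool:
    """True when name2 sits under name1 by parent links (e.g. species of a genus)."""
    targets = {tid for _, tid in index.lookup(name1.name)}
    if not targets:
        return False
    for _, tid in index.lookup(name2.name):
        seen: set[str] = set()
        cur: str | None = tid
        while cur is not None and cur not in seen:
            seen.add(cur)
            cur = index.parent_of(cur)
            if cur in targets:
                return True
    return False


def reconcile(
    name1: CandidateName | None,
    name2: CandidateName | None,
    index: TaxonomyIndex | None = None,
) -> AssignmentResult:
    """Apply rules (a)/(b)/(c) to the two candidates.

    ``index`` is optional; when given, a tree candidate nested under the
    winning metadata candidate earns a "consistent-lineage" diagnostic note
    even though the names differ.
    """
    if name1 is not None and name1.same_taxon(name2):
        return AssignmentResult(
            final_name=name1.name,
            final_rank=name1.rank,
            confidence=Confidence.BOTH_AGREE,
            name1=name1,
            name2=name2,
        )
    if name1 is not None:
        notes = []
        if name2 is not None:
            notes.append("candidates differ; metadata name preferred")
            if index is not None and _consistent_lineage(name1, name2, index):
                notes.append("consistent-lineage")
        return AssignmentResult(
            final_name=name1.name,
            final_rank=name1.rank,
            confidence=Confidence.METADATA_ONLY,
            name1=name1,
            name2=name2,
            notes=notes,
        )
    if name2 is not None:
        return AssignmentResult(
            final_name=name2.name,
            final_rank=name2.rank,
            confidence=Confidence.TREE_ONLY,
            name1=None,
            name2=name2,
        )
    return AssignmentResult(
        final_name=None,
        final_rank=None,
        confidence=Confidence.UNDETERMINED,
        notes=["undetermined; reserved for manual analysis"],
    )
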