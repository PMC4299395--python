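"""Confidence classification of functional gene annotations.

Every locus starts as a *hypothetical protein*.  Evidence — transcripts,
protein detection, sequence similarity, domain content, pseudogene signals,
experimental characterization — moves it up a ladder of curation levels:

    hypothetical < expressed < domain containing < similar to
                 < putative < probable < named   (uncertain: pseudogene)

with *translated* as an orthogonal existence qualifier (protein-level
evidence) that can stack on any level.

The similarity criterion is the classical "safe zone": a best-hit e-value
of at most 1e-20, or at least 30% identity over at least 80 contiguous
amino acids.  Direct transfer of a characterized grapevine protein's name
requires strictly more than 95% identity over the whole sequence (or the
gene itself being characterized in Vitis).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

__all__ = [
    "HomologyHit",
    "EvidenceBundle",
    "ConfidenceThresholds",
    "ConfidenceLevel",
    "FunctionalEvidence",
    "CurationLabel",
    "classify_confidence",
    "render_full_name",
    "scan_threshold_boundary",
    "best_hit",
]


@dataclass(frozen=True)
class HomologyHit:
    """One similarity-search hit against a plant protein.

    ``percent_identity`` and ``aligned_length`` describe the best contiguous
    aligned block; ``whole_sequence_identity`` is the end-to-end identity
    used for direct name transfer from a characterized Vitis protein.
    """

    subject_name: str
    subject_species: str
    e_value: float
    percent_identity: float
    aligned_length: int
    whole_sequence_identity: float = 0.0
    is_vitis: bool = False
    is_characterized: bool = False

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e-value must be > 0")
        for v in (self.percent_identity, self.whole_sequence_identity):
            if not 0 <= v <= 100:
                raise ValueError("identities must lie in [0, 100]")
        if self.aligned_length < 0:
            raise ValueError("aligned length must be >= 0")


class FunctionalEvidence(enum.Enum):
    NONE = "none"
    IN_SILICO = "in_silico"
    SOME_EXPERIMENTAL = "some_experimental"
    CHARACTERIZED_IN_VITIS = "characterized_in_vitis"


@dataclass(frozen=True)
class EvidenceBundle:
    """Everything known about one locus when the classifier runs.

    ``transcript_evidence`` covers RT-PCR / EST / RNA-seq / Northern /
    microarray proof of an RNA; ``protein_evidence`` covers Edman
    sequencing, mass spectrometry, structures, interactions or antibody
    detection; ``characterized_name`` must accompany
    ``FunctionalEvidence.CHARACTERIZED_IN_VITIS``.
    """

    transcript_evidence: bool = False
    protein_evidence: bool = False
    pseudogene_evidence: bool = False
    functional_evidence: FunctionalEvidence = FunctionalEvidence.NONE
    domain_hits: Sequence[str] = ()
    homology_hits: Sequence[HomologyHit] = ()
    characterized_name: Optional[str] = None
    go_evidence_code: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.functional_evidence is FunctionalEvidence.CHARACTERIZED_IN_VITIS
                and not self.characterized_name):
            raise ValueError(
                "a gene characterized in Vitis must come with its name"
            )


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Decision-boundary constants of the classifier.

    ``evalue_cutoff`` (inclusive) and the ``min_identity`` /
    ``min_contiguous_length`` pair (both inclusive) define the similarity
    safe zone; ``transfer_identity`` is the *exclusive* lower bound on
    whole-sequence identity for direct name transfer.
    """

    evalue_cutoff: float = 1e-20
    min_identity: float = 30.0
    min_contiguous_length: int = 80
    transfer_identity: float = 95.0

    def __post_init__(self) -> None:
        if min(self.evalue_cutoff, self.min_identity,
               self.min_contiguous_length, self.transfer_identity) <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.transfer_identity <= self.min_identity:
            raise ValueError("transfer_identity must exceed min_identity")


class ConfidenceLevel(enum.Enum):
    """Curation vocabulary, ordered by increasing confidence (uncertain is
    the pseudogene branch and outranks everything)."""

    HYPOTHETICAL = "hypothetical"
    EXPRESSED = "expressed"
    DOMAIN_CONTAINING = "domain_containing"
    SIMILAR_TO = "similar_to"
    PUTATIVE = "putative"
    PROBABLE = "probable"
    NAMED = "named"
    UNCERTAIN = "uncertain"


_RANK = {
    ConfidenceLevel.HYPOTHETICAL: 0,
    ConfidenceLevel.EXPRESSED: 1,
    ConfidenceLevel.DOMAIN_CONTAINING: 2,
    ConfidenceLevel.SIMILAR_TO: 3,
    ConfidenceLevel.PUTATIVE: 4,
    ConfidenceLevel.PROBABLE: 5,
    ConfidenceLevel.NAMED: 6,
    ConfidenceLevel.UNCERTAIN: 7,
}

_PAYLOAD_LEVELS = {
    ConfidenceLevel.DOMAIN_CONTAINING,
    ConfidenceLevel.SIMILAR_TO,
    ConfidenceLevel.NAMED,
}


def level_rank(level: ConfidenceLevel) -> int:
    return _RANK[level]


@dataclass(frozen=True)
class CurationLabel:
    """Classifier output: a level, its payload (the domain, the homolog, or
    the transferred name) and orthogonal qualifiers such as ``translated``."""

    level: ConfidenceLevel
    payload: Optional[str] = None
    qualifier_stack: tuple = ()
    go_evidence_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.level in _PAYLOAD_LEVELS and not self.payload:
            raise ValueError(f"level {self.level.value} requires a payload")
        if self.level not in _PAYLOAD_LEVELS and self.payload:
            raise ValueError(f"level {self.level.value} forbids a payload")


def best_hit(hits: Sequence[HomologyHit]) -> Optional[HomologyHit]:
    """Deterministic best hit: smallest e-value, then higher identity,
    longer alignment, and finally lexical subject name."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.e_value, -h.percent_identity,
                                    -h.aligned_length, h.subject_name))


def _similarity_met(hit: HomologyHit, t: ConfidenceThresholds) -> bool:
    return (hit.e_value <= t.evalue_cutoff
            or (hit.percent_identity >= t.min_identity
                and hit.aligned_length >= t.min_contiguous_length))


def classify_confidence(evidence: EvidenceBundle,
                        thresholds: ConfidenceThresholds = ConfidenceThresholds(),
                        ) -> CurationLabel:
    """Run the evidence decision tree and return the curation label.

    Precedence: uncertain (pseudogene) > named > probable > putative >
    similar to > domain containing > expressed > hypothetical; ``translated``
    is stacked as a qualifier whenever protein-level evidence exists.  The
    similarity-based levels additionally require transcript evidence — a
    locus leaves "hypothetical" only once an RNA is proven.
    """
    qualifiers: List[str] = []
    if evidence.protein_evidence:
        qualifiers.append("translated")
    go_code = None
    if evidence.functional_evidence in (FunctionalEvidence.SOME_EXPERIMENTAL,
                                        FunctionalEvidence.CHARACTERIZED_IN_VITIS):
        go_code = evidence.go_evidence_code

    def label(level: ConfidenceLevel, payload: Optional[str] = None
              ) -> CurationLabel:
        return CurationLabel(level, payload, tuple(qualifiers), go_code)

    if evidence.pseudogene_evidence:
        return label(ConfidenceLevel.UNCERTAIN)

    if evidence.functional_evidence is FunctionalEvidence.CHARACTERIZED_IN_VITIS:
        return label(ConfidenceLevel.NAMED, evidence.characterized_name)
    named = best_hit([
        h for h in evidence.homology_hits
        if h.is_vitis and h.is_characterized
        and h.whole_sequence_identity > thresholds.transfer_identity
    ])
    if named is not None:
        return label(ConfidenceLevel.NAMED, named.subject_name)

    if evidence.functional_evidence is FunctionalEvidence.SOME_EXPERIMENTAL:
        return label(ConfidenceLevel.PROBABLE)
    if evidence.functional_evidence is FunctionalEvidence.IN_SILICO:
        return label(ConfidenceLevel.PUTATIVE)

    if evidence.transcript_evidence:
        similar = best_hit([h for h in evidence.homology_hits
                            if _similarity_met(h, thresholds)])
        if similar is not None:
            return label(ConfidenceLevel.SIMILAR_TO, similar.subject_name)
        if evidence.domain_hits:
            return label(ConfidenceLevel.DOMAIN_CONTAINING,
                         evidence.domain_hits[0])
        return label(ConfidenceLevel.EXPRESSED)

    return label(ConfidenceLevel.HYPOTHETICAL)


_RENDERINGS = {
    ConfidenceLevel.HYPOTHETICAL: "hypothetical protein",
    ConfidenceLevel.EXPRESSED: "expressed protein",
    ConfidenceLevel.UNCERTAIN: "uncertain protein (putative pseudogene)",
}


def render_full_name(label: CurationLabel,
                     base_name: Optional[str] = None) -> str:
    """Render the full-name text carrying the confidence level."""
    level = label.level
    if level in _RENDERINGS:
        return _RENDERINGS[level]
    if level is ConfidenceLevel.DOMAIN_CONTAINING:
        return f"{label.payload} domain containing protein"
    if level is ConfidenceLevel.SIMILAR_TO:
        return f"similar to {label.payload}"
    if level is ConfidenceLevel.NAMED:
        return label.payload  # type: ignore[return-value]
    if level in (ConfidenceLevel.PUTATIVE, ConfidenceLevel.PROBABLE):
        if not base_name:
            raise ValueError(
                f"level {level.value} needs the functional name to qualify"
            )
        return f"{level.value} {base_name}"
    raise ValueError(f"unhandled level {level!r}")


def scan_threshold_boundary(axis: str,
                            evidence_template: EvidenceBundle,
                            grid: Sequence[float],
                            thresholds: ConfidenceThresholds = ConfidenceThresholds(),
                            ) -> float:
    """Recover a classifier decision boundary behaviourally.

    Scans ``grid`` (sorted ascending) along one axis of the template's
    single homology hit and reports the boundary the classifier exhibits:

    - ``e_value``: the largest value still classified "similar to";
    - ``identity``: the smallest value classified "similar to";
    - ``transfer_identity``: the largest value at which direct name
      transfer is still refused (the exclusive bound itself).
    """
    if list(grid) != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    if len(evidence_template.homology_hits) != 1:
        raise ValueError("template must contain exactly one homology hit")
    hit = evidence_template.homology_hits[0]

    def outcome(value: float) -> bool:
        if axis == "e_value":
            probe = replace(hit, e_value=value)
            target = ConfidenceLevel.SIMILAR_TO
        elif axis == "identity":
            probe = replace(hit, percent_identity=value)
            target = ConfidenceLevel.SIMILAR_TO
        elif axis == "transfer_identity":
            probe = replace(hit, whole_sequence_identity=value)
            target = ConfidenceLevel.NAMED
        else:
            raise ValueError(f"unknown axis {axis!r}")
        bundle = replace(evidence_template, homology_hits=(probe,))
        return classify_confidence(bundle, thresholds).level is target

    flags = [outcome(v) for v in grid]
    if all(flags) or not any(flags):
        raise ValueError(f"no classification transition on the {axis} grid")
    if axis == "e_value":
        return max(v for v, ok in zip(grid, flags) if ok)
    if axis == "identity":
        return min(v for v, ok in zip(grid, flags) if ok)
    return max(v for v, ok in zip(grid, flags) if not ok)
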