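"""Hotpep annotation: match a pattern bank's conserved peptides against
query proteins, apply the significance rules, assign each protein to the
best-scoring group per family and predict enzymatic function.

Scoring a sequence against a group finds every group peptide present as an
exact substring and sums their stored in-group frequencies (each distinct
peptide counted once) into the group-specific frequency score. A hit is
significant iff the sequence

* contains three or more of the group's conserved peptides,
* has a frequency score strictly greater than 1.0, and
* the matched peptides cover at least ten distinct residues.

A protein is assigned, per family, to the significant group with the
highest frequency score; multidomain proteins may legitimately carry
annotations in several families.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .ppr import PatternBank, PeptideGroup
from .seqio import ProteinRecord

MIN_PEPTIDES = 3
MIN_SCORE = 1.0  # strict: a score of exactly 1.0 is not significant
MIN_COVERAGE = 10  # inclusive: exactly ten covered residues passes


class GroupScore(NamedTuple):
    frequency_score: float
    peptide_count: int
    coverage: int
    matched_peptides: frozenset[str]


@dataclass
class Annotation:
    """One significant hit of a query protein to a PPR group."""

    accession: str
    family: str
    group_id: int
    frequency_score: float
    peptide_count: int
    coverage: int
    matched_peptides: frozenset[str]
    predicted_functions: dict[str, int] = field(default_factory=dict)


def score_against_group(sequence: str, group: PeptideGroup) -> GroupScore:
    """Score one sequence against one group's peptide list.

    A peptide occurring multiple times contributes its frequency once to
    the score but all its occurrences to coverage (coverage is the number
    of distinct residue positions under at least one matched peptide).
    """
    matched: set[str] = set()
    covered: set[int] = set()
    for peptide in group.peptides:
        start = sequence.find(peptide)
        if start == -1:
            continue
        matched.add(peptide)
        while start != -1:
            covered.update(range(start, start + len(peptide)))
            start = sequence.find(peptide, start + 1)
    score = sum(group.peptides[p] for p in matched)
    return GroupScore(score, len(matched), len(covered), frozenset(matched))


def is_significant(score: GroupScore) -> bool:
    """Apply the three significance conditions."""
    return (
        score.peptide_count >= MIN_PEPTIDES
        and score.frequency_score > MIN_SCORE
        and score.coverage >= MIN_COVERAGE
    )


def annotate_protein(record: ProteinRecord, bank: PatternBank) -> list[Annotation]:
    """Annotate one protein: at most one hit per family (the significant
    group with the highest frequency score).

    Ties on the score prefer larger peptide count, then larger coverage,
    then lower group id. Returns annotations sorted by family.
    """
    best: dict[str, tuple[tuple, PeptideGroup, GroupScore]] = {}
    for (family, _), group in bank.groups.items():
        score = score_against_group(record.sequence, group)
        if not is_significant(score):
            continue
        rank = (
            score.frequency_score,
            score.peptide_count,
            score.coverage,
            -group.group_id,
        )
        if family not in best or rank > best[family][0]:
            best[family] = (rank, group, score)
    annotations = []
    for family in sorted(best):
        _, group, score = best[family]
        annotations.append(
            Annotation(
                accession=record.accession,
                family=family,
                group_id=group.group_id,
                frequency_score=score.frequency_score,
                peptide_count=score.peptide_count,
                coverage=score.coverage,
                matched_peptides=score.matched_peptides,
                predicted_functions=dict(group.function_scores),
            )
        )
    return annotations


@dataclass
class AnnotationResult:
    """Per-hit table plus the two summary views."""

    annotations: list[Annotation]
    family_counts: dict[str, int]
    accession_families: dict[str, list[str]]


def annotate_collection(
    records: Sequence[ProteinRecord], bank: PatternBank
) -> AnnotationResult:
    """Annotate a collection; deterministic ordering (input order, then
    family lexicographic). The family summary counts each (protein, family)
    pair once."""
    annotations: list[Annotation] = []
    family_counts: dict[str, int] = defaultdict(int)
    accession_families: dict[str, list[str]] = {}
    for record in records:
        hits = annotate_protein(record, bank)
        annotations.extend(hits)
        if hits:
            accession_families[record.accession] = [h.family for h in hits]
            for hit in hits:
                family_counts[hit.family] += 1
    return AnnotationResult(annotations, dict(family_counts), accession_families)


def predict_function(annotation: Annotation) -> list[tuple[str, int]]:
    """Rank the winning group's EC numbers by descending function score
    (ties by EC string). Empty when the group has no characterized member —
    the protein gets a family but no functional prediction."""
    return sorted(annotation.predicted_functions.items(), key=lambda kv: (-kv[1], kv[0]))
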