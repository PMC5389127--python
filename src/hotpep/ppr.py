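"""Peptide Pattern Recognition (PPR): discovery of groups of related
proteins that share short conserved peptides within one enzyme family.

A PPR group is a set of family members together with a list of up to N
conserved fixed-length peptides (hexamers by default). Every peptide on the
list is present in at least a minimum fraction (default 0.20) of the group
members, and every member contains at least m (default 10) distinct
peptides from the list. Groups are extracted iteratively, largest first,
until fewer than ``min_group_size`` proteins can be grouped.

The search is a deterministic fixed-point refinement:

1. seed the peptide list with the N k-mers present in the most unassigned
   proteins (ties broken lexicographically);
2. candidate members are the unassigned proteins containing at least m
   distinct peptides of the current list;
3. recompute peptide frequencies over the candidates (over *all* their
   k-mers, so the list can both gain and lose peptides) and retain the N
   most frequent peptides at or above the frequency floor;
4. repeat 2-3 until the member set is stable;
5. finally prune to a self-consistent closure: drop members below m
   peptides and peptides below the frequency floor until both group
   invariants hold, recomputing frequencies over the final members.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import STANDARD_RESIDUES, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PprParams:
    """PPR discovery parameters.

    Defaults are the enzyme-family settings: hexapeptides, 70 conserved
    peptides per group, 10 per protein, in-group frequency floor 0.20, and
    extraction stops below 5 members. The CBM preset (short binding
    domains) uses 30 peptides per group and 3 per protein.
    """

    peptide_len: int = 6
    peptides_per_group: int = 70
    min_peptides_per_protein: int = 10
    min_peptide_frequency: float = 0.20
    min_group_size: int = 5
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.peptide_len < 3:
            raise ValueError("peptide_len must be >= 3")
        if self.min_peptides_per_protein > self.peptides_per_group:
            raise ValueError("min_peptides_per_protein must be <= peptides_per_group")
        if not 0 < self.min_peptide_frequency <= 1:
            raise ValueError("min_peptide_frequency must be in (0, 1]")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")


ENZYME_PRESET = PprParams()
CBM_PRESET = PprParams(peptides_per_group=30, min_peptides_per_protein=3)

PRESETS: Mapping[str, PprParams] = {"enzyme": ENZYME_PRESET, "cbm": CBM_PRESET}


@dataclass
class PeptideGroup:
    """One PPR group: conserved peptides with in-group frequencies, the
    member accessions, and per-EC function scores.

    ``function_scores[ec]`` is the sum, over members annotated with that EC,
    of the number of distinct group peptides each such member contains.
    ``n_characterized`` records how many members carry any EC label, so a
    stricter reporting threshold can be applied downstream.
    """

    family: str
    group_id: int
    peptides: dict[str, float]
    members: set[str]
    function_scores: dict[str, int] = field(default_factory=dict)
    n_characterized: int = 0


@dataclass
class PatternBank:
    """All PPR groups for all families plus the discovery parameters."""

    params: PprParams
    groups: dict[tuple[str, int], PeptideGroup] = field(default_factory=dict)
    provenance: str = ""

    def add_group(self, group: PeptideGroup) -> None:
        key = (group.family, group.group_id)
        if key in self.groups:
            raise ValueError(f"group {key} already in bank")
        self.groups[key] = group

    def families(self) -> list[str]:
        return sorted({fam for fam, _ in self.groups})

    def family_groups(self, family: str) -> list[PeptideGroup]:
        return [g for (fam, _), g in sorted(self.groups.items()) if fam == family]

    def validate(self) -> None:
        """Check bank-level invariants (disjoint members, consecutive ids)."""
        for family in self.families():
            groups = self.family_groups(family)
            ids = [g.group_id for g in groups]
            if ids != list(range(1, len(ids) + 1)):
                raise ValueError(f"{family}: group ids not consecutive from 1: {ids}")
            seen: set[str] = set()
            for g in groups:
                overlap = seen & g.members
                if overlap:
                    raise ValueError(f"{family}: members in two groups: {overlap}")
                seen |= g.members

    # ------------------------------------------------------------------
    # serialization: single TSV container with section markers
    # ------------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("#PARAMS\n")
            p = self.params
            for name in (
                "peptide_len",
                "peptides_per_group",
                "min_peptides_per_protein",
                "min_peptide_frequency",
                "min_group_size",
                "max_iterations",
            ):
                fh.write(f"{name}\t{getattr(p, name)}\n")
            fh.write(f"provenance\t{self.provenance}\n")
            fh.write("#PEPTIDES\n")
            fh.write("family\tgroup_id\tpeptide\tfrequency\n")
            for (fam, gid), g in sorted(self.groups.items()):
                for pep, freq in sorted(g.peptides.items(), key=lambda kv: (-kv[1], kv[0])):
                    fh.write(f"{fam}\t{gid}\t{pep}\t{freq:.6f}\n")
            fh.write("#MEMBERS\n")
            fh.write("family\tgroup_id\taccession\tec_labels\n")
            for (fam, gid), g in sorted(self.groups.items()):
                for acc in sorted(g.members):
                    fh.write(f"{fam}\t{gid}\t{acc}\t\n")
            fh.write("#FUNCTIONS\n")
            fh.write("family\tgroup_id\tec\tscore\n")
            for (fam, gid), g in sorted(self.groups.items()):
                for ec, score in sorted(g.function_scores.items(), key=lambda kv: (-kv[1], kv[0])):
                    fh.write(f"{fam}\t{gid}\t{ec}\t{score}\n")
            fh.write("#META\n")
            fh.write("family\tgroup_id\tn_characterized\n")
            for (fam, gid), g in sorted(self.groups.items()):
                fh.write(f"{fam}\t{gid}\t{g.n_characterized}\n")

    @classmethod
    def load(cls, path: str | Path) -> "PatternBank":
        raw: dict[str, list[list[str]]] = defaultdict(list)
        section = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    section = line[1:]
                    continue
                if section is None:
                    raise ValueError(f"{path}: data before first section marker")
                raw[section].append(line.split("\t"))
        kw: dict[str, object] = {}
        provenance = ""
        for row in raw.get("PARAMS", []):
            key, value = row[0], row[1] if len(row) > 1 else ""
            if key == "provenance":
                provenance = value
            elif key == "min_peptide_frequency":
                kw[key] = float(value)
            else:
                kw[key] = int(value)
        bank = cls(params=PprParams(**kw), provenance=provenance)
        groups: dict[tuple[str, int], PeptideGroup] = {}

        def get(fam: str, gid: int) -> PeptideGroup:
            key = (fam, gid)
            if key not in groups:
                groups[key] = PeptideGroup(fam, gid, {}, set())
            return groups[key]

        for fam, gid, pep, freq in _skip_header(raw.get("PEPTIDES", []), "family"):
            get(fam, int(gid)).peptides[pep] = float(freq)
        for row in _skip_header(raw.get("MEMBERS", []), "family"):
            fam, gid, acc = row[0], row[1], row[2]
            get(fam, int(gid)).members.add(acc)
        for fam, gid, ec, score in _skip_header(raw.get("FUNCTIONS", []), "family"):
            get(fam, int(gid)).function_scores[ec] = int(score)
        for fam, gid, n_char in _skip_header(raw.get("META", []), "family"):
            get(fam, int(gid)).n_characterized = int(n_char)
        bank.groups = dict(sorted(groups.items()))
        return bank


def _skip_header(rows: list[list[str]], first_field: str):
    for row in rows:
        if row and row[0] == first_field:
            continue
        yield row


def count_kmers(records: Iterable[ProteinRecord], k: int) -> dict[str, set[str]]:
    """Map each length-k peptide over standard residues to the set of
    accessions containing it (presence, not occurrence count).

    Windows containing ambiguity codes (X/B/Z/U or anything non-standard)
    are excluded: they are not reproducible sequence evidence.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    kmers: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if all(c in STANDARD_RESIDUES for c in window):
                kmers[window].add(rec.accession)
    return dict(kmers)


def build_group(
    unassigned: Sequence[ProteinRecord], params: PprParams
) -> PeptideGroup | None:
    """Extract one PPR group from the unassigned pool, or None.

    Returns the fixed point reached from the most-shared peptide seed (see
    module docstring), with family/group_id left for the caller to assign.
    None means no group of at least ``min_group_size`` members exists under
    the constraints — a valid outcome that terminates family partitioning.
    """
    if not unassigned:
        return None
    kmer_to_accs = count_kmers(unassigned, params.peptide_len)
    if not kmer_to_accs:
        return None
    acc_to_kmers: dict[str, set[str]] = defaultdict(set)
    for pep, accs in kmer_to_accs.items():
        for acc in accs:
            acc_to_kmers[acc].add(pep)

    ranked_seed = sorted(kmer_to_accs.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    peptides: set[str] = {pep for pep, _ in ranked_seed[: params.peptides_per_group]}

    members: set[str] | None = None
    for _ in range(params.max_iterations):
        candidates = {
            acc
            for acc, peps in acc_to_kmers.items()
            if len(peps & peptides) >= params.min_peptides_per_protein
        }
        if not candidates:
            return None
        if candidates == members:
            break
        members = candidates
        counts: Counter[str] = Counter()
        for acc in members:
            counts.update(acc_to_kmers[acc])
        n = len(members)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        peptides = set()
        for pep, c in ranked:
            if c / n >= params.min_peptide_frequency:
                peptides.add(pep)
                if len(peptides) == params.peptides_per_group:
                    break
        if not peptides:
            return None

    assert members is not None
    # closure prune: both invariants (member >= m peptides, freq >= floor)
    while True:
        members = {
            acc
            for acc in members
            if len(acc_to_kmers[acc] & peptides) >= params.min_peptides_per_protein
        }
        if not members:
            return None
        n = len(members)
        kept = {
            pep
            for pep in peptides
            if len(kmer_to_accs[pep] & members) / n >= params.min_peptide_frequency
        }
        if kept == peptides:
            break
        if not kept:
            return None
        peptides = kept

    if len(members) < params.min_group_size:
        return None
    n = len(members)
    freqs = {pep: len(kmer_to_accs[pep] & members) / n for pep in sorted(peptides)}
    return PeptideGroup(family="", group_id=0, peptides=freqs, members=set(members))


def partition_family(
    family_records: Sequence[ProteinRecord], family_name: str, params: PprParams
) -> list[PeptideGroup]:
    """Partition one family into PPR groups, largest first.

    Each extraction removes its members from the unassigned pool; the loop
    stops when no group of at least ``min_group_size`` proteins forms.
    Ungrouped proteins are reported via the module logger.
    """
    pool = list(family_records)
    groups: list[PeptideGroup] = []
    while pool:
        group = build_group(pool, params)
        if group is None:
            break
        group.family = family_name
        group.group_id = len(groups) + 1
        groups.append(group)
        pool = [rec for rec in pool if rec.accession not in group.members]
    logger.info(
        "%s: %d groups, %d proteins grouped, %d ungrouped",
        family_name,
        len(groups),
        sum(len(g.members) for g in groups),
        len(pool),
    )
    return groups


def assign_group_functions(
    group: PeptideGroup, records_by_accession: Mapping[str, ProteinRecord]
) -> PeptideGroup:
    """Populate per-EC function scores from the characterized members.

    For each EC number borne by at least one member, the score is the sum
    over members labeled with that EC of the number of distinct group
    peptides contained in the member's sequence. A member with several EC
    labels contributes its peptide count to each of them.
    """
    scores: dict[str, int] = defaultdict(int)
    n_characterized = 0
    for acc in group.members:
        rec = records_by_accession[acc]
        if not rec.ec_labels:
            continue
        n_characterized += 1
        n_peps = sum(1 for pep in group.peptides if pep in rec.sequence)
        for ec in rec.ec_labels:
            scores[ec] += n_peps
    group.function_scores = dict(scores)
    group.n_characterized = n_characterized
    return group


def train_bank(
    families: Mapping[str, Sequence[ProteinRecord]],
    params: PprParams,
    provenance: str = "",
) -> PatternBank:
    """Run PPR on each family and assemble a PatternBank with function
    scores attached from the members' EC labels."""
    bank = PatternBank(params=params, provenance=provenance)
    for family_name in sorted(families):
        records = families[family_name]
        by_acc = {rec.accession: rec for rec in records}
        for group in partition_family(records, family_name, params):
            assign_group_functions(group, by_acc)
            bank.add_group(group)
    bank.validate()
    return bank
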