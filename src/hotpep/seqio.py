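"""Protein sequence I/O: FASTA reading/writing, normalization, redundancy
removal and optional six-frame ORF extraction from nucleotide fragments.

Sequences are normalized on input: upper-cased, gap characters removed,
and truncated at the first stop ('*'), since downstream peptide matching
operates on predicted full-length proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Characters stripped from sequences on input (alignment gaps, whitespace).
GAP_CHARS = "-. \t"

#: The 20 standard amino acids.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Accepted amino-acid alphabet (standard + ambiguity codes + selenocysteine).
EXTENDED_RESIDUES = STANDARD_RESIDUES | frozenset("XBZU")


@dataclass
class ProteinRecord:
    """One protein sequence with a unique accession and optional EC labels.

    EC labels are strings like ``"3.2.1.8"``; partial numbers with ``"-"``
    (e.g. ``"3.2.1.-"``) are allowed.
    """

    accession: str
    sequence: str
    ec_labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.accession!r}: empty sequence")


def normalize_sequence(raw: str) -> str:
    """Upper-case, strip gap characters, truncate at the first stop ('*')."""
    seq = raw.upper()
    for ch in GAP_CHARS:
        seq = seq.replace(ch, "")
    stop = seq.find("*")
    if stop != -1:
        seq = seq[:stop]
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    The header token before the first whitespace becomes the accession.
    Raises ``ValueError`` on an empty file, a duplicate accession, or a
    record that is empty after normalization.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        seq = normalize_sequence(str(entry.seq))
        if not seq:
            raise ValueError(
                f"record {accession!r} in {path} is empty after normalization"
            )
        records.append(ProteinRecord(accession, seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (fixed line width, Unix newlines)."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def deduplicate(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Remove sequences that are 100% identical to, or an exact substring
    of, another sequence.

    When two sequences are identical the first-encountered accession
    survives and absorbs the EC labels of the removed duplicates; when one
    is a proper substring of another, the longer survives (labels of the
    removed substring record are dropped with it).

    Containment is checked against the current survivor list after sorting
    by descending length — quadratic in the worst case, which is acceptable
    at the scale of single enzyme families.
    """
    order = {rec.accession: i for i, rec in enumerate(records)}
    by_length = sorted(records, key=lambda r: (-len(r.sequence), order[r.accession]))
    survivors: list[ProteinRecord] = []
    for rec in by_length:
        absorbed = False
        for surv in survivors:
            if rec.sequence == surv.sequence:
                surv.ec_labels |= rec.ec_labels
                absorbed = True
                break
            if rec.sequence in surv.sequence:
                absorbed = True
                break
        if not absorbed:
            survivors.append(
                ProteinRecord(rec.accession, rec.sequence, set(rec.ec_labels))
            )
    kept = {rec.accession: rec for rec in survivors}
    return [kept[r.accession] for r in records if r.accession in kept]


def read_ec_table(path: str | Path, records: Sequence[ProteinRecord]) -> int:
    """Apply EC labels from a two-column TSV ``accession<TAB>EC[,EC...]``.

    Labels are added in place. Unknown accessions are ignored with a
    logged warning. Returns the number of records that received labels.
    """
    by_acc = {rec.accession: rec for rec in records}
    labeled = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed EC table line: {line!r}")
            accession, ecs = parts
            rec = by_acc.get(accession)
            if rec is None:
                logger.warning("EC table: unknown accession %r ignored", accession)
                continue
            rec.ec_labels.update(e.strip() for e in ecs.split(",") if e.strip())
            labeled += 1
    return labeled


def extract_orfs(
    nucleotide_records: Iterable[tuple[str, str]], min_len: int
) -> list[ProteinRecord]:
    """Six-frame stop-to-stop ORF translation of nucleotide fragments.

    Each stop-free segment of at least ``min_len`` residues is emitted as a
    ProteinRecord with accession ``<parent>|frame<f>|<start>-<end>`` where
    start/end are 1-based inclusive nucleotide coordinates on the forward
    strand and ``f`` is one of +1..+3 / -1..-3. ``N`` codons translate to X.
    """
    orfs: list[ProteinRecord] = []
    for parent, nt in nucleotide_records:
        nt = nt.upper()
        length = len(nt)
        rc = str(Seq(nt).reverse_complement())
        for strand, template in ((1, nt), (-1, rc)):
            for offset in range(3):
                usable = len(template) - offset
                usable -= usable % 3
                if usable < 3:
                    continue
                protein = str(Seq(template[offset : offset + usable]).translate())
                start_aa = 0
                for segment in protein.split("*"):
                    if len(segment) >= min_len:
                        # template coordinates of this stop-free segment
                        t_start = offset + 3 * start_aa + 1
                        t_end = offset + 3 * (start_aa + len(segment))
                        if strand == 1:
                            f_start, f_end = t_start, t_end
                        else:
                            f_start = length - t_end + 1
                            f_end = length - t_start + 1
                        frame = f"{'+' if strand == 1 else '-'}{offset + 1}"
                        orfs.append(
                            ProteinRecord(
                                f"{parent}|frame{frame}|{f_start}-{f_end}", segment
                            )
                        )
                    start_aa += len(segment) + 1  # skip the stop codon
    return orfs


def read_nucleotide_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a nucleotide FASTA as (accession, sequence) pairs."""
    pairs = [(e.id, str(e.seq).upper()) for e in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise ValueError(f"no sequences in {path}")
    return pairs
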