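"""Annotation run output layout: one directory per enzyme class present in
the bank, per-family hit files, per-class and top-level summaries, and
per-EC function files.

Layout written by :func:`run_annotation` under the output directory::

    summary.tsv                 family -> number of annotated proteins
    accession_families.tsv      accession -> comma-joined families
    <CLASS>/                    one per enzyme class in the bank
        summary.tsv             families of this class -> counts
        <family>.tsv            per-family hit table
        functions/
            summary.tsv         EC -> number of hits predicted with it
            EC_<number>.tsv     hits whose prediction includes this EC

Hit-file columns follow the spreadsheet convention: group, accession,
frequency score (2 decimals), peptide count, protein sequence, sequence
length, matched peptides. Function files add a ``Functions`` column with
``EC:score`` entries joined by ``;``. All outputs are TSV, UTF-8, Unix
newlines, and contain no timestamps, so identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .annotate import Annotation, AnnotationResult, annotate_collection, predict_function
from .ppr import PatternBank
from .seqio import ProteinRecord, read_fasta

logger = logging.getLogger(__name__)

#: The CAZy enzyme classes plus the carbohydrate-binding modules.
KNOWN_CLASSES = ("AA", "CBM", "CE", "GH", "GT", "PL")

HIT_COLUMNS = (
    "group",
    "accession",
    "frequency_score",
    "peptide_count",
    "protein_sequence",
    "sequence_length",
    "matched_peptides",
)


def enzyme_class(family: str) -> str:
    """Enzyme class from the family-name prefix (letters before the first
    digit): GH5 -> GH, CBM2 -> CBM; unknown prefixes map to OTHER."""
    m = re.match(r"([A-Za-z]+)", family)
    prefix = m.group(1).upper() if m else ""
    return prefix if prefix in KNOWN_CLASSES else "OTHER"


@dataclass
class RunConfig:
    fasta_path: str | Path
    bank_path: str | Path
    out_dir: str | Path
    force: bool = False


def _hit_row(hit: Annotation, sequence: str, with_functions: bool) -> str:
    fields = [
        str(hit.group_id),
        hit.accession,
        f"{hit.frequency_score:.2f}",
        str(hit.peptide_count),
        sequence,
        str(len(sequence)),
        ",".join(sorted(hit.matched_peptides)),
    ]
    if with_functions:
        ranked = predict_function(hit)
        fields.append(";".join(f"{ec}:{score}" for ec, score in ranked))
    return "\t".join(fields) + "\n"


def write_outputs(
    result: AnnotationResult,
    records: Sequence[ProteinRecord],
    bank: PatternBank,
    out_dir: str | Path,
    force: bool = False,
) -> None:
    """Write the full output tree for an annotation result."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)
    sequences = {rec.accession: rec.sequence for rec in records}

    with open(out / "summary.tsv", "w", newline="\n") as fh:
        fh.write("family\thits\n")
        for family in sorted(result.family_counts):
            fh.write(f"{family}\t{result.family_counts[family]}\n")

    with open(out / "accession_families.tsv", "w", newline="\n") as fh:
        fh.write("accession\tfamilies\n")
        for accession, families in result.accession_families.items():
            fh.write(f"{accession}\t{','.join(families)}\n")

    hits_by_family: dict[str, list[Annotation]] = {}
    for hit in result.annotations:
        hits_by_family.setdefault(hit.family, []).append(hit)

    bank_classes = sorted({enzyme_class(f) for f in bank.families()})
    for cls in bank_classes:
        cls_dir = out / cls
        (cls_dir / "functions").mkdir(parents=True, exist_ok=True)
        cls_families = sorted(
            f for f in result.family_counts if enzyme_class(f) == cls
        )
        with open(cls_dir / "summary.tsv", "w", newline="\n") as fh:
            fh.write("family\thits\n")
            for family in cls_families:
                fh.write(f"{family}\t{result.family_counts[family]}\n")
        ec_hits: dict[str, list[Annotation]] = {}
        for family in cls_families:
            hits = hits_by_family[family]
            with open(cls_dir / f"{family}.tsv", "w", newline="\n") as fh:
                fh.write("\t".join(HIT_COLUMNS) + "\n")
                for hit in hits:
                    fh.write(_hit_row(hit, sequences[hit.accession], False))
            for hit in hits:
                for ec in hit.predicted_functions:
                    ec_hits.setdefault(ec, []).append(hit)
        with open(cls_dir / "functions" / "summary.tsv", "w", newline="\n") as fh:
            fh.write("ec\thits\n")
            for ec in sorted(ec_hits):
                fh.write(f"{ec}\t{len(ec_hits[ec])}\n")
        for ec, hits in sorted(ec_hits.items()):
            path = cls_dir / "functions" / f"EC_{ec.replace('.', '_')}.tsv"
            with open(path, "w", newline="\n") as fh:
                fh.write("\t".join(HIT_COLUMNS) + "\tFunctions\n")
                for hit in hits:
                    fh.write(_hit_row(hit, sequences[hit.accession], True))


def run_annotation(config: RunConfig) -> AnnotationResult:
    """Full annotation run: load bank and FASTA, annotate, write outputs."""
    started = time.monotonic()
    bank_path = Path(config.bank_path)
    if not bank_path.exists():
        raise FileNotFoundError(f"pattern bank not found: {bank_path}")
    bank = PatternBank.load(bank_path)
    records = read_fasta(config.fasta_path)
    result = annotate_collection(records, bank)
    write_outputs(result, records, bank, config.out_dir, force=config.force)
    logger.info(
        "annotated %d of %d proteins (%d family hits) in %.1f s",
        len(result.accession_families),
        len(records),
        len(result.annotations),
        time.monotonic() - started,
    )
    return result
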