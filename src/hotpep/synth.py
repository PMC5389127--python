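"""Synthetic enzyme families with planted conserved hexapeptide motifs.

The generator emulates the statistical structure the discovery and
annotation stages assume: a family is a set of proteins that share a core
of short motifs, each motif carried by a member with a fixed probability
(the in-family motif frequency), embedded at random non-overlapping
positions in otherwise random background sequence. A labeled subset of
members carries an EC number, and unrelated pure-background decoys provide
negatives.

By default motifs and background are drawn over disjoint residue subsets,
so a planted motif occurs in a member's sequence *iff* the generator's
Bernoulli draw said so — planted-recovery tests are exact bookkeeping. A
full-alphabet background ("hard mode") is available for stress testing,
where such assertions become statistical.

One pseudo-random stream is derived per (seed, family name, role), so
adding a family or changing the query set never perturbs another family's
sequences.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import ProteinRecord, write_fasta

#: Disjoint residue subsets (10 + 10 of the 20 standard amino acids).
MOTIF_ALPHABET = "ACDEFGHIKL"
BACKGROUND_ALPHABET = "MNPQRSTVWY"
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthFamilySpec:
    """Parameters of one synthetic family.

    Defaults describe a comfortably learnable family under the standard
    discovery parameters (10-of-70 hexapeptides at frequency floor 0.20):
    20 members of 300 residues sharing 30 planted hexapeptide motifs, each
    carried with probability 0.75, so a member carries ~22 motifs.
    """

    name: str
    n_members: int = 20
    n_motifs: int = 30
    motif_frequency: float = 0.75
    seq_len: int = 300
    peptide_len: int = 6
    background_alphabet: str = BACKGROUND_ALPHABET
    motif_alphabet: str = MOTIF_ALPHABET
    ec_label: str | None = None
    labeled_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_motifs * self.peptide_len > self.seq_len:
            raise ValueError("n_motifs * peptide_len must be <= seq_len")
        if not 0 <= self.motif_frequency <= 1:
            raise ValueError("motif_frequency must be in [0, 1]")
        if not 0 <= self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in [0, 1]")


@dataclass
class FamilyTruth:
    """Generated members plus exact ground-truth bookkeeping."""

    spec: SynthFamilySpec
    records: list[ProteinRecord]
    motifs: list[str]
    #: accession -> set of planted motifs the Bernoulli draws inserted
    presence: dict[str, set[str]] = field(default_factory=dict)


def _rng(*entries: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([e % 2**31 for e in entries]))


def _family_rng(spec: SynthFamilySpec, *extra: int) -> np.random.Generator:
    return _rng(spec.seed, zlib.crc32(spec.name.encode()), *extra)


def _sample_motifs(spec: SynthFamilySpec) -> list[str]:
    """Distinct hexapeptides over the motif alphabet, family-level stream."""
    rng = _family_rng(spec, 0)
    alphabet = np.array(list(spec.motif_alphabet))
    motifs: list[str] = []
    seen: set[str] = set()
    while len(motifs) < spec.n_motifs:
        motif = "".join(rng.choice(alphabet, size=spec.peptide_len))
        if motif not in seen:
            seen.add(motif)
            motifs.append(motif)
    return motifs


def _random_background(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(np.array(list(alphabet)), size=length)) if length else ""


def generate_family(spec: SynthFamilySpec, role: str = "") -> FamilyTruth:
    """Generate one family, fully reproducible from (spec.seed, name, role).

    Each member is i.i.d. background with each planted motif inserted
    (Bernoulli(motif_frequency) per member per motif) at non-overlapping
    random positions separated by at least one background residue.
    """
    motifs = _sample_motifs(spec)
    rng = _family_rng(spec, 1, zlib.crc32(role.encode()))
    n_labeled = round(spec.labeled_fraction * spec.n_members)
    labeled_idx = (
        set(rng.choice(spec.n_members, size=n_labeled, replace=False).tolist())
        if n_labeled
        else set()
    )
    prefix = f"{spec.name}_{role}" if role else f"{spec.name}_"
    records: list[ProteinRecord] = []
    presence: dict[str, set[str]] = {}
    for i in range(spec.n_members):
        draws = rng.random(spec.n_motifs) < spec.motif_frequency
        chosen = [m for m, hit in zip(motifs, draws) if hit]
        bg_len = spec.seq_len - spec.peptide_len * len(chosen)
        if bg_len + 1 < len(chosen):
            raise ValueError(
                f"{spec.name}: infeasible insertion of {len(chosen)} motifs "
                f"into {spec.seq_len} residues"
            )
        background = _random_background(rng, spec.background_alphabet, bg_len)
        # distinct insertion points guarantee >= 1 background residue
        # between consecutive motifs, so no spurious motif copies arise
        points = np.sort(rng.choice(bg_len + 1, size=len(chosen), replace=False))
        order = rng.permutation(len(chosen))
        parts: list[str] = []
        prev = 0
        for point, j in zip(points, order):
            parts.append(background[prev:point])
            parts.append(chosen[j])
            prev = point
        parts.append(background[prev:])
        sequence = "".join(parts)
        assert len(sequence) == spec.seq_len
        accession = f"{prefix}{i + 1:04d}"
        ec = {spec.ec_label} if (spec.ec_label and i in labeled_idx) else set()
        records.append(ProteinRecord(accession, sequence, ec))
        presence[accession] = set(chosen)
    return FamilyTruth(spec=spec, records=records, motifs=motifs, presence=presence)


@dataclass
class Benchmark:
    """Disjoint training and query sets plus the ground-truth table."""

    training: dict[str, FamilyTruth]  # family name -> training members
    queries: list[ProteinRecord]  # fresh family members + decoys
    truth: pd.DataFrame  # columns: accession, family, ec

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        training = [r for t in self.training.values() for r in t.records]
        write_fasta(training, out / "training.fasta")
        write_fasta(self.queries, out / "query.fasta")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "training_ec.tsv", "w", newline="\n") as fh:
            for rec in training:
                if rec.ec_labels:
                    fh.write(f"{rec.accession}\t{','.join(sorted(rec.ec_labels))}\n")
        with open(out / "motifs.tsv", "w", newline="\n") as fh:
            fh.write("family\tmotif\n")
            for name in sorted(self.training):
                for motif in self.training[name].motifs:
                    fh.write(f"{name}\t{motif}\n")


def generate_benchmark(
    specs: Sequence[SynthFamilySpec],
    n_negatives: int,
    seed: int,
    decoy_len: int | None = None,
) -> Benchmark:
    """Training families, a disjoint query set drawn from the same specs
    (fresh members, same motifs), and pure-background decoys.

    The truth table maps each query accession to its family (empty for
    decoys) and EC label, ready for end-to-end evaluation.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("family names must be unique")
    training: dict[str, FamilyTruth] = {}
    queries: list[ProteinRecord] = []
    rows: list[dict[str, str]] = []
    for spec in specs:
        spec = replace(spec, seed=seed + spec.seed)
        training[spec.name] = generate_family(spec, role="t")
        query_truth = generate_family(spec, role="q")
        for rec in query_truth.records:
            queries.append(rec)
            rows.append(
                {
                    "accession": rec.accession,
                    "family": spec.name,
                    "ec": spec.ec_label or "",
                }
            )
    decoy_len = decoy_len or max(s.seq_len for s in specs)
    decoy_alphabet = specs[0].background_alphabet
    rng = _rng(seed, 0xDEC0)
    for i in range(n_negatives):
        seq = _random_background(rng, decoy_alphabet, decoy_len)
        acc = f"decoy_{i + 1:04d}"
        queries.append(ProteinRecord(acc, seq))
        rows.append({"accession": acc, "family": "", "ec": ""})
    truth = pd.DataFrame(rows, columns=["accession", "family", "ec"])
    return Benchmark(training=training, queries=queries, truth=truth)
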