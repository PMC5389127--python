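"""Peptide Pattern Recognition: k-mer counting, group extraction, family
partitioning, function assignment and bank serialization."""

import itertools

import pytest

from hotpep.ppr import (
    CBM_PRESET,
    ENZYME_PRESET,
    PatternBank,
    PeptideGroup,
    PprParams,
    assign_group_functions,
    build_group,
    count_kmers,
    partition_family,
)
from hotpep.seqio import ProteinRecord
from hotpep.synth import (
    BACKGROUND_ALPHABET,
    MOTIF_ALPHABET,
    SynthFamilySpec,
    generate_family,
)


def hexamers(n, alphabet=MOTIF_ALPHABET):
    """n distinct hexapeptides, deterministic."""
    return ["".join(p) for p in itertools.islice(itertools.product(alphabet, repeat=6), n)]


class TestCountKmers:
    def test_window_enumeration(self):
        kmers = count_kmers([ProteinRecord("a", "MKLGHTC")], k=6)
        assert kmers == {"MKLGHT": {"a"}, "KLGHTC": {"a"}}

    def test_ambiguous_windows_excluded(self):
        # every hexamer window of this sequence overlaps the X
        assert count_kmers([ProteinRecord("a", "MKXLGHTC")], k=6) == {}

    def test_presence_not_occurrence(self):
        records = [
            ProteinRecord("a", "MKLGHTMKLGHT"),  # peptide occurs twice
            ProteinRecord("b", "WMKLGHTW"),
        ]
        kmers = count_kmers(records, k=6)
        assert kmers["MKLGHT"] == {"a", "b"}


class TestBuildGroup:
    def test_planted_core_recovered_exactly(self):
        spec = SynthFamilySpec(
            name="fam", n_members=6, n_motifs=12, motif_frequency=1.0, seq_len=120, seed=3
        )
        truth = generate_family(spec)
        decoys = [
            ProteinRecord("neg1", "MNPQRSTVWY" * 12),
            ProteinRecord("neg2", "YWVTSRQPNM" * 12),
        ]
        group = build_group(truth.records + decoys, ENZYME_PRESET)
        assert group is not None
        assert group.members == {r.accession for r in truth.records}
        for motif in truth.motifs:
            assert group.peptides[motif] == 1.0
        # brute-force: every member contains >= m of the returned peptides,
        # and no excluded protein qualifies
        m = ENZYME_PRESET.min_peptides_per_protein
        for rec in truth.records:
            assert sum(1 for p in group.peptides if p in rec.sequence) >= m
        for rec in decoys:
            assert sum(1 for p in group.peptides if p in rec.sequence) < m

    def test_below_size_floor_yields_nothing(self):
        spec = SynthFamilySpec(
            name="fam", n_members=3, n_motifs=12, motif_frequency=1.0, seq_len=120, seed=4
        )
        assert build_group(generate_family(spec).records, ENZYME_PRESET) is None

    def test_no_shared_peptides_yields_nothing(self):
        records = [ProteinRecord(f"r{i}", ch * 30) for i, ch in enumerate("MNPQRS")]
        assert build_group(records, ENZYME_PRESET) is None


class TestPartitionFamily:
    # N=12 conserved peptides per group so the seed locks onto one
    # subfamily's 12 motifs at a time
    params = PprParams(peptides_per_group=12, min_peptides_per_protein=10)

    def make_subfamilies(self):
        spec_a = SynthFamilySpec(
            name="subA", n_members=8, n_motifs=12, motif_frequency=1.0, seq_len=120, seed=11
        )
        spec_b = SynthFamilySpec(
            name="subB", n_members=6, n_motifs=12, motif_frequency=1.0, seq_len=120, seed=12
        )
        a, b = generate_family(spec_a), generate_family(spec_b)
        assert not set(a.motifs) & set(b.motifs)
        decoys = [
            ProteinRecord(f"neg{i}", (BACKGROUND_ALPHABET * 12)[i : i + 110])
            for i in range(3)
        ]
        return a, b, decoys

    def test_two_disjoint_subfamilies_split_in_size_order(self):
        a, b, decoys = self.make_subfamilies()
        records = a.records + b.records + decoys
        groups = partition_family(records, "GH5", self.params)
        assert [len(g.members) for g in groups] == [8, 6]
        assert groups[0].members == {r.accession for r in a.records}
        assert groups[1].members == {r.accession for r in b.records}
        assert [g.group_id for g in groups] == [1, 2]
        # monotone stop: extracted sizes are non-increasing
        sizes = [len(g.members) for g in groups]
        assert sizes == sorted(sizes, reverse=True)

    def test_too_few_proteins_yields_empty(self):
        spec = SynthFamilySpec(
            name="fam", n_members=4, n_motifs=12, motif_frequency=1.0, seq_len=120, seed=5
        )
        assert partition_family(generate_family(spec).records, "GH5", ENZYME_PRESET) == []

    def test_homogeneous_family_is_one_group(self):
        spec = SynthFamilySpec(name="fam", n_members=20, seed=6)
        truth = generate_family(spec)
        groups = partition_family(truth.records, "GH5", ENZYME_PRESET)
        assert len(groups) == 1
        assert groups[0].members == {r.accession for r in truth.records}

    def test_planted_recovery_above_ninety_percent(self):
        """Parameter recovery on learnable synthetic families: >= 90% of
        planted members grouped correctly and >= 90% of planted motifs on
        the learned peptide list."""
        total_members = recovered_members = 0
        total_motifs = recovered_motifs = 0
        for i, name in enumerate(["GH10", "GH11", "CE1"]):
            truth = generate_family(SynthFamilySpec(name=name, seed=20 + i))
            groups = partition_family(truth.records, name, ENZYME_PRESET)
            assert groups
            top = groups[0]
            accs = {r.accession for r in truth.records}
            total_members += len(accs)
            recovered_members += len(top.members & accs)
            total_motifs += len(truth.motifs)
            recovered_motifs += sum(1 for m in truth.motifs if m in top.peptides)
        assert recovered_members / total_members >= 0.90
        assert recovered_motifs / total_motifs >= 0.90


def test_group_invariants_hold_on_trained_bank(bank):
    """Frequencies are exact member ratios, sizes and per-member peptide
    counts respect the discovery parameters, members are disjoint."""
    params = bank.params
    bank.validate()  # disjointness + consecutive ids
    for (family, gid), group in bank.groups.items():
        n = len(group.members)
        assert n >= params.min_group_size
        assert len(group.peptides) <= params.peptides_per_group
        for freq in group.peptides.values():
            assert params.min_peptide_frequency <= freq <= 1.0
            assert abs(freq * n - round(freq * n)) < 1e-9  # exact integer ratio


class TestAssignFunctions:
    def make_group(self, n_peptides=10):
        peps = hexamers(n_peptides)
        return PeptideGroup(
            "GH43", 1, {p: 1.0 for p in peps}, set()
        ), peps

    def member(self, acc, peps, ecs=()):
        return ProteinRecord(acc, "W".join(peps), set(ecs))

    def test_single_member_sum(self):
        group, peps = self.make_group()
        rec = self.member("a", peps, {"3.2.1.8"})
        group.members = {"a"}
        assign_group_functions(group, {"a": rec})
        assert group.function_scores == {"3.2.1.8": 10}
        assert group.n_characterized == 1

    def test_additivity_over_members(self):
        group, peps = self.make_group()
        a = self.member("a", peps, {"3.2.1.8"})  # all 10
        b = self.member("b", peps[:8], {"3.2.1.8"})  # 8 of 10
        group.members = {"a", "b"}
        assign_group_functions(group, {"a": a, "b": b})
        assert group.function_scores == {"3.2.1.8": 18}

    def test_multilabel_member_counts_toward_each_ec(self):
        group, peps = self.make_group()
        a = self.member("a", peps[:7], {"3.2.1.8", "3.2.1.4"})
        b = self.member("b", peps[:5], {"3.2.1.8"})
        c = self.member("c", peps)  # uncharacterized
        group.members = {"a", "b", "c"}
        assign_group_functions(group, {"a": a, "b": b, "c": c})
        # brute-force recount
        expected = {"3.2.1.8": 7 + 5, "3.2.1.4": 7}
        assert group.function_scores == expected
        assert group.n_characterized == 2

    def test_uncharacterized_group_gets_empty_scores(self):
        group, peps = self.make_group()
        rec = self.member("a", peps)
        group.members = {"a"}
        assign_group_functions(group, {"a": rec})
        assert group.function_scores == {}


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"peptide_len": 2},
            {"min_peptides_per_protein": 80},
            {"min_peptide_frequency": 0.0},
            {"min_peptide_frequency": 1.5},
            {"min_group_size": 1},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PprParams(**kwargs)

    def test_cbm_preset(self):
        assert CBM_PRESET.peptides_per_group == 30
        assert CBM_PRESET.min_peptides_per_protein == 3
        assert CBM_PRESET.peptide_len == 6


def test_bank_round_trip(bank, tmp_path):
    path = tmp_path / "bank.tsv"
    bank.save(path)
    loaded = PatternBank.load(path)
    assert loaded.params == bank.params
    assert loaded.provenance == bank.provenance
    assert set(loaded.groups) == set(bank.groups)
    for key, group in bank.groups.items():
        other = loaded.groups[key]
        assert other.members == group.members
        assert other.function_scores == group.function_scores
        assert other.n_characterized == group.n_characterized
        assert set(other.peptides) == set(group.peptides)
        for pep, freq in group.peptides.items():
            assert other.peptides[pep] == pytest.approx(freq, abs=5e-7)
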