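"""Cohort construction: parsing, mutation application, synthesis."""

import numpy as np
import pytest

from mutscan import (
    GeneSequence,
    LabeledDataset,
    MutationRecord,
    SyntheticCohortConfig,
    apply_mutations,
    build_labeled_dataset,
    deduplicate,
    generate_mutated_sequences,
    generate_synthetic_cohort,
    parse_mutation_records,
    read_fasta,
    write_fasta,
    write_mutation_table,
)
from mutscan.errors import (
    ConflictError,
    ConsistencyError,
    DatasetError,
    FastaParseError,
    MutationTableError,
    ParameterError,
    SequenceValidationError,
)


class TestReadFasta:
    def test_basic_parse(self, fasta_file):
        path = fasta_file([("g1", "ACGT"), ("g2", "TTAA")])
        seqs = read_fasta(path)
        assert [s.id for s in seqs] == ["g1", "g2"]
        assert [len(s) for s in seqs] == [4, 4]
        assert all(s.label is None for s in seqs)

    def test_case_normalization(self, fasta_file):
        (seq,) = read_fasta(fasta_file([("g1", "acgt")]))
        assert seq.residues == "ACGT"

    def test_empty_record_rejected(self, fasta_file):
        with pytest.raises(FastaParseError, match="g1"):
            read_fasta(fasta_file([("g1", "")]))

    def test_u_mapped_to_t_with_warning(self, fasta_file):
        with pytest.warns(UserWarning, match="U"):
            (seq,) = read_fasta(fasta_file([("g1", "ACGU")]))
        assert seq.residues == "ACGT"

    def test_bad_alphabet_rejected(self, fasta_file):
        with pytest.raises(SequenceValidationError):
            read_fasta(fasta_file([("g1", "ACGX")]))

    def test_multiline_and_roundtrip(self, tmp_path):
        path = tmp_path / "wrapped.fasta"
        path.write_text(">g1 some description\nACG\nTAC\n")
        (seq,) = read_fasta(path)
        assert seq.id == "g1"  # token before whitespace
        assert seq.residues == "ACGTAC"
        out = tmp_path / "out.fasta"
        write_fasta([seq], out)
        assert read_fasta(out)[0].residues == "ACGTAC"


class TestMutationTable:
    def test_parse_and_reject(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "gene\tposition\tref\talt\n"
            "g1\t2\tC\tT\n"
            "g1\t2\tC\tC\n"  # ref == alt
            "g1\t0\tC\tT\n"  # position out of range
        )
        with pytest.warns(UserWarning, match="rejected 2"):
            records = parse_mutation_records(path)
        assert records == [MutationRecord("g1", 2, "C", "T")]

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "muts.csv"
        path.write_text("gene,pos,ref,alt\ng1,2,C,T\n")
        with pytest.raises(MutationTableError, match="position"):
            parse_mutation_records(path)

    def test_strict_mode_raises(self, tmp_path):
        path = tmp_path / "muts.csv"
        path.write_text("gene,position,ref,alt\ng1,2,C,C\n")
        with pytest.raises(MutationTableError, match="ref equals alt"):
            parse_mutation_records(path, strict=True)

    def test_tsv_roundtrip(self, tmp_path):
        records = [MutationRecord("g1", 2, "C", "T"), MutationRecord("g2", 5, "A", "G")]
        path = tmp_path / "out.tsv"
        write_mutation_table(records, path)
        assert parse_mutation_records(path) == records

    def test_record_invariants(self):
        with pytest.raises(ParameterError):
            MutationRecord("g", 1, "C", "C")
        with pytest.raises(ParameterError):
            MutationRecord("g", 0, "C", "T")
        with pytest.raises(ParameterError):
            MutationRecord("g", 1, "N", "T")


class TestApplyMutations:
    def setup_method(self):
        self.ref = GeneSequence("g1", "ACGT")

    def test_single_substitution(self):
        mut = apply_mutations(self.ref, [MutationRecord("g1", 2, "C", "T")])
        assert mut.residues == "ATGT"
        assert mut.label == "mutated"
        assert self.ref.residues == "ACGT"  # reference untouched

    def test_multiple_and_order_independence(self):
        recs = [MutationRecord("g1", 2, "C", "T"), MutationRecord("g1", 4, "T", "A")]
        assert apply_mutations(self.ref, recs).residues == "ATGA"
        assert apply_mutations(self.ref, recs[::-1]).residues == "ATGA"

    def test_ref_allele_mismatch(self):
        with pytest.raises(ConsistencyError, match="position 3"):
            apply_mutations(self.ref, [MutationRecord("g1", 3, "A", "T")])

    def test_wrong_gene_and_out_of_range(self):
        with pytest.raises(ConsistencyError):
            apply_mutations(self.ref, [MutationRecord("g2", 2, "C", "T")])
        with pytest.raises(ConsistencyError):
            apply_mutations(self.ref, [MutationRecord("g1", 9, "C", "T")])

    def test_conflicting_duplicates(self):
        recs = [MutationRecord("g1", 2, "C", "T"), MutationRecord("g1", 2, "C", "G")]
        with pytest.raises(ConflictError):
            apply_mutations(self.ref, recs)

    def test_per_record_vs_combined(self):
        recs = [MutationRecord("g1", 2, "C", "T"), MutationRecord("g1", 4, "T", "A")]
        per = generate_mutated_sequences([self.ref], recs, mode="per_record")
        assert [s.residues for s in per] == ["ATGT", "ACGA"]
        (combined,) = generate_mutated_sequences([self.ref], recs, mode="combined")
        assert combined.residues == "ATGA"

    def test_round_trip_and_hamming(self, rng):
        """Inverse records restore the reference; Hamming = #mutated sites."""
        cfg = SyntheticCohortConfig(n_genes=30, mutations_per_gene=3, seed=5)
        dataset, records = generate_synthetic_cohort(cfg)
        by_gene = {}
        for r in records:
            by_gene.setdefault(r.gene_id, []).append(r)
        normals = {s.id: s for s in dataset.sequences if s.label == "normal"}
        mutateds = {s.id: s for s in dataset.sequences if s.label == "mutated"}
        for gid, recs in by_gene.items():
            ref, mut = normals[gid], mutateds[gid + "_mut"]
            hamming = sum(a != b for a, b in zip(ref.residues, mut.residues))
            assert hamming == len({r.position for r in recs})
            inverse = [
                MutationRecord(gid + "_mut", r.position, r.alt, r.ref) for r in recs
            ]
            restored = apply_mutations(mut, inverse)
            assert restored.residues == ref.residues


class TestDeduplicate:
    def test_exact_collapse_within_label(self):
        seqs = [
            GeneSequence("g1", "ACGT", label="normal"),
            GeneSequence("g2", "ACGT", label="normal"),
            GeneSequence("g3", "TTTT", label="normal"),
        ]
        kept = deduplicate(seqs)
        assert [s.id for s in kept] == ["g1", "g3"]

    def test_labels_are_strata(self):
        seqs = [
            GeneSequence("g1", "ACGT", label="normal"),
            GeneSequence("g2", "ACGT", label="mutated"),
        ]
        assert len(deduplicate(seqs)) == 2

    def test_threshold_identity_case(self):
        seqs = [
            GeneSequence("g1", "ACGTACGT", label="normal"),
            GeneSequence("g2", "TGCATGCA", label="normal"),
        ]
        assert deduplicate(seqs, threshold=1.0) == seqs

    def test_threshold_clusters_near_duplicates(self):
        seqs = [
            GeneSequence("g1", "ACGTACGTAC", label="normal"),
            GeneSequence("g2", "ACGTACGTAA", label="normal"),  # 90% identity
            GeneSequence("g3", "GGGGGGGGGG", label="normal"),
        ]
        kept = deduplicate(seqs, threshold=0.8)
        assert [s.id for s in kept] == ["g1", "g3"]

    def test_idempotent(self, small_cohort):
        dataset, _ = small_cohort
        once = deduplicate(dataset.sequences, threshold=0.9)
        twice = deduplicate(once, threshold=0.9)
        assert once == twice

    def test_bad_threshold(self):
        with pytest.raises(ParameterError):
            deduplicate([], threshold=0.0)


class TestLabeledDataset:
    def test_build_and_counts(self):
        normals = [GeneSequence("a", "ACGT"), GeneSequence("b", "AAAA"),
                   GeneSequence("c", "CCCC")]
        mutateds = [GeneSequence("a", "ATGT"), GeneSequence("b", "AATA")]
        ds = build_labeled_dataset(normals, mutateds)
        assert len(ds) == 5
        assert ds.class_counts == {"normal": 3, "mutated": 2}
        np.testing.assert_array_equal(ds.labels(), [0, 0, 0, 1, 1])

    def test_empty_class_rejected(self):
        with pytest.raises(DatasetError):
            build_labeled_dataset([], [GeneSequence("a", "ACGT")])

    def test_duplicate_ids_within_label_rejected(self):
        dup = [GeneSequence("a", "ACGT"), GeneSequence("a", "AAAA")]
        with pytest.raises(DatasetError, match="a"):
            build_labeled_dataset(dup, [GeneSequence("b", "ATTT")])


class TestSyntheticCohort:
    def test_seeded_reproducibility(self):
        cfg = SyntheticCohortConfig(n_genes=5, length_range=(50, 60),
                                    mutations_per_gene=2, seed=7)
        d1, r1 = generate_synthetic_cohort(cfg)
        d2, r2 = generate_synthetic_cohort(cfg)
        assert [s.residues for s in d1.sequences] == [s.residues for s in d2.sequences]
        assert r1 == r2

    def test_zero_mutations_no_signal(self):
        cfg = SyntheticCohortConfig(n_genes=4, mutations_per_gene=0, seed=1)
        dataset, records = generate_synthetic_cohort(cfg)
        assert records == []
        normals = {s.id: s for s in dataset.sequences if s.label == "normal"}
        for s in dataset.sequences:
            if s.label == "mutated":
                assert s.residues == normals[s.id[: -len("_mut")]].residues

    def test_records_satisfy_apply_preconditions(self, small_cohort):
        dataset, records = small_cohort
        normals = {s.id: s for s in dataset.sequences if s.label == "normal"}
        by_gene = {}
        for r in records:
            by_gene.setdefault(r.gene_id, []).append(r)
        for gid, recs in by_gene.items():
            apply_mutations(normals[gid], recs)  # must not raise

    def test_motif_present_at_full_strength(self, signal_cohort):
        dataset, _ = signal_cohort
        motif = SyntheticCohortConfig().motif
        for s in dataset.sequences:
            if s.label == "mutated":
                assert motif in s.residues
            else:
                assert motif not in s.residues  # overwhelmingly unlikely by chance

    def test_biased_substitution_only_transitions(self):
        cfg = SyntheticCohortConfig(
            n_genes=20, signal_mode="biased_substitution", signal_strength=1.0, seed=3
        )
        _, records = generate_synthetic_cohort(cfg)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        assert all((r.ref, r.alt) in transitions for r in records)

    def test_invalid_configs(self):
        with pytest.raises(ParameterError):
            SyntheticCohortConfig(length_range=(10, 5))
        with pytest.raises(ParameterError):
            SyntheticCohortConfig(length_range=(10, 20), mutations_per_gene=11)
        with pytest.raises(ParameterError):
            SyntheticCohortConfig(signal_strength=1.5)
        with pytest.raises(ParameterError):
            SyntheticCohortConfig(signal_mode="sideways")
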