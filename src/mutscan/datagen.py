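"""Cohort construction: sequences, point mutations, synthetic data.

The classification task is normal-vs-mutated gene sequences.  Reference
(normal) sequences come from FASTA; mutation records come from a delimited
table with columns ``gene,position,ref,alt`` (1-based positions, single
nucleotide substitutions).  Mutated sequences are *generated* by applying the
tabulated substitutions to the references — the reference allele is verified
at every site, and a mismatch is a hard error rather than a silent overwrite,
because a mislabeled training example is worse than a missing one.

A seeded synthetic-cohort generator stands in for real cohorts at desk scale.
It draws uniform-random references, applies random valid point mutations, and
can implant a class-separating signal (a fixed motif, or a biased
substitution pattern) into the mutated class with configurable strength.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    ConflictError,
    ConsistencyError,
    DatasetError,
    FastaParseError,
    MutationTableError,
    ParameterError,
    SequenceValidationError,
)

ALPHABET = "ACGTN"
NUCLEOTIDES = "ACGT"

LABEL_NORMAL = "normal"
LABEL_MUTATED = "mutated"
_LABELS = (LABEL_NORMAL, LABEL_MUTATED)
_SOURCES = ("file", "generated", "synthetic")

#: fixed CpG-repeat 16-mer implanted by the motif signal mode.  The motif is
#: a substantial fraction of a default-length sequence (50-60 nt) with an
#: extreme composition, so at full strength it is a genuinely
#: class-separating signal both in the token stream and in global
#: composition/moment feature space.
DEFAULT_MOTIF = "GCGCGCGCGCGCGCGC"

#: transition partners used by the biased_substitution signal mode
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class GeneSequence:
    """An identified nucleotide string with a class label and provenance.

    ``label`` is ``None`` until the sequence is assigned to a class (for
    instance by :func:`build_labeled_dataset`).
    """

    id: str
    residues: str
    label: str | None = None
    source: str = "file"

    def __post_init__(self):
        if not self.id:
            raise SequenceValidationError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceValidationError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise SequenceValidationError(
                f"sequence {self.id!r}: characters outside {{A,C,G,T,N}}: "
                f"{sorted(bad)}"
            )
        if self.label is not None and self.label not in _LABELS:
            raise SequenceValidationError(
                f"sequence {self.id!r}: unknown label {self.label!r}"
            )
        if self.source not in _SOURCES:
            raise SequenceValidationError(
                f"sequence {self.id!r}: unknown source {self.source!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def with_label(self, label: str) -> "GeneSequence":
        return replace(self, label=label)


@dataclass(frozen=True)
class MutationRecord:
    """One point substitution: gene, 1-based position, ref allele, alt allele."""

    gene_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.position < 1:
            raise ParameterError(
                f"{self.gene_id}: position {self.position} out of range (1-based)"
            )
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if allele not in NUCLEOTIDES:
                raise ParameterError(
                    f"{self.gene_id} pos {self.position}: {name} allele "
                    f"{allele!r} not a single nucleotide in {{A,C,G,T}}"
                )
        if self.ref == self.alt:
            raise ParameterError(
                f"{self.gene_id} pos {self.position}: ref equals alt ({self.ref})"
            )

    def inverse(self) -> "MutationRecord":
        """The substitution that undoes this one (alt -> ref)."""
        return MutationRecord(self.gene_id, self.position, self.alt, self.ref)


@dataclass
class LabeledDataset:
    """An ordered collection of labeled sequences with per-class counts."""

    sequences: list[GeneSequence]
    class_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        counts = Counter(s.label for s in self.sequences)
        if None in counts:
            raise DatasetError("dataset contains unlabeled sequences")
        for label in _LABELS:
            if counts.get(label, 0) == 0:
                raise DatasetError(f"dataset has no {label!r} sequences")
        for label in _LABELS:
            ids = [s.id for s in self.sequences if s.label == label]
            dup = [i for i, n in Counter(ids).items() if n > 1]
            if dup:
                raise DatasetError(
                    f"duplicate ids within label {label!r}: {sorted(dup)}"
                )
        self.class_counts = dict(counts)

    def __len__(self) -> int:
        return len(self.sequences)

    def labels(self) -> np.ndarray:
        """Binary labels, positive class = mutated."""
        return np.array(
            [1 if s.label == LABEL_MUTATED else 0 for s in self.sequences],
            dtype=np.int64,
        )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Stated world of the synthetic generator.

    Defaults: 100 genes of 50-60 nt (short desk-scale genes that fit the
    models' fixed 64-token window) with 2 point mutations each and no
    class-separating signal beyond the mutations themselves.
    """

    n_genes: int = 100
    length_range: tuple[int, int] = (50, 60)
    mutations_per_gene: int = 2
    signal_mode: str = "none"  # none | motif | biased_substitution
    signal_strength: float = 0.0
    motif: str = DEFAULT_MOTIF
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        if lo < 1 or hi < lo:
            raise ParameterError(f"invalid length_range {self.length_range}")
        if self.mutations_per_gene < 0:
            raise ParameterError("mutations_per_gene must be non-negative")
        if self.mutations_per_gene > lo:
            raise ParameterError(
                f"mutations_per_gene={self.mutations_per_gene} exceeds the "
                f"minimum sequence length {lo}"
            )
        if self.signal_mode not in ("none", "motif", "biased_substitution"):
            raise ParameterError(f"unknown signal_mode {self.signal_mode!r}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ParameterError("signal_strength must lie in [0, 1]")
        if self.signal_mode == "motif":
            if not self.motif or set(self.motif) - set(NUCLEOTIDES):
                raise ParameterError("motif must be a non-empty ACGT string")
            if len(self.motif) > lo:
                raise ParameterError("motif longer than the minimum sequence length")


# ---------------------------------------------------------------------------
# File readers / writers


def read_fasta(path: str | Path, source: str = "file") -> list[GeneSequence]:
    """Read FASTA records as unlabeled :class:`GeneSequence` objects.

    The header token before the first whitespace becomes the id; residues are
    uppercased; ``U`` is mapped to ``T`` with a warning (RNA-dialect FASTA).
    Characters outside {A,C,G,T,N,U} raise :class:`SequenceValidationError`;
    an empty record raises :class:`FastaParseError` naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    out: list[GeneSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if not rec.id:
            raise FastaParseError(f"{path}: record without header id")
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if "U" in residues:
            warnings.warn(
                f"{path}: record {rec.id!r} contains 'U'; mapping U->T",
                stacklevel=2,
            )
            residues = residues.replace("U", "T")
        try:
            out.append(GeneSequence(rec.id, residues, source=source))
        except SequenceValidationError as exc:
            raise SequenceValidationError(f"{path}: {exc}") from exc
    if not out and path.stat().st_size > 0:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Iterable[GeneSequence], path: str | Path) -> None:
    """Write sequences single-line (one header line, one residue line)."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def parse_mutation_records(
    path: str | Path, strict: bool = False
) -> list[MutationRecord]:
    """Parse a delimited mutation table into :class:`MutationRecord` objects.

    The table must have a header with columns ``gene``, ``position``, ``ref``
    and ``alt`` (comma- or tab-delimited, sniffed automatically).  Rows that
    violate the record invariants (position < 1, ref == alt, non-ACGT allele)
    are rejected; with ``strict=False`` (default) rejected rows are reported
    in a single warning with their 1-based data-row numbers, with
    ``strict=True`` the first offending row raises.
    """
    path = Path(path)
    if not path.exists():
        raise MutationTableError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message is enough
        raise MutationTableError(f"{path}: cannot parse table: {exc}") from exc
    missing = [c for c in ("gene", "position", "ref", "alt") if c not in df.columns]
    if missing:
        raise MutationTableError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )
    records: list[MutationRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pos = int(getattr(row, "position"))
        except (TypeError, ValueError):
            rejects.append((i, f"position {getattr(row, 'position')!r} not an integer"))
            continue
        try:
            records.append(
                MutationRecord(
                    str(getattr(row, "gene")).strip(),
                    pos,
                    str(getattr(row, "ref")).strip().upper(),
                    str(getattr(row, "alt")).strip().upper(),
                )
            )
        except ParameterError as exc:
            rejects.append((i, str(exc)))
    if rejects:
        msg = "; ".join(f"row {i}: {why}" for i, why in rejects)
        if strict:
            raise MutationTableError(f"{path}: rejected rows — {msg}")
        warnings.warn(f"{path}: rejected {len(rejects)} row(s) — {msg}", stacklevel=2)
    return records


def write_mutation_table(
    records: Iterable[MutationRecord], path: str | Path
) -> None:
    """Write records as a TSV with header ``gene\\tposition\\tref\\talt``."""
    df = pd.DataFrame(
        [(r.gene_id, r.position, r.ref, r.alt) for r in records],
        columns=["gene", "position", "ref", "alt"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutated-sequence construction


def apply_mutations(
    reference: GeneSequence,
    records: Sequence[MutationRecord],
    mutated_id: str | None = None,
) -> GeneSequence:
    """Apply point substitutions to a reference, yielding a mutated sequence.

    Every record must name the reference's gene, lie within its length, and
    agree with the reference allele at its site — a mismatch raises
    :class:`ConsistencyError` (silent application would corrupt class
    labels).  Records at distinct positions commute; two records at the same
    position must agree on the alternate allele or :class:`ConflictError`
    is raised.  The reference object is never altered.
    """
    residues = list(reference.residues)
    chosen: dict[int, str] = {}
    for rec in records:
        if rec.gene_id != reference.id:
            raise ConsistencyError(
                f"record for gene {rec.gene_id!r} applied to sequence "
                f"{reference.id!r}"
            )
        if rec.position > len(residues):
            raise ConsistencyError(
                f"{reference.id}: position {rec.position} beyond sequence "
                f"length {len(residues)}"
            )
        found = residues[rec.position - 1]
        if found != rec.ref:
            raise ConsistencyError(
                f"{reference.id}: position {rec.position} expected ref "
                f"{rec.ref!r}, found {found!r}"
            )
        if rec.position in chosen and chosen[rec.position] != rec.alt:
            raise ConflictError(
                f"{reference.id}: conflicting alts at position {rec.position} "
                f"({chosen[rec.position]!r} vs {rec.alt!r})"
            )
        chosen[rec.position] = rec.alt
    for pos, alt in chosen.items():
        residues[pos - 1] = alt
    return GeneSequence(
        mutated_id or reference.id,
        "".join(residues),
        label=LABEL_MUTATED,
        source="generated" if reference.source == "file" else reference.source,
    )


def generate_mutated_sequences(
    references: Sequence[GeneSequence],
    records: Sequence[MutationRecord],
    mode: str = "per_record",
) -> list[GeneSequence]:
    """Build mutated sequences from references plus a mutation table.

    ``mode="per_record"`` (default) emits one mutated sequence per record,
    id-suffixed ``_mut1``, ``_mut2``, ... in record order per gene;
    ``mode="combined"`` emits one sequence per gene carrying all of its
    records at once, id-suffixed ``_mut``.  Records naming genes absent from
    ``references`` raise :class:`ConsistencyError`.
    """
    if mode not in ("per_record", "combined"):
        raise ParameterError(f"unknown mode {mode!r}")
    by_id = {r.id: r for r in references}
    out: list[GeneSequence] = []
    grouped: dict[str, list[MutationRecord]] = {}
    for rec in records:
        if rec.gene_id not in by_id:
            raise ConsistencyError(f"record names unknown gene {rec.gene_id!r}")
        grouped.setdefault(rec.gene_id, []).append(rec)
    for ref in references:
        recs = grouped.get(ref.id, [])
        if not recs:
            continue
        if mode == "combined":
            out.append(apply_mutations(ref, recs, mutated_id=f"{ref.id}_mut"))
        else:
            for k, rec in enumerate(recs, start=1):
                out.append(apply_mutations(ref, [rec], mutated_id=f"{ref.id}_mut{k}"))
    return out


# ---------------------------------------------------------------------------
# Deduplication (in place of CD-HIT preprocessing)


def _identity(a: str, b: str) -> float:
    """Exact-match identity over the shorter length (ungapped, no alignment)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    matches = sum(x == y for x, y in zip(short, long_))
    return matches / len(short)


def deduplicate(
    sequences: Sequence[GeneSequence], threshold: float | None = None
) -> list[GeneSequence]:
    """Collapse redundant sequences within each label stratum.

    Exact duplicates of the residue string are always collapsed to the first
    occurrence.  With ``threshold`` t in (0, 1], a greedy single-pass
    clustering additionally drops any sequence whose exact-match identity
    over the shorter length to an already-kept sequence *of the same label*
    exceeds t.  Input order is preserved; labels are distinct strata, so
    identical residues under different labels are both kept.
    """
    if threshold is not None and not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must lie in (0, 1], got {threshold}")
    kept: list[GeneSequence] = []
    seen_exact: set[tuple[str | None, str]] = set()
    for seq in sequences:
        key = (seq.label, seq.residues)
        if key in seen_exact:
            continue
        if threshold is not None:
            redundant = any(
                k.label == seq.label and _identity(k.residues, seq.residues) > threshold
                for k in kept
            )
            if redundant:
                continue
        seen_exact.add(key)
        kept.append(seq)
    return kept


# ---------------------------------------------------------------------------
# Dataset assembly


def build_labeled_dataset(
    normals: Sequence[GeneSequence], mutateds: Sequence[GeneSequence]
) -> LabeledDataset:
    """Combine a normal and a mutated collection into one labeled dataset.

    Labels are (re)assigned from collection membership; ordering is stable
    (normals first, then mutateds) so that any downstream shuffling is
    seed-controlled.
    """
    if not normals or not mutateds:
        raise DatasetError("both the normal and the mutated class must be non-empty")
    sequences = [s.with_label(LABEL_NORMAL) for s in normals] + [
        s.with_label(LABEL_MUTATED) for s in mutateds
    ]
    return LabeledDataset(sequences)


# ---------------------------------------------------------------------------
# Synthetic cohorts


def generate_synthetic_cohort(
    config: SyntheticCohortConfig,
) -> tuple[LabeledDataset, list[MutationRecord]]:
    """Draw a seeded synthetic cohort of reference/mutated sequence pairs.

    For each gene a uniform-random ACGT reference of length in
    ``length_range`` is drawn, and one mutated counterpart is built by
    applying ``mutations_per_gene`` random valid point substitutions at
    distinct positions (so the Hamming distance to the reference equals the
    record count).  Signal modes shape the mutated class only:

    - ``motif``: with probability ``signal_strength`` the fixed motif is
      written over a random window of the mutated sequence *after* the point
      mutations (a compositional class signal outside the mutation records);
    - ``biased_substitution``: with probability ``signal_strength`` each
      alternate allele is the transition partner of the reference allele
      (A<->G, C<->T) instead of a uniform draw from the three alternatives.

    Identical configs (including seed) yield byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    normals: list[GeneSequence] = []
    mutateds: list[GeneSequence] = []
    all_records: list[MutationRecord] = []
    nuc = np.frombuffer(NUCLEOTIDES.encode(), dtype="S1").astype("U1")
    for g in range(config.n_genes):
        gid = f"synth{g:04d}"
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(nuc[rng.integers(0, 4, size=length)])
        ref_seq = GeneSequence(gid, residues, source="synthetic")
        records: list[MutationRecord] = []
        if config.mutations_per_gene:
            positions = rng.choice(length, size=config.mutations_per_gene, replace=False)
            for pos0 in sorted(int(p) for p in positions):
                ref_allele = residues[pos0]
                alternatives = [n for n in NUCLEOTIDES if n != ref_allele]
                if (
                    config.signal_mode == "biased_substitution"
                    and rng.random() < config.signal_strength
                ):
                    alt = _TRANSITION[ref_allele]
                else:
                    alt = alternatives[int(rng.integers(0, 3))]
                records.append(MutationRecord(gid, pos0 + 1, ref_allele, alt))
        mut = apply_mutations(ref_seq, records, mutated_id=f"{gid}_mut")
        if config.signal_mode == "motif" and rng.random() < config.signal_strength:
            start = int(rng.integers(0, len(mut) - len(config.motif) + 1))
            mut_res = (
                mut.residues[:start]
                + config.motif
                + mut.residues[start + len(config.motif) :]
            )
            mut = GeneSequence(mut.id, mut_res, label=LABEL_MUTATED, source="synthetic")
        normals.append(ref_seq)
        mutateds.append(mut)
        all_records.extend(records)
    return build_labeled_dataset(normals, mutateds), all_records
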