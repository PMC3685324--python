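"""Codon-alignment I/O, functional/pseudogene classification and allele filtering.

The central object is :class:`CodonAlignment`: an in-frame, gapped nucleotide
alignment whose sequences carry species/family/clade metadata.  Sequences are
classified as putatively functional or pseudogene-like (in-frame stop codons,
frame-disrupting partial-codon gaps), and within-species sets of cloned
sequences are reduced to putative alleles by requiring at least a minimum
number of nucleotide differences between any two retained sequences.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

from mhcev.errors import (
    AlphabetError,
    FormatError,
    FrameError,
    MetadataError,
)

VALID_CHARS = frozenset("ACGTN-")
CLADES = ("songbird", "nonpasserine", "outgroup")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STANDARD_STOPS = frozenset(_STANDARD_TABLE.stop_codons)


def translate_codon(codon: str, code: CodonTable.CodonTable | None = None) -> str:
    """Translate an ungapped codon; returns '*' for stops."""
    table = code or _STANDARD_TABLE
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


@dataclass(frozen=True)
class AlignedSequence:
    """One row of a codon alignment together with its metadata."""

    id: str
    species: str
    clade: str
    bases: str
    family: str = ""

    def __post_init__(self) -> None:
        bad = set(self.bases) - VALID_CHARS
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        if self.clade not in CLADES:
            raise MetadataError(
                f"sequence {self.id!r} has unknown clade {self.clade!r}; "
                f"expected one of {CLADES}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def codons(self) -> list[str]:
        return [self.bases[i : i + 3] for i in range(0, len(self.bases), 3)]


@dataclass
class CodonAlignment:
    """An in-frame alignment; all sequences equal length, length % 3 == 0."""

    sequences: list[AlignedSequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            return
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} is not a multiple of 3")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def subset(self, ids: Iterable[str]) -> "CodonAlignment":
        """Alignment restricted to `ids`, preserving original order."""
        wanted = set(ids)
        return CodonAlignment([s for s in self.sequences if s.id in wanted])

    def by_clade(self, clade: str) -> "CodonAlignment":
        return CodonAlignment([s for s in self.sequences if s.clade == clade])

    def by_species(self) -> dict[str, "CodonAlignment"]:
        """Split into per-species alignments, preserving input order."""
        groups: dict[str, list[AlignedSequence]] = {}
        for s in self.sequences:
            groups.setdefault(s.species, []).append(s)
        return {sp: CodonAlignment(seqs) for sp, seqs in groups.items()}

    def codon_columns(self) -> list[int]:
        return list(range(self.n_codons))


@dataclass(frozen=True)
class SequenceClass:
    """Functional/pseudogene call for one sequence."""

    id: str
    functional: bool
    reasons: tuple[str, ...] = ("none",)

    def __post_init__(self) -> None:
        if self.functional != (self.reasons == ("none",)):
            raise ValueError("functional flag inconsistent with reasons")


def read_metadata(metadata_path: str | Path) -> dict[str, dict[str, str]]:
    """Read the 4-column TSV (id, species, family, clade); header required."""
    path = Path(metadata_path)
    rows: dict[str, dict[str, str]] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"id", "species", "family", "clade"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MetadataError(
                f"metadata header must contain columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            sid = row["id"]
            if sid in rows:
                raise MetadataError(f"duplicate metadata row for id {sid!r}")
            rows[sid] = row
    return rows


def read_codon_alignment(
    fasta_path: str | Path, metadata_path: str | Path
) -> CodonAlignment:
    """Read an aligned FASTA plus its metadata TSV into a CodonAlignment.

    Input order of the FASTA is preserved.  Raises FormatError for ragged
    input, FrameError when the length is not a multiple of 3 and
    MetadataError when a record id has no metadata row.
    """
    meta = read_metadata(metadata_path)
    sequences: list[AlignedSequence] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in meta:
            raise MetadataError(f"no metadata row for sequence {record.id!r}")
        row = meta[record.id]
        sequences.append(
            AlignedSequence(
                id=record.id,
                species=row["species"],
                family=row.get("family", ""),
                clade=row["clade"],
                bases=str(record.seq).upper(),
            )
        )
    if not sequences:
        raise FormatError(f"no FASTA records in {fasta_path}")
    return CodonAlignment(sequences)


def write_codon_alignment(
    aln: CodonAlignment, fasta_path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write alignment to FASTA (one line per sequence) and optionally its TSV."""
    with Path(fasta_path).open("w", encoding="utf-8") as handle:
        for seq in aln:
            handle.write(f">{seq.id}\n{seq.bases}\n")
    if metadata_path is not None:
        write_metadata(aln, metadata_path)


def write_metadata(aln: CodonAlignment, metadata_path: str | Path) -> None:
    with Path(metadata_path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "species", "family", "clade"])
        for seq in aln:
            writer.writerow([seq.id, seq.species, seq.family, seq.clade])


def classify_sequence(
    seq: AlignedSequence, code: CodonTable.CodonTable | None = None
) -> SequenceClass:
    """Flag in-frame stop codons and frame-disrupting partial-codon gaps.

    A codon that is entirely gaps is a clean codon deletion and is tolerated;
    a codon with 1 or 2 gap characters disrupts the reading frame.  Codons
    containing N are skipped for stop detection (ambiguous, not evidence of
    a stop).
    """
    reasons: list[str] = []
    for codon in seq.codons():
        n_gaps = codon.count("-")
        if n_gaps in (1, 2):
            if "frameshift_gap" not in reasons:
                reasons.append("frameshift_gap")
            continue
        if n_gaps == 3 or "N" in codon:
            continue
        if translate_codon(codon, code) == "*":
            if "stop_codon" not in reasons:
                reasons.append("stop_codon")
    if reasons:
        return SequenceClass(id=seq.id, functional=False, reasons=tuple(sorted(reasons)))
    return SequenceClass(id=seq.id, functional=True, reasons=("none",))


def hamming_pairwise_deletion(a: str, b: str) -> int:
    """Count differing columns, ignoring columns where either side is a gap or N."""
    diffs = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        if x != y:
            diffs += 1
    return diffs


def filter_putative_alleles(
    seqs: Sequence[AlignedSequence], min_nt_diff: int = 3
) -> tuple[list[AlignedSequence], list[SequenceClass]]:
    """Reduce one individual's cloned sequences to putative functional alleles.

    Nonfunctional sequences (stops, disrupted frames) are discarded outright.
    The remaining sequences are clustered by single linkage at pairwise
    Hamming distance < `min_nt_diff` (gap/N columns ignored pairwise) and the
    first-by-input-order member of each cluster is retained, so every retained
    pair differs at >= `min_nt_diff` sites.

    Returns (retained sequences, classifications of discarded sequences).
    Discarded near-duplicates are reported as functional with reasons
    ("none",) — they are valid sequences, just not distinct alleles.
    """
    if min_nt_diff < 1:
        raise ValueError("min_nt_diff must be >= 1")
    discarded: list[SequenceClass] = []
    functional: list[AlignedSequence] = []
    for seq in seqs:
        cls = classify_sequence(seq)
        if cls.functional:
            functional.append(seq)
        else:
            discarded.append(cls)

    # single-linkage union-find over pairs closer than the threshold
    parent = list(range(len(functional)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(functional)):
        for j in range(i + 1, len(functional)):
            d = hamming_pairwise_deletion(functional[i].bases, functional[j].bases)
            if d < min_nt_diff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    retained: list[AlignedSequence] = []
    seen_clusters: set[int] = set()
    for i, seq in enumerate(functional):
        root = find(i)
        if root in seen_clusters:
            discarded.append(SequenceClass(id=seq.id, functional=True))
        else:
            seen_clusters.add(root)
            retained.append(seq)
    return retained, discarded


def write_discard_report(discarded: Iterable[SequenceClass], path: str | Path) -> None:
    """JSON report of discarded sequences with their reasons."""
    payload = [
        {"id": d.id, "functional": d.functional, "reasons": list(d.reasons)}
        for d in discarded
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
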