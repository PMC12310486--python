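"""Sequence ingestion, normalization, orientation handling and k-mer tokenization.

miRNA target recognition is driven by partial complementarity between a short
(~22 nt) miRNA and sites on a much longer mRNA, concentrated in the 3'UTR.
Everything downstream (embedding pretraining, the pair encoder) consumes
sequences through two primitives defined here: alphabet-normalized
:class:`SequenceRecord` objects and overlapping k-mer token streams.

mRNA sequences are *reversed* (character reversal, no complementation) before
any tokenization so that the encoder reads them 3'->5', antiparallel to the
miRNA — mirroring the physical binding geometry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "ACGU"
_VALID = set("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class Role(str, Enum):
    """Which side of the interaction a sequence belongs to."""

    MIRNA = "miRNA"
    MRNA = "mRNA"


@dataclass(frozen=True)
class SequenceRecord:
    """An identified, normalized RNA sequence (residues over A/U/C/G)."""

    id: str
    residues: str
    role: Role

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Fragment:
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    residues: str


@dataclass(frozen=True)
class FragmentSet:
    """Overlapping fragments of one parent sequence, covering it end to end."""

    parent_id: str
    fragments: tuple[Fragment, ...]


@dataclass(frozen=True)
class KmerVocabulary:
    """All 4^k k-mers in lexicographic order (A<C<G<U) with a bijective index."""

    k: int
    tokens: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.tokens)


def normalize_sequence(id: str, raw: str, role: Role) -> SequenceRecord:
    """Normalize a raw FASTA sequence into the internal RNA alphabet.

    Whitespace (line wrapping) is removed, case is folded to upper and the DNA
    alphabet is mapped onto RNA (T->U) so GENCODE-style transcript FASTA and
    RNA FASTA are interchangeable. Ambiguity codes (N, R, Y, ...) are rejected
    rather than imputed: the 4^k k-mer vocabulary has no slot for them.
    """
    if not raw or not raw.strip():
        raise ValueError(f"{id}: empty sequence")
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    for pos, residue in enumerate(cleaned):
        if residue not in _VALID:
            raise ValueError(
                f"{id}: invalid residue {residue!r} at position {pos}"
            )
    return SequenceRecord(id=id, residues=cleaned, role=Role(role))


def reverse_orientation(rec: SequenceRecord) -> SequenceRecord:
    """Reverse an mRNA 5'->3' string end-for-end (no complementation).

    The reversal aligns the read direction of the mRNA with the antiparallel
    geometry of miRNA binding; complementarity itself is left for the model
    to learn.
    """
    if rec.role is not Role.MRNA:
        raise ValueError(f"{rec.id}: only mRNA records are reversed")
    return SequenceRecord(id=rec.id, residues=rec.residues[::-1], role=rec.role)


def reverse_complement(residues: str) -> str:
    """Watson-Crick reverse complement over the RNA alphabet (A<->U, C<->G)."""
    return residues.translate(_COMPLEMENT)[::-1]


def fragment_mrna(
    rec: SequenceRecord,
    min_len: int = 200,
    max_len: int = 400,
    overlap: int = 100,
    seed: int | np.random.Generator = 0,
) -> FragmentSet:
    """Cut an mRNA into overlapping fragments with seeded-random lengths.

    Fragment lengths are drawn uniformly from [min_len, max_len]; each next
    fragment starts ``overlap`` positions before the previous end, so every
    internal boundary is covered twice. A trailing remainder shorter than
    ``min_len`` is merged into the previous fragment; a parent shorter than
    ``min_len`` yields itself as the single fragment.
    """
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")
    if not (0 <= overlap < min_len):
        raise ValueError("require 0 <= overlap < min_len")
    length = len(rec.residues)
    if length < 1:
        raise ValueError(f"{rec.id}: empty sequence cannot be fragmented")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bounds: list[tuple[int, int]] = []
    start = 0
    while start < length:
        frag_len = int(rng.integers(min_len, max_len + 1))
        end = min(start + frag_len, length)
        if end - start < min_len and bounds:
            # trailing remainder: absorb into the previous fragment
            bounds[-1] = (bounds[-1][0], length)
            break
        bounds.append((start, end))
        if end >= length:
            break
        start = end - overlap
    fragments = tuple(
        Fragment(s, e, rec.residues[s:e]) for s, e in bounds
    )
    return FragmentSet(parent_id=rec.id, fragments=fragments)


def tokenize_kmers(residues: str, k: int = 6) -> list[str]:
    """All overlapping k-mers of a sequence, left to right (L-k+1 tokens)."""
    length = len(residues)
    if length < k:
        raise ValueError(f"sequence of length {length} is too short for k={k}")
    return [residues[i : i + k] for i in range(length - k + 1)]


def build_vocabulary(k: int = 6) -> KmerVocabulary:
    """The complete k-mer vocabulary: 4^k tokens in lexicographic order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tokens = tuple("".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k))
    return KmerVocabulary(k=k, tokens=tokens, index={t: i for i, t in enumerate(tokens)})


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing


def read_fasta(path: str | Path, role: Role) -> list[SequenceRecord]:
    """Read a FASTA file, normalizing every record (id = first header token)."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(normalize_sequence(rec.id, str(rec.seq), role))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.residues), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def fragments_to_tsv(fragsets: Iterable[FragmentSet], path: str | Path) -> None:
    """Export fragment intervals as BED-like TSV (parent_id, start, end)."""
    with open(path, "w") as fh:
        for fs in fragsets:
            for frag in fs.fragments:
                fh.write(f"{fs.parent_id}\t{frag.start}\t{frag.end}\n")


def iter_fragment_intervals(fs: FragmentSet) -> Iterator[tuple[int, int]]:
    for frag in fs.fragments:
        yield frag.start, frag.end
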