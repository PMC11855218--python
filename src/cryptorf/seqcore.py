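"""Sequence primitives.

Validated nucleotide/protein sequences, genetic codes with configurable
start-codon sets, framed translation, six-frame enumeration and FASTA I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

StopPolicy = Literal["truncate", "mark", "run_through"]


@dataclass(frozen=True)
class NucSeq:
    """A validated DNA sequence over {A,C,G,T,N}, stored uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        if not residues:
            raise ValueError(f"NucSeq {self.id!r}: empty sequence")
        bad = set(residues) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"NucSeq {self.id!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item) -> str:
        return self.residues[item]

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class ProtSeq:
    """A protein sequence over the 20 amino acids plus X (ambiguous) and * (stop).

    May be empty (e.g. a reading frame shorter than one codon).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        bad = set(residues) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"ProtSeq {self.id!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item) -> str:
        return self.residues[item]

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class GeneticCode:
    """Codon table plus start/stop codon sets.

    ``table`` maps the 61 sense codons to single-letter amino acids.
    Codons containing N translate to X and are never treated as start
    or stop codons.
    """

    name: str
    table: Mapping[str, str]
    start_codons: frozenset
    stop_codons: frozenset

    def amino_acid(self, codon: str) -> str:
        codon = codon.upper()
        if len(codon) != 3:
            raise ValueError(f"not a codon: {codon!r}")
        if "N" in codon:
            return "X"
        if codon in self.stop_codons:
            return "*"
        try:
            return self.table[codon]
        except KeyError as exc:  # pragma: no cover - alphabet is pre-validated
            raise ValueError(f"unknown codon {codon!r}") from exc

    def is_start(self, codon: str) -> bool:
        return "N" not in codon and codon.upper() in self.start_codons

    def is_stop(self, codon: str) -> bool:
        return "N" not in codon and codon.upper() in self.stop_codons

    def with_start_codons(self, starts: Iterable[str]) -> "GeneticCode":
        return GeneticCode(self.name, self.table, frozenset(s.upper() for s in starts), self.stop_codons)

    @classmethod
    def from_key(cls, key: str = "bacterial") -> "GeneticCode":
        """Build a code by config key.

        ``bacterial`` (default): NCBI table 11 with start codons restricted
        to {ATG, GTG, TTG}.  ``standard``: NCBI table 1 with ATG starts.
        """
        key = key.lower()
        if key == "bacterial":
            ncbi = CodonTable.unambiguous_dna_by_id[11]
            starts = frozenset({"ATG", "GTG", "TTG"})
        elif key == "standard":
            ncbi = CodonTable.unambiguous_dna_by_id[1]
            starts = frozenset({"ATG"})
        else:
            raise ValueError(f"unknown genetic code key {key!r}")
        return cls(
            name=key,
            table=dict(ncbi.forward_table),
            start_codons=starts,
            stop_codons=frozenset(ncbi.stop_codons),
        )


_DEFAULT_CODE: GeneticCode | None = None


def default_code() -> GeneticCode:
    global _DEFAULT_CODE
    if _DEFAULT_CODE is None:
        _DEFAULT_CODE = GeneticCode.from_key("bacterial")
    return _DEFAULT_CODE


def translate(
    seq: NucSeq,
    offset: int = 0,
    code: GeneticCode | None = None,
    stop_policy: StopPolicy = "mark",
    initiator_to_met: bool = False,
) -> ProtSeq:
    """Translate consecutive codons of ``seq`` starting at ``offset``.

    The trailing partial codon is ignored.  Stop handling: ``truncate``
    ends the output at the first stop (no ``*`` emitted); ``mark`` and
    ``run_through`` emit ``*`` and continue.  ``initiator_to_met`` remaps
    a leading start codon (e.g. GTG) to M; off by default so alternate
    starts read as Val/Leu in product strings.
    """
    code = code or default_code()
    if offset < 0 or offset >= len(seq):
        raise CoordinateError(
            f"offset {offset} out of range for sequence of length {len(seq)}"
        )
    if len(seq) - offset < 3:
        raise ValueError("empty codon range: fewer than 3 nt after offset")
    residues = seq.residues
    out: list[str] = []
    for i in range(offset, len(residues) - 2, 3):
        codon = residues[i : i + 3]
        aa = code.amino_acid(codon)
        if aa == "*" and stop_policy == "truncate":
            break
        out.append(aa)
    if initiator_to_met and out and code.is_start(residues[offset : offset + 3]):
        out[0] = "M"
    return ProtSeq(seq.id, "".join(out))


def reverse_complement(seq: NucSeq) -> NucSeq:
    """Watson-Crick reverse complement (N maps to N); an involution."""
    return NucSeq(seq.id, seq.residues.translate(_COMPLEMENT)[::-1])


def six_frames(
    seq: NucSeq, code: GeneticCode | None = None
) -> list[tuple[int, ProtSeq]]:
    """Translate all six reading frames with stop_policy='mark'.

    Frame labels: +1,+2,+3 are forward offsets 0,1,2; -1,-2,-3 are
    offsets 0,1,2 on the reverse complement.  Frames shorter than one
    codon yield an empty ProtSeq.
    """
    code = code or default_code()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    frames: list[tuple[int, ProtSeq]] = []
    for label_sign, s in ((1, seq), (-1, reverse_complement(seq))):
        for offset in range(3):
            label = label_sign * (offset + 1)
            if len(s) - offset >= 3:
                prot = translate(s, offset, code, "mark")
            else:
                prot = ProtSeq(s.id, "")
            frames.append((label, ProtSeq(f"{seq.id}|frame{label:+d}", prot.residues)))
    return frames


# --------------------------------------------------------------------------
# FASTA I/O (Biopython-backed; handles wrapped and unwrapped records)

def read_fasta_nuc(path: str | Path) -> list[NucSeq]:
    return [NucSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_fasta_prot(path: str | Path) -> list[ProtSeq]:
    return [ProtSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_fasta_aligned(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA as raw (possibly gapped) strings by id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(
    records: Iterable[NucSeq | ProtSeq | tuple[str, str]],
    path: str | Path,
    width: int = 60,
) -> None:
    seqrecs = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, res = rec
        else:
            rid, res = rec.id, rec.residues
        seqrecs.append(SeqRecord(Seq(res), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)
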