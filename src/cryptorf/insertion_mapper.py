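"""Locate insertion blocks by comparing invaded and uninvaded homologs.

Insertions are detected as alignment column runs where every uninvaded
member is gapped and an invaded member carries residues; coordinates are
mapped back to the invaded member's ungapped protein and CDS, and
flanking windows are extracted for the downstream signature tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, DataError, PhaseError
from .seqcore import NucSeq, ProtSeq


@dataclass(frozen=True)
class HomologSet:
    """A family of homologous CDSs with a protein alignment and group labels.

    ``members`` maps gene id -> (CDS, translation).  ``alignment`` maps
    gene id -> aligned (gapped) protein string; it may be None, in which
    case detection falls back to pairwise alignment.  ``invaded_ids`` and
    ``uninvaded_ids`` are disjoint subsets of the member ids.
    """

    members: dict
    alignment: dict | None
    invaded_ids: frozenset
    uninvaded_ids: frozenset

    def __post_init__(self) -> None:
        ids = set(self.members)
        if not frozenset(self.invaded_ids) <= ids or not frozenset(self.uninvaded_ids) <= ids:
            raise DataError("group ids reference unknown members")
        if set(self.invaded_ids) & set(self.uninvaded_ids):
            raise DataError("invaded and uninvaded id sets overlap")
        object.__setattr__(self, "invaded_ids", frozenset(self.invaded_ids))
        object.__setattr__(self, "uninvaded_ids", frozenset(self.uninvaded_ids))
        if self.alignment is not None:
            lengths = {len(s) for s in self.alignment.values()}
            if len(lengths) > 1:
                raise DataError(f"aligned strings have unequal lengths {sorted(lengths)}")
            for mid, row in self.alignment.items():
                if mid not in self.members:
                    raise DataError(f"alignment row {mid!r} has no member")
                degapped = row.replace("-", "")
                if degapped != self.members[mid][1].residues:
                    raise DataError(
                        f"degapped alignment row for {mid!r} does not match its translation"
                    )


@dataclass(frozen=True)
class InsertionLocus:
    """An insertion block in one invaded host gene.

    Protein/nucleotide coordinates are 0-based half-open and satisfy
    nt = 3 x aa at both ends (in-phase, between-codon insertion).
    """

    host_id: str
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    insertion_nt: NucSeq
    n_flank_aa: str
    c_flank_aa: str
    n_flank_nt: str = ""
    c_flank_nt: str = ""
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.nt_end - self.nt_start != 3 * (self.aa_end - self.aa_start):
            if "phase_warning" not in self.flags:
                raise PhaseError(
                    f"{self.host_id}: insertion nt span is not 3x the aa span"
                )
        if self.nt_start % 3 != 0 and "phase_warning" not in self.flags:
            raise PhaseError(f"{self.host_id}: insertion does not sit between codons")

    @property
    def aa_len(self) -> int:
        return self.aa_end - self.aa_start

    @property
    def nt_len(self) -> int:
        return self.nt_end - self.nt_start


def map_aa_to_nt(aa_start: int, aa_end: int, cds: NucSeq) -> tuple[int, int]:
    """Protein-level span -> CDS span (both 0-based half-open): nt = 3 x aa."""
    if len(cds) % 3 != 0:
        raise DataError(f"CDS {cds.id!r} length {len(cds)} not divisible by 3")
    if aa_start < 0 or aa_end < aa_start or 3 * aa_end > len(cds):
        raise DataError(
            f"aa span ({aa_start}, {aa_end}) outside CDS of {len(cds) // 3} codons"
        )
    return 3 * aa_start, 3 * aa_end


def extract_flanks(
    protein: str, aa_start: int, aa_end: int, window_aa: int
) -> tuple[str, str, tuple]:
    """Flanking residue windows around an insertion in the invaded protein.

    The C flank starts at the first residue after the insertion (the '+1'
    residue used by the intein tests).  Windows are clipped at gene
    boundaries and flagged when short or empty.
    """
    if window_aa < 1:
        raise ValueError("window_aa must be >= 1")
    flags: list[str] = []
    n_flank = protein[max(0, aa_start - window_aa) : aa_start]
    c_flank = protein[aa_end : aa_end + window_aa]
    if len(n_flank) < window_aa:
        flags.append("n_flank_clipped")
    if len(c_flank) < window_aa:
        flags.append("c_flank_clipped")
    if not c_flank:
        flags.append("c_flank_empty")
    return n_flank, c_flank, tuple(flags)


def find_insertion_blocks(
    homologs: HomologSet,
    min_block_aa: int = 30,
    merge_gap_aa: int = 3,
    flank_window_aa: int = 11,
) -> list[InsertionLocus]:
    """Find insertion loci for every invaded member.

    A block is a maximal run of alignment columns in which the invaded
    member has residues and *every* uninvaded member is gapped; runs
    separated by fewer than ``merge_gap_aa`` columns are merged, and
    blocks shorter than ``min_block_aa`` are dropped.  When the homolog
    set carries no alignment, each invaded member is globally aligned
    (BLOSUM62, affine gaps) against its most similar uninvaded member.
    """
    if not homologs.invaded_ids or not homologs.uninvaded_ids:
        raise ConfigurationError("need at least one invaded and one uninvaded member")
    if homologs.alignment is None:
        return _find_blocks_pairwise(homologs, min_block_aa, merge_gap_aa, flank_window_aa)

    loci: list[InsertionLocus] = []
    uninvaded_rows = [homologs.alignment[u] for u in sorted(homologs.uninvaded_ids)]
    ncol = len(next(iter(homologs.alignment.values())))
    for inv_id in sorted(homologs.invaded_ids):
        row = homologs.alignment[inv_id]
        mask = [
            row[c] != "-" and all(u[c] == "-" for u in uninvaded_rows)
            for c in range(ncol)
        ]
        runs = _mask_runs(mask)
        runs = _merge_runs(runs, merge_gap_aa)
        for col_start, col_end in runs:
            block_aa = sum(1 for c in range(col_start, col_end) if row[c] != "-")
            if block_aa < min_block_aa:
                continue
            aa_start = sum(1 for c in range(col_start) if row[c] != "-")
            loci.append(
                _make_locus(homologs, inv_id, aa_start, aa_start + block_aa, flank_window_aa)
            )
    loci.sort(key=lambda l: (l.host_id, l.aa_start))
    return loci


def _mask_runs(mask: Sequence[bool]) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def _merge_runs(runs: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return runs
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < merge_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def _make_locus(
    homologs: HomologSet, host_id: str, aa_start: int, aa_end: int, window_aa: int
) -> InsertionLocus:
    cds, prot = homologs.members[host_id]
    nt_start, nt_end = map_aa_to_nt(aa_start, aa_end, cds)
    n_flank, c_flank, flags = extract_flanks(prot.residues, aa_start, aa_end, window_aa)
    n_flank_nt = cds.residues[max(0, nt_start - 3 * window_aa) : nt_start]
    c_flank_nt = cds.residues[nt_end : nt_end + 3 * window_aa]
    return InsertionLocus(
        host_id=host_id,
        aa_start=aa_start,
        aa_end=aa_end,
        nt_start=nt_start,
        nt_end=nt_end,
        insertion_nt=NucSeq(f"{host_id}|ins{aa_start + 1}-{aa_end}", cds.residues[nt_start:nt_end]),
        n_flank_aa=n_flank,
        c_flank_aa=c_flank,
        n_flank_nt=n_flank_nt,
        c_flank_nt=c_flank_nt,
        flags=flags,
    )


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _find_blocks_pairwise(
    homologs: HomologSet, min_block_aa: int, merge_gap_aa: int, flank_window_aa: int
) -> list[InsertionLocus]:
    """Fallback when no alignment is supplied: per invaded member, align
    against the best-scoring uninvaded member and call gap-run blocks."""
    aligner = _protein_aligner()
    loci: list[InsertionLocus] = []
    for inv_id in sorted(homologs.invaded_ids):
        inv_prot = homologs.members[inv_id][1].residues
        best = None
        for un_id in sorted(homologs.uninvaded_ids):
            un_prot = homologs.members[un_id][1].residues
            aln = aligner.align(inv_prot, un_prot)[0]
            if best is None or aln.score > best[0]:
                best = (aln.score, aln)
        aln = best[1]
        inv_row, un_row = str(aln[0]), str(aln[1])
        mask = [a != "-" and b == "-" for a, b in zip(inv_row, un_row)]
        runs = _merge_runs(_mask_runs(mask), merge_gap_aa)
        for col_start, col_end in runs:
            block_aa = sum(1 for c in range(col_start, col_end) if inv_row[c] != "-")
            if block_aa < min_block_aa:
                continue
            aa_start = sum(1 for c in range(col_start) if inv_row[c] != "-")
            loci.append(
                _make_locus(homologs, inv_id, aa_start, aa_start + block_aa, flank_window_aa)
            )
    loci.sort(key=lambda l: (l.host_id, l.aa_start))
    return loci
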