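"""In-frame continuity testing and exhaustive hidden-ORF scanning.

An insertion extracted in host reading phase is tested two ways: does it
translate seamlessly in the host frame (no internal stop), and does any
other reading frame hide a complete ORF behind a (possibly non-canonical)
start codon?
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import PhaseError
from .seqcore import GeneticCode, NucSeq, ProtSeq, default_code, reverse_complement, translate


@dataclass(frozen=True)
class ContinuityResult:
    """Outcome of reading an insertion straight through in the host frame.

    ``first_stop_offset_nt`` is the 1-based position of the *last* base of
    the first in-frame stop codon ("a stop codon is reached N bp into the
    insertion"), or None when the read-through is seamless.
    """

    seamless: bool
    first_stop_offset_nt: int | None
    host_frame_translation: ProtSeq


@dataclass(frozen=True)
class HiddenOrf:
    """An ORF found in an alternate reading frame of an insertion.

    Coordinates are 1-based within the insertion; for reverse-strand ORFs
    they are positions on the reverse complement read 5'->3'.
    ``frame_index`` is 1..3 relative to the host frame (negative for the
    reverse strand); the host frame itself is frame 1.
    """

    start_nt: int
    stop_nt: int | None
    strand: str
    frame_index: int
    start_codon: str
    product: ProtSeq
    product_len_aa: int
    open_ended: bool = False
    primary: bool = True


def relative_frame(start_nt_1based: int) -> int:
    """Reading frame of a 1-based position relative to frame 1: ((n-1) mod 3)+1."""
    if start_nt_1based < 1:
        raise ValueError(f"position must be >= 1, got {start_nt_1based}")
    return (start_nt_1based - 1) % 3 + 1


def continuity_test(insertion_nt: NucSeq, code: GeneticCode | None = None) -> ContinuityResult:
    """Translate the insertion in host phase and locate the first stop, if any."""
    code = code or default_code()
    if len(insertion_nt) % 3 != 0:
        raise PhaseError(
            f"insertion length {len(insertion_nt)} is not a multiple of 3"
        )
    prot = translate(insertion_nt, 0, code, "mark")
    idx = prot.residues.find("*")
    if idx < 0:
        return ContinuityResult(True, None, prot)
    return ContinuityResult(False, 3 * (idx + 1), prot)


def scan_hidden_orfs(
    insertion_nt: NucSeq,
    code: GeneticCode | None = None,
    min_len_aa: int = 50,
    require_stop: bool = True,
    strands: str = "both",
    initiator_to_met: bool = False,
) -> list[HiddenOrf]:
    """Enumerate every ORF in every requested frame of the insertion.

    For each frame and strand, every start codon opens a candidate ORF
    that runs to the first downstream in-frame stop (or, when
    ``require_stop`` is false, to the end of the frame, flagged
    open-ended).  Within one stop-anchored group the longest ORF (most
    upstream start) is marked primary; shorter in-frame alternates are
    retained.  Results are sorted by product length descending.
    """
    code = code or default_code()
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")

    reads: list[tuple[str, str]] = [("+", insertion_nt.residues)]
    if strands == "both":
        reads.append(("-", reverse_complement(insertion_nt).residues))

    raw: list[dict] = []
    for strand, s in reads:
        for offset in range(3):
            frame = (offset + 1) if strand == "+" else -(offset + 1)
            n_codons = (len(s) - offset) // 3
            open_starts: list[int] = []
            for k in range(n_codons):
                codon = s[offset + 3 * k : offset + 3 * k + 3]
                if code.is_stop(codon):
                    for ci in open_starts:
                        raw.append(
                            dict(strand=strand, frame=frame, offset=offset,
                                 start_ci=ci, stop_ci=k, seq=s)
                        )
                    open_starts = []
                elif code.is_start(codon):
                    open_starts.append(k)
            if not require_stop:
                for ci in open_starts:
                    raw.append(
                        dict(strand=strand, frame=frame, offset=offset,
                             start_ci=ci, stop_ci=None, seq=s)
                    )

    # group by stop anchor to mark the primary (longest) ORF per stop
    orfs: list[HiddenOrf] = []
    groups: dict[tuple, list[dict]] = {}
    for r in raw:
        groups.setdefault((r["strand"], r["frame"], r["stop_ci"]), []).append(r)
    for members in groups.values():
        members.sort(key=lambda r: r["start_ci"])
        for rank, r in enumerate(members):
            orf = _build_orf(r, insertion_nt.id, code, primary=(rank == 0),
                             initiator_to_met=initiator_to_met)
            if orf.product_len_aa >= min_len_aa:
                orfs.append(orf)

    orfs.sort(key=lambda o: (-o.product_len_aa, o.strand != "+", o.start_nt))
    return orfs


def _build_orf(r: dict, seq_id: str, code: GeneticCode, primary: bool,
               initiator_to_met: bool) -> HiddenOrf:
    s, offset = r["seq"], r["offset"]
    ci, stop_ci = r["start_ci"], r["stop_ci"]
    start_nt = offset + 3 * ci + 1
    if stop_ci is None:
        stop_nt = None
        end_ci = (len(s) - offset) // 3
        open_ended = True
    else:
        stop_nt = offset + 3 * (stop_ci + 1)
        end_ci = stop_ci
        open_ended = False
    aas = [code.amino_acid(s[offset + 3 * k : offset + 3 * k + 3]) for k in range(ci, end_ci)]
    start_codon = s[offset + 3 * ci : offset + 3 * ci + 3]
    if initiator_to_met and aas:
        aas[0] = "M"
    product = ProtSeq(f"{seq_id}|{r['strand']}{abs(r['frame'])}|{start_nt}", "".join(aas))
    return HiddenOrf(
        start_nt=start_nt,
        stop_nt=stop_nt,
        strand=r["strand"],
        frame_index=r["frame"],
        start_codon=start_codon,
        product=product,
        product_len_aa=len(aas),
        open_ended=open_ended,
        primary=primary,
    )
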