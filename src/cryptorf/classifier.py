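"""Rule-cascade classification of insertion elements.

Combines continuity, hidden-ORF and signature evidence into one labelled
call per element.  The cascade is a transparent, fixed-priority rule set
(intein > group I intron > group II intron > hidden ORF); each label names
a *candidate* class only and carries the evidence that triggered it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import DataError
from .insertion_mapper import InsertionLocus
from .orf_scanner import ContinuityResult, HiddenOrf
from .signatures import SignatureEvidence

LABELS = (
    "intein_candidate",
    "group1_intron_candidate",
    "group2_intron_candidate",
    "hidden_orf_element",
    "unclassified",
)


@dataclass(frozen=True)
class Thresholds:
    """Config-exposed cutoffs for the rule cascade.

    ``flank_identity_min`` (percent) gates the intron-like flank-mimicry
    clause; the default is a documented choice, not a literature value.
    """

    flank_identity_min: float = 70.0
    min_orf_len_aa: int = 50


@dataclass(frozen=True)
class ElementCall:
    """Final classification of one insertion element with its evidence trail."""

    host_id: str
    label: str
    sublabel: str | None
    continuity: ContinuityResult
    orfs: tuple
    evidence: SignatureEvidence
    notes: tuple = ()
    locus: InsertionLocus | None = None


def classify(
    locus: InsertionLocus | None,
    continuity: ContinuityResult,
    orfs: Sequence[HiddenOrf],
    evidence: SignatureEvidence,
    thresholds: Thresholds | None = None,
) -> ElementCall:
    """Apply the rule cascade to one element's evidence.

    Rules, in priority order:

    1. intein_candidate: seamless continuity AND +1 residue in {T,S,C}
       AND terminal residue Asn (or the Ser variant) AND at least one
       splicing-block motif hit.
    2. group1_intron_candidate: terminal G, OR non-seamless continuity
       with flank identity >= threshold (5'-head mimicry of the 3' flank).
    3. group2_intron_candidate: the insertion begins GTGCG.
    4. hidden_orf_element: a primary non-frame-1 ORF of at least the
       minimum length; sublabel hnh_endonuclease when its product carries
       an HNH triad, zinc_finger_bearing when a CXX(X)C pair, else other.
    5. unclassified.

    When several rules fire, the highest-priority label wins and the
    others are recorded as co-labels in the notes.
    """
    thresholds = thresholds or Thresholds()
    if locus is not None and orfs:
        for orf in orfs:
            if not orf.product.id.startswith(locus.insertion_nt.id):
                raise DataError(
                    f"ORF {orf.product.id!r} was not scanned on locus "
                    f"{locus.insertion_nt.id!r}"
                )

    host_id = locus.host_id if locus is not None else continuity.host_frame_translation.id
    notes: list[str] = list(evidence.flags)
    if locus is not None:
        notes.extend(locus.flags)

    intein = evidence.intein
    intron = evidence.intron

    satisfied: list[tuple[str, str | None]] = []

    if (
        continuity.seamless
        and intein is not None
        and intein.plus1_pass
        and intein.terminal_status in ("asn", "ser_variant")
        and intein.motifs_found
    ):
        satisfied.append(("intein_candidate", None))

    mimicry = (
        not continuity.seamless
        and evidence.flank_identity_aa is not None
        and evidence.flank_identity_aa >= thresholds.flank_identity_min
    )
    if intron is not None and (intron.g_3prime or mimicry):
        satisfied.append(("group1_intron_candidate", None))

    if intron is not None and intron.gtgcg_5prime:
        satisfied.append(("group2_intron_candidate", None))

    candidates = [
        o
        for o in orfs
        if o.primary and o.frame_index != 1 and o.product_len_aa >= thresholds.min_orf_len_aa
    ]
    if candidates:
        if evidence.hnh is not None and evidence.hnh.hits:
            sub = "hnh_endonuclease"
        elif evidence.znf is not None and evidence.znf.pairs:
            sub = "zinc_finger_bearing"
        else:
            sub = "other"
        satisfied.append(("hidden_orf_element", sub))

    if satisfied:
        label, sublabel = satisfied[0]
        for co, _ in satisfied[1:]:
            notes.append(f"co_label:{co}")
    else:
        label, sublabel = "unclassified", None

    if intein is not None and intein.proline_flag:
        notes.append("proline_flank")
    if intein is not None and intein.terminal_status == "ser_variant":
        notes.append("ser_variant_terminus")
    if any(o.open_ended for o in orfs):
        notes.append("open_ended_orf")

    return ElementCall(
        host_id=host_id,
        label=label,
        sublabel=sublabel,
        continuity=continuity,
        orfs=tuple(orfs),
        evidence=evidence,
        notes=tuple(notes),
        locus=locus,
    )
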