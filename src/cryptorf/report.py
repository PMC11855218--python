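"""Report serialization: GFF3, JSON and TSV views of element calls.

All coordinates in these outputs are 1-based inclusive; internal 0-based
half-open spans are converted at this boundary only (see ``coords``).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import pandas as pd

from .classifier import ElementCall
from .coords import to_one_based
from .orf_scanner import HiddenOrf

_SOURCE = "cryptorf"

_GFF_HEADER = [
    "##gff-version 3",
    "# coordinates are 1-based inclusive",
]


def _esc(value) -> str:
    s = str(value)
    for raw, enc in (("%", "%25"), (";", "%3B"), ("=", "%3D"), (",", "%2C"), ("&", "%26")):
        s = s.replace(raw, enc)
    return s


def _attrs(**kwargs) -> str:
    return ";".join(f"{k}={_esc(v)}" for k, v in kwargs.items() if v is not None)


def _orf_feature(orf: HiddenOrf, seqid: str, insertion_len: int, host_offset: int | None,
                 idx: str) -> str:
    """One GFF3 line per ORF; reverse-strand coordinates are mapped back
    onto the forward insertion/host axis."""
    stop_nt = orf.stop_nt if orf.stop_nt is not None else (
        orf.start_nt + 3 * orf.product_len_aa - 1
    )
    if orf.strand == "+":
        start1, end1 = orf.start_nt, stop_nt
    else:
        start1, end1 = insertion_len - stop_nt + 1, insertion_len - orf.start_nt + 1
    if host_offset is not None:
        start1 += host_offset
        end1 += host_offset
    return "\t".join(
        [
            seqid,
            _SOURCE,
            "ORF",
            str(start1),
            str(end1),
            ".",
            orf.strand,
            "0",
            _attrs(
                ID=idx,
                frame_index=orf.frame_index,
                start_codon=orf.start_codon,
                product_len_aa=orf.product_len_aa,
                primary=str(orf.primary).lower(),
                open_ended=str(orf.open_ended).lower(),
                insertion_start=orf.start_nt,
                insertion_stop=orf.stop_nt if orf.stop_nt is not None else "open",
            ),
        ]
    )


def calls_to_gff3(calls: Sequence[ElementCall]) -> str:
    lines = list(_GFF_HEADER)
    for ci, call in enumerate(calls):
        if call.locus is not None:
            locus = call.locus
            seqid = locus.host_id
            start1, end1 = to_one_based(locus.nt_start, locus.nt_end)
            host_offset = locus.nt_start
            insertion_len = locus.nt_len
            lid = f"element{ci:03d}"
            lines.append(
                "\t".join(
                    [
                        seqid,
                        _SOURCE,
                        "sequence_insertion",
                        str(start1),
                        str(end1),
                        ".",
                        "+",
                        ".",
                        _attrs(
                            ID=lid,
                            label=call.label,
                            sublabel=call.sublabel,
                            notes=" ".join(call.notes) if call.notes else None,
                        ),
                    ]
                )
            )
        else:
            seqid = call.host_id
            host_offset = None
            insertion_len = 3 * len(call.continuity.host_frame_translation)
            lid = f"element{ci:03d}"
        for oi, orf in enumerate(call.orfs):
            lines.append(
                _orf_feature(orf, seqid, insertion_len, host_offset, f"{lid}.orf{oi}")
            )
    return "\n".join(lines) + "\n"


def call_to_dict(call: ElementCall) -> dict:
    """Full evidence trail as JSON-ready primitives (1-based coordinates
    added alongside the raw internal record)."""
    d = dataclasses.asdict(call)
    if call.locus is not None:
        aa1 = to_one_based(call.locus.aa_start, call.locus.aa_end)
        nt1 = to_one_based(call.locus.nt_start, call.locus.nt_end)
        d["locus"]["aa_span_1based"] = list(aa1)
        d["locus"]["nt_span_1based"] = list(nt1)
    return d


def calls_to_json(calls: Sequence[ElementCall]) -> str:
    return json.dumps([call_to_dict(c) for c in calls], indent=2, sort_keys=True)


def calls_to_summary(calls: Sequence[ElementCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        top = next((o for o in call.orfs if o.primary and o.frame_index != 1), None)
        row = {
            "host_id": call.host_id,
            "label": call.label,
            "sublabel": call.sublabel or "",
            "seamless": call.continuity.seamless,
            "first_stop_offset_nt": call.continuity.first_stop_offset_nt,
            "top_orf_start_nt": top.start_nt if top else None,
            "top_orf_frame": top.frame_index if top else None,
            "top_orf_len_aa": top.product_len_aa if top else None,
            "flank_identity_aa": call.evidence.flank_identity_aa,
            "flank_identity_nt": call.evidence.flank_identity_nt,
            "notes": " ".join(call.notes),
        }
        if call.locus is not None:
            row["aa_start"], row["aa_end"] = to_one_based(
                call.locus.aa_start, call.locus.aa_end
            )
            row["nt_start"], row["nt_end"] = to_one_based(
                call.locus.nt_start, call.locus.nt_end
            )
        rows.append(row)
    return pd.DataFrame(rows)
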