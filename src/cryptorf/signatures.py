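"""Classification evidence for insertion elements.

Intein residue/motif tests, self-splicing-intron end-motif tests, the
5'-insertion-head vs 3'-flank similarity statistic, and HNH / zinc-finger
motif scans over alternate-frame products.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError
from .seqcore import GeneticCode, NucSeq, ProtSeq, default_code, translate


def _residues(seq) -> str:
    if isinstance(seq, (NucSeq, ProtSeq)):
        return seq.residues
    return str(seq).upper()


# --------------------------------------------------------------------------
# Motif patterns

@dataclass(frozen=True)
class MotifPattern:
    """A named regex motif with a target sequence kind."""

    name: str
    pattern: str
    target: str = "insertion_aa"  # insertion_aa | insertion_nt | hidden_orf_product

    def __post_init__(self) -> None:
        re.compile(self.pattern)  # fail fast on bad patterns


# Conservative stand-ins for the canonical intein splicing blocks.  These
# are deliberately user-overridable (see ``load_motif_patterns``): block A
# expects a nucleophile at the element's N-terminus, block B a Thr/His
# pairing, block F a hydrophobic-His core, block G a His/Gly-Asn terminus.
DEFAULT_INTEIN_BLOCKS: tuple[MotifPattern, ...] = (
    MotifPattern("block_A", r"^[CST]"),
    MotifPattern("block_B", r"T..H"),
    MotifPattern("block_F", r"[VIL].{2}H[NS]"),
    MotifPattern("block_G", r"[HG]N$"),
)


def load_motif_patterns(path: str | Path) -> tuple[MotifPattern, ...]:
    """Load motif patterns from a YAML list of {name, pattern, target}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ConfigurationError("motif pattern file must contain a list")
    return tuple(
        MotifPattern(e["name"], e["pattern"], e.get("target", "insertion_aa"))
        for e in entries
    )


# --------------------------------------------------------------------------
# Intein / intron signatures

@dataclass(frozen=True)
class InteinEvidence:
    plus1_residue: str | None  # None when the C-flank was unavailable
    plus1_pass: bool | None
    proline_flag: bool
    terminal_residue: str
    terminal_status: str  # asn | ser_variant | fail
    motifs_found: tuple = ()


def intein_signature(
    insertion_aa,
    c_flank_aa,
    patterns: Sequence[MotifPattern] = DEFAULT_INTEIN_BLOCKS,
) -> InteinEvidence:
    """Test the residues an intein would need to splice.

    The +1 test passes iff the first C-flank residue is T, S or C (a
    proline there is flagged explicitly as splicing-inhibiting).  The
    terminal test reports 'asn' for a trailing N, 'ser_variant' for a
    trailing S, otherwise 'fail'.  The splicing-block patterns are scanned
    over the in-frame translation of the insertion.
    """
    ins = _residues(insertion_aa)
    if not ins:
        raise ValueError("empty insertion translation")
    flank = _residues(c_flank_aa) if c_flank_aa is not None else ""
    if flank:
        plus1 = flank[0]
        plus1_pass = plus1 in "TSC"
        proline = plus1 == "P"
    else:
        plus1, plus1_pass, proline = None, None, False

    terminal = ins[-1]
    if terminal == "N":
        status = "asn"
    elif terminal == "S":
        status = "ser_variant"
    else:
        status = "fail"

    hits = []
    for pat in patterns:
        if pat.target != "insertion_aa":
            continue
        for m in re.finditer(pat.pattern, ins):
            hits.append((pat.name, m.start(), m.end()))
    return InteinEvidence(plus1, plus1_pass, proline, terminal, status, tuple(hits))


@dataclass(frozen=True)
class IntronEvidence:
    g_3prime: bool
    gtgcg_5prime: bool


def intron_signature(insertion_nt) -> IntronEvidence:
    """End-motif tests: terminal G (group I), leading GTGCG (group II)."""
    nt = _residues(insertion_nt)
    if len(nt) < 5:
        raise ValueError("insertion shorter than 5 nt")
    return IntronEvidence(g_3prime=nt.endswith("G"), gtgcg_5prime=nt.startswith("GTGCG"))


# --------------------------------------------------------------------------
# Flank similarity

def flank_similarity(insertion_head, c_flank, window: int | None = None) -> float:
    """Ungapped positional percent identity over a fixed window.

    Case-insensitive and symmetric; works identically for amino-acid and
    nucleotide sequences.  When either sequence is shorter than the
    window, the comparison is clipped to the shorter length.
    """
    a, b = _residues(insertion_head), _residues(c_flank)
    if not a or not b:
        raise ValueError("empty sequence in flank comparison")
    w = min(len(a), len(b))
    if window is not None:
        if window < 1:
            raise ValueError("window must be >= 1")
        w = min(w, window)
    matches = sum(1 for i in range(w) if a[i] == b[i])
    return 100.0 * matches / w


def group_flank_similarity(
    comparisons: Mapping[str, Sequence[tuple]],
    window: int = 11,
) -> dict[str, float]:
    """Arithmetic mean of ``flank_similarity`` per group.

    ``comparisons`` maps a group name (e.g. 'invaded'/'uninvaded') to the
    (insertion_head, c_flank) pairs of its members.  Note: reported group
    values are means over all member comparisons; other aggregations of
    the same statistic are possible and the choice is an interpretation.
    """
    out: dict[str, float] = {}
    for group, pairs in comparisons.items():
        if not pairs:
            raise ConfigurationError(f"group {group!r} has no comparisons")
        vals = [flank_similarity(a, b, window) for a, b in pairs]
        out[group] = sum(vals) / len(vals)
    return out


# --------------------------------------------------------------------------
# HNH and zinc-finger motif scans

@dataclass(frozen=True)
class HnhScan:
    """All H..N..H triads within spacing bounds, plus a greedy
    non-overlapping selection (by earliest end)."""

    hits: tuple            # (i, j, k) 0-based residue indices
    selected: tuple


def hnh_motif_scan(
    product, spacing: tuple[int, int, int, int] = (10, 60, 10, 60)
) -> HnhScan:
    """Find every (H, N, H) residue triad with j-i in [min1,max1] and
    k-j in [min2,max2]."""
    s = _residues(product)
    min1, max1, min2, max2 = spacing
    if min(spacing) < 0 or max1 < min1 or max2 < min2:
        raise ValueError(f"invalid spacing {spacing}")
    h_pos = [i for i, c in enumerate(s) if c == "H"]
    n_pos = [j for j, c in enumerate(s) if c == "N"]
    hits = []
    for i in h_pos:
        for j in n_pos:
            if not (min1 <= j - i <= max1):
                continue
            for k in h_pos:
                if min2 <= k - j <= max2:
                    hits.append((i, j, k))
    selected = []
    last_end = -1
    for i, j, k in sorted(hits, key=lambda t: (t[2], t[0])):
        if i > last_end:
            selected.append((i, j, k))
            last_end = k
    return HnhScan(tuple(hits), tuple(selected))


@dataclass(frozen=True)
class ZnfScan:
    """CXXC / CXXXC motifs and pairs of them within ``pair_window``."""

    motifs: tuple          # (start, end) inclusive residue spans
    pairs: tuple           # ((s1,e1),(s2,e2)) with gap <= pair_window


def znf_motif_scan(product, pair_window: int = 40) -> ZnfScan:
    """Find CXXC and CXXXC motifs; report pairs of disjoint motifs whose
    gap (residues strictly between them) is at most ``pair_window``."""
    s = _residues(product)
    if pair_window < 0:
        raise ValueError("pair_window must be >= 0")
    motifs = []
    for i, c in enumerate(s):
        if c != "C":
            continue
        if i + 3 < len(s) and s[i + 3] == "C":
            motifs.append((i, i + 3))
        if i + 4 < len(s) and s[i + 4] == "C":
            motifs.append((i, i + 4))
    pairs = []
    for a in range(len(motifs)):
        for b in range(len(motifs)):
            s1, e1 = motifs[a]
            s2, e2 = motifs[b]
            if s2 > e1 and (s2 - e1 - 1) <= pair_window:
                pairs.append(((s1, e1), (s2, e2)))
    return ZnfScan(tuple(motifs), tuple(pairs))


# --------------------------------------------------------------------------
# Aggregated evidence

@dataclass(frozen=True)
class SignatureEvidence:
    """Per-element evidence bundle consumed by the classifier."""

    intein: InteinEvidence | None
    intron: IntronEvidence | None
    flank_identity_aa: float | None
    flank_identity_nt: float | None
    hnh: HnhScan | None
    znf: ZnfScan | None
    flags: tuple = ()


def gather_evidence(
    insertion_nt: NucSeq,
    c_flank_aa=None,
    c_flank_nt=None,
    orf_product=None,
    code: GeneticCode | None = None,
    window_aa: int = 11,
    intein_patterns: Sequence[MotifPattern] = DEFAULT_INTEIN_BLOCKS,
    hnh_spacing: tuple[int, int, int, int] = (10, 60, 10, 60),
    znf_pair_window: int = 40,
) -> SignatureEvidence:
    """Run every signature test applicable to one insertion.

    The flank-similarity statistic compares the insertion head (in host
    frame) with the C-terminal flank, at the amino-acid level over
    ``window_aa`` residues and at the nucleotide level over 3x that.
    """
    code = code or default_code()
    flags: list[str] = []
    insertion_aa = translate(insertion_nt, 0, code, "mark")

    intein = intein_signature(insertion_aa, c_flank_aa, intein_patterns)
    if intein.plus1_pass is None:
        flags.append("plus1_test_skipped")
    intron = intron_signature(insertion_nt)

    fid_aa = fid_nt = None
    if c_flank_aa is not None and len(_residues(c_flank_aa)) > 0:
        head_aa = insertion_aa.residues[:window_aa]
        if len(_residues(c_flank_aa)) < window_aa or len(head_aa) < window_aa:
            flags.append("flank_window_clipped")
        fid_aa = flank_similarity(head_aa, c_flank_aa, window_aa)
    if c_flank_nt is not None and len(_residues(c_flank_nt)) > 0:
        fid_nt = flank_similarity(
            insertion_nt.residues[: 3 * window_aa], c_flank_nt, 3 * window_aa
        )

    hnh = znf = None
    if orf_product is not None and len(_residues(orf_product)) > 0:
        hnh = hnh_motif_scan(orf_product, hnh_spacing)
        znf = znf_motif_scan(orf_product, znf_pair_window)
    return SignatureEvidence(intein, intron, fid_aa, fid_nt, hnh, znf, tuple(flags))
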