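"""Synthetic host-gene families and planted insertion elements.

Everything here is seed-deterministic and emits ground truth alongside the
sequences, so every pipeline stage can be tested without downloads.  The
central primitive is a codon-wise constrained builder that keeps the host
reading frame stop-free while dictating the content of an overlapping,
shifted reading frame (start codon, internal stop-freedom, planted motif
codons) -- naive whole-sequence rejection sampling would essentially never
satisfy a several-hundred-nt stop-free shifted frame.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field, asdict

from .errors import ConfigurationError, GenerationError
from .insertion_mapper import HomologSet
from .orf_scanner import scan_hidden_orfs
from .seqcore import GeneticCode, NucSeq, ProtSeq, default_code, translate
from .signatures import DEFAULT_INTEIN_BLOCKS, intein_signature

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

_CODE = default_code()
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(_CODE.table[_codon], []).append(_codon)
AMINO_ACIDS = sorted(AA_TO_CODONS)


def _rng(*parts) -> random.Random:
    """Process-independent RNG: string seeds hash deterministically in
    ``random`` (unlike tuples, which go through PYTHONHASHSEED)."""
    return random.Random("|".join(map(str, parts)))


@dataclass(frozen=True)
class PlantSpec:
    """Layout of a planted element.

    1-based coordinates within the insertion: ``orf_start_nt`` is the
    first base of the hidden ORF's start codon, ``orf_stop_nt`` the last
    base of its stop codon.  ``terminal_motif`` pins the insertion's final
    bases (e.g. 'TAAC').
    """

    element_class: str = "hidden_orf"
    insertion_len_nt: int = 606
    orf_start_nt: int = 18
    orf_stop_nt: int = 605
    start_codon: str = "GTG"
    plant_hnh: bool = True
    plant_znf_pairs: int = 2
    flank_mimicry: float | None = None
    terminal_motif: str | None = "TAAC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.element_class not in (
            "hidden_orf", "intein_like", "group1_intron_like", "group2_intron_like", "inert"
        ):
            raise ConfigurationError(f"unknown element class {self.element_class!r}")
        if self.element_class in ("hidden_orf", "intein_like", "inert"):
            if self.insertion_len_nt % 3 != 0:
                raise ConfigurationError("seamless classes need length divisible by 3")
        if self.element_class == "hidden_orf":
            span = self.orf_stop_nt - self.orf_start_nt + 1
            if span % 3 != 0 or span < 6:
                raise ConfigurationError(f"ORF span {span} nt is not a codon multiple")
            if not (1 <= self.orf_start_nt and self.orf_stop_nt <= self.insertion_len_nt):
                raise ConfigurationError("ORF coordinates outside the insertion")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted element."""

    element_class: str
    insertion_len_nt: int
    host_id: str | None = None
    aa_start: int | None = None
    aa_end: int | None = None
    nt_start: int | None = None
    nt_end: int | None = None
    orf: dict | None = None
    motifs: dict = field(default_factory=dict)
    first_stop_offset_nt: int | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Constrained dual-frame construction

def _build_dual_frame(
    length_nt: int,
    rng: random.Random,
    orf_offset0: int,
    orf_stop_last0: int,
    start_codon: str,
    stop_codon: str,
    planted_codons: dict[int, str],
    forced_bases: dict[int, str],
    start_codons: frozenset,
    exclude_hnc: bool = True,
    max_steps: int = 500_000,
) -> str:
    """Depth-first codon-wise construction of a dual-constrained sequence.

    Host frame (offset 0): every codon drawn from the sense (stop-free)
    set.  Shifted frame at ``orf_offset0``: the start codon, a stop-free
    body (optionally also free of H/N/C so motif-scan truth is exact,
    except at planted codons), planted motif codons, the stop codon, and
    no start codon in the same frame upstream of the ORF (so the planted
    start is the primary one for its stop).
    """
    if length_nt % 3 != 0:
        raise GenerationError("length must be a codon multiple")
    n_host = length_nt // 3
    n_orf = (orf_stop_last0 + 1 - orf_offset0) // 3

    forced = dict(forced_bases)

    def force(pos: int, base: str) -> None:
        if forced.get(pos, base) != base:
            raise GenerationError(
                f"conflicting base constraints at position {pos}: "
                f"{forced[pos]} vs {base}"
            )
        forced[pos] = base

    def force_codon(span_start: int, codon: str) -> None:
        for k, b in enumerate(codon):
            force(span_start + k, b)

    force_codon(orf_offset0, start_codon)
    force_codon(orf_offset0 + 3 * (n_orf - 1), stop_codon)
    for j, codon in planted_codons.items():
        if not (0 < j < n_orf - 1):
            raise GenerationError(f"planted codon index {j} outside ORF body")
        force_codon(orf_offset0 + 3 * j, codon)

    # checks that complete when a given host codon is placed
    completing: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n_host)}
    for j in range(1, n_orf - 1):
        if j in planted_codons:
            continue
        span_start = orf_offset0 + 3 * j
        completing[(span_start + 2) // 3].append((span_start, "orf_body"))
    for p in range(orf_offset0 % 3, orf_offset0 - 2, 3):
        completing[(p + 2) // 3].append((p, "no_upstream_start"))

    base_candidates: list[list[str]] = []
    for i in range(n_host):
        cands = [
            c
            for c in SENSE_CODONS
            if all(forced.get(3 * i + k, c[k]) == c[k] for k in range(3))
        ]
        if not cands:
            # a fully forced codon (e.g. the ORF stop in a degenerate
            # frame-1 layout) is honoured even when it is a stop
            fixed = [forced.get(3 * i + k) for k in range(3)]
            if all(fixed):
                cands = ["".join(fixed)]
            else:
                raise GenerationError(f"no viable host codon at index {i}")
        base_candidates.append(cands)

    chars = [""] * length_nt
    iters: list = [None] * n_host
    i, steps = 0, 0
    while i < n_host:
        if iters[i] is None:
            cands = base_candidates[i][:]
            rng.shuffle(cands)
            iters[i] = iter(cands)
        placed = False
        for cand in iters[i]:
            steps += 1
            if steps > max_steps:
                raise GenerationError("constraint search exceeded step cap")
            chars[3 * i : 3 * i + 3] = cand
            ok = True
            for span_start, kind in completing[i]:
                codon = "".join(chars[span_start : span_start + 3])
                if kind == "orf_body":
                    if codon in STOP_CODONS:
                        ok = False
                        break
                    if exclude_hnc and _CODE.table[codon] in "HNC":
                        ok = False
                        break
                else:  # no_upstream_start
                    if codon in start_codons:
                        ok = False
                        break
            if ok:
                placed = True
                break
        if placed:
            i += 1
        else:
            iters[i] = None
            i -= 1
            if i < 0:
                raise GenerationError("unsatisfiable frame constraints")
    return "".join(chars)


def _plan_motifs(
    product_len: int, plant_hnh: bool, plant_znf_pairs: int, rng: random.Random
) -> tuple[dict[int, str], dict]:
    """Pick product positions for the H/N/H triad and CXX(X)C pairs.

    Planted zinc-finger pairs are kept >40 residues apart from each other
    and from nothing else containing C, so the scans recover exactly the
    planted motifs.
    """
    planted: dict[int, str] = {}
    motifs: dict = {}
    if plant_hnh:
        if product_len < 25:
            raise GenerationError("product too short to plant an HNH triad")
        h1 = max(1, product_len // 5)
        d = min(30, max(10, (product_len - h1 - 2) // 2))
        if h1 + 2 * d > product_len - 1:
            raise GenerationError("product too short to plant an HNH triad")
        triad = (h1, h1 + d, h1 + 2 * d)
        planted[triad[0]] = "CAC"
        planted[triad[1]] = "AAC"
        planted[triad[2]] = "CAC"
        motifs["hnh"] = triad
    if plant_znf_pairs:
        # C positions (a, a+3) and (a+9, a+13): inter-C distances of 3 and 4
        # occur only inside the two intended motifs, so the scan recovers
        # exactly one CXXC + CXXXC pair per planted group.
        spans: list[tuple[int, int]] = []
        anchors = list(range(1, product_len - 14))
        rng.shuffle(anchors)
        for _ in range(plant_znf_pairs):
            placed = None
            for a in anchors:
                pos = (a, a + 3, a + 9, a + 13)
                if any(p in planted or p >= product_len - 1 for p in pos):
                    continue
                if any(not (a > e + 44 or s > a + 13 + 44) for s, e in spans):
                    continue
                placed = pos
                break
            if placed is None:
                raise GenerationError(
                    "cannot place zinc-finger pairs without overlap; "
                    "reduce plant_znf_pairs or lengthen the ORF"
                )
            for p in placed:
                planted[p] = "TGC"
            spans.append((placed[0], placed[3]))
            motifs.setdefault("znf_pairs", []).append(
                ((placed[0], placed[1]), (placed[2], placed[3]))
            )
    return planted, motifs


def _has_intein_blocks(host_translation: str) -> bool:
    ev = intein_signature(host_translation, None, DEFAULT_INTEIN_BLOCKS)
    return bool(ev.motifs_found)


def plant_hidden_orf(
    spec: PlantSpec, seed: int | None = None, seq_id: str = "insertion"
) -> tuple[NucSeq, TruthRecord]:
    """Build an insertion carrying a hidden alternate-frame ORF per ``spec``.

    The emitted insertion is seamless in the host frame, carries the ORF
    exactly at the specified coordinates, and (by default) avoids the
    intein splicing-block motifs in its host-frame translation and a
    group-II-like GTGCG head, so the element classifies as a hidden-ORF
    element and nothing else.  Verified post hoc against the scanner; a
    rejection loop with an attempt cap guards rare accidental artefacts
    (e.g. a longer chance ORF on the reverse strand).
    """
    if spec.element_class != "hidden_orf":
        raise ConfigurationError("plant_hidden_orf requires a hidden_orf spec")
    seed = spec.seed if seed is None else seed
    o0 = spec.orf_start_nt - 1
    stop_last0 = spec.orf_stop_nt - 1
    n_orf = (stop_last0 + 1 - o0) // 3
    product_len = n_orf - 1
    frame_index = o0 % 3 + 1
    code = _CODE

    last_err: Exception | None = None
    for attempt in range(80):
        rng = _rng(seed, attempt, "plant_hidden_orf")
        planted, motifs = _plan_motifs(product_len, spec.plant_hnh, spec.plant_znf_pairs, rng)
        forced: dict[int, str] = {}
        if spec.terminal_motif:
            for k, b in enumerate(spec.terminal_motif):
                forced[spec.insertion_len_nt - len(spec.terminal_motif) + k] = b
        elif spec.insertion_len_nt - 1 > stop_last0:
            # keep the 3' end un-G'd so the group-I end test stays negative
            forced[spec.insertion_len_nt - 1] = rng.choice("ACT")
        try:
            residues = _build_dual_frame(
                spec.insertion_len_nt,
                rng,
                orf_offset0=o0,
                orf_stop_last0=stop_last0,
                start_codon=spec.start_codon,
                stop_codon="TAA",
                planted_codons=planted,
                forced_bases=forced,
                start_codons=code.start_codons,
            )
        except GenerationError as err:
            last_err = err
            continue
        if residues.startswith("GTGCG"):
            continue
        insertion = NucSeq(seq_id, residues)
        host_aa = translate(insertion, 0, code, "mark").residues
        if frame_index != 1 and "*" in host_aa:
            continue  # cannot happen by construction; belt and braces
        if _has_intein_blocks(host_aa):
            continue
        found = scan_hidden_orfs(
            insertion, code, min_len_aa=min(50, product_len), strands="both"
        )
        if not found:
            continue
        top = found[0]
        if (
            top.start_nt == spec.orf_start_nt
            and top.stop_nt == spec.orf_stop_nt
            and top.frame_index == frame_index
            and top.product_len_aa == product_len
        ):
            truth = TruthRecord(
                element_class="hidden_orf",
                insertion_len_nt=spec.insertion_len_nt,
                orf=dict(
                    start_nt=spec.orf_start_nt,
                    stop_nt=spec.orf_stop_nt,
                    strand="+",
                    frame_index=frame_index,
                    start_codon=spec.start_codon,
                    product_len_aa=product_len,
                ),
                motifs=motifs,
                seed=seed,
                params=dict(spec=asdict(spec), attempt=attempt),
            )
            return insertion, truth
    raise GenerationError(
        f"could not satisfy spec after 80 attempts"
        + (f" (last constraint failure: {last_err})" if last_err else "")
    )


# --------------------------------------------------------------------------
# Canonical fixtures

def make_shilan_fixture(seed: int = 0) -> tuple[NucSeq, TruthRecord]:
    """606-nt seamless insertion: GTG start at 1-based 18-20, TAA stop at
    603-605, TAAC terminus, frame-3 ORF of 195 aa carrying an H/N/H triad
    and two CXX(X)C pairs; the host-frame read is a stop-free 202-mer."""
    spec = PlantSpec(
        element_class="hidden_orf",
        insertion_len_nt=606,
        orf_start_nt=18,
        orf_stop_nt=605,
        start_codon="GTG",
        plant_hnh=True,
        plant_znf_pairs=2,
        terminal_motif="TAAC",
        seed=seed,
    )
    return plant_hidden_orf(spec, seed, seq_id="shilan_like_insertion")


def make_pacc40_fixture(seed: int = 0) -> tuple[NucSeq, TruthRecord]:
    """Seamless insertion with a frame-2 alternate ORF spanning 483 coding
    nt including the stop, i.e. a 160-aa product."""
    spec = PlantSpec(
        element_class="hidden_orf",
        insertion_len_nt=504,
        orf_start_nt=14,
        orf_stop_nt=496,
        start_codon="GTG",
        plant_hnh=True,
        plant_znf_pairs=1,
        terminal_motif=None,
        seed=seed,
    )
    return plant_hidden_orf(spec, seed, seq_id="pacc40_like_insertion")


def make_littlee_fixture(
    seed: int = 0, length_nt: int = 450, first_stop_offset_nt: int = 30
) -> tuple[NucSeq, TruthRecord]:
    """Group-I-intron-like insertion: reading through in host phase hits a
    stop codon ``first_stop_offset_nt`` bp in, and the final base is G."""
    if first_stop_offset_nt % 3 != 0 or first_stop_offset_nt < 3:
        raise ConfigurationError("first_stop_offset_nt must be a positive codon multiple")
    if length_nt % 3 != 0 or length_nt < first_stop_offset_nt + 3:
        raise ConfigurationError("length_nt too short or not a codon multiple")
    rng = _rng(seed, "littlee")
    stop_idx = first_stop_offset_nt // 3 - 1
    codons = [rng.choice(SENSE_CODONS) for _ in range(length_nt // 3)]
    codons[stop_idx] = rng.choice(("TAA", "TAG", "TGA"))
    chars = list("".join(codons))
    chars[-1] = "G"
    if "".join(chars[:5]) == "GTGCG":
        chars[4] = "A"
    insertion = NucSeq("littlee_like_insertion", "".join(chars))
    truth = TruthRecord(
        element_class="group1_intron_like",
        insertion_len_nt=length_nt,
        first_stop_offset_nt=first_stop_offset_nt,
        seed=seed,
        params=dict(length_nt=length_nt),
    )
    return insertion, truth


def make_intein_fixture(seed: int = 0, length_aa: int | None = None) -> tuple[NucSeq, str, TruthRecord]:
    """Seamless intein-like insertion plus a splicing-compatible C flank.

    Host-frame translation starts with a nucleophile (block A), carries a
    T..H core (block B), and ends His-Asn (block G + terminal Asn); the
    returned flank begins with T so the +1 test passes.
    """
    rng = _rng(seed, "intein")
    n = length_aa or rng.randrange(120, 201)
    codons = [rng.choice(SENSE_CODONS) for _ in range(n)]
    codons[0] = rng.choice(AA_TO_CODONS[rng.choice("CS")])
    m = rng.randrange(5, n - 12)
    codons[m] = rng.choice(AA_TO_CODONS["T"])
    codons[m + 3] = rng.choice(AA_TO_CODONS["H"])
    codons[-2] = rng.choice(AA_TO_CODONS[rng.choice("HG")])
    codons[-1] = rng.choice(("AAC", "AAT"))
    residues = "".join(codons)
    if residues.startswith("GTGCG"):  # unreachable: codon 0 encodes C/S
        raise GenerationError("unexpected group-II head")
    c_flank = rng.choice("TSC") + "".join(rng.choice(AMINO_ACIDS) for _ in range(10))
    insertion = NucSeq("intein_like_insertion", residues)
    truth = TruthRecord(
        element_class="intein_like",
        insertion_len_nt=3 * n,
        seed=seed,
        params=dict(length_aa=n, block_b_at=m),
    )
    return insertion, c_flank, truth


def make_group2_fixture(seed: int = 0, length_nt: int = 420) -> tuple[NucSeq, TruthRecord]:
    """Group-II-intron-like insertion: 5' GTGCG head, an early in-frame
    stop (non-seamless), and a non-G 3' terminus."""
    if length_nt % 3 != 0 or length_nt < 60:
        raise ConfigurationError("length_nt too short or not a codon multiple")
    rng = _rng(seed, "group2")
    n = length_nt // 3
    codons = [rng.choice(SENSE_CODONS) for _ in range(n)]
    codons[0] = "GTG"
    codons[1] = "CG" + rng.choice(BASES)
    stop_idx = rng.randrange(4, n // 2)
    codons[stop_idx] = rng.choice(("TAA", "TAG", "TGA"))
    while codons[-1].endswith("G") or codons[-1] in STOP_CODONS:
        codons[-1] = rng.choice(SENSE_CODONS)
    insertion = NucSeq("group2_intron_like_insertion", "".join(codons))
    truth = TruthRecord(
        element_class="group2_intron_like",
        insertion_len_nt=length_nt,
        first_stop_offset_nt=3 * (stop_idx + 1),
        seed=seed,
        params=dict(length_nt=length_nt),
    )
    return insertion, truth


# --------------------------------------------------------------------------
# Mutational noise

def mutate(seq: NucSeq, rate: float, rng: random.Random) -> NucSeq:
    """Per-base substitution noise (no indels); rate in [0, 1]."""
    if not 0 <= rate <= 1:
        raise ConfigurationError(f"rate {rate} outside [0, 1]")
    chars = list(seq.residues)
    for i, b in enumerate(chars):
        if rng.random() < rate:
            chars[i] = rng.choice([x for x in BASES if x != b])
    return NucSeq(seq.id, "".join(chars))


# --------------------------------------------------------------------------
# Host-gene families

def _mutate_codons(codons: list[str], rate: float, rng: random.Random) -> list[str]:
    """Site-independent, synonymous-biased codon substitution; never
    introduces a stop and never touches the initiator codon."""
    out = list(codons)
    for i in range(1, len(out)):
        if rng.random() >= rate:
            continue
        aa = _CODE.table[out[i]]
        if rng.random() < 0.75:
            choices = [c for c in AA_TO_CODONS[aa] if c != out[i]]
            if not choices:
                continue
        else:
            choices = SENSE_CODONS
        out[i] = rng.choice(choices)
    return out


def _inert_insertion(
    n_codons: int,
    rng: random.Random,
    c_flank_aa: str = "",
    mimicry: float | None = None,
    window_aa: int = 11,
) -> str:
    codons = [rng.choice(SENSE_CODONS) for _ in range(n_codons)]
    if mimicry is not None:
        for k in range(min(window_aa, n_codons, len(c_flank_aa))):
            target = c_flank_aa[k]
            if rng.random() < mimicry:
                aa = target
            else:
                aa = rng.choice([a for a in AMINO_ACIDS if a != target])
            codons[k] = rng.choice(AA_TO_CODONS[aa])
    return "".join(codons)


def make_host_family(
    n_invaded: int,
    n_uninvaded: int,
    gene_len_aa: int = 200,
    divergence: float = 0.05,
    seed: int = 0,
    insertion_sites: list[int] | None = None,
    insertion_len_nt: int | None = None,
    element_class: str = "hidden_orf",
    flank_mimicry: float | None = None,
    flank_window_aa: int = 11,
) -> tuple[HomologSet, list[TruthRecord]]:
    """Generate a family of homologous CDSs with planted insertions.

    A stop-free ancestral CDS is evolved per member by synonymous-biased
    substitution at the given divergence (no indels outside planted
    insertions), then each invaded member receives an insertion at every
    site in ``insertion_sites`` (protein coordinates, between codons).
    The matching protein alignment is emitted alongside, plus one
    TruthRecord per planted insertion.

    ``flank_mimicry`` sets the per-residue probability that the insertion
    head copies the C-flank residue (inert elements only, since the
    hidden-ORF layout constrains the head codons).
    """
    if n_invaded < 1 or n_uninvaded < 1:
        raise ConfigurationError("need at least one member per group")
    if gene_len_aa < 100:
        raise ConfigurationError("gene_len_aa must be >= 100")
    if not (0 <= divergence < 0.5):
        raise ConfigurationError("divergence must lie in [0, 0.5)")
    if flank_mimicry is not None and element_class != "inert":
        raise ConfigurationError("flank_mimicry requires element_class='inert'")
    if element_class not in ("hidden_orf", "inert"):
        raise ConfigurationError(f"unsupported family element class {element_class!r}")

    sites = sorted(insertion_sites or [gene_len_aa // 2])
    if any(not (flank_window_aa <= s <= gene_len_aa - flank_window_aa) for s in sites):
        raise ConfigurationError("insertion sites must leave room for flanks")
    ins_len = insertion_len_nt or (606 if element_class == "hidden_orf" else 150)
    if ins_len % 3 != 0:
        raise ConfigurationError("insertion_len_nt must be a codon multiple")
    ins_aa = ins_len // 3

    rng = _rng(seed, "family")
    ancestral = ["ATG"] + [rng.choice(SENSE_CODONS) for _ in range(gene_len_aa - 1)]

    member_ids = [f"invaded_{i + 1:02d}" for i in range(n_invaded)] + [
        f"uninvaded_{i + 1:02d}" for i in range(n_uninvaded)
    ]
    members: dict[str, tuple[NucSeq, ProtSeq]] = {}
    alignment: dict[str, str] = {}
    truths: list[TruthRecord] = []

    for mi, mid in enumerate(member_ids):
        mrng = _rng(seed, "member", mi)
        codons = _mutate_codons(ancestral, divergence, mrng)
        host_prot = "".join(_CODE.table[c] for c in codons)
        invaded = mid.startswith("invaded")

        insertions: dict[int, str] = {}
        if invaded:
            for si, site in enumerate(sites):
                if element_class == "hidden_orf":
                    spec = PlantSpec(
                        element_class="hidden_orf",
                        insertion_len_nt=ins_len,
                        orf_start_nt=18,
                        orf_stop_nt=ins_len - 1,
                        start_codon="GTG",
                        terminal_motif="TAAC",
                    )
                    ins, ins_truth = plant_hidden_orf(
                        spec, seed=f"{seed}|{mid}|{si}",
                        seq_id=f"{mid}|site{site}",
                    )
                    ins_nt = ins.residues
                    orf_truth, motif_truth = ins_truth.orf, ins_truth.motifs
                else:
                    c_flank = host_prot[site : site + flank_window_aa]
                    ins_nt = _inert_insertion(
                        ins_aa, mrng, c_flank, flank_mimicry, flank_window_aa
                    )
                    orf_truth, motif_truth = None, {}
                insertions[site] = ins_nt
                offset_aa = sum(ins_aa for s2 in sites if s2 < site)
                truths.append(
                    TruthRecord(
                        element_class=element_class,
                        insertion_len_nt=ins_len,
                        host_id=mid,
                        aa_start=site + offset_aa,
                        aa_end=site + offset_aa + ins_aa,
                        nt_start=3 * (site + offset_aa),
                        nt_end=3 * (site + offset_aa + ins_aa),
                        orf=orf_truth,
                        motifs=motif_truth,
                        seed=seed,
                        params=dict(
                            site_aa=site,
                            divergence=divergence,
                            flank_mimicry=flank_mimicry,
                        ),
                    )
                )

        cds_parts, aln_parts, prev = [], [], 0
        for site in sites:
            cds_parts.append("".join(codons[prev:site]))
            aln_parts.append(host_prot[prev:site])
            if invaded:
                ins_nt = insertions[site]
                cds_parts.append(ins_nt)
                aln_parts.append(
                    "".join(_CODE.amino_acid(ins_nt[k : k + 3]) for k in range(0, ins_len, 3))
                )
            else:
                aln_parts.append("-" * ins_aa)
            prev = site
        cds_parts.append("".join(codons[prev:]))
        aln_parts.append(host_prot[prev:])

        cds = NucSeq(mid, "".join(cds_parts))
        prot = translate(cds, 0, _CODE, "mark")
        members[mid] = (cds, prot)
        alignment[mid] = "".join(aln_parts)

    homologs = HomologSet(
        members=members,
        alignment=alignment,
        invaded_ids=frozenset(m for m in member_ids if m.startswith("invaded")),
        uninvaded_ids=frozenset(m for m in member_ids if m.startswith("uninvaded")),
    )
    return homologs, truths


# --------------------------------------------------------------------------
# Classification benchmark

@dataclass(frozen=True)
class BenchmarkItem:
    insertion: NucSeq
    c_flank_aa: str
    truth_label: str
    truth: TruthRecord


def make_benchmark(
    n_per_class: int, seed: int = 0, noise: float = 0.0
) -> list[BenchmarkItem]:
    """A labelled 4-class benchmark of planted insertions.

    Classes: hidden_orf, intein_like, group1_intron_like and
    group2_intron_like, each built so that exactly its own cascade rule
    fires at zero noise.  ``noise`` applies per-base substitution after
    planting (truth labels are kept, so accuracy degrades with noise).
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    items: list[BenchmarkItem] = []
    for i in range(n_per_class):
        rng = _rng(seed, "bench", i)

        n_codons = rng.randrange(160, 241)
        frame = rng.choice((2, 3))
        o0 = (frame - 1) + 3 * rng.randrange(0, 6)
        product_len = rng.randrange(60, 140)
        # two separated CXX(X)C pairs only fit in longer products
        max_pairs = 2 if product_len >= 120 else 1
        spec = PlantSpec(
            element_class="hidden_orf",
            insertion_len_nt=3 * n_codons,
            orf_start_nt=o0 + 1,
            orf_stop_nt=o0 + 3 * (product_len + 1),
            start_codon=rng.choice(("ATG", "GTG", "TTG")),
            plant_hnh=True,
            plant_znf_pairs=rng.randrange(0, max_pairs + 1),
            terminal_motif=None,
        )
        ins, truth = plant_hidden_orf(spec, seed=f"{seed}|ho|{i}",
                                      seq_id=f"bench_hidden_orf_{i}")
        flank = "T" + "".join(rng.choice(AMINO_ACIDS) for _ in range(10))
        items.append(BenchmarkItem(ins, flank, "hidden_orf", truth))

        ins, flank, truth = make_intein_fixture(seed=f"{seed}|in|{i}")
        ins = NucSeq(f"bench_intein_{i}", ins.residues)
        items.append(BenchmarkItem(ins, flank, "intein_like", truth))

        ins, truth = make_littlee_fixture(
            seed=f"{seed}|g1|{i}",
            length_nt=3 * rng.randrange(100, 180),
            first_stop_offset_nt=3 * rng.randrange(2, 15),
        )
        ins = NucSeq(f"bench_group1_{i}", ins.residues)
        flank = "".join(rng.choice(AMINO_ACIDS) for _ in range(11))
        items.append(BenchmarkItem(ins, flank, "group1_intron_like", truth))

        ins, truth = make_group2_fixture(
            seed=f"{seed}|g2|{i}",
            length_nt=3 * rng.randrange(100, 180),
        )
        ins = NucSeq(f"bench_group2_{i}", ins.residues)
        flank = "".join(rng.choice(AMINO_ACIDS) for _ in range(11))
        items.append(BenchmarkItem(ins, flank, "group2_intron_like", truth))

    if noise > 0:
        nrng = _rng(seed, "noise")
        items = [
            BenchmarkItem(mutate(it.insertion, noise, nrng), it.c_flank_aa,
                          it.truth_label, it.truth)
            for it in items
        ]
    return items
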