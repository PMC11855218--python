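"""End-to-end orchestration: inputs -> loci -> evidence -> calls -> reports."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .classifier import ElementCall, Thresholds, classify
from .errors import ConfigurationError, DataError, PhaseError
from .insertion_mapper import HomologSet, InsertionLocus, find_insertion_blocks
from .orf_scanner import continuity_test, scan_hidden_orfs
from .report import calls_to_gff3, calls_to_json, calls_to_summary
from .seqcore import (
    GeneticCode,
    NucSeq,
    ProtSeq,
    default_code,
    read_fasta_aligned,
    read_fasta_nuc,
    translate,
    write_fasta,
)
from .signatures import DEFAULT_INTEIN_BLOCKS, gather_evidence, load_motif_patterns


@dataclass
class RunConfig:
    """Parameters of one pipeline run; flags win over config-file values."""

    cds_fasta: Path
    groups_file: Path
    outdir: Path
    alignment_fasta: Path | None = None
    genetic_code: str = "bacterial"
    start_codons: tuple | None = None
    min_orf_len_aa: int = 50
    flank_window_aa: int = 11
    min_block_aa: int = 30
    merge_gap_aa: int = 3
    flank_identity_min: float = 70.0
    motif_patterns: Path | None = None
    strands: str = "both"
    require_stop: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("cds_fasta", "groups_file"):
            p = Path(getattr(self, attr))
            setattr(self, attr, p)
            if not p.exists():
                raise ConfigurationError(f"{attr} path does not exist: {p}")
        if self.alignment_fasta is not None:
            self.alignment_fasta = Path(self.alignment_fasta)
            if not self.alignment_fasta.exists():
                raise ConfigurationError(
                    f"alignment path does not exist: {self.alignment_fasta}"
                )
        self.outdir = Path(self.outdir)
        if not 0 < self.flank_identity_min <= 100:
            raise ConfigurationError("flank_identity_min must be in (0, 100]")
        if self.min_orf_len_aa < 1 or self.flank_window_aa < 1 or self.min_block_aa < 1:
            raise ConfigurationError("length parameters must be >= 1")


def load_groups(path: str | Path, member_ids) -> tuple[frozenset, frozenset]:
    """Two-column TSV (gene id, 'invaded'|'uninvaded') -> id sets."""
    invaded, uninvaded = set(), set()
    known = set(member_ids)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 'id<TAB>group'")
            mid, group = parts
            if mid not in known:
                raise DataError(f"{path}:{lineno}: unknown gene id {mid!r}")
            if group == "invaded":
                invaded.add(mid)
            elif group == "uninvaded":
                uninvaded.add(mid)
            else:
                raise DataError(
                    f"{path}:{lineno}: group must be 'invaded' or 'uninvaded', got {group!r}"
                )
    return frozenset(invaded), frozenset(uninvaded)


def _translation(cds: NucSeq, code: GeneticCode) -> ProtSeq:
    """Member translation: host frame, marked stops, trailing stop stripped."""
    prot = translate(cds, 0, code, "mark")
    residues = prot.residues
    if residues.endswith("*"):
        residues = residues[:-1]
    return ProtSeq(cds.id, residues)


def build_homolog_set(
    cds_fasta: str | Path,
    groups_file: str | Path,
    alignment_fasta: str | Path | None = None,
    code: GeneticCode | None = None,
) -> HomologSet:
    code = code or default_code()
    cdss = read_fasta_nuc(cds_fasta)
    members = {c.id: (c, _translation(c, code)) for c in cdss}
    invaded, uninvaded = load_groups(groups_file, members)
    alignment = None
    if alignment_fasta is not None:
        alignment = read_fasta_aligned(alignment_fasta)
    return HomologSet(members, alignment, invaded, uninvaded)


def analyze_locus(
    locus: InsertionLocus,
    code: GeneticCode | None = None,
    thresholds: Thresholds | None = None,
    min_orf_len_aa: int = 50,
    strands: str = "both",
    require_stop: bool = True,
    window_aa: int = 11,
    intein_patterns=DEFAULT_INTEIN_BLOCKS,
) -> ElementCall:
    """Run continuity, ORF scan and signatures on one locus and classify it."""
    code = code or default_code()
    insertion = locus.insertion_nt
    if len(insertion) % 3 != 0:
        trimmed = len(insertion) - len(insertion) % 3
        insertion = NucSeq(insertion.id, insertion.residues[:trimmed])
        locus = dataclasses.replace(locus, flags=locus.flags + ("phase_warning",))
    continuity = continuity_test(insertion, code)
    orfs = scan_hidden_orfs(insertion, code, min_orf_len_aa, require_stop, strands)
    top_alt = next((o for o in orfs if o.primary and o.frame_index != 1), None)
    evidence = gather_evidence(
        insertion,
        c_flank_aa=locus.c_flank_aa or None,
        c_flank_nt=locus.c_flank_nt or None,
        orf_product=top_alt.product if top_alt else None,
        code=code,
        window_aa=window_aa,
        intein_patterns=intein_patterns,
    )
    return classify(locus, continuity, orfs, evidence, thresholds)


def classify_insertion(
    insertion_nt: NucSeq,
    c_flank_aa: str | None = None,
    c_flank_nt: str | None = None,
    code: GeneticCode | None = None,
    thresholds: Thresholds | None = None,
    min_orf_len_aa: int = 50,
    strands: str = "both",
    require_stop: bool = True,
    window_aa: int = 11,
    intein_patterns=DEFAULT_INTEIN_BLOCKS,
) -> ElementCall:
    """Single-insertion mode: classify a pre-extracted insertion (must be
    in host phase, length a multiple of 3) without locus mapping."""
    code = code or default_code()
    if len(insertion_nt) % 3 != 0:
        raise PhaseError("pre-extracted insertion length must be a multiple of 3")
    continuity = continuity_test(insertion_nt, code)
    orfs = scan_hidden_orfs(insertion_nt, code, min_orf_len_aa, require_stop, strands)
    top_alt = next((o for o in orfs if o.primary and o.frame_index != 1), None)
    evidence = gather_evidence(
        insertion_nt,
        c_flank_aa=c_flank_aa,
        c_flank_nt=c_flank_nt,
        orf_product=top_alt.product if top_alt else None,
        code=code,
        window_aa=window_aa,
        intein_patterns=intein_patterns,
    )
    return classify(None, continuity, orfs, evidence, thresholds)


def export_queries(calls: Sequence[ElementCall], outdir: str | Path) -> Path:
    """Write original-frame and alternate-frame translations of every
    element as FASTA query records for external database searches."""
    if not calls:
        raise ValueError("no element calls to export")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: list[tuple[str, str]] = []
    for call in calls:
        if call.locus is not None:
            tag = f"{call.host_id}|ins{call.locus.aa_start + 1}-{call.locus.aa_end}"
        else:
            tag = call.host_id
        records.append((f"{tag}|original_frame", call.continuity.host_frame_translation.residues))
        top = next((o for o in call.orfs if o.primary and o.frame_index != 1), None)
        if top is not None:
            records.append(
                (f"{tag}|alt_frame{top.frame_index:+d}|{top.start_nt}", top.product.residues)
            )
    path = outdir / "query_products.faa"
    write_fasta(records, path)
    return path


def run_pipeline(config: RunConfig) -> list[ElementCall]:
    """Execute the full mapping -> scanning -> classification pipeline and
    write the report bundle (GFF3, JSON, TSV, FASTA, run log).

    An empty finding set is a successful run.
    """
    code = GeneticCode.from_key(config.genetic_code)
    if config.start_codons:
        code = code.with_start_codons(config.start_codons)
    patterns = (
        load_motif_patterns(config.motif_patterns)
        if config.motif_patterns
        else DEFAULT_INTEIN_BLOCKS
    )
    thresholds = Thresholds(
        flank_identity_min=config.flank_identity_min,
        min_orf_len_aa=config.min_orf_len_aa,
    )

    homologs = build_homolog_set(
        config.cds_fasta, config.groups_file, config.alignment_fasta, code
    )
    loci = find_insertion_blocks(
        homologs,
        min_block_aa=config.min_block_aa,
        merge_gap_aa=config.merge_gap_aa,
        flank_window_aa=config.flank_window_aa,
    )
    calls = [
        analyze_locus(
            locus,
            code,
            thresholds,
            min_orf_len_aa=config.min_orf_len_aa,
            strands=config.strands,
            require_stop=config.require_stop,
            window_aa=config.flank_window_aa,
            intein_patterns=patterns,
        )
        for locus in loci
    ]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "elements.gff3").write_text(calls_to_gff3(calls))
    (outdir / "report.json").write_text(calls_to_json(calls))
    calls_to_summary(calls).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    products = [
        orf.product
        for call in calls
        for orf in call.orfs
        if orf.primary and orf.frame_index != 1
    ]
    write_fasta(products, outdir / "hidden_orf_products.faa")
    if calls:
        export_queries(calls, outdir)

    log = {
        "cryptorf_version": __version__,
        "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
        "n_members": len(homologs.members),
        "n_loci": len(loci),
        "labels": sorted(c.label for c in calls),
    }
    (outdir / "run_log.txt").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return calls
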