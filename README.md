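# cryptorf

Detection and classification of cryptic insertion elements that hide
out-of-frame ORFs inside phage coding genes.

Some mobile insertion elements sit seamlessly inside a host gene — no
internal stop codon when read in the host frame — yet are neither inteins
nor self-splicing introns. Their payload can instead be a complete ORF
hidden in a *different* reading frame of the same nucleotides, often
starting at a non-canonical GTG codon and encoding an HNH endonuclease
with flanking zinc-finger motifs. `cryptorf` turns the characterization
workflow for such elements into a reusable, tested pipeline:

1. **Map insertions** — compare invaded and uninvaded homologs in a
   protein alignment (or fall back to pairwise BLOSUM62 alignment) and
   call gap-block loci with exact protein/CDS coordinates and flanking
   windows.
2. **Continuity test** — read the insertion in host phase and report
   whether it is seamless or where the first in-frame stop lands.
3. **Hidden-ORF scan** — exhaustively enumerate ORFs in all six frames
   with a configurable start-codon set (default ATG/GTG/TTG).
4. **Signature tests** — intein residue tests (+1 ∈ {T,S,C} vs the
   splicing-inhibiting proline, terminal Asn vs the Ser variant,
   splicing-block motifs), intron end motifs (3′ G, 5′ GTGCG), the
   5′-insertion-head vs 3′-flank similarity statistic, and HNH /
   CXX(X)C motif scans of alternate-frame products.
5. **Classify** — a transparent fixed-priority rule cascade
   (intein > group I intron > group II intron > hidden ORF) that emits
   candidate labels with a full evidence trail.
6. **Simulate** — a constrained dual-frame sequence builder that plants
   elements with known ground truth (seamless host frame + fully
   controlled shifted-frame ORF and motifs), so every stage is testable
   offline.

## Command line

```sh
# build a synthetic invaded/uninvaded family and analyse it end to end
cryptorf simulate --n-invaded 3 --n-uninvaded 3 --seed 7 --out family/
cryptorf run --cds family/cds.fna --groups family/groups.tsv \
             --alignment family/alignment.afa --out results/

# canonical packaged fixtures (606-nt hidden-ORF layout, intron-like, ...)
cryptorf fixtures shilan --seed 0 --out fx/
cryptorf scan --fasta fx/insertion.fna --out scan/
cryptorf classify --fasta fx/insertion.fna --out calls/
cryptorf export-queries --fasta fx/insertion.fna --out queries/
```

`run` writes `elements.gff3`, `report.json`, `summary.tsv`,
`hidden_orf_products.faa`, `query_products.faa` and a run log. All
human-facing coordinates are 1-based inclusive; internal APIs use
0-based half-open spans.

## Library

```python
from cryptorf import (
    make_shilan_fixture, continuity_test, scan_hidden_orfs, classify_insertion,
)

insertion, truth = make_shilan_fixture(seed=0)      # 606 nt, ground truth attached
continuity_test(insertion).seamless                  # True (202 aa, no stops)
top = scan_hidden_orfs(insertion)[0]                 # GTG at 18, frame 3, 195 aa
classify_insertion(insertion, c_flank_aa="TQHHEARIQAK").label
# 'hidden_orf_element' (sublabel 'hnh_endonuclease')
```

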