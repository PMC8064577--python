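# mapkin

Identification, classification and profiling of plant mitogen-activated
protein kinases (MAPKs) and their upstream kinases (MEKs) from degenerate
consensus motifs.

## The scientific problem

Plant MAPK cascades (MEKK → MEK → MAPK) are annotated across genomes by
looking for short, degenerate protein motifs: the conserved catalytic
subdomains shared by all members of a family, a small set of "novel"
domains diagnostic of the phylogenetic groups A–E, the activation-loop
triplet (canonical T-E-Y / T-D-Y or a non-canonical variant), and
group-specific docking/binding sites. `mapkin` implements this pipeline
end to end:

- **patterns** — a mini-language for degenerate consensus motifs
  (`D-[L/I/V]-K`, `S/T-X_3-5_-S/T`, `(L/H)-D-X_2_-D-E-P`, …) with an exact
  matcher supporting mismatch tolerance, plus a brute-force oracle used to
  test it.
- **library** — a curated, validated library of 49 motif definitions
  (MAPK and MEK conserved subdomains, novel group-diagnostic domains,
  binding-site variants, family membership signatures, MEKK/ZIK/RAF
  signatures) with TSV import/export for user overlays.
- **scan** — per-protein domain architecture: all motif hits, the
  maximum-score ordered non-overlapping domain chain, activation-loop
  typing, family gate (MAPK / MEK / MEKK-like / none) and weighted-vote
  group assignment (A–E).
- **naming** — ortholog-based nomenclature (species code + MPK/MEK +
  number of the most similar reference + a/b/c suffixes), using global
  BLOSUM62 alignments normalized to be symmetric.
- **physchem** — molecular weight and theoretical isoelectric point
  (Bjellqvist pKa set with a flat C-terminal carboxyl, solved by
  bisection), with per-group quartile/outlier summaries.
- **genestruct** — GFF3 gene models via `gffutils`: intron counts and
  untranslated-region (UTR) intron flags.
- **simulate** — a deterministic generator of labeled synthetic proteomes
  and gene models used as ground truth throughout the test suite.

## Worked example

```python
from mapkin.simulate import SynthSpec, generate_protein
from mapkin.scan import classify
from mapkin.physchem import molecular_weight, isoelectric_point

seq, truth = generate_protein("MAPK", "D", SynthSpec(seed=1), 0)
call, arch = classify("demo", seq)

call.family                      # 'MAPK'
call.group                       # 'D'
call.activation.triplet          # 'TDY'  (class 'canonical-TDY')
call.group_scores                # {'A': 1.0, 'B': 0.0, 'C': 0.0, 'D': 4.0, 'E': 1.0}
arch.chain_ids()                 # ['MAPK.I', 'MAPK.II', ..., 'MAPK.XI'] (12 subdomains)
arch.c_terminal_extension_length # 89  (long C-terminal tail, a group-D trait)
round(molecular_weight(seq), 2)  # 59214.38 Da
round(isoelectric_point(seq), 2) # 8.75
```

The same pipeline from the command line:

```bash
mapkin simulate --seed 3 --outdir sim --decoys 2
mapkin classify --in sim/cohort.fasta --out calls.tsv
mapkin name     --in sim/cohort.fasta --reference refs.fasta \
                --species-map sim/species_map.tsv --out names.tsv
mapkin introns  --gff3 sim/models.gff3 --out introns.tsv
mapkin report   --in sim/cohort.fasta --species-map sim/species_map.tsv \
                --out report.tsv
```

All reports are TSV with a reproducibility header (tool version,
parameter digest, coordinate convention).

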