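# Methods

This document describes the model implemented by `mapkin`, the default
parameters, and the numerical and design decisions behind them.

## 1. Consensus-pattern mini-language (`mapkin.patterns`)

Patterns are hyphen-separated element lists. Tokens are split on `-`
except inside brackets, parentheses or underscore-delimited repeat
bounds. Elements:

| form | meaning |
| --- | --- |
| `K` | literal residue |
| `[L/I/V]`, `(L/H)`, `S/T` | choice (one of the listed residues) |
| `X` | wildcard, one residue |
| `X_n_` | wildcard, exactly *n* residues |
| `X_m-n_` | wildcard, *m* to *n* residues |

Matching semantics:

- A window matches when the elements can be laid over it in order; the
  matcher reports **every** distinct `(start, end)` window (0-based,
  half-open) together with the minimum achievable mismatch count.
- Mismatch tolerance applies only at literal/choice positions; wildcard
  repeats are never charged.
- The sequence letter `X` (unknown residue) satisfies only wildcard
  elements; against a literal or choice it counts as a mismatch.
- `match_all` is a per-start dynamic program over elements with
  suffix-span pruning; `brute_force_match` enumerates every window and
  wildcard decomposition and is kept as the testing oracle. The two are
  asserted equal on ≥1000 random instances.

`instantiate` produces the canonical concrete sequence of a pattern:
first **listed** residue at each choice, `A` at wildcards, minimum
repeats. An optional avoid-list flips `A`→`G` at wildcard positions that
would accidentally realize a different pattern.

## 2. Motif library (`mapkin.library`)

49 entries, each with id, family (`MAPK`/`MEK`/`MEKK`), role
(`canonical`, `novel`, `signature`, `binding`, `extension`), group
associations and provenance text:

- 13 MAPK conserved subdomains (I–XI with VIa/VIb, plus the common
  docking CD domain; the CD ships with a permissive alias spelling
  `(L/H)-D-X_2_-D-E-P` that scans prefer),
- 6 MAPK novel group-diagnostic domains n12–n17,
- 1 MAPK membership signature whose pattern elements 1–3 form the
  activation T-X-Y frame,
- 11 MEK conserved domains (I–VIII, ATP-binding, generic MAPK-binding
  core, activation site), 5 group-specific binding variants plus the
  NTF2-interaction site, 6 MEK novel domains n9–n14, the group-B
  NTF2-like C-terminal extension, and the MEK membership signatures
  `D-[L/I/V]-K` and `S/T-X_3-5_-S/T`,
- 3 MEKK-subfamily signatures (MEKK, ZIK, RAF).

`validate_library` rejects duplicate ids, unparseable patterns, spans
outside [3, 30] and group associations on roles that must not carry
them; it *warns* about cross-talk (one entry's canonical instantiation
matching another entry of the same family), which legitimately happens
where a binding variant embeds the generic binding core.

## 3. Domain architecture and classification (`mapkin.scan`)

**Chain.** For each family, all library hits are reduced to the
maximum-score ordered non-overlapping chain, where the canonical order
is I…XI(+CD interleaved before XI) for MAPKs and
I, ATP, II, III, MAPKbind, IV, ACT, V, VI, VII, VIII for MEKs (the
ATP-binding, docking and activation sites sit at those positions in real
sequences). Score of a match is `length − 2·mismatches`; ties break
toward leftmost starts. The DP is validated against an exhaustive chain
oracle.

**Activation loop.** Searched between chain anchors VII and VIII when
both exist, else globally: first a signature hit (triplet = positions
1–3 of the hit), then any canonical `T·Y` frame, then the observed
non-canonical variants (MEY, TEM, THE, THL, THQ, TKT, TQM, TSY).

**Family gate** (first match wins):

1. MAPK — signature hit, or a T-X-Y activation frame plus all of
   subdomains II, III, V and VII in the chain;
2. MEK — both membership signatures (`D-[L/I/V]-K` and the S/T gap)
   plus ≥ `min_mek_domains` (default 4) canonical chain domains;
3. MEKK-like — any MEKK/ZIK/RAF signature;
4. otherwise none.

**Group assignment** is a weighted vote. MAPK: n13→C+2; n14→D+2;
TDY→D+1; C-terminal extension >60→D+1; n12→A+1,B+1; n15→B+1; n16→B+1;
n17 without n15/n16→A+1; n15 without n16→E+1; non-canonical
activation→E+1; absent CD→E+1; TEY→A,B,C +1 each. MEK: n9→A+2;
n10/n12/n13→B+1 each; n11→C+2; n14→E+2; uniquely best-matching binding
variant (fewest mismatches; ties vote nothing)→+1 to its group;
NTF2-like extension after the chain end→B+2; no novel domain but generic
binding core present→D+1. A winner must lead by ≥1 point, otherwise the
call is `ambiguous`.

Default `ScanParams`: `tolerance=0`, `sig_tol=0`, `bind_tol=2`,
`min_mek_domains=4`, `ext_min=60` residues.

## 4. Nomenclature (`mapkin.naming`)

Names are `<species code><MPK|MEK><number><suffix>`. The species code is
the genus initial + species initial (`Pinus taeda` → `Pt`), extended to
two letters each on collision (`Amborella trichopoda` vs. `At` →
`Amtr`). The ortholog number is parsed from the top-scoring reference
under global BLOSUM62 alignment (gap open −10, extend −1), normalizing
the raw score by the geometric mean of the two self-scores so that the
measure is symmetric and identity scores exactly 1.0. Sequences of one
species sharing a reference number get suffixes a, b, c… by descending
score (ties by sequence id). This is a similarity proxy for
tree-adjacency; equal-best references are reported as ties rather than
silently resolved.

## 5. Physicochemical profile (`mapkin.physchem`)

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da). The isoelectric point solves `net_charge(pH) = 0` by
bisection on [0, 14] (default tolerance 1e-4 pH units) with the
Bjellqvist pKa set (K 10.0, R 12.0, H 5.98; D 4.05, E 4.45, C 9.0,
Y 10.0; N-terminus 7.5 with residue-specific overrides). The C-terminal
carboxyl uses a **flat** pKa of 3.55, deliberately omitting the
residue-specific C-terminal overrides: with a flat terminal pKa the
charge curve is strictly decreasing in pH, bisection is guaranteed to
converge, and "appending D or E never raises the pI" is a provable
property (asserted in the tests). Agreement with an independent
implementation is within ~0.35 pH units, the spread expected between
published pKa sets. Group summaries report median/Q1/Q3
(linear-interpolation percentiles) and classical 1.5·IQR boxplot
outliers.

## 6. Gene structure (`mapkin.genestruct`)

GFF3 is parsed with `gffutils`. Per mRNA: exons sorted by genomic
start, intron count = exons − 1, and a UTR-intron flag per side computed
with the **hull rule**: an intron is a UTR intron when the inter-exon
gap lies entirely within the convex hull (min start … max end) of the
annotated UTR intervals of that side. The hull rule is
strand-symmetric, so mirrored minus-strand models give identical flags.
mRNAs with overlapping or missing exons are rejected with per-record
errors, not exceptions. Unannotated UTRs yield `NA` flags.

## 7. Synthetic cohorts (`mapkin.simulate`)

The generator is first-class, tested code; its defaults **are** the
study conditions and are never tuned toward passing tests.

A protein is assembled from the canonical instantiations of its
family's domains in chain order, with the group plan deciding the
activation triplet (MAPK A/B/C: TEY, D: TDY, E: THE), the novel-domain
complement, CD presence, the MEK binding variant, and the group-B
NTF2-like extension; random linkers (8–20 residues) join the segments.
Group-D MAPKs get an 80–100 residue C-terminal tail. The group-C MEK
binding variant writes its catalytic core position as a wildcard; the
generator pins it to `I` (the HRD-**I**-K core found in real sequences),
since the `D-[L/I/V]-K` membership signature reads through it. Assembled
sequences are sanitized: any zero-mismatch library hit not contained in
an intended implant gets one linker residue flipped to `G` (glycine runs
satisfy no bundled pattern).

Realism knobs (defaults): `mutation_rate=0` per-residue substitutions
with `protected_fraction=0.25` of motif positions spared;
`truncation_prob=0` with `truncation_fraction=0.3` clipped from a random
end; decoys (half plain random, half "near-miss" carrying a TEY but no
catalytic subdomains), regenerated until the family gate stays silent.
Mutation positions are drawn **rate-independently** (a per-position
uniform compared against the rate, from a per-record child seed), so the
mutation sets at increasing rates are nested and motif evidence can only
degrade as the rate grows — the property the degradation acceptance test
asserts.

Gene models sample intron counts from an empirical census over 0–16
introns (mode at 5 and 9); a configurable fraction of multi-exon models
(`utr_intron_fraction`, default 0.1) place their first intron entirely
inside the 5′ UTR (150 bp UTR5, 120 bp UTR3, introns 80–200 bp, CDS
length 3·protein+3, strands alternating). Everything is deterministic
under the spec seed via `numpy.random.SeedSequence` spawn keys.

## 8. Problem sizes used in the tests

- matcher↔oracle equivalence: 1000 random instances (alphabet of 4,
  sequence length ≤12, ≤4 elements, tolerance ≤1);
- recovery: 100 mutation-free records (10 per family × group), 100%
  family and group accuracy required;
- degradation: 20 records per rate over rates {0, 0.02, 0.05, 0.1};
- naming recovery: 30 mutated reference copies (seeds 1–10, 5%
  substitution), ≥95% number recovery required;
- gene models: 200 models, exact intron-histogram round-trip and a 99%
  binomial confidence check of the UTR-intron fraction.
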