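# Methods

## Model and procedure

The package implements a consensus-transfer model of opsin spectral
tuning: λmax differences between opsin families are attributed to the
identities of the ~35 residues lining the retinal-binding pocket, so a
short-wavelength receptor can be moved toward a target λmax range by
replacing its pocket residues with the residues conserved in naturally
long-wavelength opsins. The procedure is:

1. Bin annotated opsins into spectral classes by λmax. The default bins
   are 332–340, 520–540, 540–557 and 557–625 nm. Bins are half-open
   [low, high) so that the printed shared boundaries (…–540 / 540–… /
   557–…) partition the axis; the topmost bin closes its upper bound.
   The 332–340 nm bin is transcribed from its source as printed even
   though it is an unusually short (near-UV) range for a "blue" class.
2. Align each opsin to the reference sequence independently (global
   Needleman–Wunsch, affine gaps) and read off the query residues in the
   35 alignment columns holding the reference's pocket positions. This
   reference-anchored scheme replaces a joint progressive MSA: pocket
   positions are defined in reference coordinates, so per-sequence
   anchoring is sufficient, exactly testable against a brute-force
   oracle, and has no guide-tree or ordering artifacts. No sequence
   weighting (e.g. redundancy down-weighting) is applied to profiles.
3. For each class, compute per-column gap-excluded residue frequencies,
   information content IC = log₂20 − H (H the Shannon entropy, so
   IC ∈ [0, 4.32] bits), and the consensus residue with its conservation
   fraction. Gaps are reported as a separate per-column fraction;
   columns with gap fraction > 0.5 are flagged low-coverage and excluded
   from design. `X` (unknown) residues are excluded from both numerator
   and denominator.
4. Propose one candidate substitution per column where the target-class
   consensus (i) differs from the wild-type residue and (ii) has
   conservation ≥ `min_conservation` (default 0.5, i.e. a majority
   residue). Candidates are ranked by conservation × information
   content and nested designs are the top-k prefixes of the ranking.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| substitution matrix | BLOSUM62 | half-bits | standard protein default |
| gap open / extend | 11 / 1 | score | BLAST-style protein defaults; gap of length L costs 11 + L |
| min_conservation | 0.5 | fraction | a consensus below majority is not a class signature |
| low-coverage cutoff | 0.5 | gap fraction | a mostly-deleted column cannot anchor a substitution |
| codon table | human usage | fractions | swappable; only "most-frequent codon" optimization is offered |

The ranking criterion (conservation × information content) is this
package's choice — the underlying design procedure only states that
conserved long-wavelength residues are recruited, not how they were
ordered into the 17/18/19 tiers (why F282Y enters at ROM18 and A199S
only at ROM19 is not derivable from the data). The published nesting is
therefore reproduced under an explicitly supplied ranking in tests, not
claimed as the unique output of the scorer. An optional source-profile
filter (require the proposed residue to be rare in the wild type's own
class) exists but is off by default. Predicted λmax is always the target
class *range*; no residue→wavelength regression is attempted.

## Numerical and tie-break choices

- Alignment traceback is deterministic: at equal score, a diagonal step
  is preferred over a gap in the query, which is preferred over a gap in
  the reference. Scores are compared with a 1e-9 tolerance.
- Consensus ties break alphabetically by one-letter code; candidate
  rank-score ties break by ascending pocket index (equivalently,
  ascending residue number, the map being monotone).
- Preferred-codon ties break alphabetically by codon.
- Column frequencies must sum to 1 within 1e-9 before information
  content is computed; codon-usage fractions are normalized per amino
  acid at table construction.
- The residue-number → pocket-index map is inferred by pairing the
  position-sorted mutation list with the ascending differing columns —
  the unique monotone bijection — and verifying both residue identities
  at every pair. Verification failure is an error, never a trigger for
  searching alternative pairings. The inferred map covers only the 19
  mutated indices; the other 16 pocket indices have unknown residue
  numbers and are reported as unmapped, never guessed.

## The curated design set and its known inconsistencies

The packaged data record for the Opto-mGluR6/ROM series follows the
narrative mutation lists (ROM17 = 17 shared substitutions; ROM18 adds
F282Y; ROM19 adds F282Y and A199S), which the ROM19 pocket string
corroborates. Two inconsistencies in the source material are surfaced by
`validate_reference_designs` as structured discrepancies rather than
corrected: the published ROM18 pocket string equals ROM17's (it lacks
the F282Y column at pocket index 27), and the tabulated mutation-point
lists are permuted across variant rows relative to the narrative. ROM19's
λmax is stored with both published values — 605 nm (spectrophotometry,
the default) and 606 nm (the design announcement, used when computing
the announced 40/70/126 nm red-shift extrema).

## What the simulator emulates — and what it does not

`generate_family` emulates families of opsins stratified into spectral
classes: a shared 340-residue scaffold (a class-A GPCR length), 35
pocket positions (the 19 known residue numbers 75…314 at their pocket
indices plus 16 arbitrary interleaved placeholders), class-specific
planted residues carried with probability `conservation` (non-carriers
draw uniformly from the other 19 residues), independent uniform
background substitutions elsewhere (default rate 0.02), and λmax drawn
uniformly within the class bin. Defaults are two classes — an
Opto-mGluR6-like 470–490 nm class and a red 557–625 nm class differing
at the 19 known indices — with 50 sequences per class and conservation
0.9. All randomness flows through one integer-seeded numpy generator;
replicate seeds are explicit configuration, never wall-clock derived.

The simulator deliberately omits phylogenetic correlation between
sequences, indels, compositional biases, and any energetic coupling
between residues and λmax. Passing recovery tests therefore shows that
the pipeline extracts exactly the class-discriminative signal present
under an independence model with known truth — not that the designed
substitutions shift real absorption spectra, which is a wet-lab question.

## Problem sizes

The test suite and the acceptance script run the recovery experiment at
30 sequences/class (noise-free) and 100 replicates of 50 sequences/class
(conservation 0.9), with exhaustive alignment-enumeration oracles
restricted to sequence pairs of length ≤ 6 over a 4-letter sub-alphabet
— sizes at which the brute-force oracles are exact and the full suite
completes in well under a minute.

## Known limitations

- Pairwise reference anchoring cannot represent columns absent from the
  reference (insertions in a query are dropped from pocket extraction).
- The designer treats columns independently; covarying residue pairs
  are invisible to it.
- Back-translation offers only most-frequent-codon optimization; RNA
  secondary structure and folding energies of the resulting constructs
  are left to external tools.
- Structure-based filtering (docking, ΔΔG) of candidates is out of
  scope; the design space is substitution-only, with no insertions or
  deletions.
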