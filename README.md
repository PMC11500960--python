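# opsintune

Consensus-guided spectral tuning of opsin retinal-binding pockets.

## The problem

Opsins are G-protein-coupled photoreceptors whose absorption maximum
(λmax) is set largely by the ~35 residues lining the retinal-binding
pocket — the "opsin shift". Engineering a red-shifted opsin variant
therefore reduces to a sequence-analysis problem: find which pocket
residues distinguish naturally long-wavelength opsins from the parent, and
substitute them in. That is how the ROM series was derived from
Opto-mGluR6 (a melanopsin/mGluR6 chimera, λmax 480 nm): ROM17, ROM18 and
ROM19 carry 17, 18 and 19 pocket substitutions and peak near 520, 550 and
605 nm.

`opsintune` packages that design procedure for protein engineers:

- **Stratify** annotated opsins into spectral classes (λmax bins such as
  520–540, 540–557, 557–625 nm; half-open intervals, top bin closed).
- **Align** each opsin to a reference with global Needleman–Wunsch
  (affine gaps, BLOSUM62 by default) and extract the 35 pocket columns
  defined in reference coordinates.
- **Profile** each class column-by-column: gap-excluded residue
  frequencies, information content IC = log₂20 − H (bits, the scale of
  sequence-logo stacks), and the consensus residue with its conservation.
- **Design**: propose the target class's conserved consensus residues
  wherever they differ from the wild type, rank by
  conservation × information content, and cut nested variant series
  (top-k prefixes) from the ranked list.
- **Bookkeep** substitutions in `X<pos>Y` notation (1-based): parse,
  apply, diff, infer the residue-number → pocket-index map by monotone
  constraint satisfaction, and back-translate designs to codon-optimized
  DNA with a swappable codon-usage table.
- **Simulate** opsin families with planted class-discriminative pocket
  residues at controllable conservation, and measure end-to-end recovery
  of the planted signal.

## Worked example

Rebuild the ROM variants from their mutation lists and audit the packaged
design set:

```bash
python examples/04_reconstruct_and_back_translate.py
```

```
wild-type pocket: VIAFYAGAFGIMAWETSCSWYLFVFLFWYSAPAVA
ROM17: WMSSYGVSCGILAWETSCGPVLMCCLFWYTAPAYA  (17 substitutions)
ROM18: WMSSYGVSCGILAWETSCGPVLMCCLYWYTAPAYA  (18 substitutions)
ROM19: WMSSYGVSCGILSWETSCGPVLMCCLYWYTAPAYA  (19 substitutions)

ROM19 pocket DNA (105 nt):
TGGATGAGCAGC...TACGCC
translates back to input: True
```

Each line is the 35-residue pocket after applying that variant's mutation
list (V75W, I76M, … V314Y) to the wild type through the inferred
coordinate map; the mutation counts confirm the nested 17/18/19 series,
and the DNA line is the most-frequent-human-codon encoding of the ROM19
pocket. The full-length design entry point is the library call
(`propose_mutations` → `build_variant_series`) or the CLI:

```bash
opsintune validate-designs          # audit the packaged ROM design set
opsintune simulate --seed 0         # emit a synthetic family
opsintune recover --seed 0          # planted-substitution recovery
opsintune design fam.fasta fam.tsv --wt wt.fasta --pocket-map map.tsv \
    --classes classes.yaml --target-class 557-625 --sizes 17,18,19
```

The other `examples/` scripts cover class profiling, candidate ranking
and the recovery experiment; each prints what it computes and says what
the numbers mean.

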