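# mocrkit

Tools for asking, of a family of two-domain bacterial transcriptional
regulators, three questions that comparative genomics keeps raising:

1. **Does a candidate subfamily form a real group?**  MocR/GabR-type
   regulators couple an N-terminal winged helix-turn-helix (wHTH) DNA-binding
   domain to a large C-terminal domain homologous to fold type-I
   PLP-dependent aminotransferases (AAT).  A subset of them — here called
   YczR — sits head-to-head with genes for uncharacterised YczE membrane
   proteins.  `mocrkit` filters redundancy, builds UPGMA cladograms on
   amino-acid-difference distances with column-bootstrap supports, and tests
   whether the labelled set clusters in one subtree.
2. **Which alignment columns make the subfamily special?**  Two independent
   statistics locate specificity-determining positions (SDPs): a
   mutational-correlation score (Spearman rank correlation between per-pair
   residue similarity and same-subfamily membership, per column) and a
   correspondence-analysis score (between-cluster separation of each
   column's residue indicators in the reduced sequence space).  Because SDP
   calls are sensitive to alignment quality, predictions from two alternative
   alignments of the same sequences are combined under a consensus rule:
   a column counts only if both methods flag it in one alignment and at
   least one flags it in the other.
3. **What does the regulator bind?**  Intergenic regions are searched for
   5–8 bp words repeated directly or invertedly with a bounded spacer — the
   footprint a homodimer leaves on its operator — ranked into PWMs, scanned
   with exact p-values (dynamic programming over the discretised log-odds
   score distribution), and checked for regulon-specificity with a
   per-region Bonferroni-corrected best-match test.

Every stage is exercisable without downloads: the `synth` module generates
protein families and intergenic regions with planted, machine-readable
ground truth (diagnostic columns, conserved columns, motif coordinates).

## Worked example

```bash
mocrkit generate-fixture demo --seed 0     # synthetic inputs + config
mocrkit run-all demo/config.yaml           # full pipeline
```

The fixture is a 40-sequence family (20 "YczR" + 20 "MocR") of 200 aligned
columns with 8 planted SDP columns, 30 conserved columns and a clustered
background, two alternative gap placements of the same sequences, 20
intergenic regions of 100 bp carrying `GGCCA … N12 … TGGCC`, and 50
background sequences.  The run report (excerpt, exactly as printed):

```json
{
  "n_input": 40,
  "n_representatives": 40,
  "clade_found": true,
  "clade_support": 0.955,
  "consensus_columns": [6, 15, 41, 48, 53, 65, 71, 85, 90, 94, 100, 105,
                        122, 143, 159, 165, 168, 173],
  "top_motif_consensus": "GGCCA",
  "top_motif_architecture": {
    "width": 5, "coverage": 1.0,
    "n_inverted": 23, "n_direct": 10,
    "modal_spacer_inverted": 12
  },
  "uniqueness_regulon_fraction": 1.0,
  "uniqueness_background_fraction": 0.04
}
```

Reading it: the labelled subfamily is an exact clade with bootstrap support
0.955 (200 replicates); 18 columns pass the dual-alignment SDP consensus —
all of them genuinely group-separating in the planted truth, including all
8 planted SDPs (`demo/family_truth.tsv`); the top discovered motif is the
planted word with its inverted repeat at the planted 12-bp spacer; and the
full-site score matrix is significant (α = 0.05, Bonferroni per region) in
every intergenic region but in only 4% of background sequences.
`consensus_reference_residues` gives the same columns in 1-based residue
numbering of the reference sequence, the numbering logos use.

Machine-readable outputs land in `demo/results/`: cluster report,
distance matrix, Newick tree with supports, per-column SDP table, logo
data per group, motif/occurrence tables, a MEME-format PWM and the
uniqueness verdicts.  Identical config + seed reproduces every file
byte-for-byte.

Subcommands `filter`, `tree`, `sdp` and `motif` run single stages; see
`mocrkit --help`.

## Scope

Alignments are inputs (MUSCLE/ClustalO-style computation is upstream);
database retrieval, homology modelling and promoter −35/−10 element
detection are out of scope.  See `docs/methods.md` for the model
assumptions, parameter defaults and known limitations.
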