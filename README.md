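# biopepsim

Bioactive peptide mining and in silico proteolysis for protein sequences:

- **Profiling** — locate every occurrence of reference bioactive peptides
  (e.g. DPP-IV- and ACE-inhibitory di/tripeptides) in a protein and compute
  the per-activity frequency-of-occurrence statistic **A = a/N** (a =
  occurrence count, N = residue count).
- **Digestion** — simulate enzymatic hydrolysis with declarative
  P2-P1-P1′-P2′ cleavage rules for one to three proteases at once (union of
  cut sites), match released fragments against the reference set
  (whole-fragment exact match), and rank proteases by released bioactive
  peptides.
- **Mass spec utilities** — monoisotopic peptide masses, multiply-charged
  m/z values, isotope-peak spacing and charge-state inference.
- **Homology stats** — identities / positives / gaps counts and integer
  percentages on a given pairwise alignment (BLOSUM62 positives).
- **Synthetic data** — seeded generators for random proteins, planted
  bioactive motifs and planted cleavage sites with exact ground truth, so
  every stage is testable offline.

The package ships a small curated reference-peptide fixture (TSV), a
documented cleavage rulebook (YAML, PeptideCutter-style simplifications
restricted to the four-residue window), and a deterministic 615-residue
example protein. User-supplied reference tables and rulebooks are
first-class inputs; released-count results always depend on the reference
table in use, which is recorded in every run manifest.

## CLI

```sh
# occurrence profiling (A = a/N per activity)
biopepsim profile --fasta proteins.fasta [--refset ref.tsv] [--format json]

# in silico digestion with up to three enzymes, plus fragment matching
biopepsim digest --fasta proteins.fasta --enzymes "pepsin (pH > 2),trypsin" --missed 0

# rank bundled proteases by released peptides of one activity
biopepsim rank-enzymes --fasta protein.fasta --activity "DPP-IV inhibitor" \
    --combination "trypsin,chymotrypsin A"

# peptide masses and charged ions
biopepsim mass --peptide LVEPELFEYSGVYPK --charge 2

# seeded synthetic fixtures with ground truth
biopepsim synth protein --length 615 --seed 1 --out synth.fasta
biopepsim synth motifs --length 200 --motif "GP:ACE inhibitor" --copies 3 \
    --seed 1 --out-fasta m.fasta --out-truth m.json
biopepsim synth cleavage --enzyme trypsin --sites 4 --seed 1 \
    --out-fasta c.fasta --out-truth c.json

# full reproducible pipeline (profile -> digest -> match) from YAML config
biopepsim run --config run.yaml
biopepsim run --fasta proteins.fasta --enzymes trypsin --outdir out/
```

`run` writes `profile.tsv/json`, `release.tsv/json` (zero cells rendered
`ND` in the TSV, `0` in JSON) and a `manifest.json`; outputs are
byte-stable across identical runs (only the manifest carries a timestamp).

## Conventions

- Internal coordinates 0-based half-open; all reports 1-based inclusive.
- Occurrence counting is per position (overlaps and multiplicity count);
  a peptide with k activity labels counts once per activity.
- Report rounding is half away from zero (3 decimals for A, 2 for masses,
  integer percent for alignments).
- Combined digestion is simultaneous (site union), never sequential.
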