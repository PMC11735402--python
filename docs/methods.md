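# Methods

`sgescan` implements the computational side of a saturation genome
editing (SGE) deep mutational scan of a transcript region: a pooled
screen in which every possible variant of one or more exons (plus their
intronic flanks) is engineered at the endogenous locus, cells are grown
with and without a selective stimulus, and variant fitness is read out
by amplicon sequencing. This note records the models, conventions and
numerical choices behind each stage, and what the synthetic screens do
and do not demonstrate.

## Transcript model and consequence annotation

A `TranscriptModel` is a genomic segment in transcript-strand
orientation with 0-based half-open exon intervals, a CDS offset on the
spliced sequence, and the protein position of the first complete codon
(`codon_offset`, e.g. 126 when the first scanned codon is residue 126).
Each exon ± `flank_len` intronic nucleotides (default 12) is a *variable
region*; `constant_len` nucleotides (default 13) on either side form the
constant frames used as amplicon anchors. Introns are validated against
the canonical GT..AG rule (warning, not error, to tolerate annotation
oddities).

Consequences are annotated by reconstruction, not by rules: the edit is
applied to the genomic sequence, exon boundaries are re-mapped across
the indel, and the edited gene is re-spliced and re-translated.

* Disruption of an invariant GT/AG splice dinucleotide takes precedence
  over any coding classification (such variants are uniformly
  loss-of-function in the assay this emulates).
* Edits touching only intronic positions are `intronic`.
* Otherwise the class follows from the spliced-CDS comparison:
  frame-breaking length change → `frameshift`; in-frame length change →
  `inframe_indel`; equal length → `synonymous` / `missense` / `nonsense`
  by protein diff.
* `introduces_ptc` is true when the edited translation contains a stop
  strictly earlier than the wild-type stop. A frameshift whose shifted
  frame reaches the transcript end without a stop is *not* PTC.
* Edits spanning an exon/intron boundary are classified by their exonic
  effect and carry a `spans_boundary` flag; an insertion exactly at a
  boundary is assigned to the intronic side (deterministic convention).

Indels are left-aligned (VCF-style) within the variable region so that
homopolymer-ambiguous events have one canonical representation. The
standard nuclear genetic code is used; no selenocysteine handling.

## Library design

Per variable region the enumeration comprises: all 3L single-nucleotide
substitutions; per complete codon, the multi-nucleotide substitutions
needed so that the 19 missense targets plus STOP (and one synonymous
codon where the amino acid has more than one codon) are all reachable —
each chosen by minimal Hamming distance to the reference codon,
lexicographically smallest on ties (configurable); all 4L single-base
insertions (anchored before positions 0..L−1); and all deletions of 1–3
nt (3L−3 raw for L ≥ 3). Met and Trp have no synonymous entry; codons
spanning exon boundaries are excluded from the amino-acid enumeration —
both mirroring the screen design this reproduces.

Records are deduplicated by resulting sequence with precedence
substitution > deletion > insertion, then 5'-most, then alphabetical
alternative — the simplest mutational explanation of a sequence wins.
The resulting library has minimum pairwise Hamming distance 1 among
equal-length distinct members (two substitutions at one position), which
is exactly why read counting can and must be exact-match.

`silence_motif` removes restriction-site occurrences (default BbsI,
GAAGAC, both strands) before enumeration: coding occurrences by the
first synonymous codon swap (codons 5'→3', codons alphabetical) and
intronic occurrences by the first single-base change (positions 5'→3',
bases alphabetical) that eliminates the site without creating a new one
or touching splice dinucleotides; the protein is verified unchanged.

## Counting

Merged reads are trimmed of their constant flanks (anchored Hamming
comparison with a configurable mismatch tolerance, default 0) and the
interior is looked up in a hash of full variable-region sequences.
Wild-type reads and non-matching reads are tallied and discarded. No
1-mismatch rescue is offered: with adjacent library members one
substitution apart, error-tolerant matching would systematically
misassign reads. FASTQ qualities are ignored; error correction is the
job of the upstream overlap merge.

## Scoring

For each replicate pair (treated, control):

* ES_v = log2 f_t(v) − log2 f_c(v), with f = (c + 0.5)/(N + 0.5) from raw
  counts (pseudocount 0.5, the log-ratio estimator convention).
* RFS_v = (ES_v − x̃_non) / (x̃_non − x̃_syn) × 2 + 1, where x̃_non and
  x̃_syn are the medians of the nonsense and synonymous controls *within
  the same exon sub-library and replicate*. By construction the nonsense
  median maps to +1 and the synonymous median to −1, exactly, in every
  replicate and region; this anchoring is what makes screens comparable.
* RFS_median is the elementwise median across replicates (dispersion:
  median absolute deviation).

Significance uses the count score s = log2((c1+0.5)/N1) −
log2((c0+0.5)/N0) with SE = sqrt(1/(c1+0.5) + 1/(c0+0.5))/ln 2 (the
delta-method Poisson error of a log ratio). Replicates are pooled by
inverse-variance weighting; the pooled score is mapped onto the RFS
scale (the affine map also scales the SE by |2/(x̃_non − x̃_syn)|). Each
variant is then tested one-sided against the null that its score is at
or below the synonymous level: the null mean is the inverse-variance
weighted mean of synonymous scores (the weighting the source analysis
leaves unspecified; inverse-variance is the natural choice for a
weighted mean of estimates with known SEs), its variance 1/Σ(1/SE_i²),
z = (s − μ_syn)/sqrt(SE² + SE_μ²), upper-tail normal p, and
Benjamini–Hochberg q across all tested variants. Variants below a
configurable minimum control count (default 0) are flagged, not dropped.

## NMD detection

Relative abundances are computed per replicate for genomic DNA and mRNA
(cDNA) count tables with the same 0.5 pseudocount, aggregated across
replicates by the median, and compared as log2FC = log2(mRNA) −
log2(DNA). A variant is NMD⁺ iff log2FC < −2 (strict: exactly −2 is
NMD⁻). Variants with mean cDNA count below 5 are marked not evaluable
rather than classified. Median-of-abundances before the ratio (rather
than per-replicate ratios) is used because the readout being emulated
reports median abundances per material.

## Clinical calibration and evaluation

* `classify_function`: abnormal iff RFS > 0 (strict; 0 itself is
  normal). The threshold is configurable; an optional control-fit mode
  was considered and rejected as the default because the emulated
  analysis uses the sign of the RFS directly.
* Confusion metrics report None (not 0) on empty denominators.
* PR and ROC curves group tied scores into single threshold steps and
  integrate trapezoidally in threshold-sweep order, so tied blocks are
  zero-width vertical steps — sorting by recall instead silently
  reorders ties and biases PR-AUC downward; both curves are validated
  against an exhaustive-threshold brute-force oracle.
* OddsPath: P1 = pathogenic fraction of all controls; PS3 uses P2 =
  pathogenic fraction among variants called abnormal, BS3 uses the
  pathogenic fraction among variants called normal; OddsPath =
  [P2(1−P1)]/[(1−P2)P1]. Strength labels follow the published ACMG/AMP
  functional-evidence thresholds (supporting/moderate/strong/very strong
  at 2.1/4.3/18.7/350 and 0.48/0.23/0.053/0.0029); the table is
  configurable. A zero misclassification cell yields ±∞ unless the 0.5
  continuity correction is requested.
* Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| with sample (ddof=1) SDs.
* External screens are rescaled with the same control-anchored map;
  quadrants split at (0, 0) with strict > 0 on the positive side, so
  (0, 0) is lower-left.
* Mutational probability: signatures SBS1..SBS21 (or any 96-channel
  matrix) are averaged weighted by prevalence; each SNV maps to its
  pyrimidine-strand trinucleotide channel (purine references are
  reverse-complemented together with their context). Region-edge SNVs
  and indels are not applicable.
* Correlations are Spearman with the two-tailed t-approximation p.

## Structure features

PDB text is parsed with gemmi (first model only; HETATM retained and
flagged). The default inter-residue distance is the minimum heavy-atom
distance — contact-map semantics — with a Cα mode for speed; the choice
is exposed because the upstream tool being mirrored documents the map
but not the metric. TOP/BOTTOM/CENTER features are arithmetic means of
distances to the fixed reference residue sets (248/273/277/280,
153/225/260, 195/236/253 in the p53 DBD numbering); a residue inside a
reference set contributes its own zero self-distance (flagged in
output). Interface membership: any heavy atom within 10 Å of any
partner-chain heavy atom.

## Synthetic screens

`SimulationConfig` defaults define the emulated study conditions:
coverage 500 reads per variant, 3 biological replicates, 12-nt flanks
and 13-nt constant frames, 30-fold mRNA depletion of PTC variants, and a
0.55 LOF weight for the missense mixture (echoing the observed majority
of substitution variants with positive scores; a free parameter, not a
claim). The default mini-gene has two 60-nt exons with 30-nt introns —
large enough for ~2,000 variants while keeping the suite fast. Class
fitness distributions sit at ±1 with small spreads (nonsense/frameshift
+1, synonymous/intronic −1, in-frame indels +0.8, missense mixture at
±1 with sd 0.3); splice-dinucleotide variants are forced LOF.

Selection is an exponential growth differential: treated expected
abundance ∝ f₀ · 2^(g·fitness) (default g = 2, giving roughly a 4-log2
separation between control classes, comparable to a strong selective
stimulus). Initial abundances are Dirichlet perturbations of uniform
(concentration 50 per variant, mild clone-size variation); reads are
drawn multinomially at depth × n_variants per sample. This makes ES
linear in fitness, matching the affine RFS construction — which is a
modeling convenience, not a property of real screens.

mRNA simulation: the PTC depletion multiplier is *calibrated* so that
the observed post-renormalization mRNA/DNA abundance ratio of PTC
variants equals exactly 1/nmd_fold (solve m/Z = 1/k with Z the
renormalization mass). This matches how fold depletion is measured from
paired abundance tables; a naive "divide by k then renormalize" would
make the realized depletion depend on the library's PTC fraction.
Non-PTC variants consequently sit slightly above log2FC 0 (by
−log2 of the lost mass), which the NMD threshold at −2 is insensitive
to.

All randomness derives from the single config seed via named
`SeedSequence` sub-streams; identical configs are bit-identical.
Optional read emission (constant flanks + variant sequence, configurable
per-base error, default 0) exercises the counting path end to end.

### What the simulations do not show

The generator reproduces multinomial sampling noise, clone-size
dispersion, replicate structure and class-conditional fitness — not PCR
jackpots, position-dependent sequencing error, editing-efficiency
gradients, cryptic splice effects of exonic SNVs, or cell-state
heterogeneity. Passing recovery tests therefore validates the
*inference machinery* (scores, tests, classifiers) under the stated
noise model, not the experimental robustness of any particular screen.

## Known limitations

* Single-transcript, single-region-per-exon model; no genome-wide
  annotation and no consequence ontology beyond the screen's classes.
* The full published TP53 exon 5–8 library (9,225 variants) can be
  regenerated only when the user supplies the reference genomic model
  (`data/tp53_exon5_8.fa/.yaml`); the reference sequence is not
  redistributed with the package.
* Frequency-mode enrichment scores require nonzero control frequencies;
  count mode with pseudocount 0.5 is the robust default.
* The z-test treats replicate pairs as independent; shared-library
  correlations across conditions are not modeled (the null-calibration
  test shows the type-I error is near nominal under the simulator's
  assumptions).
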