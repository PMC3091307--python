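# Methods

## Scope and model

`isofunc` asks, for each coding splice isoform observed at the transcript
level, whether the available evidence is consistent with a functional
protein product. The analysis has no fitted model: it is a deterministic
pipeline of interval arithmetic, rule application and confusion-matrix
accounting, plus a calibration helper (mean ± k·SD) for the packing-score
thresholds. Its assumptions are therefore structural:

- peptide evidence is trusted at the sequence level (exact substring
  matching; no I/L equivalence, PTMs or FDR modelling — upstream search
  pipelines own those concerns);
- a peptide identifies an isoform only when its genomic footprint lies
  wholly inside sequence private to that isoform; exon-spanning peptides
  are excluded outright, even where a junction is jointly unique to one
  isoform (the conservative reading of the non-exon-spanning filter);
- absence of peptide evidence is never proof of absence; the unknown set
  only bounds specificity from below.

Coordinates are 0-based half-open everywhere; GFF3 input (1-based
inclusive) is converted on read. Exon identity is by genomic interval,
not exon id. UTR-only duplicate isoforms are collapsed *before* exon
classification (the alternative order is defensible; this one means class
frequencies are not inflated by coding-identical transcripts).

## Region classification

Per gene, exons are constitutive (interval present in every isoform),
semi-constitutive (in >1 but not all), specific (in exactly one, no
partial overlap with other isoforms' exons) or partially overlapping
(≥1 shared base, non-identical boundaries, against other isoforms only).
A boundary sweep refines this to per-base regions; regions covered by one
isoform (class `specific` or `partially_overlapping_specific_part`) are
its specific regions. No minimum region length is imposed — short regions
are filtered naturally at the peptide level, since a tryptic peptide of
7+ residues cannot sit inside them.

## Detectability

Unknown-set candidacy requires that some tryptic peptide from the
isoform's specific regions would plausibly be observed (score ≥ 0.5,
boundary inclusive). The bundled scorer is an explicit stand-in: 0 outside
the expected 7–66 residue range, otherwise a fixed logistic in peptide
length and hydrophobic fraction, `σ(0.25·(L−12) + 4·(h−0.4))`. It is not a
trained proteotypicity model; externally computed per-peptide scores
(TSV column `score`) override it and are the recommended route for real
data. Missed cleavages default to 0 (configurable).

## Dataset construction

Per AS gene with both candidate types: shortest identified isoform →
ASPos, longest detectable unidentified isoform → unknown; ties break by
lexicographic isoform id; genes lacking either candidate contribute
nothing to the paired analysis. Negative ORFs: first AUG, translate to
first stop (or transcript end), keep ≥ `min_orf_len` (default 100)
residues, longest `n` (default 555) with ties by transcript id.
Expression: probe-set value = median over tissues; isoform expression =
median of probe sets lying *wholly* within the isoform's specific regions
(boundary-crossing probe sets excluded); even counts take the midpoint of
the central pair.

## Descriptor thresholds

| parameter | default | role |
|---|---|---|
| `hmm_coverage_min` | 0.70 | domain truncated strictly below this HMM coverage |
| `evalue_max` | 1e−5 | domain-hit filter (inclusive) |
| `deletion_gap_max_A` | 15.0 Å | max accommodable deletion flank distance (strict) |
| `insertion_core_len` | 3 | residues tolerated between buried flanks |
| `core_sasa_max_A2` | 5.0 Å² | burial criterion for insertion flanks |
| `os_min` | 0.54 | occluded-surface packing floor |
| `packeff_min` | 25.9 | packing-efficiency floor |
| `model_coverage_min` | 0.90 | below this, the structural descriptor is not applicable |
| `sd_multiplier` | 2 | calibration width for `derive_threshold` |
| `pops_value` | 25.5 | calibrated solvent-accessibility operating point; deliberately not wired to any rule (its role in the original rule set is ambiguous; the 5 Å² per-residue criterion is what the insertion rule states) |

Packing floors correspond to mean − 2·SD over a reference set of
high-resolution monomeric crystal structures; `derive_threshold` (sample
SD, ddof=1) reproduces that calibration and is translation-equivariant.
The coverage in `model_coverage_min` is *target* coverage (fraction of the
candidate sequence aligned); template coverage would be an alternative
reading. Multiple hits of one HMM on one isoform are represented by the
maximum single-hit coverage — split hits are not chained into a
spuriously complete domain, and chaining is not attempted in the other
direction either. Packing rules fire only when the template itself clears
the threshold, so template-quality problems are not charged to the model.
A rule whose inputs are missing (no coordinates for a flank, no packing
score) is skipped with a warning rather than guessed.

Active-site retention maps each annotated codon through genomic
coordinates: retained iff all three bases are present, contiguous in the
candidate's spliced CDS and at a codon-aligned offset. A codon retained
but shifted out of frame counts as lost — the residue identity is
destroyed by the frameshift.

`compute_sasa` (used only when per-residue SASA is not supplied) is a
Shrake–Rupley-style sampler: each atom's probe-expanded sphere (probe
1.4 Å, van der Waals radii by element) is sampled with a deterministic
Fibonacci point set (960 points by default); per-atom accessible area is
summed per residue.

## Evaluation

TP/FN count positives (consistent/loss), FP/TN the comparison set;
not-applicable isoforms enter no cell and reduce coverage only. The
coverage denominator is the combined positive + comparison size
(1110 for the benchmark tables). For a combination, applicability is
any-member (union) or all-members (intersection); the verdict on
applicable isoforms is consistent only when every applicable member
agrees — discordant isoforms count as loss. A consequence worth stating:
the identity TP(A∪B) = TP(A) + TP(B) − TP(A∩B) holds exactly only when no
both-applicable positive is discordant; in general
TP(A∪B) + D = TP(A) + TP(B) − TP(A∩B), with D the count of such
isoforms (`discordant_positives`). The benchmark tables satisfy D = 0.

Report tables round to 2 decimals, halves away from zero, computed from
integer counts via decimal arithmetic (so exact halves like 101/200 round
predictably); full precision is retained alongside. In table-reproduction
mode a printed cell is accepted when it is within half a printed unit
(|full − printed| ≤ 0.005) of the recomputed ratio; the tool reports the
recomputed values and flags the four benchmark cells that disagree with
their own counts beyond that tolerance, rather than matching misprints.

## Synthetic cohorts

The generator emulates the statistical structure of the benchmark study,
not its biology:

- **Gene geometry.** Every exon length is a multiple of three, so any
  exon subset is in frame and no codon straddles a junction. Frameshift
  and junction-straddling cases are exercised by hand-built fixtures in
  the test-suite, not by generated cohorts. Each pair gene gives the
  positive and the unknown partner one private exon each; optional third
  isoforms create semi-constitutive exons and optional 3′-extended exon
  copies create partially overlapping ones. About 30% of genes are placed
  on the minus strand.
- **Observation model.** Each tryptic peptide (7–66 aa) of a translated
  isoform is observed independently with probability 0.35; one specific
  peptide of each positive is always observed, and a candidate gene
  enters the cohort only if its positive has an observable specific
  peptide and its partner is detectable — rejection sampling that mirrors
  how the real paired cohort is conditioned on exactly these events.
  Non-translated isoforms emit nothing.
- **Planted descriptor states.** Applicability and loss are Bernoulli per
  isoform (active sites per gene), with defaults equal to the rates in
  the benchmark tables (e.g. structural applicability 147/555 positives,
  145/555 unknowns; unknown-set active-site loss 31/79). Artifacts are
  then *constructed to realise* the planted state: truncated domains draw
  coverage below 0.70, implausible models get one of the four rules
  planted (benign indels live in the first half of the template, planted
  defects in the second, so they cannot interact). Descriptor states are
  planted independently of each other; the real data's correlations
  between descriptors are not emulated, which is why synthetic
  intersection rows differ from the benchmark's even though the single
  rows match. `fraction_functional_unknown` (default 0) optionally labels
  part of the unknown set functional and gives it positive-set rates.
- **Expression.** Log-scale normal, isoform level N(6.0, 0.9²) for
  positives and N(5.2, 0.9²) for unknowns with tissue noise SD 0.45 —
  a 0.8 shift at unit SD, i.e. ≈ 69% distribution overlap.
- **Negatives.** Non-coding transcripts carry a planted ORF behind an
  adenine-free leader (so the planted AUG is first); ORF lengths are
  uniform on 80–700 aa and the longest-n rule operates on the pool.
- One RNG stream per artifact class, spawned from the master seed; runs
  are byte-reproducible.

Passing tests on these cohorts demonstrates that the pipeline's region
arithmetic, mapping, dataset rules and rule engines are correct and
unbiased; they do not demonstrate performance on real annotation, where
exon structures are messier, peptide detectability is sequence-dependent
in ways the stand-in scorer ignores, and descriptor states are correlated.

## Problem sizes used by the tests

The test-suite verifies parameter recovery on a 500-pair cohort with all
descriptors applicable (sensitivity/specificity of every combination
within the binomial 95% CI of the planted rates), brute-force per-base
oracles on 1000 random genes, and the full 16-combination rule-engine
enumeration; the acceptance script runs the full 555/555/865/555
benchmark-shaped cohort. These sizes keep the whole suite under a minute
of compute while leaving Monte-Carlo error well below the tolerances
checked.

## Known limitations

- The detectability scorer is a stand-in; conclusions about *which*
  isoforms are detectable on real data require external scores.
- Occluded-surface and packing-efficiency values are inputs, not
  computed; only thresholding and the 2-SD calibration are implemented.
- No handling of trans-splicing, fusion transcripts, selenocysteine
  recoding, or NMD annotation (NMD transcripts are expected to be
  excluded upstream of the negative set).
- `reproduce_metric_tables` treats published counts as authoritative and
  recomputes metrics from them; it cannot detect errors in the counts
  themselves.
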