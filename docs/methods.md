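# Methods

## Cleavage model and observation convention

Each H4 copy carries one reactive S47C-phenanthroline-Cu⁺ site whose
hydroxy-radical attack positions are fixed relative to the nucleosome dyad:
Watson −2, −3, −4 and Crick −5, −6 for the copy on the negative side of the
dyad; the second copy of a two-H4 particle contributes the reflection
(Watson offset *o* ↔ Crick offset −*o*). Attack removes the deoxyribo-
nucleotide; sequencing-library end polishing (3′ trimming, 5′ fill-in) makes
the downstream fragment's left end map to `watson + 1` and the upstream
fragment's right end to `crick − 1`. This single convention is used by the
simulator, the enumeration oracles, and every empirical statistic; it is the
only place where the base-loss bookkeeping lives.

The *contact weights* are not published as numbers anywhere we could consume
them (they exist only as qualitative shading), so they were calibrated once,
analytically, to the constraint that the predicted mode sets be exactly
{−2, +5, +12} (W–C) and {+1, +7} (W–W′/C–C′): Watson −2:0.7, −3:0.2, −4:0.1
and Crick −5:0.8, −6:0.2, mirrored for copy 2. The calibration is frozen in
`ContactModel.default_two_copy()` and user-overridable through the config.
Within a cut the Watson and Crick offsets are drawn independently.

W–C distance is defined as `left_end − right_end` (giving +5 within one
copy, +12 across the particle, −2 for the particle-spanning pair); W–W′ and
C–C′ use positive lags 1–40 with lag 0 excluded. Distributions are
normalized over their lag window (−40..+40 for W–C).

## Synthetic data generator

The generator emulates the study conditions, not an arbitrary genome:

* 16 chromosomes (default 8 kb) at ~62 % A+T, each with one centromere:
  8-bp CDEI + CDEII (length drawn 78–86 bp unless fixed; A+T fraction drawn
  uniformly in [0.90, 0.98] with the minimum enforced exactly) + 26-bp
  CDEIII. Annotation is emitted in CDEI→CDEIII genomic orientation by
  default; minus-strand annotation is supported and coordinate-reflected by
  every analysis stage (`cen_strands="alternate"` exercises it). We default
  to a single orientation because the floor convention for the CDEII
  midpoint places the reflected composite of an even-length CDEII one bp off
  its mirror image — a display artifact that would blur pooled composites.
* Phased arm nucleosomes (two-H4 particles) every 165 bp, excluded within
  200 bp of mid-Cen (flanking-particle spacing of real centromeric
  chromatin), near chromosome ends, and in optional NDRs.
* Centromeric architecture per `ParticleModel`: `octasome`/`tetrasome` (one
  two-H4 particle at mid-Cen; identical cleavage geometry, both place two
  H4s symmetrically), `hemisome_mixture`, or `none`. A hemisome mixture
  places, per molecule, exactly one single-H4 particle in one of four
  mutually exclusive configurations: orientation (CDEI-proximal vs
  CDEIII-proximal, the reflected contact model) × rotational phase (0 or
  +10 bp toward mid-Cen), with equal proportions by default (the occupancy
  split is not quantified beyond "similar frequencies"; equal is the
  natural default).
* **Junction anchoring.** The hemisome cleavage anchor sits
  `junction_anchor_offset` = 22 bp from the nearer CDEII junction. The value
  was derived once from the composite-peak arithmetic: called maxima sit at
  J1+d−6, J1+d+p−6, J2−d−p+6, J2−d+6, so d = 22, p = 10 yields pooled
  spacings 10/33/53 for 117–120-bp loci and exactly 10/25/45 for a 111-bp
  locus. A junction-anchored model cannot make the inner spacing
  length-independent — it varies with CDEII length by construction — which
  is precisely the behaviour that distinguishes the 111-bp locus.
* Per-particle, per-copy cut probability 0.3 per molecule (sparse cutting:
  most fragments span particle to particle, making the fragment-length
  distribution unimodal above 147 bp). Background cleavage is uniform in
  linkers (2×10⁻⁴ cuts/bp/molecule) and elevated in NDRs; a fixed-site
  mode cuts a motif (e.g. AG^CT) to completion with blunt ends and no base
  loss. Fragments form between consecutive cuts; terminal pieces carrying a
  native chromosome end are discarded (a sequenced fragment needs cleavage
  ends on both sides).
* **AT recovery bias.** Each fragment is retained with probability 1 below a
  0.90 A+T threshold, falling concavely (shape 0.5) to 0.05 at 100 % A+T.
  The statistic is the *maximum A+T fraction over any 50-bp window inside
  the fragment* rather than the whole-fragment average: what sequencing
  discriminates against is the presence of a long extremely AT-rich
  stretch, and a whole-fragment statistic would never flag a 300-bp
  fragment containing all of CDEII (~70 % A+T overall), contradicting the
  observed depletion of long CDEII-spanning fragments and its gradient with
  distance. Whole-fragment mode remains available (`stat="whole"`).

What the generator does **not** model: sequencing errors, duplicates,
mappability, homopolymer structure within CDEII, MNase kinetics, or
cleavage-chemistry kinetics. Passing tests therefore demonstrate the
correctness and discriminating power of the *analysis* under the stated
generative assumptions, not robustness to real-data artifacts beyond the
AT-recovery bias.

## Analysis stages and numerical choices

* Coordinates are 0-based half-open throughout; right end = `end − 1`;
  midpoints use the floor convention; 1-based numbers appear only in
  user-facing reports (e.g. the dyad of a 147-bp template is base 74).
* Fragments <147 bp are excluded by default (nucleosome center-to-center
  spacing bounds a genuine particle-to-particle product); the distance
  statistics can disable the filter.
* Composite histograms stack left+right end counts over strand-reflected
  mid-Cen anchors. Peak maxima are the greedy selection of the n highest
  local maxima subject to a 5-bp separation, ties toward smaller |offset|.
  `call_peak_maxima` defaults to a 3-bp moving average, but the pipeline
  calls peaks on raw 1-bp counts (`peak_smooth_window: 1`): the chemistry
  concentrates end counts on single base pairs, and the dominant
  per-cluster mass is a two-point distribution one bp apart, for which any
  3-bp average makes the two windows containing both points exactly equal
  in expectation — the called maximum would be a coin flip. Smoothing is a
  config key; the acceptance run documents its value (1).
* The near-centromere subset for distance statistics takes fragments with
  *either end* within 125 bp of a mid-Cen (span containment would be
  confounded by the AT bias). Because such fragments can carry their other
  end far away, same-strand distributions in arm-containing genomes pick up
  arm-particle lags; architecture-discrimination analyses therefore use
  centromere-focused simulations.
* Profile scan: members (117–120 bp loci, minus-strand reflected) align at
  their left-most *prominent* peak (≥50 % of the locus maximum — a plain
  left-most local maximum would anchor on background noise), truncated or
  zero-padded to 111 positions. Filters follow the stated two-filter order:
  ≤3 positions with |z| ≥ 3 (sd = 0 positions contribute z = 0), then at
  least one position ≥ the smallest member maximum. Pearson r is computed
  for all windows; zero-variance windows are recorded as failed. Ranking
  ties favour the centromere hit. Jackknife members whose own locus fails
  the filters are reported as excluded, not scored.
* AT census: sliding 83-bp windows at ≥90 % A+T (ambiguous bases non-AT),
  overlapping/adjacent qualifying windows merged into maximal segments.
  Representation uses fragment-end (cleavage-site) counts against the
  genome-wide end density; coverage mode uses span overlap normalized to
  the genome-wide mean (1 = random expectation). The representation-vs-AT
  correlation is reported *signed* (negative under the bias).
* V-plots are count matrices (length × offset); rendering is separate.
  Midpoints of even-length fragments use floor. Coverage equalization
  samples per-anchor midpoint pools without replacement down to the
  smallest non-empty pool; empty anchors are dropped with a warning.
* Ratio tracks use log2((t+0.5)/(c+0.5)); both-zero positions map to 0.

## Statistical checks

The Monte-Carlo equivalence test compares empirical distance distributions
from ≥10⁵ simulated cuts (zero background, high molecule density) with the
enumeration oracle at every lag, at 3 standard errors. The independent
sampling unit is the cleavage event; because pair counts are quadratic in
per-position event counts, the standard error is bounded by twice the
binomial SE on the event count (measured inflation ≤1.5× for same-strand
pairings at this density). High density keeps finite-coverage corrections
(within-molecule pairs are always cross-copy; within-cut pairs always
same-copy) an order of magnitude below that tolerance.

Mixture-proportion recovery uses the simulator's ground-truth event labels
with ≥17,000 centromeric events so that the ±0.01 acceptance band sits
beyond 3 σ of a fair multinomial. The profile-scan recovery and jackknife
properties run over 20 independent seeds on compact 8-chromosome genomes
(600 molecules each); problem sizes throughout the suite were chosen as the
smallest that leave clear statistical margins for the property under test.

## Known limitations

* Per-class composite spacings inherit a ±1-bp wobble from pooling CDEII
  lengths 83–86 under integer midpoint conventions; reported spacings are
  exact only for single-length classes (e.g. the 111-bp run).
* The scan evaluates forward-strand ungapped alignments only, matching the
  one-alignment-per-start accounting; reverse-orientation scanning is not
  implemented.
* The AT-bias retention curve is phenomenological; no attempt is made to
  model the platform mechanism (PCR cluster formation) behind it.
* `find_at_rich_segments` on a real reference genome requires the genome
  FASTA as input; no reference data ships with the package.
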