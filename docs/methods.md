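# Methods

This note documents the models and procedures implemented in `pssearch`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generators do and do not emulate, and the numerical
choices a maintainer would want written down.

## Permissive-stretch detection

### Evidence model

The unit of evidence is an indel between the query protein and one homolog.
In an HSP (a local pairwise alignment that by contract begins and ends on
aligned residues):

* a maximal gap run in the **query** row sits between two adjacent query
  residues *i* and *i*+1 and yields the interval [*i*, *i*+1]
  (*insertion in homolog*: the homolog carries residues the query lacks);
* a maximal gap run in the **subject** row aligned to query residues
  *i*..*j* yields [*i*−1, *j*+1] (*deletion in homolog*), i.e. the gap plus
  both flanking residues — deletion intervals always span gap length + 2.

Coordinates are 1-based inclusive query residue positions throughout; BED
output is the only 0-based half-open surface. In an MSA the same rules
apply per homolog row, with two policies:

* **Terminal gaps are missing data, not indels.** A gap run touching an
  alignment terminus (or whose flank would fall outside the query) is
  discarded. Local alignments never contain terminal gaps; sequence
  fragments in an MSA would otherwise create spurious terminal stretches.
* **`min_support`** (default 1) is the number of homolog rows that must be
  gapped across a candidate deletion run (or carry residues across a query
  gap run) for the interval to count. One gapped homolog is accepted by
  default because a single confident indel is already informative;
  raising it trades sensitivity for robustness against alignment error.

### Merging

Stretches are the connected components of the union of evidence intervals,
where two intervals are connected iff their residue sets intersect.
Adjacent-but-disjoint intervals (e.g. [2,3] and [4,5]) do **not** merge:
the components are taken over the set union as defined, not over an
adjacency closure. Components are reported N→C and labelled with Roman
numerals. Merging is idempotent and order-independent (property-tested
against a brute-force union-find oracle).

### Hit filtering

A homolog hit (all HSPs of one subject) enters detection iff, after
dropping HSPs with E-value ≥ 10⁻³: the union of its HSPs' query ranges
covers ≥ 80% of the query; its aggregate identity (identical positions over
aligned columns, summed across HSPs) is ≥ 30%; and at least one HSP
contains an indel. Coverage and identity are aggregated at hit level, not
per HSP, since a hit fragmented into several strong HSPs is still a
near-full-length homolog. All three thresholds are exposed as parameters.
As input guidance (documented, not enforced): at least 4–6 homologs with
pairwise identities roughly in the 30–70% band give the most informative
gap structure — nearly identical homologs contain no gaps, remote ones too
much alignment noise.

### Known-site mapping

A known insertion site "after residue *k*" is mapped at residue position
*k*: *direct* when inside a stretch, *scattered* when within `window`
(default 5) residues of the nearest stretch boundary, else *unmapped*.
Whether site and nearest stretch share one maximal run of identical
secondary-structure labels is reported separately (`same_ss_element`)
rather than folded into the classification, because the ±5-residue window
and the same-element condition are distinct notions of "close".

## Accessibility scoring

Site *i* (the junction between residues *i* and *i*+1) scores
√(RSA(*i*)·RSA(*i*+1)); sites 0 and L (the termini) take the RSA of the
first and last residue. A stretch [*s*, *e*] scores
max over *i* ∈ {*s*, …, *e*−1} of the site RSA. The geometric mean never
exceeds the larger neighbour and the stretch score is monotone in every
residue RSA inside the stretch (both property-tested).

Secondary-structure probability triples (helix, strand, coil) are reduced
to hard labels by argmax; exact ties are broken coil > helix > strand —
coil is the least-committal context and the conservative choice for
loop-dependent applications such as protease access. Loop length at a site
is the length of the maximal coil run containing it.

RSA from crystal structures is absolute surface area divided by the
residue's maximum exposure, clipped at 1. The default maximum-ASA table is
Sander & Rost (1994); it is configurable because published normalizations
differ. Unknown residues (X) are accepted as-given in prediction profiles
but rejected in ASA conversion (no reference maximum exists).

## Profile comparison by distance correlation

Predicted and structure-derived profiles are compared by the sample
distance correlation (double-centered pairwise Euclidean distance
matrices). RSA vectors are compared as scalars; hard SS labels are embedded
at {(0,0), (1,0), (½, √3/2)} — the vertices of a unit equilateral triangle —
so all label disagreements are metrically equal. Residues unresolved in
either profile are excluded pairwise, per measure. Degenerate inputs with
zero distance variance (constant profiles) return 0 rather than erroring,
which synthetic constant profiles require; when a profile carries no SS
track at all the SS correlation is NaN.

## Bootstrap enrichment test

Null model: each observed stretch, with its span ℓ = *e*−*s* preserved, is
assigned to a protein with probability proportional to protein length
(redrawn if the protein cannot host ℓ) and then to a uniform start
*s* ∈ {1, …, L−ℓ}. The mean stretch RSA of each of B = 1000 shuffles forms
the null; the p-value is the add-one upper tail (1 + #{null ≥ observed}) /
(B + 1), which can never be exactly 0 — its floor at B = 1000 is
1/1001 ≈ 10⁻³. Terminal sites are never sampled as stretch interiors,
mirroring detection, which never produces flanks outside the sequence.

Two interval styles are reported deliberately: the 2.5/97.5 percentile
spread of individual stretch RSAs (wide; describes the population of
stretches) and the percentile CI of the B null means (tight; describes the
null's sampling variability). The test is a pure function of (inputs,
seed); the placement law is verified against its exact distribution by a
chi-square test in the suite.

## Tag design

`design_insertion` places a tag after residue `after_pos`, optionally
deleting the `delete_len` residues that follow and/or re-appending a
duplicated upstream run after the tag. The variant is
`seq[1..after_pos] + tag + dup + seq[after_pos+delete_len+1..]`; every
design round-trips to the original target, and junction strings are
rendered with exactly three flanking residues per side (the display
convention of the reference designs). The built-in tag library holds the
minimal TEV recognition site `ENLYFQG`, its five-residue C-terminal
extension `ENLYFQGESLFK` (markedly better hydrolysis at internal
positions), and the flanked `PPKNENLYFQGESLFKGP`. Back-translation uses
the highest-usage E. coli K-12 codon per residue by default (three
nucleotides per residue; round-trips through translation); the table is
user-overridable, and no specific DNA sequence is asserted as ground truth.
Oligo construction for genome engineering (homology arms, folding-energy
screens, strand choice) is out of scope — the design stops at the protein
variant and its coding insert.

The bundled reference targets: the full adenylate kinase sequence is
included; for the other design targets, synthetic scaffolds carry the
documented residues at their true positions on an alanine backbone (see
`reference_designs.py`), which pins every junction string exactly while making no
claim about undocumented positions.

## Decay fits

Models: conc(*t*) = *d* + *b*·e^(−*t*/τ), with *d* fixed at 2 mM for the
ATP model (the empirical floor in cell-free extract) and free for the ADP
model. τ > 0 by construction and half-life = ln(2)·τ; the equivalent
parameterization e^(*t*/c) has c = −τ, and reparameterizing removes the
sign ambiguity between a negative rate constant and a positive half-life
without changing the fitted curve. Fitting is Levenberg–Marquardt least
squares (lmfit); initial guesses come from the data (b ≈ conc(0) −
asymptote, τ ≈ half the time span, d ≈ min conc). 95% bounds are
per-parameter, from the linearized covariance at the optimum with a
Student-t quantile at n − k degrees of freedom — the standard
curve-fitting-toolbox behaviour; profile-likelihood intervals are out of
scope. A fitted b ≤ 0 means the data do not decay: the result is flagged
and the half-life reported as undefined rather than negative. Noiseless
refits recover parameters to ~10⁻¹⁴ relative; under Gaussian noise
(σ = 0.3 mM, 12 points on [0, 120] min) each parameter's CI covers its
true value at close to the nominal rate (measured ≥ 90% over 200
replicates; being per-parameter intervals, simultaneous coverage of both
parameters is necessarily somewhat lower).

## Synthetic data: what it does and does not emulate

`simulate_family` builds a homolog family from an ancestor by per-homolog
substitutions (default rate 0.35, i.e. pairwise identities in the 30–70%
band) and, in each declared indel region, an insertion or deletion of
1..max_len residues (each kind with probability ½, or forced). The true
alignment is assembled by construction, so ground-truth intervals are exact
and detector tests measure the detector alone; with real data, gap
placement depends on the aligner and its gap penalties, which is why known
sites are allowed to scatter ±5 residues. Regions must be interior and
mutually separated so their evidence extents cannot merge — the condition
under which recovery is 100% by construction. Not emulated:
phylogenetic correlation between homologs, realistic indel length
distributions, compositional biases, or alignment error. Passing tests
therefore demonstrate correctness of the machinery under its stated
assumptions, not performance on arbitrary real alignments.

`simulate_profile` draws per-residue RSA from a clipped normal around a
loop mean (default 0.8) inside declared loop regions and a core mean
(default 0.2) elsewhere (sd 0.05), labelling loops coil and the rest
helix. This is the idealized exposed-loop/buried-core contrast the
enrichment test is designed to detect; real profiles are noisier and less
bimodal. `simulate_hsps` projects the true alignment to pairwise local
windows (trimmed so neither row starts or ends with a gap), computes
identities from the pair, and draws E-values log-uniformly — at full
coverage the union of its gap sets equals the family's ground truth.

## Problem sizes in the test and acceptance runs

Oracle agreement uses 1000 random interval sets (merging) and 100 random
small instances (distance correlation). Bootstrap calibration uses the
separated-loops fixture (10 proteins × 300 residues, 30 stretches,
B = 1000) and 200 null datasets (3 proteins, 6 stretches, B = 199).
Detector recovery uses 100 random families (1–3 regions, 6 homologs,
sequences of 40–110 residues). Decay coverage uses 200 replicates of 12
points. These sizes give stable Monte-Carlo estimates (binomial standard
errors of a few percent) while keeping the full suite and the acceptance
script to seconds.

## Known limitations

* Detection quality on real data is bounded by the homolog search and
  alignment upstream of the package; the package parses their outputs and
  never runs them.
* Stretch RSA depends on the accessibility predictor's calibration; the
  maximum-ASA normalization for crystal structures is a convention
  (Sander & Rost by default) and alternatives shift absolute RSA values.
* The enrichment null preserves stretch lengths but not sequence
  composition; composition-matched nulls are not implemented.
* Distance correlation is reported as a descriptive agreement measure;
  no significance test for it is provided.
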