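# Methods

This note documents the models, statistics and numerical choices behind
`tailstriage`, and what the synthetic benchmarks do and do not demonstrate.

## Study design being modeled

The pipeline assumes a two-arm degradomics contrast: animals dosed with a
protease-inhibiting antibody ("inhibited" arm) versus control antibody
("active" arm), with N-terminal peptides enriched by TAILS and the two arms
dimethyl-labeled (light CH₂O vs heavy ¹³CD₂O formaldehyde). The default
topology is two rabbit bioreplicates — with the channel-to-arm assignment
reversed in the second, as is standard practice to cancel label bias — plus
a single cynomolgus-monkey arm sharing a subset of orthologous substrates.

## Quantification model

Each peptide row carries light/heavy channel intensities. The
orientation-corrected ratio is

    log2_ratio = log2(control / inhibited)

where the channel-to-arm mapping follows the replicate's label orientation.
Applying a channel swap together with the opposite orientation flag is an
exact no-op; this invariance is property-tested.

Label masses follow the dimethyl chemistry as printed in standard usage:
light +28.0303 Da, heavy +34.0615 Da, per-amine heavy increment +6.0312 Da
(the `LabelScheme` enforces heavy − light = increment to 1e−4 Da). Peptide
masses are sums of monoisotopic residue masses (pyteomics table) + water +
modification deltas.

**Missing channels.** A zero intensity is treated as missing. The default
policy excludes one-channel rows from ratio-based triage (with a logged
count); an optional "capped" mode assigns ±6 log₂ units instead. Exclusion
is the conservative choice given that the upstream cause (dropout vs true
absence) is not identifiable from the table.

**PSM → peptide rollup.** The best-scoring PSM per (sequence, start,
accession, replicate) represents the peptide; channel intensities are summed
across its PSMs. Ties at the FDR score threshold are all included, which
keeps the filter deterministic and order-free.

## Target–decoy FDR

The threshold is the *smallest* score `t` with
`#decoys(≥t) / #targets(≥t) ≤ q` (simple count quotient). Decoys are never
returned. The simple quotient is mildly anticonservative (realized FDP in
simulation runs ≈ 0.5 percentage points above q at q = 0.05) because the
threshold adapts to decoy fluctuations; `fdr_filter(..., plus_one=True)`
applies the standard +1 correction for users who want strict control. The
simple quotient remains the default because it is the common minimal
definition of "filtered at 5% FDR".

## Terminus classification

Start ≤ 2 → native (position 2 covers initiator-Met removal); start > 2
with a dimethyl, pyroGlu or free N-terminus → neo; start > 2 with acetyl →
native (acetylation is co-translational and marks an original terminus).
**Known limitation:** signal-peptide-processed mature N-termini are not
special-cased (no signal-peptide database is consulted) and will be reported
as neo; in real data they are removed downstream by the fold-change filter,
since constitutive termini show no arm contrast.

## Filter cascade and consensus rules

The cascade applies, in order: contaminant exclusion (immunoglobulin and
crystallin records), fold-change cutoff, cleavage-consensus predicate. All
three are pure row predicates, so they commute and the final survivor set is
order-invariant; per-stage counts are recorded for the funnel report.

* **Fold-change cutoff** defaults to log₂ > 0.58 (1.5-fold). The strictness
  of the comparison (> vs ≥) is configurable because both conventions appear
  in practice; the default is strict. The cutoff matters only for ratios
  exactly at 0.58.
* **Consensus predicate** defaults to `exclude_basic_P1` (reject cleavages
  C-terminal to K/R/H) — the only exclusion that is uncontroversial for a
  hydrophobic-P1 protease. A stricter `require_hydrophobic_P1` mode is
  available. The hydrophobic set defaults to {V, L, I, M, F, A}; membership
  of A (and possibly C, T, Y) is debatable, so the set is configurable.
* **Replication** is interpreted at the protein level: a protein is
  "observed" in an arm if ≥ 1 surviving neo peptide maps to it there. The
  default rule calls a protein when it is observed in both primary-species
  bioreplicates, or in one of them plus the second species. Peptides mapping
  to several proteins are excluded from protein-level calls (unique mapping
  only) to avoid inflating call counts.
* **Cross-species matching** uses uppercase gene-symbol equality; no
  orthology inference beyond that.
* The replicated-peptide tally counts distinct (gene, sequence, P1 site)
  triples present in every primary bioreplicate; a per-study tally (each
  study occurrence counted separately) is also reported, since either
  convention is defensible.

Cleavage sites are 1-based P1 indices on the full precursor sequence: a
cleavage "at M126" means P1 = Met-126 and the neo peptide starts at 127.
Domain mapping uses inclusive interval endpoints; sites outside all domains
are labeled by the nearest flanking domain.

## Specificity profile

For windows P4…P4′ (padding `-` where the window leaves the protein), the
profile compares the observed residue frequency at each position with a
reference composition (a proteome's overall composition, or uniform 1/20 in
tests) using

    z = (p_obs − p_ref) / sqrt(p_ref (1 − p_ref) / n)

with a two-sided normal p-value, per (position, residue) cell, no
multiple-testing correction, α = 0.05 by default. With a whole proteome as
reference the reference variance is negligible, which reduces the
two-proportion comparison to this one-sample form — the documented default
behavior of differential-logo tools. The exported profile uses the
frequency-difference scale (observed − reference), recorded in the output
metadata. Padding is excluded from counts, so each position has its own
effective n.

## Dose-response fitting

Percent activity is scaled linearly between a maximal (100%, no antibody)
and minimal (0%, fully inhibited) reference. The 4PL
`y = bottom + (top − bottom)/(1 + (c/IC₅₀)^h)` is fitted by least squares on
log₁₀ concentration for conditioning, with bounds IC₅₀ ∈ [min dose/10,
max dose×10] and h ∈ [0.1, 10], and five quantile-seeded multi-starts
against local minima. Zero-concentration points anchor `top` (their mean)
and are excluded from the logistic residuals. Non-convergent or degenerate
(bottom ≥ top) fits are flagged and their parameters withheld. Bootstrap
IC₅₀ intervals (seeded, nonparametric, 1,000 resamples by default) are
available; fits on simulated data assume triplicate measurements per dose,
the usual design of ABP competition assays.

## Synthetic-study generator

The generator is the package's ground truth and emulates, per replicate:

* a background proteome (default 40 records, 150–400 residues, average
  vertebrate composition) plus 5 substrates (each with two annotated
  domains) and 6 contaminants (alternating immunoglobulin/crystallin);
* 2 planted cleavage sites per substrate, drawn from interior hydrophobic
  positions weighted toward V/L (weights 0.3/0.3, remaining hydrophobics
  0.1 each); orthologous substrates in the second species (default 3 of 5
  shared) are cut at the same positions;
* native N-terminal peptides for every protein (position 1, or 2 after an
  initiator Met; ~30% acetylated to exercise the classifier), planted neo
  peptides starting at P1′ with tryptic C-termini (cleavage after Arg only —
  dimethylated Lys is uncleavable — 0 and 1 missed cleavages emitted),
  background proteolysis rows and contaminant-derived rows with no arm
  effect;
* intensities from a lognormal base abundance (ln-scale σ = 0.8 around 10⁶);
  the arm effect multiplies the control channel, log₂-ratio noise is
  additive Gaussian (default sd 0.5, a plausible spread for dimethyl ratios
  at moderate intensity), per-channel dropout (default 0.1);
* correct-target PSM scores ~N(60, 12) and a null distribution ~N(35, 8)
  used both for decoys (default 30% of rows) and for an equal number of
  spurious target rows (wrong identifications). The spurious rows are what
  makes *realized* false-discovery proportions measurable against ground
  truth; their 1:1 pairing with decoys encodes the target–decoy symmetry
  assumption.
* the default planted effect is log₂ = 2 (a four-fold enrichment); in vivo
  effect sizes for true substrates are not known in general, so this is a
  simulation parameter, not a measured value.

Everything derives deterministically from the design seed (per-stage,
per-replicate stream splitting), and with noise, dropout and effect
uncertainty all zeroed the pipeline must recover the planted substrate set
exactly — the noiseless-limit contract that anchors the test suite.

**What the generator does not emulate:** spectra and search-engine behavior
(scores are drawn, not computed), retention-time or isotope-envelope
structure, shared/homologous peptides across proteins, signal-peptide
biology, inter-protein abundance structure (every protein is equally
likely), and real cross-species sequence divergence (orthologs are
identical copies). Passing benchmarks therefore demonstrate the correctness
of the triage arithmetic and its statistical calibration under the stated
noise model — not performance on any particular real dataset.

The bundled demonstration study (`tailstriage.demo`) is a separate, fully
synthetic fixture whose *planted topology* (peptide counts per protein,
shared genes across species, DKK3 site/domain geometry) mirrors the shape of
a published in vivo study so that the pipeline's funnel and consensus
arithmetic can be checked against known totals; its sequences and
intensities are generated, and domain interval endpoints are fixture values.

## Benchmark sizes

The acceptance computations use 50 simulated studies for sensitivity, 200
simulated tables for FDR calibration, and 100 noisy dose-response
simulations; these sizes put Monte-Carlo error comfortably below the margins
being tested while keeping a full run in tens of seconds.
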