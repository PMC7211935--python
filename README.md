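# tailstriage

Quantitative N-terminomics (TAILS) substrate triage for in vivo protease
degradomics, with cleavage-site specificity profiling and activity-based-probe
(ABP) dose-response quantification.

## The problem

A protease's in vivo substrates can be discovered by comparing protein
N-termini between animals in which the enzyme is active and animals in which
it has been inhibited (for example by an intravitreally dosed anti-protease
antibody). TAILS (Terminal Amine Isotopic Labeling of Substrates) enriches
N-terminal peptides and dimethyl-labels the two experimental arms with light
(CH₂O) and heavy (¹³CD₂O) formaldehyde, so each peptide carries a
control/inhibited intensity ratio. A proteolytic ("neo") N-terminus that is
enriched when the protease is active is evidence for a cleavage event — but
the raw peptide lists are dominated by native termini, highly abundant
contaminants (immunoglobulins and crystallins in ocular fluid), search-engine
false positives, and cleavages made by other proteases. `tailstriage`
implements the triage that turns those lists into substrate calls:

1. **PSM-level target–decoy FDR** at q = 0.05: the score threshold *t* is the
   smallest score with #decoys(≥t)/#targets(≥t) ≤ q.
2. **Terminus classification** from the peptide start position: start ≤ 2 is
   the protein's own terminus (position 2 covers initiator-Met removal);
   deeper starts with an in-vitro dimethyl label are neo termini.
3. **Orientation-corrected quantification**:
   log₂(control/inhibited) from the light/heavy intensities, honoring the
   per-bioreplicate label orientation (labeling is reversed in bioreplicate 2).
4. **Filter cascade**: drop contaminant-derived peptides; keep peptides with
   log₂ FC > 0.58 (1.5-fold enrichment in the protease-active arm); drop
   cleavages inconsistent with the protease's consensus (default: exclude
   cleavages C-terminal to a basic residue — the protease modeled here, the
   trypsin-fold serine protease HtrA1, prefers hydrophobic P1 residues such
   as Val and Leu).
5. **Replication rule**: a protein is called if supported in both rabbit
   bioreplicates, or in one rabbit bioreplicate plus the cynomolgus-monkey
   arm; cross-species consensus intersects the calls by gene symbol.
6. **Site annotation**: each cleavage site (the 1-based index of its P1
   residue) is mapped onto the protein's domain architecture.

Around the triage the package provides the two companion analyses of such a
study: **P4–P4′ specificity profiles** (differential residue frequencies
against a reference proteome composition, per-cell proportion z-test — the
statistic behind iceLogo-style plots) and **ABP densitometry** (active/total
band ratios normalized to same-gel controls, percent-activity scaling, and
four-parameter-logistic IC₅₀ fits,
y = bottom + (top − bottom)/(1 + (c/IC₅₀)^h)).

A seeded synthetic-study generator (`tailstriage.synthetic`) plants ground-
truthed cleavage events with hydrophobic-P1 specificity, simulates the
two-channel intensity model with lognormal noise, dropout, decoys and label
swaps, and makes every stage testable end to end without any external data.

## Worked example

```python
from tailstriage.demo import run_demo

result = run_demo()
print(len(result.replicated_peptides))        # 26
print(len(result.calls))                      # 9
print([c.gene_symbol for c in result.calls[:5]])
# ['RBP3', 'DKK3', 'CLU', 'CLUL1', 'APLP2']
print(result.consensus_genes)                 # ['RBP3', 'DKK3', 'CLU']
```

`run_demo()` executes the full pipeline on a bundled synthetic demonstration
study (two rabbit bioreplicates plus one monkey arm). The numbers mean: 26
distinct neo-N-terminal peptides survive the cascade in *both* rabbit
bioreplicates, they map to 9 proteins, the five best-supported calls are
RBP3, DKK3, CLU, CLUL1 and APLP2, and three of them (CLU, DKK3, RBP3) are
independently recovered in the monkey arm. The DKK3 call carries two
cleavage sites, M126 ("upstream of CRD1") and I252 ("within CRD2") — the
positions that make the cleavage product usable as a pharmacodynamic
biomarker of protease activity.

More narrative scripts live in `examples/` (synthetic study generation,
specificity profiling, FDR + quantification, triage, dose-response), and a
thin CLI (`tailstriage synthesize|discover|logo|doseresponse|normalize`)
wraps the same functions for file-based use.

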