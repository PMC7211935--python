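"""Target-decoy FDR filtering and orientation-corrected ratio quantification.

PSMs are filtered at 5% FDR by score; surviving peptides are rolled up and
their light/heavy dimethyl intensities converted to log2(control/inhibited)
ratios, honoring each bioreplicate's label orientation (labeling is reversed
in rabbit bioreplicate 2).
"""

from tailstriage import (
    LabelScheme,
    SyntheticDesign,
    fdr_filter,
    quantify_table,
    rollup_psms,
    synthesize_study,
)

design = SyntheticDesign(seed=5)
proteins, truth, tables = synthesize_study(design)
scheme = LabelScheme(orientation=design.orientation_map)

for rep_id in ("rabbit_1", "rabbit_2"):
    rows = tables[rep_id]
    passing, threshold = fdr_filter(rows, q=0.05)
    rolled = rollup_psms(passing)
    quantified, counts = quantify_table(rolled, scheme, proteins)
    planted = [
        q.log2_ratio
        for q in quantified
        if q.peptide.accession in truth.true_substrate_accessions
        and q.terminus_class == "neo"
        and not truth.is_spurious(q.peptide)  # drop wrong-ID rows
    ]
    mean = sum(planted) / len(planted)
    print(
        f"{rep_id}: {len(passing)}/{len(rows)} PSMs pass FDR "
        f"(score >= {threshold:.1f}); {counts['quantified']} quantified, "
        f"{counts['missing_channel']} dropped with a missing channel; "
        f"mean planted-substrate log2 ratio = {mean:.2f} "
        f"(planted effect {truth.effect_log2})"
    )
# Both replicates recover the planted two-fold (log2 = 2) enrichment even
# though their channel assignments are swapped.
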