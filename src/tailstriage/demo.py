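"""A bundled synthetic demonstration study.

This is a fully synthetic stand-in dataset (no measured data): a small
two-bioreplicate rabbit study plus a one-arm cynomolgus-monkey study whose
planted topology mirrors the published in vivo HtrA1 degradomics result —
26 neo-N-terminal peptides replicating across the rabbit bioreplicates,
derived from nine proteins; the five proteins with the most replicated
peptides being RBP3, DKK3, CLU, CLUL1 and APLP2; and a three-protein
cross-species consensus of CLU, DKK3 and RBP3, with the DKK3 cleavages at
M126 (upstream of the first cysteine-rich domain) and I252 (inside the
second).  Sequences, intensities and scores are generated; only the
topology (which genes, how many peptides, which P1 residues) is planted.
Running the discovery pipeline on these raw tables recomputes all of those
counts from scratch, which makes the dataset a worked end-to-end example
and a self-check of the triage arithmetic.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .records import Domain, ProteinRecord, ProteinSet
from .quantify import NTermPeptide
from .pipeline import PipelineConfig

_DEMO_SEED = 20230214

# gene -> list of (P1 site, number of peptide forms at that site, P1 residue)
_RABBIT_PLAN = {
    "RBP3": [(50, 2, "V"), (88, 1, "L"), (120, 1, "V"), (160, 2, "L"), (200, 1, "I"), (240, 1, "V")],
    "DKK3": [(126, 3, "M"), (252, 2, "I")],
    "CLU": [(60, 2, "V"), (140, 2, "L")],
    "CLUL1": [(70, 1, "V"), (150, 2, "L")],
    "APLP2": [(90, 1, "V"), (180, 1, "L")],
    "FBN1": [(100, 1, "V")],
    "LUM": [(80, 1, "L")],
    "OPTC": [(75, 1, "V")],
    "TF": [(110, 1, "L")],
}

# monkey arm: only three of the rabbit proteins recur, plus one monkey-only
_MONKEY_PLAN = {
    "RBP3": [(50, 2, "V"), (160, 2, "L")],
    "CLU": [(60, 1, "V"), (140, 1, "L")],
    "DKK3": [(126, 1, "M"), (252, 1, "I")],
    "VTN": [(95, 1, "V")],
}

_FORM_LENGTHS = (12, 18, 24)

_AA = list("ACDEFGHIKLMNPQRSTVWY")


def _make_sequence(rng: np.random.Generator, length: int, patches: Dict[int, str]) -> str:
    seq = list(rng.choice(_AA, size=length))
    for pos, aa in patches.items():  # 1-based
        seq[pos - 1] = aa
    return "".join(seq)


def _protein(
    rng: np.random.Generator,
    gene: str,
    species: str,
    length: int,
    plan,
    contaminant_class: str = "none",
    domains: Tuple[Domain, ...] = (),
) -> ProteinRecord:
    prefix = {"rabbit": "RAB", "monkey": "CYN"}[species]
    patches = {site: p1 for site, _, p1 in plan}
    return ProteinRecord(
        accession=f"{prefix}-{gene}",
        gene_symbol=gene,
        species=species,
        sequence=_make_sequence(rng, length, patches),
        contaminant_class=contaminant_class,
        domains=domains,
    )


def demo_study() -> Tuple[ProteinSet, Dict[str, List[NTermPeptide]], PipelineConfig]:
    """Build the demonstration proteome, raw peptide tables and config."""
    rng = np.random.default_rng(_DEMO_SEED)

    records: List[ProteinRecord] = []
    rabbit_seqs: Dict[str, str] = {}

    for gene, plan in _RABBIT_PLAN.items():
        length = 350 if gene == "DKK3" else 300
        domains = ()
        if gene == "DKK3":
            domains = (Domain("CRD1", 147, 203), Domain("CRD2", 213, 282))
        rec = _protein(rng, gene, "rabbit", length, plan, domains=domains)
        records.append(rec)
        rabbit_seqs[gene] = rec.sequence

    # background proteins whose peptides are filtered at the FC or
    # specificity stage, plus a one-replicate-only protein
    records.append(_protein(rng, "ALB", "rabbit", 280, [(77, 1, "V")]))
    records.append(_protein(rng, "C3", "rabbit", 280, [(88, 1, "K")]))
    records.append(_protein(rng, "SERPINF1", "rabbit", 260, [(66, 1, "L")]))
    records.append(
        _protein(rng, "IGHG1", "rabbit", 240, [(70, 1, "V")], contaminant_class="immunoglobulin")
    )
    records.append(
        _protein(rng, "CRYAA", "rabbit", 200, [(55, 1, "L")], contaminant_class="crystallin")
    )

    for gene, plan in _MONKEY_PLAN.items():
        if gene in rabbit_seqs:
            # ortholog: identical sequence, monkey accession
            rec = next(r for r in records if r.gene_symbol == gene and r.species == "rabbit")
            records.append(
                ProteinRecord(
                    accession=f"CYN-{gene}",
                    gene_symbol=gene,
                    species="monkey",
                    sequence=rec.sequence,
                    domains=rec.domains,
                )
            )
        else:
            records.append(_protein(rng, gene, "monkey", 260, plan))

    proteome = ProteinSet(records)

    orientation = {
        "rabbit_1": "light_control",
        "rabbit_2": "heavy_control",
        "monkey_1": "light_control",
    }
    species_by_rep = {"rabbit_1": "rabbit", "rabbit_2": "rabbit", "monkey_1": "monkey"}

    def rows_for(rep_id: str, plan: Dict, species: str) -> List[NTermPeptide]:
        rows: List[NTermPeptide] = []
        prefix = {"rabbit": "RAB", "monkey": "CYN"}[species]
        i = 0

        def emit(accession: str, start: int, length: int, log2_fc: float, score: float = 80.0, is_decoy: bool = False):
            nonlocal i
            rec = proteome[accession] if not is_decoy else None
            seq = (
                rec.sequence[start - 1 : start - 1 + length]
                if rec is not None
                else "".join(rng.choice(_AA, size=length))
            )
            base = 1e6 * (1.0 + 0.013 * i)
            control = base * 2.0 ** log2_fc
            if orientation[rep_id] == "light_control":
                light, heavy = control, base
            else:
                light, heavy = base, control
            rows.append(
                NTermPeptide(
                    sequence=seq,
                    accession=accession,
                    start=start,
                    nterm_mod="dimethyl_light",
                    intensity_light=light,
                    intensity_heavy=heavy,
                    psm_score=score,
                    is_decoy=is_decoy,
                    replicate_id=rep_id,
                )
            )
            i += 1

        for gene, sites in plan.items():
            acc = f"{prefix}-{gene}"
            emit(acc, 1, 20, 0.0)  # native terminus, ratio 1:1
            for j, (site, n_forms, _p1) in enumerate(sites):
                for k in range(n_forms):
                    fc = 1.2 + 0.08 * ((site + k) % 7)  # 1.2 .. 1.68, all > 0.58
                    emit(acc, site + 1, _FORM_LENGTHS[k], fc)
        if species == "rabbit":
            # rows planted to fall at each triage stage
            emit(f"{prefix}-IGHG1", 71, 15, 3.0)  # contaminant, high FC
            emit(f"{prefix}-CRYAA", 56, 15, 2.0)  # contaminant, high FC
            emit(f"{prefix}-ALB", 78, 15, 0.30)  # below the 1.5-fold cutoff
            emit(f"{prefix}-C3", 89, 15, 2.0)  # basic P1 (K), fails specificity
            if rep_id == "rabbit_1":
                emit(f"{prefix}-SERPINF1", 67, 15, 1.5)  # passes, but only once
        # two decoy PSMs with null-level scores
        emit("DECOY_0001", 10, 14, 0.0, score=30.0, is_decoy=True)
        emit("DECOY_0002", 12, 14, 0.0, score=28.0, is_decoy=True)
        return rows

    tables = {
        "rabbit_1": rows_for("rabbit_1", _RABBIT_PLAN, "rabbit"),
        "rabbit_2": rows_for("rabbit_2", _RABBIT_PLAN, "rabbit"),
        "monkey_1": rows_for("monkey_1", _MONKEY_PLAN, "monkey"),
    }

    config = PipelineConfig(
        orientation=orientation,
        species_by_replicate=species_by_rep,
        seed=_DEMO_SEED,
    )
    return proteome, tables, config


def run_demo():
    """Run the full discovery pipeline on the demonstration study."""
    from .pipeline import discover

    proteome, tables, config = demo_study()
    return discover(proteome, tables, config)
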