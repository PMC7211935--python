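"""End-to-end orchestration: synthesize a study, run the discovery pipeline.

``run_synthesize`` writes a complete study bundle (proteome FASTA,
per-replicate peptide TSVs, ground-truth JSON, manifest with checksums);
``run_discovery`` reads such a bundle (or any files matching the schemas),
executes FDR filtering -> terminus classification -> ratio quantification ->
filter cascade -> replication consensus -> cross-species consensus -> domain
mapping -> specificity profiling, and writes every result table.  The
in-memory :func:`discover` does the same without touching disk; the file
subcommands are thin wrappers over it, so composing stages manually
reproduces ``run_discovery`` exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .records import ProteinSet
from .specificity import (
    ResidueClassConfig,
    SpecificityProfile,
    build_specificity_profile,
    extract_window,
)
from .quantify import (
    LabelScheme,
    NTermPeptide,
    QuantifiedNeoTerm,
    classify_terminus,
    fdr_filter,
    quantify_table,
    rollup_psms,
)
from .triage import (
    SubstrateCall,
    TriageConfig,
    TriageResult,
    apply_filter_cascade,
    cross_species_consensus,
    map_sites_to_domains,
    replicate_consensus,
)
from .synthetic import (
    GroundTruth,
    SyntheticDesign,
    file_sha256,
    synthesize_study,
)
from . import tableio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a discovery run needs; round-trips losslessly through YAML."""

    proteome_fasta: str = ""
    peptide_tables: Dict[str, str] = field(default_factory=dict)  # rep_id -> path
    output_dir: str = "out"
    fdr_q: float = 0.05
    orientation: Dict[str, str] = field(default_factory=dict)  # rep_id -> orientation
    species_by_replicate: Dict[str, str] = field(default_factory=dict)
    triage: TriageConfig = field(default_factory=TriageConfig)
    missing_channel_policy: str = "exclude"
    primary_species: str = "rabbit"
    seed: int = 0

    def to_yaml(self, path) -> None:
        t = self.triage
        payload = {
            "proteome_fasta": self.proteome_fasta,
            "peptide_tables": dict(self.peptide_tables),
            "output_dir": self.output_dir,
            "fdr_q": self.fdr_q,
            "orientation": dict(self.orientation),
            "species_by_replicate": dict(self.species_by_replicate),
            "missing_channel_policy": self.missing_channel_policy,
            "primary_species": self.primary_species,
            "seed": self.seed,
            "triage": {
                "log2_cutoff": t.log2_cutoff,
                "strict_inequality": t.strict_inequality,
                "excluded_contaminant_classes": sorted(t.excluded_contaminant_classes),
                "specificity_mode": t.specificity_mode,
                "replication_rule": t.replication_rule,
                "hydrophobic_set": "".join(sorted(t.residue_classes.hydrophobic_set)),
                "basic_set": "".join(sorted(t.residue_classes.basic_set)),
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        t = d.pop("triage", {})
        triage = TriageConfig(
            log2_cutoff=t.get("log2_cutoff", 0.58),
            strict_inequality=t.get("strict_inequality", True),
            excluded_contaminant_classes=frozenset(
                t.get("excluded_contaminant_classes", ["immunoglobulin", "crystallin"])
            ),
            specificity_mode=t.get("specificity_mode", "exclude_basic_P1"),
            replication_rule=t.get("replication_rule", "either"),
            residue_classes=ResidueClassConfig(
                hydrophobic_set=frozenset(t.get("hydrophobic_set", "VLIMFA")),
                basic_set=frozenset(t.get("basic_set", "KRH")),
                mode=t.get("specificity_mode", "exclude_basic_P1"),
            ),
        )
        return cls(triage=triage, **d)


@dataclass
class DiscoveryResult:
    """All artifacts of one discovery run."""

    per_replicate: Dict[str, TriageResult]
    calls: List[SubstrateCall]
    primary_calls: List[SubstrateCall]
    secondary_calls: List[SubstrateCall]
    cross_species: "object"  # DataFrame from cross_species_consensus
    profile: Optional[SpecificityProfile]
    replicated_peptides: List[Tuple[str, str, int]]  # (gene, sequence, p1 site)
    replicated_peptides_by_study: int
    fdr_thresholds: Dict[str, Optional[float]]
    quantify_counts: Dict[str, Dict[str, int]]

    @property
    def called_genes(self) -> List[str]:
        return [c.gene_symbol for c in self.calls]

    @property
    def consensus_genes(self) -> List[str]:
        return list(self.cross_species.index)


def quantify_replicate(
    peptides: Sequence[NTermPeptide],
    proteome: ProteinSet,
    scheme: LabelScheme,
    q: float,
    missing_policy: str = "exclude",
) -> Tuple[List[QuantifiedNeoTerm], Optional[float], Dict[str, int]]:
    """FDR-filter, roll up, and quantify one replicate's table."""
    passing, threshold = fdr_filter(peptides, q)
    rolled = rollup_psms(passing)
    mapped = [p for p in rolled if p.accession in proteome]
    n_unmapped = len(rolled) - len(mapped)
    quantified, counts = quantify_table(
        mapped, scheme, proteome, missing_policy=missing_policy
    )
    counts["unmapped"] = n_unmapped
    counts["fdr_input"] = len(peptides)
    counts["fdr_passing"] = len(passing)
    return quantified, threshold, counts


def discover(
    proteome: ProteinSet,
    tables: Mapping[str, Sequence[NTermPeptide]],
    config: PipelineConfig,
) -> DiscoveryResult:
    """Run the full discovery pipeline in memory."""
    scheme = LabelScheme(orientation=dict(config.orientation))
    per_rep: Dict[str, TriageResult] = {}
    thresholds: Dict[str, Optional[float]] = {}
    all_counts: Dict[str, Dict[str, int]] = {}

    for rep_id, peptides in tables.items():
        quantified, threshold, counts = quantify_replicate(
            peptides,
            proteome,
            scheme,
            config.fdr_q,
            missing_policy=config.missing_channel_policy,
        )
        thresholds[rep_id] = threshold
        all_counts[rep_id] = counts
        per_rep[rep_id] = apply_filter_cascade(
            quantified, proteome, config.triage, replicate_id=rep_id
        )

    species_map = dict(config.species_by_replicate)

    def species_of(rep_id: str) -> str:
        if rep_id in species_map:
            return species_map[rep_id]
        seen = {
            proteome[q.peptide.accession].species
            for q in per_rep[rep_id].surviving_peptides
        }
        return next(iter(seen)) if len(seen) == 1 else rep_id.split("_")[0]

    primary_reps = {r for r in per_rep if species_of(r) == config.primary_species}
    secondary_reps = set(per_rep) - primary_reps

    calls = replicate_consensus(
        per_rep,
        proteome,
        rule=config.triage.replication_rule,
        primary_species=config.primary_species,
        species_by_replicate={r: species_of(r) for r in per_rep},
    )

    # species-restricted call sets for the cross-species comparison
    def calls_for(reps: set, rule: str) -> List[SubstrateCall]:
        if not reps:
            return []
        sub = {r: per_rep[r] for r in reps}
        return replicate_consensus(
            sub,
            proteome,
            rule=rule,
            primary_species=species_of(next(iter(reps))),
            species_by_replicate={r: species_of(r) for r in reps},
        )

    primary_calls = calls_for(
        primary_reps, "both_rabbit_reps" if len(primary_reps) >= 2 else "either"
    )
    # a single-arm secondary study: any surviving protein counts as observed
    if secondary_reps:
        sub = {r: per_rep[r] for r in secondary_reps}
        genes = sorted(set().union(*(res.surviving_genes(proteome) for res in sub.values())))
        from .triage import _calls_from_evidence

        secondary_calls = _calls_from_evidence(
            {r: res.surviving_peptides for r, res in sub.items()}, proteome, genes
        )
    else:
        secondary_calls = []

    cross = cross_species_consensus(primary_calls, secondary_calls)

    # replicated peptides across the primary-species bioreplicates
    def survivor_keys(rep_id: str) -> set:
        return {
            (
                proteome[q.peptide.accession].gene_symbol.upper(),
                q.peptide.sequence,
                q.peptide.start - 1,
            )
            for q in per_rep[rep_id].surviving_peptides
        }

    replicated: set = set()
    if len(primary_reps) >= 2:
        sets = [survivor_keys(r) for r in sorted(primary_reps)]
        replicated = set.intersection(*sets)
    replicated_peptides = sorted(replicated)
    # alternative tally: each sequence+site+study combination counted separately
    replicated_by_study = sum(
        sum(1 for r in sorted(primary_reps) if key in survivor_keys(r))
        for key in replicated
    )

    # domain mapping for every call
    for call in calls:
        for species, accession in call.accessions.items():
            map_sites_to_domains(call, proteome[accession])

    # specificity profile from the surviving windows of all replicates
    windows = []
    for res in per_rep.values():
        for qn in res.surviving_peptides:
            rec = proteome[qn.peptide.accession]
            site = qn.peptide.start - 1
            if 1 <= site < len(rec.sequence):
                windows.append(extract_window(rec, site))
    profile = None
    if windows:
        profile = build_specificity_profile(
            windows, proteome.residue_composition(), alpha=0.05
        )

    return DiscoveryResult(
        per_replicate=per_rep,
        calls=calls,
        primary_calls=primary_calls,
        secondary_calls=secondary_calls,
        cross_species=cross,
        profile=profile,
        replicated_peptides=replicated_peptides,
        replicated_peptides_by_study=replicated_by_study,
        fdr_thresholds=thresholds,
        quantify_counts=all_counts,
    )


def calls_to_json(calls: Sequence[SubstrateCall]) -> List[dict]:
    out = []
    for c in calls:
        out.append(
            {
                "gene_symbol": c.gene_symbol,
                "accessions": dict(c.accessions),
                "peptides_per_replicate": dict(c.peptides_per_replicate),
                "total_peptides": c.total_peptides,
                "cleavage_sites": [list(s) for s in c.cleavage_sites],
                "median_log2_per_replicate": dict(c.median_log2_per_replicate),
                "site_annotations": {
                    f"{acc}:{site}": label
                    for (acc, site), label in sorted(c.site_annotations.items())
                },
            }
        )
    return out


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """File-based discovery: read inputs, run :func:`discover`, write outputs."""
    proteome = ProteinSet.from_fasta(config.proteome_fasta)
    tables = {
        rep_id: tableio.read_peptide_tsv(path)
        for rep_id, path in sorted(config.peptide_tables.items())
    }
    result = discover(proteome, tables, config)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rep_id, res in result.per_replicate.items():
        res.to_frame(proteome).to_csv(
            outdir / f"peptides_{rep_id}.tsv", sep="\t", index=False
        )
        res.funnel_frame().to_csv(
            outdir / f"funnel_{rep_id}.tsv", sep="\t", index=False
        )
    with open(outdir / "substrate_calls.json", "w") as fh:
        json.dump(
            {
                "replication_rule": config.triage.replication_rule,
                "log2_cutoff": config.triage.log2_cutoff,
                "strict_inequality": config.triage.strict_inequality,
                "fdr_q": config.fdr_q,
                "calls": calls_to_json(result.calls),
                "cross_species_consensus": result.consensus_genes,
                "replicated_peptides": [list(k) for k in result.replicated_peptides],
                "replicated_peptides_by_study": result.replicated_peptides_by_study,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    if result.profile is not None:
        result.profile.to_tsv(outdir / "specificity_profile.tsv")
    logger.info(
        "run_discovery: %d calls, %d consensus genes, outputs in %s",
        len(result.calls),
        len(result.consensus_genes),
        outdir,
    )
    return result


def run_synthesize(design: SyntheticDesign, output_dir) -> Dict[str, str]:
    """Write a synthetic study bundle; returns the manifest (path -> sha256)."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, truth, tables = synthesize_study(design)

    files = {}
    fasta = outdir / "proteome.fasta"
    proteins.to_fasta(fasta)
    files["proteome.fasta"] = str(fasta)
    for rep_id, rows in tables.items():
        path = outdir / f"peptides_{rep_id}.tsv"
        tableio.write_peptide_tsv(path, rows)
        files[f"peptides_{rep_id}.tsv"] = str(path)
    truth_path = outdir / "ground_truth.json"
    truth.to_json(truth_path)
    files["ground_truth.json"] = str(truth_path)

    manifest = {
        "design": {
            **{
                k: v
                for k, v in dataclasses.asdict(design).items()
                if k != "replicates"
            },
            "replicates": [list(dataclasses.astuple(r)) for r in design.replicates],
        },
        "files": {name: file_sha256(path) for name, path in files.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest["files"]


def config_for_bundle(bundle_dir, design: SyntheticDesign, output_dir=None) -> PipelineConfig:
    """PipelineConfig pointing at a bundle written by :func:`run_synthesize`."""
    bundle = Path(bundle_dir)
    return PipelineConfig(
        proteome_fasta=str(bundle / "proteome.fasta"),
        peptide_tables={
            r.replicate_id: str(bundle / f"peptides_{r.replicate_id}.tsv")
            for r in design.replicates
        },
        output_dir=str(output_dir or bundle / "discovery"),
        orientation=design.orientation_map,
        species_by_replicate={r.replicate_id: r.species for r in design.replicates},
        seed=design.seed,
    )
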