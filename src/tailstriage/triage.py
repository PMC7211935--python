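"""Substrate triage: filter cascade, replication rules, domain mapping.

The cascade turns FDR-filtered, terminus-classified, ratio-quantified neo
peptides into protein-level substrate calls:

1. exclude peptides from contaminant proteins (immunoglobulins, crystallins
   — the dominant ocular background);
2. keep peptides enriched in the protease-active arm (log2 fold change above
   the cutoff, default 0.58, i.e. 1.5-fold);
3. keep peptides whose cleavage window is consistent with the protease's
   consensus (default: exclude cleavages C-terminal to a basic residue).

A protein becomes a substrate call when its surviving evidence satisfies the
replication rule: observed in both bioreplicates of the primary species, or
in one bioreplicate plus the second species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .records import ProteinRecord, ProteinSet
from .specificity import (
    CleavageWindow,
    ResidueClassConfig,
    consensus_filter,
    extract_window,
)
from .quantify import QuantifiedNeoTerm

logger = logging.getLogger(__name__)

REPLICATION_RULES = ("both_rabbit_reps", "one_rabbit_plus_monkey", "either")

CASCADE_STAGES = (
    "input",
    "after_contaminant_exclusion",
    "after_fc_cutoff",
    "after_specificity_filter",
)


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds and modes of the filter cascade.

    ``log2_cutoff=0.58`` corresponds to a 1.5-fold enrichment of the
    protease-active over the protease-inhibited arm; the default comparison
    is strict (``> 0.58``).
    """

    log2_cutoff: float = 0.58
    strict_inequality: bool = True
    excluded_contaminant_classes: frozenset = frozenset(
        {"immunoglobulin", "crystallin"}
    )
    specificity_mode: str = "exclude_basic_P1"
    replication_rule: str = "either"
    residue_classes: ResidueClassConfig = field(default=None)

    def __post_init__(self) -> None:
        if self.log2_cutoff < 0:
            raise ValueError("log2_cutoff must be >= 0")
        if self.replication_rule not in REPLICATION_RULES:
            raise ValueError(f"unknown replication rule {self.replication_rule!r}")
        if self.residue_classes is None:
            object.__setattr__(
                self,
                "residue_classes",
                ResidueClassConfig(mode=self.specificity_mode),
            )

    def passes_cutoff(self, log2_ratio: float) -> bool:
        if self.strict_inequality:
            return log2_ratio > self.log2_cutoff
        return log2_ratio >= self.log2_cutoff


@dataclass
class SubstrateCall:
    """Protein-level call aggregated over replicates (keyed by gene symbol)."""

    gene_symbol: str
    accessions: Dict[str, str]  # species -> accession
    peptides_per_replicate: Dict[str, int]
    cleavage_sites: List[Tuple[str, int]]  # (accession, P1 site)
    median_log2_per_replicate: Dict[str, float] = field(default_factory=dict)
    site_annotations: Dict[Tuple[str, int], str] = field(default_factory=dict)

    @property
    def total_peptides(self) -> int:
        return sum(self.peptides_per_replicate.values())


@dataclass
class TriageResult:
    """Survivors and the per-stage funnel of one replicate's cascade."""

    replicate_id: str
    surviving_peptides: List[QuantifiedNeoTerm]
    stage_counts: Dict[str, int]
    dropped: List[Tuple[QuantifiedNeoTerm, str]] = field(default_factory=list)

    def surviving_genes(self, proteome: ProteinSet) -> Set[str]:
        return {
            proteome[q.peptide.accession].gene_symbol.upper()
            for q in self.surviving_peptides
        }

    def to_frame(self, proteome: Optional[ProteinSet] = None) -> pd.DataFrame:
        rows = []
        for q, reason in [(s, "") for s in self.surviving_peptides] + self.dropped:
            p = q.peptide
            gene = (
                proteome[p.accession].gene_symbol
                if proteome is not None and p.accession in proteome
                else ""
            )
            rows.append(
                {
                    "replicate_id": p.replicate_id,
                    "sequence": p.sequence,
                    "accession": p.accession,
                    "gene_symbol": gene,
                    "start": p.start,
                    "p1_site": p.start - 1,
                    "log2_ratio": q.log2_ratio,
                    "terminus_class": q.terminus_class,
                    "drop_reason": reason,
                }
            )
        return pd.DataFrame(rows)

    def funnel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_counts), "count": list(self.stage_counts.values())}
        )


def apply_filter_cascade(
    peptides: Sequence[QuantifiedNeoTerm],
    proteome: ProteinSet,
    config: TriageConfig,
    replicate_id: str = "",
) -> TriageResult:
    """Run the contaminant → fold-change → specificity cascade.

    Only ``terminus_class == "neo"`` rows are considered.  Every filter is a
    pure row predicate, so the final survivor set is order-invariant and the
    per-stage counts are weakly decreasing by construction.
    """
    missing = sorted(
        {q.peptide.accession for q in peptides if q.peptide.accession not in proteome}
    )
    if missing:
        raise KeyError(f"peptides map to accessions absent from proteome: {missing}")

    neo = [q for q in peptides if q.terminus_class == "neo"]
    counts: Dict[str, int] = {"input": len(neo)}
    dropped: List[Tuple[QuantifiedNeoTerm, str]] = []

    stage1 = []
    for q in neo:
        rec = proteome[q.peptide.accession]
        if rec.contaminant_class in config.excluded_contaminant_classes:
            dropped.append((q, f"contaminant:{rec.contaminant_class}"))
        else:
            stage1.append(q)
    counts["after_contaminant_exclusion"] = len(stage1)

    stage2 = []
    for q in stage1:
        if config.passes_cutoff(q.log2_ratio):
            stage2.append(q)
        else:
            dropped.append((q, f"log2_ratio<={config.log2_cutoff}"))
    counts["after_fc_cutoff"] = len(stage2)

    stage3 = []
    for q in stage2:
        rec = proteome[q.peptide.accession]
        window = extract_window(rec, q.peptide.start - 1)
        if consensus_filter(window, config.residue_classes):
            stage3.append(q)
        else:
            dropped.append((q, f"specificity:P1={window.p1}"))
    counts["after_specificity_filter"] = len(stage3)

    logger.info(
        "cascade[%s]: %s",
        replicate_id or "-",
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return TriageResult(
        replicate_id=replicate_id,
        surviving_peptides=stage3,
        stage_counts=counts,
        dropped=dropped,
    )


def _calls_from_evidence(
    evidence: Mapping[str, List[QuantifiedNeoTerm]],
    proteome: ProteinSet,
    genes: Iterable[str],
) -> List[SubstrateCall]:
    """Aggregate per-replicate surviving peptides into SubstrateCalls."""
    calls = []
    for gene in genes:
        peptides_per_rep: Dict[str, int] = {}
        medians: Dict[str, float] = {}
        accessions: Dict[str, str] = {}
        sites: Set[Tuple[str, int]] = set()
        for rep_id, rows in evidence.items():
            mine = [
                q
                for q in rows
                if proteome[q.peptide.accession].gene_symbol.upper() == gene
            ]
            if not mine:
                continue
            peptides_per_rep[rep_id] = len(
                {(q.peptide.sequence, q.peptide.start) for q in mine}
            )
            s = pd.Series([q.log2_ratio for q in mine])
            medians[rep_id] = float(s.median())
            for q in mine:
                rec = proteome[q.peptide.accession]
                accessions[rec.species] = rec.accession
                sites.add((rec.accession, q.peptide.start - 1))
        calls.append(
            SubstrateCall(
                gene_symbol=gene,
                accessions=accessions,
                peptides_per_replicate=peptides_per_rep,
                cleavage_sites=sorted(sites),
                median_log2_per_replicate=medians,
            )
        )
    calls.sort(key=lambda c: (-c.total_peptides, c.gene_symbol))
    return calls


def replicate_consensus(
    results: Mapping[str, TriageResult],
    proteome: ProteinSet,
    rule: str = "either",
    primary_species: str = "rabbit",
    species_by_replicate: Optional[Mapping[str, str]] = None,
) -> List[SubstrateCall]:
    """Apply the replication rule and aggregate to protein-level calls.

    ``both_rabbit_reps``: a protein needs >=1 surviving peptide in every
    bioreplicate of the primary species; ``one_rabbit_plus_monkey``: >=1
    primary-species replicate plus >=1 replicate of another species;
    ``either``: either of the two.  "Observed" is interpreted at the protein
    level.  Replicate species come from ``species_by_replicate`` when given,
    otherwise from the species of each replicate's surviving proteins
    (falling back to the ``<species>_<n>`` replicate-id convention).  Output
    is sorted by total supporting peptide count (descending), ties broken
    lexicographically by gene symbol.
    """
    if rule not in REPLICATION_RULES:
        raise ValueError(f"unknown replication rule {rule!r}")
    if not results:
        raise ValueError("need at least one replicate")

    gene_sets: Dict[str, Set[str]] = {
        rep_id: res.surviving_genes(proteome) for rep_id, res in results.items()
    }

    def infer_species(rep_id: str) -> str:
        if species_by_replicate is not None and rep_id in species_by_replicate:
            return species_by_replicate[rep_id]
        seen = {
            proteome[q.peptide.accession].species
            for q in results[rep_id].surviving_peptides
        }
        if len(seen) == 1:
            return next(iter(seen))
        return rep_id.split("_")[0]

    primary_reps = [r for r in results if infer_species(r) == primary_species]
    secondary_reps = [r for r in results if r not in primary_reps]

    all_genes: Set[str] = set().union(*gene_sets.values()) if gene_sets else set()

    def satisfies(gene: str) -> bool:
        in_primary = [r for r in primary_reps if gene in gene_sets[r]]
        in_secondary = [r for r in secondary_reps if gene in gene_sets[r]]
        both_primary = len(primary_reps) >= 2 and len(in_primary) == len(primary_reps)
        one_plus = len(in_primary) >= 1 and len(in_secondary) >= 1
        if rule == "both_rabbit_reps":
            return both_primary
        if rule == "one_rabbit_plus_monkey":
            return one_plus
        return both_primary or one_plus

    called = sorted(g for g in all_genes if satisfies(g))
    evidence = {r: res.surviving_peptides for r, res in results.items()}
    calls = _calls_from_evidence(evidence, proteome, called)
    logger.info("replicate_consensus[%s]: %d proteins called", rule, len(calls))
    return calls


def cross_species_consensus(
    calls_a: Sequence[SubstrateCall], calls_b: Sequence[SubstrateCall]
) -> pd.DataFrame:
    """Intersect two call sets by (normalized) gene symbol.

    Returns a DataFrame indexed by gene symbol with per-species supporting
    peptide counts and median log2 fold changes, sorted by combined peptide
    support.  ``set(result.index)`` is the consensus gene set.
    """
    a = {c.gene_symbol.upper(): c for c in calls_a}
    b = {c.gene_symbol.upper(): c for c in calls_b}
    shared = sorted(set(a) & set(b))
    rows = []
    for gene in shared:
        ca, cb = a[gene], b[gene]

        def _median(call: SubstrateCall) -> float:
            vals = list(call.median_log2_per_replicate.values())
            return float(pd.Series(vals).median()) if vals else float("nan")

        rows.append(
            {
                "gene_symbol": gene,
                "peptides_a": ca.total_peptides,
                "peptides_b": cb.total_peptides,
                "median_log2_a": _median(ca),
                "median_log2_b": _median(cb),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["gene_symbol", "peptides_a", "peptides_b", "median_log2_a", "median_log2_b"]
    )
    if not frame.empty:
        frame = frame.sort_values(
            ["peptides_a", "gene_symbol"], ascending=[False, True]
        ).set_index("gene_symbol")
    else:
        frame = frame.set_index("gene_symbol")
    return frame


def map_sites_to_domains(
    call: SubstrateCall, protein: ProteinRecord
) -> Dict[Tuple[str, int], str]:
    """Annotate each cleavage site with its domain context.

    A site inside a domain (inclusive endpoints) is ``"within <name>"``;
    otherwise the annotation names the nearest flanking domain
    (``"upstream of <name>"`` / ``"downstream of <name>"``); proteins with no
    domain annotations yield ``"unannotated"``.  Sites are 1-based P1 indices
    on the precursor sequence.
    """
    annotations: Dict[Tuple[str, int], str] = {}
    for accession, site in call.cleavage_sites:
        if accession != protein.accession:
            continue
        if site < 1 or site > len(protein.sequence):
            raise ValueError(
                f"site {site} outside {protein.accession} (length {len(protein.sequence)})"
            )
        label = "unannotated"
        if protein.domains:
            within = [d for d in protein.domains if d.contains(site)]
            if within:
                label = f"within {within[0].name}"
            else:
                best = None
                for d in protein.domains:
                    if site < d.start:
                        dist, rel = d.start - site, f"upstream of {d.name}"
                    else:
                        dist, rel = site - d.end, f"downstream of {d.name}"
                    if best is None or dist < best[0]:
                        best = (dist, rel)
                label = best[1]
        annotations[(accession, site)] = label
    call.site_annotations.update(annotations)
    return annotations
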