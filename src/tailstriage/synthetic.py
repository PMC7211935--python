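"""Ground-truthed synthetic TAILS studies.

Emulates the data-generating process of an in vivo degradomics experiment:
a vitreous-like proteome with a handful of true protease substrates and
highly abundant contaminants (immunoglobulins, crystallins); cleavage events
planted with hydrophobic-P1 specificity; per-replicate N-terminal peptide
tables with dimethyl two-channel intensities, a planted control-vs-inhibited
enrichment on substrate-derived neo peptides, lognormal intensity noise,
per-channel dropout, decoy PSMs, and spurious target PSMs mirroring the
decoys (so realized false-discovery proportions are measurable against
ground truth).  One bioreplicate swaps the channel-to-arm assignment, and a
second species shares a configurable subset of orthologous substrates.

Everything is deterministic for a fixed design seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .records import AMINO_ACIDS, Domain, ProteinRecord, ProteinSet
from .specificity import ResidueClassConfig
from .quantify import NTermPeptide

# Average vertebrate residue composition used for background sequences.
BACKGROUND_COMPOSITION = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.068, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.054, "W": 0.011, "Y": 0.029, "V": 0.067,
}

# Relative preference among hydrophobic P1 residues when planting cleavages;
# valine and leucine dominate, as expected for an HtrA1-like protease.
DEFAULT_P1_WEIGHTS = {"V": 0.30, "L": 0.30, "I": 0.10, "M": 0.10, "F": 0.10, "A": 0.10}

_IG_GENES = ("IGHG1", "IGKC", "IGHM")
_CRY_GENES = ("CRYAA", "CRYBB1", "CRYGS")

SPECIES_PREFIX = {"rabbit": "RAB", "monkey": "CYN"}


@dataclass(frozen=True)
class ReplicateDesign:
    replicate_id: str
    species: str
    label_orientation: str

    def __post_init__(self) -> None:
        if self.label_orientation not in ("light_control", "heavy_control"):
            raise ValueError(
                f"unknown label orientation {self.label_orientation!r}"
            )


def default_replicates() -> Tuple[ReplicateDesign, ...]:
    """Two rabbit bioreplicates (labeling reversed in the second) plus one
    cynomolgus-monkey arm — the study topology the pipeline is built for."""
    return (
        ReplicateDesign("rabbit_1", "rabbit", "light_control"),
        ReplicateDesign("rabbit_2", "rabbit", "heavy_control"),
        ReplicateDesign("monkey_1", "monkey", "light_control"),
    )


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one simulated study.  ``seed`` is mandatory."""

    seed: int
    n_background_proteins: int = 40
    n_substrates: int = 5
    n_contaminants: int = 6
    sites_per_substrate: int = 2
    replicates: Tuple[ReplicateDesign, ...] = field(default_factory=default_replicates)
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.5
    dropout_rate: float = 0.1
    decoy_fraction: float = 0.3
    n_shared_substrates: int = 3
    n_background_cleavages: int = 30
    n_contaminant_neo: int = 2
    acetyl_native_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "n_background_proteins",
            "n_substrates",
            "n_contaminants",
            "sites_per_substrate",
            "n_shared_substrates",
            "n_background_cleavages",
            "n_contaminant_neo",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dropout_rate", "decoy_fraction", "acetyl_native_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.n_shared_substrates > self.n_substrates:
            raise ValueError("n_shared_substrates cannot exceed n_substrates")

    @property
    def orientation_map(self) -> Dict[str, str]:
        return {r.replicate_id: r.label_orientation for r in self.replicates}


@dataclass
class GroundTruth:
    """What was planted: cleavage events, substrates, and nuisance rows."""

    cleavage_events: List[Tuple[str, int]]
    true_substrate_accessions: Set[str]
    effect_log2: float
    label_orientation: Dict[str, str]
    true_substrate_genes: Set[str] = field(default_factory=set)
    spurious_rows: Set[Tuple[str, str, int, str]] = field(default_factory=set)
    # (replicate_id, accession, start, sequence) of ground-truth-false targets

    def __post_init__(self) -> None:
        if self.true_substrate_accessions and self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be > 0 for planted substrates")

    def events_for(self, accessions: Set[str]) -> List[Tuple[str, int]]:
        return [(a, s) for a, s in self.cleavage_events if a in accessions]

    def is_spurious(self, peptide: NTermPeptide) -> bool:
        key = (peptide.replicate_id, peptide.accession, peptide.start, peptide.sequence)
        return key in self.spurious_rows

    def to_json(self, path) -> None:
        payload = {
            "cleavage_events": [list(e) for e in self.cleavage_events],
            "true_substrate_accessions": sorted(self.true_substrate_accessions),
            "true_substrate_genes": sorted(self.true_substrate_genes),
            "effect_log2": self.effect_log2,
            "label_orientation": self.label_orientation,
            "spurious_rows": sorted(list(r) for r in self.spurious_rows),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            cleavage_events=[tuple(e) for e in d["cleavage_events"]],
            true_substrate_accessions=set(d["true_substrate_accessions"]),
            true_substrate_genes=set(d.get("true_substrate_genes", [])),
            effect_log2=d["effect_log2"],
            label_orientation=d["label_orientation"],
            spurious_rows={tuple(r) for r in d.get("spurious_rows", [])},
        )


# --------------------------------------------------------------------------
# sequence helpers

_AA_LIST = list(BACKGROUND_COMPOSITION)
_AA_PROBS = np.array([BACKGROUND_COMPOSITION[a] for a in _AA_LIST])
_AA_PROBS = _AA_PROBS / _AA_PROBS.sum()


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_LIST, size=length, p=_AA_PROBS))


def tryptic_end(sequence: str, start0: int, missed: int = 0) -> int:
    """0-based inclusive end of a tryptic peptide starting at ``start0``.

    Cleavage occurs C-terminal to arginine only (dimethylated lysines are not
    cleaved by trypsin); ``missed`` extra R boundaries are skipped.  Runs to
    the protein C-terminus when too few arginines remain.
    """
    seen = 0
    for j in range(start0, len(sequence)):
        if sequence[j] == "R":
            if seen == missed:
                return j
            seen += 1
    return len(sequence) - 1


def tryptic_peptide(sequence: str, start: int, missed: int = 0) -> str:
    """Peptide starting at 1-based ``start``, ending at a tryptic boundary."""
    start0 = start - 1
    end0 = tryptic_end(sequence, start0, missed)
    return sequence[start0 : end0 + 1]


# --------------------------------------------------------------------------
# generation

def generate_proteome(design: SyntheticDesign) -> ProteinSet:
    """Generate the study proteome for every species in the design.

    Rabbit gets background proteins, substrates (each with two annotated
    domains) and contaminants; the monkey arm gets identical-sequence
    orthologs of the background, the contaminants and the first
    ``n_shared_substrates`` substrates (same gene symbols).  Deterministic
    for a fixed seed.
    """
    total = design.n_background_proteins + design.n_substrates + design.n_contaminants
    if total == 0:
        raise ValueError("empty proteome")
    rng = np.random.default_rng([design.seed, 101])

    rabbit: List[ProteinRecord] = []

    for i in range(design.n_background_proteins):
        seq = _random_sequence(rng, int(rng.integers(150, 400)))
        rabbit.append(
            ProteinRecord(
                accession=f"RAB-BG{i + 1:03d}",
                gene_symbol=f"BG{i + 1:03d}",
                species="rabbit",
                sequence=seq,
            )
        )

    for i in range(design.n_substrates):
        seq = _random_sequence(rng, int(rng.integers(200, 400)))
        n = len(seq)
        # two non-overlapping domains in the middle of the sequence
        d1 = Domain("domain-1", max(2, n // 5), n // 2 - 5)
        d2 = Domain("domain-2", n // 2 + 5, n - 10)
        rabbit.append(
            ProteinRecord(
                accession=f"RAB-SUB{i + 1:02d}",
                gene_symbol=f"SUB{i + 1:02d}",
                species="rabbit",
                sequence=seq,
                domains=(d1, d2),
            )
        )

    for i in range(design.n_contaminants):
        if i % 2 == 0:
            cls = "immunoglobulin"
            gene = _IG_GENES[(i // 2) % len(_IG_GENES)]
        else:
            cls = "crystallin"
            gene = _CRY_GENES[(i // 2) % len(_CRY_GENES)]
        seq = _random_sequence(rng, int(rng.integers(150, 300)))
        rabbit.append(
            ProteinRecord(
                accession=f"RAB-CT{i + 1:02d}",
                gene_symbol=gene if i < 6 else f"{gene}L{i}",
                species="rabbit",
                sequence=seq,
                contaminant_class=cls,
            )
        )

    species_needed = {r.species for r in design.replicates}
    records = list(rabbit)
    if "monkey" in species_needed:
        shared_sub = {f"RAB-SUB{i + 1:02d}" for i in range(design.n_shared_substrates)}
        for rec in rabbit:
            is_sub = rec.accession.startswith("RAB-SUB")
            if is_sub and rec.accession not in shared_sub:
                continue
            records.append(
                ProteinRecord(
                    accession=rec.accession.replace("RAB-", "CYN-"),
                    gene_symbol=rec.gene_symbol,
                    species="monkey",
                    sequence=rec.sequence,
                    contaminant_class=rec.contaminant_class,
                    domains=rec.domains,
                )
            )
    return ProteinSet(records)


def _substrates(proteins: ProteinSet) -> List[ProteinRecord]:
    return [r for r in proteins if r.domains and not r.is_contaminant]


def plant_cleavages(
    proteins: ProteinSet,
    specificity: ResidueClassConfig,
    design: SyntheticDesign,
    p1_weights: Optional[Dict[str, float]] = None,
) -> GroundTruth:
    """Plant ``sites_per_substrate`` hydrophobic-P1 cleavage sites per substrate.

    Sites are drawn from interior positions (5..len-4) whose residue is in the
    hydrophobic class, weighted by ``p1_weights`` (valine/leucine-heavy by
    default).  Orthologous substrates in a second species are cut at the same
    positions (their sequences are identical by construction).  Raises,
    naming the accession, when a substrate lacks enough eligible residues.
    """
    weights = dict(DEFAULT_P1_WEIGHTS if p1_weights is None else p1_weights)
    rng = np.random.default_rng([design.seed, 202])
    events: List[Tuple[str, int]] = []
    subs = _substrates(proteins)
    sites_by_gene: Dict[str, List[int]] = {}

    for rec in sorted(subs, key=lambda r: (r.species != "rabbit", r.accession)):
        if rec.gene_symbol in sites_by_gene and rec.species != "rabbit":
            # ortholog: reuse the primary species' sites
            for site in sites_by_gene[rec.gene_symbol]:
                events.append((rec.accession, site))
            continue
        seq = rec.sequence
        eligible = [
            pos
            for pos in range(5, len(seq) - 3)  # 1-based 5 .. len-4
            if seq[pos - 1] in specificity.hydrophobic_set
        ]
        if len(eligible) < design.sites_per_substrate:
            raise ValueError(
                f"substrate {rec.accession} has only {len(eligible)} eligible "
                f"hydrophobic residues, need {design.sites_per_substrate}"
            )
        w = np.array([weights.get(seq[pos - 1], 0.0) for pos in eligible])
        if w.sum() == 0:
            w = np.ones(len(eligible))
        w = w / w.sum()
        chosen = rng.choice(
            eligible, size=design.sites_per_substrate, replace=False, p=w
        )
        sites = sorted(int(s) for s in chosen)
        sites_by_gene[rec.gene_symbol] = sites
        for site in sites:
            events.append((rec.accession, site))

    return GroundTruth(
        cleavage_events=events,
        true_substrate_accessions={r.accession for r in subs},
        true_substrate_genes={r.gene_symbol for r in subs},
        effect_log2=design.effect_log2,
        label_orientation=design.orientation_map,
    )


def _split_channels(
    control: float, inhibited: float, orientation: str
) -> Tuple[float, float]:
    """Map (control, inhibited) arm intensities onto (light, heavy) channels."""
    if orientation == "light_control":
        return control, inhibited
    return inhibited, control


def simulate_peptide_tables(
    proteins: ProteinSet,
    truth: GroundTruth,
    design: SyntheticDesign,
) -> Dict[str, List[NTermPeptide]]:
    """Simulate per-replicate N-terminal peptide quantification tables.

    Row types per replicate (species-matched records only):

    * native N-termini — one per protein, start 1 (or 2 after initiator-Met
      removal), expected log2(control/inhibited) = 0;
    * planted neo peptides — start at P1'+0 (= site+1), tryptic C-terminus
      with 0 and 1 missed cleavages, expected ratio = ``effect_log2``;
    * background neo peptides and contaminant-derived peptides — ratio 0;
    * spurious target PSMs (wrong identifications) with null-distributed
      scores, recorded in ``truth.spurious_rows``;
    * decoy PSMs with scores from the same null distribution, making up
      ``decoy_fraction`` of all rows.

    Intensities follow a lognormal base abundance; the arm effect multiplies
    the control channel; Gaussian noise of sd ``noise_sd_log2`` is added to
    the log2 ratio; each channel independently drops out with probability
    ``dropout_rate``.  Channel assignment honors each replicate's label
    orientation.
    """
    tables: Dict[str, List[NTermPeptide]] = {}
    acc_by_species: Dict[str, List[ProteinRecord]] = {}
    for rec in proteins:
        acc_by_species.setdefault(rec.species, []).append(rec)

    for rep_idx, rep in enumerate(design.replicates):
        rng = np.random.default_rng([design.seed, 303, rep_idx])
        orientation = rep.label_orientation
        species_records = acc_by_species.get(rep.species, [])
        rows: List[NTermPeptide] = []

        def emit(
            sequence: str,
            accession: str,
            start: int,
            effect: float,
            score: float,
            nterm_mod: str = "dimethyl_light",
            is_decoy: bool = False,
        ) -> NTermPeptide:
            base = float(rng.lognormal(mean=math.log(1e6), sigma=0.8))
            eps = float(rng.normal(0.0, design.noise_sd_log2)) if design.noise_sd_log2 > 0 else 0.0
            control = base * 2.0 ** (effect + eps)
            inhibited = base
            light, heavy = _split_channels(control, inhibited, orientation)
            if rng.random() < design.dropout_rate:
                light = None
            if rng.random() < design.dropout_rate:
                heavy = None
            row = NTermPeptide(
                sequence=sequence,
                accession=accession,
                start=start,
                nterm_mod=nterm_mod,
                intensity_light=light,
                intensity_heavy=heavy,
                psm_score=float(score),
                is_decoy=is_decoy,
                replicate_id=rep.replicate_id,
            )
            rows.append(row)
            return row

        # native N termini
        for rec in species_records:
            start = 2 if rec.sequence.startswith("M") and len(rec.sequence) > 1 else 1
            pep = tryptic_peptide(rec.sequence, start, missed=0)
            mod = (
                "acetyl"
                if rng.random() < design.acetyl_native_fraction
                else "dimethyl_light"
            )
            emit(pep, rec.accession, start, 0.0, rng.normal(60, 12), nterm_mod=mod)

        # planted neo peptides (0 and 1 missed cleavages)
        species_accessions = {r.accession for r in species_records}
        by_acc = {r.accession: r for r in species_records}
        for accession, site in truth.events_for(species_accessions):
            seq = by_acc[accession].sequence
            start = site + 1
            forms = {tryptic_peptide(seq, start, missed=m) for m in (0, 1)}
            for pep in sorted(forms):
                emit(pep, accession, start, truth.effect_log2, rng.normal(60, 12))

        # background proteolysis (non-substrate neo peptides, no arm effect)
        background = [
            r
            for r in species_records
            if not r.is_contaminant and r.accession not in truth.true_substrate_accessions
        ]
        for _ in range(design.n_background_cleavages):
            if not background:
                break
            rec = background[int(rng.integers(len(background)))]
            site = int(rng.integers(5, len(rec.sequence) - 4))
            emit(
                tryptic_peptide(rec.sequence, site + 1, missed=0),
                rec.accession,
                site + 1,
                0.0,
                rng.normal(60, 12),
            )

        # contaminant-derived internal peptides
        for rec in species_records:
            if not rec.is_contaminant:
                continue
            for _ in range(design.n_contaminant_neo):
                site = int(rng.integers(5, len(rec.sequence) - 4))
                emit(
                    tryptic_peptide(rec.sequence, site + 1, missed=0),
                    rec.accession,
                    site + 1,
                    0.0,
                    rng.normal(60, 12),
                )

        # spurious targets + decoys (null score distribution, target-decoy
        # symmetry: one spurious target per decoy)
        n_real = len(rows)
        f = design.decoy_fraction
        n_decoys = int(round(f * n_real / (1.0 - 2.0 * f))) if f < 0.5 else n_real
        pool = [r for r in species_records] or None
        for _ in range(n_decoys):
            if pool is not None:
                rec = pool[int(rng.integers(len(pool)))]
                max_start = max(3, len(rec.sequence) - 25)
                start = int(rng.integers(3, max_start + 1))
                length = int(rng.integers(8, 21))
                pep = rec.sequence[start - 1 : start - 1 + length]
                row = emit(pep, rec.accession, start, 0.0, rng.normal(35, 8))
                truth.spurious_rows.add(
                    (rep.replicate_id, row.accession, row.start, row.sequence)
                )
        for i in range(n_decoys):
            pep = _random_sequence(rng, int(rng.integers(8, 21)))
            emit(
                pep,
                f"DECOY_{rep.replicate_id}_{i:04d}",
                int(rng.integers(3, 200)),
                0.0,
                rng.normal(35, 8),
                is_decoy=True,
            )

        tables[rep.replicate_id] = rows
    return tables


def synthesize_study(
    design: SyntheticDesign,
    specificity: Optional[ResidueClassConfig] = None,
) -> Tuple[ProteinSet, GroundTruth, Dict[str, List[NTermPeptide]]]:
    """Generate proteome, ground truth and peptide tables in one call."""
    if specificity is None:
        specificity = ResidueClassConfig()
    proteins = generate_proteome(design)
    truth = plant_cleavages(proteins, specificity, design)
    tables = simulate_peptide_tables(proteins, truth, design)
    return proteins, truth, tables


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
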