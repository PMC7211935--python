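"""Neo-N-terminus classification, target-decoy FDR, and ratio quantification.

In a TAILS experiment every enriched peptide carries a blocked alpha-amine:
either the protein's own terminus (possibly acetylated co-translationally)
or a neo terminus created by proteolysis and dimethylated in vitro.  The
start position of the peptide on its parent protein separates the two.  The
two experimental arms (control antibody vs protease-inhibiting antibody)
are distinguished by light (CH2O) vs heavy (13CD2O) formaldehyde dimethyl
labels; which arm got which label can be swapped between bioreplicates, so
ratio computation is orientation-aware.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mass as _pt_mass

from .records import AMINO_ACIDS, ProteinRecord, ProteinSet

logger = logging.getLogger(__name__)

NTERM_MODS = ("dimethyl_light", "dimethyl_heavy", "acetyl", "pyroglu", "free")
ORIENTATIONS = ("light_control", "heavy_control")

# Label mass deltas in Da.  The heavy/light difference per labeled amine is
# 6.0312 Da; lysine side chains are dimethylated as well, so a heavy-labeled
# peptide gains the increment once at the N-terminus and once per lysine.
DELTA_DIMETHYL_LIGHT = 28.0303
DELTA_DIMETHYL_HEAVY = 34.0615
DELTA_HEAVY_INCREMENT = 6.0312
DELTA_ACETYL = 42.0106
DELTA_PYROGLU = -17.0266

WATER_MONO = 18.0105646863


@dataclass(frozen=True)
class LabelScheme:
    """Dimethyl label masses and the per-replicate channel orientation.

    ``orientation[replicate_id]`` says which channel holds the control arm:
    ``light_control`` means light = control antibody, heavy = protease
    inhibited; ``heavy_control`` is the swap.
    """

    delta_light: float = DELTA_DIMETHYL_LIGHT
    delta_heavy: float = DELTA_DIMETHYL_HEAVY
    delta_heavy_lysine_increment: float = DELTA_HEAVY_INCREMENT
    orientation: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs((self.delta_heavy - self.delta_light) - self.delta_heavy_lysine_increment) > 1e-4:
            raise ValueError(
                "heavy - light label delta must equal the per-lysine increment"
            )
        for rep, orient in self.orientation.items():
            if orient not in ORIENTATIONS:
                raise ValueError(f"unknown orientation {orient!r} for {rep!r}")

    def orientation_for(self, replicate_id: str) -> str:
        try:
            return self.orientation[replicate_id]
        except KeyError:
            raise KeyError(
                f"no label orientation configured for replicate {replicate_id!r}"
            ) from None


@dataclass(frozen=True)
class NTermPeptide:
    """One N-terminally labeled peptide observation (a quantified PSM row)."""

    sequence: str
    accession: str
    start: int
    nterm_mod: str
    intensity_light: Optional[float]
    intensity_heavy: Optional[float]
    psm_score: float
    is_decoy: bool = False
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if self.nterm_mod not in NTERM_MODS:
            raise ValueError(f"unknown N-terminal modification {self.nterm_mod!r}")
        for v in (self.intensity_light, self.intensity_heavy):
            if v is not None and v < 0:
                raise ValueError("intensities must be nonnegative")

    @property
    def missing_channels(self) -> int:
        return sum(
            1
            for v in (self.intensity_light, self.intensity_heavy)
            if v is None or v == 0
        )


@dataclass(frozen=True)
class QuantifiedNeoTerm:
    """A terminus-classified peptide with its orientation-corrected ratio.

    ``log2_ratio`` is log2(control arm / protease-inhibited arm); positive
    values mean the peptide was more abundant when the protease was active.
    """

    peptide: NTermPeptide
    log2_ratio: float
    terminus_class: str

    def __post_init__(self) -> None:
        if self.terminus_class not in ("native", "neo", "ambiguous"):
            raise ValueError(f"unknown terminus class {self.terminus_class!r}")


def classify_terminus(peptide: NTermPeptide, protein: ProteinRecord) -> str:
    """Classify a peptide's N-terminus as ``native`` or ``neo``.

    Start positions 1 and 2 are native (position 2 covers initiator-Met
    removal).  Deeper starts with an in-vitro label (dimethyl), pyroGlu or a
    free amine are neo termini; an acetylated deep start is still called
    native because acetylation is co-translational and marks an original
    terminus.  Signal-peptide-processed termini are not special-cased and
    will be reported as neo.
    """
    if peptide.start > len(protein.sequence):
        raise ValueError(
            f"peptide does not map: start {peptide.start} beyond "
            f"{protein.accession} length {len(protein.sequence)}"
        )
    end = peptide.start + len(peptide.sequence) - 1
    if end > len(protein.sequence):
        raise ValueError(
            f"peptide does not map: {protein.accession} residues "
            f"{peptide.start}-{end} exceed length {len(protein.sequence)}"
        )
    if peptide.start <= 2:
        return "native"
    if peptide.nterm_mod == "acetyl":
        return "native"
    return "neo"


def fdr_filter(
    psms: Sequence[NTermPeptide], q: float, plus_one: bool = False
) -> Tuple[List[NTermPeptide], Optional[float]]:
    """Target-decoy FDR filter.

    The score threshold is the smallest score ``t`` such that
    ``(#decoys >= t) / (#targets >= t) <= q`` (simple count quotient by
    default); all targets at or above the threshold pass, decoys never pass,
    and ties at the threshold are all included.  Returns the passing targets
    and the threshold (None when no threshold satisfies ``q``, in which case
    the result is empty and a warning is emitted).

    The simple quotient is mildly anticonservative because the threshold
    adapts to the decoy fluctuations; ``plus_one=True`` uses the standard
    ``(#decoys + 1) / #targets`` estimate, which compensates for the
    selection effect at the cost of a slightly smaller passing set.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    targets = [p for p in psms if not p.is_decoy]
    decoys = [p for p in psms if p.is_decoy]
    if not targets:
        raise ValueError("no target PSMs supplied")

    target_scores = np.sort(np.array([p.psm_score for p in targets]))
    decoy_scores = np.sort(np.array([p.psm_score for p in decoys]))

    threshold: Optional[float] = None
    # Candidate thresholds: every observed score; scan ascending so the first
    # satisfying candidate is the smallest (most permissive) valid threshold.
    candidates = np.unique(np.concatenate([target_scores, decoy_scores]))
    n_t = len(target_scores)
    n_d = len(decoy_scores)
    for t in candidates:
        n_targets_ge = n_t - np.searchsorted(target_scores, t, side="left")
        n_decoys_ge = n_d - np.searchsorted(decoy_scores, t, side="left")
        if n_targets_ge == 0:
            continue
        estimate = (n_decoys_ge + (1 if plus_one else 0)) / n_targets_ge
        if estimate <= q:
            threshold = float(t)
            break
    if threshold is None:
        warnings.warn("no score threshold satisfies the requested FDR", stacklevel=2)
        return [], None
    passing = [p for p in targets if p.psm_score >= threshold]
    logger.info(
        "fdr_filter: %d/%d targets pass at q=%.3g (threshold %.4g, %d decoys)",
        len(passing),
        len(targets),
        q,
        threshold,
        len(decoys),
    )
    return passing, threshold


def quantify_ratio(
    peptide: NTermPeptide,
    scheme: LabelScheme,
    protein: Optional[ProteinRecord] = None,
    missing_policy: str = "exclude",
    cap_log2: float = 6.0,
) -> Optional[QuantifiedNeoTerm]:
    """Convert channel intensities to an orientation-corrected log2 ratio.

    With orientation ``light_control`` the ratio is light/heavy; with
    ``heavy_control`` it is heavy/light — either way the result is
    log2(control / inhibited).  A zero intensity is treated as a missing
    channel.  ``missing_policy="exclude"`` (default) returns None for rows
    with one missing channel; ``"cap"`` assigns +-``cap_log2`` instead.
    Rows with both channels missing are unquantifiable and raise.
    """
    if missing_policy not in ("exclude", "cap"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    light = peptide.intensity_light or None
    heavy = peptide.intensity_heavy or None
    orientation = scheme.orientation_for(peptide.replicate_id)
    if orientation == "light_control":
        control, inhibited = light, heavy
    else:
        control, inhibited = heavy, light
    if control is None and inhibited is None:
        raise ValueError("unquantifiable: both channels missing")

    if control is None or inhibited is None:
        if missing_policy == "exclude":
            return None
        log2_ratio = cap_log2 if inhibited is None else -cap_log2
    else:
        log2_ratio = math.log2(control / inhibited)

    terminus = (
        classify_terminus(peptide, protein) if protein is not None else "ambiguous"
    )
    return QuantifiedNeoTerm(
        peptide=peptide, log2_ratio=log2_ratio, terminus_class=terminus
    )


def quantify_table(
    peptides: Iterable[NTermPeptide],
    scheme: LabelScheme,
    proteome: Optional[ProteinSet] = None,
    missing_policy: str = "exclude",
) -> Tuple[List[QuantifiedNeoTerm], Dict[str, int]]:
    """Quantify a peptide list; returns (quantified rows, drop counts)."""
    out: List[QuantifiedNeoTerm] = []
    counts = {"input": 0, "missing_channel": 0, "unquantifiable": 0, "quantified": 0}
    for pep in peptides:
        counts["input"] += 1
        protein = proteome.get(pep.accession) if proteome is not None else None
        try:
            q = quantify_ratio(pep, scheme, protein, missing_policy=missing_policy)
        except ValueError:
            counts["unquantifiable"] += 1
            continue
        if q is None:
            counts["missing_channel"] += 1
            continue
        counts["quantified"] += 1
        out.append(q)
    logger.info(
        "quantify_table: %(quantified)d quantified, %(missing_channel)d dropped "
        "with one missing channel, %(unquantifiable)d unquantifiable",
        counts,
    )
    return out, counts


def rollup_psms(psms: Sequence[NTermPeptide]) -> List[NTermPeptide]:
    """Collapse PSMs to peptides per (sequence, start, accession, replicate).

    The best-scoring PSM represents the peptide; channel intensities are
    summed across its PSMs (missing stays missing only if missing in all).
    """
    groups: Dict[Tuple, List[NTermPeptide]] = {}
    for p in psms:
        key = (p.sequence, p.start, p.accession, p.replicate_id, p.is_decoy)
        groups.setdefault(key, []).append(p)
    out = []
    for rows in groups.values():
        best = max(rows, key=lambda r: r.psm_score)
        light_vals = [r.intensity_light for r in rows if r.intensity_light is not None]
        heavy_vals = [r.intensity_heavy for r in rows if r.intensity_heavy is not None]
        out.append(
            replace(
                best,
                intensity_light=sum(light_vals) if light_vals else None,
                intensity_heavy=sum(heavy_vals) if heavy_vals else None,
            )
        )
    return out


_NTERM_DELTAS = {
    "dimethyl_light": DELTA_DIMETHYL_LIGHT,
    "dimethyl_heavy": DELTA_DIMETHYL_HEAVY,
    "acetyl": DELTA_ACETYL,
    "pyroglu": DELTA_PYROGLU,
    "free": 0.0,
}


def peptide_monoisotopic_mass(
    sequence: str,
    nterm_mod: str = "free",
    lysine_label: Optional[str] = None,
) -> float:
    """Monoisotopic peptide mass with dimethyl-labeling deltas.

    Sum of residue masses + water + the N-terminal modification delta +
    one dimethyl delta per lysine side chain when ``lysine_label`` is
    ``"light"`` or ``"heavy"`` (None leaves lysines unlabeled).  Heavy minus
    light labeling at the N-terminus differs by exactly 6.0312 Da.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if nterm_mod not in _NTERM_DELTAS:
        raise ValueError(f"unknown N-terminal modification {nterm_mod!r}")
    if lysine_label not in (None, "light", "heavy"):
        raise ValueError(f"unknown lysine label {lysine_label!r}")
    total = WATER_MONO
    for aa in sequence:
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {aa!r}")
        total += _pt_mass.std_aa_mass[aa]
    total += _NTERM_DELTAS[nterm_mod]
    if lysine_label is not None:
        per_lysine = (
            DELTA_DIMETHYL_LIGHT if lysine_label == "light" else DELTA_DIMETHYL_HEAVY
        )
        total += per_lysine * sequence.count("K")
    return total
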