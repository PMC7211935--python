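"""Cleavage-site specificity profiling and the consensus predicate.

Serine proteases of the trypsin fold read out the residues flanking the
scissile bond; in Schechter–Berger nomenclature P1 is the residue immediately
N-terminal to the cut and P1' immediately C-terminal, with P4…P4' spanning
the +-4 window.  HtrA1-type proteases prefer hydrophobic P1 residues (valine
and leucine above all), so a cleavage C-terminal to a basic residue is
evidence against the protease having made the cut.

This module provides

* :func:`extract_window` — read the 8-residue P4…P4' window off a precursor,
* :func:`build_specificity_profile` — a differential residue-frequency
  profile against a reference composition with per-cell significance, the
  statistic behind iceLogo-style plots,
* :func:`consensus_filter` — the pure predicate used during substrate triage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS, ProteinRecord

POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")
PAD = "-"

DEFAULT_HYDROPHOBIC = frozenset("VLIMFA")
DEFAULT_BASIC = frozenset("KRH")


@dataclass(frozen=True)
class ResidueClassConfig:
    """Residue classes used by the consensus predicate.

    ``exclude_basic_P1`` rejects only cleavages C-terminal to a basic residue
    (the one exclusion that is uncontroversial for a hydrophobic-P1 protease);
    ``require_hydrophobic_P1`` is the stricter positive requirement.
    """

    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC
    basic_set: frozenset = DEFAULT_BASIC
    mode: str = "exclude_basic_P1"

    def __post_init__(self) -> None:
        if not self.hydrophobic_set or not self.basic_set:
            raise ValueError("residue classes must be non-empty")
        if set(self.hydrophobic_set) & set(self.basic_set):
            raise ValueError("hydrophobic and basic sets must be disjoint")
        if self.mode not in ("exclude_basic_P1", "require_hydrophobic_P1"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class CleavageWindow:
    """An aligned P4…P4' window; ``-`` pads positions beyond the termini."""

    residues: str
    source: Tuple[str, int] = ("", 0)  # (accession, P1 site)

    def __post_init__(self) -> None:
        if len(self.residues) != 8:
            raise ValueError("cleavage window must be exactly 8 characters")
        bad = set(self.residues) - set(AMINO_ACIDS) - {PAD}
        if bad:
            raise ValueError(f"invalid window characters {sorted(bad)}")

    @property
    def p1(self) -> str:
        return self.residues[3]

    @property
    def p1_prime(self) -> str:
        return self.residues[4]

    def __str__(self) -> str:
        return self.residues


def extract_window(protein: ProteinRecord, site: int) -> CleavageWindow:
    """Extract the P4…P4' window around the scissile bond after ``site``.

    ``site`` is the 1-based index of the P1 residue; the neo N-terminal
    peptide created by this cleavage starts at ``site + 1``.  A cleavage at
    the C-terminal residue has no P1' and is rejected.
    """
    seq = protein.sequence
    n = len(seq)
    if site < 1 or site > n:
        raise ValueError(f"site {site} outside sequence of length {n}")
    if site == n:
        raise ValueError("cleavage at C-terminus")
    chars = []
    for pos in range(site - 4, site + 4):  # 0-based indices site-4 .. site+3
        chars.append(seq[pos] if 0 <= pos < n else PAD)
    return CleavageWindow("".join(chars), source=(protein.accession, site))


def consensus_filter(window: CleavageWindow, config: ResidueClassConfig) -> bool:
    """Return True iff ``window`` is consistent with the protease consensus."""
    p1 = window.p1
    if p1 == PAD:
        raise ValueError("no P1 residue")
    if config.mode == "exclude_basic_P1":
        return p1 not in config.basic_set
    return p1 in config.hydrophobic_set


@dataclass
class SpecificityProfile:
    """Per-position differential residue frequencies with significance calls.

    ``observed`` and ``difference`` are DataFrames indexed by residue with one
    column per alignment position; ``p_value`` holds the two-sided normal
    p-value of the observed frequency against the reference proportion.
    Padding characters are excluded from the per-position counts, so each
    position may have its own effective n.
    """

    observed: pd.DataFrame
    reference: pd.Series
    difference: pd.DataFrame
    p_value: pd.DataFrame
    alpha: float
    n_windows: int
    n_per_position: pd.Series = field(default=None)

    @property
    def enriched(self) -> pd.DataFrame:
        return (self.p_value < self.alpha) & (self.difference > 0)

    @property
    def depleted(self) -> pd.DataFrame:
        return (self.p_value < self.alpha) & (self.difference < 0)

    def significant_cells(self) -> List[Tuple[str, str, float, float]]:
        """(position, residue, difference, p) for every significant cell."""
        out = []
        for pos in self.difference.columns:
            for aa in self.difference.index:
                p = self.p_value.loc[aa, pos]
                if p < self.alpha:
                    out.append((pos, aa, float(self.difference.loc[aa, pos]), float(p)))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (position, residue)."""
        rows = []
        for pos in POSITIONS:
            for aa in sorted(AMINO_ACIDS):
                diff = float(self.difference.loc[aa, pos])
                p = float(self.p_value.loc[aa, pos])
                status = "ns"
                if p < self.alpha:
                    status = "enriched" if diff > 0 else "depleted"
                rows.append(
                    {
                        "position": pos,
                        "residue": aa,
                        "observed_freq": float(self.observed.loc[aa, pos]),
                        "reference_freq": float(self.reference[aa]),
                        "difference": diff,
                        "p_value": p,
                        "status": status,
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        """Write the profile as TSV with a metadata comment header.

        The differential scale is frequency difference (observed - reference),
        recorded in the header so downstream consumers know which of the
        possible logo scalings was used.
        """
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write("# tailstriage specificity-profile v1.0\n")
            fh.write(f"# n_windows={self.n_windows} alpha={self.alpha} scale=difference\n")
            frame.to_csv(fh, sep="\t", index=False)


def uniform_reference() -> Dict[str, float]:
    """Flat 1/20 composition; a convenience for tests and small examples."""
    return {aa: 1.0 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}


def _two_sided_normal_p(z: np.ndarray) -> np.ndarray:
    # 2*(1 - Phi(|z|)) via erfc for numerical stability in the far tail
    return np.array(
        [math.erfc(abs(float(v)) / math.sqrt(2.0)) for v in np.atleast_1d(z)]
    )


def build_specificity_profile(
    windows: Sequence[CleavageWindow],
    reference: Mapping[str, float],
    alpha: float = 0.05,
) -> SpecificityProfile:
    """Differential specificity profile of ``windows`` against ``reference``.

    For each (position, residue) cell the observed frequency among
    non-padding residues is compared with the reference proportion by a
    z-statistic ``(p_obs - p_ref) / sqrt(p_ref (1 - p_ref) / n)`` with a
    two-sided normal p-value — the proportion test against a (proteome-sized,
    effectively fixed) reference composition.  Cells with ``p < alpha`` are
    flagged enriched (positive difference) or depleted (negative).
    """
    if not windows:
        raise ValueError("empty window list")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ref = pd.Series({aa: float(reference.get(aa, np.nan)) for aa in AMINO_ACIDS})
    total = float(np.nansum(ref.values))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"reference frequencies sum to {total}, expected 1")

    residues = sorted(AMINO_ACIDS)
    res_index = {aa: i for i, aa in enumerate(residues)}
    count_mat = np.zeros((len(residues), len(POSITIONS)))
    for w in windows:
        for j, aa in enumerate(w.residues):
            if aa == PAD:
                continue
            if math.isnan(ref[aa]):
                raise ValueError(f"reference missing residue {aa!r}")
            count_mat[res_index[aa], j] += 1
    counts = pd.DataFrame(count_mat, index=residues, columns=list(POSITIONS))

    n_per_position = counts.sum(axis=0)
    observed = counts.divide(n_per_position.replace(0, np.nan), axis=1).fillna(0.0)
    ref = ref.fillna(0.0)
    difference = observed.subtract(ref, axis=0)

    p = pd.DataFrame(1.0, index=residues, columns=list(POSITIONS))
    for pos_label in POSITIONS:
        n = float(n_per_position[pos_label])
        if n == 0:
            continue
        se = np.sqrt(ref.values * (1.0 - ref.values) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, difference[pos_label].values / se, 0.0)
        p[pos_label] = _two_sided_normal_p(z)

    return SpecificityProfile(
        observed=observed,
        reference=ref,
        difference=difference,
        p_value=p,
        alpha=alpha,
        n_windows=len(windows),
        n_per_position=n_per_position,
    )


def reference_from_fasta(path) -> Dict[str, float]:
    """Residue composition of a proteome FASTA, for use as logo reference."""
    from .records import ProteinSet

    return ProteinSet.from_fasta(path).residue_composition()


def plot_profile(profile: SpecificityProfile, path=None, ax=None):
    """Render a minimal differential logo: signed frequency-difference bars.

    Significant residues are drawn as stacked letter bars above (enriched) or
    below (depleted) the axis, one column per P position.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for i, pos in enumerate(POSITIONS):
        up = 0.0
        down = 0.0
        for aa in profile.difference.index:
            if profile.p_value.loc[aa, pos] >= profile.alpha:
                continue
            d = float(profile.difference.loc[aa, pos])
            if d > 0:
                ax.bar(i, d, bottom=up, width=0.8, color="tab:blue", alpha=0.6)
                ax.text(i, up + d / 2, aa, ha="center", va="center", fontsize=8)
                up += d
            elif d < 0:
                ax.bar(i, d, bottom=down, width=0.8, color="tab:red", alpha=0.6)
                ax.text(i, down + d / 2, aa, ha="center", va="center", fontsize=8)
                down += d
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(range(len(POSITIONS)))
    ax.set_xticklabels(POSITIONS)
    ax.set_ylabel("frequency difference (observed - reference)")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
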