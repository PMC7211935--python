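"""Versioned TSV schema for N-terminal peptide tables.

The table is the interchange format between an upstream search engine (or
the synthetic generator) and the quantification/triage stages.  The first
line is a schema comment ``# tailstriage peptide-table vMAJOR.MINOR``;
readers reject unknown major versions.  Missing channel intensities are
empty cells.
"""

from __future__ import annotations

import re
from typing import Dict, List, Sequence

import pandas as pd

from .quantify import NTermPeptide

SCHEMA_NAME = "tailstriage peptide-table"
SCHEMA_VERSION = (1, 0)

COLUMNS = [
    "replicate_id",
    "sequence",
    "accession",
    "start",
    "nterm_mod",
    "intensity_light",
    "intensity_heavy",
    "psm_score",
    "is_decoy",
]


def peptides_to_frame(peptides: Sequence[NTermPeptide]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate_id": [p.replicate_id for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "accession": [p.accession for p in peptides],
            "start": [p.start for p in peptides],
            "nterm_mod": [p.nterm_mod for p in peptides],
            "intensity_light": [p.intensity_light for p in peptides],
            "intensity_heavy": [p.intensity_heavy for p in peptides],
            "psm_score": [p.psm_score for p in peptides],
            "is_decoy": [p.is_decoy for p in peptides],
        },
        columns=COLUMNS,
    )


def write_peptide_tsv(path, peptides: Sequence[NTermPeptide]) -> None:
    frame = peptides_to_frame(peptides)
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_NAME} v{SCHEMA_VERSION[0]}.{SCHEMA_VERSION[1]}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_peptide_tsv(path) -> List[NTermPeptide]:
    with open(path) as fh:
        header = fh.readline()
        m = re.match(rf"#\s*{re.escape(SCHEMA_NAME)}\s+v(\d+)\.(\d+)", header)
        if not m:
            raise ValueError(f"{path}: missing or malformed schema header")
        major = int(m.group(1))
        if major != SCHEMA_VERSION[0]:
            raise ValueError(
                f"{path}: unsupported schema major version {major} "
                f"(reader supports {SCHEMA_VERSION[0]})"
            )
        frame = pd.read_csv(fh, sep="\t")
    missing = set(COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    peptides = []
    for i, row in frame.iterrows():
        try:
            peptides.append(
                NTermPeptide(
                    sequence=str(row["sequence"]),
                    accession=str(row["accession"]),
                    start=int(row["start"]),
                    nterm_mod=str(row["nterm_mod"]),
                    intensity_light=(
                        None if pd.isna(row["intensity_light"]) else float(row["intensity_light"])
                    ),
                    intensity_heavy=(
                        None if pd.isna(row["intensity_heavy"]) else float(row["intensity_heavy"])
                    ),
                    psm_score=float(row["psm_score"]),
                    is_decoy=bool(row["is_decoy"]),
                    replicate_id=str(row["replicate_id"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: line {i + 3}: {exc}") from exc
    return peptides


def read_densitometry_csv(path) -> pd.DataFrame:
    """Densitometry CSV: sample_id, group, gel_block, active, total[, timepoint]."""
    frame = pd.read_csv(path)
    required = {"sample_id", "group", "gel_block", "active", "total"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_doseresponse_csv(path) -> pd.DataFrame:
    """Dose-response CSV: conc, response."""
    frame = pd.read_csv(path)
    required = {"conc", "response"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame
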