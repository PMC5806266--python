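"""Sequence-level descriptors relevant to lipase thermostability.

Covers the classic desk calculations for a deduced protein sequence: average
molecular mass, isoelectric point (Henderson-Hasselbalch net charge, solved
by bisection), residue composition, the AXXXA packing motif associated with
thermostable lipases, the G-X-S-X-G nucleophilic-elbow scan, and signal
peptide cleavage bookkeeping (precursor -> mature).  Positions are 1-based
throughout, matching the residue numbering conventions of the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .constants import (
    AVERAGE_RESIDUE_MASS,
    DEFAULT_PKA_TABLE,
    NEGATIVE_GROUPS,
    PKA_TABLES,
    POSITIVE_GROUPS,
    STANDARD_RESIDUES,
    WATER_AVG_MASS,
)
from .exceptions import AlphabetError, EmptyInputError, InvalidParameterError


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence (uppercase one-letter residues; X tolerated)."""

    identifier: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise EmptyInputError("sequence must contain at least one residue")
        bad = set(self.residues) - STANDARD_RESIDUES - {"X"}
        if bad:
            raise AlphabetError(
                f"non-standard residue(s) {sorted(bad)} in {self.identifier!r}"
            )

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class SequenceFeatureReport:
    length: int
    avg_mass_Da: float
    pI: float
    ala_percent: float
    axxxa_count: int
    elbow_matches: Tuple[Tuple[int, str], ...]
    cleavage_index: Optional[int] = None


def _checked(seq: SequenceRecord, operation: str) -> str:
    residues = seq.residues
    if "X" in residues:
        warnings.warn(f"{operation}: residue 'X' excluded from the calculation")
        residues = residues.replace("X", "")
        if not residues:
            raise EmptyInputError(f"{operation}: no standard residues left")
    return residues


def average_mass(seq: SequenceRecord) -> float:
    """Average (not monoisotopic) molecular mass in Da: residue masses plus
    one water for the free chain termini."""
    residues = _checked(seq, "average_mass")
    return sum(AVERAGE_RESIDUE_MASS[a] for a in residues) + WATER_AVG_MASS


def net_charge(seq: SequenceRecord, pH: float,
               pKa_table: str = DEFAULT_PKA_TABLE) -> float:
    """Henderson-Hasselbalch net charge of the chain at a given pH.

    Positive groups (N-terminus, H, K, R) contribute 1/(1+10^(pH-pKa));
    negative groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pKa-pH)).
    """
    table = PKA_TABLES[pKa_table] if isinstance(pKa_table, str) else pKa_table
    residues = _checked(seq, "net_charge")
    counts = {g: residues.count(g) for g in "DECYHKR"}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    charge = 0.0
    for g in POSITIVE_GROUPS:
        charge += counts.get(g, 0) / (1.0 + 10.0 ** (pH - table[g]))
    for g in NEGATIVE_GROUPS:
        charge -= counts.get(g, 0) / (1.0 + 10.0 ** (table[g] - pH))
    return charge


def isoelectric_point(seq: SequenceRecord,
                      pKa_table: str = DEFAULT_PKA_TABLE) -> float:
    """pH of zero net charge, by bisection on [0, 14] to 1e-4.

    Net charge is strictly decreasing in pH, so the zero crossing is unique.
    """
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo, pKa_table) < 0:
        return lo
    if net_charge(seq, hi, pKa_table) > 0:
        return hi
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pKa_table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def residue_fraction(seq: SequenceRecord, residue: str) -> float:
    """Percentage of positions occupied by ``residue``."""
    if len(residue) != 1:
        raise InvalidParameterError("residue must be a single letter")
    return 100.0 * seq.residues.count(residue) / len(seq)


def count_axxxa(seq: SequenceRecord) -> int:
    """Occurrences of A-x-x-x-A (alanines four apart); overlaps all counted,
    so an alanine may end one motif and start the next."""
    r = seq.residues
    return sum(1 for i in range(len(r) - 4) if r[i] == "A" and r[i + 4] == "A")


def scan_pentapeptide(seq: SequenceRecord,
                      pattern: str = "GXSXG") -> List[Tuple[int, str]]:
    """All matches of a 5-residue pattern where 'X' is a wildcard.

    Returns (1-based start, matched pentapeptide) pairs; for the default
    nucleophilic-elbow pattern G-X-S-X-G the catalytic serine sits at
    start + 2.
    """
    if len(pattern) != 5:
        raise InvalidParameterError("pattern must be 5 residues long")
    r = seq.residues
    matches = []
    for i in range(len(r) - 4):
        window = r[i:i + 5]
        if all(p == "X" or p == w for p, w in zip(pattern, window)):
            matches.append((i + 1, window))
    return matches


def apply_cleavage(seq: SequenceRecord, cleavage_after: int) -> SequenceRecord:
    """Remove the signal peptide: keep residues cleavage_after+1 .. end.

    ``cleavage_after`` counts residues of the signal peptide (0 = identity).
    """
    if not (0 <= cleavage_after < len(seq)):
        raise InvalidParameterError(
            f"cleavage_after must be in [0, {len(seq) - 1}], got {cleavage_after}"
        )
    return SequenceRecord(
        identifier=f"{seq.identifier}|mature" if cleavage_after else seq.identifier,
        residues=seq.residues[cleavage_after:],
    )


def feature_report(seq: SequenceRecord,
                   cleavage_index: Optional[int] = None,
                   pKa_table: str = DEFAULT_PKA_TABLE) -> SequenceFeatureReport:
    """All descriptors for one sequence (as given, no cleavage applied)."""
    return SequenceFeatureReport(
        length=len(seq),
        avg_mass_Da=average_mass(seq),
        pI=isoelectric_point(seq, pKa_table),
        ala_percent=residue_fraction(seq, "A"),
        axxxa_count=count_axxxa(seq),
        elbow_matches=tuple(scan_pentapeptide(seq)),
        cleavage_index=cleavage_index,
    )


def read_fasta(path) -> List[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(identifier=rec.id,
                                      residues=str(rec.seq).upper()))
    return records


def write_fasta(records, path):
    bio = [_BioSeqRecord(Seq(r.residues), id=r.identifier, description="")
           for r in records]
    SeqIO.write(bio, str(path), "fasta")
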