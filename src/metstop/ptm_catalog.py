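"""Parsing, validation and indexing of post-translational modification records.

Records follow the flanking-nonamer convention used in curated PTM tables:
each modified residue is given as a 9-character window of the source sequence
with the modified residue lowercase at the center (position 5), e.g.
``VGRGrFTTY`` for a methylated arginine.  Metabolite-class modifications
(acetylation, methylation, succinylation, ...) occur on Lys/Arg sidechains;
phosphorylation occurs on Ser/Thr/Tyr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import AmbiguityError, FormatError, PlacementError, ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
PAD = "-"
FLANK_LENGTH = 9
CENTER = 5  # 1-based center position of the nonamer

#: Metabolite attachments to Lys/Arg sidechains that can block lipid binding.
METABOLITE_PTM_TYPES = frozenset(
    {
        "acetylation",
        "butyrylation",
        "hydroxyisobutyrylation",
        "glycation",
        "glutarylation",
        "malonylation",
        "methylation",
        "succinylation",
    }
)
PHOSPHO_PTM_TYPES = frozenset({"phosphorylation"})
PTM_TYPES = METABOLITE_PTM_TYPES | PHOSPHO_PTM_TYPES

METABOLITE_RESIDUES = frozenset("KR")
PHOSPHO_RESIDUES = frozenset("STY")

PTM_TABLE_COLUMNS = ("protein", "species", "residue", "ptm_type", "flank", "study_count")


def parse_flank(flank: str) -> tuple[str, int]:
    """Parse a flanking nonamer and return ``(center_letter, center_index)``.

    The center letter is returned uppercase; the index is 1-based and is
    required to be 5.  Raises :class:`FormatError` for anything else: wrong
    length, zero or multiple lowercase letters, or a lowercase letter away
    from the center.
    """
    if len(flank) != FLANK_LENGTH:
        raise FormatError(f"flank {flank!r} has length {len(flank)}, expected {FLANK_LENGTH}")
    lowers = [i for i, ch in enumerate(flank, start=1) if ch.isalpha() and ch.islower()]
    if len(lowers) != 1:
        raise FormatError(
            f"flank {flank!r} must mark exactly one residue lowercase, found {len(lowers)}"
        )
    idx = lowers[0]
    if idx != CENTER:
        raise FormatError(f"flank {flank!r} has its lowercase residue at position {idx}, not {CENTER}")
    letter = flank[idx - 1].upper()
    if letter not in AMINO_ACIDS:
        raise FormatError(f"flank {flank!r} center {letter!r} is not an amino-acid letter")
    for i, ch in enumerate(flank, start=1):
        if i == idx:
            continue
        if ch != PAD and (not ch.isalpha() or not ch.isupper() or ch not in AMINO_ACIDS):
            raise FormatError(f"flank {flank!r} position {i} holds illegal character {ch!r}")
    return letter, idx


@dataclass(frozen=True)
class PTMRecord:
    """One modification instance on one residue of one protein in one species."""

    protein: str
    species: str
    residue_letter: str
    residue_number: int
    ptm_type: str
    flank: str
    study_count: int = 1

    def __post_init__(self) -> None:
        if self.ptm_type not in PTM_TYPES:
            raise ValidationError(f"{self.protein}: unknown ptm_type {self.ptm_type!r}")
        if self.residue_number < 1:
            raise ValidationError(f"{self.protein}: residue_number must be positive")
        if self.study_count < 1:
            raise ValidationError(f"{self.protein}: study_count must be >= 1")
        letter, _ = parse_flank(self.flank)
        if letter != self.residue_letter.upper():
            raise ValidationError(
                f"{self.protein} {self.residue_letter}{self.residue_number}: "
                f"flank center {letter} disagrees with residue letter {self.residue_letter}"
            )
        if self.is_metabolite and self.residue_letter not in METABOLITE_RESIDUES:
            raise ValidationError(
                f"{self.protein}: metabolite modification {self.ptm_type} on "
                f"{self.residue_letter}, expected K or R"
            )
        if self.is_phospho and self.residue_letter not in PHOSPHO_RESIDUES:
            raise ValidationError(
                f"{self.protein}: phosphorylation on {self.residue_letter}, expected S, T or Y"
            )

    @property
    def is_metabolite(self) -> bool:
        return self.ptm_type in METABOLITE_PTM_TYPES

    @property
    def is_phospho(self) -> bool:
        return self.ptm_type in PHOSPHO_PTM_TYPES

    @property
    def residue(self) -> str:
        """Residue token, e.g. ``"K92"``."""
        return f"{self.residue_letter}{self.residue_number}"

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Aggregation key: one modification = (protein, species, residue, type)."""
        return (self.protein, self.species, self.residue_number, self.ptm_type)


def _parse_residue_token(token: str, row: int) -> tuple[str, int]:
    token = token.strip()
    if len(token) < 2 or token[0].upper() not in AMINO_ACIDS or not token[1:].isdigit():
        raise ValidationError(f"row {row}: malformed residue token {token!r}")
    return token[0].upper(), int(token[1:])


def load_ptm_table(path: str | Path) -> list[PTMRecord]:
    """Load a PTM site table from TSV.

    Required columns: protein, species, residue, ptm_type, flank.  The
    study_count column is optional and defaults to 1 per row.  Every record is
    validated, including the cross-check that the residue token's letter
    matches the lowercase flank center.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein", "species", "residue", "ptm_type", "flank"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    records: list[PTMRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        letter, number = _parse_residue_token(row.residue, i)
        count = int(getattr(row, "study_count", 1) or 1)
        try:
            rec = PTMRecord(
                protein=row.protein.strip(),
                species=row.species.strip(),
                residue_letter=letter,
                residue_number=number,
                ptm_type=row.ptm_type.strip().lower(),
                flank=row.flank.strip(),
                study_count=count,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
    logger.info("loaded %d modification records from %s", len(records), path)
    return records


def write_ptm_table(records: Iterable[PTMRecord], path: str | Path) -> None:
    """Serialize records to the TSV dialect read by :func:`load_ptm_table`."""
    df = pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "species": [r.species for r in records],
            "residue": [r.residue for r in records],
            "ptm_type": [r.ptm_type for r in records],
            "flank": [r.flank for r in records],
            "study_count": [r.study_count for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def aggregate(records: Iterable[PTMRecord]) -> list[PTMRecord]:
    """Pool duplicate records of one modification into a single record.

    A modification is identified by (protein, species, residue_number,
    ptm_type); duplicates have their study counts pooled by maximum, so that
    each original dataset is only counted once per modification.  Order of
    first appearance is preserved.
    """
    pooled: dict[tuple, PTMRecord] = {}
    for rec in records:
        prev = pooled.get(rec.key)
        if prev is None:
            pooled[rec.key] = rec
        elif rec.study_count > prev.study_count:
            pooled[rec.key] = replace(prev, study_count=rec.study_count)
    return list(pooled.values())


@dataclass(frozen=True)
class LocatedSite:
    """Result of anchoring a record onto a sequence."""

    position: int  # 1-based index into the ungapped sequence
    verified: bool = True


def _flank_matches(sequence: str, position: int, flank: str) -> bool:
    """Pad-tolerant window comparison around a 1-based sequence position."""
    for offset in range(-(CENTER - 1), FLANK_LENGTH - CENTER + 1):
        f = flank[offset + CENTER - 1]
        p = position + offset
        if f == PAD:
            continue
        if p < 1 or p > len(sequence):
            if offset == 0:
                return False
            continue  # truncated flank at a terminus
        if sequence[p - 1].upper() != f.upper():
            return False
    return True


def locate_in_sequence(
    record: PTMRecord, sequence: str, numbering_offset: int = 0
) -> LocatedSite:
    """Anchor a record onto ``sequence`` and verify it.

    ``numbering_offset`` maps source numbering onto sequence indices: the
    residue sits at sequence position ``residue_number - numbering_offset``
    (so offset 0 means the sequence starts at source residue 1).

    Raises :class:`PlacementError` when the stated position is out of range,
    holds the wrong letter, or the flank matches nowhere; raises
    :class:`AmbiguityError` (listing candidates) when the flank fails at the
    stated position but matches elsewhere.
    """
    if not sequence:
        raise PlacementError(f"{record.protein} {record.residue}: empty sequence")
    pos = record.residue_number - numbering_offset
    if pos < 1 or pos > len(sequence):
        raise PlacementError(
            f"{record.protein} {record.residue}: position {pos} outside sequence "
            f"of length {len(sequence)}"
        )
    if sequence[pos - 1].upper() != record.residue_letter:
        raise PlacementError(
            f"{record.protein} {record.residue}: sequence holds "
            f"{sequence[pos - 1]!r} at position {pos}, expected {record.residue_letter}"
        )
    if _flank_matches(sequence, pos, record.flank):
        return LocatedSite(position=pos, verified=True)
    candidates = tuple(
        p
        for p in range(1, len(sequence) + 1)
        if p != pos
        and sequence[p - 1].upper() == record.residue_letter
        and _flank_matches(sequence, p, record.flank)
    )
    if candidates:
        raise AmbiguityError(
            f"{record.protein} {record.residue}: flank {record.flank!r} does not match "
            f"at position {pos} but matches at {list(candidates)}",
            candidates=candidates,
        )
    raise PlacementError(
        f"{record.protein} {record.residue}: flank {record.flank!r} matches nowhere "
        f"consistent with the stated position"
    )


def summarize_residue_counts(records: Sequence[PTMRecord]) -> dict[str, int]:
    """Tallies of modified site residues under both counting conventions.

    The natural counting units for "modified residues" differ between
    curation styles, so both are reported: unique (protein, species, residue)
    triples, and unique (protein, species, residue, ptm_type) quadruples,
    each with its human-only subset.
    """
    by_residue = {(r.protein, r.species, r.residue_number) for r in records}
    by_residue_ptm = {r.key for r in records}
    human = "H. sapiens"
    return {
        "residue_species": len(by_residue),
        "residue_species_human": len({k for k in by_residue if k[1] == human}),
        "residue_species_ptm": len(by_residue_ptm),
        "residue_species_ptm_human": len({k for k in by_residue_ptm if k[1] == human}),
        "rows": len(records),
    }
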