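"""The domain feature registry: one row per PX domain.

Each record carries the domain's curated phosphoinositide ligand set, its
Lipid Specificity Index (LSI), the evidence-weighted MET-stop and PIP-stop
scores (MSS, PSS), the Membrane Affinity Index (MAI) and an average mRNA
expression level.  Cells printed as "nd" (not determined) load as ``None``,
a typed sentinel distinct from zero: a domain with no known ligands is not
the same as a non-binder, and undetermined rows must be excludable from
LSI-dependent statistics without perturbing the MSS/PSS columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .scoring import MAI_LABELS, PIP_CODES, compute_lsi

logger = logging.getLogger(__name__)

ND = "nd"
EMPTY_LIGANDS = "0"  # printed token for a determined non-binder

DOMAIN_TABLE_COLUMNS = (
    "name", "ligands", "lsi", "mss", "pss", "mai", "expression", "structure", "note",
)

#: Long-name spellings accepted by :func:`normalize_ligand_code`.
_LIGAND_ALIASES = {
    "PI3P": "3", "PI4P": "4", "PI5P": "5",
    "PTDINS3P": "3", "PTDINS4P": "4", "PTDINS5P": "5",
    "PI(3,4)P2": "34", "PI(3,5)P2": "35", "PI(4,5)P2": "45",
    "PI(3,4,5)P3": "345", "PIP3": "345",
}


def normalize_ligand_code(token: str) -> str:
    """Map a ligand spelling (short code or long name) to its short code."""
    token = token.strip()
    if token in PIP_CODES:
        return token
    normalized = _LIGAND_ALIASES.get(token.upper().replace(" ", ""))
    if normalized is None:
        raise ValidationError(f"unknown ligand code {token!r}")
    return normalized


@dataclass(frozen=True)
class DomainRecord:
    """One PX domain and its curated membrane-binding properties.

    ``ligand_codes``, ``lsi`` and ``mai`` are ``None`` when undetermined.
    """

    name: str
    ligand_codes: frozenset[str] | None
    lsi: int | None
    mss: int
    pss: int
    mai: str | None
    expression: float
    structure: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("domain name must be nonempty")
        if self.ligand_codes is not None:
            for code in self.ligand_codes:
                if code not in PIP_CODES:
                    raise ValidationError(f"{self.name}: unknown ligand code {code!r}")
        if self.lsi is not None and not 0 <= self.lsi <= 10:
            raise ValidationError(f"{self.name}: LSI {self.lsi} outside 0..10")
        if self.ligand_codes is not None and self.lsi is not None:
            if (self.lsi == 0) != (len(self.ligand_codes) == 0):
                raise ValidationError(
                    f"{self.name}: LSI {self.lsi} inconsistent with "
                    f"{len(self.ligand_codes)} ligand(s) (0 <=> non-binder)"
                )
        if self.mss < 0 or self.pss < 0:
            raise ValidationError(f"{self.name}: MSS and PSS must be nonnegative")
        if self.mai is not None and self.mai not in MAI_LABELS:
            raise ValidationError(f"{self.name}: MAI must be one of {MAI_LABELS}")
        if self.expression < 0:
            raise ValidationError(f"{self.name}: expression must be nonnegative")


def _ligand_cell_to_codes(cell: str) -> frozenset[str] | None:
    cell = cell.strip()
    if cell == ND:
        return None
    if cell in ("", EMPTY_LIGANDS):
        return frozenset()
    return frozenset(normalize_ligand_code(tok) for tok in cell.split(","))


def _codes_to_ligand_cell(codes: frozenset[str] | None) -> str:
    if codes is None:
        return ND
    if not codes:
        return EMPTY_LIGANDS
    return ",".join(sorted(codes, key=lambda c: (len(c), c)))


def load_domain_table(path: str | Path, strict: bool = True) -> list[DomainRecord]:
    """Load a domain feature table from TSV.

    "nd" cells become ``None``; a malformed cell aborts the load when
    ``strict`` (the default) and skips the row with a warning otherwise.
    Duplicate domain names and unknown ligand codes are always errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "ligands", "lsi", "mss", "pss", "mai", "expression"}
    if missing := required - set(df.columns):
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    records: list[DomainRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        name = row.name.strip()
        if name in seen:
            raise ValidationError(f"row {i}: duplicate domain name {name!r}")
        try:
            rec = DomainRecord(
                name=name,
                ligand_codes=_ligand_cell_to_codes(row.ligands),
                lsi=None if row.lsi.strip() == ND else int(row.lsi),
                mss=int(row.mss),
                pss=int(row.pss),
                mai=None if row.mai.strip() == ND else row.mai.strip(),
                expression=float(row.expression),
                structure=getattr(row, "structure", "").strip(),
                note=getattr(row, "note", "").strip(),
            )
        except (ValidationError, ValueError) as exc:
            if strict:
                raise ValidationError(f"row {i} ({name!r}): {exc}") from exc
            logger.warning("skipping malformed row %d (%r): %s", i, name, exc)
            continue
        seen.add(name)
        records.append(rec)
    if not records:
        logger.warning("no data rows in %s", path)
    logger.info("loaded %d domain records from %s", len(records), path)
    return records


def write_domain_table(records: Iterable[DomainRecord], path: str | Path) -> None:
    """Serialize records to the TSV dialect read by :func:`load_domain_table`.

    Expression is printed at the table's 0.1 precision; ligand codes are
    joined in canonical (length, value) order.
    """
    df = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "ligands": [_codes_to_ligand_cell(r.ligand_codes) for r in records],
            "lsi": [ND if r.lsi is None else r.lsi for r in records],
            "mss": [r.mss for r in records],
            "pss": [r.pss for r in records],
            "mai": [ND if r.mai is None else r.mai for r in records],
            "expression": [f"{r.expression:.1f}" for r in records],
            "structure": [r.structure for r in records],
            "note": [r.note for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LSICheck:
    name: str
    stored: int
    recomputed: int

    @property
    def match(self) -> bool:
        return self.stored == self.recomputed


@dataclass(frozen=True)
class LSIVerification:
    """Report comparing stored LSI values against recomputation from the
    ligand column; rows with undetermined ligands or LSI are skipped."""

    checks: tuple[LSICheck, ...]
    skipped: tuple[str, ...]

    @property
    def mismatches(self) -> tuple[LSICheck, ...]:
        return tuple(c for c in self.checks if not c.match)


def verify_lsi_column(records: Sequence[DomainRecord]) -> LSIVerification:
    """Recompute LSI from each record's ligand set and compare to the stored
    column.  Report-only: mismatches are enumerated, never raised."""
    checks = []
    skipped = []
    for rec in records:
        if rec.ligand_codes is None or rec.lsi is None:
            skipped.append(rec.name)
            continue
        checks.append(
            LSICheck(
                name=rec.name,
                stored=rec.lsi,
                recomputed=compute_lsi(rec.ligand_codes).lsi,
            )
        )
    return LSIVerification(checks=tuple(checks), skipped=tuple(skipped))
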