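"""The package's core indices for PX-domain membrane readers.

* **LSI** (Lipid Specificity Index, 0-10): how selective a domain is for a
  single phosphoinositide.  The seven phosphoinositides split into two
  classes by the number of phosphates on the inositol ring — the
  monophosphorylated species PI3P/PI4P/PI5P (codes "3", "4", "5") versus the
  bis/tris species (codes "34", "35", "45", "345").  A domain is assigned to
  the class holding the majority of its ligands, and

      LSI = 10 - n1 - 2*n2

  where n1 counts *additional* in-class ligands and n2 counts out-of-class
  ligands.  A single-ligand domain scores 10; a domain binding all seven
  phosphoinositides scores 1; a non-binder scores 0.

* **MSS / PSS** (MET-stop / PIP-stop scores): evidence-weighted counts of
  modifications inside the three consensus membrane-binding sites.  The MSS
  covers metabolite attachments to Lys/Arg; the PSS covers Ser/Thr/Tyr
  phosphorylation.  Each distinct in-site modification contributes a weight
  of 1, 2 or 3 according to whether 1, 2-4, or >= 5 independent studies
  report it.

* **MAI** (Membrane Affinity Index): categorical bilayer-binding strength —
  S (roughly nanomolar affinity), W (roughly micromolar), N (no binding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import ptm_catalog
from .errors import PlacementError, ValidationError
from .ptm_catalog import PTMRecord
from .sites import OUTSIDE, SiteWindows, residue_site, ungapped

PIP_CODES = ("3", "4", "5", "34", "35", "45", "345")
MONO_CODES = frozenset({"3", "4", "5"})
POLY_CODES = frozenset({"34", "35", "45", "345"})

SELECTIVITY_CLASSES = ("absolute", "high", "medium", "low", "none")
MAI_LABELS = ("S", "W", "N")

#: Kd boundary (in micromolar) between strong (nanomolar-range) and weak
#: (micromolar-range) membrane affinity.
MAI_KD_CUT_UM = 1.0


def pip_class(code: str) -> str:
    """Class of a phosphoinositide code: ``"mono"`` (one ring phosphate) or
    ``"poly"`` (more than one)."""
    if code in MONO_CODES:
        return "mono"
    if code in POLY_CODES:
        return "poly"
    raise ValidationError(f"unknown phosphoinositide code {code!r}")


@dataclass(frozen=True)
class SpecificityResult:
    """LSI with its n1/n2 breakdown and the class the domain was assigned to
    (``"tie"`` when mono and poly ligand counts are equal — the LSI is
    provably identical under either choice)."""

    lsi: int
    n1: int
    n2: int
    assigned_class: str


def compute_lsi(ligands: Iterable[str]) -> SpecificityResult:
    """Compute the Lipid Specificity Index for a set of ligand codes."""
    codes = frozenset(ligands)
    for code in codes:
        pip_class(code)  # validates
    if not codes:
        return SpecificityResult(lsi=0, n1=0, n2=0, assigned_class="none")
    mono = len(codes & MONO_CODES)
    poly = len(codes & POLY_CODES)
    if mono > poly:
        assigned, n_in, n_out = "mono", mono, poly
    elif poly > mono:
        assigned, n_in, n_out = "poly", poly, mono
    else:
        # tie: 10-(m-1)-2p == 10-(p-1)-2m when m == p
        assigned, n_in, n_out = "tie", mono, poly
    n1 = n_in - 1
    n2 = n_out
    return SpecificityResult(lsi=10 - n1 - 2 * n2, n1=n1, n2=n2, assigned_class=assigned)


def selectivity_class(lsi: int) -> str:
    """Bin an LSI value: 10 absolute, 8-9 high, 5-7 medium, 1-4 low, 0 none."""
    if not isinstance(lsi, int) or not 0 <= lsi <= 10:
        raise ValidationError(f"LSI must be an integer in 0..10, got {lsi!r}")
    if lsi == 10:
        return "absolute"
    if lsi >= 8:
        return "high"
    if lsi >= 5:
        return "medium"
    if lsi >= 1:
        return "low"
    return "none"


def stop_weight(study_count: int) -> int:
    """Evidence weight of one modification: 1 study -> 1, 2-4 -> 2, >= 5 -> 3."""
    if study_count < 1:
        raise ValidationError(f"study_count must be >= 1, got {study_count}")
    if study_count == 1:
        return 1
    if study_count <= 4:
        return 2
    return 3


@dataclass(frozen=True)
class Contribution:
    """One modification's contribution to a stop score."""

    key: tuple[str, str, int, str]  # (protein, species, residue_number, ptm_type)
    site: str
    weight: int


@dataclass(frozen=True)
class StopScore:
    total: int
    contributions: tuple[Contribution, ...]


def compute_stop_score(
    aligned_seq: str,
    ptms: Sequence[PTMRecord],
    windows: SiteWindows,
    mode: str = "met",
    numbering_offset: int = 0,
    same_species_only: bool = False,
    reference_species: str = "H. sapiens",
) -> StopScore:
    """Compute a domain's MET-stop (``mode="met"``) or PIP-stop
    (``mode="pip"``) score.

    ``ptms`` are records for this domain (any species); they are first pooled
    per (protein, species, residue, type) with study counts merged by max,
    then each pooled modification whose residue classifies as site1/2/3 adds
    its :func:`stop_weight`.  Cross-species records contribute by default, on
    the assumption that homolog evidence shares the domain's residue
    numbering; pass ``same_species_only=True`` to keep only
    ``reference_species`` records.  Records that cannot be anchored on the
    sequence raise :class:`PlacementError`.
    """
    if mode not in ("met", "pip"):
        raise ValidationError(f"mode must be 'met' or 'pip', got {mode!r}")
    seq = ungapped(aligned_seq)
    contributions = []
    total = 0
    selected = [
        r
        for r in ptms
        if (r.is_metabolite if mode == "met" else r.is_phospho)
        and not (same_species_only and r.species != reference_species)
    ]
    for rec in ptm_catalog.aggregate(selected):
        pos = rec.residue_number - numbering_offset
        if pos < 1 or pos > len(seq):
            raise PlacementError(
                f"{rec.protein} {rec.residue}: position {pos} outside sequence "
                f"of length {len(seq)}"
            )
        site = residue_site(aligned_seq, pos, windows)
        if site == OUTSIDE:
            continue
        w = stop_weight(rec.study_count)
        contributions.append(Contribution(key=rec.key, site=site, weight=w))
        total += w
    return StopScore(total=total, contributions=tuple(contributions))


def classify_mai(evidence: str | float) -> str:
    """Classify membrane affinity as S / W / N.

    ``evidence`` is either a category (``"nanomolar"``, ``"micromolar"``,
    ``"none"``) or a numeric dissociation constant in micromolar units; Kd
    below 1 uM classifies as strong (S), 1 uM and above as weak (W).
    """
    if isinstance(evidence, str):
        category = evidence.strip().lower()
        mapping = {"nanomolar": "S", "micromolar": "W", "none": "N"}
        if category not in mapping:
            raise ValidationError(f"unknown affinity category {evidence!r}")
        return mapping[category]
    kd_um = float(evidence)
    if kd_um < 0:
        raise ValidationError(f"dissociation constant must be nonnegative, got {kd_um}")
    return "S" if kd_um < MAI_KD_CUT_UM else "W"


def score_domains(
    alignment: Mapping[str, str],
    ptms: Sequence[PTMRecord],
    windows: SiteWindows,
    numbering_offsets: Mapping[str, int] | None = None,
    same_species_only: bool = False,
) -> list[dict]:
    """Compute MSS and PSS for every domain in an alignment.

    Returns one dict per domain with keys name, mss, pss; PTM records are
    matched to domains by protein name.
    """
    offsets = numbering_offsets or {}
    by_protein: dict[str, list[PTMRecord]] = {}
    for rec in ptms:
        by_protein.setdefault(rec.protein, []).append(rec)
    rows = []
    for name, aligned_seq in alignment.items():
        domain_ptms = by_protein.get(name, [])
        offset = offsets.get(name, 0)
        mss = compute_stop_score(
            aligned_seq, domain_ptms, windows, mode="met",
            numbering_offset=offset, same_species_only=same_species_only,
        )
        pss = compute_stop_score(
            aligned_seq, domain_ptms, windows, mode="pip",
            numbering_offset=offset, same_species_only=same_species_only,
        )
        rows.append({"name": name, "mss": mss.total, "pss": pss.total})
    return rows
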