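"""Consensus membrane-binding sites as alignment-column windows.

PX domains dock onto phosphoinositide-containing membranes through three
conserved sequence elements: the membrane-insertion loop between strands
β1 and β2 (site 1), the β3 strand running into helix α1 with the
PIP-coordinating RRY motif (site 2), and the long loop holding the
proline-rich element before helix α2 (site 3).  Here the three sites are
represented as inclusive column ranges on a superfamily alignment, so any
residue of any aligned domain classifies as inside one site or outside all
of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import MissingScoreError, ValidationError
from .ptm_catalog import METABOLITE_RESIDUES, PTMRecord

SITE_LABELS = ("site1", "site2", "site3")
OUTSIDE = "outside"

#: Default membrane-docking propensity cutoff; scores strictly above it flag
#: residues with a probable role in membrane docking.
DEFAULT_PROPENSITY_THRESHOLD = 30.0


@dataclass(frozen=True)
class SiteWindows:
    """The three consensus membrane-binding sites, as 1-based inclusive
    alignment-column ranges in increasing, non-overlapping order."""

    site1: tuple[int, int]
    site2: tuple[int, int]
    site3: tuple[int, int]

    def __post_init__(self) -> None:
        ranges = [self.site1, self.site2, self.site3]
        for label, (lo, hi) in zip(SITE_LABELS, ranges):
            if lo < 1 or hi < lo:
                raise ValidationError(f"{label}: empty or malformed range ({lo}, {hi})")
        for (label_a, a), (label_b, b) in zip(
            zip(SITE_LABELS, ranges), zip(SITE_LABELS[1:], ranges[1:])
        ):
            if b[0] <= a[1]:
                raise ValidationError(
                    f"{label_b} {b} must start after {label_a} {a} ends"
                )

    def classify_column(self, column: int) -> str:
        """Label an alignment column as site1/site2/site3 or outside."""
        for label in SITE_LABELS:
            lo, hi = getattr(self, label)
            if lo <= column <= hi:
                return label
        return OUTSIDE

    def to_dict(self) -> dict:
        return {"sites": {label: list(getattr(self, label)) for label in SITE_LABELS}}

    @classmethod
    def from_dict(cls, data: Mapping) -> "SiteWindows":
        try:
            sites = data["sites"]
            return cls(*(tuple(int(v) for v in sites[label]) for label in SITE_LABELS))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"malformed site-window configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SiteWindows":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def alignment_column(aligned_seq: str, position: int) -> int:
    """Map a 1-based position in the ungapped sequence to its 1-based
    alignment column."""
    if position < 1:
        raise ValidationError(f"position {position} out of range")
    seen = 0
    for col, ch in enumerate(aligned_seq, start=1):
        if ch != "-":
            seen += 1
            if seen == position:
                return col
    raise ValidationError(
        f"position {position} out of range for sequence of length {seen}"
    )


def ungapped(aligned_seq: str) -> str:
    return aligned_seq.replace("-", "")


def residue_site(aligned_seq: str, position: int, windows: SiteWindows) -> str:
    """Classify a residue (1-based position in the ungapped sequence) by the
    site window its alignment column falls in."""
    return windows.classify_column(alignment_column(aligned_seq, position))


@dataclass(frozen=True)
class PropensityProfile:
    """Per-residue membrane-docking propensity scores for one domain.

    ``scores`` maps 1-based sequence positions to real scores; positions
    strictly above ``threshold`` are predicted membrane-interactive.
    """

    scores: Mapping[int, float]
    threshold: float = DEFAULT_PROPENSITY_THRESHOLD

    def score(self, position: int) -> float:
        try:
            return float(self.scores[position])
        except KeyError:
            raise MissingScoreError(f"no propensity score for position {position}") from None

    def membrane_interactive(self, position: int) -> bool:
        return self.score(position) > self.threshold

    @classmethod
    def from_csv(
        cls, path: str | Path, domain: str | None = None, threshold: float = DEFAULT_PROPENSITY_THRESHOLD
    ) -> "PropensityProfile":
        """Read a (domain, position, score) CSV; filter to one domain if given."""
        import pandas as pd

        df = pd.read_csv(path)
        required = {"domain", "position", "score"}
        if missing := required - set(df.columns):
            raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
        if domain is not None:
            df = df[df["domain"] == domain]
        return cls(
            scores=dict(zip(df["position"].astype(int), df["score"].astype(float))),
            threshold=threshold,
        )


def membrane_interactive(profile: PropensityProfile, position: int) -> bool:
    """True iff the residue's propensity score strictly exceeds the threshold."""
    return profile.membrane_interactive(position)


def total_site_score(
    profile: PropensityProfile, aligned_seq: str, windows: SiteWindows
) -> float:
    """Sum propensity scores over every residue inside the three site windows.

    Unscored in-site positions contribute 0 with a warning, so profiles
    covering only part of a domain still yield a usable total.
    """
    total = 0.0
    unscored = []
    seq = ungapped(aligned_seq)
    for pos in range(1, len(seq) + 1):
        if residue_site(aligned_seq, pos, windows) == OUTSIDE:
            continue
        try:
            total += profile.score(pos)
        except MissingScoreError:
            unscored.append(pos)
    if unscored:
        warnings.warn(
            f"{len(unscored)} in-site position(s) without propensity scores "
            f"treated as 0: {unscored[:10]}",
            stacklevel=2,
        )
    return total


@dataclass(frozen=True)
class KRInventory:
    """Counts of Lys/Arg residues and their metabolite-modified subset,
    split by membrane-binding-site membership."""

    inside_kr: int
    inside_modified: int
    outside_kr: int
    outside_modified: int

    @property
    def inside_proportion(self) -> float | None:
        return self.inside_modified / self.inside_kr if self.inside_kr else None

    @property
    def outside_proportion(self) -> float | None:
        return self.outside_modified / self.outside_kr if self.outside_kr else None


def kr_inventory(
    aligned_seq: str,
    windows: SiteWindows,
    ptms: Iterable[PTMRecord],
    numbering_offset: int = 0,
) -> KRInventory:
    """Inventory K/R residues inside vs outside the site windows.

    A residue position counts as modified when at least one metabolite-class
    record maps onto it (``residue_number - numbering_offset``) with a
    matching letter; phospho records are ignored here.  Counts are over
    unique residue positions, so the inside and outside K/R totals always
    partition the sequence's K/R content.
    """
    seq = ungapped(aligned_seq)
    modified_positions = set()
    for rec in ptms:
        if not rec.is_metabolite:
            continue
        pos = rec.residue_number - numbering_offset
        if 1 <= pos <= len(seq) and seq[pos - 1].upper() == rec.residue_letter:
            modified_positions.add(pos)
    counts = {True: [0, 0], False: [0, 0]}  # inside? -> [kr_total, kr_modified]
    for pos in range(1, len(seq) + 1):
        if seq[pos - 1].upper() not in METABOLITE_RESIDUES:
            continue
        inside = residue_site(aligned_seq, pos, windows) != OUTSIDE
        counts[inside][0] += 1
        if pos in modified_positions:
            counts[inside][1] += 1
    return KRInventory(
        inside_kr=counts[True][0],
        inside_modified=counts[True][1],
        outside_kr=counts[False][0],
        outside_modified=counts[False][1],
    )
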