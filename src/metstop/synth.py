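"""Synthetic inputs with the statistical structure the analysis assumes.

Two independent generators:

* :func:`gen_domain_set` / :func:`gen_ptm_table` plant metabolite
  modifications on K/R residues of random domain sequences, with a
  configurable enrichment ratio ``rho`` between the per-residue modification
  probability inside membrane-binding site windows and outside them.  The
  truth record stores every planted modification and the per-domain
  inside/outside inventories, so site classification, stop scoring and the
  paired t-test can all be validated against known ground truth.

* :func:`gen_feature_table` draws whole feature tables (MSS, PSS, LSI,
  expression) from a latent Gaussian with a target correlation matrix, then
  discretizes: MSS/PSS to nonnegative integers, LSI to 0-10 integers,
  expression truncated at zero.  The truth record keeps the latent
  correlations, since discretization attenuates the observable ones.

Everything is driven by a single integer seed through one named generator
instance, so emitted text files are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError
from .ptm_catalog import PAD, PTMRecord, write_ptm_table
from .registry import DomainRecord, write_domain_table
from .sites import SITE_LABELS, SiteWindows

FEATURES = ("mss", "pss", "lsi", "expression")

#: Default target latent correlations, approximating the relationships
#: observed in the curated human PX-domain table.
DEFAULT_FEATURE_CORRELATIONS: dict[tuple[str, str], float] = {
    ("mss", "pss"): 0.385,
    ("lsi", "pss"): 0.314,
    ("lsi", "mss"): 0.081,
    ("expression", "mss"): 0.364,
    ("expression", "pss"): 0.484,
    ("expression", "lsi"): 0.0,
}

#: (mean, sd) of the latent Gaussian per feature, chosen to resemble the
#: curated table's margins after discretization.
FEATURE_MARGINS: dict[str, tuple[float, float]] = {
    "mss": (1.8, 3.2),
    "pss": (3.6, 4.6),
    "lsi": (7.7, 2.9),
    "expression": (24.0, 30.0),
}

_NON_KR = tuple(c for c in "ACDEFGHILMNPQSTVWY")
_K_PTM_TYPES = (
    "acetylation", "butyrylation", "glycation", "malonylation", "succinylation",
)
_SPECIES = "synthetic"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study conditions.

    Defaults mirror the scale of the real superfamily analysis: 50 domains
    of PX-domain-like length 120, a quarter of the columns inside the three
    site windows, K/R density 0.3, a 10% chance that an outside K/R carries
    a reported metabolite modification, and threefold enrichment inside
    sites.  Study counts follow a unit-shifted Poisson, mimicking
    citation-count skew while keeping every evidence-weight bin reachable.
    """

    n_domains: int = 50
    sequence_length: int = 120
    site_fraction: float = 0.25
    kr_density: float = 0.3
    enrichment: float = 3.0
    base_mod_rate: float = 0.1
    study_count_law: tuple[str, float] = ("shifted_poisson", 1.0)
    feature_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_CORRELATIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ConfigError("n_domains must be >= 2")
        if self.sequence_length < 12:
            raise ConfigError("sequence_length must be >= 12")
        if not 0.0 < self.site_fraction < 0.9:
            raise ConfigError(
                f"site_fraction must lie in (0, 0.9); {self.site_fraction} leaves no "
                "room for three windows"
            )
        for name in ("kr_density", "base_mod_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.enrichment < 0:
            raise ConfigError("enrichment must be nonnegative")
        if self.enrichment * self.base_mod_rate > 1.0:
            raise ConfigError(
                "enrichment * base_mod_rate exceeds 1: inside modification "
                "probability is not a probability"
            )
        law, _ = self.study_count_law
        if law not in ("constant", "shifted_poisson"):
            raise ConfigError(f"unknown study_count_law {law!r}")

    @property
    def inside_mod_rate(self) -> float:
        return self.enrichment * self.base_mod_rate


def make_windows(sequence_length: int, site_fraction: float) -> SiteWindows:
    """Three near-equal site windows, one centered in each third of the
    columns, jointly covering ``round(site_fraction * length)`` columns."""
    total = max(3, round(site_fraction * sequence_length))
    widths = [total // 3] * 3
    for i in range(total - 3 * (total // 3)):
        widths[i] += 1
    third = sequence_length // 3
    if max(widths) > third:
        raise ConfigError("site_fraction too large for three disjoint windows")
    ranges = []
    for i, w in enumerate(widths):
        start = i * third + (third - w) // 2 + 1
        ranges.append((start, start + w - 1))
    return SiteWindows(*ranges)


@dataclass
class DomainSet:
    """A generated set of domains plus the ground truth of planted
    modifications."""

    sequences: dict[str, str]
    alignment: dict[str, str]  # synthetic domains are generated ungapped
    windows: SiteWindows
    truth: dict


def _draw_study_count(rng: np.random.Generator, law: tuple[str, float]) -> int:
    name, param = law
    if name == "constant":
        return int(param)
    return 1 + int(rng.poisson(param))


def gen_domain_set(config: SynthConfig, seed: int | None = None) -> DomainSet:
    """Generate domain sequences with site-enriched planted K/R modifications.

    Reproducible: the same config and seed give byte-identical output.  The
    truth record stores every planted modification with its site region and
    the per-domain inside/outside K/R inventories.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = config.sequence_length
    windows = make_windows(L, config.site_fraction)
    inside_cols = {
        col for col in range(1, L + 1) if windows.classify_column(col) != "outside"
    }
    sequences: dict[str, str] = {}
    modifications: list[dict] = []
    per_domain: dict[str, dict] = {}
    width = len(str(config.n_domains))
    for d in range(config.n_domains):
        name = f"SYN{d + 1:0{width}d}"
        is_kr = rng.random(L) < config.kr_density
        kr_letters = rng.choice(["K", "R"], size=L)
        other = rng.choice(_NON_KR, size=L)
        seq = "".join(
            kr_letters[i] if is_kr[i] else other[i] for i in range(L)
        )
        sequences[name] = seq
        inv = {"inside_kr": 0, "inside_modified": 0, "outside_kr": 0, "outside_modified": 0}
        for pos in range(1, L + 1):
            if not is_kr[pos - 1]:
                continue
            inside = pos in inside_cols
            region = windows.classify_column(pos) if inside else "outside"
            inv["inside_kr" if inside else "outside_kr"] += 1
            rate = config.inside_mod_rate if inside else config.base_mod_rate
            if rng.random() >= rate:
                continue
            inv["inside_modified" if inside else "outside_modified"] += 1
            letter = seq[pos - 1]
            ptm_type = (
                "methylation" if letter == "R" else str(rng.choice(_K_PTM_TYPES))
            )
            modifications.append(
                {
                    "domain": name,
                    "position": pos,
                    "residue": letter,
                    "region": region,
                    "ptm_type": ptm_type,
                    "study_count": _draw_study_count(rng, config.study_count_law),
                }
            )
        per_domain[name] = inv
    truth = {
        "params": {
            "n_domains": config.n_domains,
            "sequence_length": L,
            "site_fraction": config.site_fraction,
            "kr_density": config.kr_density,
            "enrichment": config.enrichment,
            "base_mod_rate": config.base_mod_rate,
            "inside_mod_rate": config.inside_mod_rate,
            "study_count_law": list(config.study_count_law),
        },
        "windows": windows.to_dict(),
        "modifications": modifications,
        "per_domain": per_domain,
    }
    return DomainSet(sequences=sequences, alignment=dict(sequences), windows=windows, truth=truth)


def _flank_at(seq: str, pos: int) -> str:
    out = []
    for offset in range(-4, 5):
        p = pos + offset
        if p < 1 or p > len(seq):
            out.append(PAD)
        elif offset == 0:
            out.append(seq[p - 1].lower())
        else:
            out.append(seq[p - 1].upper())
    return "".join(out)


def gen_ptm_table(domain_set: DomainSet) -> list[PTMRecord]:
    """Emit the planted modifications as validated PTM records.

    Flank nonamers are cut from the true sequences with the modified residue
    lowercase at the center and ``-`` padding at termini; deterministic given
    the domain set (study counts were drawn at planting time).
    """
    records = []
    for mod in domain_set.truth["modifications"]:
        seq = domain_set.sequences[mod["domain"]]
        records.append(
            PTMRecord(
                protein=mod["domain"],
                species=_SPECIES,
                residue_letter=mod["residue"],
                residue_number=mod["position"],
                ptm_type=mod["ptm_type"],
                flank=_flank_at(seq, mod["position"]),
                study_count=mod["study_count"],
            )
        )
    return records


def _correlation_matrix(
    correlations: dict[tuple[str, str], float]
) -> np.ndarray:
    corr = np.eye(len(FEATURES))
    index = {f: i for i, f in enumerate(FEATURES)}
    for (a, b), rho in correlations.items():
        if a not in index or b not in index:
            raise ConfigError(f"unknown feature pair ({a}, {b})")
        corr[index[a], index[b]] = corr[index[b], index[a]] = rho
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ConfigError("feature_correlations do not form a positive-definite matrix") from None
    return corr


def gen_feature_table(
    config: SynthConfig, seed: int | None = None
) -> tuple[list[DomainRecord], dict]:
    """Generate a feature table with known latent correlation structure.

    Returns the records plus a truth dict holding the target correlation
    matrix and the realized latent (pre-discretization) sample correlations.
    Ligand sets are left undetermined (statistics on the table need only the
    index columns); MAI labels are drawn with the marginal frequencies seen
    in the curated table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    corr = _correlation_matrix(config.feature_correlations)
    z = rng.multivariate_normal(
        mean=np.zeros(len(FEATURES)), cov=corr, size=config.n_domains, method="cholesky"
    )
    latent = {f: z[:, i] for i, f in enumerate(FEATURES)}
    scaled = {
        f: FEATURE_MARGINS[f][0] + FEATURE_MARGINS[f][1] * latent[f] for f in FEATURES
    }
    mss = np.maximum(0, np.rint(scaled["mss"])).astype(int)
    pss = np.maximum(0, np.rint(scaled["pss"])).astype(int)
    lsi = np.clip(np.rint(scaled["lsi"]), 0, 10).astype(int)
    expression = np.round(np.maximum(0.0, scaled["expression"]), 1)
    mai = rng.choice(["S", "W", "N"], size=config.n_domains, p=[0.633, 0.306, 0.061])
    width = len(str(config.n_domains))
    records = [
        DomainRecord(
            name=f"SYNDOM{i + 1:0{width}d}",
            ligand_codes=None,
            lsi=int(lsi[i]),
            mss=int(mss[i]),
            pss=int(pss[i]),
            mai=str(mai[i]),
            expression=float(expression[i]),
            structure="synthetic",
            note="synthetic",
        )
        for i in range(config.n_domains)
    ]
    latent_sample_corr = np.corrcoef(z, rowvar=False)
    truth = {
        "features": list(FEATURES),
        "target_correlation": corr.tolist(),
        "latent_sample_correlation": latent_sample_corr.tolist(),
        "margins": {f: list(FEATURE_MARGINS[f]) for f in FEATURES},
    }
    return records, truth


def write_domain_set(
    domain_set: DomainSet, out_dir: str | Path, ptms: Sequence[PTMRecord] | None = None
) -> dict[str, Path]:
    """Write a domain set (FASTA, aligned FASTA, sites YAML, truth JSON and
    optionally the PTM TSV) into a directory; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "domains.fasta",
        "alignment": out / "alignment.fasta",
        "sites": out / "sites.yaml",
        "truth": out / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for name, seq in domain_set.sequences.items():
            fh.write(f">{name}\n{seq}\n")
    with open(paths["alignment"], "w") as fh:
        for name, seq in domain_set.alignment.items():
            fh.write(f">{name}\n{seq}\n")
    domain_set.windows.to_yaml(paths["sites"])
    with open(paths["truth"], "w") as fh:
        json.dump(domain_set.truth, fh, indent=1, sort_keys=True)
    if ptms is not None:
        paths["ptms"] = out / "ptms.tsv"
        write_ptm_table(ptms, paths["ptms"])
    return paths


# ---------------------------------------------------------------------------
# Paired t-test calibration under the generator's model
# ---------------------------------------------------------------------------

def simulate_proportion_samples(
    config: SynthConfig, n_replicates: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draws of per-domain modified-K/R proportions.

    Uses the same probabilistic model as :func:`gen_domain_set` (independent
    per-position K/R placement and modification), sampling the sufficient
    binomial counts directly so that many replicates are cheap.  Returns
    ``(inside, outside)`` proportion arrays of shape
    ``(n_replicates, n_domains)``; domains with no K/R in a region get NaN.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    windows = make_windows(config.sequence_length, config.site_fraction)
    n_inside_cols = sum(hi - lo + 1 for lo, hi in (windows.site1, windows.site2, windows.site3))
    n_outside_cols = config.sequence_length - n_inside_cols
    shape = (n_replicates, config.n_domains)
    kr_in = rng.binomial(n_inside_cols, config.kr_density, size=shape)
    kr_out = rng.binomial(n_outside_cols, config.kr_density, size=shape)
    mod_in = rng.binomial(kr_in, config.inside_mod_rate)
    mod_out = rng.binomial(kr_out, config.base_mod_rate)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_in = np.where(kr_in > 0, mod_in / np.maximum(kr_in, 1), np.nan)
        p_out = np.where(kr_out > 0, mod_out / np.maximum(kr_out, 1), np.nan)
    return p_in, p_out


def paired_t_rejection_rate(
    config: SynthConfig,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Fraction of replicates in which the paired t-test (inside vs outside
    modified-K/R proportion, two-sided) rejects at level ``alpha``.

    With ``enrichment=1`` this estimates the test's type-I error under the
    null of equal modification rates; with ``enrichment>1`` it estimates
    power.  Domains lacking K/R in either region are dropped pairwise.
    """
    p_in, p_out = simulate_proportion_samples(config, n_replicates, seed=seed)
    d = p_in - p_out
    n = np.sum(~np.isnan(d), axis=1)
    mean = np.nanmean(d, axis=1)
    sd = np.nanstd(d, axis=1, ddof=1)
    ok = (n >= 2) & (sd > 0)
    t = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
    p = 2.0 * sps.t.sf(np.abs(t), df=n[ok] - 1)
    return float(np.mean(p < alpha))
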