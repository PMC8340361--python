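"""Packaged reference tables and default configuration.

* ``load_px_domain_table`` — the curated feature table of the 50 human PX
  domain entries (ligand sets, LSI, MSS, PSS, MAI, mean mRNA expression,
  structure provenance).  The two splice forms of NOXO1 are separate rows;
  PXDC1's ligands, LSI and MAI are undetermined; the SNX30 and SNX33 LSI
  values are inferred from their closest characterized relatives and carry
  an ``lsi_inferred`` note.
* ``load_ptm_site_table`` — the 86 curated metabolite-modification records
  on PX-domain membrane-binding site residues across nine species, in
  flanking-nonamer notation.
* ``default_site_windows`` — default consensus site windows (a
  reconstruction; see the packaged YAML for caveats).
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .ptm_catalog import PTMRecord, load_ptm_table
from .registry import DomainRecord, load_domain_table
from .sites import SiteWindows


def _data_path(name: str) -> Path:
    return Path(str(files("metstop.data").joinpath(name)))


def px_domain_table_path() -> Path:
    return _data_path("px_domain_table.tsv")


def ptm_site_table_path() -> Path:
    return _data_path("ptm_site_table.tsv")


def default_sites_path() -> Path:
    return _data_path("default_sites.yaml")


def load_px_domain_table() -> list[DomainRecord]:
    """The packaged human PX-domain feature table (50 records)."""
    return load_domain_table(px_domain_table_path())


def load_ptm_site_table() -> list[PTMRecord]:
    """The packaged metabolite-PTM site table (86 records)."""
    return load_ptm_table(ptm_site_table_path())


def default_site_windows() -> SiteWindows:
    """Default consensus membrane-binding site windows."""
    return SiteWindows.from_yaml(default_sites_path())
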