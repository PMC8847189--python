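"""The 22-CpG buccal-swab age panel and its fixture data.

The panel covers five genes whose methylation changes approximately linearly
with age in buccal mucosa: PDE4C (7 CpGs), ELOVL2 (9), RPA2 (3), EDARADD (2)
and DDO (1). Methylation rises with age at PDE4C, ELOVL2 and RPA2 sites and
falls at EDARADD and DDO. Each site carries its GRCh38 coordinate, the 450K
array probe ID where one exists, the expected sign of the age association, and
the reference Spearman correlations with age observed in the German and
Japanese donor groups (used as calibration targets by the cohort simulator).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

__all__ = ["CpGSite", "CpGPanel", "load_default_panel", "panel_to_bed"]


@dataclass(frozen=True)
class CpGSite:
    """One CpG of the panel.

    ``direction`` is +1 where methylation rises with age and -1 where it
    falls. ``r_german``/``r_japanese`` are the reference Spearman R values of
    the methylation-age association in the two donor groups.
    """

    gene: str
    cpg_index: int
    chrom: str
    position: int  # 1-based GRCh38.p13 coordinate
    probe_id: Optional[str]
    direction: int
    r_german: float
    r_japanese: float

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")

    @property
    def column(self) -> str:
        """Column name used for this site in cohort tables, e.g. ``PDE4C_CpG2``."""
        return f"{self.gene}_CpG{self.cpg_index}"


class CpGPanel:
    """An ordered collection of :class:`CpGSite` with unique (gene, index) keys."""

    def __init__(self, sites: Sequence[CpGSite]):
        sites = tuple(sites)
        keys = [(s.gene, s.cpg_index) for s in sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (gene, cpg_index) in panel")
        self.sites = sites

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[CpGSite]:
        return iter(self.sites)

    def __getitem__(self, i: int) -> CpGSite:
        return self.sites[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CpGPanel) and self.sites == other.sites

    @property
    def columns(self) -> list[str]:
        return [s.column for s in self.sites]

    def site(self, gene: str, cpg_index: int) -> CpGSite:
        for s in self.sites:
            if s.gene == gene and s.cpg_index == cpg_index:
                return s
        raise KeyError(f"{gene} CpG {cpg_index} not in panel")

    def index_of(self, column: str) -> int:
        try:
            return self.columns.index(column)
        except ValueError:
            raise KeyError(f"{column} not in panel") from None

    def subset(self, keep: Sequence[str]) -> "CpGPanel":
        """Return a panel restricted to the site columns in ``keep``, order preserved."""
        keep = set(keep)
        return CpGPanel([s for s in self.sites if s.column in keep])


# gene, cpg_index, chrom, position (GRCh38.p13), probe_id, R german, R japanese
_PANEL_ROWS = [
    ("PDE4C", 1, "Chr.19", 18_233_106, None, 0.95, 0.93),
    ("PDE4C", 2, "Chr.19", 18_233_092, "cg17861230", 0.88, 0.81),
    ("PDE4C", 3, "Chr.19", 18_233_083, None, 0.82, 0.88),
    ("PDE4C", 4, "Chr.19", 18_233_080, None, 0.84, 0.82),
    ("PDE4C", 5, "Chr.19", 18_233_071, None, 0.81, 0.86),
    ("PDE4C", 6, "Chr.19", 18_233_059, None, 0.81, 0.83),
    ("PDE4C", 7, "Chr.19", 18_233_049, None, 0.85, 0.85),
    ("ELOVL2", 1, "Chr.6", 11_044_625, None, 0.90, 0.89),
    ("ELOVL2", 2, "Chr.6", 11_044_629, None, 0.89, 0.79),
    ("ELOVL2", 3, "Chr.6", 11_044_631, None, 0.85, 0.83),
    ("ELOVL2", 4, "Chr.6", 11_044_640, None, 0.86, 0.84),
    ("ELOVL2", 5, "Chr.6", 11_044_642, None, 0.90, 0.86),
    ("ELOVL2", 6, "Chr.6", 11_044_645, "cg16867657", 0.83, 0.85),
    ("ELOVL2", 7, "Chr.6", 11_044_648, None, 0.67, 0.73),
    ("ELOVL2", 8, "Chr.6", 11_044_664, None, 0.80, 0.78),
    ("ELOVL2", 9, "Chr.6", 11_044_683, None, 0.84, 0.79),
    ("RPA2", 1, "Chr.1", 27_915_022, None, 0.89, 0.81),
    ("RPA2", 2, "Chr.1", 27_915_024, None, 0.89, 0.83),
    ("RPA2", 3, "Chr.1", 27_915_067, "cg25410668", 0.84, 0.75),
    ("EDARADD", 1, "Chr.1", 236_394_371, "cg09809672", -0.85, -0.77),
    ("EDARADD", 2, "Chr.1", 236_394_383, None, -0.86, -0.81),
    ("DDO", 1, "Chr.6", 110_415_571, "cg02872426", -0.73, -0.62),
]


def load_default_panel() -> CpGPanel:
    """Return the default 22-site panel with coordinates, probe IDs and reference R."""
    sites = [
        CpGSite(
            gene=gene,
            cpg_index=idx,
            chrom=chrom,
            position=pos,
            probe_id=probe,
            direction=1 if r_de > 0 else -1,
            r_german=r_de,
            r_japanese=r_jp,
        )
        for gene, idx, chrom, pos, probe, r_de, r_jp in _PANEL_ROWS
    ]
    return CpGPanel(sites)


def panel_to_bed(panel: CpGPanel, path) -> None:
    """Write the panel as BED-like TSV (0-based half-open intervals).

    Columns: chrom, start, end, name (``gene_CpGk``), probe_id (``.`` if absent).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in panel:
            writer.writerow(
                [s.chrom, s.position - 1, s.position, s.column, s.probe_id or "."]
            )
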