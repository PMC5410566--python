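"""Protein physicochemical properties and catalog summary statistics.

Molecular weight uses average (not monoisotopic) residue masses plus one
water; the theoretical isoelectric point solves net charge = 0 by bisection
of the Henderson-Hasselbalch charge curve with Bjellqvist-lineage pKa
values. Both tables are plain data so alternative parameter sets (e.g.
EMBOSS pKa) drop in without code changes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .formats_io import CatalogRow, GeneRecord

#: average residue masses, Da (ExPASy convention)
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class MassTable:
    residue_mass: dict = field(default_factory=lambda: dict(AVERAGE_RESIDUE_MASS))
    water: float = WATER_MASS

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residue_mass.values()) or self.water <= 0:
            raise ValueError("masses must be positive")


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values (Bjellqvist lineage by default)."""

    acidic: dict = field(default_factory=lambda: {"C": 9.0, "D": 4.05, "E": 4.45, "Y": 10.0})
    basic: dict = field(default_factory=lambda: {"H": 5.98, "K": 10.0, "R": 12.0})
    n_term: float = 7.5
    c_term: float = 3.55

    def __post_init__(self) -> None:
        for pka in (*self.acidic.values(), *self.basic.values(), self.n_term, self.c_term):
            if not 0 < pka < 14:
                raise ValueError(f"pKa {pka} outside (0,14)")


def molecular_weight(seq: str, masses: MassTable = MassTable()) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    if not seq:
        raise ValueError("empty sequence")
    total = masses.water
    for ch in seq:
        try:
            total += masses.residue_mass[ch]
        except KeyError:
            raise ValueError(f"unknown or ambiguous residue {ch!r}") from None
    return total


def net_charge(seq: str, pH: float, pkas: PkaTable = PkaTable()) -> float:
    """Henderson-Hasselbalch net charge at a given pH, termini included."""
    counts = Counter(seq)
    charge = 1.0 / (1.0 + 10.0 ** (pH - pkas.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (pkas.c_term - pH))
    for aa, pka in pkas.basic.items():
        charge += counts[aa] / (1.0 + 10.0 ** (pH - pka))
    for aa, pka in pkas.acidic.items():
        charge -= counts[aa] / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point(
    seq: str, pkas: PkaTable = PkaTable(), tol: float = 1e-3
) -> float:
    """The unique pH in [0,14] where net charge vanishes, by bisection.

    The charge curve is strictly decreasing in pH, so the root exists and
    is unique; bisection runs to ``tol`` in pH units.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pkas) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def intron_count(gene: GeneRecord) -> int:
    """Introns of the representative mRNA: exon count minus one, floored at 0."""
    return max(0, len(gene.exons) - 1)


@dataclass(frozen=True)
class CatalogSummary:
    n: int
    min_size: tuple[int, str]
    max_size: tuple[int, str]
    min_mw: tuple[float, str]
    max_mw: tuple[float, str]
    min_pi: tuple[float, str]
    max_pi: tuple[float, str]
    intron_histogram: dict[int, int]
    chromosome_counts: dict[str, int]

    def to_text(self) -> str:
        lines = [
            f"members: {self.n}",
            f"protein length (aa): {self.min_size[0]} ({self.min_size[1]}) .. "
            f"{self.max_size[0]} ({self.max_size[1]})",
            f"molecular weight (Da): {self.min_mw[0]} ({self.min_mw[1]}) .. "
            f"{self.max_mw[0]} ({self.max_mw[1]})",
            f"pI: {self.min_pi[0]} ({self.min_pi[1]}) .. {self.max_pi[0]} ({self.max_pi[1]})",
            "introns: "
            + ", ".join(f"{k}:{v}" for k, v in sorted(self.intron_histogram.items())),
            "chromosomes: "
            + ", ".join(f"{k}:{v}" for k, v in sorted(self.chromosome_counts.items())),
        ]
        return "\n".join(lines)


def catalog_stats(rows: list[CatalogRow]) -> CatalogSummary:
    """Min/max property extrema, intron histogram and chromosome counts."""
    if not rows:
        raise ValueError("empty catalog")

    def extreme(key, fn):
        row = fn(rows, key=key)
        return (key(row), row.gene_name)

    return CatalogSummary(
        n=len(rows),
        min_size=extreme(lambda r: r.size_aa, min),
        max_size=extreme(lambda r: r.size_aa, max),
        min_mw=extreme(lambda r: r.mw_da, min),
        max_mw=extreme(lambda r: r.mw_da, max),
        min_pi=extreme(lambda r: r.pi, min),
        max_pi=extreme(lambda r: r.pi, max),
        intron_histogram=dict(Counter(r.introns for r in rows)),
        chromosome_counts=dict(Counter(r.chromosome for r in rows)),
    )
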