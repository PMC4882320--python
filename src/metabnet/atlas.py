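"""AAL-90 parcellation, region metadata and functional classification.

The pipeline indexes every matrix by the canonical atlas order defined in the
packaged region table: the 45 cerebral AAL abbreviations in standard atlas
order, left hemisphere before right (node ``i`` of every correlation or
adjacency matrix is row ``i`` of this table, 0-based).

Each region carries one of four functional classes — ``association``,
``paralimbic``, ``subcortical`` or ``primary`` — the Mesulam-style grouping
used to summarise where network hubs fall.  The packaged table's
``provenance`` column records whether a class was taken from the bundled
reference hub tables (``reported``), copied from the contralateral region
(``mirrored``), or completed from the functional scheme (``assigned``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

FUNC_CLASSES = ("association", "paralimbic", "subcortical", "primary")
HEMISPHERES = ("L", "R")

_DATA_PACKAGE = "metabnet.data"
_REGION_FILE = "aal90_regions.tsv"


class AtlasError(RuntimeError):
    """Raised when the packaged region table is absent or corrupt."""


@dataclass(frozen=True)
class Region:
    """One parcellation unit (an AAL region of one hemisphere)."""

    index: int  # 1-based canonical atlas position
    abbreviation: str
    name: str
    hemisphere: str
    func_class: str
    provenance: str = "assigned"

    @property
    def label(self) -> str:
        """Column/row label used in every matrix and panel header."""
        return f"{self.abbreviation}_{self.hemisphere}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} ({'Left' if self.hemisphere == 'L' else 'Right'})"


class RegionTable:
    """Ordered collection of :class:`Region` with index and label lookup."""

    def __init__(self, regions: Iterable[Region]):
        self.regions: tuple[Region, ...] = tuple(regions)
        self._by_key = {(r.abbreviation, r.hemisphere): r for r in self.regions}
        if len(self._by_key) != len(self.regions):
            raise AtlasError("duplicate abbreviation+hemisphere pairs in region table")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    def lookup(self, abbreviation: str, hemisphere: str) -> Region:
        try:
            return self._by_key[(abbreviation, hemisphere)]
        except KeyError:
            raise KeyError(f"no region {abbreviation!r} in hemisphere {hemisphere!r}") from None

    def by_index(self, index: int) -> Region:
        """Lookup by the 1-based canonical index."""
        region = self.regions[index - 1]
        if region.index != index:
            raise AtlasError("region table is not in canonical index order")
        return region

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    def validate(self) -> None:
        """Check the structural invariants of the canonical 90-region table."""
        if len(self.regions) != 90:
            raise AtlasError(f"expected 90 regions, found {len(self.regions)}")
        for hemi in HEMISPHERES:
            n = sum(r.hemisphere == hemi for r in self.regions)
            if n != 45:
                raise AtlasError(f"expected 45 regions in hemisphere {hemi}, found {n}")
        for pos, region in enumerate(self.regions, start=1):
            if region.index != pos:
                raise AtlasError(f"region {region.label} out of canonical order")
            if region.func_class not in FUNC_CLASSES:
                raise AtlasError(f"unknown func_class {region.func_class!r} for {region.label}")


def load_region_table() -> RegionTable:
    """Load the packaged 90-region table in canonical order."""
    try:
        text = resources.files(_DATA_PACKAGE).joinpath(_REGION_FILE).read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise AtlasError(f"packaged region table missing: {exc}") from exc
    regions = _parse_region_rows(csv.DictReader(text.splitlines(), delimiter="\t"))
    table = RegionTable(regions)
    table.validate()
    return table


def _parse_region_rows(rows: Iterable[Mapping[str, str]]) -> list[Region]:
    out = []
    for row in rows:
        try:
            out.append(
                Region(
                    index=int(row["index"]),
                    abbreviation=row["abbreviation"],
                    name=row["name"],
                    hemisphere=row["hemisphere"],
                    func_class=row["func_class"],
                    provenance=row.get("provenance", "assigned"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise AtlasError(f"corrupt region table row {row!r}") from exc
    return out


def read_region_table(path) -> RegionTable:
    """Read a region table from a TSV file (same columns as the packaged one)."""
    with open(path, newline="") as fh:
        table = RegionTable(_parse_region_rows(csv.DictReader(fh, delimiter="\t")))
    table.validate()
    return table


def write_region_table(table: RegionTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["index", "abbreviation", "name", "hemisphere", "func_class", "provenance"])
        for r in table:
            writer.writerow([r.index, r.abbreviation, r.name, r.hemisphere, r.func_class, r.provenance])


def classify_composition(regions: Iterable[Region]) -> dict[str, tuple[int, float]]:
    """Tally the functional-class composition of a set of regions.

    Returns ``{func_class: (count, fraction)}`` for the classes present.
    Counts sum to the input size and fractions to 1.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("cannot classify an empty region list")
    counts: dict[str, int] = {}
    for region in regions:
        counts[region.func_class] = counts.get(region.func_class, 0) + 1
    total = len(regions)
    return {fc: (n, n / total) for fc, n in counts.items()}


def association_paralimbic_fraction(regions: Iterable[Region]) -> tuple[int, float]:
    """Count and fraction of regions in the association or paralimbic classes."""
    comp = classify_composition(list(regions))
    n = sum(comp.get(fc, (0, 0.0))[0] for fc in ("association", "paralimbic"))
    total = sum(c for c, _ in comp.values())
    return n, n / total
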