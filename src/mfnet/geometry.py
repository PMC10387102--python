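"""Electrode-array geometry: MEA grid, microfluidic compartments, references.

The default layout models a 60-site, 8x8, 200 um-pitch array (corner
positions absent) overlaid by a dual-compartment microfluidic chip: two
columns of somatic chamber, one column of short microchannels, two columns
of synaptic chamber, two columns of long microchannels, and one column over
the empty (axon output) chamber.  Columns 1-4 are re-referenced against
reference channel R1, columns 5-8 against R2.

Grid indexing is 1-based; electrode ids follow the multichannel convention
``"<col><row>"``.  Exported x/y coordinates are micrometres from the
top-left electrode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence


class LayoutError(ValueError):
    """Raised for inconsistent layout configurations."""


class Compartment(str, Enum):
    """Closed enumeration of microfluidic compartments over the array."""

    SOMATIC_A = "somatic_chamber_A"
    SOMATIC_B = "somatic_chamber_B"
    SHORT_MICROCHANNEL = "short_microchannel"
    SYNAPTIC = "synaptic_chamber"
    LONG_MICROCHANNEL = "long_microchannel"
    EMPTY = "empty_chamber"
    UNASSIGNED = "unassigned"


#: Compartments that contain cell bodies.
SOMATIC_COMPARTMENTS = frozenset({Compartment.SOMATIC_A, Compartment.SOMATIC_B})

#: Row/column ordering used for correlation-matrix axes (color-bar order:
#: soma chamber first, then neurite compartments left to right, empty last).
COMPARTMENT_ORDER = [
    Compartment.SOMATIC_A,
    Compartment.SOMATIC_B,
    Compartment.SHORT_MICROCHANNEL,
    Compartment.SYNAPTIC,
    Compartment.LONG_MICROCHANNEL,
    Compartment.EMPTY,
    Compartment.UNASSIGNED,
]


class EdgeClass(str, Enum):
    """Geometric class of an electrode pair.

    ``soma_neurite``  at least one endpoint in a somatic chamber;
    ``same_line``     both neurite sites on the same grid row (same or
                      aligned microchannels, straight propagation);
    ``same_column``   both neurite sites in the same grid column but in
                      different (parallel) microchannels;
    ``misaligned``    neurite sites differing in both row and column.
    """

    SOMA_NEURITE = "soma_neurite"
    SAME_COLUMN = "same_column"
    SAME_LINE = "same_line"
    MISALIGNED = "misaligned"


@dataclass(frozen=True)
class Electrode:
    id: str
    row: int
    col: int
    x: float  # um
    y: float  # um


DEFAULT_LAYOUT_CONFIG: dict = {
    "grid": {
        "rows": 8,
        "cols": 8,
        "pitch_um": 200.0,
        "excluded": [[1, 1], [1, 8], [8, 1], [8, 8]],
    },
    "compartments": {
        "somatic_chamber_A": [1, 2],
        "short_microchannel": [3, 3],
        "synaptic_chamber": [4, 5],
        "long_microchannel": [6, 7],
        "empty_chamber": [8, 8],
    },
    "references": {"R1": [1, 2, 3, 4], "R2": [5, 6, 7, 8]},
}


@dataclass
class ElectrodeLayout:
    """Validated MEA grid with compartment labels and reference assignment."""

    n_rows: int
    n_cols: int
    pitch_um: float
    electrodes: list[Electrode]
    excluded: list[tuple[int, int]]
    reference_map: dict[str, str]
    compartment_map: dict[str, Compartment]
    config: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ---------------------------------------------------------
    @property
    def electrode_ids(self) -> list[str]:
        return [e.id for e in self.electrodes]

    @property
    def reference_ids(self) -> list[str]:
        return sorted(set(self.reference_map.values()))

    def electrode(self, eid: str) -> Electrode:
        try:
            return self._by_id[eid]
        except KeyError:
            raise KeyError(f"unknown electrode id {eid!r}") from None

    def compartment(self, eid: str) -> Compartment:
        self.electrode(eid)
        return self.compartment_map[eid]

    def is_somatic(self, eid: str) -> bool:
        return self.compartment(eid) in SOMATIC_COMPARTMENTS

    def somatic_ids(self) -> list[str]:
        return [e.id for e in self.electrodes if self.is_somatic(e.id)]

    def matrix_order(self, subset: Iterable[str] | None = None) -> list[str]:
        """Electrode ids in compartment color-bar order (then col, row)."""
        ids = list(subset) if subset is not None else self.electrode_ids
        rank = {c: i for i, c in enumerate(COMPARTMENT_ORDER)}
        return sorted(
            ids,
            key=lambda i: (rank[self.compartment(i)], self.electrode(i).col, self.electrode(i).row),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [e.id for e in self.electrodes]
        if len(ids) != len(set(ids)):
            raise LayoutError("electrode ids are not unique")
        self._by_id = {e.id: e for e in self.electrodes}
        expected = self.n_rows * self.n_cols - len(self.excluded)
        if len(self.electrodes) != expected:
            raise LayoutError(
                f"{len(self.electrodes)} electrodes, expected "
                f"{self.n_rows}x{self.n_cols} - {len(self.excluded)} excluded = {expected}"
            )
        for eid in ids:
            if eid not in self.compartment_map:
                raise LayoutError(f"electrode {eid} has no compartment")
            if eid not in self.reference_map:
                raise LayoutError(f"electrode {eid} has no reference channel")
        refs = set(self.reference_map.values())
        if refs & set(ids):
            raise LayoutError(f"reference channels {refs & set(ids)} collide with electrodes")

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(self.config, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ElectrodeLayout":
        return build_default_layout(json.loads(text))


def _column_compartments(config: Mapping) -> dict[int, Compartment]:
    comp_cfg = config["compartments"]
    col_map: dict[int, Compartment] = {}
    for label, (c0, c1) in comp_cfg.items():
        comp = Compartment(label)
        if c1 < c0:
            raise LayoutError(f"compartment {label}: column range [{c0}, {c1}] is inverted")
        for c in range(int(c0), int(c1) + 1):
            if c in col_map:
                raise LayoutError(
                    f"column {c} assigned to both {col_map[c].value} and {label}"
                )
            col_map[c] = comp
    return col_map


def build_default_layout(config: Mapping | None = None) -> ElectrodeLayout:
    """Build a validated :class:`ElectrodeLayout` from a layout configuration.

    ``config`` follows the schema of :data:`DEFAULT_LAYOUT_CONFIG`:
    ``grid`` (rows, cols, pitch_um, excluded positions), ``compartments``
    (label -> inclusive column range) and ``references`` (reference channel
    -> list of columns it serves).
    """
    cfg = json.loads(json.dumps(config if config is not None else DEFAULT_LAYOUT_CONFIG))
    grid = cfg["grid"]
    rows, cols = int(grid["rows"]), int(grid["cols"])
    pitch = float(grid.get("pitch_um", 200.0))
    excluded = [tuple(int(v) for v in rc) for rc in grid.get("excluded", [])]

    col_comp = _column_compartments(cfg)
    ref_cols: dict[int, str] = {}
    for ref_id, ref_columns in cfg["references"].items():
        for c in ref_columns:
            if c in ref_cols:
                raise LayoutError(f"column {c} referenced by both {ref_cols[c]} and {ref_id}")
            ref_cols[int(c)] = ref_id

    electrodes: list[Electrode] = []
    compartment_map: dict[str, Compartment] = {}
    reference_map: dict[str, str] = {}
    for col in range(1, cols + 1):
        for row in range(1, rows + 1):
            if (row, col) in excluded:
                continue
            eid = f"{col}{row}"
            if col not in col_comp:
                raise LayoutError(f"electrode {eid}: column {col} has no compartment")
            if col not in ref_cols:
                raise LayoutError(f"electrode {eid}: column {col} has no reference channel")
            electrodes.append(
                Electrode(eid, row, col, x=(col - 1) * pitch, y=(row - 1) * pitch)
            )
            compartment_map[eid] = col_comp[col]
            reference_map[eid] = ref_cols[col]

    return ElectrodeLayout(
        n_rows=rows,
        n_cols=cols,
        pitch_um=pitch,
        electrodes=electrodes,
        excluded=excluded,
        reference_map=reference_map,
        compartment_map=compartment_map,
        config=cfg,
    )


def edge_class(layout: ElectrodeLayout, a: str, b: str) -> EdgeClass:
    """Classify the electrode pair (a, b) by compartment geometry.

    Symmetric and total: any pair with a somatic endpoint is
    ``soma_neurite`` (precedence); neurite-neurite pairs are ``same_line``
    (same row), ``same_column`` (same column), or ``misaligned``.
    """
    if a == b:
        raise ValueError("edge_class requires two distinct electrodes")
    ea, eb = layout.electrode(a), layout.electrode(b)
    if layout.is_somatic(a) or layout.is_somatic(b):
        return EdgeClass.SOMA_NEURITE
    if ea.row == eb.row:
        return EdgeClass.SAME_LINE
    if ea.col == eb.col:
        return EdgeClass.SAME_COLUMN
    return EdgeClass.MISALIGNED


def edge_span(layout: ElectrodeLayout, a: str, b: str) -> int:
    """Correlation length of a pair in electrode pitches (the k of "n+k")."""
    ea, eb = layout.electrode(a), layout.electrode(b)
    return max(abs(ea.row - eb.row), abs(ea.col - eb.col))
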