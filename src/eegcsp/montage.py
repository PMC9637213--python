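"""Electrode montage as a 2-D grid with 4-neighborhood lookup.

The Laplacian mask and the channel-informativeness score both assume scalp
electrodes mapped onto a rectangular row/column matrix. Rows follow the
10-10 bands Fp/AF/F/FC/C/CP/P/PO/O and columns the lateral order
7,5,3,1,z,2,4,6,8. The grid is a plain configuration object, so any cap can
be described with a layout table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError, UnknownChannelError

#: Direction names for the four orthogonal neighbors, in reporting order.
DIRECTIONS = ("up", "left", "down", "right")


@dataclass(frozen=True)
class MontageGrid:
    """Bidirectional mapping between channel labels and (row, col) cells."""

    label_to_cell: dict[str, tuple[int, int]]
    cell_to_label: dict[tuple[int, int], str]
    n_rows: int
    n_cols: int

    def __contains__(self, label: str) -> bool:
        return label in self.label_to_cell

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.label_to_cell)


@dataclass(frozen=True)
class NeighborReport:
    """Result of a 4-neighbor lookup around a mask center.

    ``found`` maps direction -> label for the neighbors that exist;
    ``missing`` names the directions whose cell is empty or off-grid.
    """

    center: str
    d: int
    found: dict[str, str]
    missing: tuple[str, ...]

    @property
    def complete(self) -> bool:
        return not self.missing

    @property
    def labels(self) -> tuple[str, ...]:
        """Labels of the found neighbors, in DIRECTIONS order."""
        return tuple(self.found[k] for k in DIRECTIONS if k in self.found)


def build_grid(layout_spec: list[tuple[str, int, int]]) -> MontageGrid:
    """Build a montage grid from (label, row, col) triples.

    Raises ConfigurationError on duplicate labels or duplicate cells.
    """
    label_to_cell: dict[str, tuple[int, int]] = {}
    cell_to_label: dict[tuple[int, int], str] = {}
    for label, row, col in layout_spec:
        row, col = int(row), int(col)
        if label in label_to_cell:
            raise ConfigurationError(f"duplicate label {label!r} in layout")
        if (row, col) in cell_to_label:
            raise ConfigurationError(
                f"cell ({row}, {col}) assigned to both "
                f"{cell_to_label[(row, col)]!r} and {label!r}"
            )
        if row < 0 or col < 0:
            raise ConfigurationError(f"negative grid coordinate for {label!r}")
        label_to_cell[label] = (row, col)
        cell_to_label[(row, col)] = label
    n_rows = 1 + max((r for r, _ in cell_to_label), default=-1)
    n_cols = 1 + max((c for _, c in cell_to_label), default=-1)
    return MontageGrid(label_to_cell, cell_to_label, n_rows, n_cols)


def neighbors(grid: MontageGrid, center: str, d: int) -> NeighborReport:
    """The four orthogonal neighbors of ``center`` at grid distance ``d``.

    Neighbors are the cells (r-d,c), (r,c-d), (r+d,c), (r,c+d). Empty or
    off-grid cells are reported in ``missing`` by direction rather than
    raising; an unknown center does raise.
    """
    if d not in (1, 2):
        raise ConfigurationError(f"neighbor distance must be 1 or 2, got {d}")
    if center not in grid.label_to_cell:
        raise UnknownChannelError(f"channel {center!r} not on montage grid")
    r, c = grid.label_to_cell[center]
    cells = {
        "up": (r - d, c),
        "left": (r, c - d),
        "down": (r + d, c),
        "right": (r, c + d),
    }
    found: dict[str, str] = {}
    missing: list[str] = []
    for direction, cell in cells.items():
        label = grid.cell_to_label.get(cell)
        if label is None:
            missing.append(direction)
        else:
            found[direction] = label
    return NeighborReport(center, d, found, tuple(missing))


def admits_mask(grid: MontageGrid, center: str, d: int) -> bool:
    """True iff all four d-neighbors of ``center`` exist on the grid."""
    return neighbors(grid, center, d).complete


def load_layout(path: str | Path) -> MontageGrid:
    """Read a plain-text layout table: ``label<TAB>row<TAB>col`` per line.

    Blank lines and lines starting with '#' are ignored.
    """
    spec: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'label<TAB>row<TAB>col', got {line!r}"
            )
        try:
            spec.append((parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise ConfigurationError(f"{path}:{lineno}: {exc}") from None
    return build_grid(spec)


def save_layout(grid: MontageGrid, path: str | Path) -> None:
    lines = [
        f"{label}\t{r}\t{c}" for label, (r, c) in sorted(grid.label_to_cell.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# Default 60-channel layout. Rows are the 10-10 bands, columns the lateral
# positions 7,5,3,1,z,2,4,6,8 (column indices 0..8). The sparse Fp and O rows
# place their lateral electrodes in the '3'/'4' columns so that the frontal
# and central mask centers admit both the small (d=1) and large (d=2) masks;
# Oz is left out to keep exactly 60 channels.
_COLS = {"7": 0, "5": 1, "3": 2, "1": 3, "z": 4, "2": 5, "4": 6, "6": 7, "8": 8}

DEFAULT_LAYOUT: list[tuple[str, int, int]] = [
    # row 0: Fp
    ("Fp1", 0, 2), ("Fpz", 0, 4), ("Fp2", 0, 6),
    # row 1: AF
    ("AF7", 1, 0), ("AF3", 1, 2), ("AFz", 1, 4), ("AF4", 1, 6), ("AF8", 1, 8),
    # row 2: F
    ("F7", 2, 0), ("F5", 2, 1), ("F3", 2, 2), ("F1", 2, 3), ("Fz", 2, 4),
    ("F2", 2, 5), ("F4", 2, 6), ("F6", 2, 7), ("F8", 2, 8),
    # row 3: FC
    ("FT7", 3, 0), ("FC5", 3, 1), ("FC3", 3, 2), ("FC1", 3, 3), ("FCz", 3, 4),
    ("FC2", 3, 5), ("FC4", 3, 6), ("FC6", 3, 7), ("FT8", 3, 8),
    # row 4: C
    ("T7", 4, 0), ("C5", 4, 1), ("C3", 4, 2), ("C1", 4, 3), ("Cz", 4, 4),
    ("C2", 4, 5), ("C4", 4, 6), ("C6", 4, 7), ("T8", 4, 8),
    # row 5: CP
    ("TP7", 5, 0), ("CP5", 5, 1), ("CP3", 5, 2), ("CP1", 5, 3), ("CPz", 5, 4),
    ("CP2", 5, 5), ("CP4", 5, 6), ("CP6", 5, 7), ("TP8", 5, 8),
    # row 6: P
    ("P7", 6, 0), ("P5", 6, 1), ("P3", 6, 2), ("P1", 6, 3), ("Pz", 6, 4),
    ("P2", 6, 5), ("P4", 6, 6), ("P6", 6, 7), ("P8", 6, 8),
    # row 7: PO
    ("PO7", 7, 0), ("PO3", 7, 2), ("POz", 7, 4), ("PO4", 7, 6), ("PO8", 7, 8),
    # row 8: O
    ("O1", 8, 2), ("O2", 8, 6),
]

#: Channel labels of the default layout, in layout order.
DEFAULT_LABELS: tuple[str, ...] = tuple(lbl for lbl, _, _ in DEFAULT_LAYOUT)

#: Candidate Laplacian mask centers (frontal/central electrodes plus C4 for
#: left/right symmetry).
CANDIDATE_CENTERS: tuple[str, ...] = (
    "F3", "Fz", "F4", "FC3", "FCz", "FC4", "C3", "CPz", "C4",
)


def default_grid() -> MontageGrid:
    """The packaged 60-channel 10-10 grid."""
    return build_grid(DEFAULT_LAYOUT)
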