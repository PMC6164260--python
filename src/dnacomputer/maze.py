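"""Grid maze world for the wall-following robot demonstration.

The world is a rectangular occupancy grid.  Cells outside the grid count
as walls, so every maze is effectively closed.  The robot occupies one
free cell with one of four headings and carries two proximity sensors: one
facing forward, one facing left (relative to the heading).

Maze text format (one character per cell)::

    #   wall
    .   free
    ^ > v <   robot start, the character giving the initial heading
    E   exit (optional; the demo stops when the robot reaches it)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Headings in clockwise order as (row, col) steps: north, east, south, west.
HEADINGS = ((-1, 0), (0, 1), (1, 0), (0, -1))
HEADING_CHARS = "^>v<"

__all__ = ["MazeWorld", "HEADINGS", "HEADING_CHARS"]


@dataclass
class MazeWorld:
    walls: np.ndarray                 # bool (rows, cols)
    position: tuple[int, int]
    heading: int                      # index into HEADINGS
    exits: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.walls = np.asarray(self.walls, dtype=bool)
        if self.wall_at(*self.position):
            raise ValueError("robot start position is a wall cell")
        if not 0 <= self.heading < 4:
            raise ValueError("heading must be 0..3 (N, E, S, W)")

    # -- construction ----------------------------------------------------

    @classmethod
    def from_text(cls, text: str) -> "MazeWorld":
        rows = [line for line in text.splitlines() if line.strip()]
        width = max(len(r) for r in rows)
        walls = np.zeros((len(rows), width), dtype=bool)
        position = heading = None
        exits = set()
        for r, line in enumerate(rows):
            for c, ch in enumerate(line.ljust(width)):
                if ch == "#":
                    walls[r, c] = True
                elif ch in HEADING_CHARS:
                    if position is not None:
                        raise ValueError("multiple robot start positions")
                    position = (r, c)
                    heading = HEADING_CHARS.index(ch)
                elif ch == "E":
                    exits.add((r, c))
                elif ch not in ". ":
                    raise ValueError(f"unknown maze character {ch!r}")
        if position is None:
            raise ValueError("maze has no robot start (use one of ^ > v <)")
        return cls(walls=walls, position=position, heading=heading,
                   exits=frozenset(exits))

    @classmethod
    def from_file(cls, path) -> "MazeWorld":
        with open(path) as fh:
            return cls.from_text(fh.read())

    # -- geometry --------------------------------------------------------

    def wall_at(self, r: int, c: int) -> bool:
        if not (0 <= r < self.walls.shape[0] and 0 <= c < self.walls.shape[1]):
            return True  # outside the grid counts as wall
        return bool(self.walls[r, c])

    def _neighbour(self, turn: int) -> tuple[int, int]:
        dr, dc = HEADINGS[(self.heading + turn) % 4]
        return self.position[0] + dr, self.position[1] + dc

    @property
    def sensor_forward(self) -> bool:
        """True when the cell ahead is a wall."""
        return self.wall_at(*self._neighbour(0))

    @property
    def sensor_left(self) -> bool:
        """True when the cell to the robot's left is a wall."""
        return self.wall_at(*self._neighbour(-1))

    @property
    def pose(self) -> tuple[int, int, int]:
        return (*self.position, self.heading)

    @property
    def at_exit(self) -> bool:
        return self.position in self.exits

    # -- actions ---------------------------------------------------------

    def advance(self) -> None:
        """Move one cell forward; refuses to enter a wall."""
        target = self._neighbour(0)
        if self.wall_at(*target):
            raise RuntimeError(f"cannot advance into wall at {target}")
        self.position = target

    def rotate(self, direction: str) -> None:
        """Rotate 90 degrees, ``direction`` in {"L", "R"}."""
        if direction == "R":
            self.heading = (self.heading + 1) % 4
        elif direction == "L":
            self.heading = (self.heading - 1) % 4
        else:
            raise ValueError("direction must be 'L' or 'R'")

    def render(self) -> str:
        """ASCII snapshot with the robot drawn at its pose."""
        out = []
        for r in range(self.walls.shape[0]):
            row = []
            for c in range(self.walls.shape[1]):
                if (r, c) == self.position:
                    row.append(HEADING_CHARS[self.heading])
                elif (r, c) in self.exits:
                    row.append("E")
                else:
                    row.append("#" if self.walls[r, c] else ".")
            out.append("".join(row))
        return "\n".join(out)
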