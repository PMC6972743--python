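"""384-well plate layout and batch structure.

The screen ran on 384-well plates (rows A–P, columns 1–24, 1-based). Columns
1 and 24 hold only blank (water) wells used for background estimation.
Columns 3 and 22 hold the hand-plated repeated controls — five wells each of
non-targeting siCont, siKSR1 (positive control), lethal siPLK1 and siPPIB —
plus twelve unused positions (role ``empty``) that never receive siRNA and are
excluded from all computation. The remaining 320 wells carry one library
sample gene each.

Plates were assayed in experimental batches limited by shaker capacity
(8 plates); the deposited screen's batch→plate mapping is reproduced by
:func:`default_batch_map`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import AssignmentError, IntegrityError

ROWS: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOP")
N_ROWS = 16
N_COLS = 24
BLANK_COLUMNS = (1, 24)
CONTROL_COLUMNS = (3, 22)


class WellRole(str, enum.Enum):
    """Functional role of a well on the plate."""

    blank = "blank"  # water-only; plate-wise background
    sicont = "sicont"  # non-targeting negative control
    si_target = "si_target"  # positive control depletion (siKSR1)
    si_lethal = "si_lethal"  # lethal control (siPLK1)
    si_probe = "si_probe"  # depletion of a reporter probe (siPPIB)
    sample = "sample"  # one library gene
    empty = "empty"  # unused position in a control column

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CONTROL_ROLES = (
    WellRole.sicont,
    WellRole.si_target,
    WellRole.si_lethal,
    WellRole.si_probe,
)

#: gene annotation attached to each repeated-control role
CONTROL_GENES: dict[WellRole, tuple[str, int]] = {
    WellRole.sicont: ("siCONT", 0),
    WellRole.si_target: ("KSR1", 8844),
    WellRole.si_lethal: ("PLK1", 5347),
    WellRole.si_probe: ("PPIB", 5479),
}


@dataclass(frozen=True)
class PlateLayout:
    """Role map for one 384-well plate.

    ``role_map`` assigns a :class:`WellRole` to every (row, column) position;
    ``control_counts`` records the expected per-plate count of each role and is
    the reference used by layout validation.
    """

    role_map: Mapping[tuple[str, int], WellRole]
    control_counts: Mapping[WellRole, int]
    n_rows: int = N_ROWS
    n_cols: int = N_COLS

    def __post_init__(self) -> None:
        if len(self.role_map) != self.n_rows * self.n_cols:
            raise IntegrityError(
                f"role_map must cover all {self.n_rows * self.n_cols} positions"
            )
        counts: dict[WellRole, int] = {}
        for role in self.role_map.values():
            counts[role] = counts.get(role, 0) + 1
        for role, expected in self.control_counts.items():
            if counts.get(role, 0) != expected:
                raise IntegrityError(
                    f"layout declares {expected} {role} wells but maps "
                    f"{counts.get(role, 0)}"
                )

    def role_at(self, row: str, column: int) -> WellRole:
        return self.role_map[(row, column)]

    def positions(self, role: WellRole) -> list[tuple[str, int]]:
        return [pos for pos, r in sorted(self.role_map.items()) if r == role]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_rows": self.n_rows,
                "n_cols": self.n_cols,
                "role_map": {
                    f"{row}{col}": role.value
                    for (row, col), role in sorted(self.role_map.items())
                },
                "control_counts": {r.value: n for r, n in self.control_counts.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlateLayout":
        raw = json.loads(text)
        role_map = {
            (pos[0], int(pos[1:])): WellRole(role)
            for pos, role in raw["role_map"].items()
        }
        counts = {WellRole(r): int(n) for r, n in raw["control_counts"].items()}
        return cls(
            role_map=role_map,
            control_counts=counts,
            n_rows=int(raw.get("n_rows", N_ROWS)),
            n_cols=int(raw.get("n_cols", N_COLS)),
        )


def default_layout(
    control_positions: Mapping[WellRole, Sequence[tuple[str, int]]] | None = None,
) -> PlateLayout:
    """The screen's default plate layout.

    Blank wells fill columns 1 and 24 (32 wells). The four repeated-control
    roles occupy columns 3 and 22, five wells each; the exact positions were
    hand-plated and unrecorded, so the default places them deterministically,
    interleaving the four roles down the paired control columns
    (A3=sicont, A22=si_target, B3=si_lethal, B22=si_probe, C3=sicont, ...)
    until each role has five wells; the remaining 12 control-column positions
    are ``empty``. All other wells (320) are samples.

    Pass ``control_positions`` to override the control placement.
    """
    role_map: dict[tuple[str, int], WellRole] = {}
    for row in ROWS:
        for col in range(1, N_COLS + 1):
            if col in BLANK_COLUMNS:
                role_map[(row, col)] = WellRole.blank
            elif col in CONTROL_COLUMNS:
                role_map[(row, col)] = WellRole.empty
            else:
                role_map[(row, col)] = WellRole.sample

    if control_positions is None:
        slots = [(row, col) for row in ROWS for col in CONTROL_COLUMNS]
        cycle = list(CONTROL_ROLES)
        for i in range(5 * len(cycle)):
            role_map[slots[i]] = cycle[i % len(cycle)]
    else:
        for role, positions in control_positions.items():
            for pos in positions:
                if pos[1] not in CONTROL_COLUMNS:
                    raise IntegrityError(
                        f"control well {pos} outside control columns {CONTROL_COLUMNS}"
                    )
                role_map[tuple(pos)] = role

    counts = {
        WellRole.blank: 32,
        WellRole.sicont: 5,
        WellRole.si_target: 5,
        WellRole.si_lethal: 5,
        WellRole.si_probe: 5,
        WellRole.sample: 320,
        WellRole.empty: 12,
    }
    return PlateLayout(role_map=role_map, control_counts=counts)


@dataclass(frozen=True)
class BatchMap:
    """Assignment of plates to experimental batches.

    Every plate belongs to exactly one batch.
    """

    batches: Mapping[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        seen: dict[int, int] = {}
        for batch_id, plates in self.batches.items():
            for p in plates:
                if p in seen:
                    raise IntegrityError(
                        f"plate {p} assigned to batches {seen[p]} and {batch_id}"
                    )
                seen[p] = batch_id

    @property
    def plate_to_batch(self) -> dict[int, int]:
        return {
            p: b for b, plates in self.batches.items() for p in plates
        }

    def batch_of(self, plate_id: int) -> int:
        try:
            return self.plate_to_batch[plate_id]
        except KeyError:
            raise AssignmentError(
                f"plate {plate_id} is not assigned to any batch"
            ) from None

    def to_json(self) -> str:
        return json.dumps(
            {str(b): list(p) for b, p in sorted(self.batches.items())}, indent=1
        )

    @classmethod
    def from_json(cls, text: str) -> "BatchMap":
        raw = json.loads(text)
        return cls({int(b): tuple(int(p) for p in ps) for b, ps in raw.items()})


def default_batch_map() -> BatchMap:
    """The deposited screen's batch→plate mapping (seven transfection batches)."""
    return BatchMap(
        {
            1: (1, 2, 3, 4, 5, 20, 21, 22),
            2: (6, 7, 8, 9, 10, 11, 12, 13),
            3: (14, 15, 16, 17, 18, 19, 23, 24),
            4: (25, 26, 27, 28, 29, 30, 31, 32),
            5: (33, 34, 35, 36, 37, 38, 39, 40),
            6: (41, 42, 43, 44),
            7: (66, 67),
        }
    )


def batch_map_for_plates(plate_ids: Sequence[int], plates_per_batch: int) -> BatchMap:
    """Chunk ``plate_ids`` into consecutive batches of ``plates_per_batch``."""
    if plates_per_batch < 1:
        raise IntegrityError("plates_per_batch must be >= 1")
    plates = list(plate_ids)
    batches = {
        i + 1: tuple(plates[i * plates_per_batch : (i + 1) * plates_per_batch])
        for i in range((len(plates) + plates_per_batch - 1) // plates_per_batch)
    }
    return BatchMap(batches)
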