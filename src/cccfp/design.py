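"""Factorial experimental design for copper-chloride-crystallisation runs.

The Verum experiment crosses six experimental days with two crystallisation
chambers (each chamber carrying one production batch), six samples per
chamber (host tree x blending procedure) and four technical replicates per
sample, for 288 fingerprints in total.  The mistletoe subspecies is not a
free factor: it is biologically determined by the host tree (pine hosts
carry subsp. austriacum, deciduous hosts carry subsp. album).

This module is the single source of truth for plate enumeration; every
downstream stage (synthesis, features, randomisation, statistics) consumes
the :class:`DesignTable` it produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints
    from .randomise import ChamberLayout, RotationPlan

HOST_TREES = ("apple", "oak", "pine")
BLENDINGS = ("machine", "hand")
BATCHES = (2109, 2204)

#: fixed chamber -> batch mapping: each chamber carries exactly one batch
CHAMBER_BATCH = {1: 2109, 2: 2204}

#: the six samples crystallised per chamber per day
SAMPLES = tuple((h, b) for h in HOST_TREES for b in BLENDINGS)

N_REPLICATES = 4

DESIGN_COLUMNS = [
    "plate_id",
    "day",
    "batch",
    "chamber",
    "host_tree",
    "blending",
    "subspecies",
    "block",
    "allocation",
    "replicate",
]


class DesignError(ValueError):
    """Raised when a design constraint is violated."""


def derive_subspecies(host_tree: str) -> str:
    """Map a host tree to the mistletoe subspecies growing on it.

    Subsp. album (VAA) is bound to deciduous hosts (apple, oak);
    subsp. austriacum (VAAu) is bound to pine.
    """
    if host_tree in ("apple", "oak"):
        return "VAA"
    if host_tree == "pine":
        return "VAAu"
    raise DesignError(f"unknown host tree: {host_tree!r}")


@dataclass(frozen=True)
class FactorLevels:
    """Factor levels of a single plate; subspecies is derived, not free."""

    day: int
    batch: int
    chamber: int
    host_tree: str
    blending: str
    subspecies: str = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= self.day:
            raise DesignError(f"day must be >= 1, got {self.day}")
        if self.batch not in BATCHES:
            raise DesignError(f"unknown batch {self.batch}")
        if self.chamber not in CHAMBER_BATCH:
            raise DesignError(f"unknown chamber {self.chamber}")
        if CHAMBER_BATCH[self.chamber] != self.batch:
            raise DesignError(
                f"chamber {self.chamber} carries batch "
                f"{CHAMBER_BATCH[self.chamber]}, not {self.batch}"
            )
        if self.blending not in BLENDINGS:
            raise DesignError(f"unknown blending {self.blending!r}")
        object.__setattr__(self, "subspecies", derive_subspecies(self.host_tree))


@dataclass(frozen=True)
class PlateRecord:
    """One fingerprint's factor levels and provenance."""

    plate_id: str
    factors: FactorLevels
    block: int
    allocation: int
    replicate: int

    def as_row(self) -> dict:
        f = self.factors
        return {
            "plate_id": self.plate_id,
            "day": f.day,
            "batch": f.batch,
            "chamber": f.chamber,
            "host_tree": f.host_tree,
            "blending": f.blending,
            "subspecies": f.subspecies,
            "block": self.block,
            "allocation": self.allocation,
            "replicate": self.replicate,
        }


class DesignTable:
    """Ordered collection of plate records, with pandas interchange.

    Parameters
    ----------
    frame : pandas.DataFrame
        Must carry the columns in :data:`DESIGN_COLUMNS`.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)[DESIGN_COLUMNS].copy()

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield PlateRecord(
                plate_id=row.plate_id,
                factors=FactorLevels(
                    day=int(row.day),
                    batch=int(row.batch),
                    chamber=int(row.chamber),
                    host_tree=row.host_tree,
                    blending=row.blending,
                ),
                block=int(row.block),
                allocation=int(row.allocation),
                replicate=int(row.replicate),
            )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DesignTable":
        return cls(pd.read_csv(path))

    def validate(self) -> None:
        """Check balance invariants: 4 replicates per (day, chamber, sample),
        allocations unique within (day, chamber), subspecies consistent."""
        df = self.frame
        derived = df["host_tree"].map(derive_subspecies)
        if not (derived == df["subspecies"]).all():
            raise DesignError("subspecies inconsistent with host tree")
        if len(df) == 0:
            return
        counts = df.groupby(["day", "chamber", "host_tree", "blending"]).size()
        if not (counts == N_REPLICATES).all():
            raise DesignError("expected exactly 4 replicates per (day, chamber, sample)")
        dup = df.duplicated(subset=["day", "chamber", "allocation"])
        if dup.any():
            raise DesignError("allocation indices not unique within (day, chamber)")


def build_verum_design(
    n_days: int,
    layout: "ChamberLayout | None" = None,
    rotation: "RotationPlan | None" = None,
    scheme_blocks: "dict[int, list[list[int]]] | None" = None,
) -> DesignTable:
    """Enumerate the complete balanced Verum design.

    Per day each chamber crystallises 6 samples (host tree x blending) in
    4 replicates: 48 fingerprints per day, 288 over the standard six days.

    Parameters
    ----------
    n_days : int
        Number of experimental days (standard run: 6).
    layout : ChamberLayout, optional
        Physical chamber layout; defaults to the standard 43-position
        two-ring layout with the first 24 used positions.
    rotation : RotationPlan, optional
        Day x sample -> block Latin square. Defaults to the cyclic plan.
        Must cover ``n_days`` days and be a bijection sample<->block on
        every day.
    scheme_blocks : dict, optional
        Per-chamber block -> allocation-position mapping (6 blocks of 4
        positions). Defaults to consecutive groups of the layout's used
        positions.
    """
    from .randomise import ChamberLayout, RotationPlan  # local: avoid cycle

    if n_days < 0:
        raise DesignError("n_days must be non-negative")
    if layout is None:
        layout = ChamberLayout.standard()
    if rotation is None:
        rotation = RotationPlan.cyclic(max(n_days, 1))
    if rotation.n_days < n_days:
        raise DesignError(
            f"rotation covers {rotation.n_days} days, need {n_days}"
        )
    if scheme_blocks is None:
        used = layout.used_positions
        blocks = [list(used[i * 4 : (i + 1) * 4]) for i in range(6)]
        scheme_blocks = {1: blocks, 2: [list(b) for b in blocks]}

    rows = []
    for day in range(1, n_days + 1):
        assigned = rotation.blocks_for_day(day)  # sample index -> block
        if sorted(assigned) != list(range(1, 7)):
            raise DesignError(
                f"rotation on day {day} is not a bijection sample<->block"
            )
        for chamber, batch in CHAMBER_BATCH.items():
            for s_idx, (host, blend) in enumerate(SAMPLES):
                block = assigned[s_idx]
                positions = scheme_blocks[chamber][block - 1]
                if len(positions) != N_REPLICATES:
                    raise DesignError("each block must hold 4 allocations")
                for rep, pos in enumerate(positions, start=1):
                    levels = FactorLevels(
                        day=day, batch=batch, chamber=chamber,
                        host_tree=host, blending=blend,
                    )
                    rows.append(
                        PlateRecord(
                            plate_id=f"d{day}c{chamber}{host[0]}{blend[0]}r{rep}",
                            factors=levels,
                            block=block,
                            allocation=int(pos),
                            replicate=rep,
                        ).as_row()
                    )
    frame = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    table = DesignTable(frame)
    table.validate()
    return table


#: the three sensitivity tests and the contrast of interest for each:
#: (factor column, level_a, level_b); Cohen's d is mean(a) - mean(b).
SENSITIVITY_TESTS = {
    "subspecies": ("subspecies", "VAA", "VAAu"),
    "deciduous": ("host_tree", "apple", "oak"),
    "blending": ("blending", "machine", "hand"),
}


def sensitivity_subset(design: DesignTable, test_id: str) -> tuple[DesignTable, dict]:
    """Select the rows and the four ANOVA factors for one sensitivity test.

    - ``subspecies``: all plates; apple+oak pooled (VAA) vs pine (VAAu).
    - ``deciduous``: subsp. album plates only (apple vs oak); pine excluded.
    - ``blending``: all plates; machine vs hand, host tree kept as a factor.

    Returns the subset plus a factor specification: the four independent
    parameters, the factor of interest and its two contrast levels.
    """
    if test_id not in SENSITIVITY_TESTS:
        raise DesignError(f"unknown sensitivity test {test_id!r}")
    factor, level_a, level_b = SENSITIVITY_TESTS[test_id]
    df = design.frame
    if test_id == "deciduous":
        df = df[df["subspecies"] == "VAA"]
    factors = ["day", "batch", "blending", factor]
    if test_id == "blending":
        factors = ["day", "batch", "host_tree", "blending"]
    spec = {
        "test_id": test_id,
        "factors": factors,
        "factor_of_interest": factor,
        "contrast": (level_a, level_b),
    }
    return DesignTable(df), spec
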