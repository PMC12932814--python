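"""Systematic-control-driven block randomisation.

Before the blinded Verum runs, systematic-control (SC) experiments fill
every chamber position with one and the same extract.  The per-position
measurements, normalised to the day mean, drive a constrained search:
random partitions of the used positions into six blocks of four are scored
by the dispersion of the block means, and the best-scoring partition that
shows no significant position effect (one-way ANOVA across blocks) becomes
the chamber's randomisation scheme.  A Latin-square rotation then moves
every sample through every block over the six experimental days, so that
residual position effects cancel by counterbalancing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

N_BLOCKS = 6
BLOCK_SIZE = 4
N_POSITIONS = 43
N_USED = N_BLOCKS * BLOCK_SIZE


class RandomisationError(ValueError):
    pass


@dataclass(frozen=True)
class ChamberLayout:
    """Physical plate positions of one crystallisation chamber.

    43 allocation slots arranged in two concentric rings.  Only 24 of them
    are used in a Verum run; which 24 is configurable because the original
    assignment is a property of the laboratory, not of the method.
    """

    ring_labels: tuple = ()
    used_positions: tuple = ()

    @classmethod
    def standard(cls, inner: int = 18, used: "tuple | None" = None) -> "ChamberLayout":
        """Two rings (default 18 inner + 25 outer = 43 slots); the used
        subset defaults to the first 24 positions."""
        if used is None:
            used = tuple(range(1, N_USED + 1))
        labels = tuple(
            "inner" if i <= inner else "outer" for i in range(1, N_POSITIONS + 1)
        )
        return cls(ring_labels=labels, used_positions=tuple(used))

    def __post_init__(self):
        if self.ring_labels and len(self.ring_labels) != N_POSITIONS:
            raise RandomisationError(f"layout must have exactly {N_POSITIONS} positions")
        if self.used_positions and len(self.used_positions) != N_USED:
            raise RandomisationError(f"exactly {N_USED} used positions required")

    @property
    def n_positions(self) -> int:
        return len(self.ring_labels)


@dataclass(frozen=True)
class RandomisationScheme:
    """Assignment of the 24 used positions to 6 disjoint blocks of 4."""

    chamber: int
    blocks: tuple  # 6 tuples of 4 position indices
    score: float
    anova_p: dict = field(default_factory=dict)
    seed: "int | None" = None
    n_candidates: "int | None" = None

    def __post_init__(self):
        if len(self.blocks) != N_BLOCKS:
            raise RandomisationError("scheme must have 6 blocks")
        flat = [p for b in self.blocks for p in b]
        if any(len(b) != BLOCK_SIZE for b in self.blocks):
            raise RandomisationError("each block must hold 4 positions")
        if len(set(flat)) != len(flat):
            raise RandomisationError("blocks must be disjoint")

    def to_json(self, path) -> None:
        doc = {
            "chamber": self.chamber,
            "blocks": [list(map(int, b)) for b in self.blocks],
            "score": float(self.score),
            "anova_p": {k: float(v) for k, v in self.anova_p.items()},
            "seed": self.seed,
            "n_candidates": self.n_candidates,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RandomisationScheme":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            chamber=doc["chamber"],
            blocks=tuple(tuple(b) for b in doc["blocks"]),
            score=doc["score"],
            anova_p=doc.get("anova_p", {}),
            seed=doc.get("seed"),
            n_candidates=doc.get("n_candidates"),
        )


@dataclass(frozen=True)
class RotationPlan:
    """Day x sample -> block Latin square (complete counterbalancing)."""

    table: tuple  # n_days rows, each a tuple of 6 block ids (per sample)

    @property
    def n_days(self) -> int:
        return len(self.table)

    @classmethod
    def cyclic(cls, n_days: int = 6) -> "RotationPlan":
        return cls(
            table=tuple(
                tuple((d + s) % N_BLOCKS + 1 for s in range(N_BLOCKS))
                for d in range(n_days)
            )
        )

    def blocks_for_day(self, day: int) -> tuple:
        return self.table[day - 1]

    def validate_latin(self) -> None:
        if self.n_days != N_BLOCKS:
            raise RandomisationError("complete counterbalancing needs 6 days")
        arr = np.asarray(self.table)
        for axis, what in ((0, "sample"), (1, "day")):
            uniq = np.apply_along_axis(lambda v: len(set(v)), axis, arr)
            if not (uniq == N_BLOCKS).all():
                raise RandomisationError(f"not a Latin square along {what} axis")


def normalise_day_mean(sc_table: pd.DataFrame, variables: "list[str] | None" = None,
                       day_col: str = "day") -> pd.DataFrame:
    """Divide each measurement by its (variable, day) mean.

    Makes variables with different scales commensurable across days: the
    per-day per-variable mean of the output is exactly 1.
    """
    if variables is None:
        variables = [c for c in sc_table.columns
                     if c not in (day_col, "position", "chamber", "plate_id")
                     and pd.api.types.is_numeric_dtype(sc_table[c])]
    out = sc_table.copy()
    for var in variables:
        means = sc_table.groupby(day_col)[var].transform("mean")
        bad = means == 0
        if bad.any():
            day = sc_table.loc[bad, day_col].iloc[0]
            raise RandomisationError(
                f"zero day mean for variable {var!r} on day {day}"
            )
        out[var] = sc_table[var] / means
    return out


def _score_partitions(values: np.ndarray, partitions: np.ndarray,
                      aggregate: str = "mean") -> np.ndarray:
    """Score candidate partitions by the dispersion of block means.

    values : (n_positions, n_variables) normalised SC data.
    partitions : (n_candidates, 24) row indices into values, each row a
        permutation; consecutive groups of 4 form the 6 blocks.
    Score = mean (or max) over variables of the SD of the 6 block means.
    """
    n_cand = partitions.shape[0]
    grouped = values[partitions].reshape(n_cand, N_BLOCKS, BLOCK_SIZE, -1)
    block_means = grouped.mean(axis=2)               # (cand, 6, vars)
    sds = block_means.std(axis=1, ddof=1)            # (cand, vars)
    if aggregate == "max":
        return sds.max(axis=1)
    return sds.mean(axis=1)


def search_schemes(
    sc_table: pd.DataFrame,
    layout: ChamberLayout,
    n_candidates: int = 2_000_000,
    seed: "int | None" = None,
    variables: "list[str] | None" = None,
    normalise: bool = True,
    aggregate: str = "mean",
    chamber: int = 1,
    batch_size: int = 100_000,
) -> list:
    """Generate random 6x4 partitions of the used positions and rank them.

    Candidates are scored ascending by the dispersion of block means on
    day-mean-normalised SC data; deterministic for a fixed seed.  Returns
    ``(score, blocks)`` pairs sorted ascending; ties keep generation order.
    """
    if n_candidates < 1:
        raise RandomisationError("n_candidates must be >= 1")
    used = list(layout.used_positions)
    if variables is None:
        variables = [c for c in sc_table.columns
                     if c not in ("day", "position", "chamber", "plate_id")
                     and pd.api.types.is_numeric_dtype(sc_table[c])]
    if normalise and "day" in sc_table.columns:
        sc_table = normalise_day_mean(sc_table, variables)
    per_pos = sc_table.groupby("position")[variables].mean()
    missing = set(used) - set(per_pos.index)
    if missing:
        raise RandomisationError(f"SC data missing positions: {sorted(missing)}")
    values = per_pos.loc[used].to_numpy(float)

    rng = np.random.default_rng(seed)
    best: list = []
    produced = 0
    while produced < n_candidates:
        m = min(batch_size, n_candidates - produced)
        perms = np.argsort(rng.random((m, N_USED)), axis=1)
        scores = _score_partitions(values, perms, aggregate)
        for s, p in zip(scores, perms):
            blocks = tuple(
                tuple(used[i] for i in p[k * BLOCK_SIZE:(k + 1) * BLOCK_SIZE])
                for k in range(N_BLOCKS)
            )
            best.append((float(s), produced, blocks))
            produced += 1
        # keep memory bounded: retain the 1000 best-scoring candidates
        best.sort(key=lambda t: (t[0], t[1]))
        best = best[:1000]
    return [(s, blocks) for s, _, blocks in best]


def select_scheme(
    candidates: list,
    sc_table: pd.DataFrame,
    alpha: float = 0.05,
    variables: "list[str] | None" = None,
    normalise: bool = True,
    chamber: int = 1,
    seed: "int | None" = None,
    n_candidates: "int | None" = None,
) -> RandomisationScheme:
    """Pick the best-scoring candidate with no significant position effect.

    For each candidate in rank order, a one-way ANOVA of every SC variable
    across the six blocks must give p > alpha; the first candidate passing
    for all variables is returned with its per-variable p-values recorded.
    ``alpha = 0`` disables the filter (every p > 0 passes).
    """
    if not candidates:
        raise RandomisationError("no candidate schemes supplied")
    if variables is None:
        variables = [c for c in sc_table.columns
                     if c not in ("day", "position", "chamber", "plate_id")
                     and pd.api.types.is_numeric_dtype(sc_table[c])]
    if normalise and "day" in sc_table.columns:
        sc_table = normalise_day_mean(sc_table, variables)
    per_pos = sc_table.groupby("position")[variables].mean()

    best_p: dict = {}
    for score, blocks in candidates:
        pvals = {}
        ok = True
        for var in variables:
            groups = [per_pos.loc[list(b), var].to_numpy() for b in blocks]
            if np.ptp(np.concatenate(groups)) == 0:
                pvals[var] = 1.0  # constant data: no position effect
                continue
            _, p = sps.f_oneway(*groups)
            p = 1.0 if np.isnan(p) else float(p)
            pvals[var] = p
            if p <= alpha:
                ok = False
        if not best_p or min(pvals.values()) > min(best_p.values()):
            best_p = pvals
        if ok:
            return RandomisationScheme(
                chamber=chamber, blocks=blocks, score=score, anova_p=pvals,
                seed=seed, n_candidates=n_candidates,
            )
    raise RandomisationError(
        f"no candidate passed the location check at alpha={alpha}; "
        f"best per-variable p-values: {best_p}"
    )


def build_rotation(scheme: "RandomisationScheme | None" = None, n_days: int = 6,
                   seed: "int | None" = None) -> RotationPlan:
    """Random 6x6 Latin square: each sample meets each block exactly once.

    Built by permuting the rows, columns and symbols of the cyclic square;
    deterministic per seed.
    """
    if n_days != N_BLOCKS:
        raise RandomisationError("complete counterbalancing needs 6 days")
    rng = np.random.default_rng(seed)
    base = np.array([[(d + s) % N_BLOCKS for s in range(N_BLOCKS)]
                     for d in range(N_BLOCKS)])
    base = base[rng.permutation(N_BLOCKS)][:, rng.permutation(N_BLOCKS)]
    relabel = rng.permutation(N_BLOCKS)
    square = relabel[base] + 1
    plan = RotationPlan(table=tuple(tuple(int(x) for x in row) for row in square))
    plan.validate_latin()
    return plan
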