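"""PGSE acquisition schemes for kidney VERDICT-MRI.

An acquisition scheme is an ordered list of (b, delta, Delta, TE) combinations.
Each combo is acquired in three orthogonal gradient directions that are later
spherically averaged, and each combo has a matched b=0 volume at the same echo
time so that dividing by it cancels T2 decay.

Units at the interface: b in s/mm^2, delta / Delta / TE in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Combo",
    "AcquisitionScheme",
    "MeasurementTable",
    "SchemeError",
    "kidney_full_protocol",
    "load_scheme",
    "save_scheme",
    "expand_measurements",
]


class SchemeError(ValueError):
    """Raised for malformed or physically invalid acquisition schemes."""


@dataclass(frozen=True)
class Combo:
    """One b/delta/Delta/TE combination.

    b : diffusion weighting, s/mm^2
    delta : gradient pulse duration, ms
    Delta : gradient pulse separation, ms
    te : echo time, ms
    """

    b: float
    delta: float
    Delta: float
    te: float

    def validate(self) -> None:
        if self.b < 0:
            raise SchemeError(f"b must be >= 0, got {self.b}")
        if not (self.delta < self.Delta):
            raise SchemeError(
                f"delta must be < Delta, got delta={self.delta}, Delta={self.Delta}"
            )
        if self.te < self.Delta + self.delta:
            raise SchemeError(
                f"TE must be >= Delta + delta, got TE={self.te}, "
                f"Delta+delta={self.Delta + self.delta}"
            )


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered PGSE scheme: unique (b, delta, Delta) combos, 3 directions each,
    one matched b0 per combo."""

    combos: tuple[Combo, ...]
    n_directions: int = 3
    has_matched_b0: bool = True

    def __post_init__(self) -> None:
        if len(self.combos) == 0:
            raise SchemeError("no combos")
        seen = set()
        for c in self.combos:
            c.validate()
            key = (c.b, c.delta, c.Delta)
            if key in seen:
                raise SchemeError(f"duplicate combo {key}")
            seen.add(key)
        if self.n_directions < 1:
            raise SchemeError("n_directions must be >= 1")

    @property
    def n_combos(self) -> int:
        return len(self.combos)

    @property
    def b_values(self) -> np.ndarray:
        return np.array([c.b for c in self.combos], dtype=float)

    @property
    def deltas(self) -> np.ndarray:
        return np.array([c.delta for c in self.combos], dtype=float)

    @property
    def Deltas(self) -> np.ndarray:
        return np.array([c.Delta for c in self.combos], dtype=float)

    @property
    def tes(self) -> np.ndarray:
        return np.array([c.te for c in self.combos], dtype=float)

    @property
    def n_volumes(self) -> int:
        """Spherically-averaged DW volume + matched b0 per combo."""
        per_combo = 2 if self.has_matched_b0 else 1
        return per_combo * self.n_combos

    def subset(self, b_values: Iterable[float]) -> "AcquisitionScheme":
        """Sub-scheme restricted to the given b-values (matched b0s retained)."""
        wanted = set(float(b) for b in b_values)
        known = set(self.b_values.tolist())
        unknown = wanted - known
        if unknown:
            raise SchemeError(f"b-values not in scheme: {sorted(unknown)}")
        kept = tuple(c for c in self.combos if c.b in wanted)
        return AcquisitionScheme(kept, self.n_directions, self.has_matched_b0)


@dataclass(frozen=True)
class MeasurementTable:
    """Direction-resolved measurement bookkeeping for a scheme.

    rows: (combo_index, direction_index, is_b0). b0 rows carry direction -1.
    """

    rows: tuple[tuple[int, int, bool], ...]
    n_combos: int
    n_directions: int

    @property
    def n_dw_measurements(self) -> int:
        return sum(1 for _, _, is_b0 in self.rows if not is_b0)

    @property
    def n_b0(self) -> int:
        return sum(1 for _, _, is_b0 in self.rows if is_b0)

    @property
    def n_volumes(self) -> int:
        """One spherically-averaged DW volume per combo plus its matched b0."""
        return self.n_combos + self.n_b0

    def dw_combo_index(self) -> np.ndarray:
        """Combo index for each DW row, in row order (length n_dw_measurements)."""
        return np.array([c for c, _, is_b0 in self.rows if not is_b0], dtype=int)


# printed kidney protocol: nine b/delta/Delta combos, minimum TE per combo
_KIDNEY_B = [70.0, 90.0, 150.0, 500.0, 1000.0, 1500.0, 2000.0, 2200.0, 2500.0]
_KIDNEY_DELTA = [4.8, 4.8, 4.8, 12.0, 12.0, 26.3, 16.8, 16.8, 21.4]
_KIDNEY_DELTA_BIG = [27.0, 27.0, 27.0, 34.0, 34.0, 47.0, 37.5, 37.5, 43.5]
# per-combo TE: the acquisition used the minimum TE per combo, spanning 54-87 ms;
# per-combo values are not printed, so minimum feasible values on that span are
# interpolated from the encoding duration (unused by the normalised models).
_KIDNEY_TE = [54.0, 54.0, 54.0, 62.0, 62.0, 87.0, 68.0, 68.0, 78.0]


def kidney_full_protocol() -> AcquisitionScheme:
    """The full 9-combo kidney protocol, ascending b, 3 directions per combo."""
    combos = tuple(
        Combo(b, d, D, te)
        for b, d, D, te in zip(_KIDNEY_B, _KIDNEY_DELTA, _KIDNEY_DELTA_BIG, _KIDNEY_TE)
    )
    return AcquisitionScheme(combos)


def expand_measurements(scheme: AcquisitionScheme) -> MeasurementTable:
    """Expand a scheme into direction-resolved rows, order-preserving over combos."""
    rows: list[tuple[int, int, bool]] = []
    for i in range(scheme.n_combos):
        if scheme.has_matched_b0:
            rows.append((i, -1, True))
        for d in range(scheme.n_directions):
            rows.append((i, d, False))
    return MeasurementTable(tuple(rows), scheme.n_combos, scheme.n_directions)


_HEADER = "# b(s/mm^2) delta(ms) Delta(ms) TE(ms) n_directions"


def save_scheme(scheme: AcquisitionScheme, path: str | Path) -> None:
    """Write a scheme as a whitespace table, one row per combo."""
    lines = [_HEADER]
    for c in scheme.combos:
        lines.append(
            f"{c.b:g} {c.delta:g} {c.Delta:g} {c.te:g} {scheme.n_directions:d}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_scheme(path: str | Path) -> AcquisitionScheme:
    """Parse a whitespace scheme table: b delta Delta TE n_directions per row."""
    path = Path(path)
    combos: list[Combo] = []
    n_dirs: set[int] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise SchemeError(
                f"{path}:{lineno}: expected 5 fields (b delta Delta TE n_directions), "
                f"got {len(parts)}"
            )
        try:
            b, delta, Delta, te = (float(p) for p in parts[:4])
            nd = int(parts[4])
        except ValueError as exc:
            raise SchemeError(f"{path}:{lineno}: unparseable row: {raw!r}") from exc
        combos.append(Combo(b, delta, Delta, te))
        n_dirs.add(nd)
    if not combos:
        raise SchemeError(f"{path}: no combos")
    if len(n_dirs) > 1:
        raise SchemeError(f"{path}: inconsistent n_directions across rows: {n_dirs}")
    return AcquisitionScheme(tuple(combos), n_directions=n_dirs.pop())
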