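"""Abridged age grids.

Mortality data here live on an abridged grid: an infant group, an early
childhood group, five-year bands, and a single open-ended terminal group
(default ``<1, 1-4, 5-9, ..., 80-84, 85+`` — 19 groups).  The grid owns
the exact lower bounds, interval widths and the canonical string labels
used in every CSV this package reads or writes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

DEFAULT_LOWER_BOUNDS: tuple[float, ...] = (0.0, 1.0) + tuple(
    float(x) for x in range(5, 90, 5)
)


@dataclass(frozen=True)
class AgeGrid:
    """An ordered set of abridged age groups; the last group is open-ended.

    Parameters
    ----------
    lower_bounds:
        Strictly increasing exact ages in years.  The interval *i* runs
        from ``lower_bounds[i]`` to ``lower_bounds[i+1]``; the final
        interval is open (width ``inf``).
    """

    lower_bounds: tuple[float, ...] = DEFAULT_LOWER_BOUNDS
    _labels: tuple[str, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lb = tuple(float(x) for x in self.lower_bounds)
        if len(lb) < 1:
            raise ValidationError("age grid needs at least one group")
        if any(b <= a for a, b in zip(lb, lb[1:])):
            raise ValidationError("age grid lower bounds must be strictly increasing")
        object.__setattr__(self, "lower_bounds", lb)
        object.__setattr__(self, "_labels", tuple(self._make_label(i) for i in range(len(lb))))

    def _make_label(self, i: int) -> str:
        lo = self.lower_bounds[i]
        if i == len(self.lower_bounds) - 1:
            return f"{lo:g}+"
        hi = self.lower_bounds[i + 1]
        if hi - lo == 1.0:
            return "<1" if lo == 0.0 else f"{lo:g}"
        return f"{lo:g}-{hi - 1:g}"

    # -- basic geometry -------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.lower_bounds)

    @property
    def widths(self) -> np.ndarray:
        """Interval widths in years; the open interval has width ``inf``."""
        lb = np.asarray(self.lower_bounds)
        return np.append(np.diff(lb), math.inf)

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    def midpoints(self, open_interval_offset: float = 5.0) -> np.ndarray:
        """Interval midpoints; the open interval uses ``lower + offset``
        as a proxy midpoint (no upper bound exists)."""
        lb = np.asarray(self.lower_bounds)
        mids = np.append((lb[:-1] + lb[1:]) / 2.0, lb[-1] + open_interval_offset)
        return mids

    # -- label handling -------------------------------------------------
    def index_of(self, label: str) -> int:
        """Index of an age-group label such as ``"<1"``, ``"1-4"`` or ``"85+"``."""
        try:
            return self._labels.index(label)
        except ValueError:
            raise ValidationError(
                f"unparseable age-group label {label!r}; expected one of {list(self._labels)}"
            ) from None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_groups


def default_grid() -> AgeGrid:
    """The 19-group abridged grid ``<1, 1-4, 5-9, ..., 80-84, 85+``."""
    return AgeGrid(DEFAULT_LOWER_BOUNDS)
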