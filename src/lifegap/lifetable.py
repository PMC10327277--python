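"""Abridged period life tables, life expectancy and the e† disparity index.

The table is built from age-specific all-cause death rates ``m`` on an
abridged grid with the standard conversion

    q_i = n_i * m_i / (1 + (n_i - a_i) * m_i)

for closed intervals (capped at 1), where ``a_i`` is the average number
of years lived within the interval by those dying in it.  The terminal
open interval uses the constant-hazard rule: q = 1, L = l / m, e = 1 / m.

Life disparity e† ("e-dagger") is the average remaining life expectancy
at the ages people die — equivalently the average years of life lost per
death.  On an abridged grid the remaining expectancy of interval deaths
is evaluated at the interval's mean age at death ``x_i + a_i`` by linear
interpolation of e between the interval endpoints; under a constant
hazard mu this reproduces the continuous closed form e0 = e† = 1/mu.

All internal computations are vectorised over an optional leading batch
axis so that the decomposition engine can evaluate thousands of
perturbed rate schedules cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agegrid import AgeGrid
from .errors import ValidationError

#: Andreev–Kingkade coefficients for the mean age at death in infancy
#: (a0) as a piecewise-linear function of the infant death rate m0;
#: (threshold, intercept, slope) triples per sex.
_AK_COEFFS = {
    "male": ((0.02300, 0.14929, -1.99545), (0.08307, 0.02832, 3.26021), (np.inf, 0.29915, 0.0)),
    "female": ((0.01724, 0.14903, -2.05527), (0.06891, 0.04667, 3.88089), (np.inf, 0.31411, 0.0)),
}


def infant_separation_factor(m0, sex: str | None = None):
    """Average years lived in the first year of life by infants who die
    (a0), from the infant death rate via the Andreev–Kingkade rule.

    Vectorised over ``m0``.  Without a sex hint the male and female rule
    values are averaged.
    """
    if sex is None:
        return 0.5 * (
            infant_separation_factor(m0, "male") + infant_separation_factor(m0, "female")
        )
    m0 = np.asarray(m0, dtype=float)
    (t1, b1, s1), (t2, b2, s2), (_, b3, s3) = _AK_COEFFS[sex]
    out = np.where(m0 < t1, b1 + s1 * m0, np.where(m0 < t2, b2 + s2 * m0, b3 + s3 * m0))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AbridgedLifeTable:
    """A period life table on an abridged age grid (radix-normalised).

    Columns per age group: interval width ``n``, death rate ``m``,
    within-interval mean years lived by decedents ``a``, death
    probability ``q``, survivors at exact age ``l``, interval deaths
    ``d``, person-years ``L``, person-years above the age ``T`` and
    remaining expectancy ``e``.
    """

    grid: AgeGrid
    n: np.ndarray
    m: np.ndarray
    a: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    radix: float = 1.0

    def to_frame(self, decimals: int | None = 6) -> pd.DataFrame:
        """All nine columns, one row per age group."""
        df = pd.DataFrame(
            {
                "age_group": self.grid.labels,
                "n": self.n,
                "m": self.m,
                "a": self.a,
                "q": self.q,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
            }
        )
        if decimals is not None:
            num = df.columns.drop("age_group")
            df[num] = df[num].round(decimals)
        return df


def _lifetable_arrays(
    m: np.ndarray, n: np.ndarray, a: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Core recursion, vectorised over leading axes of ``m``.

    ``m`` has shape (..., G); ``n`` and ``a`` shape (G,).  The last
    interval is open: n[-1] is inf and a[-1] is ignored.  Returns
    (q, l, d, L, T, e) with l at radix 1.
    """
    m = np.asarray(m, dtype=float)
    G = m.shape[-1]
    q = np.empty_like(m)
    nc, ac = n[:-1], a[:-1]
    with np.errstate(invalid="ignore"):
        q[..., :-1] = np.clip(
            nc * m[..., :-1] / (1.0 + (nc - ac) * m[..., :-1]), 0.0, 1.0
        )
    q[..., -1] = 1.0

    surv = np.cumprod(1.0 - q, axis=-1)
    l = np.concatenate(
        [np.ones_like(m[..., :1]), np.maximum(surv[..., :-1], 0.0)], axis=-1
    )
    d = l * q

    L = np.empty_like(m)
    l_next = l[..., 1:]
    L[..., :-1] = nc * l_next + ac * d[..., :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        L[..., -1] = np.where(l[..., -1] > 0, l[..., -1] / m[..., -1], 0.0)
    # q=1 in a closed interval leaves l_next = 0 and L = a*d, already valid.

    T = np.flip(np.cumsum(np.flip(L, axis=-1), axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)
    return q, l, d, L, T, e


def _edagger_from_arrays(
    d: np.ndarray, e: np.ndarray, n: np.ndarray, a: np.ndarray
) -> np.ndarray:
    """e† = sum_i d_i * ebar_i (radix 1), ebar_i the remaining expectancy
    at the interval's mean age at death x_i + a_i (linear interpolation
    of e for closed intervals; e itself for the open interval)."""
    frac = a[:-1] / n[:-1]
    ebar_closed = (1.0 - frac) * e[..., :-1] + frac * e[..., 1:]
    contrib = d[..., :-1] * ebar_closed
    return contrib.sum(axis=-1) + d[..., -1] * e[..., -1]


def _resolve_a(
    m: np.ndarray,
    grid: AgeGrid,
    a_convention: str | np.ndarray = "midpoint",
    a0: float | str = "andreev-kingkade",
    sex: str | None = None,
) -> np.ndarray:
    """Within-interval survivorship parameters a_i.

    ``a_convention`` may be an explicit vector, or ``"midpoint"``:
    a = n/2 in all closed intervals except infancy, where ``a0`` is
    either the Andreev–Kingkade rule on m0 or an explicit constant.
    """
    widths = grid.widths
    if isinstance(a_convention, (list, tuple, np.ndarray)):
        a = np.asarray(a_convention, dtype=float)
        if a.shape != (grid.n_groups,):
            raise ValidationError("explicit a vector has wrong length")
        return a
    if a_convention != "midpoint":
        raise ValidationError(f"unknown a convention {a_convention!r}")
    a = widths / 2.0
    a[-1] = 0.0  # unused in the open interval
    if grid.n_groups > 1 and widths[0] == 1.0 and grid.lower_bounds[0] == 0.0:
        if a0 == "andreev-kingkade":
            m0 = float(np.asarray(m)[..., 0].ravel()[0])
            a[0] = infant_separation_factor(m0, sex)
        else:
            a[0] = float(a0)
    return a


def build_life_table(
    m_allcause: np.ndarray,
    grid: AgeGrid,
    a_convention: str | np.ndarray = "midpoint",
    a0: float | str = "andreev-kingkade",
    sex: str | None = None,
    radix: float = 1.0,
) -> AbridgedLifeTable:
    """Build an abridged life table from all-cause death rates.

    Parameters
    ----------
    m_allcause:
        Death rates per person-year, one per age group.  Must be
        non-negative, with a strictly positive rate in the open interval
        (otherwise remaining expectancy there is undefined).
    a_convention, a0, sex:
        See :func:`_resolve_a`; the default is a = n/2 with an
        Andreev–Kingkade infant correction.
    radix:
        Starting cohort size; internal arithmetic is radix-1, output
        l/d/L/T are scaled.
    """
    m = np.asarray(m_allcause, dtype=float)
    if m.shape != (grid.n_groups,):
        raise ValidationError(f"expected {grid.n_groups} rates, got shape {m.shape}")
    if np.any(~np.isfinite(m)) or np.any(m < 0):
        raise ValidationError("death rates must be finite and non-negative")
    if m[-1] <= 0:
        raise ValidationError("open-interval death rate must be positive")
    if radix <= 0:
        raise ValidationError("radix must be positive")
    a = _resolve_a(m, grid, a_convention, a0, sex)
    q, l, d, L, T, e = _lifetable_arrays(m, grid.widths, a)
    return AbridgedLifeTable(
        grid=grid, n=grid.widths, m=m, a=a, q=q,
        l=l * radix, d=d * radix, L=L * radix, T=T * radix, e=e, radix=radix,
    )


def evaluate_e0_edagger(
    m_batch: np.ndarray,
    grid: AgeGrid,
    a0: float | str = "andreev-kingkade",
    sex: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Life expectancy and e† for a batch of all-cause rate schedules.

    ``m_batch`` has shape (..., G).  The infant a0 rule is applied
    row-wise, so results agree exactly with :func:`build_life_table` on
    each row.  Used heavily by the decomposition engine.
    """
    m = np.asarray(m_batch, dtype=float)
    widths = grid.widths
    a = np.broadcast_to(widths / 2.0, m.shape).copy()
    a[..., -1] = 0.0
    if grid.n_groups > 1 and widths[0] == 1.0 and grid.lower_bounds[0] == 0.0:
        if a0 == "andreev-kingkade":
            a[..., 0] = infant_separation_factor(m[..., 0], sex)
        else:
            a[..., 0] = float(a0)
    # per-row a requires the closed-interval formulas to broadcast; the
    # core recursion only uses a[:-1] as a (G-1,) vector, so inline here.
    nc = widths[:-1]
    ac = a[..., :-1]
    q = np.empty_like(m)
    q[..., :-1] = np.clip(nc * m[..., :-1] / (1.0 + (nc - ac) * m[..., :-1]), 0.0, 1.0)
    q[..., -1] = 1.0
    surv = np.cumprod(1.0 - q, axis=-1)
    l = np.concatenate([np.ones_like(m[..., :1]), surv[..., :-1]], axis=-1)
    d = l * q
    L = np.empty_like(m)
    L[..., :-1] = nc * l[..., 1:] + ac * d[..., :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        L[..., -1] = np.where(l[..., -1] > 0, l[..., -1] / m[..., -1], 0.0)
    T = np.flip(np.cumsum(np.flip(L, axis=-1), axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)
    e0 = T[..., 0]
    frac = ac / nc
    ed = (d[..., :-1] * ((1.0 - frac) * e[..., :-1] + frac * e[..., 1:])).sum(axis=-1)
    ed = ed + d[..., -1] * e[..., -1]
    return e0, ed


def life_expectancy(lt: AbridgedLifeTable) -> float:
    """Life expectancy at birth, e0 = T0 / l0."""
    return float(lt.T[0] / lt.l[0])


def e_dagger(lt: AbridgedLifeTable) -> float:
    """Life disparity e†: mean remaining expectancy at death (years)."""
    return float(_edagger_from_arrays(lt.d / lt.radix, lt.e, lt.n, lt.a))


def sex_gaps(
    lt_female: AbridgedLifeTable, lt_male: AbridgedLifeTable
) -> tuple[float, float]:
    """Female-minus-male gaps (SGLE, SGLD) in years.

    Positive SGLE means females live longer; negative SGLD means female
    lifespans are less dispersed (a female disparity advantage).
    """
    if lt_female.grid != lt_male.grid:
        raise ValidationError("life tables are on different age grids")
    sgle = life_expectancy(lt_female) - life_expectancy(lt_male)
    sgld = e_dagger(lt_female) - e_dagger(lt_male)
    return sgle, sgld


def write_life_table_csv(lt: AbridgedLifeTable, path, decimals: int = 6) -> None:
    lt.to_frame(decimals=decimals).to_csv(path, index=False)
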