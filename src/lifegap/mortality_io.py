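"""Reading, validating and aggregating sex x age x cause mortality data.

The canonical in-memory container is :class:`MortalityDataset`: death
counts indexed by (sex, age group, cause) plus person-years of exposure
by (sex, age group), on a shared abridged :class:`~lifegap.agegrid.AgeGrid`.
Two file interfaces are supported:

* a tidy CSV schema (``sex, age_group, cause, deaths`` and
  ``sex, age_group, person_years``) used for all package output, and
* the WHO Mortality Database flat layout (one row per country / year /
  cause / sex with 26 age-banded count columns selected by an
  age-format code).

Death counts may be fractional: redistributing unknown-age deaths
produces non-integer counts and every downstream computation accepts
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agegrid import AgeGrid, default_grid
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

# WHO flat-file sex codes; anything else (9 = unspecified) is dropped.
_WHO_SEX = {1: "male", 2: "female"}

# Age-format codes supported for the 26-column WHO layout.  Each entry
# maps the count columns 2..26 onto exact-age bands (lo, hi); None marks
# a column unused under that format; the final listed band is open and
# column 26 always holds unknown-age counts.  Formats coarser than the
# target grid (e.g. broad 10-year bands) are rejected outright rather
# than interpolated.
_WHO_FORMATS: dict[int, list[tuple[float, float] | None]] = {
    # 0: <1, 1, 2, 3, 4, 5-9 ... 80-84, 85-89, 90-94, 95+
    0: [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
    + [(a, a + 5) for a in range(5, 95, 5)]
    + [(95, np.inf)],
    # 1: <1, 1, 2, 3, 4, 5-9 ... 80-84, 85+
    1: [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
    + [(a, a + 5) for a in range(5, 85, 5)]
    + [(85, np.inf), None, None],
    # 2: <1, 1-4, 5-9 ... 80-84, 85+
    2: [(0, 1), (1, 5), None, None, None]
    + [(a, a + 5) for a in range(5, 85, 5)]
    + [(85, np.inf), None, None],
}


@dataclass(frozen=True)
class MortalityDataset:
    """Death counts and person-years by sex, abridged age group and cause.

    ``deaths`` has shape ``(n_sexes, n_age_groups, n_causes)`` and
    ``population`` shape ``(n_sexes, n_age_groups)``; sexes and causes
    index the respective axes in order.
    """

    grid: AgeGrid
    sexes: tuple[str, ...]
    causes: tuple[str, ...]
    deaths: np.ndarray
    population: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        deaths = np.asarray(self.deaths, dtype=float)
        pop = np.asarray(self.population, dtype=float)
        S, G, C = len(self.sexes), self.grid.n_groups, len(self.causes)
        if deaths.shape != (S, G, C):
            raise ValidationError(
                f"deaths shape {deaths.shape} != (sexes, ages, causes) = {(S, G, C)}"
            )
        if pop.shape != (S, G):
            raise ValidationError(f"population shape {pop.shape} != {(S, G)}")
        if len(set(self.causes)) != C:
            raise ValidationError("cause labels must be unique")
        if not np.all(np.isfinite(deaths)) or np.any(deaths < 0):
            raise ValidationError("deaths must be finite and non-negative")
        if not np.all(np.isfinite(pop)) or np.any(pop < 0):
            raise ValidationError("population must be finite and non-negative")
        bad = (deaths.sum(axis=2) > 0) & (pop <= 0)
        if np.any(bad):
            cells = [
                (self.sexes[s], self.grid.labels[g])
                for s, g in zip(*np.nonzero(bad))
            ]
            raise ValidationError(f"deaths recorded with zero population at {cells}")
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "population", pop)

    # -- accessors ------------------------------------------------------
    def sex_index(self, sex: str) -> int:
        try:
            return self.sexes.index(sex)
        except ValueError:
            raise ValidationError(f"sex {sex!r} not in dataset (has {self.sexes})") from None

    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    def with_meta(self, **kv) -> "MortalityDataset":
        return replace(self, meta={**self.meta, **kv})

    # -- tidy frames ----------------------------------------------------
    def to_tidy(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (deaths, population) tidy frames using canonical labels."""
        rows = []
        for s, sex in enumerate(self.sexes):
            for g, age in enumerate(self.grid.labels):
                for c, cause in enumerate(self.causes):
                    rows.append((sex, age, cause, self.deaths[s, g, c]))
        deaths = pd.DataFrame(rows, columns=["sex", "age_group", "cause", "deaths"])
        prow = [
            (sex, age, self.population[s, g])
            for s, sex in enumerate(self.sexes)
            for g, age in enumerate(self.grid.labels)
        ]
        pop = pd.DataFrame(prow, columns=["sex", "age_group", "person_years"])
        return deaths, pop


@dataclass(frozen=True)
class RateMatrix:
    """Cause-specific death rates per person-year for one sex."""

    grid: AgeGrid
    causes: tuple[str, ...]
    m: np.ndarray  # shape (n_age_groups, n_causes), per person-year

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (self.grid.n_groups, len(self.causes)):
            raise ValidationError(
                f"rate matrix shape {m.shape} != {(self.grid.n_groups, len(self.causes))}"
            )
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValidationError("rates must be finite and non-negative")
        object.__setattr__(self, "m", m)

    def all_cause(self) -> np.ndarray:
        """All-cause rate per age group (row sum over causes)."""
        return self.m.sum(axis=1)


# ---------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------

def dataset_from_frames(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    grid: AgeGrid | None = None,
    meta: dict | None = None,
) -> MortalityDataset:
    """Build a validated dataset from tidy deaths / population frames."""
    grid = grid or default_grid()
    for col in ("sex", "age_group", "cause", "deaths"):
        if col not in deaths.columns:
            raise ValidationError(f"deaths table missing column {col!r}")
    for col in ("sex", "age_group", "person_years"):
        if col not in population.columns:
            raise ValidationError(f"population table missing column {col!r}")
    if (deaths["deaths"] < 0).any():
        raise ValidationError("negative death counts in input")
    sexes = tuple(s for s in SEXES if s in set(deaths["sex"]))
    unknown = set(deaths["sex"]) - set(SEXES)
    if unknown:
        logger.warning("dropping records for unrecognised sex codes: %s", sorted(unknown))
        deaths = deaths[deaths["sex"].isin(SEXES)]
    if not sexes:
        raise ValidationError("no male/female records in deaths table")
    causes = tuple(sorted(set(deaths["cause"])))
    G = grid.n_groups
    D = np.zeros((len(sexes), G, len(causes)))
    P = np.zeros((len(sexes), G))
    cidx = {c: i for i, c in enumerate(causes)}
    sidx = {s: i for i, s in enumerate(sexes)}
    for row in deaths.itertuples(index=False):
        D[sidx[row.sex], grid.index_of(str(row.age_group)), cidx[row.cause]] += row.deaths
    for row in population.itertuples(index=False):
        if row.sex in sidx:
            P[sidx[row.sex], grid.index_of(str(row.age_group))] += row.person_years
    return MortalityDataset(grid, sexes, causes, D, P, meta or {})


def read_tidy_csv(
    deaths_path,
    population_path,
    grid: AgeGrid | None = None,
) -> MortalityDataset:
    """Read the tidy CSV schema (deaths + person-years tables)."""
    deaths = pd.read_csv(deaths_path)
    pop = pd.read_csv(population_path)
    return dataset_from_frames(deaths, pop, grid=grid, meta={"source": str(deaths_path)})


def write_tidy(ds: MortalityDataset, deaths_path, population_path) -> None:
    """Write a dataset in the tidy CSV schema (round-trips with
    :func:`read_tidy_csv`)."""
    deaths, pop = ds.to_tidy()
    deaths.to_csv(deaths_path, index=False)
    pop.to_csv(population_path, index=False)


# ---------------------------------------------------------------------
# WHO Mortality Database flat files
# ---------------------------------------------------------------------

def _collapse_bands(
    counts: np.ndarray, bands: list[tuple[float, float] | None], grid: AgeGrid
) -> np.ndarray:
    """Map 25 WHO age-band counts onto the target grid (unknown-age
    column excluded).  Raises if a source band straddles a grid boundary."""
    lb = np.asarray(grid.lower_bounds)
    out = np.zeros(grid.n_groups)
    for count, band in zip(counts, bands):
        if band is None:
            if count:
                raise FormatError("counts present in a column unused by the age format")
            continue
        lo, hi = band
        i = int(np.searchsorted(lb, lo, side="right") - 1)
        upper = lb[i + 1] if i + 1 < len(lb) else np.inf
        if lo < lb[i] or (np.isfinite(hi) and hi > upper) or (not np.isfinite(hi) and np.isfinite(upper)):
            raise FormatError(
                f"source age band [{lo}, {hi}) straddles target grid boundaries"
            )
        out[i] += count
    return out


def _read_band_table(
    path, prefix: str, country_code, years, grid: AgeGrid, extra_keys: list[str]
) -> pd.DataFrame:
    """Shared reader for the deaths (Deaths1..26) / population (Pop1..26)
    flat layouts: filters country/years, maps bands onto the grid, and
    returns one row per (year, sex[, cause]) with per-group counts and
    the unknown-age count."""
    df = pd.read_csv(path)
    cols26 = [f"{prefix}{i}" for i in range(1, 27)]
    missing = [c for c in ("Country", "Year", "Sex", "Frmat", *cols26) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing expected columns {missing}")
    sel = df[(df["Country"].astype(str) == str(country_code)) & (df["Year"].isin(years))]
    if sel.empty:
        raise ValidationError(
            f"country {country_code!r} / years {list(years)} not found in {path}"
        )
    found_years = set(sel["Year"])
    if set(years) - found_years:
        raise ValidationError(
            f"years {sorted(set(years) - found_years)} not found for country {country_code!r}"
        )
    records = []
    for row in sel.itertuples(index=False):
        rowd = row._asdict()
        sex = _WHO_SEX.get(int(rowd["Sex"]))
        if sex is None:
            logger.warning("dropping record with sex code %s", rowd["Sex"])
            continue
        frmat = int(rowd["Frmat"])
        if frmat not in _WHO_FORMATS:
            raise FormatError(f"unsupported WHO age-format code {frmat}")
        bands = _WHO_FORMATS[frmat]
        counts = np.array(
            [float(rowd[f"{prefix}{i}"]) if pd.notna(rowd[f"{prefix}{i}"]) else 0.0
             for i in range(2, 26)]
        )
        unknown = float(rowd[f"{prefix}26"]) if pd.notna(rowd[f"{prefix}26"]) else 0.0
        by_group = _collapse_bands(counts, bands[: len(counts)], grid)
        rec = {k: rowd[k] for k in extra_keys if k in rowd}
        rec.update(year=rowd["Year"], sex=sex, groups=by_group, unknown=unknown)
        records.append(rec)
    return pd.DataFrame(records)


def read_who_mdb(
    deaths_path,
    population_path,
    country_code,
    years,
    grid: AgeGrid | None = None,
) -> MortalityDataset:
    """Read WHO Mortality Database flat files for one country and a set
    of years, pooling deaths and person-years across the years.

    Unknown-age deaths are redistributed proportionally to the known-age
    distribution within each sex x cause (total deaths conserved); a
    cause with only unknown-age deaths is dropped with a warning since no
    distribution exists to borrow.
    """
    grid = grid or default_grid()
    years = list(years)
    drec = _read_band_table(deaths_path, "Deaths", country_code, years, grid, ["Cause"])
    prec = _read_band_table(population_path, "Pop", country_code, years, grid, [])

    sexes = tuple(s for s in SEXES if s in set(drec["sex"]))
    causes = tuple(sorted(set(drec["Cause"].astype(str))))
    D = np.zeros((len(sexes), grid.n_groups, len(causes)))
    P = np.zeros((len(sexes), grid.n_groups))
    sidx = {s: i for i, s in enumerate(sexes)}
    cidx = {c: i for i, c in enumerate(causes)}

    for (sex, cause), sub in drec.groupby(["sex", "Cause"]):
        known = np.sum(np.stack(list(sub["groups"])), axis=0)
        unknown = float(sub["unknown"].sum())
        if unknown > 0:
            tot = known.sum()
            if tot > 0:
                known = known * (1.0 + unknown / tot)
            else:
                logger.warning(
                    "cause %s sex %s: %s unknown-age deaths with no known-age "
                    "distribution; dropped", cause, sex, unknown,
                )
        D[sidx[sex], :, cidx[str(cause)]] += known
    for row in prec.itertuples(index=False):
        if row.sex in sidx:
            P[sidx[row.sex]] += row.groups

    missing = (D.sum(axis=2) > 0) & (P <= 0)
    if np.any(missing):
        raise ValidationError("population missing for sex-age cells that have deaths")
    meta = {"country": str(country_code), "years": years, "icd_revision": "10"}
    return MortalityDataset(grid, sexes, causes, D, P, meta)


# ---------------------------------------------------------------------
# aggregation and rates
# ---------------------------------------------------------------------

def aggregate_years(datasets: list[MortalityDataset]) -> MortalityDataset:
    """Pool several datasets cell-wise (deaths and person-years summed).

    All inputs must share the grid, sexes and cause set; pooling
    identical-rate periods leaves rates unchanged (sum D / sum P).
    """
    if not datasets:
        raise ValidationError("nothing to aggregate")
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.grid != first.grid:
            raise ValidationError("cannot aggregate datasets on different age grids")
        if ds.causes != first.causes:
            raise ValidationError("cannot aggregate datasets with different cause sets")
        if ds.sexes != first.sexes:
            raise ValidationError("cannot aggregate datasets with different sexes")
    D = sum(ds.deaths for ds in datasets)
    P = sum(ds.population for ds in datasets)
    years: list = []
    for ds in datasets:
        years.extend(ds.meta.get("years") or [])
    meta = dict(first.meta)
    if years:
        meta["years"] = sorted(set(years))
    return MortalityDataset(first.grid, first.sexes, first.causes, D, P, meta)


def death_rates(ds: MortalityDataset, sex: str) -> RateMatrix:
    """Cause-specific death rates m[age, cause] = D / person-years for one
    sex; cells with zero population (and hence zero deaths) get rate 0."""
    s = ds.sex_index(sex)
    P = ds.population[s]
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(P[:, None] > 0, ds.deaths[s] / np.where(P[:, None] > 0, P[:, None], 1.0), 0.0)
    return RateMatrix(ds.grid, ds.causes, m)
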