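"""ICD-10 cause classification into mutually exclusive avoidable groups.

Avoidable mortality splits into *preventable* deaths (averted by public
health action: injuries, smoking-related cancers, alcohol and drug
deaths, vaccine-preventable infections) and *treatable* (amenable)
deaths (averted by timely, effective healthcare).  Causes that belong to
both lists form a *treatable & preventable* group, from which ischaemic
heart disease (IHD) is pulled out as its own group because its death
toll would otherwise dominate the category.  Everything else — and
every death at or above the upper age limit (default exact age 75) —
is non-avoidable.

A rule maps an ICD-10 code or inclusive code range to a group and a
human-readable report label.  Rules are resolved in group-precedence
order (IHD, then treatable & preventable, preventable, treatable), and
within a group in file order; 4-character codes match 3-character rules
by prefix.  The default map shipped with the package implements a
representative OECD/Eurostat-style list; a full-fidelity list can be
supplied as YAML or CSV config.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agegrid import AgeGrid
from .errors import ValidationError
from .mortality_io import MortalityDataset

GROUPS = ("IHD", "treatable_preventable", "preventable", "treatable", "non_avoidable")
AVOIDABLE_GROUPS = GROUPS[:4]
_PRECEDENCE = {g: i for i, g in enumerate(GROUPS)}

NON_AVOIDABLE_LABEL = "Non-avoidable"
OTHER_LABEL = "Other"

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(\d)?$")


def _parse_code(code: str) -> tuple[str, str | None]:
    """Split an ICD-10 code into its 3-character stem and optional 4th
    character; dots are tolerated (``I21.9`` == ``I219``)."""
    m = _CODE_RE.match(str(code).strip().upper().replace(".", ""))
    if not m:
        raise ValidationError(f"malformed ICD-10 code {code!r}")
    letter, digits, fourth = m.groups()
    return letter + digits, fourth


@dataclass(frozen=True)
class Rule:
    """One classification rule: an ICD-10 code or inclusive range."""

    lo: str  # 3- or 4-character code, range start
    hi: str  # range end (== lo for single-code rules)
    group: str
    label: str

    def matches(self, stem: str, fourth: str | None) -> bool:
        if len(self.lo) == 4:
            # 4-character rules require an exact 4-character match
            return fourth is not None and self.lo <= stem + fourth <= self.hi
        return self.lo <= stem <= self.hi


def _parse_pattern(pattern: str) -> tuple[str, str]:
    parts = str(pattern).strip().upper().replace(".", "").split("-")
    if len(parts) == 1:
        lo = hi = parts[0]
    elif len(parts) == 2:
        lo, hi = parts
    else:
        raise ValidationError(f"bad ICD pattern {pattern!r}")
    for p in (lo, hi):
        if not re.match(r"^[A-Z]\d{2}\d?$", p):
            raise ValidationError(f"bad ICD pattern {pattern!r}")
    if len(lo) != len(hi) or lo > hi:
        raise ValidationError(f"bad ICD pattern {pattern!r} (inverted or mixed-width range)")
    return lo, hi


@dataclass(frozen=True)
class CauseMap:
    """An ordered rule list plus the avoidability age limit (years).

    Deaths in age groups whose lower bound is at or above ``age_limit``
    are non-avoidable regardless of cause.
    """

    rules: tuple[Rule, ...]
    age_limit: float = 75.0
    _ordered: tuple[Rule, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for r in self.rules:
            if r.group not in GROUPS:
                raise ValidationError(f"unknown group {r.group!r} in rule {r}")
        # contradictory duplicates: identical pattern, different group
        seen: dict[tuple[str, str], Rule] = {}
        offenders = []
        for r in self.rules:
            key = (r.lo, r.hi)
            if key in seen and seen[key].group != r.group:
                offenders.append((seen[key], r))
            seen.setdefault(key, r)
        if offenders:
            raise ValidationError(f"contradictory duplicate rules: {offenders}")
        ordered = tuple(
            sorted(self.rules, key=lambda r: _PRECEDENCE[r.group])
        )  # stable: preserves file order within a group
        object.__setattr__(self, "_ordered", ordered)

    def with_age_limit(self, age_limit: float) -> "CauseMap":
        return replace(self, age_limit=age_limit)


def classify_code(
    code: str, age_group: int, cause_map: CauseMap, grid: AgeGrid
) -> tuple[str, str]:
    """Classify one ICD-10 code at one age group into (group, label).

    The age rule dominates: if the group's lower bound is at or above
    the map's age limit the death is non-avoidable whatever the code.
    Below the limit, the first matching rule in precedence order wins;
    a code with no matching rule is non-avoidable with an "Other" label.
    """
    stem, fourth = _parse_code(code)
    if not (0 <= age_group < grid.n_groups):
        raise ValidationError(f"age group index {age_group} outside grid")
    if grid.lower_bounds[age_group] >= cause_map.age_limit:
        return "non_avoidable", NON_AVOIDABLE_LABEL
    for rule in cause_map._ordered:
        if rule.matches(stem, fourth):
            return rule.group, rule.label
    return "non_avoidable", OTHER_LABEL


# ---------------------------------------------------------------------
# grouped datasets
# ---------------------------------------------------------------------

def cause_key(group: str, label: str) -> str:
    return f"{group}|{label}"


def split_cause_key(key: str) -> tuple[str, str]:
    group, _, label = key.partition("|")
    return group, label


def group_dataset(ds: MortalityDataset, cause_map: CauseMap) -> MortalityDataset:
    """Re-key a dataset's deaths from ICD-10 codes to (group, label)
    cause keys, applying the age limit cell-wise.

    Total deaths are conserved; the same ICD code can land in an
    avoidable label below the age limit and in the non-avoidable group
    above it.
    """
    grid = ds.grid
    # classification is per (code, age-group); cache on the code and the
    # binary above/below-limit state
    keys: dict[tuple[str, bool], str] = {}
    out: dict[str, np.ndarray] = {}
    below = np.asarray(grid.lower_bounds) < cause_map.age_limit
    for c, code in enumerate(ds.causes):
        for is_below in (True, False):
            mask = below == is_below
            if not mask.any():
                continue
            k = keys.get((code, is_below))
            if k is None:
                g = int(np.argmax(mask))
                group, label = classify_code(code, g, cause_map, grid)
                k = cause_key(group, label)
                keys[(code, is_below)] = k
            cell = out.setdefault(k, np.zeros_like(ds.deaths[:, :, 0]))
            cell[:, mask] += ds.deaths[:, mask, c]
    causes = tuple(sorted(out))
    D = (
        np.stack([out[k] for k in causes], axis=2)
        if causes
        else np.zeros((len(ds.sexes), grid.n_groups, 0))
    )
    meta = {**ds.meta, "grouped": True,
            "groups": {k: split_cause_key(k)[0] for k in causes}}
    return MortalityDataset(grid, ds.sexes, causes, D, ds.population, meta)


# ---------------------------------------------------------------------
# map loading
# ---------------------------------------------------------------------

def _rules_from_records(records) -> CauseMap:
    rules = []
    age_limit = 75.0
    for rec in records:
        lo, hi = _parse_pattern(rec["pattern"])
        rules.append(Rule(lo=lo, hi=hi, group=str(rec["group"]), label=str(rec["label"])))
    return CauseMap(tuple(rules), age_limit=age_limit)


def load_cause_map(path) -> CauseMap:
    """Load a cause map from YAML (``age_limit`` + ``rules`` list) or CSV
    (columns ``pattern, group, label``)."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        doc = yaml.safe_load(path.read_text())
        cm = _rules_from_records(doc["rules"])
        if "age_limit" in doc:
            cm = cm.with_age_limit(float(doc["age_limit"]))
        return cm
    df = pd.read_csv(path)
    for col in ("pattern", "group", "label"):
        if col not in df.columns:
            raise ValidationError(f"cause map missing column {col!r}")
    return _rules_from_records(df.to_dict("records"))


def default_cause_map() -> CauseMap:
    """The representative avoidable-cause map shipped with the package."""
    with resources.as_file(
        resources.files("lifegap.data").joinpath("default_cause_map.yaml")
    ) as p:
        return load_cause_map(p)
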