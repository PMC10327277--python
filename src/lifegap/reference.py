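"""Published reference contributions for Iran 2015-2016.

The package ships the published cause-group contribution table for the
sex gap in life expectancy (SGLE) and life disparity (SGLD) in Iran over
2015-2016 (years, female minus male, 3-decimal precision as printed).
It serves as arithmetic reference material — e.g. recomputing the
avoidable shares from the printed group totals — not as a substitute
for running the pipeline on data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cause_classification import AVOIDABLE_GROUPS


def reference_contributions() -> pd.DataFrame:
    """Columns: group, cause_label, sgle_years, sgld_years."""
    with resources.as_file(
        resources.files("lifegap.data").joinpath(
            "reference_contributions_iran_2015_2016.csv"
        )
    ) as p:
        return pd.read_csv(p)


def reference_group_totals(measure: str = "sgle") -> dict[str, float]:
    """Per-group totals (years) as printed in the published table;
    ``measure`` is ``"sgle"`` or ``"sgld"``.

    These are the published totals, not sums of the published rows: the
    printed SGLE rows carry their own rounding, so three groups differ
    from their row sums by 0.001.
    """
    with resources.as_file(
        resources.files("lifegap.data").joinpath(
            "reference_group_totals_iran_2015_2016.csv"
        )
    ) as p:
        df = pd.read_csv(p)
    return dict(zip(df["group"], df[f"{measure.lower()}_years"]))


def reference_total_gap(measure: str = "sgle") -> float:
    """The printed all-cause total gap: 3.795 (SGLE) / -1.869 (SGLD).

    Note the published SGLD table carries a 1-in-the-last-digit internal
    rounding quirk: the printed group rows sum to -1.868 while the
    printed all-cause total is -1.869.
    """
    return {"sgle": 3.795, "sgld": -1.869}[measure.lower()]


def reference_avoidable_total(measure: str = "sgle") -> float:
    totals = reference_group_totals(measure)
    return round(sum(totals.get(g, 0.0) for g in AVOIDABLE_GROUPS), 3)
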