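"""End-to-end workflow: read -> aggregate -> classify -> life tables ->
gaps -> decompose -> report.

A run is driven by a YAML config naming the input (tidy CSV files, WHO
Mortality Database flat files, or a synthetic scenario), a cause map,
and decomposition settings.  Outputs are plain CSV tables mirroring the
standard reporting shapes for this analysis: levels (LE and e† per sex),
a gap summary with avoidable shares, a cause table (group x label
contributions to SGLE and SGLD), an age table, and the full age x cause
table, plus a JSON metadata sidecar.

Report CSVs are rounded to 3 decimals; a full-precision sidecar of the
age x cause contributions is written alongside.  Avoidable shares are
computed from unrounded contributions and rounded to whole percent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agegrid import default_grid
from .cause_classification import (
    AVOIDABLE_GROUPS,
    GROUPS,
    CauseMap,
    default_cause_map,
    group_dataset,
    load_cause_map,
)
from .decomposition import DecompositionResult, decompose_sex_gap
from .errors import LifegapError, ValidationError
from .lifetable import build_life_table, e_dagger, life_expectancy
from .mortality_io import (
    MortalityDataset,
    aggregate_years,
    death_rates,
    read_tidy_csv,
    read_who_mdb,
)
from . import synthetic

logger = logging.getLogger(__name__)

_GROUP_ORDER = {g: i for i, g in enumerate(GROUPS)}


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    levels: pd.DataFrame          # sex, LE, e_dagger
    gap_summary: pd.DataFrame     # measure, gap_years, avoidable_years, avoidable_share_pct
    cause_table: pd.DataFrame     # group, cause_label, SGLE/SGLD contributions
    age_table: pd.DataFrame       # age_group, SGLE/SGLD contributions (+ avoidable-only)
    age_cause: dict[str, pd.DataFrame] = field(default_factory=dict)  # per measure, long format
    metadata: dict = field(default_factory=dict)
    results: dict[str, DecompositionResult] = field(default_factory=dict)


def avoidable_share(bundle: ReportBundle) -> tuple[float | None, float | None]:
    """Percent of the SGLE and SGLD carried by avoidable causes
    (IHD + treatable&preventable + preventable + treatable), computed
    from unrounded contributions.  ``None`` where the total gap is zero."""
    out = []
    for measure in ("SGLE", "SGLD"):
        row = bundle.gap_summary[bundle.gap_summary["measure"] == measure]
        gap = float(row["gap_years"].iloc[0])
        avoid = float(row["avoidable_years"].iloc[0])
        out.append(100.0 * avoid / gap if gap != 0.0 else None)
    return tuple(out)


def shares_from_totals(
    group_totals: dict[str, float], total_gap: float
) -> tuple[float, int]:
    """Avoidable share (percent, and its whole-percent report rounding)
    from per-group gap contributions, e.g. a published contribution
    table.  Raises on a zero total gap."""
    if total_gap == 0:
        raise ValidationError("avoidable share undefined for a zero total gap")
    avoid = sum(group_totals.get(g, 0.0) for g in AVOIDABLE_GROUPS)
    pct = 100.0 * avoid / total_gap
    return pct, int(round(pct))


# ---------------------------------------------------------------------
# input stage
# ---------------------------------------------------------------------

def _load_input(cfg: dict, seed: int | None) -> MortalityDataset:
    src = cfg.get("input", {})
    kind = src.get("type")
    if kind == "tidy":
        datasets = []
        pairs = src.get("files") or [
            {"deaths": src["deaths"], "population": src["population"]}
        ]
        for pair in pairs:
            datasets.append(read_tidy_csv(pair["deaths"], pair["population"]))
        return aggregate_years(datasets) if len(datasets) > 1 else datasets[0]
    if kind == "who_mdb":
        return read_who_mdb(
            src["deaths"], src["population"], src["country"], list(src["years"])
        )
    if kind == "synthetic":
        if "scenario_file" in src:
            sc = synthetic.load_scenario(src["scenario_file"])
        else:
            sc = synthetic.demo_scenario()
        if seed is not None:
            sc = sc.with_(seed=int(seed))
        if "noise" in src:
            sc = sc.with_(noise=src["noise"])
        return synthetic.generate(sc)
    raise ValidationError(f"unknown input type {kind!r} (expected tidy/who_mdb/synthetic)")


def _load_cause_map(cfg: dict) -> CauseMap:
    path = cfg.get("cause_map")
    cm = load_cause_map(path) if path else default_cause_map()
    if "age_limit" in cfg:
        cm = cm.with_age_limit(float(cfg["age_limit"]))
    return cm


# ---------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------

def _cause_table(res_le: DecompositionResult, res_ld: DecompositionResult) -> pd.DataFrame:
    df_le = res_le.to_frame().groupby(["group", "cause_label"], as_index=False)[
        "contribution_years"
    ].sum().rename(columns={"contribution_years": "SGLE_contribution_years"})
    df_ld = res_ld.to_frame().groupby(["group", "cause_label"], as_index=False)[
        "contribution_years"
    ].sum().rename(columns={"contribution_years": "SGLD_contribution_years"})
    df = df_le.merge(df_ld, on=["group", "cause_label"], how="outer").fillna(0.0)
    df = df.sort_values(
        by=["group", "cause_label"], key=lambda s: s.map(_GROUP_ORDER) if s.name == "group" else s
    ).reset_index(drop=True)
    return df


def _age_table(res_le: DecompositionResult, res_ld: DecompositionResult) -> pd.DataFrame:
    grid = res_le.grid
    groups = res_le.groups or {}

    def avoidable_by_age(res: DecompositionResult) -> np.ndarray:
        mask = np.array(
            [groups.get(k, k.partition("|")[0]) in AVOIDABLE_GROUPS for k in res.causes]
        )
        return res.contributions[:, mask].sum(axis=1)

    return pd.DataFrame(
        {
            "age_group": grid.labels,
            "SGLE_contribution_years": res_le.by_age(),
            "SGLD_contribution_years": res_ld.by_age(),
            "SGLE_avoidable_years": avoidable_by_age(res_le),
            "SGLD_avoidable_years": avoidable_by_age(res_ld),
        }
    )


def _write_outputs(bundle: ReportBundle, out_dir: Path, decimals: int = 3,
                   plot: bool = False) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def w(df: pd.DataFrame, name: str, round_to: int | None = decimals) -> None:
        path = out_dir / name
        out = df.copy()
        if round_to is not None:
            num = out.select_dtypes("number").columns
            out[num] = out[num].round(round_to)
        out.to_csv(path, index=False)
        written.append(path)

    w(bundle.levels, "levels.csv")
    w(bundle.gap_summary, "gap_summary.csv")
    w(bundle.cause_table, "cause_table.csv")
    w(bundle.age_table, "age_table.csv")
    for measure, df in bundle.age_cause.items():
        w(df, f"age_cause_{measure.lower()}.csv")
        w(df, f"age_cause_{measure.lower()}_full_precision.csv", round_to=None)
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
    written.append(meta_path)
    if plot:
        written.append(_plot_age_profiles(bundle, out_dir))
    return written


def _plot_age_profiles(bundle: ReportBundle, out_dir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    x = np.arange(len(bundle.age_table))
    ax.bar(x - 0.2, bundle.age_table["SGLE_avoidable_years"], width=0.4,
           label="SGLE (avoidable)")
    ax.bar(x + 0.2, bundle.age_table["SGLD_avoidable_years"], width=0.4,
           label="SGLD (avoidable)")
    ax.set_xticks(x)
    ax.set_xticklabels(bundle.age_table["age_group"], rotation=90)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("contribution (years)")
    ax.legend()
    fig.tight_layout()
    path = out_dir / "age_profiles.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------

def run(config, out_dir=None, seed: int | None = None,
        n_steps: int | None = None, plot: bool | None = None) -> ReportBundle:
    """Execute the full workflow from a config mapping or YAML path.

    Deterministic for a fixed config (and seed, when the input is a
    noisy synthetic scenario).  On error, any partially written output
    files from this run are removed and the failing stage is named.
    """
    if isinstance(config, (str, Path)):
        config_text = Path(config).read_text()
        cfg = yaml.safe_load(config_text) or {}
    else:
        cfg = dict(config)
        config_text = yaml.safe_dump(cfg, sort_keys=True)
    if n_steps is None:
        n_steps = int(cfg.get("n_steps", 1000))
    if seed is None:
        seed = cfg.get("seed")
    if plot is None:
        plot = bool(cfg.get("plot", False))
    out_dir = Path(out_dir or cfg.get("out_dir", "lifegap_output"))

    stage = "config"
    written: list[Path] = []
    try:
        t0 = time.time()
        stage = "read"
        ds = _load_input(cfg, seed)
        logger.info("read: %d sexes x %d age groups x %d causes, %.0f deaths",
                    len(ds.sexes), ds.grid.n_groups, len(ds.causes), ds.total_deaths())

        stage = "classify"
        cm = _load_cause_map(cfg)
        grouped = group_dataset(ds, cm)
        logger.info("classify: %d cause groups, deaths conserved at %.1f",
                    len(grouped.causes), grouped.total_deaths())

        stage = "life tables"
        # one shared a0 convention across sexes keeps the decomposition
        # exactly additive against these levels
        lts = {
            sex: build_life_table(death_rates(ds, sex).all_cause(), ds.grid)
            for sex in ("female", "male")
        }
        levels = pd.DataFrame(
            [
                {"sex": sex, "LE": life_expectancy(lt), "e_dagger": e_dagger(lt)}
                for sex, lt in lts.items()
            ]
        )
        sgle = levels.loc[levels.sex == "female", "LE"].iloc[0] - \
            levels.loc[levels.sex == "male", "LE"].iloc[0]
        sgld = levels.loc[levels.sex == "female", "e_dagger"].iloc[0] - \
            levels.loc[levels.sex == "male", "e_dagger"].iloc[0]
        logger.info("levels: SGLE=%.3f SGLD=%.3f", sgle, sgld)

        stage = "decompose"
        res_le = decompose_sex_gap(grouped, "LE", n_steps=n_steps)
        res_ld = decompose_sex_gap(grouped, "e_dagger", n_steps=n_steps)

        stage = "report"
        cause_table = _cause_table(res_le, res_ld)
        age_table = _age_table(res_le, res_ld)
        gap_summary = pd.DataFrame(
            [
                {
                    "measure": name,
                    "gap_years": res.total_gap,
                    "avoidable_years": res.avoidable_total(),
                    "avoidable_share_pct": (
                        round(100.0 * res.avoidable_total() / res.total_gap)
                        if res.total_gap != 0 else float("nan")
                    ),
                    "residual_years": res.residual,
                }
                for name, res in (("SGLE", res_le), ("SGLD", res_ld))
            ]
        )
        metadata = {
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "n_steps": n_steps,
            "seed": seed,
            "n_causes": len(ds.causes),
            "n_cause_groups": len(grouped.causes),
            "total_deaths": ds.total_deaths(),
            "elapsed_s": round(time.time() - t0, 3),
        }
        bundle = ReportBundle(
            levels=levels,
            gap_summary=gap_summary,
            cause_table=cause_table,
            age_table=age_table,
            age_cause={"SGLE": res_le.to_frame(), "SGLD": res_ld.to_frame()},
            metadata=metadata,
            results={"SGLE": res_le, "SGLD": res_ld},
        )
        stage = "write"
        written = _write_outputs(bundle, out_dir, plot=plot)
        logger.info("wrote %d files to %s", len(written), out_dir)
        return bundle
    except LifegapError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
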