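"""Pipeline entry points: run whole analyses and write their result files.

Each ``run_*`` function takes a :class:`RunConfig`, executes the relevant
part of the pipeline (simulate -> filter -> agreement statistics, or the
growth management model) and writes deterministic CSV/text outputs to the
output directory.  All randomness flows from the single seed in the
config's synthetic settings; identical configs produce byte-identical
files.  Numeric files carry full precision; rounding appears only in the
human-readable report.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import agreement, growth
from .cohort import Cohort, apply_inclusion_filter, read_cohort, write_cohort
from .display import round_display
from .errors import InsufficientDataError
from .simulate import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_agreement", "run_model", "run_simulate", "run_full"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one input source: a cohort CSV path, or a synthetic-cohort
    config.  Growth-model parameters follow the management-table defaults.
    """

    out_dir: Path
    input_path: Path | None = None
    synthetic: SyntheticConfig | None = None
    vmin: float = 30.0
    vmax: float = 150.0
    cut: float = 80.0
    baselines: tuple[float, ...] = (30.0, 50.0, 80.0, 115.0, 130.0, 150.0)
    growth_low: float = 0.15
    growth_high: float = 0.24
    interval_days: float = 92.0
    threshold_mm3: float = 200.0
    review_month: int = 12
    precision: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.input_path is not None:
            object.__setattr__(self, "input_path", Path(self.input_path))
        if self.input_path is not None and self.synthetic is not None:
            raise ValueError("at most one of input_path or synthetic may be set")


def _require_input(config: RunConfig) -> None:
    if config.input_path is None and config.synthetic is None:
        raise ValueError("this command needs an input: a cohort CSV or a synthetic config")


def _load_cohort(config: RunConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort(config.input_path)
    return generate_cohort(config.synthetic)


def _write_metadata(config: RunConfig, path: Path) -> None:
    meta: dict = {
        "input": str(config.input_path) if config.input_path else None,
        "vmin_mm3": config.vmin,
        "vmax_mm3": config.vmax,
        "subgroup_cut_mm3": config.cut,
    }
    if config.synthetic is not None:
        meta["synthetic"] = asdict(config.synthetic)
        meta["seed"] = config.synthetic.seed
    path.write_text(yaml.safe_dump(meta, sort_keys=True))


def run_agreement(config: RunConfig) -> dict[str, Path]:
    """Filter the cohort and run every agreement analysis.

    Writes ``results.csv`` (tidy, one row per analysis), ``plot_data.csv``
    (Bland-Altman scatter plus mean/limit lines), ``exclusions.csv`` (the
    ledger) and ``metadata.yaml``.  The interobserver rows are produced only
    when every retained pair has a second-observer measurement; otherwise a
    notice is logged and the table has 4 rows.
    """
    _require_input(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = _load_cohort(config)
    cohort = apply_inclusion_filter(raw, vmin=config.vmin, vmax=config.vmax)
    logger.info(
        "inclusion filter: %d input, %d retained, %d excluded",
        len(raw), len(cohort), len(cohort.exclusions),
    )
    for exc in cohort.exclusions:
        logger.info("excluded %s: %s", exc.nodule_id, exc.reason.value)
    if len(cohort) == 0:
        raise InsufficientDataError("no nodules retained after inclusion filter")
    if not cohort.has_second_observer():
        logger.info("second-observer measurements absent or incomplete; interobserver analysis skipped")

    table = agreement.results_table(cohort, cut=config.cut)
    paths = {
        "results": out / "results.csv",
        "plot_data": out / "plot_data.csv",
        "exclusions": out / "exclusions.csv",
        "metadata": out / "metadata.yaml",
    }
    table.to_csv(paths["results"], index=False)
    agreement.plot_data(cohort).to_csv(paths["plot_data"], index=False)
    pd.DataFrame(
        [{"nodule_id": e.nodule_id, "reason": e.reason.value} for e in cohort.exclusions],
        columns=["nodule_id", "reason"],
    ).to_csv(paths["exclusions"], index=False)
    _write_metadata(config, paths["metadata"])
    return paths


_MODEL_HEADERS = (
    "baseline_mm3",
    "vol_3m_low",
    "vol_3m_high",
    "vol_12m_low",
    "vol_12m_high",
    "intervene_earliest_m",
    "intervene_latest_m",
    "delay_m",
    "implication",
)


def run_model(config: RunConfig) -> dict[str, Path]:
    """Emit the growth-management table as CSV and aligned text."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = growth.GrowthScenario(
        v0=1.0,
        g=config.growth_low,
        interval_days=config.interval_days,
        intervention_threshold=config.threshold_mm3,
        current_review_month=config.review_month,
    )
    rows = growth.build_management_table(
        baselines=config.baselines,
        g_low=config.growth_low,
        g_high=config.growth_high,
        scenario=scenario,
    )
    records = [
        {
            "baseline_mm3": r.v0,
            "vol_3m_low": r.v_3m_low,
            "vol_3m_high": r.v_3m_high,
            "vol_12m_low": r.v_12m_low,
            "vol_12m_high": r.v_12m_high,
            "intervene_earliest_m": r.intervene_month_earliest,
            "intervene_latest_m": r.intervene_month_latest,
            "delay_m": r.delay_months,
            "implication": r.implication,
        }
        for r in rows
    ]
    df = pd.DataFrame(records, columns=list(_MODEL_HEADERS))
    paths = {"csv": out / "management_table.csv", "txt": out / "management_table.txt"}
    df.to_csv(paths["csv"], index=False)

    lines = [
        f"Growth management model: {config.growth_low:.0%}-{config.growth_high:.0%} per quarter, "
        f"intervention at {round_display(config.threshold_mm3, config.precision):g} mm3, "
        f"review at {config.review_month} months",
        "",
        df.to_string(index=False),
        "",
    ]
    paths["txt"].write_text("\n".join(lines))
    return paths


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a synthetic cohort and write it in the cohort CSV schema."""
    if config.synthetic is None:
        raise ValueError("run_simulate requires a synthetic config")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.synthetic)
    paths = {"cohort": out / "cohort.csv", "metadata": out / "metadata.yaml"}
    write_cohort(cohort, paths["cohort"])
    _write_metadata(config, paths["metadata"])
    return paths


def run_full(config: RunConfig) -> dict[str, Path]:
    """Simulate (or load), run the agreement analyses, and emit the model table."""
    paths: dict[str, Path] = {}
    if config.synthetic is not None:
        paths.update(run_simulate(config))
    paths.update(run_agreement(config))
    paths.update(run_model(config))
    return paths
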