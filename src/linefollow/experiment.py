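"""Experiment runners, behavioral indices and fit statistics.

The study design is a 5x5 factorial sweep over auto/manual command-success
capabilities Ca, Cm in {0.3, 0.4, 0.5, 0.6, 0.7}, with many independent 40 s
trials per cell.  Three per-trial indices are summarized per cell:
performance (fraction of frames on the line), auto use ratio (fraction of
trial time in auto mode), and the number of mode switches.

Fit to a reference grid of per-cell means is quantified per index by R^2
(squared Pearson correlation over the 25 paired means) and RMSE.  The
original participant means are not published, so the module ships a
synthetic reference-grid generator emulating the reported qualitative
surfaces, used to exercise the fit machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import ConflictParams, LearningParams, MotorParams, TemporalParams
from .model_rules import CognitiveAgent, ModelVariant, RewardParams
from .task_env import AUTO, MANUAL, EnvConfig, TrialResult, run_trial

__all__ = [
    "GRID_LEVELS",
    "BASELINE_AUTO",
    "BASELINE_MANUAL",
    "ConditionSummary",
    "GridResult",
    "FitStats",
    "ReferenceGridError",
    "run_condition",
    "run_grid",
    "fit_stats",
    "fit_grids",
    "load_reference",
    "synth_reference",
    "SynthTrends",
]

#: the study's capability levels (both axes)
GRID_LEVELS = (0.3, 0.4, 0.5, 0.6, 0.7)

#: baseline tags accepted wherever a ModelVariant is: the optimal auto
#: controller running alone, and the cognitive model with ToAuto removed
BASELINE_AUTO = "auto-only"
BASELINE_MANUAL = "manual-only"

INDICES = ("performance", "auto_use", "switches")


class ReferenceGridError(ValueError):
    """A reference grid is malformed (missing/duplicate cells, bad ranges)."""


@dataclass
class ConditionSummary:
    """Means and standard deviations of the three indices in one (Ca, Cm)
    cell.  sd fields use the sample standard deviation and are 0 by
    convention when n_runs = 1."""

    ca: float
    cm: float
    model: str
    performance_mean: float
    performance_sd: float
    auto_use_mean: float
    auto_use_sd: float
    switches_mean: float
    switches_sd: float
    n_runs: int


@dataclass
class GridResult:
    """A full factorial sweep's per-cell summaries."""

    summaries: list[ConditionSummary]
    model: str
    master_seed: int
    n_runs: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(s) for s in self.summaries])
        return df.sort_values(["ca", "cm"]).reset_index(drop=True)

    def means(self, index: str) -> np.ndarray:
        """The 25 cell means of one index, in (ca, cm) sort order."""
        if index not in INDICES:
            raise KeyError(f"unknown index {index!r}")
        df = self.to_frame()
        return df[f"{index}_mean"].to_numpy()

    def to_csv(self, path, config_hash: str = "", master_seed=None) -> None:
        seed = self.master_seed if master_seed is None else master_seed
        with open(path, "w") as fh:
            fh.write(f"# master_seed={seed} config_sha256={config_hash}\n")
            self.to_frame().to_csv(fh, index=False)


def _agent_for(variant, agent_params: dict):
    if variant == BASELINE_AUTO:
        return None
    if variant == BASELINE_MANUAL:
        return CognitiveAgent(manual_only=True, **agent_params)
    if isinstance(variant, str):
        variant = ModelVariant.from_label(variant)
    return CognitiveAgent(variant=variant, **agent_params)


def _label_for(variant) -> str:
    if isinstance(variant, ModelVariant):
        return variant.label
    return str(variant)


def trial_seed(master_seed: int, ca: float, cm: float, run: int) -> np.random.SeedSequence:
    """Deterministic per-trial seed from (master seed, condition, run), so
    any single trial is reproducible in isolation and condition order is
    exchangeable."""
    return np.random.SeedSequence(
        [int(master_seed), int(round(ca * 100)), int(round(cm * 100)), int(run)]
    )


def run_condition(
    variant,
    ca: float,
    cm: float,
    n_runs: int,
    master_seed: int,
    config: EnvConfig | None = None,
    agent_params: dict | None = None,
) -> ConditionSummary:
    """Run n_runs independent trials in one (Ca, Cm) cell and summarize.

    ``variant`` is a ModelVariant, its label, or one of the baseline tags
    'auto-only' / 'manual-only'.  The auto-only baseline runs the optimal
    controller with no agent (initial mode auto); the manual-only baseline
    runs the cognitive model with the ToAuto rule removed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if config is None:
        config = EnvConfig()
    initial_mode = AUTO if variant == BASELINE_AUTO else config.initial_mode
    if variant == BASELINE_MANUAL:
        initial_mode = MANUAL
    cfg = EnvConfig(
        ca=ca,
        cm=cm,
        scroll_speed=config.scroll_speed,
        frame_dt=config.frame_dt,
        command_rate=config.command_rate,
        trial_duration=config.trial_duration,
        geometry=config.geometry,
        initial_mode=initial_mode,
    )
    agent_params = agent_params or {}
    perf = np.empty(n_runs)
    auto = np.empty(n_runs)
    switches = np.empty(n_runs)
    for i in range(n_runs):
        agent = _agent_for(variant, agent_params)
        try:
            res: TrialResult = run_trial(agent, cfg, seed=trial_seed(master_seed, ca, cm, i))
        except Exception as exc:
            raise RuntimeError(
                f"trial failed in condition Ca={ca}, Cm={cm}, run {i}: {exc}"
            ) from exc
        perf[i] = res.performance
        auto[i] = res.auto_use_ratio
        switches[i] = res.n_switches

    def sd(v):
        return float(np.std(v, ddof=1)) if n_runs > 1 else 0.0

    return ConditionSummary(
        ca=ca,
        cm=cm,
        model=_label_for(variant),
        performance_mean=float(perf.mean()),
        performance_sd=sd(perf),
        auto_use_mean=float(auto.mean()),
        auto_use_sd=sd(auto),
        switches_mean=float(switches.mean()),
        switches_sd=sd(switches),
        n_runs=n_runs,
    )


def run_grid(
    variant,
    ca_levels: Sequence[float] = GRID_LEVELS,
    cm_levels: Sequence[float] = GRID_LEVELS,
    n_runs: int = 500,
    master_seed: int = 0,
    config: EnvConfig | None = None,
    agent_params: dict | None = None,
    progress=None,
) -> GridResult:
    """Full factorial sweep: one ConditionSummary per (Ca, Cm) cell."""
    if not ca_levels or not cm_levels:
        raise ValueError("capability level lists must be nonempty")
    summaries = []
    for ca in ca_levels:
        for cm in cm_levels:
            summaries.append(
                run_condition(variant, ca, cm, n_runs, master_seed, config,
                              agent_params)
            )
            if progress is not None:
                progress(summaries[-1])
    return GridResult(
        summaries=summaries,
        model=_label_for(variant),
        master_seed=master_seed,
        n_runs=n_runs,
    )


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

@dataclass
class FitStats:
    """R^2 (squared Pearson correlation) and RMSE over paired cell means.
    r_squared is None when either vector has zero variance (the correlation
    is undefined, not zero)."""

    r_squared: float | None
    rmse: float


def fit_stats(model_grid: Sequence[float], reference_grid: Sequence[float]) -> FitStats:
    """Compare paired per-cell means of one behavioral index."""
    a = np.asarray(model_grid, dtype=float)
    b = np.asarray(reference_grid, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grids differ in shape: {a.shape} vs {b.shape}")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return FitStats(r_squared=None, rmse=rmse)
    r = float(np.corrcoef(a, b)[0, 1])
    return FitStats(r_squared=r * r, rmse=rmse)


def fit_grids(model: GridResult, reference: pd.DataFrame) -> dict[str, FitStats]:
    """Per-index fit of a sweep to a reference grid (matched on (ca, cm))."""
    ref = _validate_reference(reference)
    df = model.to_frame()
    cells = list(zip(df["ca"].round(6), df["cm"].round(6)))
    ref = ref.set_index(["ca", "cm"]).loc[cells].reset_index()
    out = {}
    for index in INDICES:
        out[index] = fit_stats(df[f"{index}_mean"].to_numpy(),
                               ref[index].to_numpy())
    return out


# ---------------------------------------------------------------------------
# reference grids
# ---------------------------------------------------------------------------

def _validate_reference(
    df: pd.DataFrame,
    ca_levels: Sequence[float] = GRID_LEVELS,
    cm_levels: Sequence[float] = GRID_LEVELS,
) -> pd.DataFrame:
    required = {"ca", "cm", "performance", "auto_use", "switches"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ReferenceGridError(f"missing columns: {sorted(missing_cols)}")
    seen = set()
    for _, row in df.iterrows():
        cell = (round(float(row["ca"]), 6), round(float(row["cm"]), 6))
        if cell in seen:
            raise ReferenceGridError(f"duplicated cell (ca, cm)={cell}")
        seen.add(cell)
        for col in ("performance", "auto_use"):
            v = float(row[col])
            if not 0.0 <= v <= 1.0:
                raise ReferenceGridError(
                    f"{col}={v} out of [0, 1] in cell (ca, cm)={cell}"
                )
        if float(row["switches"]) < 0:
            raise ReferenceGridError(f"switches < 0 in cell (ca, cm)={cell}")
    expected = {(round(a, 6), round(c, 6)) for a in ca_levels for c in cm_levels}
    absent = expected - seen
    if absent:
        raise ReferenceGridError(f"missing cells (ca, cm): {sorted(absent)}")
    extra = seen - expected
    if extra:
        raise ReferenceGridError(f"unexpected cells (ca, cm): {sorted(extra)}")
    return df


def load_reference(path) -> pd.DataFrame:
    """Load and validate a 25-row reference grid CSV (columns ca, cm,
    performance, auto_use, switches; '#'-prefixed comment lines allowed)."""
    df = pd.read_csv(path, comment="#")
    return _validate_reference(df).sort_values(["ca", "cm"]).reset_index(drop=True)


@dataclass
class SynthTrends:
    """Monotone trend parameters for the synthetic reference grid, emulating
    the reported qualitative surfaces: performance rising along both axes,
    auto use rising in Ca and falling in Cm, switches falling along both.
    Slopes are per unit of normalized level ((x - 0.3) / 0.4)."""

    performance_base: float = 0.40
    performance_ca: float = 0.25
    performance_cm: float = 0.25
    auto_use_base: float = 0.55
    auto_use_ca: float = 0.30
    auto_use_cm: float = -0.25
    switches_base: float = 14.0
    switches_ca: float = -6.0
    switches_cm: float = -5.0
    noise: float = 0.0
    switches_noise: float = 0.0


def synth_reference(
    seed,
    trend_params: SynthTrends | None = None,
    ca_levels: Sequence[float] = GRID_LEVELS,
    cm_levels: Sequence[float] = GRID_LEVELS,
) -> pd.DataFrame:
    """A synthetic reference grid obeying configured monotone trends; a
    stand-in test fixture for unpublished participant means."""
    p = trend_params or SynthTrends()
    rng = np.random.default_rng(seed)
    rows = []
    for ca in ca_levels:
        for cm in cm_levels:
            a = (ca - 0.3) / 0.4
            c = (cm - 0.3) / 0.4
            perf = p.performance_base + p.performance_ca * a + p.performance_cm * c
            auto = p.auto_use_base + p.auto_use_ca * a + p.auto_use_cm * c
            sw = p.switches_base + p.switches_ca * a + p.switches_cm * c
            if p.noise:
                perf += rng.normal(0, p.noise)
                auto += rng.normal(0, p.noise)
            if p.switches_noise:
                sw += rng.normal(0, p.switches_noise)
            rows.append(
                {
                    "ca": ca,
                    "cm": cm,
                    "performance": float(np.clip(perf, 0.0, 1.0)),
                    "auto_use": float(np.clip(auto, 0.0, 1.0)),
                    "switches": float(max(sw, 0.0)),
                }
            )
    return pd.DataFrame(rows)
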