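"""Burrowing time-course analysis.

Animals are loaded at the bottom of a well under a Pluronic F-127 gel
layer with a bacterial attractant on top; the number of animals that
have burrowed up to the surface is scored every 15 minutes for 2 hours.
The per-strain readout used by the composite scoring stage is the mean
percentage at the surface at the 2-hour endpoint, with its standard
error over replicate wells.  Strain-by-time effects are assessed with a
conventional fixed-effects two-way ANOVA on replicate percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


class DataIntegrityError(ValueError):
    """A count exceeds the number of worms loaded."""


class UnbalancedDesignError(ValueError):
    """The strain x time table has empty cells; the two-way ANOVA is not run."""


@dataclass
class BurrowTrial:
    """One well's count-at-surface time course."""

    strain: str
    replicate: int
    n_total: int
    times: np.ndarray  # minutes, strictly increasing
    counts: np.ndarray  # worms at surface per time point

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if self.times.shape != self.counts.shape or self.times.size == 0:
            raise ValueError("times and counts must be equal-length, non-empty")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if (self.counts < 0).any() or (self.counts > self.n_total).any():
            raise DataIntegrityError("counts must lie in [0, n_total]")
        if np.any(np.diff(self.counts) < 0):
            warnings.warn(
                f"non-monotone counts in {self.strain} replicate "
                f"{self.replicate}: worms at the attractant are expected to stay",
                stacklevel=2)


def surface_fraction_curve(trial: BurrowTrial) -> np.ndarray:
    """Percent of loaded animals at the surface at each scoring time."""
    return 100.0 * trial.counts / trial.n_total


def endpoint_percent(
    trials: list[BurrowTrial], t: float = 120.0
) -> tuple[float, float]:
    """Mean and SEM over replicates of the percent at the surface at time t.

    With one replicate the SEM is undefined and reported as 0 with a
    warning.
    """
    if not trials:
        raise ValueError("no trials provided")
    values = []
    for trial in trials:
        hits = np.flatnonzero(np.isclose(trial.times, t))
        if hits.size == 0:
            raise ValueError(
                f"time {t} min missing from {trial.strain} replicate "
                f"{trial.replicate}")
        values.append(surface_fraction_curve(trial)[hits[0]])
    values = np.asarray(values)
    mean = float(values.mean())
    if values.size == 1:
        warnings.warn("single replicate: SEM undefined, reported as 0",
                      stacklevel=2)
        return mean, 0.0
    return mean, float(values.std(ddof=1) / np.sqrt(values.size))


def endpoint_binomial_sem(trials: list[BurrowTrial], t: float = 120.0) -> float:
    """Binomial standard error (in percent) of the pooled endpoint proportion.

    Useful as a variance floor when few replicate wells happen to report
    identical counts (e.g. every wild-type worm surfaces in every well),
    which would otherwise give a degenerate zero SEM.  The proportion is
    Laplace-smoothed so the floor stays positive at 0% and 100%.
    """
    if not trials:
        raise ValueError("no trials provided")
    total_n = 0
    total_count = 0.0
    for trial in trials:
        hits = np.flatnonzero(np.isclose(trial.times, t))
        if hits.size == 0:
            raise ValueError(
                f"time {t} min missing from {trial.strain} replicate "
                f"{trial.replicate}")
        total_n += trial.n_total
        total_count += trial.counts[hits[0]]
    p = (total_count + 1.0) / (total_n + 2.0)
    return float(100.0 * np.sqrt(p * (1.0 - p) / total_n))


def trials_to_frame(trials: list[BurrowTrial]) -> pd.DataFrame:
    """Long-format table: strain, replicate, time_min, count, n_total, pct."""
    rows = []
    for trial in trials:
        pct = surface_fraction_curve(trial)
        for t, cnt, p in zip(trial.times, trial.counts, pct):
            rows.append({"strain": trial.strain, "replicate": trial.replicate,
                         "time_min": t, "count": cnt,
                         "n_total": trial.n_total, "pct": p})
    return pd.DataFrame(rows)


def strain_time_anova(trials: list[BurrowTrial]) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA of surface percentages.

    Factors: strain, scoring time, and their interaction; observations
    are replicate-well percentages.  Requires >= 2 strains, >= 2 time
    points and >= 2 replicates per cell; a design with empty strain x
    time cells raises :class:`UnbalancedDesignError`.

    Returns the ANOVA table (sum_sq, df, F, PR(>F)) indexed by effect.
    """
    df = trials_to_frame(trials)
    if df["strain"].nunique() < 2:
        raise ValueError("need at least 2 strains")
    if df["time_min"].nunique() < 2:
        raise ValueError("need at least 2 time points")
    cell_counts = df.groupby(["strain", "time_min"]).size()
    full = df["strain"].nunique() * df["time_min"].nunique()
    if len(cell_counts) < full:
        raise UnbalancedDesignError("empty strain x time cells")
    if cell_counts.min() < 2:
        raise ValueError("need at least 2 replicates per strain x time cell")

    model = smf.ols("pct ~ C(strain) * C(time_min)", data=df).fit()
    if model.ssr <= 1e-10 * max(model.centered_tss, 1.0):
        warnings.warn("zero residual variance: F statistics are degenerate",
                      stacklevel=2)
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={
        "C(strain)": "strain", "C(time_min)": "time",
        "C(strain):C(time_min)": "strain:time", "Residual": "residual"})
    return table


def strain_endpoint_summary(
    trials: list[BurrowTrial], t: float = 120.0, sem_floor: bool = False
) -> pd.DataFrame:
    """Per-strain endpoint summary: strain, mean_endpoint_pct, sem, n_replicates.

    With ``sem_floor=True`` the replicate-level SEM is floored by the
    pooled binomial standard error (:func:`endpoint_binomial_sem`), so a
    handful of replicates reporting identical counts cannot produce a
    degenerate zero SEM for the Z-score denominator.
    """
    by_strain: dict[str, list[BurrowTrial]] = {}
    for trial in trials:
        by_strain.setdefault(trial.strain, []).append(trial)
    rows = []
    for strain, group in by_strain.items():
        mean, sem = endpoint_percent(group, t=t)
        if sem_floor:
            sem = max(sem, endpoint_binomial_sem(group, t=t))
        rows.append({"strain": strain, "mean_endpoint_pct": mean,
                     "sem": sem, "n_replicates": len(group)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File interfaces


def read_burrow_csv(path) -> list[BurrowTrial]:
    """Read burrowing counts CSV (strain, replicate, time_min, count, n_total)."""
    df = pd.read_csv(path)
    required = {"strain", "replicate", "time_min", "count", "n_total"}
    if not required.issubset(df.columns):
        raise ValueError(f"burrowing CSV must contain columns {sorted(required)}")
    trials = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"]):
        grp = grp.sort_values("time_min")
        n_total = grp["n_total"].iloc[0]
        if grp["n_total"].nunique() != 1:
            raise DataIntegrityError(
                f"n_total varies within {strain} replicate {rep}")
        trials.append(BurrowTrial(strain=str(strain), replicate=int(rep),
                                  n_total=int(n_total),
                                  times=grp["time_min"].to_numpy(),
                                  counts=grp["count"].to_numpy()))
    return trials


def write_burrow_csv(trials: list[BurrowTrial], path) -> None:
    trials_to_frame(trials).drop(columns="pct").to_csv(path, index=False)


def write_curve_csv(trials: list[BurrowTrial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)
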