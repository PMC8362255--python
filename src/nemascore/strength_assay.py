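"""Muscle strength from pillar deflections: force model and f95 statistic.

The strength readout of the micropillar assay is ``f95``: the 95th
percentile of the per-frame maximal pillar forces exerted by one animal
over a one-minute video.  Deflections convert to forces through the
stiffness of a base-clamped circular cantilever.  Because the pillars
are stout (height/diameter ~ 2), the default model is a Timoshenko beam
that includes shear compliance on top of Euler-Bernoulli bending:

    compliance(z) = z^3 / (3 E I) + z / (kappa G A)

with I = pi d^4 / 64, A = pi d^2 / 4, G = E / (2 (1 + nu)) and
kappa = 6 (1 + nu) / (7 + 6 nu) the shear factor of a circular section.
Force is linear in deflection: F = delta / compliance.

Absolute forces depend on the elastic constants; every downstream score
(Z-scores, fold changes, ranks) depends only on ratios and ranks and is
therefore robust to the calibration of the force model.

f95 is normalized by the cube of body diameter to remove the strong
dependence of exertable force on animal girth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pillar_tracking import DeflectionFrame, PillarArena, max_deflection_per_frame


@dataclass
class ForceTrace:
    """Per-frame maximal pillar force (uN) for one animal."""

    worm_id: str
    strain: str
    forces: np.ndarray
    frame_rate: float = 5.0

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 1 or self.forces.size < 1:
            raise ValueError("forces must be a non-empty 1-D array")
        if (self.forces < 0).any():
            raise ValueError("forces must be non-negative")


@dataclass
class StrengthRecord:
    """One animal's strength summary.

    ``normalized_strength`` = f95 / diameter^3 (uN / um^3).
    """

    worm_id: str
    strain: str
    f95: float
    diameter: float
    normalized_strength: float

    @classmethod
    def from_trace(cls, trace: ForceTrace, diameter: float) -> "StrengthRecord":
        value = f95(trace)
        return cls(worm_id=trace.worm_id, strain=trace.strain, f95=value,
                   diameter=diameter,
                   normalized_strength=normalize_strength(value, diameter))


def shear_coefficient(poisson_ratio: float) -> float:
    """Timoshenko shear factor kappa for a solid circular cross-section."""
    nu = poisson_ratio
    return 6.0 * (1.0 + nu) / (7.0 + 6.0 * nu)


def pillar_compliance(
    arena: PillarArena,
    contact_height: float | None = None,
    include_shear: bool = True,
) -> float:
    """Cantilever compliance (um per uN) at the worm's contact height.

    ``contact_height`` is the load application height above the base in
    um; by default the pillar tip (worst case: softest response).  With
    ``include_shear=False`` the model reduces to pure Euler-Bernoulli
    bending z^3/(3EI).
    """
    if contact_height is None:
        contact_height = arena.pillar_height
    if not 0.0 <= contact_height <= arena.pillar_height:
        raise ValueError("contact_height must lie within [0, pillar_height]")

    d = arena.pillar_diameter * 1e-6  # m
    z = contact_height * 1e-6  # m
    e_mod = arena.elastic_modulus  # Pa
    inertia = np.pi * d**4 / 64.0
    compliance = z**3 / (3.0 * e_mod * inertia)  # m / N
    if include_shear:
        area = np.pi * d**2 / 4.0
        g_mod = e_mod / (2.0 * (1.0 + arena.poisson_ratio))
        compliance += z / (shear_coefficient(arena.poisson_ratio) * g_mod * area)
    # m/N == um/uN (both scale by 1e6)
    return compliance


def deflection_to_force(
    delta: float | np.ndarray,
    arena: PillarArena,
    contact_height: float | None = None,
    include_shear: bool = True,
):
    """Convert deflection magnitude (um) to force (uN); linear in delta."""
    delta = np.asarray(delta, dtype=float)
    if (delta < 0).any():
        raise ValueError("deflection magnitude must be non-negative")
    force = delta / pillar_compliance(arena, contact_height, include_shear)
    return float(force) if force.ndim == 0 else force


def trace_from_deflections(
    frames: list[DeflectionFrame],
    arena: PillarArena,
    worm_id: str = "worm",
    strain: str = "unknown",
    contact_height: float | None = None,
    include_shear: bool = True,
) -> ForceTrace:
    """Build a per-frame maximal-force trace from tracked deflection frames."""
    if not frames:
        raise ValueError("no frames provided")
    mags = np.array([max_deflection_per_frame(fr)[1] for fr in frames])
    forces = deflection_to_force(mags, arena, contact_height, include_shear)
    return ForceTrace(worm_id=worm_id, strain=strain, forces=forces,
                      frame_rate=arena.frame_rate)


def f95(trace: ForceTrace | np.ndarray) -> float:
    """95th percentile of the per-frame maximal forces (uN).

    Uses the linear-interpolation percentile convention: with sorted
    values x_(1..n), the percentile sits at fractional order-statistic
    position 1 + 0.95 (n - 1).  A length-1 trace returns its only value.
    """
    forces = trace.forces if isinstance(trace, ForceTrace) else np.asarray(trace, dtype=float)
    if forces.size == 0:
        raise ValueError("empty force trace")
    return float(np.percentile(forces, 95.0, method="linear"))


def normalize_strength(f95_value: float, diameter: float) -> float:
    """Body-size normalized strength: f95 / diameter^3 (uN / um^3)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return f95_value / diameter**3


def fold_change(
    strain_records: list[StrengthRecord], wt_records: list[StrengthRecord]
) -> float:
    """Ratio of mean normalized strength, mutant over wild type."""
    if not strain_records or not wt_records:
        raise ValueError("both record lists must be non-empty")
    mut = np.mean([r.normalized_strength for r in strain_records])
    wt = np.mean([r.normalized_strength for r in wt_records])
    return float(mut / wt)


def ranksum_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Normal approximation with tie correction and continuity correction.
    The statistic is U for ``sample_a``: the number of (a, b) pairs with
    a > b, counting ties as 1/2.  A pooled sample in which every value
    is identical is degenerate; p = 1 is returned with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled observations identical; p set to 1",
                      stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Per-strain summaries


def strength_table(records: list[StrengthRecord]) -> pd.DataFrame:
    """Tabulate per-worm strength records."""
    return pd.DataFrame(
        [{"worm_id": r.worm_id, "strain": r.strain, "f95": r.f95,
          "diameter": r.diameter,
          "normalized_strength": r.normalized_strength} for r in records])


def strain_strength_summary(
    records: list[StrengthRecord], wt_label: str = "wild_type"
) -> pd.DataFrame:
    """Per-strain mean/SEM of normalized strength, fold change and rank-sum p.

    The mean of per-worm normalized strengths with its standard error is
    the per-strain quantity that feeds the Z-score stage.  Fold change
    and the Wilcoxon rank-sum p-value compare each strain against the
    wild-type sample.
    """
    df = strength_table(records)
    if wt_label not in set(df["strain"]):
        raise ValueError(f"wild-type strain {wt_label!r} missing from records")
    wt_values = df.loc[df["strain"] == wt_label, "normalized_strength"].to_numpy()

    rows = []
    for strain, grp in df.groupby("strain", sort=False):
        values = grp["normalized_strength"].to_numpy()
        n = len(values)
        sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        if strain == wt_label:
            fc, p = 1.0, 1.0
        else:
            fc = float(values.mean() / wt_values.mean())
            if n >= 2 and wt_values.size >= 2:
                _, p = ranksum_test(values, wt_values)
            else:
                p = np.nan
        rows.append({"strain": strain, "n": n, "mean": float(values.mean()),
                     "sem": sem, "fold_change": fc, "p": p})
    return pd.DataFrame(rows)


def read_worm_metadata(path) -> pd.DataFrame:
    """Read worm metadata CSV (worm_id, strain, diameter_um)."""
    df = pd.read_csv(path)
    required = {"worm_id", "strain", "diameter_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata CSV must contain columns {sorted(required)}")
    return df
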