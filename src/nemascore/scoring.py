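"""Composite muscle scores: assay Z-scores, muscle function score, MDS.

The two functional assays (micropillar strength and burrowing) are put
on a common scale per strain j with

    Z_j = (mu_j - mu_WT) / sigma_WT

where mu_j is the strain's assay mean (normalized strength, or percent
at the surface at 2 h) and mu_WT, sigma_WT are the wild-type mean and
*standard error of the mean*.  Note the denominator: sigma here is the
WT SEM, not the WT standard deviation, so Z measures separation in
units of the uncertainty of the wild-type mean.  Z = 0 means
indistinguishable from wild type.

Because the two assays produce Z-scores on very different scales, each
assay's vector of Z-scores is rescaled by its absolute maximum, placing
normalized scores of impaired strains in (-1, 0).  The muscle function
score (MFS) is the equal-weight sum of the two normalized Z-scores,
ranging from -2 (most impaired in both assays) to 0 (wild-type-like);
PCA of the Z matrix is provided as a diagnostic of that weighting.

Muscle structure is summarized by the Muscle Disorganization Score
(MDS): five sarcomere sites (I-band/phalloidin, A-band/MHC A, base of
dense bodies and M-lines/UNC-95, M-line depth/UNC-89, dense-body
depth/ATN-1) are each graded 0 (organized) to 3 (severely disorganized)
in half-point steps, and MDS is their sum (0..15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

SITE_COLUMNS = (
    "phalloidin_iband",
    "mhca_aband",
    "unc95_base",
    "unc89_mline",
    "atn1_dense_body",
)

N_SITES = 5
MAX_SITE_SCORE = 3.0
MAX_MDS = N_SITES * MAX_SITE_SCORE


@dataclass
class AssayScores:
    """Per-strain Z-score bookkeeping for one assay."""

    strain: str
    assay: str  # "nemaflex" or "burrowing"
    mu_j: float
    mu_wt: float
    sigma_wt: float
    z: float
    z_norm: float | None = None


@dataclass
class MuscleFunctionScore:
    """Composite per-strain muscle function score."""

    strain: str
    mfs: float
    weights: tuple[float, float] = (1.0, 1.0)
    pca_variance_explained: float | None = None


@dataclass
class MDSRecord:
    """Five ordinal site scores and their sum."""

    strain: str | None
    site_scores: tuple[float, ...]
    mds: float

    def __post_init__(self) -> None:
        self.site_scores = tuple(float(s) for s in self.site_scores)
        _validate_sites(self.site_scores)
        if not np.isclose(self.mds, sum(self.site_scores)):
            raise ValueError("mds must equal the sum of site scores")


def _validate_sites(site_scores) -> None:
    if len(site_scores) != N_SITES:
        raise ValueError(f"exactly {N_SITES} site scores required")
    arr = np.asarray(site_scores, dtype=float)
    if (arr < 0).any() or (arr > MAX_SITE_SCORE).any():
        raise ValueError(f"site scores must lie in [0, {MAX_SITE_SCORE}]")
    if not np.allclose(2 * arr, np.round(2 * arr), atol=1e-9):
        raise ValueError("site scores must be multiples of 0.5")


def z_score(mu_j: float, mu_wt: float, sigma_wt: float) -> float:
    """Assay Z-score (mu_j - mu_wt) / sigma_wt; sigma_wt is the WT SEM."""
    if sigma_wt <= 0:
        raise ValueError("sigma_wt must be positive")
    return (mu_j - mu_wt) / sigma_wt


def normalize_z(z_values) -> np.ndarray:
    """Divide a vector of Z-scores by its absolute maximum.

    Rank order is preserved; the output minimum is exactly -1 whenever
    the largest-magnitude value is negative (the usual case of every
    mutant being impaired).  Better-than-WT strains (Z > 0) are allowed
    and simply map to positive normalized values.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0 or np.all(z == 0):
        raise ValueError("need at least one nonzero Z-score to normalize")
    return z / np.max(np.abs(z))


def muscle_function_score(
    znorm_nemaflex: float,
    znorm_burrowing: float,
    weights: tuple[float, float] = (1.0, 1.0),
    strain: str = "",
) -> MuscleFunctionScore:
    """Weighted sum of the two normalized assay Z-scores (default equal)."""
    for name, value in (("nemaflex", znorm_nemaflex),
                        ("burrowing", znorm_burrowing)):
        if value is None or not np.isfinite(value):
            raise ValueError(f"missing {name} normalized Z-score for "
                             f"strain {strain!r}")
    mfs = weights[0] * znorm_nemaflex + weights[1] * znorm_burrowing
    return MuscleFunctionScore(strain=strain, mfs=float(mfs),
                               weights=tuple(weights))


def pca_weights(z_matrix) -> tuple[np.ndarray, float]:
    """First principal component of the column-scaled (strains x 2) Z matrix.

    Each column is centred and scaled to unit variance, so the PCA is an
    eigen-decomposition of the 2x2 correlation matrix.  Returns
    ``(loadings, variance_explained)`` with unit-norm loadings flipped
    so that both are >= 0 when they share a sign (impaired strains, with
    negative Z, then project to negative composite scores).

    A rank-deficient matrix (a zero-variance column) is degenerate: a
    warning is issued and ``variance_explained = 1`` is returned with
    equal loadings.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2:
        raise ValueError("z_matrix must be (n_strains, 2)")
    if z.shape[0] < 3:
        raise ValueError("need at least 3 strains for PCA")
    if not np.isfinite(z).all():
        raise ValueError("z_matrix must be finite")

    sd = z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        warnings.warn("rank-deficient Z matrix: zero-variance column",
                      stacklevel=2)
        return np.array([1.0, 1.0]) / np.sqrt(2.0), 1.0
    scaled = (z - z.mean(axis=0)) / sd
    corr = scaled.T @ scaled / (z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    loadings = eigvecs[:, -1]
    if loadings.sum() < 0:
        loadings = -loadings
    variance_explained = float(eigvals[-1] / eigvals.sum())
    return loadings, variance_explained


def mds(site_scores, strain: str | None = None) -> MDSRecord:
    """Sum five ordinal site scores into a Muscle Disorganization Score."""
    _validate_sites(site_scores)
    return MDSRecord(strain=strain, site_scores=tuple(site_scores),
                     mds=float(np.sum(site_scores)))


# ---------------------------------------------------------------------------
# Strain-table pipeline


def assay_z_table(
    summary: pd.DataFrame, wt_label: str = "wild_type"
) -> pd.DataFrame:
    """Z-scores for one assay from a per-strain (strain, mean, sem) table.

    sigma_WT is the wild-type SEM; the wild type itself gets Z = 0 by
    construction.
    """
    required = {"strain", "mean", "sem"}
    if not required.issubset(summary.columns):
        raise ValueError(f"summary must contain columns {sorted(required)}")
    wt = summary.loc[summary["strain"] == wt_label]
    if wt.empty:
        raise ValueError(f"wild-type strain {wt_label!r} missing")
    mu_wt = float(wt["mean"].iloc[0])
    sigma_wt = float(wt["sem"].iloc[0])
    out = summary[["strain"]].copy()
    out["z"] = [z_score(m, mu_wt, sigma_wt) for m in summary["mean"]]
    return out


def compute_muscle_function_scores(
    nemaflex_summary: pd.DataFrame,
    burrowing_summary: pd.DataFrame,
    wt_label: str = "wild_type",
    weights: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Combine per-strain assay summaries into the composite score table.

    Inputs are (strain, mean, sem) tables for the strength and burrowing
    assays covering the same strains.  The absolute-maximum
    normalization is taken over all strains present (wild type
    included).  Returns columns: strain, z_nf, z_bur, znorm_nf,
    znorm_bur, mfs.
    """
    z_nf = assay_z_table(nemaflex_summary, wt_label).rename(columns={"z": "z_nf"})
    z_bur = assay_z_table(burrowing_summary, wt_label).rename(columns={"z": "z_bur"})
    merged = z_nf.merge(z_bur, on="strain", how="outer")
    if merged[["z_nf", "z_bur"]].isna().any().any():
        missing = merged.loc[merged.isna().any(axis=1), "strain"].tolist()
        raise ValueError(f"strains missing an assay: {missing}")
    merged["znorm_nf"] = normalize_z(merged["z_nf"].to_numpy())
    merged["znorm_bur"] = normalize_z(merged["z_bur"].to_numpy())
    merged["mfs"] = [
        muscle_function_score(a, b, weights=weights, strain=s).mfs
        for s, a, b in zip(merged["strain"], merged["znorm_nf"],
                           merged["znorm_bur"])
    ]
    return merged


def attach_mds(
    scores: pd.DataFrame, mds_records: list[MDSRecord] | pd.DataFrame
) -> pd.DataFrame:
    """Join per-strain MDS values onto the composite score table."""
    if isinstance(mds_records, pd.DataFrame):
        mds_df = mds_records[["strain", "mds"]]
    else:
        mds_df = pd.DataFrame(
            [{"strain": r.strain, "mds": r.mds} for r in mds_records])
    return scores.merge(mds_df, on="strain", how="inner")


# ---------------------------------------------------------------------------
# Packaged structural-score fixture


def load_table2() -> pd.DataFrame:
    """Load the packaged 21-strain site-score table.

    Columns: strain, the five site scores (0-3 in 0.5 steps), the
    printed MDS, and per-site provenance flags (study / lit / unpub).
    """
    with resources.files("nemascore.fixtures").joinpath(
            "table2_mds.csv").open("r") as fh:
        return pd.read_csv(fh)


def site_scores_to_records(df: pd.DataFrame) -> list[MDSRecord]:
    """Convert a site-score table into validated MDS records (sums recomputed)."""
    records = []
    for _, row in df.iterrows():
        records.append(mds([row[c] for c in SITE_COLUMNS], strain=row["strain"]))
    return records


def read_site_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"strain", *SITE_COLUMNS}
    if not required.issubset(df.columns):
        raise ValueError(f"site-score CSV must contain columns {sorted(required)}")
    return df


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)
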