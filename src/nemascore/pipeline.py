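"""End-to-end composition: simulated study -> scores -> structure-function fit.

Thin glue over the assay modules, used both for synthetic validation
(does the composite score recover the latent health ordering?) and as
the template for analyzing real per-strain tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import burrowing_assay, scoring, structure_function, synthetic_data
from .strength_assay import strain_strength_summary
from .structure_function import RegressionResult


@dataclass
class StudyResult:
    """Analyzed study: per-strain score table plus summary statistics."""

    scores: pd.DataFrame  # strain, z_nf, z_bur, znorm_nf, znorm_bur, mfs, mds
    regression: RegressionResult  # mfs on mds
    spearman_assays: float  # Spearman(Z_nf, Z_bur) over strains
    pca_loadings: np.ndarray
    pca_variance_explained: float


def analyze_study(
    study: synthetic_data.StudyData, wt_label: str = "wild_type"
) -> StudyResult:
    """Run the full scoring pipeline on one (simulated or real) study."""
    nf = strain_strength_summary(study.strength_records, wt_label=wt_label)
    # Binomial SEM floor: three wells of a strong burrower can report
    # identical counts, and the WT SEM is the Z-score denominator.
    bur = burrowing_assay.strain_endpoint_summary(study.burrow_trials,
                                                  sem_floor=True)
    bur = bur.rename(columns={"mean_endpoint_pct": "mean"})

    scores = scoring.compute_muscle_function_scores(
        nf[["strain", "mean", "sem"]], bur[["strain", "mean", "sem"]],
        wt_label=wt_label)
    scores = scoring.attach_mds(scores, study.mds_records)

    regression = structure_function.fit_structure_function(
        scores["mds"].to_numpy(), scores["mfs"].to_numpy())
    rho = structure_function.spearman(scores["z_nf"].to_numpy(),
                                      scores["z_bur"].to_numpy())
    loadings, var_exp = scoring.pca_weights(
        scores[["z_nf", "z_bur"]].to_numpy())
    return StudyResult(scores=scores, regression=regression,
                       spearman_assays=rho, pca_loadings=loadings,
                       pca_variance_explained=var_exp)


def implied_assay_spearman(profiles) -> float:
    """Spearman between the two assays' true strain-level means.

    The generator-implied value against which an analyzed study's
    Spearman(Z_nf, Z_bur) can be compared: Z is a monotone (affine)
    transform of the assay mean, so ranks carry over exactly.
    """
    strength = [synthetic_data.expected_f95(p) / p.diameter_mean**3
                for p in profiles]
    endpoint = [synthetic_data.expected_endpoint_fraction(p)
                for p in profiles]
    return structure_function.spearman(strength, endpoint)


def recovery_experiment(
    n_runs: int = 200,
    seed: int = 0,
    n_mutants: int = 20,
    n_worms_strength: int = 25,
    n_frames: int = synthetic_data.DEFAULT_N_FRAMES,
) -> dict:
    """Repeated simulate-and-analyze runs of the default panel.

    Returns summary statistics over runs: the fraction with a negative
    function-on-disorganization slope, mean PCA loadings, mean
    Spearman(Z_nf, Z_bur), and the generator-implied Spearman.
    """
    panel = synthetic_data.default_strain_panel(n_mutants=n_mutants)
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    slopes = np.empty(n_runs)
    spearmans = np.empty(n_runs)
    loadings = np.empty((n_runs, 2))
    for i, run_seed in enumerate(seeds):
        study = synthetic_data.simulate_study(
            panel, n_worms_strength=n_worms_strength, n_frames=n_frames,
            seed=int(run_seed))
        result = analyze_study(study)
        slopes[i] = result.regression.slope
        spearmans[i] = result.spearman_assays
        loadings[i] = result.pca_loadings
    return {
        "n_runs": n_runs,
        "frac_negative_slope": float(np.mean(slopes < 0)),
        "mean_slope": float(slopes.mean()),
        "mean_spearman": float(spearmans.mean()),
        "implied_spearman": implied_assay_spearman(panel),
        "mean_loadings": loadings.mean(axis=0),
    }
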