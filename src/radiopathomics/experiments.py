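"""Parameter-recovery experiments on synthetic cohorts.

Real cohorts of this kind are private, so cohort-specific result values
cannot be reproduced.  What can be verified is that each stage of the
pipeline recovers structure that was planted by the synthetic generator:
segmentation recovers ground-truth nucleus counts, the cross-modal
Spearman stage recovers the planted radiomics loadings, the KS stage
distinguishes differing from identical endpoint couplings, and
clustering recovers planted partitions.  These experiments are used by
the analysis drivers, the test suite and the acceptance script alike.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .assoc import correlation_filter, cross_correlation, endpoint_correlation, ks_compare, spearman_matrix, zscore
from .clustering import hac_cluster
from .density import segment_nuclei
from .pipeline import RunConfig, cohort_pathomics
from .synthetic import SyntheticCohortSpec, generate_cohort, generate_tile

__all__ = [
    "segmentation_recovery",
    "cross_modal_recovery",
    "ks_coupling_replicates",
    "clustering_recovery",
    "filter_postcondition_sweep",
]


def segmentation_recovery(n_tiles: int = 200, seed: int = 0,
                          spec: SyntheticCohortSpec | None = None) -> dict:
    """Fraction of synthetic tiles whose nucleus count is recovered exactly.

    Tiles are drawn at the generator's default per-patient rates (latent
    factors resampled per tile group), so densities span the cohort's
    realistic range; nuclei are non-overlapping by construction.
    """
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(seed)
    exact = 0
    abs_err = []
    for _ in range(n_tiles):
        z = rng.normal(0.0, spec.latent_sd)
        rate = spec.nuclei_rate_base * np.exp(spec.nuclei_rate_slope * z)
        tile_seed = int(rng.integers(0, 2**31 - 1))
        img, truth = generate_tile(rate, spec.tile_size, spec.nucleus_radius_range,
                                   rng=tile_seed)
        seg = segment_nuclei(img)
        err = abs(seg.nucleus_count - int(truth.max()))
        abs_err.append(err)
        exact += err == 0
    return {
        "n_tiles": n_tiles,
        "exact_match_fraction": exact / n_tiles,
        "max_abs_error": int(max(abs_err)),
    }


def cross_modal_recovery(
    n_patients: int = 200,
    loading_range: tuple[float, float] = (-0.8, 0.8),
    noise_sd: float = 0.6,
    n_tiles_per_patient: int = 2,
    seed: int = 0,
) -> dict:
    """Recovery of planted radiomics loadings by the cross-modal stage.

    Radiomics feature j is ``a_j z + noise``; its population correlation
    with the latent factor is ``a_j / sqrt(a_j^2 + noise_sd^2)``.  The
    histology path is run end-to-end (tiles -> patches -> segmentation ->
    density maps -> Haralick -> slide aggregation) and a density-linked
    slide feature is correlated against every radiomics feature; the
    estimated Spearman vector should correlate strongly with the implied
    one across features.
    """
    spec = SyntheticCohortSpec(
        n_patients=n_patients,
        radiomics_loading_range=loading_range,
        noise_sd=noise_sd,
        n_tiles_per_patient=n_tiles_per_patient,
        seed=seed,
    )
    cohort = generate_cohort(spec)
    cfg = RunConfig(synthetic=spec, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pathomics, _ = cohort_pathomics(cohort, cfg)
    xcorr = cross_correlation({"S3": pathomics["S3"]}, cohort.radiomics,
                              report_threshold=1.1)
    # a slide feature monotone in cell density, hence in z
    estimated = xcorr.matrices["S3"].loc["mean_sum_average_D1"]
    a = cohort.radiomics_loadings
    implied = a / np.sqrt(a**2 + noise_sd**2)
    recovery = float(np.corrcoef(estimated.to_numpy(), implied)[0, 1])
    return {
        "n_patients": n_patients,
        "n_features": len(a),
        "recovery_correlation": recovery,
    }


def _coupled_table(n_patients, n_features, loading_range, z, rng, noise_sd=0.6):
    a = rng.uniform(*loading_range, size=n_features)
    x = z[:, None] * a[None, :] + rng.normal(0, noise_sd, (n_patients, n_features))
    return pd.DataFrame(x, columns=[f"g{j}" for j in range(n_features)])


def ks_coupling_replicates(
    n_reps: int = 30,
    n_patients: int = 200,
    n_features: int = 120,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Power/calibration of the KS comparison of endpoint-correlation sets.

    Per replicate, two feature 'modalities' are generated from the same
    latent factor.  Under *differing* couplings (one modality loads on
    the factor, the other is nearly decoupled) the KS test comparing
    their endpoint-correlation distributions should reject; under
    *identical* coupling ranges it should retain.  Returns the rejection
    rates over replicates.
    """
    root = np.random.SeedSequence(seed)
    reject_diff = retain_same = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        z = rng.normal(0, 1, n_patients)
        endpoint = pd.Series(z + rng.normal(0, 0.6, n_patients), name="endpoint")
        strong_a = _coupled_table(n_patients, n_features, (0.4, 0.8), z, rng)
        strong_b = _coupled_table(n_patients, n_features, (0.4, 0.8), z, rng)
        null_b = _coupled_table(n_patients, n_features, (-0.05, 0.05), z, rng)
        rho = {}
        for key, tab in (("a", strong_a), ("b", strong_b), ("null", null_b)):
            tab.index = endpoint.index
            rho[key] = endpoint_correlation(tab, endpoint).table["rho"].dropna()
        reject_diff += ks_compare(rho["a"], rho["null"]).pvalue < alpha
        retain_same += ks_compare(rho["a"], rho["b"]).pvalue >= alpha
    return {
        "n_replicates": n_reps,
        "reject_rate_differing": reject_diff / n_reps,
        "retain_rate_identical": retain_same / n_reps,
    }


def clustering_recovery(
    n_per_blob: int = 20,
    n_features: int = 5,
    separation: float = 10.0,
    seed: int = 0,
) -> dict:
    """Exact recovery of a planted two-blob partition by two-cluster HAC."""
    rng = np.random.default_rng(seed)
    x = np.vstack([
        rng.normal(0.0, 1.0, (n_per_blob, n_features)),
        rng.normal(separation, 1.0, (n_per_blob, n_features)),
    ])
    ids = [f"P{i:03d}" for i in range(2 * n_per_blob)]
    truth = np.array([0] * n_per_blob + [1] * n_per_blob)
    df = pd.DataFrame(x, index=pd.Index(ids, name="patient_id"))
    df.columns = [str(c) for c in df.columns]
    assign = hac_cluster(zscore(df), k=2)
    labels = assign.labels.loc[ids].to_numpy()
    acc = max(float((labels == truth).mean()), float((labels == 1 - truth).mean()))
    return {"n_patients": 2 * n_per_blob, "accuracy": acc}


def filter_postcondition_sweep(
    n_tables: int = 20,
    n_cols: int = 50,
    n_rows: int = 40,
    threshold: float = 0.9,
    seed: int = 0,
) -> dict:
    """Count retained pairs above threshold after filtering random tables.

    Random tables are given block correlation structure (shared latent
    factors) so that some pairs genuinely exceed the redundancy
    threshold; the post-condition requires that no retained pair does.
    """
    root = np.random.SeedSequence(seed)
    violations = 0
    for child in root.spawn(n_tables):
        rng = np.random.default_rng(child)
        latent = rng.normal(0, 1, (n_rows, 5))
        w = rng.uniform(-1, 1, (5, n_cols))
        x = latent @ w + rng.normal(0, 0.15, (n_rows, n_cols))
        df = pd.DataFrame(x, columns=[f"c{j:02d}" for j in range(n_cols)])
        kept = correlation_filter(df, threshold=threshold)
        sub = spearman_matrix(df[kept]).abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        violations += int((sub > threshold).sum()) // 2
    return {"n_tables": n_tables, "violations": violations}
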