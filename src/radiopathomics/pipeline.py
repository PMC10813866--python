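"""End-to-end orchestration of the radiopathomics association analysis.

Flow (both modality pathways converge on the clinical endpoints):

    tissue mask -> 512-px patches (>=80 % tissue) -> nucleus-score filter
    (>=15 %) -> watershed segmentation -> density maps (16/32/64 px bins)
    -> Haralick features -> slide aggregation            [pathomics path]
    radiomics table ingestion                            [radiomics path]
    -> z-score -> |rho|>0.9 redundancy filter (per modality, per scale)
    -> cross-modal Spearman -> endpoint correlations + FDR + KS
    -> two-cluster HAC per modality -> cluster summaries

Every run writes a report bundle (CSV/JSON) plus a manifest that fully
reconstructs the run: config, seed, package version, config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (correlation_filter, cross_correlation, endpoint_correlation,
                    ks_compare, zscore)
from .clustering import cluster_summary, compare_assignments, hac_cluster
from .density import density_map, segment_nuclei
from .pathomics import (SCALE_TAGS, PathomicsFeatureTable, aggregate_slide,
                        patch_features)
from .preprocess import (compute_tissue_mask, extract_patches, filter_patches,
                         nucleus_score, patch_manifest)
from .radiomics import read_radiomics_table
from .synthetic import SyntheticCohortSpec, generate_cohort

__all__ = ["RunConfig", "run", "slide_pathomics", "cohort_pathomics"]

ENDPOINTS = ("os_months", "pfs_months", "cd8_pct")


@dataclass
class RunConfig:
    """All stage parameters, defaulting to the protocol values:
    80 % tissue, 15 % nucleus score, 512-px patches, bin scales 16/32/64,
    |r| = 0.9 redundancy threshold, two clusters."""

    synthetic: SyntheticCohortSpec | None = None
    radiomics_csv: str | None = None
    clinical_csv: str | None = None
    use_radiomics: bool = True  # False: pathomics-only run, association skipped

    tissue_threshold: float = 0.8
    nucleus_min_score: float = 0.15
    patch_size: int = 512
    scales: tuple[int, ...] = (16, 32, 64)
    n_gray: int = 8
    fg_frac: float = 0.4
    density_mode: str = "fraction"
    filter_r: float = 0.9
    report_threshold: float = 0.5
    fdr_level: float = 0.05
    linkage: str = "ward"
    metric: str = "euclidean"
    n_clusters: int = 2
    cluster_on_filtered: bool = True
    seed: int = 0
    out_dir: str = "results/run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def slide_pathomics(
    image: np.ndarray,
    config: RunConfig,
    patient_id: str | None = None,
) -> tuple[pd.Series | None, pd.DataFrame]:
    """Pathomics feature row for one slide image (None if no patch survives).

    Returns the per-scale concatenated slide features (bare 260-name
    blocks per scale, suffixed) and the candidate-patch manifest.
    """
    mask = compute_tissue_mask(image)
    patches = extract_patches(image, mask, patch_size=config.patch_size,
                              tissue_threshold=config.tissue_threshold,
                              patient_id=patient_id)
    for p in patches:
        nucleus_score(p)
    kept = filter_patches(patches, min_score=config.nucleus_min_score)
    manifest = patch_manifest(patches, kept)
    if not kept:
        return None, manifest
    rows = []
    scale_by_tag = {tag: px for tag, px in SCALE_TAGS.items() if px in config.scales}
    for p in kept:
        seg = segment_nuclei(p.image, fg_frac=config.fg_frac)
        dms = {tag: density_map(seg, scale=px, n_gray=config.n_gray,
                                mode=config.density_mode)
               for tag, px in scale_by_tag.items()}
        rows.append(patch_features(dms))
    ptab = pd.DataFrame(rows)
    per_scale = {tag: aggregate_slide(ptab, tag) for tag in scale_by_tag}
    flat = pd.concat([s.add_suffix(f"_{tag}") for tag, s in per_scale.items()])
    flat.name = patient_id
    return flat, manifest


def cohort_pathomics(cohort, config: RunConfig) -> tuple[PathomicsFeatureTable, pd.DataFrame]:
    """Run the full histology path over a synthetic cohort's pseudo-slides."""
    rows, manifests, excluded = [], [], []
    for pid in cohort.patient_ids:
        flat, man = slide_pathomics(cohort.slide(pid), config, patient_id=pid)
        manifests.append(man)
        if flat is None:
            excluded.append(pid)
            continue
        rows.append(flat)
    if excluded:
        warnings.warn(f"{len(excluded)} slide(s) excluded (no retained patches): {excluded}")
    flat_tab = pd.DataFrame(rows)
    flat_tab.index.name = "patient_id"
    per_scale = {}
    for tag in SCALE_TAGS:
        cols = [c for c in flat_tab.columns if c.endswith(f"_{tag}")]
        if cols:
            per_scale[tag] = flat_tab[cols].rename(
                columns=lambda c: c[: -(len(tag) + 1)])
    return PathomicsFeatureTable(per_scale), pd.concat(manifests, ignore_index=True)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def run(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of in-memory results (tables and summaries).  With no
    radiomics table available, the association and radiomics-clustering
    stages are skipped with a notice; pathomics outputs are still
    produced.  Idempotent for a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort = generate_cohort(spec)
        radiomics = cohort.radiomics
        clinical = cohort.clinical
    else:
        if config.clinical_csv is None:
            raise ValueError("non-synthetic runs require clinical_csv")
        clinical = pd.read_csv(config.clinical_csv).set_index("patient_id")
        radiomics = None
        cohort = None
    if config.radiomics_csv is not None:
        radiomics, _ = read_radiomics_table(config.radiomics_csv)
    if not config.use_radiomics:
        radiomics = None

    # ---- pathomics path --------------------------------------------
    if cohort is not None:
        pathomics, manifest = cohort_pathomics(cohort, config)
    else:
        raise ValueError("image-directory input is supported via cohort_pathomics; "
                         "provide a synthetic spec for end-to-end runs")
    manifest.to_csv(out / "patch_manifest.csv", index=False)
    pathomics.flat().to_csv(out / "pathomics_features.csv")

    results: dict = {"pathomics": pathomics, "clinical": clinical}

    # ---- normalization + filtering ---------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are expected and logged below
        path_z = {s: zscore(df) for s, df in pathomics.per_scale.items()}
    path_kept = {s: correlation_filter(df, config.filter_r) for s, df in path_z.items()}
    path_filtered = {s: path_z[s][cols] for s, cols in path_kept.items()}
    retained_counts = {s: len(c) for s, c in path_kept.items()}

    if radiomics is not None:
        rad_z = zscore(radiomics)
        rad_kept = correlation_filter(rad_z, config.filter_r)
        rad_filtered = rad_z[rad_kept]
        retained_counts["radiomics"] = len(rad_kept)
    _write_json(out / "retained_features.json", retained_counts)
    results["retained_counts"] = retained_counts

    # ---- association stages ----------------------------------------
    if radiomics is None:
        warnings.warn("no radiomics table: association and radiomics clustering skipped")
    else:
        xcorr = cross_correlation(path_filtered, rad_filtered,
                                  report_threshold=config.report_threshold)
        xcorr.sign_counts.to_csv(out / "cross_correlation_signs.csv", index=False)
        xcorr.top_pairs.to_csv(out / "cross_correlation_top_pairs.csv", index=False)
        for s, m in xcorr.matrices.items():
            m.to_csv(out / f"cross_correlation_{s}.csv")
        results["cross_correlation"] = xcorr

        path_flat = pd.concat(
            [df.add_suffix(f"_{s}") for s, df in path_filtered.items()], axis=1)
        ks_summary = {}
        endpoint_results = {}
        for ep in ENDPOINTS:
            ep_series = clinical[ep]
            r_path = endpoint_correlation(path_flat, ep_series, config.fdr_level)
            r_rad = endpoint_correlation(rad_filtered, ep_series, config.fdr_level)
            r_path.table.to_csv(out / f"endpoint_{ep}_pathomics.csv", index=False)
            r_rad.table.to_csv(out / f"endpoint_{ep}_radiomics.csv", index=False)
            ks = ks_compare(r_path.table["rho"].dropna(), r_rad.table["rho"].dropna())
            ks_summary[ep] = {
                "statistic": ks.statistic, "pvalue": ks.pvalue,
                "n_pathomics": ks.n_a, "n_radiomics": ks.n_b,
                "pathomics_pos": r_path.n_positive, "pathomics_neg": r_path.n_negative,
                "radiomics_pos": r_rad.n_positive, "radiomics_neg": r_rad.n_negative,
            }
            endpoint_results[ep] = {"pathomics": r_path, "radiomics": r_rad}
        _write_json(out / "ks_summary.json", ks_summary)
        results["ks"] = ks_summary
        results["endpoints"] = endpoint_results

        # ---- clustering --------------------------------------------
        path_feats = path_flat if config.cluster_on_filtered else pd.concat(
            [df.add_suffix(f"_{s}") for s, df in path_z.items()], axis=1)
        rad_feats = rad_filtered if config.cluster_on_filtered else rad_z
        a_path = hac_cluster(path_feats, k=config.n_clusters, method=config.linkage,
                             metric=config.metric, modality="pathomics")
        a_rad = hac_cluster(rad_feats.loc[path_feats.index], k=config.n_clusters,
                            method=config.linkage, metric=config.metric,
                            modality="radiomics")
        pd.DataFrame({"pathomics": a_path.labels, "radiomics": a_rad.labels}
                     ).to_csv(out / "cluster_assignments.csv")
        summ_p = cluster_summary(a_path, clinical)
        summ_r = cluster_summary(a_rad, clinical)
        summ_p.insert(0, "modality", "pathomics")
        summ_r.insert(0, "modality", "radiomics")
        pd.concat([summ_p, summ_r]).to_csv(out / "cluster_summary.csv", index=False)
        switches = compare_assignments(a_path, a_rad)
        _write_json(out / "cluster_switches.json", switches)
        _write_json(out / "dendrograms.json", {
            "pathomics": a_path.linkage.tolist(),
            "radiomics": a_rad.linkage.tolist(),
        })
        results["clusters"] = {"pathomics": a_path, "radiomics": a_rad,
                               "summary": pd.concat([summ_p, summ_r]),
                               "switches": switches}

    # ---- manifest ---------------------------------------------------
    _write_json(out / "manifest.json", {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    })
    return results
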