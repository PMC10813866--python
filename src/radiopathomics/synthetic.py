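"""Seeded synthetic cohorts with planted cross-modal structure.

The study data this package targets — H&E whole-slide images, a CT
radiomics table and clinical endpoints for immunotherapy-treated NSCLC
patients — are private.  This module generates a stand-in cohort whose
structure is known exactly, so every downstream stage (tissue masking,
watershed segmentation, density-map Haralick features, cross-modal
Spearman / KS statistics, clustering) can be tested by parameter
recovery rather than against deposited data.

The generative model is a single per-patient latent severity factor
``z_i ~ Normal(0, latent_sd^2)`` that drives everything:

* tile nucleus density: ``rate_i = nuclei_rate_base * exp(nuclei_rate_slope * z_i)``
* radiomics feature j:  ``a_j * z_i + Normal(0, noise_sd^2)`` with
  loadings ``a_j ~ Uniform(radiomics_loading_range)``
* OS / PFS:  ``scale * exp(0.5 * z_i + eps)``, ``eps ~ Normal(0, 0.25)``
* CD8 %:     ``100 * logistic(cd8_slope * z_i + cd8_offset + eps)``

Tiles are pale-pink backgrounds with dark-purple elliptical nuclei —
countable blobs, not realistic histology; staining variation and scanner
artifacts are deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_tile",
    "generate_cohort",
]

# Fixed palette so grayscale/Otsu behaviour is stable across runs.
BACKGROUND_RGB = (240, 220, 225)
NUCLEUS_RGB = (90, 60, 120)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults emulate a realistic cohort: 36 patients, 512-px tiles at a
    nominal 20x magnification, survival scales giving OS/PFS month ranges
    comparable to an ICI-treated NSCLC cohort, and a CD8 intercept placing
    the cohort mean near 7.6 %.
    """

    n_patients: int = 36
    latent_sd: float = 1.0
    nuclei_rate_base: float = 600.0    # mean nuclei per 512-px tile at z = 0 (~28 % coverage)
    nuclei_rate_slope: float = 0.2     # log-linear effect of z on the rate
    n_tiles_per_patient: int = 4
    tile_size: int = 512
    nucleus_radius_range: tuple[float, float] = (5.0, 9.0)
    n_radiomics_features: int = 120
    radiomics_loading_range: tuple[float, float] = (-0.8, 0.8)
    noise_sd: float = 0.6
    os_scale: float = 18.0             # months
    pfs_scale: float = 8.0             # months
    cd8_slope: float = 1.0
    cd8_offset: float = -3.0           # logistic intercept; cohort mean CD8 ~ 7.5 %
    censor_horizon: float | None = None  # months; administrative censoring if set
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_tiles_per_patient < 1:
            raise ValueError("n_tiles_per_patient must be >= 1")
        if self.tile_size % 64 != 0 or self.tile_size <= 0:
            raise ValueError("tile_size must be a positive multiple of 64 "
                             "so that all three bin scales tile evenly")
        if self.nuclei_rate_base <= 0:
            raise ValueError("nuclei_rate_base must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus_radius_range must satisfy 0 < min <= max")
        if self.n_radiomics_features < 1:
            raise ValueError("n_radiomics_features must be >= 1")


def _ellipse_mask(shape, center, a, b, theta):
    """Boolean mask of a filled rotated ellipse (semi-axes a >= b)."""
    rr, cc = np.indices(shape)
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_tile(
    rate: float,
    tile_size: int = 512,
    nucleus_radius_range: tuple[float, float] = (5.0, 9.0),
    rng: np.random.Generator | int | None = None,
    noise_sd: float = 2.5,
    min_separation: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one synthetic H&E-like tile.

    Nuclei are filled dark-purple ellipses (eccentricity at most 2:1) on a
    pale pink background with mild additive Gaussian pixel noise.  The
    number of nuclei is Poisson(rate); placement is non-overlapping by
    rejection sampling (at most 1000 attempts per nucleus, then the
    nucleus is skipped), with a ``min_separation`` pixel gap between
    nuclei so that distinct ground-truth nuclei never form one connected
    blob.

    Returns
    -------
    image : uint8 array, shape (tile_size, tile_size, 3)
    mask : uint16 array, ground-truth labels 1..n per nucleus, 0 background
    """
    if tile_size < 64:
        raise ValueError("tile_size must be >= 64")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(rng)

    labels = np.zeros((tile_size, tile_size), dtype=np.uint16)
    n_target = int(rng.poisson(rate))
    lo, hi = nucleus_radius_range
    placed = 0
    for _ in range(n_target):
        for _attempt in range(1000):
            a = rng.uniform(lo, hi)
            b = rng.uniform(max(lo / 2.0, a / 2.0), a)  # eccentricity <= 2:1
            theta = rng.uniform(0.0, np.pi)
            margin = int(np.ceil(a)) + 1
            if tile_size <= 2 * margin:
                break
            r0 = rng.uniform(margin, tile_size - margin)
            c0 = rng.uniform(margin, tile_size - margin)
            # local window to keep the overlap check cheap
            w = int(np.ceil(a + min_separation)) + 2
            rlo, rhi = max(int(r0) - w, 0), min(int(r0) + w + 1, tile_size)
            clo, chi = max(int(c0) - w, 0), min(int(c0) + w + 1, tile_size)
            shape = (rhi - rlo, chi - clo)
            center = (r0 - rlo, c0 - clo)
            # separation enforced by checking an inflated footprint
            pad = _ellipse_mask(shape, center, a + min_separation, b + min_separation, theta)
            if labels[rlo:rhi, clo:chi][pad].any():
                continue
            sub = _ellipse_mask(shape, center, a, b, theta)
            placed += 1
            labels[rlo:rhi, clo:chi][sub] = placed
            break

    image = np.empty((tile_size, tile_size, 3), dtype=float)
    image[...] = BACKGROUND_RGB
    image[labels > 0] = NUCLEUS_RGB
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return image, labels


@dataclass
class SyntheticCohort:
    """A generated cohort: latent factors, tables, and (lazy) tile images.

    Tile images are re-generated deterministically from stored per-tile
    seeds on each access, so a large cohort never holds all pixels in
    memory at once.
    """

    spec: SyntheticCohortSpec
    patient_ids: list[str]
    z: np.ndarray                       # latent factor per patient
    tile_rates: np.ndarray              # expected nuclei per tile per patient
    radiomics: pd.DataFrame             # patients x features, patient_id index
    radiomics_loadings: np.ndarray      # ground-truth a_j
    clinical: pd.DataFrame              # os_months, pfs_months, progression, cd8_pct
    _tile_seeds: np.ndarray = field(repr=False, default=None)
    has_images: bool = True

    def tiles(self, patient_id: str) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (image, ground-truth label mask) for each tile of a patient."""
        if not self.has_images:
            raise ValueError("cohort was generated with make_images=False")
        i = self.patient_ids.index(patient_id)
        for s in self._tile_seeds[i]:
            yield generate_tile(
                rate=self.tile_rates[i],
                tile_size=self.spec.tile_size,
                nucleus_radius_range=self.spec.nucleus_radius_range,
                rng=int(s),
            )

    def slide(self, patient_id: str) -> np.ndarray:
        """Montage the patient's tiles into one pseudo-slide image (row-major grid)."""
        tiles = [img for img, _ in self.tiles(patient_id)]
        n = len(tiles)
        ncol = int(np.ceil(np.sqrt(n)))
        nrow = int(np.ceil(n / ncol))
        ts = self.spec.tile_size
        out = np.full((nrow * ts, ncol * ts, 3), 255, dtype=np.uint8)  # white = glass
        for k, t in enumerate(tiles):
            r, c = divmod(k, ncol)
            out[r * ts:(r + 1) * ts, c * ts:(c + 1) * ts] = t
        return out

    def write(self, out_dir: str | Path, write_images: bool = True) -> None:
        """Write tables as CSV and, optionally, tiles as PNG + 16-bit TIFF truth masks."""
        import imageio.v3 as iio
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.radiomics.to_csv(out / "radiomics.csv")
        self.clinical.to_csv(out / "clinical.csv")
        manifest = {
            "spec": dataclasses.asdict(self.spec),
            "patient_ids": self.patient_ids,
            "z": self.z.tolist(),
            "tile_rates": self.tile_rates.tolist(),
            "radiomics_loadings": self.radiomics_loadings.tolist(),
        }
        if write_images and self.has_images:
            tdir = out / "tiles"
            tdir.mkdir(exist_ok=True)
            counts: dict[str, list[int]] = {}
            for pid in self.patient_ids:
                for k, (img, mask) in enumerate(self.tiles(pid)):
                    iio.imwrite(tdir / f"{pid}_tile{k:02d}.png", img)
                    tifffile.imwrite(tdir / f"{pid}_tile{k:02d}_truth.tif",
                                     mask.astype(np.uint16))
                    counts.setdefault(pid, []).append(int(mask.max()))
            manifest["true_nucleus_counts"] = counts
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_cohort(spec: SyntheticCohortSpec, make_images: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort from a spec.

    With ``make_images=False`` the tile stage is skipped (no per-tile
    seeds usable); the latent factors, radiomics table and clinical table
    are identical to the image-bearing cohort for the same spec.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_z, ss_load, ss_noise, ss_clin, ss_tiles = root.spawn(5)

    z = np.random.default_rng(ss_z).normal(0.0, spec.latent_sd, size=spec.n_patients)
    patient_ids = [f"P{i + 1:03d}" for i in range(spec.n_patients)]
    tile_rates = spec.nuclei_rate_base * np.exp(spec.nuclei_rate_slope * z)

    lo, hi = spec.radiomics_loading_range
    loadings = np.random.default_rng(ss_load).uniform(lo, hi, size=spec.n_radiomics_features)
    noise = np.random.default_rng(ss_noise).normal(
        0.0, spec.noise_sd, size=(spec.n_patients, spec.n_radiomics_features))
    radiomics = pd.DataFrame(
        z[:, None] * loadings[None, :] + noise,
        index=pd.Index(patient_ids, name="patient_id"),
        columns=[f"f{j + 1}" for j in range(spec.n_radiomics_features)],
    )

    rng_c = np.random.default_rng(ss_clin)
    eps_sd = 0.5  # Normal(0, 0.25) variance
    os_months = spec.os_scale * np.exp(0.5 * z + rng_c.normal(0, eps_sd, spec.n_patients))
    pfs_months = spec.pfs_scale * np.exp(0.5 * z + rng_c.normal(0, eps_sd, spec.n_patients))
    cd8 = 100.0 / (1.0 + np.exp(-(spec.cd8_slope * z + spec.cd8_offset
                                  + rng_c.normal(0, eps_sd, spec.n_patients))))
    # Progression: logistic in z, base rate ~0.76 as typical for ICI cohorts.
    p_prog = 1.0 / (1.0 + np.exp(-(1.15 - 0.8 * z)))
    progression = (rng_c.uniform(size=spec.n_patients) < p_prog).astype(int)

    os_event = np.ones(spec.n_patients, dtype=int)
    pfs_event = np.ones(spec.n_patients, dtype=int)
    if spec.censor_horizon is not None:
        h = float(spec.censor_horizon)
        os_event = (os_months <= h).astype(int)
        pfs_event = (pfs_months <= h).astype(int)
        os_months = np.minimum(os_months, h)
        pfs_months = np.minimum(pfs_months, h)

    clinical = pd.DataFrame(
        {
            "os_months": os_months,
            "pfs_months": pfs_months,
            "os_event": os_event,
            "pfs_event": pfs_event,
            "progression": progression,
            "cd8_pct": cd8,
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )

    tile_seeds = None
    if make_images:
        # one independent child seed per tile, below 2**31 for portability
        seeds = np.random.default_rng(ss_tiles).integers(
            0, 2**31 - 1, size=(spec.n_patients, spec.n_tiles_per_patient))
        tile_seeds = seeds

    return SyntheticCohort(
        spec=spec,
        patient_ids=patient_ids,
        z=z,
        tile_rates=tile_rates,
        radiomics=radiomics,
        radiomics_loadings=loadings,
        clinical=clinical,
        _tile_seeds=tile_seeds,
        has_images=make_images,
    )
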