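"""Synthetic cohorts and phantoms with known ground truth.

The clinical data behind PSMA radioligand-therapy lesion analyses are not
publicly deposited, so this module generates (a) per-lesion uptake tables
that emulate the structure of a real mCRPC cohort — a median of ~12 lesions
per patient across bone/node/visceral/primary sites, log-normal baseline
SUV_max, liver reference uptake near 4.1 — and (b) small 3D PET phantoms
(spheres plus a liver block, Gaussian PSF, additive noise) for exercising
the isocontour quantifier.

The generative response model is a continuation-ratio (sequential) logistic
in log tumor-to-liver ratio: first whether a lesion responds, then — among
non-responders — whether it progresses.  Default coefficients are calibrated
so that the overall responding/stable/progressive mix is about 77/17/7 % and
the sub-liver stratum (TLR < 1) about 45/22/33 %, matching the magnitudes at
which liver-derived thresholds are typically evaluated.  All coefficients
are configuration, not constants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .exceptions import ConfigurationError, GeometryError
from .uptake import PetVolume

__all__ = [
    "ResponseModel",
    "ChangeModel",
    "SyntheticCohortConfig",
    "generate_cohort",
    "expected_category_mix",
    "SphereLesion",
    "PhantomSpec",
    "generate_phantom",
    "LESION_TABLE_COLUMNS",
    "REFERENCE_TABLE_COLUMNS",
]

SITES = ("bone", "lymph_node", "visceral", "primary")

LESION_TABLE_COLUMNS = [
    "patient_id",
    "lesion_id",
    "site",
    "suvmax_base",
    "suvmean_base",
    "suvmax_post",
    "suvmean_post",
]
REFERENCE_TABLE_COLUMNS = ["patient_id", "timepoint", "blood_pool", "liver_mean", "parotid"]


@dataclass(frozen=True)
class ResponseModel:
    """Continuation-ratio logistic response model in x = log(TLR).

    P(respond | x)   = expit(respond_intercept + respond_slope * x)
    P(progress | not respond, x) = expit(progress_intercept - progress_slope * x)

    so that P(RL), P(SL), P(PL) are valid and sum to one for every TLR, and
    higher baseline uptake makes response more and progression less likely.
    """

    respond_intercept: float = 0.12
    respond_slope: float = 1.00
    progress_intercept: float = -0.04
    progress_slope: float = 1.29

    def category_probs(self, tlr) -> np.ndarray:
        """(..., 3) array of (P(RL), P(SL), P(PL)) at the given TLR values."""
        tlr = np.asarray(tlr, dtype=float)
        if np.any(tlr <= 0):
            raise ValueError("TLR must be positive")
        x = np.log(tlr)
        p_rl = expit(self.respond_intercept + self.respond_slope * x)
        q = expit(self.progress_intercept - self.progress_slope * x)
        p_pl = (1.0 - p_rl) * q
        p_sl = (1.0 - p_rl) * (1.0 - q)
        return np.stack([p_rl, p_sl, p_pl], axis=-1)


@dataclass(frozen=True)
class ChangeModel:
    """Multiplicative SUV_max change distributions conditional on true category.

    Responding lesions draw ``m = responder_ceiling * Beta(*responder_beta)``
    (a decline of at least 30 %), stable lesions draw ``m`` uniformly shaped
    by a Beta on (0.7, 1.3), and progressors draw
    ``m = progressor_floor + Gamma(*progressor_gamma)``.
    """

    responder_ceiling: float = 0.70
    responder_beta: tuple[float, float] = (1.2, 1.8)
    stable_beta: tuple[float, float] = (2.0, 2.0)
    progressor_floor: float = 1.30
    progressor_gamma: tuple[float, float] = (1.5, 0.5)

    def sample(self, category: str, rng: np.random.Generator) -> float:
        if category == "RL":
            return self.responder_ceiling * rng.beta(*self.responder_beta)
        if category == "SL":
            return 0.7 + 0.6 * rng.beta(*self.stable_beta)
        if category == "PL":
            return self.progressor_floor + rng.gamma(*self.progressor_gamma)
        raise ValueError(f"unknown category {category!r}")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for a synthetic lesion cohort.

    Defaults emulate a 61-patient mCRPC radioligand-therapy cohort: lesion
    counts log-normal around a median of 12 (at least 3 per patient),
    site mix dominated by bone and lymph-node disease, baseline SUV_max
    log-normal with median 14.1, and organ references (blood pool ~1.8,
    liver ~4.1, parotid ~15) jittered per patient and timepoint.
    """

    n_patients: int = 61
    lesions_median: float = 12.0
    lesions_sigma_log: float = 0.5
    lesions_min: int = 3
    site_mix: tuple[float, float, float, float] = (0.706, 0.252, 0.031, 0.011)
    suvmax_median: float = 14.1
    suvmax_sigma_log: float = 0.76
    suvmean_fraction: float = 0.62
    suvmean_rel_sd: float = 0.05
    liver_mean: float = 4.1
    liver_sd: float = 0.30
    blood_pool_mean: float = 1.8
    blood_pool_sd: float = 0.15
    parotid_mean: float = 15.0
    parotid_sd: float = 2.0
    response_model: ResponseModel = field(default_factory=ResponseModel)
    change_model: ChangeModel = field(default_factory=ChangeModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if len(self.site_mix) != len(SITES):
            raise ConfigurationError(f"site_mix needs {len(SITES)} probabilities")
        mix = np.asarray(self.site_mix, dtype=float)
        if np.any(mix < 0) or np.any(mix > 1) or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError("site_mix entries must lie in [0,1] and sum to 1")
        for name in (
            "lesions_median",
            "lesions_sigma_log",
            "suvmax_median",
            "suvmax_sigma_log",
            "suvmean_fraction",
            "liver_mean",
            "blood_pool_mean",
            "parotid_mean",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("suvmean_rel_sd", "liver_sd", "blood_pool_sd", "parotid_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.lesions_min < 1:
            raise ConfigurationError("lesions_min must be >= 1")
        if not self.blood_pool_mean < self.liver_mean < self.parotid_mean:
            raise ConfigurationError(
                "organ means must satisfy blood_pool_mean < liver_mean < parotid_mean"
            )

    # -- JSON round-trip -------------------------------------------------
    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticCohortConfig":
        """Build a config from a JSON string or file path."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            raw = json.loads(source)
        else:
            with open(source) as fh:
                raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "response_model" in raw:
            raw["response_model"] = ResponseModel(**raw["response_model"])
        if "change_model" in raw:
            cm = raw["change_model"]
            cm = {k: tuple(v) if isinstance(v, list) else v for k, v in cm.items()}
            raw["change_model"] = ChangeModel(**cm)
        if "site_mix" in raw:
            raw["site_mix"] = tuple(raw["site_mix"])
        return cls(**raw)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    """Normal draw truncated below (redraw) — keeps organ uptakes physical."""
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > floor:
            return float(v)
    return float(floor + abs(rng.normal(0, sd)) + 1e-6)


def generate_cohort(config: SyntheticCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic lesion table and per-scan organ references.

    Returns
    -------
    lesions : DataFrame
        One row per lesion with the standard columns plus ``true_category``,
        the category sampled from the response model before the change
        distribution is applied (ground truth for recovery tests).
    references : DataFrame
        Two rows per patient (timepoints ``base`` and ``post``) with
        blood-pool, liver and parotid reference uptakes.

    A fixed ``config.seed`` yields byte-identical tables; per-patient
    sub-streams are spawned deterministically from the root seed.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_patients)

    mu_n = np.log(config.lesions_median)
    mu_s = np.log(config.suvmax_median)
    lesion_rows = []
    ref_rows = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        patient_id = f"P{p + 1:03d}"
        n_lesions = max(
            config.lesions_min, int(np.rint(rng.lognormal(mu_n, config.lesions_sigma_log)))
        )
        liver = {
            tp: _positive_normal(rng, config.liver_mean, config.liver_sd, 0.5)
            for tp in ("base", "post")
        }
        blood = {
            tp: _positive_normal(rng, config.blood_pool_mean, config.blood_pool_sd, 0.2)
            for tp in ("base", "post")
        }
        parotid = {
            tp: _positive_normal(rng, config.parotid_mean, config.parotid_sd, liver[tp] + 0.5)
            for tp in ("base", "post")
        }
        for tp in ("base", "post"):
            ref_rows.append(
                {
                    "patient_id": patient_id,
                    "timepoint": tp,
                    "blood_pool": blood[tp],
                    "liver_mean": liver[tp],
                    "parotid": parotid[tp],
                }
            )
        for k in range(n_lesions):
            site = SITES[rng.choice(len(SITES), p=np.asarray(config.site_mix))]
            suvmax_base = float(rng.lognormal(mu_s, config.suvmax_sigma_log))
            tlr = suvmax_base / liver["base"]
            probs = config.response_model.category_probs(tlr)
            cat = ("RL", "SL", "PL")[rng.choice(3, p=probs)]
            m = config.change_model.sample(cat, rng)
            suvmax_post = m * suvmax_base
            mean_base = suvmax_base * config.suvmean_fraction * (
                1.0 + config.suvmean_rel_sd * rng.standard_normal()
            )
            mean_post = suvmax_post * config.suvmean_fraction * (
                1.0 + config.suvmean_rel_sd * rng.standard_normal()
            )
            lesion_rows.append(
                {
                    "patient_id": patient_id,
                    "lesion_id": f"{patient_id}-L{k + 1:02d}",
                    "site": site,
                    "suvmax_base": suvmax_base,
                    "suvmean_base": float(np.clip(mean_base, 1e-6, suvmax_base)),
                    "suvmax_post": suvmax_post,
                    "suvmean_post": float(np.clip(mean_post, 1e-6, suvmax_post)),
                    "true_category": cat,
                }
            )
    lesions = pd.DataFrame(lesion_rows, columns=LESION_TABLE_COLUMNS + ["true_category"])
    references = pd.DataFrame(ref_rows, columns=REFERENCE_TABLE_COLUMNS)
    return lesions, references


def expected_category_mix(
    config: SyntheticCohortConfig,
    tlr_below: float | None = None,
    tlr_above: float | None = None,
    n_grid: int = 4001,
    n_hermite: int = 61,
) -> np.ndarray:
    """Model-implied (P(RL), P(SL), P(PL)), optionally conditional on a TLR stratum.

    Integrates the response model numerically over the baseline TLR
    distribution: log SUV_max is normal by construction and the per-scan
    liver mean is integrated with Gauss-Hermite quadrature.  ``tlr_below``
    (or ``tlr_above``) conditions on TLR < (>=) the given cut.
    """
    config.validate()
    if tlr_below is not None and tlr_above is not None:
        raise ValueError("give at most one of tlr_below/tlr_above")
    mu_s = np.log(config.suvmax_median)
    sd_s = config.suvmax_sigma_log
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_hermite)
    livers = config.liver_mean + config.liver_sd * nodes
    keep = livers > 0.5
    livers, weights = livers[keep], weights[keep]
    weights = weights / weights.sum()

    acc = np.zeros(3)
    total = 0.0
    for liver, w in zip(livers, weights):
        mu_x = mu_s - np.log(liver)  # x = log TLR | liver
        xs = np.linspace(mu_x - 10 * sd_s, mu_x + 10 * sd_s, n_grid)
        dens = np.exp(-0.5 * ((xs - mu_x) / sd_s) ** 2) / (sd_s * np.sqrt(2 * np.pi))
        sel = np.ones_like(xs, dtype=bool)
        if tlr_below is not None:
            sel = xs < np.log(tlr_below)
        elif tlr_above is not None:
            sel = xs >= np.log(tlr_above)
        if not sel.any():
            continue
        probs = config.response_model.category_probs(np.exp(xs[sel]))
        dx = xs[1] - xs[0]
        acc += w * (probs * dens[sel, None]).sum(axis=0) * dx
        total += w * dens[sel].sum() * dx
    if total <= 0:
        raise ValueError("stratum has vanishing probability under the model")
    return acc / total


# ---------------------------------------------------------------------------
# PET phantoms
# ---------------------------------------------------------------------------

FWHM_TO_SIGMA = 1.0 / 2.3548  # Gaussian FWHM -> standard deviation


@dataclass(frozen=True)
class SphereLesion:
    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of a synthetic PET phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    lesions: tuple[SphereLesion, ...] = ()
    liver_box_mm: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    liver_suv: float = 4.1
    noise_sigma: float = 0.0
    psf_fwhm_mm: float = 0.0

    def validate(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ConfigurationError("shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be positive")
        if self.noise_sigma < 0 or self.psf_fwhm_mm < 0:
            raise ConfigurationError("noise_sigma and psf_fwhm_mm must be non-negative")
        extent = [self.spacing[ax] * (self.shape[ax] - 1) for ax in range(3)]
        for les in self.lesions:
            if les.radius_mm <= 0:
                raise GeometryError(f"lesion radius must be positive, got {les.radius_mm}")
            for ax in range(3):
                if les.center_mm[ax] - les.radius_mm < 0 or (
                    les.center_mm[ax] + les.radius_mm > extent[ax]
                ):
                    raise GeometryError(
                        f"lesion at {les.center_mm} (r={les.radius_mm} mm) extends outside "
                        f"the grid along axis {ax}"
                    )
        if self.liver_box_mm is not None:
            lo, hi = self.liver_box_mm
            for ax in range(3):
                if not 0 <= lo[ax] < hi[ax] <= extent[ax]:
                    raise GeometryError("liver box must lie inside the grid with lo < hi")


def generate_phantom(
    spec: PhantomSpec, seed: int | np.random.Generator = 0
) -> tuple[PetVolume, dict[int, np.ndarray], list[float]]:
    """Build a phantom volume plus ground-truth lesion masks and true SUVs.

    The noiseless scene (background + liver block + spheres, assigned by
    voxel-center membership) is blurred with a Gaussian PSF of the given
    FWHM, then Gaussian noise is added — blur before noise, mirroring the
    physical order of resolution loss and count statistics.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.full(spec.shape, float(spec.background_suv))
    coords = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]

    if spec.liver_box_mm is not None:
        lo, hi = spec.liver_box_mm
        sel = tuple(
            slice(
                int(np.searchsorted(coords[ax], lo[ax], side="left")),
                int(np.searchsorted(coords[ax], hi[ax], side="right")),
            )
            for ax in range(3)
        )
        grid[sel] = spec.liver_suv

    masks: dict[int, np.ndarray] = {}
    truths: list[float] = []
    for i, les in enumerate(spec.lesions):
        d2 = (
            (coords[0][:, None, None] - les.center_mm[0]) ** 2
            + (coords[1][None, :, None] - les.center_mm[1]) ** 2
            + (coords[2][None, None, :] - les.center_mm[2]) ** 2
        )
        mask = d2 <= les.radius_mm**2
        grid[mask] = les.suv
        masks[i] = mask
        truths.append(les.suv)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing]
        grid = ndimage.gaussian_filter(grid, sigma=sigma_vox)
    if spec.noise_sigma > 0:
        grid = grid + rng.normal(0.0, spec.noise_sigma, size=grid.shape)

    return PetVolume(values=grid, spacing=spec.spacing), masks, truths
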