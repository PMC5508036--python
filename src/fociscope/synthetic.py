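"""Synthetic two-channel FISH fields and cohorts with planted ground truth.

Every downstream stage of the pipeline (segmentation, speckle detection,
measurement, association testing) is exercised on images produced here, so
the generator plants *everything* it draws into explicit ground-truth
tables: nuclei (class, centroid, radius), foci (owner nucleus, diameter,
probe) and large bright artifacts.  All randomness flows from a single
seed through named per-component streams, so identical ``(spec, seed)``
reproduce bit-identical output.

Nuclei are additive Gaussian-blurred disks; foci are isotropic Gaussian
spots whose FWHM equals the planted diameter, spread across a few planes;
cerebellar Purkinje nuclei are rendered large and faint to emulate poor
nuclear staining.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stacks import DEFAULT_PLANE_SPACING_UM, ZStack, write_stack

__all__ = [
    "CellClassSpec",
    "FieldSpec",
    "GroundTruth",
    "ClinicalModel",
    "CohortBundle",
    "PlacementError",
    "generate_field",
    "generate_cohort",
    "write_fixture",
    "default_field_spec",
    "sample_zero_truncated_poisson",
]

PROBES = ("sense", "antisense")

# named substreams hanging off the user seed; reproducible partial reruns
_STREAMS = {
    "placement": 11,
    "counts": 13,
    "render": 17,
    "noise": 19,
    "clinical": 23,
}


class PlacementError(RuntimeError):
    """Raised when a cell class cannot be placed in the requested image."""


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream], *map(int, extra)])


@dataclasses.dataclass(frozen=True)
class CellClassSpec:
    """Rendering and count model for one nucleus class."""

    class_name: str
    nucleus_radius_px: tuple  # (min, max), pixels
    dapi_mean: float
    dapi_sd: float
    count_per_field: tuple  # (min, max) inclusive integer range
    foci_positive_prob: Mapping[str, float]  # per probe
    foci_count_mu: Mapping[str, float]  # zero-truncated Poisson mean parameter
    foci_count_dist: str = "ztpoisson"

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_radius_px
        if not (0 < lo <= hi):
            raise ValueError("nucleus_radius_px must satisfy 0 < min <= max")
        if not (0 <= self.dapi_mean <= 1):
            raise ValueError("dapi_mean must lie in [0, 1]")
        if self.count_per_field[0] < 0 or self.count_per_field[0] > self.count_per_field[1]:
            raise ValueError("count_per_field must be a nonnegative range")
        for probe, p in self.foci_positive_prob.items():
            if not (0 <= p <= 1):
                raise ValueError(f"foci_positive_prob[{probe}] outside [0, 1]")
        if self.foci_count_dist != "ztpoisson":
            raise ValueError(f"unknown count distribution {self.foci_count_dist!r}")


@dataclasses.dataclass(frozen=True)
class FieldSpec:
    """One synthetic imaging field."""

    region: str  # frontal_cortex | cerebellum
    image_shape_px: tuple = (256, 256)
    n_planes: int = 8
    plane_spacing_um: float = DEFAULT_PLANE_SPACING_UM
    cell_classes: tuple = ()
    noise_sd: float = 0.015
    artifact_rate: float = 0.3
    focus_diameter_px: tuple = (2, 6)  # inclusive integer range, within gate
    max_pairwise_overlap: float = 0.20  # bound; must stay <= 0.30
    probe_background: float = 0.02

    def __post_init__(self) -> None:
        if self.region not in ("frontal_cortex", "cerebellum"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.plane_spacing_um <= 0:
            raise ValueError("plane_spacing_um must be positive")
        lo, hi = self.focus_diameter_px
        if not (1 <= lo <= hi <= 11):
            raise ValueError("focus_diameter_px must lie within [1, 11]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def spec_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclasses.dataclass
class GroundTruth:
    """Everything planted into one field."""

    nuclei: pd.DataFrame  # nucleus_id, cell_class, centroid_row, centroid_col, radius_px
    foci: pd.DataFrame  # focus_id, nucleus_id, centroid_row, centroid_col, diameter_px, probe
    artifacts: pd.DataFrame  # centroid_row, centroid_col, diameter_px

    def __post_init__(self) -> None:
        if self.nuclei["nucleus_id"].duplicated().any():
            raise ValueError("duplicate nucleus ids in ground truth")
        if len(self.foci) and self.foci["focus_id"].duplicated().any():
            raise ValueError("duplicate focus ids in ground truth")

    def foci_with_class(self) -> pd.DataFrame:
        """Foci annotated with the owning nucleus' cell class."""
        return self.foci.merge(
            self.nuclei[["nucleus_id", "cell_class"]], on="nucleus_id", how="left"
        )


# ---------------------------------------------------------------------------
# default field specifications, tuned so pipeline medians land in the
# published per-stratum interquartile ranges
# ---------------------------------------------------------------------------

def default_cell_classes(region: str) -> tuple:
    if region == "frontal_cortex":
        return (
            CellClassSpec(
                class_name="cortical_neuron",
                nucleus_radius_px=(8.0, 11.0),
                dapi_mean=0.62,
                dapi_sd=0.05,
                count_per_field=(20, 26),
                foci_positive_prob={"sense": 0.40, "antisense": 0.18},
                foci_count_mu={"sense": 1.7, "antisense": 3.8},
            ),
            CellClassSpec(
                class_name="cortical_glia",
                nucleus_radius_px=(5.0, 6.5),
                dapi_mean=0.45,
                dapi_sd=0.04,
                count_per_field=(13, 18),
                foci_positive_prob={"sense": 0.05, "antisense": 0.03},
                foci_count_mu={"sense": 0.8, "antisense": 1.0},
            ),
        )
    if region == "cerebellum":
        return (
            CellClassSpec(
                class_name="granule",
                nucleus_radius_px=(4.5, 6.0),
                dapi_mean=0.58,
                dapi_sd=0.04,
                count_per_field=(36, 44),
                foci_positive_prob={"sense": 0.23, "antisense": 0.015},
                foci_count_mu={"sense": 0.75, "antisense": 0.65},
            ),
            # faint nuclear stain: mean at ~35% of the granule mean
            CellClassSpec(
                class_name="purkinje",
                nucleus_radius_px=(14.0, 17.0),
                dapi_mean=0.20,
                dapi_sd=0.03,
                count_per_field=(1, 2),
                foci_positive_prob={"sense": 0.70, "antisense": 0.74},
                foci_count_mu={"sense": 5.4, "antisense": 11.5},
            ),
        )
    raise ValueError(f"unknown region {region!r}")


def default_field_spec(region: str, **overrides) -> FieldSpec:
    """Default synthetic field for a region; keyword overrides applied on top."""
    base = dict(
        region=region,
        cell_classes=default_cell_classes(region),
        focus_diameter_px=(2, 5) if region == "frontal_cortex" else (2, 3),
    )
    base.update(overrides)
    return FieldSpec(**base)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def sample_zero_truncated_poisson(
    mu: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw Poisson(mu) conditioned on being >= 1, by inverse transform."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    u = rng.uniform(size=size)
    # map u uniformly onto the truncated CDF, then invert by accumulation
    from scipy import stats

    p0 = np.exp(-mu)
    target = p0 + u * (1.0 - p0)
    return stats.poisson.ppf(target, mu).astype(int)


def _disk_overlap_area(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two disks with center distance ``d``."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return np.pi * r * r
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return a1 + a2 - tri


def _place_nuclei(
    spec: FieldSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Rejection-sample nucleus centers with bounded pairwise overlap."""
    h, w = spec.image_shape_px
    rows: list[dict] = []
    nucleus_id = 1
    for cls in spec.cell_classes:
        lo, hi = cls.count_per_field
        n = int(rng.integers(lo, hi + 1))
        placed = 0
        tries = 0
        max_tries = 400 * max(n, 1)
        while placed < n:
            if tries >= max_tries:
                raise PlacementError(
                    f"could not place {n} nuclei of class {cls.class_name!r} "
                    f"in a {h}x{w} image (placed {placed})"
                )
            tries += 1
            radius = float(rng.uniform(*cls.nucleus_radius_px))
            margin = radius + 2.0
            if 2 * margin >= h or 2 * margin >= w:
                raise PlacementError(
                    f"image too small for class {cls.class_name!r} "
                    f"(radius {radius:.1f}px in {h}x{w})"
                )
            r = float(rng.uniform(margin, h - margin))
            c = float(rng.uniform(margin, w - margin))
            ok = True
            for other in rows:
                d = np.hypot(r - other["centroid_row"], c - other["centroid_col"])
                overlap = _disk_overlap_area(d, radius, other["radius_px"])
                smaller = np.pi * min(radius, other["radius_px"]) ** 2
                if overlap > spec.max_pairwise_overlap * smaller:
                    ok = False
                    break
            if not ok:
                continue
            intensity = float(np.clip(rng.normal(cls.dapi_mean, cls.dapi_sd), 0.05, 1.0))
            rows.append(
                dict(
                    nucleus_id=nucleus_id,
                    cell_class=cls.class_name,
                    centroid_row=r,
                    centroid_col=c,
                    radius_px=radius,
                    dapi_intensity=intensity,
                )
            )
            nucleus_id += 1
            placed += 1
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "cell_class",
            "centroid_row",
            "centroid_col",
            "radius_px",
            "dapi_intensity",
        ],
    )


def _sample_foci(
    spec: FieldSpec,
    nuclei: pd.DataFrame,
    probe: str,
    rng: np.random.Generator,
    positive_prob_scale: float = 1.0,
) -> pd.DataFrame:
    """Draw per-nucleus positivity, counts and in-nucleus focus positions."""
    by_class = {c.class_name: c for c in spec.cell_classes}
    rows: list[dict] = []
    focus_id = 1
    d_lo, d_hi = spec.focus_diameter_px
    for nucleus in nuclei.itertuples(index=False):
        cls = by_class[nucleus.cell_class]
        p = float(np.clip(cls.foci_positive_prob[probe] * positive_prob_scale, 0.0, 0.97))
        if rng.uniform() >= p:
            continue
        count = int(sample_zero_truncated_poisson(cls.foci_count_mu[probe], 1, rng)[0])
        # keep foci well inside the planted disk and apart from each other so
        # planted counts remain recoverable by connected-component detection
        max_r = max(0.5, 0.80 * nucleus.radius_px)
        chosen: list[tuple] = []  # (row, col, diameter)
        for _ in range(count):
            diameter = int(rng.integers(d_lo, d_hi + 1))
            for _attempt in range(200):
                rho = max_r * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                fr = nucleus.centroid_row + rho * np.sin(theta)
                fc = nucleus.centroid_col + rho * np.cos(theta)
                if all(
                    np.hypot(fr - a, fc - b) >= 0.75 * (diameter + d) + 1.5
                    for a, b, d in chosen
                ):
                    break
            chosen.append((fr, fc, diameter))
            rows.append(
                dict(
                    focus_id=focus_id,
                    nucleus_id=nucleus.nucleus_id,
                    centroid_row=float(fr),
                    centroid_col=float(fc),
                    diameter_px=diameter,
                    probe=probe,
                )
            )
            focus_id += 1
    return pd.DataFrame(
        rows,
        columns=[
            "focus_id",
            "nucleus_id",
            "centroid_row",
            "centroid_col",
            "diameter_px",
            "probe",
        ],
    )


def _sample_artifacts(
    spec: FieldSpec, rng: np.random.Generator
) -> pd.DataFrame:
    h, w = spec.image_shape_px
    n = int(rng.poisson(spec.artifact_rate))
    gate_max = 11 if spec.region == "frontal_cortex" else 10
    rows = [
        dict(
            centroid_row=float(rng.uniform(20, h - 20)),
            centroid_col=float(rng.uniform(20, w - 20)),
            diameter_px=float(rng.uniform(gate_max + 5, gate_max + 12)),
        )
        for _ in range(n)
    ]
    return pd.DataFrame(rows, columns=["centroid_row", "centroid_col", "diameter_px"])


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _add_gaussian_spot(
    img: np.ndarray, row: float, col: float, sigma: float, amplitude: float
) -> None:
    """Accumulate an isotropic Gaussian spot into ``img`` (in place)."""
    h, w = img.shape
    half = max(2, int(np.ceil(4 * sigma)))
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0, r1 = max(r0, 0), min(r1, h)
    c0, c1 = max(c0, 0), min(c1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    img[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _add_disk(
    img: np.ndarray, row: float, col: float, radius: float, intensity: float
) -> None:
    h, w = img.shape
    half = int(np.ceil(radius)) + 2
    r0, r1 = max(int(row) - half, 0), min(int(row) + half + 1, h)
    c0, c1 = max(int(col) - half, 0), min(int(col) + half + 1, w)
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    img[r0:r1, c0:c1] += intensity * ((rr**2 + cc**2) <= radius**2)


def _render_nuclear(spec: FieldSpec, nuclei: pd.DataFrame) -> np.ndarray:
    from scipy import ndimage

    base = np.zeros(spec.image_shape_px, dtype=np.float64)
    for nucleus in nuclei.itertuples(index=False):
        _add_disk(
            base,
            nucleus.centroid_row,
            nucleus.centroid_col,
            nucleus.radius_px,
            nucleus.dapi_intensity,
        )
    base = ndimage.gaussian_filter(base, sigma=1.2)
    # broad axial profile: nuclei span most of the stack
    zc = (spec.n_planes - 1) / 2.0
    z = np.arange(spec.n_planes)
    profile = np.exp(-((z - zc) ** 2) / (2 * max(spec.n_planes / 2.0, 1.0) ** 2))
    return profile[:, None, None] * base[None, :, :]


def _render_probe(
    spec: FieldSpec,
    foci: pd.DataFrame,
    artifacts: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    stack = np.full(
        (spec.n_planes, *spec.image_shape_px), spec.probe_background, dtype=np.float64
    )
    z = np.arange(spec.n_planes)
    for focus in foci.itertuples(index=False):
        sigma = max(focus.diameter_px * _FWHM_TO_SIGMA, 0.45)
        amplitude = float(rng.uniform(0.55, 0.95))
        z0 = int(rng.integers(0, spec.n_planes))
        zfactor = np.exp(-((z - z0) ** 2) / (2 * 1.0**2))
        for plane, f in enumerate(zfactor):
            if f < 1e-3:
                continue
            _add_gaussian_spot(
                stack[plane],
                focus.centroid_row,
                focus.centroid_col,
                sigma,
                amplitude * f,
            )
    zc = (spec.n_planes - 1) / 2.0
    art_profile = np.exp(-((z - zc) ** 2) / (2 * max(spec.n_planes / 2.0, 1.0) ** 2))
    for artifact in artifacts.itertuples(index=False):
        sigma = artifact.diameter_px * _FWHM_TO_SIGMA
        for plane, f in enumerate(art_profile):
            _add_gaussian_spot(
                stack[plane],
                artifact.centroid_row,
                artifact.centroid_col,
                sigma,
                0.8 * f,
            )
    return stack


def _to_uint16(stack: np.ndarray) -> np.ndarray:
    return np.round(np.clip(stack, 0.0, 1.0) * 65535).astype(np.uint16)


def generate_field(
    spec: FieldSpec,
    probe: str,
    seed: int,
    positive_prob_scale: float = 1.0,
) -> tuple:
    """Generate one two-channel stack plus its ground truth.

    ``positive_prob_scale`` multiplies every class' foci-positive
    probability; cohort generation uses it to plant subject-level burden.
    """
    if probe not in PROBES:
        raise ValueError(f"unknown probe {probe!r}")
    place_rng = _rng(seed, "placement")
    count_rng = _rng(seed, "counts")
    render_rng = _rng(seed, "render")
    noise_rng = _rng(seed, "noise")

    nuclei = _place_nuclei(spec, place_rng)
    foci = _sample_foci(spec, nuclei, probe, count_rng, positive_prob_scale)
    artifacts = _sample_artifacts(spec, place_rng)

    nuclear = _render_nuclear(spec, nuclei)
    probe_chan = _render_probe(spec, foci, artifacts, render_rng)
    if spec.noise_sd > 0:
        nuclear = nuclear + noise_rng.normal(0.0, spec.noise_sd, nuclear.shape)
        probe_chan = probe_chan + noise_rng.normal(0.0, spec.noise_sd, probe_chan.shape)

    stack = ZStack(
        nuclear=_to_uint16(nuclear),
        probe=_to_uint16(probe_chan),
        plane_spacing_um=spec.plane_spacing_um,
    )
    truth = GroundTruth(
        nuclei=nuclei.drop(columns=["dapi_intensity"]),
        foci=foci,
        artifacts=artifacts,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ClinicalModel:
    """Sampling model for subject-level clinical/molecular covariates."""

    age_onset_mean: float = 62.0
    age_onset_sd: float = 8.0
    survival_log_mean: float = 1.6  # median ~ 5 years
    survival_log_sd: float = 0.6
    male_prob: float = 0.56
    diagnosis_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "FTLD": 0.41,
            "FTLD_MND": 0.25,
            "MND": 0.29,
            "other": 0.05,
        }
    )
    repeat_length_mean: float = 3000.0
    repeat_length_sd: float = 1200.0
    burden_sd: float = 0.45  # sd of the subject log-burden random effect
    association_covariate: str = "polyGP"
    association_strength: float = 0.0  # target Spearman, in [-1, 1]

    def __post_init__(self) -> None:
        if not -1.0 <= self.association_strength <= 1.0:
            raise ValueError("association_strength must lie in [-1, 1]")


CONTINUOUS_COVARIATES = (
    "age_onset_years",
    "age_death_years",
    "repeat_length",
    "transcripts_total",
    "transcripts_v1",
    "transcripts_v2",
    "transcripts_v3",
    "transcripts_intron1a",
    "transcripts_intron1b",
    "polyGP",
    "polyGA",
)


@dataclasses.dataclass
class CohortBundle:
    """A synthetic cohort: clinical table, planted burdens, and fields."""

    clinical: pd.DataFrame
    burdens: pd.DataFrame  # subject_id, burden_scale, positive_fraction (planted)
    counts: pd.DataFrame  # subject_id, field_id, nucleus_id, cell_class, foci_count
    fields: list  # (subject_id, field_id, ZStack, GroundTruth); empty if not rendered
    probe: str
    field_spec: FieldSpec
    seed: int


def _sample_clinical(
    n_subjects: int, model: ClinicalModel, latent: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the covariate table; one covariate may track the latent burden."""
    rho = model.association_strength
    diag_names = list(model.diagnosis_probs)
    diag_p = np.asarray(list(model.diagnosis_probs.values()), dtype=float)
    diag_p = diag_p / diag_p.sum()
    rows = []
    for i in range(n_subjects):
        onset = rng.normal(model.age_onset_mean, model.age_onset_sd)
        survival = float(
            np.exp(rng.normal(model.survival_log_mean, model.survival_log_sd))
        )
        row = {
            "subject_id": f"S{i + 1:03d}",
            "gender": "male" if rng.uniform() < model.male_prob else "female",
            "age_onset_years": round(float(onset), 1),
            "age_death_years": round(float(onset) + survival, 1),
            "survival_years": round(survival, 2),
            "diagnosis": diag_names[int(rng.choice(len(diag_names), p=diag_p))],
            "repeat_length": round(
                float(
                    np.clip(
                        rng.normal(model.repeat_length_mean, model.repeat_length_sd),
                        50,
                        None,
                    )
                )
            ),
            "event_indicator": 1,
        }
        for name in CONTINUOUS_COVARIATES[3:]:
            w = rng.normal()
            if name == model.association_covariate and abs(rho) > 0:
                w = rho * latent[i] + np.sqrt(1 - rho * rho) * rng.normal()
            row[name] = round(float(np.exp(0.8 * w)), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    n_subjects: int,
    field_spec: FieldSpec,
    fields_per_subject: int,
    clinical_model: ClinicalModel | None = None,
    seed: int = 0,
    probe: str = "sense",
    render_images: bool = True,
) -> CohortBundle:
    """Generate a synthetic cohort with subject-level foci burden.

    Each subject gets a multiplicative random effect on the foci-positive
    probability (log-normal, sd ``clinical_model.burden_sd``).  When
    ``render_images`` is false only the planted per-nucleus count tables
    are produced, which is orders of magnitude faster and sufficient for
    statistical calibration work.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    model = clinical_model or ClinicalModel()
    clin_rng = _rng(seed, "clinical")

    latent = clin_rng.normal(size=n_subjects)  # subject log-burden scores
    burden_scale = np.exp(model.burden_sd * latent)
    clinical = _sample_clinical(n_subjects, model, latent, clin_rng)

    fields = []
    count_rows = []
    positive_fraction = np.zeros(n_subjects)
    for i, subject_id in enumerate(clinical["subject_id"]):
        n_cells = 0
        n_pos = 0
        for f in range(fields_per_subject):
            field_seed = int(
                np.random.SeedSequence([seed, 97, i, f]).generate_state(1)[0]
            )
            if render_images:
                stack, truth = generate_field(
                    field_spec, probe, field_seed, positive_prob_scale=burden_scale[i]
                )
                fields.append((subject_id, f"F{f + 1:02d}", stack, truth))
                per_cell = (
                    truth.foci.groupby("nucleus_id").size()
                    if len(truth.foci)
                    else pd.Series(dtype=int)
                )
                for nucleus in truth.nuclei.itertuples(index=False):
                    cnt = int(per_cell.get(nucleus.nucleus_id, 0))
                    count_rows.append(
                        dict(
                            subject_id=subject_id,
                            field_id=f"F{f + 1:02d}",
                            nucleus_id=nucleus.nucleus_id,
                            cell_class=nucleus.cell_class,
                            foci_count=cnt,
                        )
                    )
                    n_cells += 1
                    n_pos += cnt > 0
            else:
                table_rng = np.random.default_rng(field_seed)
                nid = 1
                for cls in field_spec.cell_classes:
                    lo, hi = cls.count_per_field
                    n = int(table_rng.integers(lo, hi + 1))
                    p = float(
                        np.clip(
                            cls.foci_positive_prob[probe] * burden_scale[i], 0.0, 0.97
                        )
                    )
                    for _ in range(n):
                        cnt = 0
                        if table_rng.uniform() < p:
                            cnt = int(
                                sample_zero_truncated_poisson(
                                    cls.foci_count_mu[probe], 1, table_rng
                                )[0]
                            )
                        count_rows.append(
                            dict(
                                subject_id=subject_id,
                                field_id=f"F{f + 1:02d}",
                                nucleus_id=nid,
                                cell_class=cls.class_name,
                                foci_count=cnt,
                            )
                        )
                        nid += 1
                        n_cells += 1
                        n_pos += cnt > 0
        positive_fraction[i] = n_pos / n_cells if n_cells else np.nan

    burdens = pd.DataFrame(
        {
            "subject_id": clinical["subject_id"],
            "burden_scale": burden_scale,
            "positive_fraction": positive_fraction,
        }
    )
    return CohortBundle(
        clinical=clinical,
        burdens=burdens,
        counts=pd.DataFrame(count_rows),
        fields=fields,
        probe=probe,
        field_spec=field_spec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_fixture(bundle: CohortBundle, directory: str | os.PathLike) -> str:
    """Write a cohort to disk: TIFF stacks, CSV tables, plain-text manifest.

    Returns the manifest path.  The manifest has one ``key=value`` record
    line per file with its sha256, plus the generator seed and spec hash.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    written: list[str] = []

    for subject_id, field_id, stack, truth in bundle.fields:
        stem = f"{subject_id}_{field_id}_{bundle.probe}"
        tif = os.path.join(directory, f"{stem}.tif")
        write_stack(stack, tif)
        written.append(tif)
        for name, table in (
            ("nuclei", truth.nuclei),
            ("foci", truth.foci),
            ("artifacts", truth.artifacts),
        ):
            path = os.path.join(directory, f"{stem}_truth_{name}.csv")
            table.to_csv(path, index=False)
            written.append(path)

    for name, table in (
        ("clinical", bundle.clinical),
        ("burdens", bundle.burdens),
        ("counts", bundle.counts),
    ):
        path = os.path.join(directory, f"{name}.csv")
        table.to_csv(path, index=False)
        written.append(path)

    manifest = os.path.join(directory, "manifest.txt")
    with open(manifest, "w") as fh:
        fh.write(f"seed={bundle.seed}\n")
        fh.write(f"probe={bundle.probe}\n")
        fh.write(f"spec_hash={bundle.field_spec.spec_hash()}\n")
        fh.write(f"n_files={len(written)}\n")
        for path in written:
            fh.write(f"file={os.path.basename(path)} sha256={_sha256(path)}\n")
    return manifest
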