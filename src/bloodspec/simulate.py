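"""Synthetic ATR-FTIR biofluid spectra with known ground truth.

The generator emulates the structure of a dried-blood-spot ATR-FTIR study:
a 4 cm^-1-spaced axis over 400–4000 cm^-1, two classes (healthy controls and
CVID patients, the latter split into complication-free and complications
subgroups), and 20 replicate spectra per subject per biofluid (2 spots x 10
acquisition points).  Each spectrum is a sum of Gaussian absorption bands
whose per-subject amplitudes carry class/subgroup effects plus between-
subject variability, overlaid with a random low-order polynomial baseline
drift and white replicate noise.

Randomness is hierarchical: each subject's draws come from a seed sequence
keyed by (study seed, group, subject index), so adding subjects to one group
never changes the spectra of existing subjects.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .exceptions import ConfigError
from .io import SampleMeta, SpectralDataset

_GROUP_CODES = {"HC": 0, "CVID_non": 1, "CVID_comp": 2}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: centre (cm^-1), sigma (cm^-1), amplitude."""

    center: float
    width: float
    base_amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("band width must be positive")
        if self.base_amplitude < 0:
            raise ConfigError("band amplitude must be non-negative")


@dataclass(frozen=True)
class ClassEffect:
    """Additive amplitude change of one band in the CVID class.

    ``delta`` is added for every CVID subject; the complications subgroup
    gets ``delta * subgroup_scale`` (accentuated disease effect).
    """

    wavenumber: float
    delta: float
    subgroup_scale: float = 1.5

    @property
    def direction(self) -> str:
        return "up_in_CVID" if self.delta > 0 else "down_in_CVID"


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulated study."""

    n_hc: int = 30
    n_cvid_non: int = 8
    n_cvid_comp: int = 13
    spots: int = 2
    points_per_spot: int = 10
    axis_start: float = 400.0
    axis_stop: float = 4000.0
    axis_step: float = 4.0
    band_library: tuple = ()
    effects: tuple = ()
    subject_sd: float = 0.002
    subject_point_sd: float = 0.004
    smoothness: float = 16.0  # cm^-1, correlation length of subject deviations
    replicate_sd: float = 0.002
    baseline_amplitude: float = 0.01
    biofluid: str = "serum"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_cvid_non, self.n_cvid_comp) < 0:
            raise ConfigError("subject counts must be non-negative")
        if self.spots < 1 or self.points_per_spot < 1:
            raise ConfigError("replicate structure must be spots x points >= 1")
        centers = {b.center for b in self.band_library}
        for e in self.effects:
            if e.wavenumber not in centers:
                raise ConfigError(
                    f"effect at {e.wavenumber} cm^-1 has no matching band"
                )

    @property
    def replicates_per_subject(self) -> int:
        return self.spots * self.points_per_spot

    @property
    def n_subjects(self) -> int:
        return self.n_hc + self.n_cvid_non + self.n_cvid_comp

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)


#: serum-like band library: protein Amide A/B/I/II/III, lipid CH stretches,
#: phosphate and carbohydrate fingerprint bands.
DEFAULT_BANDS = (
    BandSpec(984.0, 10.0, 0.035),
    BandSpec(1034.0, 12.0, 0.050),
    BandSpec(1053.0, 10.0, 0.045),
    BandSpec(1084.0, 12.0, 0.045),
    BandSpec(1115.0, 10.0, 0.040),
    BandSpec(1170.0, 12.0, 0.030),
    BandSpec(1242.0, 14.0, 0.060),
    BandSpec(1315.0, 16.0, 0.050),
    BandSpec(1400.0, 16.0, 0.070),
    BandSpec(1455.0, 12.0, 0.060),
    BandSpec(1528.0, 10.0, 0.050),
    BandSpec(1535.0, 18.0, 0.180),
    BandSpec(1643.0, 25.0, 0.300),
    BandSpec(1759.0, 10.0, 0.030),
    BandSpec(2852.0, 12.0, 0.070),
    BandSpec(2862.0, 10.0, 0.050),
    BandSpec(2932.0, 14.0, 0.100),
    BandSpec(2960.0, 12.0, 0.080),
    BandSpec(3070.0, 30.0, 0.060),
    BandSpec(3300.0, 110.0, 0.280),
)

#: default class effects: directions follow the reported serum/plasma
#: biomarkers (phosphodiester 984, collagen 1034, P-O-C 1115 and
#: triglyceride C=O 1759 up in CVID; nu_as PO2- 1242 and nucleotide C=N
#: 1528 down).  All six sit on narrow fingerprint bands, where peak-level
#: localisation of a class effect is physically meaningful.
DEFAULT_EFFECTS = (
    ClassEffect(984.0, +0.008),
    ClassEffect(1034.0, +0.010),
    ClassEffect(1115.0, +0.008),
    ClassEffect(1242.0, -0.008),
    ClassEffect(1528.0, -0.010),
    ClassEffect(1759.0, +0.008),
    # weaker lipid CH-stretch effects in the high region
    ClassEffect(2862.0, +0.005),
    ClassEffect(2932.0, +0.006),
)

#: centres of the implanted fingerprint effects (ground truth for recovery)
FINGERPRINT_EFFECT_CENTERS = (984.0, 1034.0, 1115.0, 1242.0, 1528.0, 1759.0)


def default_config(seed: int = 0, biofluid: str = "serum") -> SimConfig:
    """The default synthetic study: 30 HC, 8 complication-free CVID and
    13 CVID-with-complications subjects, 20 replicates each, 4 cm^-1 axis
    over 400–4000 cm^-1, serum-like bands and the default class effects."""
    return SimConfig(
        band_library=DEFAULT_BANDS,
        effects=DEFAULT_EFFECTS,
        seed=seed,
        biofluid=biofluid,
    )


def null_variant(cfg: SimConfig) -> SimConfig:
    """Copy of a config with all effect deltas set to 0 (classes exchangeable)."""
    return replace(cfg, effects=tuple(replace(e, delta=0.0) for e in cfg.effects))


def scaled_effects(cfg: SimConfig, scale: float) -> SimConfig:
    """Copy of a config with every effect delta multiplied by ``scale``."""
    return replace(cfg, effects=tuple(replace(e, delta=e.delta * scale) for e in cfg.effects))


def _smooth_field(rng: np.random.Generator, n: int, sigma_pts: float, sd: float) -> np.ndarray:
    """Smooth zero-mean random field: white noise blurred with a Gaussian
    kernel of ``sigma_pts`` points, rescaled to pointwise sd ``sd``."""
    half = max(int(np.ceil(3 * sigma_pts)), 1)
    t = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (t / sigma_pts) ** 2)
    # normalise so the convolved field has unit pointwise variance
    kernel = kernel / np.sqrt(np.sum(kernel**2))
    white = rng.normal(0.0, 1.0, size=n + 2 * half)
    return sd * np.convolve(white, kernel, mode="valid")


def _subject_plan(cfg: SimConfig):
    plan = []
    for i in range(cfg.n_hc):
        plan.append((f"HC{i + 1:03d}", "HC", "none_assigned", "HC", i))
    for i in range(cfg.n_cvid_non):
        plan.append((f"CVN{i + 1:03d}", "CVID", "complication_free", "CVID_non", i))
    for i in range(cfg.n_cvid_comp):
        plan.append((f"CVC{i + 1:03d}", "CVID", "complications", "CVID_comp", i))
    return plan


def generate(cfg: SimConfig) -> tuple[SpectralDataset, dict]:
    """Generate a dataset and its ground-truth manifest.

    Per subject, each band amplitude is ``base + class effect +
    N(0, subject_sd)``, and a smooth zero-mean spectral deviation field
    (white noise convolved with a Gaussian kernel of ``smoothness`` cm^-1,
    pointwise sd ``subject_point_sd``) models biological between-subject
    heterogeneity beyond band amplitudes.  Per replicate, the spectrum is
    the band sum plus the deviation field, a random quadratic baseline and
    ``N(0, replicate_sd)`` point noise.  Bit-identical for a given config
    (including seed).
    """
    axis = cfg.axis()
    bands = list(cfg.band_library)
    basis = np.vstack(
        [np.exp(-0.5 * ((axis - b.center) / b.width) ** 2) for b in bands]
    ) if bands else np.zeros((0, axis.size))
    effect_by_center = {e.wavenumber: e for e in cfg.effects}
    x01 = (axis - axis[0]) / max(axis[-1] - axis[0], 1.0)

    rows = []
    records = []
    for subject_id, group, subgroup, gkey, idx in _subject_plan(cfg):
        ss = np.random.SeedSequence([int(cfg.seed), _GROUP_CODES[gkey], int(idx)])
        rng = np.random.default_rng(ss)
        amps = np.empty(len(bands))
        for k, b in enumerate(bands):
            delta = 0.0
            eff = effect_by_center.get(b.center)
            if eff is not None and group == "CVID":
                delta = eff.delta * (eff.subgroup_scale if subgroup == "complications" else 1.0)
            amps[k] = b.base_amplitude + delta
        amps = amps + rng.normal(0.0, cfg.subject_sd, size=len(bands))
        clean = amps @ basis if bands else np.zeros(axis.size)
        if cfg.subject_point_sd > 0:
            clean = clean + _smooth_field(
                rng, axis.size, cfg.smoothness / cfg.axis_step, cfg.subject_point_sd
            )
        for spot in range(1, cfg.spots + 1):
            for point in range(1, cfg.points_per_spot + 1):
                coef = rng.uniform(0.0, cfg.baseline_amplitude, size=3)
                baseline = coef[0] + coef[1] * x01 + coef[2] * x01**2
                noise = rng.normal(0.0, cfg.replicate_sd, size=axis.size)
                rows.append(clean + baseline + noise)
                records.append(
                    SampleMeta(subject_id, group, subgroup, cfg.biofluid, spot, point)
                )
    matrix = np.vstack(rows) if rows else np.zeros((0, axis.size))
    truth = {
        "seed": int(cfg.seed),
        "effects": [
            {
                "wavenumber": e.wavenumber,
                "delta": e.delta,
                "subgroup_scale": e.subgroup_scale,
                "direction": e.direction,
            }
            for e in cfg.effects
        ],
        "config": asdict(cfg),
    }
    return SpectralDataset(axis, matrix, records), truth
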