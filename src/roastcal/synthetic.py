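"""Synthetic roast-gas campaign generator with known ground truth.

Emulates 5-s-averaged unit-mass-resolution mass spectra of coffee roast gas
from soft two-photon UV ionization, together with per-roast reference values
(Colorette roast degree and Folin-Ciocalteu antioxidant capacity of the brew).

Model
-----
A single monotone latent roast progress ``s(t)`` drives everything.  Each
compound in the catalogue releases with a smooth unimodal (or monotone)
temporal profile built on the basis ``{s, s^2, s^3, s*softplus(K(s-C))}``;
profiles are zero before the onset of volatile release (90 s).  The two
reference properties are deterministic functions of progress at drop:

* Colorette: affine-plus-softplus plateau, strictly decreasing
  (almost linear early, levelling off toward dark roast), plus
  Gaussian measurement noise;
* FC value: quadratic in ``s`` with an early maximum (slight rise followed
  by a steady decrease), plus Gaussian measurement noise.

Catalogue amplitudes are balanced so that the total ion current over the
retained channels is proportional to ``s``: after L1 normalization the drop
spectrum is then an exact affine function of ``{s, s^2, softplus}``, so both
property curves are exactly linear in the noise-free descriptors (three
latent factors).  This makes parameter recovery by the downstream PLS
pipeline well-posed and testable against ground truth.

Noise model: additive Gaussian baseline per (channel, time bin),
multiplicative lognormal per (channel, time bin), and a lognormal
between-roast amplitude factor per compound (large for the caffeine channel,
which is why caffeine is excluded during pretreatment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from roastcal.containers import RoastRecord, SpectraMatrix

__all__ = [
    "CompoundTemplate",
    "CampaignConfig",
    "two_photon_energy",
    "channel_is_ionizable",
    "default_catalog",
    "latent_progress",
    "colorette_truth",
    "fc_truth",
    "simulate_roast",
    "simulate_campaign",
]

# 2 * h * c in eV*nm
_HC_EV_NM = 1239.841984

# Latent-progress clock: volatile release starts at ONSET_S and the progress
# variable saturates at REF_S (a 14-min roast).
ONSET_S = 90.0
REF_S = 840.0

# Softplus knee shared by the plateau-type profiles and the Colorette curve.
_K = 15.0
_SC = 0.8

# Colorette(s) = _C0 - _C1*s + (_C1/_K)*softplus(_K*(s-_SC)):
# strictly decreasing, slope -_C1 early, flat past the knee.
_C0 = 298.3
_C1 = 291.7

# FC(s) = _F0 + _F1*s - _F2*s^2: maximum at s = _F1/(2*_F2) ~ 0.52
# (a slight rise early in the calibrated window, then a steady decrease).
_F0 = 2196.0
_F1 = 2704.0
_F2 = 2600.0

CAFFEINE_CHANNELS = (193, 197)  # inclusive m/z range tied to caffeine


def two_photon_energy(wavelength_nm: float) -> float:
    """Combined energy of two UV photons, in eV.

    At 266 nm this is 9.32 eV and at 248 nm 10.0 eV — low enough that only
    compounds with matching ionization energies (aromatics, and at 248 nm
    also aliphatic amines) are ionized, which is what makes the technique
    soft and selective.
    """
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return 2.0 * _HC_EV_NM / wavelength_nm


@dataclass(frozen=True)
class CompoundTemplate:
    """One catalogued roast-gas compound mapped to a unit m/z channel.

    ``shape`` holds coefficients on the temporal basis
    ``(s, s^2, s^3, s*softplus(K*(s-C)))`` of the latent progress; the
    resulting profile must be non-negative over the roast.  ``amplitude`` is
    the mean peak intensity (arbitrary detector units) at 248 nm;
    ``response_266`` is the relative per-channel response factor at 266 nm
    (ion yields differ strongly between the two wavelengths).
    ``rsd_between_roasts`` is the relative standard deviation of the
    compound's release amplitude across nominally identical roasts.
    """

    mz: int
    name: str
    shape: tuple[float, float, float, float]
    amplitude: float
    ionization_energy_ev: float
    rsd_between_roasts: float = 0.05
    response_266: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.mz <= 350:
            raise ValueError(f"m/z {self.mz} outside 1-350")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.rsd_between_roasts < 0:
            raise ValueError("rsd must be >= 0")
        prof = self.profile(np.linspace(0.0, 1.0, 201))
        if np.any(prof < -1e-9):
            raise ValueError(f"profile of m/z {self.mz} is negative somewhere")

    def profile(self, s: np.ndarray) -> np.ndarray:
        """Evaluate the (unit-amplitude) temporal profile at progress s."""
        return _basis(np.asarray(s, dtype=float)) @ np.asarray(self.shape)

    def response(self, wavelength_nm: float) -> float:
        if abs(wavelength_nm - 266.0) < 1.0:
            return self.response_266
        return 1.0


def channel_is_ionizable(compound: CompoundTemplate, wavelength_nm: float) -> bool:
    """True iff two UV photons carry at least the compound's ionization energy.

    The boundary case (ionization energy exactly equal to the two-photon
    energy) counts as ionizable.
    """
    return compound.ionization_energy_ev <= two_photon_energy(wavelength_nm)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _basis(s: np.ndarray) -> np.ndarray:
    """Temporal basis (columns: s, s^2, s^3, s*softplus(K*(s-C)))."""
    s = np.asarray(s, dtype=float)
    return np.stack(
        [s, s**2, s**3, s * _softplus(_K * (s - _SC))], axis=-1
    )


def latent_progress(time_s: np.ndarray) -> np.ndarray:
    """Monotone latent roast progress s(t) in [0, 1]."""
    t = np.asarray(time_s, dtype=float)
    return np.clip((t - ONSET_S) / (REF_S - ONSET_S), 0.0, 1.0)


def colorette_truth(s: np.ndarray) -> np.ndarray:
    """Noise-free Colorette value at latent progress s (decreasing plateau)."""
    s = np.asarray(s, dtype=float)
    return _C0 - _C1 * s + (_C1 / _K) * _softplus(_K * (s - _SC))


def fc_truth(s: np.ndarray) -> np.ndarray:
    """Noise-free FC value (GA-eq mg/L) at latent progress s (rise then fall)."""
    s = np.asarray(s, dtype=float)
    return _F0 + _F1 * s - _F2 * s**2


# Shape archetypes: coefficients on (s, s^2, s^3, s*softplus).
_EARLY = (1.0, -0.9, 0.0, 0.0)       # peaks at s ~ 0.56
_MID = (1.2, -1.0, 0.0, 0.0)         # peaks at s ~ 0.60
_QUAD = (0.0, 1.0, 0.0, 0.0)         # monotone, accelerating
_CUBIC = (0.0, 0.0, 1.0, 0.0)        # monotone, late
_PLAT2 = (0.0, 1.0, -0.6, 0.0)       # rises, flattens toward dark roast
_PLATSP = (1.0, 0.0, 0.0, -0.25)     # rises, declines past the knee
_RISER = (1.0, 0.0, 0.0, 0.15)       # rises, steeper past the knee

# (mz, name, shape, base amplitude, IE/eV, rsd, response at 266 nm)
_CATALOG_SPEC = [
    (59, "C3-amines", _CUBIC, 22.0, 9.80, 0.05, 0.0),
    (67, "pyrrole", _CUBIC, 10.0, 8.21, 0.05, 0.3),
    (77, "methoxyphenol fragment", _MID, 4.0, 9.00, 0.05, 0.5),
    (79, "pyridine", _CUBIC, 2.5, 9.26, 0.05, 0.4),
    (94, "phenol", _PLAT2, 25.0, 8.49, 0.05, 1.2),
    (96, "furfural", _MID, 30.0, 9.21, 0.05, 0.35),
    (107, "methoxyphenol fragment", _MID, 5.0, 9.00, 0.05, 0.5),
    (108, "methylphenol", _PLAT2, 18.0, 8.34, 0.05, 1.1),
    (110, "benzenediol", _QUAD, 15.0, 8.56, 0.05, 1.2),
    (117, "indole", _EARLY, 35.0, 7.76, 0.05, 0.8),
    (120, "vinylphenol", _RISER, 20.0, 8.30, 0.05, 1.3),
    (122, "dimethylphenol", _PLAT2, 12.0, 8.13, 0.05, 1.1),
    (124, "guaiacol", _PLATSP, 30.0, 7.85, 0.05, 1.3),
    (126, "hydroxymethylfurfural", _MID, 28.0, 8.90, 0.05, 0.4),
    (136, "vinyl-dihydroxybenzene", _MID, 16.0, 8.20, 0.05, 1.3),
    (150, "vinylguaiacol", _RISER, 100.0, 7.80, 0.05, 1.0),
    (178, "difurfurylether", _MID, 8.0, 8.90, 0.05, 0.4),
    (194, "caffeine", _QUAD, 12.0, 8.10, 0.50, 0.6),
]

# Fragment of vinylguaiacol (methyl loss): same temporal shape as m/z 150,
# amplitude tied to 6% of the parent so the fragment stays below 8% of the
# base peak in any drop spectrum.
_FRAGMENT_RATIO_135 = 0.06


def _balance_amplitudes(amp0: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Minimal relative amplitude adjustment so basis totals beyond s cancel.

    Solves min sum((amp_j/amp0_j - 1)^2) s.t. coeffs.T @ amp = 0 (coeffs
    holds the s^2, s^3 and softplus columns of the catalogue shapes).  This
    makes the retained-channel total ion current exactly proportional to the
    latent progress s, so L1 normalization keeps the drop spectrum linear in
    the latent basis.  Weighting by amplitude keeps minor channels positive.
    """
    d = amp0**2
    a = np.linalg.solve(coeffs.T @ (d[:, None] * coeffs), coeffs.T @ amp0)
    amp = amp0 - d * (coeffs @ a)
    if np.any(amp <= 0):
        raise RuntimeError("amplitude balancing produced non-positive amplitudes")
    return amp


def default_catalog() -> list[CompoundTemplate]:
    """Packaged roast-gas compound catalogue.

    Nineteen informative channels (base peak vinylguaiacol at m/z 150, its
    methyl-loss fragment at m/z 135, phenolics, furans, N-heterocycles,
    amines and caffeine); every other unit-mass channel up to m/z 350
    carries baseline noise only.
    """
    mzs, names, shapes, amp0, ies, rsds, r266 = map(list, zip(*_CATALOG_SPEC))
    amp0 = np.asarray(amp0, dtype=float)
    shape_mat = np.asarray(shapes, dtype=float)

    # Balance over the channels retained during pretreatment: caffeine is
    # excluded there, and the m/z 135 fragment rides on m/z 150's amplitude.
    balance = np.array([n != "caffeine" for n in names])
    coeffs = shape_mat[:, 1:].copy()
    i150 = mzs.index(150)
    coeffs[i150] *= 1.0 + _FRAGMENT_RATIO_135
    coeffs[~balance] = 0.0
    amp = _balance_amplitudes(amp0, coeffs)
    amp[~balance] = amp0[~balance]

    catalog = [
        CompoundTemplate(
            mz=mzs[j], name=names[j], shape=tuple(shape_mat[j]),
            amplitude=float(amp[j]), ionization_energy_ev=ies[j],
            rsd_between_roasts=rsds[j], response_266=r266[j],
        )
        for j in range(len(mzs))
    ]
    catalog.append(
        CompoundTemplate(
            mz=135, name="vinylguaiacol fragment", shape=_RISER,
            amplitude=float(_FRAGMENT_RATIO_135 * amp[i150]),
            ionization_energy_ev=9.0, rsd_between_roasts=0.05,
            response_266=1.0,
        )
    )
    catalog.sort(key=lambda c: c.mz)
    return catalog


@dataclass(frozen=True)
class CampaignConfig:
    """Geometry and noise levels of a simulated roast campaign.

    Defaults mirror the measurement conditions the calibration assumes:
    roasts dropped between 7 and 14 min, spectra averaged to 5 s resolution,
    ionization at 248 nm, and moderate instrument noise.  ``seed`` is
    mandatory — every campaign must be bit-reproducible.
    """

    seed: int
    n_roasts: int = 84
    drop_time_range: tuple[float, float] = (420.0, 840.0)
    wavelength_nm: float = 248.0
    resolution_s: float = 5.0
    mz_max: int = 350
    additive_noise_sd: float = 0.15
    multiplicative_sigma: float = 0.05
    amplitude_rsd_scale: float = 1.0
    colorette_noise_sd: float = 2.0
    fc_noise_sd: float = 40.0
    catalog: tuple[CompoundTemplate, ...] = field(
        default_factory=lambda: tuple(default_catalog())
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required (reproducibility contract)")
        if self.n_roasts < 2:
            raise ValueError("a campaign needs at least 2 roasts")
        lo, hi = self.drop_time_range
        if not (0 < lo <= hi <= REF_S):
            raise ValueError(
                f"drop_time_range {self.drop_time_range} outside (0, {REF_S}]"
            )
        if colorette_truth(latent_progress(lo)) > 200.0:
            raise ValueError(
                "earliest drop time gives a Colorette value above the 0-200 scale"
            )
        if self.resolution_s <= 0:
            raise ValueError("resolution must be positive")

    def zero_noise(self) -> "CampaignConfig":
        """Copy of this config with every noise source switched off."""
        return replace(
            self, additive_noise_sd=0.0, multiplicative_sigma=0.0,
            amplitude_rsd_scale=0.0, colorette_noise_sd=0.0, fc_noise_sd=0.0,
        )


def simulate_roast(
    config: CampaignConfig, drop_time_s: float, seed: int, roast_id: str = ""
) -> RoastRecord:
    """Simulate one roast dropped at ``drop_time_s`` seconds.

    The spectra matrix covers bin centers from roast start to the drop at the
    configured time resolution; the reference Colorette and FC values are the
    ground-truth property curves evaluated at the latent progress of the
    final 5-s spectrum, plus measurement noise.  With every noise source at
    zero the output is an exact deterministic function of the drop time.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    lo, hi = config.drop_time_range
    if not lo <= drop_time_s <= hi:
        raise ValueError(f"drop time {drop_time_s} outside range {config.drop_time_range}")
    rng = np.random.default_rng(seed)
    res = config.resolution_s
    n_bins = int(round(drop_time_s / res))
    centers = (np.arange(n_bins) + 0.5) * res
    s = latent_progress(centers)

    mz = np.arange(1, config.mz_max + 1)
    intensity = np.zeros((n_bins, mz.size))

    for comp in config.catalog:
        if not channel_is_ionizable(comp, config.wavelength_nm):
            continue
        rf = comp.response(config.wavelength_nm)
        if rf <= 0.0:
            continue
        trace = comp.amplitude * rf * comp.profile(s)
        rsd = comp.rsd_between_roasts * config.amplitude_rsd_scale
        if rsd > 0:
            sig = math.sqrt(math.log1p(rsd**2))
            trace = trace * rng.lognormal(-0.5 * sig**2, sig)
        if config.multiplicative_sigma > 0:
            sig = config.multiplicative_sigma
            trace = trace * rng.lognormal(-0.5 * sig**2, sig, size=n_bins)
        intensity[:, comp.mz - 1] += trace

    if config.additive_noise_sd > 0:
        intensity += rng.normal(0.0, config.additive_noise_sd, intensity.shape)
    np.clip(intensity, 0.0, None, out=intensity)

    s_drop = float(s[-1])
    col_true = float(colorette_truth(s_drop))
    fc_true = float(fc_truth(s_drop))
    col = col_true
    fc = fc_true
    if config.colorette_noise_sd > 0:
        col += float(rng.normal(0.0, config.colorette_noise_sd))
    if config.fc_noise_sd > 0:
        fc += float(rng.normal(0.0, config.fc_noise_sd))

    spectra = SpectraMatrix(centers, mz, intensity, config.wavelength_nm)
    return RoastRecord(
        spectra=spectra,
        colorette=float(np.clip(col, 0.0, 200.0)),
        fc_value=max(fc, 0.0),
        drop_time_s=drop_time_s,
        wavelength_nm=config.wavelength_nm,
        roast_id=roast_id,
        truth={
            "s": s,
            "colorette_true": colorette_truth(s),
            "fc_true": fc_truth(s),
            "s_drop": s_drop,
            "colorette_drop_true": col_true,
            "fc_drop_true": fc_true,
        },
    )


def simulate_campaign(config: CampaignConfig) -> list[RoastRecord]:
    """Simulate a whole campaign of roasts.

    Drop times are spread evenly over the configured range (rounded to the
    time resolution), the way a designed calibration campaign staggers its
    drop points.  Per-roast noise is drawn from child seeds of the campaign
    seed, so the same config reruns bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.drop_time_range
    drops = np.linspace(lo, hi, config.n_roasts)
    drops = np.clip(np.round(drops / config.resolution_s) * config.resolution_s, lo, hi)
    seeds = rng.integers(0, 2**31, size=config.n_roasts)
    return [
        simulate_roast(config, float(drops[i]), int(seeds[i]), roast_id=f"roast{i:03d}")
        for i in range(config.n_roasts)
    ]
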