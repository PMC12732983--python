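"""Synthetic plum Vis/NIR spectra with a known, recoverable PPO signal.

The generator emulates the statistical structure the downstream analysis
assumes: two cultivars of 80 fruit each, a 350-1100 nm absorbance grid,
pigment bands in the visible region, the ~970 nm water band, smooth
per-sample baseline variability, multiplicative/additive scatter, i.i.d.
detector noise, and -- crucially -- a PPO-correlated signal planted at a
small set of visible wavelengths.  The planted wavelengths and the
per-sample nuisance parameters are returned as a :class:`PhantomTruth`
record so recovery can be scored exactly.

The response planted at the informative wavelengths is either ``linear``
(absorbance rises affinely with activity) or ``threshold`` (a low/high
plateau joined by a narrow smooth transition at the configured mean
activity -- the step-like structure a regression tree exploits and a
linear latent-variable model cannot).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import integrate, stats

from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "CultivarPPO",
    "Band",
    "ScatterSpec",
    "GeneratorConfig",
    "PhantomTruth",
    "sample_ppo_activities",
    "synthesize_spectrum",
    "generate_dataset",
    "truncated_normal_mean",
]

# Descriptive statistics of PPO activity (absorbance/min/g) per cultivar,
# used as the defaults of the truncated-normal activity model.
KHONI_PPO = dict(mean=0.003165, sd=0.001614, minimum=0.00012, maximum=0.005849)
KHORMAEI_PPO = dict(mean=0.003256, sd=0.002062, minimum=0.000145, maximum=0.006374)

# Ten informative wavelengths inside the 510-670 nm browning-pigment window.
DEFAULT_PLANTED_NM = (519.0, 535.0, 549.0, 560.0, 586.0, 604.0, 625.0, 633.0, 648.0, 667.0)


@dataclass
class CultivarPPO:
    """Truncated-normal activity model and spectral identity of one cultivar.

    ``pigment_scale`` multiplies the visible-region (< 700 nm) band
    amplitudes, giving each cultivar a distinct background pigmentation.
    ``threshold_sign`` orients the cultivar's threshold response: +1 means
    absorbance at the informative wavelengths steps low -> high with
    activity (browning pigments accumulate on a dark background), -1 means
    high -> low (native anthocyanin absorbance is bleached by oxidation).
    ``threshold_offset`` (fraction of the response amplitude) shifts a
    bleaching cultivar's plateaus upward: its native pigment absorbs at the
    informative wavelengths before any oxidation occurs.  The offset only
    exists in threshold mode, where it is what makes the cultivars
    separable from the planted columns themselves.
    """

    name: str
    n_samples: int = 80
    mean: float = KHONI_PPO["mean"]
    sd: float = KHONI_PPO["sd"]
    minimum: float = KHONI_PPO["minimum"]
    maximum: float = KHONI_PPO["maximum"]
    pigment_scale: float = 1.0
    threshold_sign: float = 1.0
    threshold_offset: float = 0.0

    def validate(self) -> None:
        if self.maximum <= self.minimum:
            raise ValueError(f"{self.name}: max must exceed min")
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.n_samples < 1:
            raise ValueError(f"{self.name}: n_samples must be >= 1")


@dataclass
class Band:
    """One Gaussian absorption band: amp * exp(-(x-center)^2 / (2 width^2))."""

    center_nm: float
    width_nm: float
    amplitude: float


@dataclass
class ScatterSpec:
    """Per-sample nuisance model: x -> b*x + a plus a smooth random baseline.

    ``slope_sd`` spreads the multiplicative factor b ~ N(1, slope_sd),
    ``offset_sd`` the additive offset a ~ N(0, offset_sd), and
    ``baseline_sd`` the coefficients of a per-sample quadratic baseline
    perturbation.  Defaults are small: averaging four probe positions per
    fruit suppresses most position-specific scatter before modeling.
    """

    slope_sd: float = 0.002
    offset_sd: float = 0.001
    baseline_sd: float = 0.001


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic acquisition campaign."""

    seed: int
    cultivars: list[CultivarPPO] = field(
        default_factory=lambda: [
            CultivarPPO(name="Khormaei", **KHORMAEI_PPO, threshold_sign=1.0, threshold_offset=0.0),
            CultivarPPO(name="Khoni", **KHONI_PPO, threshold_sign=-1.0, threshold_offset=1.0),
        ]
    )
    grid_low_nm: float = 350.0
    grid_high_nm: float = 1100.0
    grid_step_nm: float = 1.0
    bands: list[Band] = field(
        default_factory=lambda: [
            Band(560.0, 50.0, 0.50),   # anthocyanin/green-yellow pigment
            Band(670.0, 30.0, 0.45),   # chlorophyll red edge
            Band(970.0, 35.0, 0.60),   # water, O-H second overtone
            Band(1030.0, 25.0, 0.25),  # sugars/organics, C-H
        ]
    )
    # Mean baseline polynomial in u = (lambda-low)/(high-low).
    baseline_coefs: tuple[float, float, float] = (0.45, -0.25, 0.10)
    planted_wavelengths_nm: tuple[float, ...] = DEFAULT_PLANTED_NM
    # spectral width of each planted feature (Gaussian sd in nm; 0 = a
    # single-pixel spike).  Real absorption features have finite width,
    # which is what lets the smoothing filters raise the effective SNR.
    planted_band_sd_nm: float = 2.5
    response_form: str = "linear"  # "linear" | "threshold"
    response_amplitude: float = 0.10
    # Width of the smooth low->high transition of the threshold response,
    # in units of the pooled configured activity SD.
    threshold_width_sd: float = 0.5
    scatter: ScatterSpec = field(default_factory=ScatterSpec)
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    # -- derived quantities ------------------------------------------------

    @property
    def wavelengths_nm(self) -> np.ndarray:
        n = int(round((self.grid_high_nm - self.grid_low_nm) / self.grid_step_nm)) + 1
        return self.grid_low_nm + self.grid_step_nm * np.arange(n)

    @property
    def ppo_lo(self) -> float:
        return min(c.minimum for c in self.cultivars)

    @property
    def ppo_hi(self) -> float:
        return max(c.maximum for c in self.cultivars)

    @property
    def pooled_mean(self) -> float:
        w = np.array([c.n_samples for c in self.cultivars], dtype=float)
        m = np.array([c.mean for c in self.cultivars])
        return float(np.sum(w * m) / np.sum(w))

    @property
    def pooled_sd(self) -> float:
        w = np.array([c.n_samples for c in self.cultivars], dtype=float)
        s = np.array([c.sd for c in self.cultivars])
        return float(np.sqrt(np.sum(w * s**2) / np.sum(w)))

    def validate(self) -> None:
        for c in self.cultivars:
            c.validate()
        if self.response_form not in ("linear", "threshold"):
            raise ValueError(f"unknown response form {self.response_form!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        grid = self.wavelengths_nm
        for w in self.planted_wavelengths_nm:
            if not np.any(np.isclose(grid, w, atol=1e-9)):
                raise ValueError(f"planted wavelength {w} nm is not on the grid")

    def planted_indices(self) -> np.ndarray:
        grid = self.wavelengths_nm
        return np.array(
            [int(np.argmin(np.abs(grid - w))) for w in self.planted_wavelengths_nm]
        )


@dataclass
class PhantomTruth:
    """Ground truth of one generated dataset.

    Together with the config and the drawn activities this fully determines
    every spectrum (noise realizations excepted; their SD is recorded).
    """

    config: GeneratorConfig
    planted_wavelengths_nm: np.ndarray
    response_form: str
    response_amplitude: float
    breakpoint: float
    slopes_b: np.ndarray          # per-sample multiplicative factor b_i
    offsets_a: np.ndarray         # per-sample additive offset a_i
    baseline_coefs: np.ndarray    # per-sample (3,) baseline perturbation
    noise_sd: float

    def _cultivar(self, name: str | None) -> "CultivarPPO":
        if name is None:
            return self.config.cultivars[0]
        for c in self.config.cultivars:
            if c.name == name:
                return c
        raise KeyError(f"unknown cultivar {name!r}")

    def response(self, ppo: np.ndarray | float, cultivar: str | None = None) -> np.ndarray:
        return _response(
            np.asarray(ppo, dtype=float), self.config, self._cultivar(cultivar)
        )

    def clean_spectrum(self, ppo: float, cultivar: str | None = None) -> np.ndarray:
        """Noise- and scatter-free spectrum for a given activity."""
        return _clean_spectrum(float(ppo), self.config, self._cultivar(cultivar))

    def to_jsonable(self) -> dict:
        d = {
            "planted_wavelengths_nm": self.planted_wavelengths_nm.tolist(),
            "response_form": self.response_form,
            "response_amplitude": self.response_amplitude,
            "breakpoint": self.breakpoint,
            "slopes_b": self.slopes_b.tolist(),
            "offsets_a": self.offsets_a.tolist(),
            "baseline_coefs": self.baseline_coefs.tolist(),
            "noise_sd": self.noise_sd,
            "config": asdict(self.config),
        }
        return d


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent streams so toggling one component (e.g. noise)
    never shifts the draws of another."""
    root = np.random.SeedSequence(seed)
    names = ("ppo", "scatter", "noise")
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _truncated_normal_rejection(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Draw from N(mean, sd) truncated to [lo, hi] by rejection.

    Exact and simple; with the default cultivar parameters the acceptance
    rate is ~0.9, so the expected cost is barely above one draw per sample.
    """
    out = np.empty(n)
    filled = 0
    while filled < n:
        block = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = block[(block >= lo) & (block <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of the truncated normal by numerical integration (oracle use)."""
    pdf = lambda x: stats.norm.pdf(x, mean, sd)
    mass, _ = integrate.quad(pdf, lo, hi)
    num, _ = integrate.quad(lambda x: x * pdf(x), lo, hi)
    return num / mass


def sample_ppo_activities(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> ReferenceTable:
    """Draw per-sample PPO activities from each cultivar's truncated normal."""
    cfg.validate()
    if rng is None:
        rng = _substreams(cfg.seed)["ppo"]
    ids, values, = [], []
    for c in cfg.cultivars:
        vals = _truncated_normal_rejection(rng, c.mean, c.sd, c.minimum, c.maximum, c.n_samples)
        values.append(vals)
        ids.extend(f"{c.name}_{i:03d}" for i in range(c.n_samples))
    return ReferenceTable(ids, np.concatenate(values))


def _response(
    ppo: np.ndarray, cfg: GeneratorConfig, cultivar: "CultivarPPO | None" = None
) -> np.ndarray:
    """Planted absorbance increment g(ppo) at the informative wavelengths."""
    if cultivar is None:
        cultivar = cfg.cultivars[0]
    amp = cfg.response_amplitude
    if cfg.response_form == "linear":
        return amp * (ppo - cfg.ppo_lo) / (cfg.ppo_hi - cfg.ppo_lo)
    # threshold: plateaus at (offset) and (offset + amp) joined by a smooth
    # step of width threshold_width_sd * pooled sd at the pooled configured
    # mean; the cultivar's sign mirrors the step (low->high vs high->low)
    # and its offset shifts the plateau pair.
    width = cfg.threshold_width_sd * cfg.pooled_sd
    z = cultivar.threshold_sign * (ppo - cfg.pooled_mean) / width
    return cultivar.threshold_offset * amp + amp / (1.0 + np.exp(-z))


def _planted_profile(cfg: GeneratorConfig) -> np.ndarray:
    """Unit-peak spectral profile of the planted features over the grid."""
    grid = cfg.wavelengths_nm
    if cfg.planted_band_sd_nm <= 0:
        profile = np.zeros(grid.size)
        profile[cfg.planted_indices()] = 1.0
        return profile
    profile = np.zeros(grid.size)
    for w in cfg.planted_wavelengths_nm:
        profile += np.exp(-((grid - w) ** 2) / (2.0 * cfg.planted_band_sd_nm**2))
    return profile


def _clean_spectrum(
    ppo: float, cfg: GeneratorConfig, cultivar: CultivarPPO | None = None
) -> np.ndarray:
    if cultivar is None:
        cultivar = cfg.cultivars[0]
    grid = cfg.wavelengths_nm
    u = (grid - cfg.grid_low_nm) / (cfg.grid_high_nm - cfg.grid_low_nm)
    c0, c1, c2 = cfg.baseline_coefs
    spectrum = c0 + c1 * u + c2 * u**2
    for band in cfg.bands:
        amp = band.amplitude * (cultivar.pigment_scale if band.center_nm < 700 else 1.0)
        spectrum = spectrum + amp * np.exp(
            -((grid - band.center_nm) ** 2) / (2.0 * band.width_nm**2)
        )
    g = float(_response(np.asarray(ppo), cfg, cultivar))
    return spectrum + g * _planted_profile(cfg)


def synthesize_spectrum(
    ppo_value: float,
    cfg: GeneratorConfig,
    rng: dict[str, np.random.Generator] | np.random.Generator,
    cultivar: CultivarPPO | None = None,
) -> tuple[np.ndarray, dict]:
    """Generate one absorbance spectrum and its nuisance-parameter record.

    ``rng`` is either the dict of named substreams produced internally by
    :func:`generate_dataset` or a single generator (then used for both the
    scatter and noise draws).
    """
    cfg.validate()
    if not cfg.ppo_lo <= ppo_value <= cfg.ppo_hi:
        raise ValueError("ppo_value outside the configured activity bounds")
    if isinstance(rng, np.random.Generator):
        rng = {"scatter": rng, "noise": rng}
    grid = cfg.wavelengths_nm
    u = (grid - cfg.grid_low_nm) / (cfg.grid_high_nm - cfg.grid_low_nm)
    clean = _clean_spectrum(ppo_value, cfg, cultivar)

    sc = cfg.scatter
    r = rng["scatter"]
    # draw in a fixed order regardless of which SDs are zero, from one stream
    draws = r.normal(0.0, 1.0, size=5)
    b = 1.0 + sc.slope_sd * draws[0]
    a = sc.offset_sd * draws[1]
    base_coefs = sc.baseline_sd * draws[2:5]
    baseline_dev = base_coefs[0] + base_coefs[1] * u + base_coefs[2] * u**2

    spectrum = b * clean + a + baseline_dev
    if cfg.noise_sd > 0:
        spectrum = spectrum + rng["noise"].normal(0.0, cfg.noise_sd, size=grid.size)
    record = {"b": b, "a": a, "baseline_coefs": base_coefs}
    return spectrum, record


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[SpectraSet, ReferenceTable, PhantomTruth]:
    """Generate the full campaign: spectra, reference activities, truth."""
    cfg.validate()
    streams = _substreams(cfg.seed)
    reference = sample_ppo_activities(cfg, streams["ppo"])
    cultivar_of = []
    for c in cfg.cultivars:
        cultivar_of.extend([c] * c.n_samples)
    rows, bs, as_, coefs = [], [], [], []
    for ppo, cult in zip(reference.ppo_activity, cultivar_of):
        spectrum, rec = synthesize_spectrum(float(ppo), cfg, streams, cult)
        rows.append(spectrum)
        bs.append(rec["b"])
        as_.append(rec["a"])
        coefs.append(rec["baseline_coefs"])
    cultivar = [c.name for c in cultivar_of]
    spectra = SpectraSet(cfg.wavelengths_nm, np.vstack(rows), list(reference.sample_ids), cultivar)
    truth = PhantomTruth(
        config=cfg,
        planted_wavelengths_nm=np.asarray(cfg.planted_wavelengths_nm, dtype=float),
        response_form=cfg.response_form,
        response_amplitude=cfg.response_amplitude,
        breakpoint=cfg.pooled_mean,
        slopes_b=np.asarray(bs),
        offsets_a=np.asarray(as_),
        baseline_coefs=np.asarray(coefs),
        noise_sd=cfg.noise_sd,
    )
    return spectra, reference, truth
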