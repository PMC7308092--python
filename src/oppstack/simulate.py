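"""Synthetic multimodal data with known ground truth.

Emulates the statistical structure of a multimodal aging cohort: several
high-dimensional feature blocks whose signal is a partly shared, partly
block-specific function of age; a standard-normal latent "health" factor
linking brain features to behavioral scores; block-wise missingness that is
either completely at random (MCAR) or age-dependent (age_MAR); behavioral
scores with polynomial age trends; and multichannel oscillatory signals
with controllable 1/f exponent, alpha peak, band powers and envelope
coupling. No attempt is made to simulate sensor physics, head geometry or
hemodynamics — only the statistical features the downstream estimators
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from ._utils import child_rng, zscore
from .datasets import Block, MultimodalDataset

NONLINEARITIES = ("linear", "quadratic", "saturating")
MISSINGNESS_MECHANISMS = ("none", "MCAR", "age_MAR")

# fixed stream offsets so each component draws from an independent stream
_STREAM_AGE = 0
_STREAM_HEALTH = 1
_STREAM_BLOCK = 10
_STREAM_MISSING = 1000
_STREAM_SCORE = 2000
_STREAM_SIGNAL = 3000


@dataclass
class BlockSpec:
    name: str
    n_features: int
    shared_signal_weight: float = 1.0
    private_signal_weight: float = 0.0
    noise_sd: float = 1.0
    nonlinearity: str = "linear"

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError(f"block {self.name!r}: n_features must be >= 1")
        if self.nonlinearity not in NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


@dataclass
class MissingnessSpec:
    mechanism: str = "none"
    rate: float = 0.0
    mar_slope: float = 0.0  # per-year logit slope for age_MAR

    def __post_init__(self) -> None:
        if self.mechanism not in MISSINGNESS_MECHANISMS:
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("missingness rate must be in [0, 1]")


@dataclass
class ScoreSpec:
    name: str
    age_poly_coefs: tuple = ()  # coefficients on z(age)^1, z(age)^2, ...
    health_loading: float = 0.0
    noise_sd: float = 1.0


@dataclass
class SimulationConfig:
    """Stated world for the multimodal generator.

    Defaults follow the cohort the framework targets: ages uniform on
    [18, 88] years and a few hundred subjects.
    """

    n_subjects: int = 600
    age_range: tuple = (18.0, 88.0)
    block_specs: list = field(default_factory=list)
    missingness: dict = field(default_factory=dict)  # block name -> MissingnessSpec
    score_specs: list = field(default_factory=list)
    health_signal_weight: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range low must be < high")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        self.block_specs = [
            bs if isinstance(bs, BlockSpec) else BlockSpec(*bs)
            for bs in self.block_specs
        ]
        self.missingness = {
            k: (v if isinstance(v, MissingnessSpec) else MissingnessSpec(*v))
            for k, v in self.missingness.items()
        }
        self.score_specs = [
            ss if isinstance(ss, ScoreSpec) else ScoreSpec(*ss)
            for ss in self.score_specs
        ]

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "age_range": list(self.age_range),
            "block_specs": [
                [b.name, b.n_features, b.shared_signal_weight,
                 b.private_signal_weight, b.noise_sd, b.nonlinearity]
                for b in self.block_specs
            ],
            "missingness": {
                k: [m.mechanism, m.rate, m.mar_slope]
                for k, m in self.missingness.items()
            },
            "score_specs": [
                [s.name, list(s.age_poly_coefs), s.health_loading, s.noise_sd]
                for s in self.score_specs
            ],
            "health_signal_weight": self.health_signal_weight,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        d["block_specs"] = [BlockSpec(b[0], b[1], *b[2:]) for b in d["block_specs"]]
        d["missingness"] = {k: MissingnessSpec(*v) for k, v in d["missingness"].items()}
        d["score_specs"] = [ScoreSpec(s[0], tuple(s[1]), s[2], s[3])
                            for s in d["score_specs"]]
        return cls(**d)


def _apply_nonlinearity(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        out = z
    elif kind == "quadratic":
        out = z + 0.5 * (z ** 2 - 1.0)
    elif kind == "saturating":
        out = np.tanh(z)
    else:  # pragma: no cover - validated upstream
        raise ValueError(kind)
    return zscore(out)


def _mar_mask(age: np.ndarray, rate: float, slope: float,
              rng: np.random.Generator) -> np.ndarray:
    """Age-dependent missingness with marginal rate calibrated to `rate`.

    Missing probability is logistic(intercept + slope*(age - mean age)); the
    intercept solves for the requested marginal rate.
    """
    centered = age - age.mean()
    if rate <= 0:
        return np.ones(len(age), dtype=bool)
    if rate >= 1:
        return np.zeros(len(age), dtype=bool)

    def marginal(b0):
        return expit(b0 + slope * centered).mean() - rate

    b0 = brentq(marginal, -700.0, 700.0, xtol=1e-12)
    p_miss = expit(b0 + slope * centered)
    return rng.random(len(age)) >= p_miss


def generate_multimodal(config: SimulationConfig) -> MultimodalDataset:
    """Draw a multimodal dataset from the configured generative model.

    Per subject: age ~ Uniform(age_range); latent health ~ N(0, 1).
    Per block j with nonlinearity f: the shared factor is f(z(age)), the
    private factor is (f(z(age)) + eta_j)/sqrt(2) with eta_j ~ N(0,1) iid per
    block — a block-specific noisy view of age, so blocks with zero shared
    weight still carry complementary age information.  Each factor loads on
    the features through a random unit vector, and iid Gaussian noise with
    the block's noise_sd is added.  Availability masks follow the block's
    missingness mechanism.  Deterministic given the config seed.
    """
    if not config.block_specs:
        raise ValueError("config declares no blocks")
    n = config.n_subjects
    lo, hi = config.age_range
    age = child_rng(config.seed, _STREAM_AGE).uniform(lo, hi, size=n)
    health = child_rng(config.seed, _STREAM_HEALTH).standard_normal(n)
    age_z = zscore(age)

    blocks: dict[str, Block] = {}
    truth_loadings: dict[str, dict] = {}
    for j, bs in enumerate(config.block_specs):
        rng = child_rng(config.seed, _STREAM_BLOCK + j)
        shared = _apply_nonlinearity(age_z, bs.nonlinearity)
        eta = rng.standard_normal(n)
        private = (_apply_nonlinearity(age_z, bs.nonlinearity) + eta) / np.sqrt(2.0)

        def unit(v):
            return v / np.linalg.norm(v)

        u = unit(rng.standard_normal(bs.n_features))
        w = unit(rng.standard_normal(bs.n_features))
        v = unit(rng.standard_normal(bs.n_features))
        X = (bs.shared_signal_weight * np.outer(shared, u)
             + config.health_signal_weight * np.outer(health, w)
             + bs.private_signal_weight * np.outer(private, v)
             + bs.noise_sd * rng.standard_normal((n, bs.n_features)))

        mspec = config.missingness.get(bs.name, MissingnessSpec())
        mrng = child_rng(config.seed, _STREAM_MISSING + j)
        if mspec.mechanism == "none":
            mask = np.ones(n, dtype=bool)
        elif mspec.mechanism == "MCAR":
            mask = mrng.random(n) >= mspec.rate
        else:  # age_MAR
            mask = _mar_mask(age, mspec.rate, mspec.mar_slope, mrng)
        if not mask.any():
            raise ValueError(
                f"block {bs.name!r}: missingness left zero observed subjects")
        blocks[bs.name] = Block(bs.name, X, mask)
        truth_loadings[bs.name] = {"shared": u, "health": w, "private": v}

    ids = np.array([f"sub-{i:04d}" for i in range(n)])
    ds = MultimodalDataset(ids, age, blocks, health=health,
                           meta={"config": config.to_dict(),
                                 "truth_loadings": truth_loadings})
    return ds


def generate_scores(dataset: MultimodalDataset,
                    score_specs: list | None = None,
                    seed: int | None = None):
    """Behavioral scores: polynomial age trend + latent-health component.

    score = sum_k coef_k * z(age)^k + health_loading * health + noise.
    Returns a (scores DataFrame, ground-truth dict) pair so recovery tests
    can check planted loadings.
    """
    import pandas as pd

    if dataset.health is None:
        raise ValueError("dataset has no stored latent health; "
                         "generate it with generate_multimodal")
    cfg = dataset.meta.get("config", {})
    if score_specs is None:
        score_specs = [s if isinstance(s, ScoreSpec)
                       else ScoreSpec(s[0], tuple(s[1]), s[2], s[3])
                       for s in cfg.get("score_specs", [])]
    if seed is None:
        seed = cfg.get("seed", 0)
    age_z = zscore(dataset.age)
    out = {"subject_id": dataset.subject_ids}
    truth = {}
    for k, ss in enumerate(score_specs):
        if not isinstance(ss, ScoreSpec):
            ss = ScoreSpec(ss[0], tuple(ss[1]), ss[2], ss[3])
        rng = child_rng(seed, _STREAM_SCORE + k)
        trend = np.zeros(dataset.n_subjects)
        for power, coef in enumerate(ss.age_poly_coefs, start=1):
            trend += coef * age_z ** power
        score = (trend + ss.health_loading * dataset.health
                 + ss.noise_sd * rng.standard_normal(dataset.n_subjects))
        out[ss.name] = score
        truth[ss.name] = {"age_poly_coefs": tuple(ss.age_poly_coefs),
                          "health_loading": ss.health_loading,
                          "noise_sd": ss.noise_sd}
    return pd.DataFrame(out), truth


@dataclass
class OscillatorySignalSpec:
    """Controls for the multichannel oscillatory-signal generator."""

    n_channels: int = 4
    fs: float = 200.0
    duration: float = 300.0
    one_over_f_exponent: float = 1.0
    alpha_peak_hz: float | None = 10.0
    alpha_power: float = 1.0
    alpha_bandwidth_hz: float = 1.0
    band_powers: dict = field(default_factory=dict)  # (lo, hi) Hz -> variance
    envelope_coupling: float | None = None  # corr of channels 0 and 1 envelopes
    noise_power: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_peak_hz is not None and not 0 < self.alpha_peak_hz < self.fs / 2:
            raise ValueError("alpha_peak_hz must lie in (0, fs/2)")
        for (lo, hi) in self.band_powers:
            if hi >= self.fs / 2:
                raise ValueError("fs must exceed twice the highest band edge")
        if self.envelope_coupling is not None and not -1 <= self.envelope_coupling <= 1:
            raise ValueError("envelope_coupling must be in [-1, 1]")


@dataclass
class MultichannelSignal:
    data: np.ndarray  # channels x samples
    fs: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _colored_noise(n_samples: int, fs: float, exponent: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Noise with power spectrum proportional to f^(-exponent).

    Spectral shaping of white noise in the frequency domain gives the exact
    target exponent in expectation.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.ones_like(freqs)
    nonzero = freqs > 0
    gain[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandlimited_noise(n_samples: int, fs: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_envelope(n_samples: int, fs: float, rng: np.random.Generator,
                   cutoff: float = 0.5) -> np.ndarray:
    """Slowly varying standard-normal process (low-pass filtered noise)."""
    z = _bandlimited_noise(n_samples, fs, 0.0, cutoff, rng)
    return zscore(z)


def generate_oscillatory(spec: OscillatorySignalSpec) -> MultichannelSignal:
    """Multichannel signal: 1/f-colored noise + alpha bump + band components.

    When ``envelope_coupling`` is set, channels 0 and 1 carry
    amplitude-modulated alpha components whose slow envelopes are correlated
    at the requested level (envelopes are affine in correlated Gaussian
    processes, so the target correlation is preserved).
    """
    n_samples = int(round(spec.duration * spec.fs))
    data = np.zeros((spec.n_channels, n_samples))
    coupling_env = None
    if spec.envelope_coupling is not None:
        rng_env = child_rng(spec.seed, _STREAM_SIGNAL, 9999)
        e_base = _slow_envelope(n_samples, spec.fs, rng_env)
        e_other = _slow_envelope(n_samples, spec.fs, rng_env)
        rho = spec.envelope_coupling
        e2 = rho * e_base + np.sqrt(max(0.0, 1 - rho ** 2)) * e_other
        # affine map to a positive modulator preserves the correlation;
        # modulation depth 0.5 keeps envelope variance well above the
        # noise floor so the coupling survives envelope estimation
        coupling_env = [np.clip(1.0 + 0.5 * e, 0.05, None)
                        for e in (e_base, e2)]
    for ch in range(spec.n_channels):
        rng = child_rng(spec.seed, _STREAM_SIGNAL, ch)
        x = np.sqrt(spec.noise_power) * _colored_noise(
            n_samples, spec.fs, spec.one_over_f_exponent, rng)
        if spec.alpha_peak_hz is not None and spec.alpha_power > 0:
            half = spec.alpha_bandwidth_hz / 2.0
            if coupling_env is not None and ch < 2:
                t = np.arange(n_samples) / spec.fs
                phase = rng.uniform(0, 2 * np.pi)
                carrier = np.cos(2 * np.pi * spec.alpha_peak_hz * t + phase)
                alpha = coupling_env[ch] * carrier
                alpha = alpha / alpha.std()
            else:
                alpha = _bandlimited_noise(
                    n_samples, spec.fs,
                    spec.alpha_peak_hz - half, spec.alpha_peak_hz + half, rng)
            x = x + np.sqrt(spec.alpha_power) * alpha
        for (lo, hi), var in spec.band_powers.items():
            x = x + np.sqrt(var) * _bandlimited_noise(n_samples, spec.fs, lo, hi, rng)
        data[ch] = x
    return MultichannelSignal(data, spec.fs)
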