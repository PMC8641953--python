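"""Synthetic data with known ground truth for every pipeline stage.

The generators invert the forward models used for fitting: a ground-truth
pRF population is sampled, its predicted responses to the bar-sweep stimulus
are computed, and noise is added.  This yields BOLD runs (pRF drive
convolved with an HRF plus Gaussian noise), electrode position responses,
raw LFP-like oscillatory signals whose band power is modulated by the pRF
drive, and MUA traces for moving-bar cRF mapping.

Populations emulate chronic array implants in macaque V1 and V4: centers in
the lower-right visual quadrant (eccentricity <= 8 dva for V1, <= 14 dva for
V4), sizes increasing linearly with eccentricity (default slope 0.1 dva/dva
for V1 and 0.3 for V4 with lognormal jitter), and CSS exponents around 0.35
(truncated to (0, 1]).  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ephys import LFP_BANDS, BarSweepRecording, RawSignal
from .fitting import PRFDesign, ResponseDataset
from .hemodynamics import HRFKernel
from .models import PRFParams
from .stimulus import EffectiveStimulus

__all__ = [
    "GroundTruthPopulation",
    "sample_population",
    "synth_bold",
    "synth_ephys",
    "synth_raw_lfp",
    "synth_moving_bar_mua",
]

#: maximum eccentricity of the emulated implants, dva
AREA_MAX_ECC = {"V1": 8.0, "V4": 14.0}
#: default eccentricity-size slopes (dva size per dva eccentricity)
AREA_SLOPE = {"V1": 0.1, "V4": 0.3}


@dataclass
class GroundTruthPopulation:
    """Sampled ground-truth pRF population.

    ``table`` has one row per unit with the generating parameters; ``params``
    materializes row ``i`` as a :class:`PRFParams` for a given model.
    """

    table: pd.DataFrame
    area: str
    seed: int

    @property
    def n_units(self) -> int:
        return len(self.table)

    def params(self, i: int, model: str = "CSS") -> PRFParams:
        row = self.table.iloc[i]
        exponent = float(row.exponent) if model == "CSS" else 1.0
        gain = float(row.gain)
        if model in ("P-LIN", "CSS") and gain <= 0:
            raise ValueError(f"unit {i} has negative gain; only U-LIN supports it")
        kw = {}
        if model == "DoG":
            # surround/center volume ratio a*(sigma2/sigma1)^2 = 1.0
            kw = dict(sigma2=2.0 * float(row.sigma), amp_surround=0.25)
        return PRFParams(model, float(row.x0), float(row.y0), float(row.sigma),
                         gain=gain, exponent=exponent, **kw)


def sample_population(
    area: str = "V1",
    n_units: int = 100,
    ecc_size_slope: float | None = None,
    ecc_size_intercept: float = 0.5,
    exponent_mean: float = 0.35,
    exponent_sd: float = 0.1,
    seed: int = 0,
    max_ecc: float | None = None,
    negative_fraction: float = 0.0,
    size_jitter_sd: float = 0.15,
    gain_mean: float = 1.0,
) -> GroundTruthPopulation:
    """Sample a ground-truth pRF population for one cortical area.

    Centers are uniform over the lower-right quadrant disc sector of radius
    ``max_ecc``; sigma = intercept + slope * ecc times lognormal jitter
    (sd of log = ``size_jitter_sd``); CSS exponents are truncated-normal in
    (0, 1]; gains are lognormal around ``gain_mean`` with a configurable
    fraction flipped negative (for U-LIN / negative-pRF tests).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if area not in AREA_MAX_ECC:
        raise ValueError(f"unknown area {area!r}; expected V1 or V4")
    slope = AREA_SLOPE[area] if ecc_size_slope is None else ecc_size_slope
    max_ecc = AREA_MAX_ECC[area] if max_ecc is None else max_ecc
    rng = np.random.default_rng(seed)

    # uniform over the quadrant disc: r ~ sqrt(U) * max_ecc
    ecc = np.sqrt(rng.uniform(0.0, 1.0, n_units)) * max_ecc
    ang = rng.uniform(-np.pi / 2.0, 0.0, n_units)  # lower-right quadrant
    x0 = ecc * np.cos(ang)
    y0 = ecc * np.sin(ang)

    sigma = (ecc_size_intercept + slope * ecc) * rng.lognormal(0.0, size_jitter_sd, n_units)
    if np.any(sigma <= 0):
        raise ValueError("sampled non-positive sizes; check slope/intercept")

    expn = rng.normal(exponent_mean, exponent_sd, n_units)
    for _ in range(100):
        bad = (expn <= 0.05) | (expn > 1.0)
        if not bad.any():
            break
        expn[bad] = rng.normal(exponent_mean, exponent_sd, bad.sum())
    expn = np.clip(expn, 0.05, 1.0)

    gain = gain_mean * rng.lognormal(0.0, 0.2, n_units)
    neg = rng.uniform(size=n_units) < negative_fraction
    gain[neg] *= -1.0

    table = pd.DataFrame(
        {"unit": np.arange(n_units), "x0": x0, "y0": y0, "ecc": ecc,
         "sigma": sigma, "exponent": expn, "gain": gain, "area": area}
    )
    return GroundTruthPopulation(table=table, area=area, seed=seed)


def _noise_free_matrix(
    pop: GroundTruthPopulation, design: PRFDesign, model: str
) -> np.ndarray:
    return np.stack([design.predict(pop.params(i, model)) for i in range(pop.n_units)])


def synth_bold(
    pop: GroundTruthPopulation,
    stim: EffectiveStimulus,
    hrf: HRFKernel,
    noise_sd: float = 0.3,
    n_runs: int = 4,
    tr: float = 2.5,
    model: str = "CSS",
    seed: int = 0,
) -> ResponseDataset:
    """Per-voxel BOLD runs: pRF prediction convolved to TR plus white noise.

    Runs are tagged odd/even by index and averaged within each half, so the
    halves' noise SD is noise_sd / sqrt(n_runs/2).  Units are percent signal
    change.
    """
    if n_runs < 2 or n_runs % 2:
        raise ValueError("n_runs must be an even number >= 2")
    rng = np.random.default_rng(seed)
    design = PRFDesign(stim, hrf=hrf, tr=tr)
    clean = _noise_free_matrix(pop, design, model)  # (n_units, n_TR)
    halves = {0: [], 1: []}
    for r in range(n_runs):
        halves[r % 2].append(clean + rng.normal(0.0, noise_sd, clean.shape))
    data_even = np.mean(halves[0], axis=0)  # runs 0,2,... = even
    data_odd = np.mean(halves[1], axis=0)
    return ResponseDataset(
        data_odd=data_odd, data_even=data_even, modality="bold",
        stim=stim, hrf=hrf, tr=tr, ground_truth=pop.table,
    )


def synth_ephys(
    pop: GroundTruthPopulation,
    stim: EffectiveStimulus,
    noise_sd: float = 0.2,
    n_repeats: int = 8,
    model: str = "CSS",
    modality: str = "mua",
    seed: int = 0,
) -> ResponseDataset:
    """Per-electrode responses per bar position plus white noise, split into
    odd/even repeat halves."""
    if n_repeats < 2 or n_repeats % 2:
        raise ValueError("n_repeats must be an even number >= 2")
    rng = np.random.default_rng(seed)
    design = PRFDesign(stim)  # no HRF: one response per bar position
    clean = _noise_free_matrix(pop, design, model)
    halves = {0: [], 1: []}
    for r in range(n_repeats):
        halves[r % 2].append(clean + rng.normal(0.0, noise_sd, clean.shape))
    return ResponseDataset(
        data_odd=np.mean(halves[1], axis=0), data_even=np.mean(halves[0], axis=0),
        modality=modality, stim=stim, ground_truth=pop.table,
    )


def synth_raw_lfp(
    unit_params: PRFParams,
    stim: EffectiveStimulus,
    band: str = "gamma_low",
    depth: float = 0.5,
    n_repeats: int = 4,
    fs: float = 500.0,
    pre_s: float = 1.5,
    seed: int = 0,
) -> RawSignal:
    """Raw LFP-like record whose band power tracks the unit's pRF drive.

    A band-limited Gaussian-noise carrier (4th-order Butterworth band-pass in
    the requested band) is amplitude-modulated per bar position: during the
    epoch of position p the carrier is scaled by sqrt(1 + depth * drive_p),
    where drive is the unit's pRF drive normalized to unit maximum.  Negative
    ``depth`` yields stimulus-driven power decreases (negative pRFs).  Each
    repeat is one sweep sequence preceded by ``pre_s`` of unmodulated
    baseline; event times mark position onsets.
    """
    from scipy import signal as sps

    if band not in LFP_BANDS:
        raise ValueError(f"unknown band {band!r}")
    drive = _position_drive(unit_params, stim)
    dmax = np.abs(drive).max()
    if dmax > 0:
        drive = drive / dmax
    scale = np.sqrt(np.clip(1.0 + depth * drive, 0.05, None))

    step = stim.protocol.step_duration
    n_pos = drive.size
    n_step = int(round(step * fs))
    n_pre = int(round(pre_s * fs))
    rep_len = n_pre + n_pos * n_step

    rng = np.random.default_rng(seed)
    sos = sps.butter(4, LFP_BANDS[band], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal(rep_len * n_repeats))
    carrier = carrier / carrier.std()

    amp = np.ones(rep_len * n_repeats)
    events = np.zeros((n_repeats, n_pos))
    for r in range(n_repeats):
        base = r * rep_len
        for p in range(n_pos):
            i0 = base + n_pre + p * n_step
            amp[i0 : i0 + n_step] = scale[p]
            events[r, p] = i0 / fs
    return RawSignal(carrier * amp, fs, events)


def _position_drive(params: PRFParams, stim: EffectiveStimulus) -> np.ndarray:
    design = PRFDesign(stim)
    return design.predict(params)


def synth_moving_bar_mua(
    unit_params: PRFParams,
    aperture_radius: float = 14.0,
    bar_width: float = 1.0,
    bar_speed: float = 14.0,
    dt: float = 0.01,
    latency: float = 0.0,
    noise_sd: float = 0.05,
    spont_rate: float = 0.1,
    n_repeats: int = 10,
    seed: int = 0,
) -> BarSweepRecording:
    """MUA-rate traces for moving-bar cRF mapping in four directions.

    The bar sweeps from -aperture_radius to +aperture_radius along each of
    the directions 0, 180, 90, 270 degrees; the rate is the Gaussian RF's
    response to the bar (the RF profile integrated across the bar width,
    evaluated at the bar's perpendicular distance from the RF center),
    shifted by ``latency`` seconds, on top of a spontaneous rate with
    additive Gaussian noise.  Inter-sweep blank epochs provide the
    spontaneous-activity samples.
    """
    rng = np.random.default_rng(seed)
    directions = (0.0, 180.0, 90.0, 270.0)
    duration = 2.0 * aperture_radius / bar_speed
    t = np.arange(0.0, duration, dt)
    offset0, speed = -aperture_radius, bar_speed

    sx, sy = unit_params.x0, unit_params.y0
    sigma = unit_params.sigma1
    # SD of the bar response along the sweep: RF sigma broadened by bar width
    eff_sd = np.hypot(sigma, bar_width / np.sqrt(12.0))

    traces = np.zeros((len(directions), n_repeats, t.size))
    for di, d in enumerate(directions):
        ux, uy = np.cos(np.deg2rad(d)), np.sin(np.deg2rad(d))
        rf_proj = sx * ux + sy * uy  # RF center along the motion axis
        pos = offset0 + speed * (t - latency)
        rate = unit_params.gain * np.exp(-((pos - rf_proj) ** 2) / (2.0 * eff_sd**2))
        for r in range(n_repeats):
            traces[di, r] = spont_rate + rate + rng.normal(0.0, noise_sd, t.size)
    spont = spont_rate + rng.normal(0.0, noise_sd, 4 * t.size)
    return BarSweepRecording(
        traces=traces, t=t, directions=directions,
        offset0=offset0, speed=speed, spont=spont,
    )
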