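"""Seeded synthetic lock-in traces with ground-truth event logs.

Stands in for the instrument: designed cell populations (live/dead, salinity
x time conditions, polystyrene-bead controls) are sampled from log-normal
phenotype distributions, each cell transits the sensing region once as a
negative Gaussian pulse whose per-channel depth follows the circuit model,
and the channels carry additive white Gaussian noise plus a slow sinusoidal
baseline drift.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, in a fixed order (phenotypes, event
times, noise), so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .circuit import (
    DEFAULT_GEOMETRY,
    DEFAULT_MAPPING,
    CellPhenotype,
    ChannelGeometry,
    FrequencyPanel,
    MappingParams,
    SystemCircuit,
    model_transparency,
    pulse_amplitude,
)
from .errors import ParameterError
from .trace import Trace

#: Ground-truth log column order (amp_f columns appended per panel frequency).
GROUND_TRUTH_COLUMNS = [
    "event_id",
    "time_s",
    "group",
    "is_outlier",
    "diameter_um",
    "g_mem",
    "sigma_cyto",
]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution given by its median and log-space sigma."""

    median: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.median > 0:
            raise ParameterError("log-normal median must be > 0")
        if self.sigma < 0:
            raise ParameterError("log-normal sigma must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class PopulationSpec:
    """Design of one simulated condition.

    Diameter defaults bracket the tight 4.5-4.8 um size range of the study
    organism; g_mem and sigma_cyto medians are the live-cell defaults of the
    circuit mapping.  ``outlier_fraction`` of cells receive multiplicative
    ``outlier_shift`` factors on (diameter, g_mem), emulating rare phenotypes
    that stay large while keeping a permeable membrane.
    """

    n_cells: int
    group: str = ""
    diameter_um: LogNormalSpec = LogNormalSpec(4.6, 0.04)
    g_mem: LogNormalSpec = LogNormalSpec(5.0, 0.25)
    sigma_cyto: LogNormalSpec = LogNormalSpec(0.6, 0.08)
    c_mem_spec: float = 0.01
    eps_cyto: float = 60.0
    outlier_fraction: float = 0.0
    outlier_shift: tuple[float, float] = (1.3, 10.0)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ParameterError("outlier_fraction must lie in [0, 1]")
        if any(s <= 0 for s in self.outlier_shift):
            raise ParameterError("outlier_shift factors must be > 0")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition and noise settings of the simulated lock-in output.

    ``duration=None`` derives the trace length from ``n_events/event_rate``
    plus padding.  ``noise_sigma`` and ``drift_amplitude`` are relative to the
    per-channel baseline.  Default sampling rate 57.6 kHz per demodulated
    channel; transit time 1 ms (Gaussian pulse sigma = transit_time/4).
    """

    sampling_rate: float = 57600.0
    duration: float | None = None
    event_rate: float = 10.0
    transit_time: float = 1e-3
    noise_sigma: float = 3.4e-4
    drift_amplitude: float = 2e-3
    drift_period: float = 7.3
    baseline_volts: float | tuple[float, ...] = 1.0
    min_separation_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.event_rate <= 0 or self.transit_time <= 0:
            raise ParameterError("sampling_rate, event_rate and transit_time must be > 0")
        if self.sampling_rate * self.transit_time < 10:
            raise ParameterError(
                "pulses are unresolvable: need sampling_rate * transit_time >= 10"
            )
        if self.noise_sigma < 0 or self.drift_amplitude < 0:
            raise ParameterError("noise_sigma and drift_amplitude must be >= 0")
        if self.duration is not None and self.duration <= 0:
            raise ParameterError("duration must be > 0 when given")

    def baselines(self, n_channels: int) -> np.ndarray:
        b = np.asarray(self.baseline_volts, dtype=float)
        if b.ndim == 0:
            return np.full(n_channels, float(b))
        if b.shape != (n_channels,):
            raise ParameterError("baseline_volts must be scalar or one per channel")
        return b


def sample_population(
    spec: PopulationSpec, seed: int | np.random.SeedSequence, return_outlier_mask: bool = False
):
    """Draw ``spec.n_cells`` phenotypes; bit-identical for a fixed seed.

    The first ``round(outlier_fraction * n_cells)`` positions after a seeded
    permutation carry the outlier shift, so the planted set is reproducible.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_cells
    diameters = spec.diameter_um.sample(rng, n)
    g_mems = spec.g_mem.sample(rng, n)
    sigmas = spec.sigma_cyto.sample(rng, n)
    n_out = int(round(spec.outlier_fraction * n))
    mask = np.zeros(n, dtype=bool)
    if n_out:
        mask[rng.permutation(n)[:n_out]] = True
        diameters = np.where(mask, diameters * spec.outlier_shift[0], diameters)
        g_mems = np.where(mask, g_mems * spec.outlier_shift[1], g_mems)
    phenotypes = [
        CellPhenotype(
            diameter_um=float(d),
            g_mem=float(g),
            c_mem_spec=spec.c_mem_spec,
            sigma_cyto=float(s),
            eps_cyto=spec.eps_cyto,
            group=spec.group,
        )
        for d, g, s in zip(diameters, g_mems, sigmas)
    ]
    if return_outlier_mask:
        return phenotypes, mask
    return phenotypes


def bead_population(
    n: int,
    diameter: LogNormalSpec = LogNormalSpec(5.0, 0.01),
    group: str = "bead",
    seed: int | np.random.SeedSequence = 0,
) -> list[CellPhenotype]:
    """Polystyrene-bead control particles.

    Conductances sit at insulating floors and the surface/bulk capacitances
    are tiny, so the predicted pulse amplitude is flat across the panel and
    transparency is ~1 regardless of the suspending medium.  The default
    5 um size standard is matched to the cells so bead pulses occupy the
    same amplitude range.
    """
    spec = PopulationSpec(
        n_cells=n,
        group=group,
        diameter_um=diameter,
        g_mem=LogNormalSpec(1e-6),
        sigma_cyto=LogNormalSpec(1e-6),
        c_mem_spec=1e-6,
        eps_cyto=2.6,
    )
    return sample_population(spec, seed)


def _draw_event_times(
    rng: np.random.Generator,
    n_events: int,
    duration: float,
    min_separation: float,
    edge_pad: float,
) -> np.ndarray:
    """Uniform event centres conditioned on a minimum separation.

    Exact construction: draw ``n`` points uniformly in the interval shrunk by
    the total separation budget, sort them, and shift the i-th point by
    ``i * min_separation``.  Never merges or silently drops colliding events;
    an interval too short for the requested count raises instead.
    """
    if n_events == 0:
        return np.empty(0)
    lo, hi = edge_pad, duration - edge_pad
    slack = (hi - lo) - (n_events - 1) * min_separation
    if hi <= lo or slack <= 0:
        raise ParameterError(
            f"cannot place {n_events} events {min_separation}s apart in {duration}s"
        )
    u = np.sort(rng.uniform(0.0, slack, n_events))
    return lo + u + np.arange(n_events) * min_separation


def synthesize_trace(
    phenotypes: list[CellPhenotype],
    acq: AcquisitionSpec,
    system: SystemCircuit | None = None,
    panel: FrequencyPanel | None = None,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    mapping: MappingParams = DEFAULT_MAPPING,
    seed: int | np.random.SeedSequence = 0,
    outlier_mask: np.ndarray | None = None,
) -> tuple[Trace, pd.DataFrame]:
    """Simulate the demodulated channels for one run of cells.

    Each phenotype transits once.  Per channel ``c`` the signal is::

        v_c(t) = B_c * (1 + drift(t)) - sum_k B_c * a_c(k) * G(t; t_k, sigma)

    with ``G`` a unit-peak Gaussian of ``sigma = transit_time/4``, ``a_c(k)``
    the circuit-model relative amplitude of cell ``k``, plus white Gaussian
    noise of sd ``noise_sigma * B_c``.  Returns the trace and a ground-truth
    log with one row per injected event (times strictly increasing).
    """
    system = system or SystemCircuit()
    panel = panel or FrequencyPanel()
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    times_seq, noise_seq = seed_seq.spawn(2)

    n_events = len(phenotypes)
    fs = acq.sampling_rate
    sigma_t = acq.transit_time / 4.0
    min_sep = acq.min_separation_factor * acq.transit_time
    edge_pad = 3.0 * acq.transit_time
    duration = acq.duration
    if duration is None:
        duration = max(n_events / acq.event_rate, 4.0 * edge_pad) + 2.0 * edge_pad
    n_samples = int(round(duration * fs))
    baselines = acq.baselines(len(panel))

    amps = np.array(
        [pulse_amplitude(system, ph, panel, geometry, mapping) for ph in phenotypes]
    ).reshape(n_events, len(panel))
    times = _draw_event_times(
        np.random.default_rng(times_seq), n_events, duration, min_sep, edge_pad
    )
    # Snap pulse centres onto the sample grid so the constructed channel
    # minimum equals baseline * (1 - amplitude) exactly in the noiseless case.
    times = np.round(times * fs) / fs

    t = np.arange(n_samples) / fs
    channels = np.empty((len(panel), n_samples))
    drift = (
        acq.drift_amplitude * np.sin(2.0 * np.pi * t / acq.drift_period)
        if acq.drift_amplitude > 0
        else 0.0
    )
    half = int(math.ceil(6.0 * sigma_t * fs))
    rng_noise = np.random.default_rng(noise_seq)
    for c in range(len(panel)):
        x = baselines[c] * (1.0 + drift) * np.ones(n_samples)
        for k in range(n_events):
            center = times[k] * fs
            i0 = max(0, int(center) - half)
            i1 = min(n_samples, int(center) + half + 1)
            tt = (np.arange(i0, i1) - center) / fs
            x[i0:i1] -= baselines[c] * amps[k, c] * np.exp(-0.5 * (tt / sigma_t) ** 2)
        if acq.noise_sigma > 0:
            x += rng_noise.normal(0.0, acq.noise_sigma * baselines[c], n_samples)
        channels[c] = x

    log = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "time_s": times,
            "group": [ph.group for ph in phenotypes],
            "is_outlier": (
                np.zeros(n_events, dtype=bool) if outlier_mask is None else outlier_mask
            ),
            "diameter_um": [ph.diameter_um for ph in phenotypes],
            "g_mem": [ph.g_mem for ph in phenotypes],
            "sigma_cyto": [ph.sigma_cyto for ph in phenotypes],
        }
    )
    for c in range(len(panel)):
        log[f"amp_f{c + 1}"] = amps[:, c]

    trace = Trace(
        channels=channels,
        sampling_rate=fs,
        panel=panel,
        baseline_volts=baselines,
        seed=int(seed_seq.entropy) if seed_seq.entropy is not None else None,
        meta={"transit_time": acq.transit_time, "noise_sigma": acq.noise_sigma},
    )
    return trace, log


def phenotype_for_transparency(
    target: float,
    base: CellPhenotype | None = None,
    f_hi: float = 2e7,
    system: SystemCircuit | None = None,
    panel: FrequencyPanel | None = None,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    mapping: MappingParams = DEFAULT_MAPPING,
    g_bounds: tuple[float, float] = (1e-2, 5e3),
) -> CellPhenotype:
    """Solve for the membrane conductance whose model transparency hits ``target``.

    Root-finds g_mem on a bracket where transparency is monotone decreasing;
    used to construct populations with designed group-mean transparencies.
    """
    base = base or CellPhenotype(4.6)

    def f(log_g: float) -> float:
        ph = replace(base, g_mem=math.exp(log_g))
        return model_transparency(ph, f_hi, system, panel, geometry, mapping) - target

    lo, hi = math.log(g_bounds[0]), math.log(g_bounds[1])
    f_lo, f_hi_val = f(lo), f(hi)
    if f_lo * f_hi_val > 0:
        raise ParameterError(
            f"target transparency {target} outside attainable range "
            f"[{f_hi_val + target:.3f}, {f_lo + target:.3f}]"
        )
    log_g = brentq(f, lo, hi, xtol=1e-10)
    return replace(base, g_mem=math.exp(log_g))
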