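"""Per-event derived features: transparency, size proxy, diameter calibration.

Cell transparency is the ratio of the relative peak amplitude at a high
frequency over the amplitude at the 500 kHz reference, normalizing out
particle volume so the statistic reflects membrane and cytoplasm electrical
properties.  The reference amplitude itself serves as the size proxy and,
through a Coulter cube-law calibration (amplitude = k_cal * d^3), yields an
estimated diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import FrequencyPanel
from .detect import FLAG_ZERO_REFERENCE
from .errors import ParameterError, ProcessingError

#: High frequencies for which transparency columns are emitted by default:
#: 20 MHz (viability/stress contrasts) and 5 MHz (membrane-permeability axis
#: of the per-cell scatter).
DEFAULT_TRANSPARENCY_FREQS = (5e6, 2e7)


def transparency(amp_hi: float, amp_ref: float) -> float:
    """Ratio of high-frequency over reference peak amplitude.

    Scale-invariant: multiplying both amplitudes by any c > 0 leaves it
    unchanged.  Undefined when the reference amplitude is zero.
    """
    if amp_ref == 0:
        raise ProcessingError("transparency undefined: reference amplitude is zero")
    return amp_hi / amp_ref


@dataclass(frozen=True)
class SizeCalibration:
    """Cube-law amplitude-to-diameter calibration, ``amp_rel = k_cal * d_um^3``."""

    k_cal: float
    method: str = "least_squares_cube"

    def __post_init__(self) -> None:
        if not self.k_cal > 0:
            raise ParameterError("k_cal must be > 0")


def fit_size_calibration(
    amplitudes: np.ndarray, diameters_um: np.ndarray
) -> tuple[SizeCalibration, np.ndarray]:
    """Least-squares fit of ``amplitude = k_cal * d^3`` through the origin.

    ``diameters_um`` would come from an independent sizing method such as
    light microscopy.  Returns the calibration and the fit residuals.
    """
    a = np.asarray(amplitudes, dtype=float)
    d = np.asarray(diameters_um, dtype=float)
    if a.size == 0 or a.shape != d.shape:
        raise ParameterError("need equal, non-empty amplitude and diameter arrays")
    if np.any(d <= 0):
        raise ParameterError("diameters must be > 0")
    d3 = d**3
    denom = float(np.dot(d3, d3))
    if denom == 0 or np.all(a == 0):
        raise ParameterError("degenerate calibration pairs")
    k = float(np.dot(a, d3)) / denom
    if k <= 0:
        raise ParameterError("fitted k_cal is non-positive; check pairing of inputs")
    cal = SizeCalibration(k_cal=k)
    return cal, a - k * d3


def diameter_from_amplitude(amp_rel, cal: SizeCalibration):
    """Invert the cube law: ``d = (amp_rel / k_cal)^(1/3)`` (micrometres).

    Non-positive amplitudes map to NaN (flagged downstream), never an error,
    so vectorized use over noisy events is safe.
    """
    amp = np.asarray(amp_rel, dtype=float)
    with np.errstate(invalid="ignore"):
        d = np.where(amp > 0, np.cbrt(np.maximum(amp, 0.0) / cal.k_cal), np.nan)
    if np.ndim(amp_rel) == 0:
        return float(d)
    return d


def build_features(
    events: pd.DataFrame,
    panel: FrequencyPanel,
    calibration: SizeCalibration | None = None,
    transparency_freqs: tuple[float, ...] = DEFAULT_TRANSPARENCY_FREQS,
    group: str | None = None,
) -> pd.DataFrame:
    """Per-event feature table from accepted event measurements.

    Columns: ``event_id, group, size_proxy, diameter_um`` (NaN without a
    calibration), one ``transparency_<MHz>MHz`` column per requested high
    frequency, the per-channel ``amp_rel_*`` columns carried through, and
    ``qc_flags``.  Events with a zero reference amplitude are flagged
    ``zero_reference`` and dropped.
    """
    ref = panel.reference_index
    out = pd.DataFrame()
    if events.empty:
        cols = ["event_id", "group", "size_proxy", "diameter_um"]
        cols += [_t_col(f) for f in transparency_freqs]
        cols += [f"amp_rel_{c}" for c in range(len(panel))] + ["qc_flags"]
        return pd.DataFrame(columns=cols)
    out["event_id"] = events["event_id"].to_numpy()
    if group is not None:
        out["group"] = group
    elif "group" in events.columns:
        out["group"] = events["group"].to_numpy()
    else:
        out["group"] = ""
    size = events[f"amp_rel_{ref}"].to_numpy(dtype=float)
    out["size_proxy"] = size
    zero_ref = ~(size > 0)
    if calibration is not None:
        out["diameter_um"] = diameter_from_amplitude(size, calibration)
    else:
        out["diameter_um"] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        for f in transparency_freqs:
            idx = panel.index_of(f)
            out[_t_col(f)] = np.where(
                zero_ref, np.nan, events[f"amp_rel_{idx}"].to_numpy(dtype=float) / size
            )
    for c in range(len(panel)):
        out[f"amp_rel_{c}"] = events[f"amp_rel_{c}"].to_numpy(dtype=float)
    base_flags = (
        events["qc_flags"].fillna("").to_numpy()
        if "qc_flags" in events.columns
        else np.full(len(events), "")
    )
    flags = [
        ";".join(sorted(set(filter(None, bf.split(";"))) | ({FLAG_ZERO_REFERENCE} if z else set())))
        for bf, z in zip(base_flags, zero_ref)
    ]
    out["qc_flags"] = flags
    return out.loc[~zero_ref].reset_index(drop=True)


def _t_col(f_hi: float) -> str:
    mhz = f_hi / 1e6
    label = f"{mhz:g}".replace(".", "p")
    return f"transparency_{label}MHz"


def transparency_column(f_hi: float) -> str:
    """Feature-table column name for a transparency frequency."""
    return _t_col(f_hi)


def group_transparency(
    events: pd.DataFrame,
    panel: FrequencyPanel,
    f_hi: float = 2e7,
    estimator: str = "both",
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """Group-level transparency with both estimators.

    ``ratio_of_means`` divides the group-mean high-frequency amplitude by the
    group-mean reference amplitude (average peak intensities first, then the
    ratio); ``mean_of_ratios`` averages per-event transparencies.  The two
    differ on heterogeneous groups.  Optional percentile bootstrap CIs
    (95%, seeded).
    """
    if events.empty:
        raise ParameterError("empty group: no accepted events")
    ref = panel.reference_index
    hi = panel.index_of(f_hi)
    a_ref = events[f"amp_rel_{ref}"].to_numpy(dtype=float)
    a_hi = events[f"amp_rel_{hi}"].to_numpy(dtype=float)
    ok = a_ref > 0
    a_ref, a_hi = a_ref[ok], a_hi[ok]
    if a_ref.size == 0:
        raise ParameterError("no events with positive reference amplitude")
    ratios = a_hi / a_ref
    result = {
        "n": int(a_ref.size),
        "ratio_of_means": float(a_hi.mean() / a_ref.mean()),
        "mean_of_ratios": float(ratios.mean()),
        "sd_of_ratios": float(ratios.std(ddof=1)) if a_ref.size > 1 else 0.0,
    }
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, a_ref.size, size=(n_boot, a_ref.size))
        rom = a_hi[idx].mean(axis=1) / a_ref[idx].mean(axis=1)
        mor = (a_hi[idx] / a_ref[idx]).mean(axis=1)
        result["ratio_of_means_ci"] = tuple(np.percentile(rom, [2.5, 97.5]))
        result["mean_of_ratios_ci"] = tuple(np.percentile(mor, [2.5, 97.5]))
    if estimator != "both":
        if estimator not in result:
            raise ParameterError(f"unknown estimator {estimator!r}")
        return {"n": result["n"], estimator: result[estimator]}
    return result


def frequency_response(
    events: pd.DataFrame,
    panel: FrequencyPanel,
    group_col: str = "group",
) -> pd.DataFrame:
    """Mean relative amplitude per frequency, per group, with dispersion.

    Tidy output ordered by panel: ``group, frequency_hz, mean_amp_rel,
    sd_amp_rel, n``.
    """
    if events.empty:
        raise ParameterError("no accepted events")
    df = events.copy()
    if group_col not in df.columns:
        df[group_col] = ""
    rows = []
    for g, sub in df.groupby(group_col, sort=True):
        for c, f in enumerate(panel.frequencies):
            a = sub[f"amp_rel_{c}"].to_numpy(dtype=float)
            rows.append(
                {
                    "group": g,
                    "frequency_hz": f,
                    "mean_amp_rel": float(a.mean()),
                    "sd_amp_rel": float(a.std(ddof=1)) if a.size > 1 else 0.0,
                    "n": int(a.size),
                }
            )
    return pd.DataFrame(rows)
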