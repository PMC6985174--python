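"""Equivalent-circuit model of a cell in a microfluidic impedance sensing region.

A particle transiting between a pair of coplanar electrodes is described by a
lumped-element circuit: the cell is a membrane resistance in parallel with the
membrane capacitance, in series with the cytoplasm resistance in parallel with
the cytoplasm capacitance, the whole chain in series with the cell's
double-layer capacitance.  The cell sits in (partial) parallel with the
solution resistance and capacitance of the sensing region, and the electrode
double-layer capacitance is in series with everything.

The module maps a biophysical phenotype (diameter, specific membrane
conductance/capacitance, cytoplasm conductivity/permittivity) onto circuit
elements and predicts the per-frequency relative dip in sensing-branch
impedance magnitude ("pulse amplitude") caused by one transit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, ParameterError, ProcessingError

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.8541878128e-12

#: Default excitation panel, Hz.  The instrument drives eight simultaneous
#: tones from 500 kHz to 30 MHz; 2 MHz fills the one slot the published panel
#: leaves unnamed.
DEFAULT_FREQUENCIES = (5e5, 2e6, 5e6, 7.5e6, 1e7, 2e7, 2.5e7, 3e7)


def _require_positive_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ParameterError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class CellCircuit:
    """Lumped elements of one particle.

    Parameters
    ----------
    r_mem, c_mem : float
        Membrane resistance (ohm) and capacitance (F), in parallel.
    r_cyto, c_cyto : float
        Cytoplasm resistance (ohm) and capacitance (F), in parallel,
        in series with the membrane element.
    c_dl_cell : float
        Double-layer capacitance of the cell surface (F), in series with the
        membrane-cytoplasm chain; negligible above a few kHz.
    """

    r_mem: float
    c_mem: float
    r_cyto: float
    c_cyto: float
    c_dl_cell: float = 1e-9

    def __post_init__(self) -> None:
        _require_positive_finite(
            r_mem=self.r_mem,
            c_mem=self.c_mem,
            r_cyto=self.r_cyto,
            c_cyto=self.c_cyto,
            c_dl_cell=self.c_dl_cell,
        )


@dataclass(frozen=True)
class SystemCircuit:
    """Electrode-solution circuit of the empty sensing region.

    ``gain`` converts a relative impedance change into lock-in output volts;
    it rescales reported amplitudes only and defaults to 1 so that amplitudes
    stay dimensionless relative dips.
    """

    r_sol: float = 7.8e4
    c_sol: float = 5.7e-15
    c_dl_electrode: float = 1.2e-10
    gain: float = 1.0

    def __post_init__(self) -> None:
        _require_positive_finite(
            r_sol=self.r_sol,
            c_sol=self.c_sol,
            c_dl_electrode=self.c_dl_electrode,
            gain=self.gain,
        )


@dataclass(frozen=True)
class CellPhenotype:
    """Biophysical description of one particle.

    Parameters
    ----------
    diameter_um : float
        Particle diameter, micrometres.
    g_mem : float
        Specific membrane conductance, S/m^2.  A proxy for membrane ionic
        permeability: heat-killed (leaky) cells sit orders of magnitude above
        live ones.
    c_mem_spec : float
        Specific membrane capacitance, F/m^2 (~0.01 for a lipid bilayer).
    sigma_cyto : float
        Intrinsic cytoplasm conductivity, S/m.
    eps_cyto : float
        Cytoplasm relative permittivity (dimensionless).
    group : str
        Condition label (e.g. "live", "dead", "0.3M_1h", "bead").
    """

    diameter_um: float
    g_mem: float = 5.0
    c_mem_spec: float = 0.01
    sigma_cyto: float = 0.6
    eps_cyto: float = 60.0
    group: str = ""

    def __post_init__(self) -> None:
        _require_positive_finite(
            diameter_um=self.diameter_um,
            g_mem=self.g_mem,
            c_mem_spec=self.c_mem_spec,
            sigma_cyto=self.sigma_cyto,
            eps_cyto=self.eps_cyto,
        )


@dataclass(frozen=True)
class FrequencyPanel:
    """Ascending list of excitation frequencies with a size-reference channel.

    The reference channel (lowest frequency, 500 kHz by default) is the one
    where particle volume dominates the signal; it anchors event detection and
    the transparency ratio.
    """

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    reference_index: int = 0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) == 0:
            raise ParameterError("frequency panel is empty")
        if any(not math.isfinite(f) or f <= 0 for f in freqs):
            raise ParameterError("panel frequencies must be positive and finite")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ParameterError("panel frequencies must be strictly ascending")
        if not 0 <= self.reference_index < len(freqs):
            raise ParameterError("reference_index out of range")
        if freqs[self.reference_index] != min(freqs):
            raise ParameterError("reference frequency must be the panel minimum")

    @property
    def reference_frequency(self) -> float:
        return self.frequencies[self.reference_index]

    def index_of(self, frequency: float, rtol: float = 1e-6) -> int:
        for i, f in enumerate(self.frequencies):
            if abs(f - frequency) <= rtol * f:
                return i
        raise ParameterError(f"frequency {frequency!r} Hz not in panel {self.frequencies}")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class ChannelGeometry:
    """Sensing-region dimensions, micrometres (defaults match the device)."""

    width_um: float = 30.0
    height_um: float = 8.0
    electrode_gap_um: float = 30.0

    def __post_init__(self) -> None:
        _require_positive_finite(
            width_um=self.width_um,
            height_um=self.height_um,
            electrode_gap_um=self.electrode_gap_um,
        )


@dataclass(frozen=True)
class MappingParams:
    """Parameters of the phenotype -> circuit-element mapping.

    Attributes
    ----------
    medium_conductivity : float
        Suspension-medium conductivity, S/m (PBS ~1.6).
    k_geo : float
        Dimensionless geometric constant of the cytoplasm access path;
        r_cyto = 1/(sigma_eff * d * k_geo), c_cyto = eps*eps0*d*k_geo.
    g_ref : float
        Membrane-conductance scale (S/m^2) of the ion-exchange coupling: the
        effective cytoplasm conductivity relaxes toward the medium value as
        sigma_eff = sigma_med - (sigma_med - sigma_cyto)*exp(-g_mem/g_ref),
        capturing that a permeable membrane lets medium ions equilibrate with
        the cytoplasm.
    c_dl_cell : float
        Cell double-layer capacitance, F (large enough to be negligible
        above 500 kHz).
    ion_exchange : bool
        Disable to use the intrinsic sigma_cyto directly (textbook mapping).
    """

    medium_conductivity: float = 1.6
    k_geo: float = 1.5
    g_ref: float = 200.0
    c_dl_cell: float = 1e-9
    ion_exchange: bool = True

    def __post_init__(self) -> None:
        _require_positive_finite(
            medium_conductivity=self.medium_conductivity,
            k_geo=self.k_geo,
            g_ref=self.g_ref,
            c_dl_cell=self.c_dl_cell,
        )


DEFAULT_GEOMETRY = ChannelGeometry()
DEFAULT_MAPPING = MappingParams()


def parallel_rc_impedance(r: float, c: float, f: float) -> complex:
    """Complex impedance of a resistor and capacitor in parallel.

    Returns ``R / (1 + j*omega*R*C)`` with ``omega = 2*pi*f``; at ``f = 0``
    the capacitor is open and the result is exactly ``R``.
    """
    _require_positive_finite(r=r, c=c)
    if not math.isfinite(f) or f < 0:
        raise DomainError(f"frequency must be >= 0 and finite, got {f!r}")
    if f == 0:
        return complex(r)
    omega = 2.0 * math.pi * f
    return r / (1.0 + 1j * omega * r * c)


def cell_impedance(cell: CellCircuit, f: float) -> complex:
    """Impedance of one particle at frequency ``f`` (Hz, > 0).

    Series chain: cell double layer, membrane R||C, cytoplasm R||C.  As an RC
    one-port its magnitude is non-increasing in frequency: raising the
    frequency progressively shorts the membrane capacitance and exposes the
    cytoplasm.
    """
    if not math.isfinite(f) or f <= 0:
        raise DomainError(f"frequency must be > 0 and finite, got {f!r}")
    omega = 2.0 * math.pi * f
    z_dl = 1.0 / (1j * omega * cell.c_dl_cell)
    z_mem = parallel_rc_impedance(cell.r_mem, cell.c_mem, f)
    z_cyto = parallel_rc_impedance(cell.r_cyto, cell.c_cyto, f)
    return z_dl + z_mem + z_cyto


def sensing_branch_impedance(
    system: SystemCircuit,
    f: float,
    cell: CellCircuit | None = None,
    occlusion: float | None = None,
) -> complex:
    """Impedance of the solution branch between the electrodes.

    With no cell this is ``r_sol || c_sol``.  With a cell and
    ``occlusion=None`` the cell impedance is placed in plain parallel with the
    solution branch.  With an occlusion fraction ``phi`` in (0, 1] the branch
    is treated as a volume mixture: admittances combine as
    ``(1 - phi)/Z_sol + phi/Z_cell``, so an insulating particle displaces
    conducting solution and *raises* the branch impedance (Coulter principle),
    while a particle electrically identical to the medium is invisible.
    """
    if not math.isfinite(f) or f <= 0:
        raise DomainError(f"frequency must be > 0 and finite, got {f!r}")
    z_sol = parallel_rc_impedance(system.r_sol, system.c_sol, f)
    if cell is None:
        return z_sol
    z_cell = cell_impedance(cell, f)
    if occlusion is None:
        return 1.0 / (1.0 / z_sol + 1.0 / z_cell)
    if not 0.0 <= occlusion <= 1.0:
        raise ParameterError(f"occlusion fraction must lie in [0, 1], got {occlusion!r}")
    if occlusion == 0.0:
        return z_sol
    return 1.0 / ((1.0 - occlusion) / z_sol + occlusion / z_cell)


def system_impedance(
    system: SystemCircuit,
    cell: CellCircuit | None,
    f: float,
    occlusion: float | None = None,
) -> complex:
    """Total impedance seen by the lock-in: electrode double layer in series
    with the (possibly occluded) sensing branch."""
    omega = 2.0 * math.pi * f if f > 0 else None
    if omega is None or not math.isfinite(f):
        raise DomainError(f"frequency must be > 0 and finite, got {f!r}")
    z_dl = 1.0 / (1j * omega * system.c_dl_electrode)
    return z_dl + sensing_branch_impedance(system, f, cell, occlusion)


def occlusion_fraction(
    phenotype: CellPhenotype, geometry: ChannelGeometry = DEFAULT_GEOMETRY
) -> float:
    """Coulter-style volume fraction ``d^3 / (width^2 * gap)``, clipped to [0, 1]."""
    phi = phenotype.diameter_um**3 / (geometry.width_um**2 * geometry.electrode_gap_um)
    return min(phi, 1.0)


def phenotype_to_circuit(
    phenotype: CellPhenotype,
    medium_conductivity: float | None = None,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    mapping: MappingParams = DEFAULT_MAPPING,
) -> CellCircuit:
    """Map a biophysical phenotype onto lumped circuit elements.

    Membrane area scales with d^2 (c_mem = c_mem_spec * pi * d^2,
    r_mem = 1/(g_mem * pi * d^2)); the cytoplasm path scales with 1/d
    (r_cyto = 1/(sigma_eff * d * k_geo)) as for the access resistance of a
    sphere.  With ion-exchange coupling enabled (default), sigma_eff relaxes
    from the intrinsic sigma_cyto toward the medium conductivity as g_mem
    grows -- a leaky membrane lets medium ions flood the cytoplasm.

    ``medium_conductivity`` overrides the value carried by ``mapping``.
    """
    if medium_conductivity is not None:
        _require_positive_finite(medium_conductivity=medium_conductivity)
        mapping = replace(mapping, medium_conductivity=medium_conductivity)
    d = phenotype.diameter_um * 1e-6  # metres
    area = math.pi * d * d
    c_mem = phenotype.c_mem_spec * area
    r_mem = 1.0 / (phenotype.g_mem * area)
    sigma_med = mapping.medium_conductivity
    if mapping.ion_exchange:
        sigma_eff = sigma_med - (sigma_med - phenotype.sigma_cyto) * math.exp(
            -phenotype.g_mem / mapping.g_ref
        )
    else:
        sigma_eff = phenotype.sigma_cyto
    r_cyto = 1.0 / (sigma_eff * d * mapping.k_geo)
    c_cyto = phenotype.eps_cyto * EPSILON_0 * d * mapping.k_geo
    return CellCircuit(
        r_mem=r_mem,
        c_mem=c_mem,
        r_cyto=r_cyto,
        c_cyto=c_cyto,
        c_dl_cell=mapping.c_dl_cell,
    )


def pulse_amplitude(
    system: SystemCircuit,
    phenotype: CellPhenotype,
    panel: FrequencyPanel,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    mapping: MappingParams = DEFAULT_MAPPING,
) -> np.ndarray:
    """Relative impedance dip at each panel frequency for one transit.

    For each frequency, the amplitude is the relative increase of the
    sensing-branch impedance magnitude when the particle occludes its volume
    fraction of the region::

        a(f) = max(0, |Z_branch(phi, cell)| / |Z_branch(empty)| - 1)

    Because output voltage is proportional to sensing-region impedance, this
    is also the relative depth of the negative voltage pulse.  Amplitudes are
    clipped at zero: a particle more conductive than the medium would produce
    a positive voltage excursion that the negative-peak detector ignores.
    """
    phi = occlusion_fraction(phenotype, geometry)
    if phi == 0.0:
        return np.zeros(len(panel))
    circuit = phenotype_to_circuit(phenotype, geometry=geometry, mapping=mapping)
    amps = np.empty(len(panel))
    for i, f in enumerate(panel.frequencies):
        z_empty = sensing_branch_impedance(system, f)
        z_occluded = sensing_branch_impedance(system, f, circuit, occlusion=phi)
        amps[i] = max(0.0, abs(z_occluded) / abs(z_empty) - 1.0)
    return amps * system.gain


def model_transparency(
    phenotype: CellPhenotype,
    f_hi: float = 2e7,
    system: SystemCircuit | None = None,
    panel: FrequencyPanel | None = None,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    mapping: MappingParams = DEFAULT_MAPPING,
) -> float:
    """Noise-free transparency predicted by the circuit model.

    Ratio of the pulse amplitude at ``f_hi`` over the amplitude at the
    reference frequency; the ground truth against which measured
    transparencies are compared.
    """
    system = system or SystemCircuit()
    panel = panel or FrequencyPanel()
    amps = pulse_amplitude(system, phenotype, panel, geometry, mapping)
    ref = amps[panel.reference_index]
    if ref == 0.0:
        raise ProcessingError(
            f"reference-frequency amplitude is zero for phenotype {phenotype!r}"
        )
    return float(amps[panel.index_of(f_hi)] / ref)
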