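"""Closed-form accelerated-molecular-dynamics (aMD) mathematics.

aMD enhances conformational sampling by adding a non-negative boost potential
ΔV(r) to the system potential V(r) whenever V(r) falls below a reference
energy E::

    V*(r) = V(r)                    for V(r) >= E
    V*(r) = V(r) + ΔV(r)            for V(r) <  E
    ΔV(r) = (E - V(r))^2 / (α + E - V(r))

The acceleration factor α (kcal/mol) controls how aggressively the landscape
is flattened: smaller α flattens more; α → ∞ recovers conventional MD.  The
modified force is the unbiased force scaled by dV*/dV = α² / (α + E - V)²,
which lies in (0, 1] so energy ordering of states is preserved while barriers
shrink.

Dual-boost aMD applies a dihedral-term boost first and a total-energy boost on
top of the already-boosted total; the standard parameter recipe for
membrane-protein systems sets, from short conventional-MD averages,

    E_dihed = (1 + λ) V_dihed_avg,   α_dihed = λ V_dihed_avg / 5,
    E_total = V_total_avg + 0.2 N_atoms,  α_total = 0.2 N_atoms,

with λ = 0.3 the recommended acceleration for membrane proteins.

Units are kcal/mol throughout; k_B = 0.0019872041 kcal/(mol·K).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import InputError, ParameterError

__all__ = [
    "BOLTZMANN_KCAL_MOL_K",
    "DEFAULT_LAMBDA",
    "ThermodynamicState",
    "BoostSpec",
    "BoostParameters",
    "EnergyAverages",
    "BoostRecord",
    "boost_potential",
    "boosted_energy",
    "force_scale_factor",
    "dual_boost_energy",
    "compute_amd_parameters",
]

#: Boltzmann constant in kcal/(mol K).
BOLTZMANN_KCAL_MOL_K = 0.0019872041

#: Recommended dihedral acceleration parameter for membrane proteins.
DEFAULT_LAMBDA = 0.3

#: Fixed divisor in the dihedral acceleration-factor recipe.  Part of the
#: published parameter form; exposed as an advanced option of
#: :func:`compute_amd_parameters` only.
ALPHA_DIHED_DIVISOR = 5.0


@dataclass(frozen=True)
class ThermodynamicState:
    """Temperature and Boltzmann constant defining k_B·T for reweighting."""

    temperature: float = 300.0
    boltzmann_constant: float = BOLTZMANN_KCAL_MOL_K

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ParameterError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.boltzmann_constant > 0):
            raise ParameterError("boltzmann_constant must be > 0")

    @property
    def kt(self) -> float:
        """k_B·T in kcal/mol."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """1 / (k_B·T) in mol/kcal."""
        return 1.0 / self.kt


@dataclass(frozen=True)
class BoostSpec:
    """Reference energy E and acceleration factor α of one boost term (kcal/mol)."""

    reference_energy: float
    acceleration_factor: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.reference_energy):
            raise ParameterError("reference_energy must be finite")
        if not (self.acceleration_factor > 0) or not math.isfinite(self.acceleration_factor):
            # alpha = 0 makes the boost form singular at V = E.
            raise ParameterError(
                f"acceleration_factor must be > 0, got {self.acceleration_factor}"
            )


@dataclass(frozen=True)
class BoostParameters:
    """Dual-boost parameter set (E_dihed, α_dihed; E_total, α_total) plus λ."""

    dihedral: BoostSpec
    total: BoostSpec
    lambda_accel: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if not (0 < self.lambda_accel <= 1):
            raise ParameterError(
                f"lambda_accel must lie in (0, 1], got {self.lambda_accel}"
            )

    def to_dict(self) -> dict:
        return {
            "dihedral": {
                "E": self.dihedral.reference_energy,
                "alpha": self.dihedral.acceleration_factor,
            },
            "total": {
                "E": self.total.reference_energy,
                "alpha": self.total.acceleration_factor,
            },
            "lambda": self.lambda_accel,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostParameters":
        try:
            return cls(
                dihedral=BoostSpec(d["dihedral"]["E"], d["dihedral"]["alpha"]),
                total=BoostSpec(d["total"]["E"], d["total"]["alpha"]),
                lambda_accel=d["lambda"],
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise InputError(f"missing key in boost-parameter dict: {exc}") from exc

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BoostParameters":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class EnergyAverages:
    """Average dihedral/total potential energies from short conventional MD."""

    v_dihed_avg: float
    v_total_avg: float
    n_atoms: int

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ParameterError(f"n_atoms must be >= 1, got {self.n_atoms}")
        if not (math.isfinite(self.v_dihed_avg) and math.isfinite(self.v_total_avg)):
            raise ParameterError("energy averages must be finite")


@dataclass(frozen=True)
class BoostRecord:
    """Original energy, boosted energy and the applied boost for one evaluation."""

    v_original: float
    v_boosted: float
    delta_v: float


def _check_input_energy(v: float) -> float:
    v = float(v)
    if not math.isfinite(v):
        raise InputError(f"potential energy must be finite, got {v!r}")
    return v


def boost_potential(v: float, spec: BoostSpec) -> float:
    """Boost energy ΔV(v) = (E−v)²/(α+E−v) for v < E, else 0.

    ΔV is non-negative, vanishes with zero slope at v = E, and satisfies
    ΔV < E − v, so the boosted energy never crosses the reference energy.
    """
    v = _check_input_energy(v)
    e = spec.reference_energy
    if v >= e:
        return 0.0
    gap = e - v
    return gap * gap / (spec.acceleration_factor + gap)


def boosted_energy(v: float, spec: BoostSpec) -> BoostRecord:
    """Full (V, V*, ΔV) record for one energy under one boost term."""
    dv = boost_potential(v, spec)
    return BoostRecord(v_original=float(v), v_boosted=float(v) + dv, delta_v=dv)


def force_scale_factor(v: float, spec: BoostSpec) -> float:
    """dV*/dV = α²/(α+E−v)² for v < E, else 1.

    The boosted force is the unbiased force times this factor, which lies in
    (0, 1] and increases monotonically toward 1 at v = E.
    """
    v = _check_input_energy(v)
    e = spec.reference_energy
    if v >= e:
        return 1.0
    a = spec.acceleration_factor
    s = a / (a + (e - v))
    return s * s


def dual_boost_energy(
    v_total: float, v_dihed: float, params: BoostParameters
) -> tuple[float, float]:
    """Apply the dihedral boost, then the total boost, to one frame.

    The dihedral boost ΔV_d(v_dihed) is added to the total energy first; the
    total boost is then evaluated on the already-dihedral-boosted total:

        V* = v_total + ΔV_d(v_dihed) + ΔV_t(v_total + ΔV_d(v_dihed))

    Returns ``(v_star, delta_v_applied)`` where the delta is the sum of both
    boost contributions.
    """
    v_total = _check_input_energy(v_total)
    dv_dihed = boost_potential(v_dihed, params.dihedral)
    v_intermediate = v_total + dv_dihed
    dv_total = boost_potential(v_intermediate, params.total)
    return v_intermediate + dv_total, dv_dihed + dv_total


def compute_amd_parameters(
    avgs: EnergyAverages,
    lambda_accel: float = DEFAULT_LAMBDA,
    alpha_dihed_divisor: float = ALPHA_DIHED_DIVISOR,
) -> BoostParameters:
    """Dual-boost (E, α) pairs from conventional-MD energy averages.

    Implements the membrane-protein recipe::

        E_dihed = V_dihed_avg + λ·V_dihed_avg,  α_dihed = λ·V_dihed_avg / 5
        E_total = V_total_avg + 0.2·N_atoms,    α_total = 0.2·N_atoms

    λ defaults to 0.3, the value at which proper acceleration is achieved for
    membrane proteins.  The divisor 5 is a fixed constant of the recipe,
    overridable only through ``alpha_dihed_divisor``.
    """
    if not (lambda_accel > 0):
        raise ParameterError(f"lambda_accel must be > 0, got {lambda_accel}")
    if not (avgs.v_dihed_avg > 0):
        raise ParameterError(
            "v_dihed_avg must be > 0 (a non-positive average would give "
            f"alpha_dihed <= 0), got {avgs.v_dihed_avg}"
        )
    if not (alpha_dihed_divisor > 0):
        raise ParameterError("alpha_dihed_divisor must be > 0")
    e_dihed = avgs.v_dihed_avg + lambda_accel * avgs.v_dihed_avg
    a_dihed = lambda_accel * avgs.v_dihed_avg / alpha_dihed_divisor
    e_total = avgs.v_total_avg + 0.2 * avgs.n_atoms
    a_total = 0.2 * avgs.n_atoms
    return BoostParameters(
        dihedral=BoostSpec(e_dihed, a_dihed),
        total=BoostSpec(e_total, a_total),
        lambda_accel=lambda_accel,
    )
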