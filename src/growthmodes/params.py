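"""Parameter containers for the generative cell-cycle models.

The central object is :class:`ModelParams`, which fully specifies one
generative model of single-cell growth and division:

* a growth law within the cycle (exponential, linear, or super-exponential),
* a division-control strategy ``f(l_b) = 2 * l_b**(1 - alpha)`` on the
  birth length normalized by its mean, with regulation strength
  ``alpha`` in [0, 2] (``alpha = 0`` timer, ``1/2`` adder, ``1`` sizer),
* per-cycle Gaussian growth-rate (or elongation-speed) noise with CV
  ``cv_lambda``, and
* Gaussian division-timing noise, either time-additive (SD ``sigma_n``,
  applied to the generation time in units of 1/<lambda>) or size-additive
  (SD ``sigma_bd``, applied to the division length in units of <Lb>).

To first order in the noise the two timing-noise conventions generate the
same (Lb, Ld, Td) statistics under the mapping ``sigma_n = sigma_bd / 2``;
:meth:`ModelParams.sigma_n_effective` and
:meth:`ModelParams.sigma_bd_effective` expose that mapping.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Any, Mapping, Optional


class GrowthMode(str, enum.Enum):
    EXPONENTIAL = "exponential"
    LINEAR = "linear"
    SUPER_EXPONENTIAL = "super_exponential"


class NoiseKind(str, enum.Enum):
    TIME_ADDITIVE = "time_additive"
    SIZE_ADDITIVE = "size_additive"


LN2 = math.log(2.0)


@dataclass
class ModelParams:
    """Full parameterization of one generative growth/division model.

    Parameters
    ----------
    growth_mode
        Growth law within the cell cycle.
    alpha
        Regulation strength of the division strategy, in [0, 2].
    mean_Td
        Mean generation time in minutes; used to derive the mean growth
        rate ``ln(2)/mean_Td`` (exponential) or the mean normalized
        elongation speed ``1/mean_Td`` (linear) when those are not set
        explicitly.
    mean_growth_rate
        Mean exponential growth rate <lambda> in 1/min.
    cv_lambda
        Coefficient of variation of the per-cycle growth rate
        (or of the elongation speed in linear mode).
    mean_elongation_speed_norm
        Mean elongation speed normalized by the mean birth length, in
        1/min (linear mode only).
    noise_kind
        Whether division-timing noise is time- or size-additive.
    sigma_n
        SD of the time-additive noise (dimensionless; the noise enters the
        generation time as ``zeta / <lambda>``).
    sigma_bd
        SD of the size-additive noise in units of the mean birth length.
    mean_birth_length
        Mean birth length <Lb> in micrometres.
    superexp_k
        Super-exponential acceleration constant k in 1/min^3; default
        ``2 / mean_Td**3``.
    superexp_tc_frac
        Crossover age t_c/Td at which growth turns super-exponential.
    seed
        RNG seed for simulations built from these parameters.
    """

    growth_mode: GrowthMode = GrowthMode.EXPONENTIAL
    alpha: float = 0.5
    mean_Td: float = 212.0
    mean_growth_rate: Optional[float] = None
    cv_lambda: float = 0.15
    mean_elongation_speed_norm: Optional[float] = None
    noise_kind: NoiseKind = NoiseKind.TIME_ADDITIVE
    sigma_n: float = 0.15
    sigma_bd: float = 0.30
    mean_birth_length: float = 1.73
    superexp_k: Optional[float] = None
    superexp_tc_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.growth_mode = GrowthMode(self.growth_mode)
        self.noise_kind = NoiseKind(self.noise_kind)
        if not 0.0 <= self.alpha <= 2.0:
            raise ValueError(f"alpha must be in [0, 2], got {self.alpha}")
        if self.sigma_n < 0 or self.sigma_bd < 0 or self.cv_lambda < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.mean_birth_length <= 0:
            raise ValueError("mean_birth_length must be positive")
        if self.mean_Td <= 0:
            raise ValueError("mean_Td must be positive")
        if not 0.0 <= self.superexp_tc_frac <= 1.0:
            raise ValueError("superexp_tc_frac must be in [0, 1]")
        if self.mean_growth_rate is None:
            self.mean_growth_rate = LN2 / self.mean_Td
        if self.mean_elongation_speed_norm is None:
            self.mean_elongation_speed_norm = 1.0 / self.mean_Td
        if self.superexp_k is None:
            self.superexp_k = 2.0 / self.mean_Td**3

    # -- noise-kind mapping (first-order equivalence) -------------------

    def sigma_n_effective(self) -> float:
        """Time-additive SD actually in force, mapping sigma_bd/2 if needed."""
        if self.noise_kind is NoiseKind.TIME_ADDITIVE:
            return self.sigma_n
        return self.sigma_bd / 2.0

    def sigma_bd_effective(self) -> float:
        """Size-additive SD actually in force, mapping 2*sigma_n if needed."""
        if self.noise_kind is NoiseKind.SIZE_ADDITIVE:
            return self.sigma_bd
        return 2.0 * self.sigma_n

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.value if isinstance(v, enum.Enum) else v
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class ReplicationParams:
    """Adder-per-origin replication/division parameters.

    ``delta_ii_mean`` is the mean length added per origin between
    consecutive replication initiations; ``cd_mean`` the mean C+D period
    (initiation to the corresponding division); ``dt`` the simulation
    time grid in minutes.
    """

    delta_ii_mean: float = 0.41
    delta_ii_cv: float = 0.17
    cd_mean: float = 160.0
    cd_cv: float = 0.16
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.delta_ii_mean <= 0 or self.cd_mean <= 0:
            raise ValueError("replication means must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.delta_ii_cv < 0 or self.cd_cv < 0:
            raise ValueError("CVs must be non-negative")


@dataclass
class ConstrictionParams:
    """Constriction model: birth -> constriction -> division size increments.

    Defaults are the alanine-medium values: 1.18 um (CV 0.23) added between
    birth and constriction onset, 0.53 um (CV 0.26) between constriction
    and division.
    """

    delta_bn_mean: float = 1.18
    delta_bn_cv: float = 0.23
    delta_nd_mean: float = 0.53
    delta_nd_cv: float = 0.26

    def __post_init__(self) -> None:
        if self.delta_bn_mean <= 0 or self.delta_nd_mean <= 0:
            raise ValueError("constriction increment means must be positive")
        if self.delta_bn_cv < 0 or self.delta_nd_cv < 0:
            raise ValueError("CVs must be non-negative")
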