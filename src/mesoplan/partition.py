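"""Nernst partitioning of a membrane protein between mesophase and water.

The protein, assumed monomeric in both phases, distributes between the
lipidic mesophase and the aqueous pool according to a partitioning
constant

    K = C_lip / C_aq

where both concentrations are molalities: C_lip per mass of monoolein and
C_aq per mass of total water (the aqueous pool counts supernatant *and*
the water inside the mesophase channels, which exchange freely).  Writing
P for total protein mass, f·P in the lipid and (1−f)·P in the water,

    K = (f·P/M) / ((1−f)·P/W)   ⇒   f = K·M / (K·M + W)

so incorporation rises with K and falls with water content.  For K = 0 the
droplet behaves as an ideal vapor-diffusion experiment and the aqueous
protein concentration simply tracks the shrinking droplet volume; for any
K > 0 it stays below that ideal-dilution bound.

The apparent K of a real protein is estimated from a depletion assay:
known volumes of protein solution are incubated on monoolein-coated wells
in a sealed plate for 24 h, the supernatant concentration C_sup is
measured photometrically, and the depletion 1 − C_sup/C_0 is read as the
incorporated fraction (the sealed plate loses no water, so W equals the
applied volume at 1 µg/nl).
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InsufficientDataError, InvalidSpecificationError
from .hydration import (
    CalibrationParams,
    DropletSpec,
    MesoSystem,
    equilibrium_droplet_volume,
)

__all__ = [
    "PartitionParams",
    "PartitionState",
    "PartitionAssay",
    "KReplicate",
    "KEstimate",
    "fraction_incorporated",
    "partition_state",
    "aqueous_concentration_ratio",
    "estimate_K",
    "bootstrap_K_interval",
    "suggest_assay_volume",
]

FLAG_UNBOUNDED = "k-unbounded-above"
FLAG_EXCESS_SUPERNATANT = "supernatant-exceeds-sample"


class PartitionParams(BaseModel):
    """Nernst partitioning constant K = C_lip/C_aq (dimensionless)."""

    model_config = ConfigDict(frozen=True)

    K: float = Field(ge=0)


class PartitionState(BaseModel):
    """Distribution of protein for one (K, system) pair.

    ``c_lip`` and ``c_aq`` are molalities per unit total protein
    (protein mass fraction per µg of monoolein resp. water); their ratio
    equals K whenever both phases are populated.
    """

    model_config = ConfigDict(frozen=True)

    fraction_incorporated: float = Field(ge=0, le=1)
    aqueous_conc_ratio: float = Field(ge=0)
    c_lip: float = Field(ge=0)
    c_aq: float = Field(ge=0)


class PartitionAssay(BaseModel):
    """A depletion assay: applied sample and measured supernatants.

    Supernatant readings above the sample concentration are physically
    impossible under the model; they are flagged downstream rather than
    rejected here (measurement noise produces them at small depletion).
    """

    model_config = ConfigDict(frozen=True)

    sample_conc: float = Field(gt=0)  # C_0, µg/µl
    applied_volume: float = Field(gt=0)  # nl
    mo_mass: float = Field(gt=0)  # µg
    supernatant_conc: tuple[float, ...]  # C_sup per replicate, µg/µl

    @model_validator(mode="after")
    def _nonneg(self) -> "PartitionAssay":
        if any(c < 0 for c in self.supernatant_conc):
            raise ValueError("supernatant concentrations must be >= 0")
        return self

    @property
    def n_replicates(self) -> int:
        return len(self.supernatant_conc)


def fraction_incorporated(params: PartitionParams, system: MesoSystem) -> float:
    """Fraction f = K·M/(K·M + W) of total protein in the lipidic phase."""
    km = params.K * system.mo_mass
    if km == 0 and system.water_mass == 0:
        return 0.0  # no partitioning and no water: nothing incorporated
    return km / (km + system.water_mass)


def partition_state(
    params: PartitionParams,
    spec: DropletSpec,
    system: MesoSystem,
) -> PartitionState:
    """Full partition state of an equilibrated droplet."""
    f = fraction_incorporated(params, system)
    return PartitionState(
        fraction_incorporated=f,
        aqueous_conc_ratio=aqueous_concentration_ratio(params, spec, system),
        c_lip=f / system.mo_mass,
        c_aq=(1.0 - f) / system.water_mass if system.water_mass > 0 else 0.0,
    )


def aqueous_concentration_ratio(
    params: PartitionParams,
    spec: DropletSpec,
    system: MesoSystem,
) -> float:
    """Aqueous protein concentration at the endpoint relative to the sample.

    The aqueous pool holds (1−f) of the protein in a droplet shrunk from
    V_p + V_s to V_f = V_s/d, so C_aq/C_0 = (1−f)·V_p/V_f.  The K = 0
    value, V_p·d/V_s (= d for equal volumes), is the ideal-dilution upper
    bound: partitioning can only lower the aqueous concentration.
    """
    f = fraction_incorporated(params, system)
    v_f = equilibrium_droplet_volume(spec)
    return (1.0 - f) * spec.protein_volume / v_f


class KReplicate(BaseModel):
    """Per-replicate K estimate with its depletion fraction and flags."""

    model_config = ConfigDict(frozen=True)

    supernatant_conc: float
    f_hat: float
    k_hat: float
    flag: str | None = None


class KEstimate(BaseModel):
    """Apparent partitioning constant summarized over assay replicates."""

    model_config = ConfigDict(frozen=True)

    k: float  # median of replicate estimates
    replicates: tuple[KReplicate, ...]

    @property
    def n(self) -> int:
        return len(self.replicates)


def estimate_K(assay: PartitionAssay) -> KEstimate:
    """Estimate the apparent K from supernatant depletion.

    Per replicate: f̂ = 1 − C_sup/C_0 and K̂ = f̂·W / ((1−f̂)·M) with
    W = applied volume × 1 µg/nl (sealed assay, no vapor loss).  A zero
    supernatant reading means complete depletion (K̂ unbounded above,
    reported as +inf); a reading above C_0 means negative apparent
    depletion and is clamped to K̂ = 0 with a flag.  The summary is the
    median of the replicate estimates.
    """
    if assay.n_replicates == 0:
        raise InsufficientDataError("assay has no supernatant measurements")
    water = assay.applied_volume * 1.0  # µg, density 1 µg/nl
    reps = []
    for c_sup in assay.supernatant_conc:
        f_hat = 1.0 - c_sup / assay.sample_conc
        if c_sup == 0:
            reps.append(
                KReplicate(
                    supernatant_conc=c_sup, f_hat=1.0, k_hat=math.inf,
                    flag=FLAG_UNBOUNDED,
                )
            )
        elif f_hat < 0:
            reps.append(
                KReplicate(
                    supernatant_conc=c_sup, f_hat=f_hat, k_hat=0.0,
                    flag=FLAG_EXCESS_SUPERNATANT,
                )
            )
        else:
            k_hat = f_hat * water / ((1.0 - f_hat) * assay.mo_mass)
            reps.append(
                KReplicate(supernatant_conc=c_sup, f_hat=f_hat, k_hat=k_hat)
            )
    k = float(np.median([r.k_hat for r in reps]))
    return KEstimate(k=k, replicates=tuple(reps))


def bootstrap_K_interval(
    assay: PartitionAssay,
    n_resamples: int = 2000,
    seed: int | None = None,
    level: float = 95.0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the median K over replicates.

    Deterministic for a given seed; requires at least three replicates.
    """
    if assay.n_replicates < 3:
        raise InsufficientDataError(
            f"bootstrap needs >= 3 replicates, got {assay.n_replicates}"
        )
    if n_resamples <= 0:
        raise InsufficientDataError("n_resamples must be positive")
    ks = np.array([r.k_hat for r in estimate_K(assay).replicates])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ks), size=(n_resamples, len(ks)))
    medians = np.median(ks[idx], axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(medians, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def suggest_assay_volume(
    k_guess: float,
    mo_mass: float,
    v_min: float = 100.0,
    v_max: float = 900.0,
) -> float:
    """Applied volume (nl) giving ~50 % depletion for an anticipated K.

    The depletion assay is most informative when f ≈ 0.5, i.e. when the
    applied water mass matches K·M; the result is clipped to the volumes a
    coated well accommodates.  Matching the assay volume to the expected K
    is what makes small constants (K ~ 0.1) measurable at all against
    photometric noise.
    """
    if k_guess < 0 or mo_mass <= 0:
        raise InvalidSpecificationError("k_guess must be >= 0 and mo_mass > 0")
    return float(np.clip(k_guess * mo_mass, v_min, v_max))
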