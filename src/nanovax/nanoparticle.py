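"""Gold-nanoparticle dosimetry and peptide-conjugation planning.

Spherical-particle geometry (volume, surface area, gold-atom content), a
size-dependent extinction coefficient at the surface-plasmon band,
Beer-Lambert concentration from absorbance, and the bookkeeping that
converts a peptide:particle molar ratio into a surface-coverage label and
mixing recipe.

The coverage scale is anchored at a reference molar ratio of 1:100,000
(peptides per particle) on the reference 23 nm particle, which is taken to
be full monolayer coverage ("coverage 1.00") and is assigned the study's
nominal density of 0.3 nmol-peptide/nm^2.  That density unit is implemented
verbatim as a bookkeeping scale: taken at face value it is physically
implausible for a peptide monolayer, but all conversions here are linear in
it, so it functions as a label anchored at the reference point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GoldConstants:
    """Bulk-gold physical constants used for atom-count dosimetry."""

    density_g_cm3: float = 19.3
    molar_mass_g_mol: float = 196.97
    avogadro: float = 6.02214076e23


GOLD = GoldConstants()

#: nm^3 -> cm^3
_NM3_TO_CM3 = 1e-21


@dataclass(frozen=True)
class ExtinctionCalibration:
    """Log-log calibration of the SPR-band extinction coefficient.

    ln(epsilon) = a + k * ln(d_nm), epsilon in M^-1 cm^-1.  Defaults are the
    widely used empirical calibration for citrate-stabilised spherical gold
    nanoparticles (Liu et al. 2007, Colloids Surf. B 58:3-7).
    """

    k: float = 3.32111
    a: float = 10.80505
    provenance: str = (
        "ln(eps) = 10.80505 + 3.32111 ln(d/nm); empirical AuNP SPR "
        "calibration of Liu et al. (2007)"
    )


LIU_CALIBRATION = ExtinctionCalibration()

#: Reference coverage scale: 100,000 peptides per particle == coverage 1.00
#: == 0.3 nmol-peptide/nm^2 on the reference particle.
REFERENCE_RATIO = 100_000.0
REFERENCE_DENSITY = 0.3


@dataclass(frozen=True)
class NanoparticleSpec:
    """Sphere-derived quantities for one particle size."""

    label: str
    diameter_nm: float
    volume_nm3: float
    surface_area_nm2: float
    atoms_per_particle: float
    extinction_m1_cm1: float


@dataclass(frozen=True)
class ConjugationPlan:
    """Peptide:particle mixing recipe for a target surface coverage."""

    np_label: str
    np_concentration_nM: float
    np_volume_mL: float
    peptide_stock_mM: float
    coverage_label: float
    molar_ratio: float
    surface_density: float
    peptide_moles: float
    peptide_volume_uL: float
    normalized_by_area: bool


def sphere_quantities(
    diameter_nm: float,
    label: str = "",
    constants: GoldConstants = GOLD,
    calibration: ExtinctionCalibration = LIU_CALIBRATION,
) -> NanoparticleSpec:
    """Volume, area, gold-atom count and extinction for a spherical particle.

    atoms = rho * N_A * V / M with V converted from nm^3 to cm^3.
    """
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    volume = math.pi * diameter_nm**3 / 6.0
    area = math.pi * diameter_nm**2
    atoms = (
        constants.density_g_cm3
        * constants.avogadro
        * volume
        * _NM3_TO_CM3
        / constants.molar_mass_g_mol
    )
    eps = extinction_coefficient(diameter_nm, calibration)
    return NanoparticleSpec(
        label=label or f"Au{round(diameter_nm)}",
        diameter_nm=diameter_nm,
        volume_nm3=volume,
        surface_area_nm2=area,
        atoms_per_particle=atoms,
        extinction_m1_cm1=eps,
    )


def extinction_coefficient(
    diameter_nm: float, calibration: ExtinctionCalibration = LIU_CALIBRATION
) -> float:
    """SPR-band extinction coefficient, eps = exp(a + k ln d), M^-1 cm^-1."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    return math.exp(calibration.a + calibration.k * math.log(diameter_nm))


def concentration_from_absorbance(
    absorbance: float, pathlength_cm: float, extinction: float
) -> float:
    """Beer-Lambert inversion, c = A / (eps * l), in mol/L."""
    if pathlength_cm <= 0:
        raise ValueError("pathlength must be > 0")
    if extinction <= 0:
        raise ValueError("extinction coefficient must be > 0")
    return absorbance / (extinction * pathlength_cm)


def surface_density_from_ratio(
    molar_ratio: float,
    reference_ratio: float = REFERENCE_RATIO,
    reference_density: float = REFERENCE_DENSITY,
) -> float:
    """Linear density scale: density = ref_density * ratio / ref_ratio."""
    if molar_ratio <= 0:
        raise ValueError("molar ratio must be > 0")
    return reference_density * molar_ratio / reference_ratio


def format_density(density: float, decimals: int = 2) -> str:
    """Truncate (not round) to *decimals* places, matching report style.

    0.225 -> "0.22" and 0.375 -> "0.37".
    """
    scale = 10**decimals
    truncated = math.floor(density * scale + 1e-12) / scale
    return f"{truncated:.{decimals}f}"


def conjugation_recipe(
    np_conc_nM: float,
    np_vol_mL: float,
    coverage_label: float,
    np: NanoparticleSpec,
    reference_np: NanoparticleSpec | None = None,
    peptide_stock_mM: float = 30.0,
    normalize_by_area: bool = True,
) -> ConjugationPlan:
    """Mixing recipe delivering a target surface coverage on particle *np*.

    The per-particle molar ratio is R = coverage * 100,000, optionally
    scaled by the surface-area ratio to the reference particle so that a
    larger particle receives proportionally more peptides and equal surface
    densities are maintained across sizes (the default).  Peptide moles =
    particle moles * R; the pipetting volume follows from the stock
    concentration.
    """
    if min(np_conc_nM, np_vol_mL, coverage_label) <= 0:
        raise ValueError("concentration, volume and coverage must be > 0")
    if peptide_stock_mM <= 0:
        raise ValueError("peptide stock concentration must be > 0")
    if reference_np is None:
        reference_np = np if not normalize_by_area else sphere_quantities(23.0)
    ratio = coverage_label * REFERENCE_RATIO
    if normalize_by_area:
        ratio *= np.surface_area_nm2 / reference_np.surface_area_nm2
    particle_moles = np_conc_nM * 1e-9 * np_vol_mL * 1e-3
    peptide_moles = particle_moles * ratio
    peptide_volume_uL = peptide_moles / (peptide_stock_mM * 1e-3) * 1e6
    return ConjugationPlan(
        np_label=np.label,
        np_concentration_nM=np_conc_nM,
        np_volume_mL=np_vol_mL,
        peptide_stock_mM=peptide_stock_mM,
        coverage_label=coverage_label,
        molar_ratio=ratio,
        surface_density=REFERENCE_DENSITY * coverage_label,
        peptide_moles=peptide_moles,
        peptide_volume_uL=peptide_volume_uL,
        normalized_by_area=normalize_by_area,
    )


def study_particles() -> dict[str, NanoparticleSpec]:
    """The two study particle sizes at their nominal diameters."""
    return {"Au23": sphere_quantities(23.0, "Au23"), "Au68": sphere_quantities(68.0, "Au68")}
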