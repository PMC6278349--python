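"""Synthetic solute datasets with the statistical structure the analysis assumes.

The generator emulates the outputs of an explicit-solvation free-energy
engine for a family of rigid non-polar solutes:

* the electrostatic component obeys a linear-response relation
  ΔA_ES = α·⟨U_ES⟩ + noise, with the interaction energy magnitude coupled
  to solute size (larger solutes interact more);
* dispersion and cavitation are each linear in the solvent-accessible
  surface area with opposing slopes (dispersion stabilizing and growing
  more negative with size, cavitation a growing positive cost), whose sum
  leaves a small negative net slope — the near-cancellation that makes
  the non-electrostatic term deceptively small;
* a synthetic "experimental" total adds independent measurement noise.

Every column draws from its own seeded substream (spawned in a fixed,
documented order from the root seed), so adding a column later cannot
silently shift existing ones and identical (config, seed) gives
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .decomposition import SoluteRecord
from .geometry import Atom, Molecule
from .lrt import EnergyPair

__all__ = [
    "GeneratorConfig",
    "SyntheticSet",
    "generate",
    "make_fixture_geometry",
    "make_lrt_pairs",
]

# substream order is part of the format: asa, u_es, es_noise, disp_noise,
# cav_noise, reorg, exp_noise
_N_STREAMS = 7


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic solute-set generator.

    Defaults are sized to bracket an eight-solute aromatic series:
    ASA 200–450 Å², reorganization energies 0.3–0.9 kcal/mol, dispersion
    slope −0.050 and cavitation slope +0.0369 kcal/mol/Å² so the net
    non-electrostatic slope is −0.0131, intercepts summing to 3.56
    kcal/mol, and an electrostatic LRT slope of 0.41.
    """

    n_solutes: int = 50
    seed: int = 0
    asa_range: tuple[float, float] = (200.0, 450.0)
    lrt_slope: float = 0.41
    lrt_noise_sd: float = 0.2
    disp_slope: float = -0.050
    disp_intercept: float = 2.50
    cav_slope: float = 0.0369
    cav_intercept: float = 1.06
    component_noise_sd: float = 0.1
    reorg_range: tuple[float, float] = (0.3, 0.9)
    exp_noise_sd: float = 0.3
    es_asa_coupling: bool = True
    es_scale: float = -0.05  # ⟨U_ES⟩ per Å² of ASA when coupled

    def __post_init__(self) -> None:
        if self.n_solutes < 0:
            raise ValueError("n_solutes must be non-negative")
        for rng_name in ("asa_range", "reorg_range"):
            lo, hi = getattr(self, rng_name)
            if not lo < hi:
                raise ValueError(f"{rng_name}: need min < max, got ({lo}, {hi})")
        for sd_name in ("lrt_noise_sd", "component_noise_sd", "exp_noise_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be non-negative")

    @property
    def net_non_es_slope(self) -> float:
        return self.disp_slope + self.cav_slope

    @property
    def net_non_es_intercept(self) -> float:
        return self.disp_intercept + self.cav_intercept

    @property
    def total_noise_sd(self) -> float:
        """SD of (exp_dA_hyd − ideal prediction) when the non-ES line and
        the given ΔA_ES are used: two component noises plus the
        experimental noise in quadrature."""
        return math.sqrt(2 * self.component_noise_sd**2 + self.exp_noise_sd**2)


@dataclass(frozen=True)
class SyntheticSet:
    """Generated records together with the ground-truth config."""

    records: tuple[SoluteRecord, ...]
    truth: GeneratorConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def truth_dict(self) -> dict:
        return asdict(self.truth)


def generate(config: GeneratorConfig) -> SyntheticSet:
    """Draw a synthetic solute set under *config* (deterministic in seed)."""
    n = config.n_solutes
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(_N_STREAMS)]
    rng_asa, rng_ues, rng_esn, rng_dispn, rng_cavn, rng_reorg, rng_expn = streams

    asa = rng_asa.uniform(*config.asa_range, size=n)
    if config.es_asa_coupling:
        u_es = config.es_scale * asa * rng_ues.uniform(0.5, 1.5, size=n)
    else:
        u_es = config.es_scale * 0.5 * sum(config.asa_range) * rng_ues.uniform(0.5, 1.5, size=n)
    dA_es = config.lrt_slope * u_es + rng_esn.normal(0.0, config.lrt_noise_sd, size=n)
    dA_disp = (
        config.disp_slope * asa
        + config.disp_intercept
        + rng_dispn.normal(0.0, config.component_noise_sd, size=n)
    )
    dA_cav = (
        config.cav_slope * asa
        + config.cav_intercept
        + rng_cavn.normal(0.0, config.component_noise_sd, size=n)
    )
    e_reorg = rng_reorg.uniform(*config.reorg_range, size=n)
    total = e_reorg + dA_es + dA_disp + dA_cav
    exp_dA_hyd = total + rng_expn.normal(0.0, config.exp_noise_sd, size=n)

    records = tuple(
        SoluteRecord(
            name=f"synthetic-{i:04d}",
            e_reorg=float(e_reorg[i]),
            dA_es=float(dA_es[i]),
            dA_disp=float(dA_disp[i]),
            dA_cav=float(dA_cav[i]),
            dA_hyd_printed=float(total[i]),
            exp_dA_hyd=float(exp_dA_hyd[i]),
            asa=float(asa[i]),
        )
        for i in range(n)
    )
    return SyntheticSet(records=records, truth=config)


def make_lrt_pairs(n: int, slope: float, noise_sd: float, seed: int) -> list[EnergyPair]:
    """Energy pairs on dA = slope·u + noise, u ~ Uniform(−25, −1) kcal/mol."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng_u, rng_noise = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    u = rng_u.uniform(-25.0, -1.0, size=n)
    dA = slope * u + rng_noise.normal(0.0, noise_sd, size=n)
    return [EnergyPair(dA=float(dA[i]), u_mean=float(u[i]), label=f"pair-{i}") for i in range(n)]


# --- idealized rigid fixture geometries ---------------------------------

_CC_AROMATIC = 1.39  # Å
_CH = 1.09  # Å


def _benzene() -> Molecule:
    atoms = []
    for k in range(6):
        th = math.radians(60.0 * k)
        atoms.append(Atom("C", np.array([_CC_AROMATIC * math.cos(th), _CC_AROMATIC * math.sin(th), 0.0])))
    for k in range(6):
        th = math.radians(60.0 * k)
        r = _CC_AROMATIC + _CH
        atoms.append(Atom("H", np.array([r * math.cos(th), r * math.sin(th), 0.0])))
    return Molecule("benzene", tuple(atoms))


def _naphthalene_like() -> Molecule:
    # two ideal hexagons (bond 1.39 Å) fused on a vertical shared edge at x = 0
    b = _CC_AROMATIC
    apothem = b * math.sqrt(3.0) / 2.0
    carbons: list[np.ndarray] = []
    hydrogens: list[np.ndarray] = []
    shared = [np.array([0.0, b / 2.0, 0.0]), np.array([0.0, -b / 2.0, 0.0])]
    for side in (+1.0, -1.0):
        center = np.array([side * apothem, 0.0, 0.0])
        for ang in (30.0, 90.0, 270.0, 330.0):
            th = math.radians(ang if side > 0 else 180.0 - ang)
            v = center + b * np.array([math.cos(th), math.sin(th), 0.0])
            carbons.append(v)
            out = (v - center) / np.linalg.norm(v - center)
            hydrogens.append(v + _CH * out)
    atoms = [Atom("C", p) for p in shared + carbons] + [Atom("H", p) for p in hydrogens]
    return Molecule("naphthalene_like", tuple(atoms))


def _methane_like() -> Molecule:
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    dirs /= math.sqrt(3.0)
    atoms = [Atom("C", np.zeros(3))] + [Atom("H", _CH * d) for d in dirs]
    return Molecule("methane_like", tuple(atoms))


_FIXTURES = {
    "benzene": _benzene,
    "naphthalene_like": _naphthalene_like,
    "methane_like": _methane_like,
}


def make_fixture_geometry(name: str) -> Molecule:
    """Idealized rigid test geometry: ``benzene`` (planar hexagon, C–C
    1.39 Å, C–H 1.09 Å), ``naphthalene_like`` (two fused ideal hexagons)
    or ``methane_like`` (tetrahedral, C–H 1.09 Å)."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
        ) from None
    return builder()
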