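"""Synthetic native-MS / UVPD experiments with planted ground truth.

The generator emulates the structure of a conformer-selective metal-binding
study on a 140-residue intrinsically disordered protein: a precursor
charge-state distribution built from three Gaussian conformer subpopulations
(centers near 7+, 10+ and 13+), per-conformer zinc-stoichiometry profiles,
and per-scan deconvoluted fragment lists (20 scans per replicate, 3
replicates per condition) for an apo and a zinc-incubated condition.

Planted truth covers every downstream quantity: per-site true fragment
yields for both conditions (hence true ΔFY and the significant-site set),
the holo (terminus, site) map, the CDS mixture parameters, and the covered
site set (hence sequence coverage). Fragment masses are computed through the
same chemistry used by the matcher, so a noiseless simulation round-trips
exactly.

Noise model: per-scan species intensities are the true intensity times
mean-one lognormal multiplicative noise, thinned by Bernoulli dropout —
the standard caricature of MS intensity variation. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .isotope import isotope_distribution
from .sequence import (
    AdductConvention,
    ProteinSequence,
    ZN_MINUS_2H,
    alpha_synuclein,
    fragment_neutral_mass,
    species_composition,
    FragmentSpecies,
)
from .chem import PROTON_MASS

__all__ = [
    "ConformerComponent",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "make_conformer_presets",
    "PRESET_NAMES",
]

PRESET_NAMES = ("low-charge", "intermediate", "high-charge")

# intensity scales (arbitrary units)
_PRECURSOR_SCALE = 1.0e6
_FRAGMENT_SCALE = 1.0e4


@dataclass(frozen=True)
class ConformerComponent:
    """One CDS conformer subpopulation and its zinc-binding stoichiometry."""

    center: float
    sigma: float
    weight: float
    zinc_profile: tuple[float, ...]  # fraction at n = 0, 1, 2, ... zincs


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment (seed mandatory)."""

    seed: int
    sequence: ProteinSequence = field(default_factory=alpha_synuclein)
    conformers: tuple[ConformerComponent, ...] = ()
    analyzed_conformer: int = 0
    covered_sites: tuple[int, ...] = ()
    apo_fy: dict[int, float] = field(default_factory=dict)
    holo_fy: dict[int, float] = field(default_factory=dict)
    holo_sites: dict[str, tuple[int, ...]] = field(default_factory=dict)
    holo_fraction: float = 0.5
    fragment_zinc_count: int = 1
    n_scans: int = 20
    n_replicates: int = 3
    detection_prob: float = 0.9
    noise_sigma: float = 0.2
    precursor_noise_sigma: float = 0.05
    charge_range: tuple[int, int] = (4, 16)
    max_zinc: int = 3
    adduct: AdductConvention = ZN_MINUS_2H
    with_envelopes: bool = False
    envelope_noise: float = 0.02

    def validate(self) -> None:
        problems = []
        L = self.sequence.length
        if self.seed is None:
            problems.append("seed is mandatory")
        if self.conformers:
            w = sum(c.weight for c in self.conformers)
            if abs(w - 1.0) > 1e-9:
                problems.append(f"conformer weights sum to {w}, expected 1")
            for c in self.conformers:
                if abs(sum(c.zinc_profile) - 1.0) > 1e-9:
                    problems.append(f"zinc profile of component at {c.center} does not sum to 1")
        if not 0 <= self.detection_prob <= 1:
            problems.append("detection_prob must be in [0,1]")
        bad_sites = [s for s in self.covered_sites if not 1 <= s <= L - 1]
        if bad_sites:
            problems.append(f"covered_sites outside [1,{L - 1}]: {bad_sites[:5]}")
        for term, sites in self.holo_sites.items():
            if term not in ("N", "C"):
                problems.append(f"holo terminus {term!r} not in N/C")
            off = sorted(set(sites) - set(self.covered_sites))
            if off:
                problems.append(f"holo sites not covered ({term}): {off[:5]}")
        off = sorted(set(self.apo_fy) - set(self.covered_sites))
        if off:
            problems.append(f"apo_fy sites not covered: {off[:5]}")
        if self.fragment_zinc_count > self.max_zinc:
            problems.append("fragment_zinc_count exceeds max_zinc")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """What the generator planted, on the scales the pipeline reports."""

    apo_fy: dict[int, float]
    holo_fy: dict[int, float]
    delta_fy: dict[int, float]
    significant_sites: tuple[int, ...]
    covered_sites: tuple[int, ...]
    holo_sites: dict[str, tuple[int, ...]]
    holo_counts: dict[str, int]
    cds_components: tuple[tuple[float, float, float], ...]  # (center, sigma, weight)
    zinc_profile: tuple[float, ...]
    coverage_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    ground_truth: GroundTruth
    precursor: dict[str, pd.DataFrame]  # condition -> (mz, intensity)
    features: dict[tuple[str, int], pd.DataFrame]  # (condition, replicate) -> per-scan rows


def _true_species_table(config: SimulationConfig, condition: str) -> pd.DataFrame:
    """True per-species intensities for one condition.

    Each covered site carries the photodissociation-typical a/a+1/a+2/x/x+1
    ions splitting the site's FY budget 30/25/10/20/15 and b and y ions splitting the
    remaining 'other-series' budget evenly over covered sites, so the planted
    per-site FY is exact by construction. In the zinc condition, species at
    planted holo sites split into an apo and a zinc-retaining part.
    """
    fy = config.apo_fy if condition == "apo" else config.holo_fy
    sites = list(config.covered_sites)
    total_fy = sum(fy.values())
    if total_fy >= 100.0:
        raise ValueError(f"planted FY sums to {total_fy} >= 100")
    other = (100.0 - total_fy) / len(sites)

    seq = config.sequence
    holo_n = {"N": set(), "C": set()}
    if condition != "apo":
        holo_n = {t: set(s) for t, s in config.holo_sites.items()}
        holo_n.setdefault("N", set())
        holo_n.setdefault("C", set())

    rows = []

    def add(series: str, site: int, zinc: int, inten: float) -> None:
        if inten <= 0:
            return
        mass = fragment_neutral_mass(seq, series, site, zinc, config.adduct)
        rows.append((series, site, zinc, mass, inten * _FRAGMENT_SCALE))

    hf = config.holo_fraction
    nz = config.fragment_zinc_count
    n_split = {"a": 0.30, "a+1": 0.25, "a+2": 0.10}
    c_split = {"x": 0.20, "x+1": 0.15}
    for site in sites:
        f = fy.get(site, 0.0)
        for ser, w in n_split.items():
            if site in holo_n["N"]:
                add(ser, site, 0, w * f * (1 - hf))
                add(ser, site, nz, w * f * hf)
            else:
                add(ser, site, 0, w * f)
        for ser, w in c_split.items():
            if site in holo_n["C"]:
                add(ser, site, 0, w * f * (1 - hf))
                add(ser, site, nz, w * f * hf)
            else:
                add(ser, site, 0, w * f)
        add("b", site, 0, 0.5 * other)
        add("y", site, 0, 0.5 * other)
    return pd.DataFrame(rows, columns=["series", "site", "zinc_count", "mass", "intensity"])


def _envelope_for(config: SimulationConfig, series: str, site: int, zinc: int,
                  cache: dict) -> np.ndarray:
    key = (series, site, zinc)
    if key not in cache:
        comp = species_composition(
            config.sequence, FragmentSpecies(series, site, zinc, 0.0), config.adduct
        )
        pat = isotope_distribution(comp)
        cache[key] = np.column_stack([pat.masses, pat.abundances])
    return cache[key]


def _simulate_scans(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-scan feature rows for one replicate of one condition."""
    n_sp = len(truth)
    sigma = config.noise_sigma
    env_cache: dict = {}
    out = []
    masses = truth["mass"].to_numpy()
    base = truth["intensity"].to_numpy()
    charges = 1 + (masses // 1500.0).astype(int)
    for scan in range(1, config.n_scans + 1):
        detected = rng.random(n_sp) < config.detection_prob
        if sigma > 0:
            noise = np.exp(sigma * rng.standard_normal(n_sp) - 0.5 * sigma**2)
        else:
            noise = np.ones(n_sp)
        inten = base * noise
        for i in np.flatnonzero(detected):
            row = truth.iloc[i]
            env = None
            if config.with_envelopes:
                pat = _envelope_for(config, row["series"], int(row["site"]),
                                    int(row["zinc_count"]), env_cache)
                jitter = 1.0 + config.envelope_noise * rng.standard_normal(len(pat))
                env = [
                    (float(m), float(max(ab * inten[i] * j, 0.0)))
                    for (m, ab), j in zip(pat, jitter)
                ]
            out.append((scan, masses[i], int(charges[i]), inten[i], env))
    df = pd.DataFrame(out, columns=["scan", "mass", "charge", "intensity", "envelope"])
    if not config.with_envelopes:
        df = df.drop(columns=["envelope"])
    return df


def _simulate_precursor(
    config: SimulationConfig, condition: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Centroided precursor peak table (m/z, intensity) for one condition."""
    M = config.sequence.neutral_mass()
    dzn = config.adduct.delta_mass()
    z_lo, z_hi = config.charge_range
    rows = []
    for z in range(z_lo, z_hi + 1):
        for n in range(config.max_zinc + 1):
            inten = 0.0
            for c in config.conformers:
                zp = c.zinc_profile[n] if n < len(c.zinc_profile) else 0.0
                if condition == "apo":
                    zp = 1.0 if n == 0 else 0.0
                inten += c.weight * np.exp(-((z - c.center) ** 2) / (2 * c.sigma**2)) * zp
            if inten <= 1e-12:
                continue
            if config.precursor_noise_sigma > 0:
                s = config.precursor_noise_sigma
                inten *= np.exp(s * rng.standard_normal() - 0.5 * s**2)
            mz = (M + n * dzn + z * PROTON_MASS) / z
            rows.append((mz, inten * _PRECURSOR_SCALE))
    return pd.DataFrame(rows, columns=["mz", "intensity"]).sort_values("mz").reset_index(drop=True)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one complete two-condition experiment from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    delta = {
        s: config.holo_fy.get(s, 0.0) - config.apo_fy.get(s, 0.0)
        for s in config.covered_sites
    }
    sig = tuple(sorted(s for s, d in delta.items() if abs(d) > 1e-12))
    n_counts = {t: len(set(s)) for t, s in config.holo_sites.items()}
    holo_counts = {
        "Nterm": n_counts.get("N", 0),
        "Cterm": n_counts.get("C", 0),
    }
    holo_counts["Sum"] = holo_counts["Nterm"] + holo_counts["Cterm"]
    truth = GroundTruth(
        apo_fy=dict(config.apo_fy),
        holo_fy=dict(config.holo_fy),
        delta_fy=delta,
        significant_sites=sig,
        covered_sites=tuple(sorted(config.covered_sites)),
        holo_sites={t: tuple(sorted(set(s))) for t, s in config.holo_sites.items()},
        holo_counts=holo_counts,
        cds_components=tuple((c.center, c.sigma, c.weight) for c in config.conformers),
        zinc_profile=config.conformers[config.analyzed_conformer].zinc_profile
        if config.conformers
        else (),
        coverage_pct=round(100.0 * len(set(config.covered_sites)) / config.sequence.length, 2),
    )

    precursor = {
        cond: _simulate_precursor(config, cond, rng) for cond in ("apo", "holo")
    }
    features: dict[tuple[str, int], pd.DataFrame] = {}
    for cond in ("apo", "holo"):
        sp = _true_species_table(config, cond)
        for rep in range(1, config.n_replicates + 1):
            features[(cond, rep)] = _simulate_scans(config, sp, rng)
    return SimulatedExperiment(config, truth, precursor, features)


# ---------------------------------------------------------------------------
# Conformer presets
# ---------------------------------------------------------------------------

# Shared CDS: three conformer subpopulations at 7+/10+/13+ with the
# low-charge conformer binding most zinc (profile peaked at n=3), the
# intermediate conformer binding a single zinc, and the high-charge
# conformer two.
_CDS_COMPONENTS = (
    ConformerComponent(7.0, 1.2, 0.40, (0.10, 0.15, 0.25, 0.50)),
    ConformerComponent(10.0, 1.2, 0.35, (0.45, 0.55, 0.00, 0.00)),
    ConformerComponent(13.0, 1.2, 0.25, (0.20, 0.25, 0.45, 0.10)),
)

# Per-preset design: covered-site count (sets coverage %), significant-site
# counts and planted per-site FY drops per region (percentage points, chosen
# so count-weighted means land on the designed overall change), holo
# (terminus -> (site range, count)) maps, and the dominant fragment zinc
# count. Site realizations are sampled from these ranges per seed.
_PRESETS: dict[str, dict] = {
    "low-charge": dict(
        conformer=0,
        n_covered=119,  # -> 85.00 % coverage of 140 residues
        sig=(("Nterm", (1, 60), 16, 1.81),
             ("NAC", (61, 95), 5, 1.48),
             ("Cterm", ((96, 100), (120, 139)), 4, 1.48)),
        holo={"N": ((120, 139), 6), "C": ((1, 50), 31)},
        fragment_zinc=3,
    ),
    "intermediate": dict(
        conformer=1,
        n_covered=134,  # -> 95.71 %
        sig=(("Nterm", (5, 60), 16, 0.92),
             ("NAC", (61, 95), 6, 1.41),
             ("Cterm", ((96, 100), (120, 139)), 5, 0.46)),
        holo={"N": ((40, 139), 34), "C": ((1, 130), 55)},
        fragment_zinc=1,
    ),
    "high-charge": dict(
        conformer=2,
        n_covered=130,  # -> 92.86 %
        sig=(("Nterm", (20, 60), 20, 0.93),
             ("NAC", (61, 80), 10, 0.98),
             ("Cterm", (96, 139), 3, 0.73)),
        holo={"N": ((40, 139), 40), "C": ((1, 130), 13)},
        fragment_zinc=2,
    ),
}

_BASELINE_FY = 0.15  # percent FY at unperturbed covered sites
_CHANGED_SITE_FLOOR = 0.5  # percent FY remaining at changed sites after binding


def _ranges_to_sites(ranges) -> list[int]:
    if isinstance(ranges[0], int):
        ranges = (ranges,)
    out: list[int] = []
    for lo, hi in ranges:
        out.extend(range(lo, hi + 1))
    return out


def make_conformer_presets(seed: int = 0) -> dict[str, SimulationConfig]:
    """Three named configs mirroring the qualitative conformer designs:

    - ``low-charge``: compact conformer, >=3 zincs, C-terminal electrostatic
      binding mode — N-series holo fragments confined to AA120-140,
      C-series holo fragments to AA1-50, fewest holo fragments.
    - ``intermediate``: single zinc, coordination binding in AA40-80 —
      N-/C-series holo distributions overlapping there, most holo fragments.
    - ``high-charge``: two zincs, mixed mode — broad overlap AA40-130.

    Site realizations are deterministic per (seed, preset).
    """
    seq = alpha_synuclein()
    L = seq.length
    out: dict[str, SimulationConfig] = {}
    for p_idx, name in enumerate(PRESET_NAMES):
        design = _PRESETS[name]
        rng = np.random.default_rng([p_idx, seed])
        covered = np.sort(
            rng.choice(np.arange(1, L), size=design["n_covered"], replace=False)
        )
        covered_set = set(int(s) for s in covered)

        apo_fy: dict[int, float] = {int(s): _BASELINE_FY for s in covered}
        holo_fy = dict(apo_fy)
        for _region, ranges, count, drop in design["sig"]:
            pool = sorted(set(_ranges_to_sites(ranges)) & covered_set
                          - set(s for s in apo_fy if apo_fy[s] != _BASELINE_FY))
            take = rng.choice(pool, size=min(count, len(pool)), replace=False)
            for s in take:
                s = int(s)
                apo_fy[s] = drop + _CHANGED_SITE_FLOOR
                holo_fy[s] = _CHANGED_SITE_FLOOR

        holo_sites: dict[str, tuple[int, ...]] = {}
        for term, (ranges, count) in design["holo"].items():
            pool = sorted(set(_ranges_to_sites(ranges)) & covered_set)
            take = rng.choice(pool, size=min(count, len(pool)), replace=False)
            holo_sites[term] = tuple(int(s) for s in np.sort(take))

        out[name] = SimulationConfig(
            seed=int(np.random.default_rng([p_idx, seed, 7]).integers(2**31)),
            sequence=seq,
            conformers=_CDS_COMPONENTS,
            analyzed_conformer=design["conformer"],
            covered_sites=tuple(int(s) for s in covered),
            apo_fy=apo_fy,
            holo_fy=holo_fy,
            holo_sites=holo_sites,
            fragment_zinc_count=design["fragment_zinc"],
        )
    return out
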