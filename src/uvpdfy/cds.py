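"""Charge-state-distribution (CDS) extraction and Gaussian-mixture conformer
assignment.

In native MS the charge an electrosprayed protein takes reports on how
extended its conformation is: compact conformers charge low, extended ones
high. A multimodal CDS therefore indicates coexisting conformer
subpopulations. ``extract_charge_profile`` reads per-(charge, zinc-count)
intensities of the intact monomer out of a centroided precursor peak table;
``ChargeStateMixtureModel`` fits a k-component Gaussian mixture (default
k = 3, initialized at charges 7, 10 and 13 for α-synuclein) to the
per-charge totals and reports conformer subpopulation fractions and
per-charge zinc-stoichiometry profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .chem import PROTON_MASS
from .sequence import AdductConvention, ZN_MINUS_2H

__all__ = [
    "GaussianComponent",
    "extract_charge_profile",
    "ChargeStateMixtureModel",
    "ChargeStateMixtureResults",
    "conformer_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaussianComponent:
    """One CDS mixture component: height A, center mu (charge units), width sigma."""

    center: float
    sigma: float
    amplitude: float

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)


def extract_charge_profile(
    peaks: np.ndarray | list[tuple[float, float]],
    monomer_mass: float,
    charge_range: tuple[int, int] = (4, 16),
    max_zinc: int = 3,
    adduct: AdductConvention = ZN_MINUS_2H,
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Sum centroided precursor intensities into a (charge, zinc_count) table.

    Expected m/z of the intact monomer with n zincs at charge z is
    ``(M + n*dZn + z*m_proton) / z``. Each peak is assigned to the nearest
    expected position within ``tol_ppm``; an exact midway tie goes to the
    lower zinc count (then lower charge).
    """
    if monomer_mass <= 0:
        raise ValueError("monomer_mass must be positive")
    arr = np.asarray(peaks, dtype=float).reshape(-1, 2)
    z_lo, z_hi = charge_range
    grid = [
        (z, n, (monomer_mass + n * adduct.delta_mass() + z * PROTON_MASS) / z)
        for z in range(z_lo, z_hi + 1)
        for n in range(max_zinc + 1)
    ]
    index = pd.MultiIndex.from_product(
        [range(z_lo, z_hi + 1), range(max_zinc + 1)], names=["charge", "zinc_count"]
    )
    profile = pd.Series(0.0, index=index, name="intensity")
    if len(arr) == 0:
        log.warning("empty peak list; returning all-zero charge profile")
        return profile.reset_index()

    # nearest expected position wins; distances within 1e-6 m/z count as a
    # tie and resolve deterministically to lower zinc count, then lower charge
    positions = np.array([g[2] for g in grid])
    for mz, inten in arr:
        d = np.abs(positions - mz)
        near = np.flatnonzero(d <= d.min() + 1e-6)
        best = min(near, key=lambda i: (grid[i][1], grid[i][0]))
        if d[best] <= tol_ppm * 1e-6 * positions[best]:
            z, n, _ = grid[best]
            profile.loc[(z, n)] += inten
    return profile.reset_index()


def _mixture(params: Parameters, z: np.ndarray, k: int) -> np.ndarray:
    y = np.zeros_like(z, dtype=float)
    for i in range(k):
        a = params[f"a{i}"].value
        mu = params[f"mu{i}"].value
        s = params[f"s{i}"].value
        y = y + a * np.exp(-((z - mu) ** 2) / (2.0 * s**2))
    return y


class ChargeStateMixtureModel:
    """Gaussian-mixture model of a charge-state distribution.

    Parameters
    ----------
    profile : DataFrame with columns charge, zinc_count, intensity
        Output of :func:`extract_charge_profile`. The fit uses the per-charge
        totals (apo + holo summed), matching how whole CDSs are decomposed.
    k : number of conformer components (default 3).
    init_centers : initial component centers in charge units (default 7/10/13).
    """

    def __init__(
        self,
        profile: pd.DataFrame,
        k: int = 3,
        init_centers: tuple[float, ...] = (7.0, 10.0, 13.0),
        sigma_bounds: tuple[float, float] = (0.3, 5.0),
        init_sigma: float = 1.5,
    ):
        if k < 1:
            raise ValueError("k must be >= 1")
        if len(init_centers) != k:
            raise ValueError("init_centers length must equal k")
        self.profile = profile
        self.k = k
        self.init_centers = tuple(float(c) for c in init_centers)
        self.sigma_bounds = sigma_bounds
        self.init_sigma = init_sigma

        totals = profile.groupby("charge")["intensity"].sum()
        nonzero = totals[totals > 0]
        if len(nonzero) < 2 * k:
            raise ValueError(
                f"need intensity at >= {2 * k} distinct charges, have {len(nonzero)}"
            )
        self.charges = totals.index.to_numpy(dtype=float)
        self.intensities = totals.to_numpy(dtype=float)

    def fit(self) -> "ChargeStateMixtureResults":
        z, y = self.charges, self.intensities
        params = Parameters()
        s_lo, s_hi = self.sigma_bounds
        for i, mu0 in enumerate(self.init_centers):
            j = int(np.argmin(np.abs(z - mu0)))
            a0 = max(y[j], 1e-3 * y.max())
            params.add(f"a{i}", value=a0, min=0.0)
            params.add(f"mu{i}", value=mu0, min=z.min(), max=z.max())
            params.add(f"s{i}", value=self.init_sigma, min=s_lo, max=s_hi)

        def residual(p):
            return _mixture(p, z, self.k) - y

        res = minimize(residual, params, method="leastsq")
        comps = sorted(
            (
                GaussianComponent(
                    center=res.params[f"mu{i}"].value,
                    sigma=res.params[f"s{i}"].value,
                    amplitude=res.params[f"a{i}"].value,
                )
                for i in range(self.k)
            ),
            key=lambda c: c.center,
        )
        converged = bool(res.success)
        if not converged:
            log.warning("CDS mixture fit did not converge: %s", res.message)
        return ChargeStateMixtureResults(
            model=self,
            components=comps,
            converged=converged,
            residual_norm=float(np.linalg.norm(residual(res.params))),
        )


@dataclass
class ChargeStateMixtureResults:
    """Fitted CDS mixture: components sorted by center, plus diagnostics."""

    model: ChargeStateMixtureModel
    components: list[GaussianComponent]
    converged: bool
    residual_norm: float

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.components])

    @property
    def fractions(self) -> np.ndarray:
        """Subpopulation fractions: component areas normalized to 1."""
        areas = np.array([c.area for c in self.components])
        return areas / areas.sum()

    def zinc_profile(self, charge: int) -> np.ndarray:
        """Zinc-stoichiometry profile at one charge: intensity over
        zinc_count normalized to its own sum."""
        prof = self.model.profile
        sub = prof[prof["charge"] == charge].sort_values("zinc_count")
        if sub.empty:
            raise ValueError(f"charge {charge} absent from profile")
        v = sub["intensity"].to_numpy(dtype=float)
        total = v.sum()
        return v / total if total > 0 else v

    def predict(self, charges: np.ndarray | None = None) -> np.ndarray:
        z = np.asarray(charges, float) if charges is not None else self.model.charges
        y = np.zeros_like(z, dtype=float)
        for c in self.components:
            y += c.amplitude * np.exp(-((z - c.center) ** 2) / (2 * c.sigma**2))
        return y

    def summary(self) -> str:
        lines = [
            "Charge-state distribution Gaussian mixture",
            f"  components: {len(self.components)}   converged: {self.converged}"
            f"   residual norm: {self.residual_norm:.4g}",
            f"  {'center':>8} {'sigma':>8} {'amplitude':>12} {'fraction':>9}",
        ]
        for c, f in zip(self.components, self.fractions):
            lines.append(
                f"  {c.center:8.3f} {c.sigma:8.3f} {c.amplitude:12.4g} {f:9.4f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar CDS with the fitted mixture overlaid (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z, y = self.model.charges, self.model.intensities
        ax.bar(z, y, width=0.6, color="0.8", label="observed CDS")
        zz = np.linspace(z.min(), z.max(), 300)
        ax.plot(zz, self.predict(zz), "k-", label="mixture fit")
        for c in self.components:
            ax.plot(zz, c.amplitude * np.exp(-((zz - c.center) ** 2) / (2 * c.sigma**2)),
                    "--", lw=1)
        ax.set_xlabel("charge state")
        ax.set_ylabel("intensity")
        ax.legend()
        return ax


def conformer_summary(
    results: ChargeStateMixtureResults,
    charges: tuple[int, ...] = (7, 10, 13),
) -> dict:
    """Subpopulation fractions plus zinc-stoichiometry profiles at the
    requested charges (defaults: the three conformer apexes)."""
    return {
        "fractions": results.fractions.tolist(),
        "centers": results.centers.tolist(),
        "zinc_profiles": {int(z): results.zinc_profile(z).tolist() for z in charges},
    }
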