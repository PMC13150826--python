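"""Theoretical isotope distributions and envelope correlation scoring.

The distribution of a composition is computed by per-element convolution of
single-atom isotope distributions, aggregated by nominal mass shift (number of
extra neutrons relative to the monoisotopic peak). This coarse-grained
"profile" pattern is what 50k-resolution fragment spectra resolve; isotope
fine structure is deliberately not modelled. Per-bin masses are
abundance-weighted expectations, so peak spacings come out near the average
neutron mass increment rather than exactly 1 Da.

Observed envelopes are scored against the theoretical pattern with a Pearson
correlation over peaks aligned by nearest mass; ions whose envelope correlates
above a threshold (0.7 in the reference workflow) are treated as reliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import Composition, ISOTOPES, MONO_MASS

__all__ = ["IsotopePattern", "EnvelopeScore", "isotope_distribution", "envelope_correlation"]


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotope pattern: strictly increasing masses, abundances
    normalized to sum to 1."""

    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        if len(self.masses) != len(self.abundances):
            raise ValueError("masses and abundances must align")
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")

    def __len__(self) -> int:
        return len(self.masses)


@dataclass(frozen=True)
class EnvelopeScore:
    """Pearson r between theoretical and observed envelope; ``defined`` is
    False when fewer than two peak pairs align or a vector has zero variance,
    in which case the ion cannot be called reliable."""

    r: float
    n_peaks: int
    defined: bool

    def reliable(self, r_min: float = 0.7) -> bool:
        return self.defined and self.r > r_min


def _single_atom(symbol: str) -> tuple[np.ndarray, np.ndarray]:
    """(abundance, weighted-mass) arrays indexed by nominal neutron shift."""
    rows = ISOTOPES[symbol]
    mono = MONO_MASS[symbol]
    base = min(m for m, _ in rows)
    size = max(int(round(m - base)) for m, _ in rows) + 1
    p = np.zeros(size)
    w = np.zeros(size)
    for m, ab in rows:
        k = int(round(m - base))
        p[k] += ab
        w[k] += ab * m
    # re-anchor so that index 0 is the most abundant (monoisotopic) isotope
    k0 = int(round(mono - base))
    if k0 != 0:
        # elements like Zn: monoisotopic != lightest never happens for the
        # shipped table (mono is most abundant = lightest for H/C/N/O/S/Zn)
        p = np.roll(p, -k0)
        w = np.roll(w, -k0)
    return p, w


def _convolve(pa, wa, pb, wb) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two (abundance, abundance-weighted-mass) bin representations."""
    p = np.convolve(pa, pb)
    # E[mass] of a sum splits: w_new[k] = sum_{i+j=k} (wa_i*pb_j + pa_i*wb_j)
    w = np.convolve(wa, pb) + np.convolve(pa, wb)
    return p, w


def _element_power(symbol: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """n-atom distribution by binary exponentiation of the single-atom one."""
    p1, w1 = _single_atom(symbol)
    p, w = np.array([1.0]), np.array([0.0])
    base_p, base_w = p1, w1
    k = n
    while k:
        if k & 1:
            p, w = _convolve(p, w, base_p, base_w)
        k >>= 1
        if k:
            base_p, base_w = _convolve(base_p, base_w, base_p, base_w)
    return p, w


def isotope_distribution(
    composition: Composition, prune_threshold: float = 0.01
) -> IsotopePattern:
    """Aggregated (nominal-mass-binned) isotope pattern of a composition.

    Peaks below ``prune_threshold`` x the base-peak abundance are dropped and
    the pattern renormalized; the base peak itself is never pruned.
    """
    comp = {el: n for el, n in composition.items() if n != 0}
    if not comp:
        raise ValueError("empty composition")
    if not 0 <= prune_threshold < 1:
        raise ValueError("prune_threshold must be in [0, 1)")
    for el, n in comp.items():
        if el not in ISOTOPES:
            raise KeyError(f"unknown element {el!r}")
        if n < 0:
            raise ValueError(f"negative count for {el!r}; reduce the composition first")

    p, w = np.array([1.0]), np.array([0.0])
    for el, n in sorted(comp.items()):
        pe, we = _element_power(el, n)
        p, w = _convolve(p, w, pe, we)

    # numerical floor: probabilities below ~1e-45 of the base peak are at the
    # edge of double-precision underflow and their weighted masses are
    # unreliable; any real isotopologue of interest sits far above this
    keep = p > 0
    masses = np.where(keep, np.divide(w, p, out=np.zeros_like(w), where=keep), 0.0)
    base = int(np.argmax(p))
    keep &= p >= max(prune_threshold, 1e-45) * p[base]
    keep[base] = True
    p, masses = p[keep], masses[keep]
    p = p / p.sum()
    return IsotopePattern(masses=masses, abundances=p)


def envelope_correlation(
    theoretical: IsotopePattern,
    observed: list[tuple[float, float]] | np.ndarray,
    match_tol: float = 0.02,
) -> EnvelopeScore:
    """Pearson r between a theoretical pattern and observed (mass, intensity)
    peaks.

    Observed peaks are aligned to the nearest theoretical peak within
    ``match_tol`` Da (intensities of multiple hits on one theoretical peak are
    summed); theoretical peaks with no observed partner pair with intensity 0.
    Undefined scores (fewer than two pairs, or zero variance on either side)
    are flagged rather than raised — downstream they simply fail the
    reliability threshold.
    """
    obs = np.asarray(observed, dtype=float).reshape(-1, 2)
    paired = np.zeros(len(theoretical))
    matched_any = False
    for m, inten in obs:
        k = int(np.argmin(np.abs(theoretical.masses - m)))
        if abs(theoretical.masses[k] - m) <= match_tol:
            paired[k] += inten
            matched_any = True
    n = len(theoretical)
    if n < 2 or not matched_any:
        return EnvelopeScore(np.nan, n, False)
    t = theoretical.abundances
    if np.ptp(t) == 0 or np.ptp(paired) == 0:
        return EnvelopeScore(np.nan, n, False)
    r = float(np.corrcoef(t, paired)[0, 1])
    return EnvelopeScore(r, n, True)
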