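"""Matching deconvoluted fragment masses to the theoretical database and
aggregating per-scan matches into reliable fragment evidence.

The matcher mirrors a standard top-down search: each deconvoluted neutral
mass is compared against every database species within a two-sided relative
mass tolerance (default 2 ppm of the theoretical mass). Ambiguous hits are
resolved deterministically — smallest relative error first, then higher
isotope-envelope correlation, then base series before satellites, then lower
zinc count — replacing the manual inspection of overlapping monoisotopic
peaks used in interactive workflows.

Evidence aggregation applies the reliability filters: a species must be seen
in at least ``min_scans`` of the ``n_scans_total`` scans of a replicate
(16 of 20 by default) and, when envelopes are available, its mean envelope
correlation must exceed ``r_min`` (0.7 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotope import envelope_correlation, isotope_distribution
from .sequence import (
    FragmentDatabase,
    FragmentSpecies,
    SERIES_PRIORITY,
    species_composition,
)

__all__ = [
    "DeconvolutedFeature",
    "FragmentMatch",
    "match_scan",
    "resolve_ambiguity",
    "aggregate_evidence",
]

log = logging.getLogger(__name__)

_PRIORITY = {name: i for i, name in enumerate(SERIES_PRIORITY)}


@dataclass
class DeconvolutedFeature:
    """One deconvoluted fragment observation in one scan (neutral mass)."""

    scan_id: int
    mass: float
    charge: int
    intensity: float
    envelope: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class FragmentMatch:
    feature: DeconvolutedFeature
    species: FragmentSpecies
    relative_error: float  # (observed - theoretical) / theoretical
    r: float | None = None  # envelope correlation, None when no envelope
    rejected: list[FragmentSpecies] = field(default_factory=list)


class _PatternCache:
    """Memoized theoretical isotope patterns per database species index."""

    def __init__(self, db: FragmentDatabase):
        self.db = db
        self._cache: dict[int, object] = {}

    def __call__(self, idx: int):
        if idx not in self._cache:
            comp = species_composition(
                self.db.sequence, self.db.species[idx], self.db.adduct
            )
            self._cache[idx] = isotope_distribution(comp)
        return self._cache[idx]


def resolve_ambiguity(
    candidates: list[tuple[int, float, float | None]],
    db: FragmentDatabase,
) -> tuple[int, float, float | None, list[int]]:
    """Pick one assignment from ``(species_idx, relative_error, r)`` candidates.

    Order: |relative error| ascending, envelope r descending (None sorts
    last), base series before satellites (fixed priority list), lower zinc
    count. Returns the winner plus the rejected indices.
    """
    if not candidates:
        raise ValueError("no candidates")

    def key(c):
        idx, err, r = c
        sp = db.species[idx]
        r_key = -r if r is not None else np.inf
        return (abs(err), r_key, _PRIORITY[sp.series], sp.zinc_count, sp.site)

    ranked = sorted(candidates, key=key)
    winner = ranked[0]
    return winner[0], winner[1], winner[2], [c[0] for c in ranked[1:]]


def match_scan(
    db: FragmentDatabase,
    features: list[DeconvolutedFeature],
    tol: float = 2e-6,
) -> list[FragmentMatch]:
    """Match features of one scan against the database.

    Each feature is paired with every species within the relative tolerance,
    then reduced to a single assignment; features with no candidate are
    dropped (an unmatched mass is a normal outcome, not an error).

    Envelope correlations are computed only where needed: to break ties among
    equal-error candidates and, finally, for the winning assignment of any
    feature that carries an envelope.
    """
    if not features:
        return []
    patterns = _PatternCache(db)
    masses = np.array([f.mass for f in features])
    lo, hi = db.query_many(masses, tol)

    out: list[FragmentMatch] = []
    for f, i0, i1 in zip(features, lo, hi):
        if i1 <= i0:
            continue
        idxs = range(int(i0), int(i1))
        errs = [(f.mass - db.masses[i]) / db.masses[i] for i in idxs]
        cands: list[tuple[int, float, float | None]] = [
            (i, e, None) for i, e in zip(idxs, errs)
        ]
        if f.envelope is not None and len(cands) > 1:
            # r only matters among near-ties on |error|
            best = min(abs(e) for _, e, _ in cands)
            cands = [
                (i, e, envelope_correlation(patterns(i), f.envelope).r
                 if abs(e) - best < 1e-9 else None)
                for i, e, _ in cands
            ]
        idx, err, r, rejected = resolve_ambiguity(cands, db)
        if f.envelope is not None and r is None:
            score = envelope_correlation(patterns(idx), f.envelope)
            r = score.r if score.defined else np.nan
        out.append(
            FragmentMatch(f, db.species[idx], err, r,
                          [db.species[i] for i in rejected])
        )
    return out


def aggregate_evidence(
    scan_matches: list[FragmentMatch],
    n_scans_total: int = 20,
    min_scans: int = 16,
    r_min: float = 0.7,
) -> pd.DataFrame:
    """Aggregate the matches of one replicate into fragment evidence.

    Charge states of one fragment in one scan are one chemical species, so
    per-scan species intensity is the sum over its features; the intensity
    summary across scans is the median over detected scans (robust to
    per-scan fluctuations).

    Returns a DataFrame indexed by (series, site, zinc_count) with columns
    ``terminus, mass, n_scans, median_intensity, mean_r, kept``. ``kept``
    requires ``n_scans >= min_scans`` and — when any envelope was scored for
    the species — ``mean_r > r_min``; species entirely without envelopes skip
    the correlation filter with a logged warning.
    """
    if n_scans_total <= 0:
        raise ValueError("n_scans_total must be positive")
    if not scan_matches:
        return pd.DataFrame(
            columns=["terminus", "mass", "n_scans", "median_intensity", "mean_r", "kept"]
        )

    rows = []
    for m in scan_matches:
        rows.append(
            (
                m.species.series,
                m.species.site,
                m.species.zinc_count,
                m.species.terminus,
                m.species.mass,
                m.feature.scan_id,
                m.feature.intensity,
                m.r if m.r is not None else np.nan,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["series", "site", "zinc_count", "terminus", "mass", "scan_id", "intensity", "r"],
    )
    per_scan = (
        df.groupby(["series", "site", "zinc_count", "terminus", "mass", "scan_id"])
        .agg(intensity=("intensity", "sum"), r=("r", "mean"))
        .reset_index()
    )
    ev = (
        per_scan.groupby(["series", "site", "zinc_count"])
        .agg(
            terminus=("terminus", "first"),
            mass=("mass", "first"),
            n_scans=("scan_id", "nunique"),
            median_intensity=("intensity", "median"),
            mean_r=("r", "mean"),
        )
    )
    no_envelope = ev["mean_r"].isna()
    if no_envelope.any() and not no_envelope.all():
        log.warning(
            "%d of %d species have no envelope; correlation filter skipped for them",
            int(no_envelope.sum()), len(ev),
        )
    elif no_envelope.all():
        log.warning("no envelopes present; correlation filter skipped entirely")
    r_ok = ev["mean_r"].gt(r_min) | no_envelope
    ev["kept"] = (ev["n_scans"] >= min_scans) & r_ok
    return ev
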