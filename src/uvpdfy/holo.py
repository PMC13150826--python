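"""Zinc-retaining (holo) fragment identification and site-distribution
analysis.

A holo fragment is one that kept its Zn2+ adduct through photodissociation.
All twelve ion series participate here (unlike the FY calculation). Holo
fragments from the same terminus at the same cleavage site are the same
holo fragment: the set collapses to unique (terminus, site) pairs, with
intensities pooled. Counting those pairs per terminus gives the
N-terminal / C-terminal / total holo counts used to compare conformers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["identify_holo", "holo_site_profile", "terminus_counts"]


def identify_holo(evidence: pd.DataFrame) -> pd.DataFrame:
    """Collapse kept holo species (zinc_count >= 1, any series) to unique
    (terminus, site) pairs.

    Returns a DataFrame indexed by (terminus, site) with ``intensity``
    (summed within the pair) and ``species`` (contributing series names).
    Idempotent: re-identifying the output's underlying species changes
    nothing.
    """
    if len(evidence) == 0:
        return pd.DataFrame(columns=["intensity", "species"])
    ev = evidence[evidence["kept"]] if "kept" in evidence.columns else evidence
    holo = ev[ev.index.get_level_values("zinc_count") >= 1]
    if len(holo) == 0:
        return pd.DataFrame(columns=["intensity", "species"])
    df = holo.reset_index()
    out = df.groupby(["terminus", "site"]).agg(
        intensity=("median_intensity", "sum"),
        species=("series", lambda s: sorted(set(s))),
    )
    return out


def holo_site_profile(evidence: pd.DataFrame) -> pd.DataFrame:
    """Per-(terminus, site) holo/apo intensity ratio.

    Denominators pool the apo (zinc_count = 0) species of the same terminus
    and site over series, mirroring the holo pooling rule. Sites where apo
    is zero but holo is present are flagged infinite; sites with neither are
    absent from the output.
    """
    if len(evidence) == 0:
        return pd.DataFrame(columns=["holo", "apo", "ratio", "infinite"])
    ev = evidence[evidence["kept"]] if "kept" in evidence.columns else evidence
    df = ev.reset_index()
    df["kind"] = np.where(df["zinc_count"] >= 1, "holo", "apo")
    pooled = (
        df.pivot_table(
            index=["terminus", "site"],
            columns="kind",
            values="median_intensity",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=["holo", "apo"], fill_value=0.0)
    )
    pooled = pooled[(pooled["holo"] > 0) | (pooled["apo"] > 0)]
    with np.errstate(divide="ignore"):
        pooled["ratio"] = np.where(
            pooled["apo"] > 0, pooled["holo"] / pooled["apo"], np.inf
        )
    pooled["infinite"] = (pooled["apo"] == 0) & (pooled["holo"] > 0)
    pooled.columns.name = None
    return pooled


def terminus_counts(holo_set: pd.DataFrame) -> dict[str, int]:
    """Unique (terminus, site) pair counts: N-terminal, C-terminal, and sum."""
    if len(holo_set) == 0:
        return {"Nterm": 0, "Cterm": 0, "Sum": 0}
    termini = holo_set.index.get_level_values("terminus")
    n = int((termini == "N").sum())
    c = int((termini == "C").sum())
    return {"Nterm": n, "Cterm": c, "Sum": n + c}
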