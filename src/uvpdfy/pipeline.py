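"""End-to-end orchestration: deconvoluted fragment lists + precursor peaks in,
evidence / FY / ΔFY / holo / CDS reports out.

:func:`analyze_experiment` is the in-memory engine; :func:`run_pipeline`
wraps it with file IO, a parameter manifest and TSV/JSON report writing.
Every threshold that affects results is carried in :class:`PipelineParams`
with the reference-workflow defaults (2 ppm matching, envelope r > 0.7,
16-of-20 scan filter, P <= 0.001, three CDS components).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cds import ChargeStateMixtureModel, conformer_summary, extract_charge_profile
from .fy import FragmentYieldModel, median_normalize, sequence_coverage
from .holo import holo_site_profile, identify_holo, terminus_counts
from .io import (
    features_from_frame,
    read_feature_tsv,
    read_msalign,
    read_peak_tsv,
)
from .matching import aggregate_evidence, match_scan
from .sequence import (
    ALL_SERIES,
    AdductConvention,
    ProteinSequence,
    RegionScheme,
    ZN_BARE,
    ZN_MINUS_2H,
    alpha_synuclein,
    build_fragment_database,
)

__all__ = ["PipelineParams", "PipelineConfig", "AnalysisResults", "analyze_experiment", "run_pipeline"]

log = logging.getLogger(__name__)

_ADDUCTS = {"Zn-2H": ZN_MINUS_2H, "Zn": ZN_BARE}


@dataclass
class PipelineParams:
    tol: float = 2e-6
    r_min: float = 0.7
    n_scans: int = 20
    min_scans: int = 16
    alpha: float = 0.001
    t_test: str = "pooled"
    k: int = 3
    init_centers: tuple[float, ...] = (7.0, 10.0, 13.0)
    max_zinc: int = 3
    adduct: str = "Zn-2H"
    charge_range: tuple[int, int] = (4, 16)
    cds_tol_ppm: float = 10.0
    summary_charges: tuple[int, ...] = (7, 10, 13)

    def adduct_convention(self) -> AdductConvention:
        return _ADDUCTS[self.adduct]


@dataclass
class PipelineConfig:
    """File-level pipeline configuration (JSON-serializable)."""

    apo_features: list[str]
    holo_features: list[str]
    out_dir: str
    precursor_apo: str | None = None
    precursor_holo: str | None = None
    sequence_path: str | None = None  # None -> bundled P37840
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        params = PipelineParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("params", {}).items()
        })
        return cls(params=params, **raw)


@dataclass
class AnalysisResults:
    """Everything one experiment's analysis produced."""

    evidence: dict  # (condition, replicate) -> evidence DataFrame
    pooled: dict  # condition -> replicate-union evidence DataFrame
    coverage: dict  # condition -> percent
    n_fragments: dict  # condition -> distinct kept species count
    fy_results: object  # FragmentYieldResults
    holo_set: pd.DataFrame
    holo_counts: dict
    holo_profile: pd.DataFrame
    cds: dict  # condition -> ChargeStateMixtureResults (may be empty)
    conformers: dict  # condition -> conformer_summary dict

    def region_summary(self) -> dict:
        return self.fy_results.region_summary()


def _pool_replicates(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of kept species across replicates; intensity = mean over the
    replicates in which the species was kept. Pooling by union maximizes
    sensitivity, standing in for the manual curation of borderline ions."""
    kept = [f[f["kept"]] for f in frames if len(f)]
    kept = [f for f in kept if len(f)]
    if not kept:
        return pd.DataFrame(columns=["terminus", "mass", "median_intensity", "kept"])
    cat = pd.concat(kept)
    out = cat.groupby(level=["series", "site", "zinc_count"]).agg(
        terminus=("terminus", "first"),
        mass=("mass", "first"),
        median_intensity=("median_intensity", "mean"),
        n_replicates=("median_intensity", "size"),
    )
    out["kept"] = True
    return out


def analyze_experiment(
    features: dict[tuple[str, int], pd.DataFrame],
    precursor: dict[str, pd.DataFrame] | None,
    sequence: ProteinSequence | None = None,
    params: PipelineParams | None = None,
    regions: RegionScheme | None = None,
) -> AnalysisResults:
    """Run matching, filtering, normalization, FY/ΔFY, holo and CDS analysis.

    ``features`` maps (condition, replicate) to per-scan feature frames;
    conditions must be "apo" and "holo".
    """
    params = params or PipelineParams()
    seq = sequence or alpha_synuclein()
    regions = regions or RegionScheme.synuclein_default(seq.length)
    adduct = params.adduct_convention()
    db = build_fragment_database(seq, ALL_SERIES, params.max_zinc, adduct)

    evidence: dict[tuple[str, int], pd.DataFrame] = {}
    for key, frame in features.items():
        t0 = time.perf_counter()
        matches = []
        for _scan, feats in features_from_frame(frame).items():
            matches.extend(match_scan(db, feats, params.tol))
        ev = aggregate_evidence(matches, params.n_scans, params.min_scans, params.r_min)
        evidence[key] = ev
        signed = np.array([m.relative_error for m in matches])
        if len(signed) and abs(np.median(signed)) > 0.5e-6:
            log.warning(
                "%s: median signed mass error %.2e exceeds 0.5 ppm; "
                "a systematic recalibration may be warranted", key, np.median(signed)
            )
        log.info("%s: %d features -> %d species (%d kept) in %.2fs",
                 key, len(frame), len(ev), int(ev["kept"].sum()) if len(ev) else 0,
                 time.perf_counter() - t0)

    # median normalization across all replicates of both conditions
    table = pd.DataFrame({
        key: ev[ev["kept"]]["median_intensity"] for key, ev in evidence.items() if len(ev)
    })
    if table.shape[1]:
        try:
            scaled = median_normalize(table)
        except ValueError as exc:
            log.warning("median normalization skipped: %s", exc)
        else:
            factors = (scaled / table).median(axis=0)
            for key in evidence:
                if key in factors.index and len(evidence[key]):
                    evidence[key] = evidence[key].assign(
                        median_intensity=evidence[key]["median_intensity"] * factors[key]
                    )

    conditions = sorted({c for c, _ in evidence})
    pooled = {
        cond: _pool_replicates([ev for (c, _), ev in evidence.items() if c == cond])
        for cond in conditions
    }
    coverage = {c: sequence_coverage(pooled[c], seq.length) for c in conditions}
    n_fragments = {c: int(len(pooled[c])) for c in conditions}

    fy_model = FragmentYieldModel.from_evidence(
        {r: ev for (c, r), ev in evidence.items() if c == "apo" and len(ev)},
        {r: ev for (c, r), ev in evidence.items() if c == "holo" and len(ev)},
        seq.length,
        regions,
        params.alpha,
        params.t_test,
    )
    fy_results = fy_model.fit()

    holo_set = identify_holo(pooled.get("holo", pd.DataFrame()))
    counts = terminus_counts(holo_set)
    profile = holo_site_profile(pooled.get("holo", pd.DataFrame()))

    cds_results: dict = {}
    conformers: dict = {}
    if precursor:
        M = seq.neutral_mass()
        for cond, peaks in precursor.items():
            prof = extract_charge_profile(
                peaks[["mz", "intensity"]].to_numpy(),
                M,
                params.charge_range,
                params.max_zinc,
                adduct,
                params.cds_tol_ppm,
            )
            res = ChargeStateMixtureModel(prof, params.k, params.init_centers).fit()
            cds_results[cond] = res
            conformers[cond] = conformer_summary(res, params.summary_charges)

    return AnalysisResults(
        evidence=evidence,
        pooled=pooled,
        coverage=coverage,
        n_fragments=n_fragments,
        fy_results=fy_results,
        holo_set=holo_set,
        holo_counts=counts,
        holo_profile=profile,
        cds=cds_results,
        conformers=conformers,
    )


def _read_features(path: str) -> pd.DataFrame:
    if str(path).endswith(".msalign"):
        return read_msalign(path)
    return read_feature_tsv(path)


def _digest(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> AnalysisResults:
    """Execute the full analysis from files and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = (
        ProteinSequence.from_fasta(config.sequence_path)
        if config.sequence_path
        else alpha_synuclein()
    )

    features: dict[tuple[str, int], pd.DataFrame] = {}
    inputs: dict[str, str] = {}
    for cond, paths in (("apo", config.apo_features), ("holo", config.holo_features)):
        for rep, path in enumerate(paths, start=1):
            if not Path(path).exists():
                raise FileNotFoundError(f"{cond} replicate {rep}: {path}")
            features[(cond, rep)] = _read_features(path)
            inputs[f"{cond}_rep{rep}"] = f"{path} sha256:{_digest(path)}"

    precursor: dict[str, pd.DataFrame] = {}
    for cond, path in (("apo", config.precursor_apo), ("holo", config.precursor_holo)):
        if path:
            precursor[cond] = read_peak_tsv(path)
            inputs[f"precursor_{cond}"] = f"{path} sha256:{_digest(path)}"

    results = analyze_experiment(features, precursor or None, seq, config.params)

    # report bundle
    for (cond, rep), ev in results.evidence.items():
        ev.reset_index().to_csv(out / f"evidence_{cond}_rep{rep}.tsv", sep="\t", index=False)
    results.fy_results.model.apo.to_csv(out / "fy_apo.tsv", sep="\t")
    results.fy_results.model.holo.to_csv(out / "fy_holo.tsv", sep="\t")
    results.fy_results.delta.to_csv(out / "delta_fy.tsv", sep="\t")
    (out / "region_summary.json").write_text(
        json.dumps(results.region_summary(), indent=1)
    )
    (out / "coverage.json").write_text(json.dumps(results.coverage, indent=1))
    if len(results.holo_set):
        results.holo_set.reset_index().to_csv(out / "holo_sites.tsv", sep="\t", index=False)
    (out / "holo_counts.json").write_text(json.dumps(results.holo_counts, indent=1))
    if len(results.holo_profile):
        results.holo_profile.reset_index().to_csv(out / "holo_profile.tsv", sep="\t", index=False)
    cds_payload = {
        cond: {
            "components": [
                {"center": c.center, "sigma": c.sigma, "amplitude": c.amplitude}
                for c in res.components
            ],
            "fractions": res.fractions.tolist(),
            "converged": res.converged,
            "residual_norm": res.residual_norm,
        }
        for cond, res in results.cds.items()
    }
    (out / "cds_components.json").write_text(json.dumps(cds_payload, indent=1))

    from . import __version__

    manifest = {
        "uvpdfy_version": __version__,
        "parameters": asdict(config.params),
        "seed": config.seed,
        "inputs": inputs,
        "sequence": seq.identifier,
        "n_fragments": results.n_fragments,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return results
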