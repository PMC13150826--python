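"""Readers and writers for the text formats the pipeline consumes and emits.

Supported dialects:

- msalign (TopFD-style deconvolution output): ``BEGIN IONS`` / ``END IONS``
  blocks with ``KEY=VALUE`` header lines (``SCANS=`` carries the scan id)
  followed by one ``mass<TAB>intensity<TAB>charge`` row per deconvoluted
  fragment.
- plain feature tables: TSV with columns ``scan, mass, charge, intensity``.
- precursor peak tables: two-column TSV ``mz, intensity`` (centroided).

Writers format floats at fixed precision so seeded simulations re-emit
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .matching import DeconvolutedFeature
from .simulate import SimulatedExperiment

__all__ = [
    "read_msalign",
    "write_msalign",
    "read_feature_tsv",
    "write_feature_tsv",
    "read_peak_tsv",
    "write_peak_tsv",
    "features_from_frame",
    "write_experiment",
]

_FEATURE_COLS = ["scan", "mass", "charge", "intensity"]


class MsalignParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def read_msalign(path: str | Path) -> pd.DataFrame:
    """Parse an msalign file into a feature frame (scan, mass, charge, intensity)."""
    path = Path(path)
    rows = []
    in_block = False
    scan_id = None
    block_start = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                raise MsalignParseError(path, lineno, "nested BEGIN IONS")
            in_block, scan_id, block_start = True, None, lineno
            continue
        if line == "END IONS":
            if not in_block:
                raise MsalignParseError(path, lineno, "END IONS without BEGIN IONS")
            in_block = False
            continue
        if not in_block:
            raise MsalignParseError(path, lineno, "data outside BEGIN/END block")
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            if key == "SCANS":
                scan_id = int(value)
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise MsalignParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
        if scan_id is None:
            raise MsalignParseError(path, block_start, "block lacks SCANS= header")
        mass, intensity, charge = float(parts[0]), float(parts[1]), int(float(parts[2]))
        rows.append((scan_id, mass, charge, intensity))
    if in_block:
        raise MsalignParseError(path, block_start, "unterminated BEGIN IONS block")
    df = pd.DataFrame(rows, columns=_FEATURE_COLS)
    if df.empty:
        import logging

        logging.getLogger(__name__).warning("empty msalign file: %s", path)
    return df


def write_msalign(features: pd.DataFrame, path: str | Path, file_name: str = "") -> None:
    """Write a feature frame as msalign blocks, one block per scan."""
    path = Path(path)
    lines: list[str] = []
    for i, (scan, group) in enumerate(sorted(features.groupby("scan"))):
        lines.append("BEGIN IONS")
        lines.append(f"FILE_NAME={file_name or path.name}")
        lines.append(f"SPECTRUM_ID={i}")
        lines.append(f"SCANS={int(scan)}")
        lines.append("ACTIVATION=UVPD")
        for _, row in group.iterrows():
            lines.append(f"{row['mass']:.6f}\t{row['intensity']:.4f}\t{int(row['charge'])}")
        lines.append("END IONS")
        lines.append("")
    path.write_text("\n".join(lines))


def read_feature_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _FEATURE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[_FEATURE_COLS]


def write_feature_tsv(features: pd.DataFrame, path: str | Path) -> None:
    out = features[_FEATURE_COLS].copy()
    out["mass"] = out["mass"].map(lambda v: f"{v:.6f}")
    out["intensity"] = out["intensity"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_peak_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"mz", "intensity"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns mz, intensity")
    return df[["mz", "intensity"]]


def write_peak_tsv(peaks: pd.DataFrame, path: str | Path) -> None:
    out = peaks[["mz", "intensity"]].copy()
    out["mz"] = out["mz"].map(lambda v: f"{v:.6f}")
    out["intensity"] = out["intensity"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def features_from_frame(df: pd.DataFrame) -> dict[int, list[DeconvolutedFeature]]:
    """Group a feature frame into per-scan DeconvolutedFeature lists."""
    has_env = "envelope" in df.columns
    out: dict[int, list[DeconvolutedFeature]] = {}
    for row in df.itertuples(index=False):
        env = getattr(row, "envelope", None) if has_env else None
        out.setdefault(int(row.scan), []).append(
            DeconvolutedFeature(int(row.scan), float(row.mass), int(row.charge),
                                float(row.intensity), env)
        )
    return out


def write_experiment(sim: SimulatedExperiment, out_dir: str | Path,
                     dialect: str = "tsv") -> dict:
    """Write a simulated experiment to disk in the dialects the readers consume.

    Returns a manifest dict of the paths written. Ground truth goes to
    ``ground_truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"precursor": {}, "features": {}, "dialect": dialect}
    for cond, peaks in sim.precursor.items():
        p = out_dir / f"precursor_{cond}.tsv"
        write_peak_tsv(peaks, p)
        manifest["precursor"][cond] = str(p)
    for (cond, rep), df in sim.features.items():
        if dialect == "msalign":
            p = out_dir / f"fragments_{cond}_rep{rep}.msalign"
            write_msalign(df, p)
        else:
            p = out_dir / f"fragments_{cond}_rep{rep}.tsv"
            write_feature_tsv(df, p)
        manifest["features"].setdefault(cond, {})[str(rep)] = str(p)
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(sim.ground_truth.to_dict(), indent=1, default=str))
    manifest["ground_truth"] = str(gt_path)
    # the on-disk manifest carries names relative to out_dir so identical
    # seeds re-emit byte-identical trees regardless of destination
    relative = json.loads(json.dumps(manifest))
    def _rel(v):
        return str(Path(v).name) if isinstance(v, str) and v.startswith(str(out_dir)) else v
    relative["precursor"] = {k: _rel(v) for k, v in relative["precursor"].items()}
    relative["features"] = {
        c: {r: _rel(v) for r, v in reps.items()} for c, reps in relative["features"].items()
    }
    relative["ground_truth"] = _rel(relative["ground_truth"])
    (out_dir / "manifest.json").write_text(json.dumps(relative, indent=1))
    return manifest
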