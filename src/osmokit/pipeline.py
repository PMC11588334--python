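"""Pipeline driver: wire the analysis tracks into versioned JSON reports.

Three tracks mirror the analysis structure of the study:

* ``structures`` — superpose an ensemble of coordinate files, map conserved
  waters, build hydrogen-bond networks;
* ``kinetics`` — fit the chloride-inhibited autocatalytic model to a
  progress-curve CSV;
* ``equilibria`` — fit a monomer-dimer Kd to an SLS CSV and/or melt
  temperatures to a DSF CSV.

Every report embeds the schema version, the package version, a hash of the
configuration and SHA-256 checksums of the inputs; payloads are
deterministic for a fixed (config, inputs, seed), with the wall-clock
timestamp kept in a separate field.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .equilibria import DSFCurve, SLSSeries, fit_kd_dimer, fit_melt
from .kinetics import ProgressCurve, fit_autocat
from .structio import read_structure
from .watermap import build_network, cluster_waters, project_waters

REPORT_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run; hashed into every report."""

    match_cutoff: float = 2.2  # A, water-site clustering
    hbond_cutoff: float = 3.4  # A, O-O hydrogen bond
    contact_cutoff: float = 3.5  # A, site environment
    seed: int = 0
    monomer_mass_kD: float = 40.0
    enzyme_total_uM: float = 4.0
    anchor_range: tuple[int, int] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if min(self.match_cutoff, self.hbond_cutoff, self.contact_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _report_shell(config: RunConfig, inputs: list[Path]) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "inputs": {p.name: _checksum(p) for p in inputs},
        "timestamp": None,  # filled at write time, outside the payload hash
    }


def _structures_track(config: RunConfig, files: list[Path]) -> dict:
    structures = [read_structure(p) for p in files]
    for s, p in zip(structures, files):
        s.id = p.stem
    ref = structures[0]
    anchors = None
    if config.anchor_range is not None:
        rng = set(range(config.anchor_range[0], config.anchor_range[1] + 1))
        anchors = {s.id: rng for s in structures}
    sites = project_waters(structures, ref, anchors=anchors)
    clusters = cluster_waters(sites, config.match_cutoff, len(structures))
    networks = build_network(clusters, config.hbond_cutoff)
    return {
        "n_structures": len(structures),
        "n_water_sites": len(sites),
        "n_clusters": len(clusters),
        "clusters": [
            {"centroid": [round(x, 3) for x in c.centroid],
             "conservation": round(c.conservation, 4),
             "members": sorted(m.key() for m in c.members)}
            for c in clusters
        ],
        "networks": [
            {"component_id": n.component_id, "size": len(n),
             "n_edges": len(n.edges)} for n in networks
        ],
    }


def _kinetics_track(config: RunConfig, csv_path: Path) -> dict:
    df = pd.read_csv(csv_path)
    required = {"site", "chloride_mM", "enzyme_uM", "time_min", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing columns {sorted(missing)}")
    out = {}
    for site, sub in df.groupby("site"):
        curves = [
            ProgressCurve(np.asarray(g["time_min"]), np.asarray(g["fraction"]),
                          float(cl), float(g["enzyme_uM"].iloc[0]), str(site))
            for cl, g in sub.groupby("chloride_mM")
        ]
        fit = fit_autocat(curves, seed=config.seed)
        out[str(site)] = {
            "converged": fit.converged,
            "k_uM_min": round(fit.estimates.k, 6),
            "K_Cl_mM": round(fit.estimates.K_Cl, 4),
            "p0_uM": round(fit.estimates.p0, 6),
            "T_uM": fit.estimates.T,
            "ssr": round(fit.ssr, 8),
            "n_obs": fit.n_obs,
        }
    return out


def _equilibria_track(config: RunConfig, sls_csv: Path | None,
                      dsf_csv: Path | None) -> dict:
    out: dict = {}
    if sls_csv is not None:
        df = pd.read_csv(sls_csv)
        series = SLSSeries(np.asarray(df["concentration_mgml"]),
                           np.asarray(df["mass_kD"]),
                           config.monomer_mass_kD)
        kd, fractions = fit_kd_dimer(series)
        out["sls"] = {"kd_uM": round(kd, 4),
                      "dimer_fractions": [round(f, 4) for f in fractions]}
    if dsf_csv is not None:
        df = pd.read_csv(dsf_csv)
        melts = {}
        for cond, sub in df.groupby(df.get("condition", "all")):
            sub = sub.sort_values("temperature_C")
            fit = fit_melt(DSFCurve(np.asarray(sub["temperature_C"]),
                                    np.asarray(sub["fluorescence"]), str(cond)))
            melts[str(cond)] = {"tm_C": round(fit.tm, 3) if fit.converged else None,
                                "converged": fit.converged}
        out["dsf"] = melts
    return out


def run_pipeline(config: RunConfig, manifest: dict[str, list[str | Path]],
                 out_dir: str | Path) -> dict[str, Path]:
    """Execute the tracks named in ``manifest`` and write one report each.

    ``manifest`` maps track name to input files: ``structures`` (coordinate
    files), ``kinetics`` (one progress-curve CSV), ``equilibria`` (SLS CSV
    and/or DSF CSV, recognized by filename containing "sls"/"dsf").
    Returns the written report paths.  Raises on an empty manifest or a
    missing input; a failing track raises after earlier reports are written.
    """
    if not manifest or not any(manifest.values()):
        raise ValueError("empty manifest: nothing to run")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for track, files in manifest.items():
        paths = [Path(f) for f in files]
        for p in paths:
            if not p.exists():
                raise FileNotFoundError(p)
        report = _report_shell(config, paths)
        if track == "structures":
            report["results"] = _structures_track(config, paths)
        elif track == "kinetics":
            report["results"] = _kinetics_track(config, paths[0])
        elif track == "equilibria":
            sls = next((p for p in paths if "sls" in p.name.lower()), None)
            dsf = next((p for p in paths if "dsf" in p.name.lower()), None)
            report["results"] = _equilibria_track(config, sls, dsf)
        else:
            raise ValueError(f"unknown track {track!r}")
        report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        path = out_dir / f"{track}_report.json"
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written[track] = path
    return written
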