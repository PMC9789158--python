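"""File formats, run configuration and the end-to-end analysis driver.

All formats are plain text: z-scans and decay histograms are CSV with
``# key: value`` header comments for metadata; depth responses are a CSV
matrix (rows = sample depth z, columns = focus depth z_F) with a JSON
sidecar; run configuration is YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import MicroscopeConfig, PhotophysicsParams
from .lifetime import DecayHistogram
from .optics import DepthResponse, trace_depth_response
from .zscan import (
    DEFAULT_DEPTHS,
    AdsorptionResults,
    SurfaceAdsorptionModel,
    ZScanProfile,
)

__all__ = [
    "read_zscan",
    "write_zscan",
    "read_decay",
    "write_decay",
    "read_depth_response",
    "write_depth_response",
    "RunConfig",
    "load_run_config",
    "run_analysis",
]

log = logging.getLogger("rotorscan")


def _read_commented_csv(path) -> tuple[dict, pd.DataFrame]:
    """Read a CSV with ``# key: value`` header comments; malformed data rows
    are reported with their line numbers."""
    path = Path(path)
    meta: dict = {}
    rows = []
    header = None
    bad: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                bad.append(f"line {lineno}: expected {len(header)} fields, got {len(parts)}")
                continue
            try:
                rows.append([float(p) if p != "" else np.nan for p in parts])
            except ValueError:
                bad.append(f"line {lineno}: non-numeric value in {parts!r}")
    if header is None:
        raise ValueError(f"{path}: no column header found")
    if bad:
        raise ValueError(f"{path}: malformed rows:\n  " + "\n  ".join(bad))
    if "rows" in meta:
        expected = int(meta["rows"])
        if expected != len(rows):
            raise ValueError(
                f"{path}: header declares {expected} data rows but {len(rows)} were read "
                "(truncated file?)"
            )
    return meta, pd.DataFrame(rows, columns=header)


def read_zscan(path) -> ZScanProfile:
    """Read a z-scan CSV (columns ``z_um, intensity[, tau_ns]``)."""
    meta, df = _read_commented_csv(path)
    for col in ("z_um", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if df["z_um"].isna().any() or df["intensity"].isna().any():
        raise ValueError(f"{path}: empty cells in required columns")
    z = df["z_um"].to_numpy()
    if not np.any(np.isclose(z, 0.0, atol=1e-9)):
        raise ValueError(
            f"{path}: no z = 0 row — z-scans must include the interface anchor z_um = 0"
        )
    lifetime = None
    if "tau_ns" in df.columns and not df["tau_ns"].isna().all():
        lifetime = df["tau_ns"].to_numpy()
    return ZScanProfile(
        z_f=z,
        intensity=df["intensity"].to_numpy(),
        lifetime=lifetime,
        surface_kind=meta.get("surface_kind", "hydrophobic"),
        wt_glycerol=float(meta.get("wt_glycerol", 0.0)),
        dye_concentration=float(meta.get("dye_concentration_M", 1.0e-7)),
    )


def write_zscan(profile: ZScanProfile, path) -> None:
    path = Path(path)
    cols = {"z_um": profile.z_f, "intensity": profile.intensity}
    if profile.lifetime is not None:
        cols["tau_ns"] = profile.lifetime
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# surface_kind: {profile.surface_kind}\n")
        fh.write(f"# wt_glycerol: {profile.wt_glycerol}\n")
        fh.write(f"# dye_concentration_M: {profile.dye_concentration!r}\n")
        fh.write(f"# rows: {len(df)}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_decay(path) -> DecayHistogram:
    """Read a decay-histogram CSV (columns ``t_ns, counts``)."""
    meta, df = _read_commented_csv(path)
    for col in ("t_ns", "counts"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    irf = meta.get("irf_fwhm_ns")
    return DecayHistogram(
        t=df["t_ns"].to_numpy(),
        counts=df["counts"].to_numpy(),
        rep_rate=float(meta.get("rep_rate_MHz", 40.0)),
        irf_fwhm=float(irf) if irf not in (None, "", "none") else None,
    )


def write_decay(hist: DecayHistogram, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"t_ns": hist.t, "counts": hist.counts.astype(int)})
    with open(path, "w") as fh:
        fh.write(f"# rep_rate_MHz: {hist.rep_rate}\n")
        if hist.irf_fwhm is not None:
            fh.write(f"# irf_fwhm_ns: {hist.irf_fwhm}\n")
        fh.write(f"# rows: {len(df)}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def write_depth_response(dr: DepthResponse, out_dir) -> None:
    """Write phi(z | z_F) as a CSV matrix plus a JSON sidecar with the
    scalar summaries (phi00, seed, n_rays) and the derived curves."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(dr.phi.T, index=pd.Index(dr.z_grid, name="z_um"),
                      columns=[f"{zf:g}" for zf in dr.z_f_grid])
    df.to_csv(out_dir / "phi.csv", float_format="%.8g")
    sidecar = {
        "phi00_per_um": dr.phi00,
        "seed": dr.seed,
        "n_rays": dr.n_rays,
        "z_f_um": dr.z_f_grid.tolist(),
        "r_th": dr.r_th.tolist(),
        "h_pred": dr.h_pred.tolist(),
        "config": dr.config.to_dict() if dr.config is not None else None,
    }
    with open(out_dir / "depth_response.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_depth_response(out_dir) -> DepthResponse:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "phi.csv", index_col=0)
    with open(out_dir / "depth_response.json") as fh:
        sidecar = json.load(fh)
    cfg = sidecar.get("config")
    return DepthResponse(
        z_f_grid=np.asarray(sidecar["z_f_um"], dtype=float),
        z_grid=df.index.to_numpy(dtype=float),
        phi=df.to_numpy().T,
        phi00=float(sidecar["phi00_per_um"]),
        r_th=np.asarray(sidecar["r_th"], dtype=float),
        h_pred=np.asarray(sidecar["h_pred"], dtype=float),
        n_rays=int(sidecar["n_rays"]),
        seed=int(sidecar["seed"]),
        config=MicroscopeConfig.from_dict(cfg) if cfg else None,
    )


@dataclass
class RunConfig:
    """Everything needed for one end-to-end adsorption analysis."""

    sample_path: str
    microscope: MicroscopeConfig = field(default_factory=MicroscopeConfig)
    photophysics: PhotophysicsParams | None = None
    homogeneous_path: str | None = None
    depth_response_dir: str | None = None
    phi00: float | None = None
    depths: tuple = DEFAULT_DEPTHS
    smooth: bool = False
    seed: int = 0
    n_rays: int = 200_000
    rho_molar: float | None = None
    out_dir: str = "."

    def __post_init__(self) -> None:
        if len(self.depths) == 0:
            raise ValueError("depth list must not be empty")
        if not Path(self.sample_path).exists():
            raise FileNotFoundError(self.sample_path)
        for p in (self.homogeneous_path,):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    mic = MicroscopeConfig.from_dict(data.get("microscope", {}))
    phot = data.get("photophysics")
    phot = PhotophysicsParams.from_dict(phot) if phot else None
    analysis = data.get("analysis", {})
    paths = data.get("paths", {})
    return RunConfig(
        sample_path=paths["sample"],
        microscope=mic,
        photophysics=phot,
        homogeneous_path=paths.get("homogeneous"),
        depth_response_dir=paths.get("depth_response"),
        phi00=analysis.get("phi00"),
        depths=tuple(analysis.get("depths", DEFAULT_DEPTHS)),
        smooth=bool(analysis.get("smooth", False)),
        seed=int(analysis.get("seed", 0)),
        n_rays=int(analysis.get("n_rays", 200_000)),
        rho_molar=analysis.get("rho_molar"),
        out_dir=paths.get("out", "."),
    )


def run_analysis(config: RunConfig) -> AdsorptionResults:
    """Run the full pipeline: load scans, obtain H and phi00 (measured,
    stored, or ray-traced), estimate K and sigma, and write the result JSON
    plus the per-depth K table."""
    from . import __version__

    sample = read_zscan(config.sample_path)
    reference = None
    if config.homogeneous_path is not None:
        reference = read_zscan(config.homogeneous_path)

    dr = None
    phi00_source = "user-supplied"
    if config.depth_response_dir is not None:
        dr = read_depth_response(config.depth_response_dir)
        phi00_source = "stored ray trace"
    elif config.phi00 is None or reference is None:
        max_depth = max(max(config.depths), float(sample.z_f.max()))
        z_f_grid = np.unique(np.concatenate([np.arange(0.0, max_depth + 1.0, 1.0),
                                             np.asarray(config.depths, dtype=float)]))
        log.info("ray tracing depth response (n_rays=%d, seed=%d)", config.n_rays, config.seed)
        dr = trace_depth_response(
            config.microscope, z_f_grid=z_f_grid, n_rays=config.n_rays, seed=config.seed
        )
        phi00_source = "ray-traced"
    if reference is None and dr is None:
        raise ValueError(
            "no homogeneous reference scan: provide one, a stored depth response, "
            "or a microscope configuration to ray trace H"
        )
    if config.photophysics is None:
        raise ValueError("photophysics (phi_b, tau_b, phi_s, tau_s) must be configured")

    model = SurfaceAdsorptionModel(
        sample=sample,
        reference=reference,
        depth_response=dr,
        phi00=config.phi00,
        photophysics=config.photophysics,
        rho_molar=config.rho_molar,
        depths=config.depths,
        smooth=config.smooth,
    )
    try:
        results = model.fit(method="corrected" if dr is not None else "asymptotic")
    except Exception as exc:  # annotate with the pipeline stage
        raise RuntimeError(f"adsorption fit failed: {exc}") from exc

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = results.to_dict()
    payload.update(
        {
            "phi00_source": phi00_source,
            "seed": config.seed,
            "software_version": __version__,
        }
    )
    with open(out_dir / "adsorption_result.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    results.per_depth.to_csv(out_dir / "per_depth_K.csv", float_format="%.8g")
    log.info(
        "analysis complete: K = %.4g µm, sigma = %.4g µm⁻² (phi00 %s, seed %d, v%s)",
        results.k_value,
        results.sigma,
        phi00_source,
        config.seed,
        __version__,
    )
    return results
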