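"""Config-driven orchestration of the full analysis on synthetic or user data.

A :class:`RunConfig` selects a mode (``simulate``, ``waxs``, ``sans``,
``wans`` or ``all``), carries the generative ground truth (or input file
paths) and per-module parameter blocks, and :func:`run` executes the stages
in order, writing a machine-readable JSON report plus CSV tables and
profile files.  Everything stochastic flows from the single seed, so a rerun
with the same config is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigurationError
from .lattice import (
    CELLULOSE_IBETA,
    MicrofibrilEnvelope,
    chain_area,
    count_chains,
    scale_chain_area,
)
from .profiles import read_profile, write_profile
from .sans import analyze_hydration_series, contrast_match_fraction
from .simulate import (
    GroundTruth,
    generate_azimuthal,
    generate_equatorial_waxs,
    generate_sans,
    generate_wans_pair,
)
from .waxs import analyze_equatorial, fit_azimuthal
from .wans import (
    check_equatorial_consistency,
    detect_meridional,
    difference_profile,
    fit_difference_lobe,
    fit_hd_pair,
)

__all__ = ["RunConfig", "run", "validate_report", "REPORT_SCHEMA"]

log = logging.getLogger("fibrilscatter")

_MODES = ("simulate", "waxs", "sans", "wans", "all")

#: Minimal structural schema for the JSON report (section -> required keys).
REPORT_SCHEMA = {
    "provenance": ("version", "seed", "mode", "config_hash"),
    "waxs": ("d_spacings_nm", "monoclinic_angle_deg", "scherrer_L_nm",
             "disorder_g", "azimuthal_narrow_fwhm_deg", "azimuthal_wide_fwhm_deg"),
    "sans": ("spacing_trend_nm", "contrast_match_fraction"),
    "wans": ("consistency", "meridional_detections", "difference_lobe_1m10"),
    "geometry": ("area_per_chain_nm2", "chain_count_rectangle", "chain_count_ellipse"),
}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``truth`` drives simulation; in non-simulate modes, ``inputs`` may map
    stage names to profile paths instead (``waxs_equatorial``, ``sans``
    mapping fractions to paths, ``wans_h``/``wans_d``/...).  ``params``
    holds optional per-module keyword blocks (``waxs``, ``sans``, ``wans``).
    """

    mode: str = "all"
    truth: GroundTruth = field(default_factory=GroundTruth)
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0
    sans_fractions: tuple = (0.0, 0.1, 0.25)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; choose from {_MODES}")
        for name, path in self.inputs.items():
            if isinstance(path, (str, Path)) and not Path(path).exists():
                raise ConfigurationError(f"input {name!r}: path {path} does not exist")
        self.truth.seed = int(self.seed)

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update(overrides)
        if "truth" in data and isinstance(data["truth"], dict):
            data["truth"] = GroundTruth.from_dict(data["truth"])
        if "sans_fractions" in data:
            data["sans_fractions"] = tuple(data["sans_fractions"])
        return cls(**data)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(
            {
                "mode": self.mode,
                "truth": self.truth.to_dict(),
                "params": self.params,
                "seed": self.seed,
                "sans_fractions": list(self.sans_fractions),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_waxs(cfg: RunConfig) -> dict:
    p = dict(cfg.params.get("waxs", {}))
    if "waxs_equatorial" in cfg.inputs:
        profile = read_profile(cfg.inputs["waxs_equatorial"])
    else:
        profile = generate_equatorial_waxs(cfg.truth)
    analysis = analyze_equatorial(profile, **p)
    az_fit = fit_azimuthal(generate_azimuthal(cfg.truth)) if "azimuthal" not in cfg.inputs \
        else fit_azimuthal(read_profile(cfg.inputs["azimuthal"]))
    log.info(
        "waxs: d200=%.4f nm gamma=%.2f deg L=%.3f nm g=%.4f",
        analysis.fit.d_spacings[(2, 0, 0)], analysis.cell.gamma,
        analysis.broadening.L, analysis.broadening.g,
    )
    return {
        "d_spacings_nm": {
            ",".join(map(str, hkl)): d for hkl, d in analysis.fit.d_spacings.items()
        },
        "monoclinic_angle_deg": analysis.cell.gamma,
        "cell_a_nm": analysis.cell.a,
        "cell_b_nm": analysis.cell.b,
        "scherrer_L_nm": analysis.broadening.L,
        "disorder_g": analysis.broadening.g,
        "delta_q0_nm^-1": analysis.broadening.delta_q0,
        "background": analysis.background,
        "azimuthal_narrow_fwhm_deg": az_fit.narrow[1],
        "azimuthal_wide_fwhm_deg": az_fit.wide[1],
        "azimuthal_narrow_fraction": az_fit.narrow_fraction,
        "_analysis": analysis,
    }


def _stage_sans(cfg: RunConfig) -> dict:
    p = dict(cfg.params.get("sans", {}))
    if "sans" in cfg.inputs:
        profiles = {float(f): read_profile(path) for f, path in cfg.inputs["sans"].items()}
    else:
        profiles = {f: generate_sans(cfg.truth, f) for f in cfg.sans_fractions}
    series = analyze_hydration_series(profiles, **p)
    match = contrast_match_fraction()
    log.info("sans: %d fractions, %d detected peaks, match fraction %.3f",
             len(series.points), len(series.spacing_trend), match)
    return {
        "spacing_trend_nm": [[f, d] for f, d in series.spacing_trend],
        "detected": {str(f): fit.detected for f, fit in series.points},
        "contrast_match_fraction": match,
        # The nominal centre-to-centre spacing d = 2*pi/q_peak does not
        # necessarily correspond to any form of global mean.
        "spacing_caveat": "nominal centre-to-centre spacing from the Bragg peak position",
        "_series": series,
    }


def _stage_wans(cfg: RunConfig) -> dict:
    p = dict(cfg.params.get("wans", {}))
    normalisation = p.pop("normalisation", "window")
    if "wans_h" in cfg.inputs:
        h_eq = read_profile(cfg.inputs["wans_h"])
        d_eq = read_profile(cfg.inputs["wans_d"])
        h_mer = read_profile(cfg.inputs["wans_h_meridional"])
        d_mer = read_profile(cfg.inputs["wans_d_meridional"])
    else:
        h_eq, d_eq, h_mer, d_mer = generate_wans_pair(cfg.truth)
    pair = fit_hd_pair(h_eq, d_eq)
    consistency = check_equatorial_consistency(pair.h_fit, pair.d_fit, **p)
    diff = difference_profile(d_eq, h_eq, normalisation=normalisation)
    lobe = fit_difference_lobe(diff, window=(pair.q_1m10 - 1.5, pair.q_1m10 + 1.5), sign=-1)
    mer_diff = difference_profile(d_mer, h_mer, normalisation="none")
    detections = detect_meridional(mer_diff, fibre_repeat_c=cfg.truth.fibre_repeat_c)
    log.info("wans: consistency pass=%s, q(1-10)=%.3f, lobe at q=%.3f, %d meridional detections",
             consistency["pass"], pair.q_1m10, lobe["q0"],
             sum(d["detected"] for d in detections))
    return {
        "consistency": {
            "pass": consistency["pass"],
            "tolerance": consistency["tolerance"],
            "relative_differences": {
                ",".join(map(str, k)): v
                for k, v in consistency["relative_differences"].items()
            },
            # 1-10/110 positions are shared between the forms by hypothesis;
            # their zero entries record the constraint, not a measurement
            "shared_pair_positions": True,
        },
        "q_1m10_nm^-1": pair.q_1m10,
        "q_110_nm^-1": pair.q_110,
        "normalisation_scale": diff.normalisation,
        "difference_lobe_1m10": lobe,
        "meridional_detections": detections,
    }


def _stage_geometry(cfg: RunConfig, waxs_report: dict | None, sans_report: dict | None) -> dict:
    d200 = None
    if waxs_report:
        d200 = waxs_report["d_spacings_nm"]["2,0,0"]
    packing = scale_chain_area(CELLULOSE_IBETA, d200) if d200 else chain_area(CELLULOSE_IBETA)
    height = waxs_report["scherrer_L_nm"] if waxs_report else 3.8
    width = 3.0
    if sans_report and sans_report["spacing_trend_nm"]:
        dry = [d for f, d in sans_report["spacing_trend_nm"] if f == min(
            f for f, _ in sans_report["spacing_trend_nm"])]
        width = dry[0]
    rect = MicrofibrilEnvelope(height=height, width=width, shape="rectangle")
    ell = MicrofibrilEnvelope(height=height, width=width, shape="ellipse")
    return {
        "area_per_chain_nm2": packing.area_per_chain,
        "area_source": packing.source,
        "envelope_height_nm": height,
        "envelope_width_nm": width,
        "chain_count_rectangle": count_chains(rect, packing),
        "chain_count_ellipse": count_chains(ell, packing),
    }


def _write_outputs(cfg: RunConfig, report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "profiles").mkdir(exist_ok=True)
    (outdir / "tables").mkdir(exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    waxs = report.get("waxs")
    if waxs:
        with open(outdir / "tables" / "d_spacings.csv", "w") as fh:
            fh.write("hkl,d_nm\n")
            for hkl, d in sorted(waxs["d_spacings_nm"].items()):
                fh.write(f"\"{hkl}\",{d:.6f}\n")
    sans = report.get("sans")
    if sans:
        with open(outdir / "tables" / "sans_spacing_trend.csv", "w") as fh:
            fh.write("d2o_fraction,spacing_nm\n")
            for f, d in sans["spacing_trend_nm"]:
                fh.write(f"{f},{d:.6f}\n")


def _simulate_files(cfg: RunConfig, outdir: Path) -> list:
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(profile, name):
        path = prof_dir / name
        write_profile(profile, path)
        written.append(str(path))

    save(generate_equatorial_waxs(cfg.truth), "waxs_equatorial.txt")
    for f in cfg.sans_fractions:
        save(generate_sans(cfg.truth, f), f"sans_d2o_{int(round(f * 100)):03d}.txt")
    h_eq, d_eq, h_mer, d_mer = generate_wans_pair(cfg.truth)
    save(h_eq, "wans_h_equatorial.txt")
    save(d_eq, "wans_d_equatorial.txt")
    save(h_mer, "wans_h_meridional.txt")
    save(d_mer, "wans_d_meridional.txt")
    az = generate_azimuthal(cfg.truth)
    np.savetxt(prof_dir / "azimuthal.txt",
               np.column_stack([az.angle, az.intensity]),
               header="angle_deg intensity")
    written.append(str(prof_dir / "azimuthal.txt"))
    return written


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the analysis report dict.

    Stage order: simulate? -> waxs -> sans -> wans -> geometry -> report.
    When ``config.outdir`` is set, report.json, CSV tables and (in simulate
    modes) profile files are written there.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": int(config.seed),
            "mode": config.mode,
            "config_hash": config.config_hash(),
            "units": {"q": "nm^-1", "d": "nm", "angles": "deg"},
        }
    }
    outdir = Path(config.outdir) if config.outdir else None

    if config.mode == "simulate":
        if outdir is None:
            raise ConfigurationError("simulate mode needs an output directory")
        report["written"] = _simulate_files(config, outdir)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    waxs_report = sans_report = None
    if config.mode in ("waxs", "all"):
        waxs_report = _stage_waxs(config)
        report["waxs"] = {k: v for k, v in waxs_report.items() if not k.startswith("_")}
    if config.mode in ("sans", "all"):
        sans_report = _stage_sans(config)
        report["sans"] = {k: v for k, v in sans_report.items() if not k.startswith("_")}
    if config.mode in ("wans", "all"):
        report["wans"] = _stage_wans(config)
    if config.mode == "all":
        report["geometry"] = _stage_geometry(config, report.get("waxs"), report.get("sans"))

    validate_report(report, mode=config.mode)
    if outdir is not None:
        _write_outputs(config, report, outdir)
    return report


def validate_report(report: dict, mode: str = "all") -> None:
    """Structural validation of a report against :data:`REPORT_SCHEMA`."""
    required_sections = {"all": ("provenance", "waxs", "sans", "wans", "geometry"),
                         "waxs": ("provenance", "waxs"),
                         "sans": ("provenance", "sans"),
                         "wans": ("provenance", "wans"),
                         "simulate": ("provenance",)}[mode]
    for section in required_sections:
        if section not in report:
            raise ConfigurationError(f"report lacks section {section!r}")
        for key in REPORT_SCHEMA.get(section, ()):
            if key not in report[section]:
                raise ConfigurationError(f"report section {section!r} lacks key {key!r}")
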