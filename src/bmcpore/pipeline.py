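"""End-to-end orchestration of the sheet-vs-shell comparison.

Given a pair of labelled conditions (topology + trajectory each), the
pipeline runs stability metrics, monomer segmentation, solvent metrics
(SASA / water contacts / residence times) split by monomer class, pore
statistics, and — when a dose-response table is supplied — XFMS rate fitting
with structure-vs-footprinting ratio correlation. Everything is driven by a
single plain-text YAML config; identical config and seed give byte-identical
numeric tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .solvent import (
    ContactParams,
    SASAParams,
    events_to_frame,
    monomer_average,
    residence_times,
    sasa_per_residue,
    segment_monomers,
    split_by_monomer,
    water_contacts,
)
from .pore import PoreParams, profile_stats
from .stability import equilibration_mask, rmsd_series, rmsd_series_per_tile, rolling_mean, rmsf
from .structure_io import RadiusTable, read_structure, read_trajectory
from .xfms import (
    Ratio,
    RatioComparison,
    fit_dose_response,
    k_ratio,
    load_dose_response_csv,
    ratio_correlation,
)

__all__ = ["AnalysisConfig", "ConditionConfig", "PipelineError", "validate_config", "run_analysis"]

#: Equilibration cuts (ns) matching the published shell / sheet choices.
_DEFAULT_EQUIL = {"shell": 200.0, "sheet": 500.0}
_CONDITION_LABELS = ("shell", "sheet")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class ConditionConfig:
    label: str
    topology: str
    trajectory: str
    equilibration_cut: float
    dt: float = 1.0
    box: list[float] | None = None


@dataclass
class AnalysisConfig:
    conditions: dict[str, ConditionConfig]
    output_dir: str = "bmcpore_out"
    seed: int = 0
    log_level: str = "INFO"
    analysis_selection: str = "protein"
    tiles: dict[str, str] = field(default_factory=dict)
    trimer_selection: str | None = None
    pore_selection: str | None = None
    solvent_selection: str = "protein"
    contact: ContactParams = field(default_factory=ContactParams)
    sasa: SASAParams = field(default_factory=SASAParams)
    pore: PoreParams = field(default_factory=PoreParams)
    smoothing_window: int = 5
    radius_set: str | None = None
    xfms_path: str | None = None
    xfms_model: str = "fixed-amplitude"
    xfms_site_map: dict[str, list[int]] = field(default_factory=dict)

    def echo(self) -> str:
        """The effective config as YAML, annotating literature defaults."""
        notes = {
            "contact_cutoff": "5 A contact cutoff (literature default)",
            "release_cutoff": "8 A release cutoff (literature default)",
            "smoothing_window": "5-frame rolling window (literature default)",
            "equilibration_cut": "200/500 ns shell/sheet (literature defaults)",
        }
        data = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "conditions": {
                label: {
                    "topology": c.topology,
                    "trajectory": c.trajectory,
                    "equilibration_cut": c.equilibration_cut,
                    "dt": c.dt,
                    "box": c.box,
                }
                for label, c in self.conditions.items()
            },
            "selections": {
                "analysis": self.analysis_selection,
                "tiles": self.tiles,
                "trimer": self.trimer_selection,
                "pore": self.pore_selection,
                "solvent": self.solvent_selection,
            },
            "contact": asdict(self.contact),
            "sasa": asdict(self.sasa),
            "pore": {
                "z_range": list(self.pore.z_range),
                "z_step": self.pore.z_step,
                "max_radius": self.pore.max_radius,
                "mc_steps": self.pore.mc_steps,
            },
            "smoothing_window": self.smoothing_window,
            "xfms": {
                "path": self.xfms_path,
                "model": self.xfms_model,
                "site_map": self.xfms_site_map,
            },
        }
        text = yaml.safe_dump(data, sort_keys=False)
        lines = []
        for line in text.splitlines():
            key = line.strip().split(":", 1)[0]
            if key in notes:
                line = f"{line}  # {notes[key]}"
            lines.append(line)
        return "\n".join(lines) + "\n"


_TOP_KEYS = {
    "seed",
    "output_dir",
    "log_level",
    "conditions",
    "selections",
    "contact",
    "sasa",
    "pore",
    "smoothing_window",
    "radius_set",
    "xfms",
}
_CONDITION_KEYS = {"topology", "trajectory", "equilibration_cut", "dt", "box"}
_SELECTION_KEYS = {"analysis", "tiles", "trimer", "pore", "solvent"}
_CONTACT_KEYS = {"contact_cutoff", "release_cutoff"}
_SASA_KEYS = {"probe_radius", "n_sphere_points"}
_PORE_KEYS = {
    "axis",
    "seed_point",
    "z_range",
    "z_step",
    "max_radius",
    "mc_steps",
    "mc_initial_step",
    "mc_decay",
    "mc_levels",
    "mc_restarts",
    "seed",
}
_XFMS_KEYS = {"path", "model", "site_map"}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def validate_config(source: str | Path | dict) -> AnalysisConfig:
    """Parse and validate a YAML config (text, path, or pre-parsed dict).

    Unknown keys anywhere are an error (no silent typos); defaults are filled
    in and visible via :meth:`AnalysisConfig.echo`.
    """
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text() if _is_path(source) else str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    cond_raw = raw.get("conditions") or {}
    if not cond_raw:
        raise ValueError("config must define at least one condition")
    conditions: dict[str, ConditionConfig] = {}
    for label, c in cond_raw.items():
        if label not in _CONDITION_LABELS:
            raise ValueError(
                f"condition label {label!r} not in {_CONDITION_LABELS}"
            )
        _check_keys(c, _CONDITION_KEYS, f"conditions.{label}")
        for req in ("topology", "trajectory"):
            if req not in c:
                raise ValueError(f"conditions.{label} missing {req!r}")
        equil = float(c.get("equilibration_cut", _DEFAULT_EQUIL[label]))
        if equil < 0:
            raise ValueError(f"conditions.{label}: equilibration_cut must be >= 0")
        conditions[label] = ConditionConfig(
            label=label,
            topology=str(c["topology"]),
            trajectory=str(c["trajectory"]),
            equilibration_cut=equil,
            dt=float(c.get("dt", 1.0)),
            box=list(c["box"]) if c.get("box") else None,
        )

    selections = raw.get("selections") or {}
    _check_keys(selections, _SELECTION_KEYS, "selections")
    contact_raw = raw.get("contact") or {}
    _check_keys(contact_raw, _CONTACT_KEYS, "contact")
    sasa_raw = raw.get("sasa") or {}
    _check_keys(sasa_raw, _SASA_KEYS, "sasa")
    pore_raw = dict(raw.get("pore") or {})
    _check_keys(pore_raw, _PORE_KEYS, "pore")
    if "z_range" in pore_raw:
        pore_raw["z_range"] = tuple(float(v) for v in pore_raw["z_range"])
    if "axis" in pore_raw:
        pore_raw["axis"] = np.asarray(pore_raw["axis"], dtype=float)
    if "seed_point" in pore_raw and pore_raw["seed_point"] is not None:
        pore_raw["seed_point"] = np.asarray(pore_raw["seed_point"], dtype=float)
    xfms_raw = raw.get("xfms") or {}
    _check_keys(xfms_raw, _XFMS_KEYS, "xfms")

    return AnalysisConfig(
        conditions=conditions,
        output_dir=str(raw.get("output_dir", "bmcpore_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        analysis_selection=str(selections.get("analysis", "protein")),
        tiles={str(k): str(v) for k, v in (selections.get("tiles") or {}).items()},
        trimer_selection=selections.get("trimer"),
        pore_selection=selections.get("pore"),
        solvent_selection=str(selections.get("solvent", "protein")),
        contact=ContactParams(**contact_raw),
        sasa=SASAParams(**sasa_raw),
        pore=PoreParams(**pore_raw),
        smoothing_window=int(raw.get("smoothing_window", 5)),
        radius_set=raw.get("radius_set"),
        xfms_path=xfms_raw.get("path"),
        xfms_model=str(xfms_raw.get("model", "fixed-amplitude")),
        xfms_site_map={
            str(k): [int(r) for r in v]
            for k, v in (xfms_raw.get("site_map") or {}).items()
        },
    )


def _is_path(source) -> bool:
    if isinstance(source, Path):
        return True
    s = str(source)
    if "\n" in s or len(s) > 4096:
        return False
    try:
        return Path(s).exists()
    except OSError:
        return False


def _write_tsv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(path)


def run_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Run the full comparison described by ``config``.

    Produces, per condition: RMSD (raw + smoothed, whole and per-tile), RMSF,
    per-residue SASA / water-contact / retention tables split by monomer
    class, residence event lists, and pore statistics. Cross-condition:
    per-residue metric ratio tables and, when a dose-response CSV is given,
    the fitted k table, solution/shell k-ratios, and the correlation of
    experimental against structure-derived ratios.

    Any stage failure aborts with the stage name; partially written outputs
    are removed. Returns a report dict with the output paths and headline
    numbers.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict[str, Any] = {"conditions": {}, "outputs": []}
    radii = (
        RadiusTable.from_text(Path(config.radius_set))
        if config.radius_set
        else RadiusTable.bondi()
    )

    stage = "validate-inputs"
    try:
        for cond in config.conditions.values():
            for p in (cond.topology, cond.trajectory):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        if config.xfms_path and not Path(config.xfms_path).exists():
            raise FileNotFoundError(f"XFMS input not found: {config.xfms_path}")

        per_condition_tables: dict[str, dict[str, pd.DataFrame]] = {}
        class_maps: dict[str, dict[str, str]] = {}
        for label, cond in config.conditions.items():
            stage = f"read-inputs[{label}]"
            top = read_structure(Path(cond.topology), radii=radii)
            traj = read_trajectory(
                top, Path(cond.trajectory), box=cond.box, dt=cond.dt
            )
            mask = equilibration_mask(traj, cond.equilibration_cut)

            stage = f"stability[{label}]"
            series = rmsd_series(traj, config.analysis_selection, top, label="rmsd")
            smooth = rolling_mean(series, config.smoothing_window)
            rmsd_df = pd.DataFrame(
                {
                    "time_ns": series.times,
                    "rmsd": series.values,
                    "rmsd_smoothed": smooth.values,
                }
            )
            _write_tsv(rmsd_df, outdir / f"{label}_rmsd.tsv", written)
            if config.tiles:
                per_tile = rmsd_series_per_tile(traj, config.tiles, top)
                tile_df = pd.DataFrame({"time_ns": series.times})
                for name, s in per_tile.items():
                    tile_df[name] = s.values
                _write_tsv(tile_df, outdir / f"{label}_rmsd_per_tile.tsv", written)
            rmsf_df = rmsf(traj, config.analysis_selection, cond.equilibration_cut)
            _write_tsv(rmsf_df, outdir / f"{label}_rmsf.tsv", written)

            stage = f"segmentation[{label}]"
            class_map: dict[str, str] = {}
            if config.trimer_selection:
                class_map = segment_monomers(
                    traj.frame(int(mask[0])), config.trimer_selection
                )
                cm_df = pd.DataFrame(
                    sorted(class_map.items()), columns=["chain", "class"]
                )
                _write_tsv(cm_df, outdir / f"{label}_monomer_classes.tsv", written)
            class_maps[label] = class_map

            stage = f"solvent[{label}]"
            sasa_frames = [
                sasa_per_residue(traj.frame(int(f)), config.solvent_selection, config.sasa)
                for f in mask
            ]
            sasa_df = sasa_frames[0].copy()
            sasa_df["value"] = np.mean([d["value"].to_numpy() for d in sasa_frames], axis=0)
            contacts_df = water_contacts(
                traj, config.solvent_selection, config.contact, mask
            )
            events, retention_df = residence_times(
                traj, config.solvent_selection, config.contact, mask
            )
            _write_tsv(sasa_df, outdir / f"{label}_sasa.tsv", written)
            _write_tsv(contacts_df, outdir / f"{label}_contacts.tsv", written)
            _write_tsv(retention_df, outdir / f"{label}_retention.tsv", written)
            ev_path = outdir / f"{label}_residence_events.csv"
            events_to_frame(events).to_csv(ev_path, index=False, float_format="%.10g")
            written.append(ev_path)

            tables = {"sasa": sasa_df, "contacts": contacts_df, "retention": retention_df}
            if class_map:
                for metric, df in list(tables.items()):
                    split = split_by_monomer(df)
                    split = {c: s for c, s in split.items() if c in class_map}
                    for cls in sorted(set(class_map.values())):
                        avg = monomer_average(split, class_map, cls)
                        _write_tsv(
                            avg,
                            outdir / f"{label}_{metric}_{cls.replace('-', '_')}_mean.tsv",
                            written,
                        )
            per_condition_tables[label] = tables

            stage = f"pore[{label}]"
            if config.pore_selection:
                stats = profile_stats(traj, config.pore_selection, config.pore, mask)
                _write_tsv(stats.to_frame(), outdir / f"{label}_pore_stats.tsv", written)
                _write_tsv(
                    stats.bottlenecks, outdir / f"{label}_pore_bottlenecks.tsv", written
                )
                report["conditions"].setdefault(label, {})["median_bottleneck_A"] = (
                    float(stats.bottlenecks["radius"].median())
                )

        stage = "cross-condition"
        labels = list(config.conditions)
        if len(labels) == 2:
            a, b = labels
            for metric in ("sasa", "contacts", "retention"):
                da = per_condition_tables[a][metric]
                db = per_condition_tables[b][metric]
                merged = da.merge(
                    db, on=["chain", "resid", "resname"], suffixes=(f"_{a}", f"_{b}")
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    merged["ratio"] = (
                        merged[f"value_{a}"] / merged[f"value_{b}"]
                    )
                _write_tsv(merged, outdir / f"ratio_{metric}_{a}_over_{b}.tsv", written)

        if config.xfms_path:
            stage = "xfms"
            report["xfms"] = _run_xfms_stage(
                config, per_condition_tables, class_maps, outdir, written
            )

        stage = "manifest"
        echo = config.echo()
        manifest = {
            "package": "bmcpore",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(echo.encode()).hexdigest(),
            "outputs": [str(p) for p in written],
        }
        (outdir / "config_echo.yaml").write_text(echo)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        written += [outdir / "config_echo.yaml", outdir / "manifest.json"]
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report["outputs"] = [str(p) for p in written]
    report["seed"] = config.seed
    return report


def _sim_class_ratio(
    table: pd.DataFrame, class_map: dict[str, str], resids: list[int]
) -> Ratio:
    """Exposed/buried mean ratio of a per-residue metric over given resids."""
    sub = table[table["resid"].isin(resids) & table["chain"].isin(class_map)]
    if sub.empty:
        return Ratio(float("nan"), float("nan"), defined=False)
    cls = sub["chain"].map(class_map)
    exposed = sub.loc[cls == "exposed", "value"].mean()
    buried = sub.loc[cls == "buried-interface", "value"].mean()
    if not np.isfinite(buried) or buried == 0 or not np.isfinite(exposed):
        return Ratio(float("nan"), float("nan"), defined=False)
    return Ratio(float(exposed / buried), 0.0, defined=True)


def _run_xfms_stage(config, per_condition_tables, class_maps, outdir, written):
    curves = load_dose_response_csv(config.xfms_path)
    fits = {}
    for dr in curves:
        fits[(dr.site, dr.condition)] = fit_dose_response(dr, model=config.xfms_model)
    k_rows = [
        dict(site=site, condition=cond, k=kv.k, stderr=kv.stderr, at_boundary=kv.at_boundary)
        for (site, cond), kv in fits.items()
    ]
    _write_tsv(pd.DataFrame(k_rows), outdir / "xfms_kvalues.tsv", written)

    sites = sorted({s for s, _ in fits})
    # Structure-derived ratios use the shell condition's monomer classes:
    # exposed monomers stand in for dilute tiles in solution, buried-interface
    # monomers for the assembled shell.
    struct_label = "shell" if "shell" in per_condition_tables else next(iter(per_condition_tables))
    class_map = class_maps.get(struct_label, {})
    tables = per_condition_tables[struct_label]
    comparisons = []
    ratio_rows = []
    for site in sites:
        ka = fits.get((site, "solution"))
        kb = fits.get((site, "shell"))
        if ka is None or kb is None:
            continue
        exp = k_ratio(ka, kb)
        resids = config.xfms_site_map.get(site, [])
        sasa_r = _sim_class_ratio(tables["sasa"], class_map, resids) if resids else None
        ret_r = (
            _sim_class_ratio(tables["retention"], class_map, resids) if resids else None
        )
        comparisons.append(
            RatioComparison(
                site=site, exp_ratio=exp, sim_sasa_ratio=sasa_r, sim_retention_ratio=ret_r
            )
        )
        ratio_rows.append(
            dict(
                site=site,
                exp_ratio=exp.value,
                exp_ratio_stderr=exp.stderr,
                sim_sasa_ratio=sasa_r.value if sasa_r else float("nan"),
                sim_retention_ratio=ret_r.value if ret_r else float("nan"),
            )
        )
    _write_tsv(pd.DataFrame(ratio_rows), outdir / "xfms_ratios.tsv", written)

    result = {"n_sites": len(comparisons)}
    for kind in ("sasa", "retention"):
        try:
            slope, intercept, r, excluded = ratio_correlation(comparisons, x=kind)
        except ValueError:
            continue
        result[f"{kind}_correlation"] = dict(
            slope=slope, intercept=intercept, r=r, excluded=excluded
        )
        lines = [
            f"correlation of experimental k-ratios vs simulated {kind} ratios",
            f"slope     {slope:.6g}",
            f"intercept {intercept:.6g}",
            f"pearson_r {r:.6g}",
            f"excluded  {', '.join(excluded) if excluded else '(none)'}",
        ]
        path = outdir / f"xfms_correlation_{kind}.txt"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return result
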