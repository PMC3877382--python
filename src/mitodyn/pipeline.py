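"""End-to-end pipeline: simulate -> analyze -> summarize -> report bundle.

A run is described by a YAML (or dict) config naming the stages to execute,
the presets per stage and the comparisons to report.  All tabular output is
CSV with a fixed float format, so identical config + seed reproduce
byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__, bioenergetics, io, morphology, potential, presets, simulate, transport
from .stats import group_summary, two_group_t

_STAGES = ("transport", "morphology", "potential", "flux")
_FLOAT_FMT = "%.6g"


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _derived_seed(base: int, k: int) -> int:
    return int((base * 100003 + k) % (2 ** 31))


def validate_config(cfg: dict) -> None:
    """Fail before any computation if a stage references missing inputs."""
    stages = cfg.get("stages", list(_STAGES))
    for st in stages:
        if st not in _STAGES:
            raise ValueError(f"unknown stage {st!r}; known: {list(_STAGES)}")
        section = cfg.get(st)
        if section is None:
            raise ValueError(f"stage {st!r} requested but has no config section")
        if st == "transport":
            for name in section.get("presets", []):
                presets.transport_preset(name)
        elif st == "morphology":
            for name in section.get("presets", []):
                presets.morphology_preset(name)
        elif st == "flux":
            for name in section.get("presets", []):
                presets.flux_preset(name)
        elif st == "potential":
            groups = section.get("groups", {})
            ctrl = section.get("control")
            if ctrl not in groups:
                raise ValueError(f"potential control group {ctrl!r} not among "
                                 f"groups {sorted(groups)}")


def _save_bar(path, labels, means, sems, ylabel):
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(labels)), means, yerr=sems, capsize=4,
           color="#888", edgecolor="k")
    ax.set_xticks(range(len(labels)), labels, rotation=30, ha="right")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _run_transport(section, base_seed, out: Path):
    n_seeds = int(section.get("n_seeds", 2))
    rows, track_rows, comp_rows = [], [], []
    per_preset_vels: dict[str, list[np.ndarray]] = {}
    for name in section["presets"]:
        vels_by_seed = []
        for k in range(n_seeds):
            preset = presets.transport_preset(name, seed=_derived_seed(base_seed, k))
            movie, truth = simulate.simulate_transport_movie(preset)
            recovered = transport.recover_tracks(
                movie, pixel_size=preset.pixel_size,
                frame_interval=preset.frame_interval, psf_sigma=preset.psf_sigma,
                max_step=transport.max_step_for_preset(preset))
            st = transport.summarize_transport(recovered)
            vels_by_seed.append(st.per_particle["overall_velocity"].to_numpy())
            for _, r in st.per_particle.iterrows():
                track_rows.append({"preset": name, "seed_index": k, **r})
            rows.append({
                "preset": name, "seed_index": k, "n_tracks": st.n,
                "mean_velocity_um_s": st.mean_velocity,
                "sem_velocity_um_s": st.sem_velocity,
                "mobile_fraction_pct": st.mobile_fraction_pct,
                "mean_instantaneous_um_s": st.mean_instantaneous,
                "sem_instantaneous_um_s": st.sem_instantaneous,
            })
            if k == 0:
                mid = preset.height_px / 2
                kymo = transport.build_kymograph(
                    movie, [(0, mid), (movie.shape[2] - 1, mid)],
                    frame_interval=preset.frame_interval,
                    pixel_size=preset.pixel_size)
                fig, ax = plt.subplots(figsize=(6, 3))
                ax.imshow(kymo.matrix, aspect="auto", cmap="gray",
                          extent=[0, kymo.matrix.shape[1] * preset.pixel_size,
                                  preset.duration, 0])
                ax.set_xlabel("distance (μm)")
                ax.set_ylabel("time (s)")
                fig.tight_layout()
                fig.savefig(out / f"kymograph_{name}.png", dpi=120)
                plt.close(fig)
        per_preset_vels[name] = vels_by_seed
    for pair in section.get("compare", []):
        a, b = pair
        for k in range(n_seeds):
            tt = two_group_t(per_preset_vels[a][k], per_preset_vels[b][k])
            comp_rows.append({"metric": "overall_velocity", "group_a": a,
                              "group_b": b, "seed_index": k, "t": tt.t,
                              "p": tt.p, "significant_0.05": tt.p < 0.05})
    pd.DataFrame(track_rows).to_csv(out / "transport_tracks.csv", index=False,
                                    float_format=_FLOAT_FMT)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "transport_summary.csv", index=False, float_format=_FLOAT_FMT)
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(out / "transport_comparisons.csv",
                                       index=False, float_format=_FLOAT_FMT)
    g = summary.groupby("preset")["mean_velocity_um_s"]
    _save_bar(out / "transport_velocity.png", list(g.mean().index),
              g.mean().to_numpy(), g.sem().fillna(0).to_numpy(),
              "overall velocity (μm/s)")


def _run_morphology(section, base_seed, out: Path):
    n_seeds = int(section.get("n_seeds", 2))
    obj_rows, sum_rows = [], []
    lengths: dict[str, np.ndarray] = {}
    for name in section["presets"]:
        all_recs = []
        for k in range(n_seeds):
            preset = presets.morphology_preset(name, seed=_derived_seed(base_seed, k))
            image, truth = simulate.simulate_morphology_image(preset)
            labels = morphology.segment_mitochondria(image, preset.pixel_size)
            recs = morphology.filter_isolated(
                morphology.shape_descriptors(labels, preset.pixel_size, truth))
            all_recs.extend(recs)
            for r in recs:
                obj_rows.append({"preset": name, "seed_index": k, **r.__dict__})
        summ = morphology.summarize_morphology(all_recs)
        summ.insert(0, "preset", name)
        sum_rows.append(summ)
        lengths[name] = np.array([r.major_axis for r in all_recs])
    pd.DataFrame(obj_rows).to_csv(out / "morphology_objects.csv", index=False,
                                  float_format=_FLOAT_FMT)
    pd.concat(sum_rows).to_csv(out / "morphology_summary.csv", index=False,
                               float_format=_FLOAT_FMT)
    comp_rows = []
    for a, b in section.get("compare", []):
        tt = two_group_t(lengths[a], lengths[b])
        comp_rows.append({"metric": "length", "group_a": a, "group_b": b,
                          "t": tt.t, "p": tt.p, "significant_0.05": tt.p < 0.05})
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(out / "morphology_comparisons.csv",
                                       index=False, float_format=_FLOAT_FMT)
    names = list(lengths)
    _save_bar(out / "morphology_length.png", names,
              [lengths[n].mean() for n in names],
              [lengths[n].std(ddof=1) / np.sqrt(len(lengths[n])) for n in names],
              "mitochondrial length (μm)")


def _run_potential(section, base_seed, out: Path):
    groups = section["groups"]
    n_cells = int(section.get("n_cells", 30))
    intensity_sd = float(section.get("intensity_sd", 5.0))
    records = []
    for gi, (gname, mean_int) in enumerate(sorted(groups.items())):
        image, rois = simulate.simulate_soma_field(
            n_cells, mean_int, intensity_sd, seed=_derived_seed(base_seed, gi))
        records.extend(potential.measure_soma_intensity(image, rois, group=gname))
    df = potential.normalize_to_control(records, section["control"])
    df.to_csv(out / "potential_cells.csv", index=False, float_format=_FLOAT_FMT)
    rows = []
    for gname, gdf in df.groupby("group"):
        gs = group_summary(gdf["normalized_pct"].to_numpy())
        rows.append({"group": gname, "mean_normalized_pct": gs.mean,
                     "sem": gs.sem, "n": gs.n})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "potential_summary.csv", index=False, float_format=_FLOAT_FMT)
    _save_bar(out / "potential_intensity.png", list(summary["group"]),
              summary["mean_normalized_pct"].to_numpy(),
              summary["sem"].to_numpy(), "dye intensity (% of control)")


def _run_flux(section, base_seed, out: Path):
    n_wells = int(section.get("n_wells", 4))
    prof_rows = []
    by_group: dict[str, dict[str, list[float]]] = {}
    for name in section["presets"]:
        for k in range(n_wells):
            preset = presets.flux_preset(name, seed=_derived_seed(base_seed, k))
            trace = simulate.simulate_flux_trace(preset, well_id=f"{name}_{k}")
            prof = bioenergetics.normalize_per_protein(
                bioenergetics.derive_profile(trace), preset.protein_ug)
            row = {"preset": name, "well_id": prof.well_id,
                   "basal_ocr": prof.basal_ocr,
                   "ocr_ecar_ratio": prof.ocr_ecar_ratio,
                   "mito_respiration": prof.mito_respiration,
                   "atp_linked": prof.atp_linked,
                   "proton_leak": prof.proton_leak,
                   "non_mito": prof.non_mito,
                   "max_capacity": prof.max_capacity,
                   "basal_per_protein": prof.basal_per_protein,
                   "qc_warnings": ";".join(prof.warnings)}
            prof_rows.append(row)
            g = by_group.setdefault(name, {})
            for key in ("basal_ocr", "ocr_ecar_ratio", "mito_respiration",
                        "atp_linked", "proton_leak", "non_mito", "max_capacity"):
                g.setdefault(key, []).append(row[key])
    pd.DataFrame(prof_rows).to_csv(out / "flux_profiles.csv", index=False,
                                   float_format=_FLOAT_FMT)
    sum_rows = []
    for name, metrics in by_group.items():
        for key, vals in metrics.items():
            gs = group_summary(vals)
            sum_rows.append({"preset": name, "metric": key, "mean": gs.mean,
                             "sem": gs.sem, "n": gs.n})
    pd.DataFrame(sum_rows).to_csv(out / "flux_summary.csv", index=False,
                                  float_format=_FLOAT_FMT)
    comp_rows = []
    for a, b in section.get("compare", []):
        for key in by_group[a]:
            tt = two_group_t(by_group[a][key], by_group[b][key])
            comp_rows.append({"metric": key, "group_a": a, "group_b": b,
                              "t": tt.t, "p": tt.p,
                              "significant_0.05": tt.p < 0.05})
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(out / "flux_comparisons.csv", index=False,
                                       float_format=_FLOAT_FMT)


def run_pipeline(config, seed: int | None = None, out_dir=None) -> Path:
    """Execute the configured stages and write the report bundle.

    Returns the output directory.  The bundle contains per-item and summary
    CSVs, comparison tables, kymograph/bar figures and ``run_log.json``
    (seed, package version, config echo).
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    base_seed = int(cfg.get("seed", 0))
    out = Path(cfg.get("out_dir", "mitodyn_out"))
    validate_config(cfg)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", list(_STAGES))
    runners = {"transport": _run_transport, "morphology": _run_morphology,
               "potential": _run_potential, "flux": _run_flux}
    for st in stages:
        runners[st](cfg[st], base_seed, out)
    (out / "run_log.json").write_text(json.dumps(
        {"version": __version__, "seed": base_seed, "stages": list(stages),
         "config": cfg}, indent=2, sort_keys=True, default=str))
    return out


def write_synthetic_inputs(config, seed: int | None = None, out_dir=None) -> Path:
    """Materialize the configured synthetic inputs (TIFF/JSON/CSV) on disk."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    base_seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "mitodyn_out"))
    validate_config(cfg)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", list(_STAGES))
    if "transport" in stages:
        for name in cfg["transport"]["presets"]:
            preset = presets.transport_preset(name, seed=_derived_seed(base_seed, 0))
            movie, tracks = simulate.simulate_transport_movie(preset)
            io.write_movie(out / f"movie_{name}.tif", movie)
            io.write_tracks_json(out / f"tracks_{name}.json", tracks,
                                 preset.pixel_size, preset.frame_interval)
    if "morphology" in stages:
        for name in cfg["morphology"]["presets"]:
            preset = presets.morphology_preset(name, seed=_derived_seed(base_seed, 0))
            image, truth = simulate.simulate_morphology_image(preset)
            io.write_movie(out / f"field_{name}.tif", image)
            (out / f"truth_{name}.json").write_text(json.dumps(truth))
    if "potential" in stages:
        sec = cfg["potential"]
        for gi, (gname, mean_int) in enumerate(sorted(sec["groups"].items())):
            image, rois = simulate.simulate_soma_field(
                int(sec.get("n_cells", 30)), mean_int,
                float(sec.get("intensity_sd", 5.0)),
                seed=_derived_seed(base_seed, gi))
            io.write_movie(out / f"soma_{gname}.tif", image)
            io.write_rois_json(out / f"rois_{gname}.json", rois)
    if "flux" in stages:
        for name in cfg["flux"]["presets"]:
            preset = presets.flux_preset(name, seed=_derived_seed(base_seed, 0))
            io.write_flux_csv(out / f"flux_{name}.csv",
                              simulate.simulate_flux_trace(preset))
    return out
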