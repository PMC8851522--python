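"""Config-driven orchestration: simulate -> score -> gate -> effects -> SAM.

A run is fully described by a YAML/dict config plus a master seed; stages
execute in dependency order, every output is a plain CSV/JSON file, and a
manifest (config hash, seed, package/library versions, per-file SHA-256)
makes reruns auditable. Re-running with an identical config and seed
reproduces every output byte for byte (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cyto, effects as fx, ifnscore, serology, synth
from .errors import ConfigError, DataError

DEFAULT_CONFIG = {
    "seed": 0,
    "qpcr": {"n_sle": 40, "n_hc": 12, "n_genes": 44},
    "cytof": {
        "n_samples_per_group": 6,
        "cells_per_sample": 2000,
        "stimulations": ["US", "IFNa"],
        "effects": {"CD4_T|pSTAT1|IFNa": 1.0},
        "downsample": 35000,
    },
    "gates": None,  # YAML path; default = gates matching the generator
    "arcsinh_cofactor": 5.0,
    "zero_threshold": 0.125,
    "min_cells": 25,
    "effects": {"contrast": ["IFN-H", "IFN-L"], "per_stimulation": True,
                "fdr": 0.05, "sd_mode": "pooled"},
    "arrays": {"n_per_group": 6, "n_antigens": 12,
               "reactive": {"U1A": 2.0, "U1-70": 1.5}, "noise_sd": 0.4},
    "sam": {"n_perm": "exhaustive", "q": 0.05},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def load_config(path) -> dict:
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config YAML {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    merged = {}
    for key, default in DEFAULT_CONFIG.items():
        val = cfg.get(key, default)
        if isinstance(default, dict) and val is not None:
            if not isinstance(val, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            bad = set(val) - set(default)
            if bad:
                raise ConfigError(f"unknown key(s) under {key!r}: {sorted(bad)}")
            val = default | val
        merged[key] = val
    if not isinstance(merged["seed"], int) or merged["seed"] < 0:
        raise ConfigError("seed must be a nonnegative integer")
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _parse_effect_keys(d: dict) -> dict:
    out = {}
    for key, delta in (d or {}).items():
        parts = str(key).split("|")
        if len(parts) != 3:
            raise ConfigError(f"effect key must be 'population|marker|stimulation', got {key!r}")
        out[tuple(parts)] = float(delta)
    return out


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Execute the full synthetic pipeline; returns the manifest dict.

    Outputs in ``out_dir``: ct.csv, scores.csv, summaries.csv, effects.csv,
    dotmap.csv, forest.csv, mfi.csv, sam.csv, truth.json, manifest.json.
    """
    cfg = load_config(config) if not isinstance(config, dict) else validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    log: list[str] = [f"ifncyto {__version__} run, seed={seed}"]
    truth_all: dict = {}

    # --- stage 1: qPCR simulation + IFN scoring -----------------------------
    stage = "qpcr"
    try:
        q = cfg["qpcr"]
        ctm, truth_q = synth.generate_qpcr_cohort(q["n_sle"], q["n_hc"],
                                                  q["n_genes"], seed=seed)
        _write_ct_csv(ctm, out / "ct.csv")
        expr = ifnscore.normalize_to_housekeeping(ifnscore.collapse_replicates(ctm))
        table = ifnscore.compute_ifn_score(expr, groups=truth_q.groups)
        table = ifnscore.stratify_quartiles(table)
        table.to_csv(out / "scores.csv")
        truth_all["qpcr"] = truth_q.to_json_dict()
        log.append(f"qpcr: {len(ctm.samples)} samples, {len(ctm.assays)} assays; "
                   f"IFN-H n={int((table['stratum'] == 'IFN-H').sum())}")

        # --- stage 2: cytometry -------------------------------------------
        stage = "cytof"
        c = cfg["cytof"]
        tables, truth_c = synth.generate_cytof_events(
            c["n_samples_per_group"], cells_per_sample=c["cells_per_sample"],
            effects=_parse_effect_keys(c["effects"]),
            stimulations=tuple(c["stimulations"]), seed=seed)
        gates = (cyto.load_gates(cfg["gates"]) if cfg["gates"]
                 else synth.truth_gates())
        processed = []
        for i, t in enumerate(tables):
            t = cyto.arcsinh_transform(t, cfg["arcsinh_cofactor"])
            t = cyto.zero_threshold(t, cfg["zero_threshold"])
            t = cyto.downsample(t, int(c["downsample"]), seed=seed + 7919 * i)
            processed.append(t)
        gated_markers = sorted({mk for g in gates for mk, _ in g.constraints})
        pooled = pd.concat([t.data[gated_markers] for t in processed])
        cuts = {mk: cyto.derive_marker_threshold(pooled[mk].to_numpy())[0]
                for mk in gated_markers}
        summaries = pd.concat(
            [cyto.summarize(t, cyto.assign_populations(t, gates, cuts), gates,
                            min_cells=cfg["min_cells"]) for t in processed],
            ignore_index=True)
        summaries.to_csv(out / "summaries.csv", index=False)
        truth_all["cytof"] = truth_c.to_json_dict()
        log.append(f"cytof: {len(processed)} event tables, cuts={cuts}")

        # --- stage 3: effect sizes ----------------------------------------
        stage = "effects"
        e = cfg["effects"]
        res = fx.run_effects(summaries, tuple(e["contrast"]),
                             per_stimulation=e["per_stimulation"],
                             sd_mode=e["sd_mode"], stat="median")
        res.to_csv(out / "effects.csv", index=False)
        dotmap, forest = fx.build_dotmap_table(res, e["fdr"])
        dotmap.to_csv(out / "dotmap.csv", index=False)
        forest.to_csv(out / "forest.csv", index=False)
        log.append(f"effects: {len(res)} tests, {len(dotmap)} at FDR<{e['fdr']}")

        # --- stage 4: serology --------------------------------------------
        stage = "serology"
        a = cfg["arrays"]
        antigens = (["U1A", "U1-70", "SmRNP", "Smith", "Ro-SSA", "La-SSB"]
                    + [f"Ag{i:02d}" for i in range(max(0, a["n_antigens"] - 6))])[: a["n_antigens"]]
        mfim, truth_a = synth.generate_array_data(
            a["n_per_group"], antigens, a["reactive"], a["noise_sd"],
            group_labels=("IFN-L", "IFN-H"), seed=seed)
        mfim.mfi.to_csv(out / "mfi.csv")
        clean, reactive_flags = serology.preprocess_mfi(mfim)
        s = cfg["sam"]
        sam = serology.sam_rank(clean, n_perm=s["n_perm"], seed=seed,
                                q_call=s["q"], reactive=reactive_flags)
        sam.to_csv(out / "sam.csv")
        truth_all["arrays"] = truth_a.to_json_dict()
        log.append(f"sam: {int(sam['called'].sum())} antigen(s) called at q<{s['q']}")
    except (ConfigError,):
        raise
    except Exception as exc:
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "truth.json").write_text(json.dumps(truth_all, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": cfg, "config_sha256": cfg_hash, "seed": seed,
        "versions": {"ifncyto": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_ct_csv(ctm, path) -> None:
    cols = {}
    for j, assay in enumerate(ctm.assays):
        for r in range(ctm.n_replicates):
            vals = []
            for i in range(len(ctm.samples)):
                vals.append("Undetermined" if ctm.undetermined[i, j, r]
                            else f"{ctm.ct[i, j, r]:.4f}")
            cols[f"{assay}_{r+1}"] = vals
    pd.DataFrame(cols, index=pd.Index(ctm.samples, name="sample")).to_csv(path)
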