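"""Pipeline orchestration: simulate -> quant -> histology -> lefse -> associate.

Each stage reads and writes the plain-text interchange files defined in
:mod:`viscnet.io`, so any stage can be rerun standalone on the previous
stage's outputs.  :func:`run_pipeline` executes all stages from a single
config and writes a reproducibility manifest (config hash, master seed,
per-stage row counts, output file hashes); a rerun with the same config and
seed reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as vio
from .associations import associate
from .errors import ValidationError
from .histology import score_table
from .lefse import AbundanceTable, run_lefse
from .quant import TimeActivityCurve, quantify_cohort
from .simulate import (
    DEFAULT_PLANTED_EFFECTS,
    StudyDesign,
    generate_cohort,
    generate_taxa_table,
)

DEFAULT_CONFIG = {
    "seed": 0,
    "noise_cv": 0.05,
    "jitter_sigma": 0.25,
    "n_taxa": 40,
    "pid_g_convention": "per_g_bw",  # %ID/g normalisation convention
    "lefse_class": "age_group",      # stratifier for biomarker discovery
    "lda_threshold": 3.0,
    "alpha": 0.05,
}


def _merged_config(config: Optional[dict]) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValidationError(f"unknown config key(s) {sorted(unknown)}")
        cfg.update(config)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(design: StudyDesign, out_dir, n_taxa: int = 40) -> Dict[str, int]:
    """Generate a cohort and write every interchange file.

    Writes subjects.csv, one tac_<subject>.csv per subject, histology.csv
    (subjects with processed biopsies only), ct_density.csv and
    abundance.tsv (taxa table with the default planted age-group effects).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(design)

    vio.write_subject_table([r.meta for r in cohort], out_dir / "subjects.csv")
    for rec in cohort:
        curves = {
            roi: (tac.times, tac.activities) for roi, tac in rec.tacs.items()
        }
        vio.write_tac_table(curves, out_dir / f"tac_{rec.meta.subject_id}.csv")

    hist_rows = [
        {"subject_id": rec.meta.subject_id, **rec.histology}
        for rec in cohort
        if rec.meta.histology_available
    ]
    vio.write_histology_table(
        pd.DataFrame(hist_rows, columns=vio.HISTOLOGY_COLUMNS),
        out_dir / "histology.csv",
    )

    dens_rows = [
        {"subject_id": rec.meta.subject_id, "roi": roi, "density_HU": hu}
        for rec in cohort
        for roi, hu in sorted(rec.ct_density_HU.items())
    ]
    pd.DataFrame(dens_rows).to_csv(
        out_dir / "ct_density.csv", index=False
    )

    table = generate_taxa_table(
        subject_ids=[r.meta.subject_id for r in cohort],
        class_labels=[r.meta.age_group for r in cohort],
        n_taxa=n_taxa,
        planted_effects=DEFAULT_PLANTED_EFFECTS,
        seed=design.seed,
    )
    vio.write_abundance_table(table.to_dataframe(), out_dir / "abundance.tsv")
    return {
        "subjects": len(cohort),
        "histology_rows": len(hist_rows),
        "taxa": n_taxa,
    }


def stage_quant(subjects_csv, tac_dir, out_csv, convention: str = "per_g_bw") -> int:
    """Quantify every subject's TACs into the metrics table."""
    subjects = vio.read_subject_table(subjects_csv)
    tac_dir = Path(tac_dir)
    tacs = {}
    for meta in subjects:
        path = tac_dir / f"tac_{meta.subject_id}.csv"
        if not path.exists():
            raise ValidationError(
                f"missing TAC file for subject {meta.subject_id!r}: {path}"
            )
        curves = vio.read_tac_table(path)
        tacs[meta.subject_id] = {
            roi: TimeActivityCurve(t, a, roi) for roi, (t, a) in curves.items()
        }
    metrics = quantify_cohort(subjects, tacs, convention)
    metrics.to_csv(out_csv, index=False)
    return len(metrics)


def stage_histology(in_csv, out_csv) -> int:
    """Grade a raw histology table and write the scored table."""
    scored = score_table(vio.read_histology_table(in_csv))
    vio.write_histology_table(scored, out_csv)
    return len(scored)


def stage_lefse(
    abundance_tsv,
    subjects_csv,
    class_column: str,
    out_tsv,
    lda_threshold: float = 3.0,
    alpha: float = 0.05,
) -> int:
    """Run biomarker discovery stratified by a subject metadata column."""
    df = vio.read_abundance_table(abundance_tsv)
    subjects = vio.read_subject_table(subjects_csv)
    if class_column not in ("age_group", "maternal_diet"):
        raise ValidationError(
            f"class column must be 'age_group' or 'maternal_diet', got {class_column!r}"
        )
    labels = {s.subject_id: getattr(s, class_column) for s in subjects}
    table = AbundanceTable.from_dataframe(df, labels)
    result = run_lefse(table, alpha=alpha, lda_threshold=lda_threshold)
    result.to_csv(out_tsv, sep="\t", index=False)
    return len(result)


def stage_associate(metrics_csv, abundance_tsv, out_tsv) -> int:
    """Correlation screen of imaging metrics against taxa abundances."""
    metrics = pd.read_csv(metrics_csv, float_precision="round_trip").set_index("subject_id")
    X = metrics.select_dtypes(include=[np.number])
    Y = vio.read_abundance_table(abundance_tsv).T  # subjects x taxa
    out = associate(X, Y)
    out.to_csv(out_tsv, sep="\t", index=False)
    return len(out)


def run_pipeline(config: Optional[dict], out_dir) -> dict:
    """Execute all stages on a simulated cohort; return the manifest.

    ``config`` may override any :data:`DEFAULT_CONFIG` key.  The manifest
    records the canonical config hash, the master seed, per-stage row
    counts and the sha256 of every output file, and is written to
    ``manifest.json`` in ``out_dir``.
    """
    cfg = _merged_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    design = StudyDesign(
        seed=int(cfg["seed"]),
        noise_cv=float(cfg["noise_cv"]),
        jitter_sigma=float(cfg["jitter_sigma"]),
    )
    counts = {}
    counts["simulate"] = stage_simulate(design, out_dir, n_taxa=int(cfg["n_taxa"]))
    counts["quant"] = stage_quant(
        out_dir / "subjects.csv", out_dir, out_dir / "metrics.csv",
        convention=cfg["pid_g_convention"],
    )
    counts["histology"] = stage_histology(
        out_dir / "histology.csv", out_dir / "histology_scored.csv"
    )
    counts["lefse"] = stage_lefse(
        out_dir / "abundance.tsv", out_dir / "subjects.csv",
        cfg["lefse_class"], out_dir / "biomarkers.tsv",
        lda_threshold=float(cfg["lda_threshold"]), alpha=float(cfg["alpha"]),
    )
    counts["associate"] = stage_associate(
        out_dir / "metrics.csv", out_dir / "abundance.tsv",
        out_dir / "associations.tsv",
    )

    config_blob = json.dumps(cfg, sort_keys=True).encode()
    outputs = sorted(
        p.name for p in out_dir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "seed": int(cfg["seed"]),
        "stage_counts": counts,
        "outputs": {name: _sha256(out_dir / name) for name in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
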