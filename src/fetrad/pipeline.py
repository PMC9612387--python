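"""End-to-end pipeline: simulate → parametric maps → features → stats → CV.

Patients are processed one at a time (the 4D volume is dropped as soon as its
three parametric maps and six feature rows exist), so memory stays flat in
the cohort size. Everything derives from one master seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .classify import TumorClassifier, univariate_auc
from .features import DiscretizationConfig, all_feature_names, extract_all
from .io import RunConfig
from .maps import IMAGE_KINDS, compute_parametric_maps
from .phantom import cohort_recipes, simulate_patient
from .screening import PairedFeatureScreen
from .tables import validate_feature_table

log = logging.getLogger("fetrad")

__all__ = ["extract_patient_rows", "build_feature_table", "run_full_pipeline"]


def extract_patient_rows(
    patient, disc_config: DiscretizationConfig, ttp_smoothing: int | None = None
) -> list[dict]:
    """The six feature rows (2 VOIs × 3 image kinds) of one patient."""
    maps = compute_parametric_maps(
        patient.dynamic_image, patient.voi_set.crescent_mask, ttp_smoothing
    )
    vol = patient.dynamic_image.voxel_volume_mm3
    rows = []
    for kind in IMAGE_KINDS:
        for voi_label, mask in (
            ("tumor", patient.voi_set.tumor_mask),
            ("mirrored", patient.voi_set.mirrored_mask),
        ):
            fv = extract_all(
                maps[kind].voxels, mask, disc_config, vol, kind, voi_label
            )
            row = {
                "patient_id": patient.patient_id,
                "phenotype": patient.phenotype,
                "voi": voi_label,
                "kind": kind,
            }
            row.update(fv.values)
            row["degenerate"] = ";".join(sorted(fv.degenerate))
            rows.append(row)
    return rows


def build_feature_table(config: RunConfig) -> pd.DataFrame:
    """Simulate the cohort and extract the full feature table, streaming."""
    disc = DiscretizationConfig(bin_count=config.bin_count)
    mix = (config.isometabolic_fraction, 1.0 - config.isometabolic_fraction)
    rows: list[dict] = []
    for recipe in cohort_recipes(
        config.n_patients, mix, config.base_seed, config.noise_scale
    ):
        patient = simulate_patient(
            recipe["spec"],
            recipe["tissue_params"],
            recipe["seed"],
            patient_id=recipe["patient_id"],
        )
        log.info("extracted %s (%s)", patient.patient_id, patient.phenotype)
        rows.extend(extract_patient_rows(patient, disc, config.ttp_smoothing))
    table = pd.DataFrame(rows)
    validate_feature_table(table)
    return table


def run_full_pipeline(config: RunConfig) -> dict:
    """Run the whole study and write all artifacts under ``config.out_dir``.

    Returns a result bundle with the feature table, the fitted screen and
    classification results, and (optionally) the univariate ranking.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    chash = config.hash()

    try:
        table = build_feature_table(config)
    except Exception as err:  # noqa: BLE001 - stage tagging
        raise RuntimeError(f"[stage: simulate/extract] {err}") from err
    table["config_hash"] = chash
    table.to_csv(out / "features.csv", index=False)

    # subgroups with enough pairs only (a tiny smoke cohort may lack one)
    present = [
        sg
        for sg in ("all", "isometabolic", "photopenic")
        if sg == "all" or (table["phenotype"] == sg).sum() >= 5 * 6
    ]
    try:
        screen = PairedFeatureScreen(table, subgroups=present, alpha=config.alpha).fit()
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[stage: stats] {err}") from err
    results = screen.to_frame()
    results["config_hash"] = chash
    results.to_csv(out / "wilcoxon.csv", index=False)
    census = screen.census()
    census["config_hash"] = chash
    census.to_csv(out / "census.csv", index=False)

    try:
        cv = TumorClassifier(
            table, subgroups=present, config=config.classification_config()
        ).fit()
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[stage: classify] {err}") from err
    cv_frame = cv.to_frame()
    cv_frame["config_hash"] = chash
    cv_frame.to_csv(out / "cv_auc.csv", index=False)

    bundle = {"table": table, "screen": screen, "cv": cv, "census": census}

    if config.run_univariate:
        uni = {
            sg: univariate_auc(table, sg, config.classification_config())
            for sg in present
        }
        uni_frame = pd.DataFrame(
            [
                {
                    "subgroup": sg,
                    "feature_set": r.feature_set,
                    "auc_mean": r.mean,
                    "auc_sd": r.sd,
                }
                for sg, reports in uni.items()
                for r in reports
            ]
        )
        uni_frame["config_hash"] = chash
        uni_frame.to_csv(out / "univariate_auc.csv", index=False)
        bundle["univariate"] = uni
    return bundle
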