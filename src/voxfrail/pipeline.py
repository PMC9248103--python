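"""End-to-end orchestration: simulate -> extract -> score -> associate.

Each stage writes its table under the run directory; a manifest records
the config hash, seed, package version, and per-stage row counts so a
run can be reproduced and audited.  Any stage failure leaves partial
outputs in place together with a FAILED marker file.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

from . import __version__
from .acoustics import extract_features_batch
from .config import RunConfig
from .frailty import score_all
from .io import write_manifest, write_wav
from .stats import anova_table, descriptive_table, stratified_associations
from .synthdata import simulate_cohort

__all__ = ["run_pipeline"]

log = logging.getLogger("voxfrail")


def _write_probability_curves(features, assoc, path, n_points: int = 25) -> None:
    """Predicted frailty probability over each feature's observed range
    for every converged whole-cohort model."""
    import numpy as np
    import pandas as pd

    from .stats import AssociationResult, probability_curve

    rows = []
    sub = assoc[(assoc["stratum"] == "all") & assoc["converged"] & assoc["estimable"]]
    for _, r in sub.iterrows():
        vals = features[r["feature"]].dropna()
        grid = np.linspace(vals.min(), vals.max(), n_points)
        model = AssociationResult(
            r["feature"], r["index"], "all", r["or"], (r["ci_low"], r["ci_high"]),
            r["p_value"], r["scale_unit"], int(r["n"]), True,
            intercept=r["intercept"], coef=r["coef"],
        )
        probs = probability_curve(model, grid)
        rows.extend(
            {"feature": r["feature"], "index": r["index"], "x": g, "probability": p}
            for g, p in zip(grid, probs)
        )
    pd.DataFrame(rows, columns=["feature", "index", "x", "probability"]).to_csv(path, index=False)


def run_pipeline(config: RunConfig, out_dir, write_audio: bool = False) -> Path:
    """Run the full pipeline into ``out_dir``; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    try:
        cohort_cfg = config.cohort
        if config.seed != 0 and cohort_cfg.seed == 0:
            import dataclasses

            cohort_cfg = dataclasses.replace(cohort_cfg, seed=config.seed)
        log.info("simulating cohort (n=%d)", cohort_cfg.n_participants)
        cohort = simulate_cohort(cohort_cfg)
        cohort.participants.to_csv(out / "cohort.csv", index=False)
        cohort.truth.to_csv(out / "truth.csv", index=False)
        counts["participants"] = len(cohort.participants)
        if write_audio:
            wav_dir = out / "wav"
            wav_dir.mkdir(exist_ok=True)
            for rec in cohort.recordings:
                write_wav(wav_dir / f"{rec.id}.wav", rec)

        log.info("extracting acoustic features")
        features = extract_features_batch(cohort.recordings, config.acoustics)
        features.to_csv(out / "features.csv", index=False)
        counts["features"] = len(features)
        n_invalid = int((~features["valid"]).sum())
        if n_invalid:
            log.warning("%d recordings yielded incomplete features", n_invalid)

        log.info("scoring frailty indices")
        assessments = score_all(cohort.participants, config.frailty)
        assessments.to_csv(out / "assessments.csv", index=False)
        counts["assessments"] = len(assessments)

        log.info("fitting associations")
        strata = ("all", "male", "female") if config.stats.stratify_sex else ("all",)
        assoc = stratified_associations(features, assessments, strata)
        assoc.to_csv(out / "associations.csv", index=False)
        counts["associations"] = len(assoc)

        anova_table(features, assessments).to_csv(out / "anova.csv", index=False)
        _write_probability_curves(features, assoc, out / "probability_curves.csv")
        for index in ("CHS", "SOF", "FRAIL"):
            descriptive_table(cohort.participants, assessments, index).to_csv(
                out / f"descriptive_{index.lower()}.csv", index=False
            )

        write_manifest(
            out / "manifest.json",
            {
                "config_hash": config.content_hash(),
                "seed": config.seed,
                "version": __version__,
                "row_counts": counts,
                "config": config.to_dict(),
            },
        )
        config.to_yaml(out / "config.yaml")
    except Exception:
        (out / "FAILED").write_text(traceback.format_exc())
        raise
    return out
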