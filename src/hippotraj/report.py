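"""End-to-end pipeline: cohort -> preprocessing -> curves -> inference
-> slopes, with a manifest that makes runs reproducible and
verifiable.

All randomness flows from one root seed: a ``numpy.random.SeedSequence``
is spawned per stage (cohort, permutation tests, KS match) in a fixed
order, so any stage can be re-run independently yet reproducibly.
Outputs are deterministic JSON/CSV; the manifest records the config
hash, derived seeds, per-stage row counts and output checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess, synthcohort
from .inference import factorial_anova, ks_match, window_permutation_test
from .regions import (
    CONTROL_REGIONS,
    HIPPOCAMPAL_REGIONS,
    TOTAL_GREY_MATTER,
    WHOLE_HIPPOCAMPUS,
)
from .slopes import slope_panel
from .windows import WindowSpec, stratified_curves

__all__ = ["default_config", "run_pipeline", "render_figures", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and region."""


def default_config() -> dict:
    """Desk-scale defaults: a 20k-subject synthetic cohort, the standard
    10%-occupancy / 20%-kernel windows, 1000 permutations per window."""
    return {
        "seed": 0,
        "cohort": {"n_subjects": 20000, "outlier_prob": 0.002},
        "changepoint": True,
        "regions": list(HIPPOCAMPAL_REGIONS) + list(CONTROL_REGIONS),
        "measure": "volume",        # or "log_ratio"
        "window": {"occupancy": 0.10, "n_windows": 100, "kernel_width": 0.20},
        "comparison": {"group_a": "e3/e3", "group_b": "e4/e4", "sex": None},
        "inference": {"n_permutations": 1000, "alpha": 0.001, "n_boot": 1000},
        "slopes": {"regions": list(HIPPOCAMPAL_REGIONS)},
        "input": None,              # path to an existing cohort CSV, else generate
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0]) % (2**31)


def run_pipeline(config: dict | str | Path | None = None,
                 outdir: str | Path = "pipeline_out") -> dict:
    """Execute every stage and write the results bundle to ``outdir``.

    ``config`` may be a dict (merged over :func:`default_config`), a
    YAML file path, or None for the defaults.  Returns the manifest.
    Outputs: ``curves.json``, ``tests.json``, ``ksmatch.json``,
    ``anova.json``, ``slopes.csv``, ``preprocess.json``,
    ``manifest.json``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(default_config(), config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(int(cfg["seed"]))
    ss_cohort, ss_perm, ss_ks = root.spawn(3)

    # --- cohort ---------------------------------------------------------
    try:
        if cfg["input"]:
            table = synthcohort.read_cohort(cfg["input"])
            input_checksum = _sha256(Path(cfg["input"]))
        else:
            spec = synthcohort.CohortSpec(
                seed=_stage_seed(ss_cohort), **cfg["cohort"]
            )
            trajs = synthcohort.default_trajectories(
                changepoint=bool(cfg["changepoint"])
            )
            table = synthcohort.generate_cohort(spec, trajs)
            input_checksum = None
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage 'cohort' failed: {exc}") from exc
    n_raw = len(table)

    # --- preprocessing --------------------------------------------------
    try:
        clean, prep_report = preprocess.preprocess_pipeline(table)
    except Exception as exc:
        raise PipelineError(f"stage 'preprocess' failed: {exc}") from exc
    _write_json(outdir / "preprocess.json", prep_report.to_dict())

    # --- sliding-window curves ------------------------------------------
    wspec = WindowSpec(**cfg["window"])
    comparison = cfg["comparison"]
    sex_filter = comparison.get("sex")
    analysis = clean if sex_filter is None else clean[clean["sex"] == sex_filter]
    curves_out: dict[str, dict] = {}
    curve_pairs: dict[str, tuple] = {}
    for region in cfg["regions"]:
        try:
            if cfg["measure"] == "log_ratio" and region != TOTAL_GREY_MATTER:
                values = preprocess.volume_ratio(analysis, region)
                values = values.reindex(analysis.index)
            else:
                values = analysis[region]
            curves, skipped = stratified_curves(
                analysis, values, by="apoe", spec=wspec, region=region
            )
        except Exception as exc:
            raise PipelineError(
                f"stage 'curves' failed for region {region!r}: {exc}"
            ) from exc
        curves_out[region] = {
            "skipped_strata": skipped,
            "strata": {k: c.to_dict() for k, c in curves.items()},
        }
        ga, gb = comparison["group_a"], comparison["group_b"]
        if ga in curves and gb in curves:
            curve_pairs[region] = (curves[ga], curves[gb])
    _write_json(outdir / "curves.json", curves_out)

    # --- permutation tests ----------------------------------------------
    inf_cfg = cfg["inference"]
    perm_children = ss_perm.spawn(len(cfg["regions"]))
    tests_out: dict[str, dict] = {}
    for region, child in zip(cfg["regions"], perm_children):
        if region not in curve_pairs:
            continue
        ca, cb = curve_pairs[region]
        try:
            res = window_permutation_test(
                ca, cb,
                n_permutations=int(inf_cfg["n_permutations"]),
                alpha=float(inf_cfg["alpha"]),
                seed=_stage_seed(child),
            )
        except Exception as exc:
            raise PipelineError(
                f"stage 'permutation' failed for region {region!r}: {exc}"
            ) from exc
        tests_out[region] = res.to_dict()
    _write_json(outdir / "tests.json", tests_out)

    # --- KS age-distribution match --------------------------------------
    ga, gb = comparison["group_a"], comparison["group_b"]
    age_a = analysis.loc[analysis["apoe"] == ga, "age"].to_numpy()
    age_b = analysis.loc[analysis["apoe"] == gb, "age"].to_numpy()
    try:
        ks = ks_match(
            age_a, age_b,
            n_boot=int(inf_cfg["n_boot"]),
            seed=_stage_seed(ss_ks),
            labels=(ga, gb),
        )
    except Exception as exc:
        raise PipelineError(f"stage 'ksmatch' failed: {exc}") from exc
    _write_json(outdir / "ksmatch.json", ks.to_dict())

    # --- factorial ANOVA -------------------------------------------------
    anova_out = {}
    for dep in (WHOLE_HIPPOCAMPUS, TOTAL_GREY_MATTER):
        try:
            anova_out[dep] = factorial_anova(clean, dep).to_dict()
        except Exception as exc:
            raise PipelineError(
                f"stage 'anova' failed for dependent {dep!r}: {exc}"
            ) from exc
    _write_json(outdir / "anova.json", anova_out)

    # --- annualized slopes -----------------------------------------------
    try:
        slopes = slope_panel(clean, cfg["slopes"]["regions"])
    except Exception as exc:
        raise PipelineError(f"stage 'slopes' failed: {exc}") from exc
    slopes.to_csv(outdir / "slopes.csv", index=False)

    # --- manifest ---------------------------------------------------------
    outputs = [
        "preprocess.json", "curves.json", "tests.json",
        "ksmatch.json", "anova.json", "slopes.csv",
    ]
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(_canonical_json(cfg).encode()).hexdigest(),
        "seeds": {
            "root": int(cfg["seed"]),
            "cohort": _stage_seed(ss_cohort),
            "ksmatch": _stage_seed(ss_ks),
        },
        "input_checksum": input_checksum,
        "row_counts": {
            "raw": n_raw,
            "after_exclusions": prep_report.n_input - prep_report.n_excluded_clinical,
            "analysis": prep_report.n_output,
        },
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# figures


def render_figures(outdir: str | Path, regions=None) -> list[Path]:
    """Render trajectory panels (mean +/- SEM ribbons per APOE stratum,
    grey bars marking FDR-significant windows) and the slope bar panel
    from a results bundle directory.  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    curves = json.loads((outdir / "curves.json").read_text())
    tests = json.loads((outdir / "tests.json").read_text())
    if not curves:
        raise PipelineError("bundle has no curves to render")
    written: list[Path] = []

    for region in regions or curves:
        block = curves[region]["strata"]
        if not block:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for stratum, c in sorted(block.items()):
            age = np.asarray(c["mean_age"])
            mu = np.asarray(c["smoothed_mean"])
            sem = np.asarray(c["sem"])
            ax.plot(age, mu, label=stratum)
            ax.fill_between(age, mu - sem, mu + sem, alpha=0.25, lw=0)
        t = tests.get(region)
        if t is not None:
            sig = np.asarray(t["significant"], dtype=bool)
            if sig.any():
                ages = np.asarray(t["mean_age"])
                y0 = ax.get_ylim()[0]
                ax.plot(ages[sig], np.full(sig.sum(), y0), "s",
                        color="0.5", ms=3, label="FDR-significant")
        ax.set_xlabel("age (years)")
        ax.set_ylabel(region)
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / f"curve_{region}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    slopes_path = outdir / "slopes.csv"
    if slopes_path.exists():
        slopes = pd.read_csv(slopes_path)
        piv = slopes.pivot_table(
            index="region", columns="term", values="normalized_slope", sort=False
        )
        fig, ax = plt.subplots(figsize=(8, 4))
        piv.plot.bar(ax=ax)
        ax.set_ylabel("normalized slope (% / year)")
        ax.axhline(0, color="k", lw=0.5)
        fig.tight_layout()
        path = outdir / "slopes_panel.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
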