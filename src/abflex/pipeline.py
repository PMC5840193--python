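"""Manifest-driven orchestration: structures in, cohort statistics out.

The unit of input is a tab-separated cohort manifest with one row per
antibody (columns ``id``, ``path``, ``maturity``, ``bound``,
``heavy_germline_seq``, ``light_germline_seq``; the last four optional).
Each antibody's structure file may hold one model or a multi-model
ensemble; the pipeline runs the hydrogen-bond dilution sweep on every
model, averages, scores the AUC, extracts B-factor z-scores, and compares
the cohorts with KS and randomization tests.  Per-antibody failures are
collected and reported; the run fails only when nothing succeeds.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bfactors, germline, sweep
from .structure import parse_antibody_models, truncate_to_fv

__all__ = ["RunConfig", "PipelineReport", "read_manifest", "write_manifest", "run_pipeline"]

MANIFEST_COLUMNS = ["id", "path", "maturity", "bound", "heavy_germline_seq", "light_germline_seq"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if "id" not in df.columns or "path" not in df.columns:
        raise ValueError("manifest needs at least 'id' and 'path' columns")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    if df.empty:
        raise ValueError("manifest is empty")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Pipeline settings; the defaults reproduce the reference analysis.

    Sweep grid 0 to -7 kcal/mol in 0.01 steps, CDR-H3 region, 10,000
    randomization iterations repeated 10 times.
    """

    manifest: str | Path = ""
    out_dir: str | Path | None = None
    region: str = "H3"
    grid_start: float = 0.0
    grid_stop: float = -7.0
    grid_step: float = 0.01
    n_iter: int = 10_000
    n_repeat: int = 10
    seed: int = 0
    stratify: str = "maturity"
    truncate_fv: bool = False
    place_missing_hydrogens: bool = True
    run_sweep: bool = True
    run_bfactors: bool = True

    def grid(self) -> np.ndarray:
        return sweep.default_grid(self.grid_start, self.grid_stop, self.grid_step)


@dataclass
class PipelineReport:
    """Everything one pipeline run produced."""

    config: RunConfig
    profiles: dict[str, sweep.EnsembleProfile] = field(default_factory=dict)
    auc_table: pd.DataFrame | None = None
    auc_summary: pd.DataFrame | None = None
    bfactor_table: pd.DataFrame | None = None
    ks_curve: pd.DataFrame | None = None
    bfactor_ks: tuple[float, float] | None = None
    randomization: bfactors.RandomizationResult | None = None
    errors: dict[str, str] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    @property
    def n_analyzed(self) -> int:
        ids = set(self.profiles)
        if self.bfactor_table is not None:
            ids |= set(self.bfactor_table["id"])
        return len(ids)


def _load_models(row: dict, structures=None):
    if structures is not None and row["id"] in structures:
        st = structures[row["id"]]
        return st if isinstance(st, list) else [st]
    text = Path(row["path"]).read_text()
    return parse_antibody_models(text)


def run_pipeline(config: RunConfig, structures=None, manifest: pd.DataFrame | None = None,
                 log=None) -> PipelineReport:
    """Execute the full analysis over a cohort.

    ``structures`` may map ids to pre-loaded models (lists for ensembles),
    bypassing file IO; otherwise each manifest ``path`` is read as a
    (possibly multi-model) PDB file.  Deterministic given ``config.seed``.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    if manifest is None:
        manifest = read_manifest(config.manifest)
    if manifest.empty:
        raise ValueError("empty manifest")
    report = PipelineReport(config=config)
    grid = config.grid()

    bf_rows = []
    for row in manifest.to_dict("records"):
        ab = row["id"]
        try:
            models = _load_models(row, structures)
            if config.truncate_fv:
                models = [truncate_to_fv(m) for m in models]
            if config.run_sweep:
                report.profiles[ab] = sweep.dof_profile(
                    models, region=config.region, grid=grid,
                    place_missing_hydrogens=config.place_missing_hydrogens,
                )
            if config.run_bfactors:
                try:
                    z = bfactors.bfactor_zscores(models[0])
                    bf_rows.append(
                        {"id": ab, "cdrh3_mean_z": z.cdrh3_mean_z, "mu": z.mu, "sigma": z.sigma,
                         "maturity": row.get("maturity", ""), "bound": row.get("bound", "")}
                    )
                except bfactors.SigmaZeroError:
                    report.excluded.append(ab)
                    log(f"{ab}: excluded from B-factor analysis (all B-factors identical)")
        except Exception as exc:  # noqa: BLE001 - per-antibody isolation
            report.errors[ab] = str(exc)
            log(f"{ab}: FAILED ({exc})")

    if report.errors and not report.profiles and not bf_rows:
        raise RuntimeError(f"all {len(report.errors)} antibodies failed; first errors: "
                           f"{dict(list(report.errors.items())[:3])}")

    if report.profiles:
        ok = manifest[manifest["id"].isin(report.profiles)]
        report.auc_table = sweep.cohort_auc(report.profiles, ok)
        report.auc_summary = sweep.cohort_summary(report.auc_table, by=config.stratify)
        report.ks_curve = _ks_per_cutoff(report, config)
    if bf_rows:
        report.bfactor_table = pd.DataFrame(bf_rows)
        groups = report.bfactor_table.groupby(config.stratify)["cdrh3_mean_z"]
        keys = [k for k, g in groups if len(g) > 0 and k != ""]
        if len(keys) == 2:
            a = groups.get_group(keys[0]).to_numpy()
            b = groups.get_group(keys[1]).to_numpy()
            report.bfactor_ks = bfactors.ks_two_sample(a, b)
            report.randomization = bfactors.randomization_test(
                a, b, n_iter=config.n_iter, n_repeat=config.n_repeat, seed=config.seed
            )
    if config.out_dir is not None:
        _write_outputs(report, Path(config.out_dir))
    return report


def _ks_per_cutoff(report: PipelineReport, config: RunConfig) -> pd.DataFrame | None:
    """Per-cutoff two-sample KS comparison of the stratified sdof values."""
    if report.auc_table is None:
        return None
    labels = report.auc_table.set_index("id")[config.stratify]
    groups = labels[labels != ""].groupby(labels).groups
    keys = [k for k in groups if len(groups[k]) > 0]
    if len(keys) != 2:
        return None
    mat = {k: np.stack([report.profiles[i].sdof_mean for i in groups[k]]) for k in keys}
    grid = next(iter(report.profiles.values())).cutoffs
    rows = []
    for j, cut in enumerate(grid):
        d, p = bfactors.ks_two_sample(mat[keys[0]][:, j], mat[keys[1]][:, j])
        rows.append({"cutoff": cut, "D": d, "p": p})
    return pd.DataFrame(rows)


def _tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# abflex run: region={config.region} grid=[{config.grid_start},"
                 f"{config.grid_stop},{config.grid_step}] seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_outputs(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    if report.profiles:
        tidy = pd.concat([p.to_frame(ab) for ab, p in report.profiles.items()])
        _tsv(tidy, out_dir / "profiles.tsv", cfg)
        _tsv(report.auc_table, out_dir / "auc.tsv", cfg)
        _tsv(report.auc_summary, out_dir / "auc_summary.tsv", cfg)
        if report.ks_curve is not None:
            _tsv(report.ks_curve, out_dir / "ks_curve.tsv", cfg)
    if report.bfactor_table is not None:
        _tsv(report.bfactor_table, out_dir / "bfactor.tsv", cfg)
    summary_rows = [{"n_input": report.n_analyzed + len(report.errors),
                     "n_analyzed": report.n_analyzed,
                     "n_failed": len(report.errors),
                     "n_excluded_bfactor": len(report.excluded)}]
    if report.randomization is not None:
        r = report.randomization
        summary_rows[0].update(
            observed_diff=r.observed_diff, fraction_ge=r.fraction_ge,
            fraction_sd=r.fraction_sd, n_iter=r.n_iter, n_repeat=r.n_repeat,
        )
    if report.bfactor_ks is not None:
        summary_rows[0].update(ks_D=report.bfactor_ks[0], ks_p=report.bfactor_ks[1])
    _tsv(pd.DataFrame(summary_rows), out_dir / "run_summary.tsv", cfg)


def classify_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Fill empty maturity labels by germline comparison.

    Uses the optional query-sequence columns ``heavy_seq`` / ``light_seq``
    against ``heavy_germline_seq`` / ``light_germline_seq``; rows without
    sequences keep their existing label.
    """
    out = manifest.copy()
    for i, row in out.iterrows():
        if row.get("maturity"):
            continue
        ha = la = None
        if row.get("heavy_seq") and row.get("heavy_germline_seq"):
            ha = germline.count_mutations(row["heavy_seq"], row["heavy_germline_seq"], "H")
        if row.get("light_seq") and row.get("light_germline_seq"):
            la = germline.count_mutations(row["light_seq"], row["light_germline_seq"], "L")
        if ha is not None or la is not None:
            out.at[i, "maturity"] = germline.classify_maturity(ha, la)
    return out
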