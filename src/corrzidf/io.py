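"""Table readers/writers and the fit / simulate workflows.

Interchange format: tab-separated UTF-8 tables — a feature-by-sample count
table (rows = features, columns = samples, first column = feature id) and
a sample metadata table with subject, integer time index and group
columns.  All panels must be balanced; subjects with incomplete time
series are dropped with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import FeaturePanel
from .gee import FitConfig, fit_feature
from .inference import results_table, summarize_run, test_features
from .simulate import SimScenario, SimStudy, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts: str = None
    metadata: str = None
    out: str = "results.tsv"
    structure: str = "ar1"
    subject_col: str = "subject_id"
    time_col: str = "time"
    group_col: str = "group"
    covariates: tuple = ("group",)   # design columns after the intercept (U and V)
    test: str = "group"              # coefficient tested in beta_v
    fdr: float = 0.05
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fdr <= 1.0):
            raise ValueError("fdr threshold must lie in (0, 1]")


def _design_from_metadata(meta: pd.DataFrame, covariates, group_col):
    """Build the shared per-sample design matrix (intercept first)."""
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"metadata has no column {cov!r}")
        col = meta[cov]
        if cov == group_col or col.dtype == object:
            levels = sorted(col.unique())
            if len(levels) != 2:
                raise ValueError(f"covariate {cov!r} must have 2 levels, got {levels}")
            cols.append((col == levels[1]).to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
        names.append(str(cov))
    return np.column_stack(cols), tuple(names)


def read_study(counts_path, metadata_path, subject_col="subject_id",
               time_col="time", group_col="group", covariates=("group",)):
    """Yield ``(feature_id, FeaturePanel)`` for every feature in the tables.

    Hard errors: samples present in the counts but missing from the
    metadata (or vice versa), non-integer or negative counts, duplicate
    (subject, time) rows.  Subjects with incomplete time series are
    dropped with a warning.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    yield from panels_from_tables(counts, meta, subject_col=subject_col,
                                  time_col=time_col, group_col=group_col,
                                  covariates=covariates)


def panels_from_tables(counts: pd.DataFrame, meta: pd.DataFrame,
                       subject_col="subject_id", time_col="time",
                       group_col="group", covariates=("group",)):
    """In-memory variant of :func:`read_study` (counts indexed by feature)."""
    meta_ids = set(meta["sample_id"])
    missing = [s for s in counts.columns if s not in meta_ids]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    extra = [s for s in meta["sample_id"] if s not in set(counts.columns)]
    if extra:
        raise ValueError(f"metadata samples missing from counts: {extra[:5]}")
    vals = counts.to_numpy()
    if np.any(vals < 0) or not np.all(np.equal(np.mod(vals, 1), 0)):
        bad = np.argwhere((vals < 0) | (np.mod(vals, 1) != 0))[0]
        raise ValueError(f"non-integer or negative count at feature row "
                         f"{counts.index[bad[0]]!r}, sample {counts.columns[bad[1]]!r}")
    dup = meta.duplicated([subject_col, time_col])
    if dup.any():
        rows = meta.index[dup].tolist()[:5]
        raise ValueError(f"duplicate (subject, time) metadata rows: {rows}")

    meta = (meta.set_index("sample_id").loc[counts.columns]
            .rename_axis("sample_id").reset_index())
    times = sorted(meta[time_col].unique())
    M = len(times)
    by_subject = meta.groupby(subject_col)[time_col].apply(lambda t: sorted(t) == times)
    keep = by_subject[by_subject].index
    dropped = by_subject.size - len(keep)
    if dropped:
        logger.warning("dropped %d subjects with incomplete time series", dropped)
    if len(keep) == 0:
        raise ValueError("no complete subjects remain")
    meta = meta[meta[subject_col].isin(keep)]
    meta = meta.sort_values([subject_col, time_col], kind="mergesort")
    X, names = _design_from_metadata(meta, covariates, group_col)
    N = len(keep)
    Xr = X.reshape(N, M, -1)
    order = meta["sample_id"].to_numpy()
    subject_ids = tuple(meta[subject_col].to_numpy()[::M])
    for fid in counts.index:
        y = counts.loc[fid, order].to_numpy(np.int64).reshape(N, M)
        yield str(fid), FeaturePanel(y=y, U=Xr, V=Xr,
                                     subject_ids=subject_ids,
                                     time_index=tuple(times),
                                     u_names=names, v_names=names)


def write_study(study: SimStudy, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "metadata": out_dir / "metadata.tsv",
        "truth": out_dir / "truth.tsv",
    }
    study.counts.to_csv(paths["counts"], sep="\t")
    study.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    study.truth.rename("daf").astype(int).to_frame().to_csv(paths["truth"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def fit_study(panels, structure="ar1", test="group", fdr=0.05,
              config: FitConfig = None, truth=None) -> dict:
    """Fit every panel, run Wald tests + BH, and summarize.

    ``panels`` is an iterable of (feature_id, FeaturePanel); ``test`` names
    the tested count-part coefficient.  Per-feature failures become status
    flags, never exceptions.
    """
    config = config or FitConfig()
    fits = {}
    which = None
    for fid, panel in panels:
        fits[fid] = fit_feature(panel, structure=structure, config=config)
        if which is None and panel.v_names and test in panel.v_names:
            which = [list(panel.v_names).index(test)]
    results = test_features(fits, which=which)
    summary = summarize_run(results, alpha_fdr=fdr, truth=truth)
    alpha = np.array([f.alpha_hat for f in fits.values() if np.isfinite(f.alpha_hat)])
    summary["alpha_hat_median"] = float(np.median(alpha)) if alpha.size else np.nan
    return summary


def run_fit(config: RunConfig) -> pd.DataFrame:
    """Workflow: read study tables, fit all features, write the results TSV
    and a JSON run summary next to it."""
    panels = read_study(config.counts, config.metadata,
                        subject_col=config.subject_col, time_col=config.time_col,
                        group_col=config.group_col, covariates=tuple(config.covariates))
    summary = fit_study(panels, structure=config.structure, test=config.test,
                        fdr=config.fdr,
                        config=FitConfig(tol=config.tol, max_iter=config.max_iter))
    table = summary.pop("table")
    out = Path(config.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False, na_rep="NA")
    with open(out.with_suffix(".summary.json"), "w") as fh:
        json.dump({k: v for k, v in summary.items()}, fh, indent=2, default=float)
    logger.info("fit %d features; %d significant at FDR %.3g",
                summary["n_features"], summary["n_significant"], config.fdr)
    return table


def scenario_from_yaml(path) -> SimScenario:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "mu0_range" in raw:
        raw["mu0_range"] = tuple(raw["mu0_range"])
    return SimScenario(**raw)


def run_simulate(scenario: SimScenario, out_dir, dry_run: bool = False) -> dict:
    if dry_run:
        return {"scenario": asdict(scenario)}
    study = simulate_study(scenario)
    return write_study(study, out_dir)
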