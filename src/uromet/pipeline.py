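"""End-to-end pipeline: preprocess -> PCA/PLS-DA -> ASCA -> unfolded PCA
-> selection -> correlation, with TSV artifacts and a markdown report.

Each stage writes only documented TSV artifacts into the output
directory; the report collects the biomarker table and run metadata
(package version, seed, config hash).  Runs are deterministic under a
fixed seed and configuration; logs (with stage timers) go to stderr and
never into result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .asca import ASCA, asca_permutation_test
from .datamodel import (
    MetaboliteProfileTable,
    UrometError,
    ValidationError,
    read_profile_table,
)
from .latent import PCA, PLSDA
from .preprocess import (
    impute_zeros,
    normalize_to_creatinine,
    qc_repeatability,
    transform_scale,
)
from .stats import paired_power, select_biomarkers, spearman_matrix
from .unfolded import UnfoldedPCA, biplot_rank, unfold

log = logging.getLogger("uromet")


@dataclass
class PipelineConfig:
    """Pipeline parameters; the selection thresholds default to the
    reference criteria (VIP >= 1.0, p <= 0.05, |FC| >= 1.5)."""

    input: str = ""
    outdir: str = "results"
    scaling: str = "auto"            # auto | pareto | none
    n_components_plot: int = 2
    n_components_select: int = 3
    contrast: tuple[int, int] = (0, 1)
    intervention: str = "alcohol"
    vip_min: float = 1.0
    p_max: float = 0.05
    abs_fc_min: float = 1.5
    asca_ellipse_level: float = 0.95
    unfolded_ellipse_level: float = 0.90
    n_perm: int = 199
    seed: int = 17
    log_level: str = "INFO"

    def __post_init__(self):
        if min(self.vip_min, self.p_max, self.abs_fc_min) <= 0:
            raise ValidationError("selection thresholds must be positive")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Flat key-value YAML config; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contrast"] = list(self.contrast)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (filesystem locations and log
        verbosity excluded, so identical analyses hash identically)."""
        d = self.to_dict()
        for k in ("input", "outdir", "log_level"):
            d.pop(k, None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)


def _export_latent(res, outdir: Path, prefix: str) -> None:
    _write(res.scores.rename_axis("sample_id").reset_index(),
           outdir / f"{prefix}_scores.tsv")
    load = res.loadings.copy()
    if isinstance(load.index, pd.MultiIndex):
        load.index = ["|".join(map(str, i)) for i in load.index]
    _write(load.rename_axis("metabolite").reset_index(),
           outdir / f"{prefix}_loadings.tsv")
    if res.kind == "plsda":
        _write(res.vip.rename_axis("metabolite").reset_index(),
               outdir / f"{prefix}_vip.tsv")
        _write(res.summary().rename_axis("component").reset_index(),
               outdir / f"{prefix}_explained.tsv")
    else:
        _write(res.explained.rename("explained_fraction")
               .rename_axis("component").reset_index(),
               outdir / f"{prefix}_explained.tsv")


ALL_STAGES = ("preprocess", "latent", "asca", "unfolded", "select",
              "correlate", "report")


def run_pipeline(config: PipelineConfig,
                 table: MetaboliteProfileTable | None = None,
                 stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the workflow and write artifacts into ``config.outdir``.

    Returns a dict of in-memory results keyed by stage.  Any stage error
    raises :class:`UrometError` with a stage-named message; an
    ``_INCOMPLETE`` marker is left in the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "_INCOMPLETE"
    marker.write_text("run in progress or failed\n")
    results: dict = {"config": config}
    stage = "load"
    try:
        t0 = time.perf_counter()
        if table is None:
            table = read_profile_table(config.input)
        if table.experimental.empty:
            raise ValidationError("input table has no experimental samples")

        stage = "preprocess"
        norm = normalize_to_creatinine(table) if not table.normalized else table
        imputed = impute_zeros(norm)
        scaled = transform_scale(imputed, config.scaling)
        results["table"] = imputed
        results["scaled"] = scaled
        if (table.data["role"] == "qc").any():
            qc = qc_repeatability(norm)
            _write(qc, outdir / "qc_summary.tsv")
            results["qc"] = qc
        log.info("preprocess done in %.2fs", time.perf_counter() - t0)

        exp = scaled.data["role"] == "experimental"
        arm = exp & (scaled.data["intervention"] == config.intervention)
        t_ref, t_cmp = config.contrast

        if "latent" in stages:
            stage = "latent"
            t0 = time.perf_counter()
            sub = scaled.subset(arm & scaled.data["time_h"].isin([t_ref, t_cmp]))
            # cross-sectional contrast models are autoscaled on their own
            # two-group subset, so importance is not diluted by variation
            # at hours outside the contrast
            X = sub.values
            sd = X.std(ddof=1)
            X = X.drop(columns=sd.index[sd == 0])
            X = (X - X.mean(axis=0)) / sd[sd > 0]
            X.index = sub.data["sample_id"]
            y = np.where(sub.data["time_h"] == t_ref, f"t{t_ref}", f"t{t_cmp}")
            pca = PCA(X, config.n_components_plot).fit()
            plsda = PLSDA(X, y, config.n_components_select).fit()
            _export_latent(pca, outdir, "pca_contrast")
            _export_latent(plsda, outdir, "plsda_contrast")
            results["pca"] = pca
            results["plsda"] = plsda
            log.info("latent done in %.2fs", time.perf_counter() - t0)

        if "asca" in stages:
            stage = "asca"
            t0 = time.perf_counter()
            sub = scaled.subset(arm)
            X = sub.values
            X.index = sub.data["sample_id"]
            factors = pd.DataFrame({
                "time": sub.data["time_h"].to_numpy(),
                "subject": sub.data["subject_id"].to_numpy(),
            }, index=X.index)
            decomp = ASCA(X, factors).fit()
            _write(decomp.summary(), outdir / "effect_ssq.tsv")
            n_t = factors["time"].nunique()
            sca_model, levels = decomp.sca(
                "time", min(3, n_t - 1),
                ellipse_level=config.asca_ellipse_level)
            _write(levels, outdir / "asca_time_levels.tsv")
            perm = asca_permutation_test(X, factors, "time",
                                         n_perm=config.n_perm,
                                         seed=config.seed)
            (outdir / "asca_permutation.json").write_text(
                json.dumps(perm, indent=2) + "\n")
            results["asca"] = decomp
            results["asca_sca"] = (sca_model, levels)
            results["asca_perm"] = perm
            log.info("asca done in %.2fs", time.perf_counter() - t0)

        if "unfolded" in stages:
            stage = "unfolded"
            t0 = time.perf_counter()
            U = unfold(scaled, config.intervention)
            ures = UnfoldedPCA(U, config.n_components_plot,
                               ellipse_level=config.unfolded_ellipse_level).fit()
            traj = ures.trajectories.rename(
                columns={c: c.lower() for c in ures.trajectories.columns})
            _write(traj, outdir / "trajectories.tsv")
            cent = ures.centroids.rename(
                columns={c: c.lower() for c in ures.centroids.columns})
            _write(cent, outdir / "centroids.tsv")
            bp = biplot_rank(ures.model, top_k=7)
            _write(bp, outdir / "biplot.tsv")
            results["unfolded"] = ures
            results["biplot"] = bp
            log.info("unfolded done in %.2fs", time.perf_counter() - t0)

        if "select" in stages:
            stage = "select"
            t0 = time.perf_counter()
            if "plsda" not in results:
                raise ValidationError("selection requires the latent stage")
            # metabolites excluded from the fit (constant in the contrast
            # subset) carry zero importance
            vip = results["plsda"].vip.reindex(imputed.metabolites,
                                               fill_value=0.0)
            records = select_biomarkers(
                imputed, vip, config.contrast,
                intervention=config.intervention, vip_min=config.vip_min,
                p_max=config.p_max, abs_fc_min=config.abs_fc_min)
            _write(records, outdir / "biomarkers.tsv")
            results["biomarkers"] = records
            log.info("select done in %.2fs", time.perf_counter() - t0)

        if "correlate" in stages:
            stage = "correlate"
            t0 = time.perf_counter()
            if "biomarkers" in results:
                chosen = results["biomarkers"]
                variables = chosen.loc[chosen["selected"], "metabolite"].tolist()
            else:
                variables = None
            if variables:
                corr = spearman_matrix(imputed, variables, include_time=True,
                                       intervention=config.intervention)
                _write(corr.to_long(), outdir / "correlations.tsv")
                results["correlation"] = corr
            log.info("correlate done in %.2fs", time.perf_counter() - t0)

        if "report" in stages:
            stage = "report"
            _write_report(outdir, config, results)
        marker.unlink(missing_ok=True)
        return results
    except UrometError as e:
        raise UrometError(f"stage {stage!r}: {e}") from e


def _write_report(outdir: Path, config: PipelineConfig, results: dict) -> None:
    lines = ["# uromet run report", ""]
    from importlib.metadata import version as _pkg_version
    try:
        ver = _pkg_version("uromet")
    except Exception:
        ver = "unknown"
    lines += [f"- package version: {ver}",
              f"- seed: {config.seed}",
              f"- config hash: {config.config_hash}",
              f"- scaling: {config.scaling}",
              f"- contrast: {config.contrast[0]} h vs {config.contrast[1]} h "
              f"({config.intervention} arm)",
              ""]
    n_subj = results["table"].experimental["subject_id"].nunique()
    power = paired_power(0.9, n_subj, 0.05)
    lines += [f"Paired-design power for a large effect (d = 0.9, "
              f"n = {n_subj}, alpha = 0.05): {power:.3f}", ""]
    if "asca" in results:
        lines += ["## Variation partition (ASCA)", ""]
        lines.append(results["asca"].summary().round(4).to_string(index=False))
        p = results["asca_perm"]["p_value"]
        lines += ["", f"Permutation p-value for the time effect: {p:.4g}", ""]
    if "biomarkers" in results:
        rec = results["biomarkers"]
        sel = rec[rec["selected"]]
        lines += [f"## Selected biomarkers ({len(sel)} of {len(rec)} "
                  f"metabolites)", ""]
        show = [c for c in sel.columns if c not in ("selected", "fdr_bh")]
        lines.append(sel[show].round(3).to_string(index=False))
        lines.append("")
    if "biplot" in results:
        lines += ["## Top bi-plot metabolites (sum of squared loadings, "
                  "first two components)", "",
                  results["biplot"].round(4).to_string(index=False), ""]
    (outdir / "report.md").write_text("\n".join(lines))
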