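"""End-to-end orchestration: filter -> shape -> cluster -> survival ->
stats -> tree, with a manifest for reproducibility.

Each stage is a plain function over in-memory objects; ``run_pipeline``
chains them, writes every report table under the configured output
directory and records a manifest (config, derived seeds, per-stage
counts, SHA-256 of each output file).  A stage failure aborts the run
with the stage name while keeping the outputs already written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
import numpy as np
import pandas as pd

from . import cohort_stats, survival
from .cluster import cluster_cohort, save_model
from .config import PipelineConfig
from .io_formats import (
    DEFAULT_MUTATION_DIALECT,
    SIMPLE_MUTATION_DIALECT,
    read_clinical,
    read_mutations,
    read_segments,
)
from .mf_filter import FilterChainResult, run_filter_chain
from .shape_params import params_frame, profile_cohort
from .tree_classifier import cross_validate, fit_cart, render_text, save_tree

__all__ = ["PipelineError", "run_pipeline"]

DIALECTS = {"gdc": DEFAULT_MUTATION_DIALECT, "simple": SIMPLE_MUTATION_DIALECT}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for actionable messages."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _survival_stage(
    config: PipelineConfig,
    clinical_df: pd.DataFrame,
    labels: dict[str, int],
    out: Path,
) -> list[Path]:
    paths = []
    km_rows, uni_results, adj_results, ref_rows = [], [], [], []
    for cancer_type, sub in clinical_df.groupby("cancer_type"):
        sub = sub[sub["sample_id"].isin(labels)].reset_index(drop=True)
        if sub.empty:
            continue
        times = sub["survival_days"].to_numpy()
        events = sub["event"].to_numpy()
        cluster_labels = sub["sample_id"].map(labels).to_numpy()

        curves = survival.km_estimate(times, events, cluster_labels)
        for cl, curve in curves.items():
            for _, row in curve.iterrows():
                km_rows.append((cancer_type, int(cl), row["time"], row["survival"]))

        # univariate model, canonical reference (cluster 2 if eligible)
        sizes = pd.Series(cluster_labels).value_counts()
        eligible = sorted(int(c) for c in sizes.index[sizes >= config.min_cluster_size])
        if len(eligible) >= 2:
            uni_ref = (config.univariate_reference
                       if config.univariate_reference in eligible else eligible[0])
            try:
                uni_results.append(
                    survival.univariate_cluster_cox(
                        times, events, cluster_labels, uni_ref,
                        min_cluster_size=config.min_cluster_size,
                        cancer_type=str(cancer_type),
                    )
                )
            except survival.SurvivalError:
                pass

            cov = None
            usable = [c for c in config.covariates if c in sub.columns
                      and sub[c].notna().any()]
            if usable:
                cov = survival.build_covariate_frame(
                    sub, usable, stage_binary=config.stage_binary
                )
            try:
                ref, qualified = survival.select_reference_cluster(
                    times, events, cluster_labels, covariates=cov,
                    min_cluster_size=config.min_cluster_size,
                )
                ref_rows.append((cancer_type, ref, qualified))
                adj_results.append(
                    survival.fit_cox(
                        times, events, cluster_labels, ref, covariates=cov,
                        min_cluster_size=config.min_cluster_size,
                        cancer_type=str(cancer_type),
                    )
                )
            except survival.SurvivalError:
                pass

    paths.append(_write(
        pd.DataFrame(km_rows, columns=["cancer_type", "cluster", "time", "survival"]),
        out / "km_curves.tsv",
    ))
    paths.append(_write(
        survival.cox_result_frame(uni_results), out / "hr_univariate.tsv"
    ))
    paths.append(_write(
        survival.cox_result_frame(adj_results), out / "hr_adjusted.tsv"
    ))
    paths.append(_write(
        pd.DataFrame(ref_rows,
                     columns=["cancer_type", "reference_cluster", "rule_qualified"]),
        out / "reference_clusters.tsv",
    ))
    return paths


def _stats_stage(
    config: PipelineConfig,
    chain: FilterChainResult,
    clinical_df: pd.DataFrame,
    segments,
    labels: dict[str, int],
    out: Path,
) -> list[Path]:
    paths = []
    # six-class spectrum of surviving MF mutations, per cluster
    by_cluster: dict[int, list] = {}
    for sid, vs in chain.vafsets.items():
        by_cluster.setdefault(labels[sid], []).extend(vs.mutations)
    spec_rows = []
    for cl in sorted(by_cluster):
        spectrum = cohort_stats.mutation_spectrum(by_cluster[cl])
        for klass in cohort_stats.SPECTRUM_CLASSES:
            spec_rows.append((cl, klass, spectrum.counts[klass],
                              spectrum.fractions[klass]))
    paths.append(_write(
        pd.DataFrame(spec_rows, columns=["cluster", "class", "count", "fraction"]),
        out / "spectrum_by_cluster.tsv",
    ))

    # CNV abundance per sample + ANOVA across clusters
    segs_by_sample: dict[str, list] = {}
    for s in segments:
        segs_by_sample.setdefault(s.sample_id, []).append(s)
    cnv_rows = [
        (sid, labels[sid],
         cohort_stats.cnv_abundance(segs_by_sample.get(sid, []),
                                    threshold=config.cnv_abundance_threshold))
        for sid in sorted(chain.vafsets) if sid in labels
    ]
    cnv_df = pd.DataFrame(cnv_rows, columns=["sample_id", "cluster", "cnv_abundance"])
    paths.append(_write(cnv_df, out / "cnv_abundance.tsv"))

    # per-gene MF frequency, top genes per cluster
    all_muts = [m for vs in chain.vafsets.values() for m in vs.mutations]
    gene_table = cohort_stats.per_gene_mf_frequency(
        all_muts, labels, top_n=config.top_genes
    )
    gene_out = gene_table.reset_index()
    gene_out.columns = ["gene"] + [f"cluster_{c}" for c in gene_table.columns]
    paths.append(_write(gene_out, out / "top_gene_frequencies.tsv"))

    # clinical/genetic comparisons across clusters, BH-adjusted as a family
    tests: list[cohort_stats.GroupTestResult] = []
    merged = clinical_df[clinical_df["sample_id"].isin(labels)].copy()
    merged["cluster"] = merged["sample_id"].map(labels)

    groups = {
        int(cl): cnv_df.loc[cnv_df["cluster"] == cl, "cnv_abundance"].dropna().to_numpy()
        for cl in sorted(cnv_df["cluster"].unique())
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) >= 2:
        result, _ = cohort_stats.compare_continuous(groups, comparison="cnv_abundance")
        tests.append(result)
    if merged["age"].notna().all():
        age_groups = {
            int(cl): g["age"].to_numpy() for cl, g in merged.groupby("cluster")
            if len(g) >= 2
        }
        if len(age_groups) >= 2:
            result, _ = cohort_stats.compare_continuous(age_groups, comparison="age")
            tests.append(result)
    for trait in ("gender", "stage", "smoking"):
        if merged[trait].notna().all() and merged[trait].nunique() >= 2:
            col = merged[trait]
            if trait == "stage" and config.stage_binary:
                col = col.map({"I": "I/II", "II": "I/II",
                               "III": "III/IV", "IV": "III/IV"})
            table = pd.crosstab(merged["cluster"], col).to_numpy()
            try:
                tests.append(cohort_stats.compare_categorical(
                    table, comparison=trait, seed=config.stage_seed("stats")
                ))
            except ValueError:
                pass
    if tests:
        adjusted = cohort_stats.adjust_bh([t.raw_p for t in tests])
        for t, p in zip(tests, adjusted):
            t.adjusted_p = float(p)
    paths.append(_write(
        pd.DataFrame(
            [(t.comparison, t.test_used, t.raw_p, t.adjusted_p, t.effect)
             for t in tests],
            columns=["comparison", "test", "raw_p", "bh_adjusted_p", "effect"],
        ),
        out / "group_tests.tsv",
    ))
    return paths


def run_pipeline(
    config: PipelineConfig,
    mutations=None,
    segments=None,
    clinical=None,
) -> dict:
    """Execute every stage and write the output bundle.

    Inputs may be passed in memory (as record lists) or read from the
    configured paths.  Returns ``{"outputs": {name: path}, "manifest":
    dict}``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}

    stage = "load"
    try:
        if mutations is None:
            dialect = DIALECTS[config.dialect]
            mutations, _skipped = read_mutations(config.mutations_path, dialect)
        if segments is None:
            segments = read_segments(config.segments_path)
        if clinical is None:
            clinical = read_clinical(config.clinical_path)
        counts["mutations_in"] = len(mutations)
        counts["segments_in"] = len(segments)
        counts["samples_in"] = len(clinical)

        stage = "filter"
        chain = run_filter_chain(
            mutations, segments, clinical,
            min_depth=config.min_depth,
            mean_lo=config.cnv_mean_lo, mean_hi=config.cnv_mean_hi,
            min_probes=config.min_probes,
            min_mutations=config.min_mf_mutations,
            cap=config.cap_vaf,
            missing_purity=config.missing_purity,
        )
        outputs["filter_report"] = _write(chain.report, out / "filter_report.tsv")
        counts["samples_profiled"] = len(chain.vafsets)
        counts["samples_excluded"] = len(chain.excluded)

        stage = "shape"
        cancer_types = {c.sample_id: c.cancer_type for c in clinical}
        params, corr = profile_cohort(
            chain.vafsets.values(),
            cancer_types=cancer_types,
            grid_points=config.kde_grid_points,
            bw_method=config.kde_bandwidth,
            math_scale=config.math_scale_constant,
            math_percent=config.math_percent,
        )
        outputs["shape_params"] = _write(params_frame(params), out / "shape_params.tsv")
        outputs["param_correlations"] = _write(
            corr.reset_index().rename(columns={"index": "parameter"}),
            out / "param_correlations.tsv",
        )

        stage = "cluster"
        model = cluster_cohort(
            params, k=config.k, seed=config.stage_seed("cluster"),
            standardize=config.standardize, n_components=config.n_components,
        )
        labels = model.clusters.labels
        labels_df = pd.DataFrame(
            {"sample_id": model.sample_ids,
             "cluster": [labels[s] for s in model.sample_ids],
             "pc1": model.coords[:, 0], "pc2": model.coords[:, 1]}
        )
        outputs["cluster_labels"] = _write(labels_df, out / "cluster_labels.tsv")
        save_model(model, out / "cohort_model.json")
        outputs["cohort_model"] = out / "cohort_model.json"
        counts["clusters"] = config.k

        stage = "survival"
        clinical_df = pd.DataFrame([asdict_record(c) for c in clinical])
        for p in _survival_stage(config, clinical_df, labels, out):
            outputs[p.stem] = p

        stage = "stats"
        for p in _stats_stage(config, chain, clinical_df, segments, labels, out):
            outputs[p.stem] = p

        stage = "tree"
        tree_labels = np.array([labels[p.sample_id] for p in params])
        tree = fit_cart(params, tree_labels, cp=config.tree_cp,
                        min_leaf=config.tree_min_leaf)
        cv = cross_validate(
            params, tree_labels, folds=config.cv_folds,
            seed=config.stage_seed("tree"),
            cp=config.tree_cp, min_leaf=config.tree_min_leaf,
        )
        save_tree(tree, out / "tree_model.json")
        (out / "tree_rules.txt").write_text(render_text(tree) + "\n")
        outputs["tree_model"] = out / "tree_model.json"
        outputs["tree_rules"] = out / "tree_rules.txt"
        outputs["cv_accuracy"] = _write(
            pd.DataFrame(
                {"fold": range(1, len(cv.fold_accuracies) + 1),
                 "accuracy": cv.fold_accuracies}
            ),
            out / "cv_accuracy.tsv",
        )
        counts["cv_mean_accuracy_pct"] = round(cv.mean * 100, 2)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest = {
        "config": asdict_config(config),
        "stage_seeds": {s: config.stage_seed(s)
                        for s in ("simulate", "cluster", "survival", "tree", "stats")},
        "counts": counts,
        "outputs_sha256": {name: _sha256(Path(p)) for name, p in sorted(outputs.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = manifest_path
    return {"outputs": outputs, "manifest": manifest}


def asdict_record(record) -> dict:
    from dataclasses import asdict as _asdict

    return _asdict(record)


def asdict_config(config: PipelineConfig) -> dict:
    from dataclasses import asdict as _asdict

    return _asdict(config)
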